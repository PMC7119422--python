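"""Generate one synthetic spheroid per polarity group and read its features.

The sign of f1 (gp58-gp135 position difference) separates regular from
inverse polarity; the nuclear initial slope f9 reports nuclei inside the
expected lumen (large for aggregates); the actin particle count f11 picks
up the multiple lumina of group 3b.
"""

import spheropol as sp

params = sp.SCALED_PARAMS  # 96 px frames, 5 z-planes: fast desk-scale runs

print(f"{'group':<14} {'f1':>7} {'f2':>7} {'f9':>7} {'f11':>4} {'f13':>4} {'f15/um':>7}")
for group in sp.FINE_LABELS:
    stack, label = sp.generate_spheroid(group, params, seed=3)
    fv = sp.extract_features(stack)
    print(
        f"{group:<14} {fv.f1_delta_gp58_gp135:>7.3f} {fv.f2_delta_actin_gp135:>7.3f} "
        f"{fv.f9_nuclear_initial_slope:>7.3f} {fv.f11_actin_particle_count:>4.0f} "
        f"{fv.f13_nuclei_count:>4.0f} {fv.f15_r_max_um:>7.2f}"
    )

print(
    "\nf1 > 0: regular apicobasal polarity; f1 < 0: inverse polarity;\n"
    "f2 near 0: actin colocalises with the apical marker (distinct polarity);\n"
    "f9 >> 1: nuclear signal inside 30% of the radius (no lumen);\n"
    "f11: bright actin structures (several for multilumen aggregates)."
)
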