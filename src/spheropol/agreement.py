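"""Interrater agreement statistics for classifier validation.

Classifiers (or human raters) are compared spheroid by spheroid in a K x K
cross-correlation table.  Percent agreement is the share of identically
classified spheroids; Cohen's kappa corrects it for chance agreement,

    kappa = (p_o - p_e) / (1 - p_e),

where p_o is the observed agreement and p_e = sum_i p_i. * p_.i the
agreement expected from the marginal label frequencies.  The standard error
uses the Fleiss-Cohen-Everitt large-sample variance, giving the usual
normal-approximation confidence interval.  Kappa is read against the
conventional bands: 0.01-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate,
0.61-0.80 substantial, 0.81-1.00 almost perfect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import warn

DEFAULT_LABEL_ORDER = (1, 2, 3)


@dataclass
class RatingTable:
    """Cross-correlation table of two raters' labels.

    ``counts[i, j]`` is the number of items labelled ``label_order[i]`` by
    rater A (rows) and ``label_order[j]`` by rater B (columns).
    """

    counts: np.ndarray
    label_order: Tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.label_order)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts must be {k}x{k} for label order {self.label_order}"
            )
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.sum() < 1:
            raise ValueError("the table must contain at least one rated item")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "RatingTable":
        return RatingTable(self.counts.T.copy(), self.label_order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.label_order), columns=list(self.label_order)
        )


@dataclass
class AgreementStats:
    """Agreement summary of one rating table."""

    percent_agreement: float
    kappa: float
    se_kappa: float
    ci: Tuple[float, float]
    alpha: float
    band: str
    recall: Optional[float] = None
    precision: Optional[float] = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [-1, 1]")
        if not self.ci[0] <= self.kappa <= self.ci[1]:
            raise ValueError("confidence interval must contain kappa")

    def summary(self) -> str:
        lines = [
            f"percentage of agreement: {self.percent_agreement:.1f}%",
            (
                f"Cohen's k of interrater agreement: {self.kappa:.2f} "
                f"[SE k = {self.se_kappa:.3f}; CI (a = {self.alpha:.2f}) = "
                f"{self.ci[0]:.3f} to {self.ci[1]:.3f}] ({self.band})"
            ),
        ]
        if self.recall is not None and self.precision is not None:
            lines.append(
                f"group-1 recall = {self.recall:.3f}; precision = {self.precision:.3f}"
            )
        return "\n".join(lines)


def cross_table(
    ratings_a: Sequence,
    ratings_b: Sequence,
    label_order: Sequence = DEFAULT_LABEL_ORDER,
) -> RatingTable:
    """Tabulate two raters' labels into a K x K cross-correlation table."""
    if len(ratings_a) != len(ratings_b):
        raise ValueError(
            f"rating lists differ in length: {len(ratings_a)} vs {len(ratings_b)}"
        )
    order = list(label_order)
    index = {lab: i for i, lab in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=np.int64)
    for a, b in zip(ratings_a, ratings_b):
        if a not in index or b not in index:
            raise ValueError(f"unknown label in ratings: {a!r} / {b!r}")
        counts[index[a], index[b]] += 1
    return RatingTable(counts, tuple(order))


def _round_half_away(x: float, decimals: int = 1) -> float:
    f = 10**decimals
    return math.floor(abs(x) * f + 0.5) / f * (1 if x >= 0 else -1)


def percent_agreement(table: RatingTable) -> float:
    """Percentage of identically classified items, to one decimal."""
    po = np.trace(table.counts) / table.n_total
    return _round_half_away(100.0 * po, 1)


def cohens_kappa(table: RatingTable, alpha: float = 0.05) -> AgreementStats:
    """Cohen's kappa with standard error and confidence interval.

    The SE is the Fleiss-Cohen-Everitt large-sample estimate; the CI is
    kappa +/- z_{1-alpha/2} * SE, clipped to [-1, 1].
    """
    if table.n_total < 2:
        raise ValueError("kappa needs at least two rated items")
    n = table.n_total
    p = table.counts / n
    po = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0:
        raise ValueError("kappa undefined: expected agreement is 1 (single category)")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt (1969) large-sample variance
    diag = np.diag(p)
    term1 = float(np.sum(diag * ((1 - pe) - (row + col) * (1 - po)) ** 2))
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    grid = (col[:, None] + row[None, :]) ** 2  # (p_.i + p_j.)^2 for cell (i, j)
    term2 = float((1 - po) ** 2 * np.sum(off * grid))
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = math.sqrt(max(var, 0.0))

    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(-1.0, kappa - z * se)
    hi = min(1.0, kappa + z * se)
    return AgreementStats(
        percent_agreement=percent_agreement(table),
        kappa=float(np.clip(kappa, -1.0, 1.0)),
        se_kappa=se,
        ci=(lo, hi),
        alpha=alpha,
        band=kappa_band(kappa),
    )


def recall_precision(
    table: RatingTable, positive_label=1, truth_axis: str = "rows"
) -> Tuple[float, float]:
    """Recall (sensitivity) and precision (PPV) for one class.

    With ``truth_axis="rows"`` the row rater is the reference: recall is the
    diagonal count over the positive row sum, precision over the positive
    column sum.
    """
    if positive_label not in table.label_order:
        raise ValueError(f"label {positive_label!r} not in {table.label_order}")
    counts = table.counts if truth_axis == "rows" else table.counts.T
    i = table.label_order.index(positive_label)
    tp = counts[i, i]
    row_sum = counts[i, :].sum()
    col_sum = counts[:, i].sum()
    if row_sum == 0:
        raise ValueError("recall undefined: no items of the positive class")
    if col_sum == 0:
        raise ValueError("precision undefined: positive class never predicted")
    return float(tp / row_sum), float(tp / col_sum)


def kappa_band(kappa: float) -> str:
    """Interpretation band of a kappa value (conventional scale)."""
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa <= 0.0:
        return "none/chance or disagreement"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def agreement_report(
    ratings_a: Sequence,
    ratings_b: Sequence,
    label_order: Sequence = DEFAULT_LABEL_ORDER,
    positive_label=None,
    alpha: float = 0.05,
) -> AgreementStats:
    """Full two-rater agreement summary from raw rating lists."""
    table = cross_table(ratings_a, ratings_b, label_order)
    st = cohens_kappa(table, alpha=alpha)
    if positive_label is None:
        positive_label = label_order[0]
    try:
        st.recall, st.precision = recall_precision(table, positive_label)
    except ValueError as exc:
        warn(f"recall/precision unavailable: {exc}")
    return st


def consensus(
    ratings: Dict[str, Sequence],
    label_order: Sequence = DEFAULT_LABEL_ORDER,
) -> Tuple[List, List[int]]:
    """Majority consensus over several raters' aligned label lists.

    Returns the per-item consensus label (``None`` where no strict majority
    exists) and the indices of the unresolved items, which in practice go to
    a discussion round.
    """
    names = list(ratings)
    lengths = {len(ratings[r]) for r in names}
    if len(lengths) != 1:
        raise ValueError("all raters must rate the same items")
    (n,) = lengths
    out: List = []
    unresolved: List[int] = []
    for i in range(n):
        votes = [ratings[r][i] for r in names]
        best, best_count = None, 0
        for lab in label_order:
            c = votes.count(lab)
            if c > best_count:
                best, best_count = lab, c
        if best_count * 2 > len(votes):
            out.append(best)
        else:
            out.append(None)
            unresolved.append(i)
    return out, unresolved


def pairwise_tables(
    ratings: Dict[str, Sequence],
    label_order: Sequence = DEFAULT_LABEL_ORDER,
) -> Dict[Tuple[str, str], RatingTable]:
    """All pairwise cross-correlation tables among several raters."""
    names = list(ratings)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[(a, b)] = cross_table(ratings[a], ratings[b], label_order)
    return out
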