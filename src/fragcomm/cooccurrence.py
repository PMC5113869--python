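"""Occurrence-pattern metrics: C-score, NODF nestedness, proportional turnover.

All three metrics operate on a binary species x sites incidence matrix.
Species with zero occurrences in the analyzed matrix are dropped before
computation (occurrence metrics are undefined for absent species; this also
affects gamma and the number of species pairs).

* C-score (Stone & Roberts): mean number of "checkerboard units"
  (r_i - S_ij)(r_j - S_ij) over species pairs; high values indicate spatial
  segregation.
* NODF (nestedness by overlap and decreasing fill): 0-100; 100 means poorer
  assemblages are perfect subsets of richer ones.  Pairs with equal marginal
  totals contribute zero.
* beta_P: proportional species turnover 1 - alpha/gamma, alpha = mean
  per-site richness, gamma = regional richness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core_data import IncidenceMatrix

__all__ = ["MetricScore", "c_score", "nodf", "beta_p", "MetricUndefinedError", "METRICS"]


class MetricUndefinedError(ValueError):
    """The metric is not defined on this matrix (e.g. too few species)."""


@dataclass
class MetricScore:
    metric_name: str
    value: float
    n_species_used: int
    n_fragments_used: int

    def __float__(self) -> float:
        return float(self.value)


def c_score(
    inc: IncidenceMatrix,
    normalization: Literal["stone-roberts", "pairwise-fraction"] = "stone-roberts",
) -> MetricScore:
    """Checkerboard C-score over all occupied species pairs.

    ``stone-roberts`` (default) is the mean checkerboard-unit count
    (r_i - S_ij)(r_j - S_ij); ``pairwise-fraction`` divides each pair's
    term by r_i * r_j, bounding it to [0, 1].
    """
    inc = inc.drop_empty_species()
    a = inc.presence.astype(np.int64)
    s = a.shape[0]
    if s < 2:
        raise MetricUndefinedError("C-score needs at least 2 occupied species")
    r = a.sum(axis=1)
    shared = a @ a.T
    units = (r[:, None] - shared) * (r[None, :] - shared)
    if normalization == "pairwise-fraction":
        units = units / (r[:, None] * r[None, :])
    elif normalization != "stone-roberts":
        raise ValueError(f"unknown normalization {normalization!r}")
    iu = np.triu_indices(s, k=1)
    value = float(units[iu].mean())
    return MetricScore("c_score", value, s, inc.n_fragments)


def _nodf_axis_sum(a: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap percentages over all row pairs of ``a``.

    For an unordered row pair the contribution is 100 * (shared / poorer
    total) when the marginal totals differ, 0 when equal (decreasing fill).
    Rows with zero total contribute 0 as the poorer member.  Returns
    (sum, number of pairs).
    """
    n = a.shape[0]
    r = a.sum(axis=1)
    shared = (a @ a.T).astype(float)
    poorer = np.minimum(r[:, None], r[None, :]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        overlap = np.where(poorer > 0, shared / poorer, 0.0)
    overlap[r[:, None] == r[None, :]] = 0.0  # equal fills contribute zero
    iu = np.triu_indices(n, k=1)
    return float(100.0 * overlap[iu].sum()), len(iu[0])


def nodf(inc: IncidenceMatrix) -> MetricScore:
    """NODF nestedness over all row pairs and column pairs (0-100).

    Because a pair's contribution depends only on which member has the
    larger marginal total, the score is invariant to the input's row and
    column order (the conventional sort by decreasing totals is implicit).
    """
    inc = inc.drop_empty_species()
    a = inc.presence.astype(np.int64)
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise MetricUndefinedError("NODF needs >= 2 occupied rows and >= 2 columns")
    row_sum, n_row_pairs = _nodf_axis_sum(a)
    col_sum, n_col_pairs = _nodf_axis_sum(a.T)
    value = (row_sum + col_sum) / (n_row_pairs + n_col_pairs)
    return MetricScore("nodf", value, a.shape[0], a.shape[1])


def beta_p(inc: IncidenceMatrix) -> MetricScore:
    """Proportional species turnover beta_P = 1 - alpha/gamma.

    alpha is the mean per-fragment richness over all fragment columns of
    the analyzed matrix; gamma the number of species present in >= 1
    fragment.
    """
    a = inc.presence
    gamma = int((a.sum(axis=1) > 0).sum())
    if gamma < 1:
        raise MetricUndefinedError("beta_P undefined on an all-zero matrix")
    alpha = float(a.sum(axis=0).mean())
    return MetricScore("beta_p", 1.0 - alpha / gamma, gamma, inc.n_fragments)


#: Named metric registry used by the null-model engine and the CLI.
METRICS = {"c_score": c_score, "nodf": nodf, "beta_p": beta_p}
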