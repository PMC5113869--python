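"""Randomization null models, standardized effect sizes, and corrections.

The null model used throughout is the *proportional abundance* model: all
N individuals of a community matrix are re-placed independently into cells
with probability p_i * q_j, where p_i and q_j are the observed row and
column abundance fractions.  Row and column totals are random with
expectations equal to the observed totals, and the grand total is conserved
exactly.  This model is equivalent to a neutral community without dispersal
limitation or speciation, and is conservative with respect to inherent
site-quality and colonization-rate differences.

Observed metric scores are compared against an ensemble of (by default
1000) such null matrices via the standardized effect size
SES = (obs - mean_null) / sd_null and an add-one empirical two-sided p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cooccurrence import METRICS, MetricScore, MetricUndefinedError
from .core_data import (
    CommunityMatrix,
    IncidenceMatrix,
    TraitTable,
    ValidationError,
    to_incidence,
)

__all__ = [
    "NullEnsemble",
    "SESResult",
    "proportional_resample",
    "null_distribution",
    "ses",
    "bonferroni",
    "trait_reshuffle",
    "spawn_rngs",
]

#: Default number of null matrices per ensemble.
DEFAULT_ITERATIONS = 1000

#: Two-sided 5% critical value under an approximately normal null.
SES_CRITICAL = 1.96


def spawn_rngs(seed: int | np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one root seed.

    Stream splitting keeps every analysis stage reproducible regardless of
    the order stages execute in.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(s)) for s in root.spawn(n)]


@dataclass
class NullEnsemble:
    metric_name: str
    observed: float
    null_scores: np.ndarray
    iterations: int
    seed: int | None = None
    n_redraws: int = 0

    def __post_init__(self) -> None:
        self.null_scores = np.asarray(self.null_scores, dtype=float)
        if self.null_scores.shape != (self.iterations,):
            raise ValidationError("ensemble length must equal iterations")
        if not np.isfinite(self.null_scores).all() or not math.isfinite(self.observed):
            raise ValidationError("ensemble scores must be finite")

    @property
    def mean(self) -> float:
        return float(self.null_scores.mean())

    @property
    def sd(self) -> float:
        """Ensemble standard deviation (n-1 denominator)."""
        return float(self.null_scores.std(ddof=1))


@dataclass
class SESResult:
    ses: float  # nan when the ensemble SD is zero
    p_two_sided: float
    significant_raw: bool
    significant_bonferroni: bool | None = None


def proportional_resample(
    m: CommunityMatrix, rng: np.random.Generator | int
) -> CommunityMatrix:
    """One draw from the proportional abundance null model.

    All N individuals are placed independently into cells with probability
    p_i * q_j (outer product of observed row/column abundance fractions);
    the grand total is exactly N.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = m.grand_total
    if n < 1:
        raise ValidationError("cannot resample a matrix with zero grand total")
    p = m.row_totals() / n
    q = m.column_totals() / n
    cells = np.outer(p, q).ravel()
    counts = rng.multinomial(n, cells / cells.sum()).reshape(m.abundance.shape)
    return CommunityMatrix(
        species_ids=list(m.species_ids),
        fragment_ids=list(m.fragment_ids),
        abundance=counts,
        guild=m.guild,
        specialist=m.specialist,
        allow_empty_species=True,
    )


def null_distribution(
    m: CommunityMatrix,
    metric: str | Callable[..., MetricScore],
    iterations: int = DEFAULT_ITERATIONS,
    rng: np.random.Generator | int | None = None,
    max_redraw_fraction: float = 0.5,
) -> NullEnsemble:
    """Null ensemble of a named incidence metric under proportional resampling.

    The metric is evaluated on the incidence (presence/absence) pattern of
    each resampled abundance matrix.  Resamples on which the metric is
    undefined (for instance fewer than two occupied species) are redrawn so
    the ensemble keeps its full length; the redraw count is recorded.  If
    more than ``max_redraw_fraction`` of attempted draws are degenerate the
    run aborts.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1 (empty ensemble forbidden)")
    metric_fn = METRICS[metric] if isinstance(metric, str) else metric
    seed_used = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    observed = float(metric_fn(to_incidence(m)))

    # Resampling only needs the marginals; bypass per-draw object validation.
    n = m.grand_total
    if n < 1:
        raise ValidationError("cannot resample a matrix with zero grand total")
    cells = np.outer(m.row_totals() / n, m.column_totals() / n).ravel()
    cells = cells / cells.sum()
    shape = m.abundance.shape
    fragment_ids = list(m.fragment_ids)
    species_ids = list(m.species_ids)

    scores = np.empty(iterations)
    redraws = 0
    filled = 0
    while filled < iterations:
        counts = rng.multinomial(n, cells).reshape(shape)
        inc = IncidenceMatrix(species_ids, fragment_ids, (counts > 0).astype(np.int8))
        try:
            scores[filled] = float(metric_fn(inc))
            filled += 1
        except MetricUndefinedError:
            redraws += 1
            if redraws > max_redraw_fraction * (filled + redraws) and redraws >= 10:
                raise MetricUndefinedError(
                    f"metric undefined on {redraws} of {filled + redraws} null draws"
                )
    name = metric_fn.__name__ if callable(metric_fn) else str(metric)
    return NullEnsemble(
        metric_name=name,
        observed=observed,
        null_scores=scores,
        iterations=iterations,
        seed=int(seed_used) if seed_used is not None else None,
        n_redraws=redraws,
    )


def ses(e: NullEnsemble, alpha: float = 0.05) -> SESResult:
    """Standardized effect size and add-one empirical two-sided p.

    SES = (obs - mean_null) / sd_null with the n-1 SD.  The two-sided p is
    2 * min((#{null <= obs}+1)/(n+1), (#{null >= obs}+1)/(n+1)), capped at
    1; the add-one (permutation-style) estimator avoids p = 0.  With a
    zero-SD ensemble SES is reported as nan and p from tail counts only.
    """
    nscores = e.null_scores
    n = len(nscores)
    lo = (np.sum(nscores <= e.observed) + 1) / (n + 1)
    hi = (np.sum(nscores >= e.observed) + 1) / (n + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    sd = e.sd
    # SDs at floating-point noise level mean a degenerate (constant) ensemble
    degenerate = sd <= 1e-12 * max(1.0, abs(e.mean))
    s = float("nan") if degenerate else (e.observed - e.mean) / sd
    return SESResult(ses=s, p_two_sided=p, significant_raw=p <= alpha)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Bonferroni-corrected significance flags: p_i <= alpha / k.

    The family size k is the length of ``p_values``; the caller defines the
    family (by default all metric x guild x group tests of one run).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return (p <= alpha / p.size).tolist()


def trait_reshuffle(t: TraitTable, rng: np.random.Generator | int) -> TraitTable:
    """Independently permute every trait column across species.

    Marginal trait distributions are preserved exactly; the joint structure
    (trait correlations, species identity) is destroyed.  This is the null
    model used to calibrate functional diversity for richness effects.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    df = t.table.copy()
    n = len(df)
    for col in df.columns:
        if col == "species_id":
            continue
        df[col] = df[col].to_numpy()[rng.permutation(n)]
    return TraitTable(df)
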