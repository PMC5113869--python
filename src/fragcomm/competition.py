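"""Markov-chain assessment of interspecific competitive strength.

The method asks how much of the observed distribution of relative
abundances *could* be explained by pairwise competition.  A competitive-
strength matrix C assigns every species pair a strength c_ij in [0, 1]
with c_ij + c_ji = 1 (a tournament with graded outcomes; intransitive
loops are allowed).  C is turned into a column-stochastic transition
matrix by column normalization, and the stationary distribution of the
resulting Markov chain is the predicted vector of relative abundances.

Searching a large number of random candidate matrices (100,000 by
default) and keeping the one whose stationary vector best rank-correlates
with the observed per-fragment relative abundances gives r_C, an upper
bound on the explanatory power of competition: r_C**2 bounds the share of
abundance variance attributable to any competitive hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core_data import CommunityMatrix, ValidationError

__all__ = [
    "CompetitionMatrix",
    "hierarchical_competition_matrix",
    "random_competition_matrix",
    "to_transition",
    "stationary_abundances",
    "fit_competition",
    "CompetitionFit",
    "CompetitionInfeasibleError",
]

DEFAULT_CANDIDATES = 100_000

#: Diagonal retention: a species "ties" against itself with strength 0.5
#: before column normalization.  Configurable via ``diagonal=`` arguments.
DEFAULT_DIAGONAL = 0.5


class CompetitionInfeasibleError(ValueError):
    """Too few usable species/fragments for a rank-correlation fit."""


@dataclass
class CompetitionMatrix:
    """Pairwise competitive strengths: c_ij + c_ji = 1, diagonal 0.5."""

    strengths: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.strengths, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] < 2:
            raise ValidationError("competition matrix must be square, S >= 2")
        if ((c < 0) | (c > 1)).any():
            raise ValidationError("competitive strengths must lie in [0, 1]")
        if not np.allclose(c + c.T, 1.0):
            raise ValidationError("antisymmetry violated: c_ij + c_ji must be 1")
        self.strengths = c

    @property
    def n_species(self) -> int:
        return self.strengths.shape[0]


def random_competition_matrix(
    s: int, rng: np.random.Generator | int | None = None, diagonal: float = DEFAULT_DIAGONAL
) -> CompetitionMatrix:
    """Random tournament: upper triangle i.i.d. uniform, mirrored as 1 - c."""
    if s < 2:
        raise ValidationError("need at least 2 species")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    c = np.full((s, s), diagonal)
    iu = np.triu_indices(s, k=1)
    u = rng.uniform(size=len(iu[0]))
    c[iu] = u
    c[(iu[1], iu[0])] = 1.0 - u
    return CompetitionMatrix(c)


def hierarchical_competition_matrix(
    s: int, advantage: float = 0.15, diagonal: float = DEFAULT_DIAGONAL
) -> CompetitionMatrix:
    """Transitive dominance hierarchy with graded strengths.

    Species are ordered from dominant to subordinate; the strength of i
    over j is 0.5 + advantage * (j - i), clipped to [0.02, 0.98].  With
    ``advantage`` around 0.15 the chain's stationary abundances are well
    separated, so the dominance order is recoverable from sampled counts.
    """
    if s < 2:
        raise ValidationError("need at least 2 species")
    idx = np.arange(s)
    c = np.clip(0.5 + advantage * (idx[None, :] - idx[:, None]), 0.02, 0.98)
    np.fill_diagonal(c, diagonal)
    return CompetitionMatrix(c)


def to_transition(c: CompetitionMatrix) -> np.ndarray:
    """Column-stochastic transition matrix t_ij = c_ij / sum_k c_kj."""
    s = c.strengths
    return s / s.sum(axis=0, keepdims=True)


def stationary_abundances(
    t: np.ndarray, tol: float = 1e-12, max_iter: int = 1_000_000
) -> np.ndarray:
    """Stationary distribution of a column-stochastic chain by power iteration.

    Iterates x <- Tx from the uniform vector until ||Tx - x||_1 <= tol.
    For reducible chains this reports the limit reached from the uniform
    start.  Raises on non-convergence.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValidationError("transition matrix must be square")
    if not np.allclose(t.sum(axis=0), 1.0, atol=1e-9) or (t < 0).any():
        raise ValidationError("matrix is not column stochastic")
    x = np.full(t.shape[0], 1.0 / t.shape[0])
    for _ in range(int(max_iter)):
        nxt = t @ x
        if np.abs(nxt - x).sum() <= tol:
            x = nxt
            break
        x = nxt
    else:
        raise RuntimeError(
            f"power iteration did not converge; residual {np.abs(t @ x - x).sum():.3g}"
        )
    return x / x.sum()


def _batch_stationary(c_batch: np.ndarray, iters: int = 400) -> np.ndarray:
    """Stationary vectors for a (B, S, S) batch of competition matrices."""
    t = c_batch / c_batch.sum(axis=1, keepdims=True)  # column-normalize each
    b, s, _ = t.shape
    x = np.full((b, s, 1), 1.0 / s)
    check_every = 25
    for i in range(iters):
        x = t @ x
        if (i + 1) % check_every == 0:
            resid = np.abs(t @ x - x).sum(axis=(1, 2)).max()
            if resid <= 1e-13:
                break
    return (x / x.sum(axis=1, keepdims=True))[:, :, 0]


def _rank_rows(a: np.ndarray) -> np.ndarray:
    """Midranks along the last axis."""
    return rankdata(a, axis=-1)


def _spearman_matrix(pred_ranks: np.ndarray, obs_ranks: np.ndarray) -> np.ndarray:
    """Spearman correlations between (B, S) predicted and (F, S) observed ranks.

    Midrank ties are handled by computing Pearson correlation on ranks;
    rows with zero rank variance (all tied) yield correlation 0 by
    convention.  Returns a (B, F) matrix.
    """

    def _unitize(r: np.ndarray) -> np.ndarray:
        centered = r - r.mean(axis=-1, keepdims=True)
        norm = np.linalg.norm(centered, axis=-1, keepdims=True)
        safe = np.where(norm > 0, norm, 1.0)
        return np.where(norm > 0, centered / safe, 0.0)

    return _unitize(pred_ranks) @ _unitize(obs_ranks).T


@dataclass
class CompetitionFit:
    best: CompetitionMatrix
    transition: np.ndarray
    predicted: np.ndarray  # stationary relative abundances
    r_c: float
    per_fragment: dict[str, float]
    n_candidates: int
    species_ids: list[str]
    fragments_used: list[str]
    seed: int | None = None


def fit_competition(
    m: CommunityMatrix,
    guild: str | None = None,
    specialists_only: bool = False,
    n_candidates: int = DEFAULT_CANDIDATES,
    rng: np.random.Generator | int | None = None,
    min_species_per_fragment: int = 3,
    chunk_size: int = 20_000,
    diagonal: float = DEFAULT_DIAGONAL,
) -> CompetitionFit:
    """Best-of-k search for the competitive hierarchy explaining abundances.

    Candidates are scored by the mean Spearman rank correlation between
    their stationary vector and the observed relative abundances, taken
    over fragments where at least ``min_species_per_fragment`` of the
    species occur.  Ties in the argmax are broken first-found.
    """
    seed_used = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sub = m.guild_subset(guild, specialists_only) if guild is not None else m
    occurring = sub.abundance.sum(axis=1) > 0
    sub = sub.select_species(occurring)
    s = sub.n_species
    if s < 3:
        raise CompetitionInfeasibleError(
            f"only {s} usable species; rank correlation needs >= 3"
        )
    if n_candidates < 1:
        raise ValidationError("n_candidates must be >= 1")

    frag_richness = (sub.abundance > 0).sum(axis=0)
    frag_mask = frag_richness >= min_species_per_fragment
    if not frag_mask.any():
        raise CompetitionInfeasibleError(
            f"no fragment holds >= {min_species_per_fragment} of the species"
        )
    totals = sub.abundance[:, frag_mask].sum(axis=0).astype(float)
    rel_obs = (sub.abundance[:, frag_mask] / totals).T  # (F_used, S)
    obs_ranks = _rank_rows(rel_obs)
    fragments_used = [f for f, k in zip(sub.fragment_ids, frag_mask) if k]

    iu = np.triu_indices(s, k=1)
    best_score = -np.inf
    best_c: np.ndarray | None = None
    best_pred: np.ndarray | None = None
    done = 0
    while done < n_candidates:
        b = min(chunk_size, n_candidates - done)
        u = rng.uniform(size=(b, len(iu[0])))
        c = np.full((b, s, s), diagonal)
        c[:, iu[0], iu[1]] = u
        c[:, iu[1], iu[0]] = 1.0 - u
        pred = _batch_stationary(c)
        scores = _spearman_matrix(_rank_rows(pred), obs_ranks).mean(axis=1)
        i = int(np.argmax(scores))
        if scores[i] > best_score:
            best_score = float(scores[i])
            best_c = c[i]
            best_pred = pred[i]
        done += b

    assert best_c is not None and best_pred is not None
    best = CompetitionMatrix(best_c)
    per_frag = _spearman_matrix(
        _rank_rows(best_pred[None, :]), obs_ranks
    )[0]
    return CompetitionFit(
        best=best,
        transition=to_transition(best),
        predicted=best_pred,
        r_c=best_score,
        per_fragment=dict(zip(fragments_used, per_frag.tolist())),
        n_candidates=n_candidates,
        species_ids=list(sub.species_ids),
        fragments_used=fragments_used,
        seed=int(seed_used) if seed_used is not None else None,
    )
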