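"""Trait reduction, functional attribute diversity (FAD), and its linear model.

FAD measures the total trait space spanned by a set of species: the sum of
Euclidean distances between all species pairs in (Z-transformed) trait
space.  Correlated raw measurements are first collapsed to single axes —
the dominant principal component of the three bill measures, of the three
locomotion measures (wing, tarsus, tail), and of the categorical diet and
foraging-stratum scores — giving the reduced trait set

    bill_pc, body_size, dispersal (hand-wing index), locomotion_pc,
    stratum_pc (and diet_pc, coded but excluded from FAD by default).

Because FAD grows mechanically with species richness, raw scores are
calibrated against a trait-reshuffling null model (see
:func:`fragcomm.null_engine.trait_reshuffle`) and both raw and SES FAD are
related to feeding guild, trait, fragment-size group and richness in a
general linear model reporting partial eta-squared per term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .core_data import CommunityMatrix, FragmentTable, TraitTable, ValidationError
from .null_engine import NullEnsemble, SESResult, ses

__all__ = [
    "FAD_TRAITS",
    "REDUCED_TRAITS",
    "dominant_pc",
    "reduce_traits",
    "zscore",
    "fad",
    "fad_ses",
    "fad_records",
    "fad_glm",
    "GLMResult",
]

#: Reduced traits entering FAD.  Diet is coded in the trait table but not
#: part of the five-trait FAD set.
FAD_TRAITS = ["bill_pc", "body_size", "dispersal", "locomotion_pc", "stratum_pc"]
REDUCED_TRAITS = FAD_TRAITS + ["diet_pc"]

_BILL_COLS = ["culmen_length", "culmen_depth", "culmen_width"]
_LOCOMOTION_COLS = ["wing", "tarsus", "tail"]


def dominant_pc(block: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Scores on the first principal axis of a column-standardized block.

    Correlation PCA: each measure is Z-transformed before the axis is
    extracted, so measures with different units weigh equally.  The sign is
    fixed so the first input column loads positively.
    """
    x = np.asarray(block, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("dominant_pc needs >= 2 species and >= 2 measures")
    if np.isnan(x).any():
        raise ValidationError("missing values in measurement block")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        cols = (
            list(block.columns) if isinstance(block, pd.DataFrame) else list(range(x.shape[1]))
        )
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValidationError(f"zero-variance measure column(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    # first right singular vector of the standardized block = leading
    # eigenvector of the correlation matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    axis = vt[0]
    if axis[0] < 0:
        axis = -axis
    return z @ axis


def reduce_traits(t: TraitTable) -> TraitTable:
    """Collapse raw measurements to the six single-axis reduced traits."""
    df = t.table
    out = pd.DataFrame({"species_id": df["species_id"]})
    out["bill_pc"] = dominant_pc(df[_BILL_COLS])
    out["body_size"] = df["body_mass"].to_numpy(dtype=float)
    out["dispersal"] = df["hand_wing_index"].to_numpy(dtype=float)
    out["locomotion_pc"] = dominant_pc(df[_LOCOMOTION_COLS])
    stratum_cols = [c for c in df.columns if c.startswith("stratum_")]
    diet_cols = [c for c in df.columns if c.startswith("diet_")]
    if len(stratum_cols) < 2 or len(diet_cols) < 2:
        raise ValidationError("need stratum_* and diet_* category columns")
    out["stratum_pc"] = dominant_pc(df[stratum_cols])
    out["diet_pc"] = dominant_pc(df[diet_cols])
    for extra in ("guild", "specialist"):
        if extra in df.columns:
            out[extra] = df[extra].to_numpy()
    return TraitTable(out)


def zscore(values: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Z-transform columns over the species set being analyzed (sample SD)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValidationError("zero-variance trait in the analyzed pool")
    return (x - x.mean(axis=0)) / sd


def fad(traits: pd.DataFrame | np.ndarray) -> float:
    """Sum of Euclidean distances between all species pairs in trait space.

    Zero for fewer than two species.  Input is expected to be already
    Z-transformed over the relevant species pool.
    """
    x = np.atleast_2d(np.asarray(traits, dtype=float))
    if x.shape[1] == 0 or x.shape[0] < 2:
        return 0.0
    if np.isnan(x).any():
        raise ValidationError("missing trait value")
    if x.shape[1] == 1:
        # 1-D shortcut: sum of |pairwise differences| via sorted prefix sums
        v = np.sort(x[:, 0])
        n = len(v)
        return float(np.sum((2 * np.arange(n) - n + 1) * v))
    return float(pdist(x).sum())


def _subset_fad_null(
    pool_values: np.ndarray, k: int, iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """Null FAD scores for a k-species cell under trait reshuffling.

    Independently permuting each trait column over the n-species pool and
    re-reading a fixed k-species set is equivalent to drawing, per trait,
    k values without replacement from that trait's pool — which is what is
    sampled here, column by column.
    """
    n, d = pool_values.shape
    out = np.empty(iterations)
    cols = np.empty((k, d))
    for i in range(iterations):
        for j in range(d):
            idx = rng.permutation(n)[:k]
            cols[:, j] = pool_values[idx, j]
        out[i] = fad(cols)
    return out


def fad_ses(
    pool: pd.DataFrame,
    species_set: list[str] | np.ndarray,
    trait_columns: list[str] | None = None,
    iterations: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, SESResult, NullEnsemble]:
    """Observed FAD of a species set plus its trait-reshuffling SES.

    ``pool`` is a species-indexed frame of (already reduced) trait columns
    for the full species pool; Z-transformation happens here, over the
    pool.  Null scores recompute FAD on the same-size set after reshuffling
    every trait independently across the pool.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    trait_columns = trait_columns or FAD_TRAITS
    species_set = list(species_set)
    if len(species_set) < 2:
        raise ValidationError("FAD SES needs a species set of >= 2")
    z = zscore(pool[trait_columns])
    zdf = pd.DataFrame(z, index=pool.index, columns=trait_columns)
    observed = fad(zdf.loc[species_set].to_numpy())
    null_scores = _subset_fad_null(z, len(species_set), iterations, rng)
    ens = NullEnsemble("fad", observed, null_scores, iterations)
    return observed, ses(ens), ens


def fad_records(
    m: CommunityMatrix,
    reduced: TraitTable,
    fragments: FragmentTable,
    trait_columns: list[str] | None = None,
    iterations: int = 1000,
    rng: np.random.Generator | int | None = None,
    min_species: int = 2,
) -> pd.DataFrame:
    """Per guild x single-trait x fragment FAD records with SES calibration.

    For every feeding guild, every reduced trait is Z-transformed within
    that guild's species pool; each fragment's FAD on that single trait is
    the sum of pairwise distances among the guild species present there.
    Cells with fewer than ``min_species`` present species are dropped.
    Columns: guild, trait, fragment_id, group, n_species (richness
    covariate), fad, ses_fad, p.
    """
    if m.guild is None:
        raise ValidationError("community matrix needs guild annotations")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    trait_columns = trait_columns or FAD_TRAITS
    group_of = fragments.group_of()
    tdf = reduced.table.set_index("species_id")
    rows = []
    for guild in pd.unique(m.guild):
        sub = m.guild_subset(guild)
        pool = tdf.loc[sub.species_ids, trait_columns]
        z = zscore(pool)
        for ti, trait in enumerate(trait_columns):
            zcol = z[:, [ti]]
            for fj, frag in enumerate(m.fragment_ids):
                present = sub.abundance[:, fj] > 0
                k = int(present.sum())
                if k < min_species:
                    continue
                observed = fad(zcol[present])
                null_scores = _subset_fad_null(zcol, k, iterations, rng)
                ens = NullEnsemble("fad", observed, null_scores, iterations)
                r = ses(ens)
                ses_value = r.ses
                if np.isnan(ses_value) and abs(observed - ens.mean) <= 1e-9 * max(
                    1.0, abs(ens.mean)
                ):
                    # permutation-closed cell (every pool species present):
                    # observed equals every reshuffle, deviation is exactly 0
                    ses_value = 0.0
                rows.append(
                    {
                        "guild": guild,
                        "trait": trait,
                        "fragment_id": frag,
                        "group": group_of[frag],
                        "n_species": k,
                        "fad": observed,
                        "ses_fad": ses_value,
                        "p": r.p_two_sided,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class GLMResult:
    """ANOVA-style decomposition of a least-squares fit.

    ``terms`` maps term name to (degrees of freedom, partial eta-squared);
    partial eta2 = SS_term / (SS_term + SS_error) with partial
    (full-vs-reduced) sums of squares.
    """

    terms: dict[str, tuple[int, float]]
    r_squared: float
    error_df: int
    error_ss: float = field(default=float("nan"))


_GLM_TERMS = [
    ("guild", "C(guild, Sum)"),
    ("trait", "C(trait, Sum)"),
    ("size", "C(group, Sum)"),
    ("guild_x_trait", "C(guild, Sum):C(trait, Sum)"),
    ("guild_x_size", "C(guild, Sum):C(group, Sum)"),
    ("trait_x_size", "C(trait, Sum):C(group, Sum)"),
    ("species", "n_species"),
    ("species_sq", "I(n_species ** 2)"),
]


def fad_glm(records: pd.DataFrame, response: str = "fad") -> GLMResult:
    """General linear model of FAD with partial eta-squared per term.

    Fits ``response`` on guild + trait + size group, their two-way
    interactions, and richness + richness-squared, with sum-to-zero
    contrasts.  Partial sums of squares come from full-vs-reduced model
    comparison (Type-III style), so each term is adjusted for all others.
    """
    for col in ("guild", "trait", "group", "n_species", response):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
    for col in ("guild", "trait", "group"):
        if records[col].nunique() < 2:
            raise ValidationError(f"factor {col!r} needs >= 2 levels")
    import patsy
    import statsmodels.api as sm

    data = records.rename(columns={response: "_y"})
    n_missing = int(data["_y"].isna().sum())
    if n_missing:
        # cells whose SES is undefined (degenerate null with a real
        # deviation) carry no usable response; dropped explicitly
        data = data.dropna(subset=["_y"])
    rhs = " + ".join(t[1] for t in _GLM_TERMS)
    y, x = patsy.dmatrices(f"_y ~ {rhs}", data, return_type="dataframe")
    design_info = x.design_info
    n_params = x.shape[1]
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < n_params:
        raise ValidationError(
            f"rank-deficient design: rank {rank} < {n_params} columns; "
            "some guild x trait x size cells are empty or aliased"
        )
    full = sm.OLS(y, x).fit()
    if full.df_resid <= 0:
        raise ValidationError("no error degrees of freedom")
    sse_full = float(full.ssr)
    terms: dict[str, tuple[int, float]] = {}
    for name, formula_term in _GLM_TERMS:
        # Type-III partial SS: drop the term's columns from the fixed
        # sum-contrast design and refit (rebuilding the formula instead
        # would let patsy re-code interactions to absorb a dropped main
        # effect, yielding zero SS)
        slc = design_info.term_name_slices[formula_term]
        cols = list(range(*slc.indices(n_params)))
        x_red = x.drop(columns=x.columns[cols])
        red = sm.OLS(y, x_red).fit()
        ss_term = max(0.0, float(red.ssr) - sse_full)
        df_term = len(cols)
        eta2 = ss_term / (ss_term + sse_full) if (ss_term + sse_full) > 0 else 0.0
        terms[name] = (df_term, eta2)
    return GLMResult(
        terms=terms,
        r_squared=float(full.rsquared),
        error_df=int(full.df_resid),
        error_ss=sse_full,
    )
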