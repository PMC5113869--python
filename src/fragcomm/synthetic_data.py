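"""Synthetic communities with known assembly structure.

Every analysis stage in this package is testable without the original
field data: the generators here produce species x fragment abundance
matrices, trait tables and fragment metadata whose dimensions and
statistical structure mirror the study system (69 understorey bird
species in 12 cloud-forest fragments; four feeding guilds of 36
insectivores, 12 frugi-nectarivores, 11 omnivores and 10 granivores;
three large and nine small fragments; about 17,500 captured individuals).

Four assembly scenarios are available:

* ``neutral`` — individuals placed by the proportional abundance model
  itself (lognormal rank-abundance species weights, observed-like fragment
  totals), i.e. data with no co-occurrence structure beyond mass effects;
* ``nested`` — poorer fragments hold strict subsets of richer fragments'
  assemblages (deterministic prefix occupancy along a capacity gradient);
* ``checkerboard`` — species are paired within guilds and the members of a
  pair never share a fragment (strong segregation);
* ``competitive`` — per-fragment abundances are multinomial draws from the
  stationary distribution of a known competitive-strength Markov chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .competition import CompetitionMatrix, stationary_abundances, to_transition
from .core_data import CommunityMatrix, FragmentTable, TraitTable, ValidationError

__all__ = [
    "SyntheticScenario",
    "generate_neutral",
    "generate_nested",
    "generate_checkerboard",
    "generate_competitive",
    "generate_traits",
    "generate_fragments",
    "generate",
]

def _community(*args, **kwargs) -> CommunityMatrix:
    """Construct a generator output, silencing the expected empty-row note.

    Multinomial sampling legitimately leaves rare species with zero
    individuals; generators keep those rows so the species universe stays
    fixed across scenarios.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return CommunityMatrix(*args, **kwargs)


#: Per-guild species counts of the study community.
DEFAULT_GUILD_SIZES = {
    "insectivore": 36,
    "frugi-nectarivore": 12,
    "omnivore": 11,
    "granivore": 10,
}

#: Per-guild forest-specialist counts (insectivores 10, frugi-nectarivores 4,
#: omnivores 3, granivores 1).
DEFAULT_SPECIALISTS = {
    "insectivore": 10,
    "frugi-nectarivore": 4,
    "omnivore": 3,
    "granivore": 1,
}

#: Observed-like per-fragment individual totals (three large fragments first),
#: grand total 17,531.
DEFAULT_FRAGMENT_TOTALS = (1797, 7179, 4066, 219, 1492, 78, 330, 898, 1054, 239, 13, 166)


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic community.

    ``lognormal_sigma`` shapes the rank-abundance curve (larger = steeper
    dominance); 1.5 gives realistic bird-community evenness.  For the
    checkerboard scenario ``n_checker_pairs`` species pairs receive
    disjoint fragment sets; for the competitive scenario ``competition``
    supplies the true hierarchy and ``abundance_noise`` an optional
    Dirichlet jitter (0 = none) of the stationary vector per fragment.
    """

    scenario: str = "neutral"
    guild_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GUILD_SIZES))
    specialist_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIALISTS)
    )
    fragment_totals: tuple[int, ...] = DEFAULT_FRAGMENT_TOTALS
    lognormal_sigma: float = 1.5
    nested_steepness: float = 1.0
    n_checker_pairs: int | None = None
    competition: CompetitionMatrix | None = None
    abundance_noise: float = 0.0
    trait_effect_size: float = 1.0
    trait_block_correlation: float = 0.7
    seed: int = 0

    @property
    def n_species(self) -> int:
        return sum(self.guild_sizes.values())

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_totals)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def species_labels(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """(species_ids, guild, specialist) in fixed order."""
        ids, guilds, spec = [], [], []
        for g, n in self.guild_sizes.items():
            n_spec = self.specialist_counts.get(g, 0)
            for i in range(n):
                ids.append(f"{g[:4]}_{i + 1:02d}")
                guilds.append(g)
                spec.append(i < n_spec)
        return ids, np.array(guilds, dtype=object), np.array(spec, dtype=bool)

    def fragment_labels(self) -> list[str]:
        return [f"frag_{i + 1:02d}" for i in range(self.n_fragments)]


def _species_weights(scn: SyntheticScenario) -> np.ndarray:
    """Deterministic lognormal rank-abundance weights (sum 1)."""
    s = scn.n_species
    q = (np.arange(s, dtype=float) + 0.5) / s
    w = np.exp(scn.lognormal_sigma * norm.ppf(q))[::-1]
    return w / w.sum()


def generate_neutral(scn: SyntheticScenario) -> CommunityMatrix:
    """Mass-effect-only community: per-fragment multinomial placement."""
    rng = scn.rng()
    ids, guilds, spec = scn.species_labels()
    w = _species_weights(scn)
    # shuffle which species gets which abundance rank, independent of guild
    order = rng.permutation(scn.n_species)
    w = w[order]
    counts = np.column_stack(
        [rng.multinomial(n_f, w) for n_f in scn.fragment_totals]
    )
    return _community(
        ids, scn.fragment_labels(), counts, guild=guilds, specialist=spec,
        allow_empty_species=True,
    )


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to weights, each cell >= 1."""
    k = len(weights)
    if total < k:
        raise ValidationError("fragment total smaller than its species count")
    base = np.ones(k, dtype=np.int64)
    rest = total - k
    raw = weights / weights.sum() * rest
    alloc = np.floor(raw).astype(np.int64)
    rem = rest - alloc.sum()
    order = np.argsort(-(raw - alloc))
    alloc[order[:rem]] += 1
    return base + alloc


def generate_nested(scn: SyntheticScenario) -> CommunityMatrix:
    """Strictly nested occupancy along the fragment capacity gradient.

    Fragments are ranked by capacity (their individual totals); species i
    occupies a prefix of the k_i highest-capacity fragments, with k_i
    decreasing in species rank (steepness scales how fast).  Abundances
    are filled deterministically, proportional to species weights, with at
    least one individual per occupied cell — so the noiseless incidence
    pattern is exactly the designed one.
    """
    if scn.nested_steepness <= 0:
        raise ValidationError("nested_steepness must be > 0")
    ids, guilds, spec = scn.species_labels()
    s, f = scn.n_species, scn.n_fragments
    w = _species_weights(scn)
    cap_order = np.argsort(-np.asarray(scn.fragment_totals))
    # prefix lengths: richest species everywhere, rarest in the single
    # highest-capacity fragment
    ranks = np.arange(s, dtype=float)
    k = np.maximum(
        1, np.round(f - scn.nested_steepness * ranks * (f - 1) / max(s - 1, 1)).astype(int)
    )
    occupancy = np.zeros((s, f), dtype=bool)
    for i in range(s):
        occupancy[i, cap_order[: k[i]]] = True
    counts = np.zeros((s, f), dtype=np.int64)
    for j in range(f):
        present = occupancy[:, j]
        counts[present, j] = _largest_remainder(w[present], scn.fragment_totals[j])
    return _community(
        ids, scn.fragment_labels(), counts, guild=guilds, specialist=spec,
        allow_empty_species=True,
    )


def generate_checkerboard(scn: SyntheticScenario) -> CommunityMatrix:
    """Segregated community: paired species never share a fragment."""
    rng = scn.rng()
    ids, guilds, spec = scn.species_labels()
    s, f = scn.n_species, scn.n_fragments
    # pair species within guilds
    pairs: list[tuple[int, int]] = []
    offset = 0
    for g, n in scn.guild_sizes.items():
        idx = list(range(offset, offset + n))
        for a, b in zip(idx[0::2], idx[1::2]):
            pairs.append((a, b))
        offset += n
    n_pairs = scn.n_checker_pairs if scn.n_checker_pairs is not None else len(pairs)
    if n_pairs > len(pairs):
        raise ValidationError(
            f"requested {n_pairs} checkerboard pairs but only {len(pairs)} fit "
            "within guilds (odd leftovers stay unconstrained)"
        )
    pairs = pairs[:n_pairs]
    allowed = np.ones((s, f), dtype=bool)
    for a, b in pairs:
        # random split of fragments between the two members, both non-empty
        side = rng.integers(0, 2, size=f).astype(bool)
        if side.all():
            side[rng.integers(f)] = False
        if not side.any():
            side[rng.integers(f)] = True
        allowed[a] = side
        allowed[b] = ~side
    w = _species_weights(scn)[rng.permutation(s)]
    counts = np.zeros((s, f), dtype=np.int64)
    for j, n_f in enumerate(scn.fragment_totals):
        wj = np.where(allowed[:, j], w, 0.0)
        counts[:, j] = rng.multinomial(n_f, wj / wj.sum())
    return _community(
        ids, scn.fragment_labels(), counts, guild=guilds, specialist=spec,
        allow_empty_species=True,
    )


def generate_competitive(scn: SyntheticScenario) -> CommunityMatrix:
    """Abundances driven by a known competitive hierarchy.

    Per fragment, individuals are a multinomial draw from the stationary
    distribution of the scenario's competition chain; ``abundance_noise``
    > 0 adds per-fragment Dirichlet jitter around that vector (the
    concentration is stationary / noise, so larger noise = looser).
    """
    if scn.competition is None:
        raise ValidationError("competitive scenario needs a competition matrix")
    if scn.competition.n_species != scn.n_species:
        raise ValidationError(
            f"competition matrix is {scn.competition.n_species} species, "
            f"scenario has {scn.n_species}"
        )
    rng = scn.rng()
    ids, guilds, spec = scn.species_labels()
    pi = stationary_abundances(to_transition(scn.competition))
    counts = np.zeros((scn.n_species, scn.n_fragments), dtype=np.int64)
    for j, n_f in enumerate(scn.fragment_totals):
        p = pi
        if scn.abundance_noise > 0:
            p = rng.dirichlet(np.maximum(pi / scn.abundance_noise, 1e-9))
        counts[:, j] = rng.multinomial(n_f, p)
    return _community(
        ids, scn.fragment_labels(), counts, guild=guilds, specialist=spec,
        allow_empty_species=True,
    )


def generate_traits(scn: SyntheticScenario) -> TraitTable:
    """Guild-structured morphometrics with correlated measurement blocks.

    The bill trio (culmen length/depth/width) and the locomotion trio
    (wing, tarsus, tail) are drawn from guild-specific multivariate
    normals with within-block correlation ``trait_block_correlation`` so
    their dominant principal components are meaningful.  Guild means are
    offset by ``trait_effect_size`` pooled-SD units.  Body mass is
    lognormal, the hand-wing index normal, and diet (10 categories) and
    stratum (8 categories) are nonnegative preference scores peaked on a
    guild-typical category.
    """
    rng = scn.rng()
    ids, guilds, spec = scn.species_labels()
    s = scn.n_species
    guild_names = list(scn.guild_sizes)
    guild_idx = np.array([guild_names.index(g) for g in guilds])
    rho = scn.trait_block_correlation
    cov = np.full((3, 3), rho) + np.diag(np.full(3, 1 - rho))

    def _block(base: np.ndarray) -> np.ndarray:
        out = np.empty((s, 3))
        for gi in range(len(guild_names)):
            mask = guild_idx == gi
            mean = base + scn.trait_effect_size * (gi - 1.5) * 0.5
            out[mask] = rng.multivariate_normal(mean, cov, size=mask.sum())
        return out

    bill = _block(np.array([2.0, 0.8, 0.9]))
    loco = _block(np.array([8.0, 2.5, 7.0]))
    body_mass = np.exp(rng.normal(np.log(25.0) + 0.3 * (guild_idx - 1.5), 0.6))
    hwi = rng.normal(25.0 + 2.0 * scn.trait_effect_size * (guild_idx - 1.5), 5.0)
    diet = np.maximum(
        0, rng.normal(0, 0.5, size=(s, 10))
    )
    stratum = np.maximum(0, rng.normal(0, 0.5, size=(s, 8)))
    for i in range(s):
        diet[i, (2 * guild_idx[i]) % 10] += 2.0
        stratum[i, (2 * guild_idx[i] + 1) % 8] += 2.0

    df = pd.DataFrame({"species_id": ids})
    df[["culmen_length", "culmen_depth", "culmen_width"]] = bill
    df[["wing", "tarsus", "tail"]] = loco
    df["body_mass"] = body_mass
    df["hand_wing_index"] = hwi
    for c in range(10):
        df[f"diet_{c + 1}"] = diet[:, c]
    for c in range(8):
        df[f"stratum_{c + 1}"] = stratum[:, c]
    df["guild"] = guilds
    df["specialist"] = spec
    return TraitTable(df)


def generate_fragments(scn: SyntheticScenario) -> FragmentTable:
    """Fragment metadata shaped like the study's survey table.

    Areas follow the observed pattern (three fragments >= 90 ha, the rest
    < 15 ha); perimeter, isolation and cover are drawn around
    observed-like values.
    """
    rng = scn.rng()
    f = scn.n_fragments
    n_large = min(3, f)
    large_areas = rng.uniform(90, 180, size=n_large)
    small_areas = rng.uniform(1, 15, size=f - n_large)
    areas = np.concatenate([np.sort(large_areas)[::-1], np.sort(small_areas)[::-1]])
    perim = 60 * areas ** 0.7 * np.exp(rng.normal(0, 0.2, size=f))
    iso = rng.uniform(0.15, 0.6, size=f)
    cover = np.clip(areas * 0.3 + rng.normal(0, 5, size=f), 0.5, 100)
    return FragmentTable(
        pd.DataFrame(
            {
                "fragment_id": scn.fragment_labels(),
                "area": np.round(areas, 2),
                "perimeter": np.round(perim, 0),
                "isolation": np.round(iso, 2),
                "cover": np.round(cover, 1),
            }
        )
    )


_GENERATORS = {
    "neutral": generate_neutral,
    "nested": generate_nested,
    "checkerboard": generate_checkerboard,
    "competitive": generate_competitive,
}


def generate(scn: SyntheticScenario) -> CommunityMatrix:
    """Dispatch on ``scn.scenario``."""
    try:
        fn = _GENERATORS[scn.scenario]
    except KeyError:
        raise ValidationError(f"unknown scenario {scn.scenario!r}") from None
    return fn(scn)
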