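"""Data model and I/O for fragment-scale community data.

The central object is a :class:`CommunityMatrix`: integer abundances of
species (rows) across habitat fragments (columns), optionally annotated
with a feeding guild and a forest-specialist flag per species.  Binary
occurrence patterns (:class:`IncidenceMatrix`) are derived from it, and
fragment metadata (area, perimeter, isolation, forest cover) live in a
:class:`FragmentTable`.

All tabular I/O is delimited text (comma or tab, auto-detected) with one
header row and one label column.  Species-in-rows is the canonical
in-memory orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "IncidenceMatrix",
    "FragmentTable",
    "TraitTable",
    "ValidationError",
    "read_community_matrix",
    "write_community_matrix",
    "read_trait_table",
    "read_fragment_table",
    "to_incidence",
    "relative_abundances",
    "split_groups",
    "load_taita_fragments",
]

GUILDS = ("insectivore", "frugi-nectarivore", "omnivore", "granivore")

#: Area threshold (ha) separating "large" from "small" fragments.  The three
#: large study fragments are all >= 90 ha and the small ones < 15 ha, so any
#: threshold in between reproduces the published grouping.
LARGE_AREA_THRESHOLD_HA = 90.0


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


def _check_unique(labels: Sequence[str], kind: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {kind} labels: {dups}")


@dataclass
class CommunityMatrix:
    """Species x fragments abundance matrix with species annotations.

    Parameters
    ----------
    species_ids, fragment_ids
        Ordered, unique row and column labels.
    abundance
        Nonnegative integer counts of individuals, shape
        ``(len(species_ids), len(fragment_ids))``.
    guild
        Optional per-species feeding guild.
    specialist
        Optional per-species forest-specialist flag.
    allow_empty_species
        All-zero species rows are normally rejected on construction; pass
        ``True`` to keep them with a warning (used for group submatrices
        where the species universe must stay aligned).
    """

    species_ids: list[str]
    fragment_ids: list[str]
    abundance: np.ndarray
    guild: np.ndarray | None = None
    specialist: np.ndarray | None = None
    allow_empty_species: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.species_ids = [str(s) for s in self.species_ids]
        self.fragment_ids = [str(f) for f in self.fragment_ids]
        ab = np.asarray(self.abundance)
        if ab.ndim != 2 or ab.shape != (len(self.species_ids), len(self.fragment_ids)):
            raise ValidationError(
                f"abundance shape {ab.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.fragment_ids)} fragments"
            )
        if not np.issubdtype(ab.dtype, np.integer):
            if not np.allclose(ab, np.round(ab)):
                raise ValidationError("abundances must be integer counts")
            ab = np.round(ab).astype(np.int64)
        else:
            ab = ab.astype(np.int64)
        if (ab < 0).any():
            i, j = np.argwhere(ab < 0)[0]
            raise ValidationError(
                f"negative abundance at species {self.species_ids[i]!r}, "
                f"fragment {self.fragment_ids[j]!r}"
            )
        self.abundance = ab
        _check_unique(self.species_ids, "species")
        _check_unique(self.fragment_ids, "fragment")
        empty = ab.sum(axis=1) == 0
        if empty.any():
            names = [s for s, e in zip(self.species_ids, empty) if e]
            if self.allow_empty_species:
                warnings.warn(f"keeping all-zero species rows: {names}", stacklevel=2)
            else:
                raise ValidationError(f"all-zero species rows: {names}")
        if self.guild is not None:
            self.guild = np.asarray(self.guild, dtype=object)
            if self.guild.shape != (len(self.species_ids),):
                raise ValidationError("guild must have one entry per species")
        if self.specialist is not None:
            self.specialist = np.asarray(self.specialist, dtype=bool)
            if self.specialist.shape != (len(self.species_ids),):
                raise ValidationError("specialist must have one entry per species")

    # -- basic accessors -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)

    @property
    def grand_total(self) -> int:
        """Total number of individuals (N)."""
        return int(self.abundance.sum())

    def row_totals(self) -> np.ndarray:
        return self.abundance.sum(axis=1)

    def column_totals(self) -> np.ndarray:
        return self.abundance.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=self.species_ids, columns=self.fragment_ids
        )

    def select_species(self, mask: np.ndarray) -> "CommunityMatrix":
        """Row-subset by boolean mask, keeping annotations aligned.

        Empty rows are expected in subsets and kept silently.
        """
        mask = np.asarray(mask, dtype=bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return self._subset(mask)

    def _subset(self, mask: np.ndarray) -> "CommunityMatrix":
        return CommunityMatrix(
            species_ids=[s for s, m in zip(self.species_ids, mask) if m],
            fragment_ids=list(self.fragment_ids),
            abundance=self.abundance[mask],
            guild=None if self.guild is None else self.guild[mask],
            specialist=None if self.specialist is None else self.specialist[mask],
            allow_empty_species=True,
        )

    def guild_subset(self, guild: str, specialists_only: bool = False) -> "CommunityMatrix":
        if self.guild is None:
            raise ValidationError("community matrix has no guild annotation")
        mask = self.guild == guild
        if specialists_only:
            if self.specialist is None:
                raise ValidationError("community matrix has no specialist annotation")
            mask = mask & self.specialist
        return self.select_species(mask)


@dataclass
class IncidenceMatrix:
    """Binary presence/absence pattern derived from a community matrix."""

    species_ids: list[str]
    fragment_ids: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        pr = np.asarray(self.presence)
        if not np.isin(pr, (0, 1)).all():
            raise ValidationError("incidence cells must be 0 or 1")
        self.presence = pr.astype(np.int8)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)

    def row_totals(self) -> np.ndarray:
        """Occurrence totals r_i per species."""
        return self.presence.sum(axis=1)

    def drop_empty_species(self) -> "IncidenceMatrix":
        keep = self.presence.sum(axis=1) > 0
        return IncidenceMatrix(
            [s for s, k in zip(self.species_ids, keep) if k],
            list(self.fragment_ids),
            self.presence[keep],
        )


@dataclass
class FragmentTable:
    """Fragment metadata: area (ha), perimeter, isolation (PPI), % cover.

    The ``group`` column partitions fragments into "large" and "small" by
    an area threshold (default 90 ha).
    """

    table: pd.DataFrame
    area_threshold: float = LARGE_AREA_THRESHOLD_HA

    def __post_init__(self) -> None:
        t = self.table
        required = {"fragment_id", "area", "perimeter", "isolation", "cover"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"fragment table missing columns: {sorted(missing)}")
        _check_unique(t["fragment_id"].tolist(), "fragment")
        if (t["area"] <= 0).any():
            raise ValidationError("fragment areas must be positive")
        if ((t["cover"] < 0) | (t["cover"] > 100)).any():
            raise ValidationError("cover must be a percentage in [0, 100]")
        if "group" not in t.columns:
            t = t.copy()
            t["group"] = np.where(t["area"] >= self.area_threshold, "large", "small")
        else:
            expected = np.where(t["area"] >= self.area_threshold, "large", "small")
            if not (t["group"].to_numpy() == expected).all():
                raise ValidationError(
                    "group column inconsistent with area threshold "
                    f"{self.area_threshold} ha"
                )
        self.table = t.reset_index(drop=True)

    def group_of(self) -> pd.Series:
        return self.table.set_index("fragment_id")["group"]

    def fragments_in(self, group: str) -> list[str]:
        t = self.table
        return t.loc[t["group"] == group, "fragment_id"].tolist()


@dataclass
class TraitTable:
    """Per-species trait measurements, one row per species.

    Raw columns are morphometrics (body mass, bill culmen length/depth/
    width, tarsus, tail, wing, hand-wing index) plus categorical diet and
    foraging-stratum scores.  Reduced single-axis traits (bill_pc,
    locomotion_pc, diet_pc, stratum_pc, body_size, dispersal) are added by
    the trait-reduction step in :mod:`fragcomm.functional_diversity`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "species_id" not in self.table.columns:
            raise ValidationError("trait table needs a species_id column")
        _check_unique(self.table["species_id"].tolist(), "species")
        self.table = self.table.reset_index(drop=True)

    @property
    def species_ids(self) -> list[str]:
        return self.table["species_id"].tolist()

    def columns(self) -> list[str]:
        return [c for c in self.table.columns if c != "species_id"]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read CSV/TSV with auto-detected delimiter, first column as labels."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return df


def read_community_matrix(
    path: str | Path,
    orientation: Literal["rows=species", "rows=fragments"] = "rows=species",
    allow_empty_species: bool = True,
) -> CommunityMatrix:
    """Read a species x fragments abundance matrix from delimited text.

    ``orientation`` states what the file's rows are; the returned object is
    always species x fragments.  Files may legitimately contain species
    recorded nowhere (e.g. group submatrices), so all-zero rows are kept
    with a warning by default; pass ``allow_empty_species=False`` to
    enforce the strict invariant.
    """
    df = _read_delimited(path)
    bad = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation == "rows=fragments":
        df = df.T
    elif orientation != "rows=species":
        raise ValueError(f"unknown orientation {orientation!r}")
    return CommunityMatrix(
        species_ids=[str(i) for i in df.index],
        fragment_ids=[str(c) for c in df.columns],
        abundance=df.to_numpy(),
        allow_empty_species=allow_empty_species,
    )


def write_community_matrix(m: CommunityMatrix, path: str | Path) -> None:
    m.to_dataframe().to_csv(path, index_label="species_id")


def read_trait_table(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep=None, engine="python")
    if "species_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "species_id"})
    return TraitTable(df)


def read_fragment_table(path: str | Path, area_threshold: float = LARGE_AREA_THRESHOLD_HA) -> FragmentTable:
    df = pd.read_csv(path, sep=None, engine="python")
    return FragmentTable(df, area_threshold=area_threshold)


def load_taita_fragments() -> FragmentTable:
    """Fragment metadata of the 12 Taita Hills cloud-forest fragments.

    Columns mirror the published survey table: area (ha), perimeter,
    isolation (patch proximity index), % closed-canopy forest cover within
    800 m, total species richness, forest-specialist richness, and total
    individuals captured.
    """
    with resources.files("fragcomm").joinpath("data/taita_fragments.csv").open() as fh:
        df = pd.read_csv(fh)
    return FragmentTable(df)


# ---------------------------------------------------------------------------
# Derivations
# ---------------------------------------------------------------------------

def to_incidence(m: CommunityMatrix | IncidenceMatrix) -> IncidenceMatrix:
    """Presence/absence pattern: cell = 1 iff abundance > 0 (idempotent)."""
    if isinstance(m, IncidenceMatrix):
        return IncidenceMatrix(list(m.species_ids), list(m.fragment_ids), m.presence.copy())
    return IncidenceMatrix(
        list(m.species_ids), list(m.fragment_ids), (m.abundance > 0).astype(np.int8)
    )


def relative_abundances(
    m: CommunityMatrix, scope: Literal["per-fragment", "pooled"] = "per-fragment"
) -> np.ndarray:
    """Relative abundances, per fragment (columns sum to 1) or pooled.

    Raises on a zero-total fragment in per-fragment scope.
    """
    if scope == "pooled":
        n = m.grand_total
        if n == 0:
            raise ValidationError("zero grand total")
        return m.row_totals() / n
    if scope != "per-fragment":
        raise ValueError(f"unknown scope {scope!r}")
    totals = m.column_totals()
    if (totals == 0).any():
        empty = [f for f, t in zip(m.fragment_ids, totals) if t == 0]
        raise ValidationError(f"zero-total fragments: {empty}")
    return m.abundance / totals


def split_groups(
    m: CommunityMatrix, fragments: FragmentTable
) -> tuple[CommunityMatrix, CommunityMatrix]:
    """Partition fragment columns into (large, small) group submatrices.

    Species rows are retained in both submatrices, so all-zero rows may
    appear (flagged by a warning); this keeps the species universe aligned
    between groups.
    """
    groups = fragments.group_of()
    unknown = [f for f in m.fragment_ids if f not in groups.index]
    if unknown:
        raise ValidationError(f"fragments not in metadata table: {unknown}")

    def _take(which: str) -> CommunityMatrix:
        cols = [i for i, f in enumerate(m.fragment_ids) if groups[f] == which]
        if not cols:
            warnings.warn(f"no fragments in group {which!r}", stacklevel=3)
        with warnings.catch_warnings():
            # zero rows in group submatrices are expected, not reportable
            warnings.simplefilter("ignore")
            return CommunityMatrix(
                species_ids=list(m.species_ids),
                fragment_ids=[m.fragment_ids[i] for i in cols],
                abundance=m.abundance[:, cols],
                guild=m.guild,
                specialist=m.specialist,
                allow_empty_species=True,
            )

    return _take("large"), _take("small")
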