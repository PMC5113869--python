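"""End-to-end analysis: from community matrix + traits + fragment metadata
to machine-readable twins of the published result tables.

One :func:`run_full_analysis` call executes, in order: the large/small
fragment-group split, per-guild co-occurrence null-model tests (C-score,
NODF, beta_P; all-species and forest-specialist tracks), per-guild
competition fits (r_C), FAD records with trait-reshuffling SES plus the
FAD general linear model, and the scaling fits and correlations.  All
stochastic stages derive their generators deterministically from one root
seed keyed by stage name, so re-running an identical config reproduces
every number bit-for-bit regardless of which stages are enabled.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .competition import CompetitionInfeasibleError, fit_competition
from .cooccurrence import METRICS, MetricUndefinedError
from .core_data import (
    CommunityMatrix,
    FragmentTable,
    TraitTable,
    ValidationError,
    split_groups,
)
from .functional_diversity import FAD_TRAITS, GLMResult, fad_glm, fad_records
from .null_engine import bonferroni, null_distribution, ses
from .scaling import (
    DEFAULT_SAR_EXPONENT,
    log_fit,
    pearson_test,
    power_fit,
    species_density,
)

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis"]


@dataclass
class RunConfig:
    """Knobs of one full analysis run.

    ``iterations`` is the null-ensemble size per test (1000 matches the
    published analysis); ``candidates`` the competition search size
    (100,000); ``alpha`` the two-sided error level before Bonferroni
    correction.  The Bonferroni family is all metric x guild x group x
    track tests of the run.
    """

    seed: int = 0
    iterations: int = 1000
    candidates: int = 100_000
    alpha: float = 0.05
    area_threshold: float = 90.0
    sar_exponent: float = DEFAULT_SAR_EXPONENT
    run_cooccurrence: bool = True
    run_competition: bool = True
    run_fad: bool = True
    run_scaling: bool = True
    fad_traits: list[str] = field(default_factory=lambda: list(FAD_TRAITS))
    min_species_per_fragment: int = 3

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.candidates < 1:
            raise ValidationError("iterations and candidates must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    def stage_rng(self, name: str) -> np.random.Generator:
        """Deterministic per-stage generator keyed by stage name.

        Keying by name (not call order) keeps results identical when
        stages are toggled on or off.
        """
        key = zlib.crc32(name.encode())
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))
        )


@dataclass
class ReportBundle:
    fragment_summary: pd.DataFrame
    cooccurrence: pd.DataFrame | None
    competition: pd.DataFrame | None
    fad: pd.DataFrame | None
    fad_glm_raw: GLMResult | None
    fad_glm_ses: GLMResult | None
    scaling_fits: pd.DataFrame | None
    correlations: pd.DataFrame | None
    densities: pd.DataFrame | None
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.fragment_summary.to_csv(out / "fragment_summary.csv", index=False)
        named = {
            "cooccurrence.csv": self.cooccurrence,
            "competition.csv": self.competition,
            "fad_records.csv": self.fad,
            "scaling_fits.csv": self.scaling_fits,
            "correlations.csv": self.correlations,
            "species_density.csv": self.densities,
        }
        for fname, df in named.items():
            if df is not None:
                df.to_csv(out / fname, index=False)
        glm_rows = []
        for label, g in (("fad", self.fad_glm_raw), ("ses_fad", self.fad_glm_ses)):
            if g is None:
                continue
            for term, (df_t, eta2) in g.terms.items():
                glm_rows.append(
                    {"response": label, "term": term, "df": df_t, "partial_eta2": eta2}
                )
            glm_rows.append(
                {"response": label, "term": "error", "df": g.error_df, "partial_eta2": ""}
            )
            glm_rows.append(
                {"response": label, "term": "r2_model", "df": "", "partial_eta2": g.r_squared}
            )
        if glm_rows:
            pd.DataFrame(glm_rows).to_csv(out / "fad_glm.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _cooccurrence_stage(
    groups: dict[str, CommunityMatrix], cfg: RunConfig
) -> pd.DataFrame:
    rows = []
    for track in ("all", "specialists"):
        for group_name, gm in groups.items():
            guild_names = list(pd.unique(gm.guild)) if gm.guild is not None else [None]
            for guild in guild_names:
                sub = gm.guild_subset(guild, specialists_only=(track == "specialists"))
                for metric in METRICS:
                    stage = f"cooc/{track}/{group_name}/{guild}/{metric}"
                    base = {
                        "track": track,
                        "group": group_name,
                        "guild": guild,
                        "metric": metric,
                        "iterations": cfg.iterations,
                        "null_model": "proportional_abundance",
                    }
                    occupied = int(((sub.abundance.sum(axis=1)) > 0).sum())
                    if occupied < 2 or sub.grand_total == 0:
                        rows.append(
                            {**base, "status": f"skipped: insufficient species ({occupied})"}
                        )
                        continue
                    try:
                        ens = null_distribution(
                            sub, metric, iterations=cfg.iterations,
                            rng=cfg.stage_rng(stage),
                        )
                    except MetricUndefinedError as err:
                        rows.append({**base, "status": f"skipped: {err}"})
                        continue
                    r = ses(ens, alpha=cfg.alpha)
                    rows.append(
                        {
                            **base,
                            "status": "ok",
                            "n_species": occupied,
                            "observed": ens.observed,
                            "mean_null": ens.mean,
                            "sd_null": ens.sd,
                            "ses": r.ses,
                            "p": r.p_two_sided,
                            "n_redraws": ens.n_redraws,
                        }
                    )
    df = pd.DataFrame(rows)
    ok = df["status"] == "ok"
    if ok.any():
        flags = bonferroni(df.loc[ok, "p"].tolist(), alpha=cfg.alpha)
        df.loc[ok, "significant_bonferroni"] = pd.Series(flags, index=df.index[ok])
        df["bonferroni_family_size"] = int(ok.sum())
    return df


def _competition_stage(
    groups: dict[str, CommunityMatrix], cfg: RunConfig
) -> pd.DataFrame:
    rows = []
    for track in ("all", "specialists"):
        for group_name, gm in groups.items():
            for guild in pd.unique(gm.guild):
                stage = f"compete/{track}/{group_name}/{guild}"
                base = {
                    "track": track,
                    "group": group_name,
                    "guild": guild,
                    "n_candidates": cfg.candidates,
                }
                try:
                    fit = fit_competition(
                        gm,
                        guild=guild,
                        specialists_only=(track == "specialists"),
                        n_candidates=cfg.candidates,
                        rng=cfg.stage_rng(stage),
                        min_species_per_fragment=cfg.min_species_per_fragment,
                    )
                except (CompetitionInfeasibleError, ValidationError) as err:
                    rows.append({**base, "status": f"skipped: {err}"})
                    continue
                rows.append(
                    {
                        **base,
                        "status": "ok",
                        "n_species": len(fit.species_ids),
                        "n_fragments_used": len(fit.fragments_used),
                        "r_c": fit.r_c,
                    }
                )
    return pd.DataFrame(rows)


def run_full_analysis(
    comm: CommunityMatrix,
    traits: TraitTable | None,
    fragments: FragmentTable,
    cfg: RunConfig,
) -> ReportBundle:
    """Execute the configured stages and collect their result tables.

    ``traits`` must already be reduced (single-axis columns); pass None to
    skip the FAD stage.  Any stage failure raises with a stage-named
    diagnostic; partial bundles are never returned silently.
    """
    t0 = time.perf_counter()
    manifest: dict = {
        "seed": cfg.seed,
        "iterations": cfg.iterations,
        "candidates": cfg.candidates,
        "alpha": cfg.alpha,
        "area_threshold_ha": cfg.area_threshold,
        "package_version": __version__,
        "stages": {},
    }

    large, small = split_groups(comm, fragments)
    groups = {"large": large, "small": small}
    ftab = fragments.table
    summary = ftab.copy()
    col_totals = dict(zip(comm.fragment_ids, comm.column_totals()))
    richness = dict(zip(comm.fragment_ids, (comm.abundance > 0).sum(axis=1)))
    summary["observed_individuals"] = summary["fragment_id"].map(col_totals)
    summary["observed_richness"] = summary["fragment_id"].map(richness)

    def _clock(name: str, start: float) -> None:
        manifest["stages"][name] = round(time.perf_counter() - start, 3)

    cooc = compet = fadrec = scal = corr = dens = None
    glm_raw = glm_ses = None

    if cfg.run_cooccurrence:
        s = time.perf_counter()
        try:
            cooc = _cooccurrence_stage(groups, cfg)
        except Exception as err:
            raise RuntimeError(f"co-occurrence stage failed: {err}") from err
        _clock("cooccurrence", s)

    if cfg.run_competition:
        s = time.perf_counter()
        try:
            compet = _competition_stage(groups, cfg)
        except Exception as err:
            raise RuntimeError(f"competition stage failed: {err}") from err
        _clock("competition", s)

    if cfg.run_fad and traits is not None:
        s = time.perf_counter()
        try:
            fadrec = fad_records(
                comm, traits, fragments,
                trait_columns=cfg.fad_traits,
                iterations=cfg.iterations,
                rng=cfg.stage_rng("fad/records"),
            )
            glm_raw = fad_glm(fadrec, response="fad")
            glm_ses = fad_glm(fadrec, response="ses_fad")
        except Exception as err:
            raise RuntimeError(f"FAD stage failed: {err}") from err
        _clock("fad", s)

    if cfg.run_scaling:
        s = time.perf_counter()
        try:
            # printed survey columns take precedence; otherwise recompute
            # richness/abundance per fragment from the community matrix
            area = ftab["area"].to_numpy(float)
            if "richness" in ftab.columns:
                rich = ftab["richness"].to_numpy(float)
            else:
                rich = summary["observed_richness"].to_numpy(float)
            if "individuals" in ftab.columns:
                indiv = ftab["individuals"].to_numpy(float)
            else:
                indiv = summary["observed_individuals"].to_numpy(float)
            if "specialist_richness" in ftab.columns:
                spec = ftab["specialist_richness"].to_numpy(float)
            elif comm.specialist is not None:
                spec_rich = dict(
                    zip(
                        comm.fragment_ids,
                        (comm.abundance[comm.specialist] > 0).sum(axis=0),
                    )
                )
                spec = summary["fragment_id"].map(spec_rich).to_numpy(float)
            else:
                spec = None
            pf_a = power_fit(area, rich)
            pf_i = power_fit(indiv, rich)
            fit_rows = [
                {"fit": "richness_vs_area_power", "param1_name": "S0",
                 "param1": pf_a.s0, "param2_name": "z", "param2": pf_a.z,
                 "r2": pf_a.r_squared, "p": pf_a.p_slope, "n": pf_a.n},
                {"fit": "richness_vs_individuals_power", "param1_name": "S0",
                 "param1": pf_i.s0, "param2_name": "z", "param2": pf_i.z,
                 "r2": pf_i.r_squared, "p": pf_i.p_slope, "n": pf_i.n},
            ]
            tests = {
                "richness_vs_perimeter": (rich, ftab["perimeter"].to_numpy(float)),
                "richness_vs_isolation": (rich, ftab["isolation"].to_numpy(float)),
                "richness_vs_cover": (rich, ftab["cover"].to_numpy(float)),
            }
            if spec is not None:
                lf_a = log_fit(area, spec)
                lf_i = log_fit(indiv, spec)
                fit_rows += [
                    {"fit": "specialists_vs_ln_area", "param1_name": "slope",
                     "param1": lf_a.slope, "param2_name": "intercept",
                     "param2": lf_a.intercept, "r2": lf_a.r_squared,
                     "p": lf_a.p_slope, "n": lf_a.n},
                    {"fit": "specialists_vs_ln_individuals", "param1_name": "slope",
                     "param1": lf_i.slope, "param2_name": "intercept",
                     "param2": lf_i.intercept, "r2": lf_i.r_squared,
                     "p": lf_i.p_slope, "n": lf_i.n},
                ]
                tests["specialist_fraction_vs_ln_individuals"] = (
                    spec / rich, np.log(indiv)
                )
                tests["specialist_fraction_vs_area"] = (spec / rich, area)
            scal = pd.DataFrame(fit_rows)
            corr = pd.DataFrame(
                [
                    {"test": name, "r": r, "p": p, "n": len(x)}
                    for name, (x, y) in tests.items()
                    for r, p in [pearson_test(x, y)]
                ]
            )
            dens = pd.DataFrame(
                {
                    "fragment_id": ftab["fragment_id"],
                    "S": rich,
                    "A": area,
                    "z": cfg.sar_exponent,
                    "S_A": species_density(rich, area, cfg.sar_exponent),
                }
            )
        except KeyError as err:
            raise RuntimeError(
                f"scaling stage failed: fragment table missing column {err}"
            ) from err
        except Exception as err:
            raise RuntimeError(f"scaling stage failed: {err}") from err
        _clock("scaling", s)

    manifest["elapsed_s"] = round(time.perf_counter() - t0, 3)
    return ReportBundle(
        fragment_summary=summary,
        cooccurrence=cooc,
        competition=compet,
        fad=fadrec,
        fad_glm_raw=glm_raw,
        fad_glm_ses=glm_ses,
        scaling_fits=scal,
        correlations=corr,
        densities=dens,
        manifest=manifest,
    )
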