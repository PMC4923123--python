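"""End-to-end orchestration of the profile-overlap analysis.

``run_all`` sequences the stages — cohort screening and fitness estimation,
nested stratification, hemisphere combination and eTIV normalization,
per-region statistics, anatomical factor analysis, and profile-overlap
statistics — writing every intermediate as a plain delimited text file so
each stage can also be run standalone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .atlas import load_atlas
from .cohort import apply_screening, retained, summarize_groups
from .factors import (
    fit_pca, loading_report, score_regression, scree_table, select_components,
    varimax_rotate,
)
from .overlap import profile_overlap
from .regional import cohen_d_profiles, roi_correlations, roi_partial_betas
from .simulate import (
    SyntheticSpec, generate_cohort, generate_reference_volumes, generate_volumes,
)
from .stratify import stratify
from .volumes import adjust_volume, analysis_volumes, combine_hemispheres

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Choices that shape a pipeline run; serialized with the outputs."""

    out_dir: str = "results/run"
    seed: int = 0
    n: int = 54
    profile_overlap_rho: float = 0.08
    k_factors: int | None = 5
    profile_set: str = "default-48"     # or "all-52"
    interaction: str = "dichotomized"   # or "continuous"
    df_convention: str = "n-1"          # or "n-k-1"
    include_reference: bool = True
    report_threshold: float = 0.3
    high_threshold: float = 0.5
    alpha: float = 0.05


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline on a synthetic cohort; return the results.

    Writes Table-1/2/3/4-style CSVs, the effect-profile CSVs, the overlap
    statistics JSON, Figure-3/4-style data tables, and a run log under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = load_atlas()
    spec = SyntheticSpec(
        n=config.n, seed=config.seed, profile_overlap_rho=config.profile_overlap_rho
    )

    current = {"stage": "setup"}

    def stage(name):
        current["stage"] = name
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        cohort = generate_cohort(spec)
        native, truth = generate_volumes(cohort, spec, atlas)
        reference = generate_reference_volumes(spec, truth, cohort, atlas)

        stage("fitness")
        cohort = apply_screening(cohort)
        cohort.to_csv(out / "cohort.csv", index=False)

        stage("stratify")
        design = stratify(cohort, interaction=config.interaction)
        design.to_csv(out / "design.csv", index=False)
        table1 = summarize_groups(cohort, design)
        table1.to_csv(out / "table1_group_summaries.csv")

        stage("normalize")
        native_all = pd.concat([native, reference])
        bilateral = combine_hemispheres(native_all, atlas)
        adjusted = adjust_volume(bilateral, include_reference=config.include_reference)
        adjusted.to_csv(out / "volumes_adjusted.csv")
        vols = analysis_volumes(adjusted)
        keep = [r for r in vols.index if r in set(retained(cohort)["id"])]
        vols = vols.loc[keep]

        stage("analyze")
        raw_r = roi_correlations(vols, design)
        betas = roi_partial_betas(vols, design, df_convention=config.df_convention)
        table2 = raw_r.join(betas.drop(columns="flagged"))
        table2.to_csv(out / "table2_roi_associations.csv")
        profile_regions = (
            atlas.profile_regions if config.profile_set == "default-48"
            else atlas.regions
        )
        age_prof, fit_prof = cohen_d_profiles(
            vols, design, profile_regions=profile_regions,
            df_convention=config.df_convention, alpha=config.alpha,
        )
        fig3 = pd.DataFrame(
            {"age_d": age_prof.effects, "fitness_d": fit_prof.effects}
        ).sort_values("age_d", ascending=False)
        fig3.to_csv(out / "figure3_effect_profiles.csv")

        stage("factors")
        pca = fit_pca(vols, region_set=atlas.regions)
        scree = scree_table(pca.eigenvalues)
        scree.to_csv(out / "scree.csv", index=False)
        k = select_components(pca.eigenvalues, k_override=config.k_factors)
        rotated = varimax_rotate(fit_pca(vols, region_set=atlas.regions, k=k))
        rotated.loadings.to_csv(out / "factor_loadings.csv")
        rotated.scores.to_csv(out / "factor_scores.csv")
        loading_report(
            rotated, config.report_threshold, config.high_threshold
        ).to_csv(out / "table3_loading_report.csv", index=False)
        table4 = score_regression(rotated, design)
        table4.to_csv(out / "table4_factor_associations.csv")

        stage("overlap")
        result = profile_overlap(age_prof, fit_prof)
        halves = result.halves
        region_half = {
            r: half for half in halves.index for r in halves.loc[half, "regions"]
        }
        fig4 = fig3.copy()
        fig4["half"] = [region_half[r] for r in fig4.index]
        fig4.to_csv(out / "figure4_scatter_data.csv")
        overlap_json = {
            "r": result.r, "df": result.df, "p": result.p,
            "icc": result.icc, "icc_p": result.icc_p,
            "halves": halves.drop(columns="regions").to_dict("index"),
            "n_regions": len(profile_regions),
        }
        (out / "overlap.json").write_text(json.dumps(overlap_json, indent=2))
    except Exception as exc:  # annotate which stage died
        raise RuntimeError(f"stage {current['stage']!r} failed: {exc}") from exc

    run_log = {
        "agefit_version": __version__,
        "config": dataclasses.asdict(config),
        "k_factors_used": int(k),
        "n_retained": int(len(vols)),
        "planted_overlap_corr": truth.overlap_corr,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return {
        "cohort": cohort, "design": design, "table1": table1, "table2": table2,
        "age_profile": age_prof, "fitness_profile": fit_prof,
        "factors": rotated, "table4": table4, "overlap": result,
        "truth": truth, "run_log": run_log,
    }
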