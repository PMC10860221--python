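"""Orchestration: run every stage in order and write the figure-level tables.

Stage order: MAG quality filtering -> HTGC detection -> engraftment-dependent
filtering -> phylum enrichment -> longitudinal models (normalized contig HGT
rates, retention) -> functional profiling. Each stage logs record counts in
and out, so every "number surviving a filter" is auditable, and re-running
with the same configuration is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from ._util import config_hash, percent
from . import detection, engraftment, enrichment, functional, longitudinal, mag_quality
from .data_model import Bundle, read_tables, write_results
from .synthetic import GroundTruth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    bundle_dir: str | None = None
    out_dir: str = "results"
    donor_scope: str = "sex_cohort"
    completeness_min: float = mag_quality.COMPLETENESS_MIN
    contamination_max: float = mag_quality.CONTAMINATION_MAX
    enrichment_count_mode: str = "species"
    retention_cpm_threshold: float = 0.0
    n_perm: int = 999
    seed: int = 0
    manual_phylum: dict[str, str] = field(default_factory=dict)

    def hash(self) -> str:
        return config_hash(asdict(self))


@dataclass
class RunResult:
    config: RunConfig
    bundle: Bundle
    analysable: pd.DataFrame
    gene_stats: mag_quality.GeneFilterStats
    htgc_sets: dict[str, detection.HtgcSet]
    frequencies: pd.DataFrame
    arm_comparison: dict[str, dict]
    specificity: dict[str, dict]
    events: pd.DataFrame
    engraftment_events: pd.DataFrame
    attribution: pd.DataFrame
    pair_matrix: pd.DataFrame
    enrichment_results: dict[str, enrichment.EnrichmentResult]
    background: pd.Series
    waafle_lmm: longitudinal.LmmResult | None
    retention_result: longitudinal.RetentionResult
    retention_model: longitudinal.LmmResult | None
    functional_classes: pd.DataFrame
    functional_tests: pd.DataFrame
    summary: dict[str, Any]


def run_all(config: RunConfig, bundle: Bundle | None = None) -> RunResult:
    if bundle is None:
        if config.bundle_dir is None:
            raise ValueError("either a bundle or config.bundle_dir is required")
        bundle = read_tables(config.bundle_dir)

    # stage 1: MAG quality
    hq = mag_quality.filter_high_quality(
        bundle.mags, config.completeness_min, config.contamination_max
    )
    logger.info("mag_quality: %d / %d MAGs high-quality", len(hq), len(bundle.mags))
    analysable, gene_stats = mag_quality.analysable_genes(bundle.genes, hq)

    # stage 2: HTGC detection
    index = detection.DetectionIndex(bundle, analysable)
    sets = detection.detect_all(index, donor_scope=config.donor_scope)  # type: ignore[arg-type]
    freq_rows = []
    for rid, s in sets.items():
        freq_rows.append(
            {
                "participant_id": rid,
                "arm": s.arm,
                "sex": s.sex,
                "n_htgcs": len(s.clusters),
                "n_events": len(s.events),
                "frequency": detection.htgc_frequency(s, index),
            }
        )
    frequencies = pd.DataFrame(freq_rows).sort_values("participant_id").reset_index(drop=True)
    arm_comparison = detection.compare_arms(frequencies)
    specificity = {sex: detection.classify_specificity(sets.values(), sex) for sex in ("female", "male")}
    events = detection.events_frame(sets.values())
    logger.info("detection: %d events across %d participants", len(events), len(sets))

    # stage 3: engraftment-dependent HGT
    eng_events = engraftment.filter_engraftment_dependent(events, bundle.engraftment)
    attribution = engraftment.donor_attribution(eng_events)
    species_phylum = bundle.species_phylum(config.manual_phylum)
    pair_matrix = engraftment.species_pair_matrix(eng_events, species_phylum)
    logger.info(
        "engraftment: %d of %d event rows engraftment-dependent",
        len(engraftment.distinct_events(eng_events)), len(events),
    )

    # stage 4: phylum enrichment
    sex_of = dict(zip(bundle.subjects["subject_id"], bundle.subjects["sex"]))
    background = enrichment.background_distribution(analysable, bundle)
    enrichment_results: dict[str, enrichment.EnrichmentResult] = {}
    for sex in ("female", "male"):
        try:
            table = enrichment.build_contingency(
                bundle.engraftment, eng_events, species_phylum, sex_of, sex,
                count_mode=config.enrichment_count_mode, background=background,
            )
            enrichment_results[sex] = enrichment.enrichment_test(table)
        except ValueError as exc:
            logger.warning("enrichment (%s) skipped: %s", sex, exc)

    # stage 5: longitudinal models
    waafle_lmm = None
    if len(bundle.waafle):
        norm = longitudinal.normalize_hgt_rate(bundle.waafle)
        data = norm.merge(bundle.samples, on="sample_id").merge(
            bundle.subjects, on="subject_id"
        )
        data = data[data["role"] == "recipient"]
        waafle_lmm = longitudinal.fit_lmm(data, longitudinal.WAAFLE_SPEC)

    distinct = engraftment.distinct_events(eng_events)
    retention_result = longitudinal.retention(
        distinct, bundle.abundance, bundle.samples, config.retention_cpm_threshold
    )
    retention_model = None
    if retention_result.series["recipient_id"].nunique() >= 2:
        retention_model = longitudinal.retention_lmm(retention_result.series)

    # stage 6: functional profiling
    clusters = sorted(set(distinct["cluster_id"]))
    classes = functional.classify_clusters(bundle.cog, clusters)
    functional_tests = functional.compare_timepoints(
        retention_result.series, classes, n_perm=config.n_perm, seed=config.seed
    )

    summary = _summarize(
        config, gene_stats, len(bundle.mags), len(hq), frequencies, arm_comparison,
        specificity, events, distinct, enrichment_results, background, waafle_lmm,
        retention_result, retention_model, classes, functional_tests,
    )
    return RunResult(
        config=config, bundle=bundle, analysable=analysable, gene_stats=gene_stats,
        htgc_sets=sets, frequencies=frequencies, arm_comparison=arm_comparison,
        specificity=specificity, events=events, engraftment_events=eng_events,
        attribution=attribution, pair_matrix=pair_matrix,
        enrichment_results=enrichment_results, background=background,
        waafle_lmm=waafle_lmm, retention_result=retention_result,
        retention_model=retention_model, functional_classes=classes,
        functional_tests=functional_tests, summary=summary,
    )


def _summarize(
    config, gene_stats, n_mags, n_hq, frequencies, arm_comparison, specificity,
    events, distinct, enrichment_results, background, waafle_lmm,
    retention_result, retention_model, classes, functional_tests,
) -> dict[str, Any]:
    summary: dict[str, Any] = {
        "n_mags": n_mags,
        "n_hq_mags": n_hq,
        "hq_mag_pct": percent(n_hq, n_mags) if n_mags else None,
        "n_genes_on_hq_mags": gene_stats.n_genes_on_hq_mags,
        "n_excluded_unclassified": gene_stats.n_excluded_unclassified,
        "excluded_unclassified_pct": gene_stats.excluded_unclassified_pct,
        "n_analysable_genes": gene_stats.n_analysable,
        "n_events_total": len(events.drop_duplicates(["recipient_id", "cluster_id", "recipient_gene_id"])),
        "n_engraftment_dependent_events": len(distinct),
        "wilcoxon": {k: v["p"] for k, v in arm_comparison.items()},
        "specificity_counts": {sex: d["counts"] for sex, d in specificity.items()},
        "median_frequency_pct": {
            arm: float(frequencies.loc[frequencies["arm"] == arm, "frequency"].median())
            for arm in ("FMT", "placebo")
        },
        "background_fractions": {k: float(v) for k, v in background.items()},
    }
    for sex, res in enrichment_results.items():
        bact = res.cells[
            (res.cells["phylum"] == "Bacteroidetes") & (res.cells["column"] == "engrafted_with_hgt")
        ]
        summary[f"enrichment_{sex}"] = {
            "chi2": res.chi2,
            "df": res.df,
            "p": res.p,
            "bacteroidetes_direction": bact["direction"].iloc[0] if len(bact) else None,
            "bacteroidetes_p_adj": float(bact["p_adj"].iloc[0]) if len(bact) else None,
        }
    if waafle_lmm is not None:
        summary["waafle_lmm"] = {
            row["term"]: {"estimate": row["estimate"], "ci_low": row["ci_low"],
                          "ci_high": row["ci_high"], "p": row["p"]}
            for _, row in waafle_lmm.params.iterrows()
        }
        summary["waafle_lmm_lrt_p"] = waafle_lmm.lrt_p_interactions
    summary["retention"] = retention_result.by_sex.to_dict(orient="records")
    if retention_model is not None:
        summary["retention_lmm"] = {
            row["term"]: {"estimate": row["estimate"], "p": row["p"]}
            for _, row in retention_model.params.iterrows()
        }
    summary["functional_class_counts"] = (
        classes.drop_duplicates(["cluster_id", "major_class"])
        .groupby("major_class").size().to_dict()
    )
    summary["permanova"] = functional_tests.to_dict(orient="records")
    return summary


def recovery_report(result: RunResult, truth: GroundTruth) -> dict[str, float]:
    """Sensitivity/specificity of detection and the engraftment filter
    against the simulator's planted ground truth."""
    detected = {
        (s.participant_id, c) for s in result.htgc_sets.values() for c in s.clusters
    }
    planted = truth.planted_pairs()
    wk6 = result.analysable.merge(result.bundle.samples, on="sample_id")
    wk6 = wk6[wk6["timepoint"] == "week6"]
    universe = set(zip(wk6["subject_id"], wk6["cluster_id"]))
    negatives = universe - planted
    tp = len(detected & planted)
    fp = len(detected - planted)
    sens = tp / len(planted) if planted else float("nan")
    spec = (len(negatives) - fp) / len(negatives) if negatives else float("nan")

    dep_truth = set(
        zip(truth.engraftment_dependent()["recipient_id"], truth.engraftment_dependent()["cluster_id"])
    )
    dep_found = set(
        zip(result.engraftment_events["recipient_id"], result.engraftment_events["cluster_id"])
    )
    dep_sens = len(dep_found & dep_truth) / len(dep_truth) if dep_truth else float("nan")
    dep_exact = float(dep_found == dep_truth)
    return {
        "detection_sensitivity": sens,
        "detection_specificity": spec,
        "n_planted": len(planted),
        "n_detected": len(detected),
        "engraftment_sensitivity": dep_sens,
        "engraftment_set_exact": dep_exact,
    }


def write_figure_tables(result: RunResult, out_dir: str | Path) -> None:
    """Write the deterministic figure-level tables plus run_summary.json."""
    cfg_hash = result.config.hash()
    norm = (
        longitudinal.normalize_hgt_rate(result.bundle.waafle)
        if len(result.bundle.waafle) else pd.DataFrame(columns=["sample_id", "normalized_hgt"])
    )
    fig1 = norm.merge(result.bundle.samples, on="sample_id", how="left").sort_values("sample_id")

    spec_rows = []
    for sex, d in result.specificity.items():
        for k, v in d["counts"].items():
            spec_rows.append({"sex": sex, "class": k, "n_htgcs": v})
    fig2 = pd.DataFrame(spec_rows)

    fig4_rows = []
    for sex, res in result.enrichment_results.items():
        cells = res.cells.copy()
        cells.insert(0, "sex", sex)
        cells["chi2"] = res.chi2
        cells["chi2_p"] = res.p
        fig4_rows.append(cells)
    fig4 = pd.concat(fig4_rows, ignore_index=True) if fig4_rows else pd.DataFrame()

    fig6 = result.functional_tests

    tables = {
        "fig1_normalized_rates": fig1,
        "fig2_specificity": fig2,
        "fig2_frequencies": result.frequencies,
        "fig3_attribution": result.attribution,
        "fig4_enrichment": fig4,
        "fig4_species_pairs": result.pair_matrix,
        "fig5_retention": result.retention_result.by_sex,
        "fig6_functions": fig6,
        "htgcs": result.events.sort_values(
            ["recipient_id", "cluster_id", "recipient_gene_id", "donor_id", "donor_sample_id"]
        ).reset_index(drop=True),
        "events_engraftment": result.engraftment_events.sort_values(
            ["recipient_id", "cluster_id", "recipient_gene_id", "engrafted_donor_id"]
        ).reset_index(drop=True),
    }
    write_results(tables, Path(out_dir), __version__, cfg_hash, summary=result.summary)
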