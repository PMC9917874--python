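"""End-to-end orchestration of the turnover analysis.

Stage order follows the analysis narrative: aggregate peptides → measurement
CV filter → noise model → time-coverage filter → kinetic fit → fit-CV
filter → abundance → cross-subject summaries → group comparisons → interval
bins and quadrants.  Every filter's in/kept/excluded counts are recorded in
a machine-readable manifest, and identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import abundance as ab
from . import cohort, io, kinetics
from . import noise as nz


@dataclass
class PipelineConfig:
    """All thresholds and settings of one analysis run."""

    input_table: str | None = None
    out_dir: str = "results/run"
    times_h: tuple = kinetics.DESIGN_TIMES
    ratio_orientation: str = "H/L"
    noise_source: str = "fixed"  # "fixed" or "fit"
    noise_alpha: float = nz.DEFAULT_ALPHA
    noise_beta: float = nz.DEFAULT_BETA
    bin_size: float = 0.05
    bin_min_count: int = 10
    max_measurement_cv: float = 50.0
    max_fit_cv: float = 50.0
    required_time: float = 24.0
    min_subjects: int = 2
    halflife_edges: tuple = cohort.HALFLIFE_EDGES
    abundance_edges: tuple = cohort.ABUNDANCE_EDGES
    quadrant_k_threshold: float | None = None
    quadrant_abundance_threshold: float | None = None
    exclude_proteins: tuple = ()
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory handles to every stage output plus the manifest."""

    protein_ratios: pd.DataFrame
    noise_model: nz.NoiseModel
    fits: pd.DataFrame
    reliable_fits: pd.DataFrame
    abundances: pd.DataFrame
    abundance_means: pd.DataFrame
    halflife_summary: pd.DataFrame
    abundance_summary: pd.DataFrame
    halflife_comparison: pd.DataFrame
    abundance_comparison: pd.DataFrame
    quadrants: pd.DataFrame
    steady_state: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(
    config: PipelineConfig, peptides: pd.DataFrame | None = None
) -> PipelineResult:
    """Run every stage and write tables + manifest under ``config.out_dir``.

    ``peptides`` may be passed directly (read-free ingestion of simulated
    cohorts); otherwise ``config.input_table`` is read.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.hash(),
        "config": asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    stage = "read"
    try:
        if peptides is None:
            if config.input_table is None:
                raise ValueError("no input table and no in-memory peptides")
            peptides, read_report = io.read_peptide_table(
                config.input_table,
                ratio_orientation=config.ratio_orientation,
                design_times=config.times_h,
            )
            manifest["stages"]["read"] = read_report.as_dict()
        else:
            manifest["stages"]["read"] = {"n_rows_kept": int(len(peptides))}
        if config.exclude_proteins:
            n0 = len(peptides)
            peptides = peptides[
                ~peptides["protein_id"].isin(config.exclude_proteins)
            ]
            manifest["stages"]["contaminant_exclusion"] = {
                "n_in": n0, "n_kept": int(len(peptides)),
                "n_excluded": n0 - int(len(peptides)),
            }

        stage = "aggregate"
        ratios = io.aggregate_protein_ratios(peptides)
        manifest["stages"]["aggregate"] = {
            "n_protein_measurements": int(len(ratios)),
            "n_proteins": int(ratios["protein_id"].nunique()),
        }

        stage = "measurement_cv_filter"
        ratios_cv, cv_report = io.filter_measurement_cv(
            ratios, config.max_measurement_cv
        )
        manifest["stages"]["measurement_cv_filter"] = cv_report.as_dict()

        stage = "noise_model"
        if config.noise_source == "fit":
            bins = nz.bin_ratios(
                ratios_cv, config.bin_size, config.bin_min_count
            )
            model, diag = nz.fit_noise_model(bins, config.bin_min_count)
            trend = nz.constant_model_diagnostic(bins)
            _write(bins, out / "noise_bins.tsv")
            manifest["stages"]["noise_model"] = {
                "alpha": model.alpha, "beta": model.beta,
                "source": "fitted", **diag, "trend": trend,
            }
        else:
            model = nz.NoiseModel(
                config.noise_alpha, config.noise_beta, source="fixed"
            )
            manifest["stages"]["noise_model"] = {
                "alpha": model.alpha, "beta": model.beta, "source": "fixed",
            }
        nz.save_noise_model(model, out / "noise_model.txt")

        stage = "time_coverage_filter"
        covered, cov_report = kinetics.filter_time_coverage(
            ratios_cv, config.required_time
        )
        manifest["stages"]["time_coverage_filter"] = cov_report.as_dict()

        stage = "kinetic_fit"
        fits = kinetics.fit_turnover(covered, model, config.max_fit_cv)
        manifest["stages"]["kinetic_fit"] = {
            "n_fits": int(len(fits)),
            "n_proteins": int(fits["protein_id"].nunique()),
        }

        stage = "fit_cv_filter"
        reliable, fit_summary = kinetics.filter_fit_cv(fits, config.max_fit_cv)
        manifest["stages"]["fit_cv_filter"] = fit_summary

        stage = "abundance"
        per_time = ab.compute_abundances(peptides)
        ab_means = ab.average_steady_state(per_time)
        ss_table, ss_summary = ab.steady_state_check(per_time, peptides)
        manifest["stages"]["abundance"] = {
            "n_protein_subject": int(len(ab_means)),
            "n_proteins": int(ab_means["protein_id"].nunique()),
            "steady_state": ss_summary,
        }

        stage = "summaries"
        hl_summary = cohort.summarize_protein(
            reliable, "half_life_h", config.min_subjects
        )
        k_summary = cohort.summarize_protein(reliable, "k", config.min_subjects)
        ab_summary = cohort.summarize_protein(
            ab_means, "mean_abundance", config.min_subjects
        )
        log2_summary = cohort.summarize_protein(
            ab_means.assign(log2=ab_means["log2_abundance"]),
            "log2", config.min_subjects,
        )
        manifest["stages"]["summaries"] = {
            "n_proteins_halflife": int(len(hl_summary)),
            "n_proteins_abundance": int(len(ab_summary)),
            "mean_halflife_h": float(hl_summary["mean"].mean())
            if len(hl_summary) else float("nan"),
        }

        stage = "comparisons"
        hl_cmp = cohort.compare_groups(
            reliable, "half_life_h", "half_life", config.min_subjects
        )
        ab_cmp = cohort.compare_groups(
            ab_means, "mean_abundance", "abundance", config.min_subjects
        )
        manifest["stages"]["comparisons"] = {
            "n_tested_halflife": int(hl_cmp["p_value"].notna().sum()),
            "n_tested_abundance": int(ab_cmp["p_value"].notna().sum()),
            "n_p05_halflife": int((hl_cmp["p_value"] <= 0.05).sum()),
            "n_p05_abundance": int((ab_cmp["p_value"] <= 0.05).sum()),
        }

        stage = "bins_quadrants"
        hl_binned, hl_counts = cohort.bin_by_halflife(
            hl_summary, config.halflife_edges
        )
        ab_for_bins = log2_summary.rename(columns={"mean": "mean_log2"})
        ab_binned, ab_counts = cohort.bin_by_abundance(
            ab_for_bins, config.abundance_edges
        )
        quad_table = k_summary.rename(columns={"mean": "mean_k"})[
            ["protein_id", "mean_k"]
        ].merge(
            ab_summary.rename(columns={"mean": "mean_abundance"})[
                ["protein_id", "mean_abundance"]
            ],
            on="protein_id", how="inner",
        )
        k_thr = (
            config.quadrant_k_threshold
            if config.quadrant_k_threshold is not None
            else float(quad_table["mean_k"].median())
        )
        a_thr = (
            config.quadrant_abundance_threshold
            if config.quadrant_abundance_threshold is not None
            else float(quad_table["mean_abundance"].median())
        )
        quadrants = cohort.quadrant_classify(quad_table, k_thr, a_thr)
        manifest["stages"]["bins_quadrants"] = {
            "quadrant_k_threshold": k_thr,
            "quadrant_abundance_threshold": a_thr,
            "quadrant_counts": quadrants["quadrant"]
            .value_counts().to_dict(),
        }
    except Exception as exc:  # record the failing stage, then re-raise
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise

    _write(ratios_cv, out / "protein_ratios.tsv")
    _write(fits, out / "turnover_fits.tsv")
    _write(reliable, out / "turnover_fits_reliable.tsv")
    _write(ab_means, out / "abundance.tsv")
    _write(hl_summary, out / "halflife_summary.tsv")
    _write(ab_summary, out / "abundance_summary.tsv")
    _write(hl_cmp, out / "halflife_comparison.tsv")
    _write(ab_cmp, out / "abundance_comparison.tsv")
    _write(hl_binned, out / "halflife_bins.tsv")
    _write(hl_counts, out / "halflife_bin_counts.tsv")
    _write(ab_binned, out / "abundance_bins.tsv")
    _write(ab_counts, out / "abundance_bin_counts.tsv")
    _write(quadrants, out / "quadrants.tsv")
    _write(ss_table, out / "steady_state_check.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return PipelineResult(
        protein_ratios=ratios_cv,
        noise_model=model,
        fits=fits,
        reliable_fits=reliable,
        abundances=per_time,
        abundance_means=ab_means,
        halflife_summary=hl_summary,
        abundance_summary=ab_summary,
        halflife_comparison=hl_cmp,
        abundance_comparison=ab_cmp,
        quadrants=quadrants,
        steady_state=ss_table,
        manifest=manifest,
    )
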