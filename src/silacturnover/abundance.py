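"""Intensity-based relative protein quantification.

Per LC-MS/MS run, the relative abundance of a protein is

    (sum of peak intensities of its observed peptides / number of observed
     peptides) / (total intensity sum of the run)

i.e. the mean peptide relative intensity: dimensionless, in arbitrary
units, and invariant to global rescaling of the run.  Peptide intensity is
the summed light+heavy signal, so abundance is label-independent.  Under
the steady-state premise the abundance is constant over the experiment, so
per-time values are averaged; the steady-state diagnostic checks that the
across-time variance of a protein's abundance does not exceed the
technical (across-peptide) variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_run_abundance(run_measurements: pd.DataFrame) -> pd.DataFrame:
    """Relative protein abundances within one LC-MS/MS run.

    ``run_measurements`` holds the peptide rows of a single run (peptide
    intensities already merged if the run was acquired in fractions).
    Proteins absent from the run are simply absent from the output.
    """
    total = float(run_measurements["intensity"].sum())
    if total <= 0:
        raise ValueError("total run intensity is zero; cannot normalise")
    g = run_measurements.groupby("protein_id")["intensity"]
    out = (g.sum() / g.size() / total).rename("abundance").reset_index()
    return out


def compute_abundances(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per (protein, subject, time) relative abundance across the cohort.

    All peptide rows of one subject at one time point (possibly several
    runs / gel fractions) are merged at the peptide level before the run
    formula is applied, with the merged total as the normaliser.
    Returns columns ``protein_id, subject_id, group, time_h, abundance,
    n_peptides``.
    """
    rows = []
    for (subject_id, time_h), sample in measurements.groupby(
        ["subject_id", "time_h"], sort=True
    ):
        merged = (
            sample.groupby(["protein_id", "group", "peptide_id"], sort=True)[
                "intensity"
            ]
            .sum()
            .reset_index()
        )
        total = float(merged["intensity"].sum())
        if total <= 0:
            raise ValueError(
                f"zero total intensity for subject {subject_id} at {time_h} h"
            )
        g = merged.groupby(["protein_id", "group"])["intensity"]
        ab = (g.sum() / g.size() / total).rename("abundance").reset_index()
        ab["n_peptides"] = g.size().to_numpy()
        ab.insert(1, "subject_id", subject_id)
        ab.insert(3, "time_h", time_h)
        rows.append(ab)
    return pd.concat(rows, ignore_index=True)


def average_steady_state(per_time: pd.DataFrame) -> pd.DataFrame:
    """Average per-time abundances under the steady-state hypothesis.

    One row per (protein, subject): arithmetic mean over the time points at
    which the protein was quantified, its log2, and the number of
    contributing time points.
    """
    keys = ["protein_id", "subject_id", "group"]
    agg = (
        per_time.groupby(keys, sort=True)["abundance"]
        .agg(mean_abundance="mean", n_times="size")
        .reset_index()
    )
    agg["log2_abundance"] = np.log2(agg["mean_abundance"])
    return agg


def steady_state_check(
    per_time: pd.DataFrame, measurements: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Compare temporal vs technical variance of protein abundance.

    Per protein: the temporal variance is the median across subjects of
    the within-subject sample variance of per-time abundances (subjects
    quantified at ≥ 2 time points); the technical variance is the median
    across samples (subject × time, ≥ 2 observed peptides) of the
    across-peptide variance of peptide relative intensities — the same
    scale the abundance is computed on.  Under steady state the temporal
    variance should be equal to or lower than the technical one for most
    proteins.
    """
    # per-peptide relative intensities per sample, merged over runs
    tech_rows = []
    for (subject_id, time_h), sample in measurements.groupby(
        ["subject_id", "time_h"], sort=True
    ):
        merged = (
            sample.groupby(["protein_id", "peptide_id"], sort=True)["intensity"]
            .sum()
            .reset_index()
        )
        total = float(merged["intensity"].sum())
        merged["rel"] = merged["intensity"] / total
        var = (
            merged.groupby("protein_id")["rel"]
            .agg(tech_var="var", n_pep="size")
            .reset_index()
        )
        var = var[var["n_pep"] >= 2]
        var["subject_id"] = subject_id
        var["time_h"] = time_h
        tech_rows.append(var)
    tech = pd.concat(tech_rows, ignore_index=True)
    tech_med = (
        tech.groupby("protein_id")["tech_var"]
        .median()
        .rename("technical_variance")
        .reset_index()
    )

    per_subject = (
        per_time.groupby(["protein_id", "subject_id"])["abundance"]
        .agg(temporal_variance="var", n_times="size")
        .reset_index()
    )
    per_subject = per_subject[per_subject["n_times"] >= 2]
    temporal = (
        per_subject.groupby("protein_id")["temporal_variance"]
        .agg(temporal_variance="median", n_subjects="size")
        .reset_index()
    )

    table = temporal.merge(tech_med, on="protein_id", how="inner")
    table["ratio"] = table["temporal_variance"] / table["technical_variance"]
    table["steady"] = table["temporal_variance"] <= table["technical_variance"]
    summary = {
        "n_proteins": int(len(table)),
        "frac_temporal_le_technical": float(table["steady"].mean())
        if len(table)
        else np.nan,
        "median_variance_ratio": float(table["ratio"].median())
        if len(table)
        else np.nan,
    }
    return table, summary
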