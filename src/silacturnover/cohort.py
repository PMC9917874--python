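"""Cross-subject summaries and two-group cohort statistics.

Per-protein values (half-life hours or relative abundance) estimated in
individual subjects are summarised across the cohort, compared between the
two groups (diabetic controls vs diabetic-nephropathic subjects) with an
unpaired two-tailed Student t-test gated by a Shapiro-Wilk normality flag,
and organised into half-life / abundance interval bins, four abundance ×
turnover quadrants, and a macromolecular-complex coherence analysis
against random same-size protein sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUP_A = "control_diabetic"
GROUP_B = "nephropathic"

#: Half-life interval edges (hours); bins are <20, [20,30), ..., [80,90), ≥90.
HALFLIFE_EDGES = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)

#: log2-abundance interval edges; bins are <5.0 ... ≥9.0.
ABUNDANCE_EDGES = (5.0, 6.0, 6.5, 7.0, 7.5, 8.0, 9.0)


def summarize_protein(
    values: pd.DataFrame, value_col: str, min_subjects: int = 2
) -> pd.DataFrame:
    """Per-protein mean/SD/count across subjects.

    ``values`` has one row per (protein, subject) with the per-subject
    estimate in ``value_col``; only reliable/valid estimates should enter.
    Proteins estimated in fewer than ``min_subjects`` subjects are dropped.
    """
    agg = (
        values.groupby("protein_id")[value_col]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
             n_subjects="size")
        .reset_index()
    )
    return agg[agg["n_subjects"] >= min_subjects].reset_index(drop=True)


def _signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of group means (B vs A) as a signed fold change.

    Ratios ≥ 1 are kept as-is; ratios < 1 are reported as the negative
    reciprocal, so the sign encodes direction (negative = lower in group B,
    the nephropathic group) and |FC| ≥ 1 always.
    """
    ratio = mean_b / mean_a
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


def compare_groups(
    values: pd.DataFrame,
    value_col: str,
    variable: str,
    min_subjects: int = 2,
    alpha_normality: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-group comparison of per-subject protein values.

    For every protein with ≥ ``min_subjects`` values in *each* group:
    pooled-variance unpaired two-tailed t-test (Welch behind a flag for
    sensitivity), Shapiro-Wilk normality flag on the pooled within-group
    residuals at ``alpha_normality`` (a failed flag does not block the
    test, it only marks it), Benjamini-Hochberg FDR across all tested
    proteins, and — for abundance — the signed fold change of group means.

    ``values`` columns: protein_id, subject_id, group, ``value_col``.
    """
    rows = []
    for protein_id, g in values.groupby("protein_id", sort=True):
        a = g.loc[g["group"] == GROUP_A, value_col].to_numpy(float)
        b = g.loc[g["group"] == GROUP_B, value_col].to_numpy(float)
        row = {
            "protein_id": protein_id,
            "variable": variable,
            "mean_a": a.mean() if len(a) else np.nan,
            "sd_a": a.std(ddof=1) if len(a) > 1 else np.nan,
            "n_a": len(a),
            "mean_b": b.mean() if len(b) else np.nan,
            "sd_b": b.std(ddof=1) if len(b) > 1 else np.nan,
            "n_b": len(b),
        }
        if len(a) < min_subjects or len(b) < min_subjects:
            row |= {
                "p_value": np.nan,
                "normality_ok": np.nan,
                "fold_change": np.nan,
                "skipped": "insufficient subjects",
            }
            rows.append(row)
            continue
        resid = np.concatenate([a - a.mean(), b - b.mean()])
        if len(np.unique(resid)) < 3:
            normality_ok = True  # degenerate residuals: SW undefined
        else:
            normality_ok = bool(stats.shapiro(resid).pvalue >= alpha_normality)
        pooled_sd = np.sqrt(
            (
                np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
            )
            / (len(a) + len(b) - 2)
        )
        if pooled_sd == 0.0:
            # zero pooled variance: p degenerates to 0 or 1
            p = 1.0 if a.mean() == b.mean() else np.finfo(float).tiny
            flag = "zero pooled variance" if a.mean() != b.mean() else ""
        else:
            p = float(
                stats.ttest_ind(a, b, equal_var=not welch).pvalue
            )
            flag = ""
        row |= {
            "p_value": p,
            "normality_ok": normality_ok,
            "fold_change": _signed_fold_change(row["mean_a"], row["mean_b"])
            if variable == "abundance"
            else np.nan,
            "skipped": flag,
        }
        rows.append(row)
    columns = [
        "protein_id", "variable", "mean_a", "sd_a", "n_a", "mean_b", "sd_b",
        "n_b", "p_value", "normality_ok", "fold_change", "skipped",
    ]
    out = pd.DataFrame(rows, columns=columns)
    tested = out["p_value"].notna()
    out["fdr_bh"] = np.nan
    if tested.any():
        out.loc[tested, "fdr_bh"] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def _interval_label(x: float, edges: tuple, fmt: str = "g") -> str:
    if x < edges[0]:
        return f"<{edges[0]:{fmt}}"
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo <= x < hi:
            return f"[{lo:{fmt}},{hi:{fmt}})"
    return f">={edges[-1]:{fmt}}"


def bin_by_halflife(
    summary: pd.DataFrame, edges: tuple = HALFLIFE_EDGES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign proteins to half-life intervals (hours, left-closed).

    Returns (labelled table, per-bin counts).  Non-positive half-lives are
    excluded with a flag.
    """
    df = summary.copy()
    ok = df["mean"] > 0
    df["halflife_bin"] = np.where(
        ok, [_interval_label(x, edges) for x in df["mean"]], "excluded_nonpositive"
    )
    order = (
        [f"<{edges[0]:g}"]
        + [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
        + [f">={edges[-1]:g}"]
    )
    counts = (
        df[ok]["halflife_bin"].value_counts().reindex(order, fill_value=0)
        .rename("n_proteins").rename_axis("halflife_bin").reset_index()
    )
    return df, counts


def bin_by_abundance(
    summary: pd.DataFrame, edges: tuple = ABUNDANCE_EDGES,
    value_col: str = "mean_log2",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign proteins to log2-abundance intervals (left-closed)."""
    df = summary.copy()
    df["abundance_bin"] = [_interval_label(x, edges) for x in df[value_col]]
    order = (
        [f"<{edges[0]:g}"]
        + [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
        + [f">={edges[-1]:g}"]
    )
    counts = (
        df["abundance_bin"].value_counts().reindex(order, fill_value=0)
        .rename("n_proteins").rename_axis("abundance_bin").reset_index()
    )
    return df, counts


def quadrant_classify(
    table: pd.DataFrame,
    k_threshold: float,
    abundance_threshold: float,
    k_col: str = "mean_k",
    abundance_col: str = "mean_abundance",
) -> pd.DataFrame:
    """Classify proteins into the four turnover × abundance quadrants.

    Values exactly at a threshold fall on the "high" side (closed upper
    rule).  Rows missing either coordinate are labelled ``unclassified``.
    Labels follow the conventional colour coding of such plots: low-k/high-A
    ("red", stable and abundant), high-k/high-A ("blue"), high-k/low-A
    ("green"), low-k/low-A ("pink").
    """
    df = table.copy()
    k = df[k_col].to_numpy(float)
    a = df[abundance_col].to_numpy(float)
    high_k = k >= k_threshold
    high_a = a >= abundance_threshold
    label = np.where(
        np.isnan(k) | np.isnan(a),
        "unclassified",
        np.where(
            high_k,
            np.where(high_a, "high-k/high-A", "high-k/low-A"),
            np.where(high_a, "low-k/high-A", "low-k/low-A"),
        ),
    )
    df["quadrant"] = label
    return df


def complex_vs_random(
    member_ids: list,
    halflife_summary: pd.DataFrame,
    n_populations: int = 10,
    seed: int = 0,
    min_members: int = 3,
) -> dict:
    """Half-life coherence of a macromolecular complex vs random sets.

    Subunits of one complex tend to share a turnover rate; to show a
    complex's low dispersion is not coincidental, its half-life spread is
    compared with ``n_populations`` random protein sets of the same size
    drawn without replacement from the same summary table.

    Returns the complex SD/IQR, the per-population dispersions, and the
    fraction of random populations with larger dispersion than the complex.
    """
    table = halflife_summary.set_index("protein_id")["mean"]
    missing = [m for m in member_ids if m not in table.index]
    found = [m for m in member_ids if m in table.index]
    if len(found) < min_members:
        raise ValueError(
            f"only {len(found)} complex members found (need ≥ {min_members}); "
            f"missing: {missing}"
        )
    members = table.loc[found].to_numpy(float)
    rng = np.random.default_rng(seed)
    pool = table.to_numpy(float)
    pops = []
    for i in range(n_populations):
        idx = rng.choice(len(pool), size=len(found), replace=False)
        vals = pool[idx]
        pops.append(
            {
                "population": i,
                "sd": float(np.std(vals, ddof=1)),
                "iqr": float(np.subtract(*np.percentile(vals, [75, 25]))),
            }
        )
    pops_df = pd.DataFrame(pops)
    complex_sd = float(np.std(members, ddof=1))
    complex_iqr = float(np.subtract(*np.percentile(members, [75, 25])))
    return {
        "n_members": len(found),
        "missing_members": missing,
        "complex_sd": complex_sd,
        "complex_iqr": complex_iqr,
        "populations": pops_df,
        "frac_random_sd_larger": float((pops_df["sd"] > complex_sd).mean()),
        "frac_random_iqr_larger": float((pops_df["iqr"] > complex_iqr).mean()),
    }
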