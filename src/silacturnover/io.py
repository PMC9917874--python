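"""Peptide-level quantification tables and protein-level aggregation.

The canonical in-memory containers are pandas DataFrames.  A *peptide table*
has one row per peptide observation (one peptide, one LC-MS/MS run) with
columns :data:`PEPTIDE_COLUMNS`; a *protein-ratio table* has one row per
(protein, subject, time point) with the protein-level H/L ratio ``r`` equal
to the median of the contributing peptide ratios, plus the across-peptide
sample SD and CV used by the technical-noise calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Required columns of the canonical peptide table, in canonical order.
PEPTIDE_COLUMNS = [
    "subject_id",
    "group",
    "time_h",
    "protein_id",
    "peptide_id",
    "ratio_hl",
    "intensity",
    "run_id",
]

#: Recognised cohort group labels.
GROUPS = ("control_diabetic", "nephropathic")


class TableFormatError(ValueError):
    """A required column is missing or the table cannot be interpreted."""


class TableValidationError(ValueError):
    """A row violates a data-model invariant (e.g. negative ratio)."""


@dataclass
class ReadReport:
    """Bookkeeping for :func:`read_peptide_table`."""

    n_rows_in: int = 0
    n_rows_kept: int = 0
    n_dropped_missing_ratio: int = 0
    n_dropped_duplicate: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FilterReport:
    """Counts of retained/excluded entries for one filtering stage."""

    stage: str
    n_in: int
    n_kept: int
    n_excluded: int
    per_stratum: pd.DataFrame = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_in": int(self.n_in),
            "n_kept": int(self.n_kept),
            "n_excluded": int(self.n_excluded),
        }


def read_peptide_table(
    path,
    sep: str = "\t",
    column_map: dict | None = None,
    ratio_orientation: str = "H/L",
    design_times: tuple = (4.0, 7.5, 24.0),
    strict_unique_peptides: bool = False,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a delimited peptide quantification export.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    sep
        Field separator; tab for the canonical dialect.
    column_map
        Optional mapping from canonical column names to the names used in
        the file, for vendor exports with different headers.
    ratio_orientation
        ``"H/L"`` (canonical) or ``"L/H"``; the latter inverts ratios on
        load so the in-memory table is always heavy-over-light.
    design_times
        Allowed time points (hours); rows at other times are rejected.
    strict_unique_peptides
        Drop peptide identifiers mapped to more than one protein (shared
        peptides), when protein grouping upstream did not enforce this.

    Returns
    -------
    (DataFrame, ReadReport)
        Validated table in canonical column order, and drop counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "run_id": str})
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in PEPTIDE_COLUMNS if c not in raw.columns]
    if missing:
        raise TableFormatError(
            f"missing required column(s): {', '.join(missing)}"
        )
    df = raw[PEPTIDE_COLUMNS].copy()
    report = ReadReport(n_rows_in=len(df))

    df["ratio_hl"] = pd.to_numeric(df["ratio_hl"], errors="coerce")
    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
    df["time_h"] = pd.to_numeric(df["time_h"], errors="coerce")

    # Undetectable ratios (no heavy signal yet) are missing, not zero.
    missing_ratio = df["ratio_hl"].isna()
    report.n_dropped_missing_ratio = int(missing_ratio.sum())
    df = df[~missing_ratio]

    bad = df.index[(df["ratio_hl"] < 0) | (df["intensity"] < 0)]
    if len(bad):
        raise TableValidationError(
            f"negative ratio or intensity at row(s) {list(bad[:5])}"
        )
    bad_time = df.index[~df["time_h"].isin(design_times)]
    if len(bad_time):
        raise TableValidationError(
            f"time_h outside design times {design_times} at row(s) "
            f"{list(bad_time[:5])}"
        )
    unknown = set(df["group"].unique()) - set(GROUPS)
    if unknown:
        raise TableValidationError(f"unknown group label(s): {sorted(unknown)}")

    if ratio_orientation == "L/H":
        with np.errstate(divide="ignore"):
            df["ratio_hl"] = np.where(
                df["ratio_hl"] > 0, 1.0 / df["ratio_hl"], np.nan
            )
        n_inv = int(df["ratio_hl"].isna().sum())
        report.n_dropped_missing_ratio += n_inv
        df = df.dropna(subset=["ratio_hl"])
    elif ratio_orientation != "H/L":
        raise TableFormatError(
            f"ratio_orientation must be 'H/L' or 'L/H', got {ratio_orientation!r}"
        )

    key = ["subject_id", "time_h", "run_id", "peptide_id"]
    dup = df.duplicated(subset=key, keep="first")
    report.n_dropped_duplicate = int(dup.sum())
    df = df[~dup]

    if strict_unique_peptides:
        n_prot = df.groupby("peptide_id")["protein_id"].transform("nunique")
        df = df[n_prot == 1]

    report.n_rows_kept = len(df)
    return df.reset_index(drop=True), report


def write_peptide_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a peptide table in the canonical dialect (round-trip safe)."""
    df.to_csv(path, sep=sep, index=False, columns=PEPTIDE_COLUMNS)


def aggregate_protein_ratios(measurements: pd.DataFrame) -> pd.DataFrame:
    """Aggregate peptide ratios to protein-level H/L ratios.

    Per (protein, subject, time point), the protein ratio ``r`` is the
    median of the contributing peptide ratios — robust to single outlying
    peptides — and ``sd_peptides`` / ``cv_peptides`` are the sample SD
    (n−1 denominator) and percent CV over the same peptide set, treating
    the peptides as replicate measurements of the protein.  Single-peptide
    observations carry SD = CV = 0 and are flagged ``single_peptide``.
    """
    if measurements is None or len(measurements) == 0:
        raise ValueError("no peptide measurements to aggregate")

    def _agg(g: pd.Series) -> pd.Series:
        vals = g.to_numpy(dtype=float)
        n = vals.size
        med = float(np.median(vals))
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        mean = float(vals.mean())
        if n == 1:
            cv = 0.0  # single peptide: no disagreement to measure
        elif mean == 0.0:
            cv = np.nan  # undefined: flagged downstream
        else:
            cv = 100.0 * sd / mean
        return pd.Series(
            {"r": med, "n_peptides": n, "sd_peptides": sd, "cv_peptides": cv}
        )

    keys = ["protein_id", "subject_id", "group", "time_h"]
    out = (
        measurements.groupby(keys, sort=True)["ratio_hl"]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    out["n_peptides"] = out["n_peptides"].astype(int)
    out["single_peptide"] = out["n_peptides"] == 1
    return out


def filter_measurement_cv(
    protein_ratios: pd.DataFrame, max_cv_pct: float = 50.0
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop protein measurements whose across-peptide CV exceeds the cap.

    The cap is a strict inequality: CV exactly at ``max_cv_pct`` is
    retained.  Single-peptide entries (CV = 0) pass; entries with an
    undefined CV (zero peptide mean) are excluded.
    """
    cv = protein_ratios["cv_peptides"]
    keep = ~((cv > max_cv_pct) | cv.isna())
    excluded = protein_ratios[~keep]
    per_stratum = (
        excluded.groupby(["subject_id", "time_h"])
        .size()
        .rename("n_excluded")
        .reset_index()
    )
    report = FilterReport(
        stage="measurement_cv",
        n_in=len(protein_ratios),
        n_kept=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        per_stratum=per_stratum,
    )
    return protein_ratios[keep].reset_index(drop=True), report
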