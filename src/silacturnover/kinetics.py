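"""Kinetic fitting of protein degradation rate constants.

Under steady state (constant total pool, constant synthesis, no label
recycling, one compartment), the pre-existing light pool decays as
``P_L = P_TOT·exp(−kt)`` and the heavy pool grows as its complement, so the
heavy/light ratio follows ``r(t) = exp(kt) − 1`` and

    ln(r + 1) = k·t

is a straight line through the origin.  ``k`` is estimated per protein per
subject by weighted least squares on y = ln(r+1) with weights equal to the
inverse variance of y obtained from the ratio noise model by the delta
method: Var[y] = SD(r)² / (1+r)².  The half-life is T½ = ln2/k.

The fit has no intercept: y(0) = 0 is forced by the model, and an intercept
would absorb label-incorporation lag that the one-compartment model
excludes.  The standard error of k uses the a-priori weights
(se = sqrt(1/Σ w t²)) rather than residual rescaling, which is unstable
with only 2–3 time points; residual (reduced-chi-square) rescaling is
available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FilterReport
from .noise import NoiseModel

LN2 = float(np.log(2.0))

#: Experimental-design sampling times (hours after the light→heavy switch).
DESIGN_TIMES = (4.0, 7.5, 24.0)


def half_life(k: float) -> float:
    """Half-life T½ = ln2/k in hours, for k > 0 (per hour)."""
    if not k > 0:
        raise ValueError(f"half-life requires k > 0, got {k}")
    return LN2 / k


def filter_time_coverage(
    protein_ratios: pd.DataFrame,
    required_time: float = 24.0,
    min_other: int = 1,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep (protein, subject) series quantified at 24 h plus ≥1 other time.

    The latest time point anchors the fit — for slowly turning-over
    proteins the ratio is still close to 0 at early times — so series
    without it (or with it alone) are excluded.
    """
    keys = ["protein_id", "subject_id"]

    def _ok(times: pd.Series) -> bool:
        t = set(times)
        return (required_time in t) and (len(t - {required_time}) >= min_other)

    ok = protein_ratios.groupby(keys)["time_h"].transform(
        lambda s: _ok(s)
    )
    kept = protein_ratios[ok].reset_index(drop=True)
    n_series = protein_ratios.groupby(keys).ngroups
    n_series_kept = kept.groupby(keys).ngroups if len(kept) else 0
    report = FilterReport(
        stage="time_coverage",
        n_in=n_series,
        n_kept=n_series_kept,
        n_excluded=n_series - n_series_kept,
    )
    return kept, report


def kinetic_points(
    times_h: np.ndarray, ratios: np.ndarray, noise_model: NoiseModel
) -> pd.DataFrame:
    """Transform ratio observations into weighted regression points.

    y = ln(r+1); weight = (1+r)²/SD(r)², the delta-method inverse variance
    of y given the ratio noise model.
    """
    t = np.asarray(times_h, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if np.any(r < 0):
        raise ValueError("ratios must be non-negative")
    sd = np.asarray(noise_model.predict_sd(r), dtype=float)
    y = np.log1p(r)
    weight = (1.0 + r) ** 2 / sd**2
    return pd.DataFrame({"time_h": t, "r": r, "y": y, "weight": weight})


def fit_k_wls(
    points: pd.DataFrame,
    max_cv_pct: float = 50.0,
    rescale_se: bool = False,
) -> dict:
    """Weighted least-squares estimate of k from regression points.

    Through-the-origin WLS has the closed form

        k̂  = Σ wᵢ tᵢ yᵢ / Σ wᵢ tᵢ²
        se = sqrt(1 / Σ wᵢ tᵢ²)

    with absolute (inverse-variance) weights.  ``cv_k = 100·se/|k̂|`` is
    the precision metric: fits with cv_k ≤ ``max_cv_pct`` are ``reliable``.
    Negative k̂ (possible under noise for very slow proteins) is marked
    invalid and carries no half-life.
    """
    t = points["time_h"].to_numpy(float)
    y = points["y"].to_numpy(float)
    w = points["weight"].to_numpy(float)
    if len(t) == 0:
        raise ValueError("no points to fit")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        bad = np.where(~np.isfinite(w) | (w <= 0))[0]
        raise ValueError(f"non-finite or non-positive weight at point(s) {list(bad)}")
    swt2 = float(np.sum(w * t**2))
    if swt2 == 0.0:
        raise ValueError("all time points are zero; k is not identifiable")
    k = float(np.sum(w * t * y) / swt2)
    se = float(np.sqrt(1.0 / swt2))
    if rescale_se and len(t) > 1:
        chi2 = float(np.sum(w * (y - k * t) ** 2)) / (len(t) - 1)
        se *= float(np.sqrt(chi2))
    valid = k > 0
    cv_k = 100.0 * se / abs(k) if k != 0 else np.inf
    return {
        "k": k,
        "se_k": se,
        "cv_k": cv_k,
        "half_life_h": LN2 / k if valid else np.nan,
        "n_points": int(len(t)),
        "valid": bool(valid),
        "reliable": bool(valid and cv_k <= max_cv_pct),
    }


def fit_turnover(
    protein_ratios: pd.DataFrame,
    noise_model: NoiseModel,
    max_cv_pct: float = 50.0,
    rescale_se: bool = False,
) -> pd.DataFrame:
    """Fit k for every (protein, subject) series in a protein-ratio table.

    Expects the time-coverage filter to have been applied; series are fit
    independently.  Returns one row per fit with the TurnoverFit fields.
    """
    rows = []
    keys = ["protein_id", "subject_id", "group"]
    for (protein_id, subject_id, group), g in protein_ratios.groupby(
        keys, sort=True
    ):
        pts = kinetic_points(
            g["time_h"].to_numpy(), g["r"].to_numpy(), noise_model
        )
        fit = fit_k_wls(pts, max_cv_pct=max_cv_pct, rescale_se=rescale_se)
        rows.append(
            {"protein_id": protein_id, "subject_id": subject_id, "group": group}
            | fit
        )
    cols = [
        "protein_id", "subject_id", "group", "k", "se_k", "cv_k",
        "half_life_h", "n_points", "reliable", "valid",
    ]
    return pd.DataFrame(rows, columns=cols)


def filter_fit_cv(
    fits: pd.DataFrame, max_cv_pct: float = 50.0
) -> tuple[pd.DataFrame, dict]:
    """Keep reliable fits (valid k with estimate CV ≤ cap).

    The summary reports the fraction of valid fits with CV < 15%, the
    precision level reached by the vast majority of fits on well-behaved
    data, as a goodness-of-fit diagnostic.
    """
    if len(fits) == 0:
        return fits.copy(), {"n_in": 0, "n_reliable": 0, "frac_cv_below_15": np.nan}
    ok = fits["valid"] & (fits["cv_k"] <= max_cv_pct)
    kept = fits[ok].reset_index(drop=True)
    valid = fits[fits["valid"]]
    summary = {
        "n_in": int(len(fits)),
        "n_reliable": int(ok.sum()),
        "n_excluded": int((~ok).sum()),
        "frac_cv_below_15": float((valid["cv_k"] < 15.0).mean())
        if len(valid)
        else np.nan,
        "median_cv_k": float(valid["cv_k"].median()) if len(valid) else np.nan,
    }
    return kept, summary
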