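"""Synthetic dynamic-SILAC cohort generator with known ground truth.

Implements the generative model the analysis assumes, so every pipeline
stage can be exercised against a truth ledger:

* steady-state labeling — the light pool decays exponentially and the
  heavy pool is its complement, so the true heavy/light ratio at time t is
  ``r(t) = exp(k t) − 1`` (label conservation P_H + P_L = P_TOT holds
  exactly before noise);
* ratio observation noise on each peptide, normal with SD
  ``sqrt(alpha² + beta²·r²)`` truncated at zero (resampled if negative);
* per-protein half-lives log-uniform over the observed physiological range,
  with lognormal between-subject biological variability on k;
* time-stable relative abundance (steady state) spanning four orders of
  magnitude, observed through peptide-specific lognormal ionization
  factors fixed across time points, plus lognormal measurement noise;
* missing-completely-at-random dropout per protein × time point, plus an
  explicit mechanism forcing a chosen fraction of series to fail the 24 h
  coverage rule, so filter bookkeeping has known expected counts.

The default configuration is the study design: 2 groups × 5 subjects,
sampling at 4, 7.5 and 24 h, 2–15 peptides per protein, noise constants
(0.02, 0.1), half-lives 3–600 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PEPTIDE_COLUMNS


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Between-subject CVs are lognormal coefficients of variation (percent)
    on k and on abundance; ``group_effect`` maps protein ids to the
    multiplicative half-life ratio applied to nephropathic subjects.
    """

    n_subjects_per_group: int = 5
    n_proteins: int = 1200
    times_h: tuple = (4.0, 7.5, 24.0)
    halflife_range_h: tuple = (3.0, 600.0)
    abundance_orders: float = 4.0
    abundance_scale: float = 1.0
    peptides_per_protein: tuple = (2, 15)
    noise_alpha: float = 0.02
    noise_beta: float = 0.1
    between_subject_cv_k: float = 20.0
    between_subject_cv_abundance: float = 30.0
    missing_rate: float = 0.1
    force_fail_24h_frac: float = 0.0
    ionization_sigma: float = 1.0
    intensity_noise_sigma: float = 0.2
    intensity_unit: float = 1.0e6
    group_effect: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_proteins < 1:
            raise ValueError("need at least one subject and one protein")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.force_fail_24h_frac <= 1.0):
            raise ValueError("force_fail_24h_frac must be in [0, 1]")
        if self.noise_alpha < 0 or self.noise_beta < 0:
            raise ValueError("noise constants must be non-negative")
        lo, hi = self.halflife_range_h
        if not (0 < lo <= hi):
            raise ValueError("half-life range must be positive and ordered")
        plo, phi = self.peptides_per_protein
        if not (1 <= plo <= phi):
            raise ValueError("peptides_per_protein must be an ordered range ≥ 1")
        for ratio in self.group_effect.values():
            if not ratio > 0:
                raise ValueError("group-effect half-life ratios must be > 0")


LN2 = float(np.log(2.0))


def _lognormal_factors(rng, cv_pct: float, size) -> np.ndarray:
    """Unit-median lognormal multipliers with the given CV (percent)."""
    if cv_pct <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + (cv_pct / 100.0) ** 2))
    return np.exp(rng.normal(0.0, sigma, size))


def true_ratio(k: np.ndarray, t: float) -> np.ndarray:
    """Noise-free heavy/light ratio r(t) = exp(k t) − 1."""
    return np.expm1(np.asarray(k, dtype=float) * t)


def inject_group_effect(
    truth: pd.DataFrame, protein_ids, halflife_ratio: float
) -> pd.DataFrame:
    """Lengthen half-lives of the given proteins in nephropathic subjects.

    Divides true k by ``halflife_ratio`` for the nephropathic rows of the
    subset; effects compose multiplicatively on repeated application, and
    the cumulative ratio is recorded in ``effect_halflife_ratio``.
    """
    if halflife_ratio <= 0:
        raise ValueError("halflife_ratio must be > 0")
    ids = list(protein_ids)
    known = set(truth["protein_id"])
    unknown = [p for p in ids if p not in known]
    if unknown:
        raise ValueError(f"unknown protein id(s): {unknown}")
    out = truth.copy()
    mask = out["protein_id"].isin(ids) & (out["group"] == "nephropathic")
    out.loc[mask, "true_k"] /= halflife_ratio
    out.loc[mask, "true_half_life_h"] = LN2 / out.loc[mask, "true_k"]
    member = out["protein_id"].isin(ids)
    out.loc[member, "effect_halflife_ratio"] *= halflife_ratio
    out.loc[member, "effect_member"] = True
    return out


def _draw_truth(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_p = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(n_p)]
    lo, hi = config.halflife_range_h
    base_halflife = np.exp(rng.uniform(np.log(lo), np.log(hi), n_p))
    base_k = LN2 / base_halflife
    base_abundance = config.abundance_scale * 10.0 ** rng.uniform(
        0.0, config.abundance_orders, n_p
    )

    subjects = [
        (f"D{i+1:02d}", "control_diabetic")
        for i in range(config.n_subjects_per_group)
    ] + [
        (f"N{i+1:02d}", "nephropathic")
        for i in range(config.n_subjects_per_group)
    ]
    rows = []
    for subject_id, group in subjects:
        k_s = base_k * _lognormal_factors(rng, config.between_subject_cv_k, n_p)
        a_s = base_abundance * _lognormal_factors(
            rng, config.between_subject_cv_abundance, n_p
        )
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": proteins,
                    "subject_id": subject_id,
                    "group": group,
                    "true_k": k_s,
                    "true_abundance": a_s,
                }
            )
        )
    truth = pd.concat(rows, ignore_index=True)
    truth["true_half_life_h"] = LN2 / truth["true_k"]
    truth["effect_member"] = False
    truth["effect_halflife_ratio"] = 1.0
    truth["forced_fail_24h"] = False
    return truth


def _observe_ratios(
    rng: np.random.Generator, r_true: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """Truncated-at-zero normal ratio observations (resampled if < 0)."""
    sd = np.sqrt(alpha**2 + beta**2 * r_true**2)
    if np.all(sd == 0):
        return r_true.copy()
    obs = rng.normal(r_true, sd)
    bad = obs < 0
    while np.any(bad):
        obs[bad] = rng.normal(r_true[bad], sd[bad])
        bad = obs < 0
    return obs


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a peptide-level cohort table and its ground-truth ledger.

    Returns ``(peptides, truth)``: a canonical peptide table ready for
    aggregation without a disk round-trip, and one truth row per
    protein × subject.  The configuration seed fully determines both.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    for protein_id, ratio in sorted(config.group_effect.items()):
        truth = inject_group_effect(truth, [protein_id], ratio)

    n_p = config.n_proteins
    plo, phi = config.peptides_per_protein
    n_peptides = rng.integers(plo, phi + 1, n_p)
    # ionization efficiency fixed per peptide across time → stable abundance
    ion = [
        np.exp(rng.normal(0.0, config.ionization_sigma, int(n)))
        for n in n_peptides
    ]
    protein_ids = truth["protein_id"].unique()
    pep_names = {
        p: [f"{p}_pep{j:02d}" for j in range(int(n_peptides[i]))]
        for i, p in enumerate(protein_ids)
    }

    # forced 24 h failures: chosen per protein × subject series
    if config.force_fail_24h_frac > 0:
        n_series = len(truth)
        n_force = int(round(config.force_fail_24h_frac * n_series))
        forced = rng.choice(n_series, size=n_force, replace=False)
        truth.iloc[forced, truth.columns.get_loc("forced_fail_24h")] = True

    frames = []
    t24 = 24.0
    for (subject_id, group), sub in truth.groupby(
        ["subject_id", "group"], sort=True
    ):
        sub = sub.set_index("protein_id")
        for t in config.times_h:
            run_id = f"{subject_id}_t{t:g}"
            drop = rng.random(n_p) < config.missing_rate
            if t == t24:
                drop |= sub["forced_fail_24h"].to_numpy(bool)
            present = ~drop
            if not present.any():
                continue
            idx = np.where(present)[0]
            k = sub["true_k"].to_numpy(float)[idx]
            a = sub["true_abundance"].to_numpy(float)[idx]
            r_t = true_ratio(k, t)
            reps = n_peptides[idx]
            prot_rep = np.repeat(np.asarray(protein_ids)[idx], reps)
            r_rep = np.repeat(r_t, reps)
            a_rep = np.repeat(a, reps)
            obs_r = _observe_ratios(
                rng, r_rep, config.noise_alpha, config.noise_beta
            )
            ion_rep = np.concatenate([ion[i] for i in idx])
            noise = (
                np.exp(
                    rng.normal(0.0, config.intensity_noise_sigma, len(r_rep))
                )
                if config.intensity_noise_sigma > 0
                else 1.0
            )
            intensity = config.intensity_unit * a_rep * ion_rep * noise
            pep_ids = np.concatenate([pep_names[p] for p in np.asarray(protein_ids)[idx]])
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "time_h": t,
                        "protein_id": prot_rep,
                        "peptide_id": pep_ids,
                        "ratio_hl": obs_r,
                        "intensity": intensity,
                        "run_id": run_id,
                    }
                )
            )
    peptides = pd.concat(frames, ignore_index=True)[PEPTIDE_COLUMNS]
    return peptides, truth
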