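"""Generate the study-design cohort used by the downstream analyses.

Two groups (diabetic controls, nephropathic) of 5 subjects each, sampled at
4, 7.5 and 24 h after the light-to-heavy medium switch; ~1,200 proteins per
subject with 2-15 peptides, half-lives log-uniform over 3-600 h, ratio noise
SD(r) = sqrt(0.02^2 + 0.1^2 r^2), 10% random dropout per protein x time and
5% of series forced to miss the 24 h anchor.  A 23% half-life increase is
injected into 20 designated proteins of the nephropathic group so the group
comparison (05) has a known positive set.

Writes results/cohort/{peptides.tsv, ground_truth.tsv}.
"""

import sys
from pathlib import Path

from silacturnover import io
from silacturnover.simulate import SyntheticConfig, simulate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20230201
EFFECT_PROTEINS = [f"P{i:05d}" for i in range(20)]

out = Path("results/cohort")
out.mkdir(parents=True, exist_ok=True)

config = SyntheticConfig(
    n_proteins=1200,
    seed=SEED,
    force_fail_24h_frac=0.05,
    group_effect={p: 1.23 for p in EFFECT_PROTEINS},
)
peptides, truth = simulate_cohort(config)
io.write_peptide_table(peptides, out / "peptides.tsv")
truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)

n_per_subject = peptides.groupby("subject_id")["protein_id"].nunique()
print(f"cohort: {len(peptides)} peptide observations, "
      f"{truth['protein_id'].nunique()} proteins x {truth['subject_id'].nunique()} subjects")
print(f"proteins observed per subject: mean {n_per_subject.mean():.0f} "
      f"(range {n_per_subject.min()}-{n_per_subject.max()})")
print(f"injected half-life effect: x1.23 in {len(EFFECT_PROTEINS)} proteins "
      f"(nephropathic group)")
print(f"wrote {out}/peptides.tsv and {out}/ground_truth.tsv")
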