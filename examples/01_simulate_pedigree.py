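"""Simulate a walnut-style founder panel and multi-family pedigree.

Draws 27 unrelated founders under Hardy-Weinberg at a heterozygosity
matching the real discovery panel (~0.26), breeds five full-sib families
plus two open-pollinated seedlings, and corrupts genotypes and records the
way real data are corrupted.
"""

import numpy as np

import walnutsnp as w
from walnutsnp.simulate import pedigree_to_records

cfg = w.SimConfig(n_founders=27, n_sites=5_000, geno_error_rate=0.01,
                  missing_rate=0.01, mislabel_rate=0.02, seed=1)
founders, site_truth = w.simulate_founders(cfg)
print(f"founders: {founders.n_samples} samples x {founders.n_sites} sites")
print(f"mean founder heterozygosity: {(founders.geno == 1).mean():.3f} (target 0.26)")

plan = w.CrossPlan()
for dam, sire in [(0, 1), (2, 3), (4, 5), (6, 7), (0, 8)]:
    plan.add(founders.samples[dam], founders.samples[sire], 12)
plan.add(founders.samples[9], w.OPEN, 1)
plan.add(founders.samples[9], w.OPEN, 1)
gm, truth = w.simulate_pedigree(founders, plan, seed=2)
print(f"pedigree: {gm.n_samples} individuals, {truth.number_of_edges()} parent-child edges")

observed, err_mask, miss_mask = w.inject_errors(gm, cfg, seed=3)
records, mislabel_mask = w.corrupt_records(truth, cfg.mislabel_rate, seed=4)
n_bad = int(mislabel_mask[["dam_mislabelled", "sire_mislabelled"]].sum().sum())
print(f"injected: {err_mask.mean():.4f} genotype error rate, "
      f"{miss_mask.mean():.4f} missing rate, {n_bad} mislabelled parent records")

# with the *true* parents the offspring are perfectly Mendelian before errors
child = "off_00000"
dam, sire = [p for p, _, _ in truth.in_edges(child, data=True)]
rate, _ = w.mendelian_inconsistency(
    gm.genotypes_of(child), gm.genotypes_of(dam), gm.genotypes_of(sire))
print(f"trio Mendelian inconsistency before error injection: {rate:.4f} (expect 0)")
rate_noisy, _ = w.mendelian_inconsistency(
    observed.genotypes_of(child), observed.genotypes_of(dam), observed.genotypes_of(sire))
print(f"after 1% genotyping error: {rate_noisy:.4f} (expect ~0.015, still << 0.05)")
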