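"""Diversity statistics, per-family F_IS, PCA and a UPGMA dendrogram.

Two founder populations with shifted allele frequencies stand in for
geographically distinct germplasm: PC1 should separate them, and the
UPGMA tree on allele-sharing distance should cluster them apart.
"""

import numpy as np
import pandas as pd

import walnutsnp as w
from walnutsnp.genotypes import GenotypeMatrix

rng = np.random.default_rng(12)
n_sites = 3_000
p1 = rng.uniform(0.1, 0.4, n_sites)
p2 = np.clip(p1 + rng.choice([-0.3, 0.3], n_sites), 0.05, 0.95)
sites = pd.DataFrame({
    "site_id": [f"s{i}" for i in range(n_sites)], "scaffold": "sc1",
    "pos": np.arange(1, n_sites + 1) * 100, "ref": "A", "alt": "C",
})
geno = np.vstack([rng.binomial(2, p1, size=(10, n_sites)),
                  rng.binomial(2, p2, size=(10, n_sites))]).astype(np.int8)
gm = GenotypeMatrix([f"popA_{i}" for i in range(10)] +
                    [f"popB_{i}" for i in range(10)], sites, geno)

per_site, means = w.snp_stats(gm)
print(f"mean MAF {means['mean_maf']:.3f}, mean het {means['mean_het']:.3f}, "
      f"mean missing {means['mean_missing_rate']:.3f}")

fis = w.fis_per_family(gm, {s: s.split('_')[0] for s in gm.samples})
for _, row in fis.iterrows():
    print(f"F_IS[{row['family']}] = {row['fis']:+.3f} "
          "(0 = Hardy-Weinberg; negative = heterozygote excess)")

coords, proportions = w.pca(gm, n_components=2)
print(f"PC1+PC2 explain {100 * proportions[:2].sum():.2f}% of the variance")
sep = coords.loc[[s for s in gm.samples if s.startswith('popA')], "PC1"].mean() \
    - coords.loc[[s for s in gm.samples if s.startswith('popB')], "PC1"].mean()
print(f"PC1 population separation: {abs(sep):.2f} (populations split along PC1)")

newick = w.upgma(w.ibs_distance(gm))
print(f"UPGMA newick (first 80 chars): {newick[:80]}...")
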