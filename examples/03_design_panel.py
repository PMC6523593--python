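"""Select an array panel from filter-surviving sites.

Three routes: HIGH/MODERATE-effect SNPs (genic, candidate functional),
ALL_HOM SNPs (homozygous in every founder, candidate fixed alleles), and
INFP tagSNPs picked per 10-kb window under an r²<0.81 LD bound. A/T and
C/G sites cost two probes.
"""

import walnutsnp as w

cfg = w.SimConfig(n_founders=27, n_sites=10_000, seed=7)
founders, _ = w.simulate_founders(cfg)
sites = w.annotate_sites(founders, seed=8)
survivors, _ = w.run_filters(sites)
gm = founders.subset_sites_by_id(list(survivors["site_id"]))

effect = w.select_effect_snps(survivors)
all_hom = w.select_all_hom(gm)                      # <=3 missing, no hets
tags = w.select_tag_snps(gm, r2_threshold=0.81)     # per-10kb-window greedy
panel = w.assemble_panel(effect, all_hom, tags, survivors, gm=gm)

print(f"filter survivors:      {len(survivors)}")
print(f"HIGH_MOD_EFF route:    {panel.totals_by_reason['HIGH_MOD_EFF']}")
print(f"ALL_HOM route:         {panel.totals_by_reason['ALL_HOM']}")
print(f"INFP (tagSNP) route:   {panel.totals_by_reason['INFP']}")
print(f"panel size:            {len(panel.table)}")
print(f"total probe cost:      {panel.total_probe_cost} "
      f"(+{panel.total_probe_cost - len(panel.table)} for A/T and C/G sites)")

# trimming to a target removes only tagSNPs, never effect/ALL_HOM sites
trimmed = w.assemble_panel(effect, all_hom, tags, survivors, gm=gm,
                           target_total=len(panel.table) - 500)
assert set(effect) <= set(trimmed.site_ids)
print(f"after trimming to {len(trimmed.table)}: "
      f"INFP {trimmed.totals_by_reason['INFP']} (only route reduced)")
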