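"""Filter a homozygous-deleterious variant catalog and test driver enrichment.

Builds a synthetic 60-line panel, keeps the variants that are homozygous in
at least one line, absent from the non-cancerous references, amino-acid
changing and function-affecting, then asks whether the surviving genes are
enriched for a (toy) driver-gene list by Fisher's exact test.
"""

from varpharm import (
    SimulationConfig,
    driver_gene_enrichment_test,
    filter_homozygous_deleterious,
    simulate_panel,
)

catalog, matrix, _ = simulate_panel(SimulationConfig(seed=42))
report = filter_homozygous_deleterious(catalog)

print(f"catalog size: {len(catalog)} variants")
print(f"homozygous-deleterious subset: {len(report)} variants "
      f"in {report.unique_genes} genes")
for category, count in sorted(report.category_counts.items()):
    print(f"  {category:>15}: {count}")

universe = sorted({r.gene for r in catalog})
selected = {r.gene for r in report.records}
drivers = set(universe[:5])  # pretend the first five genes are known drivers
p = driver_gene_enrichment_test(selected, drivers, universe)
print(f"driver-gene enrichment p = {p:.3f}  (small p would mean the filtered "
      "genes overlap the driver list more than chance)")
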