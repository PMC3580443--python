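"""Filter a synthetic cohort and rank candidate genes.

Builds a small four-sample synthetic exome cohort, applies a Mendelian
discovery filter (coverage >= 10x, VAF >= 20%, novel against both population
site sets, coding consequences only) and collapses the survivors to a ranked
gene table under the dominant model.
"""

import pandas as pd

import snvsieve as sv
from snvsieve.collapse import summarize_frame

cm = pd.DataFrame(
    [[5, 5, 300, 200, 100]] * 4,
    index=["case1", "case2", "case3", "case4"],
    columns=["essential_splice", "nonsense", "nonsynonymous", "synonymous",
             "utr"],
)
cohort, gene_model = sv.generate(sv.CohortSpec(count_matrix=cm, n_genes=200,
                                               seed=7))
print(f"simulated: {cohort}")

cfg = sv.FilterConfig(
    min_coverage=10,
    min_vaf=0.2,
    exclude_in_sets=("dbsnp", "kg1000"),
    consequences=frozenset({"nonsynonymous", "nonsense", "essential_splice"}),
)
filtered = sv.apply_filters(cohort, cfg)
print(f"{filtered.n_observations} of {cohort.n_observations} observations "
      f"survive the filter battery")

hits = sv.call_hits(filtered, "dominant")
table = sv.rank(summarize_frame(hits),
                [("n_samples", "desc"), ("max_phylop_mammal", "desc")])
print("\ntop candidate genes (samples hit, variants, max mammal PhyloP):")
print(table.frame.head(5)[
    ["rank", "unit_id", "n_samples", "n_total_variants", "max_phylop_mammal"]
].to_string(index=False))
print("\nGenes hit in more samples rank first; conservation of the best "
      "supporting variant breaks ties — a highly ranked gene carries novel "
      "coding variants in many cases at conserved positions.")
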