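"""Scaled-down randomization benchmark with rank statistics.

Generates an eight-sample synthetic cohort (reduced per-sample counts so
the demo runs in seconds), then repeatedly: shuffles sample labels within
consequence strata, splits 4 cases / 4 controls, spikes two novel causal
variants per case into one gene, filters (>=10x, VAF >= 20%, novel only,
control-carried variants excluded, coding classes), calls recessive hits
and ranks candidates.  The empirical CDF of the causal gene's rank shows
how reliably the protocol recovers it.
"""

import pandas as pd

import snvsieve as sv

cm = pd.DataFrame(
    [[10, 10, 500, 350, 150]] * 8,
    index=[f"S{i}" for i in range(1, 9)],
    columns=["essential_splice", "nonsense", "nonsynonymous", "synonymous",
             "utr"],
)
cohort, gene_model = sv.generate(
    sv.CohortSpec(count_matrix=cm, n_genes=600, seed=42)
)
causal = sv.choose_causal_gene(gene_model)
print(f"base cohort: {cohort}\ncausal gene: {causal}")

result = sv.run_randomizations(
    cohort, gene_model, sv.miller_protocol(causal, "recessive"),
    n_case=4, n_control=4, per_case_variants=2, n_iterations=50, seed=1,
)
cdf = sv.rank_cdf(result)
print(f"\nmean candidates hit in all 4 cases: {result.mean_candidates(4):.1f}")
for r in sorted(cdf)[:5]:
    print(f"P(causal rank <= {r}) = {cdf[r]:.2f}")
print("\nA CDF near 1 at small ranks means the filter-and-sort protocol "
      "almost always surfaces the spiked causal gene among its top "
      "candidates despite the background of shuffled neutral variation.")
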