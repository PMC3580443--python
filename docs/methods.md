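# Methods

## Problem and scope

`snvsieve` addresses disease-gene discovery from multi-sample
single-nucleotide-variant (SNV) calls in rare Mendelian disorders.  The core
strategy is *filter and collapse*: remove variants unlikely to be causal
(low quality, common in the population, silent), aggregate the survivors to
functional units (genes, exons, protein complexes) under an explicit
inheritance model, and rank the units by how many affected samples they
implicate and how conserved their best supporting variant is.  A
semi-synthetic randomization benchmark quantifies how reliably such a
protocol recovers a known causal gene against neutral background variation.

Scope is deliberately restricted to coding SNVs: indels, structural
variants, phasing and regulatory annotation are out of scope.  Functional
predictor scores (SIFT/PolyPhen-style) and haploinsufficiency are treated as
passthrough annotation columns, never computed.

## Data model

Variant identity is `(chrom, 1-based pos, ref base, alt base)`;
multi-allelic VCF records are split per alternate allele at import and
chromosome names are normalized by stripping a `chr` prefix.  Only
non-reference calls are stored, so "absent" conflates reference-equal with
no-call — this matters for de novo calling (below).  An observation carries
coverage, alternate-read count, VAF (= alt/coverage by construction) and
zygosity (`het`, `hom_alt`, or `unknown` for formats without genotypes;
unknown fails any explicit zygosity filter).

Canonical storage is columnar (pandas): an interned variant table, an
observation table and a per-(variant, transcript) annotation table.  This
keeps the randomization benchmark vectorized at exome scale while the
dataclass views (`VariantKey`, `VariantObservation`, `VariantAnnotation`)
provide the object-level API.

## Consequence classification

Classes, in decreasing severity: `essential_splice`, `nonsense`,
`nonsynonymous`, `synonymous`, `utr`, `intronic`, `intergenic`.  Design
choices:

* Essential splice = *intronic* positions 1–2 bases from an internal exon
  boundary (the donor/acceptor dinucleotides).  Exonic bases at a junction
  are classified by their codon effect.
* Nonsense covers both stop gain and stop loss.
* A variant overlapping several transcripts gets one annotation per
  transcript; gene-level summaries use the most severe ("worst
  consequence"), and a canonical-only switch restricts each gene to its
  longest-CDS transcript.
* Transcripts whose CDS length is not a multiple of three are flagged
  non-analyzable and treated as non-coding (exonic positions become `utr`).

The classifier is validated against an independent oracle that mutates the
whole chromosome, rebuilds and translates the CDS with Biopython, and
compares proteins, over 1,000 random toy transcripts on both strands.

## Filter battery

All numeric thresholds are inclusive ("minimum 10×" keeps coverage exactly
10).  "Novel" means absent from every configured site set — population
databases are version-pinned *inputs* (plain site lists), not code.  Site
sets match exact alleles by default; a positions-only mode reproduces
presence semantics of older databases.  Control exclusion
(`exclude_in_samples`) and carrier-count caps are cohort-wide: they remove
the variant from every sample and are evaluated on the *unfiltered* input
(a control carrying the variant at any coverage/VAF triggers exclusion), so
criteria within one pass form a pure conjunction and are order-independent.
Variants with missing conservation scores pass a conservation filter by
default (logged), to avoid silently discarding unscored exons.

## Inheritance models

* Dominant: a unit is a hit in a sample with ≥1 qualifying variant.
* Recessive: ≥2 *distinct* variants in the unit for that sample — an
  unphased compound-heterozygote proxy; a single homozygous-alt call counts
  only when `allow_hom_alt` is set (off by default, since a causal
  homozygous non-reference variant is considered highly unlikely in an
  outbred cohort).  Phase is ignored; two variants on the same haplotype
  are indistinguishable here and counted — a documented limitation.
  At exon level the recessive rule is a locality test: both variants must
  fall in the same exon.
* De novo: present in the child, absent (no stored call) in both parents.
  Because absence also covers no-call, an optional gate
  (`min_parent_coverage` plus a coverage callback) lets users require
  parental coverage evidence before trusting absence; default off.

## Collapsing and ranking

Per unit the summary records: samples hit, distinct supporting variants
(`n_total_variants`), variants private to a single sample
(`n_unique_variants` — a recurrence measure, so one variant shared by four
samples gives total 1, unique 0), the largest per-sample variant count
(`max_sample_burden`, useful as a secondary sort for de novo-driven
phenotypes), per-clade maximum PhyloP over supporting variants, and
passthrough haploinsufficiency.  Ranking sorts descending by each key in
order (default: samples hit, then placental-mammal PhyloP), missing values
below any present value, final ties broken by unit id ascending — fully
deterministic.  Protein-complex collapsing marks a complex hit in a sample
iff any member gene is hit there, with supporting variants the union over
members.

## Synthetic exome generator

The generator emulates a cohort of real exomes whose only published
description is a per-sample, per-consequence count matrix (eight exomes,
five classes).  It builds a synthetic gene model — by default 18,000
non-overlapping single-transcript genes across 22 chromosomes, matching the
scale of the protein-coding exome, with lognormal CDS lengths
(median ≈ 400 codons, σ = 0.7), 1 + Poisson(7) exons, UTRs and short
introns, and real nucleotide sequence composed of sense codons — and a
population pool of SNVs per class whose codon effect genuinely is the
annotated class (verified against the classifier).

Each pool variant draws an allele frequency from Beta(0.2, 2); per-sample
draws are weighted sampling without replacement with weight
`af**reuse_weight`, so common variants recur across samples and the
per-cell counts are reproduced *exactly* (the generator's core contract).
Novelty is a pool-variant property: each variant is marked present in each
site set with probability 0.90 (dbSNP-like) / 0.60 (1000-Genomes-pilot-
like) independently — era-typical capture rates, giving ≈ 4% novel coding
variation.  Coverage is 5 + negative-binomial (mean 45, dispersion 8);
heterozygous allele fractions are Beta(25, 25), homozygous Beta(60, 2),
with alt reads binomial given coverage.  Conservation stand-ins: mammal
PhyloP ~ N(1.5, 1) for coding-deleterious classes, N(0, 1) for
synonymous/UTR, clipped to [−14, 6]; primate/vertebrate tracks are scaled
noisy copies, and PhastCons is a logistic transform.  The source exomes'
real coverage/VAF/conservation distributions are unpublished; these laws
are documented stand-ins, chosen once and overridable per `CohortSpec`
field.

Consequently, passing tests show that the *protocol machinery* behaves as
specified under realistic scale and sharing; they do not certify behaviour
under real-data artifacts the generator does not model (batch effects,
calling errors, linkage disequilibrium, hypervariable-gene excess, allele-
frequency-correlated database membership).

## Spike-in and the randomization benchmark

One benchmark iteration: (1) shuffle sample labels of all observations
within consequence-class strata, exactly preserving the total count, each
sample's total and each sample's per-class counts; (2) randomly split
samples into cases and controls; (3) spike fresh causal variants into each
case in the designated gene — distinct novel positions, heterozygous,
codon-verified nonsynonymous, coverage/VAF drawn from the cohort laws but
guaranteed to meet the protocol thresholds (they represent true causal
genotypes), with mammal PhyloP ~ N(2.5, 0.5) reflecting that causal coding
variants sit at strongly conserved positions; (4) filter (≥10×,
VAF ≥ 20%, novel-only, control-carried variants excluded cohort-wide,
coding classes); (5) call hits under the protocol model, restrict to cases,
rank; (6) record the causal gene's rank (`absent` when filtered out — a
distinguishable failure, not a max rank) and the candidate tallies at
k = 1..4.  The default causal gene is the one whose CDS length is closest
to 1,188 bp (a typical dehydrogenase-sized gene), chosen deterministically.

Label shuffling resolves duplicate (variant, sample) pairs by pairwise
label swaps within the stratum.  Variants carried by *every* sample have no
labeling freedom (they must receive one label per sample) and are assigned
directly; the remainder is permuted and repaired with swaps accepted only
when they strictly reduce collisions, plus occasional neutral relocations
to escape local minima.  A repair that has not converged within 200 sweeps
restarts from a fresh permutation (at most five attempts, then an error).
The three preservation invariants are asserted exactly on every call.

Each iteration's RNG stream derives from (seed, iteration index), so runs
are reproducible and restartable; the acceptance script and the benchmark
tests use 200 randomizations per protocol (the statistic is a proportion
with ~1.5% standard error at that n), with the full eight-exome count
matrix — roughly 170k observations per iteration.

## Numerical and degenerate-input choices

* TSV exports print floats with `%.10g`, making dumps byte-stable for a
  fixed seed.
* Empty inputs are legal everywhere: empty VCFs, header-only tables and
  empty filter results exit successfully.
* When multiple call files disagree for one (variant, sample), the
  higher-coverage call wins and the conflict is logged.
* `rank` on an empty summary set returns an empty table with a header.

## Known limitations

* No phasing: recessive hits may be two cis variants.
* De novo absence is evidence-free unless the parental-coverage gate is
  used.
* The generator's neutral placement has no mutation-rate heterogeneity, so
  hypervariable genes (a major source of false candidates in real exomes)
  are under-represented; real cohorts will show more high-ranking neutral
  competitors than the benchmark does.
* Site-set membership is independent of allele frequency, whereas real
  database presence correlates strongly with it.
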