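"""Shared fixtures: tiny hand-built cohorts, random cohort factories, toy
gene models and a minimal VCF renderer used for round-trip tests."""

from __future__ import annotations

import numpy as np
import pytest

import snvsieve as sv
from snvsieve.consequence import GeneModel, Transcript


def make_cohort(sample_ids, observations=(), annotations=(), site_sets=()):
    """Build a cohort through the public object API."""
    cohort = sv.Cohort([sv.SampleMeta(sample_id=s) if isinstance(s, str) else s
                        for s in sample_ids])
    for sset in site_sets:
        cohort.register_site_set(sset)
    for obs in observations:
        cohort.add_observation(obs)
    for ann in annotations:
        cohort.add_annotation(ann)
    return cohort


def random_cohort(rng, n_samples=4, n_obs=50, n_positions=30, with_ann=True,
                  n_genes=6):
    """A random small cohort with annotations and two site sets."""
    samples = [f"S{i}" for i in range(n_samples)]
    cohort = sv.Cohort([sv.SampleMeta(sample_id=s) for s in samples])
    bases = "ACGT"
    keys = []
    for p in range(n_positions):
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        keys.append(sv.VariantKey("1", 101 + 7 * p, ref, alt))
    known = [k for k in keys if rng.random() < 0.4]
    cohort.register_site_set(
        sv.SiteSet(name="dbsnp", keys=frozenset(k.astuple() for k in known))
    )
    cohort.register_site_set(
        sv.SiteSet(
            name="kg1000",
            keys=frozenset(k.astuple() for k in keys if rng.random() < 0.2),
        )
    )
    seen = set()
    placed = 0
    n_obs = min(n_obs, (n_samples * n_positions) * 3 // 4)
    while placed < n_obs:
        key = keys[int(rng.integers(0, len(keys)))]
        sid = samples[int(rng.integers(0, n_samples))]
        if (key, sid) in seen:
            continue
        seen.add((key, sid))
        cov = int(rng.integers(0, 60))
        alt_reads = int(rng.integers(0, cov + 1))
        cohort.add_observation(
            sv.VariantObservation(
                key=key, sample_id=sid, coverage=cov, alt_reads=alt_reads,
                zygosity=str(rng.choice(["het", "hom_alt", "unknown"])),
            )
        )
        placed += 1
    if with_ann:
        consequences = list(sv.CONSEQUENCES[:-1])  # everything but intergenic
        for key in keys:
            gene = f"G{int(rng.integers(0, n_genes))}"
            cohort.add_annotation(
                sv.VariantAnnotation(
                    key=key,
                    gene_id=gene,
                    transcript_id=f"{gene}.t1",
                    consequence=str(rng.choice(consequences)),
                    exon_index=int(rng.integers(1, 5)),
                    phylop={"mammal": float(rng.normal(1.0, 1.5))},
                )
            )
    return cohort


def toy_model(cds_seq="ATGAAATAG", strand="+", utr5=4, utr3=5, chrom="9",
              offset=10, cuts=(), intron_len=30, gene_id="GENE1",
              transcript_id="TX1", seed=0):
    """A single-gene model with the given coding-strand CDS sequence.

    ``cuts`` splits the CDS (coding-strand coordinates, 0 < cut < len) into
    exon pieces separated by introns of ``intron_len``.
    """
    assert len(cds_seq) % 3 == 0
    rng = np.random.default_rng(seed)
    pieces, prev = [], 0
    for cut in [*sorted(cuts), len(cds_seq)]:
        pieces.append(cds_seq[prev:cut])
        prev = cut
    if strand == "+":
        genomic_pieces = pieces  # left-to-right = 5'->3'
        utra, utrb = utr5, utr3
    else:
        genomic_pieces = [_revcomp(p) for p in reversed(pieces)]
        utra, utrb = utr3, utr5

    def rand(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    seq = rand(offset)
    exons, cds = [], []
    cursor = offset + 1
    for i, piece in enumerate(genomic_pieces):
        ex_start = cursor
        if i == 0:
            seq += rand(utra)
            cursor += utra
        cds.append((cursor, cursor + len(piece) - 1))
        seq += piece
        cursor += len(piece)
        if i == len(genomic_pieces) - 1:
            seq += rand(utrb)
            cursor += utrb
        exons.append((ex_start, cursor - 1))
        if i < len(genomic_pieces) - 1:
            seq += rand(intron_len)
            cursor += intron_len
    seq += rand(20)
    model = GeneModel(sequences={chrom: seq})
    model.add_transcript(
        Transcript(transcript_id=transcript_id, gene_id=gene_id, chrom=chrom,
                   strand=strand, exons=exons, cds=cds)
    )
    return model


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def render_vcf(cohort, path):
    """Minimal VCF 4.2 rendering of a cohort (GT:AD:DP), for round trips."""
    samples = sorted(cohort.samples)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
    ]
    var = cohort.variants_frame
    contigs = sorted(var["chrom"].unique(), key=str)
    for c in contigs:
        lines.insert(1, f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    obs = cohort.obs_frame
    by_vid = {vid: grp for vid, grp in obs.groupby("vid")}
    order = var.sort_values(["chrom", "pos", "alt"]).index
    for vid in order:
        if vid not in by_vid:
            continue
        row = var.loc[vid]
        cells = []
        grp = by_vid[vid].set_index("sample")
        for s in samples:
            if s not in grp.index:
                cells.append("./.")
                continue
            o = grp.loc[s]
            gt = "1/1" if o["zygosity"] == "hom_alt" else "0/1"
            ref_reads = int(o["coverage"]) - int(o["alt_reads"])
            cells.append(
                f"{gt}:{ref_reads},{int(o['alt_reads'])}:{int(o['coverage'])}"
            )
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
            f"\t.\tPASS\t.\tGT:AD:DP\t" + "\t".join(cells)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def obs_set(cohort):
    """Observations as a comparable set of tuples."""
    return {
        (o.key, o.sample_id, o.coverage, o.alt_reads, round(o.vaf, 6),
         o.zygosity)
        for o in cohort.observations()
    }


@pytest.fixture(scope="session")
def miller_cohort():
    """Full-scale synthetic cohort built from the published eight-exome
    count matrix with default laws; shared across acceptance tests."""
    spec = sv.CohortSpec(seed=20120926)
    return sv.generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
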