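"""Consequence classification against toy gene models.

The reference oracle mutates the full chromosome, rebuilds and translates
the coding sequence with Biopython, and compares proteins — an independent
path from the classifier's per-codon logic.
"""

import numpy as np
import pytest

import snvsieve as sv
from snvsieve.consequence import GeneModel, ScoreTracks, Transcript, classify
from _oracles import classify_oracle
from conftest import toy_model, random_cohort, _revcomp


def _first(key, model, **kw):
    (ann,) = classify(key, model, **kw)
    return ann


class TestClassifyExamples:
    def test_far_from_any_gene_is_intergenic(self):
        model = toy_model()
        ann = _first(sv.VariantKey("9", 10000, "A", "C"), model)
        assert ann.consequence == "intergenic"

    def test_codon_change_lysine_to_glutamine(self):
        # CDS ATG AAA TAG on +: codon 2 position 1 (A->C) gives AAA->CAA, K->Q
        model = toy_model("ATGAAATAG", strand="+", utr5=4, utr3=5, offset=10)
        tx = model.transcripts["TX1"]
        pos = tx.cds[0][0] + 3  # first base of codon 2
        assert model.base("9", pos) == "A"
        ann = _first(sv.VariantKey("9", pos, "A", "C"), model)
        assert ann.consequence == "nonsynonymous"
        assert classify_oracle(
            sv.VariantKey("9", pos, "A", "C"), tx, model
        ) == "nonsynonymous"

    def test_stop_gain_is_nonsense(self):
        # AAA -> TAA at codon 2 position 1
        model = toy_model("ATGAAATAG")
        pos = model.transcripts["TX1"].cds[0][0] + 3
        ann = _first(sv.VariantKey("9", pos, "A", "T"), model)
        assert ann.consequence == "nonsense"

    def test_stop_loss_is_nonsense(self):
        model = toy_model("ATGAAATAG")
        pos = model.transcripts["TX1"].cds[0][0] + 6  # TAG -> CAG
        ann = _first(sv.VariantKey("9", pos, "T", "C"), model)
        assert ann.consequence == "nonsense"

    def test_second_intronic_base_is_essential_splice(self):
        model = toy_model("ATGAAACCCTAG", cuts=[6], intron_len=30)
        tx = model.transcripts["TX1"]
        pos = tx.exons[0][1] + 2  # two bases into the intron
        ref = model.base("9", pos)
        alt = next(b for b in "ACGT" if b != ref)
        ann = _first(sv.VariantKey("9", pos, ref, alt), model)
        assert ann.consequence == "essential_splice"
        assert ann.exon_index == 1

    def test_synonymous_third_position(self):
        # CTT -> CTG both leucine
        model = toy_model("ATGCTTTAG")
        pos = model.transcripts["TX1"].cds[0][0] + 5
        ann = _first(sv.VariantKey("9", pos, "T", "G"), model)
        assert ann.consequence == "synonymous"

    def test_utr_and_intronic(self):
        model = toy_model("ATGAAACCCTAG", cuts=[6], intron_len=30, utr5=4)
        tx = model.transcripts["TX1"]
        utr_pos = tx.exons[0][0]  # first UTR base
        ref = model.base("9", utr_pos)
        alt = next(b for b in "ACGT" if b != ref)
        assert _first(sv.VariantKey("9", utr_pos, ref, alt),
                      model).consequence == "utr"
        mid_intron = tx.exons[0][1] + 15
        ref = model.base("9", mid_intron)
        alt = next(b for b in "ACGT" if b != ref)
        assert _first(sv.VariantKey("9", mid_intron, ref, alt),
                      model).consequence == "intronic"

    def test_reference_mismatch_raises(self):
        model = toy_model("ATGAAATAG")
        pos = model.transcripts["TX1"].cds[0][0]  # reference base A
        with pytest.raises(sv.DataError, match=str(pos)):
            classify(sv.VariantKey("9", pos, "C", "G"), model)

    def test_non_analyzable_cds_treated_as_noncoding(self):
        model = toy_model("ATGAAATAG")
        tx = model.transcripts["TX1"]
        broken = Transcript(
            transcript_id="TX2", gene_id="GENE1", chrom="9", strand="+",
            exons=tx.exons, cds=[(tx.cds[0][0], tx.cds[0][1] - 1)],
        )
        model2 = GeneModel(sequences=model._seq)
        model2.add_transcript(broken)
        pos = tx.cds[0][0] + 3
        ann = _first(sv.VariantKey("9", pos, "A", "T"), model2)
        assert ann.consequence == "utr"


def _random_toy_case(rng):
    """Random toy transcript plus a random SNV somewhere near it."""
    n_codons = int(rng.integers(2, 12))
    cds = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
    n_cuts = int(rng.integers(0, min(3, 3 * n_codons - 1)))
    cuts = sorted(rng.choice(np.arange(1, 3 * n_codons), size=n_cuts,
                             replace=False).tolist())
    strand = "+" if rng.random() < 0.5 else "-"
    model = toy_model(
        cds, strand=strand, cuts=cuts, intron_len=int(rng.integers(5, 25)),
        utr5=int(rng.integers(1, 8)), utr3=int(rng.integers(1, 8)),
        offset=int(rng.integers(3, 15)), seed=int(rng.integers(0, 2**31)),
    )
    tx = model.transcripts["TX1"]
    lo = max(1, tx.span[0] - 4)
    hi = min(len(model._seq["9"]), tx.span[1] + 4)
    pos = int(rng.integers(lo, hi + 1))
    ref = model.base("9", pos)
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return model, tx, sv.VariantKey("9", pos, ref, alt)


class TestClassifyProperties:
    def test_matches_translation_oracle_on_random_transcripts(self):
        """Classifier == full-translation oracle on 1000 random toy genes."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            model, tx, key = _random_toy_case(rng)
            anns = classify(key, model)
            expected = classify_oracle(key, tx, model)
            got = anns[0].consequence if anns[0].transcript_id == "TX1" \
                or expected == "intergenic" else None
            assert got == expected, f"{key} on {tx.strand} strand"

    def test_reverse_strand_twin_classifies_identically(self):
        """A minus-strand gene equals its reverse-complemented plus twin."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            model, tx, key = _random_toy_case(rng)
            if tx.strand == "-":
                continue
            L = len(model._seq["9"])
            mirror_seq = _revcomp(model._seq["9"])
            mirror = GeneModel(sequences={"9": mirror_seq})
            mirror.add_transcript(Transcript(
                transcript_id="TX1", gene_id="GENE1", chrom="9", strand="-",
                exons=[(L - e + 1, L - s + 1) for s, e in tx.exons],
                cds=[(L - e + 1, L - s + 1) for s, e in tx.cds],
            ))
            mkey = sv.VariantKey(
                "9", L - key.pos + 1, _revcomp(key.ref), _revcomp(key.alt)
            )
            assert classify(mkey, mirror)[0].consequence == \
                classify(key, model)[0].consequence

    def test_every_overlapping_transcript_gets_one_category(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            model, tx, key = _random_toy_case(rng)
            anns = classify(key, model)
            assert len(anns) == 1
            assert anns[0].consequence in sv.CONSEQUENCES


class TestGeneModelIO:
    def test_gff3_fasta_round_trip_preserves_classification(self, tmp_path):
        rng = np.random.default_rng(5)
        model = toy_model("ATGAAACCCGGGTAG", cuts=[7], strand="-")
        gff = tmp_path / "m.gff3"
        fa = tmp_path / "m.fa"
        model.to_gff3(gff)
        model.write_fasta(fa)
        back = GeneModel.from_gff3(gff, fa)
        tx = back.transcripts["TX1"]
        assert tx.exons == model.transcripts["TX1"].exons
        assert tx.cds == model.transcripts["TX1"].cds
        for _ in range(30):
            pos = int(rng.integers(model.transcripts["TX1"].span[0],
                                   model.transcripts["TX1"].span[1] + 1))
            ref = model.base("9", pos)
            alt = next(b for b in "ACGT" if b != ref)
            key = sv.VariantKey("9", pos, ref, alt)
            assert classify(key, back)[0].consequence == \
                classify(key, model)[0].consequence


class TestScoreTracks:
    def test_empty_track_yields_missing(self, rng):
        cohort = random_cohort(rng, n_obs=10)
        tracks = ScoreTracks()
        tracks.add("phylop", "mammal", {})
        sv.attach_scores(cohort, tracks)
        assert cohort.ann_frame["phylop_mammal"].isna().all()

    def test_single_position_lookup(self, rng):
        cohort = random_cohort(rng, n_obs=10)
        key = next(iter(cohort.variant_sharing_counts()))
        tracks = ScoreTracks()
        tracks.add("phylop", "mammal", {(key.chrom, key.pos): 1.5})
        sv.attach_scores(cohort, tracks)
        ann = cohort.ann_frame
        vid = cohort.vid_of(key)
        assert (ann.loc[ann["vid"] == vid, "phylop_mammal"] == 1.5).all()

    def test_random_positions_match_pointwise_lookup(self, rng, tmp_path):
        cohort = random_cohort(rng, n_obs=30)
        var = cohort.variants_frame
        values = {}
        lines = ["chrom\tpos\tscore"]
        for vid in var.index:
            if rng.random() < 0.5:
                score = float(rng.normal())
                values[(var.loc[vid, "chrom"], int(var.loc[vid, "pos"]))] = score
                lines.append(
                    f"{var.loc[vid, 'chrom']}\t{var.loc[vid, 'pos']}\t{score}"
                )
        p = tmp_path / "track.tsv"
        p.write_text("\n".join(lines) + "\n")
        tracks = ScoreTracks()
        tracks.load("phastcons", "vertebrate", p)
        # transform into [0, 1] not applied here: raw values asserted
        sv.attach_scores(cohort, tracks)
        ann = cohort.ann_frame
        for row in ann.itertuples(index=False):
            key = cohort.key_of(row.vid)
            expected = values.get((key.chrom, key.pos))
            got = row.phastcons_vertebrate
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)
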