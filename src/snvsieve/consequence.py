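"""Classify SNVs against a gene model and attach conservation scores.

Consequence classes, by decreasing severity: ``essential_splice`` (intronic
positions 1-2 bases from an exon boundary, i.e. the donor GT / acceptor AG
dinucleotides), ``nonsense`` (gain or loss of a stop codon), ``nonsynonymous``
(amino-acid change), ``synonymous``, ``utr`` (exonic, outside the CDS),
``intronic`` and ``intergenic``.  Exonic bases adjacent to a splice junction
are classified by their codon effect; only intronic bases get the splice
class.  A variant overlapping several transcripts receives one annotation per
transcript; gene-level summaries elsewhere take the most severe.

Stop-loss is folded into ``nonsense`` (the class covers gain *or* loss of a
stop codon).  Transcripts whose CDS length is not divisible by three are
flagged non-analyzable and treated as non-coding (exonic positions -> utr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import (
    CLADES,
    Cohort,
    DataError,
    VariantAnnotation,
    VariantKey,
    normalize_chrom,
    open_text,
)

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# Standard nuclear codon table; stops map to "*".
_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def translate_codon(codon: str) -> str:
    """One-letter amino acid for *codon*; ``*`` for a stop codon."""
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE = _build_codon_table()
    return _CODON_TABLE[codon.upper()]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    """Ordered exon structure of one transcript (1-based inclusive intervals)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        for name, ivs in (("exons", self.exons), ("CDS", self.cds)):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise DataError(
                        f"{self.transcript_id}: overlapping {name} intervals"
                    )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def analyzable(self) -> bool:
        """True when the transcript has a CDS of length divisible by three."""
        return bool(self.cds) and self.cds_length % 3 == 0

    def exon_index_at(self, pos: int) -> int | None:
        """1-based exon index in transcript (5'->3') order containing *pos*."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return i + 1 if self.strand == "+" else len(self.exons) - i
        return None

    def splice_context(self, pos: int) -> int | None:
        """Adjacent exon's transcript-order index if *pos* is an essential
        splice base (intronic, within two bases of an internal exon edge)."""
        first_start, last_end = self.span
        best = None
        for i, (s, e) in enumerate(self.exons):
            if s != first_start and s - 2 <= pos <= s - 1:
                best = i
            if e != last_end and e + 1 <= pos <= e + 2:
                best = i
        if best is None:
            return None
        return best + 1 if self.strand == "+" else len(self.exons) - best


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)


class GeneModel:
    """Gene/transcript structures plus reference sequence access.

    ``sequences`` maps chromosome name to its full sequence string (synthetic
    models) or is a ``pyfaidx.Fasta`` handle (models loaded from disk).
    """

    def __init__(self, sequences: Mapping[str, str] | None = None):
        self.genes: dict[str, Gene] = {}
        self.transcripts: dict[str, Transcript] = {}
        self._seq = sequences if sequences is not None else {}
        self._trees: dict[str, IntervalTree] | None = None
        self._layouts: dict[str, tuple[np.ndarray, str]] = {}

    # -- construction ------------------------------------------------------

    def add_transcript(self, tx: Transcript) -> None:
        gene = self.genes.setdefault(
            tx.gene_id, Gene(gene_id=tx.gene_id, chrom=tx.chrom, strand=tx.strand)
        )
        gene.transcripts[tx.transcript_id] = tx
        self.transcripts[tx.transcript_id] = tx
        self._trees = None

    @classmethod
    def from_gff3(cls, gff_path, fasta_path=None) -> "GeneModel":
        """Load a gene model from GFF3 or GTF (exon/CDS features) and FASTA."""
        import gffutils

        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        sequences = None
        if fasta_path is not None:
            from pyfaidx import Fasta

            sequences = Fasta(str(fasta_path), sequence_always_upper=True)
        model = cls(sequences=sequences)
        tx_types = ("mRNA", "transcript")
        for ftype in tx_types:
            for feat in db.features_of_type(ftype):
                tid = feat.id
                gene_id = feat.attributes.get("Parent", [None])[0] or \
                    feat.attributes.get("gene_id", [tid])[0]
                exons = [
                    (c.start, c.end) for c in db.children(feat, featuretype="exon")
                ]
                cds = [(c.start, c.end) for c in db.children(feat, featuretype="CDS")]
                if not exons:
                    exons = cds[:]
                if not exons:
                    continue
                model.add_transcript(
                    Transcript(
                        transcript_id=tid,
                        gene_id=gene_id,
                        chrom=feat.seqid,
                        strand=feat.strand,
                        exons=exons,
                        cds=cds,
                    )
                )
        return model

    def to_gff3(self, path) -> None:
        with open_text(path, "wt") as fh:
            fh.write("##gff-version 3\n")
            for gene in self.genes.values():
                txs = list(gene.transcripts.values())
                gs = min(t.span[0] for t in txs)
                ge = max(t.span[1] for t in txs)
                fh.write(
                    f"{gene.chrom}\tsnvsieve\tgene\t{gs}\t{ge}\t.\t{gene.strand}\t."
                    f"\tID={gene.gene_id}\n"
                )
                for tx in txs:
                    s, e = tx.span
                    fh.write(
                        f"{tx.chrom}\tsnvsieve\tmRNA\t{s}\t{e}\t.\t{tx.strand}\t."
                        f"\tID={tx.transcript_id};Parent={gene.gene_id}\n"
                    )
                    for i, (xs, xe) in enumerate(tx.exons, start=1):
                        fh.write(
                            f"{tx.chrom}\tsnvsieve\texon\t{xs}\t{xe}\t.\t{tx.strand}"
                            f"\t.\tID={tx.transcript_id}.exon{i};"
                            f"Parent={tx.transcript_id}\n"
                        )
                    blocks = tx.cds if tx.strand == "+" else tx.cds[::-1]
                    cum = 0
                    for i, (cs, ce) in enumerate(blocks, start=1):
                        phase = (3 - cum % 3) % 3
                        fh.write(
                            f"{tx.chrom}\tsnvsieve\tCDS\t{cs}\t{ce}\t.\t{tx.strand}"
                            f"\t{phase}\tID={tx.transcript_id}.cds{i};"
                            f"Parent={tx.transcript_id}\n"
                        )
                        cum += ce - cs + 1

    def write_fasta(self, path, line_width: int = 70) -> None:
        with open_text(path, "wt") as fh:
            for chrom in sorted(self._seq, key=str):
                seq = str(self._seq[chrom][:]) if not isinstance(
                    self._seq[chrom], str
                ) else self._seq[chrom]
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i:i + line_width] + "\n")

    # -- sequence access ---------------------------------------------------

    def seq(self, chrom: str, start: int, end: int) -> str:
        """Reference bases for [start, end], 1-based inclusive."""
        chrom = normalize_chrom(chrom)
        src = self._seq[chrom]
        if isinstance(src, str):
            return src[start - 1:end]
        return str(src[start - 1:end]).upper()

    def base(self, chrom: str, pos: int) -> str:
        return self.seq(chrom, pos, pos)

    # -- CDS layout --------------------------------------------------------

    def cds_layout(self, transcript_id: str) -> tuple[np.ndarray, str]:
        """Genomic positions (translation order) and coding-strand CDS sequence."""
        cached = self._layouts.get(transcript_id)
        if cached is not None:
            return cached
        tx = self.transcripts[transcript_id]
        pos_parts, seq_parts = [], []
        for s, e in tx.cds:
            pos_parts.append(np.arange(s, e + 1, dtype=np.int64))
            seq_parts.append(self.seq(tx.chrom, s, e))
        positions = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        seq = "".join(seq_parts)
        if tx.strand == "-":
            positions = positions[::-1]
            seq = reverse_complement(seq)
        self._layouts[transcript_id] = (positions, seq)
        return positions, seq

    # -- lookup ------------------------------------------------------------

    def _ensure_trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for tx in self.transcripts.values():
                s, e = tx.span
                trees.setdefault(tx.chrom, IntervalTree()).addi(
                    s, e + 1, tx.transcript_id
                )
            self._trees = trees
        return self._trees

    def overlapping_transcripts(self, chrom: str, pos: int) -> list[Transcript]:
        trees = self._ensure_trees()
        tree = trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        tids = sorted(iv.data for iv in tree.at(pos))
        return [self.transcripts[t] for t in tids]

    def canonical_transcript(self, gene_id: str) -> str:
        """Longest-CDS transcript (ties: lexicographic id) of a gene."""
        txs = self.genes[gene_id].transcripts.values()
        return max(txs, key=lambda t: (t.cds_length, t.transcript_id)).transcript_id


def classify(
    key: VariantKey, model: GeneModel, canonical_only: bool = False
) -> list[VariantAnnotation]:
    """Classify an SNV against every overlapping transcript.

    Returns one annotation per transcript (``canonical_only`` restricts each
    gene to its longest-CDS transcript), or a single intergenic annotation
    when nothing overlaps.  Raises :class:`DataError` if ``key.ref`` disagrees
    with the model's reference base.
    """
    txs = model.overlapping_transcripts(key.chrom, key.pos)
    if canonical_only:
        keep = {model.canonical_transcript(t.gene_id) for t in txs}
        txs = [t for t in txs if t.transcript_id in keep]
    if not txs:
        return [
            VariantAnnotation(
                key=key, gene_id="", transcript_id="", consequence="intergenic"
            )
        ]
    ref_base = model.base(key.chrom, key.pos)
    if ref_base != key.ref:
        raise DataError(
            f"reference mismatch at {key.chrom}:{key.pos}: "
            f"model has {ref_base}, variant claims {key.ref}"
        )
    out = []
    for tx in txs:
        consequence, exon_index = _classify_on_transcript(key, tx, model)
        out.append(
            VariantAnnotation(
                key=key,
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                consequence=consequence,
                exon_index=exon_index,
            )
        )
    return out


def _classify_on_transcript(
    key: VariantKey, tx: Transcript, model: GeneModel
) -> tuple[str, int | None]:
    exon_index = tx.exon_index_at(key.pos)
    if exon_index is None:
        splice_exon = tx.splice_context(key.pos)
        if splice_exon is not None:
            return "essential_splice", splice_exon
        return "intronic", None
    if not tx.analyzable:
        return "utr", exon_index
    in_cds = any(s <= key.pos <= e for s, e in tx.cds)
    if not in_cds:
        return "utr", exon_index
    positions, cds_seq = model.cds_layout(tx.transcript_id)
    idx = int(np.nonzero(positions == key.pos)[0][0])
    codon_start = 3 * (idx // 3)
    codon = cds_seq[codon_start:codon_start + 3]
    offset = idx - codon_start
    alt_coding = key.alt if tx.strand == "+" else key.alt.translate(_COMPLEMENT)
    mutant = codon[:offset] + alt_coding + codon[offset + 1:]
    ref_aa, alt_aa = translate_codon(codon), translate_codon(mutant)
    if (ref_aa == "*") != (alt_aa == "*"):
        return "nonsense", exon_index
    if ref_aa != alt_aa:
        return "nonsynonymous", exon_index
    return "synonymous", exon_index


# -- conservation tracks ---------------------------------------------------


class ScoreTracks:
    """Per-base conservation tracks, one per (score family, clade).

    Lookups outside a track return missing (NaN), never 0.
    """

    def __init__(self):
        self._tracks: dict[tuple[str, str], dict[tuple[str, int], float]] = {}

    def add(self, family: str, clade: str,
            values: Mapping[tuple[str, int], float]) -> None:
        if family not in ("phylop", "phastcons"):
            raise DataError(f"unknown score family {family!r}")
        if clade not in CLADES:
            raise DataError(f"unknown clade {clade!r}")
        track = self._tracks.setdefault((family, clade), {})
        track.update({(normalize_chrom(c), int(p)): float(v)
                      for (c, p), v in values.items()})

    def load(self, family: str, clade: str, path) -> None:
        """Read a 3-column TSV (chrom, pos, score), gzip ok."""
        values = {}
        with open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() in ("chrom", "chr"):
                    continue
                try:
                    values[(parts[0], int(parts[1]))] = float(parts[2])
                except (IndexError, ValueError) as exc:
                    raise DataError(
                        f"{path}: malformed score line {lineno}"
                    ) from exc
        self.add(family, clade, values)

    def lookup(self, family: str, clade: str, chrom: str, pos: int) -> float:
        track = self._tracks.get((family, clade))
        if track is None:
            return float("nan")
        return track.get((normalize_chrom(chrom), int(pos)), float("nan"))

    @property
    def families(self) -> list[tuple[str, str]]:
        return sorted(self._tracks)


def attach_scores(cohort: Cohort, tracks: ScoreTracks) -> Cohort:
    """Fill the cohort's per-annotation conservation columns from *tracks*.

    Positions absent from a track stay NaN and are excluded from max-score
    aggregations downstream.  Returns the same cohort for chaining.
    """
    ann = cohort.ann_frame
    if ann.empty:
        return cohort
    var = cohort.variants_frame
    chroms = var["chrom"].to_numpy()[ann["vid"].to_numpy()]
    poss = var["pos"].to_numpy()[ann["vid"].to_numpy()]
    for family, clade in tracks.families:
        col = f"{family}_{clade}"
        ann[col] = [
            tracks.lookup(family, clade, c, p) for c, p in zip(chroms, poss)
        ]
    return cohort


def annotate_cohort(
    cohort: Cohort,
    model: GeneModel,
    tracks: ScoreTracks | None = None,
    canonical_only: bool = False,
) -> Cohort:
    """Classify every variant in the cohort and attach annotations in bulk."""
    rows = []
    var = cohort.variants_frame
    for vid, chrom, pos, ref, alt in zip(
        var.index, var["chrom"], var["pos"], var["ref"], var["alt"]
    ):
        for a in classify(VariantKey(chrom, int(pos), ref, alt), model,
                          canonical_only=canonical_only):
            rows.append(
                {
                    "vid": vid,
                    "gene_id": a.gene_id,
                    "transcript_id": a.transcript_id,
                    "exon_index": np.nan if a.exon_index is None
                    else float(a.exon_index),
                    "consequence": a.consequence,
                }
            )
    from .model import _empty_ann

    ann = pd.DataFrame(rows) if rows else _empty_ann()
    for c in ("phylop", "phastcons"):
        for clade in CLADES:
            ann[f"{c}_{clade}"] = np.nan
    out = Cohort._from_parts(
        cohort.samples, cohort.site_sets, cohort.variants_frame,
        cohort.obs_frame, ann, cohort.gene_scores,
    )
    if tracks is not None:
        attach_scores(out, tracks)
    return out
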