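"""Synthetic multi-sample exome cohorts with controlled variant counts.

The generator builds (i) a synthetic gene model — non-overlapping
single-transcript genes with UTRs, multi-exon CDS composed of sense codons,
and real nucleotide sequence on synthetic chromosomes — and (ii) a population
pool of SNVs per consequence class, each placed so that its codon effect
*actually is* the intended class.  Per-sample draws from the pool reproduce a
requested sample x class count matrix exactly (the generator's core
contract); pool variants carry a population allele frequency controlling how
often distinct samples share the same variant, and a per-site-set "known"
flag controlling novelty.

Defaults emulate the eight published exomes behind the Miller-syndrome
benchmark: the default count matrix is their per-sample consequence tally,
sample sizes and category mix included.  Coverage, allele-fraction and
conservation laws are stand-ins (the source exomes' distributions are not
published) and are documented as such.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .consequence import GeneModel, Transcript, translate_codon, _COMPLEMENT
from .datasets import COUNT_CATEGORIES, miller_exome_counts
from .model import (
    Cohort,
    ConfigError,
    DataError,
    SampleMeta,
    SiteSet,
    VariantKey,
)

log = logging.getLogger(__name__)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
)
_CODING = ("essential_splice", "nonsense", "nonsynonymous")


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``count_matrix`` is a sample x consequence-class DataFrame of exact
    per-sample observation counts (default: the published eight-exome tally).
    ``pool_scale`` sizes each class's population pool relative to the largest
    per-sample count; ``af_beta`` is the Beta law of pool allele frequencies
    and ``reuse_weight`` raises selection weight to ``af**reuse_weight`` so
    larger values concentrate draws on common variants (more cross-sample
    sharing).  ``known_fraction`` gives, per named site set, the probability
    that a pool variant is marked present in it — novelty is a property of
    the pool variant, so shared variants are consistently known or novel
    across samples.
    """

    count_matrix: pd.DataFrame | None = None
    n_genes: int = 18000
    cds_codons_lognorm: tuple[float, float] = (6.0, 0.7)
    min_codons: int = 60
    exon_mean: float = 7.0
    utr5_len: int = 150
    utr3_len: int = 200
    intron_len: int = 300
    intergenic_gap: int = 100
    n_chroms: int = 22
    pool_scale: float = 2.0
    af_beta: tuple[float, float] = (0.2, 2.0)
    reuse_weight: float = 1.0
    known_fraction: dict = field(
        default_factory=lambda: {"dbsnp": 0.90, "kg1000": 0.60}
    )
    coverage_shift: int = 5
    coverage_nb: tuple[float, float] = (8.0, 45.0)  # dispersion k, mean
    het_vaf_beta: tuple[float, float] = (25.0, 25.0)
    hom_vaf_beta: tuple[float, float] = (60.0, 2.0)
    phylop_coding: tuple[float, float] = (1.5, 1.0)
    phylop_neutral: tuple[float, float] = (0.0, 1.0)
    phylop_bounds: tuple[float, float] = (-14.0, 6.0)
    hap_score_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.count_matrix is None:
            self.count_matrix = miller_exome_counts()
        cm = pd.DataFrame(self.count_matrix)
        missing = set(COUNT_CATEGORIES) - set(cm.columns)
        if missing:
            raise ConfigError(f"count matrix lacks categories {sorted(missing)}")
        cm = cm[list(COUNT_CATEGORIES)].astype(np.int64)
        if (cm.to_numpy() < 0).any():
            raise ConfigError("count matrix entries must be >= 0")
        self.count_matrix = cm
        for name, f in self.known_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"known_fraction[{name}]={f} outside [0, 1]")
        if self.pool_scale < 1.0:
            raise ConfigError("pool_scale must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.count_matrix)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["count_matrix"] = {
            str(s): {c: int(v) for c, v in row.items()}
            for s, row in self.count_matrix.to_dict("index").items()
        }
        for key in ("cds_codons_lognorm", "coverage_nb", "het_vaf_beta",
                    "hom_vaf_beta", "phylop_coding", "phylop_neutral",
                    "phylop_bounds", "af_beta"):
            d[key] = list(d[key])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown cohort-spec fields {sorted(unknown)}")
        if "count_matrix" in d and d["count_matrix"] is not None:
            d["count_matrix"] = pd.DataFrame(d["count_matrix"]).T
        for key in ("cds_codons_lognorm", "coverage_nb", "het_vaf_beta",
                    "hom_vaf_beta", "phylop_coding", "phylop_neutral",
                    "phylop_bounds", "af_beta"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# -- gene model ------------------------------------------------------------


def _build_gene_model(spec: CohortSpec, rng: np.random.Generator) -> GeneModel:
    mu, sigma = spec.cds_codons_lognorm
    n_codons = np.maximum(
        spec.min_codons,
        np.round(rng.lognormal(mu, sigma, spec.n_genes)).astype(np.int64),
    )
    n_exons = 1 + rng.poisson(spec.exon_mean, spec.n_genes)
    n_exons = np.minimum(n_exons, n_codons)  # every exon needs CDS content
    strands = np.where(rng.random(spec.n_genes) < 0.5, "+", "-")
    chrom_of = np.arange(spec.n_genes) % spec.n_chroms

    # sample every codon of every gene at once (sense codons only; the final
    # stop codon is appended separately)
    total_codons = int(n_codons.sum())
    codon_idx = rng.integers(0, len(_SENSE_CODONS), total_codons)
    sense = np.frombuffer(
        "".join(_SENSE_CODONS).encode(), dtype="S1"
    ).reshape(len(_SENSE_CODONS), 3)
    all_bases = sense[codon_idx].reshape(-1)  # byte array, 3 * total_codons
    codon_offsets = np.concatenate([[0], np.cumsum(3 * n_codons)])

    chrom_names = [str(i + 1) for i in range(spec.n_chroms)]
    chrom_parts: dict[str, list] = {c: [] for c in chrom_names}
    chrom_cursor = {c: 0 for c in chrom_names}

    model = GeneModel(sequences={})
    genes_meta = []
    for g in range(spec.n_genes):
        cds_len = int(3 * n_codons[g])
        k = int(n_exons[g])
        # split the CDS into k non-empty pieces
        if k > 1:
            cuts = np.sort(rng.choice(np.arange(1, cds_len), size=k - 1,
                                      replace=False))
            pieces = np.diff(np.concatenate([[0], cuts, [cds_len]]))
        else:
            pieces = np.array([cds_len])
        chrom = chrom_names[chrom_of[g]]
        start = chrom_cursor[chrom] + spec.intergenic_gap + 1
        # genomic layout left->right: UTRa + cds pieces with introns + UTRb;
        # UTRa is the 5' UTR on + genes and the 3' UTR on - genes
        utra = spec.utr5_len if strands[g] == "+" else spec.utr3_len
        utrb = spec.utr3_len if strands[g] == "+" else spec.utr5_len
        exons, cds = [], []
        cursor = start
        for i, piece in enumerate(pieces):
            ex_start = cursor
            if i == 0:
                cursor += utra
            cds.append((cursor, cursor + int(piece) - 1))
            cursor += int(piece)
            if i == len(pieces) - 1:
                cursor += utrb
            exons.append((ex_start, cursor - 1))
            if i < len(pieces) - 1:
                cursor += spec.intron_len
        end = cursor - 1
        chrom_cursor[chrom] = end
        gene_id = f"G{g:05d}"
        tx = Transcript(
            transcript_id=f"{gene_id}.t1",
            gene_id=gene_id,
            chrom=chrom,
            strand=str(strands[g]),
            exons=exons,
            cds=cds,
        )
        model.add_transcript(tx)
        genes_meta.append((gene_id, tx, start, end, g))

    # materialize chromosome sequences: random background, CDS written on top
    genome: dict[str, np.ndarray] = {}
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    for chrom in chrom_names:
        length = chrom_cursor[chrom] + spec.intergenic_gap
        genome[chrom] = base_arr[rng.integers(0, 4, length)]

    comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}
    for gene_id, tx, start, end, g in genes_meta:
        lo, hi = codon_offsets[g], codon_offsets[g + 1]
        coding = all_bases[lo:hi]
        # overwrite the final codon with a stop so translation terminates
        stop = rng.choice(sorted(_STOPS))
        coding = coding.copy()
        coding[-3:] = np.frombuffer(stop.encode(), dtype="S1")
        positions = np.concatenate(
            [np.arange(s, e + 1, dtype=np.int64) for s, e in tx.cds]
        )
        if tx.strand == "-":
            positions = positions[::-1]
            genome[tx.chrom][positions - 1] = np.array(
                [comp[bytes(b)] for b in coding], dtype="S1"
            )
        else:
            genome[tx.chrom][positions - 1] = coding
        cds_seq = coding.tobytes().decode()
        model._layouts[tx.transcript_id] = (positions, cds_seq)

    model._seq = {c: genome[c].tobytes().decode() for c in chrom_names}
    return model


# -- pool construction -----------------------------------------------------


def _alt_for_category(codon: str, offset: int, category: str,
                      rng: np.random.Generator) -> str | None:
    """A coding-strand alternate base realizing *category*, or None."""
    ref_aa = translate_codon(codon)
    choices = []
    for b in _BASES:
        if b == codon[offset]:
            continue
        alt_aa = translate_codon(codon[:offset] + b + codon[offset + 1:])
        if category == "nonsynonymous":
            ok = ref_aa != "*" and alt_aa != "*" and alt_aa != ref_aa
        elif category == "nonsense":
            ok = (alt_aa == "*") != (ref_aa == "*")
        else:  # synonymous
            ok = alt_aa == ref_aa
        if ok:
            choices.append(b)
    if not choices:
        return None
    return choices[int(rng.integers(0, len(choices)))]


class _Placer:
    """Draws fresh variant positions of each functional class from a model."""

    def __init__(self, spec: CohortSpec, model: GeneModel,
                 rng: np.random.Generator):
        self.model = model
        self.rng = rng
        self.used: set[tuple[str, int]] = set()
        self.txs = [model.transcripts[t] for t in sorted(model.transcripts)]
        cds_lens = np.array([t.cds_length for t in self.txs], dtype=np.int64)
        self.cds_cum = np.cumsum(cds_lens)
        introns = np.array([len(t.exons) - 1 for t in self.txs], dtype=np.int64)
        self.intron_cum = np.cumsum(introns)
        utr_lens = np.array(
            [sum(e - s + 1 for s, e in t.exons) - t.cds_length for t in self.txs],
            dtype=np.int64,
        )
        self.utr_cum = np.cumsum(utr_lens)

    def capacity(self, category: str) -> int:
        if category in ("nonsynonymous", "nonsense", "synonymous"):
            return int(self.cds_cum[-1])
        if category == "essential_splice":
            return int(4 * self.intron_cum[-1])
        return int(self.utr_cum[-1])

    def _fresh(self, chrom: str, pos: int) -> bool:
        if (chrom, pos) in self.used:
            return False
        self.used.add((chrom, pos))
        return True

    def draw(self, category: str):
        """One pool variant: (key, gene, transcript, exon_index) tuples."""
        rng = self.rng
        for _ in range(10000):
            if category in ("nonsynonymous", "nonsense", "synonymous"):
                gi = int(rng.integers(0, self.cds_cum[-1]))
                t = int(np.searchsorted(self.cds_cum, gi, side="right"))
                tx = self.txs[t]
                i = gi - (self.cds_cum[t - 1] if t else 0)
                positions, cds_seq = self.model.cds_layout(tx.transcript_id)
                cs = 3 * (i // 3)
                alt_c = _alt_for_category(cds_seq[cs:cs + 3], i - cs, category, rng)
                if alt_c is None:
                    continue
                pos = int(positions[i])
                if not self._fresh(tx.chrom, pos):
                    continue
                if tx.strand == "-":
                    ref = cds_seq[i].translate(_COMPLEMENT)
                    alt = alt_c.translate(_COMPLEMENT)
                else:
                    ref, alt = cds_seq[i], alt_c
                key = VariantKey(tx.chrom, pos, ref, alt)
                return key, tx, tx.exon_index_at(pos)
            if category == "essential_splice":
                gi = int(rng.integers(0, self.intron_cum[-1]))
                t = int(np.searchsorted(self.intron_cum, gi, side="right"))
                tx = self.txs[t]
                j = gi - (self.intron_cum[t - 1] if t else 0)  # intron index
                side, off = int(rng.integers(0, 2)), int(rng.integers(1, 3))
                if side == 0:
                    pos = tx.exons[j][1] + off  # donor side of intron j
                else:
                    pos = tx.exons[j + 1][0] - off  # acceptor side
                if not self._fresh(tx.chrom, pos):
                    continue
                ref = self.model.base(tx.chrom, pos)
                alt = [b for b in _BASES if b != ref][int(rng.integers(0, 3))]
                key = VariantKey(tx.chrom, pos, ref, alt)
                return key, tx, tx.splice_context(pos)
            # utr
            gi = int(rng.integers(0, self.utr_cum[-1]))
            t = int(np.searchsorted(self.utr_cum, gi, side="right"))
            tx = self.txs[t]
            j = gi - (self.utr_cum[t - 1] if t else 0)
            pos = self._utr_pos(tx, j)
            if pos is None or not self._fresh(tx.chrom, pos):
                continue
            ref = self.model.base(tx.chrom, pos)
            alt = [b for b in _BASES if b != ref][int(rng.integers(0, 3))]
            key = VariantKey(tx.chrom, pos, ref, alt)
            return key, tx, tx.exon_index_at(pos)
        raise DataError(
            f"could not place a fresh {category} variant; "
            f"gene-model capacity exhausted"
        )

    @staticmethod
    def _utr_pos(tx: Transcript, j: int) -> int | None:
        """The j-th exonic non-CDS base of *tx* in genomic order."""
        cds_lo, cds_hi = tx.cds[0][0], tx.cds[-1][1]
        seen = 0
        for xs, xe in tx.exons:
            for p_lo, p_hi in ((xs, min(xe, cds_lo - 1)),
                               (max(xs, cds_hi + 1), xe)):
                if p_hi < p_lo:
                    continue
                width = p_hi - p_lo + 1
                if j < seen + width:
                    return p_lo + (j - seen)
                seen += width
        return None


# -- generation ------------------------------------------------------------


def generate(spec: CohortSpec,
             rng: np.random.Generator | None = None) -> tuple[Cohort, GeneModel]:
    """Generate a synthetic cohort and its gene model from *spec*.

    The per-(sample, class) tallies of the returned cohort equal the spec's
    count matrix exactly.  Identical spec and seed give a byte-identical
    cohort dump.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    cm = spec.count_matrix
    if int(cm.to_numpy().sum()) == 0:
        cohort = Cohort([SampleMeta(sample_id=str(s)) for s in cm.index])
        for name in spec.known_fraction:
            cohort.register_site_set(SiteSet(name=name, keys=frozenset()))
        return cohort, GeneModel(sequences={})

    model = _build_gene_model(spec, rng)
    placer = _Placer(spec, model, rng)

    pool_rows = []
    pool_slices: dict[str, slice] = {}
    for category in COUNT_CATEGORIES:
        need = int(cm[category].max())
        size = int(math.ceil(spec.pool_scale * need)) if need else 0
        if size > placer.capacity(category):
            raise DataError(
                f"requested {category} pool ({size}) exceeds gene-model "
                f"capacity ({placer.capacity(category)}); increase n_genes"
            )
        start = len(pool_rows)
        for _ in range(size):
            key, tx, exon_index = placer.draw(category)
            pool_rows.append((key, tx, exon_index, category))
        pool_slices[category] = slice(start, len(pool_rows))
    m = len(pool_rows)

    af = rng.beta(*spec.af_beta, m)
    known = {
        name: rng.random(m) < f for name, f in spec.known_fraction.items()
    }
    cat_arr = np.array([r[3] for r in pool_rows])
    coding = np.isin(cat_arr, _CODING)
    mu_c, sd_c = spec.phylop_coding
    mu_n, sd_n = spec.phylop_neutral
    lo, hi = spec.phylop_bounds
    mammal = np.where(
        coding, rng.normal(mu_c, sd_c, m), rng.normal(mu_n, sd_n, m)
    ).clip(lo, hi)
    primate = (0.6 * mammal + rng.normal(0, 0.3, m)).clip(lo, hi)
    vertebrate = (1.1 * mammal + rng.normal(0, 0.4, m)).clip(lo, hi)

    # exact per-(sample, class) draws: weighted sampling without replacement
    # via exponential races (weight af**reuse_weight)
    obs_vid, obs_sample = [], []
    for sample in cm.index:
        for category in COUNT_CATEGORIES:
            n = int(cm.loc[sample, category])
            if n == 0:
                continue
            sl = pool_slices[category]
            w = af[sl] ** spec.reuse_weight if spec.reuse_weight else \
                np.ones(sl.stop - sl.start)
            race = rng.exponential(1.0, sl.stop - sl.start) / w
            pick = np.argpartition(race, n - 1)[:n] + sl.start
            obs_vid.append(pick)
            obs_sample.append(np.full(n, str(sample), dtype=object))
    obs_vid = np.concatenate(obs_vid)
    obs_sample = np.concatenate(obs_sample)
    n_obs = len(obs_vid)

    af_obs = af[obs_vid]
    hom = rng.random(n_obs) < af_obs
    k_nb, mean_nb = spec.coverage_nb
    m0 = mean_nb - spec.coverage_shift
    coverage = spec.coverage_shift + rng.negative_binomial(
        k_nb, k_nb / (k_nb + m0), n_obs
    )
    vaf_true = np.where(
        hom, rng.beta(*spec.hom_vaf_beta, n_obs), rng.beta(*spec.het_vaf_beta, n_obs)
    )
    alt_reads = rng.binomial(coverage, vaf_true)
    vaf = np.where(coverage > 0, alt_reads / np.maximum(coverage, 1), 0.0)

    variants = pd.DataFrame(
        {
            "chrom": [r[0].chrom for r in pool_rows],
            "pos": np.array([r[0].pos for r in pool_rows], dtype=np.int64),
            "ref": [r[0].ref for r in pool_rows],
            "alt": [r[0].alt for r in pool_rows],
        }
    )
    site_sets = {}
    for name in spec.known_fraction:
        flags = known[name]
        keys = frozenset(
            r[0].astuple() for r, f in zip(pool_rows, flags) if f
        )
        site_sets[name] = SiteSet(name=name, keys=keys)
        variants[f"in_{name}"] = flags

    obs = pd.DataFrame(
        {
            "vid": obs_vid.astype(np.int64),
            "sample": obs_sample,
            "coverage": coverage.astype(np.int64),
            "alt_reads": alt_reads.astype(np.int64),
            "vaf": vaf,
            "zygosity": np.where(hom, "hom_alt", "het"),
        }
    )

    ann = pd.DataFrame(
        {
            "vid": np.arange(m, dtype=np.int64),
            "gene_id": [r[1].gene_id for r in pool_rows],
            "transcript_id": [r[1].transcript_id for r in pool_rows],
            "exon_index": [
                np.nan if r[2] is None else float(r[2]) for r in pool_rows
            ],
            "consequence": cat_arr,
            "phylop_primate": primate,
            "phylop_mammal": mammal,
            "phylop_vertebrate": vertebrate,
        }
    )
    for clade, arr in (("primate", primate), ("mammal", mammal),
                       ("vertebrate", vertebrate)):
        ann[f"phastcons_{clade}"] = 1.0 / (1.0 + np.exp(-1.5 * arr))

    gene_scores = {
        gid: float(rng.uniform())
        for gid in sorted(model.genes)
        if rng.random() < spec.hap_score_fraction
    }

    samples = {str(s): SampleMeta(sample_id=str(s)) for s in cm.index}
    cohort = Cohort._from_parts(samples, site_sets, variants, obs, ann,
                                gene_scores)
    return cohort, model


# -- spike-in --------------------------------------------------------------


def spike_in(
    cohort: Cohort,
    model: GeneModel,
    gene_id: str,
    per_case_variants: int,
    case_ids,
    rng: np.random.Generator | int,
    min_coverage: int = 10,
    min_vaf: float = 0.2,
    coverage_shift: int = 5,
    coverage_nb: tuple[float, float] = (8.0, 45.0),
    het_vaf_beta: tuple[float, float] = (25.0, 25.0),
    phylop_causal: tuple[float, float] = (2.5, 0.5),
) -> Cohort:
    """Add fresh causal variants to each case sample in one gene.

    Each case gains ``per_case_variants`` distinct, novel (fresh positions,
    absent from every site set), qualifying (coverage >= ``min_coverage``,
    VAF >= ``min_vaf``, heterozygous, nonsynonymous) variants in *gene_id*.
    Existing observations are untouched; a new cohort is returned.
    Conservation of the spiked alleles follows ``phylop_causal``, reflecting
    that causal coding variants sit at strongly conserved positions.
    """
    if per_case_variants < 1:
        raise ConfigError("per_case_variants must be >= 1")
    if gene_id not in model.genes:
        raise DataError(f"unknown gene {gene_id!r}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    tx = next(iter(model.genes[gene_id].transcripts.values()))
    positions, cds_seq = model.cds_layout(tx.transcript_id)
    var = cohort.variants_frame
    span_lo, span_hi = tx.span
    near = var[(var["chrom"] == tx.chrom) & var["pos"].between(span_lo, span_hi)]
    used = set(near["pos"].astype(int))

    new_var_rows, new_obs_rows, new_ann_rows = [], [], []
    set_names = list(cohort.site_sets)
    next_vid = cohort.n_variants
    lo, hi = -14.0, 6.0
    for case in case_ids:
        if case not in cohort.samples:
            raise DataError(f"unknown case sample {case!r}")
        placed = 0
        for _ in range(200 * per_case_variants):
            if placed == per_case_variants:
                break
            i = int(rng.integers(0, len(cds_seq)))
            pos = int(positions[i])
            if pos in used:
                continue
            cs = 3 * (i // 3)
            alt_c = _alt_for_category(cds_seq[cs:cs + 3], i - cs,
                                      "nonsynonymous", rng)
            if alt_c is None:
                continue
            used.add(pos)
            if tx.strand == "-":
                ref = cds_seq[i].translate(_COMPLEMENT)
                alt = alt_c.translate(_COMPLEMENT)
            else:
                ref, alt = cds_seq[i], alt_c
            k_nb, mean_nb = coverage_nb
            m0 = mean_nb - coverage_shift
            coverage = int(
                coverage_shift + rng.negative_binomial(k_nb, k_nb / (k_nb + m0))
            )
            coverage = max(coverage, min_coverage)
            vaf_true = float(rng.beta(*het_vaf_beta))
            alt_reads = int(rng.binomial(coverage, vaf_true))
            alt_reads = min(max(alt_reads, math.ceil(min_vaf * coverage)),
                            coverage)
            mammal = float(np.clip(rng.normal(*phylop_causal), lo, hi))
            primate = float(np.clip(0.6 * mammal + rng.normal(0, 0.3), lo, hi))
            vert = float(np.clip(1.1 * mammal + rng.normal(0, 0.4), lo, hi))
            row = {"chrom": tx.chrom, "pos": pos, "ref": ref, "alt": alt}
            for name in set_names:
                row[f"in_{name}"] = False
            new_var_rows.append(row)
            new_obs_rows.append(
                {
                    "vid": next_vid,
                    "sample": case,
                    "coverage": coverage,
                    "alt_reads": alt_reads,
                    "vaf": alt_reads / coverage,
                    "zygosity": "het",
                }
            )
            ann_row = {
                "vid": next_vid,
                "gene_id": gene_id,
                "transcript_id": tx.transcript_id,
                "exon_index": float(tx.exon_index_at(pos)),
                "consequence": "nonsynonymous",
                "phylop_primate": primate,
                "phylop_mammal": mammal,
                "phylop_vertebrate": vert,
            }
            for clade, v in (("primate", primate), ("mammal", mammal),
                             ("vertebrate", vert)):
                ann_row[f"phastcons_{clade}"] = 1.0 / (1.0 + np.exp(-1.5 * v))
            new_ann_rows.append(ann_row)
            next_vid += 1
            placed += 1
        if placed < per_case_variants:
            raise DataError(
                f"gene {gene_id} is too short to host {per_case_variants} "
                f"fresh qualifying variants for sample {case}"
            )
    variants = pd.concat(
        [cohort.variants_frame, pd.DataFrame(new_var_rows)], ignore_index=True
    )
    obs = pd.concat(
        [cohort.obs_frame, pd.DataFrame(new_obs_rows)], ignore_index=True
    )
    ann_new = pd.DataFrame(new_ann_rows).reindex(
        columns=cohort.ann_frame.columns
    )
    ann = pd.concat([cohort.ann_frame, ann_new], ignore_index=True)
    return Cohort._from_parts(
        cohort.samples, cohort.site_sets, variants, obs, ann, cohort.gene_scores
    )


def sharing_fraction(cohort: Cohort) -> float:
    """Fraction of observed variants carried by two or more samples."""
    counts = cohort.obs_frame["vid"].value_counts()
    if counts.empty:
        return 0.0
    return float((counts >= 2).mean())
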