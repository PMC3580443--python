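"""Core domain types and the in-memory cohort container.

The unit of analysis is the single-nucleotide variant (SNV): an immutable
:class:`VariantKey` identifies a substitution by (chrom, 1-based pos, ref, alt);
a :class:`VariantObservation` is one sample's call of that substitution with
read-level evidence (coverage, alternate-read count, variant allele frequency,
zygosity); a :class:`VariantAnnotation` places the substitution in a gene model
(gene, transcript, exon, consequence class) and carries per-clade conservation
scores plus passthrough predictor scores.

A :class:`Cohort` bundles samples, observations, annotations, named population
site sets and gene-level passthrough scores.  Canonical storage is columnar
(pandas DataFrames) so that cross-sample filtering, hit calling and the
randomization benchmark stay vectorized at exome scale; the dataclass types
above are materialized views over those tables.

Conventions
-----------
* Coordinates are 1-based inclusive (VCF convention) throughout.
* Chromosome names are normalized by stripping a leading ``chr`` prefix.
* Only non-reference calls are stored: absence of an observation means
  reference-equal or no-call, which matters for de novo semantics.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Consequence classes in decreasing order of severity.
CONSEQUENCES = (
    "essential_splice",
    "nonsense",
    "nonsynonymous",
    "synonymous",
    "utr",
    "intronic",
    "intergenic",
)
#: Severity rank per class; lower value = more severe.
SEVERITY = {c: i for i, c in enumerate(CONSEQUENCES)}

CLADES = ("primate", "mammal", "vertebrate")
ZYGOSITIES = ("het", "hom_alt", "unknown")
SAMPLE_GROUPS = ("case", "control", "parent", "unassigned")

_BASES = frozenset("ACGT")

OBS_COLUMNS = ("vid", "sample", "coverage", "alt_reads", "vaf", "zygosity")
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")
ANN_SCORE_COLUMNS = tuple(f"phylop_{c}" for c in CLADES) + tuple(
    f"phastcons_{c}" for c in CLADES
)
ANN_COLUMNS = (
    "vid",
    "gene_id",
    "transcript_id",
    "exon_index",
    "consequence",
) + ANN_SCORE_COLUMNS

#: Columns of the cohort TSV dump, in order.
DUMP_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample",
    "coverage",
    "alt_reads",
    "vaf",
    "zygosity",
)


class SnvSieveError(Exception):
    """Base class for all errors raised by this package."""


class InvariantError(SnvSieveError):
    """A domain-type invariant was violated."""


class DataError(SnvSieveError):
    """Input data is malformed or internally inconsistent."""


class ConfigError(SnvSieveError):
    """A configuration value is invalid or references unknown entities."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so mixed-source inputs agree on names."""
    return chrom[3:] if chrom[:3].lower() == "chr" else chrom


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Genomic identity of an SNV: chromosome, 1-based position, ref/alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(str(self.chrom)))
        object.__setattr__(self, "pos", int(self.pos))
        object.__setattr__(self, "ref", str(self.ref))
        object.__setattr__(self, "alt", str(self.alt))
        if self.pos < 1:
            raise InvariantError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise InvariantError(
                f"ref/alt must be single bases A/C/G/T, got {self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise InvariantError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    def astuple(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # e.g. "16:72048540:G>A"
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True, slots=True)
class VariantObservation:
    """One sample's call of a :class:`VariantKey` with read-level evidence.

    ``vaf`` defaults to ``alt_reads / coverage`` (0.0 when coverage is 0); when
    passed explicitly it must agree with that ratio to 1e-9.
    """

    key: VariantKey
    sample_id: str
    coverage: int
    alt_reads: int
    vaf: float = None  # type: ignore[assignment]
    zygosity: str = "unknown"

    def __post_init__(self):
        if self.coverage < 0 or self.alt_reads < 0:
            raise InvariantError("coverage and alt_reads must be non-negative")
        if self.alt_reads > self.coverage:
            raise InvariantError(
                f"alt_reads ({self.alt_reads}) > coverage ({self.coverage}) "
                f"for {self.key} in {self.sample_id}"
            )
        implied = self.alt_reads / self.coverage if self.coverage > 0 else 0.0
        if self.vaf is None:
            object.__setattr__(self, "vaf", implied)
        elif self.coverage > 0 and abs(self.vaf - implied) > 1e-9:
            raise InvariantError(
                f"vaf {self.vaf} inconsistent with {self.alt_reads}/{self.coverage}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise InvariantError(f"vaf must lie in [0, 1], got {self.vaf}")
        if self.zygosity not in ZYGOSITIES:
            raise InvariantError(f"unknown zygosity {self.zygosity!r}")


@dataclass(frozen=True, slots=True)
class VariantAnnotation:
    """Functional context of an SNV on one transcript."""

    key: VariantKey
    gene_id: str
    transcript_id: str
    consequence: str
    exon_index: int | None = None
    phylop: Mapping[str, float] = field(default_factory=dict)
    phastcons: Mapping[str, float] = field(default_factory=dict)
    known_in: frozenset[str] = frozenset()
    predictor_scores: Mapping[str, float] = field(default_factory=dict)
    haploinsufficiency: float | None = None

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise InvariantError(f"unknown consequence {self.consequence!r}")
        for clade, v in self.phastcons.items():
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise InvariantError(f"phastcons[{clade}]={v} outside [0, 1]")


@dataclass(slots=True)
class SampleMeta:
    """Sample identity, case/control/parent group and optional trio links."""

    sample_id: str
    group: str = "unassigned"
    father_id: str | None = None
    mother_id: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in SAMPLE_GROUPS:
            raise InvariantError(f"unknown sample group {self.group!r}")


@dataclass(frozen=True)
class SiteSet:
    """A named set of sites standing in for a population database.

    ``mode`` is ``"alleles"`` (members are (chrom, pos, ref, alt), the stricter
    default) or ``"positions"`` (members are (chrom, pos), dbSNP-era presence
    semantics).
    """

    name: str
    keys: frozenset
    mode: str = "alleles"

    def __post_init__(self):
        if self.mode not in ("alleles", "positions"):
            raise InvariantError(f"unknown site-set mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.keys)

    def contains(self, key: VariantKey) -> bool:
        if self.mode == "alleles":
            return key.astuple() in self.keys
        return (key.chrom, key.pos) in self.keys


def _empty_variants() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=object), "pos": pd.Series(dtype=np.int64),
         "ref": pd.Series(dtype=object), "alt": pd.Series(dtype=object)}
    )


def _empty_obs() -> pd.DataFrame:
    return pd.DataFrame(
        {"vid": pd.Series(dtype=np.int64), "sample": pd.Series(dtype=object),
         "coverage": pd.Series(dtype=np.int64), "alt_reads": pd.Series(dtype=np.int64),
         "vaf": pd.Series(dtype=np.float64), "zygosity": pd.Series(dtype=object)}
    )


def _empty_ann() -> pd.DataFrame:
    cols: dict = {"vid": pd.Series(dtype=np.int64)}
    for c in ("gene_id", "transcript_id"):
        cols[c] = pd.Series(dtype=object)
    cols["exon_index"] = pd.Series(dtype=np.float64)
    cols["consequence"] = pd.Series(dtype=object)
    for c in ANN_SCORE_COLUMNS:
        cols[c] = pd.Series(dtype=np.float64)
    return pd.DataFrame(cols)


class Cohort:
    """Samples, observations, annotations and site sets for one analysis.

    Observations are keyed by (variant, sample): inserting a duplicate replaces
    the stored call and logs a warning.  Annotations are keyed by
    (variant, transcript).  Variants are interned: each distinct
    (chrom, pos, ref, alt) gets an integer ``vid`` used throughout the columnar
    tables.
    """

    def __init__(self, samples: Iterable[SampleMeta] = ()):
        self.samples: dict[str, SampleMeta] = {}
        self.site_sets: dict[str, SiteSet] = {}
        self.gene_scores: dict[str, float] = {}  # gene-level haploinsufficiency
        self._variants = _empty_variants()
        self._obs = _empty_obs()
        self._ann = _empty_ann()
        self._vindex: dict[tuple, int] | None = {}
        self._obs_index: dict[tuple, int] | None = {}
        self._ann_index: dict[tuple, int] | None = {}
        for s in samples:
            self.add_sample(s)

    # -- construction -----------------------------------------------------

    @classmethod
    def _from_parts(
        cls,
        samples: Mapping[str, SampleMeta],
        site_sets: Mapping[str, SiteSet],
        variants: pd.DataFrame,
        obs: pd.DataFrame,
        ann: pd.DataFrame,
        gene_scores: Mapping[str, float] | None = None,
    ) -> "Cohort":
        """Trusted bulk constructor: frames are adopted without validation."""
        c = cls.__new__(cls)
        c.samples = dict(samples)
        c.site_sets = dict(site_sets)
        c.gene_scores = dict(gene_scores or {})
        c._variants = variants
        c._obs = obs.reset_index(drop=True)
        c._ann = ann.reset_index(drop=True)
        c._vindex = None  # built lazily
        c._obs_index = None
        c._ann_index = None
        return c

    def replace_observations(self, obs: pd.DataFrame) -> "Cohort":
        """New cohort sharing everything but the observation table."""
        return Cohort._from_parts(
            self.samples, self.site_sets, self._variants, obs, self._ann,
            self.gene_scores,
        )

    # -- frame access ------------------------------------------------------

    @property
    def variants_frame(self) -> pd.DataFrame:
        """Variant table indexed by vid (chrom, pos, ref, alt + ``in_<set>``)."""
        return self._variants

    @property
    def obs_frame(self) -> pd.DataFrame:
        """Observation table (vid, sample, coverage, alt_reads, vaf, zygosity)."""
        return self._obs

    @property
    def ann_frame(self) -> pd.DataFrame:
        """Annotation table, one row per (vid, transcript)."""
        return self._ann

    @property
    def n_observations(self) -> int:
        return len(self._obs)

    @property
    def n_variants(self) -> int:
        return len(self._variants)

    def _ensure_vindex(self) -> dict[tuple, int]:
        if self._vindex is None:
            self._vindex = {
                (c, p, r, a): vid
                for vid, c, p, r, a in zip(
                    self._variants.index,
                    self._variants["chrom"],
                    self._variants["pos"],
                    self._variants["ref"],
                    self._variants["alt"],
                )
            }
        return self._vindex

    def _ensure_obs_index(self) -> dict[tuple, int]:
        if self._obs_index is None:
            self._obs_index = {
                (v, s): i
                for i, (v, s) in enumerate(zip(self._obs["vid"], self._obs["sample"]))
            }
        return self._obs_index

    def _ensure_ann_index(self) -> dict[tuple, int]:
        if self._ann_index is None:
            self._ann_index = {
                (v, t): i
                for i, (v, t) in enumerate(
                    zip(self._ann["vid"], self._ann["transcript_id"])
                )
            }
        return self._ann_index

    # -- variants ----------------------------------------------------------

    def vid_of(self, key: VariantKey) -> int | None:
        return self._ensure_vindex().get(key.astuple())

    def key_of(self, vid: int) -> VariantKey:
        row = self._variants.loc[vid]
        return VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])

    def intern_variant(self, key: VariantKey) -> int:
        """Return the vid for *key*, creating a variant row if unseen."""
        vindex = self._ensure_vindex()
        vid = vindex.get(key.astuple())
        if vid is not None:
            return vid
        vid = len(self._variants)
        row: dict = dict(zip(VARIANT_COLUMNS, key.astuple()))
        for name, sset in self.site_sets.items():
            row[f"in_{name}"] = sset.contains(key)
        self._variants.loc[vid] = row
        vindex[key.astuple()] = vid
        return vid

    # -- samples -----------------------------------------------------------

    def add_sample(self, meta: SampleMeta) -> None:
        if meta.sample_id in self.samples:
            raise DataError(f"duplicate sample id {meta.sample_id!r}")
        self.samples[meta.sample_id] = meta

    def validate_pedigree(self) -> None:
        """Check that every parent reference resolves to a cohort sample."""
        for s in self.samples.values():
            for role, pid in (("father", s.father_id), ("mother", s.mother_id)):
                if pid is not None and pid not in self.samples:
                    raise DataError(
                        f"sample {s.sample_id!r} names absent {role} {pid!r}"
                    )

    def samples_in_group(self, group: str) -> list[str]:
        return [s.sample_id for s in self.samples.values() if s.group == group]

    # -- observations ------------------------------------------------------

    def add_observation(self, obs: VariantObservation) -> None:
        """Insert one call; a duplicate (variant, sample) replaces with a warning."""
        if obs.sample_id not in self.samples:
            raise DataError(f"unknown sample id {obs.sample_id!r}")
        vid = self.intern_variant(obs.key)
        oindex = self._ensure_obs_index()
        row = (vid, obs.sample_id, obs.coverage, obs.alt_reads, obs.vaf, obs.zygosity)
        pos = oindex.get((vid, obs.sample_id))
        if pos is not None:
            log.warning(
                "replacing existing call for %s in sample %s", obs.key, obs.sample_id
            )
            self._obs.iloc[pos] = row
        else:
            oindex[(vid, obs.sample_id)] = len(self._obs)
            self._obs.loc[len(self._obs)] = row

    def merge_observation(self, obs: VariantObservation) -> None:
        """Insert a call, keeping the higher-coverage one on conflict.

        Used when combining multiple call files for one sample; the losing call
        is logged.
        """
        if obs.sample_id not in self.samples:
            raise DataError(f"unknown sample id {obs.sample_id!r}")
        vid = self.intern_variant(obs.key)
        pos = self._ensure_obs_index().get((vid, obs.sample_id))
        if pos is not None:
            existing = int(self._obs.iloc[pos]["coverage"])
            if existing >= obs.coverage:
                log.warning(
                    "conflicting call for %s in %s: keeping coverage %d over %d",
                    obs.key, obs.sample_id, existing, obs.coverage,
                )
                return
            log.warning(
                "conflicting call for %s in %s: keeping coverage %d over %d",
                obs.key, obs.sample_id, obs.coverage, existing,
            )
        self.add_observation(obs)

    def observations(self) -> Iterator[VariantObservation]:
        for row in self._obs.itertuples(index=False):
            yield VariantObservation(
                key=self.key_of(row.vid),
                sample_id=row.sample,
                coverage=int(row.coverage),
                alt_reads=int(row.alt_reads),
                vaf=float(row.vaf),
                zygosity=row.zygosity,
            )

    def sample_keys(self, sample_id: str) -> set[VariantKey]:
        vids = self._obs.loc[self._obs["sample"] == sample_id, "vid"]
        return {self.key_of(int(v)) for v in vids}

    def variant_sharing_counts(self) -> dict[VariantKey, int]:
        """Number of samples carrying each variant."""
        counts = self._obs["vid"].value_counts()
        return {self.key_of(int(v)): int(n) for v, n in counts.items()}

    def per_sample_counts(self) -> dict[str, int]:
        return self._obs["sample"].value_counts().to_dict()

    # -- annotations -------------------------------------------------------

    def add_annotation(self, ann: VariantAnnotation) -> None:
        """Attach a per-transcript annotation; (variant, transcript) is unique."""
        vid = self.intern_variant(ann.key)
        aindex = self._ensure_ann_index()
        if (vid, ann.transcript_id) in aindex:
            raise DataError(
                f"duplicate annotation for {ann.key} on {ann.transcript_id}"
            )
        row: dict = {
            "vid": vid,
            "gene_id": ann.gene_id,
            "transcript_id": ann.transcript_id,
            "exon_index": np.nan if ann.exon_index is None else float(ann.exon_index),
            "consequence": ann.consequence,
        }
        for clade in CLADES:
            row[f"phylop_{clade}"] = ann.phylop.get(clade, np.nan)
            row[f"phastcons_{clade}"] = ann.phastcons.get(clade, np.nan)
        for name, score in ann.predictor_scores.items():
            col = f"score_{name}"
            if col not in self._ann.columns:
                self._ann[col] = np.nan
            row[col] = score
        aindex[(vid, ann.transcript_id)] = len(self._ann)
        self._ann.loc[len(self._ann)] = {
            c: row.get(c, np.nan) for c in self._ann.columns
        }
        if ann.haploinsufficiency is not None:
            self.gene_scores[ann.gene_id] = ann.haploinsufficiency

    def annotations(self) -> Iterator[VariantAnnotation]:
        score_cols = [c for c in self._ann.columns if c.startswith("score_")]
        for row in self._ann.itertuples(index=False):
            key = self.key_of(row.vid)
            yield VariantAnnotation(
                key=key,
                gene_id=row.gene_id,
                transcript_id=row.transcript_id,
                consequence=row.consequence,
                exon_index=None if pd.isna(row.exon_index) else int(row.exon_index),
                phylop={c: getattr(row, f"phylop_{c}") for c in CLADES},
                phastcons={c: getattr(row, f"phastcons_{c}") for c in CLADES},
                known_in=frozenset(
                    n for n, s in self.site_sets.items() if s.contains(key)
                ),
                predictor_scores={
                    c[len("score_"):]: getattr(row, c)
                    for c in score_cols
                    if not pd.isna(getattr(row, c))
                },
                haploinsufficiency=self.gene_scores.get(row.gene_id),
            )

    def worst_consequence_per_variant(self) -> pd.Series:
        """vid -> most severe consequence over all transcripts (gene summary)."""
        if self._ann.empty:
            return pd.Series(dtype=object)
        sev = self._ann["consequence"].map(SEVERITY)
        order = sev.groupby(self._ann["vid"]).idxmin()
        return pd.Series(
            self._ann.loc[order.values, "consequence"].values, index=order.index
        )

    # -- site sets ---------------------------------------------------------

    def register_site_set(self, sset: SiteSet) -> None:
        if sset.name in self.site_sets:
            raise DataError(f"site set {sset.name!r} already registered")
        self.site_sets[sset.name] = sset
        if len(self._variants):
            if sset.mode == "alleles":
                member = [
                    (c, p, r, a) in sset.keys
                    for c, p, r, a in zip(
                        self._variants["chrom"], self._variants["pos"],
                        self._variants["ref"], self._variants["alt"],
                    )
                ]
            else:
                member = [
                    (c, p) in sset.keys
                    for c, p in zip(self._variants["chrom"], self._variants["pos"])
                ]
            self._variants[f"in_{sset.name}"] = np.asarray(member, dtype=bool)
        else:
            self._variants[f"in_{sset.name}"] = pd.Series(dtype=bool)

    def site_membership(self, name: str) -> np.ndarray:
        """Boolean membership array aligned with the variant table index."""
        if name not in self.site_sets:
            raise ConfigError(f"unknown site set {name!r}")
        return self._variants[f"in_{name}"].to_numpy(dtype=bool)

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the observation dump (one call per line, DUMP_COLUMNS order)."""
        df = self._obs.merge(
            self._variants[list(VARIANT_COLUMNS)], left_on="vid", right_index=True
        )[list(DUMP_COLUMNS)]
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def annotations_to_tsv(self, path) -> None:
        df = self._ann.merge(
            self._variants[list(VARIANT_COLUMNS)], left_on="vid", right_index=True
        )
        cols = list(VARIANT_COLUMNS) + [c for c in self._ann.columns if c != "vid"]
        df[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, samples: Iterable[SampleMeta] | None = None,
                 annotations_path=None) -> "Cohort":
        """Read a cohort dump written by :meth:`to_tsv` (gzip ok by suffix).

        Unknown samples are auto-registered with group ``unassigned`` unless
        *samples* provides metadata.
        """
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = set(DUMP_COLUMNS) - set(df.columns)
        if missing:
            raise DataError(f"cohort dump {path} lacks columns {sorted(missing)}")
        df["chrom"] = df["chrom"].map(normalize_chrom)
        metas = {m.sample_id: m for m in (samples or [])}
        cohort = cls()
        for sid in pd.unique(df["sample"]):
            cohort.add_sample(metas.pop(sid, None) or SampleMeta(sample_id=str(sid)))
        for m in metas.values():
            cohort.add_sample(m)
        variants = df[list(VARIANT_COLUMNS)].drop_duplicates().reset_index(drop=True)
        vindex = {
            t: i for i, t in enumerate(
                zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"])
            )
        }
        obs = pd.DataFrame(
            {
                "vid": [
                    vindex[t]
                    for t in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
                ],
                "sample": df["sample"].astype(str),
                "coverage": df["coverage"].astype(np.int64),
                "alt_reads": df["alt_reads"].astype(np.int64),
                "vaf": df["vaf"].astype(np.float64),
                "zygosity": df["zygosity"].astype(str),
            }
        )
        if obs.duplicated(subset=["vid", "sample"]).any():
            raise DataError(f"cohort dump {path} repeats a (variant, sample) pair")
        bad = obs["alt_reads"] > obs["coverage"]
        if bad.any():
            raise InvariantError(
                f"{int(bad.sum())} rows with alt_reads > coverage in {path}"
            )
        ann = _empty_ann()
        if annotations_path is not None:
            adf = pd.read_csv(annotations_path, sep="\t", dtype={"chrom": str})
            adf["chrom"] = adf["chrom"].map(normalize_chrom)
            vids = []
            for t in zip(adf["chrom"], adf["pos"], adf["ref"], adf["alt"]):
                if t not in vindex:
                    vindex[t] = len(vindex)
                    variants.loc[vindex[t]] = dict(zip(VARIANT_COLUMNS, t))
                vids.append(vindex[t])
            ann = adf.drop(columns=list(VARIANT_COLUMNS)).assign(vid=vids)
            ann = ann[
                ["vid"] + [c for c in ann.columns if c != "vid"]
            ].reset_index(drop=True)
        return cls._from_parts(cohort.samples, {}, variants, obs, ann)

    # -- misc --------------------------------------------------------------

    def __repr__(self) -> str:
        return (
            f"Cohort({len(self.samples)} samples, {self.n_observations} observations, "
            f"{self.n_variants} variants, {len(self._ann)} annotations)"
        )


def open_text(path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file by suffix."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)
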