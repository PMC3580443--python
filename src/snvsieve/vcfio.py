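"""Readers and writers for the standard formats the tool touches.

Multi-sample VCF 4.x is read with cyvcf2; site lists, pedigree tables,
gene-to-complex membership tables and ranked-table exports are plain TSV
(gzip accepted everywhere by suffix).

VAF source priority when reading VCF: per-sample AD (alt reads and coverage =
sum of allele depths) -> DP plus a configured allele-fraction FORMAT tag ->
coverage 0 with a logged warning.  Missing genotypes (``./.``) yield no
observation; multi-allelic records are split into one variant per alternate
allele.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    Cohort,
    DataError,
    SampleMeta,
    SiteSet,
    VariantKey,
    VariantObservation,
    normalize_chrom,
    open_text,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "read_sites",
    "read_pedigree",
    "read_complex_membership",
    "write_ranked_table",
    "SiteSet",
]

#: Column order of the ranked-table TSV export.
RANKED_COLUMNS = (
    "rank",
    "unit_id",
    "n_samples",
    "n_unique_variants",
    "n_total_variants",
    "haploinsufficiency",
    "max_phylop_mammal",
)

_SNV_BASES = frozenset("ACGT")


def read_vcf(
    path,
    sample_subset: Sequence[str] | None = None,
    cohort: Cohort | None = None,
    vaf_tag: str | None = None,
) -> Cohort:
    """Read non-reference SNV calls from a multi-sample VCF 4.x file.

    Parameters
    ----------
    path
        VCF (optionally bgzip/gzip compressed). Must carry GT and, for depth,
        AD and/or DP FORMAT fields.
    sample_subset
        Restrict to these sample ids (default: all samples in the header).
    cohort
        Merge into an existing cohort (conflicting calls for the same sample
        keep the higher-coverage one); default builds a fresh one.
    vaf_tag
        FORMAT tag holding an allele fraction, consulted when AD is absent
        but DP is present (e.g. ``FREQ`` from some callers).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = set(sample_subset) - set(all_samples)
        if missing:
            raise DataError(f"samples {sorted(missing)} not in VCF {path}")
        use = [s for s in all_samples if s in set(sample_subset)]
    else:
        use = all_samples
    col = {s: i for i, s in enumerate(all_samples)}

    if cohort is None:
        cohort = Cohort()
    for s in use:
        if s not in cohort.samples:
            cohort.add_sample(SampleMeta(sample_id=s))

    n_depthless = 0
    for rec in vcf:
        if rec.genotypes is None:
            raise DataError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        ref = rec.REF.upper()
        if ref not in _SNV_BASES:
            continue  # indel / MNV scope ends here
        def _fmt(tag):
            try:
                return rec.format(tag)
            except KeyError:  # tag not declared in the header
                return None

        ad = _fmt("AD")
        dp = _fmt("DP")
        fr = _fmt(vaf_tag) if vaf_tag else None
        for alt_index, alt in enumerate(rec.ALT, start=1):
            alt = alt.upper()
            if alt not in _SNV_BASES:
                continue
            key = VariantKey(rec.CHROM, rec.POS, ref, alt)
            for s in use:
                gt = rec.genotypes[col[s]]
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                if not alleles or alt_index not in alleles:
                    continue
                n_alt = alleles.count(alt_index)
                zyg = "hom_alt" if n_alt == len(alleles) and len(alleles) > 1 else "het"
                coverage = alt_reads = 0
                if ad is not None and not np.all(ad[col[s]] < 0):
                    depths = np.clip(ad[col[s]], 0, None)
                    coverage = int(depths.sum())
                    alt_reads = int(depths[alt_index])
                elif dp is not None and dp[col[s]] >= 0:
                    coverage = int(np.atleast_1d(dp[col[s]])[0])
                    if fr is not None:
                        frac = float(np.atleast_1d(fr[col[s]])[0])
                        alt_reads = int(round(frac * coverage))
                    else:
                        n_depthless += 1
                else:
                    n_depthless += 1
                alt_reads = min(alt_reads, coverage)
                cohort.merge_observation(
                    VariantObservation(
                        key=key,
                        sample_id=s,
                        coverage=coverage,
                        alt_reads=alt_reads,
                        zygosity=zyg,
                    )
                )
    if n_depthless:
        log.warning(
            "%d calls in %s lacked usable depth fields; coverage recorded as 0",
            n_depthless, path,
        )
    return cohort


def read_sites(path, name: str, mode: str = "alleles") -> SiteSet:
    """Read a site list (TSV chrom, pos[, ref, alt]) into a named SiteSet.

    Lines starting with ``#`` are skipped, so sites-only VCFs work too.
    Duplicate lines are deduplicated.  In ``positions`` mode any ref/alt
    columns are ignored.
    """
    keys = set()
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("chrom", "chr", "chromosome"):
                continue  # header
            try:
                chrom = normalize_chrom(parts[0])
                pos = int(parts[1])
            except (IndexError, ValueError) as exc:
                raise DataError(f"{path}: malformed site at line {lineno}") from exc
            if mode == "positions":
                keys.add((chrom, pos))
                continue
            if len(parts) < 4 or parts[2].upper() not in _SNV_BASES \
                    or parts[3].upper() not in _SNV_BASES:
                raise DataError(
                    f"{path}: line {lineno} lacks ref/alt columns needed in "
                    f"alleles mode"
                )
            keys.add((chrom, pos, parts[2].upper(), parts[3].upper()))
    return SiteSet(name=name, keys=frozenset(keys), mode=mode)


def read_pedigree(path) -> list[SampleMeta]:
    """Read a pedigree TSV with columns sample, father, mother, group.

    Empty, ``-``, ``.`` or ``0`` parent fields mean "no parent on record".
    Parent references are validated later, at cohort-assembly time
    (:meth:`Cohort.validate_pedigree`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample", "father", "mother", "group"}
    if not required <= set(df.columns):
        raise DataError(f"pedigree {path} must have columns {sorted(required)}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise DataError(f"pedigree {path}: duplicate sample id {dup!r}")
    none = {"", "-", ".", "0"}
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            SampleMeta(
                sample_id=row.sample,
                group=row.group or "unassigned",
                father_id=None if row.father in none else row.father,
                mother_id=None if row.mother in none else row.mother,
            )
        )
    return metas


def read_complex_membership(path) -> dict[str, list[str]]:
    """Read a two-column TSV gene_id -> complex_id (CORUM-style export)."""
    mapping: dict[str, list[str]] = {}
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("gene", "gene_id"):
                continue
            if len(parts) < 2:
                raise DataError(f"{path}: line {lineno} needs two columns")
            mapping.setdefault(parts[0], [])
            if parts[1] not in mapping[parts[0]]:
                mapping[parts[0]].append(parts[1])
    return mapping


def write_ranked_table(table, path) -> None:
    """Export a ranked table to TSV in the fixed RANKED_COLUMNS order."""
    df = table.frame if hasattr(table, "frame") else table
    out = pd.DataFrame({c: df.get(c, np.nan) for c in RANKED_COLUMNS})
    if len(out) and (
        out["rank"].min() != 1 or not (np.diff(out["rank"]) == 1).all()
    ):
        raise DataError("ranked table must carry contiguous 1..N ranks")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ranked_table(path) -> pd.DataFrame:
    """Re-read a ranked-table TSV (column order per :data:`RANKED_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != RANKED_COLUMNS:
        raise DataError(f"{path} is not a ranked-table export")
    return df
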