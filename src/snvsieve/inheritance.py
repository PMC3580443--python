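"""Convert a filtered cohort into unit x sample hits under a genetic model.

Models
------
dominant
    A unit (gene, exon or complex) is a hit in a sample if it carries at
    least one qualifying variant.
recessive
    At least two *distinct* variants in the unit for that sample — an
    unphased compound-heterozygote proxy (a causal homozygous non-reference
    variant being considered highly unlikely).  ``allow_hom_alt=True``
    additionally accepts a single homozygous-alt call (off by default).
de novo
    A variant present in a child and absent from both parents.  Because only
    non-reference calls are stored, "absent" conflates reference-equal with
    no-call; an optional parental-coverage gate makes that limitation
    explicit.

Phase is ignored throughout: two variants in one gene count as
recessive-compatible regardless of haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .model import Cohort, ConfigError, DataError, VariantKey

log = logging.getLogger(__name__)

MODELS = ("dominant", "recessive", "denovo")
UNIT_LEVELS = ("gene", "exon", "complex")


@dataclass
class HitMatrix:
    """Unit x sample hits with their supporting variants.

    ``support`` is a long DataFrame (unit, sample, vid) restricted to
    (unit, sample) pairs that satisfy the model; a pair is a hit iff it has
    at least one support row.
    """

    unit_level: str
    model: str
    support: pd.DataFrame
    cohort: Cohort

    @property
    def pairs(self) -> pd.DataFrame:
        """One row per hit (unit, sample) with its distinct-support count."""
        if self.support.empty:
            return pd.DataFrame(columns=["unit", "sample", "n_support"])
        return (
            self.support.groupby(["unit", "sample"], sort=True)["vid"]
            .nunique()
            .rename("n_support")
            .reset_index()
        )

    @property
    def hits(self) -> dict[tuple[str, str], list[VariantKey]]:
        """Mapping (unit_id, sample_id) -> supporting variant keys."""
        out: dict[tuple[str, str], list[VariantKey]] = {}
        for row in self.support.itertuples(index=False):
            out.setdefault((row.unit, row.sample), []).append(
                self.cohort.key_of(int(row.vid))
            )
        return out

    @property
    def units(self) -> list[str]:
        return sorted(self.support["unit"].unique()) if len(self.support) else []

    def samples_per_unit(self) -> pd.Series:
        """unit -> number of samples in which the unit is a hit."""
        if self.support.empty:
            return pd.Series(dtype=np.int64)
        return self.support.groupby("unit")["sample"].nunique()

    def restrict_samples(self, sample_ids) -> "HitMatrix":
        """Keep hits of the given samples only (e.g. cases when ranking)."""
        keep = self.support["sample"].isin(set(sample_ids))
        return HitMatrix(self.unit_level, self.model,
                         self.support[keep].reset_index(drop=True), self.cohort)

    def to_tsv(self, path) -> None:
        """Long-format export: unit, sample, n_support, semicolon-joined keys."""
        rows = []
        for (unit, sample), keys in sorted(self.hits.items()):
            rows.append(
                {
                    "unit": unit,
                    "sample": sample,
                    "n_support": len(set(keys)),
                    "supporting_variants": ";".join(str(k) for k in sorted(
                        keys, key=lambda k: (k.chrom, k.pos, k.ref, k.alt))),
                }
            )
        pd.DataFrame(
            rows, columns=["unit", "sample", "n_support", "supporting_variants"]
        ).to_csv(path, sep="\t", index=False)


def unit_map(cohort: Cohort, unit_level: str) -> pd.DataFrame:
    """Map each annotated variant to its units (columns vid, unit).

    Gene level: every gene a variant is annotated on (intergenic rows are
    ignored).  Exon level: (gene, transcript, exon_index) identity, so the
    recessive rule becomes a locality test — both variants must share the
    exon.
    """
    ann = cohort.ann_frame
    if unit_level == "gene":
        rows = ann[(ann["consequence"] != "intergenic") & (ann["gene_id"] != "")]
        out = rows[["vid", "gene_id"]].rename(columns={"gene_id": "unit"})
    elif unit_level == "exon":
        rows = ann[ann["exon_index"].notna()]
        out = pd.DataFrame(
            {
                "vid": rows["vid"].to_numpy(),
                "unit": rows["gene_id"].astype(str)
                + "|" + rows["transcript_id"].astype(str)
                + "|exon" + rows["exon_index"].astype(int).astype(str),
            }
        )
    else:
        raise ConfigError(
            f"unit level {unit_level!r} is not derivable from annotations "
            f"(complex matrices come from collapse_complexes)"
        )
    return out.drop_duplicates().reset_index(drop=True)


def call_hits(
    cohort: Cohort,
    model: str,
    unit_level: str = "gene",
    allow_hom_alt: bool = False,
) -> HitMatrix:
    """Call unit x sample hits on an (already filtered) cohort.

    Every observation in *cohort* is treated as qualifying; run
    :func:`snvsieve.filters.apply_filters` first.
    """
    if model not in ("dominant", "recessive"):
        raise ConfigError(f"unknown inheritance model {model!r}")
    units = unit_map(cohort, unit_level)
    obs = cohort.obs_frame
    support = obs[["vid", "sample", "zygosity"]].merge(units, on="vid")
    if support.empty:
        return HitMatrix(unit_level, model,
                         support[["unit", "sample", "vid"]], cohort)
    grouped = support.groupby(["unit", "sample"], sort=False)
    n_distinct = grouped["vid"].transform("nunique")
    if model == "dominant":
        ok = np.ones(len(support), dtype=bool)
    else:
        ok = (n_distinct >= 2).to_numpy()
        if allow_hom_alt:
            ok |= grouped["zygosity"].transform(
                lambda z: (z == "hom_alt").any()
            ).to_numpy()
    kept = support.loc[ok, ["unit", "sample", "vid"]].reset_index(drop=True)
    return HitMatrix(unit_level, model, kept, cohort)


def call_denovo(
    cohort: Cohort,
    child_id: str,
    unit_level: str = "gene",
    min_parent_coverage: int = 0,
    parent_coverage: Callable[[VariantKey, str], float] | None = None,
) -> HitMatrix:
    """Call de novo hits for a child against its parents.

    A child variant is de novo iff neither parent has a stored (non-reference)
    observation of it.  When ``min_parent_coverage > 0`` and a
    ``parent_coverage(key, parent_id)`` callback is supplied, absence is only
    trusted where both parents were covered at or above the gate.
    """
    if child_id not in cohort.samples:
        raise DataError(f"unknown child sample {child_id!r}")
    meta = cohort.samples[child_id]
    for role, pid in (("father", meta.father_id), ("mother", meta.mother_id)):
        if pid is None:
            raise DataError(f"child {child_id!r} has no {role} on record")
        if pid not in cohort.samples:
            raise DataError(
                f"child {child_id!r} names {role} {pid!r}, absent from cohort"
            )
    obs = cohort.obs_frame
    child_vids = set(obs.loc[obs["sample"] == child_id, "vid"])
    parent_vids = set(
        obs.loc[obs["sample"].isin([meta.father_id, meta.mother_id]), "vid"]
    )
    denovo = child_vids - parent_vids
    if min_parent_coverage > 0 and parent_coverage is not None:
        denovo = {
            v for v in denovo
            if all(
                parent_coverage(cohort.key_of(v), pid) >= min_parent_coverage
                for pid in (meta.father_id, meta.mother_id)
            )
        }
    units = unit_map(cohort, unit_level)
    support = units[units["vid"].isin(denovo)].copy()
    support["sample"] = child_id
    support = support[["unit", "sample", "vid"]].reset_index(drop=True)
    return HitMatrix(unit_level, "denovo", support, cohort)
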