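"""Per-unit summaries, candidate ranking and protein-complex collapsing.

Variant evidence is collapsed to functional units (genes, exons or protein
complexes) and summarized per unit: the number of samples implicated, the
number of distinct supporting variants, how many of those are private to a
single sample, the per-clade maximum conservation over supporting variants,
and gene-level passthrough scores.  Candidate tables are then ranked by
user-chosen keys, descending, with deterministic tie-breaking.

"Unique variants" counts distinct variants observed in exactly one sample of
the unit's hit set — a recurrence measure, so a unit whose single variant is
shared by four samples has one total and zero unique variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CLADES, ConfigError
from .inheritance import HitMatrix

log = logging.getLogger(__name__)

DEFAULT_SORT_KEYS = (("n_samples", "desc"), ("max_phylop_mammal", "desc"))

_SUMMARY_COLUMNS = (
    "unit_id",
    "n_samples",
    "n_unique_variants",
    "n_total_variants",
    "max_sample_burden",
    "max_phylop_primate",
    "max_phylop_mammal",
    "max_phylop_vertebrate",
    "haploinsufficiency",
)


@dataclass(frozen=True)
class UnitSummary:
    """Collapsed per-unit statistics over supporting variants."""

    unit_id: str
    n_samples: int
    n_unique_variants: int
    n_total_variants: int
    max_sample_burden: int
    max_phylop: Mapping[str, float] = field(default_factory=dict)
    haploinsufficiency: float | None = None


@dataclass
class RankedTable:
    """Unit summaries ordered by ``sort_keys`` with 1-based ranks."""

    frame: pd.DataFrame
    sort_keys: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.frame)

    def rank_of(self, unit_id: str) -> int | None:
        hit = self.frame.loc[self.frame["unit_id"] == unit_id, "rank"]
        return int(hit.iloc[0]) if len(hit) else None

    @property
    def unit_ids(self) -> list[str]:
        return list(self.frame["unit_id"])


def summarize_frame(hits: HitMatrix) -> pd.DataFrame:
    """Per-unit summary statistics as a flat DataFrame (one row per hit unit)."""
    support = hits.support
    if support.empty:
        return pd.DataFrame(columns=_SUMMARY_COLUMNS)
    cohort = hits.cohort
    dedup = support.drop_duplicates(["unit", "sample", "vid"])

    n_samples = dedup.groupby("unit")["sample"].nunique()
    per_variant = dedup.groupby(["unit", "vid"])["sample"].nunique()
    n_total = per_variant.groupby("unit").size()
    n_unique = (per_variant == 1).groupby("unit").sum()
    burden = (
        dedup.groupby(["unit", "sample"])["vid"].nunique().groupby("unit").max()
    )

    ann = cohort.ann_frame
    out = pd.DataFrame(
        {
            "unit_id": n_samples.index,
            "n_samples": n_samples.to_numpy(dtype=np.int64),
            "n_unique_variants": n_unique.reindex(n_samples.index)
            .to_numpy(dtype=np.int64),
            "n_total_variants": n_total.reindex(n_samples.index)
            .to_numpy(dtype=np.int64),
            "max_sample_burden": burden.reindex(n_samples.index)
            .to_numpy(dtype=np.int64),
        }
    )
    for clade in CLADES:
        col = f"phylop_{clade}"
        if len(ann):
            vid_best = ann.groupby("vid")[col].max()
            scores = dedup[["unit", "vid"]].drop_duplicates().assign(
                score=lambda d: vid_best.reindex(d["vid"]).to_numpy()
            )
            best = scores.groupby("unit")["score"].max()
            out[f"max_phylop_{clade}"] = best.reindex(n_samples.index).to_numpy()
        else:
            out[f"max_phylop_{clade}"] = np.nan
    out["haploinsufficiency"] = [
        cohort.gene_scores.get(u, np.nan) for u in out["unit_id"]
    ]
    return out.reset_index(drop=True)


def summarize(hits: HitMatrix) -> list[UnitSummary]:
    """Summaries as domain objects (one per unit with at least one hit)."""
    return [
        UnitSummary(
            unit_id=row.unit_id,
            n_samples=int(row.n_samples),
            n_unique_variants=int(row.n_unique_variants),
            n_total_variants=int(row.n_total_variants),
            max_sample_burden=int(row.max_sample_burden),
            max_phylop={
                c: getattr(row, f"max_phylop_{c}") for c in CLADES
            },
            haploinsufficiency=None
            if pd.isna(row.haploinsufficiency) else float(row.haploinsufficiency),
        )
        for row in summarize_frame(hits).itertuples(index=False)
    ]


def _summaries_to_frame(
    summaries: Iterable[UnitSummary] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries.copy()
    rows = []
    for s in summaries:
        row = {
            "unit_id": s.unit_id,
            "n_samples": s.n_samples,
            "n_unique_variants": s.n_unique_variants,
            "n_total_variants": s.n_total_variants,
            "max_sample_burden": s.max_sample_burden,
            "haploinsufficiency": np.nan
            if s.haploinsufficiency is None else s.haploinsufficiency,
        }
        for c in CLADES:
            row[f"max_phylop_{c}"] = s.max_phylop.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_SUMMARY_COLUMNS))


def normalize_sort_keys(
    sort_keys: Sequence[tuple[str, str] | str] | None,
) -> tuple[tuple[str, str], ...]:
    """Accept ("field", "desc") pairs or "field:desc" strings; default desc."""
    if sort_keys is None:
        return tuple(DEFAULT_SORT_KEYS)
    norm = []
    for key in sort_keys:
        if isinstance(key, str):
            fieldname, _, direction = key.partition(":")
            direction = direction or "desc"
        else:
            fieldname, direction = key
        if direction not in ("asc", "desc"):
            raise ConfigError(f"sort direction must be asc/desc, got {direction!r}")
        norm.append((fieldname, direction))
    return tuple(norm)


def rank(
    summaries: Iterable[UnitSummary] | pd.DataFrame,
    sort_keys: Sequence[tuple[str, str] | str] | None = None,
) -> RankedTable:
    """Order unit summaries by the given keys and assign 1-based ranks.

    Each key sorts descending (or ascending if so marked); missing values
    sort below any present value; remaining ties break by unit_id ascending,
    which makes the ordering fully deterministic.
    """
    keys = normalize_sort_keys(sort_keys)
    df = _summaries_to_frame(summaries)
    df = df.drop(columns="rank", errors="ignore")
    if df.empty:
        df = df.assign(rank=pd.Series(dtype=np.int64))
        return RankedTable(frame=df[["rank"] + [c for c in df.columns
                                               if c != "rank"]], sort_keys=keys)
    for fieldname, _ in keys:
        if fieldname not in df.columns:
            raise ConfigError(f"unknown sort field {fieldname!r}")
    # np.lexsort sorts by the last key first; unit_id is the final tie-break
    arrays: list[np.ndarray] = [df["unit_id"].to_numpy()]
    for fieldname, direction in reversed(keys):
        vals = df[fieldname].to_numpy(dtype=np.float64)
        vals = -vals if direction == "desc" else vals.copy()
        vals[np.isnan(vals)] = np.inf  # missing sorts below any present value
        arrays.append(vals)
    order = np.lexsort(arrays)
    out = df.iloc[order].reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1, dtype=np.int64))
    return RankedTable(frame=out, sort_keys=keys)


def candidates_at(hits: HitMatrix, k: int) -> set[str]:
    """Units hit in at least *k* samples (antitone in *k*)."""
    n_samples = len(hits.cohort.samples)
    if not 1 <= k <= n_samples:
        raise ConfigError(f"k must lie in 1..{n_samples}, got {k}")
    tally = hits.samples_per_unit()
    return set(tally.index[tally >= k])


def collapse_complexes(
    hits: HitMatrix, membership: Mapping[str, Sequence[str]] | pd.DataFrame
) -> HitMatrix:
    """Collapse a gene-level hit matrix onto protein complexes.

    A complex is hit in a sample iff any member gene is hit there; supporting
    variants are the union over member genes.  Genes without membership are
    dropped (their count is logged).
    """
    if isinstance(membership, pd.DataFrame):
        pairs = membership.iloc[:, :2].copy()
        pairs.columns = ["gene_id", "complex_id"]
    else:
        pairs = pd.DataFrame(
            [(g, c) for g, cs in membership.items() for c in cs],
            columns=["gene_id", "complex_id"],
        )
    support = hits.support
    merged = support.merge(pairs, left_on="unit", right_on="gene_id")
    dropped = set(support["unit"]) - set(pairs["gene_id"])
    if dropped:
        log.info("%d hit genes have no complex membership and were dropped",
                 len(dropped))
    out = (
        merged[["complex_id", "sample", "vid"]]
        .rename(columns={"complex_id": "unit"})
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return HitMatrix("complex", hits.model, out, hits.cohort)
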