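"""Semi-synthetic randomization benchmark: shuffle, spike in, filter, rank.

The harness evaluates a disease-gene discovery protocol by repeated
randomization of a base cohort: sample labels of the observations are
shuffled within consequence-class strata (preserving the total number of
variants, each sample's total, and each sample's per-class counts exactly);
samples are split at random into case and control groups; fresh causal
variants are spiked into the case samples in a designated gene; the
protocol's filter battery and inheritance model are applied; candidates are
ranked; and the causal gene's rank is recorded.  The empirical cumulative
distribution of that rank over many randomizations measures how reliably the
protocol surfaces the causal gene against a background of neutral variation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .collapse import (
    DEFAULT_SORT_KEYS,
    normalize_sort_keys,
    rank,
    summarize_frame,
)
from .consequence import GeneModel
from .filters import FilterConfig, apply_filters
from .inheritance import call_hits
from .model import Cohort, ConfigError, DataError, InvariantError, SnvSieveError
from .simulate import spike_in

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Protocol:
    """A complete discovery protocol: filters, model, unit level, ranking."""

    filter: FilterConfig
    model: str  # dominant | recessive
    causal_gene: str
    unit_level: str = "gene"
    sort_keys: tuple = DEFAULT_SORT_KEYS

    def __post_init__(self):
        if self.model not in ("dominant", "recessive"):
            raise ConfigError(f"unknown model {self.model!r}")
        keys = normalize_sort_keys(self.sort_keys)
        if keys[0][0] != "n_samples":
            # units hit in more samples always precede units hit in fewer
            keys = (("n_samples", "desc"),) + keys
        object.__setattr__(self, "sort_keys", keys)


@dataclass
class RankResult:
    """Per-randomization causal-gene ranks plus candidate-count tallies."""

    ranks: list[int | None]  # None = causal gene filtered out entirely
    candidate_counts: list[dict[int, int]]  # per iteration: k -> #units >= k
    n_randomizations: int
    model: str

    def __post_init__(self):
        if len(self.ranks) != self.n_randomizations:
            raise InvariantError("rank count does not match n_randomizations")

    @property
    def finite_ranks(self) -> list[int]:
        return [r for r in self.ranks if r is not None]

    def fraction_at_or_below(self, r: int) -> float:
        """P(rank <= r); absent counts as infinite rank."""
        return sum(1 for x in self.ranks if x is not None and x <= r) / len(
            self.ranks
        )

    def mean_candidates(self, k: int) -> float:
        return float(np.mean([c.get(k, 0) for c in self.candidate_counts]))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "iteration": np.arange(1, self.n_randomizations + 1),
                "rank": ["absent" if r is None else r for r in self.ranks],
            }
        ).to_csv(path, sep="\t", index=False)


def rank_cdf(result: RankResult) -> dict[int, float]:
    """Empirical CDF of the causal-gene rank: r -> P(rank <= r).

    Non-decreasing in r and bounded by 1; iterations where the causal gene
    was filtered out count as infinite rank, so the CDF may plateau below 1.
    """
    if result.n_randomizations == 0:
        raise DataError("empty rank result")
    finite = result.finite_ranks
    if not finite:
        return {}
    return {
        r: result.fraction_at_or_below(r) for r in range(1, max(finite) + 1)
    }


def write_cdf(result: RankResult, path) -> None:
    cdf = rank_cdf(result)
    pd.DataFrame(
        {"rank": list(cdf), "cumulative_probability": list(cdf.values())}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


# -- label shuffling -------------------------------------------------------


def shuffle_labels(
    cohort: Cohort,
    rng: np.random.Generator | int,
    max_passes: int = 200,
    max_restarts: int = 5,
) -> Cohort:
    """Randomly reassign sample labels within consequence-class strata.

    Exactly preserved: the total number of observations, each sample's
    total, and each sample's per-class count (the label multiset of every
    stratum is permuted, not resampled).  Duplicate (variant, sample) pairs
    arising when a shared variant draws one label twice are repaired by
    random pairwise label swaps within the stratum; a shuffle whose repair
    does not converge within *max_passes* sweeps is retried from a fresh
    permutation, and an error is raised after *max_restarts* attempts.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    last_error: DataError | None = None
    for _ in range(max_restarts):
        try:
            return _shuffle_once(cohort, rng, max_passes)
        except _RepairStalled as exc:
            last_error = DataError(str(exc))
    raise last_error


class _RepairStalled(Exception):
    pass


def _shuffle_once(
    cohort: Cohort, rng: np.random.Generator, max_passes: int
) -> Cohort:
    obs = cohort.obs_frame
    if obs.empty or len(cohort.samples) < 2:
        return cohort.replace_observations(obs.copy())
    vids = obs["vid"].to_numpy()
    wc = cohort.worst_consequence_per_variant()
    cat = pd.Series(vids).map(wc).fillna("unannotated").to_numpy()
    codes, uniques = pd.factorize(obs["sample"], sort=True)
    n_s = len(uniques)
    new_codes = codes.copy()
    strata = {}
    for stratum in pd.unique(cat):
        idx = np.flatnonzero(cat == stratum)
        strata[stratum] = idx
        # variants carried by every sample have no labeling freedom: they
        # must receive one label of each sample, in some within-variant
        # order; assigning them directly leaves far fewer collisions to
        # repair among the remaining rows
        order = idx[np.argsort(vids[idx], kind="stable")]
        mult = np.bincount(vids[idx] - vids[idx].min())
        mult = mult[mult > 0]  # per-variant row counts, in sorted-vid order
        full_mask_var = mult == n_s
        n_full = int(full_mask_var.sum())
        if n_full:
            label_counts = np.bincount(codes[idx], minlength=n_s)
            if (label_counts < n_full).any():
                raise DataError(
                    f"stratum {stratum!r}: {n_full} variants are carried by "
                    f"all samples but some sample has fewer rows; no "
                    f"collision-free shuffle exists"
                )
            full_rows_mask = np.repeat(full_mask_var, mult)
            full_rows = order[full_rows_mask]
            perms = rng.permuted(
                np.tile(np.arange(n_s), (n_full, 1)), axis=1
            ).reshape(-1)
            new_codes[full_rows] = perms
            rest = order[~full_rows_mask]
            # remaining label multiset = stratum labels minus one of each
            # per fully-shared variant
            rest_labels = np.repeat(
                np.arange(n_s), label_counts - n_full
            )
            new_codes[rest] = rng.permutation(rest_labels)
        else:
            new_codes[idx] = rng.permutation(new_codes[idx])

    vids64 = vids.astype(np.int64)
    combo = vids64 * n_s + new_codes
    # the repair loop is pointer-chasing; plain Python lists index an order
    # of magnitude faster than numpy scalars here
    occ = [0] * (int(vids64.max() + 1) * n_s)
    combo_l = combo.tolist()
    for c in combo_l:
        occ[c] += 1
    codes_l = new_codes.tolist()
    vbase = (vids64 * n_s).tolist()
    for _ in range(max_passes):
        dup = pd.Series(np.asarray(combo_l)).duplicated().to_numpy()
        if not dup.any():
            break
        # prefer swaps that free a duplicated (variant, sample) pair without
        # occupying another (collisions strictly decrease); when a row is
        # locally stuck, accept a neutral swap that relocates its conflict
        # to another variant so later passes can resolve it
        for stratum, idx in strata.items():
            dup_here = idx[dup[idx]]
            if not len(dup_here):
                continue
            partners = idx[
                rng.integers(0, len(idx), (len(dup_here), 24))
            ].tolist()
            for r, i in enumerate(dup_here.tolist()):
                ci = codes_l[i]
                vi = vbase[i]
                fixed = False
                for j in partners[r]:
                    cj = codes_l[j]
                    if cj == ci:
                        continue
                    ni = vi + cj
                    nj = vbase[j] + ci
                    if ni == nj or occ[ni] or occ[nj]:
                        continue
                    occ[combo_l[i]] -= 1
                    occ[combo_l[j]] -= 1
                    occ[ni] += 1
                    occ[nj] += 1
                    codes_l[i], codes_l[j] = cj, ci
                    combo_l[i], combo_l[j] = ni, nj
                    fixed = True
                    break
                if not fixed:
                    for j in partners[r]:
                        cj = codes_l[j]
                        if cj == ci or i == j:
                            continue
                        ni = vi + cj
                        if occ[ni]:
                            continue
                        nj = vbase[j] + ci
                        occ[combo_l[i]] -= 1
                        occ[combo_l[j]] -= 1
                        occ[ni] += 1
                        occ[nj] += 1
                        codes_l[i], codes_l[j] = cj, ci
                        combo_l[i], combo_l[j] = ni, nj
                        break
    else:
        raise _RepairStalled(
            f"label shuffle failed to resolve duplicate (variant, sample) "
            f"pairs within {max_passes} repair passes"
        )
    new_codes = np.asarray(codes_l, dtype=codes.dtype)

    # the three preservation invariants, asserted exactly on every run
    before = np.zeros((n_s, len(strata)), dtype=np.int64)
    after = np.zeros_like(before)
    for si, (stratum, idx) in enumerate(strata.items()):
        np.add.at(before[:, si], codes[idx], 1)
        np.add.at(after[:, si], new_codes[idx], 1)
    if not np.array_equal(before, after):
        raise InvariantError("shuffle altered per-sample-per-class counts")

    out = obs.copy()
    out["sample"] = uniques.take(new_codes)
    return cohort.replace_observations(out)


# -- the randomization loop ------------------------------------------------


def run_randomizations(
    base: Cohort,
    gene_model: GeneModel,
    protocol: Protocol,
    n_case: int = 4,
    n_control: int = 4,
    per_case_variants: int = 2,
    n_iterations: int = 1000,
    seed: int = 0,
) -> RankResult:
    """Repeat shuffle -> case/control split -> spike-in -> filter -> rank.

    Each iteration draws its RNG stream deterministically from
    (seed, iteration index), so a run is reproducible and restartable.  The
    causal gene's rank is recorded per iteration (``None`` when the gene was
    filtered out — a distinguishable protocol failure, not a max rank), as
    are the candidate tallies at k = 1..n_case case samples.
    """
    if len(base.samples) < n_case + n_control:
        raise ConfigError(
            f"cohort has {len(base.samples)} samples; "
            f"{n_case + n_control} required"
        )
    min_cov = protocol.filter.min_coverage or 1
    min_vaf = protocol.filter.min_vaf or 0.0
    ranks: list[int | None] = []
    tallies: list[dict[int, int]] = []
    sample_ids = np.array(sorted(base.samples))
    for it in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, it]))
        log.debug("randomization %d: seed entropy [%d, %d]", it, seed, it)
        try:
            shuffled = shuffle_labels(base, rng)
            perm = rng.permutation(sample_ids)
            cases = list(perm[:n_case])
            controls = list(perm[n_case:n_case + n_control])
            spiked = spike_in(
                shuffled, gene_model, protocol.causal_gene,
                per_case_variants, cases, rng,
                min_coverage=min_cov, min_vaf=min_vaf,
            )
            cfg = dataclasses.replace(
                protocol.filter, exclude_in_samples=tuple(controls)
            )
            filtered = apply_filters(spiked, cfg)
            hits = call_hits(
                filtered, protocol.model, protocol.unit_level
            ).restrict_samples(cases)
            table = rank(summarize_frame(hits), protocol.sort_keys)
            ranks.append(table.rank_of(protocol.causal_gene))
            per_unit = hits.samples_per_unit()
            tallies.append(
                {k: int((per_unit >= k).sum()) for k in range(1, n_case + 1)}
            )
        except SnvSieveError as exc:
            raise type(exc)(f"randomization iteration {it}: {exc}") from exc
    return RankResult(
        ranks=ranks,
        candidate_counts=tallies,
        n_randomizations=n_iterations,
        model=protocol.model,
    )


# -- canned Miller-style protocol ------------------------------------------


def miller_filter() -> FilterConfig:
    """The benchmark's filter battery: >=10x coverage, VAF >= 20%, novel
    only (absent from both population site sets), coding consequences."""
    return FilterConfig(
        min_coverage=10,
        min_vaf=0.2,
        exclude_in_sets=("dbsnp", "kg1000"),
        consequences=frozenset(
            {"nonsynonymous", "nonsense", "essential_splice"}
        ),
    )


def miller_protocol(causal_gene: str, model: str = "recessive") -> Protocol:
    """Recessive (or dominant) Miller-style protocol: the filter above with
    ranking by case-sample count then placental-mammal PhyloP."""
    return Protocol(
        filter=miller_filter(),
        model=model,
        causal_gene=causal_gene,
        sort_keys=(("n_samples", "desc"), ("max_phylop_mammal", "desc")),
    )


def choose_causal_gene(model: GeneModel, target_cds_len: int = 1188) -> str:
    """Deterministically pick a typical causal gene: the gene whose CDS
    length is closest to *target_cds_len* (the dihydroorotate-dehydrogenase
    coding length), ties broken by gene id."""
    if not model.genes:
        raise DataError("empty gene model")
    return min(
        sorted(model.genes),
        key=lambda g: (
            abs(next(iter(model.genes[g].transcripts.values())).cds_length
                - target_cds_len),
            g,
        ),
    )
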