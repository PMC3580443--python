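"""Cross-sample filter battery.

A filter configuration combines per-observation criteria (coverage, variant
allele frequency, zygosity) with per-variant criteria (consequence class,
membership in population site sets, conservation, gene panels) and two
cohort-wide criteria that remove a variant from *all* samples: presence in a
listed set of samples (typically the controls) and carrier-count caps.  An
observation survives iff it passes every criterion that is set; all numeric
thresholds are inclusive ("minimum 10x" keeps coverage exactly 10).

"Novel" has no built-in database knowledge: it simply means absent from every
site set named in ``exclude_in_sets``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import yaml

from .model import (
    CLADES,
    CONSEQUENCES,
    Cohort,
    ConfigError,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Declarative description of one filtering pass.

    Unset (None/empty) fields impose no constraint; the empty config is the
    identity filter.
    """

    min_coverage: int | None = None
    max_coverage: int | None = None
    min_vaf: float | None = None
    max_vaf: float | None = None
    zygosity: str | None = None  # "het" or "hom_alt"; unknown calls fail it
    consequences: frozenset[str] | None = None
    exclude_in_sets: tuple[str, ...] = ()
    exclude_in_samples: tuple[str, ...] = ()
    max_carrier_samples: int | None = None
    min_phylop: tuple[str, float] | None = None  # (clade, threshold)
    panel_include: frozenset[str] | None = None
    panel_exclude: frozenset[str] | None = None
    #: control-sample exclusion matches exact alleles (False: positions only)
    allele_exact_controls: bool = True
    #: variants with no conservation score pass a min_phylop filter (logged)
    missing_scores_pass: bool = True

    def __post_init__(self):
        object.__setattr__(self, "exclude_in_sets", tuple(self.exclude_in_sets))
        object.__setattr__(self, "exclude_in_samples",
                           tuple(self.exclude_in_samples))
        if self.consequences is not None:
            cs = frozenset(self.consequences)
            if not cs:
                raise ConfigError("consequences, when given, must be non-empty")
            unknown = cs - set(CONSEQUENCES)
            if unknown:
                raise ConfigError(f"unknown consequence classes {sorted(unknown)}")
            object.__setattr__(self, "consequences", cs)
        for lo, hi, what in (
            (self.min_coverage, self.max_coverage, "coverage"),
            (self.min_vaf, self.max_vaf, "vaf"),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ConfigError(f"min_{what} > max_{what}")
        if self.zygosity is not None and self.zygosity not in ("het", "hom_alt"):
            raise ConfigError(f"zygosity filter must be het/hom_alt, "
                              f"got {self.zygosity!r}")
        if self.min_phylop is not None:
            clade, thr = self.min_phylop
            if clade not in CLADES:
                raise ConfigError(f"unknown clade {clade!r} in min_phylop")
            object.__setattr__(self, "min_phylop", (clade, float(thr)))
        for panel in ("panel_include", "panel_exclude"):
            val = getattr(self, panel)
            if val is not None:
                object.__setattr__(self, panel, frozenset(val))

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.consequences is not None:
            d["consequences"] = sorted(self.consequences)
        for panel in ("panel_include", "panel_exclude"):
            if d[panel] is not None:
                d[panel] = sorted(d[panel])
        d["exclude_in_sets"] = list(self.exclude_in_sets)
        d["exclude_in_samples"] = list(self.exclude_in_samples)
        if self.min_phylop is not None:
            d["min_phylop"] = list(self.min_phylop)
        return {k: v for k, v in d.items() if v not in (None, [], ())}

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown filter fields {sorted(unknown)}")
        if "min_phylop" in d and d["min_phylop"] is not None:
            d["min_phylop"] = tuple(d["min_phylop"])
        for key in ("consequences", "panel_include", "panel_exclude"):
            if d.get(key) is not None:
                d[key] = frozenset(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"filter config {path} must be a mapping")
        return cls.from_dict(data)


def _validate_against(cohort: Cohort, cfg: FilterConfig) -> None:
    for name in cfg.exclude_in_sets:
        if name not in cohort.site_sets:
            raise ConfigError(f"unknown site set {name!r}")
    for sid in cfg.exclude_in_samples:
        if sid not in cohort.samples:
            raise ConfigError(f"unknown sample {sid!r} in exclude_in_samples")


def apply_filters(cohort: Cohort, cfg: FilterConfig) -> Cohort:
    """Return a cohort keeping only observations that pass every criterion.

    Per-variant criteria (consequence, site sets, conservation, panels,
    control carriers, carrier caps) remove a variant from all samples;
    per-observation criteria act row-wise.  Annotations, site sets and sample
    metadata are carried over untouched.  The effective configuration is
    echoed to the log for reproducibility.
    """
    _validate_against(cohort, cfg)
    log.info("applying filters: %s", cfg.to_dict() or "(identity)")
    obs = cohort.obs_frame
    if obs.empty:
        return cohort.replace_observations(obs)

    row_ok = np.ones(len(obs), dtype=bool)
    cov = obs["coverage"].to_numpy()
    vaf = obs["vaf"].to_numpy()
    if cfg.min_coverage is not None:
        row_ok &= cov >= cfg.min_coverage
    if cfg.max_coverage is not None:
        row_ok &= cov <= cfg.max_coverage
    if cfg.min_vaf is not None:
        row_ok &= vaf >= cfg.min_vaf
    if cfg.max_vaf is not None:
        row_ok &= vaf <= cfg.max_vaf
    if cfg.zygosity is not None:
        # "unknown" fails any explicit zygosity requirement
        row_ok &= (obs["zygosity"] == cfg.zygosity).to_numpy()

    n_var = cohort.n_variants
    vid_ok = np.ones(n_var, dtype=bool)
    ann = cohort.ann_frame
    ann_vids = ann["vid"].to_numpy() if len(ann) else np.empty(0, np.int64)

    if cfg.consequences is not None:
        allowed = np.zeros(n_var, dtype=bool)
        if len(ann):
            hit = ann["consequence"].isin(cfg.consequences).to_numpy()
            allowed[ann_vids[hit]] = True
        vid_ok &= allowed

    for name in cfg.exclude_in_sets:
        vid_ok &= ~cohort.site_membership(name)

    if cfg.min_phylop is not None:
        clade, thr = cfg.min_phylop
        scored = np.full(n_var, np.nan)
        if len(ann):
            best = ann.groupby("vid")[f"phylop_{clade}"].max()
            scored[best.index.to_numpy()] = best.to_numpy()
        missing = np.isnan(scored)
        passes = np.where(missing, cfg.missing_scores_pass, scored >= thr)
        if missing.any() and cfg.missing_scores_pass:
            log.info(
                "%d variants lack phylop_%s scores and pass min_phylop by default",
                int(missing.sum()), clade,
            )
        vid_ok &= passes

    for panel, keep_in in ((cfg.panel_include, True), (cfg.panel_exclude, False)):
        if panel is None:
            continue
        in_panel = np.zeros(n_var, dtype=bool)
        if len(ann):
            hit = ann["gene_id"].isin(panel).to_numpy()
            in_panel[ann_vids[hit]] = True
        vid_ok &= in_panel if keep_in else ~in_panel

    if cfg.exclude_in_samples:
        carried_rows = obs["sample"].isin(cfg.exclude_in_samples).to_numpy()
        carried = np.zeros(n_var, dtype=bool)
        carried[obs["vid"].to_numpy()[carried_rows]] = True
        if not cfg.allele_exact_controls:
            var = cohort.variants_frame
            pos_keys = var["chrom"].astype(str) + ":" + var["pos"].astype(str)
            carried_pos = set(pos_keys[carried])
            carried = pos_keys.isin(carried_pos).to_numpy()
        vid_ok &= ~carried

    if cfg.max_carrier_samples is not None:
        counts = np.zeros(n_var, dtype=np.int64)
        np.add.at(counts, obs["vid"].to_numpy(), 1)  # one row per (vid, sample)
        vid_ok &= counts <= cfg.max_carrier_samples

    keep = row_ok & vid_ok[obs["vid"].to_numpy()]
    return cohort.replace_observations(obs[keep])
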