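"""Filter battery semantics and its algebraic properties."""

import dataclasses

import numpy as np
import pytest

import snvsieve as sv
from _oracles import filter_oracle
from conftest import make_cohort, random_cohort


def surviving(cohort):
    return {(o.key, o.sample_id) for o in cohort.observations()}


def random_config(rng):
    kwargs = {}
    if rng.random() < 0.5:
        kwargs["min_coverage"] = int(rng.integers(0, 30))
    if rng.random() < 0.3:
        kwargs["max_coverage"] = int(rng.integers(30, 70))
    if rng.random() < 0.5:
        kwargs["min_vaf"] = float(rng.uniform(0, 0.5))
    if rng.random() < 0.3:
        kwargs["max_vaf"] = float(rng.uniform(0.5, 1.0))
    if rng.random() < 0.3:
        kwargs["zygosity"] = str(rng.choice(["het", "hom_alt"]))
    if rng.random() < 0.5:
        kwargs["consequences"] = frozenset(
            rng.choice(sv.CONSEQUENCES[:-1],
                       size=int(rng.integers(1, 5)), replace=False)
        )
    if rng.random() < 0.5:
        kwargs["exclude_in_sets"] = tuple(
            rng.choice(["dbsnp", "kg1000"],
                       size=int(rng.integers(1, 3)), replace=False)
        )
    if rng.random() < 0.4:
        kwargs["exclude_in_samples"] = ("S0",)
    if rng.random() < 0.3:
        kwargs["max_carrier_samples"] = int(rng.integers(1, 4))
    if rng.random() < 0.4:
        kwargs["min_phylop"] = ("mammal", float(rng.normal(0.5, 1.0)))
    if rng.random() < 0.2:
        kwargs["panel_include"] = frozenset(
            f"G{i}" for i in rng.integers(0, 6, size=3)
        )
    return sv.FilterConfig(**kwargs)


class TestExamples:
    def test_empty_config_is_identity(self, rng):
        cohort = random_cohort(rng)
        out = sv.apply_filters(cohort, sv.FilterConfig())
        assert surviving(out) == surviving(cohort)

    def test_minimum_coverage_threshold_is_inclusive(self):
        key9 = sv.VariantKey("1", 100, "A", "G")
        key10 = sv.VariantKey("1", 200, "C", "T")
        cohort = make_cohort(
            ["A"],
            [sv.VariantObservation(key9, "A", 9, 4),
             sv.VariantObservation(key10, "A", 10, 4)],
        )
        out = sv.apply_filters(cohort, sv.FilterConfig(min_coverage=10))
        assert surviving(out) == {(key10, "A")}

    def test_site_set_exclusion_removes_from_every_sample(self):
        key = sv.VariantKey("1", 100, "A", "G")
        other = sv.VariantKey("1", 200, "C", "T")
        cohort = make_cohort(
            ["A", "B"],
            site_sets=[sv.SiteSet("kg1000", frozenset({key.astuple()}))],
        )
        for s in "AB":
            cohort.add_observation(sv.VariantObservation(key, s, 20, 10))
            cohort.add_observation(sv.VariantObservation(other, s, 20, 10))
        out = sv.apply_filters(
            cohort, sv.FilterConfig(exclude_in_sets=["kg1000"])
        )
        assert surviving(out) == {(other, "A"), (other, "B")}

    def test_control_exclusion_is_cohort_wide(self):
        shared = sv.VariantKey("1", 100, "A", "G")
        private = sv.VariantKey("1", 200, "C", "T")
        cohort = make_cohort(
            ["case", "ctrl"],
            [sv.VariantObservation(shared, "case", 20, 10),
             sv.VariantObservation(shared, "ctrl", 3, 1),
             sv.VariantObservation(private, "case", 20, 10)],
        )
        out = sv.apply_filters(
            cohort, sv.FilterConfig(exclude_in_samples=["ctrl"])
        )
        # the shared variant disappears everywhere, at any coverage/VAF
        assert surviving(out) == {(private, "case")}

    def test_unknown_zygosity_fails_explicit_requirement(self):
        key = sv.VariantKey("1", 100, "A", "G")
        cohort = make_cohort(
            ["A"],
            [sv.VariantObservation(key, "A", 20, 10, zygosity="unknown")],
        )
        out = sv.apply_filters(cohort, sv.FilterConfig(zygosity="het"))
        assert surviving(out) == set()

    def test_unknown_names_error_before_filtering(self, rng):
        cohort = random_cohort(rng)
        with pytest.raises(sv.ConfigError, match="nosuchset"):
            sv.apply_filters(
                cohort, sv.FilterConfig(exclude_in_sets=["nosuchset"])
            )
        with pytest.raises(sv.ConfigError, match="nobody"):
            sv.apply_filters(
                cohort, sv.FilterConfig(exclude_in_samples=["nobody"])
            )

    def test_missing_conservation_passes_by_default(self):
        key = sv.VariantKey("1", 100, "A", "G")
        cohort = make_cohort(
            ["A"], [sv.VariantObservation(key, "A", 20, 10)]
        )
        cohort.add_annotation(sv.VariantAnnotation(
            key=key, gene_id="G1", transcript_id="G1.t1",
            consequence="nonsynonymous",
        ))
        keep = sv.apply_filters(
            cohort, sv.FilterConfig(min_phylop=("mammal", 2.0))
        )
        assert len(surviving(keep)) == 1
        drop = sv.apply_filters(
            cohort,
            sv.FilterConfig(min_phylop=("mammal", 2.0),
                            missing_scores_pass=False),
        )
        assert surviving(drop) == set()

    def test_invalid_configs_rejected(self):
        with pytest.raises(sv.ConfigError):
            sv.FilterConfig(min_coverage=20, max_coverage=10)
        with pytest.raises(sv.ConfigError):
            sv.FilterConfig(consequences=frozenset())

    def test_yaml_round_trip(self, tmp_path):
        cfg = sv.FilterConfig(
            min_coverage=10, min_vaf=0.2,
            exclude_in_sets=("dbsnp",),
            consequences=frozenset({"nonsense", "nonsynonymous"}),
            min_phylop=("mammal", 1.0),
        )
        p = tmp_path / "f.yaml"
        cfg.to_yaml(p)
        assert sv.FilterConfig.from_yaml(p) == cfg


class TestProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_predicate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng, n_samples=5, n_obs=200, n_positions=60)
        cfg = random_config(rng)
        got = surviving(sv.apply_filters(cohort, cfg))
        assert got == filter_oracle(cohort, cfg)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_single_field_tightening_shrinks_survivors(self, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng, n_obs=150, n_positions=50)
        cfg = random_config(rng)
        base = surviving(sv.apply_filters(cohort, cfg))
        for stricter in [
            dataclasses.replace(cfg, min_coverage=(cfg.min_coverage or 0) + 10),
            dataclasses.replace(cfg, min_vaf=(cfg.min_vaf or 0.0) + 0.2),
            dataclasses.replace(cfg, max_carrier_samples=1),
            dataclasses.replace(
                cfg, exclude_in_sets=tuple(
                    set(cfg.exclude_in_sets) | {"dbsnp", "kg1000"})
            ),
        ]:
            assert surviving(sv.apply_filters(cohort, stricter)) <= base

    @pytest.mark.parametrize("seed", [20, 21, 22])
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng, n_obs=150)
        cfg = random_config(rng)
        once = sv.apply_filters(cohort, cfg)
        twice = sv.apply_filters(once, cfg)
        assert surviving(twice) == surviving(once)

    @pytest.mark.parametrize("seed", [30, 31, 32])
    def test_order_independent(self, seed):
        """Applying the criteria one at a time, in either order, equals the
        combined application (survival is a pure intersection)."""
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng, n_obs=150)
        cfg = sv.FilterConfig(
            min_coverage=10,
            min_vaf=0.2,
            exclude_in_sets=("dbsnp",),
            consequences=frozenset(
                {"nonsynonymous", "nonsense", "essential_splice"}),
        )
        pieces = [
            sv.FilterConfig(min_coverage=10),
            sv.FilterConfig(min_vaf=0.2),
            sv.FilterConfig(exclude_in_sets=("dbsnp",)),
            sv.FilterConfig(consequences=cfg.consequences),
        ]
        combined = surviving(sv.apply_filters(cohort, cfg))
        for order in (pieces, pieces[::-1]):
            acc = cohort
            for piece in order:
                acc = sv.apply_filters(acc, piece)
            assert surviving(acc) == combined

    def test_control_carriers_judged_on_unfiltered_calls(self):
        """A control carrying a variant below the coverage threshold still
        triggers cohort-wide exclusion in the same pass."""
        shared = sv.VariantKey("1", 100, "A", "G")
        cohort = make_cohort(
            ["case", "ctrl"],
            [sv.VariantObservation(shared, "case", 50, 25),
             sv.VariantObservation(shared, "ctrl", 3, 1)],
        )
        out = sv.apply_filters(
            cohort,
            sv.FilterConfig(min_coverage=10, exclude_in_samples=["ctrl"]),
        )
        assert surviving(out) == set()
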