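"""Multi-tree aggregation, sweeps, escalation and the report bundle."""

import json

import numpy as np
import pandas as pd
import pytest

import moltevo as mv
from moltevo.coevo import MCMCSettings, SteppingStoneSettings
from moltevo.orchestrator import (
    AggregatedPMM,
    AnalysisConfig,
    count_summary,
    derive_seed,
    dichotomization_sweep,
    escalate_thinning,
    full_report,
    run_coevo_over_trees,
    run_pmm_over_trees,
)
from moltevo.phylo import TreeSet, tip_labels
from moltevo.pmm import PMMSettings
from moltevo.simulate import simulate_study_table, simulate_yule_tree
from moltevo.trait_data import BinaryTraitPair


def _named_trees(table, n_trees, seed0=50):
    trees = []
    for i in range(n_trees):
        t = simulate_yule_tree(len(table), seed=seed0 + i)
        for leaf, name in zip(t.leaf_node_iter(), table.species):
            leaf.taxon.label = name
        trees.append(t)
    return TreeSet(trees, provenance="synthetic")


@pytest.fixture(scope="module")
def small_setup():
    table = simulate_study_table(seed=31, n_species=40)
    trees = _named_trees(table, 3)
    config = AnalysisConfig(
        predictors=("log_body_mass", "migration", "gregariousness"),
        settings=PMMSettings(iterations=4200, burn_in=1000, thinning=8, seed=0),
        mcmc=MCMCSettings(iterations=4200, burn_in=1000, thinning=8, seed=0),
        ss=SteppingStoneSettings(stones=6, iterations_per_stone=80, seed=0),
        n_runs=2,
        master_seed=11,
    )
    return table, trees, config


class TestEscalation:
    def test_low_autocorrelation_leaves_settings_unchanged(self):
        s = MCMCSettings()
        assert escalate_thinning(s, 0.05) is s

    def test_escalation_doubles_thinning_and_preserves_retention(self):
        s = escalate_thinning(MCMCSettings(), 0.3)
        assert s.thinning == 4000
        assert s.iterations == 3_900_000
        assert s.n_retained == 950

    def test_repeated_escalation_keeps_retention(self):
        s = MCMCSettings()
        for _ in range(3):
            s = escalate_thinning(s, 0.5)
        assert s.n_retained == 950
        assert s.thinning == 16_000


class TestSeeds:
    def test_derived_seeds_deterministic_and_distinct(self):
        a = [derive_seed(1, i) for i in range(100)]
        assert a == [derive_seed(1, i) for i in range(100)]
        assert len(set(a)) == 100
        assert all(0 <= s < 2**31 for s in a)


class TestPMMAggregation:
    def test_aggregate_is_arithmetic_mean_of_per_tree_results(self, small_setup):
        table, trees, config = small_setup
        agg = run_pmm_over_trees(table, trees, config)
        assert isinstance(agg, AggregatedPMM)
        assert agg.n_trees == 3
        recomputed = sum(f["estimate"] for f in agg.per_tree) / 3
        pd.testing.assert_series_equal(
            agg.summary["estimate"], recomputed, check_names=False
        )
        assert list(agg.summary.index)[0] == "(Intercept)"
        assert {"estimate", "lci", "uci", "ess", "autocorrelation",
                "geweke_z", "pmcmc"} <= set(agg.summary.columns)

    def test_identical_trees_match_single_tree_run(self, small_setup):
        table, trees, config = small_setup
        one = TreeSet([trees[0]])
        clones = TreeSet([trees[0], trees[0].clone(depth=1)])
        a = run_pmm_over_trees(table, one, config)
        b = run_pmm_over_trees(table, clones, config)
        # same data, same tree: aggregates differ only by chain Monte-Carlo error
        assert np.allclose(
            a.summary["estimate"], b.summary["estimate"], atol=0.5
        )


class TestCoevoAggregation:
    def test_two_trees_two_runs_give_four_bf_estimates(self, small_setup):
        table, trees, config = small_setup
        y = table.molt_presence("inclusive")
        x = (table.predictor_frame(["migration"])["migration"] > 3).astype(int)
        pair = BinaryTraitPair(tuple(table.species), y, x.to_numpy())
        two = TreeSet(trees.trees[:2])
        bf = run_coevo_over_trees(two, pair, config)
        assert bf.bf_values.size == config.n_runs**2
        assert bf.lci <= bf.mean <= bf.uci
        # reproducible with the same master seed
        bf2 = run_coevo_over_trees(two, pair, config)
        assert np.array_equal(bf.bf_values, bf2.bf_values)


class TestCoevoEscalation:
    def test_escalation_log_preserves_retention(self, small_setup):
        from dataclasses import replace as _replace

        table, trees, config = small_setup
        y = table.molt_presence("inclusive")
        x = (table.predictor_frame(["migration"])["migration"] > 3).astype(int)
        pair = BinaryTraitPair(tuple(table.species), y, x.to_numpy())
        cfg = _replace(config, check_autocorrelation=True, n_runs=1)
        log = []
        run_coevo_over_trees(TreeSet(trees.trees[:2]), pair, cfg, escalation_log=log)
        assert len(log) == 2
        assert all(e["n_retained"] == cfg.mcmc.n_retained for e in log)
        assert all(e["thinning"] >= cfg.mcmc.thinning for e in log)


class TestSweep:
    def test_sweep_reports_every_ordinal_scheme(self, small_setup):
        table, trees, config = small_setup
        y = table.molt_presence("inclusive")
        species = tuple(table.species)
        one = TreeSet([trees[0]])

        def builder(binary):
            return BinaryTraitPair(species, y, binary)

        frame, scheme, bf = dichotomization_sweep(
            one, table, "migration", builder, config
        )
        levels = np.unique(table.predictor_frame(["migration"]))
        assert len(frame) == levels.size - 1
        assert bf.mean == frame["bf_mean"].max()


class TestCounts:
    def test_count_summary_consistency(self):
        table = simulate_study_table(seed=8)
        c = count_summary(table)
        assert c["n_species"] == 188
        assert c["molt_strict"] <= c["molt_inclusive"]
        assert c["partial_inclusive"] + c["complete_inclusive"] == c["molt_inclusive"]
        assert c["partial_strict"] + c["complete_strict"] == c["molt_strict"]
        assert 0 <= c["partial_nonflight_only"] <= c["partial_inclusive"]


class TestReport:
    def test_report_bundle_files_and_manifest(self, small_setup, tmp_path):
        table, trees, config = small_setup
        result = full_report(table, trees, config, tmp_path, run_coevo=False)
        assert (tmp_path / "pmm_summary.tsv").exists()
        assert (tmp_path / "count_summary.tsv").exists()
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["n_trees"] == 3
        assert len(manifest["per_tree_seeds"]) == 3
        assert manifest["per_tree_seeds"] == [
            derive_seed(config.master_seed, i) for i in range(3)
        ]
        written = pd.read_csv(tmp_path / "pmm_summary.tsv", sep="\t", index_col=0)
        assert "Heritability (h2)" in written.index

    def test_report_with_coevo_writes_bf_and_rate_tables(self, small_setup, tmp_path):
        from dataclasses import replace as _replace

        table, trees, config = small_setup
        y = table.molt_presence("inclusive")
        x = (table.predictor_frame(["migration"])["migration"] > 3).astype(int)
        pair = BinaryTraitPair(tuple(table.species), y, x.to_numpy())
        cfg = _replace(config, n_runs=1)
        result = full_report(
            table, TreeSet(trees.trees[:1]), cfg, tmp_path, run_coevo=True, pair=pair
        )
        assert (tmp_path / "bf_summary.tsv").exists()
        rates = pd.read_csv(tmp_path / "rate_summary.tsv", sep="\t", index_col=0)
        assert set(rates.index) == set(mv.coevo.RATE_NAMES)
        assert {"mean", "z_value"} <= set(rates.columns)
        assert result["bf"].bf_values.size == 1
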