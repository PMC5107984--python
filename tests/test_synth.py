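import numpy as np
import pandas as pd
import pytest

from pmap import phenotyping, synth
from pmap.errors import ConfigError
from pmap.phenotyping import DoseResponse, fit_ec50
from pmap.synth import SynthConfig


class TestConfigValidation:
    def test_defaults_valid(self):
        SynthConfig()

    @pytest.mark.parametrize("kwargs", [
        {"n_genes": 0},
        {"planted_n1_min_pdeg_links": 1},
        {"n_genes": 50},                        # too small for planted blocks
        {"ppi_n_nodes": 10},
        {"n_samples_per_condition": 10},        # < 2k
        {"planted_n1_min_pdeg_links": 30},      # infeasible wiring
    ])
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ConfigError):
            SynthConfig(**kwargs)


class TestDeterminism:
    def test_expression_bit_identical(self, small_config):
        def build():
            truth = synth.plant_truth(small_config)
            ec50 = synth.generate_ec50(small_config)
            assigns = phenotyping.assign_phenotypes(ec50, k=small_config.k)
            expr, _ = synth.generate_expression(small_config, assigns, truth)
            return expr

        e1, e2 = build(), build()
        np.testing.assert_array_equal(e1.values, e2.values)
        assert e1.genes == e2.genes and e1.samples == e2.samples

    def test_ppi_identical(self, small_config):
        truth = synth.plant_truth(small_config)
        assert synth.generate_ppi(small_config, truth) == \
            synth.generate_ppi(small_config, truth)

    def test_dose_response_identical(self, small_config):
        v1, t1 = synth.generate_dose_response(small_config)
        v2, t2 = synth.generate_dose_response(small_config)
        pd.testing.assert_frame_equal(v1, v2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self, small_config):
        other = small_config.with_seed(small_config.seed + 1)
        e1 = synth.generate_ec50(small_config)
        e2 = synth.generate_ec50(other)
        assert not np.allclose(e1["ec50"], e2["ec50"])


class TestPlantedStructure:
    def test_planted_blocks_disjoint(self, small_config):
        truth = synth.plant_truth(small_config)
        seen = set()
        for cls, genes in {**truth.planted_pdegs, **truth.planted_n1}.items():
            assert not genes & seen
            seen |= genes

    def test_ppi_simple_graph(self, small_scenario):
        edges = small_scenario["edges"]
        assert all(a != b for a, b in edges)
        assert len(edges) == len(set(edges))

    def test_planted_n1_wiring(self, small_scenario):
        truth = small_scenario["truth"]
        config = small_scenario["config"]
        adj = {}
        for a, b in small_scenario["edges"]:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for cls, n1_genes in truth.planted_n1.items():
            pdegs = truth.planted_pdegs[cls]
            for g in n1_genes:
                assert len(adj[g] & pdegs) >= config.planted_n1_min_pdeg_links

    def test_degree_distribution_heavy_tailed(self, small_scenario):
        degrees = {}
        for a, b in small_scenario["edges"]:
            degrees[a] = degrees.get(a, 0) + 1
            degrees[b] = degrees.get(b, 0) + 1
        values = sorted(degrees.values())
        assert values[-1] >= 10 * np.median(values)


class TestNullCalibration:
    def test_zero_effect_matches_nominal_alpha(self):
        # effect 0: planted genes are indistinguishable from nulls, and the
        # per-condition call rate should track alpha within binomial error
        from pmap import pdeg

        config = SynthConfig(n_genes=300, n_samples_per_condition=36,
                             n_planted_pdegs_per_class=15, ppi_n_nodes=450,
                             n_planted_n1=2, pdeg_effect_size=0.0, seed=21)
        truth = synth.plant_truth(config)
        ec50 = synth.generate_ec50(config)
        assigns = phenotyping.assign_phenotypes(ec50, k=config.k)
        expr, _ = synth.generate_expression(config, assigns, truth)
        alpha = 0.01
        n_calls = n_tests = 0
        for a in assigns:
            results = pdeg.template_match(expr, a, alpha=alpha)
            n_calls += len(results)
            n_tests += len(expr.genes)
        rate = n_calls / n_tests
        se = np.sqrt(alpha * (1 - alpha) / n_tests)
        assert abs(rate - alpha) < 5 * se


class TestDoseResponse:
    def test_row_count_9_doses_3_replicates(self, small_config):
        viability, _ = synth.generate_dose_response(small_config)
        per = viability.groupby(["sample_id", "drug"]).size()
        assert (per == 27).all()

    def test_noiseless_recovery(self):
        config = SynthConfig(n_genes=300, n_samples_per_condition=30,
                             n_planted_pdegs_per_class=15, ppi_n_nodes=450,
                             n_planted_n1=2, dr_noise_sd=0.0, seed=3)
        viability, truth = synth.generate_dose_response(config)
        merged = truth.set_index(["sample_id", "drug"])
        checked = 0
        for (sid, drug), sub in viability.groupby(["sample_id", "drug"]):
            if checked >= 10:
                break
            fit = fit_ec50(DoseResponse(sid, drug, sub["dose"].to_numpy(),
                                        sub["viability"].to_numpy()))
            true = merged.loc[(sid, drug), "ec50_true"]
            assert fit.converged
            assert abs(fit.ec50 - true) / true < 1e-6
            checked += 1
        assert checked == 10

    def test_noisy_recovery_within_mc_bound(self, small_config):
        # frozen Monte-Carlo bound: median |log10 ratio| ~ 0.032 at
        # noise_sd = 0.05 (200-curve simulation); assert < 0.06
        viability, truth = synth.generate_dose_response(small_config)
        merged = truth.set_index(["sample_id", "drug"])
        errors = []
        for (sid, drug), sub in viability.groupby(["sample_id", "drug"]):
            if len(errors) >= 60:
                break
            fit = fit_ec50(DoseResponse(sid, drug, sub["dose"].to_numpy(),
                                        sub["viability"].to_numpy()))
            if not fit.converged:
                continue
            true = merged.loc[(sid, drug), "ec50_true"]
            errors.append(abs(np.log10(fit.ec50 / true)))
        assert len(errors) >= 50
        assert np.median(errors) < 0.06

    def test_bad_dose_grid_errors(self, small_config):
        with pytest.raises(ConfigError):
            synth.generate_dose_response(
                small_config,
                dose_grids={"anthracycline": [0, -1, 2, 3, 4],
                            "taxane": [0, 1, 2, 3, 4]})


class TestGeneSetsAndScreen:
    def test_gene_sets_include_planted_blocks(self, small_scenario):
        truth = small_scenario["truth"]
        coll = synth.generate_gene_sets(small_scenario["config"], truth)
        planted_names = [n for n in coll if n.startswith("PLANTED_")]
        assert len(planted_names) == len(truth.planted_pdegs)
        for name in coll:
            assert len(set(coll[name].genes)) == len(coll[name].genes)

    def test_screen_agreement_rate(self, small_config):
        pf = {f"g{i}": (i % 5) - 2 for i in range(200)}
        screen = synth.generate_screen(pf, small_config, agreement=1.0)
        from pmap import consistency as cons
        calls = cons.classify_table(screen, pf)
        evaluable = [c for c in calls if c.predicted_direction is not None]
        assert all(c.matches_all_lines for c in evaluable)


class TestFixtureDir:
    def test_writes_complete_directory(self, tmp_path, small_config):
        paths = synth.write_fixture_dir(small_config, tmp_path / "fx")
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        from pmap import io_formats
        expr = io_formats.read_expression(paths["expression"])
        assert expr.shape[0] == small_config.n_genes
        truth = io_formats.read_json(paths["ground_truth"])
        assert set(truth["planted_pdegs"]) == {
            "anthracycline-sensitive", "anthracycline-resistant",
            "taxane-sensitive", "taxane-resistant"}
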