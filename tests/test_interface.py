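"""Interchange formats (YAML config, SBML), fixtures and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import cisapop as ca
from cisapop.cli import main, run_cli
from conftest import rhs_oracle


class TestNetworkConfig:
    def test_bundled_config_roundtrips(self, bundled, tmp_path):
        path = tmp_path / "model.yaml"
        ca.dump_network(bundled, path, name="cisplatin-apoptosis")
        again = ca.load_network(path)
        assert again.content_hash() == bundled.content_hash()

    def test_yaml_text_is_accepted_directly(self, bundled):
        text = ca.dump_network(bundled)
        assert ca.load_network(text).content_hash() == bundled.content_hash()

    def test_malformed_config_rejected(self):
        with pytest.raises(ca.ConfigurationError):
            ca.load_network("species:\n- role: dynamic\n")  # missing name


class TestSBML:
    def test_bundled_roundtrip_preserves_rhs_everywhere(self, bundled):
        doc = ca.export_sbml(bundled)
        again = ca.import_sbml(doc)
        r1, r2 = ca.build_rhs(bundled), ca.build_rhs(again)
        rng = np.random.default_rng(7)
        for _ in range(100):
            y = rng.uniform(0.0, 2.0, len(bundled.dynamic_species))
            np.testing.assert_allclose(r1(0, y), r2(0, y), rtol=0, atol=1e-12)

    def test_dynamic_species_count_preserved(self, bundled, tmp_path):
        path = tmp_path / "model.xml"
        ca.export_sbml(bundled, path)
        again = ca.import_sbml(path)
        assert len(again.dynamic_species) == 44
        assert {s.name for s in again.constant_species} == {
            s.name for s in bundled.constant_species
        }

    def test_constant_species_marked_boundary(self, bundled):
        doc = ca.export_sbml(bundled)
        assert 'name="Cisplatin"' in doc
        assert 'boundaryCondition="true"' in doc

    def test_empty_network_exports_validly(self):
        empty = ca.ReactionNetwork(
            species=(), reactions=(), parameters=ca.RateConstantSet({})
        )
        again = ca.import_sbml(ca.export_sbml(empty))
        assert again.species == () and again.reactions == ()

    def test_invalid_network_refused(self):
        bad = ca.ReactionNetwork(
            species=(ca.SpeciesDef("A", "dynamic", -1.0),),
            reactions=(),
            parameters=ca.RateConstantSet({}),
        )
        with pytest.raises(ca.NetworkError):
            ca.export_sbml(bad)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fixture_roundtrip_rhs(self, seed):
        net = ca.generate_fixture_network(seed, 5, 6)
        again = ca.import_sbml(ca.export_sbml(net))
        r1, r2 = ca.build_rhs(net), ca.build_rhs(again)
        rng = np.random.default_rng(seed)
        for _ in range(20):
            y = rng.uniform(0.0, 2.0, 5)
            np.testing.assert_allclose(r1(0, y), r2(0, y), rtol=0, atol=1e-12)


class TestFixtureGenerator:
    def test_same_seed_is_reproducible(self):
        a = ca.generate_fixture_network(42, 6, 8)
        b = ca.generate_fixture_network(42, 6, 8)
        assert a.content_hash() == b.content_hash()

    def test_different_seeds_differ(self):
        a = ca.generate_fixture_network(1)
        b = ca.generate_fixture_network(2)
        assert a.content_hash() != b.content_hash()

    @pytest.mark.parametrize("seed", range(5))
    def test_fixtures_validate_and_match_oracle(self, seed):
        net = ca.generate_fixture_network(seed, 4, 5)
        assert ca.validate_network(net) == []
        rhs = ca.build_rhs(net)
        rng = np.random.default_rng(seed)
        for _ in range(10):
            y = rng.uniform(0, 2, 4)
            np.testing.assert_allclose(
                rhs(0, y), rhs_oracle(net, y), rtol=1e-12, atol=1e-12
            )

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            ca.generate_fixture_network(0, n_species=0)
        with pytest.raises(ValueError):
            ca.generate_fixture_network(0, n_reactions=-1)


class TestCli:
    def test_contributions_writes_full_summary(self, tmp_path):
        out = tmp_path / "out"
        res = CliRunner().invoke(
            main,
            ["contributions", "--t-end", "4.0", "--out-dir", str(out)],
        )
        assert res.exit_code == 0, res.output
        summary = json.loads((out / "contributions.json").read_text())
        assert set(summary["exclusive"]) == {"I", "II", "III"}
        assert "crosstalk" in summary and "total" in summary
        assert "model_hash" in summary and "settings" in summary
        log = (out / "run.log").read_text()
        assert "model hash" in log and "version" in log

    def test_dose_response_writes_one_row_per_dose(self, tmp_path):
        import pandas as pd

        out = tmp_path / "out"
        res = CliRunner().invoke(
            main,
            [
                "dose-response",
                "--doses", "0.0,0.0001,0.001,0.01,0.1,0.5,1.0",
                "--t-end", "2.0",
                "--out-dir", str(out),
            ],
        )
        assert res.exit_code == 0, res.output
        df = pd.read_csv(out / "dose_response.csv")
        assert len(df) == 7

    def test_export_sbml_roundtrip_via_cli(self, tmp_path, bundled):
        target = tmp_path / "model.xml"
        res = CliRunner().invoke(main, ["export-sbml", "--out", str(target)])
        assert res.exit_code == 0, res.output
        assert ca.import_sbml(target).content_hash() == bundled.content_hash()

    def test_unknown_subcommand_fails(self):
        assert run_cli(["frobnicate"]) != 0

    def test_identical_invocations_identical_outputs(self, tmp_path):
        outs = []
        for name in ("a", "b"):
            out = tmp_path / name
            res = CliRunner().invoke(
                main,
                ["simulate", "--t-end", "2.0", "--out-dir", str(out)],
            )
            assert res.exit_code == 0, res.output
            outs.append((out / "trajectory.csv").read_text())
        assert outs[0] == outs[1]

    def test_modulation_reports_direction(self, tmp_path):
        out = tmp_path / "out"
        res = CliRunner().invoke(
            main,
            [
                "modulate",
                "--targets", "Casp8*:0.2",
                "--t-end", "4.0",
                "--out-dir", str(out),
            ],
        )
        assert res.exit_code == 0, res.output
        summary = json.loads((out / "modulation.json").read_text())
        case = summary["cases"][0]
        assert case["target"] == "Casp8*"
        assert case["comparison"]["Apop"] == "less"
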