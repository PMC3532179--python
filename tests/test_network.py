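"""Network representation, RHS compilation, stoichiometry and conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cisapop as ca
from conftest import rhs_oracle


def toy_network(**overrides):
    kwargs = dict(
        species=(
            ca.SpeciesDef("A", "dynamic", 1.0),
            ca.SpeciesDef("B", "dynamic", 0.0),
        ),
        reactions=(
            ca.ReactionStep("r1", consumed={"A": 1}, produced={"B": 1},
                            rate_constant_id="k1"),
        ),
        parameters=ca.RateConstantSet({"k1": 2.0}),
    )
    kwargs.update(overrides)
    return ca.ReactionNetwork(**kwargs)


class TestBuildRhs:
    def test_empty_network_has_zero_derivative(self):
        net = toy_network(reactions=())
        rhs = ca.build_rhs(net)
        assert np.all(rhs(0.0, np.array([3.0, 4.0])) == 0.0)

    def test_single_conversion_mass_action(self):
        rhs = ca.build_rhs(toy_network())
        dy = rhs(0.0, np.array([1.5, 0.0]))
        assert dy == pytest.approx([-3.0, 3.0])

    def test_constant_catalyst_folds_into_rate(self):
        net = toy_network(
            species=(
                ca.SpeciesDef("A", "dynamic", 0.0),
                ca.SpeciesDef("E", "constant", 0.5),
            ),
            reactions=(
                ca.ReactionStep("r1", produced={"A": 1}, catalysts={"E"},
                                rate_constant_id="k1"),
            ),
        )
        rhs = ca.build_rhs(net)
        assert rhs(0.0, np.array([0.0])) == pytest.approx([1.0])  # 2.0 * 0.5

    def test_apoptosis_flux_is_product_of_active_caspases(self, bundled):
        # with Casp9*=Casp3*=1 and everything else 0 the only Apop term is
        # the caspase-9*/3* pair, whose rate constant is 1
        rhs = ca.build_rhs(bundled)
        idx = bundled.species_index
        y = np.zeros(len(idx))
        y[idx["Casp9*"]] = 1.0
        y[idx["Casp3*"]] = 1.0
        dy = rhs(0.0, y)
        assert dy[idx["Apop"]] == pytest.approx(1.0)

    def test_initial_fluxes_of_bundled_model(self, bundled):
        # at t=0 only the cisplatin-uptake step and the spontaneous
        # Bcl-2/Bax association have nonzero factors
        rhs = ca.build_rhs(bundled)
        idx = bundled.species_index
        dy = rhs(0.0, bundled.initial_state())
        assert dy[idx["Aqcis"]] == pytest.approx(1.0)
        assert dy[idx["Bcl2_Bax"]] == pytest.approx(1.0)
        assert dy[idx["Bcl2"]] == pytest.approx(-1.0)
        assert dy[idx["Bax"]] == pytest.approx(-1.0)
        expected = {"Aqcis", "Bcl2_Bax", "Bcl2", "Bax"}
        nonzero = {name for name, i in idx.items() if dy[i] != 0.0}
        assert nonzero == expected

    def test_unresolved_parameter_raises_naming_offender(self):
        net = toy_network(parameters=ca.RateConstantSet({"wrong": 1.0}))
        with pytest.raises(ca.NetworkError, match="k1"):
            ca.build_rhs(net)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**20),
        n_species=st.integers(1, 6),
        n_reactions=st.integers(0, 6),
    )
    def test_compiled_rhs_matches_term_by_term_oracle(self, seed, n_species,
                                                      n_reactions):
        net = ca.generate_fixture_network(seed, n_species, n_reactions)
        rhs = ca.build_rhs(net)
        rng = np.random.default_rng(seed + 1000)
        for _ in range(20):
            y = rng.uniform(0.0, 3.0, len(net.dynamic_species))
            np.testing.assert_allclose(
                rhs(0.0, y), rhs_oracle(net, y), rtol=1e-12, atol=1e-12
            )


class TestStoichiometricMatrix:
    def test_single_conversion_column(self):
        S = ca.stoichiometric_matrix(toy_network())
        assert list(S["r1"]) == [-1, 1]

    def test_catalytic_release_column(self, bundled):
        # caspase-2* catalyses AIF release without being turned over
        S = ca.stoichiometric_matrix(bundled)
        col = S["k20+"]
        assert col["AIFmit"] == -1
        assert col["AIF"] == 1
        assert col["Casp2*"] == 0

    def test_apoptosis_row_is_nonnegative(self, bundled):
        # apoptosis is a pure accumulator: no reaction consumes it
        S = ca.stoichiometric_matrix(bundled)
        assert (S.loc["Apop"] >= 0).all()


class TestConservationPools:
    def test_isolated_species_is_a_pool(self):
        net = toy_network(
            species=(ca.SpeciesDef("A", "dynamic", 1.0),), reactions=()
        )
        pools = ca.conservation_pools(net)
        assert pools == [{"A": 1}]

    @staticmethod
    def in_span(pools, names, target):
        """Is the 0/1 vector over `target` in the rational span of `pools`?"""
        import sympy

        basis = sympy.Matrix([[p.get(n, 0) for n in names] for p in pools])
        vec = sympy.Matrix([[1 if n in target else 0 for n in names]])
        aug = basis.col_join(vec)
        return aug.rank() == basis.rank()

    @pytest.mark.parametrize(
        "pool",
        [
            {"Casp3", "Casp8*_Casp3", "Casp9*_Casp3", "Casp3*", "Casp3*_IAP"},
            {"IAP", "Casp9*_IAP", "Casp3*_IAP"},
            {"AIFmit", "AIF"},
        ],
        ids=["caspase-3", "IAP", "AIF"],
    )
    def test_expected_moieties_are_conserved(self, bundled, pool):
        pools = ca.conservation_pools(bundled)
        names = [s.name for s in bundled.dynamic_species]
        assert self.in_span(pools, names, pool)

    def test_pools_annihilate_stoichiometry(self, bundled):
        S = ca.stoichiometric_matrix(bundled)
        for pool in ca.conservation_pools(bundled):
            c = np.array([pool.get(n, 0) for n in S.index])
            assert np.all(c @ S.to_numpy() == 0)

    def test_pools_constant_along_trajectory(self, bundled, baseline_cal):
        traj = baseline_cal
        for pool in ca.conservation_pools(bundled):
            total = sum(coef * traj[name] for name, coef in pool.items())
            assert np.max(np.abs(total - total[0])) < 1e-6


class TestValidateNetwork:
    def test_bundled_model_is_clean(self, bundled):
        assert ca.validate_network(bundled) == []

    def test_undeclared_species_is_reported(self):
        net = toy_network(
            reactions=(
                ca.ReactionStep("r1", consumed={"Ghost": 1}, produced={"B": 1},
                                rate_constant_id="k1"),
            ),
        )
        report = ca.validate_network(net)
        assert len(report) == 1 and "Ghost" in report[0]

    def test_negative_rate_constant_is_reported(self):
        net = toy_network(parameters=ca.RateConstantSet({"k1": -0.5}))
        report = ca.validate_network(net)
        assert len(report) == 1 and "k1" in report[0]

    def test_consumed_catalyst_conflict_is_reported(self):
        net = toy_network(
            reactions=(
                ca.ReactionStep("r1", consumed={"A": 1}, produced={"B": 1},
                                catalysts={"A"}, rate_constant_id="k1"),
            ),
        )
        assert any("both consumed and catalytic" in v
                   for v in ca.validate_network(net))

    def test_constant_species_cannot_be_consumed(self):
        net = toy_network(
            species=(
                ca.SpeciesDef("A", "constant", 1.0),
                ca.SpeciesDef("B", "dynamic", 0.0),
            ),
        )
        assert any("constant species" in v for v in ca.validate_network(net))
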