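import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from momentfit import (ObservationOperator, ValidationError, builtin_model,
                       equidistant_times, make_network, propensities)


class TestBuiltins:
    @pytest.mark.parametrize("name,n_species,n_reactions,n_params", [
        ("birth_death", 1, 2, 2),
        ("dimerisation", 1, 2, 2),
        ("p53", 3, 6, 7),
    ])
    def test_shapes(self, name, n_species, n_reactions, n_params):
        net = builtin_model(name)
        assert net.n_species == n_species
        assert net.n_reactions == n_reactions
        assert net.n_params == n_params
        assert net.stoich.shape == (n_species, n_reactions)

    def test_birth_death_is_affine(self):
        assert builtin_model("birth_death").propensity_kind == ["affine", "affine"]

    def test_dimerisation_has_quadratic_propensity(self):
        net = builtin_model("dimerisation")
        assert "polynomial" in net.propensity_kind
        assert list(net.stoich[0]) == [-2, 2]

    def test_p53_has_one_rational_propensity(self):
        net = builtin_model("p53")
        assert net.propensity_kind.count("rational") == 1

    def test_unknown_model_rejected(self):
        with pytest.raises(ValidationError, match="unknown model"):
            builtin_model("lotka_volterra")

    @pytest.mark.parametrize("name", ["birth_death", "dimerisation", "p53"])
    def test_propensities_nonnegative_on_random_states(self, name):
        net = builtin_model(name)
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 300, size=net.n_species)
            h = net.propensities(x, net.default_params)
            assert np.all(h >= 0) and np.all(np.isfinite(h))

    def test_zero_when_reactants_insufficient(self):
        bd = builtin_model("birth_death")
        assert np.allclose(bd.propensities([0], [2.0, 1.0]), [0.0, 0.0])
        dim = builtin_model("dimerisation")
        # a single monomer cannot dimerise
        assert dim.propensities([1], [2.0, 1.0])[0] == 0.0


class TestMakeNetwork:
    def test_birth_death_stoichiometry_and_rates(self):
        net = make_network({
            "species": ["X"], "params": ["c1", "c2"], "x0": [10],
            "reactions": [
                {"reactants": {"X": 1}, "products": {"X": 2},
                 "law": "mass_action", "rate_param": "c1"},
                {"reactants": {"X": 1}, "products": {},
                 "law": "mass_action", "rate_param": "c2"},
            ]})
        assert net.stoich.tolist() == [[1, -1]]
        assert np.allclose(net.propensities([10], [2.0, 1.0]), [20.0, 10.0])

    def test_mass_action_homogeneous_in_parameters(self):
        net = builtin_model("birth_death")
        h1 = net.propensities([7], [0.3, 0.4])
        h2 = net.propensities([7], [0.6, 0.8])
        assert np.allclose(h2, 2 * h1)

    def test_pair_convention_for_dimerisation(self):
        # mass action for 2X -> . counts unordered pairs: c * x(x-1)/2
        net = builtin_model("dimerisation")
        assert net.propensities([10], [1.0, 1.0])[0] == pytest.approx(45.0)

    @pytest.mark.parametrize("bad", [
        {"species": ["X"], "params": ["c1"], "x0": [1],
         "reactions": [{"reactants": {"X": 1}, "products": {"X": -1},
                        "law": "mass_action", "rate_param": "c1"}]},
        {"species": ["X"], "params": ["c1"], "x0": [1],
         "reactions": [{"reactants": {"X": 1}, "products": {},
                        "law": "langmuir", "rate_param": "c1"}]},
        {"species": ["X"], "params": ["c1"], "x0": [1],
         "reactions": [{"reactants": {"Y": 1}, "products": {},
                        "law": "mass_action", "rate_param": "c1"}]},
        {"species": ["X"], "params": ["c1"], "x0": [1],
         "reactions": [{"reactants": {"X": 1}, "products": {},
                        "law": "expression", "expr": "c9*X"}]},
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValidationError):
            make_network(bad)

    def test_negative_state_rejected(self):
        net = builtin_model("birth_death")
        with pytest.raises(ValidationError):
            propensities(net, [-1], [1.0, 1.0])
        with pytest.raises(ValidationError):
            propensities(net, [1], [-1.0, 1.0])


class TestObservationOperator:
    def test_equidistant_grid_starts_after_zero(self):
        t = equidistant_times(10.0, 20)
        assert len(t) == 20
        assert t[0] == pytest.approx(0.5)
        assert t[-1] == pytest.approx(10.0)
        assert np.allclose(np.diff(t), 0.5)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValidationError):
            ObservationOperator((0, 0), [1.0, 2.0])

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValidationError):
            ObservationOperator((0,), [2.0, 1.0])

    @given(st.integers(1, 30), st.floats(0.5, 50.0))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_equidistant_spacing_property(self, k, t_end):
        t = equidistant_times(t_end, k)
        assert len(t) == k
        assert np.allclose(np.diff(t), t_end / k)
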