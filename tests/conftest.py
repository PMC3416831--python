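import pytest

from momentfit import (CostSpec, ObservationOperator, SampleMomentSeries,
                       builtin_model, equidistant_times, exact_moment_system,
                       lna_system, normal_closure_1d, predict_observed_moments)


def surrogate_moments(system, c, x0, obs, n_replicates=10_000):
    """Infinite-N surrogate data: sample moments := model predictions at c."""
    mean, cov = predict_observed_moments(system, c, x0, obs)
    return SampleMomentSeries(obs.times, 2, mean, cov, n_replicates,
                              obs.observed_indices)


@pytest.fixture(scope="session")
def bd_net():
    return builtin_model("birth_death")


@pytest.fixture(scope="session")
def dimer_net():
    return builtin_model("dimerisation")


@pytest.fixture(scope="session")
def p53_net():
    return builtin_model("p53")


@pytest.fixture(scope="session")
def bd_obs():
    return ObservationOperator((0,), equidistant_times(10.0, 20))


@pytest.fixture(scope="session")
def bd_system(bd_net):
    return exact_moment_system(bd_net)


@pytest.fixture(scope="session")
def bd_surrogate(bd_net, bd_obs, bd_system):
    """Exact-model birth-death data at the true parameters."""
    return surrogate_moments(bd_system, bd_net.default_params, bd_net.x0, bd_obs)


@pytest.fixture(scope="session")
def bd_spec_n1(bd_system, bd_obs, bd_surrogate, bd_net):
    return CostSpec(bd_system, bd_obs, bd_surrogate, bd_net.x0, order=1)


@pytest.fixture(scope="session")
def bd_spec_n2(bd_system, bd_obs, bd_surrogate, bd_net):
    return CostSpec(bd_system, bd_obs, bd_surrogate, bd_net.x0, order=2)
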