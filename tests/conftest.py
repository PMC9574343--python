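import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def latency_trajectories():
    """Single-neuron latency trajectories for 10 seeds of the headline setup.

    100 afferents at 20 Hz for 200 s, half carrying a recurring 50 ms
    pattern; one STDP neuron with default parameters per seed.
    """
    from stdpsync import AfferentPopulationSpec, generate_afferents, run_neuron
    from stdpsync.population_sim import latency_per_presentation

    out = {}
    for seed in range(1, 11):
        spec = AfferentPopulationSpec(duration=200_000.0, seed=seed)
        trains, pat = generate_afferents(spec)
        run = run_neuron(trains, seed=seed)
        out[seed] = latency_per_presentation(
            run.spike_times, pat.onsets, pat.length + 25.0, trains.duration
        )
    return out


@pytest.fixture(scope="session")
def population_runs():
    """Ten seeded population runs of the coherent-input experiment.

    Shared by the population-level statistics tests (synchrony, sparsening,
    compression) so the expensive simulations run once per session.
    """
    from stdpsync import AfferentPopulationSpec, make_coherent_input_set
    from stdpsync.population_sim import PopulationConfig, run_population

    results = {}
    for seed in range(1, 11):
        spec = AfferentPopulationSpec(duration=400_000.0, seed=seed)
        inputs = make_coherent_input_set(spec, n_neurons=6, overlap=0.5, seed=seed)
        results[seed] = run_population(
            PopulationConfig(n_neurons=6, seed=seed), inputs
        )
    return results


@pytest.fixture(scope="session")
def plasticity_off_runs():
    """Matching plasticity-off controls (frozen weights) for 10 seeds."""
    from stdpsync import AfferentPopulationSpec, make_coherent_input_set
    from stdpsync.population_sim import PopulationConfig, run_population

    results = {}
    for seed in range(1, 11):
        spec = AfferentPopulationSpec(duration=400_000.0, seed=seed)
        inputs = make_coherent_input_set(spec, n_neurons=6, overlap=0.5, seed=seed)
        results[seed] = run_population(
            PopulationConfig(n_neurons=6, seed=seed, plasticity_on=False), inputs
        )
    return results
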