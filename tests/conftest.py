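import pytest
from hypothesis import settings

import smmipseq as s

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_panel() -> s.PanelDefinition:
    """10 probes over 3 transcripts, deterministic."""
    return s.make_random_panel(n_probes=10, n_transcripts=3, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """1 patient (1 healthy + 3 tumor), duplicates, no sequencing error."""
    config = s.SimulationConfig(
        panel=small_panel,
        seed=7,
        n_patients=1,
        baseline_molecules_per_probe=80,
        duplication_mean=2.5,
        error_rate=0.0,
    )
    return s.simulate_cohort(config)


def sequences(sim: s.CohortSimulation) -> dict[str, list[str]]:
    return {sample: [seq for _, seq in reads] for sample, reads in sim.reads.items()}
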