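import numpy as np
import pytest

from magcat import synth


@pytest.fixture(scope="session")
def toy():
    """(dag, propagated counts, IC table) of the 20-term toy ontology."""
    return synth.toy_ontology()


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic community, fixed seed."""
    b, _ = synth.simulate_community(synth.SimulationConfig(seed=7))
    return b


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory):
    """The default bundle written out as fixture files."""
    directory = tmp_path_factory.mktemp("fixtures")
    files = synth.write_fixtures(bundle, str(directory))
    return files


def random_propagated_counts(dag, rng: np.random.Generator) -> dict[str, int]:
    """Random counts guaranteed upward-propagated: each term's count is
    the sum of random direct counts over itself and its descendants."""
    direct = {t: int(rng.integers(0, 1500)) for t in dag}
    return {
        t: direct[t] + sum(direct[d] for d in dag.descendants(t)) for t in dag
    }
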