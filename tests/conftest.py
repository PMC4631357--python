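import numpy as np
import pytest

from emtlogic.library import load_metastasis_model, load_wildtype_states


@pytest.fixture(scope="session")
def model():
    return load_metastasis_model()


@pytest.fixture(scope="session")
def wildtype_states(model):
    return load_wildtype_states(model)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def brute_force_stable_states(model, clamps=None):
    """Independent oracle: test every full assignment explicitly."""
    clamps = clamps or {}
    free = [n for n in model.nodes if n not in clamps]
    found = []
    for code in range(1 << len(free)):
        assign = dict(clamps)
        for j, n in enumerate(free):
            assign[n] = (code >> j) & 1
        state = model.state(assign)
        stable = True
        for node in model.ruled_nodes:
            if node in clamps:
                continue
            if model.evaluate_rule(node, assign) != assign[node]:
                stable = False
                break
        if stable:
            found.append(state)
    return sorted(found)
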