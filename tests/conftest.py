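import dataclasses

import numpy as np
import pytest

from lfnmr import simulate
from lfnmr.io import SpectraCollection


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230921)


@pytest.fixture(scope="session")
def small_collection():
    """A compact noiseless three-singlet collection on a short axis."""
    ppm = np.linspace(0.5, 2.5, 2001)
    centers = [0.9, 1.5, 2.1]
    rows = []
    for scale in (1.0, 1.3, 0.8):
        y = np.zeros_like(ppm)
        for c in centers:
            y += scale * simulate.lorentzian(ppm, c, 0.01)
        rows.append(y)
    return SpectraCollection(
        ppm=ppm,
        intensities=np.array(rows),
        sample_ids=["a", "b", "c"],
        group_labels=["sepsis", "control", "control"],
    )


@pytest.fixture(scope="session")
def neutral_panel():
    """The default signal panel with every fold change set to 1."""
    return [
        dataclasses.replace(s, group_fold_change=1.0)
        for s in simulate.default_signals()
    ]


@pytest.fixture(scope="session")
def separable_data():
    """Linearly separable two-class data, ample n: the first feature
    carries the class cleanly, the rest are noise."""
    gen = np.random.default_rng(7)
    n1 = n2 = 30
    X = gen.standard_normal((n1 + n2, 8))
    g = np.concatenate([np.ones(n1), -np.ones(n2)])
    X[:, 0] = 3.0 * g + 0.3 * gen.standard_normal(n1 + n2)
    y = np.array(["sepsis"] * n1 + ["control"] * n2)
    return X, y
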