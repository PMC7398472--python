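import dataclasses

import numpy as np
import pytest

import tcdenv
from tcdenv.synth import PRESETS, make_scene


def otsu_brute_force(values: np.ndarray, n_bins: int = 256) -> float:
    """Independent exhaustive within-class-variance scan over histogram edges.

    Bins the pixel values to bin centers, then for every interior bin edge
    computes the weighted within-class variance directly with numpy on the
    full pixel array.  Deliberately O(n_bins * n); shares no code with the
    package implementation.
    """
    x = np.asarray(values, dtype=float).ravel()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    binned = centers[idx]
    best_t, best = None, np.inf
    for k in range(1, n_bins):
        t = edges[k]
        lo = binned[binned < t - 1e-15]
        hi = binned[binned >= t - 1e-15]
        if lo.size == 0 or hi.size == 0:
            continue
        wcv = (lo.size * np.var(lo) + hi.size * np.var(hi)) / x.size
        if wcv < best - 1e-15:
            best, best_t = wcv, t
    return best_t


@pytest.fixture(scope="session")
def mca_scene():
    return make_scene(PRESETS["mca"])


@pytest.fixture(scope="session")
def ica_scene():
    return make_scene(PRESETS["ica"])


@pytest.fixture(scope="session")
def dropout_scene():
    return make_scene(PRESETS["dropout"])


@pytest.fixture(scope="session")
def mca_trace(mca_scene):
    return tcdenv.estimate_envelope(mca_scene.spectrogram)


@pytest.fixture(scope="session")
def ica_trace(ica_scene):
    return tcdenv.estimate_envelope(ica_scene.spectrogram)


@pytest.fixture(scope="session")
def dropout_trace(dropout_scene):
    return tcdenv.estimate_envelope(dropout_scene.spectrogram)


@pytest.fixture(scope="session")
def short_scene():
    cfg = dataclasses.replace(PRESETS["mca"], duration=10.0, seed=3)
    return make_scene(cfg)
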