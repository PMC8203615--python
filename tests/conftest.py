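import numpy as np
import pytest

import lumidyn as ld
from lumidyn.synth import gen_toy_structure


@pytest.fixture(scope="session")
def helix20():
    return gen_toy_structure(20, "helix", seed=0)


@pytest.fixture(scope="session")
def helix20_anm(helix20):
    return ld.build_anm(helix20)


@pytest.fixture(scope="session")
def helix_segments():
    return ld.SegmentSet([
        ld.Segment("a1", 1, 7),
        ld.Segment("L1", 8, 13),
        ld.Segment("a2", 14, 20),
    ])


def brute_force_ccor(var, r, i1, i2, j1, j2):
    """Naive double-sum evaluation of the segment-averaged cross-correlation
    (1-based inclusive ranges), the independent oracle for segment_ccor."""
    def block(a1, a2, b1, b2):
        total = 0.0
        for x in range(a1 - 1, a2):
            for y in range(b1 - 1, b2):
                total += r[x, y] * np.sqrt(var[x] * var[y])
        return total

    num = block(i1, i2, j1, j2)
    den = np.sqrt(block(i1, i2, i1, i2) * block(j1, j2, j1, j2))
    return num / den


@pytest.fixture(scope="session")
def brute_ccor():
    return brute_force_ccor


def random_fluctuation_model(rng, P):
    """Random SPD per-residue covariance wrapped as a minimal ANM-like model."""
    A = rng.normal(size=(P, P + 3))
    C = A @ A.T
    var = np.diag(C).copy()
    s = np.sqrt(var)
    ccorr = C / np.outer(s, s)
    return ld.anm.ANMModel(
        hessian=np.zeros((0, 0)), eigenvalues=np.zeros(0),
        eigenvectors=np.zeros((0, 0)), var=var, ccorr=ccorr,
        cutoff=0.0, gamma=1.0,
    )


@pytest.fixture(scope="session")
def make_fluctuation_model():
    return random_fluctuation_model
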