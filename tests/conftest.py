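import numpy as np
import pytest

from fiberkin import synth


@pytest.fixture(scope="session")
def static_fiber():
    """Noiseless, motionless fiber movie with ground truth."""
    spec = synth.FiberMovieSpec(
        n_frames=12, width_px=200, background_noise_sd=0.0,
        oscillation_amplitude=0.0, seed=1,
    )
    seq, y_um = synth.make_fiber_movie(spec)
    return spec, seq, y_um


@pytest.fixture(scope="session")
def noiseless_retraction():
    spec = synth.RetractionMovieSpec(
        seed=3,
        base=synth.FiberMovieSpec(
            n_frames=28, width_px=600, oscillation_amplitude=0.0,
            curvature=0.0, background_noise_sd=0.0),
    )
    seq, truth = synth.make_retraction_movie(spec)
    return spec, seq, truth


def brute_force_two_partition(X):
    """Minimum-SSE partition of rows of X into two non-empty clusters."""
    X = np.asarray(X, dtype=float).reshape(len(X), -1)
    n = len(X)
    best, best_sse = None, np.inf
    for code in range(1, 2 ** (n - 1)):  # fix row 0 in cluster 0
        labels = np.array([(code >> i) & 1 for i in range(n)])
        sse = 0.0
        for k in (0, 1):
            pts = X[labels == k]
            if len(pts):
                sse += ((pts - pts.mean(axis=0)) ** 2).sum()
        if sse < best_sse:
            best_sse, best = sse, labels
    return best, best_sse
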