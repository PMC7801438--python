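import numpy as np
import pytest

from hydrokin import Trajectory


def naive_msd(pos: np.ndarray, n_lags: int) -> np.ndarray:
    """O(frames^2) multiple-origin MSD oracle, independent of the package path."""
    F = pos.shape[0]
    out = np.zeros(n_lags + 1)
    for m in range(1, n_lags + 1):
        acc, cnt = 0.0, 0
        for t0 in range(F - m):
            d = pos[t0 + m] - pos[t0]
            acc += float((d * d).sum())
            cnt += pos.shape[1]
        out[m] = acc / cnt
    return out


def brute_force_count(coords: np.ndarray, pts: np.ndarray, cutoff: float) -> int:
    """Exhaustive point-to-segment distance check over all (water, segment) pairs."""
    n_in = 0
    for q in coords:
        best = np.inf
        if len(pts) == 1:
            best = np.linalg.norm(q - pts[0])
        for a, b in zip(pts[:-1], pts[1:]):
            ab = b - a
            t = np.clip(np.dot(q - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            best = min(best, np.linalg.norm(q - (a + t * ab)))
        n_in += best <= cutoff
    return n_in


@pytest.fixture
def random_walk_traj():
    """Small unwrapped 3-D random walk: 50 frames x 10 particles."""
    rng = np.random.default_rng(42)
    pos = np.cumsum(rng.normal(0, 0.6, size=(50, 10, 3)), axis=0)
    return Trajectory(np.arange(50.0), pos)
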