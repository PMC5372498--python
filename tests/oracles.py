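"""Independent brute-force oracles used by the test suite."""

import numpy as np


def quaternion_rotations(n: int, seed: int = 5) -> np.ndarray:
    """Deterministic quasi-uniform rotation-matrix sample of SO(3)."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    rots = np.empty((n, 3, 3))
    rots[:, 0, 0] = 1 - 2 * (y * y + z * z)
    rots[:, 0, 1] = 2 * (x * y - z * w)
    rots[:, 0, 2] = 2 * (x * z + y * w)
    rots[:, 1, 0] = 2 * (x * y + z * w)
    rots[:, 1, 1] = 1 - 2 * (x * x + z * z)
    rots[:, 1, 2] = 2 * (y * z - x * w)
    rots[:, 2, 0] = 2 * (x * z - y * w)
    rots[:, 2, 1] = 2 * (y * z + x * w)
    rots[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return rots


def brute_force_min_rmsd(mobile, reference, rotations) -> float:
    """Minimum RMSD over a fixed rotation set, optimal translation each time."""
    xm = mobile - mobile.mean(axis=0)
    yr = reference - reference.mean(axis=0)
    moved = np.einsum("kij,nj->kni", rotations, xm)
    rmsds = np.sqrt(np.mean(np.sum((moved - yr) ** 2, axis=2), axis=1))
    return float(rmsds.min())
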