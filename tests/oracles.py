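"""Independent brute-force oracle for the continuous shape measure.

Loops over every vertex matching explicitly; per matching it builds the
optimal proper rotation from a scipy SVD (Kabsch) and minimizes the residual
over the scale factor in closed form. Shares no code path with the
vectorized implementation under test.
"""
import itertools

import numpy as np
import scipy.linalg


def cshm_bruteforce(coords, reference):
    q = np.asarray(coords, dtype=float)
    q = q - q.mean(axis=0)
    q_norm2 = (q ** 2).sum()
    p = reference.vertices  # centered, unit total norm
    p_norm2 = (p ** 2).sum()
    best = np.inf
    for perm in itertools.permutations(range(len(q))):
        qp = q[list(perm)]
        m = qp.T @ p
        u, _, vt = scipy.linalg.svd(m)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        p_rot = p @ rot.T
        corr = float((qp * p_rot).sum())
        scale = max(corr / p_norm2, 0.0)
        resid = q_norm2 - 2.0 * scale * corr + scale ** 2 * p_norm2
        best = min(best, 100.0 * resid / q_norm2)
    return float(min(max(best, 0.0), 100.0))
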