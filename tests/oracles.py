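"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit loops, exhaustive grids —
and shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def simplex_grid_fcls(R: np.ndarray, mixed: np.ndarray,
                      step: float = 1e-3) -> tuple[np.ndarray, float]:
    """Exhaustive grid search over the 3-endmember abundance simplex.

    Evaluates every (a1, a2, a3 = 1 - a1 - a2) on a grid of the given step
    and returns the best abundances and the root-mean-square spectral
    residual.  Only supports exactly three endmembers (columns of R).
    """
    assert R.shape[1] == 3
    n = int(round(1.0 / step))
    a1 = np.repeat(np.arange(n + 1), np.arange(n + 1, 0, -1)) * step
    a2 = np.concatenate([np.arange(n + 1 - i) for i in range(n + 1)]) * step
    a3 = 1.0 - a1 - a2
    A = np.stack([a1, a2, a3])  # (3, n_grid)
    diff = R @ A - mixed[:, None]
    res2 = np.einsum("ij,ij->j", diff, diff)
    k = int(np.argmin(res2))
    return A[:, k].copy(), float(math.sqrt(res2[k] / R.shape[0]))


def glcm_pair_counts(gray: np.ndarray, offset: tuple[int, int],
                     levels: int, symmetric: bool = True) -> np.ndarray:
    """Double-loop co-occurrence counting, normalized to probabilities."""
    dr, dc = offset
    h, w = gray.shape
    mat = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                mat[gray[r, c], gray[r2, c2]] += 1
    if symmetric:
        mat = mat + mat.T
    return mat / mat.sum()


def glcm_stats_loops(p: np.ndarray) -> dict[str, float]:
    """Texture statistics computed with explicit double loops."""
    n = p.shape[0]
    mu = 0.0
    for i in range(n):
        for j in range(n):
            mu += i * p[i, j]
    out = {"VAR": 0.0, "HOM": 0.0, "CON": 0.0, "DIS": 0.0, "ENT": 0.0,
           "SEC": 0.0}
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            out["VAR"] += v * (i - mu) ** 2
            out["HOM"] += v / (1.0 + (i - j) ** 2)
            out["CON"] += v * (i - j) ** 2
            out["DIS"] += v * abs(i - j)
            if v > 0:
                out["ENT"] -= v * math.log(v)
            out["SEC"] += v * v
    return out


def harmonic_coefficients_loops(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Direct double-loop summation of the cosine/sine coefficients."""
    n = len(r)
    A = np.zeros(n)
    B = np.zeros(n)
    for t in range(1, n + 1):
        sa = sb = 0.0
        for j in range(1, n + 1):
            sa += r[j - 1] * math.cos(2.0 * math.pi * t * j / n)
            sb += r[j - 1] * math.sin(2.0 * math.pi * t * j / n)
        A[t - 1] = 2.0 * sa / n
        B[t - 1] = 2.0 * sb / n
    return A, B


def pearson_textbook(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r via the explicit covariance formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


def quantize_by_sorting(values: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width binning oracle based on explicit bin edges."""
    v = np.asarray(values, dtype=float)
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.zeros(v.shape, dtype=int)
    edges = [vmin + (vmax - vmin) * k / levels for k in range(1, levels)]
    out = np.zeros(v.shape, dtype=int)
    it = np.nditer(v, flags=["multi_index"])
    for val in it:
        b = 0
        for e in edges:
            if val >= e:
                b += 1
        out[it.multi_index] = b
    return out
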