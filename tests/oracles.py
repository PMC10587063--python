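"""Independent oracles used by the test suite.

Each oracle solves the same problem as a library routine by a different
route — exhaustive search, closed form, or Monte-Carlo — and never calls the
code path it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation


def grid_search_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD over rigid transforms by multiresolution rotation search.

    For any fixed rotation the optimal translation aligns centroids, so both
    point sets are centred and only rotations are searched: a coarse Euler
    grid refined twice (10° → 1° → 0.1°) around the incumbent.
    """
    A = coords_a - coords_a.mean(axis=0)
    B = coords_b - coords_b.mean(axis=0)

    def rmsd_of(rotations: Rotation) -> np.ndarray:
        mats = rotations.as_matrix()  # (n, 3, 3)
        moved = np.einsum("nij,kj->nki", mats, A)
        d = moved - B[None]
        return np.sqrt((d ** 2).sum(axis=2).mean(axis=1))

    best_angles = None
    best = math.inf
    step = 10.0
    centers = (180.0, 90.0, 180.0)
    spans = (360.0, 180.0, 360.0)
    for _ in range(3):
        grids = [
            np.arange(c - s / 2, c + s / 2 + 1e-9, step)
            for c, s in zip(centers, spans)
        ]
        aa, bb, cc = np.meshgrid(*grids, indexing="ij")
        angles = np.column_stack([aa.ravel(), bb.ravel(), cc.ravel()])
        vals = rmsd_of(Rotation.from_euler("zyz", angles, degrees=True))
        k = int(vals.argmin())
        if vals[k] < best:
            best = float(vals[k])
            best_angles = angles[k]
        centers = tuple(best_angles)
        spans = (4 * step, 4 * step, 4 * step)
        step /= 10.0
    return best


def brute_force_global_score(
    seq_a: str,
    seq_b: str,
    matrix,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Affine-gap global alignment score by exhaustive path enumeration.

    Recursion over alignment paths with an explicit gap state; no dynamic
    programming table, so it shares nothing with the aligner it checks.
    Feasible only for short sequences.
    """
    alphabet = matrix.alphabet
    idx = {c: alphabet.index(c) for c in set(seq_a + seq_b)}
    la, lb = len(seq_a), len(seq_b)
    best = [-math.inf]

    def rec(i: int, j: int, state: int, score: float) -> None:
        if i == la and j == lb:
            if score > best[0]:
                best[0] = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, 0, score + matrix[idx[seq_a[i]], idx[seq_b[j]]])
        if i < la:  # gap in seq_b
            cost = gap_extend if state == 1 else gap_open
            rec(i + 1, j, 1, score - cost)
        if j < lb:  # gap in seq_a
            cost = gap_extend if state == 2 else gap_open
            rec(i, j + 1, 2, score - cost)

    rec(0, 0, -1, 0.0)
    return best[0]


def monte_carlo_sasa(
    positions: np.ndarray,
    radii: np.ndarray,
    probe: float,
    n_samples: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Per-atom solvent-accessible area by random surface sampling."""
    rng = np.random.default_rng(seed)
    ext = radii + probe
    areas = np.zeros(len(positions))
    for i in range(len(positions)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = positions[i] + ext[i] * v
        free = np.ones(n_samples, dtype=bool)
        for j in range(len(positions)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - positions[j], axis=1) >= ext[j]
        areas[i] = free.mean() * 4.0 * math.pi * ext[i] ** 2
    return areas
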