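"""Independent brute-force oracles used by the test-suite.

Each oracle re-derives the quantity under test by the most direct route
available (explicit loops, all-pairs comparisons, full decompositions),
sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def laplacian_loop(counts: np.ndarray) -> np.ndarray:
    """Element-wise ``C_ij / sqrt(d_i d_j)`` via explicit loops."""
    n = counts.shape[0]
    d = [sum(counts[i, j] for i in range(n)) for j in range(n)]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = counts[i, j] / np.sqrt(d[i] * d[j])
    return out


def gaps_stepwise(vectors: np.ndarray) -> np.ndarray:
    """Step-by-step eigenvector-gap computation per the printed recipe."""
    v = np.array(vectors, dtype=float)
    k = v.shape[0]
    for j in range(2):
        v[:, j] = v[:, j] / np.sqrt(np.sum(v[:, j] ** 2))
    z = np.empty_like(v)
    for i in range(k):
        r = np.sqrt(v[i, 0] ** 2 + v[i, 1] ** 2)
        z[i] = v[i] / r
    gaps = np.empty(k - 1)
    for i in range(1, k):
        gaps[i - 1] = np.sqrt((z[i, 0] - z[i - 1, 0]) ** 2
                              + (z[i, 1] - z[i - 1, 1]) ** 2)
    return gaps


def overlap_quadratic(regions, track) -> np.ndarray:
    """All-pairs half-open interval overlap counts."""
    counts = []
    for (a, b) in regions:
        c = 0
        for (s, e) in track:
            if s < b and e > a:
                c += 1
        counts.append(c)
    return np.asarray(counts)


def classify_rule_table(flags_p, flags_r, is_diff, t_shift=5,
                        positions=None) -> list[str]:
    """Rule-table classification via explicit per-bin searches.

    Independent re-statement of the five-type decision procedure using
    all-pairs position scans instead of cumulative index tricks.
    """
    n = len(flags_p)
    if positions is None:
        positions = list(range(n))
    out = []
    for i in range(n):
        p, r, d = flags_p[i], flags_r[i], is_diff[i]
        if not p and not r:
            out.append("NonBoundary")
            continue
        if p and r:
            out.append("StrengthChange" if d else "NonDifferential")
            continue
        if not d:
            out.append("NonDifferential")
            continue
        other = flags_r if p else flags_p
        near = any(other[j] and abs(positions[j] - positions[i]) <= t_shift
                   for j in range(n))
        if near:
            out.append("Shifted")
            continue
        lefts = [j for j in range(n) if j < i and (flags_p[j] or flags_r[j])]
        rights = [j for j in range(n) if j > i and (flags_p[j] or flags_r[j])]
        shared = False
        if lefts and rights:
            jl, jr = max(lefts), min(rights)
            shared = (flags_p[jl] and flags_r[jl] and not is_diff[jl]
                      and flags_p[jr] and flags_r[jr] and not is_diff[jr])
        if shared:
            out.append("Split" if p else "Merge")
        else:
            out.append("Complex")
    return out


def classify_rule_table_batch(fp: np.ndarray, fr: np.ndarray,
                              isdiff: np.ndarray, t_shift: int = 5
                              ) -> np.ndarray:
    """Vectorized rule-table oracle via all-pairs distance matrices.

    ``fp``/``fr``/``isdiff`` are ``(B, n)`` boolean arrays.  Uses dense
    ``(n, n)`` neighbor logic, a different algorithmic route from the
    implementation's cumulative scans.  Returns ``(B, n)`` label codes
    indexing into the order (Complex, Split, Merge, Shifted,
    StrengthChange, NonDifferential, NonBoundary).
    """
    B, n = fp.shape
    idx = np.arange(n)
    within = np.abs(idx[:, None] - idx[None, :]) <= t_shift  # (n, n)
    strictly_left = idx[:, None] > idx[None, :]
    strictly_right = idx[:, None] < idx[None, :]

    both = fp & fr
    either = fp | fr
    p_only = fp & ~fr
    r_only = fr & ~fp
    flank_ok = both & ~isdiff

    near_r = (fr[:, None, :] & within[None, :, :]).any(axis=2)
    near_p = (fp[:, None, :] & within[None, :, :]).any(axis=2)
    shifted = (p_only & near_r) | (r_only & near_p)

    # nearest flagged-either neighbor on each side, via masked arg-extremes
    j_grid = np.broadcast_to(idx, (B, n, n))
    left_mask = either[:, None, :] & strictly_left[None, :, :]
    right_mask = either[:, None, :] & strictly_right[None, :, :]
    left_j = np.where(left_mask, j_grid, -1).max(axis=2)
    right_j = np.where(right_mask, j_grid, n).min(axis=2)
    has_left = left_j >= 0
    has_right = right_j <= n - 1
    left_good = np.take_along_axis(flank_ok, np.clip(left_j, 0, n - 1),
                                   axis=1) & has_left
    right_good = np.take_along_axis(flank_ok, np.clip(right_j, 0, n - 1),
                                    axis=1) & has_right
    shared = left_good & right_good

    one_diff = (p_only | r_only) & isdiff
    out = np.full((B, n), 6, dtype=np.uint8)          # NonBoundary
    out[both & isdiff] = 4                            # StrengthChange
    out[both & ~isdiff] = 5                           # NonDifferential
    out[(p_only | r_only) & ~isdiff] = 5              # NonDifferential
    out[one_diff] = 0                                 # Complex
    out[one_diff & ~shifted & shared & p_only] = 1    # Split
    out[one_diff & ~shifted & shared & r_only] = 2    # Merge
    out[one_diff & shifted] = 3                       # Shifted
    return out
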