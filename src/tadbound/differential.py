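"""Differential boundary analysis between two contact matrices.

Both matrices are reduced to eigenvector-gap profiles on their joint
informative bins.  Because log gaps are approximately normal within each
matrix, the difference of log gaps is normal with variance
``sigma_P^2 + sigma_R^2``, which yields the per-bin differential
boundary score

    DB_i = [(ln D_P,i - ln D_R,i) - (mu_P - mu_R)] / sqrt(sigma_P^2 + sigma_R^2)

distributed N(0, 1) when nothing changed.  Bins are then classified into
five change types (Complex, Split, Merge, Shifted, StrengthChange) or
NonDifferential / NonBoundary.

Directionality: the first argument ``P`` is the matrix under test and
the second ``R`` the reference.  *Split* marks a differential boundary
present only in ``P`` between shared flanks (the domain is split in
``P``); *Merge* marks one present only in ``R`` (it disappeared in
``P``, so ``P``'s domains merged).  Swapping the arguments exchanges
Merge and Split and negates ``DB``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import defaults
from .matrix_io import ContactMatrix
from .spectral import (GapProfile, harmonize_masks, informative_mask,
                       scores_from_gaps, windowed_gap_profile)

__all__ = [
    "CompareParams",
    "CATEGORIES",
    "differential_scores",
    "call_boundaries",
    "classify_pairwise",
    "compare",
]

COMPLEX = "Complex"
SPLIT = "Split"
MERGE = "Merge"
SHIFTED = "Shifted"
STRENGTH_CHANGE = "StrengthChange"
NON_DIFFERENTIAL = "NonDifferential"
NON_BOUNDARY = "NonBoundary"

#: All per-bin category labels, differential types first.
CATEGORIES = (COMPLEX, SPLIT, MERGE, SHIFTED, STRENGTH_CHANGE,
              NON_DIFFERENTIAL, NON_BOUNDARY)

_CATEGORY_ARRAY = np.array(CATEGORIES, dtype=object)
_CODE = {name: np.uint8(i) for i, name in enumerate(CATEGORIES)}


@dataclass
class CompareParams:
    """Tuning parameters for pairwise boundary comparison.

    boundary_threshold
        Boundary-score cutoff for calling a bin a boundary (default 3).
    diff_threshold
        |DB| cutoff for a differential bin (default 2, the two-sided
        5% point of the standard normal in round numbers).
    shift_bins
        Maximum distance in bins for the Shifted call (default 5).
    window
        Sliding-window size in bins (default 15).
    informative_frac
        Minimum non-zero fraction for an informative bin (default 0.2).
    """

    boundary_threshold: float = defaults.BOUNDARY_THRESHOLD
    diff_threshold: float = defaults.DIFF_THRESHOLD
    shift_bins: int = defaults.SHIFT_BINS
    window: int = defaults.WINDOW
    informative_frac: float = defaults.INFORMATIVE_FRAC

    def __post_init__(self) -> None:
        if self.boundary_threshold <= 0:
            raise ValueError("boundary_threshold must be positive")
        if self.diff_threshold <= 0:
            raise ValueError("diff_threshold must be positive")
        if self.shift_bins < 1:
            raise ValueError("shift_bins must be >= 1")


def _log_fit(profile: GapProfile) -> tuple[np.ndarray, float, float]:
    """Log gaps (zero-floored) plus fitted mu and sigma^2 of a profile."""
    fitted = scores_from_gaps(profile)  # one code path for the fit
    gaps = np.asarray(profile.gaps, dtype=float).copy()
    defined = ~np.isnan(gaps)
    vals = gaps[defined]
    if np.any(vals == 0):
        vals = np.where(vals == 0, vals[vals > 0].min(), vals)
    log_gaps = np.full(gaps.shape, np.nan)
    log_gaps[defined] = np.log(vals)
    return log_gaps, fitted.mu, fitted.sigma ** 2


def differential_scores(gaps_p: GapProfile, gaps_r: GapProfile) -> np.ndarray:
    """Per-bin differential boundary scores ``DB`` between two profiles.

    The profiles must be aligned on identical retained bins (apply
    :func:`tadbound.spectral.harmonize_masks` first).  ``mu`` and
    ``sigma^2`` are fitted per matrix over its own defined gaps; NaN
    placeholders propagate.
    """
    gp = np.asarray(gaps_p.gaps, dtype=float)
    gr = np.asarray(gaps_r.gaps, dtype=float)
    if gp.shape != gr.shape:
        raise ValueError("profiles have different lengths")
    if not np.array_equal(np.isnan(gp), np.isnan(gr)):
        raise ValueError("profiles are not aligned on the same retained bins")
    log_p, mu_p, var_p = _log_fit(gaps_p)
    log_r, mu_r, var_r = _log_fit(gaps_r)
    pooled = var_p + var_r
    if pooled == 0:
        raise ValueError("zero pooled variance of log gaps")
    return ((log_p - log_r) - (mu_p - mu_r)) / np.sqrt(pooled)


def call_boundaries(scores, t_b: float = defaults.BOUNDARY_THRESHOLD
                    ) -> np.ndarray:
    """Flag boundary bins: score >= ``t_b`` (one-sided).

    A boundary is a large eigenvector gap; large *negative* scores mean
    an unusually smooth region, never a boundary.  NaN scores are never
    boundaries.  Accepts a :class:`~tadbound.spectral.BoundaryScores`
    or a bare score array.
    """
    arr = np.asarray(getattr(scores, "scores", scores), dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(arr), False, arr >= t_b)


def _nearest_flag_distance(flags: np.ndarray, positions: np.ndarray
                           ) -> np.ndarray:
    """Distance from each bin to the nearest flagged bin (inf if none).

    Operates on the trailing axis of a (possibly batched) boolean array.
    """
    n = flags.shape[-1]
    idx = np.broadcast_to(np.arange(n), flags.shape)
    prev = np.maximum.accumulate(np.where(flags, idx, -1), axis=-1)
    nxt = n - 1 - np.maximum.accumulate(
        np.where(flags[..., ::-1], idx, -1), axis=-1)[..., ::-1]
    pos = positions.astype(float)
    dist_prev = np.where(prev >= 0,
                         pos[np.arange(n)] - pos[np.clip(prev, 0, n - 1)],
                         np.inf)
    dist_next = np.where(nxt <= n - 1,
                         pos[np.clip(nxt, 0, n - 1)] - pos[np.arange(n)],
                         np.inf)
    return np.minimum(dist_prev, dist_next)


def _flank_indices(either: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest flagged index strictly left/right of each bin (-1/n if none)."""
    n = either.shape[-1]
    idx = np.broadcast_to(np.arange(n), either.shape)
    prev_incl = np.maximum.accumulate(np.where(either, idx, -1), axis=-1)
    nxt_incl = n - 1 - np.maximum.accumulate(
        np.where(either[..., ::-1], idx, -1), axis=-1)[..., ::-1]
    left = np.full(either.shape, -1, dtype=np.int64)
    left[..., 1:] = prev_incl[..., :-1]
    right = np.full(either.shape, n, dtype=np.int64)
    right[..., :-1] = nxt_incl[..., 1:]
    # nxt_incl is n-1-(-1) = n when nothing flagged to the right: keep n
    right = np.where(right > n, n, right)
    return left, right


def classify_pairwise(flags_p, flags_r, diff,
                      params: CompareParams | None = None,
                      positions: np.ndarray | None = None) -> np.ndarray:
    """Classify each bin into one of the seven per-bin categories.

    Decision procedure per bin ``i`` with ``is_diff = |DB_i| >= t_d``:

    1. not a boundary in either matrix -> NonBoundary;
    2. boundary in both: is_diff -> StrengthChange, else NonDifferential;
    3. boundary in exactly one matrix, not is_diff -> NonDifferential;
    4. boundary in exactly one matrix and is_diff:
       a. the other matrix has a boundary within ``shift_bins`` ->
          Shifted (proximity is the most specific explanation, so it
          takes precedence);
       b. else if the nearest boundary bins on both sides are shared,
          non-differential boundaries in *both* matrices -> Merge when
          the boundary exists only in R, Split when only in P;
       c. else -> Complex.

    ``positions`` (default ``0..n-1``) give each bin's original index so
    that shift distances are measured in genomic bins even after
    non-informative bins were removed.
    """
    if params is None:
        params = CompareParams()
    fp = np.asarray(flags_p, dtype=bool)
    fr = np.asarray(flags_r, dtype=bool)
    dd = np.asarray(diff, dtype=float)
    if not (fp.shape == fr.shape == dd.shape):
        raise ValueError("misaligned inputs")
    n = fp.shape[-1]
    if positions is None:
        positions = np.arange(n)
    positions = np.asarray(positions)
    with np.errstate(invalid="ignore"):
        is_diff = np.where(np.isnan(dd), False,
                           np.abs(dd) >= params.diff_threshold)

    both = fp & fr
    p_only = fp & ~fr
    r_only = fr & ~fp

    dist_to_r = _nearest_flag_distance(fr, positions)
    dist_to_p = _nearest_flag_distance(fp, positions)
    shifted = ((p_only & (dist_to_r <= params.shift_bins)) |
               (r_only & (dist_to_p <= params.shift_bins)))

    flank_ok = both & ~is_diff
    left, right = _flank_indices(fp | fr)
    left_ok = np.take_along_axis(
        flank_ok, np.clip(left, 0, n - 1), axis=-1) & (left >= 0)
    right_ok = np.take_along_axis(
        flank_ok, np.clip(right, 0, n - 1), axis=-1) & (right <= n - 1)
    shared_flanks = left_ok & right_ok

    one_diff = (p_only | r_only) & is_diff
    codes = np.full(fp.shape, _CODE[NON_BOUNDARY], dtype=np.uint8)
    codes[both & is_diff] = _CODE[STRENGTH_CHANGE]
    codes[both & ~is_diff] = _CODE[NON_DIFFERENTIAL]
    codes[(p_only | r_only) & ~is_diff] = _CODE[NON_DIFFERENTIAL]
    codes[one_diff] = _CODE[COMPLEX]
    codes[one_diff & ~shifted & shared_flanks & p_only] = _CODE[SPLIT]
    codes[one_diff & ~shifted & shared_flanks & r_only] = _CODE[MERGE]
    codes[one_diff & shifted] = _CODE[SHIFTED]
    return _CATEGORY_ARRAY[codes]


def compare(matrix_p: ContactMatrix, matrix_r: ContactMatrix,
            params: CompareParams | None = None) -> pd.DataFrame:
    """End-to-end differential boundary comparison of two matrices.

    Pipeline: informative masks -> joint mask -> windowed gap profiles
    -> boundary scores -> differential scores -> boundary flags ->
    classification.  Returns one row per retained bin with columns
    ``chrom, start, end, gap_p, gap_r, score_p, score_r, diff_score,
    boundary_p, boundary_r, category``.
    """
    if params is None:
        params = CompareParams()
    if matrix_p.chrom != matrix_r.chrom:
        raise ValueError("chromosome mismatch")
    if matrix_p.resolution != matrix_r.resolution:
        raise ValueError("resolution mismatch")
    if matrix_p.n_bins != matrix_r.n_bins:
        raise ValueError("bin count mismatch")

    mask = harmonize_masks(
        informative_mask(matrix_p, w=params.window,
                         frac=params.informative_frac),
        informative_mask(matrix_r, w=params.window,
                         frac=params.informative_frac))
    prof_p = windowed_gap_profile(matrix_p, mask, w=params.window)
    prof_r = windowed_gap_profile(matrix_r, mask, w=params.window)
    scores_p = scores_from_gaps(prof_p)
    scores_r = scores_from_gaps(prof_r)
    db = differential_scores(prof_p, prof_r)
    flags_p = call_boundaries(scores_p, params.boundary_threshold)
    flags_r = call_boundaries(scores_r, params.boundary_threshold)

    retained = np.flatnonzero(mask)
    categories = classify_pairwise(
        flags_p[retained], flags_r[retained], db[retained],
        params=params, positions=retained)

    return pd.DataFrame({
        "chrom": matrix_p.chrom,
        "start": matrix_p.starts[retained],
        "end": matrix_p.ends[retained],
        "gap_p": prof_p.gaps[retained],
        "gap_r": prof_r.gaps[retained],
        "score_p": scores_p.scores[retained],
        "score_r": scores_r.scores[retained],
        "diff_score": db[retained],
        "boundary_p": flags_p[retained],
        "boundary_r": flags_r[retained],
        "category": categories,
    })
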