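"""Time-course tracking of TAD boundary dynamics.

Boundary scores are computed at each of >= 3 ordered time points
(replicates at a time point collapse to their median, the consensus
score).  A bin is *present* at a time point when its consensus score
clears the boundary threshold.  Each union boundary — a bin present at
one or more time points — is classified into one of six temporal
patterns (HighlyCommon, EarlyAppearing, EarlyDisappearing,
LateAppearing, LateDisappearing, Dynamic) from its presence vector.

With exactly four time points the classification is an exact lookup:

========  ==================
pattern   presence vectors
========  ==================
HighlyCommon      1111, 1011
EarlyAppearing    0111
EarlyDisappearing 1000
LateAppearing     0011, 0001
LateDisappearing  1100, 1110
Dynamic           1010, 1001 and every other non-zero vector
========  ==================

For other numbers of time points the analogous prefix/suffix rules
apply, with Dynamic as the catch-all for inconsistent trajectories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import defaults
from .differential import CompareParams
from .matrix_io import ContactMatrix
from .spectral import (harmonize_masks, informative_mask, scores_from_gaps,
                       windowed_gap_profile)

__all__ = [
    "TEMPORAL_PATTERNS",
    "presence_matrix",
    "classify_temporal",
    "timecourse_analysis",
]

HIGHLY_COMMON = "HighlyCommon"
EARLY_APPEARING = "EarlyAppearing"
EARLY_DISAPPEARING = "EarlyDisappearing"
LATE_APPEARING = "LateAppearing"
LATE_DISAPPEARING = "LateDisappearing"
DYNAMIC = "Dynamic"

TEMPORAL_PATTERNS = (HIGHLY_COMMON, EARLY_APPEARING, EARLY_DISAPPEARING,
                     LATE_APPEARING, LATE_DISAPPEARING, DYNAMIC)

#: Exact four-time-point lookup; any non-zero vector absent here is Dynamic.
_LOOKUP_T4 = {
    (1, 1, 1, 1): HIGHLY_COMMON,
    (1, 0, 1, 1): HIGHLY_COMMON,
    (0, 1, 1, 1): EARLY_APPEARING,
    (1, 0, 0, 0): EARLY_DISAPPEARING,
    (0, 0, 1, 1): LATE_APPEARING,
    (0, 0, 0, 1): LATE_APPEARING,
    (1, 1, 0, 0): LATE_DISAPPEARING,
    (1, 1, 1, 0): LATE_DISAPPEARING,
}


def presence_matrix(scores_by_timepoint,
                    t_b: float = defaults.BOUNDARY_THRESHOLD
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse replicate scores per time point and threshold presence.

    Parameters
    ----------
    scores_by_timepoint
        Time-ordered list; each element is a list of per-replicate score
        vectors (or :class:`~tadbound.spectral.BoundaryScores`), all
        aligned on the same jointly masked bins.
    t_b
        Boundary threshold applied to the per-time-point median.

    Returns
    -------
    (consensus, presence)
        ``consensus`` is a ``T x n`` float array of per-time-point
        median scores and ``presence`` the ``T x n`` boolean array
        ``consensus >= t_b`` (NaN -> absent).
    """
    if len(scores_by_timepoint) < 3:
        raise ValueError("need at least 3 time points")
    rows = []
    n = None
    for reps in scores_by_timepoint:
        arrs = [np.asarray(getattr(v, "scores", v), dtype=float)
                for v in (reps if isinstance(reps, (list, tuple)) else [reps])]
        if n is None:
            n = arrs[0].shape[0]
        if any(a.shape != (n,) for a in arrs):
            raise ValueError("misaligned score vectors across time points")
        rows.append(np.median(np.vstack(arrs), axis=0))
    consensus = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        presence = np.where(np.isnan(consensus), False, consensus >= t_b)
    return consensus, presence


def classify_temporal(presence) -> str:
    """Classify one presence vector into a temporal pattern.

    Four time points use the exact lookup table; other lengths use the
    general rules (HighlyCommon: present at both ends and at all but at
    most one time point; Early/Late Appearing/Disappearing: a single
    switch at the second or one of the last two time points; otherwise
    Dynamic).  An all-absent vector is not a union boundary and raises.
    """
    vec = tuple(int(bool(v)) for v in np.asarray(presence).ravel())
    t = len(vec)
    if t < 3:
        raise ValueError("need at least 3 time points")
    if not any(vec):
        raise ValueError("all-absent vector is not a union boundary")
    if t == 4:
        return _LOOKUP_T4.get(vec, DYNAMIC)

    total = sum(vec)
    ones_prefix = 0
    for v in vec:
        if v != 1:
            break
        ones_prefix += 1
    zeros_prefix = 0
    for v in vec:
        if v != 0:
            break
        zeros_prefix += 1
    if vec[0] and vec[-1] and total >= t - 1:
        return HIGHLY_COMMON
    if zeros_prefix + total == t:  # zeros then ones, one switch
        if zeros_prefix == 1:
            return EARLY_APPEARING
        if zeros_prefix >= t - 2:
            return LATE_APPEARING
    if ones_prefix + (t - total) == t and total == ones_prefix:
        # ones then zeros, one switch
        if ones_prefix == 1:
            return EARLY_DISAPPEARING
        if t - 2 <= ones_prefix <= t - 1:
            return LATE_DISAPPEARING
    return DYNAMIC


def timecourse_analysis(matrices_by_timepoint,
                        params: CompareParams | None = None) -> pd.DataFrame:
    """Full time-course boundary analysis.

    Parameters
    ----------
    matrices_by_timepoint
        Time-ordered list; each element is a single
        :class:`~tadbound.matrix_io.ContactMatrix` or a list of
        replicate matrices for that time point.
    params
        Shared thresholds and window size.

    Returns
    -------
    pandas.DataFrame
        One row per retained bin: coordinates, per-time-point consensus
        scores (``score_t1 .. score_tT``), presence columns, a union
        flag, and the temporal ``pattern`` (empty for non-union bins).
    """
    if params is None:
        params = CompareParams()
    groups = [list(g) if isinstance(g, (list, tuple)) else [g]
              for g in matrices_by_timepoint]
    if len(groups) < 3:
        raise ValueError("need at least 3 time points")
    flat = [m for g in groups for m in g]
    first = flat[0]
    for m in flat[1:]:
        if (m.chrom, m.resolution, m.n_bins) != (first.chrom,
                                                 first.resolution,
                                                 first.n_bins):
            raise ValueError("matrices are not aligned")
    mask = informative_mask(first, w=params.window,
                            frac=params.informative_frac)
    for m in flat[1:]:
        mask = harmonize_masks(
            mask, informative_mask(m, w=params.window,
                                   frac=params.informative_frac))

    scores_by_tp = [
        [scores_from_gaps(windowed_gap_profile(m, mask,
                                               w=params.window)).scores
         for m in g]
        for g in groups
    ]
    consensus, presence = presence_matrix(scores_by_tp,
                                          params.boundary_threshold)
    union = presence.any(axis=0)

    retained = np.flatnonzero(mask)
    patterns = np.full(first.n_bins, "", dtype=object)
    for i in np.flatnonzero(union):
        patterns[i] = classify_temporal(presence[:, i])

    table = {"chrom": first.chrom,
             "start": first.starts[retained],
             "end": first.ends[retained]}
    for t in range(consensus.shape[0]):
        table[f"score_t{t + 1}"] = consensus[t, retained]
    for t in range(presence.shape[0]):
        table[f"present_t{t + 1}"] = presence[t, retained]
    table["union_boundary"] = union[retained]
    table["pattern"] = patterns[retained]
    return pd.DataFrame(table)
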