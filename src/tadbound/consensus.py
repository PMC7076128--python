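"""Consensus boundary calling across replicate Hi-C matrices.

The consensus boundary score of a bin is the median of its boundary
scores across replicates; a consensus boundary requires the median to
clear the boundary threshold, so it must be supported by at least half
of the replicates.  The union of boundaries, by contrast, pools every
bin called in at least one replicate and therefore admits
single-replicate noise.  Two replicate *groups* are compared by
aggregating each group's log gaps into a median pseudo-profile and
running the usual differential machinery on those.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import defaults
from .differential import (CompareParams, call_boundaries, classify_pairwise,
                           differential_scores)
from .matrix_io import ContactMatrix
from .spectral import (GapProfile, harmonize_masks, informative_mask,
                       scores_from_gaps, windowed_gap_profile)

__all__ = [
    "consensus_scores",
    "union_boundaries",
    "consensus_boundaries",
    "compare_groups",
    "consensus_table",
]


def _stack_aligned(score_vectors) -> np.ndarray:
    arrs = [np.asarray(getattr(v, "scores", v), dtype=float)
            for v in score_vectors]
    if len(arrs) < 2:
        raise ValueError("need at least 2 replicates")
    n = arrs[0].shape[0]
    if any(a.shape != (n,) for a in arrs):
        raise ValueError("misaligned replicate score vectors")
    return np.vstack(arrs)


def consensus_scores(score_vectors) -> np.ndarray:
    """Element-wise median of per-replicate score vectors.

    Replicates must be aligned on the same (jointly masked) bins.  An
    even replicate count uses the midpoint of the two central values.
    NaN placeholders propagate (they are aligned across replicates).
    """
    return np.median(_stack_aligned(score_vectors), axis=0)


def union_boundaries(score_vectors,
                     t_b: float = defaults.BOUNDARY_THRESHOLD) -> np.ndarray:
    """Union flag: boundary called (score >= ``t_b``) in >= 1 replicate."""
    stacked = _stack_aligned(score_vectors)
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(stacked), False, stacked >= t_b).any(axis=0)


def consensus_boundaries(consensus,
                         t_b: float = defaults.BOUNDARY_THRESHOLD
                         ) -> np.ndarray:
    """Consensus flag: per-bin median score >= ``t_b``."""
    arr = np.asarray(consensus, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(arr), False, arr >= t_b)


def _group_log_median_profile(group: list[ContactMatrix], mask: np.ndarray,
                              w: int) -> GapProfile:
    """Median-of-log-gaps pseudo-profile for one replicate group.

    Aggregation happens on the gap (log) scale, not the score scale, so
    the differential statistic's per-matrix mu/sigma fit stays
    well-defined on the aggregated profile.
    """
    profiles = [windowed_gap_profile(m, mask, w=w) for m in group]
    stacked = np.vstack([p.gaps for p in profiles])
    with np.errstate(divide="ignore"):
        log_med = np.median(np.log(stacked), axis=0)
    return GapProfile(gaps=np.exp(log_med), window=w)


def compare_groups(group_a: list[ContactMatrix],
                   group_b: list[ContactMatrix],
                   params: CompareParams | None = None) -> pd.DataFrame:
    """Differential boundary comparison between two replicate groups.

    All matrices are jointly masked; each group's gap profiles collapse
    to a per-bin median pseudo-profile, on which boundary scores, the
    differential statistic and the change classification proceed exactly
    as in :func:`tadbound.differential.compare`.  With single-matrix
    groups the result reduces to the pairwise comparison.
    """
    if params is None:
        params = CompareParams()
    if not group_a or not group_b:
        raise ValueError("each group needs at least one matrix")
    matrices = list(group_a) + list(group_b)
    first = matrices[0]
    for m in matrices[1:]:
        if m.chrom != first.chrom:
            raise ValueError("chromosome mismatch")
        if m.resolution != first.resolution:
            raise ValueError("resolution mismatch")
        if m.n_bins != first.n_bins:
            raise ValueError("bin count mismatch")

    mask = informative_mask(matrices[0], w=params.window,
                            frac=params.informative_frac)
    for m in matrices[1:]:
        mask = harmonize_masks(
            mask, informative_mask(m, w=params.window,
                                   frac=params.informative_frac))

    prof_a = _group_log_median_profile(group_a, mask, params.window)
    prof_b = _group_log_median_profile(group_b, mask, params.window)
    scores_a = scores_from_gaps(prof_a)
    scores_b = scores_from_gaps(prof_b)
    db = differential_scores(prof_a, prof_b)
    flags_a = call_boundaries(scores_a, params.boundary_threshold)
    flags_b = call_boundaries(scores_b, params.boundary_threshold)

    retained = np.flatnonzero(mask)
    categories = classify_pairwise(
        flags_a[retained], flags_b[retained], db[retained],
        params=params, positions=retained)

    return pd.DataFrame({
        "chrom": first.chrom,
        "start": first.starts[retained],
        "end": first.ends[retained],
        "gap_p": prof_a.gaps[retained],
        "gap_r": prof_b.gaps[retained],
        "score_p": scores_a.scores[retained],
        "score_r": scores_b.scores[retained],
        "diff_score": db[retained],
        "boundary_p": flags_a[retained],
        "boundary_r": flags_b[retained],
        "category": categories,
    })


def consensus_table(matrices: list[ContactMatrix],
                    params: CompareParams | None = None) -> pd.DataFrame:
    """Per-bin replicate scores, consensus score, union and consensus flags.

    Convenience wrapper used by the CLI: masks jointly, scores each
    replicate, and returns one row per retained bin.
    """
    if params is None:
        params = CompareParams()
    if len(matrices) < 2:
        raise ValueError("need at least 2 replicate matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if (m.chrom, m.resolution, m.n_bins) != (first.chrom,
                                                 first.resolution,
                                                 first.n_bins):
            raise ValueError("replicate matrices are not aligned")
    mask = informative_mask(first, w=params.window,
                            frac=params.informative_frac)
    for m in matrices[1:]:
        mask = harmonize_masks(
            mask, informative_mask(m, w=params.window,
                                   frac=params.informative_frac))
    score_vecs = [
        scores_from_gaps(windowed_gap_profile(m, mask, w=params.window)).scores
        for m in matrices
    ]
    consensus = consensus_scores(score_vecs)
    union = union_boundaries(score_vecs, params.boundary_threshold)
    cons_flag = consensus_boundaries(consensus, params.boundary_threshold)

    retained = np.flatnonzero(mask)
    table = {"chrom": first.chrom,
             "start": first.starts[retained],
             "end": first.ends[retained]}
    for k, vec in enumerate(score_vecs, start=1):
        table[f"score_{k}"] = vec[retained]
    table["consensus_score"] = consensus[retained]
    table["union_boundary"] = union[retained]
    table["consensus_boundary"] = cons_flag[retained]
    return pd.DataFrame(table)
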