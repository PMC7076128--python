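"""Synthetic Hi-C contact matrices with planted domain boundaries.

The generator emulates the salient features of real chromosome-specific
contact matrices: a symmetric non-negative count matrix, power-law decay
of contact frequency with genomic distance, block-diagonal domain
structure, optional Poisson count noise and controllable sparsity.  The
expected count between bins ``i`` and ``j`` is

    base * (|i - j| + 1)^(-alpha) * prod(beta_b for boundaries b between i and j)

where a boundary ``b`` (an interior bin index, the first bin of the
right-hand domain) separates ``i < j`` when ``i < b <= j``.  Each
crossed boundary attenuates contacts by its ``beta < 1``, so every
planted boundary produces a contrast visible to the spectral method.

Change scenarios (merge, split, shift, strength, complex) perturb the
boundary set of the *first* returned matrix while keeping the second as
the unchanged reference, so that ``compare(first, second)`` should label
the planted bin with the scenario's name.  Time-course schedules add or
remove boundaries at chosen time points with independent replicate
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .matrix_io import ContactMatrix
from . import differential as _diff
from . import timecourse as _tc

__all__ = ["SimulationSpec", "ChangeScenario", "simulate_matrix",
           "apply_change", "simulate_timecourse"]

#: Default between-domain attenuation for newly inserted boundaries.
_DEFAULT_BETA = 0.4


@dataclass
class SimulationSpec:
    """Planted-domain description of one synthetic contact matrix.

    Parameters
    ----------
    n_bins : int
        Matrix size.
    boundaries : tuple[int, ...]
        Ordered interior bin indices (strictly inside ``(0, n_bins)``)
        at which a new domain starts.
    betas : float or tuple[float, ...]
        Between-domain attenuation per boundary, each in ``(0, 1)``; a
        scalar is broadcast to every boundary.
    base : float
        Expected near-diagonal count (within-domain base intensity).
    alpha : float
        Power-law distance-decay exponent (> 0).
    noise : str
        ``"none"`` for deterministic expected counts or ``"poisson"``
        for Poisson-sampled counts.
    sparsity : float
        Fraction in ``[0, 1)`` of off-diagonal bin pairs zeroed out
        (symmetrically) after sampling.
    resolution : int
        Bin size in bp.
    seed : int
        Seed for all randomness (noise and sparsity dropout).
    """

    n_bins: int
    boundaries: tuple[int, ...] = ()
    betas: float | tuple[float, ...] = _DEFAULT_BETA
    base: float = 1000.0
    alpha: float = 1.0
    noise: str = "poisson"
    sparsity: float = 0.0
    resolution: int = 40_000
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        self.boundaries = tuple(int(b) for b in self.boundaries)
        if any(not 0 < b < self.n_bins for b in self.boundaries):
            raise ValueError("boundaries must lie strictly inside (0, n)")
        if len(set(self.boundaries)) != len(self.boundaries):
            raise ValueError("duplicate boundary positions")
        if tuple(sorted(self.boundaries)) != self.boundaries:
            raise ValueError("boundaries must be ordered")
        if np.isscalar(self.betas):
            self.betas = tuple([float(self.betas)] * len(self.boundaries))
        else:
            self.betas = tuple(float(b) for b in self.betas)
        if len(self.betas) != len(self.boundaries):
            raise ValueError("one beta per boundary required")
        if any(not 0 < b < 1 for b in self.betas):
            raise ValueError("betas must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise mode {self.noise!r}")


def expected_counts(spec: SimulationSpec) -> np.ndarray:
    """Deterministic expected count matrix for a spec (no noise)."""
    idx = np.arange(spec.n_bins)
    expected = spec.base * (np.abs(idx[:, None] - idx[None, :]) + 1.0
                            ) ** (-spec.alpha)
    for b, beta in zip(spec.boundaries, spec.betas):
        crossed = (idx[:, None] < b) != (idx[None, :] < b)
        expected = np.where(crossed, expected * beta, expected)
    return expected


def simulate_matrix(spec: SimulationSpec) -> ContactMatrix:
    """Sample a symmetric contact matrix from a simulation spec.

    All randomness (Poisson counts, sparsity dropout) flows through
    ``spec.seed``; a fixed seed yields a bit-identical matrix.
    """
    expected = expected_counts(spec)
    n = spec.n_bins
    rng = np.random.default_rng(spec.seed)
    if spec.noise == "poisson":
        upper = np.triu(rng.poisson(expected).astype(float))
        counts = upper + np.triu(upper, 1).T
    else:
        counts = expected.copy()
    if spec.sparsity > 0:
        iu, ju = np.triu_indices(n, k=1)
        n_pairs = iu.size
        n_drop = int(round(spec.sparsity * n_pairs))
        drop = rng.choice(n_pairs, size=n_drop, replace=False)
        counts[iu[drop], ju[drop]] = 0.0
        counts[ju[drop], iu[drop]] = 0.0
    starts = np.arange(n, dtype=np.int64) * spec.resolution
    return ContactMatrix(spec.chrom, spec.resolution, starts, counts)


@dataclass
class ChangeScenario:
    """A planted boundary change between a perturbed and a base matrix.

    ``change`` is one of ``merge``, ``split``, ``shift``, ``strength``
    or ``complex``.  ``target`` names the affected boundary (for
    ``split``: the position of the inserted boundary).  ``shift_k``
    moves the target by that many bins; ``gamma`` multiplies the target
    boundary's attenuation (``gamma < 1`` strengthens it); ``new_pair``
    gives the two replacement boundaries of a complex change.
    """

    spec: SimulationSpec
    change: str
    target: int
    shift_k: int = 2
    gamma: float = 0.25
    new_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.change not in ("merge", "split", "shift", "strength",
                               "complex"):
            raise ValueError(f"unknown change type {self.change!r}")


def _spec_with_boundaries(spec: SimulationSpec, pairs) -> SimulationSpec:
    pairs = sorted(pairs)
    return replace(spec,
                   boundaries=tuple(b for b, _ in pairs),
                   betas=tuple(w for _, w in pairs))


def apply_change(scenario: ChangeScenario,
                 seed_offset: int = 1,
                 ) -> tuple[ContactMatrix, ContactMatrix, np.ndarray]:
    """Realize a change scenario as a matrix pair plus per-bin truth.

    Returns ``(changed, reference, truth)`` where ``changed`` carries
    the perturbed boundary set, ``reference`` the base spec, and
    ``truth`` is a per-bin label array: the expected
    :func:`tadbound.differential.compare` category for
    ``compare(changed, reference)`` — the scenario's own label at the
    planted bin(s), NonDifferential at untouched boundaries, NonBoundary
    elsewhere.  The two matrices use independent noise seeds.
    """
    spec = scenario.spec
    base_pairs = list(zip(spec.boundaries, spec.betas))
    t = scenario.target
    n = spec.n_bins
    truth = np.full(n, _diff.NON_BOUNDARY, dtype=object)
    for b, _ in base_pairs:
        truth[b] = _diff.NON_DIFFERENTIAL

    if scenario.change == "merge":
        if t not in spec.boundaries:
            raise ValueError(f"no boundary at bin {t}")
        changed_pairs = [(b, w) for b, w in base_pairs if b != t]
        truth[t] = _diff.MERGE
    elif scenario.change == "split":
        if t in spec.boundaries:
            raise ValueError(f"boundary already present at bin {t}")
        changed_pairs = base_pairs + [(t, _DEFAULT_BETA)]
        truth[t] = _diff.SPLIT
    elif scenario.change == "shift":
        if t not in spec.boundaries:
            raise ValueError(f"no boundary at bin {t}")
        new_pos = t + scenario.shift_k
        others = [b for b in spec.boundaries if b != t]
        if (not 0 < new_pos < n) or new_pos in others:
            raise ValueError("shift collides with a flank or the matrix edge")
        changed_pairs = [(new_pos if b == t else b, w) for b, w in base_pairs]
        truth[t] = _diff.SHIFTED
        truth[new_pos] = _diff.SHIFTED
    elif scenario.change == "strength":
        if t not in spec.boundaries:
            raise ValueError(f"no boundary at bin {t}")
        new_beta = dict(base_pairs)[t] * scenario.gamma
        if not 0 < new_beta < 1:
            raise ValueError("gamma leaves attenuation outside (0, 1)")
        changed_pairs = [(b, new_beta if b == t else w)
                         for b, w in base_pairs]
        truth[t] = _diff.STRENGTH_CHANGE
    else:  # complex
        if t not in spec.boundaries:
            raise ValueError(f"no boundary at bin {t}")
        if scenario.new_pair is None:
            raise ValueError("complex change requires new_pair")
        b1, b2 = sorted(scenario.new_pair)
        others = [b for b in spec.boundaries if b != t]
        if abs(b2 - b1) <= 1:
            raise ValueError("complex replacement boundaries must be "
                             "non-adjacent")
        for nb in (b1, b2):
            if not 0 < nb < n or nb in others or nb == t:
                raise ValueError("invalid complex replacement boundary")
        changed_pairs = ([(b, w) for b, w in base_pairs if b != t]
                         + [(b1, _DEFAULT_BETA), (b2, _DEFAULT_BETA)])
        truth[t] = _diff.COMPLEX
        truth[b1] = _diff.COMPLEX
        truth[b2] = _diff.COMPLEX

    changed_spec = _spec_with_boundaries(spec, changed_pairs)
    changed_spec = replace(changed_spec, seed=spec.seed + seed_offset)
    return (simulate_matrix(changed_spec), simulate_matrix(spec), truth)


def simulate_timecourse(base: SimulationSpec,
                        events,
                        n_timepoints: int,
                        reps: int = 1,
                        ) -> tuple[list[list[ContactMatrix]], dict[int, str]]:
    """Simulate an ordered time course with scheduled boundary events.

    Parameters
    ----------
    base
        Spec describing time point 1 (its ``boundaries`` are the
        baseline set).
    events
        List of ``(time_index, action, bin)`` with 1-based
        ``time_index`` and ``action`` in ``{"add", "remove"}``: from
        that time point on, the boundary at ``bin`` is added to or
        removed from the active set.
    n_timepoints
        Number of time points (>= 3).
    reps
        Replicates per time point, each with independent noise.

    Returns
    -------
    (matrices, truth)
        ``matrices[t]`` is the list of replicate matrices at time point
        ``t``; ``truth`` maps each bin that is ever a boundary to its
        expected temporal pattern, derived from the scheduled presence
        vector.
    """
    if n_timepoints < 3:
        raise ValueError("need at least 3 time points")
    for when, action, b in events:
        if not 1 <= when <= n_timepoints:
            raise ValueError(f"event at invalid time point {when}")
        if action not in ("add", "remove"):
            raise ValueError(f"unknown event action {action!r}")
        if not 0 < b < base.n_bins:
            raise ValueError(f"event boundary {b} outside the matrix")

    beta_of = dict(zip(base.boundaries, base.betas))
    schedule: list[set[int]] = []
    active = set(base.boundaries)
    for t in range(1, n_timepoints + 1):
        for when, action, b in events:
            if when == t:
                if action == "add":
                    active.add(b)
                else:
                    active.discard(b)
        schedule.append(set(active))

    matrices: list[list[ContactMatrix]] = []
    for t, bset in enumerate(schedule):
        pairs = [(b, beta_of.get(b, _DEFAULT_BETA)) for b in sorted(bset)]
        spec_t = _spec_with_boundaries(base, pairs)
        reps_t = []
        for r in range(reps):
            reps_t.append(simulate_matrix(
                replace(spec_t, seed=base.seed + 10_000 * (t + 1) + r)))
        matrices.append(reps_t)

    ever = sorted(set().union(*schedule))
    truth = {}
    for b in ever:
        presence = [b in s for s in schedule]
        truth[b] = _tc.classify_temporal(presence)
    return matrices, truth
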