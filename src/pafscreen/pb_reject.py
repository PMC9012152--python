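"""Premature-beat rejection cascade for candidate AF segments.

A candidate segment flagged by the rhythm-change screen is accepted as AF
only after every premature-beat explanation has failed:

1. **Single-PB rule** — one premature beat (short coupling interval plus
   compensatory pause) perturbs exactly seven sliding 6-RR windows, so a
   flagged run of at most 10 beats is rejected as a single premature beat.
2. **K-Medoids clustering** — the segment's RR intervals are clustered into
   three groups on the features (RR, ΔRR/RR), then fine-tuned to reduce the
   within-group RR standard deviation.  Premature rhythms separate into
   short / normal / long interval groups; AF does not.
3. **Bigeminy/trigeminy rule** — if some 6-RR window holds equally many
   short-group and long-group intervals (both at least twice), the long
   group is re-screened: a quiet long group means geminal rhythm, not AF.
4. **Multi-PB rule** — otherwise the group whose mean RR is closest to the
   segment median (the normal beats) is re-screened; a quiet median group
   means frequent premature beats on a regular sinus background.

Rhythm re-screening ("recheck") recomputes Rc over the selected intervals,
concatenated in temporal order, and succeeds when every defined value stays
at or below the threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .rr import RRSequence
from .screening import RC_WINDOW, CandidateSegment, _std

__all__ = [
    "VerdictClass",
    "ClusterResult",
    "CandidateVerdict",
    "kmedoids",
    "exact_kmedoids",
    "pam_kmedoids",
    "single_pb_recheck",
    "cluster_rr",
    "select_median_group",
    "recheck_rc",
    "geminy_pattern_present",
    "geminy_recheck",
    "classify_candidate",
    "segment_rr_slice",
]


class VerdictClass(str, Enum):
    AF = "AF"
    SINGLE_PB = "SINGLE_PB"
    MULTI_PB = "MULTI_PB"
    GEMINY = "GEMINY"
    NON_AF_OTHER = "NON_AF_OTHER"


@dataclass
class ClusterResult:
    """Three-group partition of a segment's RR intervals.

    Groups are relabeled by ascending mean RR, so group 0 holds the shortest
    intervals and group 2 the longest.  ``within_std`` is the summed
    within-group population standard deviation of the RRs after fine-tuning;
    it never exceeds ``within_std_initial``.
    """

    assignment: np.ndarray
    medoids: np.ndarray
    group_means: np.ndarray
    degenerate: bool
    within_std_initial: float = 0.0
    within_std: float = 0.0

    @property
    def n_groups(self) -> int:
        return int(self.group_means.shape[0])


@dataclass
class CandidateVerdict:
    """Outcome of the cascade for one candidate segment, with its evidence."""

    klass: VerdictClass
    evidence: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# K-Medoids: exact enumeration at segment scale, PAM for long segments

#: Largest instance solved by exhaustive medoid enumeration.  The screening
#: segments this cascade works on hold about 30 RR intervals, where
#: enumerating all C(n, 3) medoid triples is cheap and guarantees the
#: optimal clustering; only long merged candidates fall back to PAM.
EXACT_KMEDOIDS_MAX_N = 30


def _distance_matrix(X: np.ndarray) -> np.ndarray:
    return np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)


def exact_kmedoids(X: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal k-medoids by enumeration of all medoid subsets.

    Ties go to the lexicographically smallest medoid set.  Cost is the
    summed Euclidean distance of every point to its nearest medoid.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    D = _distance_matrix(X)
    combos = np.array(list(itertools.combinations(range(n), k)))
    costs = D[:, combos].min(axis=2).sum(axis=0)
    best = combos[int(np.argmin(costs))]
    assignment = np.argmin(D[:, best], axis=1)
    return best, assignment, float(costs.min())


def kmedoids(X: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray, float]:
    """K-medoids partition: exact for instances up to
    :data:`EXACT_KMEDOIDS_MAX_N` points, deterministic PAM beyond."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= EXACT_KMEDOIDS_MAX_N:
        return exact_kmedoids(X, k)
    return pam_kmedoids(X, k)


def pam_kmedoids(X: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray, float]:
    """Partition-around-medoids with deterministic initialization.

    BUILD greedily adds the medoid giving the largest cost decrease (ties go
    to the lowest index); SWAP applies the best strictly improving
    medoid/non-medoid exchange until none remains.  Cost is the summed
    Euclidean distance of every point to its nearest medoid.

    Returns ``(medoid_indices, assignment, cost)``; ``assignment[i]`` is the
    position of point *i*'s medoid in ``medoid_indices``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    D = _distance_matrix(X)

    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        best_j, best_gain = -1, -np.inf
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(nearest - D[:, j], 0.0).sum()
            if gain > best_gain:
                best_j, best_gain = j, gain
        medoids.append(best_j)

    def cost_of(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    cost = cost_of(medoids)
    improved = True
    while improved:
        improved = False
        best = (cost, None)
        for mi, m in enumerate(medoids):
            for j in range(n):
                if j in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = j
                c = cost_of(cand)
                if c < best[0] - 1e-12:
                    best = (c, (mi, j))
        if best[1] is not None:
            mi, j = best[1]
            medoids[mi] = j
            cost = best[0]
            improved = True

    medoid_arr = np.array(medoids)
    assignment = np.argmin(D[:, medoid_arr], axis=1)
    return medoid_arr, assignment, cost


def _features(rr: np.ndarray) -> np.ndarray:
    """Clustering features: each RR and its first-order difference ratio ΔRR/RR.

    The features are used unscaled.  In AF the difference ratio varies more
    than the interval itself, so the partition follows the beat-to-beat
    jumps and the three groups keep nearly equal mean RRs with no clear
    boundaries; in premature rhythms the intervals fall into well-separated
    short/normal/long values and dominate the partition instead.  That
    asymmetry is what the downstream rechecks rely on.
    """
    drr = np.diff(rr, prepend=rr[0])  # Δ of the first interval is 0
    return np.column_stack([rr, drr / rr])


def _within_group_std(rr: np.ndarray, assignment: np.ndarray, n_groups: int) -> float:
    total = 0.0
    for g in range(n_groups):
        members = rr[assignment == g]
        if members.size:
            total += float(np.std(members))
    return total


def _relabel_by_mean(rr: np.ndarray, assignment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    groups = np.unique(assignment)
    means = np.array([rr[assignment == g].mean() for g in groups])
    order = np.argsort(means, kind="stable")
    remap = {int(groups[o]): rank for rank, o in enumerate(order)}
    new_assignment = np.array([remap[int(g)] for g in assignment])
    return new_assignment, means[order]


#: Fine-tuning only runs when adjacent group mean RRs are separated by more
#: than this factor times the largest within-group RR standard deviation.
FINE_TUNE_SEPARATION = 2.0


def _groups_separated(rr: np.ndarray, assignment: np.ndarray, n_groups: int) -> bool:
    """Are the groups' RR bands separated?  Robust statistics (medians and
    scaled MAD) so that a single misassigned straggler does not mask an
    otherwise clean band structure."""
    centers, spreads = [], []
    for g in range(n_groups):
        members = rr[assignment == g]
        if members.size == 0:
            return False
        med = float(np.median(members))
        centers.append(med)
        spreads.append(1.4826 * float(np.median(np.abs(members - med))))
    centers = np.sort(centers)
    gap = float(np.min(np.diff(centers))) if n_groups > 1 else 0.0
    return gap > FINE_TUNE_SEPARATION * max(max(spreads), 1e-12)


def _fine_tune(rr: np.ndarray, assignment: np.ndarray, n_groups: int) -> np.ndarray:
    """Greedy single-point reassignment, strictly reducing the summed
    within-group RR standard deviation; never empties a group.

    Runs only when the groups are separated in RR (adjacent mean gaps larger
    than :data:`FINE_TUNE_SEPARATION` times the widest group): premature
    rhythms produce separated short/normal/long bands whose stragglers are
    worth reassigning, whereas AF produces overlapping groups with no clear
    boundaries, where chasing a lower within-group deviation would just sort
    the intervals into artificial bands and erase the variability the
    rechecks need to see.
    """
    if not _groups_separated(rr, assignment, n_groups):
        return assignment
    assignment = assignment.copy()
    current = _within_group_std(rr, assignment, n_groups)
    moved = True
    while moved:
        moved = False
        for i in range(rr.shape[0]):
            src = assignment[i]
            if np.count_nonzero(assignment == src) <= 1:
                continue
            for dst in range(n_groups):
                if dst == src:
                    continue
                assignment[i] = dst
                trial = _within_group_std(rr, assignment, n_groups)
                if trial < current - 1e-12:
                    current = trial
                    src = dst
                    moved = True
                else:
                    assignment[i] = src
    return assignment


def cluster_rr(rr_values, seed: int = 0) -> ClusterResult:
    """Cluster a segment's RR intervals into three groups and fine-tune.

    K-Medoids (k=3, Euclidean) runs on (RR, ΔRR/RR) features with a
    deterministic build/swap scheme (``seed`` is accepted for interface
    stability; the algorithm breaks ties by index).  When the resulting
    groups are separated in RR, fine-tuning moves single intervals between
    groups while that strictly reduces the summed within-group RR standard
    deviation.  Fewer than three distinct feature points make the result
    degenerate: points group by their value.
    """
    rr = np.asarray(rr_values, dtype=float)
    if rr.shape[0] < RC_WINDOW:
        raise ValueError(f"need at least {RC_WINDOW} RR intervals, got {rr.shape[0]}")
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be strictly positive")
    X = _features(rr)
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    if uniq.shape[0] < 3:
        assignment, means = _relabel_by_mean(rr, inverse)
        w = _within_group_std(rr, assignment, uniq.shape[0])
        return ClusterResult(
            assignment=assignment,
            medoids=uniq,
            group_means=means,
            degenerate=True,
            within_std_initial=w,
            within_std=w,
        )
    medoid_idx, assignment, _ = kmedoids(X, k=3)
    w0 = _within_group_std(rr, assignment, 3)
    assignment = _fine_tune(rr, assignment, 3)
    w1 = _within_group_std(rr, assignment, 3)
    assignment, means = _relabel_by_mean(rr, assignment)
    return ClusterResult(
        assignment=assignment,
        medoids=X[medoid_idx],
        group_means=means,
        degenerate=False,
        within_std_initial=w0,
        within_std=w1,
    )


# --------------------------------------------------------------------------
# Cascade rules


def single_pb_recheck(seg: CandidateSegment, max_run: int = 10) -> bool:
    """True (reject as single premature beat) iff the segment's longest
    flagged run does not exceed ``max_run`` beats."""
    return seg.rc_run_length <= max_run


def select_median_group(clusters: ClusterResult, rr_values) -> int:
    """Group whose mean RR is closest to the median of the whole segment.

    Ties go to the larger group, then the lower group id.  With frequent
    premature beats the normal intervals still dominate, so this selects the
    sinus-background group.
    """
    rr = np.asarray(rr_values, dtype=float)
    med = float(np.median(rr))
    sizes = np.array(
        [np.count_nonzero(clusters.assignment == g) for g in range(clusters.n_groups)]
    )
    dist = np.abs(clusters.group_means - med)
    best = np.flatnonzero(np.isclose(dist, dist.min()))
    if best.size > 1:
        best = best[sizes[best] == sizes[best].max()]
    return int(best[0])


def recheck_rc(selected_rr, threshold: float, std_mode: str = "population") -> bool:
    """Re-screen a selected RR subsequence; True iff every Rc stays at or
    below the threshold.

    The subsequence is taken in original temporal order and re-screened with
    6-RR windows.  Fewer than six intervals cannot form a window and count as
    below threshold: a tiny near-uniform group signals premature-beat
    structure rather than AF.
    """
    rr = np.asarray(selected_rr, dtype=float)
    if rr.shape[0] < RC_WINDOW:
        return True
    wins = np.lib.stride_tricks.sliding_window_view(rr, RC_WINDOW)
    rc = _std(wins, std_mode, axis=1) / np.mean(wins, axis=1)
    return bool(np.all(rc <= threshold))


def geminy_pattern_present(
    clusters: ClusterResult, min_count: int = 2
) -> bool:
    """Bigeminy/trigeminy signature over the whole segment.

    True iff *every* 6-consecutive-RR window holds equally many long-group
    and short-group intervals, both at least ``min_count`` times.  Bigeminy
    puts three shorts and three longs in every window, trigeminy two of
    each; AF satisfies the balance in some windows by chance but essentially
    never in all of them.
    """
    a = clusters.assignment
    if a.shape[0] < RC_WINDOW or clusters.n_groups < 2:
        return False
    long_id = clusters.n_groups - 1
    is_short = (a == 0).astype(int)
    is_long = (a == long_id).astype(int)
    ks = np.lib.stride_tricks.sliding_window_view(is_short, RC_WINDOW).sum(axis=1)
    kl = np.lib.stride_tricks.sliding_window_view(is_long, RC_WINDOW).sum(axis=1)
    return bool(np.all((ks == kl) & (ks >= min_count)))


def geminy_recheck(
    rr_values, clusters: ClusterResult, threshold: float, std_mode: str = "population"
) -> bool:
    """Re-screen the long-interval group; True rejects the candidate as
    bigeminy/trigeminy (the compensatory pauses are nearly uniform)."""
    rr = np.asarray(rr_values, dtype=float)
    long_id = clusters.n_groups - 1
    return recheck_rc(rr[clusters.assignment == long_id], threshold, std_mode)


def segment_rr_slice(seg: CandidateSegment, rr: RRSequence) -> np.ndarray:
    """RR intervals covered by a candidate's flagged Rc windows.

    The window anchored at beat *i* spans intervals ``i .. i+5``, so a
    candidate ``[start, end)`` covers intervals ``start .. end+4``.
    """
    return rr.rr[seg.start_beat : min(seg.end_beat + RC_WINDOW - 1, rr.n_rr)]


def classify_candidate(
    seg: CandidateSegment,
    rr: RRSequence,
    threshold: float,
    seed: int = 0,
    single_pb_max_run: int = 10,
    geminy_min_count: int = 2,
    reject_order: tuple[str, ...] = ("geminy", "multi"),
    std_mode: str = "population",
) -> CandidateVerdict:
    """Run the full cascade on one candidate segment.

    AF is returned only when every rejection test has failed to fire.
    """
    evidence: dict = {"run_length": seg.rc_run_length}
    if single_pb_recheck(seg, single_pb_max_run):
        return CandidateVerdict(VerdictClass.SINGLE_PB, evidence)

    seg_rr = segment_rr_slice(seg, rr)
    evidence["n_rr"] = int(seg_rr.shape[0])
    if seg_rr.shape[0] < RC_WINDOW:
        # Too short to cluster or re-screen; cannot be confirmed as AF.
        return CandidateVerdict(VerdictClass.NON_AF_OTHER, evidence)

    clusters = cluster_rr(seg_rr, seed=seed)
    evidence["group_means"] = clusters.group_means.tolist()
    evidence["degenerate"] = clusters.degenerate

    for rule in reject_order:
        if rule == "geminy":
            pattern = geminy_pattern_present(clusters, geminy_min_count)
            evidence["geminy_pattern"] = pattern
            if pattern and geminy_recheck(seg_rr, clusters, threshold, std_mode):
                return CandidateVerdict(VerdictClass.GEMINY, evidence)
        elif rule == "multi":
            g = select_median_group(clusters, seg_rr)
            evidence["median_group"] = g
            if recheck_rc(seg_rr[clusters.assignment == g], threshold, std_mode):
                return CandidateVerdict(VerdictClass.MULTI_PB, evidence)
        else:
            raise ValueError(f"unknown reject rule {rule!r}")
    return CandidateVerdict(VerdictClass.AF, evidence)
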