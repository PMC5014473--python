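"""Alignment-wide breakpoint-pattern statistics.

Hot/cold-spot scans, the breakpoint pair matrix, the site-pair
co-inheritance (region count) matrix and the genome-feature association
test all share the same null model: breakpoints are re-placed uniformly
at random over their permissible positions (the whole alignment, or a
detectability mask when one is supplied).  All permutation p-values use
the (k+1)/(N+1) estimator and are reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .events import RecombinationEvent

__all__ = [
    "BreakpointSet",
    "HotspotScan",
    "breakpoint_density",
    "hotspot_test",
    "breakpoint_pair_matrix",
    "region_count_matrix",
    "feature_association_test",
]


@dataclass
class BreakpointSet:
    """Flat list of breakpoints: (event id, sequence, position, kind).

    Positions are 1-based; ``mask``, when given, is a boolean per-column
    detectability mask (0-based) restricting the permutation null.
    """

    records: list[tuple[int, str, int, str]]
    length: int
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for eid, seq, pos, kind in self.records:
            if not 1 <= pos <= self.length:
                raise ValueError(f"breakpoint {pos} outside [1, {self.length}]")
            if kind not in ("begin", "end"):
                raise ValueError(f"unknown breakpoint kind {kind!r}")

    @classmethod
    def from_events(cls, events: list[RecombinationEvent], length: int,
                    mask: np.ndarray | None = None) -> "BreakpointSet":
        records = []
        for ev in events:
            records.append((ev.event_id, ev.recombinants[0] if ev.recombinants else "?",
                            ev.begin, "begin"))
            records.append((ev.event_id, ev.recombinants[0] if ev.recombinants else "?",
                            ev.end, "end"))
        return cls(records, length, mask)

    @property
    def positions0(self) -> np.ndarray:
        return np.array([pos - 1 for _, _, pos, _ in self.records], dtype=np.int64)

    def _permissible(self) -> np.ndarray:
        if self.mask is None:
            return np.arange(self.length)
        return np.flatnonzero(self.mask)


@dataclass
class HotspotScan:
    window_starts: np.ndarray          # 0-based
    window_len: int
    observed: np.ndarray
    perm_mean: np.ndarray
    local_lo: np.ndarray
    local_hi: np.ndarray
    global_lo: float
    global_hi: float
    hot: list[tuple[int, int]] = field(default_factory=list)    # 1-based inclusive
    cold: list[tuple[int, int]] = field(default_factory=list)


def breakpoint_density(bps: BreakpointSet, window_len: int, step: int = 1):
    """Sliding-window breakpoint counts; returns (window starts 0-based,
    counts)."""
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    starts = np.arange(0, max(bps.length - window_len, 0) + 1, step)
    pos = np.sort(bps.positions0)
    hi = np.searchsorted(pos, starts + window_len, side="left")
    lo = np.searchsorted(pos, starts, side="left")
    return starts, (hi - lo).astype(np.int64)


def hotspot_test(bps: BreakpointSet, window_len: int,
                 n_permutations: int = 1000, seed: int = 0) -> HotspotScan:
    """Hot/cold-spot test on non-overlapping windows.

    The null re-places every breakpoint uniformly over its permissible
    positions.  The local envelope is the per-window 2.5/97.5 percentile
    band; the global envelope is the 95th percentile of the per-
    permutation maximum count (and the 5th percentile of the minimum),
    which controls the family-wise false-call rate at ~5%.
    """
    if n_permutations < 1000:
        raise ValueError("n_permutations must be >= 1000")
    rng = np.random.default_rng(seed)
    n_win = bps.length // window_len
    if n_win < 1:
        raise ValueError("window longer than alignment")
    starts = np.arange(n_win) * window_len
    pos = bps.positions0
    nbp = pos.size

    def window_counts(p: np.ndarray) -> np.ndarray:
        idx = p // window_len
        keep = idx < n_win
        return np.bincount(idx[keep], minlength=n_win)

    observed = window_counts(pos)
    if nbp == 0:
        zeros = np.zeros(n_win)
        return HotspotScan(starts, window_len, observed, zeros, zeros, zeros,
                           0.0, 0.0, [], [])
    permissible = bps._permissible()
    perm_counts = np.empty((n_permutations, n_win), dtype=np.int64)
    for i in range(n_permutations):
        p = permissible[rng.integers(0, permissible.size, nbp)]
        perm_counts[i] = window_counts(p)
    local_lo = np.percentile(perm_counts, 2.5, axis=0)
    local_hi = np.percentile(perm_counts, 97.5, axis=0)
    global_hi = float(np.percentile(perm_counts.max(axis=1), 95))
    global_lo = float(np.percentile(perm_counts.min(axis=1), 5))
    hot = [(int(s) + 1, int(s) + window_len)
           for s, o in zip(starts, observed) if o > global_hi]
    cold = [(int(s) + 1, int(s) + window_len)
            for s, o in zip(starts, observed) if o < global_lo]
    return HotspotScan(starts, window_len, observed, perm_counts.mean(axis=0),
                       local_lo, local_hi, global_lo, global_hi, hot, cold)


def breakpoint_pair_matrix(events: list[RecombinationEvent], length: int,
                           n_bins: int = 20, n_permutations: int = 1000,
                           seed: int = 0) -> dict:
    """Binned 2-D histogram of (begin, end) breakpoint pairs with a
    per-cell permutation flag.

    The null draws begin and end independently uniform (order enforced
    by sorting); cells whose observed count exceeds the cell's 97.5
    permutation percentile are flagged — the "breakpoint hotspot pair"
    readout.
    """
    rng = np.random.default_rng(seed)
    pairs = np.array([[ev.begin, ev.end] for ev in events], dtype=np.int64)
    edges = np.linspace(0.5, length + 0.5, n_bins + 1)
    if pairs.size == 0:
        z = np.zeros((n_bins, n_bins))
        return {"counts": z, "flags": z.astype(bool), "edges": edges,
                "upper": z}
    obs, _, _ = np.histogram2d(pairs[:, 0], pairs[:, 1], bins=[edges, edges])
    n_ev = pairs.shape[0]
    draws = rng.integers(1, length + 1, size=(n_permutations, n_ev, 2))
    draws.sort(axis=2)
    bi = np.clip(np.searchsorted(edges, draws[:, :, 0], side="right") - 1, 0, n_bins - 1)
    bj = np.clip(np.searchsorted(edges, draws[:, :, 1], side="right") - 1, 0, n_bins - 1)
    flat = bi * n_bins + bj + (np.arange(n_permutations)[:, None] * n_bins * n_bins)
    counts = np.bincount(flat.ravel(), minlength=n_permutations * n_bins * n_bins)
    counts = counts.reshape(n_permutations, n_bins, n_bins)
    upper = np.percentile(counts, 97.5, axis=0)
    return {"counts": obs, "flags": obs > upper, "edges": edges, "upper": upper}


def _segment_ids(cuts: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(cuts, grid, side="right")


def region_count_matrix(aln: Alignment, events: list[RecombinationEvent],
                        n_permutations: int = 500, seed: int = 0,
                        grid_points: int = 100) -> dict:
    """Site-pair co-inheritance counts on a coarse grid.

    ``counts[i, j]`` is the number of sequences in which grid sites i and
    j descend from the same parental fragment (no breakpoint between
    them).  The permutation null re-places each sequence's breakpoints
    uniformly (preserving their number); ``q_high`` / ``q_low`` give the
    per-pair (k+1)/(N+1) probabilities of a null count at least / at
    most as large as observed (the two-sided readout).
    """
    rng = np.random.default_rng(seed)
    L = aln.length
    grid = np.unique(np.linspace(0, L - 1, grid_points).astype(np.int64))
    cuts_by_seq: dict[str, list[int]] = {nm: [] for nm in aln.names}
    for ev in events:
        b0, e0 = ev.region0
        for rec in ev.recombinants:
            if rec in cuts_by_seq:
                cuts_by_seq[rec].extend([b0, e0])
    G = grid.size

    def matrix(cutmap: dict[str, np.ndarray]) -> np.ndarray:
        M = np.zeros((G, G), dtype=np.int64)
        for nm in aln.names:
            seg = _segment_ids(cutmap[nm], grid)
            M += seg[:, None] == seg[None, :]
        return M

    obs_cuts = {nm: np.sort(np.array(v, dtype=np.int64)) for nm, v in cuts_by_seq.items()}
    observed = matrix(obs_cuts)
    ge = np.zeros((G, G), dtype=np.int64)
    le = np.zeros((G, G), dtype=np.int64)
    for _ in range(n_permutations):
        perm_cuts = {
            nm: np.sort(rng.integers(1, L, size=len(v)))
            for nm, v in cuts_by_seq.items()
        }
        M = matrix(perm_cuts)
        ge += M >= observed
        le += M <= observed
    q_high = (ge + 1) / (n_permutations + 1)
    q_low = (le + 1) / (n_permutations + 1)
    return {"grid": grid, "counts": observed, "q_high": q_high, "q_low": q_low}


def feature_association_test(bps: BreakpointSet,
                             features: list[tuple[int, int]],
                             n_permutations: int = 1000, seed: int = 0) -> dict:
    """Association between breakpoints and genome-feature boundaries.

    The statistic is the mean distance from each breakpoint to the
    nearest feature boundary; ``p_association`` is the fraction of
    uniform re-placements at most as close, ``p_avoidance`` the fraction
    at least as far (both (k+1)/(N+1) smoothed).
    """
    if not features:
        raise ValueError("feature list is empty")
    rng = np.random.default_rng(seed)
    bounds = []
    for s, e in features:
        if not 0 <= s < e <= bps.length:
            raise ValueError(f"feature [{s}, {e}) outside alignment")
        bounds.extend([s, e - 1])
    bounds = np.unique(np.array(bounds, dtype=np.int64))

    def mean_dist(p: np.ndarray) -> float:
        idx = np.searchsorted(bounds, p)
        left = np.abs(p - bounds[np.clip(idx - 1, 0, bounds.size - 1)])
        right = np.abs(bounds[np.clip(idx, 0, bounds.size - 1)] - p)
        return float(np.minimum(left, right).mean())

    pos = bps.positions0
    if pos.size == 0:
        raise ValueError("no breakpoints")
    observed = mean_dist(pos)
    permissible = bps._permissible()
    k_le = k_ge = 0
    for _ in range(n_permutations):
        p = permissible[rng.integers(0, permissible.size, pos.size)]
        d = mean_dist(p)
        k_le += d <= observed
        k_ge += d >= observed
    return {
        "observed": observed,
        "p_association": (k_le + 1) / (n_permutations + 1),
        "p_avoidance": (k_ge + 1) / (n_permutations + 1),
        "n_permutations": n_permutations,
    }
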