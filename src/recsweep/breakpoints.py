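"""HMM breakpoint placement and credible intervals.

The recombinant's informative-site vector is modelled with a two-state
hidden Markov chain: the hidden state is the parent currently being
tracked, the emission is the observed A/B symbol (mismatch probability
``emission_error``), and parent switches occur with probability
``switch_prob`` per site boundary.  The Viterbi path, compressed to
segments, gives point breakpoints; a single-switch enumeration gives a
normalized posterior over boundary positions, from which the 95% HPD
credible interval is read off.

Breakpoints live at boundaries *between* informative sites — the data
cannot localize them more finely.  A boundary ``k`` separates vector
sites ``k-1`` and ``k``; its reported alignment coordinate is the
midpoint of the two flanking informative columns (rounded down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Segment",
    "BreakpointPosterior",
    "viterbi_segments",
    "breakpoint_posterior",
    "estimate_emission_error",
    "fit_segments",
]


@dataclass
class Segment:
    start: int   # vector coordinates, half-open
    end: int
    state: int   # 0 = parent A, 1 = parent B


@dataclass
class BreakpointPosterior:
    """Posterior over single-switch boundary positions.

    ``boundaries[k]`` is the boundary before vector site ``positions`` —
    candidates run 1..n-1.  ``mass`` sums to 1; ``mode`` is the maximum-
    mass boundary (leftmost on ties); ``hpd`` is the smallest contiguous
    boundary interval (inclusive) containing the mode with >= *level*
    total mass.
    """

    boundaries: np.ndarray
    mass: np.ndarray
    mode: int
    hpd: tuple[int, int]
    level: float = 0.95


def _as_binary(vector) -> np.ndarray:
    v = np.asarray(vector)
    if v.dtype.kind in "UBS":  # string-ish input, e.g. "AABB"
        v = np.frombuffer("".join(np.atleast_1d(v)).encode(), dtype=np.uint8)
        v = (v == ord("B")).astype(np.int8)
    return v.astype(np.int8)


def viterbi_segments(informative_vector, switch_prob: float = 0.01,
                     emission_error: float = 0.05) -> list[Segment]:
    """Most probable parent-tracking path, compressed to segments.

    Ties are resolved toward state 0 and toward staying in the current
    state.  Breakpoints are the boundaries between returned segments.
    """
    if not 0 < switch_prob < 0.5:
        raise ValueError("switch_prob must be in (0, 0.5)")
    if not 0 <= emission_error < 0.5:
        raise ValueError("emission_error must be in [0, 0.5)")
    v = _as_binary(informative_vector)
    n = v.size
    if n == 0:
        raise ValueError("empty informative vector")
    eps = max(emission_error, 1e-12)
    log_e = np.log([[1 - eps, eps], [eps, 1 - eps]])  # [state][symbol]
    log_stay = np.log(1 - switch_prob)
    log_switch = np.log(switch_prob)
    delta = np.array([log_e[0, v[0]], log_e[1, v[0]]]) + np.log(0.5)
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        new = np.empty(2)
        for s in (0, 1):
            stay = delta[s] + log_stay
            move = delta[1 - s] + log_switch
            if stay >= move:           # ties prefer staying
                new[s] = stay + log_e[s, v[t]]
                back[t, s] = s
            else:
                new[s] = move + log_e[s, v[t]]
                back[t, s] = 1 - s
        delta = new
    state = 0 if delta[0] >= delta[1] else 1   # ties prefer state 0
    path = np.empty(n, dtype=np.int8)
    path[-1] = state
    for t in range(n - 1, 0, -1):
        state = back[t, state]
        path[t - 1] = state
    segments = []
    start = 0
    for t in range(1, n):
        if path[t] != path[t - 1]:
            segments.append(Segment(start, t, int(path[t - 1])))
            start = t
    segments.append(Segment(start, n, int(path[-1])))
    return segments


def estimate_emission_error(informative_vector, segments: list[Segment]) -> float:
    """Add-one-smoothed fraction of sites disagreeing with their segment's
    state: ``(mismatches + 1) / (n + 2)``, clamped below 0.5."""
    v = _as_binary(informative_vector)
    mism = sum(
        int(np.count_nonzero(v[seg.start:seg.end] != seg.state)) for seg in segments
    )
    return min((mism + 1) / (v.size + 2), 0.4999)


def fit_segments(informative_vector, switch_prob: float = 0.01,
                 emission_error: float = 0.05) -> tuple[list[Segment], float]:
    """Two-pass fit: Viterbi at the default error rate, re-estimate the
    emission error from the segmentation, refit once."""
    segs = viterbi_segments(informative_vector, switch_prob, emission_error)
    err = estimate_emission_error(informative_vector, segs)
    segs = viterbi_segments(informative_vector, switch_prob, err)
    return segs, err


def breakpoint_posterior(informative_vector, emission_error: float = 0.05,
                         level: float = 0.95) -> BreakpointPosterior:
    """Posterior over the boundary position of a single parent switch.

    For each boundary ``k`` in 1..n-1 the likelihood is the product of
    left-site emissions under one state and right-site emissions under
    the other; the better of the two orientations is kept, the prior is
    uniform over boundaries, and the posterior is normalized in log
    space.  The HPD is the shortest contiguous boundary run containing
    the mode whose mass reaches *level*.
    """
    v = _as_binary(informative_vector)
    n = v.size
    if n < 2:
        raise ValueError("need a vector of length >= 2")
    eps = min(max(emission_error, 1e-9), 0.4999)
    # per-site log emission if the site is in state 0 (A) vs state 1 (B)
    l0 = np.where(v == 0, np.log(1 - eps), np.log(eps))
    l1 = np.where(v == 1, np.log(1 - eps), np.log(eps))
    c0 = np.concatenate([[0.0], np.cumsum(l0)])
    c1 = np.concatenate([[0.0], np.cumsum(l1)])
    ks = np.arange(1, n)
    # orientation A->B: left under state0, right under state1 (and swap)
    ab = c0[ks] + (c1[n] - c1[ks])
    ba = c1[ks] + (c0[n] - c0[ks])
    loglik = np.maximum(ab, ba)
    loglik -= loglik.max()
    mass = np.exp(loglik)
    mass /= mass.sum()
    mode_i = int(np.argmax(mass))
    # shortest contiguous interval containing the mode with >= level mass
    best = None
    cmass = np.concatenate([[0.0], np.cumsum(mass)])
    m = mass.size
    for lo in range(0, mode_i + 1):
        hi = int(np.searchsorted(cmass, cmass[lo] + level - 1e-12, side="left"))
        hi = max(hi, mode_i + 1)
        if hi > m:
            continue
        if best is None or (hi - lo) < (best[1] - best[0]):
            best = (lo, hi)
    if best is None:
        best = (0, m)
    return BreakpointPosterior(
        boundaries=ks, mass=mass, mode=int(ks[mode_i]),
        hpd=(int(ks[best[0]]), int(ks[best[1] - 1])), level=level,
    )


def boundary_to_alignment(k: int, positions: np.ndarray,
                          colmap=None) -> int:
    """Alignment coordinate of vector boundary *k*: the midpoint of the
    flanking informative columns, rounded down.  Boundary 0 / n map to
    the flanking site itself."""
    n = positions.size
    if k <= 0:
        view = int(positions[0])
    elif k >= n:
        view = int(positions[-1])
    else:
        left = int(positions[k - 1])
        right = int(positions[k])
        if colmap is not None:
            return (int(colmap.to_original(left)) + int(colmap.to_original(right))) // 2
        return (left + right) // 2
    return int(colmap.to_original(view)) if colmap is not None else view
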