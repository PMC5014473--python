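"""Per-triplet recombination signal statistics.

A *triplet* is three alignment rows tested under the hypothesis that one
is a recombinant and the other two are its parents.  Each scanner here
returns a :class:`SignalCandidate` (or ``None`` when the triplet carries
no signal): a region, a peak statistic, a raw p-value, and an inferred
recombinant.  The battery comprises

* ``rdp_scan``     — pairwise-identity rank changes along sliding windows,
  binomial tail probability on the anomalous region;
* ``maxchi_scan``  — maximum 2x2 chi-square of match/mismatch counts on
  either side of a moving breakpoint (no continuity correction);
* ``chimaera_scan``— the same chi-square machinery on the candidate
  recombinant's {A,B} informative-site vector;
* ``siscan_scan``  — sister-scanning z-scores against within-column
  residue permutations;
* ``bootscan_scan``— bootstrap NJ quartet support profiles with an
  outgroup, binomial follow-up on the switched region;
* ``threeseq_scan``— maximum-descent random walk over informative sites.

Coordinates inside this module are positions in the triplet's
gap-stripped view; every candidate also carries the mapped original-
coordinate region.  Tie-breaks are leftmost throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from math import exp

import numpy as np
from scipy.stats import binom, norm

from .alignment import Alignment, ColumnMap, strip_shared_gaps

__all__ = [
    "Triplet",
    "SignalCandidate",
    "binomial_identity_p",
    "rdp_scan",
    "maxchi_scan",
    "chimaera_scan",
    "siscan_scan",
    "bootscan_scan",
    "threeseq_scan",
    "identify_recombinant",
]

_PAIRS = ((0, 1), (0, 2), (1, 2))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


class Triplet:
    """Three alignment rows with their shared gap-stripped view."""

    def __init__(self, aln: Alignment, a: int, b: int, c: int):
        if len({a, b, c}) != 3:
            raise ValueError("triplet indices must be distinct")
        self.aln = aln
        self.indices = (a, b, c)
        self.view, self.colmap = strip_shared_gaps(aln, [a, b, c])
        self.codes = self.view.codes

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @cached_property
    def variable_sites(self) -> np.ndarray:
        """View columns with >= 2 distinct residues among the three rows."""
        c = self.codes
        return np.flatnonzero((c[0] != c[1]) | (c[0] != c[2]))

    def informative(self, r: int) -> tuple[np.ndarray, np.ndarray]:
        """Informative sites for candidate recombinant *r* (0, 1 or 2).

        Returns (view positions, symbols) where symbol ``True`` means the
        candidate matches the lower-indexed parent ("A") and ``False``
        the higher-indexed one ("B").
        """
        p, q = sorted({0, 1, 2} - {r})
        c = self.codes
        mask = (c[p] != c[q]) & ((c[r] == c[p]) | (c[r] == c[q]))
        pos = np.flatnonzero(mask)
        sym = c[r, pos] == c[p, pos]
        return pos, sym

    def pair_identity(self, i: int, j: int, view_region: tuple[int, int] | None = None) -> float:
        s, e = view_region if view_region else (0, self.length)
        if e <= s:
            raise ValueError("empty region")
        return float(np.mean(self.codes[i, s:e] == self.codes[j, s:e]))


@dataclass
class SignalCandidate:
    """One method's evidence for recombination on one triplet."""

    method: str
    triplet: tuple[int, int, int]       # row indices in the parent alignment
    recombinant: int | None             # row index in the parent alignment
    region: tuple[int, int]             # original coordinates, half-open
    region_view: tuple[int, int]        # view coordinates, half-open
    stat: float
    p_raw: float
    breakpoints: list[int] = field(default_factory=list)  # original coords
    ambiguous: bool = False
    n_perm: int | None = None       # permutations behind p_raw, if any
    p_corrected: float | None = None
    donor: int | None = None            # row index of the inferred minor parent
    profile: dict | None = None


# ---------------------------------------------------------------------------
# primitives


def binomial_identity_p(l: int, m: int, p: float) -> float:
    """Probability of >= *m* identities in *l* comparable columns when the
    background per-column identity is *p* (exact binomial upper tail,
    evaluated in log space)."""
    if not 0 < p < 1:
        raise ValueError(f"background identity p={p} outside (0, 1)")
    if not 0 <= m <= l:
        raise ValueError(f"need 0 <= m <= l, got m={m}, l={l}")
    if m == 0:
        return 1.0
    return float(exp(binom.logsf(m - 1, l, p)))


def _longest_true_run(flags: np.ndarray, labels: np.ndarray | None = None):
    """Longest run of True in *flags* (labels, when given, must be constant
    within a run); leftmost on ties.  Returns (start, stop) window-index
    interval, half-open, or None."""
    best = None
    i = 0
    n = flags.size
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i + 1
        while j < n and flags[j] and (labels is None or labels[j] == labels[i]):
            j += 1
        if best is None or (j - i) > (best[1] - best[0]):
            best = (i, j)
        i = j
    return best


def _permutation_pvalue(batch_exceed, n_total, rng, k_stop=10):
    """(k+1)/(N+1) permutation p-value with early stopping once *k_stop*
    exceedances have accumulated (the estimate is then already coarse-
    grained well above any decision threshold).  Batches escalate
    geometrically so clearly-null inputs cost ~32 draws while genuine
    signals run the full budget.  *batch_exceed(b, rng)* returns how many
    of *b* permuted statistics reach the observed one."""
    k = 0
    n = 0
    batch_size = 32
    while n < n_total:
        b = min(batch_size, n_total - n)
        k += int(batch_exceed(b, rng))
        n += b
        if k >= k_stop:
            break
        batch_size = min(batch_size * 2, 1024)
    return (k + 1) / (n + 1), n


# ---------------------------------------------------------------------------
# RDP statistic


def rdp_scan(triplet: Triplet, window_len: int = 30, step: int = 1) -> SignalCandidate | None:
    """Sliding-window pairwise-identity scan (the classic RDP statistic).

    Windows are flagged where the locally most-similar pair differs from
    the globally most-similar pair; the longest run of windows flagged
    for one pair defines the candidate region, and its probability is
    the binomial tail of that pair's identity count in the region given
    its whole-view identity, Bonferroni-multiplied by the number of
    windows examined.
    """
    if window_len < 10:
        raise ValueError("window_len must be >= 10")
    L = triplet.length
    if L < window_len or triplet.variable_sites.size == 0:
        return None
    c = triplet.codes
    match = np.stack([(c[i] == c[j]) for i, j in _PAIRS]).astype(np.float64)
    cums = np.concatenate([np.zeros((3, 1)), np.cumsum(match, axis=1)], axis=1)
    starts = np.arange(0, L - window_len + 1, step)
    win = (cums[:, starts + window_len] - cums[:, starts]) / window_len  # (3, W)
    g = cums[:, -1] / L
    g_best = int(np.argmax(g))
    order = np.argsort(-win, axis=0)
    local_best = order[0]
    strict = win[order[0], np.arange(win.shape[1])] > win[order[1], np.arange(win.shape[1])]
    flags = strict & (local_best != g_best)
    run = _longest_true_run(flags, local_best)
    if run is None or (run[0] == 0 and run[1] == flags.size):
        return None  # no signal, or no *local* switch at all
    pair = int(local_best[run[0]])
    s = int(starts[run[0]])
    e = min(int(starts[run[1] - 1]) + window_len, L)
    l = e - s
    m = int(cums[pair, e] - cums[pair, s])
    p_bg = float(np.clip(g[pair], 1e-9, 1 - 1e-9))
    p_raw = min(1.0, binomial_identity_p(l, m, p_bg) * len(starts))
    rec_local, ambiguous = identify_recombinant(triplet, (s, e))
    region = triplet.colmap.interval_to_original(s, e)
    return SignalCandidate(
        method="rdp",
        triplet=triplet.indices,
        recombinant=triplet.indices[rec_local] if rec_local is not None else None,
        region=region,
        region_view=(s, e),
        stat=float(m / l),
        p_raw=p_raw,
        breakpoints=[region[0], region[1]],
        ambiguous=ambiguous,
        profile={"window_starts": starts, "identity": win, "pair": pair},
    )


# ---------------------------------------------------------------------------
# chi-square frame machinery (MaxChi, Chimaera)


def _chi2_boundaries(v: np.ndarray, w: int):
    """2x2 chi-square (no continuity correction) of (match, mismatch) x
    (left, right) for every boundary of a 2w frame sliding over the
    binary vector *v*.  With equal half-frame margins the statistic
    simplifies to ``2w (a-c)^2 / (s (2w-s))`` for left/right match
    counts a, c and s = a+c.  Returns (boundary indices, chi2 values)."""
    n = v.size
    ks = np.arange(w, n - w + 1)
    cs = np.concatenate([[0], np.cumsum(v)])
    a = cs[ks] - cs[ks - w]        # left matches
    cc = cs[ks + w] - cs[ks]       # right matches
    s = a + cc
    den = s * (2 * w - s)
    chi = np.zeros(ks.size)
    ok = den > 0
    chi[ok] = 2.0 * w * (a - cc)[ok] ** 2 / den[ok]
    return ks, chi


def _chi2_exceed_batch(mat: np.ndarray, w: int, d0_sq: int, den0: int) -> np.ndarray:
    """Per row of the (B, n) binary matrix: does any frame boundary reach
    the observed chi-square?  The comparison chi2 >= chi2_obs is done on
    the integer lattice (d^2 * den0 >= d0^2 * den), exact for ties."""
    cs = np.cumsum(mat, axis=1, dtype=np.int32)
    cs = np.concatenate([np.zeros((mat.shape[0], 1), dtype=np.int32), cs], axis=1)
    ks = np.arange(w, mat.shape[1] - w + 1)
    a = cs[:, ks] - cs[:, ks - w]
    cc = cs[:, ks + w] - cs[:, ks]
    d = (a - cc).astype(np.int64)
    s = a + cc
    den = (s * (2 * w - s)).astype(np.int64)
    return ((den > 0) & (d * d * den0 >= d0_sq * den)).any(axis=1)


def _chi_frame_candidate(v: np.ndarray, positions: np.ndarray, w: int,
                         n_permutations: int, rng) -> tuple | None:
    """Shared MaxChi/Chimaera core on a binary site vector.

    Returns (stat, boundary site-index k, permutation p) or None."""
    n = v.size
    if n < 2 * w:
        return None
    ks, chi = _chi2_boundaries(v, w)
    k_i = int(np.argmax(chi))  # leftmost on ties
    stat = float(chi[k_i])
    if stat == 0.0:
        return None
    base = np.broadcast_to(v, (1, n))

    cs = np.concatenate([[0], np.cumsum(v)])
    a0 = int(cs[ks[k_i]] - cs[ks[k_i] - w])
    c0 = int(cs[ks[k_i] + w] - cs[ks[k_i]])
    d0_sq = (a0 - c0) ** 2
    den0 = (a0 + c0) * (2 * w - a0 - c0)

    def batch_exceed(b, r):
        perm = r.permuted(np.tile(base, (b, 1)), axis=1)
        return np.count_nonzero(_chi2_exceed_batch(perm, w, d0_sq, den0))

    p, n_used = _permutation_pvalue(batch_exceed, n_permutations, _as_rng(rng))
    return stat, int(ks[k_i]), p, n_used


def maxchi_scan(x: np.ndarray, y: np.ndarray, window_len: int = 35,
                positions: np.ndarray | None = None,
                n_permutations: int = 500, rng=0,
                colmap: ColumnMap | None = None) -> SignalCandidate | None:
    """MaxChi on two rows: the binary match/mismatch vector of *x* vs *y*
    over *positions* (default: all columns), scanned with a 2x*window_len*
    frame; the reported breakpoint is the maximizing boundary (leftmost
    on ties), the p-value comes from permuting the site labels.

    *x*, *y* are residue code arrays of a shared gap-free view (e.g. a
    triplet view); *positions* would typically be the triplet's variable
    sites.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if positions is None:
        positions = np.arange(x.size)
    v = (x[positions] == y[positions]).astype(np.int8)
    res = _chi_frame_candidate(v, positions, window_len, n_permutations, rng)
    if res is None:
        return None
    stat, k, p, n_used = res
    w = window_len
    s_view = int(positions[k - w])
    e_view = int(positions[k + w - 1]) + 1
    bp_view = int(positions[k])  # first right-half site
    if colmap is not None:
        region = colmap.interval_to_original(s_view, e_view)
        bp = colmap.to_original(bp_view)
    else:
        region = (s_view, e_view)
        bp = bp_view
    return SignalCandidate(
        method="maxchi", triplet=(-1, -1, -1), recombinant=None,
        region=region, region_view=(s_view, e_view),
        stat=stat, p_raw=p, breakpoints=[bp], n_perm=n_used,
    )


def maxchi_scan_triplet(triplet: Triplet, window_len: int = 35,
                        n_permutations: int = 500, rng=0) -> SignalCandidate | None:
    """Selection-aware MaxChi on a triplet.

    The statistic is the largest peak chi-square over the three pairs;
    the permutation null applies one shared site permutation to all
    three pair vectors and takes the same maximum, so picking the best
    pair does not inflate the p-value.
    """
    pos = triplet.variable_sites
    n = pos.size
    w = window_len
    if n < 2 * w:
        return None
    rng = _as_rng(rng)
    V = np.stack([
        (triplet.codes[i, pos] == triplet.codes[j, pos]) for i, j in _PAIRS
    ]).astype(np.int8)
    best = None  # (stat, pair_index, boundary site index)
    for pi in range(3):
        ks, chi = _chi2_boundaries(V[pi], w)
        k_i = int(np.argmax(chi))
        if best is None or chi[k_i] > best[0]:
            best = (float(chi[k_i]), pi, int(ks[k_i]))
    stat, pair_i, k = best
    if stat == 0.0:
        return None
    base_idx = np.arange(n, dtype=np.int32)
    cs = np.concatenate([[0], np.cumsum(V[pair_i])])
    a0 = int(cs[k] - cs[k - w])
    c0 = int(cs[k + w] - cs[k])
    d0_sq = (a0 - c0) ** 2
    den0 = (a0 + c0) * (2 * w - a0 - c0)

    def batch_exceed(b, r):
        idx = r.permuted(np.tile(base_idx, (b, 1)), axis=1)
        hit = _chi2_exceed_batch(V[0][idx], w, d0_sq, den0)
        for pi in (1, 2):
            hit |= _chi2_exceed_batch(V[pi][idx], w, d0_sq, den0)
        return np.count_nonzero(hit)

    p, n_used = _permutation_pvalue(batch_exceed, n_permutations, rng)
    s_view = int(pos[k - w])
    e_view = int(pos[k + w - 1]) + 1
    region = triplet.colmap.interval_to_original(s_view, e_view)
    rec_local, ambiguous = identify_recombinant(triplet, (s_view, e_view))
    return SignalCandidate(
        method="maxchi", triplet=triplet.indices,
        recombinant=triplet.indices[rec_local] if rec_local is not None else None,
        region=region, region_view=(s_view, e_view),
        stat=stat, p_raw=p, n_perm=n_used, ambiguous=ambiguous,
        breakpoints=[triplet.colmap.to_original(int(pos[k]))],
    )


def chimaera_scan_triplet(triplet: Triplet, window_len: int = 35,
                          n_permutations: int = 500, rng=0) -> SignalCandidate | None:
    """Selection-aware Chimaera on a triplet: the best candidate
    recombinant's peak chi-square is compared against permutations in
    which every eligible candidate's informative vector is permuted and
    the same maximum is taken."""
    rng = _as_rng(rng)
    vecs = []
    best = None  # (stat, r, boundary index, pos)
    for r in range(3):
        pos, sym = triplet.informative(r)
        if pos.size < 2 * window_len:
            continue
        v = sym.astype(np.int8)
        ks, chi = _chi2_boundaries(v, window_len)
        k_i = int(np.argmax(chi))
        vecs.append(v)
        if best is None or chi[k_i] > best[0]:
            best = (float(chi[k_i]), r, int(ks[k_i]), pos, len(vecs) - 1)
    if best is None or best[0] == 0.0:
        return None
    stat, r, k, pos, _vi = best
    w = window_len
    cs = np.concatenate([[0], np.cumsum(vecs[_vi])])
    a0 = int(cs[k] - cs[k - w])
    c0 = int(cs[k + w] - cs[k])
    d0_sq = (a0 - c0) ** 2
    den0 = (a0 + c0) * (2 * w - a0 - c0)

    def batch_exceed(b, rr):
        hit = None
        for v in vecs:
            perm = rr.permuted(np.tile(v, (b, 1)), axis=1)
            e = _chi2_exceed_batch(perm, w, d0_sq, den0)
            hit = e if hit is None else (hit | e)
        return np.count_nonzero(hit)

    p, n_used = _permutation_pvalue(batch_exceed, n_permutations, rng)
    w = window_len
    s_view, e_view = int(pos[k - w]), int(pos[k + w - 1]) + 1
    region = triplet.colmap.interval_to_original(s_view, e_view)
    return SignalCandidate(
        method="chimaera", triplet=triplet.indices,
        recombinant=triplet.indices[r],
        region=region, region_view=(s_view, e_view),
        stat=stat, p_raw=p, n_perm=n_used,
        breakpoints=[triplet.colmap.to_original(int(pos[k]))],
    )


def threeseq_scan_triplet(triplet: Triplet, n_permutations: int = 1000,
                          rng=0) -> SignalCandidate | None:
    """Selection-aware 3seq-style scan: maximum descent over all three
    candidate recombinants, with the same maximum taken inside the
    permutation null."""
    rng = _as_rng(rng)
    vecs = []
    best = None  # (stat, r, interval, pos)
    for r in range(3):
        pos, sym = triplet.informative(r)
        if pos.size == 0:
            continue
        steps = _majority_steps(sym)
        stat, iv = _max_descent(steps)
        vecs.append(steps)
        if iv is not None and (best is None or stat > best[0]):
            best = (stat, r, iv, pos)
    if best is None:
        return None
    stat, r, iv, pos = best

    def batch_exceed(b, rr):
        hit = None
        for v in vecs:
            perm = rr.permuted(np.tile(v, (b, 1)), axis=1)
            e = _descent_batch(perm) >= stat
            hit = e if hit is None else (hit | e)
        return np.count_nonzero(hit)

    p, n_used = _permutation_pvalue(batch_exceed, n_permutations, rng)
    i, j = iv
    s_view = int(pos[i])
    e_view = int(pos[j - 1]) + 1
    region = triplet.colmap.interval_to_original(s_view, e_view)
    return SignalCandidate(
        method="threeseq", triplet=triplet.indices,
        recombinant=triplet.indices[r],
        region=region, region_view=(s_view, e_view),
        stat=float(stat), p_raw=p, n_perm=n_used,
        breakpoints=[region[0], region[1]],
    )


def chimaera_scan(triplet: Triplet, recombinant_candidate: int,
                  window_len: int = 35, n_permutations: int = 500,
                  rng=0) -> SignalCandidate | None:
    """Chimaera: the MaxChi chi-square frame applied to the {A,B}
    informative-site vector of one candidate recombinant."""
    pos, sym = triplet.informative(recombinant_candidate)
    if pos.size < 2 * window_len:
        return None
    res = _chi_frame_candidate(sym.astype(np.int8), pos, window_len,
                               n_permutations, rng)
    if res is None:
        return None
    stat, k, p, n_used = res
    w = window_len
    s_view, e_view = int(pos[k - w]), int(pos[k + w - 1]) + 1
    region = triplet.colmap.interval_to_original(s_view, e_view)
    return SignalCandidate(
        method="chimaera", triplet=triplet.indices,
        recombinant=triplet.indices[recombinant_candidate],
        region=region, region_view=(s_view, e_view),
        stat=stat, p_raw=p, n_perm=n_used,
        breakpoints=[triplet.colmap.to_original(int(pos[k]))],
    )


def best_chimaera_candidate(triplet: Triplet, window_len: int = 35) -> int | None:
    """Candidate recombinant with the largest peak Chimaera chi-square
    (permutation-free prescan; the p-value is then computed for this
    candidate only)."""
    best_r, best_stat = None, 0.0
    for r in range(3):
        pos, sym = triplet.informative(r)
        if pos.size < 2 * window_len:
            continue
        _, chi = _chi2_boundaries(sym.astype(np.int8), window_len)
        stat = float(chi.max())
        if stat > best_stat:
            best_r, best_stat = r, stat
    return best_r


def best_threeseq_candidate(triplet: Triplet) -> int | None:
    """Candidate recombinant with the largest maximum-descent statistic."""
    best_r, best_stat = None, 0
    for r in range(3):
        _, sym = triplet.informative(r)
        if sym.size == 0:
            continue
        stat = _max_descent(_majority_steps(sym))[0]
        if stat > best_stat:
            best_r, best_stat = r, stat
    return best_r


# ---------------------------------------------------------------------------
# SiScan


def siscan_scan(triplet: Triplet, window_len: int = 100, step: int = 20,
                n_randomizations: int = 500, z_threshold: float = 3.0,
                rng=0) -> SignalCandidate | None:
    """Sister-scanning: per window, z-scores of pairwise match counts
    against randomizations that permute the three residues within each
    column; the signal is a run of windows in which the overall most
    distant pair is anomalously similar (z above *z_threshold*)."""
    if n_randomizations < 100:
        raise ValueError("n_randomizations must be >= 100")
    rng = _as_rng(rng)
    L = triplet.length
    if L < window_len or triplet.variable_sites.size == 0:
        return None
    c = triplet.codes
    eq = np.stack([(c[i] == c[j]) for i, j in _PAIRS])       # (3, L)
    all_eq = eq.all(axis=0)
    # columns with exactly two residues equal: exactly one pair matches
    two_eq = eq.any(axis=0) & ~all_eq
    starts = np.arange(0, L - window_len + 1, step)
    cs_eq = np.concatenate([np.zeros((3, 1)), np.cumsum(eq, axis=1)], axis=1)
    cs3 = np.concatenate([[0], np.cumsum(all_eq)])
    cs2 = np.concatenate([[0], np.cumsum(two_eq)])
    obs = cs_eq[:, starts + window_len] - cs_eq[:, starts]   # (3, W)
    n3 = cs3[starts + window_len] - cs3[starts]
    n2 = (cs2[starts + window_len] - cs2[starts]).astype(int)
    g = cs_eq[:, -1]
    g_best = int(np.argmax(g))
    zs = np.full((3, starts.size), np.nan)
    for wi in range(starts.size):
        if n2[wi] == 0:
            continue  # sd degenerate: counts identical in every randomization
        draws = rng.multinomial(n2[wi], [1 / 3, 1 / 3, 1 / 3], size=n_randomizations)
        null = n3[wi] + draws  # (R, 3)
        sd = null.std(axis=0)
        mean = null.mean(axis=0)
        ok = sd > 0
        zs[ok, wi] = (obs[ok, wi] - mean[ok]) / sd[ok]
    if np.all(np.isnan(zs)):
        return None
    # a window signals when a pair other than the globally most similar
    # one is anomalously similar given its column patterns
    zfil = np.nan_to_num(zs, nan=-np.inf)
    top = np.argmax(zfil, axis=0)
    flags = (np.max(zfil, axis=0) > z_threshold) & (top != g_best)
    run = _longest_true_run(flags, top)
    if run is None:
        return None
    pair = int(top[run[0]])
    s = int(starts[run[0]])
    e = min(int(starts[run[1] - 1]) + window_len, L)
    z_peak = float(np.max(zfil[pair, run[0]:run[1]]))
    p_raw = min(1.0, float(norm.sf(z_peak)) * starts.size)
    rec_local, ambiguous = identify_recombinant(triplet, (s, e))
    region = triplet.colmap.interval_to_original(s, e)
    return SignalCandidate(
        method="siscan", triplet=triplet.indices,
        recombinant=triplet.indices[rec_local] if rec_local is not None else None,
        region=region, region_view=(s, e), stat=z_peak, p_raw=p_raw,
        breakpoints=[region[0], region[1]], ambiguous=ambiguous,
        profile={"window_starts": starts, "z": zs, "pair": pair},
    )


# ---------------------------------------------------------------------------
# Bootscan


def bootscan_scan(aln: Alignment, triplet: Triplet, outgroup: int,
                  window_len: int = 200, step: int = 20,
                  n_bootstraps: int = 100, support_threshold: float = 0.7,
                  rng=0) -> SignalCandidate | None:
    """Bootscan: per window, bootstrap NJ quartets (triplet + outgroup);
    the support profile of each candidate recombinant grouping with each
    parent is scanned for a supported-parent switch with both flanks at
    or above *support_threshold*; the switched region is then assessed
    with the binomial identity tail over the candidate's informative
    sites (the original bootscan's follow-up test)."""
    if n_bootstraps < 100:
        raise ValueError("n_bootstraps must be >= 100")
    if outgroup in triplet.indices:
        raise ValueError("outgroup must be distinct from the triplet rows")
    rng = _as_rng(rng)
    rows = list(triplet.indices) + [outgroup]
    view4, cmap4 = strip_shared_gaps(aln, rows)
    c4 = view4.codes
    L4 = c4.shape[1]
    if L4 < window_len:
        return None
    quartet_pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    diff = np.stack([(c4[i] != c4[j]) for i, j in quartet_pairs]).astype(np.float64)
    pair_idx = {pq: k for k, pq in enumerate(quartet_pairs)}
    # splits: {0,1|2,3}, {0,2|1,3}, {1,2|0,3}
    split_pairs = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((1, 2), (0, 3))]
    starts = np.arange(0, L4 - window_len + 1, step)
    W = starts.size
    support = np.zeros((3, W))
    w = window_len
    for wi, s in enumerate(starts):
        dwin = diff[:, s:s + w]                       # (6, w)
        counts = rng.multinomial(w, np.full(w, 1.0 / w), size=n_bootstraps)
        nd = counts @ dwin.T                          # (B, 6) difference counts
        p = np.clip(nd / w, 0.0, 0.7499)
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        sums = np.stack([
            d[:, pair_idx[a]] + d[:, pair_idx[b]] for a, b in split_pairs
        ])                                            # (3, B)
        chosen = np.argmin(sums, axis=0)
        for k in range(3):
            support[k, wi] = np.mean(chosen == k)
    split_of = {frozenset(a): k for k, (a, b) in enumerate(split_pairs)}
    split_of.update({frozenset(b): k for k, (a, b) in enumerate(split_pairs)})
    best = None
    for r in range(3):
        p1, p2 = sorted({0, 1, 2} - {r})
        s1 = support[split_of[frozenset((r, p1))]]
        s2 = support[split_of[frozenset((r, p2))]]
        label = np.where((s1 >= support_threshold) & (s1 > s2), 1,
                         np.where((s2 >= support_threshold) & (s2 > s1), 2, 0))
        cand = _bootscan_switch(triplet, r, (p1, p2), label, starts, w, L4,
                                cmap4, support_threshold)
        if cand is not None and (best is None or cand.p_raw < best.p_raw):
            best = cand
    return best


def _bootscan_switch(triplet, r, parents, label, starts, w, L4, cmap4, thr):
    """Find the longest run of windows supporting one parent that is
    flanked on both sides by windows supporting the other."""
    best_run = None
    n = label.size
    i = 0
    while i < n:
        if label[i] == 0:
            i += 1
            continue
        j = i + 1
        while j < n and label[j] == label[i]:
            j += 1
        other = 3 - label[i]
        if np.any(label[:i] == other) and np.any(label[j:] == other):
            if best_run is None or (j - i) > (best_run[1] - best_run[0]):
                best_run = (i, j, label[i])
        i = j
    if best_run is None:
        return None
    i, j, lab = best_run
    s4 = int(starts[i])
    e4 = min(int(starts[j - 1]) + w, L4)
    region = cmap4.interval_to_original(s4, e4)
    donor_local = parents[lab - 1]
    pos, sym = triplet.informative(r)
    orig = triplet.colmap.kept_columns[pos]
    in_region = (orig >= region[0]) & (orig < region[1])
    l = int(in_region.sum())
    if l == 0 or pos.size == 0:
        return None
    p_lower, _ = sorted({0, 1, 2} - {r})
    matches_donor = sym if donor_local == p_lower else ~sym
    m = int(np.count_nonzero(matches_donor & in_region))
    p_bg = float(np.clip(np.mean(matches_donor), 1e-9, 1 - 1e-9))
    p_raw = binomial_identity_p(l, m, p_bg)
    # map region back to triplet-view coordinates
    sv = triplet.colmap.from_original(region[0])
    ev = triplet.colmap.from_original(region[1] - 1) + 1
    sv, ev = min(sv, triplet.length - 1), max(min(ev, triplet.length), 1)
    if ev <= sv:
        return None
    return SignalCandidate(
        method="bootscan", triplet=triplet.indices,
        recombinant=triplet.indices[r], donor=triplet.indices[donor_local],
        region=region, region_view=(sv, ev),
        stat=float(l and m / l), p_raw=min(1.0, p_raw),
        breakpoints=[region[0], region[1]],
    )


# ---------------------------------------------------------------------------
# 3seq-style random walk


def _majority_steps(sym: np.ndarray) -> np.ndarray:
    """Orient the informative vector by its majority symbol: +1 for the
    background (major-parent) symbol, -1 for the minority.  This makes
    the maximum-descent statistic invariant under parent relabelling and
    zero for uniform vectors (no minority run to find)."""
    up = sym if np.count_nonzero(sym) * 2 >= sym.size else ~sym
    return np.where(up, 1, -1).astype(np.int64)


def _max_descent(steps: np.ndarray):
    """Maximum descent of the +/-1 walk and its leftmost achieving
    interval (site index range, half-open)."""
    walk = np.concatenate([[0], np.cumsum(steps)])
    runmax = np.maximum.accumulate(walk)
    desc = runmax - walk
    d = int(desc.max())
    if d == 0:
        return 0, None
    j = int(np.argmax(desc))
    i = int(np.argmax(walk[: j + 1] == runmax[j]))
    return d, (i, j)


def _descent_batch(mat: np.ndarray) -> np.ndarray:
    """Maximum descent per row (same orientation convention as the
    observed statistic: rows are already majority-oriented)."""
    B = mat.shape[0]
    walk = np.concatenate(
        [np.zeros((B, 1), dtype=np.int32), np.cumsum(mat, axis=1, dtype=np.int32)], axis=1)
    return (np.maximum.accumulate(walk, axis=1) - walk).max(axis=1)


def threeseq_scan(triplet: Triplet, recombinant_candidate: int,
                  n_permutations: int = 1000, rng=0) -> SignalCandidate | None:
    """3seq-style scan: walk +1 at majority-symbol (background-parent)
    sites and -1 at minority sites of the candidate's informative
    vector; the statistic is the maximum descent, its p-value by
    permutation of the vector."""
    pos, sym = triplet.informative(recombinant_candidate)
    if pos.size == 0:
        return None
    steps = _majority_steps(sym)
    stat, iv = _max_descent(steps)
    if stat == 0:
        return None
    rng = _as_rng(rng)
    base = steps.copy()

    def batch_exceed(b, r):
        perm = r.permuted(np.tile(base, (b, 1)), axis=1)
        return np.count_nonzero(_descent_batch(perm) >= stat)

    p, n_used = _permutation_pvalue(batch_exceed, n_permutations, rng)
    i, j = iv
    s_view = int(pos[i])
    e_view = int(pos[j - 1]) + 1
    region = triplet.colmap.interval_to_original(s_view, e_view)
    return SignalCandidate(
        method="threeseq", triplet=triplet.indices,
        recombinant=triplet.indices[recombinant_candidate],
        region=region, region_view=(s_view, e_view),
        stat=float(stat), p_raw=p, n_perm=n_used,
        breakpoints=[region[0], region[1]],
    )


# ---------------------------------------------------------------------------
# recombinant identification


def identify_recombinant(triplet: Triplet, region_view: tuple[int, int],
                         tie_margin: float = 0.05):
    """Pick the triplet row whose parental affinities flip most sharply
    between the inside and the outside of *region_view*.

    For each candidate the informative-site A-fraction inside (f_in) and
    outside (f_out) the region gives an affinity-flip score
    ``(2 f_in - 1)(2 f_out - 1)``; a true recombinant scores near -1
    (opposite affinities), parents near 0 or +1.  The minimizer wins;
    near-ties within *tie_margin*, a non-negative best score, or an
    undefined side make the call ambiguous.

    Returns (candidate index 0-2 or None, ambiguous flag).
    """
    s, e = region_view
    scores = np.zeros(3)
    defined = np.zeros(3, dtype=bool)
    for r in range(3):
        pos, sym = triplet.informative(r)
        if pos.size == 0:
            continue
        inside = (pos >= s) & (pos < e)
        n_in = int(inside.sum())
        n_out = int(pos.size - n_in)
        if n_in == 0 or n_out == 0:
            continue
        f_in = float(sym[inside].mean())
        f_out = float(sym[~inside].mean())
        scores[r] = (2 * f_in - 1) * (2 * f_out - 1)
        defined[r] = True
    if not defined.any():
        return None, True
    scores[~defined] = np.inf
    order = np.argsort(scores)
    best = int(order[0])
    second = scores[order[1]] if np.isfinite(scores[order[1]]) else np.inf
    ambiguous = scores[best] >= 0 or (second - scores[best]) < tie_margin
    return best, bool(ambiguous)
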