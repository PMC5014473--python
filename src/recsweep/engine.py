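"""Full-alignment scanning: triplet enumeration, multiple-testing
control, consolidation of per-triplet signals into events, and the
iterative recombinant-disassembly loop.

Multiple testing is Bonferroni across triplets only; window-level
multiplicity is already corrected inside each method, so the two
corrections compose without double counting.  Seeds are derived per
(triplet, method) from the config seed with ``SeedSequence`` spawn keys,
so results do not depend on scan order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import detection as det
from .alignment import Alignment
from .breakpoints import boundary_to_alignment, breakpoint_posterior, fit_segments
from .config import RunConfig
from .detection import SignalCandidate, Triplet
from .events import RecombinationEvent
from .phylo import jc_matrix

__all__ = [
    "enumerate_triplets",
    "scan_alignment",
    "consolidate_events",
    "iterate_disassembly",
    "ScanResult",
]

_METHOD_ID = {m: k for k, m in enumerate(
    ["rdp", "maxchi", "chimaera", "threeseq", "siscan", "bootscan"])}


def enumerate_triplets(n: int):
    """All C(n,3) row-index triplets in lexicographic order."""
    if n < 3:
        raise ValueError("recombination analysis requires >=3 sequences")
    return itertools.combinations(range(n), 3)


def _method_rng(seed: int, triplet: tuple[int, int, int], method: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(*triplet, _METHOD_ID[method]))
    return np.random.default_rng(ss)


def _run_method(method: str, aln: Alignment, trip: Triplet,
                config: RunConfig, dist: np.ndarray | None) -> SignalCandidate | None:
    rng = _method_rng(config.seed, trip.indices, method)
    if method == "rdp":
        return det.rdp_scan(trip, config.rdp_window, config.rdp_step)
    if method == "maxchi":
        return det.maxchi_scan_triplet(trip, config.maxchi_window,
                                       config.maxchi_permutations, rng)
    if method == "chimaera":
        return det.chimaera_scan_triplet(trip, config.chimaera_window,
                                         config.chimaera_permutations, rng)
    if method == "threeseq":
        return det.threeseq_scan_triplet(trip, config.threeseq_permutations, rng)
    if method == "siscan":
        return det.siscan_scan(trip, config.siscan_window, config.siscan_step,
                               config.siscan_randomizations,
                               config.siscan_z_threshold, rng)
    if method == "bootscan":
        if aln.n_sequences < 4 or dist is None:
            return None
        others = [k for k in range(aln.n_sequences) if k not in trip.indices]
        if not others:
            return None
        outgroup = max(others, key=lambda k: float(
            np.mean([dist[k, t] for t in trip.indices])))
        return det.bootscan_scan(aln, trip, outgroup, config.bootscan_window,
                                 config.bootscan_step, config.bootscan_bootstraps,
                                 config.bootscan_support, rng)
    raise ValueError(f"unknown method {method!r}")


def _with_adaptive_perms(config: RunConfig, n_triplets: int) -> RunConfig:
    # Permutation p-values must be able to resolve below alpha/n_triplets,
    # or Bonferroni across triplets would mask every permutation method;
    # raise the counts when the triplet count demands it (early stopping
    # keeps null triplets cheap regardless).  Above the cap the
    # permutation methods lose Bonferroni resolution and the exact-tail
    # rdp statistic carries detection alone.
    if config.alpha <= 0:
        return config  # nothing can pass; permutation sizing is moot
    min_perm = min(int(np.ceil(1.2 * n_triplets / config.alpha)), 12000)
    return config.replace(
        maxchi_permutations=max(config.maxchi_permutations, min_perm),
        chimaera_permutations=max(config.chimaera_permutations, min_perm),
        threeseq_permutations=max(config.threeseq_permutations, min_perm),
    )


def _scan_triplet_list(aln: Alignment, config: RunConfig,
                       triplets: list[tuple[int, int, int]],
                       n_correction: int) -> list[SignalCandidate]:
    config = _with_adaptive_perms(config, n_correction)
    dist = (jc_matrix(aln)
            if "bootscan" in config.enabled_methods and aln.n_sequences >= 4 else None)
    kept: list[SignalCandidate] = []
    for (a, b, c) in triplets:
        trip = Triplet(aln, a, b, c)
        if trip.variable_sites.size == 0:
            continue
        for method in config.enabled_methods:
            cand = _run_method(method, aln, trip, config, dist)
            if cand is None:
                continue
            cand.p_corrected = min(1.0, cand.p_raw * n_correction)
            if cand.p_corrected > config.alpha or cand.recombinant is None:
                continue
            if cand.donor is None:
                cand.donor = _infer_donor(trip, cand)
            kept.append(cand)
    return kept


def scan_alignment(aln: Alignment, config: RunConfig | None = None) -> list[SignalCandidate]:
    """Run every enabled method on every triplet; return candidates whose
    Bonferroni-corrected p (raw p x number of triplets) is <= alpha."""
    config = config or RunConfig()
    triplets = list(enumerate_triplets(aln.n_sequences))
    kept = _scan_triplet_list(aln, config, triplets, len(triplets))
    kept.sort(key=lambda s: (s.p_corrected, _METHOD_ID[s.method], s.triplet))
    return kept


def _infer_donor(trip: Triplet, cand: SignalCandidate) -> int | None:
    """Minor parent = the parent most similar to the recombinant inside
    the candidate region."""
    r_local = trip.indices.index(cand.recombinant)
    p, q = sorted({0, 1, 2} - {r_local})
    s, e = cand.region_view
    if e <= s:
        return None
    idp = trip.pair_identity(r_local, p, (s, e))
    idq = trip.pair_identity(r_local, q, (s, e))
    return trip.indices[p if idp >= idq else q]


# ---------------------------------------------------------------------------
# consolidation


def _jaccard(r1: tuple[int, int], r2: tuple[int, int]) -> float:
    lo = max(r1[0], r2[0])
    hi = min(r1[1], r2[1])
    inter = max(0, hi - lo)
    union = (r1[1] - r1[0]) + (r2[1] - r2[0]) - inter
    return inter / union if union else 0.0


def _parent_clusters(aln: Alignment, threshold: float) -> np.ndarray:
    """Single-linkage clusters of sequences at JC distance <= threshold."""
    n = aln.n_sequences
    if n == 1:
        return np.zeros(1, dtype=int)
    D = jc_matrix(aln)
    Z = linkage(squareform(D, checks=False), method="single")
    return fcluster(Z, t=threshold, criterion="distance")


@dataclass
class _Group:
    candidates: list[SignalCandidate] = field(default_factory=list)

    @property
    def best(self) -> SignalCandidate:
        return self.candidates[0]


def consolidate_events(candidates: list[SignalCandidate], aln: Alignment,
                       config: RunConfig | None = None) -> list[RecombinationEvent]:
    """Greedy clustering of signal candidates into events.

    Candidates join a group when their regions overlap reciprocally
    (Jaccard >= ``overlap_frac``) and their inferred donors fall in the
    same single-linkage JC cluster; each group becomes one event whose
    breakpoints are re-estimated by the HMM machinery on the group's
    best-supported triplet.
    """
    config = config or RunConfig()
    if not candidates:
        return []
    clusters = _parent_clusters(aln, config.parent_cluster_jc)
    ordered = sorted(candidates,
                     key=lambda s: (s.p_corrected, _METHOD_ID[s.method], s.triplet))
    groups: list[_Group] = []
    for cand in ordered:
        placed = False
        for grp in groups:
            ref = grp.best
            if _jaccard(cand.region, ref.region) < config.overlap_frac:
                continue
            if (cand.donor is not None and ref.donor is not None
                    and clusters[cand.donor] != clusters[ref.donor]):
                continue
            grp.candidates.append(cand)
            placed = True
            break
        if not placed:
            groups.append(_Group([cand]))
    events = []
    for grp in groups:
        ev = _build_event(len(events) + 1, grp, aln, config)
        # an "event" spanning the whole alignment has no internal
        # breakpoint: it is a relatedness signal, not recombination
        if ev.begin <= 1 and ev.end >= aln.length:
            continue
        events.append(ev)
    events.sort(key=lambda e: e.best_p())
    for k, ev in enumerate(events):
        ev.event_id = k + 1
    return events


def _profile_correlation(aln: Alignment, x: int, region0: tuple[int, int],
                         exclude: set[int]) -> float | None:
    """Pearson correlation of x's per-sequence difference fractions inside
    vs outside *region0* (phylpro-style).  A mosaic sequence changes its
    neighbourhood across the breakpoints, so its profiles decorrelate;
    a non-recombinant's stay strongly correlated."""
    b, e = region0
    codes = aln.codes
    gap = 4
    others = [k for k in range(aln.n_sequences) if k != x and k not in exclude]
    if len(others) < 3 or b >= e or (aln.length - (e - b)) <= 0:
        return None
    din, dout = [], []
    for k in others:
        diff = (codes[x] != codes[k])
        comp = (codes[x] < gap) & (codes[k] < gap)
        nin = int(comp[b:e].sum())
        nout = int(comp[:b].sum() + comp[e:].sum())
        if nin == 0 or nout == 0:
            continue
        din.append(float((diff & comp)[b:e].sum() / nin))
        dout.append(float(((diff & comp)[:b].sum() + (diff & comp)[e:].sum()) / nout))
    if len(din) < 3:
        return None
    din = np.array(din)
    dout = np.array(dout)
    if din.std() == 0 or dout.std() == 0:
        return None
    return float(np.corrcoef(din, dout)[0, 1])


def _orientation_swap(aln: Alignment, rec: int, donor: int,
                      region0: tuple[int, int], margin: float = 0.1) -> bool | None:
    """True when the nominated donor looks more recombinant-like than the
    nominated recombinant under the profile-correlation test; None when
    the test is undefined or inconclusive."""
    c_rec = _profile_correlation(aln, rec, region0, {donor})
    c_don = _profile_correlation(aln, donor, region0, {rec})
    if c_rec is None or c_don is None:
        return None
    if c_don < c_rec - margin:
        return True
    if c_rec < c_don - margin:
        return False
    return None


def _build_event(event_id: int, grp: _Group, aln: Alignment,
                 config: RunConfig) -> RecombinationEvent:
    best = grp.best
    trip = Triplet(aln, *best.triplet)
    rec_idx = best.recombinant
    donor_idx = best.donor if best.donor in trip.indices else None
    if donor_idx is None:
        donor_idx = _infer_donor(trip, best)
    warnings = []
    if best.ambiguous:
        warnings.append("ambiguous recombinant - possible misidentification")
    swap = _orientation_swap(aln, rec_idx, donor_idx, best.region)
    if swap:
        rec_idx, donor_idx = donor_idx, rec_idx
        warnings.append("recombinant/minor-parent roles assigned by profile correlation")

    r_local = trip.indices.index(rec_idx)
    donor_local = trip.indices.index(donor_idx)
    (major_local,) = {0, 1, 2} - {r_local, donor_local}

    pos, sym = trip.informative(r_local)
    sv, ev_ = best.region_view
    begin, begin_ci, end, end_ci = _hmm_breakpoints(
        trip, pos, sym, sv, ev_, config, warnings)

    minor = aln.names[trip.indices[donor_local]]
    major = aln.names[trip.indices[major_local]]
    recs = [aln.names[rec_idx]]
    for cand in grp.candidates:
        nm = aln.names[cand.recombinant]
        if nm not in recs and nm not in (minor, major):
            recs.append(nm)

    method_p: dict[str, float] = {}
    for cand in grp.candidates:
        method_p[cand.method] = min(method_p.get(cand.method, 1.0), cand.p_corrected)

    return RecombinationEvent(
        event_id=event_id, recombinants=recs, minor_parent=minor,
        major_parent=major, begin=begin, begin_ci=begin_ci,
        end=end, end_ci=end_ci, method_p=method_p, warnings=warnings)


def _hmm_breakpoints(trip, pos, sym, sv, ev_, config, warnings):
    """Begin/end breakpoints (1-based inclusive) with HPD CIs.

    The full informative vector is segmented by the two-pass Viterbi
    fit; the event region is the segment that overlaps the signal
    region most (window statistics often truncate the true region, the
    HMM recovers its full extent).  Each breakpoint then gets an
    independent single-switch posterior on the neighbourhood spanning
    the adjacent segment and the chosen one.
    """
    region_orig = trip.colmap.interval_to_original(sv, min(ev_, trip.length))
    fallback = (region_orig[0] + 1, region_orig[1])
    if pos.size < 2:
        warnings.append("too few informative sites for breakpoint intervals")
        return fallback[0], (fallback[0], fallback[0]), fallback[1], (fallback[1], fallback[1])
    vec = (~sym).astype(np.int8)  # 0 = matches parent A, 1 = parent B
    n = vec.size
    bv = int(np.searchsorted(pos, sv, side="left"))
    evv = int(np.searchsorted(pos, ev_, side="left"))
    segs, err = fit_segments(vec, config.switch_prob, config.emission_error)

    def seg_overlap(seg):
        return max(0, min(seg.end, evv) - max(seg.start, bv))

    si = int(np.argmax([seg_overlap(s) for s in segs]))
    if seg_overlap(segs[si]) == 0:
        kb, ke = bv, evv  # HMM found no matching segment; keep the signal
        lo, hi = 0, n
    else:
        kb, ke = segs[si].start, segs[si].end
        lo = segs[si - 1].start if si > 0 else 0
        hi = segs[si + 1].end if si + 1 < len(segs) else n

    def one_side(w_lo: int, w_hi: int):
        sub = vec[w_lo:w_hi]
        if sub.size < 2:
            return None
        post = breakpoint_posterior(sub, err, config.hpd_level)
        to_col = lambda k: boundary_to_alignment(k + w_lo, pos, trip.colmap)
        return to_col(post.mode), (to_col(post.hpd[0]), to_col(post.hpd[1]))

    begin_res = one_side(lo, ke) if kb > 0 else None
    end_res = one_side(kb, hi) if ke < n else None
    if begin_res is None:
        begin = trip.colmap.to_original(0) + 1 if kb == 0 else fallback[0]
        begin_ci = (begin, begin)
        warnings.append("begin breakpoint at alignment edge")
    else:
        b0, ci0 = begin_res
        begin, begin_ci = b0 + 1, (ci0[0] + 1, ci0[1] + 1)
    if end_res is None:
        end = (trip.colmap.to_original(len(trip.colmap) - 1) + 1
               if ke == n else fallback[1])
        end_ci = (end, end)
        warnings.append("end breakpoint at alignment edge")
    else:
        e0, ci1 = end_res
        end, end_ci = e0 + 1, (ci1[0] + 1, ci1[1] + 1)
    # When the refined interval no longer covers the signal region
    # (posterior collapse on noisy vectors), report the signal region:
    # splitting a sliver would leave the mosaic in place.
    inter = max(0, min(end, fallback[1]) - max(begin - 1, fallback[0] - 1))
    denom = min(end - begin + 1, fallback[1] - fallback[0] + 1)
    if end <= begin or inter / denom < 0.5:
        begin, begin_ci = fallback[0], (min(begin_ci[0], fallback[0]), max(begin_ci[1], fallback[0]))
        end, end_ci = fallback[1], (min(end_ci[0], fallback[1]), max(end_ci[1], fallback[1]))
        warnings.append("breakpoint posteriors diverged from signal region; region endpoints reported")
    return begin, begin_ci, end, end_ci


# ---------------------------------------------------------------------------
# iterative disassembly


@dataclass
class ScanResult:
    events: list[RecombinationEvent]
    iterations: int
    incomplete: bool = False


def iterate_disassembly(aln: Alignment, config: RunConfig | None = None) -> ScanResult:
    """Scan, consolidate, accept the best event, split its recombinant
    rows into region/complement fragments (gaps elsewhere, so column
    coordinates stay stable), and rescan until no signal remains.

    Only triplets touching rows changed by the split are rescanned each
    iteration; candidates on untouched rows carry over with their
    Bonferroni factor updated.  Successive events whose regions overlap
    reciprocally (Jaccard >= ``overlap_frac``) are folded into one
    reported event — repeated signals from one ancestral event, not new
    events (at the cost of under-counting distinct same-region events).
    Returned event coordinates always refer to the original alignment.
    """
    import math

    config = config or RunConfig()
    work = aln
    origin = {nm: nm for nm in aln.names}
    events: list[RecombinationEvent] = []
    triplets = list(enumerate_triplets(work.n_sequences))
    cands = _scan_triplet_list(work, config, triplets, len(triplets))
    incomplete = True
    iterations = 0
    while iterations < config.max_iterations:
        iterations += 1
        n_tri = math.comb(work.n_sequences, 3)
        live = []
        for c in cands:
            c.p_corrected = min(1.0, c.p_raw * n_tri)
            if (c.p_corrected > config.alpha and c.n_perm
                    and c.p_raw * (c.n_perm + 1) <= 1.001):
                # p sits at its permutation floor and the Bonferroni factor
                # has outgrown it: re-run the method at higher resolution
                c = _escalate(work, c, config, n_tri)
                if c is None:
                    continue
            if c.p_corrected <= config.alpha:
                live.append(c)
        live.sort(key=lambda s: (s.p_corrected, _METHOD_ID[s.method], s.triplet))
        if not live:
            incomplete = False
            break
        evs = consolidate_events(live, work, config)
        if not evs:
            incomplete = False
            break
        best = evs[0]
        origin_before = dict(origin)  # _disassemble consumes split names
        work2, touched = _disassemble(work, origin, best, iterations)
        if not touched:
            # nothing could be split: discard this event's candidates so
            # the loop cannot stall, and do not record a phantom event
            idxs = {work.names.index(nm) for nm in best.recombinants
                    if nm in work.names}
            remaining = [c for c in cands if c.recombinant not in idxs
                         or _jaccard(c.region, best.region0) < 0.2]
            if len(remaining) == len(cands):
                break
            cands = remaining
            continue
        _record_event(events, best, origin_before, config)
        work = work2
        if work.n_sequences < 3:
            incomplete = False
            break
        cands = [c for c in live if not set(c.triplet) & touched]
        n_new = math.comb(work.n_sequences, 3)
        new_triplets = [t for t in enumerate_triplets(work.n_sequences)
                        if set(t) & touched]
        cands += _scan_triplet_list(work, config, new_triplets, n_new)
    return ScanResult(events, iterations, incomplete)


def _escalate(work: Alignment, cand: SignalCandidate, config: RunConfig,
              n_tri: int) -> SignalCandidate | None:
    trip = Triplet(work, *cand.triplet)
    if trip.variable_sites.size == 0:
        return None
    new = _run_method(cand.method, work, trip,
                      _with_adaptive_perms(config, n_tri), None)
    if new is None or new.recombinant is None:
        return None
    new.p_corrected = min(1.0, new.p_raw * n_tri)
    if new.donor is None:
        new.donor = _infer_donor(trip, new)
    return new


def _record_event(events: list[RecombinationEvent], best: RecombinationEvent,
                  origin: dict, config: RunConfig) -> None:
    recs = sorted({origin.get(nm, nm) for nm in best.recombinants})
    minor = origin.get(best.minor_parent, best.minor_parent)
    major = origin.get(best.major_parent, best.major_parent)
    recs = [nm for nm in recs if nm not in (minor, major)] or recs
    for prior in events:
        # containment-tolerant overlap: repeated signals from one event
        # come back with jittered or truncated boundaries
        b = best.region0
        p = prior.region0
        inter = max(0, min(b[1], p[1]) - max(b[0], p[0]))
        denom = min(b[1] - b[0], p[1] - p[0])
        if denom and inter / denom >= config.overlap_frac:
            for nm in recs:
                if nm not in prior.recombinants and nm not in (
                        prior.minor_parent, prior.major_parent):
                    prior.recombinants.append(nm)
            for m, p in best.method_p.items():
                prior.method_p[m] = min(prior.method_p.get(m, 1.0), p)
            return
    events.append(RecombinationEvent(
        event_id=len(events) + 1, recombinants=recs, minor_parent=minor,
        major_parent=major, begin=best.begin, begin_ci=best.begin_ci,
        end=best.end, end_ci=best.end_ci, method_p=best.method_p,
        warnings=list(best.warnings)))


def _disassemble(work: Alignment, origin: dict, event: RecombinationEvent,
                 iteration: int) -> tuple[Alignment, set[int]]:
    """Split each recombinant row in place (region fragment replaces the
    row, complement fragment is appended) so untouched row indices stay
    valid; returns the new alignment and the touched row indices."""
    b0, e0 = event.region0
    names = list(work.names)
    rows = list(work.rows)
    touched: set[int] = set()
    for rec in event.recombinants:
        if rec not in names:
            continue
        idx = names.index(rec)
        row = rows[idx]
        minor = "-" * b0 + row[b0:e0] + "-" * (len(row) - e0)
        major = row[:b0] + "-" * (e0 - b0) + row[e0:]
        frags = [(f"{rec}|m{iteration}", minor), (f"{rec}|M{iteration}", major)]
        frags = [(nm, fr) for nm, fr in frags if any(ch != "-" for ch in fr)]
        if not frags or (len(frags) == 1 and frags[0][1] == row):
            continue  # split would be a no-op (region covers the whole support)
        src = origin.pop(rec)
        names[idx], rows[idx] = frags[0]
        origin[frags[0][0]] = src
        touched.add(idx)
        for nm, fr in frags[1:]:
            names.append(nm)
            rows.append(fr)
            origin[nm] = src
            touched.add(len(names) - 1)
    return Alignment(names, rows), touched
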