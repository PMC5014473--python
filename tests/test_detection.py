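"""Per-triplet signal statistics: worked examples, brute-force oracles
and symmetry invariants."""

from fractions import Fraction

import numpy as np
import pytest

import recsweep as rs
from recsweep.alignment import Alignment
from recsweep.detection import (Triplet, binomial_identity_p, bootscan_scan,
                                chimaera_scan, chimaera_scan_triplet,
                                identify_recombinant, maxchi_scan,
                                maxchi_scan_triplet, rdp_scan, siscan_scan,
                                threeseq_scan, threeseq_scan_triplet,
                                _chi2_boundaries, _max_descent)


# ---------------------------------------------------------------------------
# oracles


def chi2_oracle(v, w):
    """Exact 2x2 chi-square over every frame boundary, in rationals."""
    n = len(v)
    out = []
    for k in range(w, n - w + 1):
        a = sum(v[k - w:k])          # left matches
        c = sum(v[k:k + w])          # right matches
        b, d = w - a, w - c
        den = (a + b) * (c + d) * (a + c) * (b + d)
        if den == 0:
            out.append(Fraction(0))
        else:
            out.append(Fraction(2 * w * (a * d - b * c) ** 2, den))
    return out


def descent_oracle(steps):
    """Max over i<j of walk[i]-walk[j], O(n^2)."""
    walk = [0]
    for s in steps:
        walk.append(walk[-1] + s)
    best = 0
    for i in range(len(walk)):
        for j in range(i + 1, len(walk)):
            best = max(best, walk[i] - walk[j])
    return best


# ---------------------------------------------------------------------------
# binomial identity tail


def test_binomial_identity_examples():
    assert binomial_identity_p(5, 0, 0.3) == 1.0
    assert binomial_identity_p(1, 1, 0.25) == pytest.approx(0.25)
    assert binomial_identity_p(10, 10, 0.5) == pytest.approx(0.5 ** 10)
    with pytest.raises(ValueError):
        binomial_identity_p(5, 2, 1.5)
    with pytest.raises(ValueError):
        binomial_identity_p(5, 7, 0.5)


# ---------------------------------------------------------------------------
# chi-square frame machinery


def test_maxchi_step_vector_peak_and_statistic():
    # 20 matches then 20 mismatches, window 20: single boundary, chi2 = 40
    v = np.array([1] * 20 + [0] * 20, dtype=np.int8)
    ks, chi = _chi2_boundaries(v, 20)
    assert list(ks) == [20]
    assert chi[0] == pytest.approx(40.0)


def test_chimaera_step_vector_statistic():
    # informative vector AAAABBBB, window 4 -> peak at the centre, chi2 = 8
    v = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int8)
    ks, chi = _chi2_boundaries(v, 4)
    assert int(ks[np.argmax(chi)]) == 4
    assert chi.max() == pytest.approx(8.0)


def test_chi2_matches_rational_oracle_on_random_vectors(rng):
    for _ in range(30):
        n = int(rng.integers(12, 120))
        w = int(rng.integers(3, max(4, n // 3)))
        if n < 2 * w:
            continue
        v = rng.integers(0, 2, n).astype(np.int8)
        ks, chi = _chi2_boundaries(v, w)
        exact = chi2_oracle([int(x) for x in v], w)
        assert np.allclose(chi, [float(x) for x in exact], atol=1e-9)
        # leftmost argmax agrees with the exact-arithmetic argmax
        best = max(exact)
        assert int(np.argmax(chi)) == exact.index(best)


def test_max_descent_matches_quadratic_oracle(rng):
    assert _max_descent(np.array([1, 1, 1, -1, -1, -1, 1, 1, 1]))[0] == 3
    assert _max_descent(np.array([1, 1, 1]))[0] == 0
    for _ in range(40):
        n = int(rng.integers(2, 150))
        steps = rng.choice([-1, 1], n)
        assert _max_descent(steps)[0] == descent_oracle(steps)


def test_constant_vectors_give_no_chi_signal():
    v = np.ones(40, dtype=np.int8)
    _, chi = _chi2_boundaries(v, 10)
    assert np.all(chi == 0)


# ---------------------------------------------------------------------------
# scanners on the benchmark triplet


def test_rdp_scan_finds_implanted_region(bench_triplet):
    aln, truth = bench_triplet
    trip = Triplet(aln, 0, 1, 2)
    cand = rdp_scan(trip)
    ev = truth.events[0]
    assert cand is not None
    assert cand.region[0] < ev.end and cand.region[1] > ev.begin
    assert aln.names[cand.recombinant] == ev.recombinant
    assert cand.p_raw < 1e-3


def test_rdp_scan_trivial_absences():
    same = Alignment(["a", "b", "c"], ["ACGT" * 20] * 3)
    assert rdp_scan(Triplet(same, 0, 1, 2)) is None
    with pytest.raises(ValueError):
        rdp_scan(Triplet(same, 0, 1, 2), window_len=5)


def test_maxchi_triplet_breakpoint_near_junction(bench_triplet):
    aln, truth = bench_triplet
    trip = Triplet(aln, 0, 1, 2)
    cand = maxchi_scan_triplet(trip, rng=5)
    assert cand is not None and cand.p_raw < 0.01
    ev = truth.events[0]
    assert min(abs(cand.breakpoints[0] - ev.begin),
               abs(cand.breakpoints[0] - ev.end)) <= 40


def test_maxchi_pairwise_constant_vector_absent():
    x = np.zeros(100, dtype=np.uint8)
    y = np.zeros(100, dtype=np.uint8)
    assert maxchi_scan(x, y, window_len=10) is None  # all matches, chi2 = 0


def test_chimaera_and_threeseq_on_benchmark(bench_triplet):
    aln, truth = bench_triplet
    trip = Triplet(aln, 0, 1, 2)
    ev = truth.events[0]
    ch = chimaera_scan_triplet(trip, rng=5)
    ts = threeseq_scan_triplet(trip, rng=5)
    for cand in (ch, ts):
        assert cand is not None and cand.p_raw < 0.01
        assert aln.names[cand.recombinant] == ev.recombinant
    assert ts.region[0] < ev.end and ts.region[1] > ev.begin


def test_threeseq_trivial_cases():
    # all-A informative vector -> descent 0 -> absent
    aln = Alignment(["a", "b", "c"],
                    ["A" * 30, "C" * 30, "A" * 30])
    trip = Triplet(aln, 0, 1, 2)
    assert threeseq_scan(trip, 2, rng=0) is None


def test_parent_relabel_invariance(bench_triplet):
    """Swapping the two parent rows must not change statistics."""
    aln, _ = bench_triplet
    ia, ic, ib = aln.index_of("A"), aln.index_of("C"), aln.index_of("B")
    t1 = Triplet(aln, ia, ic, ib)
    sw = Alignment([aln.names[i] for i in (ib, ic, ia)],
                   [aln.rows[i] for i in (ib, ic, ia)])
    t2 = Triplet(sw, 0, 1, 2)
    r1 = rdp_scan(t1)
    r2 = rdp_scan(t2)
    assert r1.region_view == r2.region_view
    assert r1.stat == pytest.approx(r2.stat)
    m1 = maxchi_scan_triplet(t1, rng=3)
    m2 = maxchi_scan_triplet(t2, rng=3)
    assert m1.stat == pytest.approx(m2.stat)
    assert m1.region_view == m2.region_view
    c_local1 = t1.indices.index(ic)
    s1 = threeseq_scan(t1, c_local1, rng=3)
    s2 = threeseq_scan(t2, 1, rng=3)
    assert s1.stat == s2.stat and s1.region_view == s2.region_view


def test_informative_vector_flip_under_parent_swap(bench_triplet):
    aln, _ = bench_triplet
    trip = Triplet(aln, 0, 1, 2)
    r = 1
    pos, sym = trip.informative(r)
    assert pos.size > 0
    swapped = Alignment([aln.names[i] for i in (2, 1, 0)],
                        [aln.rows[i] for i in (2, 1, 0)])
    pos2, sym2 = Triplet(swapped, 0, 1, 2).informative(1)
    assert np.array_equal(pos, pos2)
    assert np.array_equal(sym, ~sym2)


def test_permutation_pvalues_in_unit_interval_and_nonzero(bench_triplet):
    aln, _ = bench_triplet
    trip = Triplet(aln, 0, 1, 2)
    for cand in (maxchi_scan_triplet(trip, n_permutations=200, rng=0),
                 chimaera_scan_triplet(trip, n_permutations=200, rng=0),
                 threeseq_scan_triplet(trip, n_permutations=200, rng=0)):
        assert cand is not None
        assert 0 < cand.p_raw <= 1
        assert cand.p_raw >= 1 / (cand.n_perm + 1)


def test_siscan_on_benchmark_and_determinism(bench_quartet):
    aln, truth = bench_quartet
    idx = sorted(aln.index_of(n) for n in "ABC")
    trip = Triplet(aln, *idx)
    s1 = siscan_scan(trip, rng=7)
    s2 = siscan_scan(trip, rng=7)
    ev = truth.events[0]
    assert s1 is not None
    assert s1.region[0] < ev.end and s1.region[1] > ev.begin
    assert s1.stat == s2.stat and s1.region == s2.region

    same = Alignment(["a", "b", "c"], ["ACGT" * 50] * 3)
    assert siscan_scan(Triplet(same, 0, 1, 2), rng=0) is None


def test_bootscan_on_benchmark(bench_quartet):
    aln, truth = bench_quartet
    idx = sorted(aln.index_of(n) for n in "ABC")
    trip = Triplet(aln, *idx)
    cand = bootscan_scan(aln, trip, aln.index_of("O"), rng=7)
    ev = truth.events[0]
    assert cand is not None
    assert aln.names[cand.recombinant] == ev.recombinant
    assert aln.names[cand.donor] == ev.donor
    assert cand.region[0] < ev.end and cand.region[1] > ev.begin
    assert cand.p_raw < 1e-6

    same = Alignment(["a", "b", "c", "o"], ["ACGT" * 100] * 4)
    t0 = Triplet(same, 0, 1, 2)
    assert bootscan_scan(same, t0, 3, rng=0) is None
    with pytest.raises(ValueError):
        bootscan_scan(aln, trip, idx[0], rng=0)


def test_identify_recombinant(bench_triplet):
    aln, truth = bench_triplet
    trip = Triplet(aln, 0, 1, 2)
    cand = rdp_scan(trip)
    r, ambiguous = identify_recombinant(trip, cand.region_view)
    assert aln.names[trip.indices[r]] == truth.events[0].recombinant
    assert not ambiguous
    # three near-equidistant rows with no event -> ambiguous
    null = rs.simulate_tree_alignment("((a:0.1,b:0.1):0.0,c:0.1);", 1000, seed=8)
    tn = Triplet(null, 0, 1, 2)
    _, amb = identify_recombinant(tn, (200, 600))
    assert amb
    # whole-view region is ambiguous by construction
    _, amb2 = identify_recombinant(trip, (0, trip.length))
    assert amb2
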