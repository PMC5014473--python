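"""Scan orchestration, consolidation and iterative disassembly."""

import math

import numpy as np
import pytest

import recsweep as rs
from recsweep.config import RunConfig
from recsweep.detection import SignalCandidate
from recsweep.engine import (consolidate_events, enumerate_triplets,
                             iterate_disassembly, scan_alignment)
from recsweep.events import read_events_tsv, write_events_tsv


def test_enumerate_triplets_counts():
    assert len(list(enumerate_triplets(3))) == 1
    assert len(list(enumerate_triplets(5))) == math.comb(5, 3) == 10
    trips = list(enumerate_triplets(4))
    assert trips == sorted(trips) and len(set(trips)) == len(trips)
    with pytest.raises(ValueError, match="3 sequences"):
        list(enumerate_triplets(2))


def test_alpha_zero_returns_nothing(bench_triplet):
    aln, _ = bench_triplet
    assert scan_alignment(aln, RunConfig(seed=0, alpha=0.0)) == []


def test_scan_triplet_dataset_recovers_event(bench_triplet):
    aln, truth = bench_triplet
    cands = scan_alignment(aln, RunConfig(seed=0))
    assert cands
    ev = truth.events[0]
    best = cands[0]
    assert best.region[0] < ev.end and best.region[1] > ev.begin
    events = consolidate_events(cands, aln, RunConfig(seed=0))
    assert len(events) == 1
    e = events[0]
    assert ev.recombinant in e.recombinants
    assert e.begin_ci[0] <= e.begin <= e.begin_ci[1]
    assert e.end_ci[0] <= e.end <= e.end_ci[1]
    assert e.begin < e.end
    assert min(e.method_p.values()) <= 0.05
    assert not set(e.recombinants) & {e.minor_parent, e.major_parent}


def _candidate(region, rec, donor, p, trip=(0, 1, 2)):
    return SignalCandidate(
        method="rdp", triplet=trip, recombinant=rec, region=region,
        region_view=region, stat=1.0, p_raw=p, p_corrected=p, donor=donor)


def test_consolidation_grouping_rules(bench_triplet):
    aln, _ = bench_triplet
    cfg = RunConfig(seed=0)
    # same recombinant, heavily overlapping regions, same donor -> 1 event
    c1 = _candidate((300, 700), 1, 2, 1e-6)
    c2 = _candidate((310, 690), 1, 2, 1e-5)
    evs = consolidate_events([c1, c2], aln, cfg)
    assert len(evs) == 1
    # disjoint regions of different recombinants -> 2 events
    aln2, truth2 = rs.simulate_events_dataset(6, 1500, [(100, 400), (900, 1300)],
                                              seed=55)
    cands = []
    for p, te in zip((1e-6, 1e-4), truth2.events):
        rec = aln2.index_of(te.recombinant)
        donor = aln2.index_of(te.donor)
        third = next(k for k in range(6) if k not in (rec, donor))
        cands.append(_candidate((te.begin, te.end), rec, donor, p,
                                trip=tuple(sorted((rec, donor, third)))))
    evs2 = consolidate_events(cands, aln2, cfg)
    assert len(evs2) == 2
    assert evs2[0].best_p() <= evs2[1].best_p()


def test_no_recombination_gives_no_events():
    aln = rs.simulate_tree_alignment(rs.random_tree(6, seed=21), 1500, seed=21)
    res = iterate_disassembly(aln, RunConfig(seed=21))
    assert res.events == []
    assert res.iterations == 1
    assert not res.incomplete


def test_single_event_disassembly(bench_quartet):
    aln, truth = bench_quartet
    res = iterate_disassembly(aln, RunConfig(seed=2))
    assert len(res.events) == 1
    ev, te = res.events[0], truth.events[0]
    assert te.recombinant in ev.recombinants
    assert ev.begin - 1 < te.end and ev.end > te.begin
    assert ev.minor_parent == te.donor


def test_two_disjoint_events_recovered():
    aln, truth = rs.simulate_events_dataset(8, 2000, [(200, 700), (1200, 1700)],
                                            seed=31)
    res = iterate_disassembly(aln, RunConfig(seed=31))
    assert len(res.events) == 2
    for te in truth.events:
        assert any(e.begin - 1 < te.end and e.end > te.begin
                   and te.recombinant in e.recombinants for e in res.events)


def test_scan_is_deterministic_given_seed(bench_quartet):
    aln, _ = bench_quartet
    cfg = RunConfig(seed=13)
    c1 = scan_alignment(aln, cfg)
    c2 = scan_alignment(aln, cfg)
    assert [(c.method, c.triplet, c.region, c.p_raw) for c in c1] == \
           [(c.method, c.triplet, c.region, c.p_raw) for c in c2]


def test_event_coordinates_within_alignment(bench_quartet):
    aln, _ = bench_quartet
    res = iterate_disassembly(aln, RunConfig(seed=2))
    for e in res.events:
        assert 1 <= e.begin < e.end <= aln.length
        assert 1 <= e.begin_ci[0] <= e.begin_ci[1] <= aln.length


def test_events_tsv_round_trip(tmp_path, bench_quartet):
    aln, _ = bench_quartet
    res = iterate_disassembly(aln, RunConfig(seed=2))
    path = tmp_path / "events.tsv"
    write_events_tsv(res.events, path)
    back = read_events_tsv(path)
    assert len(back) == len(res.events)
    for a, b in zip(res.events, back):
        assert (a.recombinants, a.minor_parent, a.begin, a.end) == \
               (b.recombinants, b.minor_parent, b.begin, b.end)
        assert a.method_p.keys() == b.method_p.keys()


def test_config_round_trip_and_unknown_keys(tmp_path):
    cfg = RunConfig(seed=5, alpha=0.01, enabled_methods=["rdp", "maxchi"])
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    assert RunConfig.from_json(path) == cfg
    with pytest.raises(ValueError, match="unknown config keys"):
        RunConfig.from_dict({"nonsense": 1})
    with pytest.raises(ValueError, match="unknown methods"):
        RunConfig(enabled_methods=["rdp", "mystery"])
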