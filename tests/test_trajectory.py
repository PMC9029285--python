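"""Frame statistics: per-pair overlap, histograms, events, complexes."""
import numpy as np
import pytest

from strandfit import (
    HBFrame,
    InputError,
    Oligomer,
    PairTrace,
    binding_events,
    build_traces,
    complex_report,
    detect_complexes,
    ensemble_timeseries,
    frame_pair_overlap,
    histogram,
    self_fold,
    topology_from_oligomers,
)
from strandfit.trajectory import composition_label, default_species_of


def trace(mco, tmo=None, pair=("a", "b"), interval=1000):
    mco = np.asarray(mco)
    tmo = mco if tmo is None else np.asarray(tmo)
    steps = np.arange(len(mco)) * interval
    return PairTrace(pair, steps, mco, tmo)


class TestFramePairOverlap:
    def test_antiparallel_run_of_three(self, two_acgt_topology):
        # a: globals 0..3, b: globals 4..7; (a0,b3),(a1,b2),(a2,b1)
        frame = HBFrame(0, {(0, 7), (1, 6), (2, 5)})
        assert frame_pair_overlap(frame, two_acgt_topology, "a", "b") == (3, 3)

    def test_isolated_pairs_have_unit_mco(self, two_acgt_topology):
        frame = HBFrame(0, {(0, 7), (2, 5)})
        assert frame_pair_overlap(frame, two_acgt_topology, "a", "b") == (1, 2)

    def test_empty_frame(self, two_acgt_topology):
        assert frame_pair_overlap(
            HBFrame(0), two_acgt_topology, "a", "b") == (0, 0)

    def test_parallel_register_counts_only_toward_tmo(self):
        topo = topology_from_oligomers(
            [Oligomer("a", "ACGTAC"), Oligomer("b", "ACGTAC")])
        # parallel register: both local indices increase together
        frame = HBFrame(0, {(0, 6), (1, 7), (2, 8)})
        mco, tmo = frame_pair_overlap(frame, topo, "a", "b")
        assert tmo == 3
        assert mco == 1  # no antiparallel chain

    def test_third_strand_bonds_ignored(self):
        topo = topology_from_oligomers(
            [Oligomer("a", "ACGT"), Oligomer("b", "ACGT"),
             Oligomer("c", "ACGT")])
        frame = HBFrame(0, {(0, 7), (1, 8)})  # a-b and a-c
        assert frame_pair_overlap(frame, topo, "a", "b") == (1, 1)

    def test_unknown_strand_rejected(self, two_acgt_topology):
        with pytest.raises(InputError, match="zzz"):
            frame_pair_overlap(HBFrame(0), two_acgt_topology, "a", "zzz")

    def test_frame_mco_never_exceeds_omega(self):
        # bonds generated from a known scenario respect the sequence bound
        from strandfit import generate_trajectory, preset, profile

        config = preset("p10res", n_frames=300, rng_seed=5)
        topo, frames, _ = generate_trajectory(config)
        bound = profile(config.oligomers[0], config.oligomers[1]).omega
        for frame in frames:
            mco, tmo = frame_pair_overlap(frame, topo, "p10", "res")
            assert mco <= bound
            assert tmo >= mco


class TestHistogram:
    def test_direct_count(self):
        h = histogram([trace([4, 4, 0, 4])])
        assert h.p_mco == {4: 0.75, 0: 0.25}
        assert h.n_frames_total == 4 and h.n_runs == 1

    def test_probabilities_sum_to_one(self):
        h = histogram([trace([0, 1, 2, 3, 4, 4], tmo=[0, 2, 3, 4, 6, 7])])
        assert sum(h.p_mco.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(h.p_tmo.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_bin_always_present(self):
        assert 0 in histogram([trace([3, 3, 3])]).p_mco

    def test_equal_length_pooling_is_average(self):
        t1, t2 = trace([4, 4, 0, 0]), trace([4, 0, 0, 0])
        pooled = histogram([t1, t2])
        h1, h2 = histogram([t1]), histogram([t2])
        for v in pooled.p_mco:
            assert pooled.p_mco[v] == pytest.approx(
                (h1.p_mco.get(v, 0) + h2.p_mco.get(v, 0)) / 2)
        assert pooled.n_frames_total == 8

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            histogram([])
        with pytest.raises(InputError, match="same strand pair"):
            histogram([trace([1]), trace([1], pair=("x", "y"))])


class TestEnsembleTimeseries:
    def test_pointwise_mean(self):
        ts = ensemble_timeseries([trace([4, 4, 4]), trace([0, 0, 0])])
        assert list(ts["mean_mco"]) == [2.0, 2.0, 2.0]

    def test_single_run_identity(self):
        ts = ensemble_timeseries([trace([1, 2, 3])])
        assert list(ts["mean_mco"]) == [1.0, 2.0, 3.0]

    def test_mismatched_grids_rejected(self):
        with pytest.raises(InputError, match="resample"):
            ensemble_timeseries([trace([1, 2]), trace([1, 2, 3])])

    def test_planted_decay_recovered_with_negative_slope(self):
        # ensemble of traces whose bound probability decays linearly
        rng = np.random.default_rng(11)
        n = 400
        p = np.linspace(0.9, 0.1, n)
        traces = [trace((rng.random(n) < p) * 4) for _ in range(10)]
        ts = ensemble_timeseries(traces)
        slope = np.polyfit(ts["step"], ts["mean_mco"], 1)[0]
        assert slope < 0


class TestBindingEvents:
    def test_two_events_with_censoring(self):
        events = binding_events(trace([4, 5, 4, 0, 4]), threshold=4)
        assert [e.lifetime_steps for e in events] == [3000, 1000]
        assert events[0].censored is False
        assert events[1].censored is True  # still bound at the trace end
        assert events[0].left_censored is True  # bound from the first frame

    def test_event_bounds_and_threshold(self):
        (e,) = binding_events(trace([0, 4, 6, 0]), threshold=4)
        assert (e.start_step, e.end_step) == (1000, 3000)
        assert e.lifetime_steps == 2000 and e.threshold == 4

    def test_all_zero_trace_has_no_events(self):
        assert binding_events(trace([0, 0, 0])) == []

    def test_reconstruction_matches_thresholded_trace(self):
        rng = np.random.default_rng(3)
        mco = rng.integers(0, 6, size=200)
        t = trace(mco)
        events = binding_events(t, threshold=4)
        covered = np.zeros(len(t), bool)
        for e in events:
            lo = e.start_step // 1000
            hi = e.end_step // 1000
            covered[lo:hi] = True
        assert np.array_equal(covered, mco >= 4)

    def test_threshold_validation(self):
        with pytest.raises(InputError):
            binding_events(trace([1]), threshold=0)


class TestComplexes:
    @pytest.fixture
    def three_strand_topo(self):
        from strandfit import P4_SEQ, P10_SEQ, RES_SEQ

        return topology_from_oligomers(
            [Oligomer("p4", P4_SEQ), Oligomer("p10", P10_SEQ),
             Oligomer("res", RES_SEQ)])

    def test_trimer_via_parasite_edges(self, three_strand_topo):
        topo = three_strand_topo
        # p10-res bond and p4-p10 bond only: one trimer component
        frame = HBFrame(0)
        frame.pairs.add((topo.global_index("p10", 19),
                         topo.global_index("res", 18)))
        frame.pairs.add((topo.global_index("p4", 18),
                         topo.global_index("p10", 16)))
        entry = detect_complexes(frame, topo)
        assert entry.components == [("p10", "p4", "res")]
        assert entry.labels == ["trimer[p10+p4+res]"]

    def test_no_bonds_all_singletons(self, three_strand_topo):
        entry = detect_complexes(HBFrame(0), three_strand_topo)
        assert entry.components == [("p10",), ("p4",), ("res",)]

    def test_tetramer_with_two_resources(self):
        from strandfit import P4_SEQ, P10_SEQ, RES_SEQ

        topo = topology_from_oligomers(
            [Oligomer("res_1", RES_SEQ), Oligomer("p10", P10_SEQ),
             Oligomer("res_2", RES_SEQ), Oligomer("p4", P4_SEQ)])
        frame = HBFrame(0)
        frame.pairs.add((topo.global_index("res_1", 9),
                         topo.global_index("p10", 28)))
        frame.pairs.add((topo.global_index("p10", 5),
                         topo.global_index("res_2", 3)))
        frame.pairs.add((topo.global_index("p10", 40),
                         topo.global_index("p4", 2)))
        entry = detect_complexes(frame, topo)
        assert len(entry.components) == 1
        assert entry.labels == ["tetramer[p10+p4+2xres]"]

    def test_mco_edge_rule_is_stricter(self, three_strand_topo):
        topo = three_strand_topo
        frame = HBFrame(0)
        frame.pairs.add((topo.global_index("p4", 0),
                         topo.global_index("res", 0)))
        loose = detect_complexes(frame, topo, min_edge=("tmo", 1))
        strict = detect_complexes(frame, topo, min_edge=("mco", 4))
        assert ("p4", "res") in loose.components
        assert ("p4", "res") not in strict.components

    def test_report_occupancy_sums_to_one(self, three_strand_topo):
        frames = [HBFrame(step=i * 1000) for i in range(5)]
        report = complex_report(frames, three_strand_topo)
        assert sum(report.occupancy.values()) == pytest.approx(1.0)

    def test_species_label_conventions(self):
        assert default_species_of("res_2") == "res"
        assert default_species_of("res1") == "res"
        assert default_species_of("p4") == "p4"
        assert default_species_of("p10") == "p10"
        assert composition_label(["p4", "res", "res"]) == "trimer[p4+2xres]"


class TestSelfFold:
    @pytest.fixture
    def hairpin_topo(self):
        return topology_from_oligomers([Oligomer("h", "GGGTTTTCCC")])

    def test_hairpin_run_and_loop(self, hairpin_topo):
        frame = HBFrame(0, {(0, 9), (1, 8), (2, 7)})
        rec = self_fold(frame, hairpin_topo, "h", min_loop=3)
        assert rec.n_intra_pairs == 3
        assert rec.longest_run == 3
        assert rec.loop_length == 4  # bases 3..6 close the loop

    def test_no_intra_pairs(self, hairpin_topo):
        rec = self_fold(HBFrame(0), hairpin_topo, "h")
        assert (rec.n_intra_pairs, rec.longest_run, rec.loop_length) == \
            (0, 0, 0)

    def test_min_loop_excludes_tight_turns(self, hairpin_topo):
        frame = HBFrame(0, {(0, 2)})
        rec = self_fold(frame, hairpin_topo, "h", min_loop=3)
        assert rec.n_intra_pairs == 0

    def test_inter_strand_bonds_not_counted(self):
        topo = topology_from_oligomers(
            [Oligomer("h", "GGGTTTTCCC"), Oligomer("x", "AAAA")])
        frame = HBFrame(0, {(0, 10)})
        assert self_fold(frame, topo, "h").n_intra_pairs == 0


class TestBuildTraces:
    def test_traces_cover_all_pairs_and_frames(self, two_acgt_topology):
        frames = [HBFrame(0, {(0, 7)}), HBFrame(1000), HBFrame(2000, {(1, 6)})]
        traces = build_traces(two_acgt_topology, frames)
        t = traces[("a", "b")]
        assert list(t.steps) == [0, 1000, 2000]
        assert list(t.tmo) == [1, 0, 1]
        assert t.bound_fraction == pytest.approx(2 / 3)
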