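"""Trace idealization and dwell extraction with censoring."""

import numpy as np
import pytest

from termkin import (extract_dwells, idealize_trace, render_trace,
                     simulate_timelines)
from termkin.idealization import DwellRecord, StateSequence
from termkin.synthetic_traces import STATE_LEVELS, Trace


def _truth_labels(timeline, n, frame_rate):
    """Ground-truth per-frame ribosome state from a timeline (same
    frame-binning convention as the renderer)."""
    L = []
    ends = (np.arange(n) + 1) / frame_rate
    for te in ends:
        state = "PIC"
        if timeline.subunit_join is not None and timeline.subunit_join < te:
            state = "nonrotated"
        for a, b in timeline.elongation_rotations:
            if a < te:
                state = "rotated" if not b < te else "nonrotated"
        if timeline.rotation is not None and timeline.rotation < te:
            state = "rotated"
        if timeline.subunit_split is not None and timeline.subunit_split < te:
            state = "split"
        L.append(state)
    return np.array(L, dtype=object)


class TestIdealizeTrace:
    def test_noiseless_round_trip_recovers_ground_truth(self, rf1_20c, rf3_gtp):
        tls = simulate_timelines(rf1_20c, rf3_gtp, 0.075, 2, 30, seed=8)
        for tl in tls:
            tr = render_trace(tl, noise_sd=0.0, seed=0)
            seq = idealize_trace(tr)
            truth = _truth_labels(tl, tr.n_frames, tr.frame_rate)
            assert np.array_equal(seq.ribosome_state, truth)

    def test_high_accuracy_under_noise(self, rf1_20c, rf3_gtp):
        """>= 99% frame-label accuracy at noise_sd 0.05 on 100 seeded traces."""
        tls = simulate_timelines(rf1_20c, rf3_gtp, 0.075, 2, 100, seed=13)
        total = correct = 0
        for i, tl in enumerate(tls):
            tr = render_trace(tl, noise_sd=0.05, seed=100 + i)
            seq = idealize_trace(tr)
            truth = _truth_labels(tl, tr.n_frames, tr.frame_rate)
            total += len(truth)
            correct += int((seq.ribosome_state == truth).sum())
        assert correct / total >= 0.99

    def test_trace_without_factor_channels_keeps_ribosome_states(self):
        n = 50
        tr = Trace(frame_times=np.arange(n) / 10.0,
                   cy3b=np.full(n, STATE_LEVELS["cy3b"]["nonrotated"]),
                   cy5=np.full(n, STATE_LEVELS["unbound"]),
                   cy5_5=np.full(n, STATE_LEVELS["unbound"]),
                   frame_rate=10.0, movie_length=5.0, noise_sd=0.0,
                   bleach_times={"cy3b": None, "cy5": None, "cy5_5": None})
        seq = idealize_trace(tr)
        assert not seq.rf_i_bound.any() and not seq.rf3_bound.any()
        assert np.all(seq.ribosome_state == "nonrotated")

    def test_out_of_calibration_frames_labelled_unknown(self):
        n = 30
        cy3b = np.full(n, STATE_LEVELS["cy3b"]["nonrotated"])
        cy3b[10:15] = 5.0  # far outside any calibrated level
        tr = Trace(frame_times=np.arange(n) / 10.0, cy3b=cy3b,
                   cy5=np.full(n, STATE_LEVELS["unbound"]),
                   cy5_5=np.full(n, STATE_LEVELS["unbound"]),
                   frame_rate=10.0, movie_length=3.0, noise_sd=0.0,
                   bleach_times={"cy3b": None, "cy5": None, "cy5_5": None})
        seq = idealize_trace(tr)
        assert np.all(seq.ribosome_state[10:15] == "unknown")


class TestExtractDwells:
    def test_unresolved_dissociation_censored_at_movie_end(self):
        n = 100
        seq = StateSequence(
            ribosome_state=np.array(["nonrotated"] * n, dtype=object),
            rf_i_bound=np.array([False] * 10 + [True] * 90),
            rf3_bound=np.zeros(n, dtype=bool), frame_rate=10.0,
            metadata={"trace_id": "x"})
        recs = extract_dwells(seq)
        bd = [r for r in recs if r.dwell_class == "t_iBD"]
        assert len(bd) == 1 and bd[0].censored
        assert bd[0].censor_reason == "movie_end"
        assert bd[0].duration == pytest.approx(9.0)

    def test_single_rotation_dwell_duration(self):
        n = 200
        ribo = np.array(["nonrotated"] * 100 + ["rotated"] * 100, dtype=object)
        seq = StateSequence(
            ribosome_state=ribo,
            rf_i_bound=np.array([True] * 150 + [False] * 50),
            rf3_bound=np.zeros(n, dtype=bool), frame_rate=10.0,
            metadata={"trace_id": "x"})
        recs = {r.dwell_class: r for r in extract_dwells(seq)}
        assert recs["t_iBR"].duration == pytest.approx(10.0)
        assert not recs["t_iBR"].censored

    def test_sequences_without_binding_give_empty_list(self):
        n = 20
        seq = StateSequence(
            ribosome_state=np.array(["nonrotated"] * n, dtype=object),
            rf_i_bound=np.zeros(n, dtype=bool),
            rf3_bound=np.zeros(n, dtype=bool), frame_rate=10.0)
        assert extract_dwells(seq) == []

    def test_decomposition_identity_on_simulated_traces(self, rf1_20c, rf3_gtp):
        """t_iBD = t_iBR + t_iRD for every uncensored record over a large
        simulated set."""
        tls = simulate_timelines(rf1_20c, rf3_gtp, 0.075, 1, 1000, seed=17)
        checked = 0
        for tl in tls:
            tr = render_trace(tl, noise_sd=0.0, seed=0)
            recs = extract_dwells(idealize_trace(tr), bleach_times=tr.bleach_times)
            u = {r.dwell_class: r.duration for r in recs if not r.censored}
            if {"t_iBD", "t_iBR", "t_iRD"} <= set(u):
                # identical in frame counts (durations are frames * period)
                frames = {k: round(v * 10) for k, v in u.items()}
                assert frames["t_iBD"] == frames["t_iBR"] + frames["t_iRD"]
                assert abs(u["t_iBD"] - u["t_iBR"] - u["t_iRD"]) < 1e-9
                checked += 1
        assert checked > 500

    def test_round_trip_dwells_within_one_frame(self, rf1_20c, rf3_gtp):
        """simulate -> render (noiseless) -> idealize -> extract recovers
        every ground-truth class-I RF dwell to one frame period."""
        tls = simulate_timelines(rf1_20c, rf3_gtp, 0.075, 2, 200, seed=19)
        period = 0.1
        n_checked = 0
        for tl in tls:
            tr = render_trace(tl, noise_sd=0.0, seed=0)
            recs = extract_dwells(idealize_trace(tr), bleach_times=tr.bleach_times)
            u = {r.dwell_class: r.duration for r in recs if not r.censored}
            if tl.rf_i_bind is not None and tl.rf_i_dissoc is not None \
                    and "t_iBD" in u:
                truth = tl.rf_i_dissoc - tl.rf_i_bind
                assert abs(u["t_iBD"] - truth) <= period + 1e-12
                n_checked += 1
            if tl.rotation is not None and "t_iBR" in u:
                assert abs(u["t_iBR"] - (tl.rotation - tl.rf_i_bind)) \
                    <= period + 1e-12
        assert n_checked > 100

    def test_censoring_never_ends_after_bleach_or_on_last_frame(self, rf1_20c,
                                                                rf3_gtp):
        tls = simulate_timelines(rf1_20c, rf3_gtp, 0.075, 2, 100, seed=29)
        for i, tl in enumerate(tls):
            tr = render_trace(tl, noise_sd=0.0,
                              bleach_rates={"cy5_5": 0.02}, seed=300 + i)
            seq = idealize_trace(tr)
            recs = extract_dwells(seq, bleach_times=tr.bleach_times)
            n = seq.n_frames
            tb = tr.bleach_times.get("cy5_5")
            rf = seq.rf_i_bound
            f_bind = int(np.argmax(rf)) if rf.any() else None
            for r in recs:
                if r.censored:
                    continue
                assert r.duration < n / seq.frame_rate
                if r.dwell_class == "t_iBD" and tb is not None:
                    # uncensored dissociation must predate the bleach
                    end_s = f_bind / seq.frame_rate + r.duration
                    assert end_s <= tb + 0.1

    def test_bleach_censoring_flagged_with_reason(self):
        n = 100
        seq = StateSequence(
            ribosome_state=np.array(["nonrotated"] * n, dtype=object),
            rf_i_bound=np.array([False] * 10 + [True] * 60 + [False] * 30),
            rf3_bound=np.zeros(n, dtype=bool), frame_rate=10.0,
            metadata={"trace_id": "x"})
        recs = extract_dwells(seq, bleach_times={"cy5_5": 3.0})
        bd = [r for r in recs if r.dwell_class == "t_iBD"][0]
        assert bd.censored and bd.censor_reason == "photobleach"
        assert bd.duration <= 3.0 - 1.0 + 0.101  # truncated at the bleach


def test_dwell_record_validation():
    with pytest.raises(ValueError):
        DwellRecord("t", "t_iBD", -1.0, False, "none")
    with pytest.raises(ValueError):
        DwellRecord("t", "t_iBD", 1.0, True, "none")
    with pytest.raises(ValueError):
        DwellRecord("t", "nope", 1.0, False, "none")
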