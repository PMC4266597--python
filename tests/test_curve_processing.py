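"""Curve reduction: detection, loading rates, transforms and classification."""

import numpy as np
import pytest

import forcespec as fs
from forcespec.curve_processing import (
    ContourLengthHistogram,
    RuptureEvent,
    barrier_positions,
)
from forcespec.pipeline import RunConfig, analyze_curve
from forcespec.polymer_models import extension_model


def _sawtooth_curve(n_teeth=3, peak=100.0, samples=200, dt=1e-4):
    """Noiseless sawtooth: force ramps to ``peak`` then drops to zero."""
    force = np.tile(np.linspace(0.0, peak, samples), n_teeth)
    force = np.append(force, 0.0)
    t = np.arange(len(force)) * dt
    ext = np.linspace(0.0, 100.0, len(force))
    return fs.ForceCurve(time=t, extension=ext, force=force, pulling_speed=1000.0)


class TestDetection:
    def test_constructed_sawtooth(self):
        curve = _sawtooth_curve(n_teeth=3)
        events = fs.detect_unfolding_events(curve, min_drop=50.0)
        assert len(events) == 3
        assert events[-1].is_final
        assert all(e.force == pytest.approx(100.0) for e in events)

    def test_pure_noise_yields_nothing(self):
        rng = np.random.default_rng(0)
        n = 2000
        curve = fs.ForceCurve(
            time=np.arange(n) * 1e-4,
            extension=np.linspace(0, 100, n),
            force=rng.normal(0.0, 5.0, n),
            pulling_speed=1000.0,
        )
        assert fs.detect_unfolding_events(curve, min_drop=50.0) == []

    def test_matches_simulator_ground_truth(self, dataset_1600):
        curves, logs, _ = dataset_1600
        hits = total = 0
        for curve, log in zip(curves, logs):
            det_idx = np.array([e.index for e in fs.detect_unfolding_events(curve)])
            for ev in log.events:
                total += 1
                if len(det_idx) and np.min(np.abs(det_idx - ev.index)) <= 2:
                    hits += 1
        assert hits / total >= 0.98


class TestLoadingRate:
    def test_exact_line(self):
        t = np.linspace(0.0, 0.1, 200)
        curve = fs.ForceCurve(
            time=t, extension=t * 1000.0, force=1000.0 * t, pulling_speed=1000.0
        )
        ev = RuptureEvent(index=len(t) - 1, force=float(curve.force[-1]))
        assert fs.extract_loading_rate(curve, ev) == pytest.approx(1000.0, rel=1e-9)

    def test_too_few_samples_rejected(self):
        t = np.array([0.0, 1e-4, 2e-4])
        curve = fs.ForceCurve(
            time=t, extension=t * 1e3, force=np.array([0.0, 50.0, 100.0]),
            pulling_speed=1000.0,
        )
        with pytest.raises(ValueError):
            fs.extract_loading_rate(curve, RuptureEvent(index=2, force=100.0))

    def test_median_error_vs_ground_truth(self, dataset_1600):
        curves, logs, _ = dataset_1600
        cfg = RunConfig()
        rel = []
        for curve, log in zip(curves[:100], logs[:100]):
            res = analyze_curve(curve, cfg)
            fin = [e for e in res["events"] if e.is_final]
            rup = log.rupture
            if fin and rup is not None and np.isfinite(fin[0].loading_rate):
                rel.append(abs(fin[0].loading_rate - rup.loading_rate) / rup.loading_rate)
        assert len(rel) >= 90
        assert np.median(rel) < 0.10


class TestTransform:
    def test_single_state_model_curve(self, frc_params):
        L0 = 120.0
        forces = np.linspace(60.0, 400.0, 500)
        ext = extension_model(forces, L0, frc_params)
        curve = fs.ForceCurve(
            time=np.arange(500) * 1e-4, extension=ext, force=forces,
            pulling_speed=1000.0,
        )
        hist = fs.transform_to_contour_length(curve, frc_params, force_threshold=50.0)
        peak_center = hist.centers[np.argmax(hist.counts)]
        assert peak_center == pytest.approx(L0, abs=1.0)
        # essentially all mass in one bin for a noiseless model curve
        assert hist.counts.max() >= 0.99 * hist.total

    def test_two_state_trace_increment(self, frc_params):
        # simulated trace with a single 89-nm domain, no linker, no noise
        system = fs.SystemSpec(
            domains=(
                fs.DomainSpec("Xyn", 89.0, kinetics=fs.BellParams(1e-3, 0.45)),
            ),
            complex_intact=fs.BellParams(k_off=1e-4, delta_x=0.25),
            complex_shielded=None,
            shield_branch_probability=0.0,
            peg_contour=50.0,
        )
        protocol = fs.ProtocolSpec(pulling_speed=800.0, seed=4, force_noise_sd=0.0)
        curve, log = fs.simulate_trace(system, protocol)
        assert any(e.kind == "domain_unfold" for e in log.events)
        hist = fs.transform_to_contour_length(
            curve, system.polymer, force_threshold=50.0, linker_contour=50.0
        )
        peaks = fs.measure_increments(hist, prominence=0.05)
        incs = [inc for _, inc in peaks if np.isfinite(inc)]
        assert len(incs) >= 1
        assert min(abs(i - 89.0) for i in incs) < 2.0

    def test_all_below_threshold_warns_empty(self, frc_params):
        curve = fs.ForceCurve(
            time=np.arange(10) * 1e-4,
            extension=np.linspace(1, 5, 10),
            force=np.full(10, 20.0),
            pulling_speed=100.0,
        )
        with pytest.warns(UserWarning):
            hist = fs.transform_to_contour_length(curve, frc_params, force_threshold=50.0)
        assert hist.total == 0


class TestBarrierPositions:
    def test_positions_track_cumulative_increments(self, dataset_1600):
        curves, logs, _ = dataset_1600
        cfg = RunConfig()
        errors = []
        for curve, log in zip(curves[:30], logs[:30]):
            events = fs.detect_unfolding_events(curve)
            pos = barrier_positions(
                curve, events, cfg.polymer,
                force_threshold=cfg.force_threshold, linker_contour=cfg.peg_contour,
            )
            if len(pos) != len(log.events):
                continue
            incs = {"Xyn-1": 30.0, "Xyn-2": 30.0, "Xyn-3": 29.0, "CBM": 56.0, "XMod": 34.0}
            expected = 0.0
            for got, ev in zip(pos, log.events):
                if np.isfinite(got):
                    errors.append(got - expected)
                if ev.kind == "domain_unfold":
                    expected += incs[ev.name]
        assert len(errors) > 50
        assert abs(np.median(errors)) < 2.0


class TestMasterHistogram:
    def test_single_histogram_identity(self):
        h = ContourLengthHistogram(np.arange(0.0, 11.0), np.arange(10.0))
        master = fs.assemble_master_histogram([h])
        assert master.total == h.total
        assert h.offset == 0.0

    def test_recovers_constructed_shift(self):
        edges = np.arange(0.0, 51.0)
        counts = np.zeros(50)
        counts[[10, 25, 40]] = 100.0
        h1 = ContourLengthHistogram(edges, counts.copy())
        h2 = ContourLengthHistogram(edges + 5.0, counts.copy())  # shifted +5 nm
        master = fs.assemble_master_histogram([h1, h2], max_shift=10.0)
        assert h2.offset == pytest.approx(-5.0)
        idx = np.where(master.counts == 200.0)[0]
        assert len(idx) == 3  # peaks co-localized

    def test_incompatible_binning_rejected(self):
        h1 = ContourLengthHistogram(np.arange(0.0, 11.0), np.ones(10))
        h2 = ContourLengthHistogram(np.arange(0.0, 22.0, 2.0), np.ones(10))
        with pytest.raises(ValueError):
            fs.assemble_master_histogram([h1, h2])

    def test_order_insensitive_peaks(self, dataset_1600, frc_params):
        curves, _, _ = dataset_1600
        cfg = RunConfig()
        hists = []
        for curve in curves[:60]:
            events = fs.detect_unfolding_events(curve)
            end = events[-1].index if events else None
            hists.append(
                fs.transform_to_contour_length(
                    curve, cfg.polymer, force_threshold=cfg.force_threshold,
                    linker_contour=cfg.peg_contour, end_index=end,
                )
            )
        m1 = fs.assemble_master_histogram(list(hists))
        rng = np.random.default_rng(5)
        order = rng.permutation(len(hists))
        m2 = fs.assemble_master_histogram([hists[i] for i in order])
        p1 = [p for p, _ in fs.measure_increments(m1, prominence=0.05)]
        p2 = [p for p, _ in fs.measure_increments(m2, prominence=0.05)]
        assert len(p1) == len(p2)
        assert np.allclose(sorted(p1), sorted(p2), atol=1.0)


class TestIncrementsAndClassification:
    def test_increment_arithmetic(self):
        edges = np.arange(0.0, 121.0)
        counts = np.zeros(120)
        counts[10] = 50.0  # center 10.5
        counts[99] = 50.0  # center 99.5
        hist = ContourLengthHistogram(edges, counts)
        out = fs.measure_increments(hist, prominence=0.05)
        assert out[1][1] == pytest.approx(89.0)

    def test_single_peak_no_increments(self):
        edges = np.arange(0.0, 21.0)
        counts = np.zeros(20)
        counts[10] = 5.0
        with pytest.warns(UserWarning):
            out = fs.measure_increments(ContourLengthHistogram(edges, counts))
        assert all(not np.isfinite(inc) for _, inc in out)

    def test_classify_single_increment_fingerprint(self):
        match = fs.classify_fingerprint([90.0, 55.0], tolerance=8.0)
        assert match.label == "specific"
        assert match.history == "intact"

    def test_classify_empty(self):
        match = fs.classify_fingerprint([])
        assert match.label == "unclassified"

    def test_classify_shielded_with_xmod(self):
        match = fs.classify_fingerprint([90.0, 55.0, 34.0], tolerance=8.0)
        assert match.label == "specific"
        assert match.history == "shielded"

    def test_classify_three_step_xylanase(self):
        match = fs.classify_fingerprint([30.0, 30.0, 29.0, 56.0], tolerance=8.0)
        assert match.label == "specific"
        assert match.matches["Xyn"] == pytest.approx(89.0)
        assert match.matches["CBM"] == pytest.approx(56.0)

    def test_classify_interleaved_order(self):
        # CBM unfolding between the xylanase sub-steps
        match = fs.classify_fingerprint([30.0, 56.0, 30.0, 29.0], tolerance=8.0)
        assert match.label == "specific"
        assert match.matches["Xyn"] == pytest.approx(89.0)

    def test_classification_accuracy_on_simulated_traces(self, dataset_1600):
        curves, logs, _ = dataset_1600
        cfg = RunConfig()
        ok_specific = ok_history = n = 0
        for curve, log in zip(curves, logs):
            res = analyze_curve(curve, cfg)
            n += 1
            if res["match"].label == "specific":
                ok_specific += 1
                truth = "shielded" if log.shielded_path else "intact"
                if res["match"].history == truth:
                    ok_history += 1
        assert ok_specific / n >= 0.95
        assert ok_history / ok_specific >= 0.95

    def test_junk_traces_rarely_specific(self):
        system = fs.default_system()
        protocol = fs.ProtocolSpec(pulling_speed=1600.0, seed=55)
        curves, _, truth = fs.simulate_dataset(system, protocol, 200, junk_fraction=1.0)
        cfg = RunConfig()
        labels = [analyze_curve(c, cfg)["match"].label for c in curves]
        assert np.mean([lb == "specific" for lb in labels]) < 0.05

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            fs.classify_fingerprint([90.0], tolerance=0.0)
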