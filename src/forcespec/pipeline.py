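"""Orchestration: configuration and the simulation → reduction → fit chain.

``run_pipeline`` chains the full reduction the way the experimental data
were handled: event detection, contour-length transformation, master
histogram assembly, fingerprint classification with bond-history tagging,
loading-rate extraction, per-speed Gaussian modal fits, and the per-history
Bell-Evans dynamic-force-spectrum fits. The JSON report embeds the config
hash and master seed, so two runs from the same configuration are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curve_processing import (
    ContourLengthHistogram,
    ForceCurve,
    FingerprintMatch,
    assemble_master_histogram,
    barrier_positions,
    classify_fingerprint,
    detect_unfolding_events,
    extract_loading_rate,
    measure_increments,
    transform_to_contour_length,
)
from .io import read_curves, write_events_csv, write_histogram_csv
from .polymer_models import IncrementEntry, IncrementTable, PolymerParams
from .rupture_kinetics import BellEvansFit, ModalPoint, fit_bell_evans, fit_gaussian_mode

logger = logging.getLogger("forcespec")

__all__ = ["RunConfig", "run_pipeline", "analyze_curve", "build_modal_points"]


@dataclass
class RunConfig:
    """All knobs of one analysis run; every output embeds its hash."""

    curves_path: str = ""
    out_dir: str = "."
    # polymer / transform
    polymer: PolymerParams = field(default_factory=PolymerParams)
    force_threshold: float = 50.0   # pN, contour-length transform
    bin_width: float = 1.0          # nm
    correct_linkers: bool = True
    peg_contour: float = 64.0       # nm, total linker contour (both linkers)
    # detection
    min_drop: float = 30.0          # pN
    min_force: float = 50.0         # pN
    min_separation: float = 5.0     # nm
    window_fraction: float = 0.3    # loading-rate fit window
    # histogram assembly / increments
    max_shift: float = 10.0         # nm
    prominence: float = 0.05        # fraction of tallest bin
    # classification
    templates: IncrementTable = field(default_factory=IncrementTable)
    tolerance: float = 8.0          # nm
    required: tuple[str, ...] = ("Xyn", "CBM")
    shield_template: str = "XMod"
    # modal / Bell-Evans fits
    min_events_per_point: int = 10
    log_rate_fit: bool = True
    weight_by_counts: bool = False
    # bookkeeping
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        pol = raw.pop("polymer", {})
        if pol:
            qm = pol.pop("qm_correction", None)
            kwargs = dict(pol)
            if qm is not None:
                kwargs["qm_correction"] = tuple(qm) if qm else None
            cfg.polymer = dataclasses.replace(cfg.polymer, **kwargs)
        tmpl = raw.pop("templates", None)
        if tmpl:
            entries = tuple(
                IncrementEntry(e["name"], int(e["residue_count"]), float(e["folded_length"]))
                for e in tmpl.get("entries", [])
            )
            cfg.templates = IncrementTable(
                entries=entries or cfg.templates.entries,
                residue_length=float(tmpl.get("residue_length", cfg.templates.residue_length)),
            )
        for section in raw.values() if all(isinstance(v, dict) for v in raw.values()) else [raw]:
            for key, val in (section.items() if isinstance(section, dict) else []):
                if hasattr(cfg, key):
                    cur = getattr(cfg, key)
                    if isinstance(cur, tuple):
                        val = tuple(val)
                    setattr(cfg, key, val)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["polymer"]["model"] = self.polymer.model.value
        d["polymer"]["qm_correction"] = (
            list(self.polymer.qm_correction) if self.polymer.qm_correction else None
        )
        d["templates"] = {
            "residue_length": self.templates.residue_length,
            "entries": [dataclasses.asdict(e) for e in self.templates.entries],
        }
        d["required"] = list(self.required)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths and logging excluded)."""
        d = self.to_dict()
        for key in ("curves_path", "out_dir", "log_level"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def analyze_curve(curve: ForceCurve, config: RunConfig) -> dict:
    """Reduce one curve: events, loading rates, increments, classification.

    Returns a dict with the detected events, the per-curve contour-length
    histogram (truncated at the final rupture), the measured increments and
    the fingerprint/bond-history classification.
    """
    events = detect_unfolding_events(
        curve,
        min_drop=config.min_drop,
        min_force=config.min_force,
        min_separation=config.min_separation,
    )
    for ev in events:
        try:
            ev.loading_rate = extract_loading_rate(
                curve, ev, window_fraction=config.window_fraction
            )
        except ValueError:
            ev.loading_rate = float("nan")
    end_index = events[-1].index if events else None
    linker = config.peg_contour if config.correct_linkers else 0.0
    hist = transform_to_contour_length(
        curve,
        config.polymer,
        force_threshold=config.force_threshold,
        bin_width=config.bin_width,
        linker_contour=linker,
        end_index=end_index,
    )
    peaks = measure_increments(hist, prominence=config.prominence)
    # classification uses per-state (inter-event segment) barrier positions,
    # which are robust on single curves; the histogram feeds the master
    positions = barrier_positions(
        curve,
        events,
        config.polymer,
        force_threshold=config.force_threshold,
        linker_contour=linker,
    )
    finite = [p for p in positions if np.isfinite(p)]
    increments = list(np.diff(finite)) if len(finite) >= 2 else []
    match = classify_fingerprint(
        increments,
        templates=config.templates,
        tolerance=config.tolerance,
        required=config.required,
        shield_template=config.shield_template,
    )
    for ev in events:
        if ev.is_final:
            ev.history = match.history
    return {
        "curve": curve,
        "events": events,
        "histogram": hist,
        "peaks": peaks,
        "positions": positions,
        "match": match,
    }


def build_modal_points(
    events: pd.DataFrame,
    history: str,
    min_events: int = 10,
    log_rate: bool = True,
) -> list[ModalPoint]:
    """Per-pulling-speed Gaussian modal points for one history class."""
    sel = events[(events["is_final"]) & (events["history"] == history)]
    sel = sel[np.isfinite(sel["loading_rate_pN_s"]) & (sel["loading_rate_pN_s"] > 0)]
    points: list[ModalPoint] = []
    for speed, grp in sel.groupby("pulling_speed_nm_s"):
        if len(grp) < min_events:
            logger.debug("skipping speed %s for %s: %d events", speed, history, len(grp))
            continue
        try:
            f_mode, f_sd = fit_gaussian_mode(grp["force_pN"].to_numpy())
            r_mode, _ = fit_gaussian_mode(
                grp["loading_rate_pN_s"].to_numpy(), log=log_rate
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("modal fit failed at speed %s (%s): %s", speed, history, exc)
            continue
        points.append(
            ModalPoint(
                pulling_speed=float(speed),
                most_probable_force=f_mode,
                most_probable_loading_rate=r_mode,
                force_sd=f_sd,
                n_events=len(grp),
            )
        )
    return points


def run_pipeline(config: RunConfig, curves: list[ForceCurve] | None = None) -> dict:
    """Execute the full reduction and write report + tables to ``out_dir``.

    ``curves`` may be passed directly (e.g. fresh from the simulator);
    otherwise they are read from ``config.curves_path``. Any stage failure
    raises with the stage name in the message.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return _time.perf_counter()

    t0 = stage("read")
    if curves is None:
        try:
            curves = read_curves(config.curves_path)
        except (OSError, ValueError) as exc:
            raise RuntimeError(f"stage 'read' failed: {exc}") from exc
    n_total = len(curves)
    logger.info("read %d curves in %.2fs", n_total, _time.perf_counter() - t0)

    t0 = stage("reduce")
    rows: list[dict] = []
    specific_hists: list[ContourLengthHistogram] = []
    n_with_events = 0
    n_specific = 0
    history_counts = {"intact": 0, "shielded": 0}
    try:
        for curve in curves:
            res = analyze_curve(curve, config)
            if res["events"]:
                n_with_events += 1
            match: FingerprintMatch = res["match"]
            if match.label == "specific":
                n_specific += 1
                specific_hists.append(res["histogram"])
                if match.history in history_counts:
                    history_counts[match.history] += 1
            for ev in res["events"]:
                rows.append(
                    {
                        "curve_id": curve.curve_id,
                        "index": ev.index,
                        "force_pN": ev.force,
                        "loading_rate_pN_s": ev.loading_rate,
                        "domain": ev.assigned_domain or "",
                        "history": ev.history if ev.is_final else "",
                        "is_final": ev.is_final,
                        "label": match.label,
                        "pulling_speed_nm_s": curve.pulling_speed,
                    }
                )
    except Exception as exc:
        raise RuntimeError(f"stage 'reduce' failed: {exc}") from exc
    events_df = pd.DataFrame(
        rows,
        columns=[
            "curve_id", "index", "force_pN", "loading_rate_pN_s", "domain",
            "history", "is_final", "label", "pulling_speed_nm_s",
        ],
    )
    logger.info("reduced in %.2fs", _time.perf_counter() - t0)

    t0 = stage("assemble")
    master = None
    master_peaks: list[tuple[float, float]] = []
    master_match: FingerprintMatch | None = None
    if specific_hists:
        try:
            master = assemble_master_histogram(specific_hists, max_shift=config.max_shift)
            master_peaks = measure_increments(master, prominence=config.prominence)
            incs = [inc for _, inc in master_peaks if np.isfinite(inc)]
            master_match = classify_fingerprint(
                incs,
                templates=config.templates,
                tolerance=config.tolerance,
                required=config.required,
                shield_template=config.shield_template,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'assemble' failed: {exc}") from exc
    logger.info("assembled in %.2fs", _time.perf_counter() - t0)

    t0 = stage("fit")
    fits: dict[str, dict] = {}
    n_fitted = 0
    for history in ("intact", "shielded"):
        points = build_modal_points(
            events_df[events_df["label"] == "specific"],
            history,
            min_events=config.min_events_per_point,
            log_rate=config.log_rate_fit,
        )
        if len(points) < 3:
            logger.info("not enough modal points for %s fit (%d)", history, len(points))
            continue
        try:
            fit = fit_bell_evans(
                points,
                kBT=config.polymer.kBT,
                history_class=history,
                weight_by_counts=config.weight_by_counts,
            )
        except ValueError as exc:
            logger.warning("Bell-Evans fit failed for %s: %s", history, exc)
            continue
        fits[history] = fit.to_dict()
        n_fitted += sum(p.n_events for p in points)
    logger.info("fits done in %.2fs", _time.perf_counter() - t0)

    report = {
        "provenance": {
            "package": "forcespec",
            "version": __version__,
            "config_hash": config.config_hash,
            "seed": config.seed,
            "numpy": np.__version__,
        },
        "counts": {
            "curves_total": n_total,
            "curves_with_events": n_with_events,
            "curves_specific": n_specific,
            "history": history_counts,
            "events_fitted": n_fitted,
        },
        "master_histogram": {
            "peaks_nm": [p for p, _ in master_peaks],
            "increments_nm": [inc for _, inc in master_peaks if np.isfinite(inc)],
            "fingerprint_matches_nm": master_match.matches if master_match else {},
        },
        "fits": fits,
        "config": config.to_dict(),
    }

    write_events_csv(out_dir / "events.csv", events_df)
    if master is not None:
        write_histogram_csv(out_dir / "master_histogram.csv", master)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
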