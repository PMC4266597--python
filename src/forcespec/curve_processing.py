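"""Force-curve data reduction.

Implements the reduction chain applied to constant-speed pulling traces:

1. sawtooth segmentation — detect unfolding/rupture peaks as local force
   maxima followed by a sharp drop;
2. loading-rate extraction — line fit to force vs time just before a peak;
3. contour-length transformation — map every (force, extension) sample above
   a force threshold to an apparent contour length via the QM-FRC model,
   optionally after subtracting the modelled WLC extension of the PEG
   linkers (see docs/methods.md on why the composite chain is corrected);
4. cross-correlation assembly of per-curve contour-length histograms into a
   master barrier-position histogram;
5. increment measurement (peak-to-peak spacings) and fingerprint
   classification against an increment template table, including the bond
   history of the final rupture (intact vs shielded by XMod unfolding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .polymer_models import (
    ChainModel,
    IncrementTable,
    PolymerParams,
    apparent_contour_length,
    wlc_extension_ratio,
)

__all__ = [
    "ForceCurve",
    "RuptureEvent",
    "ContourLengthHistogram",
    "detect_unfolding_events",
    "extract_loading_rate",
    "transform_to_contour_length",
    "barrier_positions",
    "assemble_master_histogram",
    "measure_increments",
    "classify_fingerprint",
    "FingerprintMatch",
]


@dataclass
class ForceCurve:
    """One constant-speed pulling trace.

    ``extension`` is the tip-surface separation corrected for cantilever
    deflection (i.e. the polymer end-to-end distance), zero at contact.
    """

    time: np.ndarray        # s
    extension: np.ndarray   # nm
    force: np.ndarray       # pN
    pulling_speed: float    # nm/s
    curve_id: str = ""
    configuration: str = "I"  # I | II | unknown

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = len(self.time)
        if not (len(self.extension) == len(self.force) == n) or n < 2:
            raise ValueError("time/extension/force must have equal length >= 2")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class RuptureEvent:
    """A detected unfolding or rupture peak."""

    index: int
    force: float                 # pN, peak force
    loading_rate: float = np.nan  # pN/s; NaN until extracted
    is_final: bool = False
    assigned_domain: str | None = None
    history: str = "unassigned"  # intact | shielded | unassigned


@dataclass
class ContourLengthHistogram:
    """Histogram of apparent contour length (barrier positions)."""

    bin_edges: np.ndarray   # nm, uniform width, strictly increasing
    counts: np.ndarray
    offset: float = 0.0     # nm, alignment shift that was applied
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(widths) and not np.allclose(widths, widths[0]):
            raise ValueError("bins must have uniform width")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def detect_unfolding_events(
    curve: ForceCurve,
    min_drop: float = 30.0,
    min_force: float = 50.0,
    min_separation: float = 5.0,
) -> list[RuptureEvent]:
    """Segment a sawtooth trace into unfolding/rupture events.

    Unfolding relaxes the force essentially instantaneously, so an event is
    localized by a sharp *drop*: sample ``j`` is an event when its force is
    at least ``min_force`` pN, the single-step fall ``f[j] - f[j+1]`` is at
    least ``min_drop / 2``, and the force stays at least ``min_drop`` below
    ``f[j]`` over the following few samples (median, robust to noise).
    Candidates closer than ``min_separation`` nm of extension are merged,
    keeping the largest drop. A trace that *ends* above ``min_force`` pN is
    treated as truncated at its final rupture peak (the last sample), the
    convention for simulated traces; real traces that return to baseline
    after rupture show the rupture as an ordinary drop instead.

    The last detected event is flagged ``is_final``. An empty list is
    returned for featureless traces.
    """
    f = curve.force
    x = curve.extension
    n = len(f)
    events: list[RuptureEvent] = []
    if n >= 3:
        k = min(5, n - 1)
        # robust post-drop level: median of the next up-to-k samples
        padded = np.concatenate([f[1:], np.full(k - 1, f[-1])])
        post = np.median(np.lib.stride_tricks.sliding_window_view(padded, k), axis=1)
        step_fall = f[:-1] - f[1:]
        cand = np.where(
            (f[:-1] >= min_force)
            & (step_fall >= min_drop / 2.0)
            & (f[:-1] - post >= min_drop)
        )[0]
        for j in cand:
            drop = float(step_fall[j])
            if events and abs(x[j] - x[events[-1].index]) < min_separation:
                prev = events[-1]
                prev_drop = float(f[prev.index] - f[prev.index + 1])
                if drop > prev_drop:
                    events[-1] = RuptureEvent(index=int(j), force=float(f[j]))
                continue
            events.append(RuptureEvent(index=int(j), force=float(f[j])))
    # terminal rupture: trace truncated while still under load
    if n >= 3 and float(np.median(f[-3:])) >= min_force:
        last = n - 1
        if not events or abs(x[last] - x[events[-1].index]) >= min_separation:
            events.append(RuptureEvent(index=int(last), force=float(f[last])))
    if events:
        events[-1].is_final = True
    return events


def extract_loading_rate(
    curve: ForceCurve,
    event: RuptureEvent,
    window_fraction: float = 0.3,
    min_samples: int = 5,
    min_rise: float = 20.0,
) -> float:
    """Loading rate (pN/s) from a line fit to force vs time before a peak.

    The fit window spans the final ``window_fraction`` of the force rise to
    the peak (from the preceding valley), mirroring the 'immediate vicinity
    before the rupture peak' convention. The valley search runs on a lightly
    smoothed trace and only terminates once a rise of at least ``min_rise``
    pN has accumulated, so force noise cannot truncate the window.
    """
    i = event.index
    f = curve.force[: i + 1]
    t = curve.time[: i + 1]
    if len(f) < min_samples:
        raise ValueError("too few samples before the event")
    w = min(9, len(f))
    kernel = np.ones(w) / w
    f_s = np.convolve(np.pad(f, (w // 2, w // 2), mode="edge"), kernel, mode="valid")[
        : len(f)
    ]
    peak = max(float(f[i]), float(f_s[i]))
    # walk back from the peak to the preceding valley of this force rise;
    # stop once the (smoothed) force climbs the flank of the previous peak
    valley = i
    for j in range(i - 1, -1, -1):
        if f_s[j] < f_s[valley]:
            valley = j
        elif (peak - f_s[valley]) > min_rise and f_s[j] > f_s[valley] + 0.5 * (
            peak - f_s[valley]
        ):
            break
    lo_force = f_s[valley] + (1.0 - window_fraction) * (peak - f_s[valley])
    sel = np.arange(valley, i + 1)
    sel = sel[f_s[sel] >= lo_force]
    if len(sel) < min_samples:
        sel = np.arange(max(valley, i - min_samples + 1), i + 1)
    if len(sel) < min_samples:
        raise ValueError("too few samples in the loading-rate window")
    tt, ff = t[sel], f[sel]
    if np.ptp(tt) == 0:
        raise ValueError("zero time variance in the loading-rate window")
    slope = float(np.polyfit(tt, ff, 1)[0])
    return slope


def _linker_extension(force: np.ndarray, linker_contour: float, params: PolymerParams) -> np.ndarray:
    wlc = PolymerParams(
        model=ChainModel.WLC,
        persistence_length=params.persistence_length,
        kBT=params.kBT,
        qm_correction=None,
    )
    return linker_contour * wlc_extension_ratio(np.maximum(force, 0.0), wlc)


def transform_to_contour_length(
    curve: ForceCurve,
    params: PolymerParams,
    force_threshold: float = 50.0,
    bin_width: float = 1.0,
    linker_contour: float = 0.0,
    end_index: int | None = None,
) -> ContourLengthHistogram:
    """Per-curve histogram of apparent contour length.

    Every sample with ``force > force_threshold`` (and positive extension)
    is mapped through the QM-FRC transform; with ``linker_contour > 0`` the
    modelled WLC extension of the PEG linkers at the sample force is
    subtracted first, so the histogram is in protein contour length with the
    linker contribution removed. ``end_index`` truncates the trace (e.g. at
    the final rupture).
    """
    stop = len(curve) if end_index is None else int(end_index) + 1
    f = curve.force[:stop]
    x = curve.extension[:stop]
    ok = (f > force_threshold) & (x > 0)
    if not np.any(ok):
        warnings.warn("no samples above the force threshold; empty histogram", stacklevel=2)
        edges = np.array([0.0, bin_width])
        return ContourLengthHistogram(edges, np.zeros(1), source_ids=(curve.curve_id,))
    fo, xo = f[ok], x[ok]
    if linker_contour > 0:
        xo = xo - _linker_extension(fo, linker_contour, params)
    L = apparent_contour_length(fo, xo, params, force_threshold=force_threshold)
    L = L[np.isfinite(L)]
    if len(L) == 0:
        edges = np.array([0.0, bin_width])
        return ContourLengthHistogram(edges, np.zeros(1), source_ids=(curve.curve_id,))
    # negative apparent lengths are noise around the contact baseline; keep
    # them so the baseline peak stays centred instead of half-clipped
    lo = (np.floor(L.min() / bin_width) - 0.5) * bin_width
    hi = (np.floor(L.max() / bin_width) + 1.5) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(L, bins=edges)
    return ContourLengthHistogram(edges, counts.astype(float), source_ids=(curve.curve_id,))


def barrier_positions(
    curve: ForceCurve,
    events: Sequence[RuptureEvent],
    params: PolymerParams,
    force_threshold: float = 50.0,
    linker_contour: float = 0.0,
    min_samples: int = 3,
) -> list[float]:
    """Apparent contour length of each folding state, one per event.

    The trace is split at the detected events; the state *preceding* event
    ``i`` is summarized by the median apparent contour length of its samples
    above the force threshold (median: robust to the low-force tails).
    States with fewer than ``min_samples`` usable samples yield NaN.
    """
    positions: list[float] = []
    start = 0
    for ev in events:
        f = curve.force[start : ev.index + 1]
        x = curve.extension[start : ev.index + 1]
        ok = (f > force_threshold) & (x > 0)
        if np.count_nonzero(ok) < min_samples:
            positions.append(float("nan"))
        else:
            fo, xo = f[ok], x[ok]
            if linker_contour > 0:
                xo = xo - _linker_extension(fo, linker_contour, params)
            L = apparent_contour_length(fo, xo, params, force_threshold=force_threshold)
            positions.append(float(np.nanmedian(L)))
        start = ev.index + 1
    return positions


def _on_common_grid(
    h: ContourLengthHistogram, lo: float, n: int, width: float
) -> np.ndarray:
    out = np.zeros(n)
    start = int(round((h.bin_edges[0] - lo) / width))
    stop = start + len(h.counts)
    s0, s1 = max(start, 0), min(stop, n)
    if s1 > s0:
        out[s0:s1] = h.counts[s0 - start : s1 - start]
    return out


def assemble_master_histogram(
    histograms: Sequence[ContourLengthHistogram],
    max_shift: float = 10.0,
) -> ContourLengthHistogram:
    """Cross-correlation assembly of a master barrier-position histogram.

    The first histogram seeds the master; each subsequent one is shifted by
    the integer-bin offset (within ``+/- max_shift`` nm) that maximizes its
    cross-correlation with the running master, then added. Ties are broken
    toward the smaller |shift|. Offsets are recorded on the inputs.
    """
    if len(histograms) == 0:
        raise ValueError("need at least one histogram")
    width = histograms[0].bin_width
    phase = histograms[0].bin_edges[0] % width
    for h in histograms:
        if not np.isclose(h.bin_width, width):
            raise ValueError("histograms must share a common bin width")
        dphase = (h.bin_edges[0] - phase) / width
        if not np.isclose(dphase, round(dphase), atol=1e-6):
            raise ValueError("histogram bin grids are not commensurate")
    lo = min(h.bin_edges[0] for h in histograms) - max_shift - width
    hi = max(h.bin_edges[-1] for h in histograms) + max_shift + width
    lo = phase + np.floor((lo - phase) / width) * width
    n = int(round((hi - lo) / width)) + 1
    max_lag = int(round(max_shift / width))

    master = _on_common_grid(histograms[0], lo, n, width)
    histograms[0].offset = 0.0
    ids: list[str] = list(histograms[0].source_ids)
    for h in histograms[1:]:
        g = _on_common_grid(h, lo, n, width)
        if master.sum() == 0 or g.sum() == 0:
            best_lag = 0
        else:
            lags = np.arange(-max_lag, max_lag + 1)
            scores = np.array(
                [np.dot(master, np.roll(g, lag)) for lag in lags]
            )
            # ties toward the smallest |shift|
            order = np.lexsort((np.abs(lags), -scores))
            best_lag = int(lags[order[0]])
        h.offset = best_lag * width
        master = master + np.roll(g, best_lag)
        ids.extend(h.source_ids)
    edges = lo + width * np.arange(n + 1)
    return ContourLengthHistogram(edges, master, source_ids=tuple(ids))


def measure_increments(
    master: ContourLengthHistogram,
    prominence: float = 0.05,
    min_distance: float = 5.0,
) -> list[tuple[float, float]]:
    """Peak positions and successive peak-to-peak increments (nm).

    Peaks are found by prominence-based detection (``prominence`` is a
    fraction of the tallest bin); returns ``[(peak_nm, increment_nm), ...]``
    where the increment is the spacing to the *previous* peak (NaN for the
    first). Fewer than two peaks yields no increments, with a warning.
    """
    if master.total == 0:
        warnings.warn("empty master histogram; no peaks", stacklevel=2)
        return []
    counts = master.counts
    dist = max(1, int(round(min_distance / master.bin_width)))
    idx, _ = find_peaks(
        counts, prominence=prominence * counts.max(), distance=dist
    )
    centers = master.centers[idx]
    if len(centers) < 2:
        if len(centers) == 1:
            warnings.warn("single peak: no increments measurable", stacklevel=2)
            return [(float(centers[0]), float("nan"))]
        warnings.warn("no peaks found", stacklevel=2)
        return []
    out: list[tuple[float, float]] = [(float(centers[0]), float("nan"))]
    for prev, cur in zip(centers[:-1], centers[1:]):
        out.append((float(cur), float(cur - prev)))
    return out


@dataclass(frozen=True)
class FingerprintMatch:
    """Result of matching measured increments against a template table."""

    label: str                      # specific | unclassified
    history: str                    # intact | shielded | unassigned
    matches: dict                   # template name -> matched summed increment (nm)
    increments: tuple[float, ...]   # measured increments used


def classify_fingerprint(
    increments: Sequence[float],
    templates: IncrementTable | None = None,
    tolerance: float = 8.0,
    required: Sequence[str] = ("Xyn", "CBM"),
    shield_template: str = "XMod",
    max_parts: int = 3,
) -> FingerprintMatch:
    """Match measured increments to fingerprint templates; tag bond history.

    Each template is matched to a disjoint subset of up to ``max_parts``
    measured increments whose sum lies within ``tolerance`` of the template
    value. Subsets rather than single increments let a multi-peaked
    fingerprint (the three-step xylanase) match its total increment even
    when another domain unfolds in between; a subset of size one is the
    ordinary case. The assignment is chosen globally: maximize the number of
    matched templates, then minimize the total |error|, then the number of
    increments consumed — so an exact multi-part sum cannot steal the
    increments another template needs.

    The curve is labelled ``specific`` when every template in ``required``
    matched; history is ``shielded`` when the XMod template also matched
    (XMod unfolded before the final rupture), else ``intact``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if templates is None:
        templates = IncrementTable()
    inc = [float(v) for v in increments if np.isfinite(v)]
    targets = sorted(templates.increments().items(), key=lambda kv: -kv[1])

    # per-template candidate subsets within tolerance
    candidates: list[list[tuple[float, tuple[int, ...]]]] = []
    for _, target in targets:
        opts: list[tuple[float, tuple[int, ...]]] = []
        for nparts in range(1, max_parts + 1):
            for idx in combinations(range(len(inc)), nparts):
                err = abs(sum(inc[k] for k in idx) - target)
                if err <= tolerance:
                    opts.append((err, idx))
        opts.sort()
        candidates.append(opts)

    best_score: tuple[int, float, int] | None = None  # (-matched, err, parts)
    best_assign: list[tuple[int, ...] | None] = [None] * len(targets)

    def search(ti: int, used: frozenset, assign: list, matched: int, err: float, parts: int):
        nonlocal best_score, best_assign
        if ti == len(targets):
            score = (-matched, err, parts)
            if best_score is None or score < best_score:
                best_score = score
                best_assign = list(assign)
            return
        # bound: even matching all remaining templates cannot beat best
        if best_score is not None and -(matched + len(targets) - ti) > best_score[0]:
            return
        for cerr, idx in candidates[ti]:
            if used.isdisjoint(idx):
                assign.append(idx)
                search(ti + 1, used | frozenset(idx), assign, matched + 1,
                       err + cerr, parts + len(idx))
                assign.pop()
        assign.append(None)
        search(ti + 1, used, assign, matched, err, parts)
        assign.pop()

    search(0, frozenset(), [], 0, 0.0, 0)
    matches: dict[str, float] = {}
    for (name, _), idx in zip(targets, best_assign):
        if idx is not None:
            matches[name] = float(sum(inc[k] for k in idx))
    if inc and all(name in matches for name in required):
        label = "specific"
        history = "shielded" if shield_template in matches else "intact"
    else:
        label = "unclassified"
        history = "unassigned"
    return FingerprintMatch(
        label=label, history=history, matches=matches, increments=tuple(inc)
    )
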