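"""Kinetic Monte Carlo simulation of constant-speed AFM pulling.

The simulated mechanical circuit is the experimental one: a cantilever
(Hookean spring, stiffness ``k_c``) in series with two PEG linkers (WLC) and
a polyprotein whose unfolded polypeptide stretches as a QM-FRC chain. At
piezo separation ``z = v t`` the force follows from the series force
balance

    z = F / k_c + x_peg(F) + L_unfolded * x_frc(F) / L,

solved on a precomputed monotone ``z(F)`` grid. Domain unfolding and
complex rupture are stochastic with Bell kinetics ``k(F)``; event times are
drawn by inverting the cumulative hazard accumulated along the force
schedule (exact for rates piecewise-constant over one time step), so no
per-step event probability ever needs to stay small.

Bond history is reproduced by an explicit branch: a fraction
``shield_branch_probability`` of traces takes the two-step pathway in which
the XMod domain unfolds first and the final rupture is governed by the
'shielded' kinetics; the remainder rupture with XMod intact. An emergent
mode where all channels simply compete is available behind a flag
(``emergent_competition``) — see docs/methods.md for why the explicit
branch is the default.

The xylanase fingerprint is modelled as three sequential sub-domain
unfolding steps (30 + 30 + 29 nm by default) so traces show the
characteristic three-peaked pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curve_processing import ForceCurve
from .polymer_models import (
    ChainModel,
    PolymerParams,
    backbone_stretch_factor,
    wlc_extension_ratio,
)
from .rupture_kinetics import (
    INTACT_COMPLEX,
    SHIELDED_COMPLEX,
    XMOD_UNFOLDING,
    BellParams,
)

__all__ = [
    "DomainSpec",
    "SystemSpec",
    "ProtocolSpec",
    "Event",
    "EventLog",
    "default_system",
    "default_protocol",
    "simulate_trace",
    "simulate_dataset",
    "random_junk_system",
]

_MAX_FORCE = 2500.0  # pN, top of the force-balance grid


@dataclass(frozen=True)
class DomainSpec:
    """One unfoldable (sub-)domain of the polyprotein."""

    name: str
    delta_Lc: float            # unfolding contour-length increment, nm
    folded_length: float = 3.0  # nm (bookkeeping; rigid in the force balance)
    kinetics: BellParams = BellParams(k_off=1e-3, delta_x=0.45)
    refoldable: bool = True
    shields_complex: bool = False  # its unfolding switches rupture kinetics

    def __post_init__(self) -> None:
        if self.delta_Lc <= 0:
            raise ValueError("delta_Lc must be positive")


@dataclass(frozen=True)
class SystemSpec:
    """Mechanical ground truth of the simulated pulling construct."""

    domains: tuple[DomainSpec, ...]
    complex_intact: BellParams | None = INTACT_COMPLEX
    complex_shielded: BellParams | None = SHIELDED_COMPLEX
    shield_branch_probability: float = 0.375
    peg_contour: float = 64.0       # nm, total for both linkers
    peg_persistence: float = 0.38   # nm
    cantilever_stiffness: float = 50.0  # pN/nm
    polymer: PolymerParams = PolymerParams()
    emergent_competition: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.shield_branch_probability <= 1.0:
            raise ValueError("shield_branch_probability must be in [0, 1]")
        if self.cantilever_stiffness <= 0:
            raise ValueError("cantilever stiffness must be positive")
        if self.peg_contour < 0:
            raise ValueError("peg_contour must be non-negative")


@dataclass(frozen=True)
class ProtocolSpec:
    """Constant-speed pulling protocol."""

    pulling_speed: float            # nm/s
    sampling_rate: float = 25_000.0  # 1/s, output rate
    force_noise_sd: float = 5.0     # pN
    max_extension: float = 400.0    # nm of piezo travel
    time_step: float = 1e-5         # s, internal KMC step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pulling_speed <= 0:
            raise ValueError("pulling speed must be positive")
        if self.time_step > 1.0 / self.sampling_rate + 1e-15:
            raise ValueError("time_step must be <= 1/sampling_rate")


@dataclass(frozen=True)
class Event:
    time: float          # s
    index: int           # sample index in the emitted ForceCurve
    force: float         # pN, as reported in the curve (incl. noise)
    kind: str            # domain_unfold | complex_rupture
    name: str            # domain name, or 'complex'
    loading_rate: float  # pN/s, true instantaneous dF/dt at the event
    force_true: float    # pN, noise-free model force


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)
    shielded_path: bool = False

    def validate(self) -> None:
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        ruptures = [i for i, e in enumerate(self.events) if e.kind == "complex_rupture"]
        if len(ruptures) > 1 or (ruptures and ruptures[0] != len(self.events) - 1):
            raise ValueError("complex rupture must be unique and last")

    @property
    def rupture(self) -> Event | None:
        if self.events and self.events[-1].kind == "complex_rupture":
            return self.events[-1]
        return None

    def unfolded_names(self) -> list[str]:
        return [e.name for e in self.events if e.kind == "domain_unfold"]


def default_system() -> SystemSpec:
    """Configuration-I construct: three-peaked Xyn, CBM, XMod, Doc:Coh."""
    xyn_kin = BellParams(k_off=1e-3, delta_x=0.45)
    cbm_kin = BellParams(k_off=5e-4, delta_x=0.40)
    return SystemSpec(
        domains=(
            DomainSpec("Xyn-1", 30.0, kinetics=xyn_kin, refoldable=False),
            DomainSpec("Xyn-2", 30.0, kinetics=xyn_kin, refoldable=False),
            DomainSpec("Xyn-3", 29.0, kinetics=xyn_kin, refoldable=False),
            DomainSpec("CBM", 56.0, kinetics=cbm_kin),
            DomainSpec(
                "XMod", 34.0, kinetics=XMOD_UNFOLDING, shields_complex=True
            ),
        ),
    )


def default_protocol(
    pulling_speed: float = 1600.0, seed: int = 0, **kwargs
) -> ProtocolSpec:
    return ProtocolSpec(pulling_speed=pulling_speed, seed=seed, **kwargs)


def _frc_ratio_clipped(force: np.ndarray, params: PolymerParams) -> np.ndarray:
    """FRC fractional extension, clipped to [0, 1) at sub-validity forces."""
    f = np.maximum(np.asarray(force, dtype=float), 1e-12)
    p = params.frc_persistence
    low = 1.0 - np.sqrt(params.kBT / (4.0 * f * p))
    high = 1.0 - params.kBT / (2.0 * f * params.b)
    return np.clip(np.where(f < params.frc_regime_boundary, low, high), 0.0, 1.0)


class _ForceBalance:
    """Precomputed monotone z(F) grid for the series elastic circuit."""

    def __init__(self, system: SystemSpec):
        self.system = system
        self.f_grid = np.concatenate(
            [[0.0], np.geomspace(1e-3, 20.0, 600), np.arange(20.25, _MAX_FORCE, 0.25)]
        )
        pol = system.polymer
        self.unit_prot = _frc_ratio_clipped(self.f_grid, pol) * backbone_stretch_factor(
            self.f_grid, pol
        )
        if system.peg_contour > 0:
            wlc = PolymerParams(
                model=ChainModel.WLC,
                persistence_length=system.peg_persistence,
                kBT=pol.kBT,
                qm_correction=None,
            )
            self.x_peg = system.peg_contour * wlc_extension_ratio(self.f_grid, wlc)
        else:
            self.x_peg = np.zeros_like(self.f_grid)

    def z_of_f(self, unfolded_contour: float) -> np.ndarray:
        return (
            self.f_grid / self.system.cantilever_stiffness
            + self.x_peg
            + unfolded_contour * self.unit_prot
        )

    def force_at(self, z: np.ndarray, unfolded_contour: float) -> np.ndarray:
        zg = self.z_of_f(unfolded_contour)
        return np.interp(z, zg, self.f_grid)

    def loading_rate_at(self, force: float, unfolded_contour: float, speed: float) -> float:
        zg = self.z_of_f(unfolded_contour)
        dzdf = np.gradient(zg, self.f_grid)
        return speed / float(np.interp(force, self.f_grid, dzdf))


def _clipped_rates(force: np.ndarray, p: BellParams, kBT: float) -> np.ndarray:
    expo = np.minimum(np.log(p.k_off) + force * p.delta_x / kBT, 700.0)
    return np.exp(expo)


def simulate_trace(
    system: SystemSpec,
    protocol: ProtocolSpec,
    rng: np.random.Generator | None = None,
) -> tuple[ForceCurve, EventLog]:
    """Simulate one constant-speed pulling trace.

    Returns the (noisy) force curve with extension corrected for cantilever
    deflection, plus the ground-truth event log. Event samples are always
    included in the output sampling grid, so the logged event force equals
    the curve force at the event index.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    fb = _ForceBalance(system)
    kBT = system.polymer.kBT
    v = protocol.pulling_speed
    dt = protocol.time_step
    n_steps = int(math.ceil(protocol.max_extension / (v * dt)))

    shielded_path = False
    if (
        not system.emergent_competition
        and any(d.shields_complex for d in system.domains)
        and system.complex_shielded is not None
    ):
        shielded_path = bool(rng.random() < system.shield_branch_probability)

    folded = list(system.domains)
    if not system.emergent_competition and not shielded_path:
        folded = [d for d in folded if not d.shields_complex]
    shield_folded = any(d.shields_complex for d in folded)
    unfolded_contour = 0.0

    times = np.arange(1, n_steps + 1) * dt  # step grid; z>0 from step 1
    forces_full = np.empty(n_steps)
    i0 = 0
    log = EventLog(shielded_path=shielded_path)
    event_steps: list[int] = []
    event_meta: list[tuple[str, str, float]] = []  # kind, name, loading rate

    while i0 < n_steps:
        t_seg = times[i0:]
        f_seg = fb.force_at(v * t_seg, unfolded_contour)
        # active kinetic channels in this segment
        channels: list[tuple[str, str, BellParams]] = [
            ("domain_unfold", d.name, d.kinetics) for d in folded
        ]
        rupture_kin: BellParams | None
        if shield_folded and not system.emergent_competition:
            rupture_kin = None  # explicit branch: XMod always unfolds first
        elif shield_folded:
            rupture_kin = system.complex_intact
        else:
            rupture_kin = (
                system.complex_shielded
                if any(d.shields_complex for d in system.domains)
                and not any(d.shields_complex for d in folded)
                and (shielded_path or system.emergent_competition)
                else system.complex_intact
            )
        if rupture_kin is not None:
            channels.append(("complex_rupture", "complex", rupture_kin))
        if not channels:
            forces_full[i0:] = f_seg
            i0 = n_steps
            break
        rates = np.vstack([_clipped_rates(f_seg, k, kBT) for _, _, k in channels])
        total = rates.sum(axis=0)
        hazard = np.cumsum(total) * dt
        draw = rng.exponential()
        idx = int(np.searchsorted(hazard, draw))
        if idx >= len(t_seg):
            forces_full[i0:] = f_seg
            i0 = n_steps
            break
        # event fires during step idx; record at its sample
        forces_full[i0 : i0 + idx + 1] = f_seg[: idx + 1]
        probs = rates[:, idx] / rates[:, idx].sum()
        ch = int(rng.choice(len(channels), p=probs))
        kind, name, _ = channels[ch]
        r_true = fb.loading_rate_at(float(f_seg[idx]), unfolded_contour, v)
        event_steps.append(i0 + idx)
        event_meta.append((kind, name, r_true))
        if kind == "complex_rupture":
            i0 = i0 + idx + 1
            n_steps = i0
            break
        dom = folded[ch]  # domain channels precede the rupture channel
        folded.remove(dom)
        unfolded_contour += dom.delta_Lc
        if dom.shields_complex:
            shield_folded = False
        i0 = i0 + idx + 1

    times = times[:n_steps]
    forces_full = forces_full[:n_steps]

    # output sampling: regular decimation plus the exact event samples
    decim = max(1, int(round(1.0 / (protocol.sampling_rate * dt))))
    keep = np.arange(0, n_steps, decim)
    keep = np.union1d(keep, np.array(event_steps, dtype=int)) if event_steps else keep
    keep = np.union1d(keep, [n_steps - 1]) if n_steps else keep
    keep = keep[keep < n_steps]

    t_out = times[keep]
    f_true = forces_full[keep]
    noise = (
        rng.normal(0.0, protocol.force_noise_sd, len(keep))
        if protocol.force_noise_sd > 0
        else np.zeros(len(keep))
    )
    f_out = f_true + noise
    ext = v * t_out - f_true / system.cantilever_stiffness

    curve = ForceCurve(
        time=t_out,
        extension=ext,
        force=f_out,
        pulling_speed=v,
        curve_id="",
        configuration="I",
    )
    pos = {step: int(np.searchsorted(keep, step)) for step in event_steps}
    for step, (kind, name, r_true) in zip(event_steps, event_meta):
        j = pos[step]
        log.events.append(
            Event(
                time=float(times[step]),
                index=j,
                force=float(f_out[j]),
                kind=kind,
                name=name,
                loading_rate=r_true,
                force_true=float(forces_full[step]),
            )
        )
    log.validate()
    return curve, log


def random_junk_system(rng: np.random.Generator) -> SystemSpec:
    """A nonspecific-adhesion stand-in: short tether, weak random events.

    Emulates the unusable fraction of an AFM data set — short-range
    nonspecific sticking with no fingerprint — used to exercise the
    screening stage. Synthetic by construction.
    """
    n_dom = int(rng.integers(0, 3))
    domains = tuple(
        DomainSpec(
            name=f"junk-{i}",
            delta_Lc=float(rng.uniform(5.0, 30.0)),
            kinetics=BellParams(k_off=0.05, delta_x=0.5),
            shields_complex=False,
        )
        for i in range(n_dom)
    )
    return SystemSpec(
        domains=domains,
        complex_intact=BellParams(k_off=0.02, delta_x=0.5),
        complex_shielded=None,
        shield_branch_probability=0.0,
        peg_contour=float(rng.uniform(10.0, 50.0)),
    )


def simulate_dataset(
    system: SystemSpec,
    protocol: ProtocolSpec,
    n_traces: int,
    junk_fraction: float = 0.0,
    xyn_single_use: bool = False,
    xyn_prefix: str = "Xyn",
) -> tuple[list[ForceCurve], list[EventLog], pd.DataFrame]:
    """Simulate a seeded dataset of traces plus its ground-truth table.

    Per-trace seeds derive from ``protocol.seed`` via a SeedSequence, so a
    fixed master seed reproduces the dataset bit for bit. With
    ``xyn_single_use`` the xylanase sub-domains are removed after the first
    trace in which they unfolded (the configuration-II behaviour where the
    fingerprint is lost early in a series).
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    if not 0.0 <= junk_fraction <= 1.0:
        raise ValueError("junk_fraction must be in [0, 1]")
    ss = np.random.SeedSequence(protocol.seed)
    children = ss.spawn(n_traces)
    curves: list[ForceCurve] = []
    logs: list[EventLog] = []
    rows: list[dict] = []
    current_system = system
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        is_junk = junk_fraction > 0 and rng.random() < junk_fraction
        sys_i = random_junk_system(rng) if is_junk else current_system
        curve, log = simulate_trace(sys_i, protocol, rng)
        curve.curve_id = f"trace{i:05d}"
        curve.configuration = "unknown" if is_junk else "I"
        curves.append(curve)
        logs.append(log)
        history = "shielded" if (not is_junk and log.shielded_path) else "intact"
        for ev in log.events:
            rows.append(
                {
                    "trace_id": i,
                    "curve_id": curve.curve_id,
                    "kind": ev.kind,
                    "name": ev.name,
                    "time_s": ev.time,
                    "force_pN": ev.force,
                    "force_true_pN": ev.force_true,
                    "loading_rate_pN_s": ev.loading_rate,
                    "history": history if ev.kind == "complex_rupture" else "",
                    "pulling_speed_nm_s": protocol.pulling_speed,
                    "is_junk": is_junk,
                }
            )
        if (
            xyn_single_use
            and not is_junk
            and any(n.startswith(xyn_prefix) for n in log.unfolded_names())
        ):
            current_system = replace(
                current_system,
                domains=tuple(
                    d for d in current_system.domains if not d.name.startswith(xyn_prefix)
                ),
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "trace_id", "curve_id", "kind", "name", "time_s", "force_pN",
            "force_true_pN", "loading_rate_pN_s", "history",
            "pulling_speed_nm_s", "is_junk",
        ],
    )
    return curves, logs, truth
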