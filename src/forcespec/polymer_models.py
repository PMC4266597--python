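"""Polymer elasticity models for force-spectroscopy analysis.

Two chain models are provided:

* **QM-FRC** — a freely rotating chain (bond length ``b``, fixed bond angle
  ``gamma``) with an optional quantum-mechanically motivated backbone-stretch
  correction. This is the model of choice for unfolded polypeptide: above
  ~200 pN it describes protein stretching without free fit parameters.
* **WLC** — the worm-like chain interpolation formula, used for PEG linkers.

The FRC enters through its effective persistence length

    p = b * cos(gamma/2) / |ln cos(gamma)|

and is evaluated in the two stretching regimes relevant above the
transformation threshold (forces of tens of pN and up):

    x/L = 1 - (4 F p / kBT)^(-1/2)      for F b / kBT <  p / b
    x/L = 1 - kBT / (2 F b)             for F b / kBT >= p / b

The two branches are continuous at the regime boundary (both equal
1 - b/(2p) there). Below ``F = kBT / (4 p)`` the first branch is not
physical (x/L <= 0) and a domain error is raised; the contour-length
transform rejects such low-force points anyway.

With the QM correction enabled, the contour length is force dependent,
``L(F) = L0 * stretch_factor(F)``; the ratio returned by
:func:`frc_extension_ratio` is relative to the *stretched* contour, so the
extension of a chain of zero-force contour ``L0`` is
``L0 * stretch_factor(F) * frc_extension_ratio(F)``.

Units are fixed package-wide: lengths nm, forces pN, energies pN nm.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KBT_ROOM",
    "RESIDUE_LENGTH",
    "ChainModel",
    "PolymerParams",
    "IncrementEntry",
    "IncrementTable",
    "LowForceWarning",
    "frc_extension_ratio",
    "backbone_stretch_factor",
    "wlc_extension_ratio",
    "wlc_force",
    "extension_model",
    "force_at_extension",
    "apparent_contour_length",
    "expected_increment",
]

#: Thermal energy at room temperature (~298-300 K), pN nm.
KBT_ROOM = 4.114

#: Contour length per stretched amino acid, nm.
RESIDUE_LENGTH = 0.365

#: Default QM backbone-stretch coefficients (1/pN, 1/pN^2): ~3% at 600 pN.
DEFAULT_QM_COEFFS = (3.0e-5, 3.0e-8)


class ChainModel(enum.Enum):
    QM_FRC = "qm_frc"
    WLC = "wlc"


class LowForceWarning(UserWarning):
    """Force below the model's validity floor: computed, but flagged."""


@dataclass(frozen=True)
class PolymerParams:
    """Elasticity parameters for one chain model.

    Parameters
    ----------
    model:
        ``ChainModel.QM_FRC`` for polypeptide, ``ChainModel.WLC`` for linkers.
    b:
        FRC bond length, nm.
    gamma:
        FRC fixed bond angle, degrees, in (0, 90).
    persistence_length:
        WLC persistence length, nm (also used for linker compliance).
    qm_correction:
        Ordered polynomial coefficients ``(c1, c2, ...)`` of the backbone
        stretch factor ``1 + c1 F + c2 F^2 + ...``; ``None`` disables the
        correction (factor identically 1).
    kBT:
        Thermal energy, pN nm.
    validity_floor:
        Force (pN) below which the FRC ratio is flagged with
        :class:`LowForceWarning`.
    """

    model: ChainModel = ChainModel.QM_FRC
    b: float = 0.11
    gamma: float = 41.0
    persistence_length: float = 0.38
    qm_correction: tuple[float, ...] | None = DEFAULT_QM_COEFFS
    kBT: float = KBT_ROOM
    validity_floor: float = 10.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"bond length must be positive, got {self.b}")
        if not 0.0 < self.gamma < 90.0:
            raise ValueError(f"bond angle must be in (0, 90) deg, got {self.gamma}")
        if self.persistence_length <= 0:
            raise ValueError("persistence length must be positive")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")

    @property
    def frc_persistence(self) -> float:
        """Effective FRC persistence length p = b cos(g/2)/|ln cos g|, nm."""
        g = math.radians(self.gamma)
        return self.b * math.cos(g / 2.0) / abs(math.log(math.cos(g)))

    @property
    def frc_regime_boundary(self) -> float:
        """Force (pN) separating the WLC-like and discrete FRC regimes."""
        return self.frc_persistence * self.kBT / self.b**2

    @property
    def frc_minimum_force(self) -> float:
        """Force (pN) below which the FRC extension ratio is non-positive."""
        return self.kBT / (4.0 * self.frc_persistence)


def backbone_stretch_factor(force, params: PolymerParams):
    """Force-dependent backbone stretch factor L(F)/L(0) >= 1.

    Polynomial parametrization ``1 + c1 F + c2 F^2 + ...`` of the elastic
    lengthening of the polypeptide backbone under load; equals 1 at zero
    force and identically 1 when the correction is disabled.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    if params.qm_correction is None:
        out = np.ones_like(f)
    else:
        out = np.ones_like(f)
        for k, c in enumerate(params.qm_correction, start=1):
            out = out + c * f**k
    return out if out.ndim else float(out)


def frc_extension_ratio(force, params: PolymerParams, warn: bool = True):
    """Fractional extension x/L of the (QM-)FRC at a given force.

    Returns the extension relative to the (force-stretched, if the QM
    correction is enabled) contour length. Strictly increasing in force and
    bounded by 1.

    Raises
    ------
    ValueError
        For non-positive force, for forces at/below the positivity limit
        ``kBT/(4 p)``, or if ``params.model`` is not QM_FRC.
    """
    if params.model is not ChainModel.QM_FRC:
        raise ValueError("frc_extension_ratio requires a QM_FRC parameter set")
    f = np.asarray(force, dtype=float)
    if np.any(f <= 0):
        raise ValueError("force must be positive")
    if np.any(f <= params.frc_minimum_force):
        raise ValueError(
            f"force below the FRC positivity limit {params.frc_minimum_force:.3g} pN"
        )
    if warn and np.any(f < params.validity_floor):
        warnings.warn(
            f"force below validity floor ({params.validity_floor} pN); "
            "ratio computed but entropic-regime accuracy is reduced",
            LowForceWarning,
            stacklevel=2,
        )
    p = params.frc_persistence
    kBT = params.kBT
    low = 1.0 - np.sqrt(kBT / (4.0 * f * p))
    high = 1.0 - kBT / (2.0 * f * params.b)
    out = np.where(f < params.frc_regime_boundary, low, high)
    return out if out.ndim else float(out)


def wlc_force(ratio, params: PolymerParams):
    """Marko-Siggia interpolation force (pN) at fractional extension x/L."""
    s = np.asarray(ratio, dtype=float)
    if np.any((s < 0) | (s >= 1)):
        raise ValueError("WLC fractional extension must be in [0, 1)")
    out = (params.kBT / params.persistence_length) * (
        0.25 / (1.0 - s) ** 2 - 0.25 + s
    )
    return out if out.ndim else float(out)


def wlc_extension_ratio(force, params: PolymerParams):
    """Fractional extension x/L of the WLC interpolation formula at a force.

    Inverts :func:`wlc_force`; the inversion is the real root in [0, 1) of a
    cubic, found by a safeguarded Newton iteration (vectorized).
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    fp = f * params.persistence_length / params.kBT
    # initial guess: high-force asymptote, clipped into the low-force regime
    s = np.clip(1.0 - 0.5 / np.sqrt(np.maximum(fp, 1e-12) + 0.25), 0.0, 0.999)
    for _ in range(60):
        g = 0.25 / (1.0 - s) ** 2 - 0.25 + s - fp
        dg = 0.5 / (1.0 - s) ** 3 + 1.0
        step = g / dg
        s = np.clip(s - step, 0.0, 1.0 - 1e-12)
        if np.all(np.abs(step) < 1e-14):
            break
    return s if s.ndim else float(s)


def extension_model(force, contour_length: float, params: PolymerParams):
    """Extension (nm) of a chain of zero-force contour ``contour_length``."""
    if contour_length <= 0:
        raise ValueError("contour length must be positive")
    if params.model is ChainModel.QM_FRC:
        ratio = frc_extension_ratio(force, params, warn=False)
        return contour_length * backbone_stretch_factor(force, params) * ratio
    return contour_length * wlc_extension_ratio(force, params)


def force_at_extension(
    extension: float,
    contour_length: float,
    params: PolymerParams,
    rtol: float = 1e-9,
) -> float:
    """Force (pN) at which the chain model reaches a given extension.

    Root-solves ``extension_model(F) = extension``. For the WLC the
    interpolation formula is inverted in closed form instead.
    """
    if contour_length <= 0:
        raise ValueError("contour length must be positive")
    if extension < 0:
        raise ValueError("extension must be non-negative")
    if extension == 0.0:
        return 0.0
    if params.model is ChainModel.WLC:
        s = extension / contour_length
        if s >= 1.0:
            raise ValueError("extension beyond the WLC contour length")
        return wlc_force(s, params)

    f_lo = params.frc_minimum_force * (1.0 + 1e-12)
    f_hi = 1e7
    x_hi = extension_model(f_hi, contour_length, params)
    if extension >= x_hi:
        raise ValueError(
            f"extension {extension} nm not attainable below {f_hi} pN "
            f"(max {x_hi:.6g} nm)"
        )
    x_lo = extension_model(f_lo, contour_length, params)
    if extension <= x_lo:
        # smoothly ramp to zero force below the model floor: treat the chain
        # as slack (linear in the tiny bracket), adequate for sub-pN forces
        return f_lo * extension / x_lo

    def residual(f: float) -> float:
        return extension_model(f, contour_length, params) - extension

    try:
        return float(brentq(residual, f_lo, f_hi, rtol=rtol, maxiter=200))
    except Exception as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"force_at_extension failed to bracket a root for extension="
            f"{extension} nm, L0={contour_length} nm: {exc}"
        ) from exc


def apparent_contour_length(
    force,
    extension,
    params: PolymerParams,
    force_threshold: float = 10.0,
):
    """Zero-force contour length (nm) implied by a (force, extension) sample.

    Inverts the QM-FRC extension model,
    ``L0 = extension / (stretch_factor(F) * ratio(F))``. Samples at or below
    ``force_threshold`` are rejected: they return NaN rather than raising, so
    callers can count rejections.
    """
    f = np.asarray(force, dtype=float)
    x = np.asarray(extension, dtype=float)
    ok = f > max(force_threshold, params.frc_minimum_force * (1 + 1e-9))
    out = np.full(np.broadcast(f, x).shape, np.nan)
    if np.any(ok):
        fo = np.broadcast_to(f, out.shape)[ok]
        xo = np.broadcast_to(x, out.shape)[ok]
        ratio = frc_extension_ratio(fo, params, warn=False)
        out[ok] = xo / (backbone_stretch_factor(fo, params) * ratio)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class IncrementEntry:
    """One fingerprint domain: residue count and folded N-C length."""

    name: str
    residue_count: int
    folded_length: float  # nm

    def increment(self, residue_length: float = RESIDUE_LENGTH) -> float:
        return expected_increment(self.residue_count, self.folded_length, residue_length)


def expected_increment(
    residue_count: int,
    folded_length: float,
    residue_length: float = RESIDUE_LENGTH,
) -> float:
    """Expected unfolding contour-length increment (nm).

    ``residue_count * residue_length - folded_length``: the fully stretched
    backbone length of the domain minus the length it already contributed
    while folded.
    """
    if residue_count <= 0:
        raise ValueError("residue count must be positive")
    if folded_length < 0:
        raise ValueError("folded length must be non-negative")
    if residue_length <= 0:
        raise ValueError("residue length must be positive")
    inc = residue_count * residue_length - folded_length
    if inc <= 0:
        raise ValueError(
            f"folded length {folded_length} nm exceeds stretched length "
            f"{residue_count * residue_length:.3f} nm (increment {inc:.3f} nm)"
        )
    return inc


@dataclass(frozen=True)
class IncrementTable:
    """Fingerprint increment bookkeeping.

    The default entries reproduce the hallmark increments of the
    Xyn-XMod-Doc : Coh-CBM pulling assay — xylanase ~89 nm, CBM ~56 nm and
    an XMod entry of ~34 nm — from nominal residue counts and folded
    lengths at 0.365 nm per stretched amino acid. They are placeholders at
    the printed precision of the assay, not exact construct bookkeeping.
    """

    entries: tuple[IncrementEntry, ...] = (
        IncrementEntry("Xyn", 255, 4.075),   # -> 89.0 nm
        IncrementEntry("CBM", 160, 2.4),     # -> 56.0 nm
        IncrementEntry("XMod", 100, 2.5),    # -> 34.0 nm
    )
    residue_length: float = RESIDUE_LENGTH

    def __post_init__(self) -> None:
        if self.residue_length <= 0:
            raise ValueError("residue length must be positive")
        for e in self.entries:
            e.increment(self.residue_length)  # validates positivity

    def increments(self) -> dict[str, float]:
        return {e.name: e.increment(self.residue_length) for e in self.entries}
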