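"""Bell-Evans rupture kinetics and dynamic-force-spectrum fitting.

The Bell-Evans model describes a bond loaded at constant rate ``r`` whose
off-rate grows exponentially with force,

    k(F) = k_off * exp(F * dx / kBT),

where ``dx`` is the distance to the transition state and ``k_off`` the
intrinsic (zero-force) off-rate. The rupture-force density at loading rate
``r`` follows from first-passage statistics,

    p(F) = k(F)/r * exp[ (k_off kBT)/(dx r) * (1 - e^{F dx / kBT}) ],

with most probable rupture force

    F* = (kBT/dx) * ln( r dx / (k_off kBT) ),

linear in ln(r): a dynamic force spectrum. Fitting (ln r, F*) pairs with a
straight line therefore returns dx from the slope and k_off from the
intercept. Because k_off enters through a logarithm it is exponentially
sensitive to the intercept: recovered off-rates are only order-of-magnitude
quantities (documented in docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .polymer_models import KBT_ROOM

__all__ = [
    "BellParams",
    "ModalPoint",
    "BellEvansFit",
    "INTACT_COMPLEX",
    "SHIELDED_COMPLEX",
    "XMOD_UNFOLDING",
    "bell_rate",
    "log_bell_rate",
    "rupture_force_pdf",
    "rupture_force_cdf",
    "most_probable_force",
    "sample_rupture_forces",
    "fit_gaussian_mode",
    "fit_bell_evans",
]


@dataclass(frozen=True)
class BellParams:
    """Bell kinetics: intrinsic off-rate (1/s) and barrier distance (nm)."""

    k_off: float
    delta_x: float

    def __post_init__(self) -> None:
        if self.k_off <= 0:
            raise ValueError("k_off must be positive")
        if self.delta_x <= 0:
            raise ValueError("delta_x must be positive")


# Fitted parameter sets for the XMod-Doc:Coh system (dynamic force spectra):
# final complex rupture with XMod intact, the 'shielded' rupture after XMod
# unfolding, and XMod unfolding itself.
INTACT_COMPLEX = BellParams(k_off=7.3e-7, delta_x=0.13)
SHIELDED_COMPLEX = BellParams(k_off=4.7e-4, delta_x=0.19)
XMOD_UNFOLDING = BellParams(k_off=2.6e-6, delta_x=0.15)


@dataclass(frozen=True)
class ModalPoint:
    """Most probable rupture force / loading rate at one pulling speed."""

    pulling_speed: float          # nm/s
    most_probable_force: float    # pN
    most_probable_loading_rate: float  # pN/s
    force_sd: float               # pN
    n_events: int

    def __post_init__(self) -> None:
        if self.most_probable_loading_rate <= 0:
            raise ValueError("most probable loading rate must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass(frozen=True)
class BellEvansFit:
    """Least-squares Bell-Evans fit of a dynamic force spectrum."""

    params: BellParams
    param_stderr: tuple[float, float]  # (k_off 1/s, delta_x nm)
    residuals: tuple[float, ...]       # pN, per point
    points: tuple[ModalPoint, ...]
    history_class: str = "intact"      # intact | shielded | xmod_unfolding
    kBT: float = KBT_ROOM

    def predict(self, loading_rate) -> np.ndarray:
        return most_probable_force(loading_rate, self.params, self.kBT, clamp=True)

    def to_dict(self) -> dict:
        return {
            "history_class": self.history_class,
            "delta_x_nm": self.params.delta_x,
            "k_off_per_s": self.params.k_off,
            "stderr": {
                "k_off_per_s": self.param_stderr[0],
                "delta_x_nm": self.param_stderr[1],
            },
            "kBT_pN_nm": self.kBT,
            "points": [
                {
                    "pulling_speed_nm_s": p.pulling_speed,
                    "force_pN": p.most_probable_force,
                    "loading_rate_pN_s": p.most_probable_loading_rate,
                    "force_sd_pN": p.force_sd,
                    "n_events": p.n_events,
                }
                for p in self.points
            ],
            "residuals_pN": list(self.residuals),
        }


def log_bell_rate(force, p: BellParams, kBT: float = KBT_ROOM):
    """Natural log of the Bell off-rate; safe at forces where exp overflows."""
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    out = np.log(p.k_off) + f * p.delta_x / kBT
    return out if out.ndim else float(out)


def bell_rate(force, p: BellParams, kBT: float = KBT_ROOM):
    """Force-dependent off-rate k(F) = k_off exp(F dx / kBT), 1/s."""
    out = np.exp(log_bell_rate(force, p, kBT))
    if not np.all(np.isfinite(out)):
        raise OverflowError("Bell rate overflowed to a non-finite value")
    return out


def rupture_force_pdf(force, loading_rate: float, p: BellParams, kBT: float = KBT_ROOM):
    """Rupture-force probability density (1/pN) at constant loading rate."""
    if loading_rate <= 0:
        raise ValueError("loading rate must be positive")
    f = np.asarray(force, dtype=float)
    a = p.k_off * kBT / (p.delta_x * loading_rate)
    expo = f * p.delta_x / kBT
    out = np.exp(log_bell_rate(f, p, kBT) - math.log(loading_rate) + a * (1.0 - np.exp(expo)))
    return out if out.ndim else float(out)


def rupture_force_cdf(force, loading_rate: float, p: BellParams, kBT: float = KBT_ROOM):
    """Rupture-force cumulative distribution at constant loading rate."""
    if loading_rate <= 0:
        raise ValueError("loading rate must be positive")
    f = np.asarray(force, dtype=float)
    a = p.k_off * kBT / (p.delta_x * loading_rate)
    out = 1.0 - np.exp(a * (1.0 - np.exp(f * p.delta_x / kBT)))
    return out if out.ndim else float(out)


def most_probable_force(
    loading_rate, p: BellParams, kBT: float = KBT_ROOM, clamp: bool = True
):
    """Most probable rupture force F* (pN) at constant loading rate.

    ``F* = (kBT/dx) ln(r dx / (k_off kBT))``. At loading rates too low for a
    positive mode the value is clamped to 0 with a warning (the distribution
    is then monotonically decreasing).
    """
    r = np.asarray(loading_rate, dtype=float)
    if np.any(r <= 0):
        raise ValueError("loading rate must be positive")
    out = (kBT / p.delta_x) * np.log(r * p.delta_x / (p.k_off * kBT))
    if np.any(out < 0):
        if clamp:
            warnings.warn(
                "most probable force is negative at this loading rate; clamped to 0",
                stacklevel=2,
            )
            out = np.maximum(out, 0.0)
        else:
            raise ValueError("loading rate too low for a positive modal force")
    return out if out.ndim else float(out)


def sample_rupture_forces(
    n: int,
    loading_rate: float,
    p: BellParams,
    kBT: float = KBT_ROOM,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw i.i.d. rupture forces (pN) by inverting the analytic CDF.

    With survival S(F) = exp[a (1 - e^{F dx/kBT})], a = k_off kBT/(dx r),
    the quantile function is F(u) = (kBT/dx) ln(1 - ln(1-u)/a).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loading_rate <= 0:
        raise ValueError("loading rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = p.k_off * kBT / (p.delta_x * loading_rate)
    u = rng.random(n)
    return (kBT / p.delta_x) * np.log1p(-np.log1p(-u) / a)


def _freedman_diaconis_bins(values: np.ndarray) -> np.ndarray:
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        iqr = np.std(values)
    width = 2.0 * iqr / len(values) ** (1.0 / 3.0)
    span = values.max() - values.min()
    nbins = max(5, int(math.ceil(span / width))) if width > 0 else 5
    return np.histogram_bin_edges(values, bins=nbins)


def fit_gaussian_mode(
    values,
    bins: int | str | np.ndarray | None = None,
    log: bool = False,
) -> tuple[float, float]:
    """Most probable value and s.d. from a Gaussian fit to a histogram.

    Histograms the sample (Freedman-Diaconis bins by default), then
    least-squares fits ``A exp(-(x-mu)^2 / 2 sigma^2)``; returns
    ``(mu, sigma)``. With ``log=True`` the fit is done on ln(values) and the
    returned mode/sd are mapped back (mode = exp(mu), sd via delta method) —
    the default for loading-rate histograms.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if len(v) < 10:
        raise ValueError(f"need >= 10 values for a modal fit, got {len(v)}")
    x = np.log(v) if log else v
    sd0 = np.std(x)
    if sd0 <= 0 or (not log and sd0 < 1e-12 * max(1.0, abs(np.mean(x)))):
        raise ValueError("degenerate spread: sample s.d. below resolution")
    if bins is None:
        edges = _freedman_diaconis_bins(x)
    else:
        edges = np.histogram_bin_edges(x, bins=bins)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(xx, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((xx - mu) / sigma) ** 2)

    span = float(edges[-1] - edges[0])
    p0 = (float(counts.max()), float(centers[np.argmax(counts)]), float(sd0))
    bounds = ([0.0, edges[0] - span, 1e-6 * max(sd0, 1.0)], [np.inf, edges[-1] + span, 10 * span])
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Gaussian modal fit did not converge: {exc}") from exc
    mu, sigma = float(popt[1]), abs(float(popt[2]))
    if log:
        return math.exp(mu), math.exp(mu) * sigma
    return mu, sigma


def fit_bell_evans(
    points: list[ModalPoint] | tuple[ModalPoint, ...],
    kBT: float = KBT_ROOM,
    history_class: str = "intact",
    weight_by_counts: bool = False,
) -> BellEvansFit:
    """Least-squares Bell-Evans fit of modal (force, loading-rate) points.

    Fits ``F* = m ln r + c`` in (ln r, F*) space; then ``dx = kBT / m`` and
    ``k_off = (dx / kBT) r0`` with ``ln r0 = -c/m``. Standard errors come
    from the linear-fit covariance via the delta method.
    """
    pts = tuple(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 modal points")
    rates = np.array([p.most_probable_loading_rate for p in pts])
    forces = np.array([p.most_probable_force for p in pts])
    if rates.max() / rates.min() < 3.0:
        raise ValueError(
            "loading rates must span at least a factor of 3 "
            f"(got {rates.max() / rates.min():.2f}x)"
        )
    x = np.log(rates)
    w = np.array([p.n_events for p in pts], dtype=float) if weight_by_counts else np.ones(len(pts))
    X = np.column_stack([x, np.ones_like(x)])
    Xw = X * np.sqrt(w)[:, None]
    yw = forces * np.sqrt(w)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    m, c = float(beta[0]), float(beta[1])
    rss = float(np.sum(w * (forces - (m * x + c)) ** 2))
    dof = max(len(pts) - 2, 1)
    cov = rss / dof * np.linalg.inv(Xw.T @ Xw)
    if m <= 0:
        raise ValueError("fitted slope non-positive: delta_x would be negative")
    delta_x = kBT / m
    k_off = (delta_x / kBT) * math.exp(-c / m)
    # delta method: dx = kBT/m; ln k_off = ln(dx/kBT) - c/m
    var_m, cov_mc, var_c = cov[0, 0], cov[0, 1], cov[1, 1]
    sd_dx = kBT / m**2 * math.sqrt(var_m)
    dlnk_dm = -1.0 / m + c / m**2
    dlnk_dc = -1.0 / m
    var_lnk = (
        dlnk_dm**2 * var_m + dlnk_dc**2 * var_c + 2 * dlnk_dm * dlnk_dc * cov_mc
    )
    sd_koff = k_off * math.sqrt(max(var_lnk, 0.0))
    resid = forces - (m * x + c)
    return BellEvansFit(
        params=BellParams(k_off=k_off, delta_x=delta_x),
        param_stderr=(sd_koff, sd_dx),
        residuals=tuple(float(r) for r in resid),
        points=pts,
        history_class=history_class,
        kBT=kBT,
    )
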