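"""Shielding analysis: barrier transmission, TVL fits and the distance model.

The barrier transmission used throughout is the ratio that enters the
standard NCRP-style point calculation  P = B W U T / d^2:

    B = (K_air / D0) * (d / 1 m)^2,

with K_air the air kerma per source photon tallied 0.3 m beyond the distal
barrier face on the central axis, D0 the water dose per source photon at
d_max, 1 m, 10x10 cm^2, and d the source-detector distance.  Transmission
curves are summarized either by three sequential tenth-value layers,

    B = 10^(-t/TVL1)                      t < TVL1
    B = 10^-1 10^(-(t-TVL1)/TVL2)          TVL1 < t < TVL1+TVL2
    B = 10^-2 10^(-(t-TVL1-TVL2)/TVL3)     t > TVL1+TVL2,

or by a first plus equilibrium tenth-value layer,

    B = 10^-1 10^(-(t-TVL1)/TVLe)          t > TVL1.

Beyond the barrier the irradiated slab behaves as an extended ("pseudo")
source: the axial air-kerma rate falls off like the finite disc-source
kernel  P(d) ∝ ln{1 + [alpha (f + f0) / (d - d_s)]^2}  rather than like
1/d^2, which this module fits and evaluates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .transport import TallyResult, TransportConfig, run_transport

LN10 = math.log(10.0)


# --------------------------------------------------------------------------
# transmission curves
# --------------------------------------------------------------------------

@dataclass
class TransmissionCurve:
    """(thickness, B, sigma_B) points at fixed geometry and beam."""

    thickness: np.ndarray  # cm, ascending
    B: np.ndarray
    sigma_B: np.ndarray
    beam: str = ""
    d_s: float = 6.0  # m
    d_w: float = 0.3  # m
    field_size: float = 240.0  # cm at the distal surface

    def __post_init__(self):
        t = np.asarray(self.thickness, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("thicknesses must be strictly ascending")
        if np.any((self.B <= 0) | (self.B > 1.0 + 1e-12)):
            raise ValueError("B must lie in (0, 1]")
        if np.any(np.asarray(self.sigma_B) < 0):
            raise ValueError("sigma_B must be non-negative")

    def to_csv(self, path):
        pd.DataFrame({"t_cm": self.thickness, "B": self.B,
                      "sigma_B": self.sigma_B}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw):
        df = pd.read_csv(path)
        return cls(df["t_cm"].to_numpy(), df["B"].to_numpy(),
                   df["sigma_B"].to_numpy(), **kw)


@dataclass(frozen=True)
class ComputedB:
    """Barrier transmission with uncertainty; may be an upper bound only."""

    B: float
    sigma_B: float
    upper_bound: bool = False

    def __iter__(self):  # tuple-like unpacking (B, sigma)
        yield self.B
        yield self.sigma_B


def compute_B(tally: TallyResult, dose_per_photon: float,
              d: float | None = None,
              reference_field_cm: float = 10.0) -> ComputedB:
    """Distance-corrected transmission from a tally (see module docstring).

    ``dose_per_photon`` is referenced to a 10x10 cm^2 beam, i.e. to photons
    emitted into the reference solid angle.  A simulation of a larger field
    emits its histories into a larger solid angle at the same machine
    output, so the tallied kerma per source photon is rescaled by
    (field side at isocenter / reference side)^2 for divergent sources
    before forming B = (K_a / D0) d^2.  (Head-scatter variation of the
    output with field size is neglected.)

    When no photon reached the principal detector, a one-sided 95% upper
    bound (rule of three on the expected count) is returned and flagged;
    such points should be excluded from TVL fits.
    """
    if dose_per_photon <= 0:
        raise ValueError("dose_per_photon must be positive")
    det = tally.principal
    if d is None:
        d = det.distance_m
    omega = 1.0
    if tally.config.source.kind == "divergent_square":
        omega = (tally.config.source.field_side_at_iso / reference_field_cm) ** 2
    scale = omega * d**2 / dose_per_photon
    if det.counts == 0:
        # three hypothetical normal-incidence crossings of the detector disc
        from .xsec import air_kerma_per_fluence
        area = math.pi * det.radius_cm**2
        src = tally.config.source
        e_ref = (src.mono_energy if src.mono_energy is not None
                 else src.spectrum.mean_energy())
        kerma_bound = 3.0 / (tally.n_histories * area) * float(air_kerma_per_fluence(e_ref))
        return ComputedB(kerma_bound * scale, float("nan"), upper_bound=True)
    return ComputedB(det.kerma * scale, det.kerma_sigma * scale)


def sweep_thickness(base_config: TransportConfig, thicknesses,
                    dose_per_photon: float, histories=None,
                    beam: str = "") -> TransmissionCurve:
    """Run the transport engine over a thickness ladder and assemble a curve."""
    Bs, sigmas, ts = [], [], []
    for i, t in enumerate(thicknesses):
        cfg = replace(base_config, slab=replace(base_config.slab, thickness=float(t)))
        if histories is not None:
            n = histories[i] if np.ndim(histories) else int(histories)
            cfg = replace(cfg, histories=int(n))
        res = compute_B(run_transport(cfg), dose_per_photon)
        if res.upper_bound:
            continue
        ts.append(float(t)); Bs.append(res.B); sigmas.append(res.sigma_B)
    src = base_config.source
    field = (src.field_side_at_iso * src.source_to_distal
             if src.kind == "divergent_square" else 2 * src.radius)
    return TransmissionCurve(np.array(ts), np.array(Bs), np.array(sigmas),
                             beam=beam, d_s=src.source_to_distal,
                             d_w=base_config.detectors.principal_dw,
                             field_size=field)


# --------------------------------------------------------------------------
# required transmission
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShieldingSpec:
    """NCRP-style point-protection parameters."""

    P: float  # shielding design goal, Sv/week
    W: float  # workload, Gy/week at 1 m
    U: float  # use factor
    T_occ: float  # occupancy factor
    d: float  # source to point of interest, m

    def __post_init__(self):
        if min(self.P, self.W, self.U, self.T_occ, self.d) <= 0:
            raise ValueError("all shielding parameters must be positive")
        if self.U > 1 or self.T_occ > 1:
            raise ValueError("U and T must not exceed 1")


def required_B(spec: ShieldingSpec) -> float:
    """Transmission needed to meet the design goal: B = P d^2 / (W U T)."""
    return spec.P * spec.d**2 / (spec.W * spec.U * spec.T_occ)


# --------------------------------------------------------------------------
# TVL parameterizations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TVLFit3:
    TVL1: float
    TVL2: float
    TVL3: float
    sigma: tuple = (float("nan"),) * 3
    relative_residual: float = float("nan")  # percent


@dataclass(frozen=True)
class TVLFit2:
    TVL1: float
    TVLe: float
    sigma: tuple = (float("nan"),) * 2
    relative_residual: float = float("nan")  # percent


def _log10_B_three(t, tvl1, tvl2, tvl3):
    t = np.asarray(t, float)
    b1 = -t / tvl1
    b2 = -1.0 - (t - tvl1) / tvl2
    b3 = -2.0 - (t - tvl1 - tvl2) / tvl3
    return np.where(t < tvl1, b1, np.where(t < tvl1 + tvl2, b2, b3))


def _log10_B_two(t, tvl1, tvle):
    t = np.asarray(t, float)
    return np.where(t < tvl1, -t / tvl1, -1.0 - (t - tvl1) / tvle)


def evaluate_B_tvl3(t, fit: TVLFit3):
    """Piecewise three-TVL transmission; continuous at both breakpoints."""
    if np.any(np.asarray(t, float) < 0):
        raise ValueError("thickness must be non-negative")
    return 10.0 ** _log10_B_three(t, fit.TVL1, fit.TVL2, fit.TVL3)


def evaluate_B_tvl2(t, fit: TVLFit2):
    """TVL1/TVLe transmission, extended below TVL1 with 10^(-t/TVL1)."""
    if np.any(np.asarray(t, float) < 0):
        raise ValueError("thickness must be non-negative")
    return 10.0 ** _log10_B_two(t, fit.TVL1, fit.TVLe)


def fit_tvl(curve: TransmissionCurve, model: str = "three"):
    """Weighted nonlinear least squares of the TVL forms on log10 B.

    Weights are 1/sigma_log^2 with sigma_log = sigma_B / (B ln 10); the
    reported parameter uncertainties are 1 SD from the fit covariance, and
    the relative residual is the mean of |B_fit(t_i) - B_i| / B_i in
    percent.  Multi-start initialization from crude graphical estimates;
    parameters are bounded to [5, 100] cm.
    """
    t, B, sig = curve.thickness, curve.B, curve.sigma_B
    n_par = 3 if model == "three" else 2
    if model not in ("two", "three"):
        raise ValueError("model must be 'two' or 'three'")
    if t.size < 2 * n_par:
        raise ValueError(f"need at least {2 * n_par} points for the {model}-TVL fit")
    if np.any(sig <= 0):
        raise ValueError("all points need positive sigma_B")
    logB = np.log10(B)
    sig_log = sig / (B * LN10)
    fn = _log10_B_three if model == "three" else _log10_B_two

    # graphical starting values: thickness of the first decade, late slope
    tvl1_guess = float(np.interp(-1.0, logB[::-1], t[::-1])) if logB.min() < -1 \
        else float(t[-1] / max(-logB[-1], 0.2))
    late = max(2, t.size // 3)
    slope = np.polyfit(t[-late:], logB[-late:], 1)[0]
    tvle_guess = min(max(-1.0 / slope, 5.0), 100.0) if slope < 0 else 35.0
    tvl1_guess = min(max(tvl1_guess, 5.0), 100.0)

    starts = []
    if model == "three":
        starts = [(tvl1_guess, 0.8 * tvle_guess, tvle_guess),
                  (tvl1_guess, tvle_guess, tvle_guess),
                  (40.0, 30.0, 35.0)]
    else:
        starts = [(tvl1_guess, tvle_guess), (40.0, 33.0)]

    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(fn, t, logB, p0=p0, sigma=sig_log,
                                   absolute_sigma=True,
                                   bounds=(5.0, 100.0), maxfev=20000)
        except RuntimeError:
            continue
        cost = float(np.sum(((fn(t, *popt) - logB) / sig_log) ** 2))
        if best is None or cost < best[2]:
            best = (popt, pcov, cost)
    if best is None:
        raise RuntimeError("TVL fit failed to converge from all starts")
    popt, pcov, _ = best
    if np.any(popt <= 0):
        raise RuntimeError("TVL fit converged to a non-positive parameter")
    perr = tuple(np.sqrt(np.diag(pcov)))
    resid = float(np.mean(np.abs(10.0 ** fn(t, *popt) - B) / B) * 100.0)
    if model == "three":
        return TVLFit3(*popt, sigma=perr, relative_residual=resid)
    return TVLFit2(*popt, sigma=perr, relative_residual=resid)


def density_scale_factor(rho_actual: float, rho_ref: float) -> float:
    """Thickness-equivalence ratio rho_actual / rho_ref (e.g. 2.29/2.35 = 0.974).

    Multiplying an *actual* thickness of lighter concrete by this factor
    gives the standard-density-equivalent thickness.
    """
    if rho_actual <= 0 or rho_ref <= 0:
        raise ValueError("densities must be positive")
    return rho_actual / rho_ref


def scale_tvl_density(fit, rho_actual: float, rho_ref: float):
    """Rescale TVLs from the reference density to the actual density.

    Areal density is conserved: TVL' = TVL * (rho_ref / rho_actual), so a
    lighter concrete has a proportionally larger TVL.  (Equivalently one may
    keep the reference TVLs and scale thicknesses by
    :func:`density_scale_factor`.)
    """
    k = 1.0 / density_scale_factor(rho_actual, rho_ref)
    if isinstance(fit, TVLFit3):
        return replace(fit, TVL1=fit.TVL1 * k, TVL2=fit.TVL2 * k,
                       TVL3=fit.TVL3 * k, sigma=tuple(s * k for s in fit.sigma))
    if isinstance(fit, TVLFit2):
        return replace(fit, TVL1=fit.TVL1 * k, TVLe=fit.TVLe * k,
                       sigma=tuple(s * k for s in fit.sigma))
    raise TypeError("fit must be TVLFit2 or TVLFit3")


# --------------------------------------------------------------------------
# distal-surface pseudo-source distance model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceFit:
    """Finite-disc pseudo-source parameters for the axial AKR fall-off."""

    alpha: float = 28.0
    f0: float = 0.02  # m
    d_s: float = 6.0  # m
    d_w: float = 0.3  # m
    f: float = 2.4  # field side at the barrier, m

    def __post_init__(self):
        if self.alpha <= 0 or self.f0 < 0:
            raise ValueError("alpha must be positive and f0 non-negative")


def distance_profile_model(d, fit: DistanceFit):
    """Relative axial AKR at distance(s) ``d`` (m from the target).

    ln{1 + [alpha (f + f0) / (d - d_s)]^2}, normalized to 1 at the
    reference point d = d_s + d_w.  Proportional to 1/d^2 when d >> d_s.
    """
    d = np.asarray(d, float)
    if np.any(d <= fit.d_s):
        raise ValueError("model is defined beyond the distal surface (d > d_s)")
    eff = fit.alpha * (fit.f + fit.f0)
    num = np.log1p((eff / (d - fit.d_s)) ** 2)
    den = np.log1p((eff / fit.d_w) ** 2)
    return num / den


def inverse_square_profile(d, d_ref: float):
    """Point-source-at-target expectation (d_ref/d)^2, normalized at d_ref."""
    return (d_ref / np.asarray(d, float)) ** 2


def fit_distance_model(profile, d_s: float = 6.0, d_w: float = 0.3,
                       f: float = 2.4) -> DistanceFit:
    """Weighted least squares of the pseudo-source model to (d, AKR, sigma).

    ``profile`` is an iterable of (d_m, relative_AKR, sigma) with the AKR
    normalized to 1 at d = d_s + d_w; at least four points beyond the
    reference distance are required.
    """
    arr = np.asarray(list(profile), float)
    d, y, sig = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.sum(d > d_s + d_w) < 4:
        raise ValueError("need at least four points beyond d_s + d_w")

    def model(dd, alpha, f0):
        return distance_profile_model(dd, DistanceFit(alpha, f0, d_s, d_w, f))

    sig = np.where(sig > 0, sig, np.nanmax(sig[sig > 0]) if np.any(sig > 0) else 1.0)
    popt, _ = curve_fit(model, d, y, p0=(28.0, 0.02), sigma=sig,
                        absolute_sigma=True,
                        bounds=((1e-3, 0.0), (1e4, 10.0)), maxfev=20000)
    return DistanceFit(float(popt[0]), float(popt[1]), d_s, d_w, f)


# --------------------------------------------------------------------------
# narrow-beam slope regression (code validation protocol)
# --------------------------------------------------------------------------

def fit_attenuation_slope(thicknesses, counts, n_histories):
    """Weighted regression of ln(B_N) vs t for pencil-beam count tallies.

    Poisson weighting (sigma_lnB = 1/sqrt(N)); zero-count points are
    excluded.  Returns (slope magnitude cm^-1, standard error, half-width of
    the 95% CI).
    """
    t = np.asarray(thicknesses, float)
    n = np.asarray(counts, float)
    n0 = np.asarray(n_histories, float) * np.ones_like(n)
    keep = n > 0
    if keep.sum() < 3:
        raise ValueError("need at least three non-empty thickness points")
    t, n, n0 = t[keep], n[keep], n0[keep]
    y = np.log(n / n0)
    w = n  # 1/sigma^2 with sigma = 1/sqrt(counts)
    W = w.sum()
    tbar = (w * t).sum() / W
    ybar = (w * y).sum() / W
    sxx = (w * (t - tbar) ** 2).sum()
    slope = (w * (t - tbar) * (y - ybar)).sum() / sxx
    se = 1.0 / math.sqrt(sxx)
    return -slope, se, 1.96 * se
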