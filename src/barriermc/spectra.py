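"""Incident-beam spectra: containers, file I/O, sampling and surrogates.

Published linac spectra (e.g. the Sheikh-Bagheri & Rogers compilations) are
distributed as two-column differential-fluence tables and must be supplied
by the user; this module reads them, exposes the Table-3-style per-photon
dose normalization constants, and can manufacture an analytic
bremsstrahlung-like surrogate

    Phi(E)  ∝  (E_max - E) * exp(-b E),   E in [E_min, E_max],

with ``b`` tuned so the surrogate reproduces a requested mean energy.  The
surrogate is the stand-in beam used by the test-suite; it emulates the
gross shape of a flattened megavoltage spectrum (rise to a few hundred keV,
quasi-exponential fall-off, end point at the accelerating potential) but
none of the machine-specific structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import brentq

_DATA = resources.files("barriermc") / "data"


@dataclass(frozen=True)
class Spectrum:
    """Binned differential photon fluence (relative units per MeV)."""

    bin_edges: np.ndarray  # MeV, ascending, length n+1
    differential_fluence: np.ndarray  # per MeV, length n
    label: str = ""

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        val = np.asarray(self.differential_fluence, dtype=float)
        if edges.ndim != 1 or val.ndim != 1 or edges.size != val.size + 1:
            raise ValueError("need n+1 edges for n fluence values")
        if np.any(np.diff(edges) < 0):
            raise ValueError("bin edges must be ascending")
        if np.any(val < 0) or not np.any(val > 0):
            raise ValueError("fluence must be >= 0 with at least one positive bin")
        if edges[-1] > 25.0:
            raise ValueError("spectrum extends beyond the 25 MeV data range")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "differential_fluence", val)

    @property
    def bin_centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_weights(self):
        """Per-bin integrated fluence; zero-width bins carry their value."""
        widths = np.diff(self.bin_edges)
        w = self.differential_fluence * widths
        return np.where(widths == 0.0, self.differential_fluence, w)

    def mean_energy(self) -> float:
        """Fluence-weighted mean of the bin centers, MeV."""
        w = self.bin_weights
        return float(np.sum(w * self.bin_centers) / np.sum(w))

    @classmethod
    def monoenergetic(cls, energy: float, label: str = "") -> "Spectrum":
        return cls(np.array([energy, energy]), np.array([1.0]),
                   label or f"{energy} MeV")


def load_spectrum(path, label: str = "") -> Spectrum:
    """Read a spectrum file: '#' comments, 2 cols (center, fluence) or 3
    cols (edge_lo, edge_hi, fluence)."""
    raw = np.loadtxt(path, comments="#", ndmin=2)
    if raw.size == 0:
        raise ValueError(f"empty spectrum file {path}")
    if raw.shape[1] == 2:
        centers, fluence = raw[:, 0], raw[:, 1]
        if centers.size == 1:
            return Spectrum.monoenergetic(float(centers[0]),
                                          label or str(path))
        if np.any(np.diff(centers) <= 0):
            raise ValueError("bin-center energies must be strictly ascending")
        mid = 0.5 * (centers[:-1] + centers[1:])
        edges = np.concatenate([[centers[0] - (mid[0] - centers[0])], mid,
                                [centers[-1] + (centers[-1] - mid[-1])]])
        edges[0] = max(edges[0], 0.0)
    elif raw.shape[1] == 3:
        lo, hi, fluence = raw[:, 0], raw[:, 1], raw[:, 2]
        if np.any(lo[1:] != hi[:-1]) or np.any(hi < lo):
            raise ValueError("bin edges must be contiguous and ascending")
        edges = np.concatenate([lo, [hi[-1]]])
    else:
        raise ValueError("spectrum file must have 2 or 3 numeric columns")
    return Spectrum(edges, fluence, label or str(path))


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write the 3-column (edge_lo, edge_hi, fluence) form (lossless)."""
    with open(path, "w") as fh:
        fh.write(f"# spectrum: {spectrum.label}\n# edge_lo_MeV edge_hi_MeV fluence_per_MeV\n")
        for lo, hi, v in zip(spectrum.bin_edges[:-1], spectrum.bin_edges[1:],
                             spectrum.differential_fluence):
            fh.write(f"{float(lo)!r} {float(hi)!r} {float(v)!r}\n")


def mean_energy(spectrum: Spectrum) -> float:
    return spectrum.mean_energy()


def sample_energies(spectrum: Spectrum, n: int, rng) -> np.ndarray:
    """Inverse-CDF sampling: choose a bin by weight, then uniform within it."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    w = spectrum.bin_weights
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: no positive fluence")
    cdf = np.cumsum(w) / total
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    lo = spectrum.bin_edges[idx]
    hi = spectrum.bin_edges[idx + 1]
    return lo + (hi - lo) * rng.random(n)


@dataclass(frozen=True)
class BeamNormalization:
    """Nominal-MV beam constants: mean energy and dose per photon.

    ``dose_per_photon`` is the absorbed dose in water at d_max, 100 cm from
    the target, 10x10 cm^2 field, per photon emitted into the field -- the
    normalization that converts tallied air kerma per photon into a barrier
    transmission factor.
    """

    nominal_MV: str
    mean_energy: float  # MeV
    dose_per_photon: float  # Gy
    dose_per_photon_sigma: float  # Gy
    max_energy: float  # MeV


def beam_normalization(label: str) -> BeamNormalization:
    """Reference constants keyed by '4', '6', '6E', '10', '15', '18'."""
    table = json.loads((_DATA / "beam_normalization.json").read_text())
    if label not in table:
        raise KeyError(f"unknown beam label {label!r}; have {sorted(table)}")
    rec = table[label]
    return BeamNormalization(label, rec["mean_MeV"], rec["dose_per_photon_Gy"],
                             rec["dose_per_photon_sigma_Gy"], rec["max_MeV"])


def make_surrogate_spectrum(nominal_MV: float, target_mean: float | None = None,
                            e_min: float = 0.05, bin_width: float = 0.05,
                            label: str = "") -> Spectrum:
    """Analytic surrogate for an unprinted published linac spectrum.

    Parameters
    ----------
    nominal_MV : accelerating potential; sets the end-point energy E_max.
    target_mean : mean energy to reproduce, MeV.  Defaults to the reference
        Table-3-style constant when ``nominal_MV`` matches a known beam,
        otherwise to 0.3 * E_max.
    """
    e_max = float(nominal_MV)
    if not 1.0 <= e_max <= 25.0:
        raise ValueError("nominal_MV must be in [1, 25]")
    if target_mean is None:
        table = json.loads((_DATA / "beam_normalization.json").read_text())
        match = [r for r in table.values() if abs(r["max_MeV"] - e_max) < 1e-9]
        target_mean = match[0]["mean_MeV"] if match else 0.3 * e_max

    edges = np.arange(e_min, e_max + 0.5 * bin_width, bin_width)
    if edges[-1] < e_max:
        edges = np.append(edges, e_max)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)

    def binned_mean(b):
        w = (e_max - centers) * np.exp(-b * centers) * widths
        return float(np.sum(w * centers) / np.sum(w))

    lo_mean = binned_mean(60.0)   # hardest possible decay -> softest beam
    hi_mean = binned_mean(-20.0)
    if not lo_mean < target_mean < hi_mean:
        raise ValueError(
            f"target mean {target_mean} MeV unattainable for E_max={e_max}")
    b = brentq(lambda x: binned_mean(x) - target_mean, -20.0, 60.0, xtol=1e-10)
    fluence = (e_max - centers) * np.exp(-b * centers)
    fluence /= fluence.max()
    return Spectrum(edges, fluence,
                    label or f"surrogate {nominal_MV:g} MV (mean {target_mean:g} MeV)")
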