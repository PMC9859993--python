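"""Photon interaction data: elements, mixtures and air-kerma conversion.

The package ships per-element mass interaction coefficients (photoelectric,
incoherent, coherent, pair) on a common 0.01-25 MeV grid, built from
published attenuation data and Klein-Nishina theory (see docs/methods.md).
Mixtures follow the standard weight-fraction additivity rule

    (mu/rho)_mix(E) = sum_i w_i (mu/rho)_i(E),

and linear coefficients are obtained by multiplying with the bulk density.
Coherent (Rayleigh) scattering is tabulated but excluded from the default
total coefficient; the transmission values quoted for concrete in the
shielding literature correspond to the coherent-free total at megavoltage
energies, and the transport engine does not simulate coherent deflections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import brentq

from .constants import AVOGADRO, E_MAX_MEV, E_MIN_MEV, MEV_TO_J, PAIR_THRESHOLD_MEV

PROCESSES = ("photoelectric", "incoherent", "coherent", "pair")

_DATA = resources.files("barriermc") / "data"


def _loglog_interp(energy, grid, values):
    """Log-log linear interpolation; zero table entries map to zero output.

    Used for all coefficient lookups.  ``values`` may contain leading zeros
    (pair production below threshold); queries that fall in the zero region
    return 0.
    """
    energy = np.asarray(energy, dtype=float)
    pos = values > 0.0
    if not np.any(pos):
        return np.zeros_like(energy)
    out = np.zeros_like(energy)
    lo = grid[pos][0]
    inside = energy >= lo
    out[inside] = np.exp(
        np.interp(np.log(energy[inside]), np.log(grid[pos]), np.log(values[pos]))
    )
    return out


@dataclass(frozen=True)
class ElementRecord:
    """Per-element mass interaction coefficients on an ascending energy grid."""

    symbol: str
    Z: int
    A: float  # g/mol
    energy_grid: np.ndarray  # MeV
    mu_rho_photoelectric: np.ndarray  # cm^2/g
    mu_rho_incoherent: np.ndarray
    mu_rho_coherent: np.ndarray
    mu_rho_pair: np.ndarray

    def mass_coefficient(self, energy, process):
        table = getattr(self, f"mu_rho_{process}")
        return _loglog_interp(energy, self.energy_grid, table)


_ELEMENT_META = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.98977), "Mg": (12, 24.305), "Al": (13, 26.9815),
    "Si": (14, 28.0855), "S": (16, 32.06), "Ar": (18, 39.948),
    "K": (19, 39.0983), "Ca": (20, 40.078), "Fe": (26, 55.845),
}

_element_cache: dict[str, ElementRecord] = {}


def element(symbol: str) -> ElementRecord:
    """Load (and cache) the embedded data for one element."""
    if symbol not in _ELEMENT_META:
        raise KeyError(f"no embedded data for element {symbol!r}")
    if symbol not in _element_cache:
        Z, A = _ELEMENT_META[symbol]
        raw = np.loadtxt(str(_DATA / "elements" / f"{symbol}.txt"))
        grid = raw[:, 0]
        if np.any(np.diff(grid) <= 0):
            raise ValueError(f"{symbol}: energy grid not strictly ascending")
        _element_cache[symbol] = ElementRecord(
            symbol=symbol, Z=Z, A=A, energy_grid=grid,
            mu_rho_photoelectric=raw[:, 1], mu_rho_incoherent=raw[:, 2],
            mu_rho_coherent=raw[:, 3], mu_rho_pair=raw[:, 4],
        )
    return _element_cache[symbol]


@dataclass(frozen=True)
class Material:
    """A homogeneous mixture defined by element weight fractions and density."""

    name: str
    density: float  # g/cm^3
    weight_fractions: dict  # symbol -> mass fraction

    @property
    def electron_density(self) -> float:
        """Electrons per cm^3: rho * N_A * sum_i w_i Z_i / A_i."""
        za = sum(w * _ELEMENT_META[s][0] / _ELEMENT_META[s][1]
                 for s, w in self.weight_fractions.items())
        return self.density * AVOGADRO * za

    @property
    def electrons_per_gram(self) -> float:
        return self.electron_density / self.density

    def with_density(self, density: float) -> "Material":
        return Material(self.name, density, dict(self.weight_fractions))


def build_material(fractions: dict, density: float, name: str = "material",
                   renormalize: bool = False) -> Material:
    """Validate a composition and return a :class:`Material`.

    Fractions must be non-negative and sum to 1 within 1e-3 (in which case
    they are renormalized to exactly 1); larger deviations require
    ``renormalize=True``.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    for sym, w in fractions.items():
        if sym not in _ELEMENT_META:
            raise KeyError(f"unknown element symbol {sym!r}")
        if w < 0:
            raise ValueError(f"negative weight fraction for {sym}")
    total = sum(fractions.values())
    if total <= 0:
        raise ValueError("all weight fractions are zero")
    if abs(total - 1.0) > 1e-3 and not renormalize:
        raise ValueError(
            f"weight fractions sum to {total:.5f}; pass renormalize=True to accept"
        )
    return Material(name, density, {s: w / total for s, w in fractions.items()})


def _load_material_spec(key: str, density: float | None) -> Material:
    spec = json.loads((_DATA / "materials.json").read_text())[key]
    return build_material(spec["fractions"],
                          density if density is not None else spec["density"],
                          name=key)


def standard_concrete(density: float | None = None) -> Material:
    """Ordinary concrete (White-Grodstein composition), default 2.35 g/cm^3."""
    return _load_material_spec("concrete", density)


def dry_air(density: float | None = None) -> Material:
    """Standard dry air (N, O, Ar, C), default 1.205e-3 g/cm^3 (20 C)."""
    return _load_material_spec("air", density)


class CoefficientSet:
    """Precomputed per-process linear attenuation coefficients for a material.

    The default total excludes coherent scattering (``include_coherent``
    switches it on).  All lookups are vectorized log-log interpolations,
    which is what the transport engine samples from.
    """

    def __init__(self, material: Material, include_coherent: bool = False,
                 processes: tuple = ("photoelectric", "incoherent", "pair")):
        self.material = material
        self.include_coherent = include_coherent
        self.processes = tuple(processes) + (("coherent",) if include_coherent else ())
        grids = {s: element(s).energy_grid for s in material.weight_fractions}
        # all shipped elements share one grid; fall back to union otherwise
        first = next(iter(grids.values()))
        if all(g.shape == first.shape and np.allclose(g, first) for g in grids.values()):
            self.energy_grid = first
        else:
            self.energy_grid = np.unique(np.concatenate(list(grids.values())))
        self._mass = {}
        for proc in PROCESSES:
            acc = np.zeros_like(self.energy_grid)
            for sym, w in material.weight_fractions.items():
                acc += w * element(sym).mass_coefficient(self.energy_grid, proc)
            self._mass[proc] = acc

    def _check(self, energy):
        energy = np.asarray(energy, dtype=float)
        if np.any(energy < E_MIN_MEV) or np.any(energy > E_MAX_MEV):
            raise ValueError(
                f"energy outside tabulated range [{E_MIN_MEV}, {E_MAX_MEV}] MeV"
            )
        return energy

    def mu_process(self, energy, process):
        """Linear coefficient of one process, cm^-1."""
        energy = self._check(energy)
        out = self.material.density * _loglog_interp(
            energy, self.energy_grid, self._mass[process])
        if process == "pair":
            out = np.where(energy < PAIR_THRESHOLD_MEV, 0.0, out)
        return out

    def mu(self, energy):
        """Total linear attenuation coefficient, cm^-1 (active processes)."""
        energy = self._check(energy)
        return sum(self.mu_process(energy, p) for p in self.processes)

    def process_probabilities(self, energy):
        """Relative interaction probabilities per active process at ``energy``."""
        mus = np.array([self.mu_process(energy, p) for p in self.processes])
        tot = mus.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, mus / tot, 0.0)


def linear_attenuation(material: Material, energy, include_coherent: bool = False):
    """Mixture-rule linear attenuation coefficient mu(E), cm^-1."""
    return CoefficientSet(material, include_coherent=include_coherent).mu(energy)


def narrow_beam_transmission(material: Material, energy, thickness,
                             include_coherent: bool = False):
    """Good-geometry exponential transmission exp(-mu t)."""
    thickness = np.asarray(thickness, dtype=float)
    if np.any(thickness < 0):
        raise ValueError("thickness must be non-negative")
    return np.exp(-linear_attenuation(material, energy, include_coherent) * thickness)


def process_crossing_energy(material: Material, proc_a: str, proc_b: str):
    """Lowest energy at which two process coefficients are equal, MeV."""
    if proc_a == proc_b:
        raise ValueError("processes must differ")
    for p in (proc_a, proc_b):
        if p not in PROCESSES:
            raise ValueError(f"unknown process {p!r}")
    cs = CoefficientSet(material, include_coherent=True)
    grid = cs.energy_grid

    def diff(loge):
        e = np.exp(loge)
        return float(cs.mu_process(e, proc_a) - cs.mu_process(e, proc_b))

    vals = cs.mu_process(grid, proc_a) - cs.mu_process(grid, proc_b)
    sign = np.sign(vals)
    idx = np.nonzero((sign[:-1] != 0) & (sign[1:] != 0) & (sign[:-1] != sign[1:]))[0]
    if idx.size == 0:
        raise ValueError(f"no {proc_a}/{proc_b} crossing in tabulated range")
    i = idx[0]
    return float(np.exp(brentq(diff, np.log(grid[i]), np.log(grid[i + 1]))))


class KermaCoefficients:
    """Fluence-to-air-kerma conversion from the embedded mu_tr/rho table."""

    def __init__(self):
        raw = np.loadtxt(str(_DATA / "air_kerma.txt"))
        self.energy_grid = raw[:, 0]
        self.mass_energy_transfer_air = raw[:, 2]  # cm^2/g

    def mutr_over_rho(self, energy):
        energy = np.asarray(energy, dtype=float)
        if np.any(energy < E_MIN_MEV) or np.any(energy > E_MAX_MEV):
            raise ValueError("energy outside tabulated range")
        return _loglog_interp(energy, self.energy_grid, self.mass_energy_transfer_air)

    def conversion(self, energy):
        """Air kerma per unit fluence, Gy cm^2: E * (mu_tr/rho)_air * 1.602e-10."""
        return (np.asarray(energy, dtype=float) * self.mutr_over_rho(energy)
                * MEV_TO_J * 1e3)


_kerma_singleton: KermaCoefficients | None = None


def air_kerma_per_fluence(energy):
    """Module-level shortcut for :meth:`KermaCoefficients.conversion`."""
    global _kerma_singleton
    if _kerma_singleton is None:
        _kerma_singleton = KermaCoefficients()
    return _kerma_singleton.conversion(energy)
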