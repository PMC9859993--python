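"""Analog Monte Carlo photon transport through a concrete slab.

Geometry convention: the source (linac target) sits at the origin with the
beam along +z.  The slab occupies z in [d_s - t, d_s] (d_s = source to
*distal* surface); detector planes sit at z = d_s + d_w.  Photons are
followed analogically -- free paths from the total linear attenuation
coefficient, interaction channel by relative process coefficients,
Klein-Nishina Compton sampling, photoelectric absorption, and pair events
that deposit the primary and emit two back-to-back 0.511 MeV annihilation
photons with an isotropic random axis.  Histories end below the 10 keV
cutoff, beyond 10 m lateral distance, or on backward exit through the
proximal face ("reflected back into the vault").  No variance reduction is
applied.

The engine is vectorized over batches of histories; reproducibility is
guaranteed for a fixed (seed, batch size) pair, each batch drawing from an
independent Philox substream.

Fluence is tallied with a planar crossing estimator: every crossing of a
detector disc scores 1/(A |cos theta|), with |cos theta| floored at 0.1 to
bound the estimator variance.  Air kerma is the fluence-energy-weighted sum
of air conversion coefficients; statistical uncertainties use the
history-by-history estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import MEC2_MEV
from .kn import sample_compton
from .spectra import Spectrum, sample_energies
from .xsec import CoefficientSet, KermaCoefficients, Material, dry_air

M_TO_CM = 100.0
_COS_FLOOR = 0.1


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceConfig:
    """Beam description: divergent square, parallel circle, or pencil."""

    kind: str  # 'divergent_square' | 'parallel_circle' | 'pencil'
    mono_energy: Optional[float] = None  # MeV
    spectrum: Optional[Spectrum] = None
    field_side_at_iso: float = 40.0  # cm, side of square field at 1 m
    radius: float = 135.0  # cm, parallel beam radius
    source_to_distal: float = 6.0  # m

    def __post_init__(self):
        if self.kind not in ("divergent_square", "parallel_circle", "pencil"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if (self.mono_energy is None) == (self.spectrum is None):
            raise ValueError("set exactly one of mono_energy / spectrum")
        if self.kind == "divergent_square" and self.field_side_at_iso <= 0:
            raise ValueError("field_side_at_iso must be positive")
        if self.kind == "parallel_circle" and self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class SlabGeometry:
    thickness: float  # cm
    material: Material
    lateral_halfwidth: float = 10.0  # m

    def __post_init__(self):
        if self.thickness < 0:
            raise ValueError("thickness must be non-negative")


@dataclass(frozen=True)
class DetectorSet:
    """Axial disc detectors plus an annular profile at the principal plane."""

    principal_dw: float = 0.3  # m beyond the distal face
    principal_radius: float = 50.0  # cm
    extra_axial_dw: tuple = ()  # m, additional detector planes
    annular_ring_width: float = 15.0  # cm
    n_annular: int = 20

    def __post_init__(self):
        if self.principal_radius <= 0:
            raise ValueError("principal detector radius must be positive")

    @property
    def all_dw(self):
        return (self.principal_dw,) + tuple(self.extra_axial_dw)


@dataclass(frozen=True)
class TransportConfig:
    source: SourceConfig
    slab: SlabGeometry
    detectors: DetectorSet = field(default_factory=DetectorSet)
    histories: int = 100_000
    cutoff: float = 0.010  # MeV
    scatter_mode: str = "full"  # 'full' | 'single_scatter_only' | 'primary_only'
    rng_seed: int = 0
    include_air_attenuation: bool = False
    processes: tuple = ("photoelectric", "incoherent", "pair")
    batch_size: int = 1_000_000
    spectrum_bin_width: float = 0.05  # MeV, tallied-spectrum resolution
    force_generic: bool = False  # disable specialized kernels (validation aid)

    def __post_init__(self):
        if self.histories < 1:
            raise ValueError("histories must be >= 1")
        if self.scatter_mode not in ("full", "single_scatter_only", "primary_only"):
            raise ValueError(f"unknown scatter_mode {self.scatter_mode!r}")
        if self.cutoff < 0.01:
            raise ValueError("cutoff below tabulated data range")
        half_cm = self.slab.lateral_halfwidth * M_TO_CM
        if self.source.kind == "divergent_square":
            foot = 0.5 * self.source.field_side_at_iso * self.source.source_to_distal
        elif self.source.kind == "parallel_circle":
            foot = self.source.radius
        else:
            foot = 0.0
        if foot >= half_cm:
            raise ValueError("beam footprint exceeds the lateral slab extent")


# --------------------------------------------------------------------------
# tallies
# --------------------------------------------------------------------------

@dataclass
class DetectorTally:
    """Fluence/kerma tally of one axial disc detector."""

    dw_m: float
    distance_m: float  # from the source
    radius_cm: float
    counts: int = 0
    fluence: float = 0.0  # per cm^2 per source photon
    fluence_sigma: float = 0.0
    kerma: float = 0.0  # Gy per source photon
    kerma_sigma: float = 0.0
    spectrum_edges: Optional[np.ndarray] = None
    spectrum_fluence: Optional[np.ndarray] = None  # per cm^2 per photon, per bin
    sum_we: float = 0.0  # fluence-energy sum for the mean emergent energy

    def mean_energy(self) -> float:
        if self.fluence <= 0:
            raise ValueError("no photons tallied at this detector")
        return self.sum_we / self.fluence


@dataclass
class TallyResult:
    config: TransportConfig
    n_histories: int
    detectors: list  # DetectorTally, principal first
    ring_edges: np.ndarray = None
    ring_fluence: np.ndarray = None
    ring_counts: np.ndarray = None

    @property
    def principal(self) -> DetectorTally:
        return self.detectors[0]


def estimate_uncertainty(per_history_scores) -> float:
    """History-by-history standard error of the mean score."""
    x = np.asarray(per_history_scores, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two histories")
    m = x.mean()
    s2 = np.mean((x - m) ** 2) * n / (n - 1)
    return float(np.sqrt(max(s2, 0.0) / n))


def emergent_mean_energy(tally: TallyResult, detector: int = 0) -> float:
    """Fluence-weighted mean energy of the tallied spectrum, MeV."""
    return tally.detectors[detector].mean_energy()


# --------------------------------------------------------------------------
# sampling helpers
# --------------------------------------------------------------------------

def select_interaction(material_or_cs, energy, rng):
    """Draw interaction channel(s) with probability mu_proc / mu_total."""
    cs = (material_or_cs if isinstance(material_or_cs, CoefficientSet)
          else CoefficientSet(material_or_cs))
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    energy = np.atleast_1d(np.asarray(energy, dtype=float))
    probs = cs.process_probabilities(energy)  # (n_proc, n)
    u = rng.random(energy.size)
    idx = (u[None, :] >= np.cumsum(probs, axis=0)).sum(axis=0)
    idx = np.minimum(idx, len(cs.processes) - 1)
    names = np.array(cs.processes)[idx]
    return names if energy.size > 1 else str(names[0])


def _rotate_direction(d, cos_t, rng):
    """Rotate unit vectors ``d`` by polar angle acos(cos_t), uniform azimuth.

    Uses the standard direction-cosine update; the polar-axis degeneracy
    |w| -> 1 is handled with the explicit small-sin branch.
    """
    n = d.shape[0]
    phi = rng.random(n) * 2.0 * np.pi
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    cphi, sphi = np.cos(phi), np.sin(phi)
    u, v, w = d[:, 0], d[:, 1], d[:, 2]
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, 1.0))
    safe = s > 1e-10
    s_safe = np.where(safe, s, 1.0)
    out = np.empty_like(d)
    out[:, 0] = u * cos_t + sin_t * (u * w * cphi - v * sphi) / s_safe
    out[:, 1] = v * cos_t + sin_t * (v * w * cphi + u * sphi) / s_safe
    out[:, 2] = w * cos_t - s * sin_t * cphi
    if not np.all(safe):
        i = ~safe
        sign = np.sign(w[i])
        out[i, 0] = sin_t[i] * cphi[i]
        out[i, 1] = sign * sin_t[i] * sphi[i]
        out[i, 2] = sign * cos_t[i]
    return out


def _isotropic_directions(n, rng):
    cos_t = 2.0 * rng.random(n) - 1.0
    phi = 2.0 * np.pi * rng.random(n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


# --------------------------------------------------------------------------
# the engine
# --------------------------------------------------------------------------

class _Accumulator:
    """Batch-wise history-by-history accumulation for one detector."""

    def __init__(self, n_bins):
        self.sum_f = 0.0
        self.sum_f2 = 0.0
        self.sum_k = 0.0
        self.sum_k2 = 0.0
        self.counts = 0
        self.sum_we = 0.0
        self.spec = np.zeros(n_bins)

    def add_batch(self, n_batch, hist_idx, w, kerma_w, energies, bin_idx):
        f = np.zeros(n_batch)
        k = np.zeros(n_batch)
        np.add.at(f, hist_idx, w)
        np.add.at(k, hist_idx, kerma_w)
        self.sum_f += f.sum()
        self.sum_f2 += (f**2).sum()
        self.sum_k += k.sum()
        self.sum_k2 += (k**2).sum()
        self.counts += w.size
        self.sum_we += float((w * energies).sum())
        np.add.at(self.spec, bin_idx, w)

    def finalize(self, tally: DetectorTally, n_total):
        n = n_total
        tally.counts = int(self.counts)
        tally.fluence = self.sum_f / n
        tally.kerma = self.sum_k / n
        var_f = (self.sum_f2 / n - (self.sum_f / n) ** 2) / max(n - 1, 1)
        var_k = (self.sum_k2 / n - (self.sum_k / n) ** 2) / max(n - 1, 1)
        tally.fluence_sigma = float(np.sqrt(max(var_f, 0.0)))
        tally.kerma_sigma = float(np.sqrt(max(var_k, 0.0)))
        tally.spectrum_fluence = self.spec / n
        tally.sum_we = self.sum_we / n


def run_transport(config: TransportConfig) -> TallyResult:
    """Run the analog transport simulation described by ``config``."""
    src, slab, det = config.source, config.slab, config.detectors
    ds_cm = src.source_to_distal * M_TO_CM
    z_distal = ds_cm
    z_proximal = ds_cm - slab.thickness
    if z_proximal < 0:
        raise ValueError("slab thicker than the source-to-distal distance")
    lateral_cm = slab.lateral_halfwidth * M_TO_CM

    cs = CoefficientSet(slab.material, processes=config.processes)
    kerma = KermaCoefficients()
    air_cs = CoefficientSet(dry_air()) if config.include_air_attenuation else None

    if src.mono_energy is not None:
        e_max = src.mono_energy
    else:
        e_max = float(src.spectrum.bin_edges[-1])
    bw = config.spectrum_bin_width
    spec_edges = np.arange(config.cutoff, e_max + 2 * bw, bw)
    n_bins = spec_edges.size - 1

    plane_z = np.array([ds_cm + dw * M_TO_CM for dw in det.all_dw])
    plane_r = np.array([det.principal_radius] * len(det.all_dw))
    areas = np.pi * plane_r**2
    accs = [_Accumulator(n_bins) for _ in plane_z]

    ring_edges = np.arange(0.0, (det.n_annular + 1) * det.annular_ring_width,
                           det.annular_ring_width)
    ring_area = np.pi * (ring_edges[1:] ** 2 - ring_edges[:-1] ** 2)
    ring_f = np.zeros(det.n_annular)
    ring_c = np.zeros(det.n_annular, dtype=np.int64)

    n_total = config.histories
    batch = min(config.batch_size, n_total)
    n_batches = (n_total + batch - 1) // batch

    # dedicated kernels for the single-scatter validation mode
    fast_ss = (config.scatter_mode == "single_scatter_only"
               and tuple(config.processes) == ("incoherent",)
               and src.kind in ("parallel_circle", "pencil")
               and src.mono_energy is not None
               and not config.include_air_attenuation
               and not config.force_generic
               and slab.thickness > 0.0)

    from ._fastpath import HAVE_NUMBA, single_scatter_kernel
    if fast_ss and HAVE_NUMBA:
        e0 = float(src.mono_energy)
        e_tab = np.geomspace(config.cutoff, e0, 512)
        lmu_e, lmu_v = np.log(e_tab), np.log(cs.mu(e_tab))
        lcv_v = np.log(kerma.conversion(e_tab) / e_tab)
        dws_cm = plane_z - z_distal
        beam_r = src.radius if src.kind == "parallel_circle" else 0.0
        for ib in range(n_batches):
            nb = min(batch, n_total - ib * batch)
            seed32 = int(np.random.SeedSequence(
                [config.rng_seed, ib]).generate_state(1)[0])
            out = single_scatter_kernel(
                nb, seed32, beam_r, slab.thickness, dws_cm, plane_r.astype(float),
                lateral_cm, e0, config.cutoff, lmu_e, lmu_v, lmu_e, lcv_v,
                config.cutoff, config.spectrum_bin_width, len(spec_edges) - 1,
                det.annular_ring_width, det.n_annular)
            counts_k, sf, sf2, sk, sk2, swe, spec_k, rf, rc = out
            for k, acc in enumerate(accs):
                acc.counts += int(counts_k[k])
                acc.sum_f += sf[k]
                acc.sum_f2 += sf2[k]
                acc.sum_k += sk[k]
                acc.sum_k2 += sk2[k]
                acc.sum_we += swe[k]
                acc.spec += spec_k[k]
            ring_f += rf
            ring_c += rc
    else:
        for ib in range(n_batches):
            nb = min(batch, n_total - ib * batch)
            rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, ib]))
            runner = _run_batch_single_scatter if fast_ss else _run_batch
            runner(nb, rng, config, cs, kerma, air_cs,
                   z_proximal, z_distal, lateral_cm,
                   plane_z, plane_r, areas, accs, spec_edges,
                   ring_edges, ring_area, ring_f, ring_c)

    detectors = []
    for i, dw in enumerate(det.all_dw):
        tal = DetectorTally(dw_m=dw, distance_m=src.source_to_distal + dw,
                            radius_cm=plane_r[i], spectrum_edges=spec_edges)
        accs[i].finalize(tal, n_total)
        detectors.append(tal)
    return TallyResult(config=config, n_histories=n_total, detectors=detectors,
                       ring_edges=ring_edges, ring_fluence=ring_f / n_total,
                       ring_counts=ring_c)


def _source_batch(nb, src, rng, z_distal):
    """Initial positions (cm), unit directions and energies for one batch."""
    if src.mono_energy is not None:
        e = np.full(nb, float(src.mono_energy))
    else:
        e = sample_energies(src.spectrum, nb, rng)
    if src.kind == "pencil":
        pos = np.zeros((nb, 3))
        d = np.tile([0.0, 0.0, 1.0], (nb, 1))
    elif src.kind == "parallel_circle":
        r = src.radius * np.sqrt(rng.random(nb))
        phi = 2 * np.pi * rng.random(nb)
        pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(nb)])
        d = np.tile([0.0, 0.0, 1.0], (nb, 1))
    else:  # divergent_square: uniform fluence over the square at the distal plane
        side = src.field_side_at_iso * src.source_to_distal  # cm at z = d_s
        x = (rng.random(nb) - 0.5) * side
        y = (rng.random(nb) - 0.5) * side
        target = np.column_stack([x, y, np.full(nb, z_distal)])
        d = target / np.linalg.norm(target, axis=1)[:, None]
        pos = np.zeros((nb, 3))
    return pos, d, e


def _run_batch(nb, rng, config, cs, kerma, air_cs, z_prox, z_dist, lateral_cm,
               plane_z, plane_r, areas, accs, spec_edges,
               ring_edges, ring_area, ring_f, ring_c):
    src = config.source
    pos, dirs, E = _source_batch(nb, src, rng, z_dist)
    hist = np.arange(nb)
    nscat = np.zeros(nb, dtype=np.int32)

    # advance from the source to the proximal face (vacuum on the way in)
    with np.errstate(divide="ignore"):
        s_in = (z_prox - pos[:, 2]) / dirs[:, 2]
    keep = dirs[:, 2] > 0
    pos = pos[keep] + s_in[keep, None] * dirs[keep]
    dirs, E, hist, nscat = dirs[keep], E[keep], hist[keep], nscat[keep]

    exited = []  # (pos, dir, E, hist) of photons leaving the distal face

    for _ in range(100_000):
        if E.size == 0:
            break
        if config.slab.thickness == 0.0:
            exited.append((pos, dirs, E, hist))
            break
        mu = cs.mu(E)
        step = -np.log(rng.random(E.size)) / mu

        dz = dirs[:, 2]
        with np.errstate(divide="ignore"):
            s_exit = np.where(dz > 0, (z_dist - pos[:, 2]) / dz,
                              np.where(dz < 0, (z_prox - pos[:, 2]) / dz, np.inf))
        # lateral escape: |r + s u|^2 = lateral^2 (positive root)
        b = pos[:, 0] * dirs[:, 0] + pos[:, 1] * dirs[:, 1]
        c = pos[:, 0] ** 2 + pos[:, 1] ** 2 - lateral_cm**2
        ur2 = dirs[:, 0] ** 2 + dirs[:, 1] ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            disc = np.sqrt(np.maximum(b**2 - ur2 * c, 0.0))
            s_lat = np.where(ur2 > 0, (-b + disc) / ur2, np.inf)

        interacts = (step < s_exit) & (step < s_lat)
        leaves = ~interacts & (s_exit <= s_lat)
        distal = leaves & (dz > 0)
        # photons leaving through the proximal face or the lateral edge die

        if np.any(distal):
            p_out = pos[distal] + s_exit[distal, None] * dirs[distal]
            exited.append((p_out, dirs[distal], E[distal], hist[distal]))

        # process interactions
        idx = np.nonzero(interacts)[0]
        if idx.size == 0:
            pos, dirs, E, hist, nscat = (a[:0] for a in (pos, dirs, E, hist, nscat))
            continue
        pos = pos[idx] + step[idx, None] * dirs[idx]
        dirs, E, hist, nscat = dirs[idx], E[idx], hist[idx], nscat[idx]

        if config.scatter_mode == "primary_only":
            # any interaction removes the photon from the tallied population
            pos, dirs, E, hist, nscat = (a[:0] for a in (pos, dirs, E, hist, nscat))
            continue

        probs = cs.process_probabilities(E)  # (n_proc, n)
        u = rng.random(E.size)
        choice = (u[None, :] >= np.cumsum(probs, axis=0)).sum(axis=0)
        choice = np.minimum(choice, len(cs.processes) - 1)
        proc_names = cs.processes

        survivors_mask = np.zeros(E.size, dtype=bool)
        new_parts = []

        for ip, pname in enumerate(proc_names):
            sel = choice == ip
            if not np.any(sel):
                continue
            if pname == "photoelectric" or pname == "coherent":
                if pname == "coherent":
                    survivors_mask |= sel  # direction unchanged (approximation)
                continue
            if pname == "incoherent":
                j = np.nonzero(sel)[0]
                e_new, cos_t = sample_compton(E[j], rng)
                dirs[j] = _rotate_direction(dirs[j], cos_t, rng)
                E[j] = e_new
                nscat[j] += 1
                ok = E[j] >= config.cutoff
                if config.scatter_mode == "single_scatter_only":
                    ok &= nscat[j] <= 1
                survivors_mask[j[ok]] = True
            elif pname == "pair":
                j = np.nonzero(sel)[0]
                if j.size:
                    axis = _isotropic_directions(j.size, rng)
                    for sign in (1.0, -1.0):
                        ns = nscat[j] + 1
                        keep2 = np.ones(j.size, dtype=bool)
                        if config.scatter_mode == "single_scatter_only":
                            keep2 = ns <= 1
                        if np.any(keep2):
                            new_parts.append((pos[j[keep2]], sign * axis[keep2],
                                              np.full(keep2.sum(), MEC2_MEV),
                                              hist[j[keep2]], ns[keep2]))

        pos, dirs, E, hist, nscat = (pos[survivors_mask], dirs[survivors_mask],
                                     E[survivors_mask], hist[survivors_mask],
                                     nscat[survivors_mask])
        if new_parts:
            pos = np.concatenate([pos] + [p[0] for p in new_parts])
            dirs = np.concatenate([dirs] + [p[1] for p in new_parts])
            E = np.concatenate([E] + [p[2] for p in new_parts])
            hist = np.concatenate([hist] + [p[3] for p in new_parts])
            nscat = np.concatenate([nscat] + [p[4] for p in new_parts])
    else:  # pragma: no cover
        raise RuntimeError("transport loop failed to terminate")

    _tally_exits(nb, exited, kerma, air_cs, z_prox, z_dist,
                 plane_z, plane_r, areas, accs, spec_edges,
                 ring_edges, ring_area, ring_f, ring_c)


def _run_batch_single_scatter(nb, rng, config, cs, kerma, air_cs, z_prox,
                              z_dist, lateral_cm, plane_z, plane_r, areas,
                              accs, spec_edges, ring_edges, ring_area,
                              ring_f, ring_c):
    """Unrolled analog kernel for single-scatter-only, Compton-only runs.

    With one scattering generation and a single open process the analog
    history has a closed control flow (at most two free paths), so the
    whole batch is simulated without the generic stepping loop.  Physics
    and estimators are identical to the generic path; only the RNG draw
    order differs.
    """
    src = config.source
    t_slab = config.slab.thickness
    e0 = float(src.mono_energy)
    mu0 = float(cs.mu(e0))
    hist = np.arange(nb)
    if src.kind == "parallel_circle":
        r = src.radius * np.sqrt(rng.random(nb))
        phi = 2 * np.pi * rng.random(nb)
        x, y = r * np.cos(phi), r * np.sin(phi)
    else:  # pencil
        x = np.zeros(nb)
        y = np.zeros(nb)

    depth = -np.log(rng.random(nb)) / mu0
    prim = depth >= t_slab
    exited = [(
        np.column_stack([x[prim], y[prim], np.full(prim.sum(), z_dist)]),
        np.tile([0.0, 0.0, 1.0], (int(prim.sum()), 1)),
        np.full(int(prim.sum()), e0),
        hist[prim],
    )]

    j = np.nonzero(~prim)[0]
    if j.size:
        e2, cos_t = sample_compton(np.full(j.size, e0), rng)
        phi2 = 2 * np.pi * rng.random(j.size)
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
        fwd = (cos_t > 0.0) & (e2 >= config.cutoff)
        j, e2, cos_t, sin_t, phi2 = (a[fwd] for a in (j, e2, cos_t, sin_t, phi2))
        d_exit = (t_slab - depth[j]) / cos_t
        mu2 = cs.mu(e2)
        esc = -np.log(rng.random(j.size)) / mu2 >= d_exit
        j, e2, cos_t, sin_t, phi2, d_exit = (
            a[esc] for a in (j, e2, cos_t, sin_t, phi2, d_exit))
        xe = x[j] + d_exit * sin_t * np.cos(phi2)
        ye = y[j] + d_exit * sin_t * np.sin(phi2)
        inside = xe**2 + ye**2 < lateral_cm**2
        dirs = np.column_stack([sin_t * np.cos(phi2), sin_t * np.sin(phi2), cos_t])
        exited.append((
            np.column_stack([xe, ye, np.full(j.size, z_dist)])[inside],
            dirs[inside], e2[inside], hist[j][inside],
        ))
    _tally_exits(nb, exited, kerma, air_cs, z_prox, z_dist,
                 plane_z, plane_r, areas, accs, spec_edges,
                 ring_edges, ring_area, ring_f, ring_c)


def _tally_exits(nb, exited, kerma, air_cs, z_prox, z_dist, plane_z, plane_r,
                 areas, accs, spec_edges, ring_edges, ring_area, ring_f,
                 ring_c):
    """Score photons that left the distal surface at every detector plane."""
    if not exited:
        for acc in accs:
            acc.add_batch(nb, np.empty(0, int), np.empty(0), np.empty(0),
                          np.empty(0), np.empty(0, int))
        return
    p_out = np.concatenate([e[0] for e in exited])
    d_out = np.concatenate([e[1] for e in exited])
    e_out = np.concatenate([e[2] for e in exited])
    h_out = np.concatenate([e[3] for e in exited])
    conv = kerma.conversion(e_out)
    bin_idx = np.clip(np.searchsorted(spec_edges, e_out, side="right") - 1,
                      0, spec_edges.size - 2)

    for i, (zk, rk, area, acc) in enumerate(zip(plane_z, plane_r, areas, accs)):
        with np.errstate(divide="ignore"):
            s = (zk - p_out[:, 2]) / d_out[:, 2]
        xy = p_out[:, :2] + s[:, None] * d_out[:, :2]
        r2 = np.einsum("ij,ij->i", xy, xy)
        sel = (d_out[:, 2] > 0) & (s >= 0) & (r2 <= rk**2)
        w = 1.0 / (area * np.maximum(d_out[sel, 2], _COS_FLOOR))
        if air_cs is not None:
            # straight-line air path: source->proximal face plus exit->plane
            air_path = (z_prox + (zk - z_dist)) / np.maximum(d_out[sel, 2], _COS_FLOOR)
            w = w * np.exp(-air_cs.mu(e_out[sel]) * air_path)
        acc.add_batch(nb, h_out[sel], w, w * conv[sel], e_out[sel], bin_idx[sel])
        if i == 0:
            r = np.sqrt(r2[d_out[:, 2] > 0])
            ring_idx = np.floor(r / ring_edges[1]).astype(int)
            ok = ring_idx < ring_f.size
            np.add.at(ring_f, ring_idx[ok],
                      1.0 / (ring_area[ring_idx[ok]]
                             * np.maximum(d_out[d_out[:, 2] > 0][ok, 2], _COS_FLOOR)))
            np.add.at(ring_c, ring_idx[ok], 1)
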