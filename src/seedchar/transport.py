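"""Analog photon Monte Carlo for seed-in-phantom dosimetry.

Two transport routes are provided on purpose:

* :func:`transport_photon` / :func:`score_kerma` — a plain per-photon Python
  implementation that returns explicit track segments.  It is slow but easy to
  audit and serves as an independent reference for the batch kernel.
* :func:`air_kerma_strength` / :func:`dose_rate_table` — the production route,
  a numba batch kernel with ring-cell track-length kerma tallies (see
  :mod:`seedchar._kernel`).

Physics (both routes): analog transport with exponential free paths; channels
photoelectric / incoherent (free-electron Klein-Nishina) / coherent (screened
form factor); silver K fluorescence above the 25.514 keV edge; kerma
approximation (collision kerma scored by track length, no electron transport —
secondary electron ranges at <= 35.5 keV are far below the cell sizes); energy
cutoff delta = 5 keV.

Dose tallies are per emitted photon in keV/g.  Air-kerma strength is returned
as K(d)*d^2 in keV*cm^2/g per emitted photon; the ratio of a water dose rate
to that quantity is numerically the dose rate constant in cGy/h/U because
cGy/(uGy*m^2) = 1/cm^2 and the per-history normalisation cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel, geometry
from .geometry import SeedModel
from .materials import (
    AG_K_EDGE_KEV,
    AG_K_XRAY_KEV,
    AG_K_YIELD,
    MATERIAL_INDEX,
    MATERIALS,
    CrossSectionTable,
    default_table,
)

__all__ = [
    "I125_SPECTRUM",
    "DEFAULT_RNG_SEED",
    "ENERGY_CUTOFF_KEV",
    "PhotonSpectrum",
    "PhotonState",
    "PhantomSpec",
    "TallyGrid",
    "sample_emission",
    "transport_photon",
    "score_kerma",
    "air_kerma_strength",
    "dose_rate_table",
]

ENERGY_CUTOFF_KEV = 5.0
DEFAULT_RNG_SEED = 20170914

# screening coefficient (per keV) for coherent angle sampling, indexed like
# MATERIAL_INDEX; built from an effective Z of the dominant scatterer
_FF_SCALE = 0.2754
_Z_EFF = {"vacuum": 1.0, "water": 8.0, "pmma": 6.7, "air": 7.4, "titanium": 22.0, "silver": 47.0}
_ALPHA_COEF = np.array(
    [_FF_SCALE * _Z_EFF[n] ** (-1.0 / 3.0) for n in sorted(MATERIAL_INDEX, key=MATERIAL_INDEX.get)]
)
_DENSITIES = np.array(
    [MATERIALS[n].density for n in sorted(MATERIAL_INDEX, key=MATERIAL_INDEX.get)]
)


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete line spectrum: energies in keV with emission probabilities."""

    energies_kev: tuple
    probabilities: tuple

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if e.size == 0:
            raise ValueError("empty spectrum")
        if e.size != p.size:
            raise ValueError("energies and probabilities differ in length")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"emission probabilities sum to {p.sum()}")
        object.__setattr__(self, "energies_kev", tuple(e))
        object.__setattr__(self, "probabilities", tuple(p))

    @property
    def mean_energy_kev(self) -> float:
        return float(
            np.dot(np.asarray(self.energies_kev), np.asarray(self.probabilities))
        )

    def cdf(self) -> np.ndarray:
        c = np.cumsum(np.asarray(self.probabilities))
        c[-1] = 1.0
        return c


#: The five-line 125-I emission spectrum (keV, probability).
I125_SPECTRUM = PhotonSpectrum(
    energies_kev=(27.2, 27.5, 31.0, 31.7, 35.5),
    probabilities=(0.275, 0.513, 0.137, 0.030, 0.045),
)


@dataclass
class PhotonState:
    position: np.ndarray
    direction: np.ndarray
    energy_kev: float
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            d = d / n
        self.direction = d


@dataclass(frozen=True)
class PhantomSpec:
    """Spherical phantom: medium name and radius in cm."""

    medium: str = "water"
    radius_cm: float = 15.0


@dataclass
class TallyGrid:
    """Ring-cell dose tallies on an (r, theta) grid.

    ``dose`` holds dose per emitted photon (keV/g) for each (radius, angle)
    cell; ``rel_err`` the relative standard error of the mean.
    """

    radii_cm: np.ndarray
    theta_deg: np.ndarray
    theta_edges_deg: np.ndarray
    shell_halfwidth_cm: float
    medium: str
    histories: int
    rng_seed: int
    dose: np.ndarray = None
    rel_err: np.ndarray = None
    energy_audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.radii_cm = np.asarray(self.radii_cm, dtype=float)
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.theta_edges_deg = np.asarray(self.theta_edges_deg, dtype=float)
        shape = (self.radii_cm.size, self.theta_deg.size)
        if self.dose is None:
            self.dose = np.zeros(shape)
        if self.rel_err is None:
            self.rel_err = np.zeros(shape)
        if self.histories <= 0:
            raise ValueError("history count must be positive")
        if np.any(np.diff(self.theta_edges_deg) <= 0):
            raise ValueError("theta edges must increase")

    def cell_volumes(self) -> np.ndarray:
        """Ring-cell volumes in cm^3, shape (n_r, n_theta)."""
        rlo = self.radii_cm - self.shell_halfwidth_cm
        rhi = self.radii_cm + self.shell_halfwidth_cm
        if np.any(rlo < 0):
            raise ValueError("shell halfwidth exceeds a scoring radius")
        tlo = np.radians(self.theta_edges_deg[:-1])
        thi = np.radians(self.theta_edges_deg[1:])
        radial = (rhi**3 - rlo**3) / 3.0
        polar = np.cos(tlo) - np.cos(thi)
        vol = 2.0 * math.pi * np.outer(radial, polar)
        if np.any(vol <= 0):
            raise ValueError("zero-volume tally cell")
        return vol

    def _indices(self, r: float, theta: float):
        ir = int(np.argmin(np.abs(self.radii_cm - r)))
        it = int(np.argmin(np.abs(self.theta_deg - theta)))
        if abs(self.radii_cm[ir] - r) > 1e-6 or abs(self.theta_deg[it] - theta) > 1e-6:
            raise KeyError(f"no tally cell at (r={r}, theta={theta})")
        return ir, it

    def value(self, r: float, theta: float = 90.0) -> float:
        ir, it = self._indices(r, theta)
        return float(self.dose[ir, it])

    def rel_err_at(self, r: float, theta: float = 90.0) -> float:
        ir, it = self._indices(r, theta)
        return float(self.rel_err[ir, it])

    def transverse(self) -> pd.DataFrame:
        """Transverse-axis (theta = 90 deg) profile as a DataFrame."""
        it = int(np.argmin(np.abs(self.theta_deg - 90.0)))
        return pd.DataFrame(
            {
                "r_cm": self.radii_cm,
                "dose_per_history": self.dose[:, it],
                "rel_err": self.rel_err[:, it],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rr, tt = np.meshgrid(self.radii_cm, self.theta_deg, indexing="ij")
        return pd.DataFrame(
            {
                "r_cm": rr.ravel(),
                "theta_deg": tt.ravel(),
                "dose_per_history": self.dose.ravel(),
                "rel_err": self.rel_err.ravel(),
                "medium": self.medium,
                "histories": self.histories,
                "seed": self.rng_seed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TallyGrid":
        df = pd.read_csv(path)
        radii = np.unique(df["r_cm"].to_numpy())
        theta = np.unique(df["theta_deg"].to_numpy())
        dose = np.full((radii.size, theta.size), np.nan)
        rel = np.full_like(dose, np.nan)
        ir = np.searchsorted(radii, df["r_cm"].to_numpy())
        it = np.searchsorted(theta, df["theta_deg"].to_numpy())
        dose[ir, it] = df["dose_per_history"].to_numpy()
        rel[ir, it] = df["rel_err"].to_numpy()
        edges = _theta_edges(theta)
        return cls(
            radii_cm=radii,
            theta_deg=theta,
            theta_edges_deg=edges,
            shell_halfwidth_cm=0.05,
            medium=str(df["medium"].iloc[0]),
            histories=int(df["histories"].iloc[0]),
            rng_seed=int(df["seed"].iloc[0]),
            dose=dose,
            rel_err=rel,
        )


def _theta_edges(theta_deg: np.ndarray, halfwidth: float = 5.0) -> np.ndarray:
    theta_deg = np.asarray(theta_deg, dtype=float)
    if theta_deg.size == 1:
        t = theta_deg[0]
        return np.array([max(0.0, t - halfwidth), min(180.0, t + halfwidth)])
    mids = 0.5 * (theta_deg[:-1] + theta_deg[1:])
    first = max(0.0, theta_deg[0] - (mids[0] - theta_deg[0]))
    last = min(180.0, theta_deg[-1] + (theta_deg[-1] - mids[-1]))
    return np.concatenate([[first], mids, [last]])


# ---------------------------------------------------------------------------
# Python reference route
# ---------------------------------------------------------------------------


def sample_emission(
    seed: SeedModel, spectrum: PhotonSpectrum, rng: np.random.Generator
) -> PhotonState:
    """Sample a source photon: uniform on the coating surface, isotropic."""
    rc = 0.5 * (seed.marker_radius + seed.coat_outer_radius)
    lat_area = 2.0 * math.pi * rc * seed.marker_length
    end_area = 2.0 * math.pi * seed.marker_radius**2 if seed.coat_end_faces else 0.0
    if rng.random() < lat_area / (lat_area + end_area):
        phi = 2.0 * math.pi * rng.random()
        pos = np.array(
            [
                rc * math.cos(phi),
                rc * math.sin(phi),
                seed.marker_half_length * (2.0 * rng.random() - 1.0),
            ]
        )
    else:
        phi = 2.0 * math.pi * rng.random()
        rr = seed.marker_radius * math.sqrt(rng.random())
        zmid = 0.5 * (seed.marker_half_length + seed.coat_half_length)
        pos = np.array(
            [rr * math.cos(phi), rr * math.sin(phi), zmid if rng.random() < 0.5 else -zmid]
        )
    mu = 1.0 - 2.0 * rng.random()
    phi = 2.0 * math.pi * rng.random()
    s = math.sqrt(max(0.0, 1.0 - mu * mu))
    direction = np.array([s * math.cos(phi), s * math.sin(phi), mu])
    energies = np.asarray(spectrum.energies_kev)
    idx = int(np.searchsorted(spectrum.cdf(), rng.random()))
    return PhotonState(pos, direction, float(energies[min(idx, energies.size - 1)]))


def _rotate_direction(d: np.ndarray, cos_t: float, phi: float) -> np.ndarray:
    s = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp, sp = math.cos(phi), math.sin(phi)
    ux, uy, uz = d
    if abs(uz) < 0.99999:
        denom = math.sqrt(1.0 - uz * uz)
        v = np.array(
            [
                (ux * uz * cp - uy * sp) / denom,
                (uy * uz * cp + ux * sp) / denom,
                -denom * cp,
            ]
        )
        out = d * cos_t + v * s
    else:
        out = np.array([s * cp, s * sp, cos_t if uz > 0 else -cos_t])
    return out / np.linalg.norm(out)


def _sample_kn_py(energy: float, rng: np.random.Generator):
    k = energy / 510.99895
    while True:
        c = 1.0 - 2.0 * rng.random()
        p = 1.0 / (1.0 + k * (1.0 - c))
        if rng.random() < 0.5 * p * p * (p + 1.0 / p - (1.0 - c * c)):
            return c, p


def _sample_rayleigh_py(alpha: float, rng: np.random.Generator) -> float:
    a2 = alpha * alpha
    while True:
        c = 1.0 - 2.0 * rng.random()
        ff = 1.0 / (1.0 + a2 * 0.5 * (1.0 - c)) ** 2
        if rng.random() < 0.5 * (1.0 + c * c) * ff * ff:
            return c


def transport_photon(
    state: PhotonState,
    seed: SeedModel | None,
    phantom: PhantomSpec,
    xs: CrossSectionTable | None = None,
    rng: np.random.Generator | None = None,
    cutoff_kev: float = ENERGY_CUTOFF_KEV,
):
    """Transport one photon; returns (segments, fate).

    ``segments`` is a list of ``(start, end, region, energy_kev)`` tuples,
    ``fate`` one of ``"absorbed" | "escaped" | "cutoff"``.  ``seed=None``
    transports in the bare phantom (point/pencil sources).
    """
    xs = xs or default_table()
    rng = rng or np.random.default_rng()
    if not state.alive:
        raise ValueError("photon is not alive")

    pos = state.position.copy()
    d = state.direction.copy()
    energy = state.energy_kev
    segments = []

    region_material = {
        "marker": "silver",
        "coating": "vacuum",
        "capsule_gap": "vacuum",
        "capsule_wall": "titanium",
        "exterior": phantom.medium,
    }

    while True:
        if seed is None:
            region = "exterior"
        else:
            region = geometry.region_at(seed, pos)
        mat = region_material[region]

        if seed is None or region == "exterior":
            b = float(np.dot(pos, d))
            c = float(np.dot(pos, pos)) - phantom.radius_cm**2
            t_sph = -b + math.sqrt(max(0.0, b * b - c))
            if seed is None:
                t_geo = math.inf
            else:
                t_geo, _ = geometry.distance_to_boundary(seed, geometry.Ray(pos, d))
            t_b = min(t_sph, t_geo)
            exits = t_sph <= t_geo
        else:
            t_b, _ = geometry.distance_to_boundary(seed, geometry.Ray(pos, d))
            exits = False
            if math.isinf(t_b):
                raise RuntimeError("inconsistent geometry: no boundary found")

        density = MATERIALS[mat].density
        if mat == "vacuum" or density == 0.0:
            mu = 0.0
        else:
            pe, inc, coh, _ = xs.coefficients(mat, energy)
            mu = (pe + inc + coh) * density

        step = -math.log(rng.random()) / mu if mu > 0 else math.inf
        t = min(step, t_b)
        end = pos + t * d
        segments.append((pos.copy(), end.copy(), region, energy))

        if step < t_b:
            pos = end
            u = rng.random() * (pe + inc + coh)
            if u < pe:
                if mat == "silver" and energy > AG_K_EDGE_KEV and rng.random() < AG_K_YIELD:
                    energy = AG_K_XRAY_KEV
                    mu_c = 1.0 - 2.0 * rng.random()
                    phi = 2.0 * math.pi * rng.random()
                    s = math.sqrt(max(0.0, 1.0 - mu_c * mu_c))
                    d = np.array([s * math.cos(phi), s * math.sin(phi), mu_c])
                    continue
                return segments, "absorbed"
            if u < pe + inc:
                cos_t, ratio = _sample_kn_py(energy, rng)
                d = _rotate_direction(d, cos_t, 2.0 * math.pi * rng.random())
                energy *= ratio
                if energy < cutoff_kev:
                    return segments, "cutoff"
            else:
                alpha = _ALPHA_COEF[MATERIAL_INDEX[mat]] * energy
                cos_t = _sample_rayleigh_py(alpha, rng)
                d = _rotate_direction(d, cos_t, 2.0 * math.pi * rng.random())
        else:
            pos = end + 1e-7 * d
            if exits and (seed is None or region == "exterior"):
                return segments, "escaped"


def score_kerma(
    histories,
    tally: TallyGrid,
    xs: CrossSectionTable | None = None,
    substep_cm: float = 0.01,
    score_medium: str | None = None,
) -> TallyGrid:
    """Track-length kerma estimator over the exterior segments of histories.

    ``histories`` is an iterable of per-photon segment lists as produced by
    :func:`transport_photon`.  Substeps of length ``substep_cm`` are binned by
    their midpoints, which converges to the exact ring-cell path length as the
    substep shrinks.  Variance is accumulated history by history.
    """
    xs = xs or default_table()
    medium = score_medium or tally.medium
    vol = tally.cell_volumes()
    rlo = tally.radii_cm - tally.shell_halfwidth_cm
    rhi = tally.radii_cm + tally.shell_halfwidth_cm
    t_edges = np.radians(tally.theta_edges_deg)
    cos_edges = np.cos(t_edges)  # decreasing
    rmax = rhi.max()

    n = len(histories)
    if n == 0:
        return tally
    sums = np.zeros_like(tally.dose)
    sumsq = np.zeros_like(tally.dose)
    for segs in histories:
        contrib = np.zeros_like(tally.dose)
        for start, end, region, energy in segs:
            if region != "exterior":
                continue
            start = np.asarray(start, dtype=float)
            end = np.asarray(end, dtype=float)
            vec = end - start
            length = float(np.linalg.norm(vec))
            if length <= 0:
                continue
            u = vec / length
            # clip to the radial band covered by the shells
            b = float(np.dot(start, u))
            c = float(np.dot(start, start)) - rmax * rmax
            disc = b * b - c
            if disc <= 0:
                continue
            t0 = max(0.0, -b - math.sqrt(disc))
            t1 = min(length, -b + math.sqrt(disc))
            if t1 <= t0:
                continue
            nstep = max(1, int(math.ceil((t1 - t0) / substep_cm)))
            h = (t1 - t0) / nstep
            tm = t0 + (np.arange(nstep) + 0.5) * h
            pts = start[None, :] + tm[:, None] * u[None, :]
            r = np.linalg.norm(pts, axis=1)
            ct = pts[:, 2] / r
            ir = np.searchsorted(rlo, r, side="right") - 1
            ok = (ir >= 0) & (r <= rhi[np.clip(ir, 0, len(rhi) - 1)])
            it = np.searchsorted(-cos_edges, -ct, side="right") - 1
            ok &= (it >= 0) & (it < tally.theta_deg.size)
            if not np.any(ok):
                continue
            w = h * energy * xs.mu_en(medium, energy)
            np.add.at(contrib, (ir[ok], it[ok]), w)
        contrib /= vol
        sums += contrib
        sumsq += contrib**2

    mean = sums / n
    var = np.maximum(0.0, sumsq / n - mean**2) / max(1, n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, np.sqrt(var) / mean, 0.0)
    tally.dose = tally.dose + mean
    tally.rel_err = rel
    tally.histories = n
    return tally


# ---------------------------------------------------------------------------
# Batch kernel route
# ---------------------------------------------------------------------------


def _run_kernel(
    seed_model: SeedModel | None,
    medium: str,
    score_medium: str,
    radii: np.ndarray,
    shell_halfwidth: float,
    theta_deg: np.ndarray,
    theta_edges_deg: np.ndarray,
    histories: int,
    rng_seed: int,
    spectrum: PhotonSpectrum,
    phantom_radius: float,
    xs: CrossSectionTable,
    substep: float = 0.02,
):
    point_source = 1 if seed_model is None else 0
    g = (seed_model or SeedModel()).geometry_params()
    region_mat = np.array(
        [
            MATERIAL_INDEX["silver"],
            MATERIAL_INDEX["vacuum"],
            MATERIAL_INDEX["vacuum"],
            MATERIAL_INDEX["titanium"],
            MATERIAL_INDEX[medium],
        ],
        dtype=np.int64,
    )
    log_e, log_pe, log_inc, log_coh, log_men, xs_len = xs.kernel_arrays()

    radii = np.asarray(radii, dtype=float)
    if np.any(radii + shell_halfwidth > phantom_radius):
        raise ValueError("scoring radius beyond the phantom boundary")
    edges = np.radians(np.asarray(theta_edges_deg, dtype=float))
    cos_hi = np.cos(edges[:-1])
    cos_lo = np.cos(edges[1:])

    tally = TallyGrid(
        radii_cm=radii,
        theta_deg=np.asarray(theta_deg, dtype=float),
        theta_edges_deg=np.asarray(theta_edges_deg, dtype=float),
        shell_halfwidth_cm=shell_halfwidth,
        medium=medium,
        histories=histories,
        rng_seed=rng_seed,
    )
    vol = tally.cell_volumes()

    n_cells = radii.size * tally.theta_deg.size
    tally_sum = np.zeros(n_cells)
    tally_sumsq = np.zeros(n_cells)

    emitted, absorbed, escaped, cut = _kernel.run_histories(
        histories,
        int(rng_seed) % (2**31),
        g,
        point_source,
        1 if (seed_model is None or seed_model.coat_end_faces) else 0,
        np.asarray(spectrum.energies_kev),
        spectrum.cdf(),
        region_mat,
        phantom_radius,
        _DENSITIES,
        log_e, log_pe, log_inc, log_coh, log_men, xs_len,
        MATERIAL_INDEX[score_medium],
        _ALPHA_COEF,
        radii - shell_halfwidth,
        radii + shell_halfwidth,
        cos_hi,
        cos_lo,
        vol.ravel(),
        ENERGY_CUTOFF_KEV,
        AG_K_EDGE_KEV,
        AG_K_XRAY_KEV,
        AG_K_YIELD,
        substep,
        tally_sum,
        tally_sumsq,
    )

    n = histories
    mean = tally_sum / n
    var = np.maximum(0.0, tally_sumsq / n - mean**2) / max(1, n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, np.sqrt(var) / mean, 0.0)
    tally.dose = mean.reshape(vol.shape)
    tally.rel_err = rel.reshape(vol.shape)
    tally.energy_audit = {
        "emitted_kev": emitted,
        "absorbed_kev": absorbed,
        "escaped_kev": escaped,
        "cutoff_kev": cut,
    }
    return tally


def air_kerma_strength(
    seed: SeedModel | None,
    spectrum: PhotonSpectrum = I125_SPECTRUM,
    histories: int = 2_000_000,
    rng_seed: int = DEFAULT_RNG_SEED,
    distance_cm: float = 10.0,
    shell_halfwidth_cm: float = 0.05,
    theta_halfwidth_deg: float = 1.0,
    vacuum_radius_cm: float = 15.0,
    xs: CrossSectionTable | None = None,
):
    """Air-kerma strength per emitted photon, scored in vacuum.

    The seed sits at the centre of a vacuum sphere; an air-response ring cell
    of radial extent ``2*shell_halfwidth_cm`` straddles the transverse axis at
    ``distance_cm`` (the ring-tally equivalent of a small transverse voxel).
    Returns ``(S_k per history in keV*cm^2/g, relative standard error)``.
    """
    if histories < 10_000:
        raise ValueError("air_kerma_strength needs at least 1e4 histories")
    xs = xs or default_table()
    tally = _run_kernel(
        seed,
        "vacuum",
        "air",
        np.array([distance_cm]),
        shell_halfwidth_cm,
        np.array([90.0]),
        np.array([90.0 - theta_halfwidth_deg, 90.0 + theta_halfwidth_deg]),
        histories,
        rng_seed,
        spectrum,
        vacuum_radius_cm,
        xs,
    )
    kerma = tally.value(distance_cm, 90.0)
    return kerma * distance_cm**2, tally.rel_err_at(distance_cm, 90.0)


def dose_rate_table(
    seed: SeedModel | None,
    medium: str,
    radii_cm,
    angles_deg,
    histories: int = 5_000_000,
    rng_seed: int = DEFAULT_RNG_SEED,
    shell_halfwidth_cm: float = 0.05,
    phantom_radius_cm: float = 15.0,
    spectrum: PhotonSpectrum = I125_SPECTRUM,
    xs: CrossSectionTable | None = None,
) -> TallyGrid:
    """Dose per emitted photon on an (r, theta) grid in a spherical phantom.

    ``medium`` is ``water`` or ``pmma`` (30 cm diameter sphere by default, the
    phantom used for parameter extraction).  Angles are polar angles in
    degrees measured from the seed long axis.
    """
    if medium not in ("water", "pmma"):
        raise ValueError("phantom medium must be 'water' or 'pmma'")
    xs = xs or default_table()
    radii = np.asarray(radii_cm, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    edges = _theta_edges(angles)
    return _run_kernel(
        seed,
        medium,
        medium,
        radii,
        shell_halfwidth_cm,
        angles,
        edges,
        histories,
        rng_seed,
        spectrum,
        phantom_radius_cm,
        xs,
    )
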