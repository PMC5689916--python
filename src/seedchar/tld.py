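"""Synthetic thermoluminescent-dosimetry campaign and its analysis chain.

The generator emulates the measurement protocol used to characterise a
low-energy seed in machined PMMA phantoms:

* Phantom I — holes in the transverse plane of the seed (polar angle 90 deg)
  at radii 0.5, 0.7 and 1-10 cm in 0.5 cm steps, every 5 deg of azimuth; used
  for the dose rate constant and the radial dose function.
* Phantom II — holes at radii 0.5, 0.7, 1, 1.5, 2, 3, 4, 5, 6, 7 cm and polar
  angles 0-350 deg in 10 deg steps (20 deg at r = 0.5 cm); used for the 2-D
  anisotropy function.

Six seeds of the labelled strengths are measured; readings are converted to
dose through a linear calibration curve (valid below 10 Gy), corrected for
the relative energy response of LiF dosimeters in PMMA, decay-corrected,
normalised per seed strength, averaged over seeds, and converted from PMMA to
water with P_phant(r, theta).  Angle columns are folded onto the 0-90 deg
quadrant by averaging each angle with its mirror images.

The noise model follows the standard budget for such campaigns: repetitive
reading scatter (CV 4.5%, independent per reading), hole positioning
(radial jitter equivalent to a 3.5% dose effect at 1 cm, drawn once per hole
per campaign — the holes are machined once and shared by all seeds), and
campaign-level systematics for calibration (2.6%), seed strength (3.0%) and
the PMMA-to-water conversion (3.0%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tg43 import (
    R0_CM,
    THETA0_DEG,
    TG43Dataset,
    geometry_function,
    reconstruct_dose_rate,
    reconstruct_dose_rate_array,
)
from .uncertainty import experimental_budget

__all__ = [
    "I125_HALF_LIFE_DAYS",
    "U_PER_MCI",
    "DEFAULT_STRENGTHS_MCI",
    "PhantomLayout",
    "NoiseModel",
    "CalibrationCurve",
    "TLDReadingSet",
    "generate_synthetic_readings",
    "readings_to_dose_rates",
    "average_supplementary_angles",
    "derive_experimental_parameters",
    "synthetic_truth_dataset",
]

I125_HALF_LIFE_DAYS = 59.4
U_PER_MCI = 1.270  # air-kerma strength per unit contained activity, U/mCi

#: labelled strengths of the six measured seeds, mCi
DEFAULT_STRENGTHS_MCI = (1.041, 1.016, 0.995, 0.991, 0.901, 0.860)

#: relative energy response of the LiF dosimeters in PMMA at the measurement
#: quality (~33 keV) and at the 48 keV calibration quality
ENERGY_RESPONSE_33 = 1.14
ENERGY_RESPONSE_48 = 1.17


@dataclass(frozen=True)
class PhantomLayout:
    """Hole pattern of one PMMA phantom."""

    phantom_id: str
    holes: pd.DataFrame  # columns: r_cm, angle_deg
    rod_length_cm: float = 0.6
    rod_diameter_cm: float = 0.1
    machining_tolerance_cm: float = 0.005

    @classmethod
    def phantom_I(cls) -> "PhantomLayout":
        """Transverse-plane layout (dose rate constant, g(r)); angle = azimuth."""
        radii = np.concatenate([[0.5, 0.7], np.arange(1.0, 10.01, 0.5)])
        angles = np.arange(0.0, 360.0, 5.0)
        rr, aa = np.meshgrid(radii, angles, indexing="ij")
        return cls("I", pd.DataFrame({"r_cm": rr.ravel(), "angle_deg": aa.ravel()}))

    @classmethod
    def phantom_II(cls) -> "PhantomLayout":
        """Polar layout (anisotropy function); angle = polar angle from seed axis."""
        rows = []
        for r in (0.5, 0.7, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0):
            # the innermost ring is sparser (20 deg) and offset by 10 deg so
            # that the 90 deg normalisation angle is among its holes
            angles = np.arange(10.0, 360.0, 20.0) if r == 0.5 else np.arange(0.0, 360.0, 10.0)
            for a in angles:
                rows.append((r, a))
        return cls("II", pd.DataFrame(rows, columns=["r_cm", "angle_deg"]))


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes of the measurement campaign, in percent."""

    repetitive_cv_pct: float = 4.5
    positioning_dose_pct: float = 3.5
    calibration_pct: float = 2.6
    seed_strength_pct: float = 3.0
    pmma_to_water_pct: float = 3.0

    def __post_init__(self) -> None:
        for f in (
            self.repetitive_cv_pct,
            self.positioning_dose_pct,
            self.calibration_pct,
            self.seed_strength_pct,
            self.pmma_to_water_pct,
        ):
            if f < 0:
                raise ValueError("noise components must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    @property
    def positioning_sigma_cm(self) -> float:
        """Radial jitter sigma giving the stated dose CV at r0 (dose ~ r^-2)."""
        return 0.5 * (self.positioning_dose_pct / 100.0) * R0_CM


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear TLD calibration: dose = slope * light; valid below 10 Gy."""

    slope_gy_per_unit: float = 5.0e-3
    linearity_bound_gy: float = 10.0

    def __post_init__(self) -> None:
        if self.slope_gy_per_unit <= 0:
            raise ValueError("calibration slope must be positive")


@dataclass
class TLDReadingSet:
    """Raw light-unit readings for a campaign of six seeds."""

    readings: pd.DataFrame  # seed_id, phantom, r_cm, angle_deg, reading, exposure_h
    strengths_mci: tuple = DEFAULT_STRENGTHS_MCI
    calibration: CalibrationCurve = field(default_factory=CalibrationCurve)
    energy_response: tuple = (ENERGY_RESPONSE_33, ENERGY_RESPONSE_48)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.strengths_mci) != 6:
            raise ValueError("a campaign measures six seeds")
        if (self.readings["reading"] < 0).any():
            raise ValueError("readings must be non-negative")

    def to_csv(self, path) -> None:
        self.readings.to_csv(path, index=False)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def effective_exposure_hours(exposure_h: float) -> float:
    """Decay-weighted exposure time: integral of 2^(-t/T1/2) over the exposure."""
    if exposure_h <= 0:
        raise ValueError("exposure must be positive")
    tau_h = I125_HALF_LIFE_DAYS * 24.0 / math.log(2.0)
    return tau_h * -math.expm1(-exposure_h / tau_h)


def _pphant_lookup(p_phant: pd.DataFrame | None, r, theta_deg):
    """Bilinear P_phant(r, theta) on the long-format conversion table."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta_deg, dtype=float)
    if p_phant is None:
        return np.ones(np.broadcast(r, theta).shape)
    grid = p_phant.pivot_table(index="r_cm", columns="theta_deg", values="p_phant")
    rr = grid.index.to_numpy(dtype=float)
    th = grid.columns.to_numpy(dtype=float)
    vals = grid.to_numpy()
    theta = np.where(theta > 180.0, 360.0 - theta, theta)
    theta = np.where((theta > 90.0) & (th.max() <= 90.0 + 1e-9), 180.0 - theta, theta)
    ir = np.clip(np.searchsorted(rr, r) - 1, 0, max(0, rr.size - 2))
    it = np.clip(np.searchsorted(th, theta) - 1, 0, max(0, th.size - 2))
    if rr.size == 1:
        fr = np.zeros_like(r)
        ir1 = ir
    else:
        fr = np.clip((r - rr[ir]) / (rr[ir + 1] - rr[ir]), 0.0, 1.0)
        ir1 = ir + 1
    if th.size == 1:
        ft = np.zeros_like(theta)
        it1 = it
    else:
        ft = np.clip((theta - th[it]) / (th[it + 1] - th[it]), 0.0, 1.0)
        it1 = it + 1
    return (
        vals[ir, it] * (1 - fr) * (1 - ft)
        + vals[ir, it1] * (1 - fr) * ft
        + vals[ir1, it] * fr * (1 - ft)
        + vals[ir1, it1] * fr * ft
    )


def _hole_polar_angles(layout: PhantomLayout) -> np.ndarray:
    """Polar angle (from the seed long axis) of every hole."""
    if layout.phantom_id == "I":
        return np.full(len(layout.holes), THETA0_DEG)
    return layout.holes["angle_deg"].to_numpy(dtype=float)


def generate_synthetic_readings(
    truth: TG43Dataset,
    layout: PhantomLayout,
    strengths_mci=DEFAULT_STRENGTHS_MCI,
    noise: NoiseModel | None = None,
    exposure_h: float = 48.0,
    rng: np.random.Generator | None = None,
    calibration: CalibrationCurve | None = None,
    rod_axis_points: int = 1,
) -> TLDReadingSet:
    """Simulate raw TLD readings for one campaign over ``layout``.

    The true dose to each dosimeter is the TG-43 reconstruction from ``truth``
    divided by P_phant (dose in PMMA), scaled by the decayed exposure;
    the reading is that dose through the calibration curve and energy
    response, degraded by the noise model.  ``rod_axis_points > 1`` averages
    the dose over sample points along the rod axis (volume averaging); the
    default treats dosimeters as points so that the noiseless chain inverts
    exactly.
    """
    if exposure_h <= 0:
        raise ValueError("exposure must be positive")
    noise = noise if noise is not None else NoiseModel()
    rng = rng or np.random.default_rng()
    calibration = calibration or CalibrationCurve()

    holes = layout.holes
    n_holes = len(holes)
    r_nom = holes["r_cm"].to_numpy(dtype=float)
    theta = _hole_polar_angles(layout) % 360.0
    theta = np.where(theta > 180.0, 360.0 - theta, theta)  # seed symmetry

    # campaign-level systematics (drawn once)
    f_cal = float(_lognormal_factor(rng, noise.calibration_pct / 100.0))
    f_strength = float(_lognormal_factor(rng, noise.seed_strength_pct / 100.0))
    f_pmma = float(_lognormal_factor(rng, noise.pmma_to_water_pct / 100.0))
    # hole positions are machined once: one radial jitter per hole
    dr = rng.normal(0.0, noise.positioning_sigma_cm, size=n_holes)
    r_true = np.clip(r_nom + dr, 0.05, None)

    pph = _pphant_lookup(truth.p_phant, r_nom, theta)
    resp = ENERGY_RESPONSE_33 / ENERGY_RESPONSE_48
    eff_h = effective_exposure_hours(exposure_h)

    rows = []
    for seed_id, strength in enumerate(strengths_mci):
        sk_true = strength * U_PER_MCI * f_strength
        if rod_axis_points <= 1:
            rate_w = reconstruct_dose_rate_array(truth, sk_true, r_true, theta)
        else:
            # volume averaging: sample points along the rod axis
            offs = (
                (np.arange(rod_axis_points) - (rod_axis_points - 1) / 2)
                / rod_axis_points
                * layout.rod_length_cm
            )
            rate_w = np.zeros(n_holes)
            for dz in offs:
                rp = np.hypot(r_true, dz)
                if layout.phantom_id == "I":
                    ct = np.full(n_holes, dz) / rp
                else:
                    ct = r_true * np.cos(np.radians(theta)) / rp
                rate_w += reconstruct_dose_rate_array(
                    truth, sk_true, rp, np.degrees(np.arccos(np.clip(ct, -1, 1)))
                )
            rate_w /= rod_axis_points
        rate_pmma = rate_w / pph * f_pmma  # cGy/h in the PMMA phantom
        dose_gy = rate_pmma / 100.0 * eff_h
        light = dose_gy * resp / (calibration.slope_gy_per_unit * f_cal)
        light = light * _lognormal_factor(rng, noise.repetitive_cv_pct / 100.0, n_holes)
        for i in range(n_holes):
            rows.append(
                (seed_id, layout.phantom_id, r_nom[i], holes["angle_deg"].iloc[i],
                 light[i], exposure_h)
            )

    readings = pd.DataFrame(
        rows, columns=["seed_id", "phantom", "r_cm", "angle_deg", "reading", "exposure_h"]
    )
    return TLDReadingSet(
        readings=readings,
        strengths_mci=tuple(strengths_mci),
        calibration=calibration,
        metadata={"exposure_h": exposure_h, "rod_axis_points": rod_axis_points},
    )


def readings_to_dose_rates(
    rs: TLDReadingSet, calibration: CalibrationCurve | None = None
) -> pd.DataFrame:
    """Per-hole PMMA dose rates per unit seed strength, averaged over seeds.

    dose = reading * slope / energy-response; rate = dose / decayed exposure;
    per-seed rates are normalised by the labelled strength (in U) and averaged
    over the six seeds.  Raises if any reading exceeds the calibration
    linearity bound (saturation).
    """
    cal = calibration or rs.calibration
    df = rs.readings.copy()
    dose_gy = df["reading"].to_numpy() * cal.slope_gy_per_unit
    if np.any(dose_gy > cal.linearity_bound_gy):
        raise ValueError("reading above the calibration linearity bound (saturation)")
    resp = rs.energy_response[0] / rs.energy_response[1]
    eff_h = np.array([effective_exposure_hours(t) for t in df["exposure_h"]])
    rate_cgy_h = dose_gy / resp / eff_h * 100.0
    sk_u = np.asarray(rs.strengths_mci)[df["seed_id"].to_numpy()] * U_PER_MCI
    df["rate_per_u"] = rate_cgy_h / sk_u
    out = (
        df.groupby(["phantom", "r_cm", "angle_deg"], as_index=False)["rate_per_u"]
        .mean()
    )
    return out


def average_supplementary_angles(table: pd.DataFrame) -> pd.DataFrame:
    """Fold a full-circle (r x angle) table onto the 0-90 deg quadrant.

    Each output angle theta is the mean of the available entries at theta,
    180-theta, 180+theta and 360-theta.  Idempotent on already-folded tables;
    missing entries are skipped, and the number averaged per cell is recorded
    in ``result.attrs["n_averaged"]``.
    """
    cols = np.asarray(table.columns, dtype=float)
    out_angles = sorted({a if a <= 90 else None for a in (_fold_angle(c) for c in cols)} - {None})
    data = {}
    counts = {}
    for a in out_angles:
        group = [c for c in cols if _fold_angle(c) == a]
        block = table[group].to_numpy(dtype=float)
        n = np.sum(np.isfinite(block), axis=1)
        s = np.nansum(block, axis=1)
        data[a] = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        counts[a] = n
    folded = pd.DataFrame(data, index=table.index)
    folded.columns.name = "theta_deg"
    folded.attrs["n_averaged"] = pd.DataFrame(counts, index=table.index)
    return folded


def _fold_angle(angle: float) -> float:
    a = angle % 360.0
    if a > 180.0:
        a = 360.0 - a
    if a > 90.0:
        a = 180.0 - a
    return round(a, 9)


def derive_experimental_parameters(
    rates_I: pd.DataFrame | None,
    rates_II: pd.DataFrame | None,
    p_phant: pd.DataFrame | None,
    active_length_cm: float,
    attach_uncertainty: bool = True,
) -> TG43Dataset:
    """Experimental-arm TG-43 parameters from measured dose rates.

    ``rates_I``/``rates_II`` are the outputs of :func:`readings_to_dose_rates`
    for Phantom I (transverse plane) and Phantom II (polar grid); either may
    be None if only part of the campaign ran.  PMMA rates are converted to
    water with ``p_phant``, then Lambda = D(r0, 90)/S_k (the rates are already
    per U), g(r) and F(r, theta) follow the TG-43 definitions with
    supplementary angles folded onto one quadrant.
    """
    if rates_I is None:
        raise ValueError("Phantom I rates are required (reference hole at r0)")

    d_I = rates_I[rates_I["phantom"] == "I"] if "phantom" in rates_I else rates_I
    pph = _pphant_lookup(
        p_phant, d_I["r_cm"].to_numpy(), np.full(len(d_I), THETA0_DEG)
    )
    water = d_I["rate_per_u"].to_numpy() * pph
    by_r = (
        pd.DataFrame({"r_cm": d_I["r_cm"].to_numpy(), "rate": water})
        .groupby("r_cm", as_index=False)["rate"]
        .mean()
    )
    radii = by_r["r_cm"].to_numpy()
    rates = by_r["rate"].to_numpy()
    at_r0 = np.isclose(radii, R0_CM)
    if not at_r0.any():
        raise ValueError("missing reference hole at r0 = 1 cm")

    # Lambda comes from the designated reference hole (lowest azimuth at r0),
    # matching the budget's treatment of positioning and repetitive scatter as
    # full-size components; the azimuthal ring averages are used for g(r).
    ref = d_I[np.isclose(d_I["r_cm"].to_numpy(), R0_CM)]
    ref = ref[ref["angle_deg"] == ref["angle_deg"].min()]
    ref_pph = _pphant_lookup(p_phant, ref["r_cm"].to_numpy(), np.array([THETA0_DEG]))
    lam = float(ref["rate_per_u"].to_numpy()[0] * ref_pph[0])

    gg = geometry_function(radii, THETA0_DEG, active_length_cm)
    g0 = geometry_function(R0_CM, THETA0_DEG, active_length_cm)
    g = (rates / float(rates[at_r0][0])) * (g0 / gg)  # ring means, Eq. of g(r)
    g[at_r0] = 1.0
    g_table = pd.DataFrame({"r_cm": radii, "g": g, "rel_err": np.nan})

    if rates_II is not None:
        d_II = rates_II[rates_II["phantom"] == "II"] if "phantom" in rates_II else rates_II
        pph2 = _pphant_lookup(
            p_phant, d_II["r_cm"].to_numpy(), d_II["angle_deg"].to_numpy()
        )
        wide = (
            pd.DataFrame(
                {
                    "r_cm": d_II["r_cm"].to_numpy(),
                    "angle_deg": d_II["angle_deg"].to_numpy(),
                    "rate": d_II["rate_per_u"].to_numpy() * pph2,
                }
            )
            .pivot_table(index="r_cm", columns="angle_deg", values="rate")
        )
        folded = average_supplementary_angles(wide)
        rr = folded.index.to_numpy(dtype=float)
        th = folded.columns.to_numpy(dtype=float)
        if not np.any(np.isclose(th, THETA0_DEG)):
            raise ValueError("Phantom II grid is missing the 90 deg column")
        ggrid = geometry_function(rr[:, None], th[None, :], active_length_cm)
        it90 = int(np.flatnonzero(np.isclose(th, THETA0_DEG))[0])
        d = folded.to_numpy()
        f = (d / d[:, [it90]]) * (ggrid[:, [it90]] / ggrid)
        f[:, it90] = 1.0
        f_table = pd.DataFrame(
            f, index=pd.Index(rr, name="r_cm"), columns=pd.Index(th, name="theta_deg")
        )
    else:
        f_table = pd.DataFrame(
            np.ones((radii.size, 1)),
            index=pd.Index(radii, name="r_cm"),
            columns=pd.Index([THETA0_DEG], name="theta_deg"),
        )

    unc = experimental_budget().total_pct if attach_uncertainty else None
    return TG43Dataset(
        lambda_=lam,
        active_length_cm=active_length_cm,
        g_table=g_table,
        f_table=f_table,
        p_phant=p_phant,
        lambda_uncertainty_pct=unc,
        provenance={"arm": "experimental (synthetic TLD campaign)"},
    )


def synthetic_truth_dataset(
    lambda_=0.965, active_length_cm: float = 0.325
) -> TG43Dataset:
    """A smooth synthetic TG-43 parameter set used as ground truth in tests.

    Not derived from any measurement or simulation: g(r) is a falling
    exponential matching the typical transverse fall-off of a low-energy
    seed, F dips toward the long axis with a radius-dependent amplitude, and
    P_phant carries the typical magnitude and slow radial trend of a
    medium-dose ratio.  Useful wherever a known, cheap ground truth is needed
    (e.g. parameter-recovery studies of the measurement chain).
    """
    radii = np.concatenate([[0.5, 0.7], np.arange(1.0, 10.01, 0.5)])
    g = np.exp(-0.25 * (radii - 1.0) - 0.005 * (radii**2 - 1.0))
    g_table = pd.DataFrame({"r_cm": radii, "g": g, "rel_err": 0.0})

    th = np.arange(0.0, 90.01, 10.0)
    f_rad = np.concatenate([[0.5, 0.7], np.arange(1.0, 7.01, 0.5)])
    amp = 0.6 / (1.0 + 0.1 * (f_rad - 1.0))
    f = 1.0 - np.outer(amp, np.cos(np.radians(th)) ** 2)
    f_table = pd.DataFrame(
        f, index=pd.Index(f_rad, name="r_cm"), columns=pd.Index(th, name="theta_deg")
    )

    rr, tt = np.meshgrid(radii, np.arange(0.0, 180.01, 10.0), indexing="ij")
    pp = 1.60 * np.exp(-0.03 * (rr - 1.0))
    p_phant = pd.DataFrame(
        {
            "r_cm": rr.ravel(),
            "theta_deg": tt.ravel(),
            "p_phant": pp.ravel(),
            "rel_err": 0.0,
        }
    )
    return TG43Dataset(
        lambda_=lambda_,
        active_length_cm=active_length_cm,
        g_table=g_table,
        f_table=f_table,
        p_phant=p_phant,
        provenance={"arm": "synthetic truth"},
    )
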