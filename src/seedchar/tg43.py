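"""TG-43 formalism: geometry function, dose rate constant, g(r), F(r,theta).

The formalism factorises the dose rate around a cylindrically symmetric seed
as::

    D(r, theta) = S_k * Lambda * G(r,theta)/G(r0,theta0) * g(r) * F(r,theta)

with the reference point at r0 = 1 cm on the transverse axis (theta0 = 90
deg), the line-source geometry function G(r,theta) = beta/(L r sin theta)
(beta = angle subtended by the active length L at the field point), the radial
dose function g(r) normalised to 1 at r0, and the 2-D anisotropy function
F(r,theta) normalised to 1 at 90 deg for every radius.

Radial dose functions and per-radius anisotropy columns are additionally
summarised by unweighted fifth-order polynomial fits (g in r; F in theta
expressed in radians).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .transport import TallyGrid

__all__ = [
    "R0_CM",
    "THETA0_DEG",
    "GeometryFunctionParams",
    "TG43Dataset",
    "geometry_function",
    "dose_rate_constant",
    "average_dose_rate_constant",
    "radial_dose_function",
    "fit_radial_poly",
    "anisotropy_function",
    "fit_anisotropy_poly",
    "pmma_to_water_factor",
    "reconstruct_dose_rate",
]

R0_CM = 1.0
THETA0_DEG = 90.0


@dataclass(frozen=True)
class GeometryFunctionParams:
    """Line-source parameters at a field point: active length and beta."""

    length_cm: float
    beta_rad: float

    def __post_init__(self) -> None:
        if self.length_cm <= 0:
            raise ValueError("active length must be positive")
        if not (0.0 < self.beta_rad < math.pi):
            raise ValueError("beta must lie in (0, pi)")


def geometry_function(r, theta_deg, length_cm: float):
    """Line-source geometry function G(r, theta) in cm^-2.

    ``beta/(L r sin theta)`` with the TG-43 long-axis limit ``1/(r^2 - L^2/4)``
    at theta = 0 or 180 deg, and the point-source limit ``1/r^2`` for L = 0.
    Raises if a long-axis point lies inside the source extent (r <= L/2).
    """
    r = np.asarray(r, dtype=float)
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if length_cm == 0.0:
        return 1.0 / (r * r) if r.shape else float(1.0 / (r * r))

    half = length_cm / 2.0
    sin_t = np.sin(theta)
    cos_t = np.cos(theta)
    on_axis = np.isclose(sin_t, 0.0, atol=1e-12)
    if np.any(on_axis & (r <= half)):
        raise ValueError("field point on the long axis inside the source extent")

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.arctan2(half + r * cos_t, r * sin_t) + np.arctan2(
            half - r * cos_t, r * sin_t
        )
        g = beta / (length_cm * r * sin_t)
    g_axis = 1.0 / (r * r - half * half)
    out = np.where(on_axis, g_axis, g)
    return float(out) if out.shape == () else out


def dose_rate_constant(dose_rate_at_ref: float, s_k: float) -> float:
    """Lambda = D(r0, theta0) / S_k.

    Both inputs must share one emission normalisation (e.g. per history); the
    normalisation cancels in the ratio.  With the dose in keV/g and S_k in
    keV cm^2/g per history the result is numerically in cGy/h/U, because
    1 cGy/(uGy m^2) = 1 cm^-2.
    """
    if s_k <= 0:
        raise ValueError("air-kerma strength must be positive")
    return dose_rate_at_ref / s_k


def average_dose_rate_constant(lambda_mc: float, lambda_exp: float) -> float:
    """Consensus dose rate constant: arithmetic mean of the MC and measured values."""
    if lambda_mc <= 0 or lambda_exp <= 0:
        raise ValueError("dose rate constants must be positive")
    return 0.5 * (lambda_mc + lambda_exp)


def _transverse_column(tally: TallyGrid):
    it = np.flatnonzero(np.isclose(tally.theta_deg, THETA0_DEG))
    if it.size == 0:
        raise ValueError("tally has no theta = 90 deg cells")
    return int(it[0])


def radial_dose_function(tally: TallyGrid, length_cm: float) -> pd.DataFrame:
    """g(r) from a tally: [D(r,90)/D(r0,90)] * [G(r0,90)/G(r,90)]; g(r0) = 1."""
    it = _transverse_column(tally)
    ir0 = np.flatnonzero(np.isclose(tally.radii_cm, R0_CM))
    if ir0.size == 0:
        raise ValueError("tally is missing the reference radius r0 = 1 cm")
    d = tally.dose[:, it]
    e = tally.rel_err[:, it]
    d0 = d[int(ir0[0])]
    if d0 <= 0:
        raise ValueError("empty reference cell")
    gg = geometry_function(tally.radii_cm, THETA0_DEG, length_cm)
    g0 = geometry_function(R0_CM, THETA0_DEG, length_cm)
    g = (d / d0) * (g0 / gg)
    rel = np.sqrt(e**2 + e[int(ir0[0])] ** 2)
    rel[int(ir0[0])] = 0.0
    g[int(ir0[0])] = 1.0  # exact by construction
    return pd.DataFrame({"r_cm": tally.radii_cm, "g": g, "rel_err": rel})


def fit_radial_poly(g_table: pd.DataFrame):
    """Unweighted fifth-order polynomial fit of g(r); returns (coeffs, residuals).

    ``coeffs`` are a0..a5 with g(r) = sum a_i r^i; ``residuals`` the per-point
    fit residuals (max reported by callers as a diagnostic).
    """
    r = np.asarray(g_table["r_cm"], dtype=float)
    g = np.asarray(g_table["g"], dtype=float)
    keep = np.isfinite(g)
    r, g = r[keep], g[keep]
    if r.size < 7:
        raise ValueError("need at least 7 radii for a quintic fit")
    v = np.vander(r, 6, increasing=True)
    if np.linalg.matrix_rank(v) < 6:
        raise ValueError("rank-deficient design matrix")
    coeffs, *_ = np.linalg.lstsq(v, g, rcond=None)
    residuals = g - v @ coeffs
    return coeffs, residuals


def anisotropy_function(tally: TallyGrid, length_cm: float) -> pd.DataFrame:
    """F(r, theta) table (rows r, columns theta in degrees), F(r, 90) = 1."""
    it90 = _transverse_column(tally)
    gg = geometry_function(
        tally.radii_cm[:, None],
        tally.theta_deg[None, :],
        length_cm,
    )
    d = tally.dose
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (d / d[:, [it90]]) * (gg[:, [it90]] / gg)
    f[:, it90] = 1.0  # exact by construction
    return pd.DataFrame(f, index=pd.Index(tally.radii_cm, name="r_cm"),
                        columns=pd.Index(tally.theta_deg, name="theta_deg"))


def fit_anisotropy_poly(f_column, theta_deg=None):
    """Quintic fit of one F(r, .) column with theta in radians.

    Accepts a pandas Series indexed by theta in degrees, or (values, angles).
    Missing entries (NaN) are skipped.  Returns (p0..p5, residuals); p0
    approximates F(r, 0).
    """
    if theta_deg is None:
        theta_deg = np.asarray(f_column.index, dtype=float)
        values = np.asarray(f_column, dtype=float)
    else:
        values = np.asarray(f_column, dtype=float)
        theta_deg = np.asarray(theta_deg, dtype=float)
    keep = np.isfinite(values)
    th = np.radians(theta_deg[keep])
    f = values[keep]
    if f.size < 7:
        raise ValueError("need at least 7 angles for a quintic fit")
    v = np.vander(th, 6, increasing=True)
    if np.linalg.matrix_rank(v) < 6:
        raise ValueError("rank-deficient design matrix")
    coeffs, *_ = np.linalg.lstsq(v, f, rcond=None)
    return coeffs, f - v @ coeffs


def pmma_to_water_factor(tally_water: TallyGrid, tally_pmma: TallyGrid) -> pd.DataFrame:
    """P_phant(r, theta) = D_water(r, theta) / D_pmma(r, theta), long format.

    Relative errors combine in quadrature (independent runs).
    """
    if (
        not np.array_equal(tally_water.radii_cm, tally_pmma.radii_cm)
        or not np.array_equal(tally_water.theta_deg, tally_pmma.theta_deg)
    ):
        raise ValueError("water and PMMA tallies are on different grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tally_water.dose / tally_pmma.dose
    rel = np.sqrt(tally_water.rel_err**2 + tally_pmma.rel_err**2)
    rr, tt = np.meshgrid(tally_water.radii_cm, tally_water.theta_deg, indexing="ij")
    return pd.DataFrame(
        {
            "r_cm": rr.ravel(),
            "theta_deg": tt.ravel(),
            "p_phant": ratio.ravel(),
            "rel_err": rel.ravel(),
        }
    )


@dataclass
class TG43Dataset:
    """A complete parameter set for one seed model.

    ``lambda_`` in cGy/h/U; ``g_table`` from :func:`radial_dose_function`;
    ``f_table`` from :func:`anisotropy_function`; optional fit coefficients
    and PMMA-to-water conversion factors; ``provenance`` records histories,
    RNG seeds and media.
    """

    lambda_: float
    active_length_cm: float
    g_table: pd.DataFrame
    f_table: pd.DataFrame
    g_coeffs: np.ndarray | None = None
    f_coeffs: pd.DataFrame | None = None  # rows r_cm, columns p0..p5
    p_phant: pd.DataFrame | None = None
    lambda_uncertainty_pct: float | None = None
    provenance: dict = field(default_factory=dict)
    r0_cm: float = R0_CM
    theta0_deg: float = THETA0_DEG

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, g_tol: float = 0.05) -> None:
        if self.lambda_ <= 0:
            raise ValueError("Lambda must be positive")
        if self.active_length_cm <= 0:
            raise ValueError("active length must be positive")
        g = self.g_table.set_index("r_cm")["g"]
        if not any(np.isclose(g.index, self.r0_cm)):
            raise ValueError("g table is missing r0")
        g_r0 = float(g.loc[np.isclose(g.index, self.r0_cm)].iloc[0])
        if abs(g_r0 - 1.0) > g_tol:
            raise ValueError(f"g(r0) = {g_r0}, expected 1 within {g_tol}")
        f90 = self.f_table[THETA0_DEG] if THETA0_DEG in self.f_table.columns else None
        if f90 is None or not np.allclose(f90.to_numpy(), 1.0):
            raise ValueError("F(r, 90 deg) must equal 1 for every tabulated radius")
        vals = self.f_table.to_numpy()
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("anisotropy function must be positive")

    # -- evaluation ---------------------------------------------------------
    def g_of_r(self, r: float, allow_extrapolation: bool = False) -> float:
        rr = self.g_table["r_cm"].to_numpy()
        if not allow_extrapolation and not (rr.min() - 1e-9 <= r <= rr.max() + 1e-9):
            raise ValueError(f"r = {r} outside tabulated range [{rr.min()}, {rr.max()}]")
        if self.g_coeffs is not None:
            return float(np.polynomial.polynomial.polyval(r, self.g_coeffs))
        g = self.g_table["g"].to_numpy()
        # log-linear in r between table nodes
        return float(np.exp(np.interp(r, rr, np.log(g))))

    def f_of(self, r: float, theta_deg: float, allow_extrapolation: bool = False) -> float:
        rr = self.f_table.index.to_numpy(dtype=float)
        th = self.f_table.columns.to_numpy(dtype=float)
        theta_deg = float(theta_deg) % 360.0
        if theta_deg > 180.0:
            theta_deg = 360.0 - theta_deg
        if theta_deg > 90.0 and th.max() <= 90.0 + 1e-9:
            theta_deg = 180.0 - theta_deg  # symmetric seed, folded table
        if not allow_extrapolation:
            if not (rr.min() - 1e-9 <= r <= rr.max() + 1e-9):
                raise ValueError(f"r = {r} outside tabulated F range")
            if not (th.min() - 1e-9 <= theta_deg <= th.max() + 1e-9):
                raise ValueError(f"theta = {theta_deg} outside tabulated F range")
        vals = self.f_table.to_numpy()
        # bilinear with NaN-aware column fill
        ir = np.clip(np.searchsorted(rr, r) - 1, 0, rr.size - 2)
        it = np.clip(np.searchsorted(th, theta_deg) - 1, 0, th.size - 2)
        fr = 0.0 if rr[ir + 1] == rr[ir] else (r - rr[ir]) / (rr[ir + 1] - rr[ir])
        ft = 0.0 if th[it + 1] == th[it] else (theta_deg - th[it]) / (th[it + 1] - th[it])
        fr = min(max(fr, 0.0), 1.0)
        ft = min(max(ft, 0.0), 1.0)
        quad = vals[ir : ir + 2, it : it + 2]
        if np.any(~np.isfinite(quad)):
            finite = vals[np.isfinite(vals[:, it]), it]
            return float(finite[0]) if finite.size else 1.0
        top = quad[0, 0] * (1 - ft) + quad[0, 1] * ft
        bot = quad[1, 0] * (1 - ft) + quad[1, 1] * ft
        return float(top * (1 - fr) + bot * fr)

    # -- persistence --------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "lambda_cgy_per_h_per_u": [self.lambda_],
                "uncertainty_pct": [self.lambda_uncertainty_pct],
                "active_length_cm": [self.active_length_cm],
            }
        ).to_csv(d / "lambda.csv", index=False)
        self.g_table.to_csv(d / "g.csv", index=False)
        if self.g_coeffs is not None:
            pd.DataFrame({"coeff": [f"a{i}" for i in range(6)], "value": self.g_coeffs}).to_csv(
                d / "g_fit.csv", index=False
            )
        self.f_table.to_csv(d / "F.csv")
        if self.f_coeffs is not None:
            self.f_coeffs.to_csv(d / "F_fit.csv")
        if self.p_phant is not None:
            self.p_phant.to_csv(d / "pphant.csv", index=False)
        (d / "metadata.json").write_text(
            json.dumps(
                {
                    "r0_cm": self.r0_cm,
                    "theta0_deg": self.theta0_deg,
                    "provenance": self.provenance,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, directory) -> "TG43Dataset":
        d = Path(directory)
        lam = pd.read_csv(d / "lambda.csv")
        g_table = pd.read_csv(d / "g.csv")
        f_table = pd.read_csv(d / "F.csv", index_col=0)
        f_table.columns = f_table.columns.astype(float)
        f_table.index = f_table.index.astype(float)
        g_coeffs = None
        if (d / "g_fit.csv").exists():
            g_coeffs = pd.read_csv(d / "g_fit.csv")["value"].to_numpy()
        f_coeffs = None
        if (d / "F_fit.csv").exists():
            f_coeffs = pd.read_csv(d / "F_fit.csv", index_col=0)
        p_phant = pd.read_csv(d / "pphant.csv") if (d / "pphant.csv").exists() else None
        meta = json.loads((d / "metadata.json").read_text())
        unc = lam["uncertainty_pct"].iloc[0]
        return cls(
            lambda_=float(lam["lambda_cgy_per_h_per_u"].iloc[0]),
            active_length_cm=float(lam["active_length_cm"].iloc[0]),
            g_table=g_table,
            f_table=f_table,
            g_coeffs=g_coeffs,
            f_coeffs=f_coeffs,
            p_phant=p_phant,
            lambda_uncertainty_pct=None if pd.isna(unc) else float(unc),
            provenance=meta.get("provenance", {}),
            r0_cm=float(meta["r0_cm"]),
            theta0_deg=float(meta["theta0_deg"]),
        )


def reconstruct_dose_rate_array(
    ds: TG43Dataset, s_k: float, r, theta_deg
) -> np.ndarray:
    """Vectorised TG-43 reconstruction over arrays of (r, theta).

    Equivalent to calling :func:`reconstruct_dose_rate` elementwise with
    ``allow_extrapolation=True``; requires an all-finite anisotropy table.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float)) % 360.0
    theta = np.where(theta > 180.0, 360.0 - theta, theta)

    if ds.g_coeffs is not None:
        g = np.polynomial.polynomial.polyval(r, ds.g_coeffs)
    else:
        rr = ds.g_table["r_cm"].to_numpy(dtype=float)
        g = np.exp(np.interp(r, rr, np.log(ds.g_table["g"].to_numpy(dtype=float))))

    fr_r = ds.f_table.index.to_numpy(dtype=float)
    fr_t = ds.f_table.columns.to_numpy(dtype=float)
    vals = ds.f_table.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        f = np.array(
            [ds.f_of(ri, ti, allow_extrapolation=True) for ri, ti in zip(r, theta)]
        )
    else:
        th = np.where((theta > 90.0) & (fr_t.max() <= 90.0 + 1e-9), 180.0 - theta, theta)
        ir = np.clip(np.searchsorted(fr_r, r) - 1, 0, max(0, fr_r.size - 2))
        it = np.clip(np.searchsorted(fr_t, th) - 1, 0, max(0, fr_t.size - 2))
        fr = np.clip((r - fr_r[ir]) / (fr_r[ir + 1] - fr_r[ir]), 0.0, 1.0)
        ft = np.clip((th - fr_t[it]) / (fr_t[it + 1] - fr_t[it]), 0.0, 1.0)
        f = (
            vals[ir, it] * (1 - fr) * (1 - ft)
            + vals[ir, it + 1] * (1 - fr) * ft
            + vals[ir + 1, it] * fr * (1 - ft)
            + vals[ir + 1, it + 1] * fr * ft
        )

    gg = geometry_function(r, theta, ds.active_length_cm)
    g0 = geometry_function(ds.r0_cm, ds.theta0_deg, ds.active_length_cm)
    return s_k * ds.lambda_ * (gg / g0) * g * f


def reconstruct_dose_rate(
    ds: TG43Dataset,
    s_k: float,
    r: float,
    theta_deg: float,
    allow_extrapolation: bool = False,
) -> float:
    """Dose rate in cGy/h at (r, theta) for a seed of strength ``s_k`` (U).

    Standard TG-43 recombination: S_k * Lambda * G/G0 * g(r) * F(r,theta).
    Polar angles outside [0, 180] deg are folded by the source symmetry.
    """
    theta_deg = float(theta_deg) % 360.0
    if theta_deg > 180.0:
        theta_deg = 360.0 - theta_deg
    gg = geometry_function(r, theta_deg, ds.active_length_cm)
    g0 = geometry_function(ds.r0_cm, ds.theta0_deg, ds.active_length_cm)
    return (
        s_k
        * ds.lambda_
        * (gg / g0)
        * ds.g_of_r(r, allow_extrapolation)
        * ds.f_of(r, theta_deg, allow_extrapolation)
    )
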