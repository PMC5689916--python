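"""Type A / Type B uncertainty budgets combined in quadrature.

Components are relative standard uncertainties in percent.  Totals are the
root sum of squares with no covariance terms, reported at one decimal
(half-up), matching standard dosimetry budget tables; full precision is kept
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .transport import TallyGrid

__all__ = [
    "BudgetComponent",
    "UncertaintyBudget",
    "rss_total",
    "lambda_uncertainty",
    "mc_statistical_errors",
    "experimental_budget",
    "mc_budget",
]


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BudgetComponent:
    name: str
    value_pct: float
    type: str  # "A" (statistical) or "B" (systematic)

    def __post_init__(self) -> None:
        if self.value_pct < 0:
            raise ValueError("uncertainty components must be non-negative")
        if self.type not in ("A", "B"):
            raise ValueError("component type must be 'A' or 'B'")


@dataclass
class UncertaintyBudget:
    name: str
    components: list = field(default_factory=list)

    def add(self, name: str, value_pct: float, type: str) -> "UncertaintyBudget":
        self.components.append(BudgetComponent(name, value_pct, type))
        return self

    @property
    def total_pct(self) -> float:
        """Quadrature total at full precision."""
        return float(np.sqrt(sum(c.value_pct**2 for c in self.components)))

    @property
    def reported_total_pct(self) -> float:
        """Quadrature total rounded half-up to one decimal."""
        return _round_half_up(self.total_pct)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": c.name, "type": c.type, "value_pct": c.value_pct}
            for c in self.components
        ]
        rows.append(
            {"component": "Total standard uncertainty", "type": "",
             "value_pct": self.reported_total_pct}
        )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "UncertaintyBudget":
        df = pd.read_csv(path)
        budget = cls(name or str(path))
        for _, row in df.iterrows():
            if str(row["component"]).lower().startswith("total"):
                continue
            budget.add(str(row["component"]), float(row["value_pct"]), str(row["type"]))
        return budget


def rss_total(components_pct) -> float:
    """Root-sum-square total of percent components, one decimal, half-up."""
    comps = np.asarray(list(components_pct), dtype=float)
    if np.any(comps < 0):
        raise ValueError("uncertainty components must be non-negative")
    return _round_half_up(float(np.sqrt(np.sum(comps**2))))


def lambda_uncertainty(u_dose_pct: float, u_sk_pct: float) -> float:
    """%u_Lambda = sqrt(%u_D(r0,theta0)^2 + %u_Sk^2), full precision."""
    if u_dose_pct < 0 or u_sk_pct < 0:
        raise ValueError("uncertainties must be non-negative")
    return float(np.hypot(u_dose_pct, u_sk_pct))


def mc_statistical_errors(tally: TallyGrid) -> pd.DataFrame:
    """Per-cell relative standard errors in percent from an MC tally."""
    if tally.histories <= 0:
        raise ValueError("tally has no histories")
    rr, tt = np.meshgrid(tally.radii_cm, tally.theta_deg, indexing="ij")
    return pd.DataFrame(
        {
            "r_cm": rr.ravel(),
            "theta_deg": tt.ravel(),
            "rel_err_pct": 100.0 * tally.rel_err.ravel(),
        }
    )


def experimental_budget(
    seed_strength: float = 3.0,
    positioning: float = 3.5,
    calibration: float = 2.6,
    pmma_to_water: float = 3.0,
    repetitive: float = 4.5,
) -> UncertaintyBudget:
    """The TLD-measurement budget for the dose rate constant."""
    b = UncertaintyBudget("experimental dose rate constant")
    b.add("Seed strength", seed_strength, "B")
    b.add("TLD source position", positioning, "B")
    b.add("TLD dose calibration", calibration, "B")
    b.add("PMMA-to-water conversion", pmma_to_water, "B")
    b.add("Repetitive measurements", repetitive, "A")
    return b


def mc_budget(
    statistics: float = 3.2,
    positioning: float = 3.5,
    cross_sections: float = 1.5,
    seed_geometry: float = 2.0,
    source_spectrum: float = 0.2,
    dose_deposition: float = 0.5,
) -> UncertaintyBudget:
    """The Monte Carlo budget for the dose rate constant."""
    b = UncertaintyBudget("Monte Carlo dose rate constant")
    b.add("MC Statistics", statistics, "A")
    b.add("Seed/TLD positioning uncertainty", positioning, "B")
    b.add("Cross-sections", cross_sections, "B")
    b.add("Seed geometry", seed_geometry, "B")
    b.add("Source spectrum", source_spectrum, "B")
    b.add("Dose deposition", dose_deposition, "A")
    return b
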