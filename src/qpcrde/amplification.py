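"""Standard-curve amplification efficiency and efficiency-adjusted Cp.

A qPCR reaction at amplification factor ``E`` multiplies the template by
``E`` each cycle; a perfectly efficient reaction doubles it (``E = 2``).
Efficiencies are reported throughout as the *fraction* ``E - 1`` -- so
"93%" means ``E = 1.93``.  A serial-dilution standard curve of Cp against
log10 relative concentration has slope ``-1/log10(E)``; ordinary least
squares on that line is the estimator.

Downstream modelling works on the efficiency-adjusted scale
``y = Cp * log2(1 + efficiency)``: one unit of ``y`` corresponds to a
two-fold difference in starting template regardless of the gene's
efficiency, which makes fold changes ``2**(-diff)`` exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "EfficiencyEstimate",
    "fit_standard_curve",
    "transform_cp",
    "read_dilution_series",
    "write_efficiencies",
]


@dataclass(frozen=True)
class DilutionSeries:
    """A per-gene standard curve: (relative concentration, Cp) points.

    Concentrations are dimensionless fractions relative to the undiluted
    pool (1, 0.5, 0.25, 0.125 for a 1:2 series).
    """

    gene: str
    concentrations: tuple[float, ...]
    cps: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.cps):
            raise ValueError("concentrations and cps differ in length")
        if len(self.concentrations) < 3:
            raise ValueError("a standard curve needs at least 3 points")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if len(set(self.concentrations)) < 2:
            raise ValueError("concentrations must not all be equal")


@dataclass(frozen=True)
class EfficiencyEstimate:
    gene: str
    slope: float  # cycles per log10 concentration
    efficiency_fraction: float  # E - 1
    r2_fit: float


def fit_standard_curve(series: DilutionSeries) -> EfficiencyEstimate:
    """Estimate amplification efficiency from a dilution series by OLS.

    Regresses Cp on log10(relative concentration); the efficiency fraction
    is ``10**(-1/slope) - 1``.  A slope of exactly ``-1/log10(2)`` (about
    -3.32 cycles per decade) corresponds to perfect doubling.  Estimates
    above 110% are physically implausible and trigger a warning.
    """
    x = np.log10(np.asarray(series.concentrations, dtype=float))
    y = np.asarray(series.cps, dtype=float)
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if slope >= 0:
        raise ValueError(
            f"standard curve for {series.gene} has non-negative slope {slope:.3f}; "
            "Cp must decrease with concentration"
        )
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    r2 = float(fit.rvalue) ** 2
    if efficiency > 1.1:
        warnings.warn(
            f"{series.gene}: estimated efficiency {efficiency:.1%} exceeds 110%; "
            "check the dilution series",
            stacklevel=2,
        )
    return EfficiencyEstimate(
        gene=series.gene, slope=slope, efficiency_fraction=efficiency, r2_fit=r2
    )


def transform_cp(cp: float | np.ndarray, efficiency_fraction: float):
    """Map Cp cycles onto the log2 template-quantity scale.

    Returns ``cp * log2(1 + efficiency_fraction)``; at 100% efficiency the
    transform is the identity.  Linear in ``cp``, so contrasts of
    transformed values are contrasts of log2 template amounts.
    """
    if efficiency_fraction <= 0:
        raise ValueError(f"efficiency_fraction must be > 0, got {efficiency_fraction}")
    if efficiency_fraction > 1.1:
        warnings.warn(
            f"efficiency_fraction {efficiency_fraction:.3f} exceeds 110%",
            stacklevel=2,
        )
    return cp * math.log2(1.0 + efficiency_fraction)


def read_dilution_series(path: str) -> list[DilutionSeries]:
    """Read a dilution CSV with columns gene, dilution_factor, cp.

    ``dilution_factor`` is the fold dilution (1, 2, 4, 8); the relative
    concentration used in the regression is its reciprocal.
    """
    df = pd.read_csv(path)
    for colname in ("gene", "dilution_factor", "cp"):
        if colname not in df.columns:
            raise ValueError(f"dilution CSV is missing column {colname!r}")
    out = []
    for gene, grp in df.groupby("gene", sort=True):
        conc = tuple(1.0 / grp["dilution_factor"].astype(float))
        out.append(
            DilutionSeries(
                gene=str(gene), concentrations=conc, cps=tuple(grp["cp"].astype(float))
            )
        )
    return out


def write_efficiencies(estimates: list[EfficiencyEstimate], path: str) -> None:
    pd.DataFrame(
        {
            "gene": [e.gene for e in estimates],
            "slope": [e.slope for e in estimates],
            "efficiency_fraction": [e.efficiency_fraction for e in estimates],
            "r2_fit": [e.r2_fit for e in estimates],
        }
    ).to_csv(path, sep="\t", index=False)
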