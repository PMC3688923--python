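"""Estimate per-gene amplification efficiencies from dilution series.

Builds four-point 1:2 serial dilution curves for three reference genes
at their known efficiencies (93%, 80%, 87%) plus a perfectly doubling
assay, fits each standard curve by OLS of Cp on log10 concentration, and
prints slope, efficiency and fit quality.  The slope of -3.32 cycles per
decade is the textbook signature of 100% efficiency.
"""

import math

from qpcrde import DilutionSeries, fit_standard_curve

GENES = {"B2M": 1.93, "ACTB": 1.80, "TOP2B": 1.87, "perfect": 2.00}

for gene, E in GENES.items():
    conc = (1.0, 0.5, 0.25, 0.125)
    cps = tuple(24.0 - math.log10(c) / math.log10(E) for c in conc)
    est = fit_standard_curve(DilutionSeries(gene, conc, cps))
    print(
        f"{gene:8s} slope={est.slope:8.4f} cycles/decade   "
        f"efficiency={est.efficiency_fraction:7.2%}   r2={est.r2_fit:.4f}"
    )

print(
    "\nEfficiency is the per-cycle amplification factor minus 1; it feeds "
    "the Cp transform y = Cp * log2(1 + efficiency) used by the mixed model."
)
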