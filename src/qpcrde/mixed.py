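"""Joint target+reference Cp mixed model and normalized expression contrasts.

The response is the efficiency-adjusted crossing point
``y = Cp * log2(1 + E_gene)``.  For tissue profiling the model is

    y = plate + [sex] + TG(tissue, gene) + B(gene, animal, tissue)
        + D(animal, tissue) + e,

with ``TG`` fixed cell-mean effects, ``B`` a gene-specific random effect
of each biological sample, ``D`` a random sample effect shared by all
genes measured on that sample, and a homogeneous residual.  For
genotype-conditional analyses the ``TG`` cells are genotype x tissue x
gene.  Variance components are estimated by REML (statsmodels MixedLM);
fixed effects are the corresponding GLS solutions.

Differential expression between two classes a, b (tissues or genotypes)
for a target gene, normalized by K reference genes, is the contrast

    diff = [TG(target,a) - TG(target,b)] - (1/K) * sum_ref [TG(ref,a) - TG(ref,b)]

on the transformed-Cp scale.  Because higher Cp means less template, the
fold change is ``FC = 2**(-diff)`` with the asymmetric 95% interval
``(2**(-diff - z*SE), 2**(-diff + z*SE))``, multiplicatively symmetric
about FC (so ci_low * ci_high = FC**2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .amplification import transform_cp
from .data import Dataset, GenotypeTable, validate_dataset

__all__ = [
    "ModelSpec",
    "MixedFit",
    "ContrastResult",
    "FitError",
    "ContrastError",
    "fold_change",
    "fold_change_ci",
    "build_model",
    "fit_reml",
    "normalized_contrast",
    "run_tissue_profile",
    "run_genotype_profile",
]

#: two-sided 95% standard-normal multiplier used for the asymmetric CIs
Z_95 = float(sps.norm.ppf(0.975))

CELL_SEP = "|"


class FitError(RuntimeError):
    """REML estimation failed to converge or the design is degenerate."""


class ContrastError(ValueError):
    """A requested contrast names a cell that was not estimated."""


# ----------------------------------------------------------------------
# fold change / CI transforms
# ----------------------------------------------------------------------

def fold_change(estimate: float) -> float:
    """Fold change implied by a transformed-Cp contrast: ``2**(-estimate)``.

    A negative contrast (class a cycles earlier) means class a has *more*
    template, hence FC > 1.
    """
    return float(2.0 ** (-estimate))


def fold_change_ci(
    estimate: float, se: float, level: float = 0.95
) -> tuple[float, float]:
    """Asymmetric confidence interval for a fold change.

    Computed on the log2 scale as ``estimate -/+ z*se`` and
    back-transformed; returned ordered (low, high).  The interval is
    multiplicatively symmetric about ``fold_change(estimate)``.
    """
    if se < 0:
        raise ValueError("se must be non-negative")
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    a = 2.0 ** (-estimate - z * se)
    b = 2.0 ** (-estimate + z * se)
    return (min(a, b), max(a, b))


# ----------------------------------------------------------------------
# model building
# ----------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A ready-to-fit design: long-format frame plus formula pieces."""

    frame: pd.DataFrame  # columns: y, cell, plate, sex, sample, gene
    analysis: str  # "tissue" | "genotype"
    include_sex: bool
    snp: str | None = None
    dropped_classes: list[str] = field(default_factory=list)

    @property
    def formula(self) -> str:
        terms = ["0", "C(cell)"]
        if self.frame["plate"].nunique() > 1:
            terms.append("C(plate)")
        if self.include_sex and self.frame["sex"].nunique() > 1:
            terms.append("C(sex)")
        return "y ~ " + " + ".join(terms)

    @property
    def cells(self) -> list[str]:
        return sorted(self.frame["cell"].unique())

    @property
    def n_b_levels(self) -> int:
        return self.frame.groupby(["gene", "sample"]).ngroups

    @property
    def n_d_levels(self) -> int:
        return self.frame["sample"].nunique()

    @property
    def b_identifiable(self) -> bool:
        """B is separable from the residual only if some gene x sample is
        measured more than once and B does not coincide with D."""
        if self.frame["gene"].nunique() < 2:
            return False
        counts = self.frame.groupby(["gene", "sample"]).size()
        return bool((counts > 1).any())


def _cell_label(*parts: str) -> str:
    return CELL_SEP.join(parts)


def build_model(
    ds: Dataset,
    analysis: str = "tissue",
    genes: Sequence[str] | None = None,
    genotypes: GenotypeTable | None = None,
    snp: str | None = None,
    include_sex: bool = False,
    quant_threshold: float = 0.5,
    min_class_animals: int = 2,
) -> ModelSpec:
    """Assemble the mixed-model design from a validated dataset.

    Observations enter the response only if they are detectable and their
    gene x tissue cell passes the quantifiability screen (fraction
    detectable >= ``quant_threshold``).  For ``analysis="genotype"`` each
    animal is labelled by its call at ``snp``; animals without a call are
    dropped, as are genotype classes with fewer than ``min_class_animals``
    animals (near-empty homozygote classes in a backcross).
    """
    if analysis not in ("tissue", "genotype"):
        raise ValueError(f"unknown analysis {analysis!r}")
    gene_set = set(genes) if genes is not None else set(ds.genes)
    unknown = gene_set - set(ds.genes)
    if unknown:
        raise ValueError(f"genes not in dataset: {sorted(unknown)}")

    flagged = validate_dataset(ds, threshold=quant_threshold).flagged_cells

    genotype_of: dict[str, str] = {}
    dropped: list[str] = []
    if analysis == "genotype":
        if genotypes is None or snp is None:
            raise ValueError("genotype analysis needs a GenotypeTable and a SNP id")
        if snp not in genotypes.snps:
            raise ValueError(f"SNP {snp!r} absent from genotype table")
        classes = genotypes.genotype_classes(snp)
        for cls, animals in sorted(classes.items()):
            if len(animals) < min_class_animals:
                dropped.append(cls)
                warnings.warn(
                    f"genotype class {cls} at {snp} has {len(animals)} animal(s); "
                    "dropped from the analysis",
                    stacklevel=2,
                )
                continue
            for a in animals:
                genotype_of[a] = cls
        if len(set(genotype_of.values())) < 2:
            raise FitError(
                f"fewer than 2 genotype classes survive at {snp}; cannot contrast"
            )

    rows = []
    for o in ds.observations:
        if o.gene not in gene_set or not o.detectable:
            continue
        if (o.gene, o.tissue) in flagged:
            continue
        if analysis == "genotype":
            cls = genotype_of.get(o.animal_id)
            if cls is None:
                continue
            cell = _cell_label(cls, o.tissue, o.gene)
        else:
            cell = _cell_label(o.tissue, o.gene)
        eff = ds.efficiency_of(o.gene)
        rows.append(
            {
                "y": transform_cp(o.cp_mean, eff),
                "cell": cell,
                "plate": o.plate_id,
                "sex": o.sex,
                "sample": _cell_label(o.animal_id, o.tissue),
                "gene": o.gene,
            }
        )
    if not rows:
        raise FitError("no usable observations after detectability screening")
    frame = pd.DataFrame(rows)

    small = frame.groupby("cell").size()
    thin = small[small < 2]
    if len(thin):
        warnings.warn(
            f"{len(thin)} model cell(s) have a single observation: "
            f"{list(thin.index)[:5]}...",
            stacklevel=2,
        )
    return ModelSpec(
        frame=frame,
        analysis=analysis,
        include_sex=include_sex,
        snp=snp,
        dropped_classes=dropped,
    )


# ----------------------------------------------------------------------
# REML fitting
# ----------------------------------------------------------------------

@dataclass
class MixedFit:
    """REML variance components and GLS fixed effects with covariance."""

    spec: ModelSpec
    fixed_estimates: pd.Series  # indexed by design-column name
    fixed_covariance: pd.DataFrame
    variance_components: dict  # sigma2_b, sigma2_d, sigma2_e
    converged: bool
    loglik_reml: float
    b_confounded: bool

    def cell_coef_name(self, cell: str) -> str:
        return f"C(cell)[{cell}]"

    def cell_estimate(self, cell: str) -> float:
        name = self.cell_coef_name(cell)
        if name not in self.fixed_estimates.index:
            raise ContrastError(f"cell {cell!r} was not estimated (flagged or empty)")
        return float(self.fixed_estimates[name])


def _ols_fit(spec: ModelSpec):
    import statsmodels.formula.api as smf

    return smf.ols(spec.formula, data=spec.frame).fit()


def fit_reml(spec: ModelSpec, max_iter: int = 200) -> MixedFit:
    """Fit the mixed model by REML.

    The sample effect D is a per-(animal, tissue) random intercept; the
    gene-specific effect B is a variance component over genes within each
    sample.  When the design measures every gene x sample exactly once, B
    is indistinguishable from the residual and is folded into it (reported
    as 0 with ``b_confounded=True``); contrast estimates and their
    standard errors are unaffected.

    Noise-free data (a perfect fit) short-circuits to ordinary least
    squares with all variance components zero.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    ols = _ols_fit(spec)
    n, k = spec.frame.shape[0], len(ols.params)
    if n > k and ols.ssr / max(n - k, 1) < 1e-12:
        cov = pd.DataFrame(
            np.zeros((k, k)), index=ols.params.index, columns=ols.params.index
        )
        return MixedFit(
            spec=spec,
            fixed_estimates=ols.params,
            fixed_covariance=cov,
            variance_components={"sigma2_b": 0.0, "sigma2_d": 0.0, "sigma2_e": 0.0},
            converged=True,
            loglik_reml=float("nan"),
            b_confounded=not spec.b_identifiable,
        )

    use_vc = spec.b_identifiable
    kwargs = dict(groups="sample", re_formula="1")
    if use_vc:
        kwargs["vc_formula"] = {"bgene": "0 + C(gene)"}
    model = smf.mixedlm(spec.formula, data=spec.frame, **kwargs)

    result = None
    errors = []
    for method in ("bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                cand = model.fit(reml=True, method=method, maxiter=max_iter)
            if cand.converged:
                result = cand
                break
            if result is None:
                result = cand
            errors.append(f"{method}: did not converge")
        except (np.linalg.LinAlgError, ValueError) as exc:
            errors.append(f"{method}: {exc}")
    if result is None:
        raise FitError("REML fit failed: " + "; ".join(errors))

    k_fe = model.k_fe
    fe = result.fe_params
    cov_all = result.cov_params()
    cov_fe = pd.DataFrame(
        np.asarray(cov_all)[:k_fe, :k_fe], index=fe.index, columns=fe.index
    )
    sigma2_d = float(np.asarray(result.cov_re)[0, 0])
    sigma2_b = float(result.vcomp[0]) if use_vc else 0.0
    return MixedFit(
        spec=spec,
        fixed_estimates=fe,
        fixed_covariance=cov_fe,
        variance_components={
            "sigma2_b": max(sigma2_b, 0.0),
            "sigma2_d": max(sigma2_d, 0.0),
            "sigma2_e": float(result.scale),
        },
        converged=bool(result.converged),
        loglik_reml=float(result.llf),
        b_confounded=not use_vc,
    )


# ----------------------------------------------------------------------
# contrasts
# ----------------------------------------------------------------------

@dataclass
class ContrastResult:
    target_gene: str
    class_a: str
    class_b: str
    tissue: str | None
    estimate: float
    se: float
    t_stat: float
    p_value: float
    fold_change: float
    ci_low: float
    ci_high: float
    references: tuple[str, ...] = ()

    def as_row(self) -> dict:
        return {
            "target": self.target_gene,
            "tissue": self.tissue,
            "comparison": f"{self.class_a}-{self.class_b}",
            "FC": self.fold_change,
            "estimator": self.estimate,
            "SE": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "t": self.t_stat,
            "p_value": self.p_value,
        }


def _contrast_cells(
    spec: ModelSpec, gene: str, cls: str, tissue: str | None
) -> str:
    if spec.analysis == "genotype":
        if tissue is None:
            raise ContrastError("genotype contrasts need an explicit tissue")
        return _cell_label(cls, tissue, gene)
    return _cell_label(cls, gene)


def normalized_contrast(
    fit: MixedFit,
    target: str,
    class_a: str,
    class_b: str,
    references: Sequence[str],
    tissue: str | None = None,
    level: float = 0.95,
    df: float | None = None,
) -> ContrastResult:
    """Reference-normalized expression contrast between two classes.

    ``df=None`` (default) uses the standard-normal reference distribution
    for the p-value and the CI multiplier; passing a numeric ``df`` uses a
    Student t reference instead.
    """
    references = list(references)
    if not references:
        raise ValueError("reference gene list must not be empty")
    coeffs: dict[str, float] = {}

    def add(cell: str, w: float) -> None:
        name = fit.cell_coef_name(cell)
        if name not in fit.fixed_estimates.index:
            raise ContrastError(f"cell {cell!r} was not estimated (flagged or empty)")
        coeffs[name] = coeffs.get(name, 0.0) + w

    add(_contrast_cells(fit.spec, target, class_a, tissue), 1.0)
    add(_contrast_cells(fit.spec, target, class_b, tissue), -1.0)
    k = len(references)
    for ref in references:
        add(_contrast_cells(fit.spec, ref, class_a, tissue), -1.0 / k)
        add(_contrast_cells(fit.spec, ref, class_b, tissue), 1.0 / k)

    c = pd.Series(0.0, index=fit.fixed_estimates.index)
    for name, w in coeffs.items():
        c[name] = w
    est = float(c @ fit.fixed_estimates)
    var = float(c @ fit.fixed_covariance @ c)
    se = math.sqrt(max(var, 0.0))

    if se > 0:
        t_stat = est / se
        if df is None:
            p = float(2.0 * sps.norm.sf(abs(t_stat)))
        else:
            p = float(2.0 * sps.t.sf(abs(t_stat), df))
    else:
        t_stat = 0.0 if est == 0 else math.copysign(math.inf, est)
        p = float("nan") if est != 0 else 1.0

    if df is None:
        lo, hi = fold_change_ci(est, se, level)
    else:
        q = float(sps.t.ppf(0.5 + level / 2.0, df))
        lo, hi = sorted((2.0 ** (-est - q * se), 2.0 ** (-est + q * se)))
    return ContrastResult(
        target_gene=target,
        class_a=class_a,
        class_b=class_b,
        tissue=tissue,
        estimate=est,
        se=se,
        t_stat=t_stat,
        p_value=p,
        fold_change=fold_change(est),
        ci_low=lo,
        ci_high=hi,
        references=tuple(references),
    )


def _bh_adjust(results: list[ContrastResult]) -> None:
    from statsmodels.stats.multitest import multipletests

    ps = [r.p_value for r in results]
    if any(math.isnan(p) for p in ps):
        return
    _, adj, _, _ = multipletests(ps, method="fdr_bh")
    for r, p in zip(results, adj):
        r.p_value = float(p)


def run_tissue_profile(
    ds: Dataset,
    target: str,
    references: Sequence[str],
    include_sex: bool = False,
    quant_threshold: float = 0.5,
    bh: bool = False,
    fit: MixedFit | None = None,
) -> list[ContrastResult]:
    """All pairwise tissue contrasts for one target gene.

    Fits the joint target+reference model once and emits every tissue
    pair, oriented so that ``class_b`` is the lower-expression tissue of
    the pair (fold changes >= 1, the convention used for reporting
    expression relative to the least-expressing tissue).  Benjamini-
    Hochberg adjustment across the emitted contrasts is optional and off
    by default.
    """
    references = list(references)
    if fit is None:
        spec = build_model(
            ds,
            analysis="tissue",
            genes=[target, *references],
            include_sex=include_sex,
            quant_threshold=quant_threshold,
        )
        fit = fit_reml(spec)
    # tissues where the target was quantifiable
    tissues = sorted(
        {
            cell.split(CELL_SEP)[0]
            for cell in fit.spec.cells
            if cell.split(CELL_SEP)[1] == target
        }
    )
    # normalized level per tissue on the transformed-Cp scale; the tissue
    # with the highest level has the lowest expression
    level_of = {}
    for t in tissues:
        tg = fit.cell_estimate(_cell_label(t, target))
        refmean = np.mean(
            [fit.cell_estimate(_cell_label(t, r)) for r in references]
        )
        level_of[t] = tg - refmean
    out: list[ContrastResult] = []
    for i, a in enumerate(tissues):
        for b in tissues[i + 1 :]:
            lo_expr = a if level_of[a] >= level_of[b] else b  # higher Cp level
            hi_expr = b if lo_expr == a else a
            out.append(
                normalized_contrast(fit, target, hi_expr, lo_expr, references)
            )
    if bh:
        _bh_adjust(out)
    return out


def run_genotype_profile(
    ds: Dataset,
    genotypes: GenotypeTable,
    snp: str,
    target: str,
    references: Sequence[str],
    tissue: str,
    include_sex: bool = False,
    quant_threshold: float = 0.5,
    bh: bool = False,
) -> list[ContrastResult]:
    """Pairwise genotype contrasts for one target gene in one tissue.

    Genotype classes with fewer than two animals are dropped before
    fitting; contrasts are emitted for every surviving pair in
    lexicographic order (e.g. CC-CT, CC-TT, CT-TT).
    """
    references = list(references)
    spec = build_model(
        ds,
        analysis="genotype",
        genes=[target, *references],
        genotypes=genotypes,
        snp=snp,
        include_sex=include_sex,
        quant_threshold=quant_threshold,
    )
    fit = fit_reml(spec)
    classes = sorted(
        {
            cell.split(CELL_SEP)[0]
            for cell in fit.spec.cells
            if cell.split(CELL_SEP)[1] == tissue
            and cell.split(CELL_SEP)[2] == target
        }
    )
    if len(classes) < 2:
        raise ContrastError(
            f"fewer than 2 genotype classes with quantifiable {target} in {tissue}"
        )
    out = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            out.append(
                normalized_contrast(fit, target, a, b, references, tissue=tissue)
            )
    if bh:
        _bh_adjust(out)
    return out


def results_table(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Flatten contrast results into a report table."""
    return pd.DataFrame([r.as_row() for r in results])
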