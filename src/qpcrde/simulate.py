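"""Synthetic Cp datasets, genotypes and parameter-recovery experiments.

The generator draws data from exactly the model family the analysis fits:
on the efficiency-adjusted scale each measurement is

    y = baseline - expression + plate + [sex] + B(gene, sample) + D(sample) + e,

where ``expression`` is the configured true log2 template level of the
gene in that tissue (plus any additive SNP effects), B and D are the
gene-specific and shared random sample effects, and e is residual noise.
y is back-converted to Cp cycles through the per-gene efficiency, and
triplicate well noise is added on the Cp scale before averaging --
mimicking a thermocycler run.  Undetectable gene x tissue combinations
are emitted as missing wells.

Everything is driven by one integer seed; the same seed reproduces the
dataset byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CpObservation, Dataset, GeneInfo, GenotypeTable
from .mixed import build_model, fit_reml, normalized_contrast, MixedFit

__all__ = [
    "GeneSim",
    "SnpSim",
    "SimulationConfig",
    "SimulationTruth",
    "ContrastSpec",
    "simulate_cp_dataset",
    "simulate_genotypes",
    "recovery_experiment",
    "paper_mimic_config",
]

DEFAULT_TISSUES = ("hypothalamus", "liver", "backfat", "longissimus_dorsi", "diaphragm")


@dataclass(frozen=True)
class GeneSim:
    """True simulation parameters for one gene."""

    name: str
    role: str  # "target" | "reference"
    efficiency: float  # fraction, e.g. 0.93
    baseline_cp: float = 25.0
    levels: Mapping[str, float] = field(default_factory=dict)  # tissue -> log2 expr
    detectable_tissues: tuple[str, ...] | None = None  # None = everywhere

    def level(self, tissue: str) -> float:
        return float(self.levels.get(tissue, 0.0))


@dataclass(frozen=True)
class SnpSim:
    """A SNP (or a block of perfectly cosegregating SNPs).

    All SNPs in ``names`` are copies of one underlying genotype draw, so
    within-block r^2 is 1 by construction.  ``effects`` maps
    (gene, tissue) to the additive log2 expression shift per copy of the
    minor allele.
    """

    names: tuple[str, ...]
    maf: float
    alleles: tuple[str, str] = ("C", "T")  # (major, minor)
    effects: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf must be in [0, 1], got {self.maf}")


@dataclass(frozen=True)
class SimulationConfig:
    """The study design the generator emulates.

    Defaults mirror a backcross expression study: 40 animals, five
    tissues, two reference plus four target transcripts measured in
    triplicate wells on 384-well plates, with variance components
    (sigma2_b, sigma2_d, sigma2_e) = (0.25, 0.25, 0.5) on the
    efficiency-adjusted log2 scale and 0.15 cycles of well-level noise.
    """

    seed: int
    genes: tuple[GeneSim, ...]
    n_animals: int = 40
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_plates: int = 10
    sigma2_b: float = 0.25
    sigma2_d: float = 0.25
    sigma2_e: float = 0.5
    plate_effect_sd: float = 0.2
    replicate_count: int = 3
    replicate_sd: float = 0.15
    snps: tuple[SnpSim, ...] = ()
    n_females: int = 0
    sex_effect: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.sigma2_b, self.sigma2_d, self.sigma2_e):
            if v < 0:
                raise ValueError("variance components must be >= 0")
        if not self.genes:
            raise ValueError("at least one gene must be configured")
        if self.n_animals < 2:
            raise ValueError("need at least 2 animals")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated dataset."""

    config: SimulationConfig
    genotypes: GenotypeTable | None
    dosages: pd.DataFrame | None  # animals x snps, minor-allele copies

    def expression(self, gene: str, tissue: str, animal: str | None = None) -> float:
        """True log2 expression of a gene in a tissue (optionally per animal,
        including its SNP effects)."""
        gsim = next(g for g in self.config.genes if g.name == gene)
        level = gsim.level(tissue)
        if animal is not None and self.dosages is not None:
            for snp in self.config.snps:
                d = float(self.dosages.at[animal, snp.names[0]])
                level += d * snp.effects.get((gene, tissue), 0.0)
        return level

    def true_contrast(
        self,
        target: str,
        class_a: str,
        class_b: str,
        tissue: str | None = None,
        snp: str | None = None,
    ) -> dict:
        """True model-scale estimate and fold change for a contrast.

        For tissue contrasts the classes are tissue labels; for genotype
        contrasts they are genotype strings at ``snp`` and ``tissue``
        names the tissue.  The model-scale estimate carries the opposite
        sign of the log2 expression difference (more template = fewer
        cycles), so FC = 2**(-estimate).
        """
        if snp is None:
            ea = self.expression(target, class_a)
            eb = self.expression(target, class_b)
        else:
            snpsim = next(s for s in self.config.snps if snp in s.names)
            eff = snpsim.effects.get((target, tissue), 0.0)
            minor = snpsim.alleles[1]
            ea = self.expression(target, tissue) + class_a.count(minor) * eff
            eb = self.expression(target, tissue) + class_b.count(minor) * eff
        log2_diff = ea - eb
        return {"estimate": -log2_diff, "log2_fc": log2_diff, "fc": 2.0 ** log2_diff}


def _animal_ids(cfg: SimulationConfig) -> list[str]:
    return [f"pig{i + 1:03d}" for i in range(cfg.n_animals)]


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Draw genotypes for every configured SNP block.

    Genotypes are Hardy-Weinberg draws at the configured minor-allele
    frequency, independent across blocks; every SNP inside a block copies
    the block draw (complete cosegregation).  Returns the table and the
    animal x SNP minor-allele dosage matrix.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    animals = _animal_ids(cfg)
    calls: dict[str, list[str]] = {}
    dosages: dict[str, np.ndarray] = {}
    for snp in cfg.snps:
        d = rng.binomial(2, snp.maf, size=cfg.n_animals)
        major, minor = snp.alleles
        col = ["".join(sorted(major * (2 - k) + minor * k)) for k in d]
        for name in snp.names:
            calls[name] = col
            dosages[name] = d
    snp_names = [n for s in cfg.snps for n in s.names]
    table = GenotypeTable(
        animals=animals,
        snps=snp_names,
        calls=pd.DataFrame(calls, index=animals, dtype=object),
    )
    return table, pd.DataFrame(dosages, index=animals)


def _simulate_frame(
    cfg: SimulationConfig, rng: np.random.Generator, dosages: pd.DataFrame | None
):
    """Core generator: per-measurement true transformed values.

    Returns a long frame with one row per gene x sample including the
    noiseless transformed mean and the realized random effects.
    """
    animals = _animal_ids(cfg)
    sexes = {
        a: ("female" if i >= cfg.n_animals - cfg.n_females else "male")
        for i, a in enumerate(animals)
    }
    plate_effects = rng.normal(0.0, cfg.plate_effect_sd, size=cfg.n_plates)
    rows = []
    sample_idx = 0
    for a in animals:
        for t in cfg.tissues:
            d_eff = rng.normal(0.0, math.sqrt(cfg.sigma2_d))
            # random plate assignment: keeps plates crossed with tissues so
            # plate effects stay estimable alongside the tissue x gene cells
            plate = int(rng.integers(cfg.n_plates))
            for g in cfg.genes:
                b_eff = rng.normal(0.0, math.sqrt(cfg.sigma2_b))
                expr = g.level(t)
                if dosages is not None:
                    for snp in cfg.snps:
                        eff = snp.effects.get((g.name, t), 0.0)
                        if eff:
                            expr += eff * float(dosages.at[a, snp.names[0]])
                scale = math.log2(1.0 + g.efficiency)
                y = (
                    g.baseline_cp * scale
                    - expr
                    + plate_effects[plate]
                    + (cfg.sex_effect if sexes[a] == "female" else 0.0)
                    + b_eff
                    + d_eff
                    + rng.normal(0.0, math.sqrt(cfg.sigma2_e))
                )
                detectable = (
                    g.detectable_tissues is None or t in g.detectable_tissues
                )
                rows.append(
                    {
                        "animal": a,
                        "tissue": t,
                        "sex": sexes[a],
                        "plate": f"P{plate + 1:02d}",
                        "gene": g.name,
                        "role": g.role,
                        "efficiency": g.efficiency,
                        "y": y,
                        "detectable": detectable,
                    }
                )
            sample_idx += 1
    return pd.DataFrame(rows)


def simulate_cp_dataset(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[Dataset, SimulationTruth]:
    """Generate a full Cp dataset (and genotypes, if SNPs are configured).

    Well-level noise of ``replicate_sd`` cycles is added to each of the
    ``replicate_count`` technical replicates on the Cp scale; the stored
    ``cp_mean`` is their average.  Undetectable gene x tissue cells are
    emitted with missing replicates so that dataset validation flags them
    exactly as it would flag a real run.
    """
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    geno_rng, frame_rng, well_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    genotypes = None
    dosages = None
    if cfg.snps:
        genotypes, dosages = simulate_genotypes(cfg, geno_rng)

    frame = _simulate_frame(cfg, frame_rng, dosages)
    observations = []
    genes_meta = {
        g.name: GeneInfo(role=g.role, efficiency=g.efficiency) for g in cfg.genes
    }
    for row in frame.itertuples():
        scale = math.log2(1.0 + row.efficiency)
        if row.detectable:
            cp_true = row.y / scale
            wells = cp_true + well_rng.normal(
                0.0, cfg.replicate_sd, size=cfg.replicate_count
            )
            reps = tuple(float(w) for w in wells)
            cp_mean = float(np.mean(reps))
        else:
            # keep the generator's stream aligned regardless of detectability
            well_rng.normal(0.0, cfg.replicate_sd, size=cfg.replicate_count)
            reps = ()
            cp_mean = float("nan")
        observations.append(
            CpObservation(
                sample_id=f"{row.animal}:{row.tissue}",
                animal_id=row.animal,
                tissue=row.tissue,
                plate_id=row.plate,
                sex=row.sex,
                gene=row.gene,
                gene_role=row.role,
                cp_mean=cp_mean,
                cp_replicates=reps,
                detectable=bool(row.detectable),
            )
        )
    ds = Dataset(observations=observations, genes=genes_meta)
    truth = SimulationTruth(config=cfg, genotypes=genotypes, dosages=dosages)
    return ds, truth


@dataclass(frozen=True)
class ContrastSpec:
    """A contrast to evaluate inside a recovery experiment."""

    target: str
    class_a: str
    class_b: str
    references: tuple[str, ...]
    tissue: str | None = None
    snp: str | None = None

    @property
    def analysis(self) -> str:
        return "genotype" if self.snp is not None else "tissue"


def recovery_experiment(
    cfg: SimulationConfig,
    contrasts: Sequence[ContrastSpec],
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Repeatedly simulate, refit and contrast; summarize estimator quality.

    For each contrast the summary reports the true model-scale estimate,
    the mean estimated value and its bias, the RMSE, the empirical
    coverage of the nominal 95% fold-change interval, and the rejection
    rate of the two-sided test at ``alpha``.  Replicates whose fit fails
    are counted in ``n_failed`` and excluded from the averages.
    """
    if not contrasts:
        raise ValueError("at least one contrast is required")
    child_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    records: dict[ContrastSpec, list[dict]] = {c: [] for c in contrasts}
    n_failed = 0
    # contrasts sharing an analysis type and SNP are evaluated on one joint
    # fit of all their target and reference genes
    gene_lists: dict[tuple, list[str]] = {}
    for c in contrasts:
        key = (c.analysis, c.snp)
        pool = gene_lists.setdefault(key, [])
        for g in (c.target, *c.references):
            if g not in pool:
                pool.append(g)
    for child in child_seeds:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        ds, truth = simulate_cp_dataset(cfg, seed=rep_seed)
        fits: dict[tuple, MixedFit] = {}
        try:
            for c in contrasts:
                key = (c.analysis, c.snp)
                if key not in fits:
                    spec = build_model(
                        ds,
                        analysis=c.analysis,
                        genes=gene_lists[key],
                        genotypes=truth.genotypes,
                        snp=c.snp,
                    )
                    fits[key] = fit_reml(spec)
                fit = fits[key]
                res = normalized_contrast(
                    fit, c.target, c.class_a, c.class_b, c.references, tissue=c.tissue
                )
                tc = truth.true_contrast(
                    c.target, c.class_a, c.class_b, tissue=c.tissue, snp=c.snp
                )
                records[c].append(
                    {
                        "estimate": res.estimate,
                        "se": res.se,
                        "p": res.p_value,
                        "covered": res.ci_low <= tc["fc"] <= res.ci_high,
                        "rejected": res.p_value < alpha,
                        "true_estimate": tc["estimate"],
                    }
                )
        except Exception:
            n_failed += 1
            continue
    rows = []
    for c in contrasts:
        recs = pd.DataFrame(records[c])
        if recs.empty:
            raise RuntimeError("all replicates failed; cannot summarize")
        err = recs["estimate"] - recs["true_estimate"]
        rows.append(
            {
                "target": c.target,
                "comparison": f"{c.class_a}-{c.class_b}",
                "tissue": c.tissue,
                "snp": c.snp,
                "true_estimate": recs["true_estimate"].iloc[0],
                "mean_estimate": recs["estimate"].mean(),
                "bias": err.mean(),
                "rmse": float(np.sqrt((err**2).mean())),
                "mean_se": recs["se"].mean(),
                "coverage": recs["covered"].mean(),
                "rejection_rate": recs["rejected"].mean(),
                "n_ok": len(recs),
                "n_failed": n_failed,
            }
        )
    return pd.DataFrame(rows)


def paper_mimic_config(seed: int = 20130618) -> SimulationConfig:
    """The default study-design configuration.

    40 backcross animals, five tissues, two reference genes (with the
    efficiencies estimated for them: 80% and 93%) and four target
    transcripts with tissue-restricted detectability: the long receptor
    isoform quantifiable only in hypothalamus, leptin only in adipose and
    muscle.  Expression levels reproduce the qualitative tissue ordering
    of the study (receptor highest in liver; leptin far higher in backfat
    than in muscle).  Four promoter SNP blocks at MAFs 0.12/0.22/0.24/0.09
    plus one distal, unlinked coding SNP complete the genotype design.
    """
    genes = (
        GeneSim("ACTB", "reference", 0.80),
        GeneSim("B2M", "reference", 0.93),
        GeneSim(
            "LEP",
            "target",
            0.90,
            levels={"backfat": 6.8, "longissimus_dorsi": 0.9, "diaphragm": 0.0},
            detectable_tissues=("backfat", "longissimus_dorsi", "diaphragm"),
        ),
        GeneSim(
            "LEPRglobal",
            "target",
            0.90,
            levels={
                "liver": 4.0,
                "hypothalamus": 2.5,
                "longissimus_dorsi": 1.2,
                "diaphragm": 1.0,
                "backfat": 0.0,
            },
        ),
        GeneSim(
            "LEPRa",
            "target",
            0.90,
            levels={
                "liver": 3.9,
                "longissimus_dorsi": 2.0,
                "diaphragm": 1.9,
                "hypothalamus": 0.9,
                "backfat": 0.0,
            },
        ),
        GeneSim(
            "LEPRb",
            "target",
            0.90,
            levels={"hypothalamus": 0.0},
            detectable_tissues=("hypothalamus",),
        ),
    )
    snps = (
        SnpSim(("LEPR34996C.T",), maf=0.12, alleles=("T", "C")),
        SnpSim(
            ("LEPR35592G.A", "LEPR35598A.G", "LEPR35605C.T", "LEPR35624G.A"),
            maf=0.22,
            alleles=("A", "G"),
        ),
        SnpSim(
            ("LEPR35657G.C", "LEPR35702T.C", "LEPR35729A.G"),
            maf=0.24,
            alleles=("C", "G"),
        ),
        SnpSim(
            ("LEPR35856G.A", "LEPR35001T.C"),
            maf=0.09,
            alleles=("G", "A"),
            effects={("LEPRa", "liver"): 3.3, ("LEPRglobal", "liver"): 3.3},
        ),
        SnpSim(("LEPRc1987C.T",), maf=0.40, alleles=("C", "T")),
    )
    return SimulationConfig(seed=seed, genes=genes, snps=snps)
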