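"""Reference-gene stability ranking (geNorm) and reference-pair selection.

The geNorm stability measure of a candidate reference gene j is

    M_j = mean over all other candidates k of V_jk,

where V_jk is the sample standard deviation, across samples, of the
per-sample log2 expression ratio of genes j and k.  A gene whose
expression tracks every other candidate up and down (i.e. is a constant
multiple of them) has M = 0; noisy or regulated genes have large M.
Candidates are excluded one at a time (highest M first) until two remain.

Expression input is a matrix of *linear-scale relative quantities*; the
helper :func:`relative_quantities` builds one from Cp values as
``(1 + E)**(Cp_min - Cp)`` per gene, the standard efficiency-corrected
transformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = [
    "ExpressionMatrix",
    "StabilityRanking",
    "pairwise_variation",
    "stability_m",
    "rank_reference_genes",
    "select_reference_pair",
    "relative_quantities",
]


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix of strictly positive relative quantities."""

    values: pd.DataFrame  # index: samples, columns: genes

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need at least 2 samples and 2 genes")
        if not (self.values.to_numpy(dtype=float) > 0).all():
            raise ValueError("relative quantities must be strictly positive")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class StabilityRanking:
    """Per-round M values and exclusions, plus the surviving pair."""

    rounds: list[dict]  # {"genes": [...], "m": {gene: M}, "excluded": gene|None}
    final_pair: tuple[str, str]

    def final_m(self) -> dict[str, float]:
        """M value each gene had in the last round it participated in."""
        out: dict[str, float] = {}
        for rnd in self.rounds:
            for gene, m in rnd["m"].items():
                out[gene] = m
        return out


def pairwise_variation(matrix: ExpressionMatrix, gene_j: str, gene_k: str) -> float:
    """V_jk: sample SD (n-1 denominator) of log2(q_j / q_k) across samples."""
    if gene_j == gene_k:
        raise ValueError("pairwise variation needs two distinct genes")
    ratios = np.log2(
        matrix.values[gene_j].to_numpy(dtype=float)
        / matrix.values[gene_k].to_numpy(dtype=float)
    )
    return float(np.std(ratios, ddof=1))


def stability_m(matrix: ExpressionMatrix) -> pd.Series:
    """geNorm M per gene: mean of V_jk over all other genes k."""
    genes = matrix.genes
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to compute M")
    logq = np.log2(matrix.values.to_numpy(dtype=float))
    m = {}
    for j, gene in enumerate(genes):
        vs = [
            float(np.std(logq[:, j] - logq[:, k], ddof=1))
            for k in range(len(genes))
            if k != j
        ]
        m[gene] = float(np.mean(vs))
    return pd.Series(m, name="M")


def rank_reference_genes(matrix: ExpressionMatrix) -> StabilityRanking:
    """Stepwise geNorm exclusion: drop the highest-M gene until two remain.

    Ties on M are broken by excluding the lexicographically *last* gene id,
    so the retained set is deterministic and reproducible.
    """
    if len(matrix.genes) < 3:
        raise ValueError("ranking needs at least 3 candidate genes")
    current = matrix.values.copy()
    rounds: list[dict] = []
    while current.shape[1] > 2:
        m = stability_m(ExpressionMatrix(current))
        # highest M excluded; lexicographic last wins ties
        worst_m = m.max()
        candidates = sorted(m.index[np.isclose(m, worst_m, rtol=0, atol=1e-12)])
        excluded = candidates[-1]
        rounds.append(
            {"genes": list(current.columns), "m": m.to_dict(), "excluded": excluded}
        )
        current = current.drop(columns=[excluded])
    m = stability_m(ExpressionMatrix(current))
    rounds.append({"genes": list(current.columns), "m": m.to_dict(), "excluded": None})
    final_pair = tuple(sorted(current.columns))
    return StabilityRanking(rounds=rounds, final_pair=final_pair)  # type: ignore[arg-type]


def select_reference_pair(
    ranking: StabilityRanking,
    efficiencies: Mapping[str, float],
    m_threshold: float = 1.1,
    efficiency_tie_margin: float = 0.0,
) -> tuple[str, str]:
    """Choose two reference genes from a stability ranking.

    Genes whose final M is below ``m_threshold`` are candidates; among
    them the two with the lowest M are selected.  When two candidates' M
    values differ by no more than ``efficiency_tie_margin`` the one with
    the higher amplification efficiency is preferred (with the default
    margin of 0.0 efficiency only breaks exact ties, and gene id breaks
    any remainder).  If fewer than two candidates pass the threshold the
    geNorm final pair is returned with a warning.
    """
    final_m = ranking.final_m()
    candidates = [g for g, m in final_m.items() if m < m_threshold]
    if not candidates:
        raise ValueError(
            f"no candidate gene has M below {m_threshold}; "
            f"observed M: { {g: round(m, 3) for g, m in final_m.items()} }"
        )
    if len(candidates) < 2:
        import warnings

        warnings.warn(
            f"only {candidates} passed M < {m_threshold}; "
            "falling back to the geNorm final pair",
            stacklevel=2,
        )
        return ranking.final_pair

    def sort_key(gene: str):
        return (final_m[gene], -efficiencies.get(gene, 0.0), gene)

    ordered = sorted(candidates, key=sort_key)
    if efficiency_tie_margin > 0:
        # re-rank within near-tie clusters by efficiency
        chosen: list[str] = []
        remaining = list(ordered)
        while len(chosen) < 2:
            head_m = final_m[remaining[0]]
            cluster = [g for g in remaining if final_m[g] - head_m <= efficiency_tie_margin]
            cluster.sort(key=lambda g: (-efficiencies.get(g, 0.0), final_m[g], g))
            chosen.append(cluster[0])
            remaining.remove(cluster[0])
        return tuple(sorted(chosen))  # type: ignore[return-value]
    return tuple(sorted(ordered[:2]))  # type: ignore[return-value]


def relative_quantities(
    ds: Dataset,
    genes: Sequence[str] | None = None,
    samples: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Linear relative quantities from Cp: q = (1+E)**(Cp_min,gene - Cp).

    Only samples with detectable values for *all* requested genes are
    kept, since geNorm needs a complete matrix.
    """
    genes = list(genes) if genes is not None else sorted(ds.genes)
    cp: dict[str, dict[str, float]] = {g: {} for g in genes}
    for o in ds.observations:
        if o.gene in cp and o.detectable:
            cp[o.gene][o.sample_id] = o.cp_mean
    common = set.intersection(*(set(d) for d in cp.values())) if genes else set()
    if samples is not None:
        common &= set(samples)
    common_sorted = sorted(common)
    if len(common_sorted) < 2:
        raise ValueError("fewer than 2 samples have complete data for all genes")
    data = {}
    for g in genes:
        e = ds.efficiency_of(g)
        cps = np.array([cp[g][s] for s in common_sorted])
        data[g] = (1.0 + e) ** (cps.min() - cps)
    return ExpressionMatrix(pd.DataFrame(data, index=common_sorted))
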