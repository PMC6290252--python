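"""Candidate-gene identification around detected SNPLDB markers.

Three filters, applied in order: (1) proximity — the gene interval overlaps
the marker interval or the gap between them is strictly under the window
(default 100 kb); (2) content — the gene must contain at least one genotyped
SNP; (3) association — among the gene's SNPs, at least one must be
significantly associated with the marker's allele classes by a chi-square
independence test (Monte-Carlo fallback under sparse expected counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GeneSet, GenotypeMatrix
from .snpldb import SNPLDBMarker

log = logging.getLogger(__name__)


@dataclass
class CandidateGene:
    gene_id: str
    marker_id: str
    distance_bp: int
    n_snps_in_gene: int = 0
    min_p: float = float("nan")
    passes: bool = False
    note: str = ""


def genes_near(markers: list[SNPLDBMarker], genes: GeneSet,
               window_bp: int = 100_000) -> list[CandidateGene]:
    """Proximity filter: gap strictly < window, overlap counts as distance 0."""
    gt = genes.table
    marker_chroms = {m.chromosome for m in markers}
    gene_chroms = set(gt["chromosome"].unique())
    if markers and len(gt) and not (marker_chroms & gene_chroms):
        raise ValueError(
            "chromosome naming mismatch between markers and genes: "
            f"markers use {sorted(marker_chroms)[:3]}..., genes use "
            f"{sorted(gene_chroms)[:3]}...")
    out = []
    for m in markers:
        sub = gt[gt["chromosome"] == m.chromosome]
        for _, g in sub.iterrows():
            # gap = bases strictly between the intervals (1-based inclusive)
            if g["end_bp"] < m.start_bp:
                gap = m.start_bp - g["end_bp"] - 1
            elif g["start_bp"] > m.end_bp:
                gap = g["start_bp"] - m.end_bp - 1
            else:
                gap = 0
            if gap < window_bp:
                out.append(CandidateGene(g["gene_id"], m.id, int(gap)))
    return out


def _chisq_table(snp_calls: np.ndarray, marker_alleles: np.ndarray,
                 rng: np.random.Generator, n_resamples: int = 10_000) -> float:
    """p-value of SNP genotype class x marker allele class independence."""
    ok = snp_calls != MISSING
    a, b = snp_calls[ok], marker_alleles[ok]
    tab = pd.crosstab(a, b).to_numpy()
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 1.0
    chi2, p, dof, expected = stats.chi2_contingency(tab, correction=False)
    if (expected >= 5).all():
        return float(p)
    sampler = stats.random_table(tab.sum(axis=1), tab.sum(axis=0))
    batch = sampler.rvs(n_resamples, random_state=rng)
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        stat_obs = np.nansum((tab - exp) ** 2 / exp)
        stats_mc = np.nansum((batch - exp) ** 2 / exp, axis=(1, 2))
    return float(((stats_mc >= stat_obs - 1e-12).sum() + 1) / (n_resamples + 1))


def gene_marker_association(cand: CandidateGene, gm: GenotypeMatrix,
                            marker: SNPLDBMarker, genes: GeneSet,
                            alpha_gene: float = 0.05,
                            rng: np.random.Generator | None = None,
                            ) -> CandidateGene:
    """Content + association filters on one proximity-qualified gene."""
    rng = np.random.default_rng(0) if rng is None else rng
    g = genes.table.set_index("gene_id").loc[cand.gene_id]
    in_gene = np.flatnonzero(
        (gm.chromosome == g["chromosome"])
        & (gm.position_bp >= g["start_bp"]) & (gm.position_bp <= g["end_bp"]))
    cand.n_snps_in_gene = len(in_gene)
    if len(in_gene) == 0:
        cand.passes = False
        cand.note = "no SNP"
        return cand
    ps = [_chisq_table(gm.calls[:, j], marker.allele_of, rng) for j in in_gene]
    cand.min_p = float(min(ps))
    cand.passes = cand.min_p < alpha_gene
    return cand


def candidate_genes(markers: list[SNPLDBMarker], genes: GeneSet,
                    gm: GenotypeMatrix, window_bp: int = 100_000,
                    alpha_gene: float = 0.05,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Full three-step filter; returns one row per (marker, nearby gene)."""
    rng = np.random.default_rng(0) if rng is None else rng
    by_id = {m.id: m for m in markers}
    rows = []
    for cand in genes_near(markers, genes, window_bp):
        cand = gene_marker_association(cand, gm, by_id[cand.marker_id], genes,
                                       alpha_gene, rng)
        rows.append({"marker": cand.marker_id, "gene": cand.gene_id,
                     "distance_bp": cand.distance_bp,
                     "n_snps": cand.n_snps_in_gene, "min_p": cand.min_p,
                     "passes": cand.passes, "note": cand.note})
    return pd.DataFrame(rows, columns=["marker", "gene", "distance_bp",
                                       "n_snps", "min_p", "passes", "note"])
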