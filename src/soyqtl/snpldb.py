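"""SNP linkage-disequilibrium block (SNPLDB) marker construction.

Tightly linked SNPs are grouped into blocks; the distinct within-block
genotype strings of the (homozygous) accessions are the block's haplotype
alleles, turning each block into one multi-allelic marker.  Because the
panel is inbred, each accession's genotype string IS its haplotype, so no
phasing is needed.

Block calling follows the confidence-interval convention for "strong LD":
a SNP pair is in strong LD when the likelihood-based CI of |D'| has lower
bound >= ld_lower (default 0.70) and upper bound >= ld_upper (default 0.98);
a candidate block requires at least ``min_strong_frac`` (default 0.95) of its
informative pairs in strong LD, blocks never span chromosomes, and candidate
spans are capped at ``max_block_bp``.  Longest candidates are accepted first;
leftover SNPs become singleton markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_DP_GRID = np.linspace(0.0, 1.0, 201)


@dataclass
class LDEstimate:
    snp_i: str
    snp_j: str
    d: float
    d_prime: float
    ci_low: float
    ci_high: float
    r2: float


@dataclass
class SNPLDBMarker:
    """A multi-allelic block marker: haplotype strings as alleles."""

    id: str
    chromosome: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]
    alleles: list[str]            # haplotype strings, ordered by descending frequency
    allele_of: np.ndarray         # per-accession allele index
    allele_freqs: np.ndarray

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class StructureCovariates:
    similarity: np.ndarray        # (n, n), unit diagonal
    eigenvalues: np.ndarray       # descending
    eigenvectors: np.ndarray      # (n, k)
    k: int
    cumulative_variance: float


# ---------------------------------------------------------------------------
# D' and its likelihood CI

def ld_counts_to_dprime(n11: int, n12: int, n21: int, n22: int,
                        ) -> tuple[float, float, float]:
    """(D, D', r2) from 2x2 haplotype counts (A/a at locus 1, B/b at locus 2)."""
    n = n11 + n12 + n21 + n22
    if n == 0:
        raise ValueError("empty haplotype table")
    p11 = n11 / n
    pA = (n11 + n12) / n
    pB = (n11 + n21) / n
    d = p11 - pA * pB
    if min(pA, 1 - pA, pB, 1 - pB) == 0:
        raise ValueError("monomorphic SNP in pair")
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(d) / dmax
    r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
    return d, min(dprime, 1.0), r2


def dprime_ci(n11: int, n12: int, n21: int, n22: int,
              ) -> tuple[float, float]:
    """Likelihood-profile CI on |D'| from 2x2 haplotype counts.

    The multinomial likelihood is evaluated on a grid of |D'| in [0, 1] with
    allele frequencies fixed at their MLEs and the sign of D fixed at its
    observed sign; the 5th/95th percentiles of the normalized likelihood mass
    give the interval (the convention used for CI-based block calling).
    """
    n = n11 + n12 + n21 + n22
    pA = (n11 + n12) / n
    pB = (n11 + n21) / n
    d_obs = n11 / n - pA * pB
    sign = 1.0 if d_obs >= 0 else -1.0
    if sign > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_grid = sign * dmax * _DP_GRID
    p11 = pA * pB + d_grid
    p12 = pA * (1 - pB) - d_grid
    p21 = (1 - pA) * pB - d_grid
    p22 = (1 - pA) * (1 - pB) + d_grid
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (n11 * np.log(np.clip(p11, 1e-12, None))
              + n12 * np.log(np.clip(p12, 1e-12, None))
              + n21 * np.log(np.clip(p21, 1e-12, None))
              + n22 * np.log(np.clip(p22, 1e-12, None)))
    lik = np.exp(ll - ll.max())
    cdf = np.cumsum(lik)
    cdf /= cdf[-1]
    low = _DP_GRID[int(np.searchsorted(cdf, 0.05))]
    high = _DP_GRID[min(int(np.searchsorted(cdf, 0.95)), len(_DP_GRID) - 1)]
    return float(low), float(high)


def _pair_counts(col_i: np.ndarray, col_j: np.ndarray) -> tuple[int, int, int, int]:
    ok = (col_i != MISSING) & (col_j != MISSING)
    a, b = col_i[ok], col_j[ok]
    n11 = int(((a == 0) & (b == 0)).sum())
    n12 = int(((a == 0) & (b == 1)).sum())
    n21 = int(((a == 1) & (b == 0)).sum())
    n22 = int(((a == 1) & (b == 1)).sum())
    return n11, n12, n21, n22


def pairwise_ld(gm: GenotypeMatrix, max_window_bp: int = 200_000):
    """Yield LDEstimate for SNP pairs within ``max_window_bp`` on a chromosome.

    Inbred homozygotes: the genotype columns are the haplotypes.  Monomorphic
    pairs are skipped with a warning.
    """
    for chrom in pd.unique(gm.chromosome):
        idx = np.flatnonzero(gm.chromosome == chrom)
        pos = gm.position_bp[idx]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if pos[b] - pos[a] > max_window_bp:
                    break
                i, j = idx[a], idx[b]
                counts = _pair_counts(gm.calls[:, i], gm.calls[:, j])
                try:
                    d, dp, r2 = ld_counts_to_dprime(*counts)
                except ValueError:
                    log.debug("skipping monomorphic pair %s-%s", gm.snp_ids[i],
                              gm.snp_ids[j])
                    continue
                lo, hi = dprime_ci(*counts)
                yield LDEstimate(gm.snp_ids[i], gm.snp_ids[j], d, dp, lo, hi, r2)


# ---------------------------------------------------------------------------
# block partitioning

@dataclass
class BlockParams:
    max_block_bp: int = 200_000
    ld_lower: float = 0.70
    ld_upper: float = 0.98
    ci_recomb: float = 0.90      # CI high below this = historical recombination
    min_strong_frac: float = 0.95
    max_block_snps: int = 50


def build_blocks(gm: GenotypeMatrix, params: BlockParams | None = None,
                 ) -> list[np.ndarray]:
    """Partition SNPs into blocks; returns per-block global SNP index arrays.

    Every SNP lands in exactly one block (singletons allowed); the union of
    blocks is the full SNP set and blocks never span chromosomes.
    """
    params = params or BlockParams()
    out: list[np.ndarray] = []
    for chrom in pd.unique(gm.chromosome):
        idx = np.flatnonzero(gm.chromosome == chrom)
        out.extend(_blocks_one_chrom(gm, idx, params))
    # deterministic genome order
    out.sort(key=lambda b: (str(gm.chromosome[b[0]]), int(gm.position_bp[b[0]])))
    return out


def _blocks_one_chrom(gm: GenotypeMatrix, idx: np.ndarray, params: BlockParams,
                      ) -> list[np.ndarray]:
    m = len(idx)
    pos = gm.position_bp[idx]
    W = params.max_block_snps
    # strong[a, b-a]: pair (a, b) in strong LD; informative if polymorphic
    strong = np.zeros((m, W + 1), dtype=bool)
    inform = np.zeros((m, W + 1), dtype=bool)
    for a in range(m):
        for off in range(1, min(W, m - 1 - a) + 1):
            b = a + off
            if pos[b] - pos[a] > params.max_block_bp:
                break
            counts = _pair_counts(gm.calls[:, idx[a]], gm.calls[:, idx[b]])
            try:
                ld_counts_to_dprime(*counts)
            except ValueError:
                continue
            lo, hi = dprime_ci(*counts)
            is_strong = lo >= params.ld_lower and hi >= params.ld_upper
            is_recomb = hi < params.ci_recomb
            # pairs whose CI is too wide to call either way are uninformative
            strong[a, off] = is_strong
            inform[a, off] = is_strong or is_recomb

    candidates = []  # (length, start, end) inclusive index range into idx
    for a in range(m):
        for b in range(a + 1, min(a + W, m - 1) + 1):
            if pos[b] - pos[a] > params.max_block_bp:
                break
            n_strong = n_inf = 0
            for u in range(a, b + 1):
                span = min(b - u, W)
                n_inf += int(inform[u, 1:span + 1].sum())
                n_strong += int(strong[u, 1:span + 1].sum())
            if n_inf > 0 and n_strong / n_inf >= params.min_strong_frac:
                candidates.append((b - a + 1, a, b))
    candidates.sort(key=lambda t: (-t[0], t[1]))

    taken = np.zeros(m, dtype=bool)
    blocks = []
    for _, a, b in candidates:
        if taken[a:b + 1].any():
            continue
        taken[a:b + 1] = True
        blocks.append(idx[a:b + 1])
    for a in np.flatnonzero(~taken):
        blocks.append(idx[a:a + 1])
    return blocks


# ---------------------------------------------------------------------------
# haplotype-allele calling

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def call_haplotype_alleles(block: np.ndarray, gm: GenotypeMatrix,
                           min_allele_freq: float = 0.01,
                           block_serial: int | None = None) -> SNPLDBMarker:
    """Enumerate within-block genotype strings as alleles; merge rare ones.

    Strings with frequency below ``min_allele_freq`` are merged into the
    Hamming-nearest frequent haplotype (ties: the more frequent, then
    lexicographic).  Allele indices are assigned by descending frequency.
    Raises on a monomorphic block (a marker needs >= 2 alleles).
    """
    calls = gm.calls[:, block]
    if (calls == MISSING).any():
        raise ValueError("impute missing calls before allele calling")
    strings = ["".join(map(str, row)) for row in calls.astype(int)]
    freq = pd.Series(strings).value_counts(normalize=True)
    if len(freq) < 2:
        raise ValueError("monomorphic block rejected: needs >= 2 alleles")

    frequent = [h for h in freq.index if freq[h] >= min_allele_freq]
    if len(frequent) < 2:  # keep the top two so the marker stays polymorphic
        frequent = list(freq.index[:2])
    merged_to: dict[str, str] = {h: h for h in frequent}
    for h in freq.index:
        if h in merged_to:
            continue
        best = min(frequent, key=lambda f: (_hamming(h, f), -freq[f], f))
        merged_to[h] = best

    mapped = [merged_to[s] for s in strings]
    final = pd.Series(mapped).value_counts(normalize=True)
    order = sorted(final.index, key=lambda h: (-final[h], h))
    index_of = {h: i for i, h in enumerate(order)}
    allele_of = np.array([index_of[s] for s in mapped], dtype=np.int64)
    freqs = np.array([final[h] for h in order])

    chrom = str(gm.chromosome[block[0]])
    start = int(gm.position_bp[block[0]])
    end = int(gm.position_bp[block[-1]])
    if len(block) == 1:
        marker_id = f"{chrom}_{start}"
    else:
        k = block_serial if block_serial is not None else 0
        marker_id = f"{chrom}_BLOCK{k}_{start}_{end}"
    return SNPLDBMarker(marker_id, chrom, start, end,
                        [gm.snp_ids[i] for i in block], order, allele_of, freqs)


def build_markers(gm: GenotypeMatrix, blocks: list[np.ndarray] | None = None,
                  params: BlockParams | None = None,
                  min_allele_freq: float = 0.01) -> list[SNPLDBMarker]:
    """Blocks -> markers; imputes missing to major allele, drops monomorphics."""
    gm = gm.impute_major()
    if blocks is None:
        blocks = build_blocks(gm, params)
    markers = []
    serial = {}
    for block in blocks:
        chrom = str(gm.chromosome[block[0]])
        serial[chrom] = serial.get(chrom, 0) + 1
        try:
            markers.append(call_haplotype_alleles(block, gm, min_allele_freq,
                                                  block_serial=serial[chrom]))
        except ValueError:
            log.debug("dropping monomorphic block on %s", chrom)
    return markers


def marker_table(markers: list[SNPLDBMarker]) -> pd.DataFrame:
    return pd.DataFrame([
        {"id": m.id, "chromosome": m.chromosome, "start_bp": m.start_bp,
         "end_bp": m.end_bp, "n_snps": m.n_snps, "n_alleles": m.n_alleles,
         "freqs": ",".join(f"{f:.4f}" for f in m.allele_freqs)}
        for m in markers])


def allele_assignment_matrix(markers: list[SNPLDBMarker],
                             accession_ids: list[str]) -> pd.DataFrame:
    """markers x accessions matrix of allele indices."""
    data = np.vstack([m.allele_of for m in markers])
    return pd.DataFrame(data, index=[m.id for m in markers], columns=accession_ids)


# ---------------------------------------------------------------------------
# genetic similarity and eigenvector covariates

def similarity_and_eigen(markers: list[SNPLDBMarker], k: int = 10,
                         ) -> StructureCovariates:
    """Allele-sharing similarity over markers, and top-k eigenvectors.

    similarity(i, j) = fraction of markers at which i and j carry the same
    allele.  The matrix is double-centered before the eigendecomposition (a
    principal-coordinates layout); the cumulative variance fraction is over
    the positive eigenvalues.
    """
    if not markers:
        raise ValueError("need at least one marker")
    n = len(markers[0].allele_of)
    if k > n:
        raise ValueError("k exceeds accession count")
    sim = np.zeros((n, n))
    for m in markers:
        a = m.allele_of
        sim += (a[:, None] == a[None, :])
    sim /= len(markers)
    centered = sim - sim.mean(0, keepdims=True) - sim.mean(1, keepdims=True) + sim.mean()
    vals, vecs = np.linalg.eigh(centered)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals[vals > 0].sum()
    cum = float(vals[:k][vals[:k] > 0].sum() / pos) if pos > 0 else 0.0
    return StructureCovariates(sim, vals, vecs[:, :k], k, cum)
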