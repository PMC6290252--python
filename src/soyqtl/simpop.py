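"""Synthetic inbred germplasm panel generator.

Emulates the statistical structure the downstream analysis assumes: a few
hundred fully homozygous accessions, SNPs arranged in linkage-disequilibrium
blocks (each block carries a small pool of haplotypes, so within-block pairs
are in strong LD and between-block draws are independent), six subpopulations
whose block-haplotype frequencies have drifted apart, a subset of blocks
hosting multi-allelic QTLs with zero-sum additive allele effects, and an RCBD
phenotype with genotype, environment, GxE and plot-error variance components.

Haplotype pools are built under a perfect-phylogeny (infinite-sites, no
recombination) scheme: each haplotype derives from an existing one by
mutating a fresh set of sites.  This guarantees |D'| = 1 for every
within-block SNP pair, which is exactly the structure block-calling assumes;
unconstrained random pools would plant four-gamete violations inside blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, GroupPartition, TraitObservations


@dataclass
class SimConfig:
    """Stated world for the simulated panel.

    Defaults mirror the target study design: 366 accessions in 6 ecoregions,
    4 environments x 2 replications, ~90% multi-environment heritability,
    population mean 20 (seed-oil-content-like, % units), genotypic variance
    about 10x the GxE variance, QTL allele counts 2-9.
    """

    n_accessions: int = 366
    n_groups: int = 6
    n_chromosomes: int = 20
    snps_per_chromosome: int = 150
    block_snp_range: tuple[int, int] = (1, 10)   # SNPs per planted block
    pool_size_range: tuple[int, int] = (2, 6)    # haplotypes per block pool
    n_qtl: int = 50
    qtl_allele_range: tuple[int, int] = (2, 9)
    mu: float = 20.0
    sigma_g2: float = 8.0
    sigma_ge2: float | None = None   # default sigma_g2 / ge_ratio
    sigma_e2: float | None = None    # default solved from target_h2
    sigma_env2: float | None = None  # default = sigma_e2
    ge_ratio: float = 10.0           # sigma_g2 / sigma_ge2
    target_h2: float = 0.90          # multi-environment h2 (used iff sigma_e2 is None)
    n_environments: int = 4
    n_replications: int = 2
    drift: float = 0.05              # Balding-Nichols-style F between groups
    snp_spacing_bp: int = 2_000
    block_gap_bp: int = 50_000
    seed: int = 0

    def resolve_variances(self) -> tuple[float, float, float, float]:
        """Return (sigma_g2, sigma_ge2, sigma_e2, sigma_env2), filling defaults."""
        s, r = self.n_environments, self.n_replications
        sg2 = float(self.sigma_g2)
        sge2 = sg2 / self.ge_ratio if self.sigma_ge2 is None else float(self.sigma_ge2)
        if self.sigma_e2 is None:
            if not 0 < self.target_h2 <= 1:
                raise ValueError("target_h2 must be in (0, 1]")
            # invert h2 = sg2 / (sg2 + sge2/s + se2/(s r))
            se2 = s * r * (sg2 / self.target_h2 - sg2 - sge2 / s)
            if se2 < -1e-9:
                raise ValueError("target_h2 unreachable with the given GxE variance")
            se2 = max(se2, 0.0)
        else:
            se2 = float(self.sigma_e2)
        senv2 = se2 if self.sigma_env2 is None else float(self.sigma_env2)
        return sg2, sge2, se2, senv2

    def validate(self) -> None:
        for name in ("n_accessions", "n_groups", "n_chromosomes",
                     "snps_per_chromosome", "n_environments", "n_replications"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_g2 > 0 and self.sigma_e2 is None and self.target_h2 == 0:
            raise ValueError("target_h2 = 0 inconsistent with nonzero QTL variance")
        self.resolve_variances()


@dataclass
class PlantedBlock:
    """Truth record for one simulated LD block."""

    chromosome: str
    start_bp: int
    end_bp: int
    snp_indices: np.ndarray          # global column indices into the GenotypeMatrix
    haplotypes: np.ndarray           # (pool, n_snps) 0/1
    base_freqs: np.ndarray           # ancestral haplotype frequencies
    group_freqs: np.ndarray          # (n_groups, pool)
    assignment: np.ndarray           # per-accession haplotype index


@dataclass
class TrueModel:
    """Planted QTLs with zero-sum additive haplotype effects."""

    mu: float
    qtl_block_indices: list[int]
    effects: list[np.ndarray]        # per QTL, one effect per pool haplotype
    genotypic_values: np.ndarray     # per accession, sum of carried effects

    def value_of(self, blocks: list[PlantedBlock]) -> np.ndarray:
        g = np.zeros_like(self.genotypic_values)
        for b, eff in zip(self.qtl_block_indices, self.effects):
            g += eff[blocks[b].assignment]
        return g


def _phylogeny_pool(n_snps: int, pool: int, rng: np.random.Generator) -> np.ndarray:
    """Pool of haplotypes under infinite sites: no four-gamete violations."""
    haps = np.zeros((pool, n_snps), dtype=np.int8)
    if pool == 1 or n_snps == 0:
        return haps
    # partition the SNPs over the pool-1 branching events; every branch mutates >=0
    owners = rng.integers(1, pool, size=n_snps)  # SNP j arises on the branch to hap owners[j]
    for k in range(1, pool):
        parent = int(rng.integers(0, k))
        haps[k] = haps[parent]
        haps[k, owners == k] ^= 1
    return haps


def _drifted_freqs(base: np.ndarray, drift: float, n_groups: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols-style per-group haplotype frequencies."""
    if drift <= 0:
        return np.tile(base, (n_groups, 1))
    conc = base * (1.0 - drift) / drift
    conc = np.clip(conc, 1e-3, None)
    return rng.dirichlet(conc, size=n_groups)


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None,
                       ) -> tuple[GenotypeMatrix, list[PlantedBlock], GroupPartition]:
    """Draw the panel: blocked genotypes, planted-block truth, group labels."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    n = cfg.n_accessions
    group_of = np.arange(n) % cfg.n_groups  # balanced groups, deterministic
    accession_ids = [f"ACC{i:04d}" for i in range(n)]

    blocks: list[PlantedBlock] = []
    snp_ids, chroms, pos_all, cols = [], [], [], []
    col_idx = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"Gm{c + 1:02d}"
        pos = int(rng.integers(1_000, 10_000))
        placed = 0
        while placed < cfg.snps_per_chromosome:
            m = int(rng.integers(cfg.block_snp_range[0], cfg.block_snp_range[1] + 1))
            m = min(m, cfg.snps_per_chromosome - placed)
            pool = int(rng.integers(cfg.pool_size_range[0], cfg.pool_size_range[1] + 1))
            haps = _phylogeny_pool(m, pool, rng)
            base = rng.dirichlet(np.full(pool, 2.0))
            gfreq = _drifted_freqs(base, cfg.drift, cfg.n_groups, rng)
            assign = np.empty(n, dtype=np.int64)
            for g in range(cfg.n_groups):
                members = np.flatnonzero(group_of == g)
                assign[members] = rng.choice(pool, size=members.size, p=gfreq[g])
            positions = pos + cfg.snp_spacing_bp * np.arange(m)
            blocks.append(PlantedBlock(
                chromosome=chrom, start_bp=int(positions[0]), end_bp=int(positions[-1]),
                snp_indices=np.arange(col_idx, col_idx + m),
                haplotypes=haps, base_freqs=base, group_freqs=gfreq, assignment=assign))
            block_calls = haps[assign]  # (n, m)
            cols.append(block_calls.astype(np.int8))
            for k in range(m):
                snp_ids.append(f"{chrom}_{positions[k]}")
                chroms.append(chrom)
                pos_all.append(int(positions[k]))
            col_idx += m
            placed += m
            pos = int(positions[-1]) + cfg.block_gap_bp + int(rng.integers(0, 10_000))

    gm = GenotypeMatrix(
        accession_ids, snp_ids, np.asarray(chroms, dtype=object),
        np.asarray(pos_all, dtype=np.int64), np.hstack(cols),
        np.full(col_idx, "A", object), np.full(col_idx, "T", object))
    gm.validate()
    partition = GroupPartition(pd.Series(
        [f"E{g + 1}" for g in group_of], index=pd.Index(accession_ids, name="accession"),
        name="group"))
    return gm, blocks, partition


def plant_qtls(cfg: SimConfig, blocks: list[PlantedBlock],
               rng: np.random.Generator) -> TrueModel:
    """Pick QTL-hosting blocks and draw zero-sum effects scaled to sigma_g2."""
    lo, hi = cfg.qtl_allele_range
    eligible = [i for i, b in enumerate(blocks)
                if lo <= len(np.unique(b.assignment)) <= hi]
    if len(eligible) < cfg.n_qtl:
        raise ValueError(f"only {len(eligible)} blocks eligible for {cfg.n_qtl} QTLs")
    chosen = sorted(rng.choice(len(eligible), size=cfg.n_qtl, replace=False))
    qtl_blocks = [eligible[i] for i in chosen]

    effects = []
    for b in qtl_blocks:
        pool = blocks[b].haplotypes.shape[0]
        e = rng.normal(0.0, 1.0, size=pool)
        e -= e.mean()  # exact unweighted zero sum per locus
        effects.append(e)

    sg2, _, _, _ = cfg.resolve_variances()
    g = np.zeros(cfg.n_accessions)
    for b, e in zip(qtl_blocks, effects):
        g += e[blocks[b].assignment]
    var_g = g.var()
    if cfg.n_qtl > 0 and sg2 > 0:
        if var_g <= 0:
            raise ValueError("planted QTLs are monomorphic; cannot scale to sigma_g2")
        scale = np.sqrt(sg2 / var_g)
        effects = [e * scale for e in effects]
        g = g * scale
    return TrueModel(mu=cfg.mu, qtl_block_indices=qtl_blocks, effects=effects,
                     genotypic_values=g)


def simulate_trait(model: TrueModel, blocks: list[PlantedBlock], cfg: SimConfig,
                   rng: np.random.Generator,
                   accession_ids: list[str] | None = None) -> TraitObservations:
    """RCBD phenotype: mu + g_i + E_j + GE_ij + e_ijk with configured variances."""
    sg2, sge2, se2, senv2 = cfg.resolve_variances()
    if cfg.n_qtl > 0 and sg2 > 0 and cfg.target_h2 == 0:
        raise ValueError("target_h2 = 0 inconsistent with nonzero QTL effects")
    n, s, r = cfg.n_accessions, cfg.n_environments, cfg.n_replications
    g = model.genotypic_values
    env = rng.normal(0.0, np.sqrt(senv2), size=s) if senv2 > 0 else np.zeros(s)
    ge = rng.normal(0.0, np.sqrt(sge2), size=(n, s)) if sge2 > 0 else np.zeros((n, s))
    err = rng.normal(0.0, np.sqrt(se2), size=(n, s, r)) if se2 > 0 else np.zeros((n, s, r))
    values = model.mu + g[:, None, None] + env[None, :, None] + ge[:, :, None] + err

    ids = accession_ids or [f"ACC{i:04d}" for i in range(n)]
    idx = pd.MultiIndex.from_product(
        [ids, [f"ENV{j + 1}" for j in range(s)], [f"R{k + 1}" for k in range(r)]],
        names=["accession", "environment", "replication"])
    table = pd.DataFrame({"value": values.reshape(-1)}, index=idx).reset_index()
    return TraitObservations(table)


@dataclass
class SimResult:
    """One full draw of the stated world."""

    config: SimConfig
    genotypes: GenotypeMatrix
    blocks: list[PlantedBlock]
    partition: GroupPartition
    model: TrueModel
    observations: TraitObservations


def simulate(cfg: SimConfig) -> SimResult:
    """Genotypes, planted truth, group labels and phenotypes from one seed."""
    rng = np.random.default_rng(cfg.seed)
    gm, blocks, partition = simulate_genotypes(cfg, rng)
    model = plant_qtls(cfg, blocks, rng) if cfg.n_qtl > 0 else TrueModel(
        cfg.mu, [], [], np.zeros(cfg.n_accessions))
    obs = simulate_trait(model, blocks, cfg, rng, gm.accession_ids)
    return SimResult(cfg, gm, blocks, partition, model, obs)
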