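"""Orchestration of the end-to-end analysis over files on disk.

The numbered drivers under ``analysis/`` and the acceptance script are thin
wrappers around these steps.  Every artifact is plain text (VCF, TSV, JSON)
so each stage can be re-run or audited independently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import allelematrix, crosspred, genio, herit, rtmgwas, simpop, snpldb

log = logging.getLogger(__name__)


def default_sim_config(seed: int, scale: float = 1.0) -> simpop.SimConfig:
    """The panel the generator emulates: 366 accessions, 6 ecoregions,
    4 environments x 2 replications, h2 ~ 0.9, 50 QTLs with 2-9 alleles.

    ``scale`` shrinks the SNP panel (not the accession panel) for fast runs;
    the study's ~116k SNPs are far beyond what desk-scale block calling
    needs to exercise every stage.
    """
    return simpop.SimConfig(
        n_accessions=366, n_groups=6, n_chromosomes=20,
        snps_per_chromosome=max(int(150 * scale), 20),
        n_qtl=50, target_h2=0.90, mu=20.0, sigma_g2=8.0,
        n_environments=4, n_replications=2, seed=seed)


# ---------------------------------------------------------------------------
# step 1: simulate and write the raw inputs

def simulate_panel(cfg: simpop.SimConfig, data_dir: str | Path) -> simpop.SimResult:
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    sim = simpop.simulate(cfg)
    genio.write_vcf(sim.genotypes, data_dir / "panel.vcf")
    genio.write_phenotypes(sim.observations, data_dir / "phenotypes.tsv")
    genio.write_groups(sim.partition, data_dir / "groups.tsv")
    truth = {
        "mu": sim.model.mu,
        "qtls": [
            {"block": int(b),
             "chromosome": sim.blocks[b].chromosome,
             "start_bp": sim.blocks[b].start_bp,
             "end_bp": sim.blocks[b].end_bp,
             "effects": [float(e) for e in eff]}
            for b, eff in zip(sim.model.qtl_block_indices, sim.model.effects)],
        "genotypic_values": {a: float(g) for a, g in
                             zip(sim.genotypes.accession_ids,
                                 sim.model.genotypic_values)},
        "blocks": [{"chromosome": b.chromosome, "start_bp": b.start_bp,
                    "end_bp": b.end_bp,
                    "n_snps": int(len(b.snp_indices))} for b in sim.blocks],
    }
    (data_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return sim


# ---------------------------------------------------------------------------
# step 2: SNPLDB markers

def markers_step(gm: genio.GenotypeMatrix, out_dir: str | Path,
                 params: snpldb.BlockParams | None = None,
                 min_allele_freq: float = 0.01, eigen_k: int = 10):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    markers = snpldb.build_markers(gm, params=params,
                                   min_allele_freq=min_allele_freq)
    tab = snpldb.marker_table(markers)
    tab["snp_ids"] = [",".join(m.snp_ids) for m in markers]
    tab["alleles"] = ["|".join(m.alleles) for m in markers]
    tab.to_csv(out_dir / "markers.tsv", sep="\t", index=False)
    assign = snpldb.allele_assignment_matrix(markers, gm.accession_ids)
    assign.to_csv(out_dir / "allele_assignment.tsv", sep="\t")
    sc = snpldb.similarity_and_eigen(markers, k=min(eigen_k, gm.n_accessions))
    pd.DataFrame(sc.eigenvectors, index=gm.accession_ids,
                 columns=[f"EV{i + 1}" for i in range(sc.k)]
                 ).to_csv(out_dir / "eigenvectors.tsv", sep="\t")
    return markers, sc


def load_markers(out_dir: str | Path) -> list[snpldb.SNPLDBMarker]:
    out_dir = Path(out_dir)
    tab = pd.read_csv(out_dir / "markers.tsv", sep="\t")
    assign = pd.read_csv(out_dir / "allele_assignment.tsv", sep="\t",
                         index_col=0)
    markers = []
    for _, row in tab.iterrows():
        freqs = np.array([float(f) for f in str(row["freqs"]).split(",")])
        markers.append(snpldb.SNPLDBMarker(
            id=row["id"], chromosome=row["chromosome"],
            start_bp=int(row["start_bp"]), end_bp=int(row["end_bp"]),
            snp_ids=str(row["snp_ids"]).split(","),
            alleles=str(row["alleles"]).split("|"),
            allele_of=assign.loc[row["id"]].to_numpy(int),
            allele_freqs=freqs))
    return markers


# ---------------------------------------------------------------------------
# step 3: heritability

def heritability_step(obs: genio.TraitObservations, out_dir: str | Path,
                      ) -> pd.DataFrame:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vc = herit.fit_variance_components(obs)
    rows = [{
        "sigma_g2": vc.sigma_g2, "sigma_ge2": vc.sigma_ge2,
        "sigma_e2": vc.sigma_e2, "s": vc.s, "r": vc.r,
        "mean": vc.grand_mean,
        "h2_multi_env": herit.heritability(vc, "multi_env"),
        "gcv_percent": herit.gcv(vc),
    }]
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "heritability.tsv", sep="\t", index=False)
    per_env = herit.per_environment_h2(obs)
    per_env.to_csv(out_dir / "h2_per_environment.tsv", sep="\t")
    return df


# ---------------------------------------------------------------------------
# step 4: association

def gwas_step(markers, obs: genio.TraitObservations, covariates: np.ndarray,
              accession_ids: list[str], out_dir: str | Path,
              alpha: float = 0.02, alpha_stringent: float = 0.0002,
              stage1_p: float = 0.05, trait: str = "Oil"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    y = obs.accession_means().reindex(accession_ids).to_numpy()
    md = rtmgwas.markers_to_data(markers)
    s1 = rtmgwas.stage1_scan(md, y, covariates)
    cand = rtmgwas.preselect(s1, stage1_p)
    model = rtmgwas.stage2_stepwise(cand, md, y, covariates,
                                    alpha_enter=alpha,
                                    n_genome_tests=len(md))
    stringent = rtmgwas.stage2_stepwise(cand, md, y, covariates,
                                        alpha_enter=alpha_stringent,
                                        n_genome_tests=len(md))
    effects = rtmgwas.allele_effects(model)

    rtmgwas.qtl_table(model, trait).to_csv(out_dir / "qtl_normal.tsv",
                                           sep="\t", index=False)
    rtmgwas.qtl_table(stringent, trait).to_csv(out_dir / "qtl_stringent.tsv",
                                               sep="\t", index=False)
    rows = [{"marker": mid, "allele": a, "effect": e}
            for mid, eff in effects.effects.items() for a, e in eff.items()]
    pd.DataFrame(rows).to_csv(out_dir / "allele_effects.tsv", sep="\t",
                              index=False)
    summary = {"mu": effects.mu, "alpha": alpha,
               "alpha_stringent": alpha_stringent,
               "n_markers_scanned": len(md), "n_candidates": len(cand),
               "n_selected": len(model.selected),
               "n_selected_stringent": len(stringent.selected),
               "model_r2": model.model_r2,
               "total_seq_r2": float(sum(model.seq_r2.values()))}
    (out_dir / "gwas_summary.json").write_text(json.dumps(summary, indent=1))
    return model, stringent, effects


def load_effects(out_dir: str | Path) -> rtmgwas.AlleleEffects:
    out_dir = Path(out_dir)
    tab = pd.read_csv(out_dir / "allele_effects.tsv", sep="\t")
    mu = json.loads((out_dir / "gwas_summary.json").read_text())["mu"]
    eff: dict = {}
    for _, row in tab.iterrows():
        eff.setdefault(row["marker"], {})[int(row["allele"])] = float(row["effect"])
    return rtmgwas.AlleleEffects(mu=float(mu), effects=eff)


# ---------------------------------------------------------------------------
# step 5: allele matrix and differentiation

def matrix_step(effects, markers, obs, partition, model, out_dir: str | Path,
                rng: np.random.Generator):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    detected = [m for m in markers if m.id in effects.effects]
    means = obs.accession_means()
    qam = allelematrix.build_qam(effects, detected, means, partition,
                                 locus_r2=model.seq_r2 if model else None)
    qam.sorted_view().to_csv(out_dir / "qtl_allele_matrix.tsv", sep="\t")
    counts = allelematrix.count_signed_alleles(qam)
    counts.to_csv(out_dir / "signed_allele_counts.tsv", sep="\t")
    freqs = allelematrix.group_allele_freqs(detected, partition,
                                            accession_ids=list(means.index))
    freqs.to_csv(out_dir / "group_allele_freqs.tsv", sep="\t", index=False)
    diff = allelematrix.differentiation_table(freqs, rng)
    diff.to_csv(out_dir / "differentiation.tsv", sep="\t", index=False)
    spec = allelematrix.specific_alleles(freqs)
    spec.to_csv(out_dir / "specific_alleles.tsv", sep="\t", index=False)
    return qam, counts, diff, spec


# ---------------------------------------------------------------------------
# step 6: cross prediction

def cross_step(effects, markers, obs, partition, out_dir: str | Path,
               n_parents: int = 60, n_progeny: int = 2000, seed: int = 0,
               direction: str = "max", cm_per_mb: float = 2.5):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    detected = [m for m in markers if m.id in effects.effects]
    loci = pd.DataFrame({"id": [m.id for m in detected],
                         "chromosome": [m.chromosome for m in detected],
                         "position_bp": [m.start_bp for m in detected]})
    gmap = crosspred.build_genetic_map(loci, cm_per_mb=cm_per_mb)
    means = obs.accession_means()
    accessions = list(means.index)
    # parent subset: the phenotypic extremes plus a deterministic spread
    order = means.sort_values().index.tolist()
    k = min(n_parents, len(order))
    top = order[-k // 2:]
    rest = order[: len(order) - k // 2]
    spread = rest[:: max(len(rest) // (k - k // 2), 1)][: k - k // 2]
    parents = sorted(set(top) | set(spread))
    assign = pd.DataFrame(
        {m.id: m.allele_of for m in detected}, index=accessions).T
    out = crosspred.enumerate_and_rank(
        parents, assign, effects, gmap, partition, direction=direction,
        n_progeny=n_progeny, seed=seed)
    out["crosses"].to_csv(out_dir / "cross_predictions.tsv", sep="\t",
                          index=False)
    out["group_summary"].to_csv(out_dir / "cross_group_summary.tsv", sep="\t",
                                index=False)
    out["top"].to_csv(out_dir / "top_crosses.tsv", sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# step 7: candidate genes (synthetic gene models around detected markers)

def synthetic_gene_models(gm: genio.GenotypeMatrix, markers,
                          rng: np.random.Generator,
                          genes_per_marker: int = 4) -> genio.GeneSet:
    """Synthetic stand-in gene annotation (no public GFF is bundled).

    Plants gene intervals around each detected marker so that every filter
    branch is exercised: one gene straddling a member SNP (contains a SNP),
    one overlapping the block elsewhere, one inside the 100-kb window and
    one beyond it.
    """
    snp_pos = {sid: int(p) for sid, p in zip(gm.snp_ids, gm.position_bp)}
    rows = []
    gid = 0

    def add(chrom, start, end):
        nonlocal gid
        rows.append({"gene_id": f"SynGene{gid:05d}", "chromosome": chrom,
                     "start_bp": max(int(start), 1), "end_bp": int(end),
                     "strand": "+" if rng.random() < 0.5 else "-"})
        gid += 1

    for m in markers:
        anchor = snp_pos[m.snp_ids[int(rng.integers(len(m.snp_ids)))]]
        add(m.chromosome, anchor - int(rng.integers(500, 2_000)),
            anchor + int(rng.integers(500, 2_000)))           # contains a SNP
        add(m.chromosome, m.start_bp - int(rng.integers(0, 1_000)),
            m.start_bp + int(rng.integers(200, 900)))         # overlaps block
        near = m.end_bp + int(rng.integers(10_000, 90_000))
        add(m.chromosome, near, near + int(rng.integers(2_000, 8_000)))  # in window
        add(m.chromosome, m.end_bp + 150_000,
            m.end_bp + 150_000 + int(rng.integers(2_000, 8_000)))  # outside
    return genio.GeneSet(pd.DataFrame(rows))


def write_gff(genes: genio.GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.table.iterrows():
            fh.write(f"{g['chromosome']}\tsoyqtl_synthetic\tgene\t"
                     f"{g['start_bp']}\t{g['end_bp']}\t.\t{g['strand']}\t.\t"
                     f"ID={g['gene_id']}\n")


def genes_step(gm: genio.GenotypeMatrix, markers, effects, genes,
               out_dir: str | Path, rng: np.random.Generator,
               window_bp: int = 100_000, alpha_gene: float = 0.05):
    from . import genes as genes_mod

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    detected = [m for m in markers if m.id in effects.effects]
    table = genes_mod.candidate_genes(detected, genes, gm, window_bp,
                                      alpha_gene, rng)
    table.to_csv(out_dir / "candidate_genes.tsv", sep="\t", index=False)
    return table
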