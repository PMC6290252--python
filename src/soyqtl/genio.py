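"""Readers and writers for the formats the pipeline touches.

Genotypes come in as VCF (v4.x) or HapMap text from an inbred, essentially
homozygous panel; phenotypes as a long-format delimited table over
(accession, environment, replication); subpopulation labels as a two-column
table; gene models as GFF3.  All coordinates are 1-based inclusive.

Heterozygous genotype calls are set to missing on ingestion (the panels this
pipeline targets are inbred lines, so residual heterozygotes are treated as
call errors); missing calls can later be imputed to the per-SNP major allele,
which keeps within-block haplotype strings defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: sentinel for a missing homozygous call in :class:`GenotypeMatrix.calls`
MISSING = np.int8(-1)


@dataclass
class GenotypeMatrix:
    """Accession x SNP matrix of homozygous calls.

    ``calls[i, j]`` is 0 (reference homozygote), 1 (alternate homozygote) or
    :data:`MISSING`.  SNPs are sorted by (chromosome, position) and unique per
    position; accession order is never changed by ingestion.
    """

    accession_ids: list[str]
    snp_ids: list[str]
    chromosome: np.ndarray  # per-SNP, dtype object/str
    position_bp: np.ndarray  # per-SNP, 1-based int64
    calls: np.ndarray  # (n_accessions, n_snps) int8
    ref_allele: np.ndarray | None = None
    alt_allele: np.ndarray | None = None

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        if self.calls.shape != (self.n_accessions, self.n_snps):
            raise ValueError("calls shape mismatch")
        # strictly increasing positions within chromosome, no duplicates
        for chrom in pd.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if np.any((self.calls == MISSING).all(axis=1)):
            raise ValueError("accession with no genotyped SNP")

    def impute_major(self) -> "GenotypeMatrix":
        """Fill missing calls with the per-SNP major allele (ties -> 0)."""
        calls = self.calls.copy()
        n_missing = int((calls == MISSING).sum())
        for j in range(self.n_snps):
            col = calls[:, j]
            miss = col == MISSING
            if not miss.any():
                continue
            n1 = int((col == 1).sum())
            n0 = int((col == 0).sum())
            col[miss] = 1 if n1 > n0 else 0
        if n_missing:
            log.info("imputed %d missing calls to the major allele", n_missing)
        return GenotypeMatrix(
            self.accession_ids, self.snp_ids, self.chromosome,
            self.position_bp, calls, self.ref_allele, self.alt_allele,
        )


@dataclass
class TraitObservations:
    """Long-format RCBD multi-environment phenotype records."""

    table: pd.DataFrame  # columns: accession, environment, replication, value

    def __post_init__(self) -> None:
        required = {"accession", "environment", "replication", "value"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"phenotype table must have columns {sorted(required)}")
        dup = self.table.duplicated(["accession", "environment", "replication"])
        if dup.any():
            key = self.table.loc[dup.idxmax(), ["accession", "environment", "replication"]]
            raise ValueError(f"duplicate phenotype key {tuple(key)}")
        if not np.isfinite(self.table["value"].to_numpy(float)).all():
            raise ValueError("non-finite phenotype values")

    @property
    def n_environments(self) -> int:
        return self.table["environment"].nunique()

    @property
    def n_replications(self) -> int:
        return int(self.table.groupby(["accession", "environment"]).size().max())

    def accession_means(self) -> pd.Series:
        """Across-environment accession means (the GWAS trait input)."""
        return self.table.groupby("accession", sort=False)["value"].mean()


@dataclass
class GroupPartition:
    """Accession -> subpopulation (ecoregion) label."""

    labels: pd.Series  # index accession_id, values group label

    def groups(self) -> list:
        return sorted(self.labels.unique())

    def check_against(self, accession_ids: list[str]) -> None:
        unknown = set(self.labels.index) - set(accession_ids)
        if unknown:
            raise ValueError(f"labeled accessions absent from genotypes: {sorted(unknown)[:5]}")


@dataclass
class GeneSet:
    """Gene models with 1-based inclusive coordinates."""

    table: pd.DataFrame  # columns: gene_id, chromosome, start_bp, end_bp, strand

    def __post_init__(self) -> None:
        t = self.table
        if (t["start_bp"] > t["end_bp"]).any():
            bad = t.loc[t["start_bp"] > t["end_bp"], "gene_id"].iloc[0]
            raise ValueError(f"gene {bad} has end < start")
        if t["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")


# ---------------------------------------------------------------------------
# genotype readers/writers

def _finalize_matrix(accessions, snp_ids, chroms, pos, calls, ref, alt,
                     n_dropped_multiallelic, n_het, n_all_missing) -> GenotypeMatrix:
    chroms = np.asarray(chroms, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    calls = np.asarray(calls, dtype=np.int8)
    order = np.lexsort((pos, chroms.astype(str)))
    gm = GenotypeMatrix(
        list(accessions),
        [snp_ids[i] for i in order],
        chroms[order],
        pos[order],
        calls[:, order],
        np.asarray(ref, dtype=object)[order] if ref is not None else None,
        np.asarray(alt, dtype=object)[order] if alt is not None else None,
    )
    if n_dropped_multiallelic:
        log.info("dropped %d non-biallelic sites", n_dropped_multiallelic)
    if n_het:
        log.info("set %d heterozygous calls to missing", n_het)
    if n_all_missing:
        log.warning("dropped %d all-missing SNPs", n_all_missing)
    gm.validate()
    return gm


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF of bi-allelic SNPs from homozygous accessions.

    Non-biallelic records are dropped; heterozygous calls become missing;
    all-missing sites are dropped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    accessions = list(vcf.samples)
    snp_ids, chroms, pos, ref, alt, cols = [], [], [], [], [], []
    n_multi = n_het = n_allmiss = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types)  # 0 HOM_REF, 1 HET, 2 HOM_ALT, 3 UNKNOWN
        col = np.full(len(accessions), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 2] = 1
        n_het += int((gt == 1).sum())
        if (col == MISSING).all():
            n_allmiss += 1
            continue
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        cols.append(col)
    vcf.close()
    calls = np.column_stack(cols) if cols else np.empty((len(accessions), 0), np.int8)
    return _finalize_matrix(accessions, snp_ids, chroms, pos, calls, ref, alt,
                            n_multi, n_het, n_allmiss)


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    ref = gm.ref_allele if gm.ref_allele is not None else np.full(gm.n_snps, "A", object)
    alt = gm.alt_allele if gm.alt_allele is not None else np.full(gm.n_snps, "T", object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.chromosome):
            maxpos = int(gm.position_bp[gm.chromosome == chrom].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.accession_ids) + "\n")
        code = {0: "0/0", 1: "1/1"}
        for j in range(gm.n_snps):
            gts = "\t".join(code.get(int(c), "./.") for c in gm.calls[:, j])
            fh.write(f"{gm.chromosome[j]}\t{gm.position_bp[j]}\t{gm.snp_ids[j]}\t"
                     f"{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


_HAPMAP_META = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
                "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]


def read_hapmap(path: str) -> GenotypeMatrix:
    """Read HapMap-format genotypes (diploid letter pairs, e.g. ``AA``/``CC``).

    The first allele listed in the ``alleles`` column is taken as reference.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:11]) != _HAPMAP_META:
        raise ValueError("not a HapMap file: unexpected leading columns")
    accessions = list(df.columns[11:])
    snp_ids, chroms, pos, ref, alt, cols = [], [], [], [], [], []
    n_het = n_allmiss = n_multi = 0
    for _, row in df.iterrows():
        alleles = row["alleles"].split("/")
        if len(alleles) != 2:
            n_multi += 1
            continue
        a_ref, a_alt = alleles
        col = np.full(len(accessions), MISSING, dtype=np.int8)
        for i, acc in enumerate(accessions):
            g = row[acc]
            if g in ("NN", "N", "--", "."):
                continue
            if g == a_ref * 2 or g == a_ref:
                col[i] = 0
            elif g == a_alt * 2 or g == a_alt:
                col[i] = 1
            else:
                n_het += 1  # heterozygote or off-ladder call -> missing
        if (col == MISSING).all():
            n_allmiss += 1
            continue
        snp_ids.append(row["rs#"])
        chroms.append(row["chrom"])
        pos.append(int(row["pos"]))
        ref.append(a_ref)
        alt.append(a_alt)
        cols.append(col)
    calls = np.column_stack(cols) if cols else np.empty((len(accessions), 0), np.int8)
    return _finalize_matrix(accessions, snp_ids, chroms, pos, calls, ref, alt,
                            n_multi, n_het, n_allmiss)


def write_hapmap(gm: GenotypeMatrix, path: str) -> None:
    ref = gm.ref_allele if gm.ref_allele is not None else np.full(gm.n_snps, "A", object)
    alt = gm.alt_allele if gm.alt_allele is not None else np.full(gm.n_snps, "T", object)
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + gm.accession_ids) + "\n")
        for j in range(gm.n_snps):
            meta = [gm.snp_ids[j], f"{ref[j]}/{alt[j]}", str(gm.chromosome[j]),
                    str(gm.position_bp[j]), "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            gts = [{0: str(ref[j]) * 2, 1: str(alt[j]) * 2}.get(int(c), "NN")
                   for c in gm.calls[:, j]]
            fh.write("\t".join(meta + gts) + "\n")


def read_genotypes(path: str, format: str = "vcf") -> GenotypeMatrix:
    if format == "vcf":
        return read_vcf(path)
    if format == "hapmap":
        return read_hapmap(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotype / group / gene tables

def read_phenotypes(path: str, sep: str = "\t") -> TraitObservations:
    df = pd.read_csv(path, sep=sep, dtype={"accession": str, "environment": str,
                                           "replication": str})
    required = ["accession", "environment", "replication", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 1-based
        raise ValueError(f"non-numeric phenotype values at lines {lines}")
    df["value"] = values.astype(float)
    return TraitObservations(df[required].copy())


def write_phenotypes(obs: TraitObservations, path: str, sep: str = "\t") -> None:
    obs.table.to_csv(path, sep=sep, index=False)


def read_groups(path: str, sep: str = "\t") -> GroupPartition:
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("group table needs two columns: accession, group")
    df = df.iloc[:, :2]
    df.columns = ["accession", "group"]
    return GroupPartition(df.set_index("accession")["group"])


def write_groups(partition: GroupPartition, path: str, sep: str = "\t") -> None:
    partition.labels.rename("group").rename_axis("accession").to_csv(path, sep=sep)


def read_gff(path: str) -> GeneSet:
    """Extract ``gene`` features from a GFF3 file (1-based inclusive)."""
    import gffutils

    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"malformed GFF3 line {i}: expected 9 columns")
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = [
        {"gene_id": g.id, "chromosome": g.seqid, "start_bp": g.start,
         "end_bp": g.end, "strand": g.strand}
        for g in db.features_of_type("gene")
    ]
    return GeneSet(pd.DataFrame(rows, columns=["gene_id", "chromosome", "start_bp",
                                               "end_bp", "strand"]))


def load_config(path: str) -> dict:
    """Run-level YAML configuration (inputs, alphas, windows, seeds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
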