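import numpy as np
import pandas as pd
import pytest

from soyqtl.genio import GenotypeMatrix, GroupPartition, TraitObservations
from soyqtl import simpop


def make_matrix(calls, chroms=None, positions=None, accessions=None,
                snp_ids=None) -> GenotypeMatrix:
    """GenotypeMatrix from a plain (accessions x snps) 0/1/-1 array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    accessions = accessions or [f"A{i}" for i in range(n)]
    chroms = np.asarray(chroms if chroms is not None else ["c1"] * m, dtype=object)
    positions = np.asarray(positions if positions is not None
                           else 1000 * (np.arange(m) + 1), dtype=np.int64)
    snp_ids = snp_ids or [f"{chroms[j]}_{positions[j]}" for j in range(m)]
    gm = GenotypeMatrix(accessions, snp_ids, chroms, positions, calls)
    gm.validate()
    return gm


def make_obs(records) -> TraitObservations:
    """TraitObservations from (accession, env, rep, value) tuples."""
    return TraitObservations(pd.DataFrame(
        records, columns=["accession", "environment", "replication", "value"]))


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated panel shared by read-only tests."""
    cfg = simpop.SimConfig(n_accessions=200, n_chromosomes=4,
                           snps_per_chromosome=60, n_qtl=8,
                           sigma_g2=8.0, sigma_ge2=4.0, sigma_e2=4.0, seed=11)
    return simpop.simulate(cfg)
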