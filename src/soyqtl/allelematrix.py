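"""QTL-allele matrix assembly and subpopulation differentiation.

The QTL-allele matrix is the loci x accessions table whose cell (l, i) is
the estimated effect of the allele accession i carries at detected locus l —
a compact picture of the population's genetic constitution.  Rows order by
ascending positive-allele frequency and columns by ascending phenotype for
display.  Differentiation among subpopulations (ecoregions) is tested per
locus with a Pearson chi-square on the allele x group count table, with a
fixed-margin Monte-Carlo fallback when expected counts drop below 5, and a
Benjamini-Hochberg FDR column across loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genio import GroupPartition
from .rtmgwas import AlleleEffects

log = logging.getLogger(__name__)


@dataclass
class QTLAlleleMatrix:
    effects: pd.DataFrame        # loci x accessions, cell = carried-allele effect
    allele_idx: pd.DataFrame     # loci x accessions, carried allele index
    row_meta: pd.DataFrame       # per locus: r2, positive_allele_freq
    col_meta: pd.DataFrame       # per accession: phenotype_mean, group

    def sorted_view(self) -> pd.DataFrame:
        """Rows by ascending positive-allele frequency, columns by phenotype."""
        rows = self.row_meta.sort_values("positive_allele_freq").index
        cols = self.col_meta.sort_values("phenotype_mean").index
        return self.effects.loc[rows, cols]


def build_qam(effects: AlleleEffects, markers, phenotype_means: pd.Series,
              partition: GroupPartition | None = None,
              locus_r2: dict | None = None) -> QTLAlleleMatrix:
    """Join per-locus allele effects with per-accession allele assignments."""
    by_id = {m.id: m for m in markers}
    accessions = None
    eff_rows, idx_rows, meta_rows = {}, {}, []
    for mid, eff in effects.effects.items():
        m = by_id[mid]
        if accessions is None:
            accessions = list(phenotype_means.index)
        alle = np.asarray(m.allele_of)
        missing = set(np.unique(alle)) - set(eff)
        if missing:
            raise ValueError(f"locus {mid}: no effect for carried allele(s) "
                             f"{sorted(missing)}")
        cells = np.array([eff[int(a)] for a in alle])
        eff_rows[mid] = cells
        idx_rows[mid] = alle
        pos_freq = float(np.mean(cells > 0))
        meta_rows.append({"locus": mid, "positive_allele_freq": pos_freq,
                          "r2": (locus_r2 or {}).get(mid, np.nan)})
    eff_df = pd.DataFrame(eff_rows, index=accessions).T
    idx_df = pd.DataFrame(idx_rows, index=accessions).T
    col_meta = pd.DataFrame({"phenotype_mean": phenotype_means})
    col_meta["group"] = (partition.labels.reindex(col_meta.index)
                         if partition is not None else pd.NA)
    row_meta = pd.DataFrame(meta_rows).set_index("locus")
    return QTLAlleleMatrix(eff_df, idx_df, row_meta, col_meta)


def count_signed_alleles(qam: QTLAlleleMatrix) -> pd.DataFrame:
    """Strict-sign counts of carried-allele effects per accession."""
    e = qam.effects
    return pd.DataFrame({
        "n_positive": (e > 0).sum(axis=0),
        "n_negative": (e < 0).sum(axis=0),
        "n_zero": (e == 0).sum(axis=0),
    })


def group_allele_freqs(markers, partition: GroupPartition,
                       loci: list[str] | None = None,
                       accession_ids: list[str] | None = None) -> pd.DataFrame:
    """Tidy count/frequency table: locus x allele x group, plus overall.

    ``accession_ids`` gives the order of each marker's ``allele_of`` rows;
    when omitted the partition's own index order is assumed to match.  Empty
    groups are dropped with a warning.  Within (locus, group) the frequencies
    sum to 1 and the counts to the group size.
    """
    by_id = {m.id: m for m in markers}
    loci = loci or list(by_id)
    labels = (partition.labels.reindex(accession_ids)
              if accession_ids is not None else partition.labels)
    groups = [g for g in sorted(labels.dropna().unique())
              if (labels == g).sum() > 0]
    dropped = set(partition.labels.unique()) - set(groups)
    if dropped:
        log.warning("dropping empty group(s) %s", sorted(dropped))
    rows = []
    for mid in loci:
        m = by_id[mid]
        alle = np.asarray(m.allele_of)
        acc_groups = labels.to_numpy()
        n_total = len(alle)
        for a in np.unique(alle):
            row = {"locus": mid, "allele": int(a),
                   "overall_count": int((alle == a).sum()),
                   "overall_freq": float((alle == a).mean())}
            for g in groups:
                sel = acc_groups == g
                row[f"count_{g}"] = int((alle[sel] == a).sum())
                row[f"freq_{g}"] = float((alle[sel] == a).mean())
            rows.append(row)
        _ = n_total
    return pd.DataFrame(rows)


def _locus_contingency(table: pd.DataFrame, locus: str) -> np.ndarray:
    sub = table[table["locus"] == locus]
    count_cols = [c for c in table.columns if c.startswith("count_")]
    return sub[count_cols].to_numpy(int)


def chisq_differentiation(table: pd.DataFrame, locus: str,
                          rng: np.random.Generator | None = None,
                          n_resamples: int = 10_000,
                          ) -> tuple[float, int, float, bool]:
    """Pearson chi-square of allele x group independence for one locus.

    When any expected count is < 5 the p-value is replaced by a fixed-margin
    Monte-Carlo permutation p (``n_resamples`` tables), flagged in the fourth
    return slot.  Degenerate tables (one allele or one group) raise.
    """
    obs = _locus_contingency(table, locus)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(f"degenerate table for locus {locus}")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if (expected >= 5).all():
        return float(chi2), int(dof), float(p), False
    rng = np.random.default_rng(0) if rng is None else rng
    sampler = stats.random_table(obs.sum(axis=1), obs.sum(axis=0))
    exceed = 0
    batch = sampler.rvs(n_resamples, random_state=rng)
    colsums = obs.sum(axis=0)
    rowsums = obs.sum(axis=1)
    exp = np.outer(rowsums, colsums) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        stat_obs = np.nansum((obs - exp) ** 2 / exp)
        stats_mc = np.nansum((batch - exp) ** 2 / exp, axis=(1, 2))
    exceed = int((stats_mc >= stat_obs - 1e-12).sum())
    p_mc = (exceed + 1) / (n_resamples + 1)
    return float(chi2), int(dof), float(p_mc), True


def differentiation_table(freq_table: pd.DataFrame,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-locus chi-square, raw p, Monte-Carlo flag and BH-FDR q-value."""
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for locus in freq_table["locus"].unique():
        try:
            chi2, dof, p, mc = chisq_differentiation(freq_table, locus, rng)
        except ValueError:
            continue
        rows.append({"locus": locus, "chi2": chi2, "df": dof, "p": p,
                     "monte_carlo": mc})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr_q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def specific_alleles(freq_table: pd.DataFrame, max_groups: int = 2,
                     ) -> pd.DataFrame:
    """Alleles carried in at most ``max_groups`` subpopulations."""
    count_cols = [c for c in freq_table.columns if c.startswith("count_")]
    carriers = freq_table[count_cols].gt(0)
    n_groups = carriers.sum(axis=1)
    sel = freq_table[n_groups <= max_groups].copy()
    sel["carrier_groups"] = [
        [c.removeprefix("count_") for c in count_cols if row[c] > 0]
        for _, row in sel.iterrows()]
    return sel[["locus", "allele", "overall_freq", "carrier_groups"]]
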