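"""Restricted two-stage multi-locus association on multi-allelic markers.

Stage 1 tests each marker's allele-class factor (an F-test on allele_count-1
degrees of freedom) added to a covariate-only model (top eigenvectors of the
allele-sharing similarity matrix) and keeps markers below a lenient p
threshold.  Stage 2 builds the joint multi-locus model by forward-backward
stepwise regression over the surviving candidates.

Experiment-wise error control: the normal significance level alpha (default
0.02) is applied experiment-wise at entry — a candidate enters only if its
Sidak-adjusted partial-F p over the m candidates examined at that step,
1-(1-p)^m, is below alpha.  This is what makes alpha a control on the
probability that a global-null scan selects anything at all, rather than a
per-test level that any min-p search would overrun.  Retained markers always
satisfy raw partial p < alpha as well (the adjusted p bounds it from above),
and the backward pass removes any marker whose raw partial p drifts to or
above alpha as competitors enter.

Markers are coded with zero-sum contrasts, so back-transformed per-allele
effects sum to zero at every locus (unweighted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class MarkerData:
    """Minimal per-marker view the engine needs."""

    id: str
    chromosome: str
    position_bp: int
    n_alleles: int
    allele_of: np.ndarray  # per (phenotyped) accession allele index


def markers_to_data(markers, accession_index: np.ndarray | None = None,
                    ) -> list[MarkerData]:
    """Adapt SNPLDBMarker objects (optionally subset to phenotyped rows)."""
    out = []
    for m in markers:
        alle = m.allele_of if accession_index is None else m.allele_of[accession_index]
        out.append(MarkerData(m.id, m.chromosome, int(m.start_bp),
                              m.n_alleles, np.asarray(alle)))
    return out


def _contrast_columns(allele_of: np.ndarray, n_alleles: int) -> np.ndarray:
    """Zero-sum coding: k-1 columns; allele k-1 carries -1 everywhere."""
    k = n_alleles
    X = np.zeros((len(allele_of), k - 1))
    for j in range(k - 1):
        X[allele_of == j, j] = 1.0
    X[allele_of == k - 1, :] = -1.0
    return X


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and matrix rank of the least-squares fit."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0]), int(rank)
    return float(((y - X @ beta) ** 2).sum()), int(rank)


@dataclass
class Stage1Result:
    table: pd.DataFrame  # index marker id; columns F, df, p, r2


def stage1_scan(markers: list[MarkerData], y: np.ndarray,
                covariates: np.ndarray | None = None) -> Stage1Result:
    """Single-locus F-scan of every marker over the covariate-only model."""
    y = np.asarray(y, float)
    n = len(y)
    base = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    rss0, rank0 = _rss(base, y)
    tss = float(((y - y.mean()) ** 2).sum())
    rows = {}
    for m in markers:
        present = np.unique(m.allele_of)
        if len(present) < 2:
            log.debug("marker %s has one allele class; skipped", m.id)
            continue
        C = _contrast_columns(m.allele_of, m.n_alleles)
        # drop columns for absent alleles to keep the design full rank
        C = C[:, np.abs(C).sum(0) > 0]
        X = np.column_stack([base, C])
        rss1, rank1 = _rss(X, y)
        df_num = rank1 - rank0
        df_den = n - rank1
        if df_num < 1 or df_den < 1:
            continue
        if rss0 <= 1e-12 * (1.0 + float(y @ y)):
            # nothing left to explain (constant phenotype)
            f, p = 0.0, 1.0
        elif rss1 <= 0:
            f, p = np.inf, 0.0
        else:
            f = ((rss0 - rss1) / df_num) / (rss1 / df_den)
            p = float(stats.f.sf(f, df_num, df_den))
        rows[m.id] = {"F": f, "df": df_num, "p": p,
                      "r2": (rss0 - rss1) / tss if tss > 0 else 0.0}
    return Stage1Result(pd.DataFrame.from_dict(rows, orient="index"))


def preselect(stage1: Stage1Result, threshold: float = 0.05) -> list[str]:
    """Marker ids with p < threshold, ordered by ascending p."""
    t = stage1.table
    kept = t[t["p"] < threshold].sort_values("p")
    if kept.empty:
        log.info("no markers pass stage-1 threshold %.3g; model is covariates-only",
                 threshold)
    return list(kept.index)


@dataclass
class MultiLocusModel:
    selected: list[str]                  # in selection order
    markers: dict                        # id -> MarkerData
    coef: np.ndarray
    partial_p: dict
    seq_r2: dict
    partial_r2: dict
    model_r2: float
    covariate_r2: float
    residual_var: float
    alpha_enter: float
    alpha_exit: float
    y: np.ndarray = field(repr=False, default=None)
    covariates: np.ndarray | None = field(repr=False, default=None)


def _design(markers: dict, selected: list[str], y_len: int,
            covariates: np.ndarray | None, skip: str | None = None) -> np.ndarray:
    cols = [np.ones((y_len, 1))]
    if covariates is not None:
        cols.append(covariates)
    for mid in selected:
        if mid == skip:
            continue
        m = markers[mid]
        C = _contrast_columns(m.allele_of, m.n_alleles)
        cols.append(C[:, np.abs(C).sum(0) > 0])
    return np.column_stack(cols)


def _partial_f_p(rss_red: float, rank_red: int, rss_full: float, rank_full: int,
                 n: int) -> float:
    df_num = rank_full - rank_red
    df_den = n - rank_full
    if df_num < 1 or df_den < 1:
        return 1.0
    if rss_full <= 0:
        return 0.0
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    return float(stats.f.sf(max(f, 0.0), df_num, df_den))


def stage2_stepwise(candidates: list[str], markers: list[MarkerData],
                    y: np.ndarray, covariates: np.ndarray | None = None,
                    alpha_enter: float = 0.02, alpha_exit: float | None = None,
                    n_genome_tests: int | None = None,
                    max_steps: int = 200) -> MultiLocusModel:
    """Forward-backward stepwise build of the joint multi-locus model.

    ``n_genome_tests`` is the number of markers the genome scan examined
    (defaults to the full marker list handed in); the Sidak entry adjustment
    runs over this count so that alpha stays an experiment-wise level for the
    whole scan, not a per-candidate one.  Ties at entry break on (smallest p,
    then genome position), making the result invariant to candidate input
    order.
    """
    alpha_exit = alpha_enter if alpha_exit is None else alpha_exit
    m_tests = n_genome_tests if n_genome_tests is not None else len(markers)
    y = np.asarray(y, float)
    n = len(y)
    by_id = {m.id: m for m in markers}
    pool = sorted(set(candidates), key=lambda mid: (by_id[mid].chromosome,
                                                    by_id[mid].position_bp))
    selected: list[str] = []

    for _ in range(max_steps):
        changed = False
        X_cur = _design(by_id, selected, n, covariates)
        rss_cur, rank_cur = _rss(X_cur, y)
        # forward: best candidate by Sidak-adjusted partial p over the pool
        remaining = [mid for mid in pool if mid not in selected]
        if remaining:
            best = None
            for mid in remaining:
                m = by_id[mid]
                if len(np.unique(m.allele_of)) < 2:
                    continue
                X_try = _design(by_id, selected + [mid], n, covariates)
                rss_try, rank_try = _rss(X_try, y)
                if rank_try <= rank_cur:
                    log.debug("candidate %s collinear with current model; skipped", mid)
                    continue
                p = _partial_f_p(rss_cur, rank_cur, rss_try, rank_try, n)
                key = (p, m.chromosome, m.position_bp)
                if best is None or key < best[0]:
                    best = (key, mid, p)
            if best is not None:
                m_adj = max(m_tests, len(remaining), 1)
                p_adj = 1.0 - (1.0 - best[2]) ** m_adj if best[2] < 1 else 1.0
                if p_adj < alpha_enter:
                    selected.append(best[1])
                    changed = True
        # backward: drop the worst included marker at raw partial p >= alpha_exit
        while len(selected) > 0:
            X_full = _design(by_id, selected, n, covariates)
            rss_full, rank_full = _rss(X_full, y)
            worst = None
            for mid in selected:
                X_red = _design(by_id, selected, n, covariates, skip=mid)
                rss_red, rank_red = _rss(X_red, y)
                p = _partial_f_p(rss_red, rank_red, rss_full, rank_full, n)
                if worst is None or p > worst[1]:
                    worst = (mid, p)
            if worst is not None and worst[1] >= alpha_exit:
                selected.remove(worst[0])
                changed = True
            else:
                break
        if not changed:
            break

    return _finalize_model(selected, by_id, y, covariates, alpha_enter, alpha_exit)


def _finalize_model(selected: list[str], by_id: dict, y: np.ndarray,
                    covariates: np.ndarray | None, alpha_enter: float,
                    alpha_exit: float) -> MultiLocusModel:
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    X_full = _design(by_id, selected, n, covariates)
    beta, _, rank_full, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_full = float(((y - X_full @ beta) ** 2).sum())

    base = _design(by_id, [], n, covariates)
    rss_base, _ = _rss(base, y)
    cov_r2 = (tss - rss_base) / tss if tss > 0 else 0.0

    partial_p, partial_r2 = {}, {}
    for mid in selected:
        X_red = _design(by_id, selected, n, covariates, skip=mid)
        rss_red, rank_red = _rss(X_red, y)
        partial_p[mid] = _partial_f_p(rss_red, rank_red, rss_full, rank_full, n)
        partial_r2[mid] = (rss_red - rss_full) / tss if tss > 0 else 0.0

    seq_r2 = {}
    rss_prev = rss_base
    for i, mid in enumerate(selected):
        X_i = _design(by_id, selected[:i + 1], n, covariates)
        rss_i, _ = _rss(X_i, y)
        seq_r2[mid] = (rss_prev - rss_i) / tss if tss > 0 else 0.0
        rss_prev = rss_i

    df_den = max(n - rank_full, 1)
    return MultiLocusModel(
        selected=selected, markers={mid: by_id[mid] for mid in selected},
        coef=beta, partial_p=partial_p, seq_r2=seq_r2, partial_r2=partial_r2,
        model_r2=(tss - rss_full) / tss if tss > 0 else 0.0,
        covariate_r2=cov_r2, residual_var=rss_full / df_den,
        alpha_enter=alpha_enter, alpha_exit=alpha_exit, y=y,
        covariates=covariates)


def partition_r2(model: MultiLocusModel) -> pd.DataFrame:
    """Sequential (selection-order) and partial (last-entry) R2 per marker."""
    rows = [{"marker": mid, "seq_r2": model.seq_r2[mid],
             "partial_r2": model.partial_r2[mid], "p": model.partial_p[mid]}
            for mid in model.selected]
    return pd.DataFrame(rows)


@dataclass
class AlleleEffects:
    mu: float
    effects: dict  # marker id -> {allele index: effect}


def allele_effects(model: MultiLocusModel) -> AlleleEffects:
    """Back-transform the zero-sum contrast coefficients to per-allele effects.

    Alleles absent from the phenotyped accessions get no effect.  The
    population mean term is the phenotype mean.
    """
    n = len(model.y)
    offset = 1 + (model.covariates.shape[1] if model.covariates is not None else 0)
    out = {}
    pos = offset
    for mid in model.selected:
        m = model.markers[mid]
        C = _contrast_columns(m.allele_of, m.n_alleles)
        keep = np.abs(C).sum(0) > 0
        ncol = int(keep.sum())
        beta = model.coef[pos:pos + ncol]
        pos += ncol
        # per-allele effect implied by the coding, for alleles present only
        present = np.unique(m.allele_of)
        eff = {}
        full_beta = np.zeros(m.n_alleles - 1)
        full_beta[np.flatnonzero(keep)] = beta
        for a in present:
            if a < m.n_alleles - 1:
                eff[int(a)] = float(full_beta[a])
            else:
                eff[int(a)] = float(-full_beta.sum())
        # re-center over the supported alleles (absent alleles carry no mass)
        absent = set(range(m.n_alleles)) - set(int(a) for a in present)
        if absent:
            log.info("marker %s: alleles %s unsupported in phenotyped set",
                     mid, sorted(absent))
            center = np.mean(list(eff.values()))
            eff = {a: v - center for a, v in eff.items()}
        out[mid] = eff
    return AlleleEffects(mu=float(np.mean(model.y)), effects=out)


def run_rtm_gwas(markers: list[MarkerData], y: np.ndarray,
                 covariates: np.ndarray | None = None,
                 stage1_p: float = 0.05, alpha: float = 0.02,
                 ) -> tuple[Stage1Result, MultiLocusModel, AlleleEffects]:
    """Convenience wrapper: scan, preselect, stepwise, effects."""
    s1 = stage1_scan(markers, y, covariates)
    cand = preselect(s1, stage1_p)
    model = stage2_stepwise(cand, markers, y, covariates, alpha_enter=alpha)
    return s1, model, allele_effects(model)


def qtl_table(model: MultiLocusModel, trait: str = "Trait") -> pd.DataFrame:
    """Detected-locus table: QTL name, marker, allele number, -log10 p, R2.

    QTL naming convention: "<Trait>-a-<chrom#>-<serial>" with serials running
    along each chromosome in genome order.
    """
    ordered = sorted(model.selected,
                     key=lambda mid: (model.markers[mid].chromosome,
                                      model.markers[mid].position_bp))
    serial: dict[str, int] = {}
    rows = []
    for mid in ordered:
        m = model.markers[mid]
        chrom_num = "".join(ch for ch in m.chromosome if ch.isdigit()) or m.chromosome
        serial[m.chromosome] = serial.get(m.chromosome, 0) + 1
        p = model.partial_p[mid]
        rows.append({
            "qtl": f"{trait}-a-{int(chrom_num):02d}-{serial[m.chromosome]}"
                   if chrom_num.isdigit() else f"{trait}-a-{chrom_num}-{serial[m.chromosome]}",
            "marker": mid,
            "n_alleles": m.n_alleles,
            "neg_log10_p": float(-np.log10(max(p, 1e-300))),
            "r2_seq": model.seq_r2[mid],
            "r2_partial": model.partial_r2[mid],
        })
    return pd.DataFrame(rows)
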