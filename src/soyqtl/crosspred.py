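"""Genomic selection for optimal crosses over the detected QTL-allele set.

For every parent pair, a population of fully homozygous recombinant inbred
lines (RILs, F-infinity selfs of the F1) is simulated over the detected loci.
Along a chromosome, parental origin follows a two-state Markov chain whose
switch probability between adjacent loci is the Haldane-Waddington RIL
recombination R = 2r/(1+2r), where r comes from the Haldane map function
r = (1 - exp(-2d/100))/2 at map distance d cM (physical positions scaled by
a cM/Mb rate unless a map is supplied).  The independent-assortment model
forces R = 0.5 everywhere.  A cross's predicted value is the nearest-rank
99th (maximize) or 1st (minimize) percentile of the progeny genotypic values
mu + sum of carried allele effects.

An exact enumerator over the 2^L parental-origin vectors of small crosses
serves as the verification oracle for the Monte-Carlo path.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GroupPartition
from .rtmgwas import AlleleEffects

log = logging.getLogger(__name__)


def haldane_r(d_cm: float) -> float:
    """Haldane map function: recombination fraction at distance d cM."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def ril_switch_prob(r: float) -> float:
    """Haldane-Waddington RIL (selfed to fixation) recombination: 2r/(1+2r)."""
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass
class GeneticMap:
    locus_ids: list[str]
    chromosome: np.ndarray
    position_bp: np.ndarray
    position_cm: np.ndarray
    rec_fraction: np.ndarray  # r to the PREVIOUS locus; r[0] = 0.5 by convention

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


def build_genetic_map(loci: pd.DataFrame, cm_per_mb: float = 2.5,
                      map_cm: pd.Series | None = None) -> GeneticMap:
    """Map over detected loci sorted by genome position.

    ``loci`` needs columns id, chromosome, position_bp.  cM positions default
    to bp * cm_per_mb / 1e6; adjacent-locus r is Haldane within a chromosome
    and 0.5 across chromosomes.
    """
    if cm_per_mb < 0:
        raise ValueError("cm_per_mb must be non-negative")
    df = loci.sort_values(["chromosome", "position_bp"]).reset_index(drop=True)
    if map_cm is not None:
        cm = map_cm.reindex(df["id"]).to_numpy(float)
    else:
        cm = df["position_bp"].to_numpy(float) * cm_per_mb / 1e6
    r = np.full(len(df), 0.5)
    for i in range(1, len(df)):
        if df.loc[i, "chromosome"] == df.loc[i - 1, "chromosome"]:
            r[i] = haldane_r(abs(cm[i] - cm[i - 1]))
    return GeneticMap(list(df["id"]), df["chromosome"].to_numpy(object),
                      df["position_bp"].to_numpy(np.int64), cm, r)


def _switch_probs(gmap: GeneticMap, model: str) -> np.ndarray:
    if model == "independent":
        return np.full(gmap.n_loci, 0.5)
    if model != "linkage":
        raise ValueError(f"unknown model {model!r}")
    return np.array([ril_switch_prob(r) for r in gmap.rec_fraction])


def simulate_inbred_progeny(p1: np.ndarray, p2: np.ndarray, gmap: GeneticMap,
                            model: str = "linkage", n: int = 2000,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """n x loci allele table of fully homozygous recombinant progeny."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != (gmap.n_loci,) or p2.shape != (gmap.n_loci,):
        raise ValueError("parent allele vectors must cover every mapped locus")
    if np.any(p1 < 0) or np.any(p2 < 0):
        bad = gmap.locus_ids[int(np.argmax((p1 < 0) | (p2 < 0)))]
        raise ValueError(f"parent missing an allele at locus {bad}")
    rng = np.random.default_rng() if rng is None else rng
    R = _switch_probs(gmap, model)
    origins = np.empty((n, gmap.n_loci), dtype=bool)
    origins[:, 0] = rng.random(n) < 0.5
    for l in range(1, gmap.n_loci):
        switch = rng.random(n) < R[l]
        origins[:, l] = origins[:, l - 1] ^ switch
    return np.where(origins, p2[None, :], p1[None, :])


def genotypic_value(progeny: np.ndarray, effects: AlleleEffects,
                    locus_ids: list[str]) -> np.ndarray:
    """mu + sum of carried allele effects, per progeny row."""
    vals = np.full(progeny.shape[0], effects.mu)
    for j, mid in enumerate(locus_ids):
        eff = effects.effects[mid]
        lut_size = max(eff) + 1
        lut = np.zeros(lut_size)
        for a, e in eff.items():
            lut[a] = e
        vals += lut[progeny[:, j]]
    return vals


def nearest_rank_percentile(sample: np.ndarray, q: float) -> float:
    """The ceil(q*n)-th order statistic of the sample (deterministic)."""
    x = np.sort(np.asarray(sample))
    rank = max(int(math.ceil(q * len(x))), 1)
    return float(x[rank - 1])


@dataclass
class CrossPrediction:
    parent1: str
    parent2: str
    model: str
    direction: str               # "max" -> 99th pct, "min" -> 1st pct
    n_progeny: int
    predicted: float
    progeny_mean: float
    progeny_min: float
    progeny_max: float


def predict_cross(p1_id: str, p2_id: str, p1: np.ndarray, p2: np.ndarray,
                  effects: AlleleEffects, gmap: GeneticMap,
                  model: str = "linkage", direction: str = "max",
                  n: int = 2000, rng: np.random.Generator | None = None,
                  ) -> CrossPrediction:
    if n < 100:
        log.warning("n=%d progenies: percentile estimate will be unstable", n)
    prog = simulate_inbred_progeny(p1, p2, gmap, model, n, rng)
    vals = genotypic_value(prog, effects, gmap.locus_ids)
    q = 0.99 if direction == "max" else 0.01
    return CrossPrediction(p1_id, p2_id, model, direction, n,
                           nearest_rank_percentile(vals, q),
                           float(vals.mean()), float(vals.min()), float(vals.max()))


# ---------------------------------------------------------------------------
# exact small-cross oracle

def exact_small_cross(p1: np.ndarray, p2: np.ndarray, effects: AlleleEffects,
                      gmap: GeneticMap, model: str = "linkage",
                      max_loci: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Exact RIL progeny value distribution (values, probabilities).

    Enumerates parental-origin vectors over the segregating loci, with the
    effective switch probability between consecutive segregating loci obtained
    by collapsing the intervening steps of the origin chain:
    R_eff = (1 - prod(1 - 2 R_k)) / 2.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    R = _switch_probs(gmap, model)
    seg = np.flatnonzero(p1 != p2)
    if len(seg) > max_loci:
        raise ValueError(f"{len(seg)} segregating loci exceed cap {max_loci}")
    base = float(effects.mu)
    for j in np.flatnonzero(p1 == p2):
        base += effects.effects[gmap.locus_ids[j]][int(p1[j])]
    if len(seg) == 0:
        return np.array([base]), np.array([1.0])

    # effective switch prob between consecutive segregating loci
    R_eff = np.empty(len(seg))
    R_eff[0] = 0.5  # first origin is a fair coin
    for t in range(1, len(seg)):
        prod = 1.0
        for l in range(seg[t - 1] + 1, seg[t] + 1):
            prod *= (1.0 - 2.0 * R[l])
        R_eff[t] = (1.0 - prod) / 2.0

    eff1 = np.array([effects.effects[gmap.locus_ids[j]][int(p1[j])] for j in seg])
    eff2 = np.array([effects.effects[gmap.locus_ids[j]][int(p2[j])] for j in seg])
    values, probs = [], []
    for origin in itertools.product((0, 1), repeat=len(seg)):
        pr = 0.5
        for t in range(1, len(seg)):
            sw = origin[t] != origin[t - 1]
            pr *= R_eff[t] if sw else (1.0 - R_eff[t])
        v = base + sum(e2 if o else e1
                       for o, e1, e2 in zip(origin, eff1, eff2))
        values.append(v)
        probs.append(pr)
    # aggregate identical values; round away float noise from summation order
    df = pd.DataFrame({"v": np.round(values, 9), "p": probs}).groupby(
        "v", sort=True).sum()
    return df.index.to_numpy(), df["p"].to_numpy()


def exact_percentile(values: np.ndarray, probs: np.ndarray, q: float) -> float:
    """Smallest support value v with CDF(v) >= q."""
    cdf = np.cumsum(probs)
    return float(values[int(np.searchsorted(cdf, q - 1e-12))])


# ---------------------------------------------------------------------------
# panel-wide enumeration and ranking

def count_crosses(n_parents: int) -> int:
    """Number of unordered single crosses among n parents: C(n, 2)."""
    return math.comb(n_parents, 2)


def enumerate_pairs(accession_ids: list[str]):
    """All unordered parent pairs, in deterministic lexical-index order."""
    return itertools.combinations(accession_ids, 2)


def _pair_rng(global_seed: int, i: str, j: str) -> np.random.Generator:
    a, b = sorted((i, j))
    key = [ord(c) for c in (a + "|" + b)]
    return np.random.default_rng(np.random.SeedSequence([global_seed] + key))


def enumerate_and_rank(accession_ids: list[str], parent_alleles: pd.DataFrame,
                       effects: AlleleEffects, gmap: GeneticMap,
                       partition: GroupPartition | None = None,
                       direction: str = "max",
                       models: tuple[str, ...] = ("linkage", "independent"),
                       n_progeny: int = 2000, seed: int = 0,
                       top_k: int = 15) -> dict:
    """Score every unordered pair under each model and summarize.

    ``parent_alleles`` is the loci x accessions allele-index table (rows in
    ``gmap`` order).  Per-cross RNG streams derive from (seed, sorted pair),
    so results are independent of enumeration order.  Returns dict with keys
    ``crosses`` (per-pair table), ``group_summary`` and ``top`` (best top_k
    by the first model).
    """
    if len(accession_ids) < 2:
        raise ValueError("need at least two parents")
    A = parent_alleles.loc[gmap.locus_ids, accession_ids].to_numpy(int)
    col = {acc: i for i, acc in enumerate(accession_ids)}
    labels = (partition.labels if partition is not None else None)
    rows = []
    for pair in enumerate_pairs(accession_ids):
        p1_id, p2_id = sorted(pair)  # canonical order: invariant to enumeration
        rec = {"parent1": p1_id, "parent2": p2_id}
        if labels is not None:
            g1, g2 = labels.get(p1_id), labels.get(p2_id)
            rec["group1"], rec["group2"] = g1, g2
            rec["scope"] = f"within {g1}" if g1 == g2 else "among"
        for model in models:
            rng = _pair_rng(seed, p1_id, p2_id)
            cp = predict_cross(p1_id, p2_id, A[:, col[p1_id]], A[:, col[p2_id]],
                               effects, gmap, model, direction, n_progeny, rng)
            rec[f"predicted_{model}"] = cp.predicted
            rec[f"mean_{model}"] = cp.progeny_mean
        rows.append(rec)
    crosses = pd.DataFrame(rows)
    first = f"predicted_{models[0]}"
    ascending = direction == "min"
    crosses = crosses.sort_values(first, ascending=ascending).reset_index(drop=True)

    summary = None
    if labels is not None:
        pred_cols = [f"predicted_{m}" for m in models]
        parts = []
        for scope, sub in crosses.groupby("scope"):
            agg = {"crosses": len(sub)}
            for c in pred_cols:
                agg[f"{c}_mean"] = sub[c].mean()
                agg[f"{c}_min"] = sub[c].min()
                agg[f"{c}_max"] = sub[c].max()
            parts.append({"scope": scope, **agg})
        entire = {"scope": "entire", "crosses": len(crosses)}
        for c in pred_cols:
            entire[f"{c}_mean"] = crosses[c].mean()
            entire[f"{c}_min"] = crosses[c].min()
            entire[f"{c}_max"] = crosses[c].max()
        summary = pd.DataFrame(parts + [entire])
    return {"crosses": crosses, "group_summary": summary,
            "top": crosses.head(top_k)}


def multi_trait_select(predictions: dict[str, pd.DataFrame],
                       directions: dict[str, str],
                       weights: dict[str, float] | None = None,
                       top_k: int = 15,
                       value_col: str = "predicted_linkage") -> pd.DataFrame:
    """Rank crosses by a weighted standardized score over several traits.

    Each trait's predicted values are z-scored across crosses; maximize
    traits add +z, minimize traits add -z; weights default to equal.  All
    trait tables must cover the same parent pairs.
    """
    traits = list(predictions)
    weights = weights or {t: 1.0 for t in traits}
    key = ["parent1", "parent2"]
    merged = None
    for t in traits:
        df = predictions[t][key + [value_col]].rename(columns={value_col: t})
        merged = df if merged is None else merged.merge(df, on=key, how="inner")
        if len(merged) != len(df):
            raise ValueError("trait panels cover different crosses")
    score = np.zeros(len(merged))
    for t in traits:
        v = merged[t].to_numpy(float)
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        score += weights[t] * (z if directions[t] == "max" else -z)
    merged["score"] = score
    return merged.sort_values("score", ascending=False).head(top_k).reset_index(drop=True)
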