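"""Variance components, heritability and GCV for RCBD multi-environment trials.

The trial model is y_ijk = mu + G_i + E_j + R(E)_jk + GE_ij + e_ijk with
genotype, environment, replication-within-environment and GxE all random.
For balanced data the components come from the expected-mean-squares
identities of the two-way ANOVA:

    E[MS_error] = s2,  E[MS_GE] = s2 + r*s2_ge,  E[MS_G] = s2 + r*s2_ge + r*s*s2_g

so s2_g = (MS_G - MS_GE)/(r*s), s2_ge = (MS_GE - MS_error)/r, which equals
REML on balanced data up to truncation of negative estimates at zero.
Unbalanced data are routed to an iterative REML fit (statsmodels MixedLM with
a genotype intercept and a genotype-by-environment variance component).

Heritability:  single-env  h2 = s2_g / (s2_g + s2/r)
               multi-env   h2 = s2_g / (s2_g + s2_ge/s + s2/(s*r))
GCV = 100 * s_g / mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import TraitObservations

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    s: int                      # environments
    r: int                      # replications per environment
    grand_mean: float
    accession_means: pd.Series
    env_means: pd.Series
    mean_squares: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)   # pre-truncation estimates


def _check_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["accession", "environment"]).size()
    full = df["accession"].nunique() * df["environment"].nunique()
    return len(counts) == full and counts.nunique() == 1


def fit_variance_components(obs: TraitObservations) -> VarianceComponents:
    """Estimate (s2_g, s2_ge, s2) from RCBD multi-environment observations."""
    df = obs.table
    g = df["accession"].nunique()
    s = df["environment"].nunique()
    r = int(df.groupby(["accession", "environment"]).size().max())
    if s == 1 and r == 1:
        raise ValueError("sigma_g2 inseparable from sigma_e2 with one "
                         "environment and one replication")
    if not _check_balanced(df):
        return _fit_reml(obs)

    y = df["value"].to_numpy(float)
    grand = y.mean()
    acc_means = df.groupby("accession", sort=False)["value"].mean()
    env_means = df.groupby("environment", sort=False)["value"].mean()
    ge_means = df.groupby(["accession", "environment"], sort=False)["value"].mean()
    rep_means = df.groupby(["environment", "replication"], sort=False)["value"].mean()

    ss_g = s * r * float(((acc_means - grand) ** 2).sum())
    ss_e = g * r * float(((env_means - grand) ** 2).sum())
    ss_re = g * float(((rep_means - env_means.reindex(
        rep_means.index.get_level_values(0)).to_numpy()) ** 2).sum())
    ge_dev = (ge_means
              - acc_means.reindex(ge_means.index.get_level_values(0)).to_numpy()
              - env_means.reindex(ge_means.index.get_level_values(1)).to_numpy()
              + grand)
    ss_ge = r * float((ge_dev ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_g - ss_e - ss_re - ss_ge

    df_g, df_e, df_re = g - 1, s - 1, s * (r - 1)
    df_ge = (g - 1) * (s - 1)
    df_err = (g - 1) * s * (r - 1)
    ms = {"G": ss_g / df_g if df_g else 0.0,
          "E": ss_e / df_e if df_e else 0.0,
          "R(E)": ss_re / df_re if df_re else 0.0,
          "GE": ss_ge / df_ge if df_ge else 0.0,
          "error": ss_err / df_err if df_err else 0.0}

    if s == 1:
        # GE not estimable; G tested against error within the single trial
        raw_g = (ms["G"] - ms["error"]) / r
        raw_ge = 0.0
    elif r == 1:
        # no within-environment replication: error and GE are confounded
        raw_ge = 0.0
        ms["error"] = ms["GE"]
        raw_g = (ms["G"] - ms["GE"]) / (s * r)
    else:
        raw_g = (ms["G"] - ms["GE"]) / (s * r)
        raw_ge = (ms["GE"] - ms["error"]) / r
    raw_e = ms["error"]

    comps = {}
    for name, v in (("sigma_g2", raw_g), ("sigma_ge2", raw_ge), ("sigma_e2", raw_e)):
        if v < 0:
            log.info("negative %s estimate %.4g truncated to 0", name, v)
        comps[name] = max(v, 0.0)
    return VarianceComponents(
        comps["sigma_g2"], comps["sigma_ge2"], comps["sigma_e2"], s, r,
        grand, acc_means, env_means, mean_squares=ms,
        raw={"sigma_g2": raw_g, "sigma_ge2": raw_ge, "sigma_e2": raw_e})


def _fit_reml(obs: TraitObservations) -> VarianceComponents:
    """Iterative REML for unbalanced data (environment treated as a stratum)."""
    import statsmodels.formula.api as smf

    df = obs.table.copy()
    s = df["environment"].nunique()
    r = int(round(df.groupby(["accession", "environment"]).size().mean()))
    multi_env = s > 1
    # environment and replication-within-environment enter as strata (fixed)
    if multi_env and r > 1:
        fixed = "value ~ C(environment) + C(environment):C(replication)"
    elif multi_env:
        fixed = "value ~ C(environment)"
    elif r > 1:
        fixed = "value ~ C(replication)"
    else:
        fixed = "value ~ 1"
    vc = {"ge": "0 + C(environment)"} if multi_env and r > 1 else None
    model = smf.mixedlm(fixed, df, groups=df["accession"], re_formula="1",
                        vc_formula=vc)
    fit = model.fit(reml=True, method="lbfgs")
    sigma_g2 = float(fit.cov_re.iloc[0, 0])
    sigma_ge2 = float(fit.vcomp[0]) if vc else 0.0
    sigma_e2 = float(fit.scale)
    return VarianceComponents(
        max(sigma_g2, 0.0), max(sigma_ge2, 0.0), max(sigma_e2, 0.0), s, max(r, 1),
        float(df["value"].mean()),
        df.groupby("accession", sort=False)["value"].mean(),
        df.groupby("environment", sort=False)["value"].mean(),
        raw={"sigma_g2": sigma_g2, "sigma_ge2": sigma_ge2, "sigma_e2": sigma_e2})


def heritability(vc: VarianceComponents, mode: str = "multi_env") -> float:
    """Entry-mean heritability, clipped to [0, 1]."""
    if vc.sigma_g2 == 0 and vc.sigma_ge2 == 0 and vc.sigma_e2 == 0:
        raise ValueError("all variance components are zero: h2 undefined")
    if mode == "single_env":
        denom = vc.sigma_g2 + vc.sigma_e2 / vc.r
    elif mode == "multi_env":
        denom = vc.sigma_g2 + vc.sigma_ge2 / vc.s + vc.sigma_e2 / (vc.s * vc.r)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        return 1.0
    return float(np.clip(vc.sigma_g2 / denom, 0.0, 1.0))


def gcv(vc: VarianceComponents) -> float:
    """Genetic coefficient of variation, percent: 100 * sigma_g / mean."""
    if vc.grand_mean == 0:
        raise ValueError("GCV undefined at zero mean")
    return 100.0 * float(np.sqrt(vc.sigma_g2)) / abs(vc.grand_mean)


def per_environment_h2(obs: TraitObservations) -> pd.Series:
    """Single-environment h2 per environment (each trial analyzed alone)."""
    out = {}
    for env, sub in obs.table.groupby("environment", sort=False):
        vc = fit_variance_components(TraitObservations(sub.copy()))
        out[env] = heritability(vc, "single_env")
    return pd.Series(out, name="h2_single_env")
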