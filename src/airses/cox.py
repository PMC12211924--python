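"""Proportional-hazards fitting and diagnostics for the joint analysis.

Builds the 9-level joint exposure-SES category (air-pollution-score tertile
crossed with the three-level socioeconomic class), fits Cox models with
Efron tie handling and optional delayed entry, and provides likelihood-ratio
interaction tests, Schoenfeld-residual proportionality diagnostics, and
Rubin's-rule pooling of multiply-imputed estimates.

Partial-likelihood maximization is delegated to lifelines'
``CoxPHFitter``; the contract here is the returned coefficient /
covariance / log-likelihood triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from airses.lca import AREA_LEVELS, SES_LEVELS
from airses.scores import TERTILE_LEVELS

#: Joint-group levels in reference-first order: tertile 1 x most-favourable
#: SES is the reference cell.
JOINT_LEVELS = [f"T{t}x{s}" for t in (1, 2, 3) for s in ("high", "medium", "low")]


def make_joint_exposure(tertiles, ses) -> pd.Categorical:
    """Cross the score tertile with the SES level into a 9-level category.

    Accepts tertile labels (``first``/``second``/``third``) and either
    individual (``high``/``medium``/``low``) or area
    (``least``/``moderately``/``severely``) SES labels; area labels are
    mapped onto the same generic ordering.  The reference level is
    ``T1xhigh`` (lowest exposure, most favourable status).
    """
    tert = pd.Categorical(tertiles)
    ses_c = pd.Categorical(ses)
    if len(tert) != len(ses_c):
        raise ValueError("tertile and SES vectors must be aligned")
    if (tert.codes < 0).any() or (ses_c.codes < 0).any():
        raise ValueError("missing tertile or SES category")
    t_map = {lev: i + 1 for i, lev in enumerate(TERTILE_LEVELS)}
    s_map = {lev: g for lev, g in zip(SES_LEVELS, ("high", "medium", "low"))}
    s_map.update({lev: g for lev, g in zip(AREA_LEVELS, ("high", "medium", "low"))})
    try:
        labels = [
            f"T{t_map[t]}x{s_map[s]}" for t, s in zip(tert, ses_c)
        ]
    except KeyError as err:  # pragma: no cover - defensive
        raise ValueError(f"unrecognised category {err}") from err
    return pd.Categorical(labels, categories=JOINT_LEVELS)


@dataclass
class HazardFit:
    """Result of a proportional-hazards fit."""

    params: pd.Series                 # log hazard ratios
    covariance: pd.DataFrame
    log_likelihood: float
    n_events: int
    n: int
    ties: str = "efron"
    _fitter: CoxPHFitter | None = field(default=None, repr=False)
    _design: pd.DataFrame | None = field(default=None, repr=False)
    _meta: dict = field(default_factory=dict, repr=False)

    def hazard_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """HRs with Wald confidence limits and p-values."""
        se = np.sqrt(np.diag(self.covariance.to_numpy()))
        z = stats.norm.ppf(1 - alpha / 2)
        b = self.params.to_numpy()
        with np.errstate(over="ignore"):
            return self._hr_frame(b, se, z)

    def _hr_frame(self, b, se, z) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hr": np.exp(b),
                "lo": np.exp(b - z * se),
                "hi": np.exp(b + z * se),
                "p": 2 * stats.norm.sf(np.abs(b) / se),
            },
            index=self.params.index,
        )


def _build_design(data: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Expand categorical covariates to dummies (first level dropped)."""
    parts = []
    for col in covariates:
        s = data[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            d = pd.get_dummies(pd.Categorical(s), prefix=col, drop_first=True).astype(float)
            d.index = data.index
            parts.append(d)
        else:
            parts.append(s.astype(float).to_frame(col))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=data.index)


def fit_hazard_model(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    entry_col: str | None = None,
    ties: str = "efron",
) -> HazardFit:
    """Fit a Cox proportional-hazards model.

    ``covariates`` may mix numeric columns and categoricals (dummy-coded
    against their first level).  Right censoring is taken from
    ``event_col``; delayed entry (left truncation) from ``entry_col`` when
    given.  The design is checked for exact collinearity before fitting.
    """
    n_events = int(data[event_col].sum())
    if n_events < 1:
        raise ValueError("no events in the data; cannot fit a hazard model")

    X = _build_design(data, covariates)
    if X.shape[1] == 0:
        raise ValueError("no covariates supplied")
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    if np.linalg.matrix_rank(Xc) < X.shape[1]:
        raise ValueError("design matrix is collinear; drop redundant covariates")

    df = X.copy()
    df[duration_col] = data[duration_col].to_numpy(dtype=float)
    df[event_col] = data[event_col].to_numpy(dtype=int)
    kwargs = {}
    if entry_col is not None:
        df["__entry"] = data[entry_col].to_numpy(dtype=float)
        kwargs["entry_col"] = "__entry"

    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col, **kwargs)

    fit = HazardFit(
        params=cph.params_.copy(),
        covariance=cph.variance_matrix_.copy(),
        log_likelihood=float(cph.log_likelihood_),
        n_events=n_events,
        n=len(df),
        ties=ties,
        _fitter=cph,
        _design=df,
        _meta={"duration_col": duration_col, "event_col": event_col, "entry_col": entry_col},
    )
    return fit


def joint_hazard_table(fit: HazardFit, prefix: str = "group_") -> pd.DataFrame:
    """Reference-anchored HR table for the 9 joint exposure-SES cells."""
    hr = fit.hazard_ratios()
    rows = [{"group": JOINT_LEVELS[0], "hr": 1.0, "lo": np.nan, "hi": np.nan, "p": np.nan}]
    for lev in JOINT_LEVELS[1:]:
        key = f"{prefix}{lev}"
        if key in hr.index:
            r = hr.loc[key]
            rows.append({"group": lev, "hr": r["hr"], "lo": r["lo"], "hi": r["hi"], "p": r["p"]})
    return pd.DataFrame(rows)


def lr_interaction_test(full: HazardFit, reduced: HazardFit, tol: float = 1e-6):
    """Likelihood-ratio test of nested Cox models.

    Returns ``(statistic, df, p)`` with the statistic ``2 (l_full - l_red)``
    and a chi-square reference on the parameter-count difference.  A full
    model whose likelihood falls below the reduced one beyond ``tol``
    indicates an optimizer failure and raises.
    """
    df_diff = len(full.params) - len(reduced.params)
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if df_diff < 1:
        if df_diff == 0 and abs(stat) <= tol:
            return 0.0, 0, 1.0  # identical models
        raise ValueError("full model must have more parameters than the reduced model")
    if stat < -tol:
        raise ValueError(
            f"full-model log-likelihood below reduced ({stat / 2:.3g}); optimizer failure"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df_diff))
    return stat, df_diff, p


def pool_rubin(estimates, variances):
    """Pool estimates across imputations by Rubin's rules.

    Returns a :class:`PooledEstimate` with the pooled mean, within-imputation
    variance ``W``, between-imputation variance ``B`` and total variance
    ``T = W + (1 + 1/m) B``.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = est.size
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    if var.size != m:
        raise ValueError("estimates and variances must have equal length")
    W = float(var.mean())
    B = float(est.var(ddof=1))
    T = W + (1 + 1 / m) * B
    return PooledEstimate(pooled=float(est.mean()), within=W, between=B, total=T, m=m)


@dataclass
class PooledEstimate:
    pooled: float
    within: float
    between: float
    total: float
    m: int


def schoenfeld_residuals(fit: HazardFit) -> pd.DataFrame:
    """Schoenfeld residuals at event times (risk-set-weighted centring).

    For each event time the residual is the event subject's covariate value
    minus the ``exp(x beta)``-weighted mean over the risk set (subjects with
    entry < t <= exit).  Tied events each get their own row against the
    common risk set.  Rows are ordered by event time.
    """
    if fit._design is None:
        raise ValueError("fit does not retain its training data")
    meta = fit._meta
    df = fit._design
    cols = list(fit.params.index)
    X = df[cols].to_numpy(dtype=float)
    T = df[meta["duration_col"]].to_numpy(dtype=float)
    E = df[meta["event_col"]].to_numpy(dtype=int)
    entry = df["__entry"].to_numpy(dtype=float) if meta.get("entry_col") else np.zeros(len(df))
    if E.sum() < 2:
        raise ValueError("need at least 2 events for Schoenfeld residuals")

    w = np.exp(X @ fit.params.to_numpy())
    order = np.argsort(T, kind="stable")
    rows, times = [], []
    for i in order:
        if not E[i]:
            continue
        t = T[i]
        at_risk = (entry < t) & (T >= t)
        ww = w[at_risk]
        xbar = (ww[:, None] * X[at_risk]).sum(axis=0) / ww.sum()
        rows.append(X[i] - xbar)
        times.append(t)
    out = pd.DataFrame(rows, columns=cols)
    out.insert(0, "time", times)
    return out


def ph_diagnostic(fit: HazardFit) -> pd.DataFrame:
    """Proportional-hazards check from scaled Schoenfeld residuals.

    Scales the residuals by ``d * Var(beta)`` (d = number of events) and
    correlates each covariate's scaled residual with the rank of the event
    time; the p-value is the Pearson correlation test.  Covariates whose
    residuals are degenerate (zero variance) are excluded.
    """
    res = schoenfeld_residuals(fit)
    d = len(res)
    scaled = res.drop(columns="time").to_numpy() @ (d * fit.covariance.to_numpy())
    t_rank = stats.rankdata(res["time"].to_numpy())
    rows = []
    for j, name in enumerate(fit.params.index):
        col = scaled[:, j]
        if np.allclose(col.std(), 0):
            rows.append({"covariate": name, "rho": np.nan, "p": np.nan, "tested": False})
            continue
        rho, p = stats.pearsonr(col, t_rank)
        rows.append({"covariate": name, "rho": rho, "p": p, "tested": True})
    return pd.DataFrame(rows)
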