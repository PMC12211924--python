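"""Risk-stratified period life tables and life-expectancy differences.

A population's sex- and age-specific central mortality rates m(a) are
partitioned across joint exposure-SES groups using each group's prevalence
p_g and all-cause-mortality hazard ratio HR_g: the reference-group rate is

    m_ref(a) = m(a) / sum_g p_g HR_g,        m_g(a) = HR_g m_ref(a),

so the prevalence-weighted group rates reproduce the population rate
exactly at every age.  Each group's rates feed a standard period life
table from age 50 to 100 (actuarial a(x) = 0.5 conversion, open terminal
interval), and life-expectancy differences at 50 are reported against the
reference group.  Uncertainty in the hazard ratios is propagated by
parametric bootstrap: log HRs are redrawn from their normal sampling
distribution, the whole pipeline is recomputed per draw, and percentile
confidence intervals are taken over the runs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

AGE_LO, AGE_HI = 50, 100
AGES = np.arange(AGE_LO, AGE_HI + 1)
RADIX = 100_000.0


def validate_reference(rates: pd.Series) -> np.ndarray:
    """Check an age-indexed mortality-rate series covers ages 50..100 with
    positive rates; returns the rates as an array aligned to AGES."""
    idx = np.asarray(rates.index, dtype=int)
    missing = sorted(set(AGES) - set(idx))
    if missing:
        raise ValueError(f"reference mortality missing ages {missing[:5]}...")
    m = rates.reindex(AGES).to_numpy(dtype=float)
    if np.any(~np.isfinite(m)) or np.any(m <= 0):
        raise ValueError("mortality rates must be positive and finite at every age")
    return m


def read_reference(path) -> dict[str, pd.Series]:
    """Read an ONS-style life-table CSV (columns: age, sex, rate) into
    per-sex age-indexed rate series."""
    df = pd.read_csv(path)
    need = {"age", "sex", "rate"}
    if not need <= set(df.columns):
        raise ValueError(f"reference CSV needs columns {sorted(need)}")
    out = {}
    for sex, sub in df.groupby("sex"):
        out[str(sex)] = sub.set_index("age")["rate"].sort_index()
    return out


def synthetic_reference(
    a_female: float = 2.2e-5,
    a_male: float = 3.6e-5,
    b: float = 0.095,
) -> dict[str, pd.Series]:
    """Synthetic Gompertz reference mortality, m(x) = a exp(b x), per sex.

    A stand-in for national single-year-of-age mortality rates with
    realistic magnitudes (male remaining life expectancy at 50 around 30
    years, female a few years higher); not calibrated to any real register.
    """
    out = {}
    for sex, a in [("female", a_female), ("male", a_male)]:
        m = a * np.exp(b * AGES)
        out[sex] = pd.Series(m, index=AGES, name="rate")
    return out


def bundled_reference() -> dict[str, pd.Series]:
    """The packaged copy of the synthetic Gompertz reference table."""
    ref = importlib.resources.files("airses") / "data" / "synthetic_gompertz_rates.csv"
    with importlib.resources.as_file(ref) as path:
        return read_reference(path)


@dataclass
class GroupRiskProfile:
    """Per-group prevalence, mortality hazard ratio and log-HR standard error."""

    table: pd.DataFrame  # columns: group, prevalence, hr, se_loghr
    reference: str

    def __post_init__(self) -> None:
        t = self.table
        need = {"group", "prevalence", "hr", "se_loghr"}
        if not need <= set(t.columns):
            raise ValueError(f"profile needs columns {sorted(need)}")
        if self.reference not in set(t["group"]):
            raise ValueError(f"reference group {self.reference!r} missing from profile")
        if abs(t["prevalence"].sum() - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1, got {t['prevalence'].sum()!r}")
        if (t["hr"] <= 0).any():
            raise ValueError("hazard ratios must be positive")
        if (t["se_loghr"] < 0).any():
            raise ValueError("log-HR standard errors must be non-negative")
        ref_hr = float(t.loc[t["group"] == self.reference, "hr"].iloc[0])
        if abs(ref_hr - 1.0) > 1e-12:
            raise ValueError("reference group must have HR exactly 1")


def partition_mortality(
    rates: pd.Series,
    profile: GroupRiskProfile,
    mode: str = "normalized",
) -> pd.DataFrame:
    """Split population mortality into group-specific age schedules.

    ``mode="normalized"`` (default) uses the prevalence-weighted
    normalization, guaranteeing ``sum_g p_g m_g(a) = m(a)`` exactly;
    ``mode="direct"`` applies each HR to the population rate as-is
    (``m_g = HR_g m``), which inflates the implied population mortality
    when any HR exceeds 1.
    """
    m = validate_reference(rates)
    t = profile.table
    if mode == "normalized":
        denom = float((t["prevalence"] * t["hr"]).sum())
        m_ref = m / denom
    elif mode == "direct":
        m_ref = m
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame(index=AGES)
    for _, row in t.iterrows():
        out[row["group"]] = row["hr"] * m_ref
    return out


def build_life_table(rates: pd.Series | np.ndarray) -> pd.DataFrame:
    """Period life table from central mortality rates on ages 50..100.

    Death probabilities use the actuarial mid-interval approximation
    ``q = m / (1 + 0.5 m)``; the terminal age is an open interval with
    ``q(100) = 1`` and person-years ``L(100) = l(100) / m(100)``.  Columns:
    m, q, l (radix 100000), d, L, T and remaining expectancy e = T / l.
    """
    if isinstance(rates, pd.Series):
        m = validate_reference(rates)
    else:
        m = np.asarray(rates, dtype=float)
        if m.shape != AGES.shape:
            raise ValueError(f"need {AGES.size} rates for ages {AGE_LO}..{AGE_HI}")
        if np.any(m <= 0):
            raise ValueError("mortality rates must be positive")

    q = m / (1 + 0.5 * m)
    q[-1] = 1.0
    surv = np.concatenate([[1.0], np.cumprod(1 - q[:-1])])
    l = RADIX * surv
    d = l * q
    L = np.empty_like(l)
    L[:-1] = l[1:] + 0.5 * d[:-1]
    L[-1] = l[-1] / m[-1]
    T = np.cumsum(L[::-1])[::-1]
    e = T / l
    return pd.DataFrame({"m": m, "q": q, "l": l, "d": d, "L": L, "T": T, "e": e}, index=AGES)


def life_expectancy_difference(
    tables: dict[str, pd.DataFrame],
    reference: str,
    age: int = 50,
) -> pd.Series:
    """Years of remaining life expectancy lost at ``age`` versus the
    reference group (positive = shorter life in that group)."""
    if reference not in tables:
        raise ValueError(f"reference group {reference!r} missing")
    e_ref = float(tables[reference].loc[age, "e"])
    return pd.Series(
        {g: e_ref - float(tab.loc[age, "e"]) for g, tab in tables.items()},
        name=f"delta_e{age}",
    )


def _e50_vectorized(m: np.ndarray, age: int = 50) -> np.ndarray:
    """Remaining life expectancy at ``age`` for rate arrays (..., n_ages)."""
    q = m / (1 + 0.5 * m)
    q = q.copy()
    q[..., -1] = 1.0
    one = np.ones(m.shape[:-1] + (1,))
    surv = np.concatenate([one, np.cumprod(1 - q[..., :-1], axis=-1)], axis=-1)
    l = RADIX * surv
    d = l * q
    L = np.empty_like(l)
    L[..., :-1] = l[..., 1:] + 0.5 * d[..., :-1]
    L[..., -1] = l[..., -1] / m[..., -1]
    start = age - AGE_LO
    T = L[..., start:].sum(axis=-1)
    return T / l[..., start]


def monte_carlo_ci(
    profile: GroupRiskProfile,
    rates: pd.Series,
    runs: int = 10_000,
    seed: int = 0,
    mode: str = "normalized",
    age: int = 50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Parametric-bootstrap confidence intervals for life-expectancy loss.

    Each run redraws every non-reference group's log HR from
    ``Normal(log hr, se_loghr)``, re-partitions the population mortality,
    rebuilds the group life tables and recomputes the expectancy difference
    at ``age``; the interval is the 2.5th/97.5th percentile of the runs
    (at the default ``alpha``).  Prevalences are held fixed.  Reproducible
    under a fixed seed; groups with zero standard error give zero-width
    intervals.
    """
    if runs < 2:
        raise ValueError("need at least 2 bootstrap runs")
    m = validate_reference(rates)
    t = profile.table.reset_index(drop=True)
    groups = t["group"].to_numpy()
    prev = t["prevalence"].to_numpy(dtype=float)
    hr_hat = t["hr"].to_numpy(dtype=float)
    se = t["se_loghr"].to_numpy(dtype=float)
    ref_pos = int(np.flatnonzero(groups == profile.reference)[0])

    rng = np.random.default_rng(seed)
    log_hr = rng.normal(np.log(hr_hat), se, size=(runs, len(groups)))
    log_hr[:, ref_pos] = 0.0
    hr = np.exp(log_hr)  # (runs, G)

    if mode == "normalized":
        denom = (hr * prev).sum(axis=1)  # (runs,)
        m_ref = m[None, :] / denom[:, None]
    elif mode == "direct":
        m_ref = np.broadcast_to(m, (runs, m.size)).copy()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    e = np.empty((runs, len(groups)))
    for g in range(len(groups)):
        e[:, g] = _e50_vectorized(hr[:, g][:, None] * m_ref, age=age)
    delta = e[:, [ref_pos]] - e  # (runs, G)

    point_tables = {
        g: build_life_table(r.to_numpy())
        for g, r in partition_mortality(rates, profile, mode=mode).items()
    }
    point = life_expectancy_difference(point_tables, profile.reference, age=age)

    lo = np.percentile(delta, 100 * alpha / 2, axis=0)
    hi = np.percentile(delta, 100 * (1 - alpha / 2), axis=0)
    return pd.DataFrame(
        {
            "group": groups,
            "delta_e": [point[g] for g in groups],
            "lo": lo,
            "hi": hi,
        }
    )
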