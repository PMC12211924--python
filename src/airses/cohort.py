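"""Synthetic cohort generator with recoverable ground truth.

Generates seeded cohorts whose statistical structure mirrors what the
downstream analysis assumes: a correlated five-pollutant mixture (PM2.5,
PM10, PM2.5-10, NO2, NOx), three latent socioeconomic classes emitting
categorical education / income / employment indicators, and event
histories on a five-transition illness-death structure
(baseline -> AMD -> ocular comorbidity, with death reachable from every
state) under proportional hazards with group-specific hazard ratios.

Every generated quantity is paired with a truth record so that score
construction, latent-class recovery, hazard-ratio estimation and
life-expectancy calculations can all be checked against known values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

DAYS_PER_YEAR = 365.25

#: Pollutant column order is fixed throughout the package.
POLLUTANTS = ["pm25", "pm10", "pm_coarse", "no2", "nox"]

#: Default annual-mean concentrations (ug/m3) for the five pollutants.
DEFAULT_MEANS = np.array([9.96, 16.20, 6.42, 26.38, 43.55])

#: Default standard deviations (ug/m3) matching the means above.
DEFAULT_SDS = np.array([1.05, 1.90, 0.90, 7.57, 15.46])

#: Default log-scale correlations: strong within the particulate block and
#: within the nitrogen-oxide block, moderate across blocks.  Real pollutant
#: correlation magnitudes are configurable, not calibrated.
DEFAULT_CORR = np.array(
    [
        [1.00, 0.85, 0.70, 0.50, 0.50],
        [0.85, 1.00, 0.80, 0.50, 0.50],
        [0.70, 0.80, 1.00, 0.45, 0.45],
        [0.50, 0.50, 0.45, 1.00, 0.90],
        [0.50, 0.50, 0.45, 0.90, 1.00],
    ]
)

SES_ITEMS = ["education", "income", "employment"]
SES_CLASSES = ["high", "medium", "low"]

#: Marginal class shares close to the observed individual-level SES split.
DEFAULT_PREVALENCES = np.array([0.31, 0.47, 0.22])

#: Item-response probabilities rho[class][category] per indicator.  Category 0
#: is always the most advantaged level (degree education, highest income band,
#: active employment).
DEFAULT_ITEM_RESPONSE: dict[str, np.ndarray] = {
    "education": np.array(
        [
            [0.65, 0.25, 0.07, 0.03],
            [0.25, 0.35, 0.27, 0.13],
            [0.05, 0.15, 0.35, 0.45],
        ]
    ),
    "income": np.array(
        [
            [0.15, 0.40, 0.30, 0.10, 0.05],
            [0.02, 0.15, 0.33, 0.33, 0.17],
            [0.01, 0.04, 0.12, 0.33, 0.50],
        ]
    ),
    "employment": np.array(
        [
            [0.85, 0.15],
            [0.60, 0.40],
            [0.25, 0.75],
        ]
    ),
}

TRANSITION_NAMES = {
    1: "baseline->AMD",
    2: "baseline->death",
    3: "AMD->OCMD",
    4: "AMD->death",
    5: "OCMD->death",
}

#: Default yearly baseline transition intensities.  Chosen so that over a
#: 12.5-year administrative follow-up roughly 1.2% of subjects develop AMD,
#: about three quarters of AMD cases progress to an ocular comorbidity, and
#: ~7.3% die, matching the event proportions the analysis is designed around.
DEFAULT_BASELINE_RATES = np.array([0.00097, 0.0060, 0.28, 0.012, 0.012])

DEFAULT_ENTRY_DATE = "2008-01-01"


def default_covariance() -> np.ndarray:
    """Default 5x5 pollutant covariance (diagonal = natural-scale variances,
    off-diagonal correlations applied on the log scale)."""
    return DEFAULT_CORR * np.outer(DEFAULT_SDS, DEFAULT_SDS)


def _check_psd(matrix: np.ndarray, name: str) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(matrix)
    if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue {eigvals.min():.3g})"
        )


def generate_pollutants(
    n: int,
    means: Sequence[float] | None = None,
    covariance: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a five-pollutant concentration panel from a moment-matched
    log-normal distribution.

    The marginal log-normals are moment-matched so that the *natural-scale*
    sample means and standard deviations converge to ``means`` and to the
    square roots of ``covariance``'s diagonal.  The off-diagonal entries of
    ``covariance`` are read as correlations and applied to the underlying
    Gaussian (log) scale; the induced natural-scale correlation is the usual
    log-normal attenuation of the log-scale one.

    Parameters
    ----------
    n : number of subjects (> 0).
    means : length-5 positive target means (ug/m3); defaults to typical
        UK annual-average values.
    covariance : 5x5 symmetric PSD matrix as described above.
    seed : RNG seed; identical seed and parameters give identical panels.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    means = DEFAULT_MEANS if means is None else np.asarray(means, dtype=float)
    if means.shape != (5,) or np.any(means <= 0):
        raise ValueError("means must be 5 positive values")
    covariance = default_covariance() if covariance is None else np.asarray(covariance, float)
    _check_psd(covariance, "covariance")

    sds = np.sqrt(np.diag(covariance))
    corr = covariance / np.outer(sds, sds)
    # moment matching: if X ~ logN(mu, s2) then E X = exp(mu + s2/2),
    # Var X = (E X)^2 (exp(s2) - 1)
    s2 = np.log1p((sds / means) ** 2)
    mu = np.log(means) - s2 / 2
    log_cov = corr * np.outer(np.sqrt(s2), np.sqrt(s2))
    _check_psd(log_cov, "log-scale covariance")

    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(mu, log_cov, size=n, method="svd")
    panel = pd.DataFrame(np.exp(z), columns=POLLUTANTS)
    return panel


def generate_ses_indicators(
    n: int,
    prevalences: Sequence[float] | None = None,
    item_response: Mapping[str, np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw categorical SES indicators from a 3-class latent structure.

    Each subject is assigned one latent class from ``prevalences``; the three
    indicators (education, income, employment) are then drawn independently
    given the class from ``item_response[item][class]``.

    Returns the indicator table (integer category codes, 0 = most advantaged)
    and the true class index per subject (0 = high, 1 = medium, 2 = low).
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    prev = DEFAULT_PREVALENCES if prevalences is None else np.asarray(prevalences, float)
    resp = DEFAULT_ITEM_RESPONSE if item_response is None else dict(item_response)
    if abs(prev.sum() - 1.0) > 1e-9:
        raise ValueError(f"prevalences must sum to 1, got {prev.sum()!r}")
    for item, probs in resp.items():
        probs = np.asarray(probs, float)
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError(f"item-response rows for {item!r} must each sum to 1")

    rng = np.random.default_rng(seed)
    classes = rng.choice(len(prev), size=n, p=prev)
    data = {}
    for item, probs in resp.items():
        probs = np.asarray(probs, float)
        u = rng.random(n)
        cum = probs.cumsum(axis=1)[classes]  # (n, n_cat)
        data[item] = (u[:, None] > cum).sum(axis=1)
    return pd.DataFrame(data), classes


@dataclass
class TransitionHazards:
    """Baseline intensities and group-specific log hazard ratios for the
    five illness-death transitions."""

    baseline_rates: np.ndarray = field(default_factory=lambda: DEFAULT_BASELINE_RATES.copy())
    #: mapping group label -> length-5 vector of log HRs (one per transition)
    log_hr: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.baseline_rates = np.asarray(self.baseline_rates, dtype=float)
        if self.baseline_rates.shape != (5,):
            raise ValueError("baseline_rates must have length 5")
        if np.any(self.baseline_rates < 0):
            raise ValueError("baseline rates must be non-negative")
        self.log_hr = {k: np.asarray(v, dtype=float) for k, v in self.log_hr.items()}
        for k, v in self.log_hr.items():
            if v.shape != (5,):
                raise ValueError(f"log_hr[{k!r}] must have length 5")

    def rates_for(self, groups: Sequence[str]) -> np.ndarray:
        """Per-subject transition intensities (n, 5)."""
        out = np.tile(self.baseline_rates, (len(groups), 1))
        if self.log_hr:
            mult = np.array([np.exp(self.log_hr.get(g, np.zeros(5))) for g in groups])
            out = out * mult
        return out


def simulate_event_history(
    n: int,
    hazards: TransitionHazards | None = None,
    groups: Sequence[str] | None = None,
    censor_years: float = 12.5,
    tie_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate illness-death event histories under proportional hazards.

    Competing transitions out of each state are realised as latent
    exponential clocks on the study-time (clock-forward) scale; the earliest
    clock wins.  Administrative censoring is applied at ``censor_years``.
    A ``tie_fraction`` of AMD->OCMD pairs is coerced onto the same calendar
    day to exercise the downstream half-day untying rule.

    Returns
    -------
    events : per-subject observed history with integer day counts
        (``amd_day``, ``ocmd_day``, ``death_day`` — NaN when unobserved) and
        ``censor_day``.
    truth : latent transition times (years), per-transition hazard
        multipliers and the censoring time — the generator's ground truth.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not 0.0 <= tie_fraction < 1.0:
        raise ValueError("tie_fraction must lie in [0, 1)")
    hazards = hazards if hazards is not None else TransitionHazards()
    if groups is None:
        groups = ["ref"] * n
    if len(groups) != n:
        raise ValueError("groups must have length n")

    rates = hazards.rates_for(groups)  # (n, 5)
    rng = np.random.default_rng(seed)

    with np.errstate(divide="ignore"):
        gaps = rng.exponential(1.0, size=(n, 5)) / rates  # inf where rate 0

    t_amd_latent = gaps[:, 0]
    t_death0 = gaps[:, 1]

    amd = (t_amd_latent < t_death0) & (t_amd_latent < censor_years)
    t_amd = np.where(amd, t_amd_latent, np.nan)

    t_ocmd_latent = t_amd + gaps[:, 2]
    t_death_amd = t_amd + gaps[:, 3]
    ocmd = amd & (t_ocmd_latent < t_death_amd) & (t_ocmd_latent < censor_years)
    t_ocmd = np.where(ocmd, t_ocmd_latent, np.nan)

    t_death = np.full(n, np.nan)
    # death straight from baseline
    direct = ~amd & (t_death0 < censor_years)
    t_death[direct] = t_death0[direct]
    # death from the AMD state (no comorbidity first)
    from_amd = amd & ~ocmd & (t_death_amd < censor_years)
    t_death[from_amd] = t_death_amd[from_amd]
    # death after the comorbidity
    t_death_ocmd = t_ocmd + gaps[:, 4]
    from_ocmd = ocmd & (t_death_ocmd < censor_years)
    t_death[from_ocmd] = t_death_ocmd[from_ocmd]

    events = pd.DataFrame(
        {
            "amd_day": np.floor(t_amd * DAYS_PER_YEAR),
            "ocmd_day": np.floor(t_ocmd * DAYS_PER_YEAR),
            "death_day": np.floor(t_death * DAYS_PER_YEAR),
            "censor_day": np.floor(censor_years * DAYS_PER_YEAR),
        }
    )

    # coerce a fraction of AMD->OCMD pairs onto the same calendar day
    if tie_fraction > 0:
        ocmd_idx = np.flatnonzero(ocmd)
        tie = ocmd_idx[rng.random(ocmd_idx.size) < tie_fraction]
        events.loc[tie, "ocmd_day"] = events.loc[tie, "amd_day"]

    truth = pd.DataFrame(
        {
            "group": list(groups),
            "t1_latent": t_amd_latent,
            "t2_latent": t_death0,
            "t_amd": t_amd,
            "t_ocmd": t_ocmd,
            "t_death": t_death,
            "censor_years": censor_years,
        }
    )
    for t in range(5):
        truth[f"hr_t{t + 1}"] = rates[:, t] / np.where(
            hazards.baseline_rates[t] > 0, hazards.baseline_rates[t], 1.0
        )
    return events, truth


def make_truth_groups(panel: pd.DataFrame, classes: np.ndarray) -> pd.Series:
    """Ground-truth joint exposure groups: tertile of the summed standardized
    log concentrations crossed with the latent SES class.

    Labels look like ``"T3xlow"``; the most favourable cell is ``"T1xhigh"``.
    """
    logp = np.log(panel[POLLUTANTS].to_numpy())
    z = (logp - logp.mean(axis=0)) / logp.std(axis=0, ddof=1)
    index = z.sum(axis=1)
    q1, q2 = np.quantile(index, [1 / 3, 2 / 3])
    tert = 1 + (index >= q1).astype(int) + (index >= q2).astype(int)
    labels = [f"T{t}x{SES_CLASSES[c]}" for t, c in zip(tert, classes)]
    return pd.Series(labels, name="truth_group")


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Lifestyle / environment covariate columns (plumbing, not calibrated)."""
    return pd.DataFrame(
        {
            "age_entry": np.round(rng.uniform(45, 73, n), 1),
            "sex": rng.choice(["female", "male"], n, p=[0.523, 0.477]),
            "bmi_cat": rng.choice(
                ["normal", "underweight", "overweight", "obese"], n, p=[0.32, 0.005, 0.435, 0.24]
            ),
            "smoking": rng.choice(["never", "previous", "current"], n, p=[0.54, 0.36, 0.10]),
            "alcohol": rng.choice(["frequent", "occasional", "never"], n, p=[0.46, 0.47, 0.07]),
            "activity": rng.choice(["high", "moderate", "low"], n, p=[0.40, 0.41, 0.19]),
            "diet_score": rng.integers(0, 8, n),
            "sleep_cat": rng.choice(["7-8h", "<7h", ">8h"], n, p=[0.68, 0.245, 0.075]),
            "noise": np.round(rng.normal(56.0, 4.3, n), 1),
            "greenspace": np.round(rng.uniform(0, 100, n), 1),
            "road_inv_dist": np.round(rng.exponential(0.01, n), 4),
            "tenure": rng.choice(["<=10y", "10-20y", ">20y"], n, p=[0.33, 0.265, 0.405]),
            "prs": np.round(rng.normal(0.0, 1.0, n), 4),
            "deprivation": np.round(rng.normal(0.0, 3.0, n), 3),
        }
    )


def assemble_cohort(
    panel: pd.DataFrame,
    indicators: pd.DataFrame,
    events: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    entry_date: str = DEFAULT_ENTRY_DATE,
) -> pd.DataFrame:
    """Join the pollutant panel, SES indicators and event history into a
    single validated cohort table with ISO calendar dates.

    Raises ``ValueError`` naming the offending row indices when any cohort
    invariant is violated (temporal sequencing, age floor, date bounds).
    """
    n = len(panel)
    if not (len(indicators) == n and len(events) == n):
        raise ValueError("panel, indicators and events must have equal row counts")
    rng = np.random.default_rng(seed)
    if covariates is None:
        covariates = _simulate_covariates(n, rng)
    elif len(covariates) != n:
        raise ValueError("covariates must match the panel row count")

    entry = pd.Timestamp(entry_date)

    def to_date(days: pd.Series) -> pd.Series:
        return entry + pd.to_timedelta(days, unit="D")

    df = pd.concat(
        [
            pd.DataFrame({"subject_id": np.arange(n)}),
            covariates.reset_index(drop=True),
            panel.reset_index(drop=True),
            indicators.reset_index(drop=True),
        ],
        axis=1,
    )
    df["entry_date"] = entry
    df["amd_date"] = to_date(events["amd_day"])
    df["ocmd_date"] = to_date(events["ocmd_day"])
    df["death_date"] = to_date(events["death_day"])
    df["censor_date"] = to_date(events["censor_day"])
    validate_cohort(df)
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    """Enforce the cohort invariants, raising with row indices on failure.

    Checks: entry age >= 45, no ocular comorbidity without prior AMD, no
    comorbidity dated before AMD (same-day ties are allowed; the half-day
    rule untangles them), and every event date within the follow-up window.
    """
    problems = []

    young = df.index[df["age_entry"] < 45]
    if len(young):
        problems.append(f"age at entry below 45 for rows {list(young[:5])}")

    has_ocmd = df["ocmd_date"].notna()
    orphan = df.index[has_ocmd & df["amd_date"].isna()]
    if len(orphan):
        problems.append(f"OCMD without prior AMD for rows {list(orphan[:5])}")

    bad_seq = df.index[has_ocmd & df["amd_date"].notna() & (df["ocmd_date"] < df["amd_date"])]
    if len(bad_seq):
        problems.append(f"OCMD dated before AMD for rows {list(bad_seq[:5])}")

    end = df["death_date"].fillna(df["censor_date"])
    for col in ["amd_date", "ocmd_date"]:
        late = df.index[df[col].notna() & (df[col] > end)]
        if len(late):
            problems.append(f"{col} after death-or-censor date for rows {list(late[:5])}")

    if problems:
        raise ValueError("cohort invariants violated: " + "; ".join(problems))


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write the cohort as CSV with ISO-8601 dates."""
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    date_cols = ["entry_date", "amd_date", "ocmd_date", "death_date", "censor_date"]
    df = pd.read_csv(path)
    for col in date_cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
    return df


@dataclass
class CohortConfig:
    """Parameters of a full synthetic-cohort run."""

    n: int = 20000
    seed: int = 0
    means: Sequence[float] | None = None
    covariance: np.ndarray | None = None
    prevalences: Sequence[float] | None = None
    item_response: Mapping[str, np.ndarray] | None = None
    baseline_rates: Sequence[float] | None = None
    log_hr: Mapping[str, Sequence[float]] | None = None
    censor_years: float = 12.5
    tie_fraction: float = 0.02

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariance" in raw and raw["covariance"] is not None:
            raw["covariance"] = np.asarray(raw["covariance"], float)
        if "item_response" in raw and raw["item_response"] is not None:
            raw["item_response"] = {k: np.asarray(v, float) for k, v in raw["item_response"].items()}
        return cls(**raw)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full generator: pollutants -> SES indicators -> truth groups ->
    event history -> assembled, validated cohort table.

    Returns ``(cohort, truth)`` where ``truth`` carries the latent class,
    the ground-truth joint group and the latent transition times.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    panel = generate_pollutants(config.n, config.means, config.covariance, seed=seeds[0])
    indicators, classes = generate_ses_indicators(
        config.n, config.prevalences, config.item_response, seed=seeds[1]
    )
    groups = make_truth_groups(panel, classes)
    hazards = TransitionHazards(
        baseline_rates=(
            DEFAULT_BASELINE_RATES if config.baseline_rates is None else config.baseline_rates
        ),
        log_hr={k: np.asarray(v, float) for k, v in (config.log_hr or {}).items()},
    )
    events, truth = simulate_event_history(
        config.n,
        hazards,
        groups=groups.tolist(),
        censor_years=config.censor_years,
        tie_fraction=config.tie_fraction,
        seed=seeds[2],
    )
    df = assemble_cohort(panel, indicators, events, seed=seeds[3])
    truth.insert(0, "subject_id", np.arange(config.n))
    truth["latent_class"] = np.asarray(SES_CLASSES)[classes]
    return df, truth


def cohort_to_csv_bytes(df: pd.DataFrame) -> bytes:
    """Serialize a cohort deterministically (used for checksum manifests)."""
    buf = io.StringIO()
    df.to_csv(buf, index=False, date_format="%Y-%m-%d")
    return buf.getvalue().encode()
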