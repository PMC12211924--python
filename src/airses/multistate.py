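"""Five-transition illness-death multistate expansion and fitting.

The cohort is expanded into the long multistate format with one row per
subject per at-risk transition:

1. baseline -> AMD
2. baseline -> death
3. AMD -> OCMD (ocular comorbidity)
4. AMD -> death
5. OCMD -> death

Time runs on the study clock (years since entry) with delayed entry into
the post-AMD transitions; subjects entering two states on the same
calendar day are untied by backdating the theoretically prior state by
half a day before expansion.  Each transition gets its own
proportional-hazards fit (stratified baselines, transition-specific
coefficients); transitions with no events are reported as not estimable
rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from airses.cohort import DAYS_PER_YEAR
from airses.cox import HazardFit, fit_hazard_model

TRANSITIONS = {
    1: ("baseline", "AMD"),
    2: ("baseline", "death"),
    3: ("AMD", "OCMD"),
    4: ("AMD", "death"),
    5: ("OCMD", "death"),
}

_DAY_COLS = ["entry_day", "amd_day", "ocmd_day", "death_day"]


def apply_halfday_rule(days: pd.DataFrame) -> pd.DataFrame:
    """Untie same-day state entries by backdating the prior state half a day.

    ``days`` holds float day counts for ``entry_day``, ``amd_day``,
    ``ocmd_day`` and ``death_day`` (NaN = state never entered; missing
    columns are treated as all-NaN, ``entry_day`` as 0); a ``censor_day``
    column, when present, bounds event-free follow-up and participates in
    the untying so censored windows also stay strictly positive.  The rule
    runs from the latest occupied state backwards, so a chain of ties stays
    ordered: AMD = OCMD = death = 1000 becomes death 1000, OCMD 999.5,
    AMD 999.  A prior state dated *after* a later one is a sequencing
    violation and raises.
    """
    out = days.copy()
    for col in _DAY_COLS:
        if col not in out.columns:
            out[col] = 0.0 if col == "entry_day" else np.nan
    out = out.astype({c: float for c in _DAY_COLS})

    death = out["death_day"].to_numpy()
    if "censor_day" in out.columns:
        original = np.where(np.isnan(death), out["censor_day"].to_numpy(dtype=float), death)
    else:
        original = np.where(np.isnan(death), np.inf, death)
    adjusted = original.copy()

    for col in ["ocmd_day", "amd_day", "entry_day"]:
        val = out[col].to_numpy().copy()
        val0 = val.copy()
        occupied = ~np.isnan(val)
        bad = occupied & (val > original)
        if bad.any():
            rows = list(np.flatnonzero(bad)[:5])
            raise ValueError(
                f"state sequencing violation: {col} after a later state in rows {rows}"
            )
        # a tie with the (possibly already backdated) later state cascades
        tie = occupied & (val >= adjusted)
        val[tie] = adjusted[tie] - 0.5
        out[col] = val
        original = np.where(occupied, val0, original)
        adjusted = np.where(occupied, val, adjusted)
    return out


def expand_to_transitions(
    cohort: pd.DataFrame,
    covariate_cols: list[str] | None = None,
    id_col: str = "subject_id",
) -> pd.DataFrame:
    """Expand a cohort into the long five-transition format.

    Expects day-count columns (as produced by :func:`cohort_days` or
    directly by the generator) with the half-day rule already applied.
    Returns rows ``(subject, transition, tstart, tstop, status)`` in years
    on the study clock: every subject is at risk for transitions 1 and 2
    from entry; AMD cases additionally for 3 and 4 from their AMD time
    (left truncation); OCMD cases for 5 from their OCMD time.
    """
    covariate_cols = list(covariate_cols or [])
    days = cohort[[c for c in _DAY_COLS if c in cohort.columns]].astype(float)
    if "entry_day" not in days.columns:
        days["entry_day"] = 0.0

    entry = days["entry_day"].to_numpy()
    amd = days["amd_day"].to_numpy() if "amd_day" in days else np.full(len(cohort), np.nan)
    ocmd = days["ocmd_day"].to_numpy() if "ocmd_day" in days else np.full(len(cohort), np.nan)
    death = days["death_day"].to_numpy() if "death_day" in days else np.full(len(cohort), np.nan)
    censor = cohort["censor_day"].to_numpy(dtype=float)

    terminal = np.where(np.isnan(death), censor, death)
    died = ~np.isnan(death)
    has_amd = ~np.isnan(amd)
    has_ocmd = ~np.isnan(ocmd)

    ids = cohort[id_col].to_numpy()
    cov = cohort[covariate_cols]

    frames = []

    def rows(mask, trans, tstart, tstop, status):
        f = pd.DataFrame(
            {
                id_col: ids[mask],
                "transition": trans,
                "tstart": (tstart[mask] - entry[mask]) / DAYS_PER_YEAR,
                "tstop": (tstop[mask] - entry[mask]) / DAYS_PER_YEAR,
                "status": status[mask].astype(int),
            }
        )
        frames.append(pd.concat([f.reset_index(drop=True),
                                 cov[mask].reset_index(drop=True)], axis=1))

    all_mask = np.ones(len(cohort), dtype=bool)
    exit_baseline = np.where(has_amd, amd, terminal)
    rows(all_mask, 1, entry, exit_baseline, has_amd)
    rows(all_mask, 2, entry, exit_baseline, died & ~has_amd)

    if has_amd.any():
        exit_amd = np.where(has_ocmd, ocmd, terminal)
        rows(has_amd, 3, amd, exit_amd, has_ocmd)
        rows(has_amd, 4, amd, exit_amd, died & has_amd & ~has_ocmd)
    if has_ocmd.any():
        rows(has_ocmd, 5, ocmd, terminal, died & has_ocmd)

    out = pd.concat(frames, ignore_index=True)
    if (out["tstop"] <= out["tstart"]).any():
        raise RuntimeError(
            "zero-length transition window after expansion; "
            "was the half-day rule applied?"
        )
    return out.sort_values([id_col, "transition"], ignore_index=True)


def cohort_days(cohort: pd.DataFrame) -> pd.DataFrame:
    """Convert a dated cohort table into day-count columns for expansion."""
    out = pd.DataFrame({"subject_id": cohort["subject_id"]})
    entry = cohort["entry_date"]
    for state, col in [("entry", "entry_date"), ("amd", "amd_date"),
                       ("ocmd", "ocmd_date"), ("death", "death_date")]:
        out[f"{state}_day"] = (cohort[col] - entry).dt.days.astype(float)
    out["censor_day"] = (cohort["censor_date"] - entry).dt.days.astype(float)
    return out


@dataclass
class TransitionFitResult:
    """Per-transition fit or an explicit not-estimable record."""

    transition: int
    fit: HazardFit | None
    n: int
    n_events: int
    reason: str | None = None

    @property
    def estimable(self) -> bool:
        return self.fit is not None


def fit_transition_hazards(
    td: pd.DataFrame,
    covariates: list[str],
    min_events: int = 1,
) -> dict[int, TransitionFitResult]:
    """Fit one proportional-hazards model per transition.

    Baseline hazards are stratified by fitting each transition separately
    (covariate effects are transition-specific); delayed entry is honoured
    through the ``tstart`` column.  A transition with fewer than
    ``min_events`` events — or one where the fit fails — is returned as a
    not-estimable record instead of raising.
    """
    results: dict[int, TransitionFitResult] = {}
    for trans in sorted(TRANSITIONS):
        sub = td[td["transition"] == trans]
        n_events = int(sub["status"].sum())
        if len(sub) == 0 or n_events < min_events:
            results[trans] = TransitionFitResult(
                transition=trans, fit=None, n=len(sub), n_events=n_events,
                reason=f"too few events ({n_events})",
            )
            continue
        try:
            fit = fit_hazard_model(
                sub, "tstop", "status", covariates, entry_col="tstart"
            )
        except Exception as err:  # noqa: BLE001 - surfaced, not hidden
            results[trans] = TransitionFitResult(
                transition=trans, fit=None, n=len(sub), n_events=n_events,
                reason=f"fit failed: {err}",
            )
            continue
        results[trans] = TransitionFitResult(
            transition=trans, fit=fit, n=len(sub), n_events=n_events
        )
    return results


def transition_hazard_table(results: dict[int, TransitionFitResult]) -> pd.DataFrame:
    """Tabulate per-transition HRs (one row per transition x coefficient)."""
    rows = []
    for trans, res in sorted(results.items()):
        frm, to = TRANSITIONS[trans]
        if not res.estimable:
            rows.append(
                {"transition": trans, "from": frm, "to": to, "term": None,
                 "hr": np.nan, "lo": np.nan, "hi": np.nan, "p": np.nan,
                 "n_events": res.n_events, "note": res.reason}
            )
            continue
        hr = res.fit.hazard_ratios()
        for term, r in hr.iterrows():
            rows.append(
                {"transition": trans, "from": frm, "to": to, "term": term,
                 "hr": r["hr"], "lo": r["lo"], "hi": r["hi"], "p": r["p"],
                 "n_events": res.n_events, "note": None}
            )
    return pd.DataFrame(rows)
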