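"""Additive and multiplicative interaction between exposure and SES.

From a Cox model with dummy coefficients for the exposure-only (10),
SES-only (01) and joint (11) cells, computes the relative excess risk due
to interaction (RERI), the attributable proportion (AP) and the synergy
index (S), with delta-method confidence intervals propagated from the fit
covariance.  Under exact additivity of excess risks RERI = 0, AP = 0 and
S = 1; multiplicative interaction is read off the product-term coefficient
of a two-binary-factor model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from airses.cox import HazardFit, fit_hazard_model


@dataclass
class IntervalEstimate:
    value: float
    lo: float
    hi: float
    se: float


@dataclass
class InteractionMeasures:
    """Additive-interaction measures with delta-method 95% CIs."""

    reri: IntervalEstimate
    ap: IntervalEstimate
    synergy: IntervalEstimate | None       # None when undefined
    synergy_reason: str | None
    hr10: float
    hr01: float
    hr11: float


def additive_interaction(
    fit: HazardFit,
    idx10: str,
    idx01: str,
    idx11: str,
    alpha: float = 0.05,
) -> InteractionMeasures:
    """RERI, AP and S from three dummy coefficients of a joint model.

    ``idx10``/``idx01``/``idx11`` name the coefficients of the
    exposure-only, SES-only and joint cells (all against the double-
    reference cell).  Variances come from the delta method on the fit's
    coefficient covariance; the synergy index uses the conventional
    log-scale delta method and is reported as undefined when its
    denominator ``(HR10 - 1) + (HR01 - 1)`` is not positive.
    """
    names = [idx10, idx01, idx11]
    b = fit.params.loc[names].to_numpy()
    V = fit.covariance.loc[names, names].to_numpy()
    h10, h01, h11 = np.exp(b)
    z = stats.norm.ppf(1 - alpha / 2)

    def interval(value: float, grad: np.ndarray, log_scale: bool = False) -> IntervalEstimate:
        se = float(np.sqrt(grad @ V @ grad))
        if log_scale:
            return IntervalEstimate(
                value=value,
                lo=float(np.exp(np.log(value) - z * se)),
                hi=float(np.exp(np.log(value) + z * se)),
                se=se,
            )
        return IntervalEstimate(value=value, lo=value - z * se, hi=value + z * se, se=se)

    reri_val = h11 - h10 - h01 + 1
    reri = interval(float(reri_val), np.array([-h10, -h01, h11]))

    # AP = RERI / HR11 = 1 - (h10 + h01 - 1)/h11
    ap_val = reri_val / h11
    ap_grad = np.array([-h10 / h11, -h01 / h11, (h10 + h01 - 1) / h11])
    ap = interval(float(ap_val), ap_grad)

    denom = (h10 - 1) + (h01 - 1)
    if denom <= 0 or h11 <= 1:
        synergy = None
        reason = (
            "synergy index undefined: denominator (HR10-1)+(HR01-1) <= 0"
            if denom <= 0
            else "synergy index undefined on the log scale: HR11 <= 1"
        )
    else:
        s_val = (h11 - 1) / denom
        # delta method on log S
        s_grad = np.array([-h10 / denom, -h01 / denom, h11 / (h11 - 1)])
        synergy = interval(float(s_val), s_grad, log_scale=True)
        reason = None

    return InteractionMeasures(
        reri=reri,
        ap=ap,
        synergy=synergy,
        synergy_reason=reason,
        hr10=float(h10),
        hr01=float(h01),
        hr11=float(h11),
    )


def reri_from_hrs(hr10: float, hr01: float, hr11: float) -> float:
    """RERI = HR11 - HR10 - HR01 + 1 (pure formula, no uncertainty)."""
    return hr11 - hr10 - hr01 + 1


@dataclass
class MultiplicativeInteraction:
    hr: float
    lo: float
    hi: float
    p: float
    lr_stat: float
    lr_p: float


def multiplicative_interaction(
    data: pd.DataFrame,
    exposure_col: str,
    ses_col: str,
    duration_col: str,
    event_col: str,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> MultiplicativeInteraction:
    """Product-term interaction of two binary factors on the hazard scale.

    ``exposure_col`` and ``ses_col`` must be 0/1 columns (each exposure
    dichotomized at its highest-risk level).  The interaction HR is the
    exponentiated product-term coefficient; the likelihood-ratio test
    compares the models with and without the cross-product term.
    """
    from airses.cox import lr_interaction_test

    covariates = list(covariates or [])
    work = data.copy()
    work["__prod"] = work[exposure_col].astype(float) * work[ses_col].astype(float)
    full = fit_hazard_model(
        work, duration_col, event_col, [exposure_col, ses_col, "__prod"] + covariates
    )
    reduced = fit_hazard_model(
        work, duration_col, event_col, [exposure_col, ses_col] + covariates
    )
    stat, _, lr_p = lr_interaction_test(full, reduced)
    b = float(full.params["__prod"])
    se = float(np.sqrt(full.covariance.loc["__prod", "__prod"]))
    z = stats.norm.ppf(1 - alpha / 2)
    return MultiplicativeInteraction(
        hr=float(np.exp(b)),
        lo=float(np.exp(b - z * se)),
        hi=float(np.exp(b + z * se)),
        p=float(2 * stats.norm.sf(abs(b) / se)),
        lr_stat=stat,
        lr_p=lr_p,
    )
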