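"""Latent class analysis of socioeconomic indicators.

Individual-level socioeconomic status is modelled as a three-class latent
variable generating the categorical education, income and employment
indicators, which are conditionally independent given the class.  The
model is fitted by EM (best of several random starts); classes are then
ordered high / medium / low by their probability of the most-advantaged
education category, with income and prevalence as tie-breakers.  Area-level
status is simply a deprivation-score tertile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from airses.scores import tertile_cut

SES_LEVELS = ["high", "medium", "low"]
AREA_LEVELS = ["least", "moderately", "severely"]

_EPS = 1e-12


@dataclass
class LatentClassModel:
    """Fitted conditional-independence latent class model."""

    items: list[str]
    categories: dict[str, np.ndarray]        # surviving category codes per item
    prevalences: np.ndarray                  # pi, (C,)
    item_response: dict[str, np.ndarray]     # rho[item] with shape (C, K_item)
    log_likelihood: float
    loglik_trace: np.ndarray                 # best start's trace
    all_traces: list[np.ndarray] = field(default_factory=list)
    converged: bool = False
    n_obs: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.prevalences)

    def pattern_loglik(self, codes: np.ndarray) -> np.ndarray:
        """log P(pattern | class) for coded responses, shape (n, C)."""
        n = codes.shape[0]
        ll = np.zeros((n, self.n_classes))
        for j, item in enumerate(self.items):
            rho = np.clip(self.item_response[item], _EPS, 1.0)
            ll += np.log(rho[:, codes[:, j]]).T
        return ll

    def posterior(self, indicators: pd.DataFrame) -> np.ndarray:
        """Class posterior probabilities via Bayes' rule, rows sum to 1."""
        codes = _encode(indicators, self.items, self.categories)
        ll = self.pattern_loglik(codes) + np.log(np.clip(self.prevalences, _EPS, 1.0))
        ll -= logsumexp(ll, axis=1, keepdims=True)
        return np.exp(ll)


def _encode(indicators: pd.DataFrame, items: list[str], categories: dict[str, np.ndarray]) -> np.ndarray:
    cols = []
    for item in items:
        mapping = {cat: i for i, cat in enumerate(categories[item])}
        col = indicators[item].map(mapping)
        if col.isna().any():
            raise ValueError(f"unseen category in item {item!r}")
        cols.append(col.to_numpy(dtype=int))
    return np.column_stack(cols)


def fit_lca(
    indicators: pd.DataFrame,
    n_classes: int = 3,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
) -> LatentClassModel:
    """Fit a latent class model to categorical indicators by EM.

    The E and M steps run over distinct response patterns weighted by their
    multiplicities, so cost scales with the number of patterns rather than
    subjects.  The best of ``n_starts`` random initializations is kept;
    convergence is declared when the relative log-likelihood change falls
    below ``tol``.  The log-likelihood is non-decreasing within every start.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    items = list(indicators.columns)

    # drop globally-empty categories (they carry no likelihood information)
    categories: dict[str, np.ndarray] = {}
    for item in items:
        observed = np.unique(indicators[item].to_numpy())
        if observed.size < 2:
            warnings.warn(f"item {item!r} has a single observed category; it is uninformative")
        categories[item] = observed

    codes = _encode(indicators, items, categories)
    n = codes.shape[0]
    patterns, counts = np.unique(codes, axis=0, return_counts=True)
    if n_classes > patterns.shape[0]:
        raise ValueError(
            f"n_classes={n_classes} exceeds the {patterns.shape[0]} distinct response patterns"
        )

    ncat = {item: categories[item].size for item in items}
    rng = np.random.default_rng(seed)

    best: LatentClassModel | None = None
    traces: list[np.ndarray] = []
    for _ in range(max(1, n_starts)):
        pi = rng.dirichlet(np.ones(n_classes))
        rho = {
            item: rng.dirichlet(np.ones(ncat[item]), size=n_classes) for item in items
        }
        trace = []
        converged = False
        for _it in range(max_iter):
            # E step on patterns
            ll = np.zeros((patterns.shape[0], n_classes))
            for j, item in enumerate(items):
                ll += np.log(np.clip(rho[item], _EPS, 1.0))[:, patterns[:, j]].T
            ll += np.log(np.clip(pi, _EPS, 1.0))
            norm = logsumexp(ll, axis=1, keepdims=True)
            post = np.exp(ll - norm)                      # (m, C)
            loglik = float(counts @ norm.ravel())
            trace.append(loglik)
            # M step
            w = post * counts[:, None]                    # (m, C)
            class_mass = w.sum(axis=0)
            pi = class_mass / n
            for j, item in enumerate(items):
                new = np.zeros((n_classes, ncat[item]))
                np.add.at(new.T, patterns[:, j], w)
                rho[item] = new / np.maximum(class_mass[:, None], _EPS)
            if len(trace) > 1:
                rel = (trace[-1] - trace[-2]) / max(abs(trace[-2]), 1.0)
                if rel < tol:
                    converged = True
                    break
        trace = np.asarray(trace)
        traces.append(trace)
        if best is None or trace[-1] > best.log_likelihood:
            best = LatentClassModel(
                items=items,
                categories=categories,
                prevalences=pi,
                item_response=rho,
                log_likelihood=float(trace[-1]),
                loglik_trace=trace,
                converged=converged,
                n_obs=n,
            )
    best.all_traces = traces
    return best


@dataclass
class SesAssignment:
    """Per-subject posterior probabilities and ordered hard labels."""

    posterior: pd.DataFrame      # columns p_high, p_medium, p_low
    labels: pd.Categorical       # high / medium / low
    order: np.ndarray            # fitted-class index of (high, medium, low)


def assign_and_order_classes(
    model: LatentClassModel,
    indicators: pd.DataFrame,
    ordering_item: str = "education",
    top_category: int = 0,
    secondary_item: str = "income",
) -> SesAssignment:
    """Posterior class membership with classes relabelled high/medium/low.

    Classes are ordered by descending probability of the most-advantaged
    category of ``ordering_item`` (education degree level by default); exact
    ties fall back to ``secondary_item``'s top category, then to prevalence.
    Hard labels are the posterior argmax (modal assignment).
    """
    if model.n_classes != 3:
        raise ValueError("high/medium/low ordering requires a 3-class model")
    cats = model.categories[ordering_item]
    if top_category not in cats:
        raise ValueError(f"category {top_category} absent from item {ordering_item!r}")
    key_primary = model.item_response[ordering_item][:, np.searchsorted(cats, top_category)]
    cats2 = model.categories[secondary_item]
    key_secondary = model.item_response[secondary_item][:, np.searchsorted(cats2, top_category)] \
        if top_category in cats2 else np.zeros(3)
    order = np.lexsort((-model.prevalences, -key_secondary, -key_primary))

    post = model.posterior(indicators)[:, order]
    hard = post.argmax(axis=1)
    labels = pd.Categorical.from_codes(hard, categories=SES_LEVELS, ordered=True)
    posterior = pd.DataFrame(post, columns=[f"p_{lev}" for lev in SES_LEVELS])
    return SesAssignment(posterior=posterior, labels=labels, order=order)


def area_deprivation_tertiles(deprivation) -> pd.Categorical:
    """Area-level SES: deprivation-score tertiles.

    Higher deprivation means worse area-level status, so the lowest third is
    labelled ``least`` deprived and the highest third ``severely`` deprived.
    """
    cut = tertile_cut(deprivation)
    return pd.Categorical.from_codes(
        cut.labels.codes, categories=AREA_LEVELS, ordered=True
    )
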