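"""Composite air-pollution scores.

Two constructions are supported:

* **APS1** — principal component analysis of the correlation matrix of the
  five pollutants, varimax rotation of the retained component loadings, and
  a variance-share-weighted sum of the rotated component scores.
* **APS2** — a coefficient-weighted concentration sum,
  ``(sum_i beta_i x_i) / (5 / sum_i beta_i)``, where the betas are
  log-hazard coefficients per ug/m3 from a multipollutant hazard model.

Scores are categorized into tertiles (empirical 1/3 and 2/3 quantiles,
left-closed intervals) for the joint exposure-SES analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from airses.cohort import POLLUTANTS

TERTILE_LEVELS = ["first", "second", "third"]


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax criterion: summed variance of squared loadings per factor."""
    L2 = np.asarray(loadings, float) ** 2
    p = L2.shape[0]
    return float(np.sum((L2**2).sum(axis=0) / p - (L2.sum(axis=0) / p) ** 2))


def varimax_rotate(
    loadings: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
    kaiser: bool = True,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Varimax rotation of a p x k loading matrix.

    Iterates the standard SVD update until the criterion stops increasing.
    With ``kaiser=True`` rows are normalized to unit communality during the
    rotation (the common convention) and rescaled afterwards.

    Returns ``(rotated, rotation, converged)`` with ``rotation`` orthogonal;
    on non-convergence the best iterate is returned with ``converged=False``.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2 or L.shape[1] < 1:
        raise ValueError("loadings must be a p x k matrix with k >= 1")
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1), True

    h = np.ones(p)
    if kaiser:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
    Ln = L / h[:, None]

    R = np.eye(k)
    d = 0.0
    converged = False
    for _ in range(max_iter):
        Lr = Ln @ R
        u, s, vt = np.linalg.svd(
            Ln.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol) + 1e-15:
            converged = True
            break
        d = d_new
    rotated = (Ln @ R) * h[:, None]
    return rotated, R, converged


@dataclass
class PcaScoreModel:
    """Fitted correlation-matrix PCA score model for the pollutant panel."""

    means: np.ndarray
    sds: np.ndarray
    eigenvalues: np.ndarray           # all five, descending
    loadings: np.ndarray              # retained unrotated loadings (5 x k)
    rotated_loadings: np.ndarray      # after varimax + sign convention (5 x k)
    rotation: np.ndarray              # orthogonal k x k
    explained_share: np.ndarray       # per rotated component, fraction of total
    weights: np.ndarray               # score weights (explained shares, sum 1)
    scores: np.ndarray                # training-panel APS1 values

    @property
    def n_components(self) -> int:
        return self.rotated_loadings.shape[1]

    def transform(self, panel: pd.DataFrame) -> np.ndarray:
        """APS1 scores for a (possibly new) panel using the stored
        standardization and rotation."""
        X = panel[POLLUTANTS].to_numpy(dtype=float)
        Z = (X - self.means) / self.sds
        k = self.n_components
        V = self.loadings / np.sqrt(self.eigenvalues[:k])
        F = Z @ V @ self.rotation  # standardized rotated component scores
        F = F * self._signs
        return F @ self.weights

    _signs: np.ndarray = None  # set during fit; column sign convention


def fit_pca_score(panel: pd.DataFrame, n_components: int | None = None) -> PcaScoreModel:
    """Fit the PCA-based pollution score (APS1).

    Standardizes the five pollutants, eigendecomposes their correlation
    matrix, retains ``n_components`` components (default: eigenvalue > 1,
    at least one), varimax-rotates the loadings, orients each component so
    its loading sum is positive, and scores each subject by the
    explained-variance-weighted sum of the rotated standardized component
    scores.  With one retained component APS1 is that component's score.
    """
    X = panel[POLLUTANTS].to_numpy(dtype=float)
    if X.shape[0] < 6:
        raise ValueError("need at least 6 rows to fit the PCA score")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        const = [POLLUTANTS[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant pollutant column(s): {const}")
    means = X.mean(axis=0)
    Z = (X - means) / sds

    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if n_components is None:
        k = max(1, int((eigvals > 1.0).sum()))
    else:
        k = int(n_components)
        if not 1 <= k <= 5:
            raise ValueError("n_components must be between 1 and 5")

    loadings = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    rotated, R, _ = varimax_rotate(loadings)

    signs = np.where(rotated.sum(axis=0) >= 0, 1.0, -1.0)
    rotated = rotated * signs

    share = (rotated**2).sum(axis=0) / corr.shape[0]
    weights = share / share.sum()

    model = PcaScoreModel(
        means=means,
        sds=sds,
        eigenvalues=eigvals,
        loadings=loadings,
        rotated_loadings=rotated,
        rotation=R,
        explained_share=share,
        weights=weights,
        scores=np.empty(0),
    )
    model._signs = signs
    model.scores = model.transform(panel)
    return model


def weighted_score(panel: pd.DataFrame, betas) -> np.ndarray:
    """Coefficient-weighted pollution score (APS2).

    Evaluates ``(sum_i beta_i x_i) / (5 / sum_i beta_i)`` exactly as written,
    i.e. ``(sum_i beta_i x_i) * (sum_i beta_i) / 5``.  The beta sum must be
    nonzero.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (5,):
        raise ValueError("betas must have length 5 (one per pollutant)")
    bsum = betas.sum()
    if bsum == 0:
        raise ValueError("sum of betas is zero; the score's divisor 5/sum(beta) is undefined")
    X = panel[POLLUTANTS].to_numpy(dtype=float)
    return (X @ betas) / (5.0 / bsum)


@dataclass
class TertileLabel:
    """Tertile categorization of a score vector."""

    labels: pd.Categorical          # levels first/second/third
    cuts: tuple[float, float]

    def __len__(self) -> int:
        return len(self.labels)


def tertile_cut(scores) -> TertileLabel:
    """Cut a score vector at its empirical 1/3 and 2/3 quantiles (type-7).

    Intervals are left-closed: ``first`` = [min, q1), ``second`` = [q1, q2),
    ``third`` = [q2, max].  Tied values at a cut necessarily share a label.
    """
    x = np.asarray(scores, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct score values for tertiles")
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3], method="linear")
    idx = (x >= q1).astype(int) + (x >= q2).astype(int)
    labels = pd.Categorical.from_codes(idx, categories=TERTILE_LEVELS, ordered=True)
    return TertileLabel(labels=labels, cuts=(float(q1), float(q2)))


def score_table(
    panel: pd.DataFrame,
    betas,
    n_components: int | None = None,
    subject_id: pd.Series | None = None,
) -> tuple[pd.DataFrame, PcaScoreModel]:
    """Convenience: both scores plus their tertiles as one table."""
    model = fit_pca_score(panel, n_components=n_components)
    aps2 = weighted_score(panel, betas)
    t1 = tertile_cut(model.scores)
    t2 = tertile_cut(aps2)
    out = pd.DataFrame(
        {
            "subject_id": (
                subject_id.to_numpy() if subject_id is not None else np.arange(len(panel))
            ),
            "aps1": model.scores,
            "aps2": aps2,
            "aps1_tertile": t1.labels,
            "aps2_tertile": t2.labels,
        }
    )
    return out, model
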