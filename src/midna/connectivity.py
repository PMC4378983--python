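"""Partial-least-squares connectivity scores for one group's network.

Each analyte ``x_j`` in turn is predicted from the remaining ``p - 1``
analytes plus the covariates with a univariate-response PLS regression on
``v`` orthogonal latent factors (NIPALS with deflation).  Writing the fitted
model back on the predictor scale gives one composite coefficient per
predictor; the coefficient ``a_jk`` of analyte ``k`` in the model for ``j``
measures how strongly ``k`` drives ``j`` once every other analyte is in the
model.  The connectivity score symmetrises the two directions,

    s_jk = (a_jk + a_kj) / 2,

and covariate coefficients are discarded — covariates shape the latent
factors (adjustment) but never score as connections.  PLS rather than
ordinary least squares keeps the fits defined and stable when ``p`` rivals or
exceeds the group sample size; at full rank the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stacking import StackedData

_W_TOL = 1e-12


@dataclass
class ConnectivityMatrix:
    """``p x p`` symmetric score matrix for one group (diagonal zero)."""

    scores: np.ndarray
    analyte_ids: list
    v: int
    group_label: object = None
    rescaled: bool = False

    @property
    def p(self) -> int:
        return self.scores.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.analyte_ids, columns=self.analyte_ids)


def fit_pls(y: np.ndarray, X: np.ndarray, v: int) -> tuple[np.ndarray, np.ndarray]:
    """Univariate-response NIPALS PLS with ``v`` latent factors.

    Columns of ``X`` are centred internally (data are standardised upstream;
    subgroup means need not be zero).  Returns ``(coef, scores)`` where
    ``coef`` are the composite regression coefficients on the predictor scale
    — ``y_hat = X_centered @ coef + mean(y)`` — and ``scores`` the ``n x v``
    matrix of mutually orthogonal latent factors.  With ``v`` equal to the
    predictor rank the coefficients reduce to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if v < 1 or v > min(n - 1, k):
        raise ValueError(f"v={v} outside 1..min(n-1, p)={min(n - 1, k)}")
    yc = y - y.mean()
    if np.abs(yc).max() < _W_TOL:
        raise ValueError("constant response")
    Xd = X - X.mean(axis=0)

    W = np.zeros((k, v))
    P = np.zeros((k, v))
    q = np.zeros(v)
    T = np.zeros((n, v))
    used = 0
    for a in range(v):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm < _W_TOL:  # predictors exhausted (rank < v)
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < _W_TOL:
            break
        p_load = Xd.T @ t / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, p_load, float(yc @ t) / tt, t
        Xd = Xd - np.outer(t, p_load)
        used = a + 1
    if used == 0:
        raise ValueError("no usable latent factor (response uncorrelated or rank 0)")
    W, P, q, T = W[:, :used], P[:, :used], q[:used], T[:, :used]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return coef, T


def connectivity_scores(
    sd: StackedData,
    v: int = 3,
    include_covariates: bool = True,
    group_label=None,
) -> ConnectivityMatrix:
    """Fit the ``p`` PLS models for one group and symmetrise the coefficients.

    ``sd`` must be (variance-corrected) standardized stacked data restricted
    to a single group.  ``v`` is clipped to the available predictor count for
    very small panels.
    """
    if not sd.standardized:
        raise ValueError("connectivity scores expect standardized stacked data")
    V = sd.values
    C = sd.covariates if include_covariates else np.empty((V.shape[0], 0))
    p = V.shape[1]
    v_eff = min(v, p - 1 + C.shape[1], V.shape[0] - 1)
    A = np.zeros((p, p))
    others_idx = [np.delete(np.arange(p), j) for j in range(p)]
    for j in range(p):
        X = np.column_stack([V[:, others_idx[j]], C])
        coef, _ = fit_pls(V[:, j], X, v_eff)
        A[j, others_idx[j]] = coef[: p - 1]  # covariate coefficients discarded
    scores = 0.5 * (A + A.T)
    np.fill_diagonal(scores, 0.0)
    return ConnectivityMatrix(
        scores=scores,
        analyte_ids=list(sd.analyte_ids),
        v=v_eff,
        group_label=group_label,
        rescaled=False,
    )


def rescale_scores(cm: ConnectivityMatrix, resymmetrize: str = "max") -> ConnectivityMatrix:
    """Rescale so each analyte's largest score has magnitude one.

    Row ``j`` is divided by ``max_k |s_jk|`` (all-zero rows untouched).  Row
    scaling breaks symmetry, so the matrix is re-symmetrised: ``"max"`` keeps,
    for each pair, the entry of larger magnitude (each analyte's strongest
    connection stays at magnitude 1); ``"mean"`` averages the two entries.
    """
    if cm.rescaled:
        raise ValueError("connectivity matrix already rescaled")
    if resymmetrize not in ("max", "mean"):
        raise ValueError(f"unknown resymmetrize mode {resymmetrize!r}")
    s = cm.scores.copy()
    row_max = np.abs(s).max(axis=1)
    nz = row_max > 0
    s[nz] = s[nz] / row_max[nz, None]
    if resymmetrize == "max":
        s = np.where(np.abs(s) >= np.abs(s.T), s, s.T)
    else:
        s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 0.0)
    return replace(cm, scores=s, rescaled=True)
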