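"""Multiple imputation by chained equations with left-censored draws.

Each incomplete analyte is imputed from a Bayesian normal linear regression on
all other analytes, the group label and the covariates ("norm" imputation):
the residual variance is drawn from its scaled inverse-chi-square posterior,
the coefficients from a normal around the (ridge-stabilised) least-squares
fit, and each missing cell from the resulting predictive normal.  The two
missingness types differ only in which draws are kept:

* MCAR cells accept every draw (full predictive distribution);
* left-censored cells accept a draw only if it falls below ``log(l_j)``
  (acceptance–rejection from the left tail); after ``max_reject`` vectorised
  rounds the remaining cells switch to exact inverse-CDF truncated-normal
  sampling from the same predictive normal, which is distributionally
  equivalent and never stalls when the mass below the bound is tiny.

The chained cycle sweeps all incomplete analytes in fixed column order and is
repeated ``n_cycles`` times; ``M`` independent chains give the ``M`` completed
copies.  Observed cells are never modified and censored cells never reach or
exceed their bound, at every stage of every chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .io import LipidDataset, MissingCode

#: gap (log units) below the censoring bound used by the initial fill
_INIT_DELTA = 0.01


@dataclass
class ImputationModelSpec:
    """Settings of the chained-equation imputer.

    ``M`` completed copies, ``n_cycles`` sweeps per chain, ridge penalty
    stabilising each conditional regression when predictors approach or
    exceed the number of observed rows, ``max_reject`` vectorised
    acceptance–rejection rounds before the truncated-normal fallback, and the
    minimum fraction of observed cells required per analyte (interacts with
    the upstream detection filter).
    """

    M: int = 5
    n_cycles: int = 10
    ridge: float = 1e-5
    max_reject: int = 100
    min_observed_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.max_reject < 1:
            raise ValueError("max_reject must be >= 1")


@dataclass
class ImputationSet:
    """``M`` completed copies of a dataset (observed cells identical across copies)."""

    completed: np.ndarray  # (M, n, p)
    source: LipidDataset
    seed: object
    convergence_trace: np.ndarray | None = None  # (M, n_cycles, p) imputed-cell means

    @property
    def M(self) -> int:
        return self.completed.shape[0]

    def to_frames(self):
        import pandas as pd

        v = self.source.values
        return [pd.DataFrame(c, index=v.index, columns=v.columns) for c in self.completed]

    def validate(self) -> None:
        arr = self.source.arrays()
        obs = arr["code"] == int(MissingCode.OBSERVED)
        cens = arr["code"] == int(MissingCode.CENSORED)
        for c in self.completed:
            if not np.array_equal(c[obs], arr["values"][obs]):
                raise ValueError("observed cells differ between source and completed copy")
            bounds = np.broadcast_to(arr["lloq"], c.shape)
            if not np.all(c[cens] < bounds[cens]):
                raise ValueError("censored cell imputed at or above its bound")


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------

def initial_fill(ds: LipidDataset) -> np.ndarray:
    """Simple start values: column mean for MCAR cells, just-below-bound for
    censored cells (so the bound holds from the very first state)."""
    if ds.scale != "log":
        raise ValueError("imputation operates on log-scale data")
    arr = ds.arrays()
    return _initial_fill(arr["values"], arr["code"], arr["lloq"])


def _initial_fill(values: np.ndarray, code: np.ndarray, lloq: np.ndarray) -> np.ndarray:
    out = values.copy()
    obs = code == int(MissingCode.OBSERVED)
    for j in range(values.shape[1]):
        col_obs = obs[:, j]
        if not col_obs.any():
            raise ValueError(f"column {j} has no observed cells")
        mean = values[col_obs, j].mean()
        mcar = code[:, j] == int(MissingCode.MCAR)
        cens = code[:, j] == int(MissingCode.CENSORED)
        out[mcar, j] = mean
        out[cens, j] = lloq[j] - _INIT_DELTA
    return out


def sample_truncated_below(mu, sigma, upper, rng, max_reject: int = 100) -> np.ndarray:
    """Draw from N(mu, sigma^2) conditioned on being strictly below ``upper``.

    Vectorised acceptance–rejection against the untruncated normal; cells
    still unaccepted after ``max_reject`` rounds are drawn exactly through the
    inverse CDF of the truncated normal (same distribution, guaranteed to
    terminate).  ``upper = +inf`` degenerates to plain normal sampling.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), mu.shape)
    upper = np.broadcast_to(np.asarray(upper, dtype=float), mu.shape)
    out = np.empty_like(mu)

    free = ~np.isfinite(upper)  # no bound: every draw accepted
    if free.any():
        out[free] = mu[free] + sigma[free] * rng.standard_normal(int(free.sum()))
    pending = ~free
    remaining = max_reject
    while pending.any() and remaining > 0:
        # draw a block of candidates per cell; keep the first one below the
        # bound (identical in distribution to one-at-a-time rejection)
        block = min(16, remaining)
        idx = np.flatnonzero(pending)
        cand = mu[idx, None] + sigma[idx, None] * rng.standard_normal((idx.size, block))
        ok = cand < upper[idx, None]
        hit = ok.any(axis=1)
        first = ok.argmax(axis=1)
        got = idx[hit]
        out[got] = cand[hit, first[hit]]
        pending[got] = False
        remaining -= block
    if pending.any():
        # exact inverse-CDF truncated draw for the stubborn cells
        z = (upper[pending] - mu[pending]) / sigma[pending]
        log_phi = special.log_ndtr(z)
        u = rng.random(int(pending.sum()))
        # quantile of the lower tail: Phi^{-1}(u * Phi(z)), computed in logs
        out[pending] = mu[pending] + sigma[pending] * special.ndtri_exp(
            np.log(u) + log_phi
        )
    return out


def _posterior_predictive_params(X, y, ridge, rng):
    """Draw (beta, sigma) from the approximate posterior of a normal linear model."""
    n_obs, k = X.shape
    A = X.T @ X + ridge * np.eye(k)
    L = np.linalg.cholesky(A)
    beta_hat = np.linalg.solve(A, X.T @ y)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    nu = max(n_obs - k, 1)
    sigma2 = rss / max(rng.chisquare(nu), 1e-300)
    sigma2 = max(sigma2, 1e-12)
    # beta | sigma2 ~ N(beta_hat, sigma2 * A^{-1});  A = L L'
    z = rng.standard_normal(k)
    beta = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
    return beta, np.sqrt(sigma2)


def draw_conditional(
    target_j: int,
    completed: np.ndarray,
    ds: LipidDataset,
    rng,
    spec: ImputationModelSpec | None = None,
) -> np.ndarray:
    """One conditional-regression draw for every missing cell of one analyte.

    The observed values of analyte ``target_j`` are regressed on all other
    (currently completed) analytes, the group label and the covariates; draws
    come from the posterior-predictive normal, truncated below ``log(l_j)``
    for censored cells and untruncated for MCAR cells.  Returns the new values
    for the missing cells of the column, in row order.
    """
    spec = spec or ImputationModelSpec()
    arr = ds.arrays()
    X_full = _design_matrix(completed, target_j, arr["y"], arr["covariates"])
    return _draw_conditional(
        X_full,
        arr["values"][:, target_j],
        arr["code"][:, target_j],
        arr["lloq"][target_j],
        rng,
        spec,
    )


def _design_matrix(completed, j, y, covariates):
    others = np.delete(completed, j, axis=1)
    return np.column_stack([np.ones(completed.shape[0]), others, y, covariates])


def _draw_conditional(X_full, y_col, code_col, bound, rng, spec):
    obs = code_col == int(MissingCode.OBSERVED)
    if not obs.any():
        raise ValueError("target analyte has no observed values")
    beta, sigma = _posterior_predictive_params(X_full[obs], y_col[obs], spec.ridge, rng)
    mis = ~obs
    mu = X_full[mis] @ beta
    upper = np.where(
        code_col[mis] == int(MissingCode.CENSORED), bound, np.inf
    )
    return sample_truncated_below(mu, sigma, upper, rng, spec.max_reject)


# ---------------------------------------------------------------------------
# The chained cycle
# ---------------------------------------------------------------------------

def run_chained_imputation(
    ds: LipidDataset, spec: ImputationModelSpec | None = None, seed=0
) -> ImputationSet:
    """Run ``M`` independent chains of censoring-aware MICE.

    Each chain starts from :func:`initial_fill` and performs ``n_cycles``
    sweeps over the incomplete analytes in fixed left-to-right column order,
    refreshing that column's missing cells from its conditional regression at
    each visit.  Chain ``c`` uses the RNG ``default_rng([*seed, c])``, so the
    result is bit-reproducible and chains are independent.
    """
    spec = spec or ImputationModelSpec()
    if ds.scale != "log":
        raise ValueError("imputation operates on log-scale data")
    arr = ds.arrays()
    values, code, lloq = arr["values"], arr["code"], arr["lloq"]
    obs = code == int(MissingCode.OBSERVED)
    rates = obs.mean(axis=0)
    low = rates < spec.min_observed_rate
    if low.any():
        names = [a for a, b in zip(ds.analyte_ids, low) if b]
        raise ValueError(
            f"analytes below the {spec.min_observed_rate:.0%} observed-rate floor: {names}"
        )

    seed_tuple = tuple(seed) if isinstance(seed, (list, tuple)) else (int(seed),)
    incomplete = np.flatnonzero(~obs.all(axis=0))
    mis_cells = {j: ~obs[:, j] for j in incomplete}

    completed = np.empty((spec.M, ds.n, ds.p))
    trace = np.zeros((spec.M, spec.n_cycles, ds.p))
    for chain in range(spec.M):
        rng = np.random.default_rng([*seed_tuple, chain])
        cur = _initial_fill(values, code, lloq)
        for cycle in range(spec.n_cycles):
            for j in incomplete:
                X_full = _design_matrix(cur, j, arr["y"], arr["covariates"])
                try:
                    draws = _draw_conditional(
                        X_full, values[:, j], code[:, j], lloq[j], rng, spec
                    )
                except np.linalg.LinAlgError as err:
                    raise ValueError(
                        f"conditional fit failed for analyte {ds.analyte_ids[j]}: {err}"
                    ) from err
                cur[mis_cells[j], j] = draws
                trace[chain, cycle, j] = draws.mean()
        completed[chain] = cur
    return ImputationSet(completed=completed, source=ds, seed=seed_tuple, convergence_trace=trace)
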