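"""Stacking multiply imputed copies and variance-corrected standardisation.

Instead of analysing the ``M`` completed copies separately and somehow
reconciling ``M`` different networks, the copies are stacked into one
``Mn``-row dataset that is analysed once.  Stacking leaves sample means
unchanged but shrinks the sample variance: for a column whose ``n`` values
are replicated ``M`` times,

    s2_stack = M (n - 1) / (M n - 1) * s2 = (n - 1) / (n - 1/M) * s2,

so multiplying the stacked sample variance by ``(n - 1/M) / (n - 1)``
recovers the single-copy variance exactly.  Standardisation divides each
column by the square root of this corrected variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .impute import ImputationSet


@dataclass
class StackedData:
    """``Mn x p`` stacked matrix plus replicated metadata.

    ``patient_index`` maps each stacked row to its original row (0..n-1);
    ``y`` is the replicated 0/1 group indicator; continuous covariates are
    standardised alongside the analytes, binary ones stay 0/1.
    """

    values: np.ndarray  # (M*n, p)
    patient_index: np.ndarray  # (M*n,)
    M: int
    n: int
    y: np.ndarray  # (M*n,) 0/1
    covariates: np.ndarray  # (M*n, q)
    analyte_ids: list
    covariate_ids: list
    group_labels: tuple
    standardized: bool = False

    @property
    def p(self) -> int:
        return self.values.shape[1]


def stack(imp: ImputationSet) -> StackedData:
    """Concatenate the ``M`` completed copies row-block by row-block."""
    src = imp.source
    arr = src.arrays()
    M, n, p = imp.completed.shape
    values = imp.completed.reshape(M * n, p)
    idx = np.tile(np.arange(n), M)
    return StackedData(
        values=values.copy(),
        patient_index=idx,
        M=M,
        n=n,
        y=np.tile(arr["y"], M),
        covariates=np.tile(arr["covariates"], (M, 1)),
        analyte_ids=src.analyte_ids,
        covariate_ids=list(src.covariates.columns),
        group_labels=src.group_labels,
        standardized=False,
    )


def corrected_variance(column: np.ndarray, M: int, n: int) -> float:
    """Stacked sample variance times the correction factor ``(n - 1/M)/(n - 1)``."""
    s2_stack = column.var(ddof=1)
    return s2_stack * (n - 1.0 / M) / (n - 1.0)


def _is_binary(col: np.ndarray) -> bool:
    return np.unique(col).size <= 2


def center_scale_corrected(sd: StackedData) -> StackedData:
    """Center each column at its stacked mean and scale by the corrected SD.

    Applied to every analyte and to the continuous covariates (binary
    covariates are left 0/1).  Raises on zero-variance analytes.
    """
    if sd.standardized:
        raise ValueError("stacked data already standardized")
    vals = sd.values - sd.values.mean(axis=0)
    s2 = np.array([corrected_variance(sd.values[:, j], sd.M, sd.n) for j in range(sd.p)])
    if np.any(s2 <= 0):
        bad = [a for a, v in zip(sd.analyte_ids, s2) if v <= 0]
        raise ValueError(f"zero-variance analytes cannot be standardized: {bad}")
    vals /= np.sqrt(s2)

    cov = sd.covariates.copy()
    for q in range(cov.shape[1]):
        if not _is_binary(cov[:, q]):
            s2q = corrected_variance(cov[:, q], sd.M, sd.n)
            cov[:, q] = (cov[:, q] - cov[:, q].mean()) / np.sqrt(s2q)
    return replace(sd, values=vals, covariates=cov, standardized=True)


def split_by_group(sd: StackedData) -> dict:
    """Split standardized stacked rows by group label (networks are fitted per group)."""
    out = {}
    for label, indicator in zip(sd.group_labels, (1.0, 0.0)):
        mask = sd.y == indicator
        out[label] = replace(
            sd,
            values=sd.values[mask],
            patient_index=sd.patient_index[mask],
            y=sd.y[mask],
            covariates=sd.covariates[mask],
        )
    return out
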