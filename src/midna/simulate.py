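"""Synthetic two-group lipidome generator with known network structure.

Emulates the features of a two-group mass-spectrometry concentration study
that drive the downstream analysis: block-correlated log-normal
concentrations (lipids of one class rise and fall together), a group-specific
"hub" analyte whose extra cross-block couplings exist in the case group only,
per-analyte quantile-based left-censoring at the lower limit of
quantification, and sparse completely-at-random dropout from quality control.

All randomness flows through :func:`numpy.random.default_rng` seeded
explicitly, so every generated dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import LipidDataset, MissingCode


@dataclass
class SyntheticTruth:
    """Ground-truth generating structure for a two-group synthetic study.

    ``blocks`` partitions the analytes into correlated blocks shared by both
    groups (within-block correlation ``rho``, cross-block zero).  Each hub
    analyte additionally correlates, at ``hub_coupling`` (default ``0.65 rho``
    — a coupling as strong as ``rho`` itself makes the matrix indefinite once
    blocks have a few members), with every analyte of its target block — in
    group 1 (cases) only.  Censoring is applied at
    the per-analyte empirical ``censor_quantile``; MCAR dropout thins observed
    cells at rate ``mcar_rate``.
    """

    blocks: np.ndarray
    rho: float = 0.7
    hub_analytes: tuple[int, ...] = ()
    hub_targets: tuple[int, ...] = ()
    hub_coupling: float | None = None
    censor_quantile: float | np.ndarray = 0.15
    mcar_rate: float = 0.02
    analyte_means: np.ndarray | None = None
    group_shift: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.blocks = np.asarray(self.blocks, dtype=int)
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        q = np.asarray(self.censor_quantile, dtype=float)
        if np.any(q < 0) or np.any(q >= 1):
            raise ValueError("censor_quantile must be in [0, 1)")
        if not 0 <= self.mcar_rate <= 0.5:
            raise ValueError("mcar_rate must be in [0, 0.5]")
        if len(self.hub_analytes) != len(self.hub_targets):
            raise ValueError("hub_analytes and hub_targets must pair up")

    @property
    def p(self) -> int:
        return self.blocks.size

    def covariance(self, group: int) -> np.ndarray:
        """Generating correlation matrix for group 1 (cases) or 2 (controls)."""
        same = self.blocks[:, None] == self.blocks[None, :]
        sigma = np.where(same, self.rho, 0.0)
        np.fill_diagonal(sigma, 1.0)
        if group == 1:
            c = 0.65 * self.rho if self.hub_coupling is None else self.hub_coupling
            for h, b in zip(self.hub_analytes, self.hub_targets):
                tgt = np.flatnonzero(self.blocks == b)
                tgt = tgt[tgt != h]
                sigma[h, tgt] = c
                sigma[tgt, h] = c
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            raise ValueError(
                "generating covariance is not positive definite "
                "(rho/hub_coupling too large for the hub construction)"
            ) from None
        return sigma

    def module_assignment(self, group: int) -> dict[int, int]:
        """True analyte → block map; in group 1 a hub merges its two blocks."""
        assign = {j: int(b) for j, b in enumerate(self.blocks)}
        if group == 1:
            for h, b in zip(self.hub_analytes, self.hub_targets):
                merged = assign[h]
                for j, bj in assign.items():
                    if bj == b:
                        assign[j] = merged
        return assign


def make_truth(
    p: int = 20,
    block_size: int = 5,
    rho: float = 0.7,
    hub: bool = True,
    hub_coupling: float | None = None,
    censor_quantile: float | np.ndarray = 0.15,
    mcar_rate: float = 0.02,
) -> SyntheticTruth:
    """Equal-size-block truth, optionally with a bridge hub.

    With ``hub`` set, analyte 0 sits in its own singleton block and couples to
    both block 1 and block 2 in the case group only: the two modules are
    isolated in the control network but bound into one larger module through
    the hub in the case network.  Without a hub, analytes are simply tiled
    into blocks of ``block_size``.
    """
    if hub and p >= 1 + 2 * block_size:
        blocks = np.r_[0, np.arange(p - 1) // block_size + 1]
        hubs, targets = (0, 0), (1, 2)
    else:
        blocks = np.arange(p) // block_size
        hubs, targets = (), ()
    return SyntheticTruth(
        blocks=blocks,
        rho=rho,
        hub_analytes=hubs,
        hub_targets=targets,
        hub_coupling=hub_coupling,
        censor_quantile=censor_quantile,
        mcar_rate=mcar_rate,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_two_group_lipidome(
    n1: int, n2: int, p: int, truth: SyntheticTruth, seed
) -> tuple[LipidDataset, SyntheticTruth]:
    """Draw a fully observed two-group log-scale dataset from ``truth``.

    Group 1 rows come first ("case"), then group 2 ("control").  Covariates
    (age, BMI, statin use, smoking) are drawn independently of group,
    mirroring a frequency-matched design.  Per-analyte mean log-concentrations
    default to N(1.5, 1) draws (roughly μM-scale lipid levels) and are
    recorded in the returned truth.
    """
    if n1 < 5 or n2 < 5:
        raise ValueError("need at least 5 patients per group")
    if p < 4:
        raise ValueError("need at least 4 analytes")
    if truth.p != p:
        raise ValueError(f"truth describes {truth.p} analytes, not {p}")
    rng = np.random.default_rng(seed if isinstance(seed, (list, tuple)) else [int(seed)])

    if truth.analyte_means is None:
        mu = rng.normal(1.5, 1.0, size=p)
        truth = replace(truth, analyte_means=mu)
    else:
        mu = np.asarray(truth.analyte_means, dtype=float)
    shift = np.broadcast_to(np.asarray(truth.group_shift, dtype=float), (p,))

    x1 = rng.multivariate_normal(mu + shift, truth.covariance(1), size=n1, method="cholesky")
    x2 = rng.multivariate_normal(mu, truth.covariance(2), size=n2, method="cholesky")
    values = np.vstack([x1, x2])
    n = n1 + n2

    patients = [f"P{i:04d}" for i in range(n)]
    analytes = [f"L{j + 1}" for j in range(p)]
    group = pd.Series(["case"] * n1 + ["control"] * n2, index=patients, name="group")
    covariates = pd.DataFrame(
        {
            "age": rng.normal(62.0, 10.0, size=n),
            "bmi": rng.normal(27.5, 4.0, size=n),
            "statin": rng.binomial(1, 0.6, size=n).astype(float),
            "smoking": rng.binomial(1, 0.3, size=n).astype(float),
        },
        index=patients,
    )
    ds = LipidDataset(
        values=pd.DataFrame(values, index=patients, columns=analytes),
        missing_code=pd.DataFrame(
            np.zeros((n, p), dtype=np.int8), index=patients, columns=analytes
        ),
        lloq=pd.Series(np.nan, index=analytes),
        group=group,
        covariates=covariates,
        scale="log",
    )
    return ds, truth


def apply_censoring(ds: LipidDataset, censor_quantile) -> LipidDataset:
    """Left-censor each column at its empirical ``censor_quantile``.

    The LLOQ ``l_j`` is set to the quantile (method ``"higher"``, so with no
    ties exactly ``floor(n q)`` cells fall strictly below it); cells strictly
    below ``l_j`` are blanked and coded CENSORED.  Deterministic.
    """
    if ds.n_missing():
        raise ValueError("apply_censoring expects a fully observed dataset")
    if ds.scale != "log":
        raise ValueError("apply_censoring expects log-scale data")
    q = np.broadcast_to(np.asarray(censor_quantile, dtype=float), (ds.p,))
    if np.any(q < 0) or np.any(q >= 1):
        raise ValueError("censor quantile must be in [0, 1)")
    vals = ds.values.to_numpy(dtype=float).copy()
    lloq = np.array(
        [np.quantile(vals[:, j], q[j], method="higher") for j in range(ds.p)]
    )
    cens = vals < lloq[None, :]
    code = ds.missing_code.to_numpy().copy()
    code[cens] = int(MissingCode.CENSORED)
    vals[cens] = np.nan
    return replace(
        ds,
        values=pd.DataFrame(vals, index=ds.values.index, columns=ds.values.columns),
        missing_code=pd.DataFrame(code, index=ds.values.index, columns=ds.values.columns),
        lloq=pd.Series(lloq, index=ds.values.columns),
    )


def apply_mcar(ds: LipidDataset, rate: float, seed) -> LipidDataset:
    """Independently drop each currently observed cell with probability ``rate``."""
    if not 0 <= rate <= 0.5:
        raise ValueError("MCAR rate must be in [0, 0.5]")
    if rate == 0:
        return ds
    rng = np.random.default_rng(seed if isinstance(seed, (list, tuple)) else [int(seed)])
    vals = ds.values.to_numpy(dtype=float).copy()
    code = ds.missing_code.to_numpy().copy()
    observed = code == int(MissingCode.OBSERVED)
    drop = observed & (rng.random(vals.shape) < rate)
    code[drop] = int(MissingCode.MCAR)
    vals[drop] = np.nan
    return replace(
        ds,
        values=pd.DataFrame(vals, index=ds.values.index, columns=ds.values.columns),
        missing_code=pd.DataFrame(code, index=ds.values.index, columns=ds.values.columns),
    )


def simulate_study(
    n1: int, n2: int, p: int, truth: SyntheticTruth | None = None, seed=0
) -> tuple[LipidDataset, SyntheticTruth]:
    """Generate, censor and MCAR-thin a study in one call (the CLI entry)."""
    if truth is None:
        truth = make_truth(p)
    full, truth = generate_two_group_lipidome(n1, n2, p, truth, seed)
    ds = apply_censoring(full, truth.censor_quantile)
    ds = apply_mcar(ds, truth.mcar_rate, [int(seed) if np.isscalar(seed) else seed[0], 991])
    return ds, truth


def write_study_csvs(ds: LipidDataset, outdir, prefix: str = "study") -> dict[str, str]:
    """Write the CSV triple (+ codes file) that :func:`midna.io.read_lipid_dataset`
    reads.  Returns the paths.  Log-scale datasets are exponentiated back to
    raw μM concentrations so the files round-trip through the raw-scale
    reader followed by :func:`midna.io.log_transform`."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": str(outdir / f"{prefix}_values.csv"),
        "lloq": str(outdir / f"{prefix}_lloq.csv"),
        "covariates": str(outdir / f"{prefix}_covariates.csv"),
        "codes": str(outdir / f"{prefix}_codes.csv"),
    }
    values, lloq = ds.values, ds.lloq
    if ds.scale == "log":
        values, lloq = np.exp(values), np.exp(lloq)
    values.rename_axis("patient_id").to_csv(paths["values"])
    lloq.rename_axis("analyte_id").rename("lloq").dropna().to_csv(paths["lloq"])
    cov = ds.covariates.copy()
    cov.insert(0, "group", ds.group)
    cov.rename_axis("patient_id").to_csv(paths["covariates"])
    letters = ds.missing_code.replace(
        {int(MissingCode.OBSERVED): "O", int(MissingCode.CENSORED): "C", int(MissingCode.MCAR): "M"}
    )
    letters.rename_axis("patient_id").to_csv(paths["codes"])
    return paths
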