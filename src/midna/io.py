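"""Lipid concentration data: containers, parsing, validation, transforms, export.

The central container is :class:`LipidDataset`, a patient x analyte
concentration table together with a per-cell missingness code, per-analyte
lower limits of quantification (LLOQ), a binary group label per patient and a
complete covariate table.  Two kinds of missingness are distinguished:

* ``CENSORED`` — a left-censored non-detect: the concentration is known to lie
  between zero and the analyte's LLOQ ``l_j`` (between ``-inf`` and
  ``log(l_j)`` after the log transform);
* ``MCAR`` — missing completely at random, e.g. a quality-control removal,
  carrying no information about the underlying value.

Everything downstream (imputation, stacking, network fitting) operates on the
log scale; :func:`log_transform` moves a raw dataset there.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


class MissingCode(enum.IntEnum):
    """Per-cell missingness status."""

    OBSERVED = 0
    CENSORED = 1
    MCAR = 2


#: Accepted single-letter cell codes in a companion codes CSV.
_CODE_LETTERS = {"O": MissingCode.OBSERVED, "C": MissingCode.CENSORED, "M": MissingCode.MCAR}


class LipidDataValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class LipidDataset:
    """A two-group concentration study with censored and MCAR missing cells.

    Parameters
    ----------
    values
        ``n x p`` concentrations, ``NaN`` exactly where the cell is not
        observed.  μM on the raw scale, unitless after log transform.
    missing_code
        ``n x p`` integer frame over :class:`MissingCode`, aligned to
        ``values``.
    lloq
        Length-``p`` series of detection limits, indexed by analyte.  May be
        ``NaN`` for analytes without censored cells; must be finite (and, on
        the raw scale, positive) wherever a column has a censored cell.
        Stored on the same scale as ``values``.
    group
        Length-``n`` series with exactly two distinct labels.
    covariates
        ``n x q`` complete numeric/binary frame (may have zero columns).
    scale
        ``"raw"`` or ``"log"``.
    """

    values: pd.DataFrame
    missing_code: pd.DataFrame
    lloq: pd.Series
    group: pd.Series
    covariates: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def patient_ids(self) -> list:
        return list(self.values.index)

    @property
    def group_labels(self) -> tuple:
        """The two group labels in sorted order (convention: (group1, group2))."""
        return tuple(sorted(pd.unique(self.group), key=str))

    def detection_rate(self) -> pd.Series:
        """Fraction of OBSERVED cells per analyte (censored and MCAR both count
        as undetected)."""
        return (self.missing_code == int(MissingCode.OBSERVED)).mean(axis=0)

    def n_missing(self) -> int:
        return int((self.missing_code.to_numpy() != int(MissingCode.OBSERVED)).sum())

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        v, c = self.values, self.missing_code
        if v.shape != c.shape or list(v.index) != list(c.index) or list(v.columns) != list(c.columns):
            raise LipidDataValidationError("values and missing_code are not aligned")
        if v.index.has_duplicates:
            raise LipidDataValidationError("duplicated patient ids")
        if v.columns.has_duplicates:
            raise LipidDataValidationError("duplicated analyte ids")
        if list(self.group.index) != list(v.index) or list(self.covariates.index) != list(v.index):
            raise LipidDataValidationError("group/covariates not aligned with values")
        if self.scale not in ("raw", "log"):
            raise LipidDataValidationError(f"unknown scale {self.scale!r}")

        codes = c.to_numpy()
        valid = np.isin(codes, [int(m) for m in MissingCode])
        if not valid.all():
            raise LipidDataValidationError("missing_code contains unknown codes")

        absent = ~np.isfinite(v.to_numpy(dtype=float))
        if not (absent == (codes != int(MissingCode.OBSERVED))).all():
            raise LipidDataValidationError(
                "values must be absent exactly where missing_code != OBSERVED"
            )
        if self.scale == "raw":
            vals = v.to_numpy(dtype=float)
            if np.any(vals[~absent] <= 0):
                raise LipidDataValidationError("non-positive concentration on raw scale")

        lloq = self.lloq.reindex(v.columns)
        has_cens = (codes == int(MissingCode.CENSORED)).any(axis=0)
        lloq_vals = lloq.to_numpy(dtype=float)
        bad = has_cens & ~np.isfinite(lloq_vals)
        if self.scale == "raw":
            bad |= has_cens & (lloq_vals <= 0)
        if bad.any():
            names = [a for a, b in zip(v.columns, bad) if b]
            raise LipidDataValidationError(f"censored cell without LLOQ: {names}")
        object.__setattr__(self, "lloq", lloq)

        labels = pd.unique(self.group)
        if len(labels) != 2:
            raise LipidDataValidationError("group must have exactly two distinct labels")
        if self.covariates.shape[1] and self.covariates.isna().any().any():
            raise LipidDataValidationError("covariates must be complete")

    # -- numpy views used by the numeric layer --------------------------
    def arrays(self) -> dict:
        """Plain numpy views for the numeric pipeline (log scale expected)."""
        g1, g2 = self.group_labels
        return {
            "values": self.values.to_numpy(dtype=float),
            "code": self.missing_code.to_numpy(dtype=np.int8),
            "lloq": self.lloq.to_numpy(dtype=float),
            "y": (self.group.to_numpy() == g1).astype(float),
            "covariates": self.covariates.to_numpy(dtype=float)
            if self.covariates.shape[1]
            else np.empty((self.n, 0)),
        }


@dataclass
class NetworkEdgeList:
    """Edges surviving a connectivity threshold, plus the full node universe.

    ``edges`` holds ``(analyte_j, analyte_k, score)`` triples with ``j < k`` in
    the analyte ordering; nodes with no surviving edge stay in ``nodes`` so
    exports can list them as isolated.
    """

    edges: list[tuple[str, str, float]]
    epsilon: float
    nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = {a: i for i, a in enumerate(self.nodes)}
        for j, k, s in self.edges:
            if j == k:
                raise ValueError("self-edge in network")
            if abs(s) < self.epsilon:
                raise ValueError(f"edge ({j},{k}) below threshold {self.epsilon}")
            if order and order[j] >= order[k]:
                raise ValueError("edges must be ordered j < k")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def read_lipid_dataset(
    values_path,
    lloq_path,
    covariates_path,
    group_column: str,
    codes_path=None,
    id_column: str = "patient_id",
) -> LipidDataset:
    """Read the CSV triple (values, LLOQ, covariates) into a raw-scale dataset.

    ``values`` is one row per patient with an ``id_column`` plus one column per
    analyte; blank cells are missing.  ``lloq`` is long format with columns
    ``analyte_id, lloq``.  ``covariates`` carries ``id_column``, the binary
    ``group_column`` and any further covariates.  An optional ``codes`` CSV
    with the same layout as ``values`` holds per-cell letters O/C/M; cells
    missing in ``values`` but unflagged default to CENSORED when the analyte
    has a finite LLOQ and to MCAR otherwise.  Rows are joined on patient id,
    so row order across files is irrelevant.
    """
    values = pd.read_csv(values_path).set_index(id_column)
    if values.index.has_duplicates:
        raise LipidDataValidationError("duplicated patient ids in values file")
    values = values.astype(float)

    lloq_tab = pd.read_csv(lloq_path)
    lloq = pd.Series(
        lloq_tab["lloq"].to_numpy(dtype=float), index=lloq_tab["analyte_id"].astype(str)
    )
    if lloq.index.has_duplicates:
        raise LipidDataValidationError("duplicated analyte ids in LLOQ file")
    lloq = lloq.reindex(values.columns)

    cov = pd.read_csv(covariates_path).set_index(id_column)
    if cov.index.has_duplicates:
        raise LipidDataValidationError("duplicated patient ids in covariates file")
    if group_column not in cov.columns:
        raise LipidDataValidationError(f"group column {group_column!r} not found")
    if set(values.index) != set(cov.index):
        raise LipidDataValidationError("patient ids differ between values and covariates")
    cov = cov.reindex(values.index)
    group = cov[group_column]
    if group.nunique() != 2:
        raise LipidDataValidationError("group column is not binary")
    covariates = cov.drop(columns=[group_column]).astype(float)

    absent = ~np.isfinite(values.to_numpy())
    code = np.full(values.shape, int(MissingCode.OBSERVED), dtype=np.int8)
    finite_lloq = np.isfinite(lloq.to_numpy(dtype=float))
    default = np.where(finite_lloq[None, :], int(MissingCode.CENSORED), int(MissingCode.MCAR))
    code[absent] = np.broadcast_to(default, values.shape)[absent]

    if codes_path is not None:
        flags = pd.read_csv(codes_path).set_index(id_column).reindex(values.index)
        flags = flags.reindex(columns=values.columns)
        for letter, mc in _CODE_LETTERS.items():
            mask = (flags == letter).to_numpy()
            if mc is MissingCode.OBSERVED and (mask & absent).any():
                raise LipidDataValidationError("cell flagged observed but blank in values")
            if mc is not MissingCode.OBSERVED and (mask & ~absent).any():
                raise LipidDataValidationError("cell flagged missing but has a value")
            code[mask] = int(mc)

    missing_code = pd.DataFrame(code, index=values.index, columns=values.columns)
    return LipidDataset(
        values=values,
        missing_code=missing_code,
        lloq=lloq,
        group=group,
        covariates=covariates,
        scale="raw",
    )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log_transform(ds: LipidDataset, base: float | None = None) -> LipidDataset:
    """Move concentrations and LLOQs to the log scale (natural log by default)."""
    if ds.scale != "raw":
        raise ValueError("dataset already on log scale")
    vals = ds.values.to_numpy(dtype=float)
    observed = ds.missing_code.to_numpy() == int(MissingCode.OBSERVED)
    if np.any(vals[observed] <= 0):
        raise ValueError("cannot log-transform non-positive concentrations")
    denom = 1.0 if base is None else np.log(base)
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.log(vals) / denom
        lloq = np.log(ds.lloq.to_numpy(dtype=float)) / denom
    return replace(
        ds,
        values=pd.DataFrame(logged, index=ds.values.index, columns=ds.values.columns),
        lloq=pd.Series(lloq, index=ds.lloq.index),
        scale="log",
    )


def apply_detection_filter(ds: LipidDataset, min_rate: float = 0.60) -> LipidDataset:
    """Keep analytes observed in at least ``min_rate`` of the patients.

    Censored and MCAR cells both count as undetected.  Column order is
    preserved; idempotent.  Raises if fewer than two analytes survive.
    """
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    keep = ds.detection_rate() >= min_rate
    kept = [a for a in ds.analyte_ids if keep[a]]
    if len(kept) < 2:
        raise ValueError(
            f"detection filter at {min_rate:.2f} leaves {len(kept)} analyte(s); need >= 2"
        )
    return replace(
        ds,
        values=ds.values[kept],
        missing_code=ds.missing_code[kept],
        lloq=ds.lloq.reindex(kept),
    )


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def export_network(edges: NetworkEdgeList, modules, path, format: str = "sif") -> None:
    """Write a thresholded network for external viewers (e.g. Cytoscape).

    ``format="sif"`` writes one ``j interacts k`` line per edge.
    ``format="graphml"`` writes every node (isolated ones included) with a
    ``module`` attribute (empty string when module-free) and each edge with its
    connectivity ``score``.
    """
    import networkx as nx

    fmt = format.lower()
    member_of: Mapping = getattr(modules, "member_of", {}) if modules is not None else {}
    if fmt == "sif":
        lines = [f"{j}\tinteracts\t{k}" for j, k, _ in edges.edges]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = nx.Graph()
        for node in edges.nodes:
            mid = member_of.get(node)
            g.add_node(node, module="" if mid is None else str(mid))
        for j, k, s in edges.edges:
            g.add_edge(j, k, score=float(s))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path) -> NetworkEdgeList:
    """Read back a GraphML export (mainly for round-trip checks)."""
    import networkx as nx

    g = nx.read_graphml(path)
    nodes = sorted(g.nodes)
    order = {a: i for i, a in enumerate(nodes)}
    edges = []
    for j, k, data in g.edges(data=True):
        a, b = (j, k) if order[j] < order[k] else (k, j)
        edges.append((a, b, float(data["score"])))
    edges.sort(key=lambda e: (order[e[0]], order[e[1]]))
    eps = min((abs(s) for *_, s in edges), default=0.0)
    return NetworkEdgeList(edges=edges, epsilon=eps, nodes=nodes)
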