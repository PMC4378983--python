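"""Differential network statistics and the permutation-imputation test.

Two statistics compare the case and control networks built on the same
analyte panel:

* the modular-difference statistic ``N`` — one minus the mean Jaccard overlap
  of each shared analyte's modules across the two networks (0 = identical
  modular structures, 1 = fully different), with the conventions that ``N = 0``
  when neither network has any module and ``N = 1`` when modules exist on one
  side only;
* the per-analyte differential connectivity ``d(j)`` — the mean absolute
  difference of analyte ``j``'s rescaled connectivity scores to the other
  ``p - 1`` analytes between the two networks.

Because the group label is itself a predictor in the imputation model, a
permutation of the labels changes the imputations: each permutation therefore
re-runs the entire impute → stack → standardise → network pipeline before the
statistics are recomputed.  P-values are the fraction of permutations whose
statistic reaches the observed one; all ``d(j)`` p-values share one set of
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, connectivity_scores, rescale_scores
from .impute import ImputationModelSpec, run_chained_imputation
from .io import LipidDataset
from .modules import ModuleSet, extract_modules, threshold_network
from .stacking import center_scale_corrected, split_by_group, stack


@dataclass
class PipelineSettings:
    """Knobs of one impute→network→test run (defaults: the standard analysis)."""

    m: int = 3
    epsilon: float = 0.4
    v: int = 3
    M: int = 5
    n_cycles: int = 10
    ridge: float = 1e-5
    resymmetrize: str = "max"
    include_covariates: bool = True
    add_one: bool = False  #: use the conservative (b+1)/(P+1) p-value estimator

    def imputation_spec(self) -> ImputationModelSpec:
        return ImputationModelSpec(M=self.M, n_cycles=self.n_cycles, ridge=self.ridge)


@dataclass
class GroupNetwork:
    """One group's fitted network: scores, thresholded edges and modules."""

    connectivity: ConnectivityMatrix
    modules: ModuleSet


@dataclass
class DifferentialReport:
    """Observed statistics, permutation archive and p-values of one test run."""

    N_observed: float
    N_pvalue: float
    d_observed: pd.Series
    d_pvalues: pd.Series
    P: int
    perm_N: np.ndarray
    perm_d: np.ndarray  # (P, p)
    seed: int
    settings: PipelineSettings
    networks: dict = field(default_factory=dict)

    def d_table(self) -> pd.DataFrame:
        """Per-analyte d(j) and raw p-values, most differential first.

        P-values are raw by design: the d(j) tests are mutually dependent
        through the shared network, so independent-test corrections do not
        apply; interpret jointly.
        """
        tab = pd.DataFrame({"d": self.d_observed, "p_value": self.d_pvalues})
        return tab.sort_values(["d"], ascending=False).rename_axis("analyte")

    def summary(self) -> dict:
        s = self.settings
        return {
            "N": self.N_observed,
            "p_N": self.N_pvalue,
            "P": self.P,
            "seed": self.seed,
            "settings": {
                "m": s.m, "epsilon": s.epsilon, "v": s.v, "M": s.M,
                "n_cycles": s.n_cycles, "resymmetrize": s.resymmetrize,
                "add_one": s.add_one,
            },
        }


# ---------------------------------------------------------------------------
# The two statistics
# ---------------------------------------------------------------------------

def module_overlap_terms(ms1: ModuleSet, ms2: ModuleSet) -> dict:
    """Per-analyte (|F1 ∩ F2|, |F1 ∪ F2|) for analytes in modules on both sides."""
    if set(ms1.universe) != set(ms2.universe):
        raise ValueError("module sets cover different analyte universes")
    shared = ms1.covered() & ms2.covered()
    out = {}
    for j in shared:
        f1, f2 = ms1.module_of(j), ms2.module_of(j)
        out[j] = (len(f1 & f2), len(f1 | f2))
    return out


def modular_difference_statistic(ms1: ModuleSet, ms2: ModuleSet) -> float:
    """``N = 1 - mean_j |F1(j) ∩ F2(j)| / |F1(j) ∪ F2(j)|`` over shared analytes.

    Conventions: no modules in either network → 0 (nothing to differ);
    modules on at least one side but no shared analyte → 1 (fully different).
    """
    if ms1.n_modules == 0 and ms2.n_modules == 0:
        return 0.0
    terms = module_overlap_terms(ms1, ms2)
    if not terms:
        return 1.0
    jacc = [num / den for num, den in terms.values()]
    return 1.0 - float(np.mean(jacc))


def connectivity_difference(cm1: ConnectivityMatrix, cm2: ConnectivityMatrix) -> np.ndarray:
    """``d(j)``: mean absolute score difference of analyte j to the others."""
    if cm1.scores.shape != cm2.scores.shape:
        raise ValueError("connectivity matrices differ in shape")
    if cm1.analyte_ids != cm2.analyte_ids:
        raise ValueError("connectivity matrices cover different analytes")
    if not (cm1.rescaled and cm2.rescaled):
        raise ValueError("d(j) is defined on rescaled connectivity matrices")
    diff = np.abs(cm1.scores - cm2.scores)
    np.fill_diagonal(diff, 0.0)
    p = cm1.scores.shape[0]
    return diff.sum(axis=1) / (p - 1)


# ---------------------------------------------------------------------------
# One full analysis pass (shared by the observed data and every permutation)
# ---------------------------------------------------------------------------

def group_connectivities(ds: LipidDataset, settings: PipelineSettings, seed) -> dict:
    """Impute, stack, standardise and fit both groups' rescaled score matrices."""
    imp = run_chained_imputation(ds, settings.imputation_spec(), seed)
    sd = center_scale_corrected(stack(imp))
    cms = {}
    for label, sub in split_by_group(sd).items():
        cms[label] = rescale_scores(
            connectivity_scores(
                sub, v=settings.v, include_covariates=settings.include_covariates,
                group_label=label,
            ),
            resymmetrize=settings.resymmetrize,
        )
    return cms


def _networks_at(cms: dict, epsilon: float, m: int) -> dict:
    return {
        label: GroupNetwork(
            connectivity=cm, modules=extract_modules(threshold_network(cm, epsilon), m)
        )
        for label, cm in cms.items()
    }


def single_analysis(
    ds: LipidDataset, settings: PipelineSettings, seed
) -> tuple[float, np.ndarray, dict]:
    """Impute, stack, standardise, fit both group networks; return (N, d, networks)."""
    cms = group_connectivities(ds, settings, seed)
    nets = _networks_at(cms, settings.epsilon, settings.m)
    g1, g2 = ds.group_labels
    N = modular_difference_statistic(nets[g1].modules, nets[g2].modules)
    d = connectivity_difference(nets[g1].connectivity, nets[g2].connectivity)
    return N, d, nets


def _permuted_dataset(ds: LipidDataset, perm: np.ndarray) -> LipidDataset:
    """Reassign group labels by permuting them over patients (data unchanged)."""
    new_group = pd.Series(ds.group.to_numpy()[perm], index=ds.group.index, name=ds.group.name)
    return replace(ds, group=new_group)


def _one_permutation(ds, settings, seed, i):
    """Statistics for permutation ``i`` (a pure function of master seed and i)."""
    for attempt in range(5):
        rng = np.random.default_rng([int(seed), i, attempt])
        perm = rng.permutation(ds.n)
        try:
            N, d, _ = single_analysis(
                _permuted_dataset(ds, perm), settings, [int(seed), i, attempt]
            )
            return N, d
        except ValueError:
            continue  # degenerate permutation (e.g. singular fit): redraw
    raise RuntimeError(f"permutation {i} failed 5 times")


def permutation_imputation_test(
    ds: LipidDataset,
    settings: PipelineSettings | None = None,
    P: int = 500,
    seed: int = 0,
    n_jobs: int = 1,
) -> DifferentialReport:
    """Permutation-imputation test for differential modular structure and d(j).

    The observed run and each of the ``P`` permutations re-runs the complete
    imputation-stacking-network pipeline (the group label feeds the
    imputation model, so imputations are permutation-specific).  Each
    permutation's RNG stream is a pure function of ``(seed, permutation
    index)``, so results are identical for any ``n_jobs``.
    """
    settings = settings or PipelineSettings()
    if P < 1:
        raise ValueError("P must be >= 1")
    N_obs, d_obs, nets = single_analysis(ds, settings, [int(seed), 0])

    if n_jobs == 1:
        results = [_one_permutation(ds, settings, seed, i) for i in range(1, P + 1)]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_permutation)(ds, settings, seed, i) for i in range(1, P + 1)
        )
    perm_N = np.array([r[0] for r in results])
    perm_d = np.vstack([r[1] for r in results])

    if settings.add_one:
        p_N = (1.0 + np.sum(perm_N >= N_obs)) / (P + 1)
        p_d = (1.0 + np.sum(perm_d >= d_obs[None, :], axis=0)) / (P + 1)
    else:
        p_N = float(np.mean(perm_N >= N_obs))
        p_d = np.mean(perm_d >= d_obs[None, :], axis=0)

    ids = ds.analyte_ids
    return DifferentialReport(
        N_observed=float(N_obs),
        N_pvalue=float(p_N),
        d_observed=pd.Series(d_obs, index=ids, name="d"),
        d_pvalues=pd.Series(p_d, index=ids, name="p_value"),
        P=P,
        perm_N=perm_N,
        perm_d=perm_d,
        seed=int(seed),
        settings=settings,
        networks=nets,
    )


def epsilon_sweep(
    ds: LipidDataset,
    epsilons,
    settings: PipelineSettings | None = None,
    P: int = 500,
    seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """``N`` and ``p(N)`` across a grid of thresholds (one row per epsilon).

    One permutation set (and hence one imputation per permutation) is shared
    across the grid: each permutation's connectivity matrices are fitted once
    and only the thresholding and module extraction are repeated per epsilon.
    Grid rows are therefore mutually comparable but not independent.
    """
    settings = settings or PipelineSettings()
    epsilons = [float(e) for e in epsilons]

    def stats_for(cms, g1, g2):
        return [
            modular_difference_statistic(
                *(extract_modules(threshold_network(cms[g], eps), settings.m) for g in (g1, g2))
            )
            for eps in epsilons
        ]

    g1, g2 = ds.group_labels
    obs = stats_for(group_connectivities(ds, settings, [int(seed), 0]), g1, g2)

    def one_perm(i):
        for attempt in range(5):
            rng = np.random.default_rng([int(seed), i, attempt])
            perm = rng.permutation(ds.n)
            try:
                cms = group_connectivities(
                    _permuted_dataset(ds, perm), settings, [int(seed), i, attempt]
                )
                return stats_for(cms, g1, g2)
            except ValueError:
                continue
        raise RuntimeError(f"permutation {i} failed 5 times")

    if n_jobs == 1:
        perm_stats = np.array([one_perm(i) for i in range(1, P + 1)])
    else:
        from joblib import Parallel, delayed

        perm_stats = np.array(
            Parallel(n_jobs=n_jobs)(delayed(one_perm)(i) for i in range(1, P + 1))
        )
    rows = []
    for e_idx, eps in enumerate(epsilons):
        if settings.add_one:
            p = (1.0 + np.sum(perm_stats[:, e_idx] >= obs[e_idx])) / (P + 1)
        else:
            p = float(np.mean(perm_stats[:, e_idx] >= obs[e_idx]))
        rows.append({"epsilon": eps, "N": obs[e_idx], "p_value": p})
    return pd.DataFrame(rows)
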