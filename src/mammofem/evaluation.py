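"""Evaluation metrics, the ablation protocol, parameter grid search with
cross-validation, and the statistical comparison procedure.

Metrics: the tumor centroid alignment error (distance between the mean of
the estimated supine tumor cloud and the mean of the ground-truth cloud)
and the directed Hausdorff distance from the ground-truth tumor to the
estimate — directed, truth-to-estimate, because it measures how far any
true tumor point can be from the estimated excision region (a surgical-
margin proxy). A symmetrized variant exists behind a flag but is never
the default.

The ablation compares four mechanism combinations:

    A        : chest wall fixed, no deep-layer fluidity, no anchoring
    B        : chest wall free,  no deep-layer fluidity, no anchoring
    C        : chest wall free,  fluid deep layer,       no anchoring
    proposed : chest wall free,  fluid deep layer,       anchoring on

where "no fluidity" sets the deep-adipose modulus to the gland's 9.75 kPa
and "no anchoring" sets the anchoring weight to zero.

The grid search scans the anchoring weight over {0.00003, 0.00006,
0.00012, 0.00018, 0.00024, 0.0003} and the deep-adipose modulus over
{0.10, 0.50, 1.0, 1.5, 2.0} kPa, selecting per training fold the pair
minimizing the mean tumor centroid error, then scoring the held-out
validation cases (default 6 train / 3 validation, 3 folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import directed_hausdorff

from . import anchoring as anch_mod
from . import fem
from . import phantom as phantom_mod
from .registration import RegistrationConfig, prepare_model, run_registration

#: grid values scanned for the anchoring weight
DEFAULT_W_A_GRID = (0.00003, 0.00006, 0.00012, 0.00018, 0.00024, 0.0003)
#: grid values scanned for the deep-adipose Young's modulus [kPa]
DEFAULT_E_DEEP_GRID = (0.10, 0.50, 1.0, 1.5, 2.0)

#: cross-validated optimal parameters (mean over folds) used by "proposed"
OPTIMAL_W_A = 1e-4
OPTIMAL_E_DEEP = 0.83

#: gland / no-fluidity stiffness [kPa]
E_GLAND = 9.75

METHOD_FLAGS = {
    "A": {"fix_chest": True, "E_deep": E_GLAND, "w_a": 0.0},
    "B": {"fix_chest": False, "E_deep": E_GLAND, "w_a": 0.0},
    "C": {"fix_chest": False, "E_deep": OPTIMAL_E_DEEP, "w_a": 0.0},
    "proposed": {"fix_chest": False, "E_deep": OPTIMAL_E_DEEP, "w_a": OPTIMAL_W_A},
}


# -- metrics -------------------------------------------------------------

def centroid_error(estimated_tumor: np.ndarray, truth_tumor: np.ndarray) -> float:
    """Euclidean distance between the centroids of the two tumor clouds."""
    est = np.atleast_2d(np.asarray(estimated_tumor, float))
    tru = np.atleast_2d(np.asarray(truth_tumor, float))
    if est.size == 0 or tru.size == 0:
        raise ValueError("tumor point sets must be nonempty")
    return float(np.linalg.norm(est.mean(axis=0) - tru.mean(axis=0)))


def hausdorff_directed(estimated_tumor: np.ndarray, truth_tumor: np.ndarray,
                       symmetric: bool = False) -> float:
    """Directed Hausdorff distance from the truth cloud to the estimate:
    max over truth points of the distance to the nearest estimated point.

    ``symmetric=True`` returns the symmetrized variant (max of the two
    directions); the directed form is the default and the reported one.
    """
    est = np.atleast_2d(np.asarray(estimated_tumor, float))
    tru = np.atleast_2d(np.asarray(truth_tumor, float))
    if est.size == 0 or tru.size == 0:
        raise ValueError("tumor point sets must be nonempty")
    d = directed_hausdorff(tru, est)[0]
    if symmetric:
        d = max(d, directed_hausdorff(est, tru)[0])
    return float(d)


# -- synthetic cohort ----------------------------------------------------

@dataclass
class Case:
    """One synthetic patient: prone mesh plus supine observation/truth."""

    case_id: int
    mesh: object
    sim: fem.SimulationConfig
    observation: object
    truth: phantom_mod.GroundTruth
    params: phantom_mod.PhantomParams
    true_w_a: float = OPTIMAL_W_A
    true_E_deep: float = OPTIMAL_E_DEEP


def make_cohort(n_cases: int = 9, seed: int = 0, target_nodes: int = 1000,
                noise_sd: float = 0.5, n_surface: int = 1200, n_chest: int = 500,
                true_w_a_cycle=(6e-5, 1.2e-4, 1.8e-4),
                true_E_deep_cycle=(0.5, 1.0, 1.5),
                sim: fem.SimulationConfig | None = None) -> list:
    """Seeded cohort of synthetic cases with per-case anatomy variation.

    Radius, chest curvature and tumor location vary case to case; the
    "true" semi-fluid parameters generating each supine state cycle
    through values inside the search grids.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        R = float(rng.uniform(44.0, 58.0))
        th = rng.uniform(0, 2 * np.pi)
        rr = rng.uniform(0.2, 0.45) * R
        params = phantom_mod.PhantomParams(
            breast_radius=R,
            chest_curvature=float(rng.uniform(0.0012, 0.0028)),
            tumor_center=(rr * np.cos(th), rr * np.sin(th),
                          float(rng.uniform(0.3, 0.55)) * R),
            tumor_radius=0.15 * R,
            target_node_count=target_nodes,
            seed=int(seed * 1000 + i),
        )
        mesh = phantom_mod.generate_breast_phantom(params)
        w_a = true_w_a_cycle[i % len(true_w_a_cycle)]
        E_deep = true_E_deep_cycle[i % len(true_E_deep_cycle)]
        csim = fem.SimulationConfig(w_a=w_a, E_deep=E_deep) if sim is None else sim
        materials = fem.assign_tissue_stiffness(mesh, E_deep=E_deep)
        obs, truth = phantom_mod.generate_supine_observation(
            mesh, materials, csim, noise_sd=noise_sd, seed=int(seed * 1000 + i + 500),
            n_surface=n_surface, n_chest=n_chest)
        cases.append(Case(case_id=i, mesh=mesh, sim=csim, observation=obs,
                          truth=truth, params=params, true_w_a=w_a,
                          true_E_deep=E_deep))
    return cases


def _register_case(case: Case, w_a: float, E_deep: float, fix_chest: bool,
                   config: RegistrationConfig, state=None):
    materials = fem.assign_tissue_stiffness(case.mesh, E_deep=E_deep)
    sim = fem.SimulationConfig(w_a=w_a, E_deep=E_deep,
                               gravity_vector=case.sim.gravity_vector,
                               w_p=case.sim.w_p)
    anchor = (anch_mod.build_anchoring(case.mesh, w_a) if w_a > 0 else None)
    return run_registration(case.mesh, materials, sim, anchor, case.observation,
                            config, tumor_points=case.truth.prone_tumor_points,
                            state=state, fix_chest=fix_chest)


# -- ablation ------------------------------------------------------------

def run_ablation(cases: list, methods=("A", "B", "C", "proposed"),
                 config: RegistrationConfig | None = None,
                 optimal_w_a: float = OPTIMAL_W_A,
                 optimal_E_deep: float = OPTIMAL_E_DEEP) -> pd.DataFrame:
    """One registration per (case, method); per-case metrics table.

    A failed case is recorded with NaN metrics and the run continues.
    Returns a DataFrame with columns (case, method, hausdorff, centroid).
    """
    config = config or RegistrationConfig()
    rows = []
    for case in cases:
        for method in methods:
            flags = dict(METHOD_FLAGS[method])
            if flags["E_deep"] == OPTIMAL_E_DEEP:
                flags["E_deep"] = optimal_E_deep
            if flags["w_a"] == OPTIMAL_W_A:
                flags["w_a"] = optimal_w_a
            try:
                res = _register_case(case, flags["w_a"], flags["E_deep"],
                                     flags["fix_chest"], config)
                h = hausdorff_directed(res.deformed_tumor,
                                       case.truth.supine_tumor_points)
                c = centroid_error(res.deformed_tumor,
                                   case.truth.supine_tumor_points)
            except Exception as exc:  # recorded as missing, run continues
                h = c = float("nan")
                rows.append({"case": case.case_id, "method": method,
                             "hausdorff": h, "centroid": c, "error": str(exc)})
                continue
            rows.append({"case": case.case_id, "method": method,
                         "hausdorff": h, "centroid": c, "error": None})
    return pd.DataFrame(rows)


# -- grid search with cross-validation -----------------------------------

@dataclass
class GridSpec:
    w_a_values: tuple = DEFAULT_W_A_GRID
    E_deep_values: tuple = DEFAULT_E_DEEP_GRID
    n_cases: int = 9
    train_size: int = 6
    folds: int = 3

    def __post_init__(self):
        if not self.w_a_values or not self.E_deep_values:
            raise ValueError("grid value lists must be nonempty")
        if self.train_size >= self.n_cases:
            raise ValueError("train_size must be < n_cases")


@dataclass
class GridSearchResult:
    error_table: pd.DataFrame  # columns: case, w_a, E_deep, centroid
    fold_best: list  # per fold: dict(w_a, E_deep, train_error)
    validation_errors: list  # per fold: array of held-out case errors
    mean_w_a: float = 0.0
    mean_E_deep: float = 0.0
    pooled_mean: float = 0.0
    pooled_sd: float = 0.0
    fold_assignments: list = field(default_factory=list)


def fold_split(n_cases: int, folds: int, seed: int = 0):
    """Deterministic round-robin fold assignment of case indices."""
    order = np.random.default_rng(seed).permutation(n_cases)
    return [sorted(int(c) for c in order[f::folds]) for f in range(folds)]


def build_error_table(cases: list, grid: GridSpec,
                      config: RegistrationConfig | None = None,
                      evaluate=None) -> pd.DataFrame:
    """Centroid error of every case at every grid pair.

    The default evaluator runs the full registration; the stiffness
    factorization and deformation bases are rebuilt only when E_deep
    changes (they do not depend on w_a), which collapses the grid cost
    from |w_a| x |E_deep| basis builds per case to |E_deep|.
    """
    config = config or RegistrationConfig()
    rows = []
    for case in cases:
        for E_deep in grid.E_deep_values:
            state = None
            if evaluate is None:
                materials = fem.assign_tissue_stiffness(case.mesh, E_deep=E_deep)
                sim = fem.SimulationConfig(E_deep=E_deep,
                                           gravity_vector=case.sim.gravity_vector,
                                           w_p=case.sim.w_p)
                state = prepare_model(case.mesh, materials, sim, config)
            for w_a in grid.w_a_values:
                if evaluate is not None:
                    err = float(evaluate(case, w_a, E_deep))
                else:
                    try:
                        res = _register_case(case, w_a, E_deep, False, config,
                                             state=state)
                        err = centroid_error(res.deformed_tumor,
                                             case.truth.supine_tumor_points)
                    except Exception:
                        err = float("nan")
                rows.append({"case": case.case_id, "w_a": w_a,
                             "E_deep": E_deep, "centroid": err})
    return pd.DataFrame(rows)


def select_best_pair(table: pd.DataFrame, case_ids) -> dict:
    """Grid pair minimizing the mean centroid error over the given cases.

    Ties break toward the earlier grid entry (stable sort order of the
    table), matching the exhaustive-scan oracle.
    """
    sub = table[table["case"].isin(list(case_ids))]
    means = sub.groupby(["w_a", "E_deep"], sort=False)["centroid"].mean()
    w_a, E_deep = means.index[int(np.argmin(means.to_numpy()))]
    return {"w_a": float(w_a), "E_deep": float(E_deep),
            "train_error": float(means.min())}


def grid_search_cv(cases: list, grid: GridSpec | None = None,
                   config: RegistrationConfig | None = None,
                   evaluate=None, seed: int = 0,
                   error_table: pd.DataFrame | None = None) -> GridSearchResult:
    """Exhaustive grid search with k-fold cross-validation.

    For each fold the best (w_a, E_deep) on the training cases is chosen
    by mean tumor centroid error and then scored on the held-out cases.
    Reports per-fold optima, validation errors, the arithmetic mean of the
    per-fold optimal parameters, and the pooled validation mean +/- sd.
    """
    grid = grid or GridSpec(n_cases=len(cases))
    if error_table is None:
        error_table = build_error_table(cases, grid, config, evaluate)
    ids = sorted({c.case_id for c in cases})
    folds = fold_split(len(ids), grid.folds, seed)
    fold_ids = [[ids[i] for i in f] for f in folds]

    fold_best, val_errors = [], []
    for f, val in enumerate(fold_ids):
        train = [c for c in ids if c not in val]
        best = select_best_pair(error_table, train)
        fold_best.append(best)
        sub = error_table[(error_table["case"].isin(val))
                          & (error_table["w_a"] == best["w_a"])
                          & (error_table["E_deep"] == best["E_deep"])]
        val_errors.append(sub["centroid"].to_numpy())
    pooled = np.concatenate(val_errors) if val_errors else np.array([])
    return GridSearchResult(
        error_table=error_table, fold_best=fold_best,
        validation_errors=val_errors,
        mean_w_a=float(np.mean([b["w_a"] for b in fold_best])),
        mean_E_deep=float(np.mean([b["E_deep"] for b in fold_best])),
        pooled_mean=float(np.nanmean(pooled)) if pooled.size else float("nan"),
        pooled_sd=float(np.nanstd(pooled, ddof=1)) if pooled.size > 1 else 0.0,
        fold_assignments=fold_ids)


# -- statistics ----------------------------------------------------------

def variance_f_test(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sided F-test for equality of variances of two samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vy == 0 and vx == 0:
        return {"F": 1.0, "p": 1.0}
    if vx >= vy:
        F, dfn, dfd = (vx / vy if vy > 0 else np.inf), len(x) - 1, len(y) - 1
    else:
        F, dfn, dfd = vy / vx, len(y) - 1, len(x) - 1
    p = 2.0 * min(stats.f.sf(F, dfn, dfd), 1.0 - stats.f.sf(F, dfn, dfd)) \
        if np.isfinite(F) else 0.0
    return {"F": float(F), "p": float(min(p, 1.0))}


def compare_methods(per_case_table: pd.DataFrame, value: str = "hausdorff",
                    alpha: float = 0.05) -> dict:
    """Friedman test plus pairwise Wilcoxon signed-rank with Bonferroni.

    Expects a long-format table with columns (case, method, <value>) of
    paired per-case results (>= 3 methods, >= 2 cases). Also reports
    pairwise variance F-tests as a homogeneity pre-check (reported, not
    gating). Exact zero-differences in Wilcoxon are dropped (the standard
    signed-rank convention); all-tied data short-circuits to Friedman
    p = 1 with no pairwise tests.
    """
    wide = per_case_table.pivot(index="case", columns="method", values=value)
    wide = wide.dropna()
    methods = list(wide.columns)
    if len(methods) < 3:
        raise ValueError("need >= 3 paired method columns")
    if len(wide) < 2:
        raise ValueError("need >= 2 complete cases")
    cols = [wide[m].to_numpy() for m in methods]

    report = {"methods": methods, "n_cases": int(len(wide)),
              "means": {m: float(wide[m].mean()) for m in methods},
              "sds": {m: float(wide[m].std(ddof=1)) for m in methods}}

    report["variance_f_tests"] = {
        f"{a} vs {b}": variance_f_test(wide[a], wide[b])
        for a, b in combinations(methods, 2)}

    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        report["friedman"] = {"statistic": 0.0, "p": 1.0}
        report["pairwise"] = {}
        report["significant"] = {}
        return report

    fr_stat, fr_p = stats.friedmanchisquare(*cols)
    report["friedman"] = {"statistic": float(fr_stat), "p": float(fr_p)}

    n_comp = len(methods) * (len(methods) - 1) // 2
    pairwise, signif = {}, {}
    for a, b in combinations(methods, 2):
        diff = wide[a].to_numpy() - wide[b].to_numpy()
        key = f"{a} vs {b}"
        if np.all(diff == 0):
            raw = 1.0
        else:
            raw = float(stats.wilcoxon(wide[a], wide[b], zero_method="wilcox").pvalue)
        adj = min(raw * n_comp, 1.0)
        pairwise[key] = {"p_raw": raw, "p_bonferroni": adj}
        signif[key] = bool(adj < alpha)
    report["pairwise"] = pairwise
    report["significant"] = signif
    return report


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """Bonferroni adjustment: multiply by the comparison count, cap at 1."""
    return min(float(p_raw) * int(n_comparisons), 1.0)
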