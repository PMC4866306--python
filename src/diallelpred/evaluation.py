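"""Experimental designs: parent-split cross-validation, close/distant
training scenarios, learning curves, replacement and cross-fitting
experiments, and calibration summaries.

The outer cross-validation splits each parental panel into two groups; the
four (row-group x column-group) blocks of the diallel are the folds.  For a
test block, the opposite block contains only *distant* relatives (no shared
parent with any test individual) and the two off-blocks contain the *close*
relatives (exactly one shared parent), which are downsampled to the distant
set's size for a fair comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from . import predictors as pred
from .relatedness import Grm, classify_pair, compute_grm
from .simulate import GenotypeMatrix, Pedigree, PhenotypeTable

__all__ = [
    "DiallelDataset",
    "CvPlan",
    "ScenarioResult",
    "build_cv_folds",
    "build_training_scenario",
    "fit_and_predict",
    "run_crossval",
    "learning_curve",
    "replacement_experiment",
    "cross_fit_experiment",
    "calibration_summary",
    "r2_score",
]

MODELS = ("P", "BLUP", "QTL", "LMM", "LMM+P", "MT-LMM", "midparent")

SCENARIOS = ("random", "close", "distant")


def r2_score(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on the given set.

    SS_tot uses the mean of ``y`` itself (the test set); the value can be
    negative for predictions worse than the test mean.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return float(1.0 - np.sum((y - yhat) ** 2) / sst)


@dataclass
class DiallelDataset:
    """Genotypes, pedigree and phenotypes with consistent individual ids."""

    genotypes: GenotypeMatrix
    pedigree: Pedigree
    phenotypes: PhenotypeTable

    def __post_init__(self) -> None:
        gids = set(self.genotypes.individuals)
        pids = set(self.pedigree.hybrid_id)
        if gids != pids:
            raise ValueError("genotype and pedigree individual ids differ")
        phen_ids = set(self.phenotypes.frame["hybrid_id"])
        if phen_ids and not phen_ids <= gids:
            raise ValueError("phenotype table contains unknown individuals")

    @cached_property
    def grm(self) -> Grm:
        return compute_grm(self.genotypes)

    @cached_property
    def means(self) -> pd.DataFrame:
        return self.phenotypes.means()

    @property
    def traits(self) -> list[str]:
        return self.phenotypes.traits


@dataclass(frozen=True)
class CvPlan:
    """Parent-split fourfold CV plan.

    Each panel's parents are split into two near-equal groups; fold ``f`` in
    1..4 is the block (row-group, column-group) = ((f-1)//2, (f-1)%2).
    """

    a_group: dict
    alpha_group: dict
    fold_of: dict
    seed: int

    @property
    def n_folds(self) -> int:
        return 4

    def fold_members(self, fold: int) -> list:
        return [h for h, f in self.fold_of.items() if f == fold]

    def block_of(self, fold: int) -> tuple[int, int]:
        if fold not in (1, 2, 3, 4):
            raise ValueError("fold must be in 1..4")
        return (fold - 1) // 2, (fold - 1) % 2


def build_cv_folds(ped: Pedigree, seed: int = 0) -> CvPlan:
    """Randomly split each parental panel into two groups; blocks are folds.

    Odd panel sizes split ceil(n/2) / floor(n/2) with seeded random
    assignment.
    """
    rng = np.random.default_rng(seed)
    pa = list(ped.parents_a)
    pb = list(ped.parents_alpha)
    if len(pa) < 2 or len(pb) < 2:
        raise ValueError("each parental panel needs at least two parents")

    def split(parents, r):
        perm = r.permutation(len(parents))
        half = math.ceil(len(parents) / 2)
        return {parents[i]: (0 if k < half else 1) for k, i in enumerate(perm)}

    ra, rb = rng.spawn(2)
    a_group = split(pa, ra)
    alpha_group = split(pb, rb)
    fold_of = {}
    for h, a, b in zip(ped.hybrid_id, ped.parent_a, ped.parent_alpha):
        fold_of[h] = 2 * a_group[a] + alpha_group[b] + 1
    return CvPlan(a_group=a_group, alpha_group=alpha_group, fold_of=fold_of,
                  seed=seed)


def build_training_scenario(
    plan: CvPlan,
    ped: Pedigree,
    test_fold: int,
    scenario: str = "random",
    seed: int = 0,
) -> list:
    """Training individuals for a test fold under a relatedness scenario.

    random: all non-test individuals.  distant: the opposite block (no
    shared parents with any test individual).  close: a uniform sample,
    matching the distant set's size, from the hybrids that share exactly one
    parent with at least one test individual (the two off-blocks).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    ga, gb = plan.block_of(test_fold)
    test = set(plan.fold_members(test_fold))
    if scenario == "random":
        return [h for h in ped.hybrid_id if h not in test]
    blocks: dict[tuple[int, int], list] = {}
    for h, a, b in zip(ped.hybrid_id, ped.parent_a, ped.parent_alpha):
        blocks.setdefault((plan.a_group[a], plan.alpha_group[b]), []).append(h)
    distant = blocks.get((1 - ga, 1 - gb), [])
    if scenario == "distant":
        return list(distant)
    close_pool = blocks.get((ga, 1 - gb), []) + blocks.get((1 - ga, gb), [])
    n = len(distant)
    if n > len(close_pool):
        raise ValueError("not enough close relatives to match the distant set size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(close_pool), size=n, replace=False)
    return [close_pool[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# model dispatch
# ---------------------------------------------------------------------------


def _default_opts(model_opts: dict | None) -> dict:
    opts = {"max_terms": 50, "interactions_max": 20, "inner_folds": 4}
    opts.update(model_opts or {})
    return opts


def fit_and_predict(
    model: str,
    ds: DiallelDataset,
    trait: str,
    train_ids,
    test_ids,
    seed: int = 0,
    model_opts: dict | None = None,
) -> pred.PredictiveDistribution:
    """Fit one model on the training individuals and predict the test ones."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    opts = _default_opts(model_opts)
    train_ids = list(train_ids)
    test_ids = list(test_ids)
    means = ds.means
    y_tr = means.loc[train_ids, trait].to_numpy()
    y_ids = np.asarray(test_ids, dtype=object)
    other = [t for t in means.columns if t != trait]

    if model == "P":
        P_tr = means.loc[train_ids, other].to_numpy()
        P_te = means.loc[test_ids, other].to_numpy()
        reg = pred.fit_phenotype_regression(P_tr, y_tr)
        mean = reg.predict(P_te)
        resid = y_tr - reg.predict(P_tr)
        dof = max(len(y_tr) - len(other) - 1, 1)
        sd = np.full(len(test_ids), float(np.sqrt(resid @ resid / dof)))
        return pred.PredictiveDistribution(ids=y_ids, mean=mean, sd=sd)

    if model == "midparent":
        mp = pred.fit_midparent(ds.pedigree, y_tr, train_ids)
        mean = pred.predict_midparent(mp, ds.pedigree, test_ids)
        resid_sd = float(np.std(y_tr - np.array(
            [mp.midparent(*ds.pedigree.parents_of(h)) for h in train_ids])))
        return pred.PredictiveDistribution(
            ids=y_ids, mean=mean, sd=np.full(len(test_ids), resid_sd))

    K = ds.grm
    X_tr = ds.genotypes.subset(train_ids).G.astype(np.float64)
    X_te = ds.genotypes.subset(test_ids).G.astype(np.float64)

    if model == "BLUP":
        lmm = pred.fit_lmm(None, K, y_tr, train_ids)
        return lmm.predict(K, None, test_ids, ids=y_ids)

    if model == "QTL":
        qtl = pred.fit_qtl_model(
            X_tr, y_tr, max_terms=opts["max_terms"], interactions=False,
            n_folds=opts["inner_folds"], seed=seed,
        )
        return qtl.predict(X_te, ids=y_ids)

    if model == "LMM":
        qtl = pred.fit_qtl_model(
            X_tr, y_tr, max_terms=opts["max_terms"], interactions=True,
            max_int_terms=opts["interactions_max"],
            n_folds=opts["inner_folds"], seed=seed,
        )
        lmm = pred.fit_lmm(qtl, K, y_tr, train_ids, X_train=X_tr)
        return lmm.predict(K, X_te, test_ids, ids=y_ids)

    if model == "LMM+P":
        P_tr = means.loc[train_ids, other].to_numpy()
        P_te = means.loc[test_ids, other].to_numpy()
        m = pred.fit_lmm_plus_p(
            P_tr, y_tr, K, train_ids, X_train=X_tr,
            qtl_kwargs={
                "max_terms": opts["max_terms"], "interactions": True,
                "max_int_terms": opts["interactions_max"],
                "n_folds": opts["inner_folds"], "seed": seed,
            },
        )
        return m.predict(K, P_te, X_te, test_ids, ids=y_ids)

    # MT-LMM: per-trait fixed effects as in the LMM, then joint Kronecker fit
    traits = list(means.columns)
    focal = traits.index(trait)
    Y_tr = means.loc[train_ids, traits].to_numpy()
    Y_te = means.loc[test_ids, traits].to_numpy()
    F_tr = np.zeros_like(Y_tr)
    F_te = np.zeros_like(Y_te)
    for k, t in enumerate(traits):
        qtl_t = pred.fit_qtl_model(
            X_tr, Y_tr[:, k], max_terms=opts["max_terms"], interactions=True,
            max_int_terms=opts["interactions_max"],
            n_folds=opts["inner_folds"], seed=seed,
        )
        F_tr[:, k] = qtl_t.predict_mean(X_tr)
        F_te[:, k] = qtl_t.predict_mean(X_te)
    mt = pred.fit_mtlmm(Y_tr, F_tr, K, train_ids, trait_names=traits)
    return pred.predict_mtlmm(mt, K, test_ids, focal, Y_te, F_te, ids=y_ids)


# ---------------------------------------------------------------------------
# cross-validation experiments
# ---------------------------------------------------------------------------


@dataclass
class ScenarioResult:
    """Predictions and per-fold metrics for one model x scenario run."""

    predictions: pd.DataFrame  # hybrid_id, trait, fold, scenario, model, y, pred, sd
    failures: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Per (trait, scenario, fold): R^2, n_train, mean pred SD, residual SD."""
        rows = []
        for (trait, scen, fold), g in self.predictions.groupby(
            ["trait", "scenario", "fold"], sort=False
        ):
            rows.append(
                {
                    "trait": trait,
                    "scenario": scen,
                    "fold": fold,
                    "model": g["model"].iloc[0],
                    "r2": r2_score(g["y"], g["pred"]),
                    "n_train": int(g["n_train"].iloc[0]),
                    "mean_pred_sd": float(np.sqrt(np.mean(g["sd"] ** 2))),
                    "resid_sd": float(np.std(g["y"] - g["pred"])),
                }
            )
        return pd.DataFrame(rows)

    def pooled_r2(self) -> pd.Series:
        """Per-trait R^2 over the pooled test predictions of all folds."""
        return self.predictions.groupby("trait", sort=False).apply(
            lambda g: r2_score(g["y"], g["pred"]), include_groups=False
        )


def run_crossval(
    ds: DiallelDataset,
    model: str,
    plan: CvPlan,
    scenario: str = "random",
    traits=None,
    seed: int = 0,
    model_opts: dict | None = None,
) -> ScenarioResult:
    """Fourfold outer CV of one model under one training scenario."""
    traits = list(traits) if traits is not None else ds.traits
    records = []
    failures = []
    for fold in range(1, 5):
        test_ids = plan.fold_members(fold)
        train_ids = build_training_scenario(
            plan, ds.pedigree, fold, scenario, seed=seed + 1000 * fold
        )
        for trait in traits:
            try:
                pd_out = fit_and_predict(
                    model, ds, trait, train_ids, test_ids,
                    seed=seed + fold, model_opts=model_opts,
                )
            except Exception as exc:  # noqa: BLE001 - fold marked failed
                failures.append({"fold": fold, "trait": trait, "error": str(exc)})
                continue
            y_te = ds.means.loc[test_ids, trait].to_numpy()
            records.append(
                pd.DataFrame(
                    {
                        "hybrid_id": test_ids,
                        "trait": trait,
                        "fold": fold,
                        "scenario": scenario,
                        "model": model,
                        "n_train": len(train_ids),
                        "y": y_te,
                        "pred": pd_out.mean,
                        "sd": pd_out.sd,
                    }
                )
            )
    if not records:
        raise RuntimeError(f"all folds failed: {failures}")
    return ScenarioResult(predictions=pd.concat(records, ignore_index=True),
                          failures=failures)


def learning_curve(
    ds: DiallelDataset,
    model: str,
    plan: CvPlan,
    trait: str,
    sizes,
    order: str = "close_first",
    seed: int = 0,
    model_opts: dict | None = None,
) -> pd.DataFrame:
    """R^2 versus training-set size, exhausting one relative class first.

    With ``order='close_first'`` the training set grows through shuffled
    close relatives, then appends distant ones (and vice versa); mirrors the
    crossover analysis of prediction accuracy against training size.
    """
    if order not in ("close_first", "distant_first"):
        raise ValueError("order must be 'close_first' or 'distant_first'")
    rng = np.random.default_rng(seed)
    rows = []
    for fold in range(1, 5):
        test_ids = plan.fold_members(fold)
        ga, gb = plan.block_of(fold)
        non_test = [h for h in ds.pedigree.hybrid_id if h not in set(test_ids)]
        distant = build_training_scenario(plan, ds.pedigree, fold, "distant")
        close_pool = [h for h in non_test if h not in set(distant)]
        r = np.random.default_rng(rng.integers(2**31))
        close_shuf = list(np.array(close_pool, dtype=object)[r.permutation(len(close_pool))])
        distant_shuf = list(np.array(distant, dtype=object)[r.permutation(len(distant))])
        first, second = (
            (close_shuf, distant_shuf) if order == "close_first"
            else (distant_shuf, close_shuf)
        )
        ordering = first + second
        y_te = ds.means.loc[test_ids, trait].to_numpy()
        for size in sizes:
            if size > len(ordering):
                raise ValueError(f"size {size} exceeds available individuals")
            if size == 0:
                mean = float(ds.means.loc[non_test, trait].mean())
                r2 = r2_score(y_te, np.full(len(test_ids), mean))
            else:
                train_ids = ordering[:size]
                out = fit_and_predict(model, ds, trait, train_ids, test_ids,
                                      seed=seed + fold, model_opts=model_opts)
                r2 = r2_score(y_te, out.mean)
            rows.append({"order": order, "size": size, "fold": fold, "r2": r2})
    return pd.DataFrame(rows)


def replacement_experiment(
    ds: DiallelDataset,
    model: str,
    plan: CvPlan,
    trait: str,
    fraction: float = 0.01,
    seed: int = 0,
    model_opts: dict | None = None,
) -> pd.DataFrame:
    """Swap a small fraction of distant training individuals for close ones.

    For each fold: train on the distant block, then on the same set with
    ceil(fraction * n) members replaced (without replacement) by close
    relatives of the test set; report in-sample and out-of-sample R^2 for
    both training sets.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for fold in range(1, 5):
        test_ids = plan.fold_members(fold)
        distant = build_training_scenario(plan, ds.pedigree, fold, "distant")
        non_test = [h for h in ds.pedigree.hybrid_id if h not in set(test_ids)]
        close_pool = [h for h in non_test if h not in set(distant)]
        k = math.ceil(fraction * len(distant))
        if k > len(close_pool):
            raise ValueError("not enough close relatives for the requested swap")
        r = np.random.default_rng(rng.integers(2**31))
        out_idx = r.choice(len(distant), size=k, replace=False)
        in_ids = [close_pool[i] for i in r.choice(len(close_pool), size=k,
                                                  replace=False)]
        swapped = [h for i, h in enumerate(distant) if i not in set(out_idx)] + in_ids
        y_te = ds.means.loc[test_ids, trait].to_numpy()
        for label, train_ids in (("before", distant), ("after", swapped)):
            out = fit_and_predict(model, ds, trait, train_ids, test_ids,
                                  seed=seed + fold, model_opts=model_opts)
            rows.append(
                {
                    "fold": fold,
                    "training": label,
                    "r2_out": r2_score(y_te, out.mean),
                    "r2_in": _in_sample_r2(ds, model, trait, train_ids,
                                           seed=seed + fold,
                                           model_opts=model_opts),
                }
            )
    return pd.DataFrame(rows)


def _in_sample_r2(ds, model, trait, train_ids, seed=0, model_opts=None) -> float:
    """In-sample R^2: fit on the training set, predict the same individuals.

    Models that condition on training data (BLUP/LMM) would reproduce the
    data exactly; for fixed-effect models (P, QTL, midparent) this measures
    the apparent in-sample fit, which is what overfitting inflates.
    """
    opts = _default_opts(model_opts)
    means = ds.means
    y = means.loc[list(train_ids), trait].to_numpy()
    if model == "QTL":
        X = ds.genotypes.subset(train_ids).G.astype(np.float64)
        qtl = pred.fit_qtl_model(X, y, max_terms=opts["max_terms"],
                                 interactions=False,
                                 n_folds=opts["inner_folds"], seed=seed)
        return r2_score(y, qtl.predict_mean(X))
    if model == "P":
        other = [t for t in means.columns if t != trait]
        P = means.loc[list(train_ids), other].to_numpy()
        reg = pred.fit_phenotype_regression(P, y)
        return r2_score(y, reg.predict(P))
    if model == "midparent":
        mp = pred.fit_midparent(ds.pedigree, y, list(train_ids))
        yhat = pred.predict_midparent(mp, ds.pedigree, list(train_ids))
        return r2_score(y, yhat)
    return float("nan")


def cross_fit_experiment(
    ds: DiallelDataset,
    plan: CvPlan,
    trait: str,
    seed: int = 0,
    model_opts: dict | None = None,
) -> pd.DataFrame:
    """Decouple QTL mapping (term selection) from weight estimation.

    For every fold, QTL terms are selected on set A (close or distant) and
    their weights refit by OLS (fixed term set) on set B; all four
    (map, weights) combinations are evaluated on the test fold.
    """
    opts = _default_opts(model_opts)
    rows = []
    for fold in range(1, 5):
        test_ids = plan.fold_members(fold)
        sets = {
            "distant": build_training_scenario(plan, ds.pedigree, fold, "distant"),
            "close": build_training_scenario(plan, ds.pedigree, fold, "close",
                                             seed=seed + 1000 * fold),
        }
        y_te = ds.means.loc[test_ids, trait].to_numpy()
        X_te = ds.genotypes.subset(test_ids).G.astype(np.float64)
        qtls = {}
        for name, ids in sets.items():
            X = ds.genotypes.subset(ids).G.astype(np.float64)
            y = ds.means.loc[ids, trait].to_numpy()
            qtls[name] = pred.fit_qtl_model(
                X, y, max_terms=opts["max_terms"], interactions=False,
                n_folds=opts["inner_folds"], seed=seed + fold,
            )
        for map_set in ("close", "distant"):
            for w_set in ("close", "distant"):
                terms = qtls[map_set].terms
                ids = sets[w_set]
                X = ds.genotypes.subset(ids).G.astype(np.float64)
                y = ds.means.loc[ids, trait].to_numpy()
                D = np.column_stack(
                    [np.ones(len(y)), pred.design_from_terms(X, terms)]
                )
                coef, *_ = np.linalg.lstsq(D, y, rcond=None)
                D_te = np.column_stack(
                    [np.ones(len(y_te)), pred.design_from_terms(X_te, terms)]
                )
                rows.append(
                    {
                        "fold": fold,
                        "map": map_set,
                        "weights": w_set,
                        "r2": r2_score(y_te, D_te @ coef),
                    }
                )
    return pd.DataFrame(rows)


def calibration_summary(predictions: pd.DataFrame) -> dict:
    """Pair model-derived predictive SD with realized residual SD.

    Groups predictions by (trait, scenario); each point is (mean predictive
    SD, residual SD).  Returns the points plus the slope of the regression of
    residual variance on predictive variance (through the origin-free OLS)
    and the squared correlation across points.
    """
    required = {"trait", "scenario", "y", "pred", "sd"}
    if not required <= set(predictions.columns):
        raise ValueError(f"predictions must have columns {sorted(required)}")
    rows = []
    for (trait, scen), g in predictions.groupby(["trait", "scenario"], sort=False):
        rows.append(
            {
                "trait": trait,
                "scenario": scen,
                "pred_sd": float(np.sqrt(np.mean(g["sd"] ** 2))),
                "resid_sd": float(np.std(g["y"] - g["pred"])),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("need at least 3 (trait, scenario) points for calibration")
    x = table["pred_sd"] ** 2
    yv = table["resid_sd"] ** 2
    if np.var(x) == 0:
        raise ValueError("predictive SDs are all equal; calibration undefined")
    slope = float(np.cov(x, yv, ddof=0)[0, 1] / np.var(x))
    r = float(np.corrcoef(table["pred_sd"], table["resid_sd"])[0, 1])
    return {"table": table, "slope": slope, "r2": r**2}
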