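"""Prediction models for diallel trait data.

Implements the model zoo used to predict a focal trait from genome and/or
phenome information:

* phenotype regression (``P``): OLS of the focal trait on the other traits;
* genomic BLUP: multivariate-normal conditioning under
  y ~ N(mu 1, sigma_g^2 K + sigma_e^2 I) with K the realized relatedness
  matrix, variance components fit by maximum likelihood;
* forward-selection QTL models with inner cross-validated size selection
  (double cross-validation when used inside an outer CV);
* LMM: QTL + dominance + epistasis fixed effects plus a polygenic random
  effect on the residuals;
* LMM+P: phenotype regression first, LMM on its residuals;
* midparent: additive two-way parental-value model;
* multi-trait LMM with Kronecker covariance C (x) K + Sigma (x) I.

Also provides narrow-sense heritability (from the BLUP fit) and
repeatability estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .relatedness import Grm
from .simulate import Pedigree, PhenotypeTable

__all__ = [
    "VarianceComponents",
    "PredictiveDistribution",
    "QtlModel",
    "MidparentModel",
    "MultiTraitModel",
    "PhenotypeRegression",
    "LmmModel",
    "fit_phenotype_regression",
    "fit_variance_components",
    "blup_predict",
    "estimate_repeatability",
    "forward_select_terms",
    "select_model_size",
    "expand_interaction_candidates",
    "term_column",
    "design_from_terms",
    "fit_qtl_model",
    "fit_lmm",
    "fit_lmm_plus_p",
    "fit_midparent",
    "predict_midparent",
    "fit_mtlmm",
    "predict_mtlmm",
]

_JITTER = 1e-8


def _chol_factor(S: np.ndarray):
    """Cholesky factor of a covariance block; jitters only if needed."""
    try:
        return linalg.cho_factor(S, lower=True)
    except linalg.LinAlgError:
        jitter = _JITTER * max(float(np.mean(np.diag(S))), 1.0)
        try:
            return linalg.cho_factor(S + jitter * np.eye(len(S)), lower=True)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                "covariance block is singular even after jitter") from exc


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceComponents:
    """ML variance components of y ~ N(mu 1, sigma_g2 K + sigma_e2 I)."""

    sigma_g2: float
    sigma_e2: float
    mu: float
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return 0.0 if tot == 0 else self.sigma_g2 / tot


@dataclass(frozen=True)
class PredictiveDistribution:
    """Per-individual predictive mean and standard deviation for one trait."""

    ids: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=object))
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=np.float64))
        if not (len(self.ids) == len(self.mean) == len(self.sd)):
            raise ValueError("ids, mean and sd must have equal length")
        if np.any(self.sd < -1e-12):
            raise ValueError("predictive sd must be non-negative")

    @property
    def mean_sd(self) -> float:
        """sqrt of the average predictive variance (summary of uncertainty)."""
        return float(np.sqrt(np.mean(self.sd**2)))


# ---------------------------------------------------------------------------
# phenotype regression ('P')
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeRegression:
    weights: np.ndarray
    intercept: float

    def predict(self, P: np.ndarray) -> np.ndarray:
        P = np.asarray(P, dtype=np.float64)
        return self.intercept + P @ self.weights


def fit_phenotype_regression(P_train: np.ndarray, y_train: np.ndarray) -> PhenotypeRegression:
    """OLS of the focal trait on the other traits (plus intercept).

    Rank-deficient designs are solved by the minimum-norm solution.
    """
    P = np.atleast_2d(np.asarray(P_train, dtype=np.float64))
    y = np.asarray(y_train, dtype=np.float64)
    if P.shape[0] != len(y):
        raise ValueError("P_train rows must match len(y_train)")
    if np.isnan(P).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported (no imputation)")
    D = np.column_stack([np.ones(len(y)), P])
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank < D.shape[1]:
        warnings.warn("rank-deficient covariate matrix; minimum-norm solution used")
    return PhenotypeRegression(weights=coef[1:], intercept=float(coef[0]))


# ---------------------------------------------------------------------------
# variance components and BLUP
# ---------------------------------------------------------------------------


def _as_kernel(K) -> np.ndarray:
    return K.K if isinstance(K, Grm) else np.asarray(K, dtype=np.float64)


def fit_variance_components(
    K,
    y: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    ratio_bounds: tuple[float, float] = (1e-6, 1e6),
    tol: float = 1e-8,
) -> VarianceComponents:
    """Maximum-likelihood fit of y ~ N(mu 1, sigma_g2 K + sigma_e2 I).

    The likelihood is profiled: after an eigendecomposition K = U S U^T only
    the variance ratio delta = sigma_e2 / sigma_g2 needs a 1-D search (Brent
    over log delta); mu and the overall scale have closed forms at each delta.
    """
    Km = _as_kernel(K)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if Km.shape != (n, n):
        raise ValueError("K shape must match len(y)")
    if np.var(y) < 1e-14:
        warnings.warn("constant phenotype; returning sigma_g2 = 0")
        return VarianceComponents(0.0, float(np.var(y)), float(np.mean(y)))
    if eig is None:
        s, U = linalg.eigh(Km)
    else:
        s, U = eig
    if s[0] < -1e-6 * max(s[-1], 1.0):
        raise ValueError("K is not positive semi-definite")
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    ot = U.T @ np.ones(n)

    def profile(log_delta: float) -> tuple[float, float, float]:
        delta = np.exp(log_delta)
        w = 1.0 / (s + delta)
        mu = float(np.sum(w * ot * yt) / np.sum(w * ot * ot))
        r = yt - mu * ot
        sigma_g2 = float(np.sum(w * r * r) / n)
        ll = -0.5 * (
            n * np.log(2 * np.pi * sigma_g2) + np.sum(np.log(s + delta)) + n
        )
        return ll, mu, sigma_g2

    lo, hi = np.log(ratio_bounds[0]), np.log(ratio_bounds[1])
    res = optimize.minimize_scalar(
        lambda ld: -profile(ld)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    ll, mu, sigma_g2 = profile(res.x)
    delta = float(np.exp(res.x))
    return VarianceComponents(sigma_g2, sigma_g2 * delta, mu, loglik=ll)


def _resolve_indices(K, ids) -> np.ndarray:
    if isinstance(K, Grm):
        return np.array([K.index_of(h) for h in ids], dtype=np.intp)
    return np.asarray(ids, dtype=np.intp)


def blup_predict(
    K,
    y_train: np.ndarray,
    train_ids,
    test_ids,
    vc: VarianceComponents,
    include_residual: bool = True,
) -> PredictiveDistribution:
    """Conditional mean/variance of test individuals under the BLUP model.

    The joint distribution of measured phenotypes is
    N(mu 1, sigma_g2 K + sigma_e2 I); the predictive distribution of a test
    phenotype is obtained by conditioning on the training phenotypes.  With
    ``include_residual`` the predictive variance covers a *measured* test
    phenotype (genetic conditional variance + sigma_e2); without it, only the
    genetic value's uncertainty.
    """
    Km = _as_kernel(K)
    ti = _resolve_indices(K, train_ids)
    si = _resolve_indices(K, test_ids)
    if np.intersect1d(ti, si).size:
        raise ValueError("train and test sets must be disjoint")
    y = np.asarray(y_train, dtype=np.float64)
    if len(y) != len(ti):
        raise ValueError("y_train length must match train_ids")

    sg, se, mu = vc.sigma_g2, vc.sigma_e2, vc.mu
    S_tt = sg * Km[np.ix_(ti, ti)] + se * np.eye(len(ti))
    S_st = sg * Km[np.ix_(si, ti)]
    var_marg = sg * np.diag(Km)[si] + (se if include_residual else 0.0)

    cf = _chol_factor(S_tt)
    alpha = linalg.cho_solve(cf, y - mu)
    mean = mu + S_st @ alpha
    V = S_st @ linalg.cho_solve(cf, S_st.T)
    cond_var = np.clip(var_marg - np.diag(V), 0.0, None)
    ids = test_ids if isinstance(K, Grm) else np.asarray(test_ids)
    return PredictiveDistribution(ids=np.asarray(ids, dtype=object),
                                  mean=mean, sd=np.sqrt(cond_var))


def estimate_repeatability(pheno: PhenotypeTable, trait: str) -> tuple[float, float]:
    """Repeatability (H2_mean, H2_single) from replicate measurements.

    Fits r_ij = y_i + eps_ij with y_i the individual replicate mean; the
    residual variance sigma^2 (population denominator) gives
    H2_single = 1 - sigma^2 / Var(r).  H2_mean is the repeatability of the
    n_rep-average: (Var(r) - sigma^2) / ((Var(r) - sigma^2) + sigma^2/n_rep).
    """
    R = pheno.replicates(trait)
    if R.isna().any().any():
        raise ValueError("incomplete replicate table")
    n_rep = R.shape[1]
    if n_rep < 2:
        raise ValueError("repeatability requires >= 2 replicates per individual")
    vals = R.to_numpy(dtype=float)
    resid = vals - vals.mean(axis=1, keepdims=True)
    sigma2 = float(np.mean(resid**2))
    var_r = float(np.var(vals))
    if var_r == 0:
        return 1.0, 1.0
    h2_single = 1.0 - sigma2 / var_r
    sigma_b2 = max(var_r - sigma2, 0.0)
    denom = sigma_b2 + sigma2 / n_rep
    h2_mean = 1.0 if denom == 0 else sigma_b2 / denom
    return h2_mean, h2_single


# ---------------------------------------------------------------------------
# forward-selection QTL models
# ---------------------------------------------------------------------------


def term_column(X: np.ndarray, term: tuple) -> np.ndarray:
    """Design column for a term: ('add', j) -> dosage; ('int', i, j) -> product.

    A self-pair ('int', j, j) is the squared dosage column, which (together
    with the linear column) spans the heterozygote indicator, i.e. dominance.
    """
    if term[0] == "add":
        return X[:, term[1]].astype(np.float64)
    if term[0] == "int":
        return (X[:, term[1]] * X[:, term[2]]).astype(np.float64)
    raise ValueError(f"unknown term kind: {term[0]!r}")


def design_from_terms(X: np.ndarray, terms) -> np.ndarray:
    if not terms:
        return np.empty((X.shape[0], 0))
    return np.column_stack([term_column(X, t) for t in terms])


@dataclass
class ForwardPath:
    terms: list
    rss: list  # residual sum of squares after each step


def _forward_select(C: np.ndarray, y: np.ndarray, max_terms: int,
                    base: np.ndarray | None = None) -> tuple[list[int], list[float]]:
    """Greedy RSS-minimizing forward selection over the columns of C.

    ``base`` columns (plus an intercept) are always in the model.  Uses
    incremental orthogonalization: each step scores every candidate by the
    squared projection of the current residual on the candidate's component
    orthogonal to the selected design, which equals its RSS reduction.
    """
    n, m = C.shape
    y = np.asarray(y, dtype=np.float64)
    Q = np.ones((n, 1)) / np.sqrt(n)
    if base is not None and base.shape[1]:
        for k in range(base.shape[1]):
            c = base[:, k] - Q @ (Q.T @ base[:, k])
            nrm = np.linalg.norm(c)
            if nrm > 1e-10 * np.sqrt(n):
                Q = np.column_stack([Q, c / nrm])
    r = y - Q @ (Q.T @ y)
    Cp = C - Q @ (Q.T @ C)
    chosen: list[int] = []
    rss: list[float] = []
    current = float(r @ r)
    for _ in range(min(max_terms, m)):
        den = np.einsum("ij,ij->j", Cp, Cp)
        num = Cp.T @ r
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(den > 1e-10, num**2 / den, -np.inf)
        score[chosen] = -np.inf
        best = int(np.argmax(score))
        if not np.isfinite(score[best]) or score[best] <= 1e-12 * max(current, 1e-300):
            break
        q = Cp[:, best] / np.sqrt(den[best])
        r = r - q * (q @ r)
        Cp = Cp - np.outer(q, q @ Cp)
        current = max(current - float(score[best]), 0.0)
        chosen.append(best)
        rss.append(current)
    return chosen, rss


def forward_select_terms(D: dict, y: np.ndarray, max_terms: int,
                         candidates=None) -> ForwardPath:
    """Greedy forward selection minimizing OLS residual sum of squares.

    ``D`` maps term labels to design columns; ``candidates`` restricts (and
    orders) the labels considered.  Ties and floating-point near-ties resolve
    to the earliest candidate.
    """
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    labels = list(candidates) if candidates is not None else list(D)
    if not labels:
        raise ValueError("no candidate terms")
    C = np.column_stack([np.asarray(D[t], dtype=np.float64) for t in labels])
    idx, rss = _forward_select(C, np.asarray(y, dtype=np.float64), max_terms)
    return ForwardPath(terms=[labels[i] for i in idx], rss=rss)


def _cv_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=np.intp)
    for f in range(n_folds):
        assign[perm[f::n_folds]] = f
    return assign


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = np.sum((y - np.mean(y)) ** 2)
    if sst == 0:
        return float("nan")
    return float(1.0 - np.sum((y - yhat) ** 2) / sst)


def select_model_size(
    C: np.ndarray,
    y: np.ndarray,
    n_folds: int = 4,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose the number of leading columns of a forward path by inner CV.

    ``C`` holds the path's design columns in selection order.  For every size
    t in 0..T the inner-CV mean out-of-fold R^2 of the OLS model with the
    first t columns (plus intercept) is computed; returns (best_t, curve)
    with the smallest t on ties.  Size 0 is the intercept-only (empty) model,
    so the chosen size never scores below the empty model.
    """
    y = np.asarray(y, dtype=np.float64)
    n, T = C.shape
    if n_folds > n:
        raise ValueError("more folds than training observations")
    rng = np.random.default_rng(seed)
    assign = _cv_folds(n, n_folds, rng)
    curve = np.zeros(T + 1)
    scores = np.zeros((n_folds, T + 1))
    for f in range(n_folds):
        tr, te = assign != f, assign == f
        ytr, yte = y[tr], y[te]
        scores[f, 0] = _r2(yte, np.full(te.sum(), ytr.mean()))
        for t in range(1, T + 1):
            D = np.column_stack([np.ones(tr.sum()), C[tr, :t]])
            coef, *_ = np.linalg.lstsq(D, ytr, rcond=None)
            pred = np.column_stack([np.ones(te.sum()), C[te, :t]]) @ coef
            scores[f, t] = _r2(yte, pred)
    curve = np.nanmean(scores, axis=0)
    best = int(np.argmax(np.round(curve, 12)))
    return best, curve


def expand_interaction_candidates(selected_sites, n_sites: int) -> list[tuple]:
    """All pair terms (i, j) with i previously selected and j any site.

    Pairs are canonicalized as (min, max); self-pairs (i, i) give squared
    dosage columns and thereby dominance.
    """
    selected = list(dict.fromkeys(selected_sites))
    if not selected:
        raise ValueError("need at least one selected additive site")
    seen = set()
    out = []
    for i in selected:
        for j in range(n_sites):
            a, b = (i, j) if i <= j else (j, i)
            if (a, b) not in seen:
                seen.add((a, b))
                out.append(("int", a, b))
    return out


@dataclass
class QtlModel:
    """Sparse linear model over selected genomic terms."""

    terms: list
    beta: np.ndarray
    intercept: float
    sigma2: float  # residual variance estimate on training data
    xtx_inv: np.ndarray  # (1+k) x (1+k), for OLS predictive variance
    cv_curve: np.ndarray = field(default_factory=lambda: np.zeros(1))
    path: list = field(default_factory=list)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        D = design_from_terms(X, self.terms)
        return self.intercept + (D @ self.beta if self.n_terms else 0.0)

    def predict(self, X: np.ndarray, ids=None) -> PredictiveDistribution:
        D = np.column_stack([np.ones(X.shape[0]), design_from_terms(X, self.terms)])
        mean = D @ np.concatenate([[self.intercept], self.beta])
        lev = np.einsum("ij,jk,ik->i", D, self.xtx_inv, D)
        sd = np.sqrt(self.sigma2 * (1.0 + np.clip(lev, 0.0, None)))
        if ids is None:
            ids = np.arange(X.shape[0])
        return PredictiveDistribution(ids=np.asarray(ids, dtype=object),
                                      mean=mean, sd=sd)


def _refit_ols(X: np.ndarray, y: np.ndarray, terms, cv_curve, path) -> QtlModel:
    D = np.column_stack([np.ones(X.shape[0]), design_from_terms(X, terms)])
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    dof = max(len(y) - rank, 1)
    sigma2 = float(resid @ resid / dof)
    xtx_inv = np.linalg.pinv(D.T @ D)
    return QtlModel(
        terms=list(terms), beta=coef[1:], intercept=float(coef[0]),
        sigma2=sigma2, xtx_inv=xtx_inv, cv_curve=np.asarray(cv_curve),
        path=list(path),
    )


def fit_qtl_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    max_terms: int = 50,
    interactions: bool = False,
    max_int_terms: int = 20,
    n_folds: int = 4,
    seed: int = 0,
) -> QtlModel:
    """Forward-selection QTL model with inner-CV size selection.

    Stage 1 selects up to ``max_terms`` additive sites by greedy RSS
    reduction and sizes the model by ``n_folds``-fold CV on the training
    data.  With ``interactions``, pair terms between every selected site and
    every site (including self-pairs, i.e. dominance) are appended by
    continued forward selection and the concatenated path is re-sized by
    inner CV.
    """
    X = np.asarray(X_train, dtype=np.float64)
    y = np.asarray(y_train, dtype=np.float64)
    n, M = X.shape
    add_idx, _ = _forward_select(X, y, max_terms)
    path = [("add", j) for j in add_idx]
    C = design_from_terms(X, path)
    t1, curve = select_model_size(C, y, n_folds=n_folds, seed=seed)
    terms = path[:t1]
    if interactions and terms:
        cand = expand_interaction_candidates([t[1] for t in terms], M)
        C_base = design_from_terms(X, terms)
        C_cand = design_from_terms(X, cand)
        idx2, _ = _forward_select(C_cand, y, max_int_terms, base=C_base)
        full_path = terms + [cand[i] for i in idx2]
        C_full = design_from_terms(X, full_path)
        t2, curve = select_model_size(C_full, y, n_folds=n_folds, seed=seed)
        terms = full_path[:t2]
        path = full_path
    return _refit_ols(X, y, terms, curve, path)


# ---------------------------------------------------------------------------
# LMM and LMM+P
# ---------------------------------------------------------------------------


@dataclass
class LmmModel:
    """Fixed genomic effects plus a polygenic random effect on the residual."""

    qtl: QtlModel | None
    vc: VarianceComponents
    train_idx: np.ndarray
    resid_train: np.ndarray

    def predict(self, K, X_test: np.ndarray | None, test_idx,
                ids=None) -> PredictiveDistribution:
        gen = blup_predict(K, self.resid_train, self.train_idx, test_idx, self.vc)
        fixed = 0.0
        if self.qtl is not None and X_test is not None:
            fixed = self.qtl.predict_mean(X_test)
        ids = gen.ids if ids is None else np.asarray(ids, dtype=object)
        return PredictiveDistribution(ids=ids, mean=fixed + gen.mean, sd=gen.sd)


def fit_lmm(
    qtl: QtlModel | None,
    K,
    y_train: np.ndarray,
    train_idx,
    X_train: np.ndarray | None = None,
    eig: tuple | None = None,
) -> LmmModel:
    """Combine fixed genomic effects with a polygenic random effect.

    The fixed-effect design (a fitted :class:`QtlModel`, built on training
    data only) is subtracted from y and the variance components of the
    residual are re-fit against the training block of K; prediction adds the
    fixed-effect mean to the BLUP conditional mean of the residual.  With
    ``qtl=None`` this reduces exactly to genomic BLUP.
    """
    y = np.asarray(y_train, dtype=np.float64)
    ti = _resolve_indices(K, train_idx)
    resid = y - (qtl.predict_mean(X_train) if qtl is not None else 0.0)
    Km = _as_kernel(K)
    vc = fit_variance_components(Km[np.ix_(ti, ti)], resid, eig=eig)
    return LmmModel(qtl=qtl, vc=vc, train_idx=np.asarray(train_idx, dtype=object)
                    if isinstance(K, Grm) else ti, resid_train=resid)


@dataclass
class LmmPlusP:
    """Two-stage model: phenotype regression, then LMM on its residuals."""

    stage1: PhenotypeRegression
    stage2: LmmModel

    def predict(self, K, P_test: np.ndarray, X_test: np.ndarray | None,
                test_idx, ids=None) -> PredictiveDistribution:
        P_test = np.asarray(P_test, dtype=np.float64)
        if np.isnan(P_test).any():
            raise ValueError("missing covariate traits for a test individual")
        p1 = self.stage1.predict(P_test)
        g = self.stage2.predict(K, X_test, test_idx, ids=ids)
        return PredictiveDistribution(ids=g.ids, mean=p1 + g.mean, sd=g.sd)


def fit_lmm_plus_p(
    P_train: np.ndarray,
    y_train: np.ndarray,
    K,
    train_idx,
    X_train: np.ndarray | None = None,
    qtl_kwargs: dict | None = None,
    eig: tuple | None = None,
) -> LmmPlusP:
    """LMM+P: regress y on the other traits, then fit the genomic LMM on the
    stage-1 residuals (QTL fixed effects re-selected on those residuals)."""
    stage1 = fit_phenotype_regression(P_train, y_train)
    resid = np.asarray(y_train, dtype=np.float64) - stage1.predict(P_train)
    qtl = None
    if X_train is not None:
        qtl = fit_qtl_model(X_train, resid, **(qtl_kwargs or {}))
    stage2 = fit_lmm(qtl, K, resid, train_idx, X_train=X_train, eig=eig)
    return LmmPlusP(stage1=stage1, stage2=stage2)


# ---------------------------------------------------------------------------
# midparent
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MidparentModel:
    """Fitted parental values; prediction for hybrid (i, j) is their average."""

    values_a: dict
    values_alpha: dict

    def midparent(self, parent_a: str, parent_alpha: str) -> float:
        if parent_a not in self.values_a or parent_alpha not in self.values_alpha:
            return float("nan")
        return 0.5 * (self.values_a[parent_a] + self.values_alpha[parent_alpha])


def fit_midparent(ped: Pedigree, y_train: np.ndarray, train_ids) -> MidparentModel:
    """Least-squares parental values from the additive two-way layout.

    y_ij = (P_i^1 + P_j^2) / 2 + noise; the layout is rank-deficient by the
    usual additive shift, resolved by the minimum-norm solution (predictions
    are invariant to it).
    """
    train_ids = list(train_ids)
    y = np.asarray(y_train, dtype=np.float64)
    if len(y) != len(train_ids):
        raise ValueError("y_train length must match train_ids")
    pa = [ped.parents_of(h)[0] for h in train_ids]
    pb = [ped.parents_of(h)[1] for h in train_ids]
    ua = list(dict.fromkeys(pa))
    ub = list(dict.fromkeys(pb))
    ia = {p: k for k, p in enumerate(ua)}
    ib = {p: k for k, p in enumerate(ub)}
    D = np.zeros((len(y), len(ua) + len(ub)))
    for r, (a, b) in enumerate(zip(pa, pb)):
        D[r, ia[a]] = 0.5
        D[r, len(ua) + ib[b]] = 0.5
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    return MidparentModel(
        values_a={p: float(coef[ia[p]]) for p in ua},
        values_alpha={p: float(coef[len(ua) + ib[p]]) for p in ub},
    )


def predict_midparent(model: MidparentModel, ped: Pedigree, test_ids) -> np.ndarray:
    """Midparent predictions; NaN where a parent was unseen in training."""
    preds = []
    for h in test_ids:
        a, b = ped.parents_of(h)
        preds.append(model.midparent(a, b))
    out = np.array(preds, dtype=np.float64)
    if np.isnan(out).any():
        warnings.warn(f"{int(np.isnan(out).sum())} test hybrids have unseen parents")
    return out


# ---------------------------------------------------------------------------
# multi-trait LMM
# ---------------------------------------------------------------------------


def _nearest_psd(A: np.ndarray) -> np.ndarray:
    A = (A + A.T) / 2
    w, V = linalg.eigh(A)
    return (V * np.clip(w, 0.0, None)) @ V.T


def _chol_params(A: np.ndarray) -> np.ndarray:
    """Flatten a PSD matrix into free Cholesky parameters (log diagonal)."""
    T = A.shape[0]
    L = linalg.cholesky(A + 1e-6 * np.mean(np.diag(A)) * np.eye(T), lower=True)
    out = []
    for i in range(T):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(out)


def _params_chol(p: np.ndarray, T: int) -> np.ndarray:
    L = np.zeros((T, T))
    k = 0
    for i in range(T):
        for j in range(i + 1):
            L[i, j] = np.exp(p[k]) if i == j else p[k]
            k += 1
    return L


@dataclass
class MultiTraitModel:
    """Kronecker-covariance multi-trait LMM: cov = C (x) K + Sigma (x) I."""

    trait_names: list
    C: np.ndarray
    Sigma: np.ndarray
    mu: np.ndarray  # per-trait residual mean
    train_idx: np.ndarray
    R_train: np.ndarray  # training residuals (Y - F), N x T
    loglik: float


def _mt_negloglik(p: np.ndarray, T: int, s: np.ndarray, Rt: np.ndarray) -> float:
    half = T * (T + 1) // 2
    Lc = _params_chol(p[:half], T)
    Ls = _params_chol(p[half:], T)
    C = Lc @ Lc.T
    Sig = Ls @ Ls.T
    # batched over the rotated rows: row i has covariance s_i C + Sigma
    V = s[:, None, None] * C + Sig + 1e-10 * np.eye(T)
    try:
        Lb = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * np.sum(np.log(np.diagonal(Lb, axis1=1, axis2=2)))
    z = np.linalg.solve(Lb, Rt[:, :, None])[:, :, 0]
    return float(0.5 * (logdet + np.sum(z * z)))


def fit_mtlmm(
    Y: np.ndarray,
    F: np.ndarray,
    K,
    train_idx,
    trait_names=None,
    maxiter: int = 300,
) -> MultiTraitModel:
    """ML fit of the multi-trait LMM on training individuals.

    ``Y`` and ``F`` are individuals x traits matrices of phenotypes and
    fixed-effect predictions (the per-trait QTL models' means).  The residual
    R = Y - F is modelled as matrix-normal with row covariance
    sigma-structure K (genetic) + I (noise) and trait covariances C and
    Sigma; vec(R) ~ N(0, C (x) K + Sigma (x) I).  C and Sigma are
    parameterized by Cholesky factors and optimized by quasi-Newton search,
    initialized from single-trait variance-component fits and empirical
    residual correlations.
    """
    Y = np.asarray(Y, dtype=np.float64)
    F = np.asarray(F, dtype=np.float64)
    if Y.shape != F.shape:
        raise ValueError("Y and F must have the same shape")
    N, T = Y.shape
    if T > 12:
        raise ValueError("dense Kronecker covariance supports at most ~12 traits")
    Km = _as_kernel(K)
    ti = _resolve_indices(K, train_idx)
    Ktt = Km[np.ix_(ti, ti)]
    R = Y - F
    mu = R.mean(axis=0)
    R0 = R - mu
    s, U = linalg.eigh(Ktt)
    s = np.clip(s, 0.0, None)
    Rt = U.T @ R0

    # initialization from single-trait fits and residual correlations
    sg = np.empty(T)
    se = np.empty(T)
    for t in range(T):
        vc = fit_variance_components(Ktt, R0[:, t], eig=(s, U))
        sg[t] = max(vc.sigma_g2, 1e-4 * np.var(R0[:, t]) + 1e-12)
        se[t] = max(vc.sigma_e2, 1e-4 * np.var(R0[:, t]) + 1e-12)
    corr = np.corrcoef(R0, rowvar=False) if T > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    C0 = _nearest_psd(0.5 * corr * np.sqrt(np.outer(sg, sg)) + 0.5 * np.diag(sg))
    S0 = _nearest_psd(0.5 * corr * np.sqrt(np.outer(se, se)) + 0.5 * np.diag(se))
    p0 = np.concatenate([_chol_params(C0), _chol_params(S0)])

    res = optimize.minimize(
        _mt_negloglik, p0, args=(T, s, Rt), method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-10},
    )
    half = T * (T + 1) // 2
    Lc = _params_chol(res.x[:half], T)
    Ls = _params_chol(res.x[half:], T)
    names = list(trait_names) if trait_names is not None else [f"t{k}" for k in range(T)]
    return MultiTraitModel(
        trait_names=names, C=Lc @ Lc.T, Sigma=Ls @ Ls.T, mu=mu,
        train_idx=np.asarray(train_idx, dtype=object) if isinstance(K, Grm) else ti,
        R_train=R0, loglik=-float(res.fun),
    )


def predict_mtlmm(
    model: MultiTraitModel,
    K,
    test_idx,
    focal_trait: int,
    Y_test_other: np.ndarray,
    F_test: np.ndarray,
    ids=None,
) -> PredictiveDistribution:
    """Predict the focal trait of test individuals from the joint MVN.

    Conditions on all training phenotypes (all traits) *and* the test
    individuals' other observed traits.  ``Y_test_other`` is a test x traits
    matrix whose focal column is ignored; ``F_test`` holds the fixed-effect
    predictions for the test individuals (all traits).
    """
    Km = _as_kernel(K)
    ti = _resolve_indices(K, model.train_idx)
    si = _resolve_indices(K, test_idx)
    T = len(model.trait_names)
    n_tr, n_te = len(ti), len(si)
    comb = np.concatenate([ti, si])
    Kc = Km[np.ix_(comb, comb)]
    n_c = n_tr + n_te
    cov = np.kron(model.C, Kc) + np.kron(model.Sigma, np.eye(n_c))

    Y_test_other = np.asarray(Y_test_other, dtype=np.float64)
    F_test = np.asarray(F_test, dtype=np.float64)
    R_test = Y_test_other - F_test - model.mu  # focal column unused

    def flat(t: int, local_idx: np.ndarray) -> np.ndarray:
        return t * n_c + local_idx

    tr_loc = np.arange(n_tr)
    te_loc = np.arange(n_tr, n_c)
    obs_idx, obs_val = [], []
    for t in range(T):
        obs_idx.append(flat(t, tr_loc))
        obs_val.append(model.R_train[:, t])
        if t != focal_trait:
            obs_idx.append(flat(t, te_loc))
            obs_val.append(R_test[:, t])
    obs_idx = np.concatenate(obs_idx)
    obs_val = np.concatenate(obs_val)
    pred_idx = flat(focal_trait, te_loc)

    S_oo = cov[np.ix_(obs_idx, obs_idx)]
    S_po = cov[np.ix_(pred_idx, obs_idx)]
    S_pp = cov[np.ix_(pred_idx, pred_idx)]
    cf = _chol_factor(S_oo)
    mean_r = S_po @ linalg.cho_solve(cf, obs_val)
    var = np.clip(np.diag(S_pp) - np.diag(S_po @ linalg.cho_solve(cf, S_po.T)),
                  0.0, None)
    mean = F_test[:, focal_trait] + model.mu[focal_trait] + mean_r
    if ids is None:
        ids = np.asarray(test_idx)
    return PredictiveDistribution(ids=np.asarray(ids, dtype=object),
                                  mean=mean, sd=np.sqrt(var))
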