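"""Doubly robust estimation and testing of per-gene causal log fold changes.

For each gene j the estimand is the log ratio of mean potential outcomes,

    tau_j = log( E[Y_j(1)] / E[Y_j(0)] ),

estimated by augmented inverse-probability weighting (AIPW): potential
outcomes are imputed as

    Yhat(a) = mu_a(W) + 1{A = a} / pi_a(W) * (Y - mu_a(W)),

where mu_a is an NB GLM outcome model (log link, size-factor offset) and
pi_a a propensity model, both conditioning on W = [X, Uhat] (observed
covariates plus estimated confounders). The estimator is consistent when
either nuisance model is correct. Inference is based on the influence
function of tau_j obtained by the delta method; two-sided p-values use the
normal reference, with BH FDR and Lehmann-Romano FDX multiple-testing
control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from statsmodels.stats.multitest import multipletests

from . import nb
from .containers import CountMatrix, DesignMatrix, GeneEffectTable
from .factor import estimate_dispersion, fit_factor_model
from .io import estimate_size_factors

logger = logging.getLogger(__name__)

__all__ = [
    "NuisanceInput",
    "OutcomeFit",
    "PotentialOutcomes",
    "AIPWEffects",
    "fit_outcome_models",
    "fit_propensity",
    "impute_potential_outcomes",
    "estimate_lfc",
    "debias_effects",
    "estimate_variance",
    "test_effects",
    "adjust_fdr",
    "adjust_fdx",
    "run_contrasts",
]

# random-forest propensity defaults: min 10 samples per leaf, min 20 to
# split, sqrt features per split, balanced class weights, cost-complexity
# pruning 0.02; the tuning grid spans 200-1000 trees, depth {3,5,7} and
# per-tree subsample fractions {0.4, 0.6, 0.8, 1.0}
RF_DEFAULTS = dict(
    min_samples_leaf=10,
    min_samples_split=20,
    max_features="sqrt",
    class_weight="balanced",
    ccp_alpha=0.02,
    n_estimators=500,
    max_depth=5,
    max_samples=0.8,
)
RF_TUNING_GRID = {
    "n_estimators": [200, 600, 1000],
    "max_depth": [3, 5, 7],
    "max_samples": [0.4, 0.6, 0.8, 1.0],
}


@dataclass
class NuisanceInput:
    """Inputs shared by the nuisance models: W = [X, Uhat], A, Y, s."""

    W: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.W.shape[0] != len(self.A):
            self.W = self.W.T
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W contains missing values")
        self.A = np.asarray(self.A, dtype=float)
        if not set(np.unique(self.A)) <= {0.0, 1.0}:
            raise ValueError("treatment must be binary {0,1} for AIPW")
        if self.A.sum() == 0 or self.A.sum() == len(self.A):
            raise ValueError("both treatment arms must be non-empty")
        self.Y = np.asarray(self.Y, dtype=float)
        self.s = np.asarray(self.s, dtype=float)

    @property
    def n(self) -> int:
        return len(self.A)


@dataclass
class OutcomeFit:
    """Per-gene NB outcome-model predictions on the size-factor-adjusted scale."""

    mu1: np.ndarray  # (n, p)
    mu0: np.ndarray  # (n, p)
    coef: np.ndarray
    flagged: np.ndarray  # genes refit with ridge stabilization or floored


@dataclass
class PotentialOutcomes:
    """Imputed per-observation, per-gene potential outcomes (adjusted scale)."""

    y1_hat: np.ndarray
    y0_hat: np.ndarray
    mu1: np.ndarray
    mu0: np.ndarray
    pi1: np.ndarray
    fold_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.fold_ids is None:
            self.fold_ids = np.zeros(len(self.pi1), dtype=int)


def fit_outcome_models(
    ni: NuisanceInput,
    dispersions: Optional[np.ndarray] = None,
    max_iter: int = 30,
) -> OutcomeFit:
    """Fit per-gene NB GLMs of Y_j on (W, A) with log link and offset log s.

    Non-converged genes are refit with a ridge penalty and flagged; predicted
    means are floored at 1e-8 (all-zero genes end up at the floor).
    """
    n, p = ni.Y.shape
    if dispersions is None:
        yadj = ni.Y / ni.s[:, None]
        dispersions = nb.dispersion_moments(yadj)
    Z = np.column_stack([np.ones(n), ni.W, ni.A])
    fitres = nb.fit_nb_glm_log_link(
        ni.Y, Z, dispersions, np.log(ni.s), max_iter=max_iter
    )
    coef = fitres.coef
    Z1 = Z.copy()
    Z1[:, -1] = 1.0
    Z0 = Z.copy()
    Z0[:, -1] = 0.0

    def _predict(C):
        m1 = np.clip(np.exp(np.clip(Z1 @ C.T, -30, 30)), 1e-8, None)
        m0 = np.clip(np.exp(np.clip(Z0 @ C.T, -30, 30)), 1e-8, None)
        return m1, m0

    mu1, mu0 = _predict(coef)
    # flag non-convergence and separation-style extrapolation: counterfactual
    # predictions far beyond the observed range of a gene signal an unstable
    # fit (near-all-zero genes with a few isolated counts are the usual case)
    yadj_max = (ni.Y / ni.s[:, None]).max(axis=0)
    mu_max = np.maximum(mu1.max(axis=0), mu0.max(axis=0))
    flagged = (~fitres.converged) | (mu_max > 10.0 * yadj_max + 10.0)
    if flagged.any():
        logger.info("refitting %d outcome models with ridge", int(flagged.sum()))
        refit = nb.fit_nb_glm_log_link(
            ni.Y[:, flagged],
            Z,
            dispersions[flagged],
            np.log(ni.s),
            max_iter=max_iter,
            ridge=1e-2,
        )
        coef[flagged] = refit.coef
        mu1, mu0 = _predict(coef)
    return OutcomeFit(mu1=mu1, mu0=mu0, coef=coef, flagged=flagged)


def fit_propensity(
    ni: NuisanceInput,
    model: str = "logistic",
    clip: float = 0.01,
    folds: int = 5,
    tune: bool = False,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate P(A=1 | W), clipped to [clip, 1-clip].

    Logistic regression is fit in sample (a parametric, Donsker-class
    nuisance); the random forest is cross-fitted over ``folds`` stratified
    folds, optionally grid-searched over the standard tuning grid. Returns
    (pi1, fold_ids).
    """
    A = ni.A.astype(int)
    if ni.W.shape[1] == 0:
        # no confounding covariates: intercept-only model, marginal rate
        return np.clip(np.full(ni.n, A.mean()), clip, 1 - clip), np.zeros(ni.n, int)
    if model == "logistic":
        lr = LogisticRegression(penalty=None, max_iter=1000)
        lr.fit(ni.W, A)
        pi1 = lr.predict_proba(ni.W)[:, 1]
        fold_ids = np.zeros(ni.n, dtype=int)
    elif model == "random_forest":
        pi1 = np.empty(ni.n)
        fold_ids = np.zeros(ni.n, dtype=int)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
        for k, (tr, te) in enumerate(skf.split(ni.W, A)):
            rf = RandomForestClassifier(random_state=random_state, **RF_DEFAULTS)
            if tune:
                search = GridSearchCV(
                    rf, RF_TUNING_GRID, cv=3, scoring="neg_log_loss", n_jobs=1
                )
                search.fit(ni.W[tr], A[tr])
                rf = search.best_estimator_
            else:
                rf.fit(ni.W[tr], A[tr])
            pi1[te] = rf.predict_proba(ni.W[te])[:, 1]
            fold_ids[te] = k
    else:
        raise ValueError(f"unknown propensity model {model!r}")
    clipped = np.mean((pi1 < clip) | (pi1 > 1 - clip))
    if clipped > 0:
        logger.info("propensity clipping applied to %.1f%% of observations", 100 * clipped)
    return np.clip(pi1, clip, 1 - clip), fold_ids


def impute_potential_outcomes(
    ni: NuisanceInput, mu: OutcomeFit, pi1: np.ndarray, fold_ids=None
) -> PotentialOutcomes:
    """Elementwise AIPW imputation on the size-factor-adjusted scale."""
    yadj = ni.Y / ni.s[:, None]
    A = ni.A[:, None]
    w1 = A / pi1[:, None]
    w0 = (1.0 - A) / (1.0 - pi1)[:, None]
    y1 = mu.mu1 + w1 * (yadj - mu.mu1)
    y0 = mu.mu0 + w0 * (yadj - mu.mu0)
    return PotentialOutcomes(
        y1_hat=y1, y0_hat=y0, mu1=mu.mu1, mu0=mu.mu0, pi1=pi1, fold_ids=fold_ids
    )


def estimate_lfc(po: PotentialOutcomes) -> tuple[np.ndarray, np.ndarray]:
    """LFC tau_j = log(mean Yhat_j(1) / mean Yhat_j(0)) and its influence values.

    eta_ij = (Yhat_ij(1) - psi1_j)/psi1_j - (Yhat_ij(0) - psi0_j)/psi0_j
    (delta method); influence values are mean-zero per gene by construction.
    Genes with a non-positive arm mean are flagged with tau = NaN.
    """
    psi1 = po.y1_hat.mean(axis=0)
    psi0 = po.y0_hat.mean(axis=0)
    # arms whose mean sits at (or below) the outcome-model floor carry no
    # ratio information; their log-ratio would be arbitrary
    ok = (psi1 > 1e-6) & (psi0 > 1e-6)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} genes with non-positive arm means flagged (tau = NaN)",
            stacklevel=2,
        )
    tau = np.full(po.y1_hat.shape[1], np.nan)
    tau[ok] = np.log(psi1[ok] / psi0[ok])
    eta = np.full(po.y1_hat.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        eta_all = (po.y1_hat - psi1) / psi1 - (po.y0_hat - psi0) / psi0
    eta[:, ok] = eta_all[:, ok]
    return tau, eta


def debias_effects(tau: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Remove residual dense confounding from effect estimates.

    Estimation error in the latent confounder scores leaves a bias component
    that is approximately linear in the gene loadings and shared across all
    genes, while true effects are sparse. A Huber-robust regression of tau
    on [1, Gamma] estimates that dense component (true effects act as
    outliers) and subtracts it -- the standard second-stage correction of
    factor-based confounder adjustment.
    """
    import statsmodels.api as sm

    tau = np.asarray(tau, dtype=float).copy()
    ok = np.isfinite(tau)
    if loadings is None or loadings.size == 0 or ok.sum() <= loadings.shape[1] + 2:
        return tau
    exog = np.column_stack([np.ones(len(tau)), loadings])
    try:
        res = sm.RLM(tau[ok], exog[ok], M=sm.robust.norms.HuberT()).fit()
    except Exception:  # noqa: BLE001 - degenerate loadings: skip correction
        logger.warning("effect-level debias regression failed; skipped")
        return tau
    tau[ok] = tau[ok] - exog[ok] @ res.params
    return tau


def estimate_variance(eta: np.ndarray, mode: str = "standard") -> np.ndarray:
    """Standard error of the per-gene influence-function mean.

    ``standard``: sigma_j^2 = (1/n) * sample variance of eta_j (the usual
    one-step SE). ``paper_formula``: the printed expression
    sigma_j^2 = (sqrt(n)/(n-1)) * sum_i eta_ij^2, retained verbatim for audit;
    its sqrt(n) scaling is dimensionally inconsistent with the sqrt(n)-rate
    expansion, which the Monte-Carlo coverage tests arbitrate.
    """
    n = eta.shape[0]
    if n < 2:
        raise ValueError("variance estimation needs n >= 2")
    if mode == "standard":
        var = np.nanvar(eta, axis=0, ddof=1) / n
    elif mode == "paper_formula":
        var = np.sqrt(n) / (n - 1) * np.nansum(eta**2, axis=0)
        var[np.all(np.isnan(eta), axis=0)] = np.nan
    else:
        raise ValueError(f"unknown variance mode {mode!r}")
    return np.sqrt(var)


def test_effects(tau_hat: np.ndarray, sigma_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided z-tests of H0: tau_j = 0 with T_j = tau_j / sigma_j."""
    tau_hat = np.asarray(tau_hat, dtype=float)
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    if np.any(sigma_hat < 0):
        raise ValueError("sigma_hat must be non-negative")
    T = np.full_like(tau_hat, np.nan)
    p = np.full_like(tau_hat, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = sigma_hat > 0
        T[pos] = tau_hat[pos] / sigma_hat[pos]
        p[pos] = 2.0 * norm.sf(np.abs(T[pos]))
        degenerate = (~pos) & np.isfinite(tau_hat)
        T[degenerate] = np.where(tau_hat[degenerate] == 0, 0.0, np.inf)
        p[degenerate] = np.where(tau_hat[degenerate] == 0, 1.0, 0.0)
    return T, p


def adjust_fdr(p: np.ndarray, alpha: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (q-values, rejection flags)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        reject[ok] = rej
    return q, reject


def adjust_fdx(
    p: np.ndarray, gamma: float = 0.1, alpha: float = 0.05
) -> np.ndarray:
    """Lehmann-Romano step-down controlling P(FDP > gamma) <= alpha.

    Thresholds alpha_i = (floor(gamma*i) + 1) * alpha / (m + floor(gamma*i)
    + 1 - i); rejects the largest prefix of sorted p-values below the
    thresholds.
    """
    if not (0 < gamma < 1 and 0 < alpha < 1):
        raise ValueError("gamma and alpha must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    m = int(ok.sum())
    reject = np.zeros(p.shape, dtype=bool)
    if m == 0:
        return reject
    order = np.argsort(p[ok], kind="stable")
    sorted_p = p[ok][order]
    i = np.arange(1, m + 1)
    floor_gi = np.floor(gamma * i)
    thresholds = (floor_gi + 1) * alpha / (m + floor_gi + 1 - i)
    passing = sorted_p <= thresholds
    k = 0
    for flag in passing:
        if not flag:
            break
        k += 1
    idx_ok = np.flatnonzero(ok)
    reject[idx_ok[order[:k]]] = True
    return reject


# ---------------------------------------------------------------------------
# estimator class and multi-treatment contrasts
# ---------------------------------------------------------------------------


class AIPWEffects(BaseEstimator):
    """Per-gene doubly robust LFC estimation with influence-function inference.

    Parameters
    ----------
    propensity : {"logistic", "random_forest"}
    clip : float
        Propensity clipping bound (positivity enforcement).
    folds : int
        Cross-fitting folds for the random forest.
    tune_propensity : bool
        Grid-search the forest over the standard tuning grid.
    fdr_alpha, fdx_gamma, fdx_alpha : multiple-testing levels.
    variance : {"standard", "paper_formula"}
    random_state : int

    Attributes (after ``fit``)
    --------------------------
    tau_, sigma_, T_, pvalues_, qvalues_, reject_fdr_, reject_fdx_ : (p,)
    potential_outcomes_ : :class:`PotentialOutcomes`
    clipped_fraction_ : overlap diagnostic.
    """

    def __init__(
        self,
        propensity: str = "logistic",
        clip: float = 0.01,
        folds: int = 5,
        tune_propensity: bool = False,
        fdr_alpha: float = 0.1,
        fdx_gamma: float = 0.1,
        fdx_alpha: float = 0.05,
        variance: str = "standard",
        debias: bool = True,
        empirical_null: bool = True,
        random_state: int = 0,
    ) -> None:
        self.propensity = propensity
        self.clip = clip
        self.folds = folds
        self.tune_propensity = tune_propensity
        self.fdr_alpha = fdr_alpha
        self.fdx_gamma = fdx_gamma
        self.fdx_alpha = fdx_alpha
        self.variance = variance
        self.debias = debias
        self.empirical_null = empirical_null
        self.random_state = random_state

    def fit(
        self,
        cm: CountMatrix,
        design: DesignMatrix,
        confounders: Optional[np.ndarray] = None,
        dispersions: Optional[np.ndarray] = None,
        loadings: Optional[np.ndarray] = None,
    ):
        if cm.size_factors is None:
            estimate_size_factors(cm)
        U = (
            np.zeros((cm.n_obs, 0))
            if confounders is None
            else np.atleast_2d(np.asarray(confounders, dtype=float))
        )
        if U.shape[0] != cm.n_obs:
            U = U.T
        W = np.column_stack([design.covariates, U])
        ni = NuisanceInput(W=W, A=design.binary_indicator(), Y=cm.counts, s=cm.size_factors)
        if dispersions is None:
            dispersions = estimate_dispersion(cm, design)
        outcome = fit_outcome_models(ni, dispersions=dispersions)
        raw_pi, fold_ids = fit_propensity(
            ni,
            model=self.propensity,
            clip=self.clip,
            folds=self.folds,
            tune=self.tune_propensity,
            random_state=self.random_state,
        )
        po = impute_potential_outcomes(ni, outcome, raw_pi, fold_ids)
        tau, eta = estimate_lfc(po)
        if self.debias and loadings is not None:
            tau = debias_effects(tau, loadings)
        sigma = estimate_variance(eta, mode=self.variance)
        T, p = test_effects(tau, sigma)
        self.null_scale_ = 1.0
        if self.empirical_null:
            # Efron-style empirical-null recalibration: with mostly-null
            # genes, the median absolute z-score estimates the actual null
            # scale, absorbing variance from confounder-estimation error;
            # the scale is folded into sigma (never deflating it) so that
            # T = tau/sigma remains exact
            ok = np.isfinite(T)
            if ok.sum() >= 20:
                mad = np.median(np.abs(T[ok] - np.median(T[ok]))) / 0.6745
                self.null_scale_ = float(max(1.0, mad))
                sigma = sigma * self.null_scale_
                T, p = test_effects(tau, sigma)
        q, rej_fdr = adjust_fdr(p, alpha=self.fdr_alpha)
        rej_fdx = adjust_fdx(p, gamma=self.fdx_gamma, alpha=self.fdx_alpha)
        self.tau_ = tau
        self.sigma_ = sigma
        self.T_ = T
        self.pvalues_ = p
        self.qvalues_ = q
        self.reject_fdr_ = rej_fdr
        self.reject_fdx_ = rej_fdx
        self.eta_ = eta
        self.potential_outcomes_ = po
        self.outcome_fit_ = outcome
        self.clipped_fraction_ = float(
            np.mean((raw_pi <= self.clip) | (raw_pi >= 1 - self.clip))
        )
        self.gene_ids_ = np.asarray(cm.gene_ids)
        self.n_obs_ = cm.n_obs
        return self

    def to_table(self) -> GeneEffectTable:
        return GeneEffectTable.from_arrays(
            self.gene_ids_,
            self.tau_,
            self.sigma_,
            self.T_,
            self.pvalues_,
            self.qvalues_,
            self.reject_fdr_,
            self.reject_fdx_,
            metadata={
                "estimand": "lfc",
                "n": int(self.n_obs_),
                "propensity": self.propensity,
                "variance": self.variance,
                "clipped_fraction": self.clipped_fraction_,
            },
        )


def run_contrasts(
    cm: CountMatrix,
    design: DesignMatrix,
    control_label,
    r: int = 4,
    min_arm_size: int = 2,
    factor_opts: Optional[dict] = None,
    **aipw_opts,
) -> dict:
    """One-vs-control AIPW contrasts for a categorical treatment.

    The factor model is fit once on all observations with one-hot treatment
    columns; each contrast then reruns the binary pipeline on the subset
    {level} u {control}, reusing the shared confounder rows. Levels with
    fewer than ``min_arm_size`` observations are skipped with a warning.
    """
    levels = np.unique(design.treatment)
    if control_label not in levels:
        raise ValueError(f"control label {control_label!r} not among levels {levels}")
    design.control_label = control_label
    fit = fit_factor_model(cm, design, r, **(factor_opts or {}))
    tables = {}
    control_mask = design.treatment == control_label
    for lv in levels:
        if lv == control_label:
            continue
        mask = design.treatment == lv
        if mask.sum() < min_arm_size:
            warnings.warn(
                f"treatment level {lv!r} has {int(mask.sum())} < {min_arm_size} "
                "observations; skipped",
                stacklevel=2,
            )
            continue
        sel = mask | control_mask
        sub_cm = CountMatrix(
            cm.counts[sel],
            obs_ids=np.asarray(cm.obs_ids)[sel],
            gene_ids=cm.gene_ids,
            size_factors=cm.size_factors[sel] if cm.size_factors is not None else None,
        )
        sub_design = DesignMatrix(
            treatment=(design.treatment[sel] == lv).astype(int),
            covariates=design.covariates[sel],
            covariate_names=design.covariate_names,
        )
        est = AIPWEffects(**aipw_opts)
        est.fit(
            sub_cm,
            sub_design,
            confounders=fit.U_causal[sel] if r > 0 else None,
            dispersions=fit.dispersions,
        )
        tables[lv] = est.to_table()
    return tables
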