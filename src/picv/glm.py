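"""Logistic main-effects and interaction models for two categorical SNPs.

The two model families are

    P(case) = logistic(b0 + b1*SNP1 + b2*SNP2)                (main effects)
    P(case) = logistic(b0 + b1*SNP1 + b2*SNP2 + b3*SNP1*SNP2) (interaction)

with SNP1 and SNP2 treated as 3-level categorical variables under
treatment (reference-cell) coding, reference level 0 = homozygous for
the major allele, and the interaction term the Cartesian product of the
two genotypes (9 combinations).  Without covariates the interaction
model is saturated on the 9 genotype cells, so its maximum-likelihood
fitted probability in each occupied cell is exactly the observed case
fraction; the implementation uses that closed form as a fast path and
aggregated IRLS (via statsmodels) for the main-effects model.  With
covariates both models are fit by individual-level IRLS.

Log-likelihoods are always reported on the Bernoulli (individual-level)
scale so main-effects and interaction fits are directly comparable in a
likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from .datasim import GenotypeDataset

__all__ = [
    "ModelSpec",
    "LogisticFit",
    "fit_logistic",
    "predict_prob",
    "classify",
    "likelihood_ratio_test",
    "coefficient_table",
]

_KINDS = ("main_effects", "interaction")
_MAX_ITER = 100
_LL_TOL = 1e-10
# logit clip for saturated 0/1 cell fractions: separation is benign here,
# only the fitted probability (exactly 0 or 1) matters downstream
_PROB_CLIP = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    kind: str = "main_effects"
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))


@dataclass
class LogisticFit:
    """A fitted logistic model.

    ``cell_probs`` holds fitted P(case) per genotype cell for
    covariate-free fits (None otherwise); for interaction fits, cells
    absent from training carry the main-effects prediction as a
    fallback.  ``df_model`` counts estimated parameters excluding the
    intercept.
    """

    spec: ModelSpec
    coefficients: dict[str, float]
    log_likelihood: float
    df_model: int
    n_params: int
    n_obs: int
    cell_probs: np.ndarray | None
    training_cells_present: np.ndarray
    converged: bool = True
    flags: tuple[str, ...] = ()
    _params: np.ndarray | None = None
    _colnames: list[str] | None = None


def _bernoulli_ll(cases: np.ndarray, totals: np.ndarray, probs: np.ndarray) -> float:
    p = np.clip(probs, _PROB_CLIP, 1 - _PROB_CLIP)
    ctrl = totals - cases
    return float(np.sum(cases * np.log(p) + ctrl * np.log(1 - p)))


def _cell_counts(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    cell = 3 * dataset.snp1 + dataset.snp2
    totals = np.bincount(cell, minlength=9).reshape(3, 3)
    cases = np.bincount(cell, weights=dataset.status, minlength=9).reshape(3, 3)
    return cases.astype(float), totals.astype(float)


def _main_effect_design(cases: np.ndarray, totals: np.ndarray):
    """Aggregated design over occupied cells: intercept + level dummies."""
    occ = np.argwhere(totals > 0)
    cols = ["intercept"]
    mats = [np.ones(len(occ))]
    lvl1 = sorted({i for i, _ in occ})
    lvl2 = sorted({j for _, j in occ})
    for lv in lvl1[1:]:
        cols.append(f"snp1[{lv}]")
        mats.append((occ[:, 0] == lv).astype(float))
    for lv in lvl2[1:]:
        cols.append(f"snp2[{lv}]")
        mats.append((occ[:, 1] == lv).astype(float))
    return occ, np.column_stack(mats), cols


def _fit_main_effects_aggregated(dataset: GenotypeDataset) -> LogisticFit:
    cases, totals = _cell_counts(dataset)
    occ, X, cols = _main_effect_design(cases, totals)
    y_cases = cases[occ[:, 0], occ[:, 1]]
    y_totals = totals[occ[:, 0], occ[:, 1]]
    endog = np.column_stack([y_cases, y_totals - y_cases])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    flags: list[str] = []
    converged = True
    try:
        res = model.fit(maxiter=_MAX_ITER, tol=_LL_TOL)
        converged = bool(res.converged)
    except Exception:  # perfect separation etc.; retry damped
        res = model.fit(maxiter=_MAX_ITER, tol=_LL_TOL, method="lbfgs")
        converged = False
    if not converged:
        flags.append("main_effects_not_converged")
    params = np.asarray(res.params, dtype=float)
    # fill cell probabilities for all 27.. 9 cells from the linear predictor;
    # an absent SNP level has no dummy and falls back to the reference level
    cell_probs = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            eta = params[0]
            for k, c in enumerate(cols):
                if c == f"snp1[{i}]" or c == f"snp2[{j}]":
                    eta += params[k]
            cell_probs[i, j] = expit(eta)
    ll = _bernoulli_ll(y_cases, y_totals, cell_probs[occ[:, 0], occ[:, 1]])
    coefs = dict(zip(cols, params.tolist()))
    return LogisticFit(
        spec=ModelSpec("main_effects"),
        coefficients=coefs,
        log_likelihood=ll,
        df_model=len(cols) - 1,
        n_params=len(cols),
        n_obs=int(totals.sum()),
        cell_probs=cell_probs,
        training_cells_present=totals > 0,
        converged=converged,
        flags=tuple(flags),
    )


def _fit_interaction_saturated(dataset: GenotypeDataset) -> LogisticFit:
    cases, totals = _cell_counts(dataset)
    present = totals > 0
    flags: list[str] = []
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(present, cases / np.where(present, totals, 1), np.nan)
    cell_probs = frac.copy()
    if not present.all():
        # empty training cells: predict from the main-effects part
        flags.append(f"empty_training_cells={int((~present).sum())}")
        fallback = _fit_main_effects_aggregated(dataset)
        cell_probs[~present] = fallback.cell_probs[~present]
    if np.any(present & ((frac == 0) | (frac == 1))):
        flags.append("saturated_cells")
    ll = _bernoulli_ll(cases[present], totals[present], frac[present])
    # treatment-coded coefficients implied by the saturated fit (clipped logits)
    lg = logit(np.clip(frac, _PROB_CLIP, 1 - _PROB_CLIP))
    coefs: dict[str, float] = {}
    if present[0, 0]:
        coefs["intercept"] = float(lg[0, 0])
        for i in (1, 2):
            if present[i, 0]:
                coefs[f"snp1[{i}]"] = float(lg[i, 0] - lg[0, 0])
        for j in (1, 2):
            if present[0, j]:
                coefs[f"snp2[{j}]"] = float(lg[0, j] - lg[0, 0])
        for i in (1, 2):
            for j in (1, 2):
                if present[i, j] and present[i, 0] and present[0, j]:
                    coefs[f"snp1[{i}]:snp2[{j}]"] = float(
                        lg[i, j] - lg[i, 0] - lg[0, j] + lg[0, 0]
                    )
    n_params = int(present.sum())
    return LogisticFit(
        spec=ModelSpec("interaction"),
        coefficients=coefs,
        log_likelihood=ll,
        df_model=n_params - 1,
        n_params=n_params,
        n_obs=int(totals.sum()),
        cell_probs=cell_probs,
        training_cells_present=present,
        converged=True,
        flags=tuple(flags),
    )


def _individual_design(
    dataset: GenotypeDataset, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    n = dataset.n
    cols = ["intercept"]
    mats = [np.ones(n)]
    for lv in (1, 2):
        cols.append(f"snp1[{lv}]")
        mats.append((dataset.snp1 == lv).astype(float))
    for lv in (1, 2):
        cols.append(f"snp2[{lv}]")
        mats.append((dataset.snp2 == lv).astype(float))
    if spec.kind == "interaction":
        for i in (1, 2):
            for j in (1, 2):
                cols.append(f"snp1[{i}]:snp2[{j}]")
                mats.append(((dataset.snp1 == i) & (dataset.snp2 == j)).astype(float))
    for name in spec.covariate_names:
        if dataset.covariates is None or name not in dataset.covariates:
            raise ValueError(f"covariate {name!r} missing from dataset")
        cols.append(name)
        mats.append(dataset.covariates[name].to_numpy(dtype=float))
    return np.column_stack(mats), cols


def _fit_individual(dataset: GenotypeDataset, spec: ModelSpec) -> LogisticFit:
    X, cols = _individual_design(dataset, spec)
    # drop all-zero columns (absent levels / empty interaction cells)
    keep = X.any(axis=0)
    dropped = [c for c, k in zip(cols, keep) if not k]
    X = X[:, keep]
    cols = [c for c, k in zip(cols, keep) if k]
    flags = [f"dropped_terms={len(dropped)}"] if dropped else []
    model = sm.GLM(dataset.status, X, family=sm.families.Binomial())
    converged = True
    try:
        res = model.fit(maxiter=_MAX_ITER, tol=_LL_TOL)
        converged = bool(res.converged)
    except Exception:
        res = model.fit(maxiter=_MAX_ITER, tol=_LL_TOL, method="lbfgs")
        converged = False
    if not converged:
        flags.append("not_converged")
    params = np.asarray(res.params, dtype=float)
    probs = expit(X @ params)
    ll = _bernoulli_ll(dataset.status.astype(float), np.ones(dataset.n), probs)
    _, totals = _cell_counts(dataset)
    fit = LogisticFit(
        spec=spec,
        coefficients=dict(zip(cols, params.tolist())),
        log_likelihood=ll,
        df_model=len(cols) - 1,
        n_params=len(cols),
        n_obs=dataset.n,
        cell_probs=None,
        training_cells_present=totals > 0,
        converged=converged,
        flags=tuple(flags),
    )
    fit._params = params
    fit._colnames = cols
    return fit


def fit_logistic(dataset: GenotypeDataset, spec: ModelSpec) -> LogisticFit:
    """Maximum-likelihood logistic fit of the requested model family.

    Requires at least one case and one control.  Covariate-free fits
    use exact aggregated computations on the 9 genotype cells; fits
    with covariates use individual-level IRLS.
    """
    n_case = int(dataset.status.sum())
    if n_case == 0 or n_case == dataset.n:
        raise ValueError("dataset must contain at least one case and one control")
    if spec.covariate_names:
        return _fit_individual(dataset, spec)
    if spec.kind == "interaction":
        return _fit_interaction_saturated(dataset)
    return _fit_main_effects_aggregated(dataset)


def predict_prob(fit: LogisticFit, dataset: GenotypeDataset) -> np.ndarray:
    """Fitted P(case) for each row of ``dataset`` under ``fit``.

    For covariate-free fits this is a lookup into the fitted cell
    probabilities; rows in genotype cells that were absent from training
    receive the main-effects fallback stored in the fit.
    """
    if fit.cell_probs is not None:
        return fit.cell_probs[dataset.snp1, dataset.snp2]
    X, cols = _individual_design(dataset, fit.spec)
    keep = [c in fit.coefficients for c in cols]
    X = X[:, keep]
    params = np.array([fit.coefficients[c] for c, k in zip(cols, keep) if k])
    return expit(X @ params)


def classify(probs: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff prob strictly exceeds the cutoff (ties -> control)."""
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs > cutoff).astype(int)


def likelihood_ratio_test(
    fit_null: LogisticFit, fit_alt: LogisticFit
) -> tuple[float, int, float]:
    """LRT of nested logistic fits: (statistic, df, p).

    The statistic is 2*(ll_alt - ll_null) clipped at zero, the degrees
    of freedom the difference in parameter counts (4 for the
    covariate-free interaction vs main-effects comparison on full-cell
    data), and p the chi-square upper tail.
    """
    if fit_null.n_obs != fit_alt.n_obs:
        raise ValueError("fits must be computed on the same rows")
    df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError("alternative model must have more parameters than the null")
    stat = max(0.0, 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood))
    return stat, df, float(stats.chi2.sf(stat, df))


def coefficient_table(fit: LogisticFit) -> pd.DataFrame:
    """Fit summary as a delimited-exportable table (term, estimate)."""
    rows = [{"term": k, "estimate": v} for k, v in fit.coefficients.items()]
    df = pd.DataFrame(rows)
    df.attrs["reference"] = "treatment coding, reference genotype (0, 0)"
    return df
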