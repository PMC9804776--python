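"""Multilevel meta-analytic model: REML estimation and heterogeneity.

The model is a Gaussian linear mixed model with *known* heteroscedastic
residual variances, the standard formulation for a multilevel
meta-analysis.  For effect sizes y_i with sampling variances v_i,

    y = X beta + Z_u u + Z_a a + Z_s s + e + m,

where u ~ N(0, sigma_u^2 I) are study effects, a ~ N(0, sigma_a^2 A) are
phylogenetic species effects with correlation matrix A from shared
ancestry, s ~ N(0, sigma_s^2 I) are non-phylogenetic species effects,
e ~ N(0, sigma_e^2 I) are estimate-level effects, and m ~ N(0, diag(v))
is the known sampling error.  The marginal covariance is

    V(theta) = sigma_u^2 Z_u Z_u' + sigma_a^2 Z_a A Z_a'
             + sigma_s^2 Z_s Z_s' + sigma_e^2 I + diag(v).

Variance components are estimated by maximising the restricted
log-likelihood; fixed effects are then GLS at the optimum.  Heterogeneity
is summarised by I^2 = (sum of components) / (sum of components + typical
sampling-error variance) and by each component's share of the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, qr

from . import effects_io
from .effects_io import EffectSizeRecord
from .phylo import PhyloCorrelation

__all__ = [
    "ModelSpec",
    "FitResult",
    "HeterogeneityReport",
    "RankDeficiencyError",
    "build_model",
    "build_design",
    "fit_reml",
    "typical_sampling_variance",
    "heterogeneity",
    "wald_tests",
    "lrt_random_effect",
    "drop_random_term",
]

RANDOM_TERMS = ("study", "phylogeny", "species", "estimate")

# Treatment-coding reference level for each moderator.
DEFAULT_REFERENCES = {
    "environmental_setting": "artificial",
    "age_at_measurement": "adult",
    "laboratory_method": "TRF_southern",
    "statistical_method": "correlation",
    "repeated_measurement": "yes",
    "parental_sex": "nonspecific",
}

_CANONICAL_LEVELS = {
    "environmental_setting": effects_io.ENVIRONMENTAL_SETTINGS,
    "age_at_measurement": effects_io.AGES,
    "laboratory_method": effects_io.LAB_METHODS,
    "statistical_method": effects_io.STAT_METHODS,
    "repeated_measurement": effects_io.REPEATED,
    "parental_sex": effects_io.PARENTAL_SEX,
}

MODERATORS = (
    "environmental_setting",
    "age_at_measurement",
    "laboratory_method",
    "statistical_method",
    "repeated_measurement",
)


class RankDeficiencyError(ValueError):
    """The fixed-effect design is not full column rank."""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class RandomTermStruct:
    """One variance component: its name and n-by-n structure matrix ZGZ'."""

    name: str
    M: np.ndarray


@dataclass
class ModelSpec:
    """Response, known sampling variances, design, and random structures."""

    y: np.ndarray
    v: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    random_terms: list[RandomTermStruct]
    estimate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.y)
        if len(self.v) != n or self.X.shape[0] != n:
            raise ValueError("y, v and X must have one entry per record")
        if np.any(self.v <= 0):
            raise ValueError("all sampling variances must be positive")
        for term in self.random_terms:
            if term.M.shape != (n, n):
                raise ValueError(f"structure matrix for {term.name} has wrong shape")
        _check_full_rank(self.X, self.fixed_names)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.random_terms]


@dataclass
class FitResult:
    """REML variance components, GLS fixed effects and restricted loglik."""

    spec: ModelSpec
    components: dict[str, float]
    beta: np.ndarray
    beta_se: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list[str]
    loglik: float
    converged: bool
    n_iter: int

    @property
    def fitted(self) -> np.ndarray:
        return self.spec.X @ self.beta

    @property
    def residuals(self) -> np.ndarray:
        """Marginal residuals y - X beta-hat."""
        return self.spec.y - self.fitted

    def marginal_covariance(self) -> np.ndarray:
        V = np.diag(self.spec.v).astype(float)
        for term in self.spec.random_terms:
            V += self.components[term.name] * term.M
        return V

    def conditional_residuals(self) -> np.ndarray:
        """Residuals after subtracting BLUPs of every random term."""
        V = self.marginal_covariance()
        r = self.residuals
        w = np.linalg.solve(V, r)
        blup_total = np.zeros_like(r)
        for term in self.spec.random_terms:
            if term.name == "estimate":
                continue
            blup_total += self.components[term.name] * (term.M @ w)
        return r - blup_total


@dataclass
class HeterogeneityReport:
    sigma_m2: float
    i2: float
    proportions: dict[str, float]

    def to_series(self) -> pd.Series:
        data = dict(self.proportions)
        data["I2"] = self.i2
        data["sigma_m2"] = self.sigma_m2
        return pd.Series(data)


def _grouping_matrix(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    levels = list(dict.fromkeys(labels))
    Z = np.zeros((len(labels), len(levels)))
    index = {lev: j for j, lev in enumerate(levels)}
    for i, lab in enumerate(labels):
        Z[i, index[lab]] = 1.0
    return Z, levels


def build_design(
    records: Sequence[EffectSizeRecord],
    moderators: Sequence[str] | None = None,
    interaction: bool = False,
    references: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded fixed-effect design matrix with an intercept.

    Dummy columns are created for each non-reference level *observed in the
    data*; the reference level may be overridden per moderator (used for
    the SNP-reference refit).  ``interaction=True`` adds parental-sex main
    effects and the parental-sex x statistical-method product columns.
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    def add_factor(name: str) -> list[tuple[str, np.ndarray]]:
        values = [getattr(r, name) for r in records]
        ref = refs[name]
        if ref not in _CANONICAL_LEVELS[name]:
            raise ValueError(f"unknown reference level {ref!r} for {name}")
        observed = set(values)
        if ref not in observed:
            raise ValueError(f"reference level {ref!r} of {name} absent from data")
        added = []
        for level in _CANONICAL_LEVELS[name]:
            if level == ref or level not in observed:
                continue
            col = np.array([1.0 if val == level else 0.0 for val in values])
            added.append((f"{name}[{level}]", col))
        return added

    for moderator in moderators or ():
        for colname, col in add_factor(moderator):
            cols.append(col)
            names.append(colname)

    if interaction:
        sex_cols = add_factor("parental_sex")
        for colname, col in sex_cols:
            cols.append(col)
            names.append(colname)
        stat_cols = [
            (nm, c) for nm, c in zip(names, cols) if nm.startswith("statistical_method[")
        ]
        for sex_name, sex_col in sex_cols:
            for stat_name, stat_col in stat_cols:
                prod = sex_col * stat_col
                if prod.any():
                    cols.append(prod)
                    names.append(f"{sex_name}:{stat_name}")

    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return X, names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] > X.shape[0]:
        raise RankDeficiencyError("more fixed-effect columns than records")
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        aliased = [names[piv[j]] for j in range(rank, X.shape[1])]
        raise RankDeficiencyError(
            "design matrix rank deficient; aliased column(s): " + ", ".join(aliased)
        )


def build_model(
    records: Sequence[EffectSizeRecord],
    moderators: Sequence[str] | None = None,
    random_terms: Sequence[str] = RANDOM_TERMS,
    A: PhyloCorrelation | None = None,
    interaction: bool = False,
    references: dict[str, str] | None = None,
    response: str = "h2",
) -> ModelSpec:
    """Assemble a :class:`ModelSpec` from validated records.

    ``response='z'`` uses the Fisher-z value and variance of
    :class:`~phylometa.effects_io.TransformedRecord` inputs.  The
    ``phylogeny`` random term requires ``A`` to cover every species in the
    data; missing species are a hard error rather than silently pruned.
    """
    if not records:
        raise ValueError("no records")
    if response == "h2":
        y = np.array([r.h2 for r in records])
        v = np.array([r.sampling_variance for r in records])
    elif response == "z":
        y = np.array([r.z for r in records])
        v = np.array([r.var_z for r in records])
    else:
        raise ValueError(f"unknown response {response!r}")

    X, names = build_design(records, moderators, interaction, references)

    species = [r.species for r in records]
    studies = [r.study_id for r in records]
    n = len(records)
    terms: list[RandomTermStruct] = []
    for term in random_terms:
        if term == "study":
            Z, _ = _grouping_matrix(studies)
            terms.append(RandomTermStruct("study", Z @ Z.T))
        elif term == "species":
            Z, _ = _grouping_matrix(species)
            terms.append(RandomTermStruct("species", Z @ Z.T))
        elif term == "phylogeny":
            if A is None:
                raise ValueError("phylogeny term requires a correlation matrix A")
            Z, levels = _grouping_matrix(species)
            G = A.submatrix(levels)
            terms.append(RandomTermStruct("phylogeny", Z @ G @ Z.T))
        elif term == "estimate":
            terms.append(RandomTermStruct("estimate", np.eye(n)))
        else:
            raise ValueError(f"unknown random term {term!r}")

    return ModelSpec(
        y=y,
        v=v,
        X=X,
        fixed_names=names,
        random_terms=terms,
        estimate_ids=[r.estimate_id for r in records],
    )


def _reml_pieces(sigma2: np.ndarray, spec: ModelSpec):
    """Restricted loglik, its gradient, and GLS quantities at sigma2."""
    n, p = spec.X.shape
    V = np.diag(spec.v).astype(float)
    for s2, term in zip(sigma2, spec.random_terms):
        if s2 != 0.0:
            V += s2 * term.M
    c, low = cho_factor(V, lower=True)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = cho_solve((c, low), np.eye(n))
    ViX = Vinv @ spec.X
    XtViX = spec.X.T @ ViX
    cx, lowx = cho_factor(XtViX)
    logdet_XtViX = 2.0 * np.sum(np.log(np.diag(cx)))
    XtViX_inv = cho_solve((cx, lowx), np.eye(p))
    beta = XtViX_inv @ (ViX.T @ spec.y)
    r = spec.y - spec.X @ beta
    Py = Vinv @ r
    quad = float(r @ Py)
    # Harville's REML likelihood, including the 0.5 log|X'X| constant so
    # values are comparable across software using the same convention.
    _, logdet_XtX = np.linalg.slogdet(spec.X.T @ spec.X)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + logdet_V
        + logdet_XtViX
        - logdet_XtX
        + quad
    )
    P = Vinv - ViX @ XtViX_inv @ ViX.T
    grad = np.array(
        [
            -0.5 * (np.sum(P * term.M) - float(Py @ term.M @ Py))
            for term in spec.random_terms
        ]
    )
    return ll, grad, beta, XtViX_inv


def reml_loglik(sigma2: Iterable[float], spec: ModelSpec) -> float:
    """Restricted log-likelihood at the given variance components."""
    sigma2 = np.asarray(list(sigma2), dtype=float)
    if len(sigma2) != len(spec.random_terms):
        raise ValueError("one variance per random term required")
    ll, *_ = _reml_pieces(sigma2, spec)
    return float(ll)


def _starting_points(spec: ModelSpec) -> list[np.ndarray]:
    """Deterministic REML starts: moment-based, equal-split, near-zero."""
    k = len(spec.random_terms)
    W = np.diag(1.0 / spec.v)
    XtWX = spec.X.T @ W @ spec.X
    beta0 = np.linalg.solve(XtWX, spec.X.T @ W @ spec.y)
    resid = spec.y - spec.X @ beta0
    excess = max(float(np.var(resid)) - float(np.mean(spec.v)), 1e-4)
    starts = [np.full(k, excess / max(k, 1)), np.full(k, excess), np.full(k, 1e-6)]
    return starts


def fit_reml(
    spec: ModelSpec,
    maxiter: int = 500,
    gtol: float = 1e-8,
    ftol: float = 1e-12,
) -> FitResult:
    """Maximise the restricted likelihood over non-negative components.

    Bound-constrained quasi-Newton (L-BFGS-B) with the analytic gradient,
    restarted from three deterministic points; a component whose
    unconstrained optimum would be negative lands exactly on the zero
    boundary.  GLS fixed effects and model-based SEs are evaluated at the
    optimum.
    """
    k = len(spec.random_terms)
    if k == 0:
        sigma2_best = np.zeros(0)
        nit = 0
        success = True
    else:
        def objective(s2: np.ndarray):
            ll, grad, *_ = _reml_pieces(s2, spec)
            return -ll, -grad

        best = None
        nit = 0
        success = False
        for start in _starting_points(spec):
            res = optimize.minimize(
                objective,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=[(0.0, None)] * k,
                options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol},
            )
            nit += int(res.nit)
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            success = success or bool(res.success)
        sigma2_best = np.maximum(best.x, 0.0)

    ll, _, beta, XtViX_inv = _reml_pieces(sigma2_best, spec)
    beta_se = np.sqrt(np.diag(XtViX_inv))
    components = {t.name: float(s2) for t, s2 in zip(spec.random_terms, sigma2_best)}
    result = FitResult(
        spec=spec,
        components=components,
        beta=beta,
        beta_se=beta_se,
        beta_cov=XtViX_inv,
        fixed_names=list(spec.fixed_names),
        loglik=float(ll),
        converged=success,
        n_iter=nit,
    )
    if not success:
        raise ConvergenceError("REML did not converge from any start", best=result)
    return result


def typical_sampling_variance(v: Iterable[float]) -> float:
    """Summary 'typical' within-study variance of heteroscedastic v_i.

    With weights w_i = 1/v_i:  sigma_m^2 = (k - 1) sum(w) /
    ((sum w)^2 - sum(w^2)).  Returns the common value when all v_i are
    equal.
    """
    v = np.asarray(list(v), dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two sampling variances")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    w = 1.0 / v
    sw = w.sum()
    return float((len(v) - 1) * sw / (sw**2 - (w**2).sum()))


def heterogeneity(fit: FitResult, sigma_m2: float) -> HeterogeneityReport:
    """I^2 and per-component shares of the total variance.

    Total variance = sum of estimated components + sigma_m^2; I^2 is the
    non-sampling share.  Proportions sum to 1 by construction.
    """
    comps = dict(fit.components)
    total = sum(comps.values()) + sigma_m2
    if total <= 0:
        raise ValueError("total variance is zero; I2 undefined")
    proportions = {name: val / total for name, val in comps.items()}
    proportions["sampling_error"] = sigma_m2 / total
    i2 = 1.0 - proportions["sampling_error"]
    return HeterogeneityReport(sigma_m2=sigma_m2, i2=i2, proportions=proportions)


def wald_tests(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient normal-theory tests and Wald CIs."""
    crit = stats.norm.ppf(0.5 + level / 2)
    z = np.where(fit.beta_se > 0, fit.beta / fit.beta_se, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "estimate": fit.beta,
            "se": fit.beta_se,
            "z": z,
            "p": p,
            "ci_low": fit.beta - crit * fit.beta_se,
            "ci_high": fit.beta + crit * fit.beta_se,
        },
        index=fit.fixed_names,
    )


def drop_random_term(spec: ModelSpec, name: str) -> ModelSpec:
    """A copy of the spec without one random term (for LRTs)."""
    if name not in spec.term_names:
        raise ValueError(f"no random term named {name!r}")
    return ModelSpec(
        y=spec.y.copy(),
        v=spec.v.copy(),
        X=spec.X.copy(),
        fixed_names=list(spec.fixed_names),
        random_terms=[t for t in spec.random_terms if t.name != name],
        estimate_ids=list(spec.estimate_ids),
    )


def lrt_random_effect(
    full: FitResult,
    reduced: FitResult,
    boundary_mixture: bool = False,
) -> dict[str, float]:
    """Likelihood-ratio test for one dropped variance component.

    The statistic is 2(l_full - l_reduced), clamped at zero.  By default
    the p-value uses a plain chi-square with 1 df (the convention most
    meta-analytic software reports); ``boundary_mixture=True`` instead
    uses the 50:50 mixture of chi2(0) and chi2(1) appropriate for a null
    on the boundary of the parameter space.
    """
    if len(full.spec.random_terms) - len(reduced.spec.random_terms) != 1:
        raise ValueError("reduced model must drop exactly one random term")
    if not np.array_equal(full.spec.y, reduced.spec.y) or not np.array_equal(
        full.spec.X, reduced.spec.X
    ):
        raise ValueError("full and reduced models must share data and fixed design")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(stat, df=1))
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return {
        "statistic": stat,
        "df": 1.0,
        "p": p,
        "loglik_reduced": reduced.loglik,
    }
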