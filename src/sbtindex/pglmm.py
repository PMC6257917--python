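"""Penalized-likelihood GLMM engine: log-link GLMs with ridge random effects.

The standardization models need crossed random interaction terms (year:month,
year:area, month:area, year:month:area) inside Gamma and Tweedie GLMs.  Each
random term is an indicator block ``Z_m b_m`` with ``b_m ~ N(0, sigma2_m I)``;
equivalently a quadratic (ridge) penalty ``lambda_m ||b_m||^2`` on that block
with ``lambda_m = phi / sigma2_m`` — the same device mgcv uses to fit random
effects as penalized smooths.  Fitting alternates

* inner penalized IRLS for the coefficients at fixed smoothing parameters,
  with step-halving so the penalized deviance never increases, and
* outer REML-type (PQL/EM) updates of the variance components
  ``sigma2_m <- (||b_m||^2 + phi tr(V_bm)) / q_m`` and of the dispersion
  ``phi`` by the Pearson estimator, where ``V`` is the joint penalized
  ("Bayesian") coefficient covariance phi (C'WC + S)^-1.

Predictions are conditional: they include the estimated random effects, and
strata never observed get the shrunken value zero with the prior variance —
which is exactly how thinly-surveyed space-time cells borrow strength.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats

from . import tweedie

__all__ = [
    "ModelSpec",
    "DesignInfo",
    "FittedComponentModel",
    "FitError",
    "RankError",
    "fit",
    "fit_tweedie_power",
    "predict",
    "wald_table",
    "randomized_quantile_residuals",
]


class FitError(RuntimeError):
    """IRLS or variance-component iteration failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class RankError(ValueError):
    """Fixed-effect design is column-rank deficient; aliased columns named."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"fixed-effect design is rank deficient; aliased columns: {self.aliased}")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one component model.

    ``fixed`` are categorical main effects (first level = reference, dropped);
    ``covariates`` enter linearly, centred at their training means;
    ``random`` lists interaction factors, each crossing declared main factors
    and carrying its own variance; ``offsets`` name columns holding log-scale
    additive known terms.
    """

    family: str  # 'gamma' | 'tweedie' | 'poisson'
    response: str
    fixed: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    random: tuple[tuple[str, ...], ...] = ()
    offsets: tuple[str, ...] = ()
    var_power: float | None = None  # Tweedie p; required for family='tweedie'

    def __post_init__(self):
        if self.family not in ("gamma", "tweedie", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        for factors in self.random:
            unknown = set(factors) - set(self.fixed)
            if unknown:
                raise ValueError(f"random term {factors} uses undeclared factors {sorted(unknown)}")


@dataclass
class DesignInfo:
    """Everything needed to rebuild the design for new data."""

    fixed_levels: dict[str, list]
    cov_centers: dict[str, float]
    random_levels: list[tuple[str, list[tuple]]]  # (term name, full level crossing)
    colnames_fixed: list[str]
    n_fixed: int
    block_slices: list[slice]


def _term_name(factors: tuple[str, ...]) -> str:
    return ":".join(factors)


def build_design(spec: ModelSpec, df: pd.DataFrame, info: DesignInfo | None = None):
    """Return (X dense, Z sparse, offset, info).  With ``info`` given, rebuild
    for new data using training levels/centres; unseen fixed levels raise."""
    n = len(df)
    new = info is None
    if new:
        fixed_levels = {f: sorted(pd.unique(df[f])) for f in spec.fixed}
        cov_centers = {c: float(df[c].mean()) for c in spec.covariates}
    else:
        fixed_levels = info.fixed_levels
        cov_centers = info.cov_centers

    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for f in spec.fixed:
        levels = fixed_levels[f]
        seen = set(pd.unique(df[f]))
        unseen = seen - set(levels)
        if unseen:
            raise ValueError(f"factor {f!r}: unseen levels {sorted(unseen)}")
        for lev in levels[1:]:
            cols.append((df[f] == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    for c in spec.covariates:
        cols.append(df[c].to_numpy(dtype=float) - cov_centers[c])
        names.append(c)
    X = np.column_stack(cols)

    if new:
        # full crossing of training levels so never-observed strata are
        # representable (their coefficients shrink to exactly zero)
        random_levels = []
        for factors in spec.random:
            combos = list(itertools.product(*(fixed_levels[f] for f in factors)))
            random_levels.append((_term_name(factors), combos))
    else:
        random_levels = info.random_levels

    zblocks = []
    block_slices = []
    start = X.shape[1]
    for (tname, combos), factors in zip(random_levels, spec.random):
        index = {c: i for i, c in enumerate(combos)}
        keys = list(zip(*(df[f] for f in factors)))
        rows = np.arange(n)
        colidx = np.array([index[k] for k in keys])
        Z = sp.csr_matrix((np.ones(n), (rows, colidx)), shape=(n, len(combos)))
        zblocks.append(Z)
        block_slices.append(slice(start, start + len(combos)))
        start += len(combos)
    Z = sp.hstack(zblocks, format="csr") if zblocks else sp.csr_matrix((n, 0))

    offset = np.zeros(n)
    for o in spec.offsets:
        offset = offset + df[o].to_numpy(dtype=float)

    if new:
        info = DesignInfo(fixed_levels=fixed_levels, cov_centers=cov_centers,
                          random_levels=random_levels, colnames_fixed=names,
                          n_fixed=X.shape[1], block_slices=block_slices)
    return X, Z, offset, info


# ---------------------------------------------------------------------------
# family helpers
# ---------------------------------------------------------------------------

def _var_power(spec: ModelSpec) -> float:
    if spec.family == "gamma":
        return 2.0
    if spec.family == "poisson":
        return 1.0
    if spec.var_power is None:
        raise ValueError("family='tweedie' requires var_power (use fit_tweedie_power)")
    return float(spec.var_power)


def _deviance(y: np.ndarray, mu: np.ndarray, spec: ModelSpec) -> float:
    if spec.family == "gamma":
        return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))
    if spec.family == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(t - (y - mu)))
    return float(np.sum(tweedie.unit_deviance(y, mu, _var_power(spec))))


def _loglik(y: np.ndarray, mu: np.ndarray, phi: float, spec: ModelSpec) -> float:
    if spec.family == "gamma":
        return float(np.sum(stats.gamma.logpdf(y, a=1.0 / phi, scale=phi * mu)))
    if spec.family == "poisson":
        return float(np.sum(stats.poisson.logpmf(np.round(y).astype(int), mu)))
    return float(np.sum(tweedie.logpdf(y, mu, phi, _var_power(spec))))


def _simulate(rng: np.random.Generator, mu: np.ndarray, phi: float,
              spec: ModelSpec) -> np.ndarray:
    if spec.family == "gamma":
        return rng.gamma(1.0 / phi, phi * mu)
    if spec.family == "poisson":
        return rng.poisson(mu).astype(float)
    return tweedie.sample_cpg(rng, mu, phi, _var_power(spec))


# ---------------------------------------------------------------------------
# fitted model container
# ---------------------------------------------------------------------------

@dataclass
class FittedComponentModel:
    """A fitted component GLMM: coefficients, covariance, family parameters."""

    spec: ModelSpec
    info: DesignInfo
    coef: np.ndarray
    cov: np.ndarray              # joint penalized (Bayesian) covariance
    phi: float
    sigma2: dict[str, float]     # variance per random term
    lambdas: dict[str, float]    # phi / sigma2 per random term
    edf: float
    deviance: float
    null_deviance: float
    loglik: float
    n: int
    y: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    offset: np.ndarray = field(repr=False)
    irls_trace: list = field(default_factory=list, repr=False)

    @property
    def var_power(self) -> float:
        return _var_power(self.spec)

    @property
    def deviance_explained(self) -> float:
        if self.null_deviance <= 0:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    @property
    def aic(self) -> float:
        n_fam = {"gamma": 1, "poisson": 0, "tweedie": 2}[self.spec.family]
        return -2.0 * self.loglik + 2.0 * (self.edf + n_fam)

    @property
    def coef_names(self) -> list[str]:
        names = list(self.info.colnames_fixed)
        for (tname, combos) in self.info.random_levels:
            names += [f"{tname}[{'_'.join(map(str, c))}]" for c in combos]
        return names

    def coef_fixed(self) -> pd.Series:
        return pd.Series(self.coef[: self.info.n_fixed],
                         index=self.info.colnames_fixed)

    def covariate_estimates(self) -> pd.Series:
        names = self.info.colnames_fixed
        idx = [names.index(c) for c in self.spec.covariates]
        return pd.Series(self.coef[idx], index=list(self.spec.covariates))

    def covariate_cov(self) -> pd.DataFrame:
        names = self.info.colnames_fixed
        idx = [names.index(c) for c in self.spec.covariates]
        sub = self.cov[np.ix_(idx, idx)]
        return pd.DataFrame(sub, index=list(self.spec.covariates),
                            columns=list(self.spec.covariates))


# ---------------------------------------------------------------------------
# core fit
# ---------------------------------------------------------------------------

def _check_fixed_rank(X: np.ndarray, names: list[str]) -> None:
    q, r, piv = sla.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        raise RankError([names[i] for i in piv[rank:]])


def fit(spec: ModelSpec, data: pd.DataFrame, *,
        max_outer: int = 60, max_irls: int = 100,
        tol_dev: float = 1e-8, tol_outer: float = 1e-3,
        lambda_bounds: tuple[float, float] = (1e-7, 1e7),
        fixed_lambdas: dict[str, float] | None = None,
        _skip_null: bool = False) -> FittedComponentModel:
    """Fit the penalized GLMM by IRLS with REML-type variance-component updates.

    The inner IRLS runs to convergence (relative change in penalized deviance
    below ``tol_dev``) at the current smoothing parameters; the outer loop
    then updates each random term's variance and the dispersion, stopping when
    the log smoothing parameters move less than ``tol_outer``.
    """
    y = data[spec.response].to_numpy(dtype=float)
    n = len(y)
    if spec.family == "gamma" and np.any(y <= 0):
        raise ValueError("gamma family requires a strictly positive response")
    if spec.family == "tweedie":
        if np.all(y == 0):
            raise ValueError("all-zero response: Tweedie power is not estimable")
        if np.any(y < 0):
            raise ValueError("Tweedie response must be nonnegative")

    X, Z, offset, info = build_design(spec, data)
    _check_fixed_rank(X, info.colnames_fixed)
    if n < info.n_fixed:
        raise ValueError(f"n={n} below the number of fixed coefficients {info.n_fixed}")
    C = sp.hstack([sp.csr_matrix(X), Z], format="csr")
    p_total = C.shape[1]
    pv = _var_power(spec)
    terms = [t for (t, _) in info.random_levels]
    qs = {t: s.stop - s.start for t, s in zip(terms, info.block_slices)}

    # initial state
    ybar = max(float(y.mean()), 1e-8)
    mu = np.clip((y + ybar) / 2.0, 1e-8, None)
    eta = np.log(mu)
    if fixed_lambdas is not None:
        missing = set(terms) - set(fixed_lambdas)
        if missing:
            raise ValueError(f"fixed_lambdas lacks terms {sorted(missing)}")
        lam = {t: float(fixed_lambdas[t]) for t in terms}
    else:
        lam = {t: 1.0 for t in terms}
    phi = 1.0
    theta = np.zeros(p_total)

    def penalty_vec(lam):
        s = np.zeros(p_total)
        for t, sl in zip(terms, info.block_slices):
            s[sl] = lam[t]
        return s

    def penalized_dev(mu, theta, lam):
        pen = sum(lam[t] * float(theta[sl] @ theta[sl])
                  for t, sl in zip(terms, info.block_slices))
        return _deviance(y, mu, spec) + pen

    trace = []
    A = None
    consistent = False  # initial mu is heuristic, not exp(offset + C@theta)
    for outer in range(max_outer):
        svec = penalty_vec(lam)
        pdev = penalized_dev(mu, theta, lam) if consistent else np.inf
        for it in range(max_irls):
            w = mu ** (2.0 - pv)
            z = (eta - offset) + (y - mu) / mu
            Cw = C.multiply(w[:, None])
            A = (C.T @ Cw).toarray()
            A[np.diag_indices_from(A)] += svec
            rhs = Cw.T @ z
            try:
                cf = sla.cho_factor(A, check_finite=False)
            except np.linalg.LinAlgError as e:  # pragma: no cover
                raise FitError(f"normal equations not positive definite: {e}", trace)
            theta_new = sla.cho_solve(cf, rhs, check_finite=False)

            # step-halving: penalized deviance must not increase
            step = 1.0
            for _ in range(30):
                cand = theta + step * (theta_new - theta)
                eta_c = np.clip(offset + C @ cand, -30.0, 30.0)
                mu_c = np.exp(eta_c)
                pdev_c = penalized_dev(mu_c, cand, lam)
                if pdev_c <= pdev * (1.0 + 1e-12) or step < 1e-6:
                    break
                step *= 0.5
            theta, eta, mu = cand, eta_c, mu_c
            consistent = True
            rel = abs(pdev - pdev_c) / max(abs(pdev_c), 1e-10)
            trace.append((outer, it, pdev_c))
            pdev = pdev_c
            if rel < tol_dev:
                break
        else:
            # flat-tail safeguard: accept when the remaining per-iteration
            # drift is negligible, error on genuine non-convergence
            if rel > 1e-6:
                raise FitError(f"IRLS failed to converge within {max_irls} "
                               f"iterations (last rel change {rel:.2e})", trace)

        # REML-type updates: posterior covariance is phi * A^{-1}
        Ainv = sla.cho_solve(sla.cho_factor(A, check_finite=False),
                             np.eye(p_total), check_finite=False)
        pearson = float(np.sum((y - mu) ** 2 / mu ** pv))
        # edf = tr[(C'WC + S)^{-1} C'WC]
        edf = p_total - float(np.sum(Ainv[np.diag_indices_from(Ainv)] * svec))
        phi = max(pearson / max(n - edf, 1.0), 1e-10)
        if spec.family == "poisson":
            phi_penalty = 1.0  # Poisson has fixed dispersion for the penalty scale
        else:
            phi_penalty = phi
        if fixed_lambdas is not None:
            break
        # Fellner-Schall update of each smoothing parameter; numerator
        # q/lambda - tr(A^{-1}) >= 0, and a vanishing ||b|| drives lambda to
        # its upper bound (the term shrinks out).  The raw update can settle
        # into a damped 2-cycle, so step 60% of the way in log space.
        moved = 0.0
        damp = 0.6
        for t, sl in zip(terms, info.block_slices):
            b = theta[sl]
            bb = float(b @ b)
            tr_block = float(np.trace(Ainv[sl, sl]))
            num = max(qs[t] / lam[t] - tr_block, 0.0)
            target = phi_penalty * num / max(bb, 1e-300) if num > 0 else lambda_bounds[1]
            target = float(np.clip(target, *lambda_bounds))
            lam_new = float(np.exp(np.log(lam[t])
                                   + damp * (np.log(target) - np.log(lam[t]))))
            lam_new = float(np.clip(lam_new, *lambda_bounds))
            moved = max(moved, abs(np.log(lam_new) - np.log(lam[t])))
            lam[t] = lam_new
        if moved < tol_outer:
            break
    else:
        if terms:  # only an error when there were smoothing parameters to tune
            raise FitError(f"variance components failed to settle in {max_outer} outer "
                           f"iterations", trace)

    phi_penalty = 1.0 if spec.family == "poisson" else phi
    sigma2 = {t: phi_penalty / lam[t] for t in terms}
    dev = _deviance(y, mu, spec)
    cov = phi_penalty * Ainv
    ll = _loglik(y, mu, phi, spec)

    if _skip_null or (not spec.fixed and not spec.covariates and not spec.random):
        null_dev = dev
    else:
        null_spec = replace(spec, fixed=(), covariates=(), random=())
        null_fit = fit(null_spec, data, _skip_null=True)
        null_dev = null_fit.deviance

    return FittedComponentModel(
        spec=spec, info=info, coef=theta, cov=cov, phi=phi, sigma2=sigma2,
        lambdas=dict(lam), edf=edf, deviance=dev, null_deviance=null_dev,
        loglik=ll, n=n, y=y, fitted=mu, offset=offset, irls_trace=trace,
    )


# ---------------------------------------------------------------------------
# Tweedie power profiling
# ---------------------------------------------------------------------------

def fit_tweedie_power(spec: ModelSpec, data: pd.DataFrame,
                      p_grid=(1.05, 1.15, 1.3, 1.5, 1.7, 1.9),
                      refine: bool = True, refine_tol: float = 1e-3,
                      **fit_kw) -> FittedComponentModel:
    """Profile the Tweedie power p over a grid, optionally golden-section refined.

    Each candidate p gets a full penalized fit; candidates are scored by the
    Tweedie log-likelihood (Dunn-Smyth density) at the Pearson dispersion
    estimate, and the maximiser is refined to ``refine_tol`` by golden-section
    search between its grid neighbours.
    """
    y = data[spec.response].to_numpy(dtype=float)
    if np.all(y == 0):
        raise ValueError("all-zero response")
    if not np.any(y == 0):
        raise ValueError("response has no zeros; a gamma model is appropriate instead")
    if not np.any(y > 0):
        raise ValueError("response has no positive values")

    cache: dict[float, FittedComponentModel] = {}

    def score(p: float) -> float:
        p = float(np.clip(p, 1.01, 1.99))
        if p not in cache:
            cache[p] = fit(replace(spec, family="tweedie", var_power=p), data, **fit_kw)
        return cache[p].loglik

    grid = sorted(float(p) for p in p_grid)
    lls = [score(p) for p in grid]
    k = int(np.argmax(lls))
    best = grid[k]
    if refine and len(grid) > 1:
        lo = grid[k - 1] if k > 0 else max(1.01, grid[0] - 0.05)
        hi = grid[k + 1] if k < len(grid) - 1 else min(1.99, grid[-1] + 0.05)
        res = optimize.minimize_scalar(lambda p: -score(p), bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": refine_tol})
        if -res.fun >= lls[k]:
            best = float(np.clip(res.x, 1.01, 1.99))
            score(best)
    return cache[min(cache, key=lambda p: abs(p - best))]


# ---------------------------------------------------------------------------
# prediction and inference
# ---------------------------------------------------------------------------

def predict(model: FittedComponentModel, newdata: pd.DataFrame):
    """Conditional prediction: (mean on response scale, SE of linear predictor).

    The linear predictor includes fixed effects, the estimated random effects
    (zero, i.e. fully shrunk, for strata without data) and any offsets present
    in ``newdata``; the SE comes from the joint penalized covariance.
    """
    X, Z, offset, _ = build_design(model.spec, newdata, info=model.info)
    C = sp.hstack([sp.csr_matrix(X), Z], format="csr")
    eta = offset + C @ model.coef
    CV = C @ model.cov
    var_eta = np.einsum("ij,ij->i", np.asarray(CV), C.toarray())
    return np.exp(eta), np.sqrt(np.maximum(var_eta, 0.0))


def wald_table(model: FittedComponentModel) -> pd.DataFrame:
    """Estimates, SEs, z and two-sided normal p for the unpenalized coefficients."""
    k = model.info.n_fixed
    est = model.coef[:k]
    se = np.sqrt(np.diag(model.cov)[:k])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    p = np.where(np.isfinite(z), 2.0 * stats.norm.sf(np.abs(z)), 0.0)
    p = np.where((est == 0) & (se == 0), 1.0, p)
    return pd.DataFrame({"term": model.info.colnames_fixed,
                         "estimate": est, "se": se, "z": z, "p": p})


BUNDLE_VERSION = 1


def to_bundle(model: FittedComponentModel) -> dict:
    """Serialize a fitted model to a versioned JSON-compatible bundle."""
    info = model.info
    return {
        "bundle_version": BUNDLE_VERSION,
        "spec": {
            "family": model.spec.family,
            "response": model.spec.response,
            "fixed": list(model.spec.fixed),
            "covariates": list(model.spec.covariates),
            "random": [list(t) for t in model.spec.random],
            "offsets": list(model.spec.offsets),
            "var_power": model.spec.var_power,
        },
        "info": {
            "fixed_levels": {k: list(v) for k, v in info.fixed_levels.items()},
            "cov_centers": dict(info.cov_centers),
            "random_levels": [[t, [list(c) for c in combos]]
                              for t, combos in info.random_levels],
            "colnames_fixed": list(info.colnames_fixed),
            "n_fixed": info.n_fixed,
            "block_slices": [[s.start, s.stop] for s in info.block_slices],
        },
        "coef": model.coef.tolist(),
        "cov": model.cov.tolist(),
        "phi": model.phi,
        "sigma2": dict(model.sigma2),
        "lambdas": dict(model.lambdas),
        "edf": model.edf,
        "deviance": model.deviance,
        "null_deviance": model.null_deviance,
        "loglik": model.loglik,
        "n": model.n,
        "y": model.y.tolist(),
        "fitted": model.fitted.tolist(),
        "offset": model.offset.tolist(),
    }


def from_bundle(bundle: dict) -> FittedComponentModel:
    """Rebuild a fitted model from :func:`to_bundle` output."""
    if bundle.get("bundle_version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {bundle.get('bundle_version')}")
    s = bundle["spec"]
    spec = ModelSpec(family=s["family"], response=s["response"],
                     fixed=tuple(s["fixed"]), covariates=tuple(s["covariates"]),
                     random=tuple(tuple(t) for t in s["random"]),
                     offsets=tuple(s["offsets"]), var_power=s["var_power"])
    i = bundle["info"]
    info = DesignInfo(
        fixed_levels={k: list(v) for k, v in i["fixed_levels"].items()},
        cov_centers=dict(i["cov_centers"]),
        random_levels=[(t, [tuple(c) for c in combos])
                       for t, combos in i["random_levels"]],
        colnames_fixed=list(i["colnames_fixed"]),
        n_fixed=int(i["n_fixed"]),
        block_slices=[slice(a, b) for a, b in i["block_slices"]],
    )
    return FittedComponentModel(
        spec=spec, info=info,
        coef=np.asarray(bundle["coef"], dtype=float),
        cov=np.asarray(bundle["cov"], dtype=float),
        phi=float(bundle["phi"]), sigma2=dict(bundle["sigma2"]),
        lambdas=dict(bundle["lambdas"]), edf=float(bundle["edf"]),
        deviance=float(bundle["deviance"]),
        null_deviance=float(bundle["null_deviance"]),
        loglik=float(bundle["loglik"]), n=int(bundle["n"]),
        y=np.asarray(bundle["y"], dtype=float),
        fitted=np.asarray(bundle["fitted"], dtype=float),
        offset=np.asarray(bundle["offset"], dtype=float),
    )


def randomized_quantile_residuals(model: FittedComponentModel,
                                  seed: int | np.random.Generator = 0,
                                  n_sim: int = 250) -> np.ndarray:
    """Simulation-based PIT residuals on (0, 1), uniform under a correct model.

    For each observation the residual is the (tie-randomized) position of the
    observed value among ``n_sim`` draws from the fitted distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = np.stack([_simulate(rng, model.fitted, model.phi, model.spec)
                     for _ in range(n_sim)])
    below = (sims < model.y).sum(axis=0)
    ties = (sims == model.y).sum(axis=0)
    u = rng.uniform(size=model.n)
    return (below + u * (1 + ties)) / (n_sim + 1.0)
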