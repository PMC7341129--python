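"""Maximum-likelihood DFE estimation from paired uSFS datasets.

The likelihood is the independent-Poisson (PRF) likelihood over the
neutral uSFS entries (mean ``theta*L_neut/i``), the selected entries (mean
from the DFE-averaged expected uSFS) and, when divergence is modelled, the
two substitution counts.  The full model is a gamma distribution of
deleterious effects plus a discrete beneficial class (``p_a``, ``gamma_a``);
the null model fixes ``p_a = 0`` and drops both beneficial parameters.

Fitting and testing follow the standard uSFS-analysis workflow: data-driven
initial parameters, bounded quasi-Newton maximization on transformed scales
(log for theta, |mean_gamma_d|, beta, gamma_a and the divergence scale
delta; logit for p_a) with jittered restarts, a likelihood-ratio test of
the beneficial class against chi-square with 2 degrees of freedom, Akaike
model averaging of the two models, and grid likelihood surfaces in
(gamma_a, p_a) with nuisance parameters re-optimized at each grid point.

Bin-wise distortion and ancestral-mispolarization nuisances are deliberately
not modelled: the synthetic data here are undistorted and perfectly
polarized, which isolates the identifiability of the positive-selection
parameters themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .dfe_model import DFEParams, make_dfe
from .prf_core import (
    _class_means,
    _dfe_nodes,
    alpha_dfe,
    relative_fixation_rate,
)
from .usfs_summaries import USFSDataset

__all__ = [
    "InferenceParams",
    "FitResult",
    "LikelihoodSurface",
    "neg_log_likelihood",
    "initial_params",
    "fit_model",
    "likelihood_ratio_test",
    "akaike_average",
    "likelihood_surface",
    "alpha_from_fit",
]

_PENALTY = 1e12
GRADIENT_TOL = 0.01  # max-norm on the transformed scale


@dataclass(frozen=True)
class InferenceParams:
    """Free parameters of the PRF likelihood (natural scale)."""

    theta_site: float
    beta: float
    mean_gamma_d: float
    p_a: float = 0.0
    gamma_a: float = 0.0
    delta_neut: Optional[float] = None

    def dfe(self) -> DFEParams:
        return make_dfe(self.beta, self.mean_gamma_d, self.p_a, self.gamma_a)


@dataclass
class FitResult:
    model: str                      # 'full' | 'null'
    with_divergence: bool
    estimates: InferenceParams
    loglik: float
    gradient_norm: float
    converged: bool
    n_params: int
    aic: float
    n_starts: int = 1
    seed: Optional[int] = None
    data_fingerprint: tuple = ()


@dataclass
class LikelihoodSurface:
    gamma_a_grid: np.ndarray
    p_a_grid: np.ndarray
    delta_loglik: np.ndarray        # (len(gamma_a_grid), len(p_a_grid)), >= 0
    loglik: np.ndarray              # raw profile log-likelihoods
    best_loglik: float


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _poisson_loglik(counts, means) -> float:
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    if np.any(means < 0) or np.any((means == 0) & (counts > 0)):
        return -_PENALTY
    safe = np.where(means > 0, means, 1.0)
    return float(np.sum(counts * np.log(safe) - means - special.gammaln(counts + 1.0)))


def _mean_fixation_rate(dfe: DFEParams) -> float:
    """DFE-averaged relative fixation rate on the fixed quadrature nodes.

    Node-based (not adaptive) so the likelihood stays smooth in the
    parameters; cross-checked against the adaptive-quadrature route in the
    test suite.
    """
    gammas, weights = _dfe_nodes(dfe)
    return float(weights @ relative_fixation_rate(gammas))


def expected_means(params: InferenceParams, data: USFSDataset,
                   with_divergence: bool):
    """Poisson means implied by ``params`` for every observed count."""
    n = data.n_chrom
    i = np.arange(1, n)
    neut_poly = params.theta_site * data.L_neut / i
    dfe = params.dfe()
    cm = _class_means(dfe, n)
    sel_poly = params.theta_site * data.L_sel * cm[: n - 1]
    if not with_divergence:
        return neut_poly, sel_poly, None, None
    cm0 = _class_means(0.0, n)
    mu_div_neut = (params.delta_neut * data.L_neut
                   + params.theta_site * data.L_neut * cm0[n - 1])
    mu_div_sel = (params.delta_neut * data.L_sel * _mean_fixation_rate(dfe)
                  + params.theta_site * data.L_sel * cm[n - 1])
    return neut_poly, sel_poly, mu_div_neut, mu_div_sel


def neg_log_likelihood(params: InferenceParams, data: USFSDataset,
                       with_divergence: bool = True) -> float:
    """Negative Poisson log-likelihood of a dataset under the PRF model.

    Invalid parameter values (including ``theta = 0`` against non-zero
    counts) yield a large finite penalty rather than raising, so that
    optimizers can recover.
    """
    if with_divergence and not data.has_divergence:
        raise ValueError("with_divergence requested but dataset has no divergence counts")
    if with_divergence and params.delta_neut is None:
        raise ValueError("with_divergence requires a delta_neut parameter")
    try:
        neut_mu, sel_mu, dn_mu, ds_mu = expected_means(params, data, with_divergence)
    except (ValueError, FloatingPointError):
        return _PENALTY
    ll = _poisson_loglik(data.neutral_sfs, neut_mu)
    ll += _poisson_loglik(data.selected_sfs, sel_mu)
    if with_divergence:
        ll += _poisson_loglik([data.div_neut], [dn_mu])
        ll += _poisson_loglik([data.div_sel], [ds_mu])
    if not np.isfinite(ll):
        return _PENALTY
    return -ll


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

_INIT_P_A = 0.005
_INIT_GAMMA_A = 10.0
_INIT_BETA_GRID = (0.1, 0.2, 0.3, 0.5, 0.8, 1.2)
_INIT_MEAN_GRID = (-50.0, -200.0, -1000.0, -2000.0, -10000.0, -50000.0)


def initial_params(data: USFSDataset,
                   with_divergence: bool = True) -> InferenceParams:
    """Data-driven starting values for the maximization.

    theta from the neutral-SFS maximum under the 1/i law; the deleterious
    gamma parameters from a coarse deterministic profile over (beta, mean)
    against the observed selected uSFS; fixed mild starting values for the
    beneficial class (``p_a = 0.005``, ``gamma_a = 10``); the divergence
    scale from the neutral substitution count.
    """
    if data.neutral_sfs.sum() == 0:
        raise ValueError("cannot initialize from an all-zero neutral uSFS")
    n = data.n_chrom
    i = np.arange(1, n)
    harmonic = np.sum(1.0 / i)
    theta0 = float(data.neutral_sfs.sum() / (data.L_neut * harmonic))

    obs = data.selected_sfs.astype(float)
    best = None
    for beta in _INIT_BETA_GRID:
        for mean in _INIT_MEAN_GRID:
            cm = _class_means(make_dfe(beta, mean, 0.0, 0.0), n)[: n - 1]
            pred = theta0 * data.L_sel * cm
            score = float(np.sum((np.log(pred + 0.5) - np.log(obs + 0.5)) ** 2))
            if best is None or score < best[0]:
                best = (score, beta, mean)
    _, beta0, mean0 = best

    delta0 = None
    if with_divergence:
        if not data.has_divergence:
            raise ValueError("with_divergence requested but dataset has no divergence counts")
        fixed_neut = theta0 / n  # expected sample-fixed neutral alleles per site
        delta0 = max((data.div_neut / data.L_neut) - fixed_neut, 1e-6)
    return InferenceParams(theta_site=theta0, beta=beta0, mean_gamma_d=mean0,
                           p_a=_INIT_P_A, gamma_a=_INIT_GAMMA_A, delta_neut=delta0)


# ---------------------------------------------------------------------------
# Transformed-scale optimization
# ---------------------------------------------------------------------------

_BOUNDS = {
    "log_theta": (np.log(1e-8), np.log(10.0)),
    "log_beta": (np.log(0.01), np.log(10.0)),
    "log_mean": (np.log(1e-2), np.log(1e7)),       # |mean_gamma_d|
    "logit_pa": (special.logit(1e-10), special.logit(0.9999)),
    "log_gamma_a": (np.log(1e-3), np.log(1e4)),
    "log_delta": (np.log(1e-10), np.log(10.0)),
}


def _free_names(model: str, with_divergence: bool) -> list:
    names = ["log_theta", "log_beta", "log_mean"]
    if model == "full":
        names += ["logit_pa", "log_gamma_a"]
    if with_divergence:
        names.append("log_delta")
    return names


def _pack(params: InferenceParams, names: Sequence[str]) -> np.ndarray:
    vals = {
        "log_theta": np.log(params.theta_site),
        "log_beta": np.log(params.beta),
        "log_mean": np.log(abs(params.mean_gamma_d)),
        "logit_pa": special.logit(np.clip(params.p_a, 1e-10, 0.9999)),
        "log_gamma_a": np.log(max(params.gamma_a, 1e-3)),
        "log_delta": (np.log(params.delta_neut)
                      if params.delta_neut is not None else 0.0),
    }
    lo = np.array([_BOUNDS[n][0] for n in names])
    hi = np.array([_BOUNDS[n][1] for n in names])
    return np.clip(np.array([vals[n] for n in names], dtype=float), lo, hi)


def _unpack(x: np.ndarray, names: Sequence[str], model: str,
            with_divergence: bool) -> InferenceParams:
    d = dict(zip(names, x))
    return InferenceParams(
        theta_site=float(np.exp(d["log_theta"])),
        beta=float(np.exp(d["log_beta"])),
        mean_gamma_d=-float(np.exp(d["log_mean"])),
        p_a=float(special.expit(d["logit_pa"])) if model == "full" else 0.0,
        gamma_a=float(np.exp(d["log_gamma_a"])) if model == "full" else 0.0,
        delta_neut=float(np.exp(d["log_delta"])) if with_divergence else None,
    )


def fit_model(data: USFSDataset, model: str = "full",
              with_divergence: bool = True, n_starts: int = 5,
              seed: Optional[int] = None,
              init: Optional[InferenceParams] = None) -> FitResult:
    """Fit the full or null DFE model by bounded quasi-Newton maximization.

    The first start uses the data-driven initialization; the remaining
    ``n_starts - 1`` jitter it multiplicatively (factor ~2) on the
    transformed scale.  The best start by log-likelihood (ties broken by
    lower gradient norm) is returned; ``converged`` records whether the
    final gradient max-norm fell below 0.01.
    """
    if model not in ("full", "null"):
        raise ValueError("model must be 'full' or 'null'")
    names = _free_names(model, with_divergence)
    if init is None:
        init = initial_params(data, with_divergence=with_divergence)
    x0 = _pack(init, names)
    bounds = [_BOUNDS[n] for n in names]
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        p = _unpack(x, names, model, with_divergence)
        return neg_log_likelihood(p, data, with_divergence)

    best = None
    failures = []
    for start in range(max(1, n_starts)):
        if start == 0:
            xs = x0.copy()
        else:
            jitter = rng.normal(0.0, np.log(2.0), size=len(names))
            xs = np.clip(x0 + jitter, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = optimize.minimize(objective, xs, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 500, "maxfun": 4000})
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(repr(exc))
            continue
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        cand = (-res.fun, -gnorm, res.x)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        raise RuntimeError(f"all optimizer starts failed: {failures}")

    loglik, neg_gnorm, x_best = best
    est = _unpack(x_best, names, model, with_divergence)
    k = len(names)
    return FitResult(
        model=model,
        with_divergence=with_divergence,
        estimates=est,
        loglik=float(loglik),
        gradient_norm=-neg_gnorm,
        converged=-neg_gnorm < GRADIENT_TOL,
        n_params=k,
        aic=2.0 * k - 2.0 * float(loglik),
        n_starts=n_starts,
        seed=seed,
        data_fingerprint=_fingerprint(data),
    )


def _fingerprint(data: USFSDataset) -> tuple:
    return (
        data.n_chrom, float(data.L_neut), float(data.L_sel),
        int(data.neutral_sfs.sum()), int(data.selected_sfs.sum()),
        data.div_neut, data.div_sel,
    )


# ---------------------------------------------------------------------------
# Tests, averaging, surfaces
# ---------------------------------------------------------------------------


def likelihood_ratio_test(full: FitResult, null: FitResult) -> tuple[float, float]:
    """LRT of the beneficial class: 2*dlnL against chi-square, 2 df.

    The statistic is clipped at zero (the null is nested on the ``p_a = 0``
    boundary, where the plain chi-square reference is conservative).
    """
    if full.model != "full" or null.model != "null":
        raise ValueError("arguments must be a full-model and a null-model fit")
    if full.with_divergence != null.with_divergence:
        raise ValueError("fits differ in divergence mode")
    if full.data_fingerprint != null.data_fingerprint:
        raise ValueError("fits were obtained from different datasets")
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    return stat, float(stats.chi2.sf(stat, df=2))


@dataclass
class ModelAverage:
    weight_full: float
    weight_null: float
    params: InferenceParams
    alpha_dfe: float


def akaike_average(full: FitResult, null: FitResult) -> ModelAverage:
    """Akaike-weighted average of the full and null fits.

    Weights are ``exp(-dAIC/2)`` normalized over the two models; the null
    contributes 0 to ``p_a``, ``gamma_a`` and ``alpha_DFE``.
    """
    if full.data_fingerprint != null.data_fingerprint:
        raise ValueError("fits were obtained from different datasets")
    d_full = full.aic - min(full.aic, null.aic)
    d_null = null.aic - min(full.aic, null.aic)
    wf = np.exp(-d_full / 2.0)
    wn = np.exp(-d_null / 2.0)
    tot = wf + wn
    wf, wn = float(wf / tot), float(wn / tot)
    ef, en = full.estimates, null.estimates
    if ef.delta_neut is not None and en.delta_neut is not None:
        delta = wf * ef.delta_neut + wn * en.delta_neut
    else:
        delta = ef.delta_neut if ef.delta_neut is not None else en.delta_neut
    params = InferenceParams(
        theta_site=wf * ef.theta_site + wn * en.theta_site,
        beta=wf * ef.beta + wn * en.beta,
        mean_gamma_d=wf * ef.mean_gamma_d + wn * en.mean_gamma_d,
        p_a=wf * ef.p_a,
        gamma_a=wf * ef.gamma_a,
        delta_neut=delta,
    )
    return ModelAverage(weight_full=wf, weight_null=wn, params=params,
                        alpha_dfe=wf * alpha_from_fit(full))


def likelihood_surface(data: USFSDataset, gamma_a_grid, p_a_grid,
                       with_divergence: bool = True, n_starts: int = 1,
                       seed: Optional[int] = None) -> LikelihoodSurface:
    """Profile log-likelihood over a (gamma_a, p_a) grid.

    At each grid point the beneficial parameters are held fixed and the
    remaining parameters re-optimized (warm-started from the neighbouring
    cell).  ``delta_loglik`` is the best grid profile log-likelihood minus
    each cell's, so it is >= 0 with 0 at the grid optimum; failed cells are
    recorded as NaN rather than raising.
    """
    gamma_a_grid = np.asarray(gamma_a_grid, dtype=float)
    p_a_grid = np.asarray(p_a_grid, dtype=float)
    if gamma_a_grid.size == 0 or p_a_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    names = _free_names("null", with_divergence)  # nuisances only
    init = initial_params(data, with_divergence=with_divergence)
    bounds = [_BOUNDS[n] for n in names]
    ll = np.full((gamma_a_grid.size, p_a_grid.size), np.nan)
    x_prev = _pack(init, names)
    for a, ga in enumerate(gamma_a_grid):
        x_row_start = x_prev.copy()
        for b, pa in enumerate(p_a_grid):

            def objective(x):
                nuis = _unpack(x, names, "null", with_divergence)
                p = replace(nuis, p_a=float(pa), gamma_a=float(ga))
                return neg_log_likelihood(p, data, with_divergence)

            try:
                res = optimize.minimize(objective, x_prev, method="L-BFGS-B",
                                        bounds=bounds,
                                        options={"maxiter": 300, "maxfun": 2000})
                ll[a, b] = -res.fun
                x_prev = res.x
            except Exception:
                pass
            if b == 0:
                x_row_start = x_prev.copy()
        x_prev = x_row_start
    best = float(np.nanmax(ll))
    return LikelihoodSurface(gamma_a_grid=gamma_a_grid, p_a_grid=p_a_grid,
                             delta_loglik=best - ll, loglik=ll, best_loglik=best)


def alpha_from_fit(fit: FitResult) -> float:
    """alpha_DFE implied by a fitted model (0 for the null by construction)."""
    if fit.model == "null" or fit.estimates.p_a == 0.0:
        return 0.0
    return alpha_dfe(fit.estimates.dfe())
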