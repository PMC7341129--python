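"""Poisson-random-field expectations for the unfolded SFS and divergence.

Under the PRF model each uSFS entry is an independent Poisson count whose
mean follows from the diffusion sojourn density of a semidominant mutation
with scaled effect ``gamma = 2*N_e*s`` (homozygote ``s``, ``h = 1/2``):

    tau(x; gamma) = (1 - exp(-gamma*(1-x))) / (x*(1-x)*(1 - exp(-gamma)))

with the neutral limit ``1/x``.  The expected count in sample-frequency
class ``i`` of ``2n`` genome copies, for ``L`` sites at scaled mutation rate
``theta = 4*N_e*mu`` per site, is

    E[SFS_i] = theta*L * Integral_0^1 Binom(i; 2n, x) * tau(x; gamma) dx,

averaged over the DFE when a full :class:`~usfsdfe.dfe_model.DFEParams` is
supplied.  The relative fixation rate ``r(gamma) = gamma/(1 - exp(-gamma))``
(fixation probability relative to a neutral mutation) gives expected
divergence and the model-implied proportion of adaptive substitutions,
``alpha_DFE``.

Numerics: the frequency integral uses composite Gauss-Legendre panels that
are geometrically refined toward both endpoints, so sojourn densities
concentrated near 0 (strongly deleterious) or near 1 (strongly beneficial)
are resolved for |gamma| up to at least 1e4; exponentials are evaluated in
log space for gamma < 0.  The DFE average substitutes the gamma quantile
function and integrates over (0,1) on a fixed panelled grid, which keeps the
likelihood a smooth deterministic function of the DFE parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats

from .dfe_model import DFEParams, dfe_expectation
from .usfs_summaries import USFSDataset

__all__ = [
    "ExpectedUSFS",
    "sojourn_density",
    "expected_usfs",
    "expected_fixed_class",
    "relative_fixation_rate",
    "alpha_dfe",
    "expected_divergence",
    "expected_dataset",
    "sample_poisson_usfs",
]

# ---------------------------------------------------------------------------
# Sojourn density
# ---------------------------------------------------------------------------


def sojourn_density(x, gamma: float):
    """Scaled sojourn density tau(x; gamma) of a semidominant mutation.

    Parameters
    ----------
    x : float or array
        Population frequency, strictly inside (0, 1).
    gamma : float
        Scaled selection coefficient ``2*N_e*s`` (homozygote).

    Returns the expected (scaled) time a new mutation spends at frequency
    ``x``; ``1/x`` at ``gamma = 0``.  Stable for ``|gamma|`` up to 1e4 and
    beyond: positive gamma uses ``expm1`` directly, negative gamma is
    evaluated in log space to avoid overflow.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("population frequency x must lie strictly in (0, 1)")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = _tau_matrix(x, np.array([float(gamma)]))[:, 0]
    return float(out[0]) if scalar else out


def relative_fixation_rate(gamma):
    """Fixation probability of a new mutation relative to neutral.

    ``r(gamma) = gamma / (1 - exp(-gamma))`` with ``r(0) = 1``; tends to
    ``gamma`` for strongly beneficial and to 0 for strongly deleterious
    effects, without overflow at any float input.
    """
    g = np.asarray(gamma, dtype=float)
    scalar = g.ndim == 0
    g = np.atleast_1d(g)
    out = np.empty_like(g)
    zero = g == 0.0
    pos = g > 0.0
    neg = g < 0.0
    out[zero] = 1.0
    out[pos] = g[pos] / (-np.expm1(-g[pos]))
    # gamma < 0:  r = gamma * e^gamma / (e^gamma - 1); e^gamma underflows
    # harmlessly to 0 for gamma << -700.
    out[neg] = g[neg] * np.exp(g[neg]) / np.expm1(g[neg])
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Quadrature grids
# ---------------------------------------------------------------------------

# frequency panels, refined toward 0 and 1 so that sojourn densities with
# scales down to ~1e-5 from either endpoint are resolved
_X_BREAKS = np.array(
    [0.0, 1e-4, 1e-2, 0.1, 0.5, 0.9, 0.99, 0.9999, 1.0]
)
# quantile-space panels for the deleterious gamma integral, refined toward
# u = 0 where the effect magnitude changes fastest for shape < 1
_U_BREAKS = np.array([0.0, 1e-3, 0.01, 0.05, 0.15, 0.35, 0.65, 1.0])
_U_NODES_PER_PANEL = 10


def _panel_gauss(breaks: np.ndarray, k: int):
    """Composite Gauss-Legendre nodes/weights on the given panels."""
    xg, wg = np.polynomial.legendre.leggauss(k)
    nodes, weights = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        nodes.append(0.5 * (a + b) + half * xg)
        weights.append(half * wg)
    return np.concatenate(nodes), np.concatenate(weights)


_UNODES, _UWEIGHTS = _panel_gauss(_U_BREAKS, _U_NODES_PER_PANEL)


@dataclass
class _FreqGrid:
    x: np.ndarray
    w: np.ndarray
    pmf: np.ndarray  # (n_chrom, n_nodes): binomial pmf rows for i = 1 .. 2n


_GRID_CACHE: dict = {}


def _freq_grid(n_chrom: int) -> _FreqGrid:
    grid = _GRID_CACHE.get(n_chrom)
    if grid is None:
        # per-panel order exact for the degree-(2n-1) neutral polynomial
        k = max(22, n_chrom // 2 + 3)
        x, w = _panel_gauss(_X_BREAKS, k)
        i = np.arange(1, n_chrom + 1)[:, None]
        logpmf = (
            special.gammaln(n_chrom + 1)
            - special.gammaln(i + 1)
            - special.gammaln(n_chrom - i + 1)
            + i * np.log(x[None, :])
            + (n_chrom - i) * np.log1p(-x[None, :])
        )
        grid = _FreqGrid(x=x, w=w, pmf=np.exp(logpmf))
        _GRID_CACHE[n_chrom] = grid
    return grid


def _tau_matrix(x: np.ndarray, gammas: np.ndarray) -> np.ndarray:
    """Sojourn density on the (frequency, gamma) grid, shape (Nx, G)."""
    xc = (x * (1.0 - x))[:, None]
    out = np.empty((x.size, gammas.size))
    near_zero = np.abs(gammas) < 1e-12
    pos = (gammas > 0) & ~near_zero
    neg = (gammas < 0) & ~near_zero
    if near_zero.any():
        out[:, near_zero] = (1.0 / x)[:, None]
    if pos.any():
        g = gammas[pos][None, :]
        out[:, pos] = np.expm1(-g * (1.0 - x)[:, None]) / np.expm1(-g) / xc
    if neg.any():
        b = -gammas[neg][None, :]
        a = b * (1.0 - x)[:, None]
        # log(1 - e^-t) = log(-expm1(-t)), accurate from t ~ 1e-300 to t >> 1
        out[:, neg] = np.exp((a - b) + np.log(-np.expm1(-a)) - np.log(-np.expm1(-b))) / xc
    return out


def _sfs_integrals(gammas: np.ndarray, n_chrom: int) -> np.ndarray:
    """Matrix of Integral binom(i; 2n, x) tau(x; gamma) dx.

    Returns shape ``(n_chrom, len(gammas))`` with rows i = 1 .. 2n (the last
    row is the sample-fixed class).
    """
    grid = _freq_grid(n_chrom)
    tau = _tau_matrix(grid.x, np.asarray(gammas, dtype=float))
    return grid.pmf @ (tau * grid.w[:, None])


_PPF_CACHE: dict = {}


def _del_base_quantiles(beta: float) -> np.ndarray:
    """Unit-scale gamma quantiles at the u-nodes, cached per shape.

    During optimization most finite-difference steps leave the shape
    untouched, so caching on ``beta`` avoids recomputing the ppf."""
    base = _PPF_CACHE.get(beta)
    if base is None:
        if len(_PPF_CACHE) > 512:
            _PPF_CACHE.clear()
        base = stats.gamma.ppf(_UNODES, a=beta)
        _PPF_CACHE[beta] = base
    return base


def _dfe_nodes(dfe: DFEParams):
    """Quadrature nodes (gammas) and weights for averaging over the DFE."""
    gammas = []
    weights = []
    if dfe.p_a < 1.0:
        g_del = _del_base_quantiles(dfe.beta) * dfe.del_scale
        gammas.append(-g_del)
        weights.append((1.0 - dfe.p_a) * _UWEIGHTS)
    if dfe.p_a > 0.0:
        gammas.append(np.array([dfe.gamma_a]))
        weights.append(np.array([dfe.p_a]))
    return np.concatenate(gammas), np.concatenate(weights)


_NEUTRAL_MEANS_CACHE: dict = {}


def _class_means(dfe_or_gamma, n_chrom: int) -> np.ndarray:
    """Per-theta*L expected counts for classes i = 1 .. 2n."""
    if isinstance(dfe_or_gamma, DFEParams):
        gammas, weights = _dfe_nodes(dfe_or_gamma)
        return _sfs_integrals(gammas, n_chrom) @ weights
    g = float(dfe_or_gamma)
    if g == 0.0:
        cached = _NEUTRAL_MEANS_CACHE.get(n_chrom)
        if cached is None:
            cached = _sfs_integrals(np.array([0.0]), n_chrom)[:, 0]
            _NEUTRAL_MEANS_CACHE[n_chrom] = cached
        return cached
    return _sfs_integrals(np.array([g]), n_chrom)[:, 0]


# ---------------------------------------------------------------------------
# Public expectations
# ---------------------------------------------------------------------------


def expected_usfs(dfe_or_gamma, n_chrom: int, theta_site: float, L: float) -> np.ndarray:
    """Expected uSFS counts for frequency classes ``1 .. 2n-1``.

    ``dfe_or_gamma`` is either a fixed scaled effect or a
    :class:`~usfsdfe.dfe_model.DFEParams` to average over.  At ``gamma = 0``
    the result is the neutral ``theta*L/i`` law.
    """
    if n_chrom < 4 or n_chrom % 2:
        raise ValueError("n_chrom must be an even integer >= 4")
    if theta_site < 0 or L < 0:
        raise ValueError("theta_site and L must be non-negative")
    vals = theta_site * L * _class_means(dfe_or_gamma, n_chrom)[: n_chrom - 1]
    if not np.all(np.isfinite(vals)):
        bad = int(np.flatnonzero(~np.isfinite(vals))[0]) + 1
        raise FloatingPointError(
            f"expected uSFS quadrature produced a non-finite value in frequency class {bad}"
        )
    return vals


def expected_fixed_class(dfe_or_gamma, n_chrom: int, theta_site: float, L: float) -> float:
    """Expected count of derived alleles fixed in the sample (class ``2n``).

    These are polymorphic in the population but appear as substitutions in
    the sample; they are pooled with divergence counts when divergence is
    modelled.
    """
    return float(theta_site * L * _class_means(dfe_or_gamma, n_chrom)[n_chrom - 1])


def alpha_dfe(dfe: DFEParams) -> float:
    """Proportion of adaptive substitutions implied by a full DFE.

    ``p_a*r(gamma_a) / (p_a*r(gamma_a) + (1-p_a)*E_del[r])`` where ``r`` is
    the relative fixation rate; 0 when ``p_a = 0``.
    """
    if dfe.p_a == 0.0:
        return 0.0
    num = dfe.p_a * relative_fixation_rate(dfe.gamma_a)
    den = dfe_expectation(relative_fixation_rate, dfe)
    return float(num / den)


def expected_divergence(dfe: DFEParams, delta_neut: float, L_sel: float,
                        L_neut: float) -> tuple[float, float]:
    """Expected substitution counts (selected, neutral).

    ``delta_neut`` is the per-site neutral divergence (``mu*T`` under the
    simulation model); the selected class accumulates substitutions at the
    neutral rate times the DFE-averaged relative fixation rate.
    """
    if delta_neut < 0:
        raise ValueError("delta_neut must be non-negative")
    r_bar = dfe_expectation(relative_fixation_rate, dfe)
    return float(delta_neut * L_sel * r_bar), float(delta_neut * L_neut)


@dataclass
class ExpectedUSFS:
    """Expected uSFS and divergence under the PRF model."""

    selected: np.ndarray
    neutral: np.ndarray
    n_chrom: int
    theta_site: float
    L_sel: float
    L_neut: float
    exp_div_sel: Optional[float] = None
    exp_div_neut: Optional[float] = None

    def to_dataset(self) -> USFSDataset:
        """Expectation rounded to integer counts, for the uSFS text format."""
        div = self.exp_div_sel is not None
        return USFSDataset(
            neutral_sfs=np.rint(self.neutral).astype(np.int64),
            selected_sfs=np.rint(self.selected).astype(np.int64),
            L_neut=self.L_neut, L_sel=self.L_sel, n_chrom=self.n_chrom,
            div_neut=int(round(self.exp_div_neut)) if div else None,
            div_sel=int(round(self.exp_div_sel)) if div else None,
            provenance={"generator": "prf-expectation",
                        "theta_site": self.theta_site},
        )


def expected_dataset(dfe: DFEParams, n_chrom: int, theta_site: float,
                     L_sel: float, L_neut: float,
                     delta_neut: Optional[float] = None,
                     with_divergence: bool = False) -> ExpectedUSFS:
    """Full expectation of a paired neutral/selected uSFS dataset.

    When ``with_divergence`` is set, divergence means include both the
    ``delta_neut`` substitution term and the expected sample-fixed derived
    alleles of each class (which the sampling scheme pools with divergence).
    """
    sel = expected_usfs(dfe, n_chrom, theta_site, L_sel)
    neut = expected_usfs(0.0, n_chrom, theta_site, L_neut)
    d_sel = d_neut = None
    if with_divergence:
        if delta_neut is None:
            raise ValueError("delta_neut is required when with_divergence is set")
        d_sel, d_neut = expected_divergence(dfe, delta_neut, L_sel, L_neut)
        d_sel += expected_fixed_class(dfe, n_chrom, theta_site, L_sel)
        d_neut += expected_fixed_class(0.0, n_chrom, theta_site, L_neut)
    return ExpectedUSFS(selected=sel, neutral=neut, n_chrom=n_chrom,
                        theta_site=theta_site, L_sel=L_sel, L_neut=L_neut,
                        exp_div_sel=d_sel, exp_div_neut=d_neut)


def sample_poisson_usfs(dfe: DFEParams, n_chrom: int, theta_site: float,
                        L_sel: float, L_neut: float,
                        delta_neut: Optional[float] = None,
                        with_divergence: bool = False,
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None) -> USFSDataset:
    """Draw a synthetic uSFS dataset with independent Poisson counts.

    Every polymorphism class (and, with divergence, each class's
    substitution count) is sampled around its PRF expectation.  This is the
    fast model-based generator: it reproduces the sampling noise of the
    inference model exactly but carries no linked-selection effects.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    exp = expected_dataset(dfe, n_chrom, theta_site, L_sel, L_neut,
                           delta_neut=delta_neut, with_divergence=with_divergence)
    neutral = rng.poisson(exp.neutral)
    selected = rng.poisson(exp.selected)
    div_sel = div_neut = None
    if with_divergence:
        div_sel = int(rng.poisson(exp.exp_div_sel))
        div_neut = int(rng.poisson(exp.exp_div_neut))
    return USFSDataset(
        neutral_sfs=neutral.astype(np.int64),
        selected_sfs=selected.astype(np.int64),
        L_neut=float(L_neut),
        L_sel=float(L_sel),
        n_chrom=n_chrom,
        div_neut=div_neut,
        div_sel=div_sel,
        provenance={
            "generator": "poisson-prf",
            "seed": seed,
            "dfe": dfe.to_dict(),
            "theta_site": theta_site,
            "delta_neut": delta_neut,
            "with_divergence": bool(with_divergence),
        },
    )
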