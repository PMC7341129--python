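"""Distribution of fitness effects (DFE) for new nonsynonymous mutations.

The DFE combines a gamma distribution of deleterious scaled effects with a
discrete class of beneficial effects.  Scaled effects are written
``gamma = 2*N_e*s`` where ``s`` is the selection coefficient of the mutant
homozygote; deleterious effects are negative, beneficial effects positive.
A new selected mutation is beneficial with probability ``p_a`` (fixed effect
``gamma_a``) and deleterious with probability ``1 - p_a`` (effect ``-g`` with
``g ~ Gamma(shape=beta, mean=|mean_gamma_d|)``).

The gamma component is parameterised by shape and *mean* because that is how
empirical deleterious DFEs are reported; the scale (``mean/shape``) is an
internal detail.  The deleterious gamma is untruncated: effects far beyond
lethality carry negligible weight in every functional computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate
from scipy import stats

__all__ = ["DFEParams", "make_dfe", "dfe_expectation", "sample_gamma",
           "read_dfe_config", "write_dfe_config"]


@dataclass(frozen=True)
class DFEParams:
    """Full DFE: gamma deleterious component plus a beneficial point mass.

    Attributes
    ----------
    beta : float
        Shape of the deleterious gamma distribution (> 0).
    mean_gamma_d : float
        Mean scaled deleterious effect, ``2*N_e*s_d`` (< 0).
    p_a : float
        Proportion of new selected mutations that are beneficial, in [0, 1].
    gamma_a : float
        Scaled beneficial effect, ``2*N_e*s_a`` (>= 0).
    """

    beta: float
    mean_gamma_d: float
    p_a: float
    gamma_a: float

    def __post_init__(self) -> None:
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError(f"beta must be a positive finite real, got {self.beta}")
        if not (self.mean_gamma_d < 0 and np.isfinite(self.mean_gamma_d)):
            raise ValueError(
                f"mean_gamma_d must be a negative finite real, got {self.mean_gamma_d}"
            )
        if not (0.0 <= self.p_a <= 1.0):
            raise ValueError(f"p_a must lie in [0, 1], got {self.p_a}")
        if not (self.gamma_a >= 0 and np.isfinite(self.gamma_a)):
            raise ValueError(f"gamma_a must be non-negative and finite, got {self.gamma_a}")

    @property
    def del_scale(self) -> float:
        """Scale of the deleterious gamma distribution, ``|mean|/shape``."""
        return abs(self.mean_gamma_d) / self.beta

    def del_quantile(self, u) -> np.ndarray:
        """Quantile function of the deleterious effect magnitude ``g``."""
        return stats.gamma.ppf(u, a=self.beta, scale=self.del_scale)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "mean_gamma_d": self.mean_gamma_d,
            "p_a": self.p_a,
            "gamma_a": self.gamma_a,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DFEParams":
        return cls(
            beta=float(d["beta"]),
            mean_gamma_d=float(d["mean_gamma_d"]),
            p_a=float(d["p_a"]),
            gamma_a=float(d["gamma_a"]),
        )


def make_dfe(beta: float, mean_gamma_d: float, p_a: float, gamma_a: float) -> DFEParams:
    """Construct a validated :class:`DFEParams`.

    Raises ``ValueError`` naming the offending field for out-of-range input.
    """
    return DFEParams(beta=float(beta), mean_gamma_d=float(mean_gamma_d),
                     p_a=float(p_a), gamma_a=float(gamma_a))


def dfe_expectation(f: Callable[[float], float], dfe: DFEParams,
                    rtol: float = 1e-9) -> float:
    """Expectation of ``f(gamma)`` over the full DFE.

    Returns ``p_a * f(gamma_a) + (1 - p_a) * E_del[f(-g)]``.  The deleterious
    integral is evaluated by adaptive quadrature after substituting the gamma
    quantile function, i.e. over ``u in (0, 1)`` with ``g = Q(u)``; this
    removes the density singularity at 0 that arises when ``beta < 1`` and
    adapts automatically to the heavy right tail.

    Raises
    ------
    RuntimeError
        If the quadrature fails to converge to the requested tolerance.
    """
    point = dfe.p_a * f(dfe.gamma_a) if dfe.p_a > 0 else 0.0
    if dfe.p_a == 1.0:
        return point

    def integrand(u: float) -> float:
        return f(-dfe.del_quantile(u))

    val, err = integrate.quad(integrand, 0.0, 1.0, epsrel=rtol, epsabs=1e-300,
                              limit=200)
    scale = max(abs(val), 1e-12)
    if not np.isfinite(val) or err > 1e-4 * scale:
        raise RuntimeError(
            f"deleterious-DFE quadrature did not converge: value={val}, "
            f"abs. error estimate={err} (beta={dfe.beta}, "
            f"mean_gamma_d={dfe.mean_gamma_d})"
        )
    return point + (1.0 - dfe.p_a) * val


def write_dfe_config(path, dfe: DFEParams) -> None:
    """Write the DFE as a flat ``key = value`` file."""
    with open(path, "w") as fh:
        for key, val in dfe.to_dict().items():
            fh.write(f"{key} = {val!r}\n")


def read_dfe_config(path) -> DFEParams:
    """Read a DFE from a flat ``key = value`` file (extra keys ignored)."""
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            values[key] = val
    try:
        return make_dfe(float(values["beta"]), float(values["mean_gamma_d"]),
                        float(values["p_a"]), float(values["gamma_a"]))
    except KeyError as exc:
        raise ValueError(f"{path}: missing DFE key {exc}") from None


def sample_gamma(dfe: DFEParams, rng: np.random.Generator, size=None):
    """Draw scaled selection coefficients from the DFE.

    With probability ``p_a`` a draw equals ``gamma_a``; otherwise it is
    ``-g`` with ``g`` gamma-distributed (shape ``beta``, mean
    ``|mean_gamma_d|``).  ``size=None`` returns a scalar.
    """
    if size is None:
        if rng.random() < dfe.p_a:
            return dfe.gamma_a
        return -rng.gamma(dfe.beta, dfe.del_scale)
    n = int(size)
    out = -rng.gamma(dfe.beta, dfe.del_scale, size=n)
    if dfe.p_a > 0:
        adv = rng.random(n) < dfe.p_a
        out[adv] = dfe.gamma_a
    return out
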