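"""Parametric generative distributions.

Each family supports IID sampling from a ``numpy.random.Generator`` and a
natural-log density, so models can be both simulated forward and (in a
downstream inference engine) evaluated as priors.  Parameterizations follow
the conventions of the model-specification language this package interprets:

* ``LogNormal(meanlog, sdlog)`` — mean and standard deviation in log space;
* ``Exp(mean)`` — parameterized by its mean, not its rate;
* ``Gamma(shape, scale)``; ``Beta(alpha, beta)``; ``Uniform(lower, upper)``;
  ``Normal(mean, sd)``; ``Dirichlet(conc)``.

Densities are delegated to :mod:`scipy.stats`; parameter validation happens
eagerly at construction and raises :class:`~pylphy.errors.InvalidParameter`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import InvalidParameter

__all__ = [
    "Distribution",
    "Uniform",
    "Normal",
    "LogNormal",
    "Gamma",
    "Exp",
    "Beta",
    "Dirichlet",
]


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise InvalidParameter(message)


class Distribution:
    """Base class: a validated parametric family instance."""

    family: str = "?"

    def sample(self, n: int, rng: np.random.Generator):
        """Return ``n`` IID draws (shape ``(n,)`` or ``(n, k)``)."""
        raise NotImplementedError

    def sample_one(self, rng: np.random.Generator):
        return self.sample(1, rng)[0]

    def log_density(self, x) -> float:
        """Natural-log density at ``x`` (``-inf`` outside the support)."""
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        params = ", ".join(f"{k}={v}" for k, v in self.__dict__.items())
        return f"{self.family}({params})"


class Uniform(Distribution):
    family = "Uniform"

    def __init__(self, lower: float, upper: float):
        _require(np.isfinite(lower) and np.isfinite(upper), "Uniform bounds must be finite")
        _require(lower < upper, f"Uniform requires lower < upper, got [{lower}, {upper}]")
        self.lower = float(lower)
        self.upper = float(upper)

    def sample(self, n, rng):
        return rng.uniform(self.lower, self.upper, size=n)

    def log_density(self, x):
        return float(stats.uniform.logpdf(x, loc=self.lower, scale=self.upper - self.lower))


class Normal(Distribution):
    family = "Normal"

    def __init__(self, mean: float, sd: float):
        _require(sd > 0, f"Normal requires sd > 0, got {sd}")
        self.mean = float(mean)
        self.sd = float(sd)

    def sample(self, n, rng):
        return rng.normal(self.mean, self.sd, size=n)

    def log_density(self, x):
        return float(stats.norm.logpdf(x, loc=self.mean, scale=self.sd))


class LogNormal(Distribution):
    family = "LogNormal"

    def __init__(self, meanlog: float, sdlog: float):
        _require(sdlog > 0, f"LogNormal requires sdlog > 0, got {sdlog}")
        self.meanlog = float(meanlog)
        self.sdlog = float(sdlog)

    def sample(self, n, rng):
        return rng.lognormal(self.meanlog, self.sdlog, size=n)

    def log_density(self, x):
        return float(stats.lognorm.logpdf(x, s=self.sdlog, scale=np.exp(self.meanlog)))


class Gamma(Distribution):
    family = "Gamma"

    def __init__(self, shape: float, scale: float):
        _require(shape > 0, f"Gamma requires shape > 0, got {shape}")
        _require(scale > 0, f"Gamma requires scale > 0, got {scale}")
        self.shape = float(shape)
        self.scale = float(scale)

    def sample(self, n, rng):
        return rng.gamma(self.shape, self.scale, size=n)

    def log_density(self, x):
        return float(stats.gamma.logpdf(x, a=self.shape, scale=self.scale))


class Exp(Distribution):
    family = "Exp"

    def __init__(self, mean: float):
        _require(mean > 0, f"Exp requires mean > 0, got {mean}")
        self.mean = float(mean)

    def sample(self, n, rng):
        return rng.exponential(self.mean, size=n)

    def log_density(self, x):
        return float(stats.expon.logpdf(x, scale=self.mean))


class Beta(Distribution):
    family = "Beta"

    def __init__(self, alpha: float, beta: float):
        _require(alpha > 0, f"Beta requires alpha > 0, got {alpha}")
        _require(beta > 0, f"Beta requires beta > 0, got {beta}")
        self.alpha = float(alpha)
        self.beta = float(beta)

    def sample(self, n, rng):
        return rng.beta(self.alpha, self.beta, size=n)

    def log_density(self, x):
        return float(stats.beta.logpdf(x, a=self.alpha, b=self.beta))


class Dirichlet(Distribution):
    family = "Dirichlet"

    def __init__(self, conc):
        conc = np.asarray(conc, dtype=float)
        _require(conc.ndim == 1 and conc.size >= 2, "Dirichlet conc must be a vector (k >= 2)")
        _require(bool(np.all(conc > 0)), "Dirichlet conc entries must be > 0")
        self.conc = conc

    def sample(self, n, rng):
        return rng.dirichlet(self.conc, size=n)

    def sample_one(self, rng):
        return rng.dirichlet(self.conc)

    def log_density(self, x):
        x = np.asarray(x, dtype=float)
        if x.shape != self.conc.shape or np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
            return float("-inf")
        return float(stats.dirichlet.logpdf(np.clip(x, 1e-300, 1.0), self.conc))
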