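"""Prior densities for model parameters and trees.

Scalar/vector priors implement ``logpdf`` (fast, pure arithmetic — they
sit in the MCMC inner loop), ``sample`` and ``median``.  Tree priors give
the joint density of (labelled topology, internal-node heights) under the
matching generative process in :mod:`errophylo.simulate`: both are built
from backward merge processes where the waiting time with k extant
lineages is exponential, Exp(k·birthrate) for the pure-birth (Yule)
process and Exp(k(k−1)/(2θ)) for the constant-size coalescent, with a
uniformly chosen pair merging at each event.  Out-of-support values give
−inf (a rejected proposal), not an exception.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .trees import TimeTree


class Prior:
    dim = 1

    def logpdf(self, x) -> float:
        raise NotImplementedError

    def sample(self, rng):
        raise NotImplementedError

    def median(self):
        raise NotImplementedError


class BetaPrior(Prior):
    def __init__(self, a: float, b: float):
        self.a, self.b = float(a), float(b)
        self._lnorm = math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)

    def logpdf(self, x) -> float:
        if not 0.0 <= x <= 1.0:
            return -math.inf
        try:
            la = (self.a - 1.0) * math.log(x) if self.a != 1.0 else 0.0
            lb = (self.b - 1.0) * math.log1p(-x) if self.b != 1.0 else 0.0
        except ValueError:  # log(0) with negative exponent
            return -math.inf
        return self._lnorm + la + lb

    def sample(self, rng):
        return float(rng.beta(self.a, self.b))

    def median(self):
        return float(stats.beta.median(self.a, self.b))

    @property
    def mean(self):
        return self.a / (self.a + self.b)


class LogNormalPrior(Prior):
    """Lognormal with log-scale mean ``mu`` and log-scale sd ``sigma``."""

    def __init__(self, mu: float, sigma: float = 1.0):
        self.mu, self.sigma = float(mu), float(sigma)
        self._lnorm = -math.log(self.sigma) - 0.5 * math.log(2 * math.pi)

    def logpdf(self, x) -> float:
        if x <= 0:
            return -math.inf
        lx = math.log(x)
        z = (lx - self.mu) / self.sigma
        return self._lnorm - lx - 0.5 * z * z

    def sample(self, rng):
        return float(math.exp(rng.normal(self.mu, self.sigma)))

    def median(self):
        return math.exp(self.mu)


class NormalPrior(Prior):
    """Normal, optionally truncated below (e.g. positive birth rates)."""

    def __init__(self, mu: float, sigma: float, lower: float | None = None):
        self.mu, self.sigma, self.lower = float(mu), float(sigma), lower
        self._lnorm = -math.log(self.sigma) - 0.5 * math.log(2 * math.pi)
        if lower is not None:
            tail = stats.norm.sf(lower, mu, sigma)
            self._lnorm -= math.log(tail)

    def logpdf(self, x) -> float:
        if self.lower is not None and x < self.lower:
            return -math.inf
        z = (x - self.mu) / self.sigma
        return self._lnorm - 0.5 * z * z

    def sample(self, rng):
        while True:
            x = float(rng.normal(self.mu, self.sigma))
            if self.lower is None or x >= self.lower:
                return x

    def median(self):
        if self.lower is None:
            return self.mu
        return float(stats.truncnorm.median(
            (self.lower - self.mu) / self.sigma, np.inf, self.mu, self.sigma))


class DirichletPrior(Prior):
    def __init__(self, concentration):
        self.conc = np.asarray(concentration, dtype=float)
        self.dim = len(self.conc)
        self._lnorm = (math.lgamma(self.conc.sum())
                       - sum(math.lgamma(c) for c in self.conc))
        self._cm1 = self.conc - 1.0

    def logpdf(self, x) -> float:
        if x.min() <= 0.0 or abs(x.sum() - 1.0) > 1e-9:
            return -math.inf
        return self._lnorm + float(np.dot(self._cm1, np.log(x)))

    def sample(self, rng):
        return rng.dirichlet(self.conc)

    def median(self):  # simplex "centre": the mean
        return self.conc / self.conc.sum()


class UniformPrior(Prior):
    def __init__(self, lo: float, hi: float):
        self.lo, self.hi = float(lo), float(hi)
        self._lpdf = -math.log(hi - lo)

    def logpdf(self, x) -> float:
        return self._lpdf if self.lo <= x <= self.hi else -math.inf

    def sample(self, rng):
        return float(rng.uniform(self.lo, self.hi))

    def median(self):
        return 0.5 * (self.lo + self.hi)


def _merge_intervals(tree: TimeTree):
    """Waiting intervals u_k (k lineages, k = m..2) from node heights."""
    m = tree.n_tips
    tip_max = float(tree.heights[:m].max())
    heights = np.sort(tree.heights[m:])
    times = np.concatenate([[tip_max], heights])
    return times[1:] - times[:-1]  # u_m, u_{m-1}, ..., u_2


class YuleTreePrior:
    """Density of the pure-birth tree process given its birth rate.

    With contemporaneous tips, Σ_k k·u_k is the tree length L, so the
    density reduces to Π_k (k·b) · exp(−b·L)."""

    hyperparam = "birthrate"

    def __init__(self):
        self._logk = {}

    def log_density(self, tree: TimeTree, birthrate: float) -> float:
        if birthrate <= 0:
            return -math.inf
        m = tree.n_tips
        logk = self._logk.get(m)
        if logk is None:
            logk = self._logk[m] = float(np.log(np.arange(2, m + 1)).sum())
        h = tree.heights
        bl = h[tree.parent] - h
        length = float(bl.sum() - bl[tree.root])
        return logk + (m - 1) * math.log(birthrate) - birthrate * length


class CoalescentTreePrior:
    """Density of the constant-size Kingman coalescent given θ."""

    hyperparam = "theta"

    def __init__(self):
        self._coef = {}

    def log_density(self, tree: TimeTree, theta: float) -> float:
        if theta <= 0:
            return -math.inf
        m = tree.n_tips
        cached = self._coef.get(m)
        if cached is None:
            ks = np.arange(m, 1, -1)
            pairs = ks * (ks - 1) / 2.0
            cached = self._coef[m] = (pairs, float(np.log(pairs).sum()))
        pairs, logpairs = cached
        u = _merge_intervals(tree)
        return (logpairs - (m - 1) * math.log(theta)
                - float(pairs @ u) / theta)
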