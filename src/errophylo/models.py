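"""Model specifications binding parameters, priors and tree priors.

A spec knows how to build the rate matrix and error table from the
current parameter dictionary, how to evaluate the joint log prior, and
which MCMC operators apply.  Two concrete specs cover the studies: the
binary model (back-mutation rate λ, optional α/β error model, Yule tree
prior with a birth-rate hyperprior) and the GT16 model (genotype
frequencies π, exchangeabilities r, optional ϵ/δ error model, constant
coalescent tree prior with a θ hyperprior).
"""

from __future__ import annotations

import math

from . import operators as ops
from .errors import (BinaryErrorParams, Gt16ErrorParams, binary_error_table,
                     gt16_error_table)
from .priors import (BetaPrior, CoalescentTreePrior, DirichletPrior,
                     LogNormalPrior, NormalPrior, Prior, YuleTreePrior)
from .simulate import simulate_coalescent, simulate_yule
from .states import BINARY, GT16
from .substitution import (BinaryModelParams, Gt16ModelParams, build_binary_q,
                           build_gt16_q)

#: parameters that enter the substitution model (trigger a Q rebuild)
_RATE_PARAMS = {"lam", "freqs", "rates"}
#: parameters that enter the error model (trigger a table rebuild)
_ERROR_PARAMS = {"alpha", "beta", "eps", "delta"}


class ModelSpec:
    state_space = None
    tree_prior = None

    def __init__(self, priors: dict[str, Prior], use_error_model: bool):
        self.priors = priors
        self.use_error_model = use_error_model

    # -- model construction -------------------------------------------------

    def rate_model(self, params):
        raise NotImplementedError

    def error_table(self, params):
        raise NotImplementedError

    def rate_params_changed(self, changed) -> bool:
        return bool(_RATE_PARAMS & set(changed))

    def error_params_changed(self, changed) -> bool:
        return self.use_error_model and bool(_ERROR_PARAMS & set(changed))

    # -- prior --------------------------------------------------------------

    def log_prior(self, params: dict, tree) -> float:
        total = 0.0
        for name, prior in self.priors.items():
            lp = prior.logpdf(params[name])
            if lp == -math.inf:
                return -math.inf
            total += lp
        total += self.tree_prior.log_density(
            tree, params[self.tree_prior.hyperparam])
        return total

    def sample_params(self, rng) -> dict:
        return {name: prior.sample(rng) for name, prior in self.priors.items()}

    def init_params(self) -> dict:
        return {name: prior.median() for name, prior in self.priors.items()}

    # -- simulation ---------------------------------------------------------

    def sample_tree(self, m: int, params: dict, rng, labels=None):
        hyper = params[self.tree_prior.hyperparam]
        if isinstance(self.tree_prior, YuleTreePrior):
            return simulate_yule(m, hyper, rng, labels=labels)
        return simulate_coalescent(m, hyper, rng, labels=labels)

    def default_operators(self) -> list:
        raise NotImplementedError

    def _tree_operators(self) -> list:
        return [
            ops.NodeSlideOperator(weight=8.0),
            ops.TreeScaleOperator(weight=3.0),
            ops.RootScaleOperator(weight=1.5),
            ops.ExchangeOperator(narrow=True, weight=6.0),
            ops.ExchangeOperator(narrow=False, weight=2.0),
            ops.WilsonBaldingOperator(weight=4.0),
        ]


class BinaryModelSpec(ModelSpec):
    """Binary SNV model: λ with a lognormal prior, Yule tree prior with a
    (truncated) normal birth-rate prior, optional α/β error model."""

    state_space = BINARY

    def __init__(self, lam_prior=None, birthrate_prior=None,
                 alpha_prior=None, beta_prior=None,
                 use_error_model: bool = True):
        priors = {
            "lam": lam_prior or LogNormalPrior(-1.0, 1.0),
            "birthrate": birthrate_prior or NormalPrior(7.0, 1.0, lower=0.0),
        }
        if use_error_model:
            priors["alpha"] = alpha_prior or BetaPrior(1, 50)
            priors["beta"] = beta_prior or BetaPrior(1, 50)
        super().__init__(priors, use_error_model)
        self.tree_prior = YuleTreePrior()

    def rate_model(self, params):
        return build_binary_q(BinaryModelParams(params["lam"]))

    def error_table(self, params):
        if not self.use_error_model:
            return None
        return binary_error_table(
            BinaryErrorParams(params["alpha"], params["beta"]))

    def default_operators(self):
        out = [
            ops.ScaleOperator("lam", weight=2.0),
            ops.ScaleOperator("birthrate", weight=1.0,
                              affects_likelihood=False),
        ]
        if self.use_error_model:
            out.append(ops.ScaleOperator("alpha", weight=2.0, window=1.0))
            out.append(ops.ScaleOperator("beta", weight=2.0, window=1.0))
            out.append(ops.WalkOperator("alpha", weight=1.5, window=0.05))
            out.append(ops.WalkOperator("beta", weight=1.5, window=0.05))
            out.append(ops.UpDownOperator(down=("alpha", "beta"), weight=6.0))
        out.append(ops.UpDownOperator(down=("birthrate",), weight=3.0))
        return out + self._tree_operators()


class Gt16ModelSpec(ModelSpec):
    """GT16 diploid genotype model: π ~ Dirichlet, r ~ Dirichlet, constant
    coalescent tree prior with lognormal θ, optional ϵ/δ error model."""

    state_space = GT16

    def __init__(self, freqs_prior=None, rates_prior=None, theta_prior=None,
                 eps_prior=None, delta_prior=None,
                 use_error_model: bool = True, normalize_q: bool = True):
        priors = {
            "freqs": freqs_prior or DirichletPrior([3.0] * 16),
            "rates": rates_prior or DirichletPrior([1, 2, 1, 1, 2, 1]),
            "theta": theta_prior or LogNormalPrior(-2.0, 1.0),
        }
        if use_error_model:
            priors["eps"] = eps_prior or BetaPrior(2, 18)
            priors["delta"] = delta_prior or BetaPrior(1.5, 4.5)
        super().__init__(priors, use_error_model)
        self.tree_prior = CoalescentTreePrior()
        self.normalize_q = normalize_q

    def rate_model(self, params):
        return build_gt16_q(
            Gt16ModelParams(params["rates"], params["freqs"]),
            normalize=self.normalize_q)

    def error_table(self, params):
        if not self.use_error_model:
            return None
        return gt16_error_table(
            Gt16ErrorParams(params["eps"], params["delta"]))

    def default_operators(self):
        out = [
            ops.DeltaExchangeOperator("freqs", weight=8.0, window=0.05),
            ops.DeltaExchangeOperator("rates", weight=4.0, window=0.1),
            ops.ScaleOperator("theta", weight=3.0, affects_likelihood=False),
        ]
        if self.use_error_model:
            out.append(ops.WalkOperator("eps", weight=1.5, window=0.05))
            out.append(ops.WalkOperator("delta", weight=1.5, window=0.1))
        out.append(ops.UpDownOperator(up=("theta",), weight=3.0))
        return out + self._tree_operators()


def scalar_param_names(spec: ModelSpec) -> list[str]:
    """Names of logged scalar columns, expanding vector parameters."""
    out = []
    for name, prior in spec.priors.items():
        if getattr(prior, "dim", 1) > 1:
            if name == "freqs":
                out.extend(f"freq_{s}" for s in GT16.states)
            elif name == "rates":
                out.extend(
                    f"rate_{a}{b}" for a, b in
                    (("A", "C"), ("A", "G"), ("A", "T"),
                     ("C", "G"), ("C", "T"), ("G", "T")))
            else:  # pragma: no cover
                out.extend(f"{name}_{i}" for i in range(prior.dim))
        else:
            out.append(name)
    return out


def flatten_params(spec: ModelSpec, params: dict) -> dict[str, float]:
    """Expand vector parameters into the scalar columns of the trace."""
    out = {}
    for name, prior in spec.priors.items():
        if getattr(prior, "dim", 1) > 1:
            vec = params[name]
            if name == "freqs":
                keys = [f"freq_{s}" for s in GT16.states]
            elif name == "rates":
                keys = ["rate_AC", "rate_AG", "rate_AT",
                        "rate_CG", "rate_CT", "rate_GT"]
            else:  # pragma: no cover
                keys = [f"{name}_{i}" for i in range(len(vec))]
            out.update(zip(keys, vec))
        else:
            out[name] = float(params[name])
    return out
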