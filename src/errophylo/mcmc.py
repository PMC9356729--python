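"""Metropolis–Hastings sampler over trees and model parameters.

The chain targets P(τ, θ | D) ∝ P(D | τ, θ) P(τ | θ_tree) P(θ).  With no
data (``alignment=None``) the likelihood term is identically zero and
the chain samples the joint prior — the validation mode used to test
operator correctness.  Operator step sizes adapt toward a target
acceptance rate during burn-in only, so the post-burn-in kernel is a
fixed, valid MH kernel.  Runs are bit-reproducible given the Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .diagnostics import ess, hpd_interval
from .likelihood import LikelihoodEngine
from .models import ModelSpec, flatten_params
from .substitution import InvalidParameterError


@dataclass
class McmcConfig:
    chain_length: int = 30_000
    sample_every: int = 20
    tree_every: int = 200          # thinning for stored topologies
    burnin_frac: float = 0.1
    tune: bool = True

    def __post_init__(self):
        if self.chain_length <= 0 or self.sample_every <= 0:
            raise ValueError("chain_length and sample_every must be positive")
        if not 0 <= self.burnin_frac < 1:
            raise ValueError("burnin_frac must be in [0, 1)")


@dataclass
class McmcTrace:
    """Sampled states: scalar columns, stored trees, and diagnostics."""

    columns: dict[str, np.ndarray]
    states: np.ndarray
    trees: list                     # (state index, TimeTree)
    burnin_frac: float
    acceptance: dict[str, float] = field(default_factory=dict)

    def post_burnin(self, name: str) -> np.ndarray:
        col = self.columns[name]
        start = int(len(col) * self.burnin_frac)
        return col[start:]

    def post_burnin_trees(self) -> list:
        if not self.trees:
            return []
        cutoff = self.states[-1] * self.burnin_frac
        return [t for s, t in self.trees if s >= cutoff]

    def hpd(self, name: str, mass: float = 0.95):
        return hpd_interval(self.post_burnin(name), mass)

    def ess(self, name: str) -> float:
        return ess(self.post_burnin(name))

    def min_ess(self, names=None) -> float:
        names = names or [n for n in self.columns
                          if n not in ("posterior", "likelihood", "prior")]
        return min(self.ess(n) for n in names)


def run_mcmc(alignment, spec: ModelSpec, config: McmcConfig,
             rng: np.random.Generator, init_params: dict | None = None,
             init_tree=None, n_tips: int | None = None,
             tip_labels=None, operators=None) -> McmcTrace:
    """Run the MH chain; ``alignment=None`` samples the prior.

    For prior sampling the tip count comes from ``n_tips``/``tip_labels``;
    otherwise the alignment fixes the tips.  ``operators`` overrides the
    spec's default proposal kernels (weights are taken from each
    operator).
    """
    params = dict(init_params) if init_params is not None else spec.init_params()
    if alignment is not None:
        labels = alignment.cells
        m = len(labels)
    else:
        if init_tree is None and n_tips is None and tip_labels is None:
            raise ValueError("prior sampling needs n_tips or tip_labels")
        labels = tip_labels
        m = n_tips if n_tips is not None else len(labels)
    if init_tree is not None:
        tree = init_tree.copy()
    else:
        tree = spec.sample_tree(m, params, rng, labels=labels)

    engine = LikelihoodEngine(alignment, tree) if alignment is not None else None
    rate_model = spec.rate_model(params)
    error_table = spec.error_table(params)

    log_prior = spec.log_prior(params, tree)
    if not np.isfinite(log_prior):
        raise RuntimeError("non-finite prior at initialization")
    log_lik = (engine.total(tree, rate_model, error_table)
               if engine is not None else 0.0)
    if not np.isfinite(log_lik):
        raise RuntimeError("non-finite likelihood at initialization")

    if operators is None:
        operators = spec.default_operators()
    weights = np.array([op.weight for op in operators], dtype=float)
    weights /= weights.sum()
    burnin_end = int(config.chain_length * config.burnin_frac)

    col_names = (["posterior", "likelihood", "prior", "tree_length",
                  "tree_height"] + list(_scalar_names(spec)))
    n_samples = config.chain_length // config.sample_every + 1
    columns = {name: np.empty(n_samples) for name in col_names}
    states = np.empty(n_samples, dtype=np.int64)
    trees = []
    n_logged = 0

    def log_state(step):
        nonlocal n_logged
        row = flatten_params(spec, params)
        row["posterior"] = log_prior + log_lik
        row["likelihood"] = log_lik
        row["prior"] = log_prior
        row["tree_length"] = tree.tree_length()
        row["tree_height"] = tree.tree_height()
        for name, val in row.items():
            columns[name][n_logged] = val
        states[n_logged] = step
        n_logged += 1
        if step % config.tree_every == 0:
            trees.append((step, tree.copy()))

    log_state(0)
    op_indices = rng.choice(len(operators), size=config.chain_length, p=weights)
    for step in range(1, config.chain_length + 1):
        op = operators[int(op_indices[step - 1])]
        prop = op.propose(params, tree, rng)
        accepted = False
        if prop is not None:
            new_params = prop.params if prop.params is not None else params
            new_tree = prop.tree if prop.tree is not None else tree
            try:
                new_rate = (spec.rate_model(new_params)
                            if spec.rate_params_changed(prop.changed)
                            else rate_model)
                new_table = (spec.error_table(new_params)
                             if spec.error_params_changed(prop.changed)
                             else error_table)
                new_prior = spec.log_prior(new_params, new_tree)
                if new_prior > -math.inf:
                    needs_lik = (engine is not None
                                 and (prop.tree is not None
                                      or op.affects_likelihood))
                    new_lik = (engine.total(new_tree, new_rate, new_table)
                               if needs_lik else log_lik)
                    log_ratio = (new_prior + new_lik - log_prior - log_lik
                                 + prop.log_hastings)
                    if log_ratio >= 0 or rng.random() < math.exp(log_ratio):
                        params, tree = new_params, new_tree
                        rate_model, error_table = new_rate, new_table
                        log_prior, log_lik = new_prior, new_lik
                        accepted = True
            except (InvalidParameterError, FloatingPointError):
                pass
        if hasattr(op, "record"):
            op.record(accepted)
        else:
            op.n_proposed += 1
            op.n_accepted += int(accepted)
        if config.tune and op.tunable and step <= burnin_end and step % 50 == 0:
            op.tune()
        if step % config.sample_every == 0:
            log_state(step)

    columns = {k: v[:n_logged] for k, v in columns.items()}
    acc = {op.name: op.acceptance_rate for op in operators}
    return McmcTrace(columns=columns, states=states[:n_logged], trees=trees,
                     burnin_frac=config.burnin_frac, acceptance=acc)


def _scalar_names(spec: ModelSpec):
    from .models import scalar_param_names
    return scalar_param_names(spec)
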