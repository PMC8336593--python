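"""Numerical self-checks for the trainer.

The analytic gradients have many moving parts (five parameter blocks,
activation derivatives, leave-one-out Hadamard products, penalty scalings);
central finite differencing of the objective is the independent arbiter.
"""

from __future__ import annotations

import numpy as np

from .core import LTRParameters
from .trainer import HyperParams, compute_gradients, compute_objective, init_params

__all__ = ["finite_difference_worst", "random_extended"]


def random_extended(rng: np.random.Generator, n: int = 5, n_d: int = 3,
                    n_t: int = 4, n_k: int = 3, n_y: int = 2,
                    activation: str = "tanh") -> tuple[LTRParameters, HyperParams]:
    """A fully random (non-degenerate) extended-LTR parameter set with its
    matching hyperparameter record, for randomized checks."""
    hyper = HyperParams(n_d=n_d, n_t=n_t, n_k=n_k, activation=activation,
                        epochs=1)
    params = init_params(hyper, n, n_y, seed=int(rng.integers(2**31)))
    params.lam = rng.standard_normal(n_t)
    params.lambda_u = rng.standard_normal(n)
    return params, hyper


def finite_difference_worst(params: LTRParameters, X: np.ndarray,
                            Y: np.ndarray, hyper: HyperParams,
                            step: float = 1e-6, per_block: int = 8) -> float:
    """Worst relative deviation between analytic gradients and central
    finite differences of the objective, sampled over entries of every
    parameter block.  Values around 1e-9 indicate exact gradients; 1e-5 is
    the acceptance threshold used by the self-tests."""
    grads = compute_gradients(params, X, Y, hyper)
    worst = 0.0
    for name, arr in params.blocks().items():
        analytic = grads.blocks()[name].reshape(-1)
        flat = arr.reshape(-1)
        idx = np.linspace(0, flat.size - 1, min(per_block, flat.size)).astype(int)
        for i in idx:
            old = flat[i]
            flat[i] = old + step
            f1 = compute_objective(params, X, Y, hyper)
            flat[i] = old - step
            f2 = compute_objective(params, X, Y, hyper)
            flat[i] = old
            fd = (f1 - f2) / (2 * step)
            worst = max(worst, abs(fd - analytic[i]) / (1 + abs(fd)))
    return worst
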