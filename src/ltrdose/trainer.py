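"""Projection-based training of the extended LTR model.

The fitted objective is

    h = 1/(m*n_y) * ||Y - F D_lam Q||_F^2
        + C_p/(n_t*n_d*n_k) * sum_d (||U^(d)||^2 + ||V^(d)||^2)
        + C_q/(n_t*n_y) * ||Q||^2
        + C_lam/n_t * ||lam||^2

with ``F = o_d A(X D_{lambda_u} U^(d)) V^(d)^T``.  Because the predictor is
linear in each parameter block separately, analytic gradients have a compact
matrix form (see :func:`compute_gradients`) and the scale vector ``lam`` has
a closed-form ridge solution with all other blocks fixed
(:func:`solve_lambda`).

The training loop alternates seeded mini-batch gradient steps (plain,
Nesterov-momentum or ADAM updates) with projection of the factor rows back
onto the unit sphere and a periodic exact re-solve of ``lam``.  Row
normalization keeps every rank-one term at a comparable scale so that
``lam`` alone carries the magnitude of each term, mirroring the singular
values of a tensor decomposition.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict
from functools import reduce
from typing import Sequence

import numpy as np

from .core import (
    LTRParameters,
    eval_extended,
    get_activation,
    normalize_rows,
)

__all__ = [
    "HyperParams",
    "TrainingTrace",
    "GradientSet",
    "init_params",
    "solve_lambda",
    "compute_objective",
    "compute_gradients",
    "fit",
    "predict",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the objective blows up; carries the trace so far."""

    def __init__(self, message: str, trace: "TrainingTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass
class HyperParams:
    """Everything the optimizer needs; defaults follow the tool's standard
    configuration (degree 5 — one slot per component of the response
    quintuplet — and rank 200 for the full-size model)."""

    n_d: int = 5
    n_t: int = 200
    n_k: int = 0                  # 0 -> use the input dimension (no bottleneck)
    gamma: float = 0.01           # learning rate, 0 < gamma < 1
    C_p: float = 0.0
    C_q: float = 0.0
    C_lam: float = 1e-6
    C_u: float = 0.0              # ridge on lambda_u: soft input-feature selection
    epochs: int = 100
    batch_size: int = 512
    update_rule: str = "adam"     # plain | nesterov | adam
    momentum: float = 0.9
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    lambda_cadence: int = 1       # re-solve lam every this many epochs (0 = never)
    activation: str = "identity"
    seed: int = 0
    tol: float = 0.0              # relative objective improvement threshold
    patience: int = 5
    normalize_every_batch: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("learning rate gamma must lie in (0, 1)")
        if min(self.C_p, self.C_q, self.C_lam, self.C_u) < 0:
            raise ValueError("penalty constants must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.update_rule not in ("plain", "nesterov", "adam"):
            raise ValueError(f"unknown update rule {self.update_rule!r}")
        get_activation(self.activation)


@dataclass
class TrainingTrace:
    """Per-epoch record of the optimization."""

    objective: list[float] = field(default_factory=list)
    validation: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    seed: int = 0
    hyper: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.objective)


@dataclass
class GradientSet:
    """One array per parameter block, shapes mirroring the model."""

    lambda_u: np.ndarray
    lam: np.ndarray
    U: list[np.ndarray]
    V: list[np.ndarray]
    Q: np.ndarray

    def blocks(self) -> dict[str, np.ndarray]:
        out = {"lambda_u": self.lambda_u, "lam": self.lam}
        for d, u in enumerate(self.U):
            out[f"U{d}"] = u
        for d, v in enumerate(self.V):
            out[f"V{d}"] = v
        out["Q"] = self.Q
        return out


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_params(hyper: HyperParams, n: int, n_y: int, seed: int | None = None) -> LTRParameters:
    """Seeded initialization: ``lambda_u`` and ``lam`` all ones, factor
    matrices standard normal, immediately followed by row normalization."""
    if min(n, n_y, hyper.n_d, hyper.n_t) < 1:
        raise ValueError("all dimensions must be positive")
    n_k = hyper.n_k if hyper.n_k > 0 else n
    rng = np.random.default_rng(hyper.seed if seed is None else seed)
    params = LTRParameters(
        lambda_u=np.ones(n),
        lam=np.ones(hyper.n_t),
        U=[rng.standard_normal((n, n_k)) for _ in range(hyper.n_d)],
        V=[rng.standard_normal((hyper.n_t, n_k)) for _ in range(hyper.n_d)],
        Q=rng.standard_normal((hyper.n_t, n_y)),
        activation=hyper.activation,
    )
    _normalize(params)
    return params


def _normalize(params: LTRParameters) -> None:
    """Project rows of U, V and Q onto the unit sphere in place.

    ``lam`` stays unnormalized (it carries the scale of each rank-one term)
    and ``lambda_u`` is a free per-input scaling, also left untouched.
    """
    for d in range(params.degree):
        params.U[d] = normalize_rows(params.U[d])
        params.V[d] = normalize_rows(params.V[d])
    params.Q = normalize_rows(params.Q)


# ---------------------------------------------------------------------------
# objective / lam sub-step
# ---------------------------------------------------------------------------

def _forward(params: LTRParameters, X: np.ndarray):
    act = get_activation(params.activation)
    Xs = X * params.lambda_u
    Z = [Xs @ u for u in params.U]
    A = [act(z) for z in Z]
    G = [a @ v.T for a, v in zip(A, params.V)]
    F = reduce(lambda a, b: a * b, G)
    return Z, A, G, F


def _penalty(params: LTRParameters, hyper: HyperParams) -> float:
    n_t, n_d, n_k, n_y = params.rank, params.degree, params.n_k, params.n_y
    pen = 0.0
    if hyper.C_p:
        ssq = sum(float(np.sum(u * u)) + float(np.sum(v * v))
                  for u, v in zip(params.U, params.V))
        pen += hyper.C_p / (n_t * n_d * n_k) * ssq
    if hyper.C_q:
        pen += hyper.C_q / (n_t * n_y) * float(np.sum(params.Q**2))
    if hyper.C_lam:
        pen += hyper.C_lam / n_t * float(np.sum(params.lam**2))
    if hyper.C_u:
        pen += hyper.C_u / params.n * float(np.sum(params.lambda_u**2))
    return pen


def compute_objective(params: LTRParameters, X: np.ndarray, Y: np.ndarray,
                      hyper: HyperParams) -> float:
    """Penalized mean squared reconstruction error (see module docstring)."""
    m, n_y = Y.shape
    _, _, _, F = _forward(params, X)
    E = (F * params.lam) @ params.Q - Y
    return float(np.sum(E * E)) / (m * n_y) + _penalty(params, hyper)


def solve_lambda(params: LTRParameters, X: np.ndarray, Y: np.ndarray,
                 hyper: HyperParams) -> np.ndarray:
    """Exact ridge solution for the scale vector with all else fixed.

    The prediction is linear in ``lam``:
    ``Yhat = sum_t lam_t F[:, t] Q[t, :]``, so minimizing the penalized
    objective over ``lam`` is a ridge regression with Gram matrix
    ``(F^T F) o (Q Q^T)`` and right-hand side ``((F^T Y) o Q) 1``.
    """
    m, n_y = Y.shape
    n_t = params.rank
    _, _, _, F = _forward(params, X)
    G = (F.T @ F) * (params.Q @ params.Q.T)
    b = ((F.T @ Y) * params.Q) @ np.ones(n_y)
    scale = 1.0 / (m * n_y)
    A_mat = G * scale + (hyper.C_lam / n_t) * np.eye(n_t)
    rhs = b * scale
    if hyper.C_lam > 0:
        lam = np.linalg.solve(A_mat, rhs)
    else:
        lam, *_ = np.linalg.lstsq(A_mat, rhs, rcond=None)
        if np.linalg.matrix_rank(A_mat) < n_t:
            warnings.warn(
                "rank-deficient normal matrix in the lambda sub-step; "
                "returning the minimum-norm solution",
                RuntimeWarning,
            )
    return lam


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def compute_gradients(params: LTRParameters, X: np.ndarray, Y: np.ndarray,
                      hyper: HyperParams) -> GradientSet:
    """Analytic gradients of :func:`compute_objective` for all five blocks.

    Intermediates: residual ``E = F D_lam Q - Y``; ``F\\d`` the Hadamard
    product of all degree factors except ``d``; ``B^(d) = (E Q^T) o F\\d``;
    ``C^(d) = X^T ((B^(d) D_lam V^(d)) o H^(d))`` with ``H^(d)`` the
    pointwise activation derivative at ``X D_{lambda_u} U^(d)``.
    Every block is the exact derivative of the penalized objective
    (verified against central finite differences in the test suite).
    """
    act = get_activation(params.activation)
    m, n_y = Y.shape
    n_t, n_d, n_k = params.rank, params.degree, params.n_k

    Z, A, G, F = _forward(params, X)
    H = [act.df(z) for z in Z]
    E = (F * params.lam) @ params.Q - Y
    M = E @ params.Q.T                      # m x n_t
    scale = 2.0 / (m * n_y)

    # leave-one-out products F\d without repeated full products
    Fexcl = _leave_one_out_products(G)

    grad_U: list[np.ndarray] = []
    grad_V: list[np.ndarray] = []
    grad_lu = np.zeros_like(params.lambda_u)
    Xs = X * params.lambda_u
    for d in range(n_d):
        B = M * Fexcl[d]                    # m x n_t
        dG = B * params.lam                 # dL/dG^(d) up to `scale`
        dA = (dG @ params.V[d]) * H[d]      # m x n_k
        C = X.T @ dA                        # n x n_k
        grad_U.append(scale * C * params.lambda_u[:, None])
        grad_lu += scale * np.sum(C * params.U[d], axis=1)
        gV = scale * (dG.T @ A[d])
        grad_V.append(gV)
    grad_lam = scale * ((F * M).T @ np.ones(m))
    grad_Q = scale * ((F * params.lam).T @ E)

    if hyper.C_p:
        c = 2.0 * hyper.C_p / (n_t * n_d * n_k)
        for d in range(n_d):
            grad_U[d] = grad_U[d] + c * params.U[d]
            grad_V[d] = grad_V[d] + c * params.V[d]
    if hyper.C_q:
        grad_Q = grad_Q + 2.0 * hyper.C_q / (n_t * n_y) * params.Q
    if hyper.C_lam:
        grad_lam = grad_lam + 2.0 * hyper.C_lam / n_t * params.lam
    if hyper.C_u:
        grad_lu = grad_lu + 2.0 * hyper.C_u / params.n * params.lambda_u

    grads = GradientSet(lambda_u=grad_lu, lam=grad_lam, U=grad_U, V=grad_V, Q=grad_Q)
    for name, g in grads.blocks().items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in block {name}")
    return grads


def _leave_one_out_products(G: Sequence[np.ndarray]) -> list[np.ndarray]:
    """``out[d] = prod_{b != d} G[b]`` via prefix/suffix products, O(n_d)."""
    n_d = len(G)
    if n_d == 1:
        return [np.ones_like(G[0])]
    prefix = [None] * n_d
    suffix = [None] * n_d
    acc = np.ones_like(G[0])
    for d in range(n_d):
        prefix[d] = acc
        acc = acc * G[d]
    acc = np.ones_like(G[0])
    for d in range(n_d - 1, -1, -1):
        suffix[d] = acc
        acc = acc * G[d]
    return [prefix[d] * suffix[d] for d in range(n_d)]


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class _Updater:
    """Plain / Nesterov / ADAM update state over the named parameter blocks."""

    def __init__(self, hyper: HyperParams, params: LTRParameters):
        self.h = hyper
        self.state: dict[str, dict[str, np.ndarray]] = {}
        self.t = 0
        for name, arr in params.blocks().items():
            self.state[name] = {
                "m": np.zeros_like(arr),
                "v": np.zeros_like(arr),
            }

    def step(self, params: LTRParameters, grads: GradientSet) -> None:
        self.t += 1
        h = self.h
        pb = params.blocks()
        for name, g in grads.blocks().items():
            p = pb[name]
            st = self.state[name]
            if h.update_rule == "plain":
                p -= h.gamma * g
            elif h.update_rule == "nesterov":
                v_prev = st["m"].copy()
                st["m"] = h.momentum * st["m"] - h.gamma * g
                p += -h.momentum * v_prev + (1.0 + h.momentum) * st["m"]
            else:  # adam
                st["m"] = h.adam_beta1 * st["m"] + (1 - h.adam_beta1) * g
                st["v"] = h.adam_beta2 * st["v"] + (1 - h.adam_beta2) * g * g
                mhat = st["m"] / (1 - h.adam_beta1**self.t)
                vhat = st["v"] / (1 - h.adam_beta2**self.t)
                p -= h.gamma * mhat / (np.sqrt(vhat) + h.adam_eps)


# ---------------------------------------------------------------------------
# fit / predict
# ---------------------------------------------------------------------------

def fit(X: np.ndarray, Y: np.ndarray, hyper: HyperParams,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
        restore_best: bool = False,
        verbose: bool = False) -> tuple[LTRParameters, TrainingTrace]:
    """Train the extended LTR model with seeded mini-batch epochs.

    ``X`` must already carry the homogeneous constant column.  Per epoch:
    seeded shuffle, mini-batch gradient steps under the configured update
    rule with row re-normalization, a periodic exact ``lam`` re-solve, and
    the full-data penalized objective recorded into the trace.  Stops on the
    epoch budget or once the relative objective improvement stays below
    ``tol`` for ``patience`` consecutive epochs.

    When a ``validation`` split is given its RMSE is traced per epoch, and
    with ``restore_best`` the returned model is the epoch snapshot with the
    lowest validation RMSE — the standard guard against late-epoch
    memorization when the validation split mirrors the deployment scenario.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    m = X.shape[0]
    if Y.shape[0] != m:
        raise ValueError(f"X has {m} rows but Y has {Y.shape[0]}")
    batch = min(hyper.batch_size, m)

    params = init_params(hyper, X.shape[1], Y.shape[1], hyper.seed)
    params.lam = solve_lambda(params, X, Y, hyper)
    updater = _Updater(hyper, params)
    rng = np.random.default_rng(np.random.SeedSequence([hyper.seed, 1]))  # shuffle stream

    trace = TrainingTrace(seed=hyper.seed, hyper=asdict(hyper))
    obj0 = compute_objective(params, X, Y, hyper)
    best = obj0
    stall = 0
    diverged_streak = 0
    best_val = np.inf
    best_params: LTRParameters | None = None

    for epoch in range(hyper.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(m)
        for start in range(0, m, batch):
            idx = order[start:start + batch]
            grads = compute_gradients(params, X[idx], Y[idx], hyper)
            updater.step(params, grads)
            if hyper.normalize_every_batch:
                _normalize(params)
        if not hyper.normalize_every_batch:
            _normalize(params)
        if hyper.lambda_cadence and (epoch + 1) % hyper.lambda_cadence == 0:
            params.lam = solve_lambda(params, X, Y, hyper)
        obj = compute_objective(params, X, Y, hyper)
        trace.objective.append(obj)
        if validation is not None:
            Xv, Yv = validation
            Yv = np.asarray(Yv, dtype=float)
            Yv = Yv[:, None] if Yv.ndim == 1 else Yv
            resid = predict(params, Xv) - Yv
            val_rmse = float(np.sqrt(np.mean(resid**2)))
            trace.validation.append(val_rmse)
            if restore_best and val_rmse < best_val:
                best_val = val_rmse
                best_params = params.copy()
        trace.epoch_seconds.append(time.perf_counter() - t0)
        if verbose:
            print(f"epoch {epoch + 1}: objective {obj:.6g}")

        if not np.isfinite(obj) or obj > 1e3 * max(obj0, 1e-30):
            diverged_streak += 1
            if diverged_streak >= 3:
                raise TrainingDivergedError(
                    f"objective diverged ({obj:.3g} vs initial {obj0:.3g})", trace
                )
        else:
            diverged_streak = 0
        if hyper.tol > 0:
            if best - obj <= hyper.tol * max(abs(best), 1e-30):
                stall += 1
                if stall >= hyper.patience:
                    break
            else:
                stall = 0
        best = min(best, obj)
    if restore_best and best_params is not None:
        params = best_params
    return params, trace


def predict(params: LTRParameters, X: np.ndarray) -> np.ndarray:
    """Stateless prediction; thin wrapper over the batched evaluator."""
    return eval_extended(params, np.asarray(X, dtype=float))
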