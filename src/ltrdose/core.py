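"""Factorized polynomial predictors via latent tensor reconstruction (LTR).

A degree-``n_d`` multivariate polynomial can be written as the inner product
of a coefficient tensor ``T`` (order ``n_d``, dimension ``n`` per mode) with
the ``n_d``-fold tensor power of the input vector::

    pi(x) = < T, x (x) x (x) ... (x) x >

Storing ``T`` densely costs ``n**n_d`` parameters.  LTR instead represents
``T`` as a sum of ``n_t`` rank-one tensors,

    T = sum_t  lambda_t * p_t^(1) (x) ... (x) p_t^(n_d),

which collapses evaluation to products of inner products,

    pi(x) = sum_t lambda_t * prod_d <p_t^(d), x>,

an ``O(n_d * n_t * n)`` computation.  Unlike factorization machines the
rank-one factors are free per degree slot, so the represented polynomial is
NOT constrained to be symmetric in its variables — the property that lets
the model treat the two drug slots of a combination asymmetrically.

Two parameterizations live here:

* :class:`BasicPolyParameters` — the plain factorized polynomial
  (factor matrices ``P^(d)`` of shape ``n_t x n``).
* :class:`LTRParameters` — the extended ("bottlenecked") model,

      pi(x) = sum_t lambda_t prod_d <v_t^(d), A(U^(d)^T D_{lambda_u} x)>,

  where each ``U^(d)`` projects the input into ``n_k`` dimensions,
  ``lambda_u`` is a per-input scaling vector, and ``A`` a pointwise
  activation.  With identity activation, ``n_k = n``, ``U^(d) = I`` and
  ``lambda_u = 1`` the extended form reduces exactly to the basic one.

:func:`expand_full_tensor` materializes the dense coefficient tensor and is
test-only scaffolding: it provides an independent brute-force oracle at tiny
sizes and refuses to build anything large.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from functools import reduce
from typing import Callable

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "Activation",
    "BasicPolyParameters",
    "FullTensor",
    "LTRParameters",
    "eval_basic",
    "eval_extended",
    "expand_full_tensor",
    "homogenize",
    "normalize_rows",
    "save_model",
    "load_model",
]

FULL_TENSOR_CAP = 10**6


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Activation:
    """A pointwise activation with its derivative (needed for gradients)."""

    name: str
    f: Callable[[np.ndarray], np.ndarray]
    df: Callable[[np.ndarray], np.ndarray]

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.f(z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


ACTIVATIONS: dict[str, Activation] = {
    "identity": Activation("identity", lambda z: z, lambda z: np.ones_like(z)),
    "tanh": Activation("tanh", np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "sigmoid": Activation(
        "sigmoid", _sigmoid, lambda z: _sigmoid(z) * (1.0 - _sigmoid(z))
    ),
}


def get_activation(name: str) -> Activation:
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class BasicPolyParameters:
    """Plain factorized polynomial: ``pi(x) = sum_t lambda_t prod_d <p_t^(d), x>``.

    ``P[d]`` has shape ``(n_t, n)``; row ``t`` is the factor ``p_t^(d)``.
    """

    lam: np.ndarray          # (n_t,)
    P: list[np.ndarray]      # n_d matrices, each (n_t, n)

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.P = [np.asarray(p, dtype=float) for p in self.P]
        if self.lam.ndim != 1:
            raise ValueError("lambda must be a vector")
        n_t = self.lam.shape[0]
        if not self.P:
            raise ValueError("need at least one factor matrix (degree >= 1)")
        shape = self.P[0].shape
        for d, p in enumerate(self.P):
            if p.ndim != 2 or p.shape[0] != n_t:
                raise ValueError(
                    f"factor matrix for degree slot {d} has shape {p.shape}, "
                    f"expected ({n_t}, n)"
                )
            if p.shape != shape:
                raise ValueError(
                    f"factor matrix for degree slot {d} has shape {p.shape}, "
                    f"expected {shape}"
                )

    @property
    def degree(self) -> int:
        return len(self.P)

    @property
    def rank(self) -> int:
        return self.lam.shape[0]

    @property
    def n(self) -> int:
        return self.P[0].shape[1]


@dataclass
class LTRParameters:
    """Full state of the extended LTR predictor.

    Shapes: ``lambda_u (n,)``, ``lam (n_t,)``, ``U[d] (n, n_k)``,
    ``V[d] (n_t, n_k)``, ``Q (n_t, n_y)``.
    """

    lambda_u: np.ndarray
    lam: np.ndarray
    U: list[np.ndarray]
    V: list[np.ndarray]
    Q: np.ndarray
    activation: str = "identity"

    def __post_init__(self) -> None:
        self.lambda_u = np.asarray(self.lambda_u, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.U = [np.asarray(u, dtype=float) for u in self.U]
        self.V = [np.asarray(v, dtype=float) for v in self.V]
        self.Q = np.asarray(self.Q, dtype=float)
        get_activation(self.activation)
        if len(self.U) != len(self.V):
            raise ValueError("U and V must have one matrix per degree slot")
        n, n_k = self.U[0].shape
        n_t = self.lam.shape[0]
        for d, u in enumerate(self.U):
            if u.shape != (n, n_k):
                raise ValueError(
                    f"U for degree slot {d} has shape {u.shape}, expected {(n, n_k)}"
                )
        for d, v in enumerate(self.V):
            if v.shape != (n_t, n_k):
                raise ValueError(
                    f"V for degree slot {d} has shape {v.shape}, expected {(n_t, n_k)}"
                )
        if self.lambda_u.shape != (n,):
            raise ValueError(
                f"lambda_u has shape {self.lambda_u.shape}, expected ({n},)"
            )
        if self.Q.ndim != 2 or self.Q.shape[0] != n_t:
            raise ValueError(
                f"Q has shape {self.Q.shape}, expected ({n_t}, n_y)"
            )

    @property
    def degree(self) -> int:
        return len(self.U)

    @property
    def rank(self) -> int:
        return self.lam.shape[0]

    @property
    def n(self) -> int:
        return self.U[0].shape[0]

    @property
    def n_k(self) -> int:
        return self.U[0].shape[1]

    @property
    def n_y(self) -> int:
        return self.Q.shape[1]

    def copy(self) -> "LTRParameters":
        return LTRParameters(
            lambda_u=self.lambda_u.copy(),
            lam=self.lam.copy(),
            U=[u.copy() for u in self.U],
            V=[v.copy() for v in self.V],
            Q=self.Q.copy(),
            activation=self.activation,
        )

    def check_finite(self) -> None:
        for name, arr in self.blocks().items():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite entries in parameter block {name}")

    def blocks(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {"lambda_u": self.lambda_u, "lam": self.lam}
        for d, u in enumerate(self.U):
            out[f"U{d}"] = u
        for d, v in enumerate(self.V):
            out[f"V{d}"] = v
        out["Q"] = self.Q
        return out


@dataclass
class FullTensor:
    """Dense order-``n_d`` coefficient tensor; brute-force oracle only."""

    coeffs: np.ndarray

    @property
    def order(self) -> int:
        return self.coeffs.ndim

    @property
    def n(self) -> int:
        return self.coeffs.shape[0]

    def evaluate(self, x: np.ndarray) -> float:
        """``< T, x (x) ... (x) x >`` by successive mode contractions."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(
                f"x has shape {x.shape}, expected ({self.n},) for mode dimension"
            )
        out = self.coeffs
        for _ in range(self.order):
            out = out @ x
        return float(out)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def eval_basic(params: BasicPolyParameters, x: np.ndarray) -> float:
    """Evaluate the factorized polynomial at one point.

    Uses the Hadamard-product form ``lam^T (P^(1) x o P^(2) x o ...)``,
    equivalent to the sum over rank-one terms of products of inner products.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n,):
        raise ValueError(
            f"x has shape {x.shape}, expected ({params.n},) to match the factors"
        )
    prods = reduce(lambda a, b: a * b, (p @ x for p in params.P))
    return float(params.lam @ prods)


def _extended_factor_path(
    params: LTRParameters, X: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Shared forward pass: returns per-degree activations ``A^(d)``,
    pre-activations ``Z^(d) = X D_{lambda_u} U^(d)``, and ``F`` (m x n_t)."""
    act = get_activation(params.activation)
    Xs = X * params.lambda_u  # X D_{lambda_u}
    Z = [Xs @ u for u in params.U]
    A = [act(z) for z in Z]
    F = reduce(lambda a, b: a * b, (a @ v.T for a, v in zip(A, params.V)))
    return A, Z, F


def eval_extended(params: LTRParameters, X: np.ndarray) -> np.ndarray:
    """Batched evaluation of the extended LTR predictor.

    ``X`` is ``(m, n)`` with the homogeneous constant already appended.
    Returns the ``(m, n_y)`` prediction matrix ``F D_lam Q`` where
    ``F = o_d A(X D_{lambda_u} U^(d)) V^(d)^T``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.n:
        raise ValueError(
            f"X has shape {X.shape}, expected (m, {params.n}) to match the model"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    _, _, F = _extended_factor_path(params, X)
    return (F * params.lam) @ params.Q


def expand_full_tensor(params: BasicPolyParameters, cap: int = FULL_TENSOR_CAP) -> FullTensor:
    """Materialize ``T = sum_t lam_t p_t^(1) (x) ... (x) p_t^(n_d)`` densely.

    Brute-force oracle for small instances; refuses when ``n**n_d`` exceeds
    ``cap`` because dense storage defeats the point of the factorization.
    """
    n, n_d = params.n, params.degree
    size = n**n_d
    if size > cap:
        raise MemoryError(
            f"dense tensor would hold {size} > {cap} coefficients; "
            "the expansion is an oracle for test-scale instances only"
        )
    T = np.zeros((n,) * n_d)
    for t in range(params.rank):
        rank_one = params.lam[t]
        for p in params.P:
            rank_one = np.tensordot(rank_one, p[t], axes=0)
        T = T + rank_one
    return FullTensor(T)


def homogenize(X_raw: np.ndarray) -> np.ndarray:
    """Append the homogeneous constant-1 column (always the LAST column).

    With the constant present, a degree-``n_d`` homogeneous-style model
    covers every polynomial of degree up to ``n_d`` including the intercept.
    Not idempotent — callers must apply exactly once and record it in the
    feature layout.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.ndim == 1:
        X_raw = X_raw[None, :]
    if not np.all(np.isfinite(X_raw)):
        raise ValueError("X contains non-finite entries")
    return np.hstack([X_raw, np.ones((X_raw.shape[0], 1))])


def normalize_rows(M: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Project each row of ``M`` onto the unit sphere; zero rows stay zero."""
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    safe = np.where(norms > eps, norms, 1.0)
    return M / safe


def basic_from_extended(params: LTRParameters) -> BasicPolyParameters:
    """Absorb the bottleneck into plain factors (identity activation only).

    With ``A = id``, ``<v_t^(d), U^(d)^T D_{lambda_u} x> = <p_t^(d), x>``
    for ``p_t^(d) = D_{lambda_u} U^(d) v_t^(d)``; the output projection ``Q``
    (single output) folds into ``lambda``.
    """
    if params.activation != "identity":
        raise ValueError("algebraic absorption requires the identity activation")
    if params.n_y != 1:
        raise ValueError("absorption into a scalar polynomial needs n_y == 1")
    P = [(params.U[d] * params.lambda_u[:, None]) @ params.V[d].T for d in range(params.degree)]
    # P entries above are (n, n_t); transpose to (n_t, n) row-per-factor form.
    return BasicPolyParameters(
        lam=params.lam * params.Q[:, 0], P=[p.T for p in P]
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(path, params: LTRParameters, hyper: dict | None = None,
               layout_json: str | None = None) -> None:
    """Write the model to a single ``.npz``-style zip archive.

    The archive holds every parameter array plus a JSON header with the
    format version, activation name, hyperparameter snapshot and (optionally)
    the feature-block layout used at training time.  Round trip is exact.
    """
    header = {
        "format_version": _FORMAT_VERSION,
        "activation": params.activation,
        "degree": params.degree,
        "hyper": hyper or {},
        "layout": json.loads(layout_json) if layout_json else None,
    }
    arrays = {"lambda_u": params.lambda_u, "lam": params.lam, "Q": params.Q}
    for d in range(params.degree):
        arrays[f"U{d}"] = params.U[d]
        arrays[f"V{d}"] = params.V[d]
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    buf.seek(0)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        zf.writestr("arrays.npz", buf.read())


def load_model(path) -> tuple[LTRParameters, dict, str | None]:
    """Inverse of :func:`save_model`; returns (params, hyper, layout_json)."""
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        if header["format_version"] != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {header['format_version']}"
            )
        with zf.open("arrays.npz") as fh:
            data = np.load(io.BytesIO(fh.read()))
            n_d = header["degree"]
            params = LTRParameters(
                lambda_u=data["lambda_u"],
                lam=data["lam"],
                U=[data[f"U{d}"] for d in range(n_d)],
                V=[data[f"V{d}"] for d in range(n_d)],
                Q=data["Q"],
                activation=header["activation"],
            )
    layout = header.get("layout")
    layout_json = json.dumps(layout) if layout is not None else None
    return params, header.get("hyper", {}), layout_json
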