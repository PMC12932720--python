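"""Linear and quadratic selection indices (LPSI, LGSI, QPSI, QGSI).

The breeding objective is the quadratic net genetic merit

    H_q = w'g + g'Wg,

where ``g`` is the vector of true genetic values, ``w`` the linear economic
weights and ``W`` a symmetric matrix of quadratic / cross-product weights.
Each index is the minimum-MSPE predictor of ``H_q`` from its information
source under joint multivariate normality:

* **LPSI** (phenotypic, linear): ``I = b'y`` with ``b = P^-1 G w``.
* **QPSI** (phenotypic, quadratic): the conditional expectation
  ``E[H_q | y] = b'y + y' (P^-1 G W G P^-1) y + tr(W (G - G P^-1 G))``.
* **LGSI** (genomic, linear): ``I = w' gebv`` — GEBVs carry their own
  regression toward the mean, so the weights are applied directly.
* **QGSI** (genomic, quadratic): ``I = w' gebv + gebv' W gebv`` — under the
  classical genomic assumption ``Cov(gebv) = Cov(gebv, g) = Gamma`` the
  MSPE-minimising coefficients are the economic weights themselves.

Setting ``W = 0`` reduces each quadratic index exactly to its linear
counterpart. All scored inputs are mean-centered before evaluation so the
closed-form moments (which assume zero-mean normals) apply; the constant
part of the conditional expectation is carried in ``offset``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._linalg import check_symmetric, is_psd
from .covariance import CovarianceSet

logger = logging.getLogger(__name__)

__all__ = [
    "EconomicWeights",
    "IndexModel",
    "lpsi_coefficients",
    "qpsi_coefficients",
    "lgsi_model",
    "qgsi_model",
    "evaluate_index",
    "index_moments",
    "merit_hq",
]

LINEAR_KINDS = ("LPSI", "LGSI")
QUADRATIC_KINDS = ("QPSI", "QGSI")
PHENOTYPIC_KINDS = ("LPSI", "QPSI")
GENOMIC_KINDS = ("LGSI", "QGSI")


@dataclass
class EconomicWeights:
    """Linear weights w (merit per trait unit) and symmetric quadratic W."""

    w: np.ndarray
    W: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        t = self.w.size
        if self.W is None:
            self.W = np.zeros((t, t))
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (t, t):
            raise ValueError(f"W must be {t}x{t}")
        self.W = 0.5 * (self.W + self.W.T)

    @classmethod
    def zero(cls, w: np.ndarray) -> "EconomicWeights":
        return cls(w=w)

    @classmethod
    def rank1(cls, w: np.ndarray) -> "EconomicWeights":
        """W = (1/2) w w' — quadratic weights aligned with the linear goal."""
        w = np.asarray(w, dtype=float).ravel()
        return cls(w=w, W=0.5 * np.outer(w, w))

    @classmethod
    def diag(cls, w: np.ndarray, d: np.ndarray) -> "EconomicWeights":
        return cls(w=w, W=np.diag(np.asarray(d, dtype=float)))

    @property
    def is_linear(self) -> bool:
        return not np.any(self.W)


@dataclass
class IndexModel:
    """An index: kind, linear coefficients, quadratic matrix and offset.

    Score of a (centered) input row x is ``linear'x + x'quad x + offset``.
    """

    kind: str
    linear: np.ndarray
    quad: np.ndarray
    offset: float = 0.0
    traits: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in LINEAR_KINDS + QUADRATIC_KINDS:
            raise ValueError(f"unknown index kind {self.kind!r}")
        self.linear = np.asarray(self.linear, dtype=float).ravel()
        self.quad = check_symmetric(np.asarray(self.quad, dtype=float), name="quad")
        if self.quad.shape[0] != self.linear.size:
            raise ValueError("linear and quad dimensions disagree")
        if not (np.isfinite(self.linear).all() and np.isfinite(self.quad).all()):
            raise ValueError("non-finite index coefficients")

    @property
    def is_quadratic(self) -> bool:
        return bool(np.any(self.quad))

    @property
    def is_genomic(self) -> bool:
        return self.kind in GENOMIC_KINDS


def _solve_P(P: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(P)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"P is singular or ill-conditioned (condition number {cond:.3g})")
    return np.linalg.solve(P, rhs)


def lpsi_coefficients(covs: CovarianceSet, weights: EconomicWeights) -> IndexModel:
    """Smith-Hazel coefficients b = P^-1 G w (quad = 0)."""
    b = _solve_P(covs.P, covs.G @ weights.w)
    t = weights.w.size
    return IndexModel(kind="LPSI", linear=b, quad=np.zeros((t, t)), offset=0.0, traits=covs.traits)


def qpsi_coefficients(covs: CovarianceSet, weights: EconomicWeights) -> IndexModel:
    """Minimum-MSPE quadratic phenotypic predictor of H_q given y.

    linear = P^-1 G w;  quad = P^-1 G W G P^-1;
    offset = tr(W (G - G P^-1 G))  (the conditional-variance constant).
    With W = 0 this is exactly the LPSI.
    """
    P, G, W = covs.P, covs.G, weights.W
    b = _solve_P(P, G @ weights.w)
    PiG = _solve_P(P, G)  # P^-1 G
    quad = PiG @ W @ PiG.T
    offset = float(np.trace(W @ (G - G @ PiG)))
    return IndexModel(
        kind="QPSI", linear=b, quad=0.5 * (quad + quad.T), offset=offset, traits=covs.traits
    )


def lgsi_model(weights: EconomicWeights, traits: list[str] | None = None) -> IndexModel:
    """Linear genomic index: GEBVs weighted directly by w."""
    t = weights.w.size
    return IndexModel(kind="LGSI", linear=weights.w.copy(), quad=np.zeros((t, t)), traits=traits)


def qgsi_model(covs: CovarianceSet | None, weights: EconomicWeights) -> IndexModel:
    """Quadratic genomic index I = w'gebv + gebv' W gebv (theta = w, D = W).

    ``covs`` (with Gamma) is only validated here; under
    Cov(gebv) = Cov(gebv, g) = Gamma the weights are MSPE-optimal as given.
    """
    if covs is not None and covs.Gamma is not None and not is_psd(covs.Gamma):
        raise ValueError("Gamma is not positive semi-definite")
    traits = covs.traits if covs is not None else None
    return IndexModel(
        kind="QGSI", linear=weights.w.copy(), quad=weights.W.copy(), offset=0.0, traits=traits
    )


def evaluate_index(model: IndexModel, scores_input: np.ndarray, center: bool = True) -> np.ndarray:
    """Score candidates: ``linear'x + x'quad x + offset`` per row.

    ``scores_input`` is an n x t matrix of phenotype entry means (phenotypic
    kinds) or GEBVs (genomic kinds), columns in the model's trait order.
    Inputs are mean-centered by default (the package's scoring convention).
    """
    X = np.asarray(scores_input, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.linear.size:
        raise ValueError(
            f"input has {X.shape[1]} traits but the model expects {model.linear.size}"
        )
    if center:
        X = X - X.mean(axis=0)
    scores = X @ model.linear + model.offset
    if model.is_quadratic:
        scores = scores + np.einsum("ij,jk,ik->i", X, model.quad, X)
    return scores


def index_moments(model: IndexModel, Sigma: np.ndarray) -> tuple[float, float]:
    """Mean and variance of the index for a zero-mean normal scored variable.

    mean = tr(quad Sigma) + offset;
    variance = linear' Sigma linear + 2 tr(quad Sigma quad Sigma).
    """
    S = check_symmetric(Sigma, tol=1e-8, name="Sigma")
    qs = model.quad @ S
    mean = float(np.trace(qs)) + model.offset
    var = float(model.linear @ S @ model.linear) + 2.0 * float(np.trace(qs @ qs))
    return mean, var


def merit_hq(g: np.ndarray, weights: EconomicWeights) -> np.ndarray:
    """Quadratic net genetic merit H_q = w'g + g'Wg per row of g."""
    G = np.asarray(g, dtype=float)
    if G.ndim == 1:
        G = G[None, :]
    h = G @ weights.w
    if not weights.is_linear:
        h = h + np.einsum("ij,jk,ik->i", G, weights.W, G)
    return h
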