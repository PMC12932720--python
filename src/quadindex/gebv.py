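"""Genomic prediction engines producing GEBVs for the selection indices.

Two engines are provided:

* **GBLUP** — additive multi-trait ridge/BLUP on standardized markers.  The
  multi-trait system is block-diagonal across traits (shared marker matrix),
  so it is solved exactly per trait.  The marker form
  ``beta_t = (M'M + lambda_t I)^-1 M' y_t`` and the kernel (GRM) form
  ``gebv = K (K + (lambda/c) I)^-1 y`` are algebraically identical; the
  cheaper one is used automatically.
* **RKHS** — a Bayesian multi-trait Gaussian-kernel regression
  ``Y = U + E`` with ``U ~ MN(0, K, Sigma_u)`` and ``E ~ MN(0, I, Sigma_e)``,
  fitted by a Gibbs sampler with inverse-Wishart priors on the trait
  covariance components.  The kernel captures nonlinear (epistatic-like)
  genomic signal that the additive engine cannot.

Markers are coded as allele counts in {0,1,2} and standardized columnwise to
``2-2p`` (AA), ``1-2p`` (Aa), ``-2p`` (aa), where ``p`` is the training-set
frequency of allele A.  Training frequencies are frozen and re-used for any
test set so that predictions stay on the training scale — this matters in
recurrent selection where allele frequencies drift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._linalg import nearest_psd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "MarkerEffects",
    "Kernel",
    "standardize_markers",
    "grm",
    "gaussian_kernel",
    "GBLUP",
    "RKHSRegressor",
    "fit_gblup",
    "predict_gebv",
    "fit_rkhs_multitrait",
]


@dataclass
class MarkerMatrix:
    """Biallelic genotype codes plus frequencies and the standardized coding.

    ``codes`` holds allele-A counts in {0,1,2} (missing imputed to the column
    mean before standardization), ``freqs`` the training-set allele-A
    frequencies, and ``M`` the standardized matrix with entries
    ``codes - 2 p`` columnwise.
    """

    codes: np.ndarray
    freqs: np.ndarray
    M: np.ndarray
    ids: np.ndarray | None = None
    marker_names: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    def scaling_constant(self) -> float:
        """GRM denominator c = 2 * sum_j p_j (1 - p_j)."""
        return float(2.0 * np.sum(self.freqs * (1.0 - self.freqs)))


@dataclass
class MarkerEffects:
    """Per-marker additive effects for t traits (m x t) with shrinkage used."""

    beta: np.ndarray
    lam: np.ndarray
    freqs: np.ndarray
    traits: list[str] | None = None


@dataclass
class Kernel:
    """A genomic similarity kernel (GRM or Gaussian)."""

    values: np.ndarray
    kind: str
    bandwidth: float | None = None


def standardize_markers(
    codes: np.ndarray,
    freqs: np.ndarray | None = None,
    ids: np.ndarray | None = None,
    marker_names: np.ndarray | None = None,
    drop_monomorphic: bool = True,
) -> MarkerMatrix:
    """Standardize allele-count codes to the 2-2p / 1-2p / -2p coding.

    If ``freqs`` is omitted, allele frequencies are computed from ``codes``
    (the training set); pass training frequencies when standardizing a test
    set. Missing codes (NaN) are imputed to the column mean of the observed
    codes. Monomorphic columns (p in {0,1}) carry no information and are
    excluded with a warning unless frequencies were supplied externally.
    """
    codes = np.asarray(codes, dtype=float)
    if codes.ndim != 2:
        raise ValueError("codes must be an n x m matrix")
    obs = ~np.isnan(codes)
    if not obs.any(axis=0).all():
        bad = np.flatnonzero(~obs.any(axis=0))
        raise ValueError(f"all-missing marker columns: {bad.tolist()}")
    valid = np.clip(np.nan_to_num(codes, nan=0.0), 0, 2)
    if not np.array_equal(valid[obs], codes[obs]) or not np.isin(codes[obs], (0.0, 1.0, 2.0)).all():
        raise ValueError("codes must be allele counts in {0, 1, 2} or missing")

    col_mean = np.where(obs, codes, 0.0).sum(axis=0) / obs.sum(axis=0)
    imputed = np.where(obs, codes, col_mean)

    own_freqs = freqs is None
    if own_freqs:
        freqs = col_mean / 2.0
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (codes.shape[1],):
        raise ValueError("freqs length must match marker count")

    if drop_monomorphic and own_freqs:
        poly = (freqs > 0.0) & (freqs < 1.0)
        if not poly.all():
            warnings.warn(f"excluding {int((~poly).sum())} monomorphic markers", stacklevel=2)
            imputed = imputed[:, poly]
            freqs = freqs[poly]
            if marker_names is not None:
                marker_names = np.asarray(marker_names)[poly]
        if imputed.shape[1] == 0:
            raise ValueError("no polymorphic markers remain")

    M = imputed - 2.0 * freqs
    return MarkerMatrix(codes=imputed, freqs=freqs, M=M, ids=ids, marker_names=marker_names)


def grm(markers: MarkerMatrix) -> Kernel:
    """Genomic relationship matrix Phi = M M' / (2 sum p(1-p))."""
    if markers.m < 1:
        raise ValueError("no polymorphic markers")
    c = markers.scaling_constant()
    if c <= 0:
        raise ValueError("no polymorphic markers (scaling constant is zero)")
    phi = markers.M @ markers.M.T / c
    return Kernel(values=0.5 * (phi + phi.T), kind="GRM")


def gaussian_kernel(markers: MarkerMatrix | np.ndarray, bandwidth: float | str = "median") -> Kernel:
    """Gaussian (RKHS) kernel on standardized marker rows.

    ``K_ij = exp(-d2_ij / (h * q))`` with ``d2`` the squared Euclidean
    distance between rows, ``q`` the median of the nonzero ``d2`` (the median
    heuristic) and ``h`` a positive multiplier. ``bandwidth="median"`` uses
    ``h = 1``; a numeric bandwidth sets ``h`` directly.
    """
    M = markers.M if isinstance(markers, MarkerMatrix) else np.asarray(markers, dtype=float)
    sq = np.sum(M**2, axis=1)
    d2 = np.clip(sq[:, None] + sq[None, :] - 2.0 * (M @ M.T), 0.0, None)
    np.fill_diagonal(d2, 0.0)
    if bandwidth == "median":
        h = 1.0
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    nz = d2[np.triu_indices_from(d2, k=1)]
    nz = nz[nz > 0]
    if nz.size == 0:
        raise ValueError("median bandwidth heuristic undefined: all rows identical")
    q = float(np.median(nz))
    K = np.exp(-d2 / (h * q))
    np.fill_diagonal(K, 1.0)
    return Kernel(values=0.5 * (K + K.T), kind="Gaussian", bandwidth=h * q)


class GBLUP(BaseEstimator, RegressorMixin):
    """Multi-trait additive GBLUP as per-trait ridge on standardized markers.

    Parameters
    ----------
    lam:
        Shrinkage per trait: scalar, length-t array, or None.  With None,
        ``h2`` must be given and ``lam_t = c (1 - h2_t) / h2_t`` where
        ``c = 2 sum p(1-p)`` (the marker-variance scaling that makes the
        ridge equivalent to the GRM mixed model with variance ratio
        ``(1-h2)/h2`` on the entry-mean basis).
    h2:
        Per-trait heritabilities used to derive ``lam`` when lam is None.
    """

    def __init__(self, lam: float | np.ndarray | None = None, h2: np.ndarray | None = None):
        self.lam = lam
        self.h2 = h2

    def _resolve_lam(self, markers: MarkerMatrix, t: int) -> np.ndarray:
        if self.lam is not None:
            lam = np.broadcast_to(np.asarray(self.lam, dtype=float), (t,)).copy()
        elif self.h2 is not None:
            h2 = np.clip(np.broadcast_to(np.asarray(self.h2, dtype=float), (t,)), 1e-6, 1 - 1e-6)
            lam = markers.scaling_constant() * (1.0 - h2) / h2
        else:
            raise ValueError("provide lam or h2")
        if (lam < 0).any():
            raise ValueError("lam must be nonnegative")
        return lam

    def fit(self, markers: MarkerMatrix, Y: np.ndarray) -> "GBLUP":
        """Fit marker effects from training markers and entry-mean phenotypes."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, m = markers.M.shape
        if Y.shape[0] != n:
            raise ValueError("phenotype rows must match marker rows")
        t = Y.shape[1]
        lam = self._resolve_lam(markers, t)
        if (lam == 0).any() and m > n:
            raise ValueError("singular system: m > n with lam=0; use lam > 0")
        self.mu_ = Y.mean(axis=0)
        Yc = Y - self.mu_
        M = markers.M
        beta = np.empty((m, t))
        if m <= n:
            mtm = M.T @ M
            for k in range(t):
                beta[:, k] = np.linalg.solve(mtm + lam[k] * np.eye(m), M.T @ Yc[:, k])
        else:
            mmt = M @ M.T
            for k in range(t):
                alpha = np.linalg.solve(mmt + lam[k] * np.eye(n), Yc[:, k])
                beta[:, k] = M.T @ alpha
        self.lam_ = lam
        self.effects_ = MarkerEffects(beta=beta, lam=lam, freqs=markers.freqs.copy())
        self.n_features_in_ = m
        self.gebv_ = M @ beta
        return self

    def predict(self, markers: MarkerMatrix) -> np.ndarray:
        """GEBVs for a (test) marker set standardized with training frequencies."""
        if not hasattr(self, "effects_"):
            raise ValueError("GBLUP instance is not fitted")
        if markers.M.shape[1] != self.n_features_in_:
            raise ValueError(
                f"marker count mismatch: fitted with {self.n_features_in_}, got {markers.M.shape[1]}"
            )
        return markers.M @ self.effects_.beta


def fit_gblup(
    panel_means: np.ndarray,
    markers: MarkerMatrix,
    lam: float | np.ndarray | None = None,
    h2: np.ndarray | None = None,
) -> MarkerEffects:
    """Functional wrapper: fit GBLUP on entry means, return marker effects."""
    return GBLUP(lam=lam, h2=h2).fit(markers, panel_means).effects_


def predict_gebv(effects: MarkerEffects, markers_test: MarkerMatrix) -> np.ndarray:
    """GEBVs = M beta per trait for a test set on the training standardization."""
    if markers_test.M.shape[1] != effects.beta.shape[0]:
        raise ValueError(
            f"marker count mismatch: effects for {effects.beta.shape[0]}, got {markers_test.M.shape[1]}"
        )
    return markers_test.M @ effects.beta


class RKHSRegressor(BaseEstimator, RegressorMixin):
    """Bayesian multi-trait kernel regression fitted by Gibbs sampling.

    Model: ``Y = mu + U + E`` with ``U ~ MN(0, K, Sigma_u)`` (rows =
    individuals, columns = traits) and ``E ~ MN(0, I, Sigma_e)``; conjugate
    inverse-Wishart priors on both trait covariance components with df
    ``t + 2`` and prior mean ``prior_scale`` times the observed trait
    variances (the default 0.5 splits the variance evenly between signal
    and noise a priori; lower it toward zero for near-noiseless data).
    The trait means ``mu`` are fixed at the sample means. The sampler works
    in the eigenbasis of K, where the full conditional of U factorises over
    individuals and traits, so each sweep is a vectorised n x t update.

    A seed is required: chains are bit-identical under a fixed seed.
    """

    def __init__(
        self,
        n_iter: int = 4000,
        burn_in: int = 1000,
        thin: int = 5,
        seed: int | None = None,
        prior_df: float | None = None,
        prior_scale: float = 0.5,
        eig_tol: float = 1e-10,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_df = prior_df
        self.prior_scale = prior_scale
        self.eig_tol = eig_tol

    def fit(self, K: Kernel | np.ndarray, Y: np.ndarray) -> "RKHSRegressor":
        Kv = K.values if isinstance(K, Kernel) else np.asarray(K, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, t = Y.shape
        if Kv.shape != (n, n):
            raise ValueError("kernel not conformable with phenotypes")
        if self.seed is None:
            raise ValueError("RKHSRegressor requires an explicit seed")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn-in must be smaller than the iteration count")
        evals, evecs = np.linalg.eigh(0.5 * (Kv + Kv.T))
        if evals.min() < -1e-8:
            raise ValueError("kernel is not positive semi-definite")
        evals = np.clip(evals, 0.0, None)
        pos = evals > self.eig_tol * max(evals.max(), 1.0)

        rng = np.random.default_rng(self.seed)
        nu = float(self.prior_df) if self.prior_df is not None else t + 2.0
        vy = np.var(Y, axis=0, ddof=1)
        vy = np.where(vy > 0, vy, 1.0)
        psi = np.diag(self.prior_scale * vy) * max(nu - t - 1.0, 1.0)

        mu = Y.mean(axis=0)
        Yc = Y - mu
        Yt = evecs.T @ Yc  # rotated responses
        s = evals
        sig_u = np.diag(0.5 * vy)
        sig_e = np.diag(0.5 * vy)
        Ut = np.zeros((n, t))
        n_pos = int(pos.sum())

        keep_u = []
        keep_su = []
        keep_se = []
        for it in range(self.n_iter):
            # --- U | rest, in the simultaneously diagonalising basis
            Le = np.linalg.cholesky(sig_e)
            Bmat = np.linalg.solve(Le, np.linalg.solve(Le, sig_u.T).T)
            lam_b, Q = np.linalg.eigh(0.5 * (Bmat + Bmat.T))
            lam_b = np.clip(lam_b, 0.0, None)
            T = Q.T @ np.linalg.inv(Le)  # t x t: maps trait space to whitened coords
            Z = Yt @ T.T
            shrink = (s[:, None] * lam_b[None, :]) / (1.0 + s[:, None] * lam_b[None, :])
            mean = shrink * Z
            sd = np.sqrt(shrink)
            draws = mean + sd * rng.standard_normal((n, t))
            draws[~pos, :] = 0.0
            Tinv = Le @ Q
            Ut = draws @ Tinv.T

            # --- Sigma_u | U
            if n_pos > 0:
                su_scatter = (Ut[pos].T / s[pos]) @ Ut[pos]
                sig_u = stats.invwishart.rvs(df=nu + n_pos, scale=psi + su_scatter, random_state=rng)
            sig_u = np.atleast_2d(sig_u)

            # --- Sigma_e | residuals
            resid = Yt - Ut
            sig_e = stats.invwishart.rvs(df=nu + n, scale=psi + resid.T @ resid, random_state=rng)
            sig_e = np.atleast_2d(sig_e)

            if not (np.isfinite(sig_u).all() and np.isfinite(sig_e).all() and np.isfinite(Ut).all()):
                raise RuntimeError(f"divergent chain at iteration {it}")

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                keep_u.append(evecs @ Ut)
                keep_su.append(sig_u.copy())
                keep_se.append(sig_e.copy())

        self.mu_ = mu
        self.u_samples_ = np.array(keep_u)
        self.Sigma_u_samples_ = np.array(keep_su)
        self.Sigma_e_samples_ = np.array(keep_se)
        self.u_ = self.u_samples_.mean(axis=0)
        self.Sigma_u_ = self.Sigma_u_samples_.mean(axis=0)
        self.Sigma_e_ = self.Sigma_e_samples_.mean(axis=0)
        return self

    def predict(self, K_new_train: np.ndarray | None = None) -> np.ndarray:
        """Posterior-mean GEBVs; with ``K_new_train`` (n_new x n_train cross-
        kernel) GEBVs are interpolated to new individuals via the kernel."""
        if not hasattr(self, "u_"):
            raise ValueError("RKHSRegressor instance is not fitted")
        if K_new_train is None:
            return self.u_
        raise NotImplementedError("out-of-sample RKHS prediction is not provided")


def fit_rkhs_multitrait(
    Y: np.ndarray,
    K: Kernel | np.ndarray,
    seed: int,
    n_iter: int = 4000,
    burn_in: int = 1000,
    thin: int = 5,
) -> tuple[np.ndarray, dict]:
    """Functional wrapper: posterior-mean GEBVs and variance components."""
    model = RKHSRegressor(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed).fit(K, Y)
    post = {
        "Sigma_u": model.Sigma_u_,
        "Sigma_e": model.Sigma_e_,
        "Sigma_u_samples": model.Sigma_u_samples_,
        "Sigma_e_samples": model.Sigma_e_samples_,
    }
    return model.u_, post
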