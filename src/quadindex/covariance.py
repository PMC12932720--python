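"""Phenotypic (P), genotypic (G) and genomic (Gamma) covariance estimation.

The estimators operate on replicated multi-trait trials: each genotype is
observed in ``r`` replicates for ``t`` traits.  The analysis basis is the
genotype entry mean (the mean over replicates), which is the scale on which
selection indices are evaluated in replicated trials.

For a balanced two-way layout ``value = trait mean + genotype + residual`` the
multivariate method-of-moments (MANOVA cross-product) estimators are

* ``MS_g`` — among-genotype mean cross-product matrix,
* ``MS_e`` — residual (within-genotype) mean cross-product matrix,
* ``G = (MS_g - MS_e) / r``  (genotypic covariance),
* ``P = MS_g / r``           (covariance of entry means),
* ``h2_t = s2g_t / (s2g_t + s2e_t / r)`` (broad-sense, entry-mean basis).

Unbalanced replicate counts are handled with the harmonic mean of ``r``.
All matrices are clamped to the nearest positive semi-definite matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import nearest_psd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitPanel",
    "CovarianceSet",
    "estimate_P_G",
    "estimate_Gamma",
    "index_heritability",
]


@dataclass
class TraitPanel:
    """Replicated multi-trait phenotype records.

    Parameters
    ----------
    data:
        Long-format table with columns ``genotype``, ``rep`` and one column
        per trait. Every genotype must have at least one replicate and the
        trait list is shared by all records.
    """

    data: pd.DataFrame
    traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not {"genotype", "rep"}.issubset(self.data.columns):
            raise ValueError("panel requires 'genotype' and 'rep' columns")
        if not self.traits:
            self.traits = [c for c in self.data.columns if c not in ("genotype", "rep")]
        if not self.traits:
            raise ValueError("panel has no trait columns")
        vals = self.data[self.traits]
        if not all(np.issubdtype(d, np.number) for d in vals.dtypes):
            bad = [t for t in self.traits if not np.issubdtype(vals[t].dtype, np.number)]
            raise ValueError(f"non-numeric trait columns: {bad}")
        with np.errstate(invalid="ignore"):
            inf = np.isinf(vals.to_numpy(dtype=float, na_value=np.nan))
        if inf.any():
            raise ValueError("non-finite trait values in panel")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def genotypes(self) -> np.ndarray:
        return self.data["genotype"].unique()

    def entry_means(self) -> pd.DataFrame:
        """Genotype entry means (mean over replicates), one row per genotype."""
        return self.data.groupby("genotype", sort=True)[self.traits].mean()

    def rep_counts(self) -> pd.Series:
        return self.data.groupby("genotype", sort=True).size()


@dataclass
class CovarianceSet:
    """Estimated trait covariance structure.

    Attributes
    ----------
    P : phenotypic covariance of genotype entry means (t x t, PSD)
    G : genotypic covariance (t x t, PSD)
    Gamma : genomic covariance of GEBVs (t x t, PSD), optional
    h2 : per-trait broad-sense heritabilities on the entry-mean basis
    n_reps : (harmonic mean) replicate count used
    """

    P: np.ndarray | None = None
    G: np.ndarray | None = None
    Gamma: np.ndarray | None = None
    h2: np.ndarray | None = None
    n_reps: float | None = None
    traits: list[str] | None = None


def _pairwise_cross_products(panel: TraitPanel) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Among-genotype and residual mean cross-product matrices.

    Returns (MS_g, MS_e, harmonic-mean r, per-trait residual variances).
    Missing cells are dropped pairwise per trait pair with a warning.
    """
    traits = panel.traits
    t = len(traits)
    df = panel.data
    has_na = df[traits].isna().any().any()
    if has_na:
        warnings.warn("missing phenotype cells dropped pairwise per trait pair", stacklevel=3)

    counts = panel.rep_counts()
    n_geno = len(counts)
    if n_geno < 2:
        raise ValueError("at least 2 genotypes required")
    if (counts < 2).all():
        raise ValueError("genotypic covariance not estimable: single replicate everywhere")
    r_harm = len(counts) / np.sum(1.0 / counts.to_numpy())

    ms_g = np.empty((t, t))
    ms_e = np.empty((t, t))

    if has_na:
        gvals = df[["genotype"] + traits]
        for i in range(t):
            for j in range(i, t):
                cols = [traits[i]] if i == j else [traits[i], traits[j]]
                sub = gvals[["genotype"] + cols].dropna()
                sub = sub.sort_values("genotype")
                g = sub.groupby("genotype", sort=True)
                means = g[cols].mean()
                sizes = g.size().to_numpy()
                xm = means[traits[i]].to_numpy()
                ym = means[traits[j]].to_numpy()
                n = len(xm)
                if n < 2:
                    raise ValueError(
                        f"fewer than 2 genotypes with data for pair ({traits[i]},{traits[j]})"
                    )
                rh = n / np.sum(1.0 / sizes)
                xc = xm - xm.mean()
                yc = ym - ym.mean()
                ms_g[i, j] = ms_g[j, i] = rh * np.sum(xc * yc) / (n - 1)
                xi = sub[traits[i]].to_numpy() - np.repeat(xm, sizes)
                yj = sub[traits[j]].to_numpy() - np.repeat(ym, sizes)
                dfree = max(int(sizes.sum()) - n, 1)
                ms_e[i, j] = ms_e[j, i] = np.sum(xi * yj) / dfree
    else:
        g = df.groupby("genotype", sort=True)
        means = g[traits].mean()
        x = df[traits].to_numpy(dtype=float)
        gm = means.loc[df["genotype"]].to_numpy()
        resid = x - gm
        dfree = len(df) - n_geno
        ms_e = resid.T @ resid / dfree
        xc = means.to_numpy() - means.to_numpy().mean(axis=0)
        ms_g = r_harm * (xc.T @ xc) / (n_geno - 1)

    s2e = np.diag(ms_e).copy()
    return ms_g, ms_e, float(r_harm), s2e


def estimate_P_G(panel: TraitPanel) -> CovarianceSet:
    """Estimate P, G and per-trait heritabilities from a replicated panel.

    Raises if fewer than 2 genotypes are present or if no genotype has more
    than one replicate (G inestimable).
    """
    ms_g, ms_e, r, s2e = _pairwise_cross_products(panel)
    g_raw = (ms_g - ms_e) / r
    p_raw = ms_g / r
    s2g = np.clip(np.diag(g_raw), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        h2 = np.where(s2g + s2e / r > 0, s2g / (s2g + s2e / r), 0.0)
    h2 = np.clip(h2, 0.0, 1.0)
    G = nearest_psd(g_raw)
    P = nearest_psd(p_raw)
    return CovarianceSet(P=P, G=G, h2=h2, n_reps=r, traits=list(panel.traits))


def estimate_Gamma(gebvs: np.ndarray) -> np.ndarray:
    """Sample covariance of GEBV rows across individuals, clamped to PSD."""
    gebvs = np.atleast_2d(np.asarray(gebvs, dtype=float))
    if gebvs.shape[0] < 2:
        raise ValueError("at least 2 individuals required to estimate Gamma")
    return nearest_psd(np.cov(gebvs, rowvar=False).reshape(gebvs.shape[1], gebvs.shape[1]))


def index_heritability(P: np.ndarray, G: np.ndarray, b: np.ndarray) -> float:
    """Heritability of a linear index: b'Gb / b'Pb (in [0,1] when P-G is PSD)."""
    b = np.asarray(b, dtype=float)
    if not np.any(b):
        raise ValueError("index coefficients must not be all zero")
    denom = float(b @ np.asarray(P, dtype=float) @ b)
    if denom <= 0:
        raise ValueError("b'Pb = 0: index has no phenotypic variance")
    return float(b @ np.asarray(G, dtype=float) @ b) / denom
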