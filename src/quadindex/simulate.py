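"""Recurrent-selection simulator for multi-trait genomic selection studies.

The simulator emulates a maize-style recurrent selection experiment: a
multi-chromosome genome with uniformly spaced markers and randomly placed
pleiotropic QTLs, founder populations in linkage equilibrium, replicated
phenotypes with per-trait heritability, truncation selection on an index,
and random mating with Haldane (no-interference) recombination.

Genetic correlations between traits arise from shared QTLs.  Because founder
loci are independent with allele frequency ``f`` (dosage variance
``2f(1-f)``), the founder genetic covariance is available in closed form,
``Sigma = 2f(1-f) E'E`` for the QTL-effect matrix ``E``, and the QTL
allocator solves the target correlation matrix exactly by construction:

* a *core* block of QTLs shared by all traits carries the cross-trait
  covariance through an orthonormalised effect basis (``E_core = Q A'`` with
  ``Q'Q = I`` and ``A`` the Cholesky factor of the required covariance);
* *pair* blocks shared by two traits absorb the remaining sharing budget
  with exactly orthogonal effect vectors (zero covariance contribution);
* *trait-specific* QTLs fill the per-trait counts and contribute only
  diagonal variance.

The achieved founder correlation then matches the target up to sampling
error of the founder draw (standard error about ``(1-r^2)/sqrt(n)``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import is_psd, nearest_psd
from .covariance import CovarianceSet, TraitPanel, estimate_Gamma, estimate_P_G
from .gebv import GBLUP, MarkerMatrix, RKHSRegressor, gaussian_kernel, standardize_markers
from .indices import (
    EconomicWeights,
    IndexModel,
    evaluate_index,
    lgsi_model,
    lpsi_coefficients,
    merit_hq,
    qgsi_model,
    qpsi_coefficients,
)
from .response import SelectionConfig, SelectionSummary, empirical_summary, truncation_select

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeConfig",
    "Genome",
    "Population",
    "build_genome",
    "found_population",
    "phenotype",
    "advance_cycle",
    "run_recurrent_selection",
    "mvn_generator",
]

#: target genotypic correlations of the four-trait simulated-maize design
MAIZE_TARGET_CORR = np.array(
    [
        [1.0, -0.5, 0.4, 0.3],
        [-0.5, 1.0, -0.3, -0.2],
        [0.4, -0.3, 1.0, 0.1],
        [0.3, -0.2, 0.1, 1.0],
    ]
)


@dataclass
class GenomeConfig:
    """Genome layout and trait-architecture targets for the simulator."""

    n_chromosomes: int = 10
    n_markers: int = 2806
    n_qtl: int = 315
    qtl_per_trait: tuple[int, ...] = (300, 100, 60, 40)
    target_genetic_corr: np.ndarray = field(default_factory=lambda: MAIZE_TARGET_CORR.copy())
    target_h2: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5)
    chromosome_length_cM: float = 100.0
    founder_freq: float = 0.5
    trait_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.target_genetic_corr = np.asarray(self.target_genetic_corr, dtype=float)
        t = len(self.qtl_per_trait)
        if self.target_genetic_corr.shape != (t, t):
            raise ValueError("target correlation matrix must be t x t")
        if not np.allclose(np.diag(self.target_genetic_corr), 1.0):
            raise ValueError("target correlation matrix must have unit diagonal")
        if not is_psd(self.target_genetic_corr):
            raise ValueError("target correlation matrix is not positive semi-definite")
        if any(c > self.n_qtl for c in self.qtl_per_trait):
            raise ValueError("per-trait QTL counts cannot exceed the total QTL count")
        if not 0.0 < self.founder_freq < 1.0:
            raise ValueError("founder allele frequency must be in (0, 1)")
        if self.trait_names is None:
            self.trait_names = tuple(f"T{i + 1}" for i in range(t))

    @property
    def n_traits(self) -> int:
        return len(self.qtl_per_trait)

    @classmethod
    def simulated_maize(cls) -> "GenomeConfig":
        """The built-in four-trait simulated-maize design (defaults as-is)."""
        return cls()


@dataclass
class Genome:
    """Ordered loci (markers + QTLs) with map positions and QTL effects."""

    chrom: np.ndarray  # per-locus chromosome id
    pos_cM: np.ndarray  # per-locus map position, nondecreasing within chromosome
    is_qtl: np.ndarray  # boolean mask over loci
    qtl_effects: np.ndarray  # n_qtl x t, rows in locus order of the QTLs
    config: GenomeConfig
    expected_corr: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    @property
    def marker_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    def chromosome_slices(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.chrom == c) for c in np.unique(self.chrom)]


@dataclass
class Population:
    """Diploid haplotypes over the genome's loci plus true genetic values."""

    haplotypes: np.ndarray  # n x 2 x L, uint8
    genome: Genome
    true_genetic_values: np.ndarray  # n x t
    cycle: int = 0

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1)

    def marker_codes(self) -> np.ndarray:
        return self.dosages()[:, self.genome.marker_index].astype(float)


def _allocate_qtl(counts: tuple[int, ...], n_qtl: int, corr: np.ndarray):
    """Split the per-trait QTL counts into core / pair / single blocks.

    Returns (core_size, pair_blocks, singles) with pair_blocks a dict
    {(s, t): m}. Sharing budget = sum(counts) - n_qtl assignments that must
    land on already-used QTLs.
    """
    t = len(counts)
    sharing = sum(counts) - n_qtl
    need_corr = bool(np.any(np.abs(corr - np.eye(t)) > 1e-12))
    core = 0
    if need_corr:
        core_wanted = max(t, math.ceil(max(sharing, 0) / max(t - 1, 1)))
        core = min(min(counts), core_wanted)
        if core < t:
            raise ValueError(
                "infeasible correlation targets: the smallest per-trait QTL count "
                f"({min(counts)}) is below the trait count ({t})"
            )
    remaining = [c - core for c in counts]
    left = max(sharing - (t - 1) * core, 0)
    pair_blocks: dict[tuple[int, int], int] = {}
    while left > 0:
        order = np.argsort(remaining)[::-1]
        s, u = int(order[0]), int(order[1])
        if remaining[s] <= 0 or remaining[u] <= 0:
            raise ValueError(
                "infeasible QTL sharing structure: cannot absorb the sharing budget "
                "with the given per-trait counts"
            )
        key = (min(s, u), max(s, u))
        pair_blocks[key] = pair_blocks.get(key, 0) + 1
        remaining[s] -= 1
        remaining[u] -= 1
        left -= 1
    singles = list(remaining)
    return core, pair_blocks, singles


def build_genome(config: GenomeConfig, seed: int) -> Genome:
    """Lay out the genome and calibrate QTL effects to the correlation targets.

    Raises if the targets are infeasible for the sharing structure, reporting
    the achieved matrix.
    """
    rng = np.random.default_rng(seed)
    t = config.n_traits
    counts = tuple(int(c) for c in config.qtl_per_trait)
    corr = config.target_genetic_corr
    v_locus = 2.0 * config.founder_freq * (1.0 - config.founder_freq)

    core, pair_blocks, singles = _allocate_qtl(counts, config.n_qtl, corr)
    n_assigned = core + sum(pair_blocks.values()) + sum(singles)
    if n_assigned > config.n_qtl:
        raise ValueError("QTL allocation exceeds the configured QTL count")

    # variance budget: share of each trait's unit genetic variance carried by
    # non-core QTLs, scaled down until the core covariance stays PSD
    k_noncore = np.array(
        [sum(m for (s, u), m in pair_blocks.items() if trait in (s, u)) + singles[trait]
         for trait in range(t)],
        dtype=float,
    )
    if core == 0:
        d = np.where(k_noncore > 0, 1.0, 0.0)
    else:
        frac = np.divide(k_noncore, counts, out=np.zeros(t), where=np.asarray(counts) > 0)
        d = 0.5 * frac
        for _ in range(60):
            if np.linalg.eigvalsh(corr - np.diag(d)).min() >= 1e-3:
                break
            d *= 0.8
        else:
            raise ValueError("could not find a PSD core covariance for the targets")

    effects = np.zeros((config.n_qtl, t))
    cursor = 0
    if core > 0:
        sigma_core = corr - np.diag(d)
        a = np.linalg.cholesky(sigma_core + 1e-12 * np.eye(t))
        z = rng.standard_normal((core, t))
        q, _ = np.linalg.qr(z)
        effects[cursor : cursor + core] = (q @ a.T) / np.sqrt(v_locus)
        cursor += core
    for (s, u), m in sorted(pair_blocks.items()):
        v_s = d[s] / k_noncore[s]
        v_u = d[u] / k_noncore[u]
        if m == 1:
            effects[cursor, s] = np.sqrt(v_s / v_locus)
        else:
            u1 = rng.standard_normal(m)
            u2 = rng.standard_normal(m)
            u2 -= u1 * (u1 @ u2) / (u1 @ u1)
            effects[cursor : cursor + m, s] = u1 * np.sqrt(m * v_s / v_locus) / np.linalg.norm(u1)
            effects[cursor : cursor + m, u] = u2 * np.sqrt(m * v_u / v_locus) / np.linalg.norm(u2)
        cursor += m
    for trait in range(t):
        m = singles[trait]
        if m == 0:
            continue
        v_t = d[trait] / k_noncore[trait]
        effects[cursor : cursor + m, trait] = rng.choice([-1.0, 1.0], size=m) * np.sqrt(v_t / v_locus)
        cursor += m
    # any remaining QTL rows stay at zero effect (unassigned placements)

    expected_cov = v_locus * effects.T @ effects
    sd = np.sqrt(np.clip(np.diag(expected_cov), 1e-12, None))
    achieved = expected_cov / np.outer(sd, sd)
    off = ~np.eye(t, dtype=bool)
    if t > 1 and np.max(np.abs(achieved[off] - corr[off])) > 0.05:
        raise ValueError(
            f"calibration failed: achieved correlations\n{np.round(achieved, 3)}\n"
            f"do not match the targets within 0.05"
        )

    # locus placement: markers uniform, QTLs random
    chroms, poss, isq = [], [], []
    per_chr = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per_chr[: config.n_markers % config.n_chromosomes] += 1
    for c in range(config.n_chromosomes):
        mpos = np.linspace(0.0, config.chromosome_length_cM, per_chr[c])
        chroms.append(np.full(per_chr[c], c))
        poss.append(mpos)
        isq.append(np.zeros(per_chr[c], dtype=bool))
    qtl_chrom = rng.integers(0, config.n_chromosomes, size=config.n_qtl)
    qtl_pos = rng.uniform(0.0, config.chromosome_length_cM, size=config.n_qtl)
    chroms.append(qtl_chrom)
    poss.append(qtl_pos)
    isq.append(np.ones(config.n_qtl, dtype=bool))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    is_qtl = np.concatenate(isq)
    order = np.lexsort((~is_qtl, pos, chrom))
    chrom, pos, is_qtl = chrom[order], pos[order], is_qtl[order]

    # effect rows follow QTL order after sorting; shuffle assignment so block
    # structure is not confounded with genome position
    perm = rng.permutation(config.n_qtl)
    return Genome(
        chrom=chrom, pos_cM=pos, is_qtl=is_qtl, qtl_effects=effects[perm],
        config=config, expected_corr=achieved,
    )


def found_population(genome: Genome, n: int, seed: int) -> Population:
    """Founders with independent loci at the configured allele frequency."""
    if n < 2:
        raise ValueError("at least 2 founders required")
    rng = np.random.default_rng(seed)
    f = genome.config.founder_freq
    hap = (rng.random((n, 2, genome.n_loci)) < f).astype(np.uint8)
    g = hap.sum(axis=1)[:, genome.qtl_index].astype(float) @ genome.qtl_effects
    return Population(haplotypes=hap, genome=genome, true_genetic_values=g, cycle=0)


def phenotype(
    pop: Population,
    n_reps: int = 4,
    h2: np.ndarray | None = None,
    seed: int = 0,
    error_var: np.ndarray | None = None,
) -> TraitPanel:
    """Replicated phenotypes: genetic value plus iid normal error per rep.

    Per-trait error variance defaults to ``var(g) (1 - h2) / h2`` computed on
    the current population; pass ``error_var`` to freeze the environmental
    variance across cycles.
    """
    cfg = pop.genome.config
    t = cfg.n_traits
    if h2 is None:
        h2 = np.asarray(cfg.target_h2, dtype=float)
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), (t,))
    if (h2 <= 0).any() or (h2 > 1).any():
        raise ValueError("heritabilities must be in (0, 1]")
    g = pop.true_genetic_values
    if error_var is None:
        s2g = g.var(axis=0)
        error_var = s2g * (1.0 - h2) / h2
    error_var = np.broadcast_to(np.asarray(error_var, dtype=float), (t,))
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        e = rng.standard_normal((pop.n, t)) * np.sqrt(error_var)
        df = pd.DataFrame(g + e, columns=list(cfg.trait_names))
        df.insert(0, "rep", rep)
        df.insert(0, "genotype", np.arange(pop.n))
        rows.append(df)
    return TraitPanel(pd.concat(rows, ignore_index=True))


def _gamete(hap: np.ndarray, genome: Genome, chrom_loci: list[np.ndarray], rng) -> np.ndarray:
    """One recombinant gamete: Poisson crossover counts per chromosome
    (Haldane, no interference), uniform crossover positions, random start
    strand."""
    L = genome.n_loci
    out = np.empty(L, dtype=np.uint8)
    length = genome.config.chromosome_length_cM
    for loci in chrom_loci:
        start = rng.integers(0, 2)
        n_x = rng.poisson(length / 100.0)
        if n_x == 0:
            out[loci] = hap[start, loci]
            continue
        xpos = np.sort(rng.uniform(0.0, length, size=n_x))
        strand = (start + np.searchsorted(xpos, genome.pos_cM[loci], side="right")) % 2
        out[loci] = hap[strand, loci]
    return out


def advance_cycle(
    pop: Population, selected_ids: np.ndarray, seed: int, n_offspring: int | None = None
) -> Population:
    """Next generation by random pairing of the selected parents."""
    selected_ids = np.asarray(selected_ids)
    if selected_ids.size < 2:
        raise ValueError("at least 2 selected parents required")
    n_offspring = pop.n if n_offspring is None else n_offspring
    rng = np.random.default_rng(seed)
    genome = pop.genome
    chrom_loci = genome.chromosome_slices()
    hap_new = np.empty((n_offspring, 2, genome.n_loci), dtype=np.uint8)
    for i in range(n_offspring):
        mother, father = rng.choice(selected_ids, size=2, replace=False)
        hap_new[i, 0] = _gamete(pop.haplotypes[mother], genome, chrom_loci, rng)
        hap_new[i, 1] = _gamete(pop.haplotypes[father], genome, chrom_loci, rng)
    g = hap_new.sum(axis=1)[:, genome.qtl_index].astype(float) @ genome.qtl_effects
    return Population(
        haplotypes=hap_new, genome=genome, true_genetic_values=g, cycle=pop.cycle + 1
    )


def mvn_generator(
    G: np.ndarray, P: np.ndarray, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Paired draws g ~ N(0, G) and y = g + e with e ~ N(0, P - G)."""
    G = np.asarray(G, dtype=float)
    P = np.asarray(P, dtype=float)
    resid = P - G
    if np.linalg.eigvalsh(0.5 * (resid + resid.T)).min() < -1e-8:
        raise ValueError("P - G is not positive semi-definite")
    rng = np.random.default_rng(seed)
    t = G.shape[0]

    def sqrtm(a):
        vals, vecs = np.linalg.eigh(0.5 * (a + a.T))
        return vecs * np.sqrt(np.clip(vals, 0.0, None))

    g = rng.standard_normal((n, t)) @ sqrtm(G).T
    y = g + rng.standard_normal((n, t)) @ sqrtm(resid).T
    return g, y


def _gaussian_cross(M_new: np.ndarray, M_train: np.ndarray, denom: float) -> np.ndarray:
    d2 = (
        np.sum(M_new**2, axis=1)[:, None]
        + np.sum(M_train**2, axis=1)[None, :]
        - 2.0 * M_new @ M_train.T
    )
    return np.exp(-np.clip(d2, 0.0, None) / denom)


def run_recurrent_selection(
    config: GenomeConfig,
    index_kind: str,
    weights: EconomicWeights,
    cycles: int = 10,
    n: int = 500,
    n_reps: int = 4,
    proportion: float = 0.10,
    engine: str = "gblup",
    seed: int = 0,
    rkhs_options: dict | None = None,
) -> list[SelectionSummary]:
    """Full recurrent-selection experiment returning per-cycle summaries.

    Cycle 0 trains everything: covariances (P, G, h2) from replicated
    phenotypes, GEBV engine (GBLUP or Gaussian-kernel RKHS) on entry means,
    allele frequencies for marker standardization (frozen for all later
    cycles). Genomic indices then run phenotype-free; phenotypic indices
    re-phenotype each cycle with the cycle-0 environmental variance. True
    genetic values are centered within each cycle before computing H_q.
    """
    if index_kind not in ("LPSI", "QPSI", "LGSI", "QGSI"):
        raise ValueError(f"unknown index kind {index_kind!r}")
    genomic = index_kind in ("LGSI", "QGSI")
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    genome = build_genome(config, seed=sub())
    pop = found_population(genome, n=n, seed=sub())
    sel = SelectionConfig(proportion=proportion, seed=sub())

    panel0 = phenotype(pop, n_reps=n_reps, seed=sub())
    covs0 = estimate_P_G(panel0)
    s2g0 = pop.true_genetic_values.var(axis=0)
    h2 = np.asarray(config.target_h2, dtype=float)
    error_var = s2g0 * (1.0 - h2) / h2

    markers0 = standardize_markers(pop.marker_codes())
    freqs0 = markers0.freqs
    gblup = kernel0 = rkhs = None
    if genomic:
        y0 = panel0.entry_means().to_numpy()
        if engine == "gblup":
            gblup = GBLUP(h2=np.clip(covs0.h2, 0.05, 0.99)).fit(markers0, y0)
        elif engine == "rkhs":
            opts = {"n_iter": 1500, "burn_in": 500, "thin": 5}
            opts.update(rkhs_options or {})
            kernel0 = gaussian_kernel(markers0)
            rkhs = RKHSRegressor(seed=sub(), **opts).fit(kernel0, y0)
            # kernel-interpolation coefficients for later cycles
            kv = kernel0.values
            alpha0 = np.linalg.solve(kv + 1e-8 * np.eye(kv.shape[0]), rkhs.u_)
        else:
            raise ValueError(f"unknown engine {engine!r}")

    summaries: list[SelectionSummary] = []
    panel = panel0
    covs = covs0
    for c in range(1, cycles + 1):
        g_centered = pop.true_genetic_values - pop.true_genetic_values.mean(axis=0)
        hq = merit_hq(g_centered, weights)
        if genomic:
            mm = standardize_markers(pop.marker_codes(), freqs=freqs0)
            if engine == "gblup":
                gebv = gblup.predict(mm)
            else:
                kx = _gaussian_cross(mm.M, markers0.M, kernel0.bandwidth)
                gebv = kx @ alpha0
            gamma = estimate_Gamma(gebv)
            covs_c = CovarianceSet(P=covs0.P, G=covs0.G, Gamma=gamma, traits=covs0.traits)
            model = (
                lgsi_model(weights, traits=covs0.traits)
                if index_kind == "LGSI"
                else qgsi_model(covs_c, weights)
            )
            scores = evaluate_index(model, gebv)
            traits_mat = g_centered
        else:
            if c > 1:
                panel = phenotype(pop, n_reps=n_reps, seed=sub(), error_var=error_var)
                covs = estimate_P_G(panel)
            model = (
                lpsi_coefficients(covs, weights)
                if index_kind == "LPSI"
                else qpsi_coefficients(covs, weights)
            )
            scores = evaluate_index(model, panel.entry_means().to_numpy())
            traits_mat = g_centered
        row = empirical_summary(scores, hq, traits_mat, sel, index_kind=index_kind, cycle=c)
        summaries.append(row)
        chosen = truncation_select(scores, proportion)
        pop = advance_cycle(pop, chosen, seed=sub())
    return summaries
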