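"""Synthetic genotype/trait generator for the clustering simulation study.

Individual-level data are generated from a latent-factor model: n = 100
independent biallelic variants (80 clustered + 20 noise) for N = 20000
individuals, with minor allele frequencies maf_j ~ Uniform(0.01, 0.5) and
genotypes G_ij ~ Binomial(2, maf_j).  Each of the K clusters drives a latent
factor L_ik = sum_{j in cluster k} beta_jk G_ij, and trait l is

    X_il = sum_k delta_kl L_ik + sum_{j noise} alpha_j G_ij
           + gamma U_i + sqrt(1 - gamma^2) eps_il,

with U_i and eps_il independent standard normal.  gamma controls the
residual correlation between traits induced by the shared confounder U.
Per-cluster effect sizes beta_jk come from Uniform(0.03, 0.06) with
probability 1 - phi and from N(0.1, 0.02^2) with probability phi, where
phi ~ Uniform(0.05, 0.2) is drawn once per cluster; noise-variant direct
effects alpha_jl ~ Uniform(-0.1, 0.1), drawn independently per trait so
each noise variant carries its own arbitrary association direction.  The delta matrices for each
(m, K) design fix the direction and relative magnitude of each cluster's
trait signature.  Associations are then estimated by simple per-variant,
per-trait linear regression, as they would be in a GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import AssociationTable

__all__ = [
    "DELTA_MATRICES",
    "CLUSTER_SIZES",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "estimate_associations",
    "filter_genome_wide",
]

#: Cluster-signature matrices delta (K rows, m columns) for each supported
#: (m, K) design.  Row k gives the loading of each trait on latent factor k.
DELTA_MATRICES: dict[tuple[int, int], np.ndarray] = {
    (2, 1): np.array([[1.0, 1.0]]),
    (2, 2): np.array([[1.0, 1.0], [1.0, -1.0]]),
    (2, 4): np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]]),
    (9, 1): np.ones((1, 9)),
    (9, 2): np.array(
        [
            [1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
            [1.0, -1.0, -1.0, 0.5, 0.5, 0.5, 0.5, -0.5, -0.5],
        ]
    ),
    (9, 4): np.array(
        [
            [1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
            [1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0],
            [-1.0, -1.0, -1.0, 0.5, 0.5, 0.5, 0.5, -0.5, -0.5],
            [-1.0, -1.0, -1.0, -1.0, -1.0, 0.0, 0.0, 0.0, 0.0],
        ]
    ),
}

#: Default split of the 80 clustered variants for each true K.
CLUSTER_SIZES: dict[int, tuple[int, ...]] = {1: (80,), 2: (40, 40), 4: (30, 20, 20, 10)}


@dataclass
class SimulationConfig:
    """Parameters of one simulated scenario.

    Defaults reproduce the primary study design: a single sample of
    N = 20000 individuals, 80 clustered plus 20 noise variants, with
    ``per_trait_n`` switching to the variant where each trait's
    associations are estimated in an independent subsample of size
    Uniform-integer(10000, 50000).
    """

    m: int = 2
    K: int = 1
    gamma_conf: float = 0.0
    N: int = 20_000
    n_clustered: int = 80
    n_noise: int = 20
    cluster_sizes: tuple[int, ...] | None = None
    delta: np.ndarray | None = None
    per_trait_n: bool = False
    per_trait_n_range: tuple[int, int] = (10_000, 50_000)
    filter_gws: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_conf <= 1.0:
            raise ValueError("gamma_conf must lie in [0, 1]")
        if self.cluster_sizes is None:
            if self.K not in CLUSTER_SIZES:
                raise ValueError(
                    f"no default cluster sizes for K={self.K}; pass cluster_sizes"
                )
            sizes = CLUSTER_SIZES[self.K]
        else:
            sizes = tuple(int(s) for s in self.cluster_sizes)
        if len(sizes) != self.K or sum(sizes) != self.n_clustered:
            raise ValueError(
                f"cluster_sizes must have K={self.K} entries summing to {self.n_clustered}"
            )
        self.cluster_sizes = sizes
        if self.delta is None:
            if (self.m, self.K) not in DELTA_MATRICES:
                raise ValueError(
                    f"no built-in delta matrix for (m={self.m}, K={self.K}); pass delta"
                )
            self.delta = DELTA_MATRICES[(self.m, self.K)]
        self.delta = np.atleast_2d(np.asarray(self.delta, dtype=float))
        if self.delta.shape != (self.K, self.m):
            raise ValueError(f"delta must have shape ({self.K}, {self.m})")

    @property
    def n_variants(self) -> int:
        return self.n_clustered + self.n_noise


@dataclass
class SimulatedDataset:
    """Individual-level data plus ground truth and estimated associations."""

    genotypes: np.ndarray
    traits: np.ndarray
    true_labels: list[str]
    assoc: AssociationTable
    true_trait_corr: np.ndarray
    config: SimulationConfig = field(repr=False)


def _true_labels(config: SimulationConfig) -> list[str]:
    labels: list[str] = []
    for k, size in enumerate(config.cluster_sizes, start=1):
        labels.extend([str(k)] * size)
    labels.extend(["noise"] * config.n_noise)
    return labels


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate one replicate of the simulation design.

    Deterministic given ``config.seed``: all randomness flows from the
    master seed through named substreams (maf, genotypes, effect sizes,
    confounder/noise, subsampling), so individual pieces are stable under
    changes elsewhere.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_maf, rng_geno, rng_beta, rng_env, rng_sub = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    n, m, K, N = config.n_variants, config.m, config.K, config.N

    n_gen = N
    per_trait_sizes = None
    if config.per_trait_n:
        lo, hi = config.per_trait_n_range
        per_trait_sizes = rng_sub.integers(lo, hi + 1, size=m)
        n_gen = int(per_trait_sizes.max())

    maf = rng_maf.uniform(0.01, 0.5, size=n)
    genotypes = rng_geno.binomial(2, maf, size=(n_gen, n)).astype(np.int8)

    # effect sizes: per cluster k, a small proportion phi of its variants get
    # the stronger N(0.1, 0.02^2) effect, the rest Uniform(0.03, 0.06)
    beta = np.zeros(config.n_clustered)
    start = 0
    for size in config.cluster_sizes:
        phi = rng_beta.uniform(0.05, 0.2)
        strong = rng_beta.random(size) < phi
        b = rng_beta.uniform(0.03, 0.06, size=size)
        b[strong] = rng_beta.normal(0.1, 0.02, size=int(strong.sum()))
        beta[start : start + size] = b
        start += size
    # direct effects of noise variants: drawn independently per trait so each
    # noise variant has its own arbitrary association direction
    alpha = rng_beta.uniform(-0.1, 0.1, size=(config.n_noise, m))

    # latent factors and traits
    G = genotypes.astype(np.float64)
    L = np.empty((n_gen, K))
    start = 0
    for k, size in enumerate(config.cluster_sizes):
        L[:, k] = G[:, start : start + size] @ beta[start : start + size]
        start += size
    direct = G[:, config.n_clustered :] @ alpha
    U = rng_env.standard_normal(n_gen)
    eps = rng_env.standard_normal((n_gen, m))
    g = config.gamma_conf
    traits = L @ config.delta + direct + g * U[:, None] + np.sqrt(1.0 - g**2) * eps

    subsamples = None
    if config.per_trait_n:
        subsamples = [
            rng_sub.choice(n_gen, size=int(sz), replace=False) for sz in per_trait_sizes
        ]

    assoc = estimate_associations(genotypes, traits, per_trait_subsample=subsamples)
    if config.filter_gws:
        assoc = filter_genome_wide(assoc)

    # map labels through any rows dropped by the regression or the filter
    id_to_label = dict(zip((f"v{j + 1}" for j in range(n)), _true_labels(config)))
    kept_labels = [id_to_label[v] for v in assoc.variant_ids]

    return SimulatedDataset(
        genotypes=genotypes,
        traits=traits,
        true_labels=kept_labels,
        assoc=assoc,
        true_trait_corr=np.corrcoef(traits, rowvar=False),
        config=config,
    )


def estimate_associations(
    genotypes: np.ndarray,
    traits: np.ndarray,
    per_trait_subsample: list[np.ndarray] | None = None,
) -> AssociationTable:
    """Per-variant, per-trait simple linear regression (slope and SE).

    Regresses each trait on each genotype in turn with an intercept.  With
    ``per_trait_subsample``, trait l's regressions use only the given row
    subset, emulating per-trait GWAS sample sizes.  Variants with constant
    genotype (no minor alleles in sample) are dropped with a warning.
    """
    G = np.asarray(genotypes, dtype=np.float64)
    X = np.atleast_2d(np.asarray(traits, dtype=np.float64))
    N, n = G.shape
    m = X.shape[1]

    beta = np.empty((n, m))
    se = np.empty((n, m))

    def _regress_block(Gb: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Nb = Gb.shape[0]
        Gc = Gb - Gb.mean(axis=0)
        sxx = np.einsum("ij,ij->j", Gc, Gc)
        yc = y - y.mean(axis=0)
        syy = np.einsum("ij,ij->j", yc, yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = (Gc.T @ yc) / sxx[:, None]
            rss = syy[None, :] - slopes**2 * sxx[:, None]
            ses = np.sqrt(np.maximum(rss, 0.0) / (Nb - 2) / sxx[:, None])
        return slopes, ses

    if per_trait_subsample is None:
        beta, se = _regress_block(G, X)
    else:
        if len(per_trait_subsample) != m:
            raise ValueError("need one subsample per trait")
        for l, rows in enumerate(per_trait_subsample):
            b, s = _regress_block(G[rows], X[rows, l][:, None])
            beta[:, l] = b[:, 0]
            se[:, l] = s[:, 0]

    ids = [f"v{j + 1}" for j in range(n)]
    ok = np.all(np.isfinite(beta), axis=1) & np.all(np.isfinite(se), axis=1) & np.all(se > 0, axis=1)
    if not ok.all():
        import logging

        logging.getLogger("navmix").warning(
            "dropped %d variant(s) with degenerate (constant-genotype) regression",
            int((~ok).sum()),
        )
    return AssociationTable(
        variant_ids=[v for v, keep in zip(ids, ok) if keep],
        beta=beta[ok],
        se=se[ok],
        trait_names=[f"trait{l + 1}" for l in range(m)],
    )


def filter_genome_wide(table: AssociationTable, alpha: float = 5e-8) -> AssociationTable:
    """Keep variants reaching genome-wide significance for at least one trait.

    Two-sided normal p-values from |beta/se|; the default threshold is the
    conventional 5e-8.
    """
    z = np.abs(table.beta / table.se)
    p = 2.0 * stats.norm.sf(z)
    keep = np.any(p < alpha, axis=1)
    if not keep.any():
        raise ValueError("no variant reaches the significance threshold")
    primary = table.primary_trait_beta[keep] if table.primary_trait_beta is not None else None
    return AssociationTable(
        variant_ids=[v for v, k in zip(table.variant_ids, keep) if k],
        beta=table.beta[keep],
        se=table.se[keep],
        trait_names=list(table.trait_names),
        primary_trait_beta=primary,
    )
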