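"""End-to-end pipelines: associations -> clusters, and scenario replication.

These functions glue the preprocessing, fitting and evaluation stages
together; the command-line interface is a thin wrapper around them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import em
from .evaluate import adjusted_rand_index, noise_cluster_size, spherical_silhouette
from .io import AssociationTable, DirectionalDataset, TraitCorrelation, normalize_to_unit, standardize
from .simulate import SimulationConfig, simulate

__all__ = ["ClusterRun", "cluster_associations", "run_replicates", "summarize_replicates"]


@dataclass
class ClusterRun:
    """Everything produced by one clustering run."""

    data: DirectionalDataset
    fit: em.FitResult
    assignment: em.ClusterAssignment

    def membership_frame(self) -> pd.DataFrame:
        K = self.fit.model.K
        cols = [f"cluster_{k + 1}" for k in range(K)] + ["noise"]
        df = pd.DataFrame(self.fit.resp.gamma, columns=cols)
        df.insert(0, "label", self.assignment.hard_labels)
        df.insert(0, "variant", self.data.variant_ids)
        return df


def cluster_associations(
    table: AssociationTable,
    corr: TraitCorrelation | None = None,
    k_fixed: int | None = None,
    k_min: int = 1,
    k_max: int = 10,
    patience: int = 2,
    n_restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 500,
    noise_prop0: float = 0.05,
    kappa_cap: float = 500.0,
    seed: int | None = None,
    assign_mode: str = "hard",
    threshold: float | None = None,
) -> ClusterRun:
    """Standardise, normalise, fit the noise-augmented vMF mixture, assign.

    With ``k_fixed`` the model is fitted at exactly that K; otherwise K is
    selected by BIC over ``k_min..k_max``.
    """
    z = standardize(table, corr)
    data = normalize_to_unit(z, table.variant_ids, table.trait_names)
    common = dict(
        n_restarts=n_restarts,
        tol=tol,
        max_iter=max_iter,
        noise_prop0=noise_prop0,
        kappa_cap=kappa_cap,
        seed=seed,
    )
    if k_fixed is not None:
        fit = em.fit_fixed_k(data, k_fixed, **common)
    else:
        fit = em.select_k(data, k_min=k_min, k_max_cap=k_max, patience=patience, **common)
    assignment = em.assign(fit, mode=assign_mode, threshold=threshold)
    return ClusterRun(data=data, fit=fit, assignment=assignment)


def run_replicates(
    gamma_conf: float,
    m: int,
    K: int,
    n_reps: int,
    seed: int | None = None,
    use_corr: bool = False,
    per_trait_n: bool = False,
    filter_gws: bool = False,
    N: int = 20_000,
    **fit_kwargs,
) -> pd.DataFrame:
    """Simulate and cluster ``n_reps`` replicates of one scenario.

    Returns one row per replicate with the selected number of clusters, the
    noise-cluster size, the adjusted Rand index against the true labels and
    the spherical silhouette of the estimated partition.  With ``use_corr``
    the trait correlation estimated from the simulated individual-level
    data is fed into the covariance standardisation.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_reps)):
        sim_seed, fit_seed = (int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2))
        config = SimulationConfig(
            m=m,
            K=K,
            gamma_conf=gamma_conf,
            N=N,
            per_trait_n=per_trait_n,
            filter_gws=filter_gws,
            seed=sim_seed,
        )
        sim = simulate(config)
        corr = None
        if use_corr:
            c = np.corrcoef(sim.traits, rowvar=False)
            c = (c + c.T) / 2.0
            np.fill_diagonal(c, 1.0)
            corr = TraitCorrelation(corr=c)
        run = cluster_associations(sim.assoc, corr=corr, seed=fit_seed, **fit_kwargs)
        labels = run.assignment.hard_labels
        try:
            sil = spherical_silhouette(run.data, labels)
        except ValueError:  # a single estimated cluster: silhouette undefined
            sil = np.nan
        rows.append(
            {
                "replicate": rep,
                "selected_k": run.fit.model.K,
                "noise_size": noise_cluster_size(labels),
                "ari": adjusted_rand_index(sim.true_labels, labels),
                "silhouette": sil,
                "n_variants": run.data.n,
            }
        )
    return pd.DataFrame(rows)


def summarize_replicates(df: pd.DataFrame) -> dict:
    """Scenario summary: mean K-hat, mean noise size, median ARI, mean silhouette.

    Monte-Carlo standard errors accompany the means (absent for a single
    replicate).
    """
    n = len(df)
    out = {
        "n_reps": n,
        "mean_k": float(df["selected_k"].mean()),
        "mean_noise_size": float(df["noise_size"].mean()),
        "median_ari": float(df["ari"].median()),
        "mean_silhouette": float(df["silhouette"].mean(skipna=True)),
    }
    if n > 1:
        out["se_mean_k"] = float(df["selected_k"].std(ddof=1) / np.sqrt(n))
        out["se_mean_noise_size"] = float(df["noise_size"].std(ddof=1) / np.sqrt(n))
    else:
        out["se_mean_k"] = None
        out["se_mean_noise_size"] = None
    return out
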