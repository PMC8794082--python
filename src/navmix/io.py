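"""Summary-statistic I/O, covariance construction, and directional preprocessing.

Turns per-variant, per-trait GWAS association estimates (beta, se) into
directional data: each variant's association vector is standardised by the
inverse square root of its covariance matrix, Sigma_j^{-1/2} beta_j, then
normalised to unit length so that only the direction (the proportional
association pattern across traits) is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("navmix")

__all__ = [
    "AssociationTable",
    "TraitCorrelation",
    "DirectionalDataset",
    "read_association_table",
    "read_trait_correlation",
    "orient_to_primary_trait",
    "build_covariance",
    "standardize",
    "normalize_to_unit",
]


class ConfigurationError(ValueError):
    """A required column, field, or option is missing or invalid."""


@dataclass
class AssociationTable:
    """Per-variant, per-trait association estimates and standard errors.

    ``beta[j, l]`` is the estimated association of variant j with trait l
    (in trait units) and ``se[j, l]`` its standard error — the diagonal
    information of the per-variant covariance matrix Sigma_j.
    ``primary_trait_beta`` optionally carries associations with the variant
    selection trait, used only to orient alleles.
    """

    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    trait_names: list[str]
    primary_trait_beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.se = np.atleast_2d(np.asarray(self.se, dtype=float))
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.trait_names = [str(t) for t in self.trait_names]
        n, m = self.beta.shape
        if self.se.shape != (n, m):
            raise ValueError("beta and se must have identical shape")
        if n < 1 or m < 2:
            raise ValueError("need at least 1 variant and 2 traits")
        if len(self.variant_ids) != n:
            raise ValueError("variant_ids length must match beta rows")
        if len(set(self.variant_ids)) != n:
            raise ValueError("variant_ids must be unique")
        if len(self.trait_names) != m:
            raise ValueError("trait_names length must match beta columns")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta entries must be finite")
        if not (np.all(np.isfinite(self.se)) and np.all(self.se > 0)):
            raise ValueError("se entries must be strictly positive and finite")
        if self.primary_trait_beta is not None:
            self.primary_trait_beta = np.asarray(self.primary_trait_beta, dtype=float)
            if self.primary_trait_beta.shape != (n,):
                raise ValueError("primary_trait_beta must have one entry per variant")

    @property
    def n_variants(self) -> int:
        return self.beta.shape[0]

    @property
    def n_traits(self) -> int:
        return self.beta.shape[1]


@dataclass(frozen=True)
class TraitCorrelation:
    """An m x m trait correlation matrix, cor(X_k, X_l).

    Used to fill the off-diagonal entries of each variant's covariance
    matrix via se_k * se_l * cor(X_k, X_l); a single matrix is applied to
    all variants.
    """

    corr: np.ndarray
    trait_names: list[str] | None = None
    psd_tol: float = field(default=1e-8, repr=False)

    def __post_init__(self) -> None:
        corr = np.atleast_2d(np.asarray(self.corr, dtype=float))
        object.__setattr__(self, "corr", corr)
        m = corr.shape[0]
        if corr.shape != (m, m):
            raise ValueError("correlation matrix must be square")
        if np.max(np.abs(corr - corr.T)) > 1e-10:
            raise ValueError("correlation matrix must be symmetric")
        if np.max(np.abs(np.diag(corr) - 1.0)) > 1e-10:
            raise ValueError("correlation matrix must have unit diagonal")
        if np.max(np.abs(corr)) > 1.0 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")
        if np.linalg.eigvalsh(corr)[0] < -self.psd_tol:
            raise ValueError("correlation matrix is not positive semidefinite")

    @property
    def dim(self) -> int:
        return self.corr.shape[0]


@dataclass
class DirectionalDataset:
    """Unit direction vectors (rows of ``x``), one per variant."""

    x: np.ndarray
    variant_ids: list[str]
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        norms = np.linalg.norm(self.x, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-10:
            raise ValueError("every row of x must have unit Euclidean norm")
        if len(self.variant_ids) != self.x.shape[0]:
            raise ValueError("variant_ids length must match rows of x")
        if len(self.trait_names) != self.x.shape[1]:
            raise ValueError("trait_names length must match columns of x")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def m(self) -> int:
        return self.x.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.x, columns=self.trait_names)
        df.insert(0, "variant", self.variant_ids)
        return df

    def to_csv(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "DirectionalDataset":
        df = pd.read_csv(path, sep=sep, engine="python")
        ids = df.iloc[:, 0].astype(str).tolist()
        x = df.iloc[:, 1:].to_numpy(dtype=float)
        return cls(x=x, variant_ids=ids, trait_names=list(df.columns[1:]))


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    # delimiter None -> sniff among tab/comma via the python engine
    return pd.read_csv(path, sep=delimiter if delimiter else None, engine="python")


def read_association_table(
    path: str | Path,
    column_map: Mapping[str, Mapping[str, str] | Sequence[str]],
    variant_id_column: str = "rsid",
    primary_beta_column: str | None = None,
    delimiter: str | None = None,
) -> AssociationTable:
    """Read a wide summary-statistics table into an :class:`AssociationTable`.

    Parameters
    ----------
    path
        Delimited text file (TSV or CSV; delimiter sniffed unless given)
        with a header row and one row per variant.
    column_map
        Mapping from trait name to its beta/se columns, either as a mapping
        ``{"beta": col, "se": col}`` or a two-element sequence (beta, se).
    variant_id_column
        Column holding unique variant identifiers.
    primary_beta_column
        Optional column of associations with the selection trait, retained
        for allele orientation.

    Rows with any missing or non-finite beta/se (or non-positive se) among
    the mapped columns are dropped with a logged count.
    """
    df = _read_delimited(path, delimiter)
    trait_names = list(column_map.keys())
    if len(trait_names) < 2:
        raise ConfigurationError("column_map must name at least two traits")

    beta_cols, se_cols = [], []
    for trait, spec in column_map.items():
        if isinstance(spec, Mapping):
            bcol, scol = spec["beta"], spec["se"]
        else:
            bcol, scol = spec
        beta_cols.append(bcol)
        se_cols.append(scol)

    needed = [variant_id_column, *beta_cols, *se_cols]
    if primary_beta_column is not None:
        needed.append(primary_beta_column)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing column(s) in {path}: {', '.join(missing)}")

    beta = df[beta_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    se = df[se_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    ok = np.all(np.isfinite(beta), axis=1) & np.all(np.isfinite(se), axis=1) & np.all(se > 0, axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d variant row(s) with missing or invalid beta/se", n_dropped)
    if not ok.any():
        raise ValueError(f"no usable variant rows in {path}")

    primary = None
    if primary_beta_column is not None:
        primary = pd.to_numeric(df[primary_beta_column], errors="coerce").to_numpy(dtype=float)[ok]
    return AssociationTable(
        variant_ids=df.loc[ok, variant_id_column].astype(str).tolist(),
        beta=beta[ok],
        se=se[ok],
        trait_names=trait_names,
        primary_trait_beta=primary,
    )


def read_trait_correlation(path: str | Path, delimiter: str | None = None) -> TraitCorrelation:
    """Read a trait correlation matrix with a header row and leading name column."""
    df = pd.read_csv(path, sep=delimiter if delimiter else None, engine="python", index_col=0)
    return TraitCorrelation(corr=df.to_numpy(dtype=float), trait_names=list(df.columns))


def orient_to_primary_trait(table: AssociationTable) -> AssociationTable:
    """Flip allele orientation so associations with the primary trait are positive.

    Variants whose primary-trait beta is negative have all trait betas (and
    the primary beta) sign-flipped; standard errors are unchanged.
    Idempotent.
    """
    if table.primary_trait_beta is None:
        raise ConfigurationError("primary_trait_beta is required for allele orientation")
    flip = table.primary_trait_beta < 0
    sign = np.where(flip, -1.0, 1.0)
    return AssociationTable(
        variant_ids=list(table.variant_ids),
        beta=table.beta * sign[:, None],
        se=table.se.copy(),
        trait_names=list(table.trait_names),
        primary_trait_beta=np.abs(table.primary_trait_beta),
    )


def build_covariance(se_row: np.ndarray, corr: TraitCorrelation | None = None) -> np.ndarray:
    """Covariance matrix Sigma_j of one variant's association estimates.

    Entry (k, l) is se_k * se_l * cor(X_k, X_l).  With no correlation matrix
    (separate samples, or independent traits) this is diag(se^2).
    """
    se_row = np.asarray(se_row, dtype=float)
    if se_row.ndim != 1 or not np.all(se_row > 0):
        raise ValueError("se_row must be a vector of positive standard errors")
    if corr is None:
        return np.diag(se_row**2)
    if corr.dim != se_row.size:
        raise ValueError("correlation matrix dimension does not match se_row")
    return np.outer(se_row, se_row) * corr.corr


def _inv_sqrt_psd(sigma: np.ndarray, variant: str, rel_floor: float = 1e-12) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition (unique PSD root)."""
    w, v = np.linalg.eigh(sigma)
    floor = rel_floor * w[-1]
    if w[0] < floor:
        raise np.linalg.LinAlgError(
            f"covariance matrix for variant {variant!r} is singular "
            f"(eigenvalue {w[0]:.3e} below floor {floor:.3e})"
        )
    return (v / np.sqrt(w)) @ v.T


def standardize(table: AssociationTable, corr: TraitCorrelation | None = None) -> np.ndarray:
    """Standardised association estimates Sigma_j^{-1/2} beta_j, one row per variant.

    With no trait correlation this reduces to elementwise z-scores
    beta / se.  Each standardised element has unit standard error and, under
    the model, the elements are independent.
    """
    if corr is None or np.allclose(corr.corr, np.eye(corr.dim), atol=1e-14):
        return table.beta / table.se
    out = np.empty_like(table.beta)
    for j in range(table.n_variants):
        sigma = build_covariance(table.se[j], corr)
        out[j] = _inv_sqrt_psd(sigma, table.variant_ids[j]) @ table.beta[j]
    return out


def normalize_to_unit(
    z: np.ndarray,
    variant_ids: Sequence[str],
    trait_names: Sequence[str],
    norm_floor: float = 1e-12,
) -> DirectionalDataset:
    """Scale each row to unit Euclidean norm, keeping only its direction."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    norms = np.linalg.norm(z, axis=1)
    bad = np.nonzero(norms < norm_floor)[0]
    if bad.size:
        names = ", ".join(str(variant_ids[i]) for i in bad[:5])
        raise ValueError(f"degenerate (near-zero) association vector(s) for variant(s): {names}")
    return DirectionalDataset(
        x=z / norms[:, None],
        variant_ids=list(variant_ids),
        trait_names=list(trait_names),
    )
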