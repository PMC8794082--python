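"""von Mises-Fisher density evaluation and concentration-parameter estimation.

The vMF distribution on the unit (m-1)-sphere has density

    f(x | mu, kappa) = C_m(kappa) * exp(kappa * mu'x),   ||x|| = ||mu|| = 1,

with normalising constant

    C_m(kappa) = kappa^(m/2-1) / ((2*pi)^(m/2) * I_{m/2-1}(kappa)),

where I_nu is the modified Bessel function of the first kind.  kappa = 0
gives the uniform distribution on the sphere; large kappa concentrates mass
around the mean direction mu.  All Bessel evaluations use the exponentially
scaled form I_nu(k)*exp(-k) so densities remain finite up to the
concentration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

#: Default upper bound on fitted concentration parameters.  Resultant lengths
#: r_bar near 1 (near-coincident observations) would otherwise send kappa to
#: infinity and overflow the Bessel evaluation.
KAPPA_CAP: float = 500.0

__all__ = [
    "KAPPA_CAP",
    "VMFParams",
    "log_norm_const",
    "vmf_log_density",
    "estimate_kappa",
    "bessel_ratio",
    "invert_bessel_ratio",
]


@dataclass(frozen=True)
class VMFParams:
    """Parameters of one vMF component: unit mean direction and concentration."""

    mu: np.ndarray
    kappa: float
    kappa_cap: float = field(default=KAPPA_CAP, repr=False)

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        if mu.ndim != 1 or mu.size < 2:
            raise ValueError("mu must be a vector of dimension >= 2")
        if abs(np.linalg.norm(mu) - 1.0) > 1e-10:
            raise ValueError("mu must be a unit vector")
        if not np.isfinite(self.kappa) or self.kappa < 0:
            raise ValueError("kappa must be finite and non-negative")
        if self.kappa > self.kappa_cap:
            raise ValueError(f"kappa={self.kappa} exceeds cap {self.kappa_cap}")

    @property
    def dim(self) -> int:
        return self.mu.size


def log_norm_const(m: int, kappa: float) -> float:
    """log C_m(kappa), the log normalising constant of the m-dimensional vMF.

    Evaluated as (m/2-1)*log(kappa) - (m/2)*log(2*pi) - log(I_{m/2-1}(kappa))
    using scaled Bessel functions (``scipy.special.ive``), so the result is
    finite for kappa up to several thousand.  At kappa = 0 the continuity
    limit is the log reciprocal surface area of the (m-1)-sphere.
    """
    if m < 2:
        raise ValueError("dimension m must be >= 2")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    nu = m / 2.0 - 1.0
    if kappa < 1e-12:
        # kappa^nu / I_nu(kappa) -> 2^nu * Gamma(nu + 1) as kappa -> 0,
        # giving C_m(0) = Gamma(m/2) / (2 * pi^(m/2)): 1/area of sphere.
        return nu * np.log(2.0) + special.gammaln(nu + 1.0) - (m / 2.0) * np.log(2.0 * np.pi)
    log_bessel = np.log(special.ive(nu, kappa)) + kappa
    return nu * np.log(kappa) - (m / 2.0) * np.log(2.0 * np.pi) - log_bessel


def vmf_log_density(x: np.ndarray, params: VMFParams) -> float | np.ndarray:
    """Log density of the vMF distribution at unit vector(s) ``x``.

    ``x`` may be a single vector or an (n, m) array of row vectors.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.dim:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[-1]} coordinates, mu has {params.dim}"
        )
    return log_norm_const(params.dim, params.kappa) + params.kappa * (x @ params.mu)


def estimate_kappa(r_bar: float, m: int, kappa_cap: float = KAPPA_CAP) -> float:
    """Banerjee et al. approximation to the concentration MLE.

    Inverts A_m(kappa) = I_{m/2}(kappa)/I_{m/2-1}(kappa) = r_bar approximately:

        kappa_hat = (r_bar * m - r_bar^3) / (1 - r_bar^2),

    capped at ``kappa_cap``.  ``r_bar`` is the mean resultant length of the
    (weighted) sample; callers must clip values >= 1 before estimation.
    """
    if not 0.0 <= r_bar < 1.0:
        raise ValueError(f"r_bar must lie in [0, 1), got {r_bar}")
    kappa = (r_bar * m - r_bar**3) / (1.0 - r_bar**2)
    return min(kappa, kappa_cap)


def bessel_ratio(m: int, kappa: float) -> float:
    """A_m(kappa) = I_{m/2}(kappa) / I_{m/2-1}(kappa).

    The mean resultant length of a vMF sample with concentration kappa.
    Strictly increasing in kappa, with values in (0, 1).  The exponential
    scaling of ``ive`` cancels in the ratio.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return float(special.ive(m / 2.0, kappa) / special.ive(m / 2.0 - 1.0, kappa))


def invert_bessel_ratio(r_bar: float, m: int, kappa_cap: float = KAPPA_CAP) -> float:
    """Exact inversion of A_m(kappa) = r_bar by root finding.

    Newton-grade alternative to :func:`estimate_kappa`; not used by the
    default fitting path.
    """
    from scipy.optimize import brentq

    if not 0.0 <= r_bar < 1.0:
        raise ValueError(f"r_bar must lie in [0, 1), got {r_bar}")
    if r_bar == 0.0:
        return 0.0
    if bessel_ratio(m, kappa_cap) <= r_bar:
        return kappa_cap
    return float(brentq(lambda k: bessel_ratio(m, k) - r_bar, 1e-8, kappa_cap, xtol=1e-10))
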