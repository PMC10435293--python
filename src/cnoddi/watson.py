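"""Watson distribution on the sphere.

The Watson distribution is the antipodally symmetric analogue of a Gaussian
on the unit sphere: density proportional to ``exp(kappa * (mu . n)**2)``
about a mean axis ``mu`` with concentration ``kappa >= 0``.  It is the
orientation-dispersion kernel of the intracellular (stick) compartment and,
through its second moment, of the extracellular tensor compartment.

The scalar dispersion summary used throughout is the orientation dispersion
index ``ODI = (2/pi) * arctan(1/kappa)``, which maps ``kappa in [0, inf)``
onto ``(0, 1]`` with ODI = 1 for a uniform axis distribution and ODI -> 0
for a delta on the mean axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "WatsonParams",
    "watson_normalization",
    "watson_density",
    "odi_from_kappa",
    "kappa_from_odi",
    "watson_second_moment",
    "watson_axis_legendre_coeffs",
    "sphere_quadrature",
    "KAPPA_MAX",
]

#: Concentration clamp used during fitting. ODI below ~0.005 is not
#: resolvable with two-shell protocols, and the clamp keeps the
#: hypergeometric normalization well inside double-precision range.
KAPPA_MAX = 128.0

#: Quadrature orders for which node sets are provided (number of polar
#: Gauss-Legendre nodes; the azimuthal circle uses 2*order equispaced nodes).
SUPPORTED_ORDERS = (4, 8, 16, 32, 64, 128)


@dataclass(frozen=True)
class WatsonParams:
    """Mean axis and concentration of a Watson distribution.

    ``mean_orientation`` is an axis: the density is invariant under
    ``mu -> -mu``.  ``kappa`` is dimensionless and non-negative.
    """

    mean_orientation: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    kappa: float = 0.0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mean_orientation, dtype=float)
        if mu.shape != (3,):
            raise ValueError("mean_orientation must be a 3-vector")
        norm = np.linalg.norm(mu)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("mean_orientation must be unit-norm (within 1e-9)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        object.__setattr__(self, "mean_orientation", mu)

    @property
    def odi(self) -> float:
        return odi_from_kappa(self.kappa)


def watson_normalization(kappa):
    """Confluent-hypergeometric normalization constant M(1/2, 3/2, kappa).

    The Watson density per steradian is
    ``exp(kappa t**2) / (4 pi M(1/2, 3/2, kappa))`` with ``t = mu . n``.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    return special.hyp1f1(0.5, 1.5, kappa)


def watson_density(direction, params: WatsonParams):
    """Watson density per steradian at one or more unit directions."""
    n = np.asarray(direction, dtype=float)
    t = n @ params.mean_orientation
    m = watson_normalization(params.kappa)
    return np.exp(params.kappa * t**2) / (4.0 * np.pi * m)


def odi_from_kappa(kappa):
    """Map concentration to the orientation dispersion index.

    ODI = (2/pi) arctan(1/kappa); strictly decreasing, ODI(0) = 1,
    ODI(inf) = 0.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    with np.errstate(divide="ignore"):
        out = (2.0 / np.pi) * np.arctan2(1.0, kappa)
    return out if out.ndim else float(out)


def kappa_from_odi(odi):
    """Inverse of :func:`odi_from_kappa`: kappa = 1 / tan(odi * pi / 2)."""
    odi = np.asarray(odi, dtype=float)
    if np.any((odi <= 0) | (odi > 1)):
        raise ValueError("odi must lie in (0, 1]")
    out = 1.0 / np.tan(odi * np.pi / 2.0)
    # tan(pi/2) is finite-but-huge in floating point; pin odi=1 to kappa=0
    out = np.where(odi == 1.0, 0.0, out)
    return out if out.ndim else float(out)


def watson_second_moment(kappa):
    """E[(mu . n)**2] under the Watson distribution.

    Equals d/dkappa log M(1/2,3/2,kappa) = M(3/2,5/2,kappa) / (3 M(1/2,3/2,kappa)),
    rising from 1/3 at kappa = 0 toward 1 as kappa -> inf.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    small = np.minimum(kappa, 512.0)
    out = special.hyp1f1(1.5, 2.5, small) / (3.0 * special.hyp1f1(0.5, 1.5, small))
    # hyp1f1 overflows near kappa ~ 700; d/dk log M -> 1 - 1/k asymptotically
    out = np.where(kappa > 512.0, 1.0 - 1.0 / np.maximum(kappa, 1.0), out)
    return out if out.ndim else float(out)


_quad_cache: dict = {}


def _coeff_quadrature(lmax: int, n_points: int):
    """Cached Gauss-Legendre nodes with pre-weighted Legendre Vandermonde."""
    key = (lmax, n_points)
    if key not in _quad_cache:
        t, gw = np.polynomial.legendre.leggauss(n_points)
        vander = np.polynomial.legendre.legvander(t, lmax)
        _quad_cache[key] = (t, (vander * gw[:, None]).T)
    return _quad_cache[key]


def watson_axis_legendre_coeffs(kappa: float, lmax: int, n_points: int = 128):
    """Legendre coefficients of the axis marginal of a Watson distribution.

    Returns ``w_l = int_{-1}^{1} p(t) P_l(t) dt`` for l = 0..lmax, where
    ``p(t) = exp(kappa t**2) / (2 M(1/2,3/2,kappa))`` is the density of
    ``t = mu . n``.  Odd coefficients vanish by antipodal symmetry; w_0 = 1.
    Computed by Gauss-Legendre quadrature, exact for the polynomial factor.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    t, weighted_vander = _coeff_quadrature(lmax, n_points)
    p = np.exp(kappa * t**2) / (2.0 * watson_normalization(kappa))
    return weighted_vander @ p


def sphere_quadrature(order: int):
    """Deterministic quadrature nodes and weights on the unit sphere.

    Product rule: ``order`` Gauss-Legendre nodes in cos(theta) crossed with
    ``2 * order`` equispaced azimuthal nodes.  Weights are positive and sum
    to 1 (mean-over-sphere convention), so constants integrate exactly and
    the rule integrates spherical harmonics up to high degree.

    Parameters
    ----------
    order : int
        One of ``SUPPORTED_ORDERS``.

    Returns
    -------
    nodes : (N, 3) array of unit vectors
    weights : (N,) array summing to 1
    """
    if order not in SUPPORTED_ORDERS:
        raise ValueError(
            f"unsupported quadrature order {order}; supported: {SUPPORTED_ORDERS}"
        )
    ct, gw = np.polynomial.legendre.leggauss(order)
    n_phi = 2 * order
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    st = np.sqrt(1.0 - ct**2)
    x = np.outer(st, np.cos(phi)).ravel()
    y = np.outer(st, np.sin(phi)).ravel()
    z = np.repeat(ct, n_phi)
    nodes = np.column_stack([x, y, z])
    weights = np.repeat(gw, n_phi) / (2.0 * n_phi)
    return nodes, weights
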