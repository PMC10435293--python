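"""Voxelwise NODDI and C-NODDI parameter estimation.

Both fits minimize the misfit between the measured normalized attenuation
A = S / S(b=0) and the composite model

    A = f_in * S_in + f_ex * S_ex + F_iso * S_iso.

The original three-compartment fit (``noddi``) estimates the neurite
fraction, the Watson concentration kappa, the mean orientation mu and the
isotropic fraction F_iso jointly.  The constrained fit (``cnoddi``) takes
F_iso as a known per-voxel input — typically from the HMRF-EM segmentation
of the b = 0 image — and enforces f_in + f_ex = 1 - F_iso, leaving only
(ndi, kappa, mu) free.  Shrinking the parameter space this way avoids the
flat, sloppy least-squares surfaces of the full model and removes the
CSF/tissue trade-off that inflates neurite density estimates.

Optimization is two-stage per voxel: a coarse deterministic grid over the
scalar parameters at the tensor-initialized orientation, then
derivative-based refinement of all parameters through smooth unconstrained
reparametrizations (fractions via a logistic map, kappa via a scaled
logistic capped at ``kappa_max``, orientation via a tangent-plane chart).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

from .forward import DiffusivityConstants, compartment_signals, signal_iso
from .io import DWIVolume
from .scheme import AcquisitionScheme
from .watson import (
    KAPPA_MAX,
    kappa_from_odi,
    odi_from_kappa,
    watson_second_moment,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "estimate_mean_orientation",
    "fit_voxel_noddi",
    "fit_voxel_cnoddi",
    "fit_volume",
]

logger = logging.getLogger(__name__)

#: Voxels whose supplied isotropic fraction exceeds this carry too little
#: tissue signal for a meaningful bicomponent fit and are flagged instead.
FISO_TISSUE_LIMIT = 0.95


@dataclass(frozen=True)
class FitConfig:
    model: str = "cnoddi"  # {"noddi", "cnoddi"}
    grid_resolution: int = 8
    tol: float = 1e-6
    max_iter: int = 200
    noise_model: str = "gaussian_lsq"  # {"gaussian_lsq", "rician"}
    kappa_max: float = KAPPA_MAX
    seed: int = 0
    sigma: float | None = None  # Rician noise sd on the normalized signal

    def __post_init__(self) -> None:
        if self.model not in ("noddi", "cnoddi"):
            raise ValueError("model must be 'noddi' or 'cnoddi'")
        if self.grid_resolution < 2:
            raise ValueError("grid_resolution must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.noise_model not in ("gaussian_lsq", "rician"):
            raise ValueError("noise_model must be 'gaussian_lsq' or 'rician'")
        if self.noise_model == "rician" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("rician noise model requires sigma > 0")


@dataclass
class FitResult:
    """Parameter maps plus per-voxel diagnostics from :func:`fit_volume`."""

    ndi_map: np.ndarray
    raw_fin_map: np.ndarray
    odi_map: np.ndarray
    kappa_map: np.ndarray
    fiso_map: np.ndarray
    mu_theta_map: np.ndarray
    mu_phi_map: np.ndarray
    residual_map: np.ndarray
    converged_map: np.ndarray
    n_iter_map: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def maps(self) -> dict[str, np.ndarray]:
        return {
            "ndi": self.ndi_map,
            "fin_raw": self.raw_fin_map,
            "odi": self.odi_map,
            "kappa": self.kappa_map,
            "fiso": self.fiso_map,
            "rss": self.residual_map,
            "converged": self.converged_map.astype(float),
        }


def estimate_mean_orientation(voxel_signal, scheme: AcquisitionScheme):
    """Initial fiber orientation from a log-linear tensor fit.

    Uses the lowest non-zero shell (least sensitive to non-Gaussian
    restriction).  Returns (mu, degenerate): the principal eigenvector of
    the fitted tensor, sign-fixed to a non-negative z component, and a flag
    set when the leading eigenvalue gap is below 1e-9 (isotropic signal).
    """
    a = np.asarray(voxel_signal, dtype=float)
    b = scheme.b_values
    shell = b == scheme.shells[scheme.shells > 0][0]
    if shell.sum() < 6:
        raise ValueError("tensor initialization needs >= 6 low-b directions")
    g = scheme.directions[shell]
    y = -np.log(np.clip(a[shell], 1e-8, None)) / b[shell]
    design = np.column_stack(
        [
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ]
    )
    d, *_ = np.linalg.lstsq(design, y, rcond=None)
    tensor = np.array(
        [[d[0], d[3], d[4]], [d[3], d[1], d[5]], [d[4], d[5], d[2]]]
    )
    evals, evecs = np.linalg.eigh(tensor)
    degenerate = bool(evals[2] - evals[1] < 1e-9)
    if degenerate:
        return np.array([0.0, 0.0, 1.0]), True
    mu = evecs[:, 2]
    if mu[2] < 0:
        mu = -mu
    return mu, False


def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-np.clip(u, -500.0, 500.0)))


def _logit(p):
    p = np.clip(p, 1e-6, 1.0 - 1e-6)
    return np.log(p / (1.0 - p))


def _tangent_basis(mu):
    """Orthonormal basis of the tangent plane at axis mu."""
    helper = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    return e1, e2


def _model_attenuation(scheme, consts, ndi, kappa, fiso, mu):
    s_in, s_ex, s_iso = compartment_signals(scheme, consts, kappa, ndi, mu)
    tissue = 1.0 - fiso
    return tissue * (ndi * s_in + (1.0 - ndi) * s_ex) + fiso * s_iso


def _rician_nll(model, data, sigma):
    """Negative log-likelihood of Rician-distributed magnitudes."""
    s2 = sigma**2
    z = model * data / s2
    log_i0 = np.abs(z) + np.log(special.i0e(z))
    return float(
        -np.sum(np.log(data / s2) - (data**2 + model**2) / (2 * s2) + log_i0)
    )


def _grid_search(a, scheme, consts, mu, config, fiso_fixed=None):
    """Coarse deterministic search over (ndi, odi[, fiso]) at fixed mu.

    Ties in the objective are broken toward the lowest kappa (the less
    concentrated solution).
    """
    r = config.grid_resolution
    ndi_grid = np.linspace(0.05, 0.95, r)
    odi_grid = np.linspace(0.05, 0.95, r)  # descending kappa order
    kappa_grid = kappa_from_odi(odi_grid)
    fiso_grid = (
        np.array([fiso_fixed]) if fiso_fixed is not None else np.linspace(0.0, 0.9, r)
    )
    s_iso = signal_iso(scheme.b_values, consts.d_iso)
    b = scheme.b_values
    c2 = (scheme.directions @ mu) ** 2
    best = None
    # iterate kappa ascending so ties prefer the less concentrated solution
    for kappa in np.sort(kappa_grid):
        s_in, _, _ = compartment_signals(scheme, consts, kappa, 0.0, mu)
        tau = watson_second_moment(kappa)
        proj = tau * c2 + 0.5 * (1.0 - tau) * (1.0 - c2)
        d_perp = consts.d_par * (1.0 - ndi_grid)  # (R,)
        adc = d_perp[:, None] + (consts.d_par - d_perp[:, None]) * proj[None, :]
        s_ex = np.exp(-b[None, :] * adc)  # (R_ndi, N)
        s_ex[:, scheme.b0_mask] = 1.0
        tissue = ndi_grid[:, None] * s_in[None, :] + (1 - ndi_grid[:, None]) * s_ex
        # (R_ndi, R_fiso, N)
        model = (
            (1.0 - fiso_grid[None, :, None]) * tissue[:, None, :]
            + fiso_grid[None, :, None] * s_iso[None, None, :]
        )
        sse = np.sum((model - a[None, None, :]) ** 2, axis=2)
        idx = np.unravel_index(np.argmin(sse), sse.shape)
        if best is None or sse[idx] < best[0] - 1e-15:
            best = (float(sse[idx]), ndi_grid[idx[0]], kappa, fiso_grid[idx[1]])
    return best[1], best[2], best[3]


def _refine(a, scheme, consts, config, ndi0, kappa0, fiso0, mu0, fiso_fixed=None):
    """Derivative-based refinement through unconstrained reparametrization."""
    e1, e2 = _tangent_basis(mu0)
    kappa_max = config.kappa_max
    free_fiso = fiso_fixed is None

    def unpack(u):
        ndi = _sigmoid(u[0])
        kappa = kappa_max * _sigmoid(u[1])
        fiso = _sigmoid(u[2]) if free_fiso else fiso_fixed
        j = 3 if free_fiso else 2
        mu = mu0 + u[j] * e1 + u[j + 1] * e2
        mu = mu / np.linalg.norm(mu)
        return ndi, kappa, fiso, mu

    u0 = [_logit(ndi0), _logit(np.clip(kappa0 / kappa_max, 1e-6, 1 - 1e-6))]
    if free_fiso:
        u0.append(_logit(fiso0))
    u0 += [0.0, 0.0]
    u0 = np.array(u0)

    if config.noise_model == "gaussian_lsq":

        def residuals(u):
            ndi, kappa, fiso, mu = unpack(u)
            return _model_attenuation(scheme, consts, ndi, kappa, fiso, mu) - a

        sol = optimize.least_squares(
            residuals,
            u0,
            method="lm",
            ftol=config.tol,
            xtol=config.tol,
            max_nfev=config.max_iter * u0.size,
        )
        u, cost, nfev = sol.x, 2.0 * sol.cost, sol.nfev
        converged = sol.status > 0
    else:

        def nll(u):
            ndi, kappa, fiso, mu = unpack(u)
            model = _model_attenuation(scheme, consts, ndi, kappa, fiso, mu)
            return _rician_nll(model, a, config.sigma)

        sol = optimize.minimize(
            nll,
            u0,
            method="Nelder-Mead",
            options={"fatol": config.tol, "maxiter": config.max_iter * 20},
        )
        u, nfev, converged = sol.x, sol.nfev, bool(sol.success)
        ndi, kappa, fiso, mu = unpack(u)
        model = _model_attenuation(scheme, consts, ndi, kappa, fiso, mu)
        cost = float(np.sum((model - a) ** 2))

    ndi, kappa, fiso, mu = unpack(u)
    if config.noise_model == "gaussian_lsq":
        model = _model_attenuation(scheme, consts, ndi, kappa, fiso, mu)
        cost = float(np.sum((model - a) ** 2))
    return ndi, kappa, fiso, mu, cost, int(nfev), converged


def _empty_voxel(fiso=np.nan, flag="invalid"):
    return {
        "ndi": np.nan, "raw_fin": np.nan, "odi": np.nan, "kappa": np.nan,
        "fiso": fiso, "mu": np.array([np.nan] * 3), "rss": np.nan,
        "converged": False, "n_iter": 0, "flag": flag,
    }


def _voxel_result(ndi, kappa, fiso, mu, rss, n_iter, converged, degenerate):
    if mu[2] < 0:
        mu = -mu
    return {
        "ndi": float(ndi),
        "raw_fin": float(ndi * (1.0 - fiso)),
        "odi": float(odi_from_kappa(kappa)),
        "kappa": float(kappa),
        "fiso": float(fiso),
        "mu": mu,
        "rss": float(rss),
        "converged": bool(converged),
        "n_iter": n_iter,
        "flag": "degenerate_orientation" if degenerate else "ok",
    }


def fit_voxel_noddi(
    voxel_signal,
    scheme: AcquisitionScheme,
    config: FitConfig = FitConfig(model="noddi"),
    consts: DiffusivityConstants = DiffusivityConstants(),
) -> dict:
    """Three-compartment fit with F_iso free.

    ``voxel_signal`` must already be normalized by the b = 0 signal.
    Returns a dict of scalar estimates and diagnostics; a voxel dominated
    by free water (fitted F_iso > 0.95) keeps its F_iso estimate but its
    tissue parameters are flagged unreliable.
    """
    a = np.asarray(voxel_signal, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        return _empty_voxel()
    mu0, degenerate = estimate_mean_orientation(a, scheme)
    ndi0, kappa0, fiso0 = _grid_search(a, scheme, consts, mu0, config)
    ndi, kappa, fiso, mu, rss, nit, conv = _refine(
        a, scheme, consts, config, ndi0, kappa0, fiso0, mu0
    )
    out = _voxel_result(ndi, kappa, fiso, mu, rss, nit, conv, degenerate)
    if fiso > FISO_TISSUE_LIMIT:
        out["flag"] = "insufficient_tissue"
    return out


def fit_voxel_cnoddi(
    voxel_signal,
    scheme: AcquisitionScheme,
    fiso: float,
    config: FitConfig = FitConfig(model="cnoddi"),
    consts: DiffusivityConstants = DiffusivityConstants(),
) -> dict:
    """Constrained fit with the isotropic fraction supplied, not estimated.

    Enforces f_in + f_ex = 1 - fiso; with fiso = 0 the model reduces
    exactly to the two-compartment tissue model
    A = f_in S_in + (1 - f_in) S_ex.
    """
    if not 0 <= fiso <= 1:
        raise ValueError("fiso must lie in [0, 1]")
    a = np.asarray(voxel_signal, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        return _empty_voxel(fiso=fiso)
    if fiso > FISO_TISSUE_LIMIT:
        return _empty_voxel(fiso=fiso, flag="insufficient_tissue")
    mu0, degenerate = estimate_mean_orientation(a, scheme)
    ndi0, kappa0, _ = _grid_search(a, scheme, consts, mu0, config, fiso_fixed=fiso)
    ndi, kappa, _, mu, rss, nit, conv = _refine(
        a, scheme, consts, config, ndi0, kappa0, fiso, mu0, fiso_fixed=fiso
    )
    return _voxel_result(ndi, kappa, fiso, mu, rss, nit, conv, degenerate)


def fit_volume(
    dwi: DWIVolume,
    config: FitConfig = FitConfig(),
    fiso_map: np.ndarray | None = None,
    consts: DiffusivityConstants = DiffusivityConstants(),
) -> FitResult:
    """Apply the per-voxel fit over a masked volume.

    Signals are normalized by the mean of the b = 0 volumes.  For the
    constrained model a per-voxel ``fiso_map`` is required.
    """
    if config.model == "cnoddi" and fiso_map is None:
        raise ValueError("model 'cnoddi' requires a fiso_map")
    shape = dwi.shape
    nan = np.full(shape, np.nan)
    res = FitResult(
        ndi_map=nan.copy(), raw_fin_map=nan.copy(), odi_map=nan.copy(),
        kappa_map=nan.copy(), fiso_map=nan.copy(),
        mu_theta_map=nan.copy(), mu_phi_map=nan.copy(),
        residual_map=nan.copy(),
        converged_map=np.zeros(shape, dtype=bool),
        n_iter_map=np.zeros(shape, dtype=int),
        affine=dwi.affine,
    )
    b0 = dwi.scheme.b0_mask
    voxels = np.argwhere(dwi.mask)
    n_total = len(voxels)
    for count, (i, j, k) in enumerate(voxels):
        s = dwi.signal[i, j, k]
        s0 = s[b0].mean()
        if not np.isfinite(s0) or s0 <= 0:
            continue
        a = s / s0
        if config.model == "noddi":
            out = fit_voxel_noddi(a, dwi.scheme, config, consts)
        else:
            out = fit_voxel_cnoddi(
                a, dwi.scheme, float(fiso_map[i, j, k]), config, consts
            )
        res.ndi_map[i, j, k] = out["ndi"]
        res.raw_fin_map[i, j, k] = out["raw_fin"]
        res.odi_map[i, j, k] = out["odi"]
        res.kappa_map[i, j, k] = out["kappa"]
        res.fiso_map[i, j, k] = out["fiso"]
        mu = out["mu"]
        if np.all(np.isfinite(mu)):
            res.mu_theta_map[i, j, k] = np.arccos(np.clip(mu[2], -1, 1))
            res.mu_phi_map[i, j, k] = np.arctan2(mu[1], mu[0])
        res.residual_map[i, j, k] = out["rss"]
        res.converged_map[i, j, k] = out["converged"]
        res.n_iter_map[i, j, k] = out["n_iter"]
        if (count + 1) % 500 == 0:
            logger.info("fit %d/%d voxels", count + 1, n_total)
    return res
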