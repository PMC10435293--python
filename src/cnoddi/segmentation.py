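"""Isotropic-fraction estimation by HMRF-EM tissue segmentation.

The apparent CSF fraction F_iso needed by the constrained fit is estimated
from the T2-weighted b = 0 image: a three-class (WM / GM / CSF) Gaussian
mixture is fitted by expectation-maximization, spatially regularized by a
hidden Markov random field with a 6-neighbour Potts prior whose labels are
updated by iterated conditional modes (ICM).  On a T2-weighted image CSF
is the brightest class, so F_iso is taken as the posterior probability of
the highest-mean class.

This emulates, rather than re-implements, the FAST-style segmentation
stage: the posterior under HMRF smoothing stands in for a full
partial-volume mixel model, and no bias-field correction is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SegmentationResult", "em_gmm", "hmrf_icm", "segment_fiso",
           "fiso_from_segmentation"]

_VAR_FLOOR = 1e-8


@dataclass
class SegmentationResult:
    class_means: np.ndarray  # (K,) ascending intensity order
    class_variances: np.ndarray  # (K,)
    posteriors: np.ndarray  # (n_masked, K), rows sum to 1
    labels: np.ndarray  # 3D int, -1 outside mask
    mask: np.ndarray  # 3D bool
    intensities: np.ndarray  # masked 1D intensities (model input)
    log_likelihood: list[float] = field(default_factory=list)
    mixing: np.ndarray | None = None  # (K,) mixture weights (MRF off)

    @property
    def n_classes(self) -> int:
        return self.class_means.size

    def label_volume(self) -> np.ndarray:
        return self.labels

    def posterior_volume(self, k: int) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.posteriors[:, k]
        return vol


def _gauss_log_pdf(x, mean, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x[:, None] - mean) ** 2 / var)


def _kmeans_init(x, k, seed, n_iter=15, n_init=8):
    """Seeded k-means++ initialization with restarts (lowest inertia kept).

    Deterministic given seed.  Restarts matter when class volumes are very
    unbalanced (e.g. a thin tissue rim inside a large CSF pool), where a
    single D^2-weighted draw tends to split the dominant class.
    """
    rng = np.random.default_rng(seed)
    best_centers, best_inertia = None, np.inf
    for _ in range(n_init):
        centers = [x[rng.integers(x.size)]]
        for _ in range(k - 1):
            d2 = np.min((x[:, None] - np.array(centers)) ** 2, axis=1)
            total = d2.sum()
            if total <= 0:
                centers.append(x[rng.integers(x.size)])
                continue
            centers.append(
                x[np.searchsorted(np.cumsum(d2), rng.uniform() * total)]
            )
        centers = np.array(centers, dtype=float)
        for _ in range(n_iter):
            assign = np.argmin((x[:, None] - centers) ** 2, axis=1)
            for j in range(k):
                sel = assign == j
                if sel.any():
                    centers[j] = x[sel].mean()
        inertia = np.min((x[:, None] - centers) ** 2, axis=1).sum()
        if inertia < best_inertia:
            best_centers, best_inertia = centers, inertia
    return np.sort(best_centers)


def em_gmm(
    intensities: np.ndarray,
    mask: np.ndarray | None = None,
    n_classes: int = 3,
    tol: float = 1e-6,
    max_iter: int = 100,
    seed: int = 0,
) -> SegmentationResult:
    """Plain Gaussian-mixture EM on masked intensities (no MRF prior).

    The observed-data log-likelihood is non-decreasing across iterations;
    classes are reported in ascending-mean order.  Degenerate variances are
    floored with a warning.
    """
    intensities = np.asarray(intensities, dtype=float)
    if mask is None:
        mask = np.ones(intensities.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    x = intensities[mask]
    if x.size == 0:
        raise ValueError("empty mask")
    if np.unique(x).size < n_classes:
        raise ValueError(
            f"need >= {n_classes} distinct intensities, got {np.unique(x).size}"
        )
    means = _kmeans_init(x, n_classes, seed)
    assign = np.argmin((x[:, None] - means) ** 2, axis=1)
    variances = np.empty(n_classes)
    mixing = np.empty(n_classes)
    for j in range(n_classes):
        sel = assign == j
        mixing[j] = max(sel.mean(), 1e-6)
        variances[j] = max(x[sel].var() if sel.any() else x.var(), _VAR_FLOOR)

    loglik_trace: list[float] = []
    post = None
    for _ in range(max_iter):
        logp = _gauss_log_pdf(x, means, variances) + np.log(mixing)
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        post = np.exp(logp - lse[:, None])
        loglik = float(lse.sum())
        loglik_trace.append(loglik)
        nk = post.sum(axis=0)
        mixing = nk / x.size
        means = (post * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        variances = (post * (x[:, None] - means) ** 2).sum(axis=0) / np.maximum(
            nk, 1e-12
        )
        if np.any(variances < _VAR_FLOOR):
            warnings.warn("degenerate class variance floored", stacklevel=2)
            variances = np.maximum(variances, _VAR_FLOOR)
        if len(loglik_trace) > 1 and (
            abs(loglik_trace[-1] - loglik_trace[-2])
            <= tol * abs(loglik_trace[-2])
        ):
            break

    order = np.argsort(means)
    means, variances, mixing = means[order], variances[order], mixing[order]
    post = post[:, order]
    labels = np.full(mask.shape, -1, dtype=int)
    labels[mask] = np.argmax(post, axis=1)
    return SegmentationResult(
        class_means=means, class_variances=variances, posteriors=post,
        labels=labels, mask=mask, intensities=x,
        log_likelihood=loglik_trace, mixing=mixing,
    )


def _neighbor_counts(labels, mask, k):
    """Per-voxel count of 6-neighbours currently carrying each class label."""
    counts = np.zeros(labels.shape + (k,))
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(labels, shift, axis=axis)
            valid = np.roll(mask, shift, axis=axis) & mask
            # voxels rolled in across the boundary are not neighbours
            edge = [slice(None)] * 3
            edge[axis] = 0 if shift == 1 else -1
            valid[tuple(edge)] = False
            for j in range(k):
                counts[..., j] += valid & (rolled == j)
    return counts


def _potts_energy(labels, mask, counts, beta, log_lik_map):
    """Posterior energy: negative log-likelihood + Potts disagreement."""
    idx = labels[mask]
    data_term = -log_lik_map[np.arange(idx.size), idx].sum()
    agree = counts[mask][np.arange(idx.size), idx].sum()
    # each agreeing pair counted twice across the sweep; constant factor ok
    return float(data_term - beta * agree / 2.0)


def hmrf_icm(
    result: SegmentationResult, beta: float = 1.0, n_sweeps: int = 5
) -> SegmentationResult:
    """Regularize labels by ICM under a 6-neighbour Potts prior.

    Each sweep assigns every masked voxel the class maximizing
    ``log N(x | mu_k, var_k) + beta * (#neighbours with label k)``, which
    cannot increase the posterior energy.  ``beta = 0`` reproduces the
    maximum-likelihood labels.  Posteriors are recomputed with the
    neighbour-dependent prior after the final sweep.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    k = result.n_classes
    x = result.intensities
    log_lik = _gauss_log_pdf(x, result.class_means, result.class_variances)
    labels = result.labels.copy()
    mask = result.mask
    if beta == 0:
        labels[mask] = np.argmax(log_lik, axis=1)
    else:
        for _ in range(n_sweeps):
            counts = _neighbor_counts(labels, mask, k)
            score = log_lik + beta * counts[mask]
            new = np.argmax(score, axis=1)
            if np.array_equal(new, labels[mask]):
                break
            labels[mask] = new
    counts = _neighbor_counts(labels, mask, k)
    logp = log_lik + beta * counts[mask]
    m = logp.max(axis=1, keepdims=True)
    post = np.exp(logp - m)
    post /= post.sum(axis=1, keepdims=True)
    return SegmentationResult(
        class_means=result.class_means,
        class_variances=result.class_variances,
        posteriors=post, labels=labels, mask=mask, intensities=x,
        log_likelihood=list(result.log_likelihood), mixing=result.mixing,
    )


def potts_energy(result: SegmentationResult, beta: float) -> float:
    """Posterior energy of the current labelling (for monitoring ICM)."""
    log_lik = _gauss_log_pdf(
        result.intensities, result.class_means, result.class_variances
    )
    counts = _neighbor_counts(result.labels, result.mask, result.n_classes)
    return _potts_energy(result.labels, result.mask, counts, beta, log_lik)


def fiso_from_segmentation(result: SegmentationResult) -> np.ndarray:
    """Apparent isotropic fraction = posterior of the brightest class.

    On a T2-weighted b = 0 image the highest-mean class is CSF.  Requires a
    3-class segmentation (WM / GM / CSF).
    """
    if result.n_classes != 3:
        raise ValueError("F_iso extraction requires a 3-class segmentation")
    csf = int(np.argmax(result.class_means))
    return result.posterior_volume(csf)


def segment_fiso(
    b0: np.ndarray,
    mask: np.ndarray | None = None,
    beta: float = 1.0,
    n_classes: int = 3,
    tol: float = 1e-6,
    max_iter: int = 100,
    n_icm_sweeps: int = 5,
    n_outer: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, SegmentationResult]:
    """Full HMRF-EM loop: EM parameter updates interleaved with ICM.

    Returns ``(fiso_map, result)`` where the map is 0 outside the mask.
    """
    result = em_gmm(b0, mask, n_classes, tol, max_iter, seed)
    if beta > 0:
        x = result.intensities
        for _ in range(n_outer):
            result = hmrf_icm(result, beta, n_icm_sweeps)
            post = result.posteriors
            nk = np.maximum(post.sum(axis=0), 1e-12)
            means = (post * x[:, None]).sum(axis=0) / nk
            variances = np.maximum(
                (post * (x[:, None] - means) ** 2).sum(axis=0) / nk, _VAR_FLOOR
            )
            if np.allclose(means, result.class_means, rtol=tol) and np.allclose(
                variances, result.class_variances, rtol=tol
            ):
                result.class_means, result.class_variances = means, variances
                break
            result.class_means, result.class_variances = means, variances
        result = hmrf_icm(result, beta, n_icm_sweeps)
    fiso = fiso_from_segmentation(result)
    return fiso, result
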