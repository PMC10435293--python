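"""Acquisition-scheme data model and gradient-direction design.

An :class:`AcquisitionScheme` records, per acquired volume, the diffusion
weighting ``b`` (s/mm^2), the unit gradient direction, the echo time TE (ms,
scalar or per-volume) and the repetition time TR (ms).  Directions follow
the FSL bvec dialect (3 rows x N columns on disk, image coordinate frame);
no gradient reorientation is applied anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionScheme", "build_scheme"]


@dataclass(frozen=True)
class AcquisitionScheme:
    b_values: np.ndarray  # (N,) s/mm^2
    directions: np.ndarray  # (N, 3) unit vectors (b > 0) or anything at b = 0
    echo_time: np.ndarray  # ms; scalar stored broadcast to (N,)
    repetition_time: float  # ms

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        g = np.asarray(self.directions, dtype=float)
        if g.shape != (b.size, 3):
            raise ValueError(
                f"directions shape {g.shape} does not match {b.size} b-values"
            )
        te = np.broadcast_to(
            np.asarray(self.echo_time, dtype=float), b.shape
        ).copy()
        if np.any(b < 0):
            raise ValueError("b-values must be >= 0")
        if not np.any(b == 0):
            raise ValueError("scheme must contain at least one b = 0 volume")
        if np.any(te <= 0) or self.repetition_time <= 0:
            raise ValueError("echo_time and repetition_time must be > 0")
        dwi = b > 0
        norms = np.linalg.norm(g[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("directions at b > 0 must be unit-norm within 1e-6")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)
        object.__setattr__(self, "echo_time", te)
        object.__setattr__(self, "repetition_time", float(self.repetition_time))

    @property
    def n_volumes(self) -> int:
        return self.b_values.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique b-values."""
        return np.unique(self.b_values)

    def with_echo_time(self, echo_time) -> "AcquisitionScheme":
        """Copy of the scheme at a different TE (multi-TE experiments)."""
        return AcquisitionScheme(
            self.b_values, self.directions, echo_time, self.repetition_time
        )


def _repulsion_directions(n: int, seed: int, n_iter: int = 300, step: float = 0.05):
    """Approximately uniform antipodal point set by electrostatic repulsion.

    Minimizes the Coulomb energy of n charge pairs {x, -x} by projected
    gradient descent from a seeded random start; deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    for it in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]  # (n, n, 3)
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            np.fill_diagonal(d2, np.inf)
            force += (diff / (d2[..., None] ** 1.5)).sum(axis=1)
        # project onto tangent plane; normalize so the step size controls
        # the largest displacement (raw Coulomb forces diverge near pairs)
        force -= (np.einsum("ij,ij->i", force, x))[:, None] * x
        max_norm = np.linalg.norm(force, axis=1).max()
        if max_norm == 0:
            break
        decay = step * (1.0 - 0.9 * it / n_iter)
        x = x + decay * force / max_norm
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def build_scheme(
    b_per_shell,
    n_dirs_per_shell,
    echo_time: float = 67.0,
    repetition_time: float = 10_000.0,
    seed: int = 0,
) -> AcquisitionScheme:
    """Build a multi-shell scheme with repulsion-optimized directions.

    Parameters mirror a typical two-shell neurite-imaging protocol, e.g.
    ``build_scheme([0, 700, 2000], [1, 32, 32])`` gives 65 volumes with 32
    approximately uniform directions on each non-zero shell.  Shells with
    the same direction count share one optimized point set (same q-space
    sampling), matching common acquisition practice.
    """
    b_per_shell = list(b_per_shell)
    n_dirs_per_shell = [int(n) for n in n_dirs_per_shell]
    if len(b_per_shell) != len(n_dirs_per_shell):
        raise ValueError("b_per_shell and n_dirs_per_shell lengths differ")
    if any(n < 1 for n in n_dirs_per_shell):
        raise ValueError("direction counts must be >= 1")
    if any(b < 0 for b in b_per_shell):
        raise ValueError("b-values must be >= 0")

    cache: dict[int, np.ndarray] = {}
    b_list, g_list = [], []
    for b, n in zip(b_per_shell, n_dirs_per_shell):
        if b == 0:
            dirs = np.zeros((n, 3))
        else:
            if n not in cache:
                cache[n] = _repulsion_directions(n, seed=seed)
            dirs = cache[n]
        b_list.append(np.full(n, float(b)))
        g_list.append(dirs)
    return AcquisitionScheme(
        np.concatenate(b_list), np.vstack(g_list), echo_time, repetition_time
    )
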