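"""Digital phantoms and noise simulation.

Everything the pipeline consumes can be generated here with no external
data: parameter maps over a WM/GM/CSF geometry, multi-shell DWI volumes
from the composite signal model, relaxation-weighted multi-TE series, and
a synthetic subject cohort for the statistics stage.  Every simulated
output carries its ground truth alongside so downstream stages can be
tested closed-loop.

Default tissue presets are plausibility values for adult brain (WM:
neurite fraction 0.6, ODI 0.2; GM: 0.4, 0.6; CSF: pure free water); the
default protocol is two shells of 32 directions at b = 700 and
2000 s/mm^2 plus one b = 0 volume, TE 67 ms, TR 10 s; the default noise
level is SNR 30 at b = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import (
    DiffusivityConstants,
    RelaxationParams,
    TissueParams,
    apparent_fractions,
    signal_composite,
    signal_relaxation_weighted,
)
from .io import DWIVolume
from .scheme import AcquisitionScheme, build_scheme
from .watson import WatsonParams, kappa_from_odi

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "default_scheme",
    "simulate_dwi",
    "simulate_multi_te",
    "make_cohort",
    "add_rician_noise",
]

# label codes in phantom volumes
BG, WM, GM, CSF = 0, 1, 2, 3

#: Mean b = 0 intensities per class (arbitrary units, T2-weighted
#: contrast: CSF brightest) and within-class spread used by make_phantom.
B0_CLASS_MEANS = {WM: 250.0, GM: 350.0, CSF: 800.0}


def _default_wm():
    return TissueParams.from_ndi(0.6, 0.0, WatsonParams(kappa=kappa_from_odi(0.2)))


def _default_gm():
    return TissueParams.from_ndi(0.4, 0.0, WatsonParams(kappa=kappa_from_odi(0.6)))


def _default_csf():
    return TissueParams.from_ndi(0.0, 1.0, WatsonParams(kappa=0.0))


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple = (24, 24, 16)
    geometry: str = "nested_boxes"  # {"nested_boxes", "concentric_shells"}
    wm_params: TissueParams = field(default_factory=_default_wm)
    gm_params: TissueParams = field(default_factory=_default_gm)
    csf_params: TissueParams = field(default_factory=_default_csf)
    fiber_field: str = "uniform_z"  # {"uniform_z", "random"}
    rim: int = 2  # CSF rim thickness in voxels
    ring: int = 2  # GM ring thickness in voxels
    core_margin: int = 2  # erosion depth defining the deep-WM core
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("nested_boxes", "concentric_shells"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.fiber_field not in ("uniform_z", "random"):
            raise ValueError(f"unknown fiber_field {self.fiber_field!r}")


@dataclass
class Phantom:
    """Ground-truth parameter maps over a labelled voxel grid."""

    labels: np.ndarray  # int volume with BG/WM/GM/CSF codes
    ndi: np.ndarray
    odi: np.ndarray
    kappa: np.ndarray
    fiso: np.ndarray
    mu: np.ndarray  # (x, y, z, 3) unit axes
    s0: np.ndarray  # b = 0 intensity volume (class-contrast, noiseless)
    deep_wm: np.ndarray  # boolean core mask
    affine: np.ndarray = field(default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0]))

    @property
    def mask(self) -> np.ndarray:
        return self.labels != BG

    def params_at(self, i, j, k) -> TissueParams:
        return TissueParams.from_ndi(
            float(self.ndi[i, j, k]),
            float(self.fiso[i, j, k]),
            WatsonParams(self.mu[i, j, k], float(self.kappa[i, j, k])),
        )


def _erode(mask: np.ndarray, n: int) -> np.ndarray:
    out = mask.copy()
    for _ in range(n):
        inner = out.copy()
        for axis in range(3):
            inner &= np.roll(out, 1, axis=axis) & np.roll(out, -1, axis=axis)
        # voxels on the array border have missing neighbours: not interior
        edge = np.zeros_like(out)
        edge[1:-1, 1:-1, 1:-1] = True
        out = inner & edge
    return out


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Build a labelled digital phantom with ground-truth parameter maps.

    ``nested_boxes``: a CSF rim, a GM ring and a WM interior arranged as
    nested rectangular shells; ``concentric_shells`` uses Euclidean
    distance from the grid centre instead.  Deep-WM voxels (WM eroded by
    ``core_margin``) have F_iso exactly 0; the CSF rim has F_iso exactly 1.
    The b = 0 volume is drawn per class with CSF brightest.
    """
    nx, ny, nz = spec.shape
    labels = np.full(spec.shape, CSF, dtype=int)
    if spec.geometry == "nested_boxes":
        r, g = spec.rim, spec.rim + spec.ring
        labels[r:nx - r, r:ny - r, r:nz - r] = GM
        labels[g:nx - g, g:ny - g, g:nz - g] = WM
    else:
        center = (np.array(spec.shape) - 1) / 2.0
        ii = np.stack(np.meshgrid(*[np.arange(n) for n in spec.shape],
                                  indexing="ij"), axis=-1)
        dist = np.linalg.norm(ii - center, axis=-1)
        rmax = min(spec.shape) / 2.0
        labels[dist < rmax - spec.rim] = GM
        labels[dist < rmax - spec.rim - spec.ring] = WM

    rng = np.random.default_rng(spec.seed)
    ndi = np.zeros(spec.shape)
    odi = np.zeros(spec.shape)
    fiso = np.zeros(spec.shape)
    for code, params in ((WM, spec.wm_params), (GM, spec.gm_params),
                         (CSF, spec.csf_params)):
        sel = labels == code
        ndi[sel] = params.ndi if params.f_in + params.f_ex > 0 else 0.0
        odi[sel] = params.watson.odi
        fiso[sel] = params.f_iso
    kappa = np.zeros(spec.shape)
    inside = labels != BG
    kappa[inside] = kappa_from_odi(np.clip(odi[inside], 1e-6, 1.0))

    mu = np.zeros(spec.shape + (3,))
    if spec.fiber_field == "uniform_z":
        mu[..., 2] = 1.0
    else:
        v = rng.standard_normal(spec.shape + (3,))
        mu = v / np.linalg.norm(v, axis=-1, keepdims=True)
        mu[mu[..., 2] < 0] *= -1.0

    s0 = np.zeros(spec.shape)
    for code, mean in B0_CLASS_MEANS.items():
        sel = labels == code
        s0[sel] = mean

    deep_wm = _erode(labels == WM, spec.core_margin)
    return Phantom(labels=labels, ndi=ndi, odi=odi, kappa=kappa, fiso=fiso,
                   mu=mu, s0=s0, deep_wm=deep_wm)


def default_scheme(echo_time: float = 67.0, seed: int = 0) -> AcquisitionScheme:
    """The two-shell protocol: b = 0/700/2000 s/mm^2, 32 directions per shell."""
    return build_scheme([0, 700, 2000], [1, 32, 32], echo_time=echo_time,
                        repetition_time=10_000.0, seed=seed)


def add_rician_noise(signal: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Magnitude of the signal perturbed by complex Gaussian noise."""
    noise_r = rng.normal(0.0, sigma, signal.shape)
    noise_i = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + noise_r) ** 2 + noise_i**2)


def simulate_dwi(
    phantom: Phantom,
    scheme: AcquisitionScheme,
    snr: float = 30.0,
    noise_model: str = "rician",
    seed: int = 0,
    consts: DiffusivityConstants = DiffusivityConstants(),
) -> DWIVolume:
    """Simulate a multi-shell DWI volume from phantom ground truth.

    The noiseless channel equals the composite forward signal scaled by the
    phantom's b = 0 intensity exactly.  Noise sd is ``s0_ref / snr`` with
    ``s0_ref`` the WM class mean, i.e. SNR is quoted for white matter at
    b = 0 and the noise field is spatially homogeneous, as on a scanner.
    """
    if noise_model not in ("none", "gaussian", "rician"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    if noise_model != "none" and snr <= 0:
        raise ValueError("snr must be > 0")
    shape = phantom.labels.shape
    signal = np.zeros(shape + (scheme.n_volumes,))
    for i, j, k in np.argwhere(phantom.mask):
        att = signal_composite(phantom.params_at(i, j, k), scheme, consts)
        signal[i, j, k] = phantom.s0[i, j, k] * att
    if noise_model != "none":
        rng = np.random.default_rng(seed)
        sigma = B0_CLASS_MEANS[WM] / snr
        if noise_model == "gaussian":
            signal = np.clip(signal + rng.normal(0, sigma, signal.shape), 0, None)
        else:
            signal = add_rician_noise(signal, sigma, rng)
    return DWIVolume(signal=signal, scheme=scheme, affine=phantom.affine,
                     mask=phantom.mask)


def simulate_multi_te(
    phantom: Phantom,
    relax: RelaxationParams,
    te_list,
    scheme_base: AcquisitionScheme,
    snr: float = 30.0,
    noise_model: str = "rician",
    seed: int = 0,
    consts: DiffusivityConstants = DiffusivityConstants(),
):
    """Simulate one relaxation-weighted DWI series per echo time.

    The phantom fractions are interpreted as physical volume fractions and
    each series is generated with per-compartment T2 decay and T1
    saturation at its TE.  Returns ``(volumes, fiso_apparent)`` where
    ``fiso_apparent[t]`` is the ground-truth apparent isotropic fraction
    map at ``te_list[t]`` — the constrained fit's correct input, which
    grows with TE whenever CSF T2 exceeds tissue T2.
    """
    volumes: list[DWIVolume] = []
    fiso_apparent: list[np.ndarray] = []
    shape = phantom.labels.shape
    for t_idx, te in enumerate(te_list):
        scheme = scheme_base.with_echo_time(te)
        signal = np.zeros(shape + (scheme.n_volumes,))
        fiso_app = np.zeros(shape)
        for i, j, k in np.argwhere(phantom.mask):
            params = phantom.params_at(i, j, k)
            signal[i, j, k] = signal_relaxation_weighted(
                params, relax, scheme, consts, s0=phantom.s0[i, j, k]
            )
            fiso_app[i, j, k] = apparent_fractions(
                params, relax, te, scheme.repetition_time
            )[2]
        if noise_model != "none":
            rng = np.random.default_rng(seed + t_idx)
            # SNR quoted for WM at b = 0 at the shortest TE of the series
            te0 = min(te_list)
            wm_ref = B0_CLASS_MEANS[WM] * np.exp(-te0 / relax.t2_in_ex) * (
                1 - np.exp(-scheme.repetition_time / relax.t1_in)
            )
            sigma = wm_ref / snr
            if noise_model == "gaussian":
                signal = np.clip(signal + rng.normal(0, sigma, signal.shape), 0, None)
            else:
                signal = add_rician_noise(signal, sigma, rng)
        volumes.append(DWIVolume(signal=signal, scheme=scheme,
                                 affine=phantom.affine, mask=phantom.mask))
        fiso_apparent.append(fiso_app)
    return volumes, fiso_apparent


def make_cohort(
    n_subjects: int = 58,
    age_range: tuple = (21.0, 83.0),
    peak_age: float = 42.0,
    curvature: float = -6e-5,
    sex_effect: float = 0.0,
    noise_sd: float = 0.02,
    ndi_peak: float = 0.55,
    rois: tuple = ("WB", "FL", "PL", "OL", "TL"),
    nfl_coupling: float = -0.5,
    nfl_noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a synthetic subject cohort with ROI summaries.

    Per subject and ROI, mean neurite density follows an inverted-U
    quadratic in age, ``ndi_peak + curvature * (age - peak_age)^2`` plus a
    sex offset and Gaussian noise.  Plasma NfL (pg/mL) is log-normal with
    ``log NfL`` depending linearly (negatively, by default) on the
    whole-brain NDI z-score plus noise, emulating higher neurofilament
    levels with lower axonal density.  ODI is generated age-constant.

    Returns a tidy table with one row per subject x ROI and columns
    subject_id, age, sex (0/1), nfl, roi, mean_ndi, mean_odi.
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    rng = np.random.default_rng(seed)
    age = rng.uniform(age_range[0], age_range[1], n_subjects)
    sex = rng.integers(0, 2, n_subjects)
    rows = []
    ndi_by_subject = {}
    for s in range(n_subjects):
        for roi in rois:
            mean = ndi_peak + curvature * (age[s] - peak_age) ** 2
            mean += sex_effect * sex[s]
            ndi = mean + rng.normal(0, noise_sd)
            odi = 0.35 + rng.normal(0, noise_sd)
            rows.append((f"sub-{s:03d}", age[s], int(sex[s]), roi,
                         float(np.clip(ndi, 0, 1)), float(np.clip(odi, 0, 1))))
            if roi == rois[0]:
                ndi_by_subject[s] = rows[-1][4]
    df = pd.DataFrame(rows, columns=["subject_id", "age", "sex", "roi",
                                     "mean_ndi", "mean_odi"])
    wb = np.array([ndi_by_subject[s] for s in range(n_subjects)])
    z = (wb - wb.mean()) / wb.std()
    log_nfl = np.log(12.0) + 0.02 * (age - age.mean()) + nfl_coupling * z
    nfl = np.exp(log_nfl + rng.normal(0, nfl_noise_sd, n_subjects))
    df["nfl"] = df["subject_id"].map(
        {f"sub-{s:03d}": nfl[s] for s in range(n_subjects)}
    )
    return df
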