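"""Synthetic multimodal MRI study generator with known ground truth.

Emulates the acquisition and statistical structure of a two-group rodent
MRI study:

* resting-state BOLD: 1200 frames at TR = 0.5 s, band-limited (0.01-0.1
  Hz) region signals with a prescribed inter-regional correlation matrix,
  broadcast into an atlas label volume with voxel noise, a global signal,
  six motion traces and a linear drift (all stored as known nuisance
  regressors);
* pharmacological MRI: 20 baseline + 80 post-injection frames, a
  gamma-variate drug response per subject x region with hierarchical
  group structure, physiological covariate effects and AR(1) noise;
* diffusion MRI: prolate-tensor fiber-bundle phantoms and the single-shell
  forward signal model with optional Rician noise.

Every simulator is deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RoiAtlas
from .scheme import DiffusionScheme


@dataclass
class GroundTruth:
    """Simulation truth carried alongside synthetic data.

    Only the fields relevant to the simulator that produced it are set.
    """

    fc_target: np.ndarray | None = None
    gamma_truth: pd.DataFrame | None = None
    gamma_group_means: dict | None = None
    bundle_spec: list | None = None
    covariate_truth: pd.DataFrame | None = None
    covariate_effects: dict | None = None
    tensors: np.ndarray | None = None
    fa: np.ndarray | None = None
    md: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# resting-state BOLD
# ---------------------------------------------------------------------------

def _bandlimited_noise(rng, n_series, n_frames, tr, low=0.01, high=0.1):
    """White Gaussian noise band-passed to [low, high] Hz and standardized.

    Uses the same zero-phase spectral band-pass as the analysis pipeline
    so the simulated spectrum matches the analysis band exactly.
    """
    from .bold import bandpass_data

    x = rng.standard_normal((n_series, n_frames))
    y = bandpass_data(x, tr, low, high)
    y -= y.mean(axis=-1, keepdims=True)
    y /= y.std(axis=-1, keepdims=True)
    return y


def _check_correlation_matrix(c):
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("fc_target must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("fc_target must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise ValueError("fc_target must have unit diagonal")
    w, v = np.linalg.eigh(c)
    if w.min() < -1e-10:
        w_clip = np.clip(w, 0, None)
        near = (v * w_clip) @ v.T
        d = np.sqrt(np.diag(near))
        near = near / np.outer(d, d)
        raise ValueError(
            "fc_target is not positive semi-definite; nearest PSD correlation "
            f"matrix has entries within {np.abs(near - c).max():.3g} of the input"
        )
    return c, np.clip(w, 0, None), v


def sim_rest_bold(
    atlas: RoiAtlas,
    fc_target: np.ndarray,
    n_frames: int = 1200,
    tr: float = 0.5,
    noise: dict | None = None,
    voxel_volume: bool = True,
    seed: int | None = None,
):
    """Simulate a resting-state BOLD run over the atlas' gray-matter ROIs.

    Region signals are band-limited Gaussian processes colored by the
    matrix square root of ``fc_target`` so their population correlation
    equals the target. The voxel volume broadcasts each region's signal
    into its label mask and adds voxel noise, a global signal, six motion
    traces (random-walk shaped) and a linear drift; all additive nuisance
    time courses are returned so ideal preprocessing can remove them.

    Parameters
    ----------
    atlas : RoiAtlas
    fc_target : ndarray
        Valid correlation matrix over the gray ROIs (ordered as
        ``atlas.gray_table``).
    n_frames, tr : int, float
        Default 1200 frames at TR = 0.5 s.
    noise : dict, optional
        Amplitudes relative to the unit-variance ROI signals. Keys
        ``voxel`` (default 0.5), ``global`` (0.3), ``motion`` (0.2),
        ``drift`` (0.3).
    seed : int, optional

    Returns
    -------
    (dict, GroundTruth)
        The dict holds ``roi_signals`` (n_roi, n_frames), ``volume``
        (x, y, z, t), ``frame_times``, ``tr``, ``nuisance`` (DataFrame of
        global/motion/trend regressors) and ``gray_labels``.
    """
    noise = {"voxel": 0.5, "global": 0.3, "motion": 0.2, "drift": 0.3, **(noise or {})}
    gray = atlas.gray_table
    n_roi = len(gray)
    c, w, v = _check_correlation_matrix(fc_target)
    if c.shape[0] != n_roi:
        raise ValueError(f"fc_target must be {n_roi}x{n_roi} for this atlas")
    rng = np.random.default_rng(seed)

    base = _bandlimited_noise(rng, n_roi, n_frames, tr)
    sqrt_c = (v * np.sqrt(w)) @ v.T
    roi_signals = sqrt_c @ base

    t = np.arange(n_frames) * tr
    glob = _bandlimited_noise(rng, 1, n_frames, tr)[0] * noise["global"]
    motion = np.cumsum(rng.standard_normal((6, n_frames)), axis=1)
    motion -= motion.mean(axis=1, keepdims=True)
    motion /= motion.std(axis=1, keepdims=True)
    motion *= noise["motion"]
    drift = (t - t.mean()) / t.std() * noise["drift"]

    if voxel_volume:
        labels = atlas.label_volume
        vol = rng.standard_normal((*labels.shape, n_frames)) * noise["voxel"]
        for i, lab in enumerate(gray["label_id"]):
            vol[labels == int(lab)] += roi_signals[i]
        vol[labels > 0] += glob + motion.sum(axis=0) * 0.1 + drift
    else:
        vol = None

    nuis = pd.DataFrame(
        {"global": glob, **{f"motion_{k}": motion[k] for k in range(6)}, "trend": drift}
    )
    data = {
        "roi_signals": roi_signals,
        "volume": vol,
        "frame_times": t,
        "tr": tr,
        "nuisance": nuis,
        "gray_labels": gray["label_id"].to_numpy(),
    }
    return data, GroundTruth(fc_target=c)


# ---------------------------------------------------------------------------
# pharmacological MRI
# ---------------------------------------------------------------------------

#: Default group-level gamma-variate parameter means. The wild-type
#: response (shape 2, rate 0.6/min, scale 12 %BOLD*min) peaks ~1.7 min
#: post-injection at ~2.7 %BOLD and has peak/AUC ~ 0.22/min, the regime
#: of measured cocaine responses; the "knockout-style" group inflates the
#: scale by 40%.
DEFAULT_PHMRI_GROUPS = {
    "WT": {"alpha": 2.0, "beta": 0.6, "lam": 12.0},
    "KO": {"alpha": 2.0, "beta": 0.6, "lam": 16.8},
}


def _gamma_curve(t, alpha, beta, lam):
    # normalized gamma density times scale; 0 before injection
    from .phmri import gamma_response, GammaParams

    return gamma_response(t, GammaParams(alpha=alpha, beta=beta, lam=lam))


def sim_phmri(
    groups: dict | None = None,
    n_subjects=(12, 15),
    n_rois: int = 21,
    baseline_frames: int = 20,
    post_frames: int = 80,
    frame_interval_min: float = 0.5,
    subject_sd_log: float = 0.3,
    noise_sd: float = 0.5,
    ar1_phi: float = 0.4,
    covariates: dict | None = None,
    missing_covariate_rate: float = 0.1,
    seed: int | None = None,
):
    """Simulate a two-group pharmacological-MRI study.

    Each subject x ROI series (in %BOLD relative to baseline) is::

        y(t) = lam * g(t - t_inj; alpha, beta) + covariate effects + AR(1) noise

    with subject x ROI log-parameters drawn around the group-level means
    (``groups``) with log-SD ``subject_sd_log``. Noise is discrete AR(1)
    on the frame grid, Corr(e_i, e_j) = phi^|dt| with dt in frames.

    Parameters
    ----------
    groups : dict
        ``{group: {"alpha": .., "beta": .., "lam": ..}}`` group-level
        means (defaults to a wild-type and a scale-inflated knockout-style
        group).
    n_subjects : tuple of int
        Per-group subject counts (default 12 vs 15).
    baseline_frames, post_frames : int
        Default 20 + 80 frames, 0.5 min apart (10 min baseline + 40 min
        post-injection).
    covariates : dict, optional
        ``{"PaCO2_before": coeff, ...}`` linear effect of each covariate
        (per unit, added as a constant offset to the whole series). By
        default small nonzero effects are used.
    missing_covariate_rate : float
        Fraction of covariate entries set missing (for imputation tests).
    seed : int, optional

    Returns
    -------
    (list of dict, GroundTruth)
        One session dict per subject with ``series`` (n_roi, n_frames),
        ``frame_times_min``, ``injection_time_min``, ``group``,
        ``covariates`` and counts; GroundTruth carries the per-subject
        gamma parameters, group means and covariate truth.
    """
    if post_frames == 0:
        raise ValueError("post_frames = 0 leaves the response unidentifiable")
    if not (0 <= ar1_phi < 1):
        raise ValueError("ar1_phi must be in [0, 1)")
    groups = groups or DEFAULT_PHMRI_GROUPS
    covariates = covariates if covariates is not None else {
        "PaCO2_before": 0.02, "MABP_before": 0.005, "MABP_peak": 0.005,
    }
    cov_dists = {  # population mean/SD of each physiological covariate (mmHg)
        "PaCO2_before": (37.0, 4.0),
        "MABP_before": (120.0, 30.0),
        "MABP_peak": (122.0, 30.0),
    }
    rng = np.random.default_rng(seed)
    n_frames = baseline_frames + post_frames
    t = np.arange(n_frames) * frame_interval_min
    t_inj = baseline_frames * frame_interval_min
    t_post = np.clip(t - t_inj, 0, None)

    sessions, truth_rows, cov_rows = [], [], []
    sid = 0
    for (gname, gmeans), n_g in zip(groups.items(), n_subjects):
        mu_log = np.log([gmeans["alpha"], gmeans["beta"], gmeans["lam"]])
        for _ in range(n_g):
            cov_vals = {k: rng.normal(*cov_dists.get(k, (0.0, 1.0))) for k in covariates}
            cov_offset = sum(covariates[k] * (cov_vals[k] - cov_dists.get(k, (0, 1))[0])
                             for k in covariates)
            series = np.empty((n_rois, n_frames))
            for r in range(n_rois):
                a, b, lam = np.exp(mu_log + rng.normal(0, subject_sd_log, 3))
                resp = _gamma_curve(t_post, a, b, lam)
                eps = rng.standard_normal(n_frames) * noise_sd
                if ar1_phi > 0:  # stationary AR(1) innovation recursion
                    e = np.empty(n_frames)
                    e[0] = eps[0]
                    c = np.sqrt(1 - ar1_phi**2)
                    for i in range(1, n_frames):
                        e[i] = ar1_phi * e[i - 1] + c * eps[i]
                else:
                    e = eps
                series[r] = resp + cov_offset + e
                truth_rows.append((sid, gname, r, a, b, lam))
            observed = {
                k: (np.nan if rng.random() < missing_covariate_rate else v)
                for k, v in cov_vals.items()
            }
            sessions.append({
                "subject": sid,
                "group": gname,
                "series": series,
                "frame_times_min": t,
                "injection_time_min": t_inj,
                "baseline_frames": baseline_frames,
                "post_frames": post_frames,
                "covariates": observed,
            })
            cov_rows.append({"subject": sid, "group": gname, **cov_vals})
            sid += 1

    gamma_truth = pd.DataFrame(
        truth_rows, columns=["subject", "group", "roi", "alpha", "beta", "lam"]
    )
    gt = GroundTruth(
        gamma_truth=gamma_truth,
        gamma_group_means=groups,
        covariate_truth=pd.DataFrame(cov_rows),
        covariate_effects=dict(covariates),
        extra={"subject_sd_log": subject_sd_log, "noise_sd": noise_sd,
               "ar1_phi": ar1_phi},
    )
    return sessions, gt


# ---------------------------------------------------------------------------
# diffusion phantoms
# ---------------------------------------------------------------------------

def eigenvalues_for_fa(fa: float, md: float = 0.7e-3) -> np.ndarray:
    """Prolate eigenvalues (l1 >= l2 = l3) with given FA and MD.

    Closed form for the axially-symmetric case: with l2 = l3, FA maps
    monotonically onto the ratio l1/l2.
    """
    if not (0 <= fa < 1):
        raise ValueError("fa must be in [0, 1)")
    if fa == 0:
        return np.full(3, md)
    # solve FA(r) for r = l1/l2 with l2=l3=1: FA = (r-1)/sqrt(r^2+2) * sqrt(...)
    # FA^2 = ( (r-1)^2 ) / (r^2 + 2)  * ... derive directly:
    # lambda = (r,1,1); mean m=(r+2)/3; num = 3/2*((r-m)^2+2(1-m)^2); den=r^2+2
    # FA^2 = num/den -> quadratic in r
    f2 = fa * fa
    # num/den = f2 -> (r-1)^2 = f2*(r^2+2)  [since 3/2*((r-m)^2+2(1-m)^2) = (r-1)^2]
    a = 1 - f2
    b = -2.0
    c = 1 - 2 * f2
    r = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    lam = np.array([r, 1.0, 1.0])
    lam *= 3 * md / lam.sum()
    return lam


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 diffusion tensors (mm^2/s) on a grid."""

    tensors: np.ndarray          # (x, y, z, 3, 3)
    voxel_size: np.ndarray       # mm per axis
    mask: np.ndarray | None = None
    clamped: np.ndarray | None = None  # voxels where eigenvalues were clamped

    def __post_init__(self):
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if self.mask is None:
            self.mask = np.ones(self.tensors.shape[:3], dtype=bool)


def sim_tensor_phantom(
    atlas: RoiAtlas,
    bundle_spec: list,
    fa_inside: float = 0.8,
    fa_outside: float = 0.1,
    md: float = 0.7e-3,
):
    """Build a tensor field with prolate fiber bundles on an atlas grid.

    Parameters
    ----------
    bundle_spec : list of dict
        Each with ``start_roi``/``end_roi`` (label ids), ``centerline``
        (polyline in mm) and ``radius`` (mm). Voxels within ``radius`` of
        the centerline get a prolate tensor aligned with the local tangent
        (first-listed bundle wins in crossings: single-tensor model);
        background voxels are near-isotropic at ``fa_outside``.
    fa_inside, fa_outside : float
        Must satisfy ``fa_inside > 0.2 > fa_outside`` so the standard
        seeding threshold separates bundle from background.

    Returns
    -------
    (TensorField, GroundTruth)
    """
    if not (fa_inside > 0.2 > fa_outside):
        raise ValueError("need fa_inside > 0.2 > fa_outside")
    shape = atlas.label_volume.shape
    vs = atlas.voxel_size
    extent = np.asarray(shape) * vs

    lam_out = eigenvalues_for_fa(fa_outside, md)
    d_out = np.diag(lam_out)
    tensors = np.broadcast_to(d_out, (*shape, 3, 3)).copy()
    assigned = np.zeros(shape, dtype=bool)
    lam_in = eigenvalues_for_fa(fa_inside, md)

    centers = (np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                        axis=-1) + 0.5) * vs

    for spec in bundle_spec:
        line = np.asarray(spec["centerline"], dtype=float)
        if np.any(line < 0) or np.any(line > extent):
            raise ValueError("bundle centerline exits the grid")
        radius = float(spec["radius"])
        # densify the polyline, then assign voxels within radius of it
        seg = np.diff(line, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        pts, tangents = [], []
        for p0, d, L in zip(line[:-1], seg, seglen):
            n_steps = max(int(np.ceil(L / (vs.min() / 2))), 1)
            s = np.linspace(0, 1, n_steps, endpoint=False)
            pts.append(p0 + s[:, None] * d)
            tangents.append(np.tile(d / L, (n_steps, 1)))
        pts = np.vstack(pts + [line[-1][None]])
        tangents = np.vstack(tangents + [tangents[-1][-1][None]])

        flat_centers = centers.reshape(-1, 3)
        d2 = ((flat_centers[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        nearest = d2.argmin(axis=1)
        inside = d2[np.arange(len(flat_centers)), nearest] <= radius**2
        inside = inside.reshape(shape)
        for idx in np.argwhere(inside & ~assigned):
            e1 = tangents[nearest[np.ravel_multi_index(idx, shape)]]
            tensors[tuple(idx)] = _prolate_tensor(e1, lam_in)
        assigned |= inside

    fa, md_map = _eig_scalars(tensors)
    tf = TensorField(tensors=tensors, voxel_size=vs)
    gt = GroundTruth(bundle_spec=list(bundle_spec), tensors=tensors.copy(),
                     fa=fa, md=md_map,
                     extra={"fa_inside": fa_inside, "fa_outside": fa_outside})
    return tf, gt


def _prolate_tensor(e1, lam):
    e1 = np.asarray(e1, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    # complete an orthonormal frame
    a = np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, a)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.stack([e1, e2, e3], axis=1)
    return R @ np.diag(lam) @ R.T


def _eig_scalars(tensors):
    w = np.linalg.eigvalsh(tensors.reshape(-1, 3, 3))
    md = w.mean(axis=1)
    num = np.sqrt(((w - md[:, None]) ** 2).sum(axis=1))
    den = np.sqrt((w**2).sum(axis=1))
    fa = np.sqrt(1.5) * np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    shape = tensors.shape[:3]
    return fa.reshape(shape), md.reshape(shape)


def sim_dwi(
    tensor_field: TensorField,
    scheme: DiffusionScheme,
    s0: float = 1000.0,
    snr: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Forward single-shell diffusion signal from a tensor field.

    Noiseless signal per volume: ``S = s0 * exp(-b * g^T D g)``; optional
    Rician noise (magnitude of complex Gaussian) at SNR = s0 / sigma.

    Returns a 4-D array (x, y, z, n_volumes).
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")
    D = tensor_field.tensors
    w = np.linalg.eigvalsh(D.reshape(-1, 3, 3))
    if w.min() < -1e-12:
        raise ValueError("tensors must be positive semi-definite")
    g = scheme.directions
    b = scheme.b_values
    # g^T D g for all voxels and volumes
    Dg = np.einsum("...ij,vj->...vi", D, g)
    adc = np.einsum("vi,...vi->...v", g, Dg)
    sig = s0 * np.exp(-b * adc)
    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        sig = np.sqrt(
            (sig + rng.normal(0, sigma, sig.shape)) ** 2
            + rng.normal(0, sigma, sig.shape) ** 2
        )
    return sig
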