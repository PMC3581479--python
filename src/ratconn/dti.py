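"""Diffusion tensor fitting, streamline tractography and connectomes.

Tensor estimation is the classic log-linear least-squares fit of
``ln(S/S0) = -b g^T D g``. Tractography integrates the principal
eigenvector of the trilinearly interpolated tensor field bidirectionally
from random seeds in every voxel above the FA threshold, terminating on
low FA, sharp turns or volume exit. Structural connectomes connect ROI
pairs through streamlines with endpoints in both regions and at least the
minimum length, weighted by the mean FA sampled along the connecting
tracts.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RoiAtlas
from .scheme import DiffusionScheme
from .simulate import TensorField, _eig_scalars
from . import stats as _stats

__all__ = [
    "fit_tensor", "tensor_scalars", "track_streamlines", "build_connectome",
    "roi_fa_stats", "Streamline", "Connectome", "TensorField",
    "save_streamlines_jsonl", "load_streamlines_jsonl",
]


@dataclass
class Streamline:
    """Ordered polyline in mm world coordinates."""

    points: np.ndarray

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class Connectome:
    """FA-weighted ROI-pair structural connectivity.

    ``weights[i, j]`` is the mean FA along all qualifying streamlines
    between ROI i and j (NaN where no streamline qualifies); ``counts``
    holds streamline counts per pair.
    """

    weights: np.ndarray
    counts: np.ndarray
    roi_ids: np.ndarray

    def to_frame(self, names=None) -> pd.DataFrame:
        idx = names if names is not None else self.roi_ids
        return pd.DataFrame(self.weights, index=idx, columns=idx)


def fit_tensor(dwi: np.ndarray, scheme: DiffusionScheme, voxel_size=1.0,
               mask=None, clamp_negative: bool = True) -> TensorField:
    """Log-linear least-squares diffusion tensor fit per voxel.

    Solves ``ln S = ln S0 - b g^T D g`` with the 6 unique tensor elements
    plus ln S0 as unknowns. Non-positive signals are clamped to a small
    epsilon before the log and the voxel flagged. Negative eigenvalues are
    clamped to zero (flagged) when ``clamp_negative``.
    """
    dwi = np.asarray(dwi, dtype=float)
    b = scheme.b_values
    g = scheme.directions
    if scheme.n_weighted < 6:
        raise ValueError("tensor fit needs >= 6 diffusion-weighted volumes")
    if scheme.n_b0 < 1:
        raise ValueError("tensor fit needs at least one b=0 volume")
    # design: ln S = X @ [Dxx Dyy Dzz Dxy Dxz Dyz lnS0]
    X = np.column_stack([
        -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1], -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
        np.ones_like(b),
    ])
    shape = dwi.shape[:3]
    flat = dwi.reshape(-1, dwi.shape[-1])
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mflat = mask.ravel()
    clamped_signal = (flat <= 0).any(axis=1) & mflat
    logs = np.log(np.clip(flat, 1e-12, None))
    coef = np.linalg.lstsq(X, logs[mflat].T, rcond=None)[0].T
    tensors = np.zeros((flat.shape[0], 3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = coef[:, 0], coef[:, 1], coef[:, 2], coef[:, 3], coef[:, 4], coef[:, 5]
    t = np.zeros((coef.shape[0], 3, 3))
    t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = dxx, dyy, dzz
    t[:, 0, 1] = t[:, 1, 0] = dxy
    t[:, 0, 2] = t[:, 2, 0] = dxz
    t[:, 1, 2] = t[:, 2, 1] = dyz
    clamped_eig = np.zeros(coef.shape[0], dtype=bool)
    if clamp_negative:
        w, v = np.linalg.eigh(t)
        neg = (w < 0).any(axis=1)
        if neg.any():
            w_cl = np.clip(w[neg], 0, None)
            t[neg] = np.einsum("nij,nj,nkj->nik", v[neg], w_cl, v[neg])
            clamped_eig = neg
    tensors[mflat] = t
    flags = np.zeros(flat.shape[0], dtype=bool)
    flags[mflat] = clamped_eig
    flags |= clamped_signal
    return TensorField(
        tensors=tensors.reshape(*shape, 3, 3),
        voxel_size=voxel_size,
        mask=mask,
        clamped=flags.reshape(shape),
    )


def tensor_scalars(tf: TensorField):
    """FA and MD maps from a tensor field.

    MD = mean eigenvalue; FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||,
    in [0, 1]; the zero tensor maps to FA = 0, MD = 0.
    """
    return _eig_scalars(tf.tensors)


class _TrilinearField:
    """Trilinear interpolation of tensors and FA at mm coordinates.

    Voxel centers sit at (index + 0.5) * voxel_size; queries are clamped
    to the outermost centers (constant extrapolation at the border).
    """

    def __init__(self, tf: TensorField, fa: np.ndarray):
        self.vals = np.concatenate(
            [tf.tensors.reshape(*tf.tensors.shape[:3], 9), fa[..., None]], axis=-1
        )
        self.vs = tf.voxel_size
        self.shape = np.asarray(tf.tensors.shape[:3])

    def __call__(self, pts_mm):
        p = np.atleast_2d(pts_mm) / self.vs - 0.5
        p = np.clip(p, 0, self.shape - 1 - 1e-9)
        i0 = np.floor(p).astype(int)
        f = p - i0
        out = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                         * np.where(dy, f[:, 1], 1 - f[:, 1])
                         * np.where(dz, f[:, 2], 1 - f[:, 2]))
                    idx = np.minimum(i0 + [dx, dy, dz], self.shape - 1)
                    out = out + w[:, None] * self.vals[idx[:, 0], idx[:, 1], idx[:, 2]]
        tens = out[:, :9].reshape(-1, 3, 3)
        return tens, out[:, 9]


def _principal_dir(tensors):
    w, v = np.linalg.eigh(tensors)
    return v[..., :, 2]  # eigenvector of the largest eigenvalue


def track_streamlines(
    tf: TensorField,
    fa_thresh: float = 0.2,
    angle_thresh_deg: float = 35.0,
    seeds_per_voxel: int = 10,
    step_mm: float = 0.1,
    max_steps: int = 2000,
    seed: int | None = None,
) -> list[Streamline]:
    """Deterministic principal-eigenvector streamline tractography.

    Seeds are placed uniformly at random inside every voxel with
    FA > ``fa_thresh`` (``seeds_per_voxel`` each). From each seed the
    track is integrated in both directions along the principal eigenvector
    of the trilinearly interpolated tensor, with sign continuity between
    consecutive steps. A track terminates when interpolated FA drops to
    the threshold, the turn between consecutive steps exceeds the angle
    threshold, or the point leaves the volume. Reproducible by seed.
    """
    fa, _ = tensor_scalars(tf)
    field = _TrilinearField(tf, fa)
    vs = tf.voxel_size
    extent = np.asarray(tf.tensors.shape[:3]) * vs
    cos_thresh = np.cos(np.radians(angle_thresh_deg))
    rng = np.random.default_rng(seed)

    seed_voxels = np.argwhere(fa > fa_thresh)
    if len(seed_voxels) == 0:
        return []
    starts = (
        np.repeat(seed_voxels, seeds_per_voxel, axis=0)
        + rng.random((len(seed_voxels) * seeds_per_voxel, 3))
    ) * vs
    tens0, f0 = field(starts)
    valid = f0 > fa_thresh
    starts = starts[valid]
    d0 = _principal_dir(tens0[valid])
    n = len(starts)
    if n == 0:
        return []

    def propagate(dirs0):
        """Integrate all seeds at once; returns per-seed point lists."""
        paths = [starts.copy()]
        p = starts.copy()
        d_prev = dirs0.copy()
        active = np.ones(n, dtype=bool)
        for _ in range(max_steps):
            if not active.any():
                break
            p_new = p.copy()
            p_new[active] = p[active] + step_mm * d_prev[active]
            inb = active & np.all((p_new >= 0) & (p_new < extent), axis=1)
            d_new = d_prev.copy()
            if inb.any():
                tens, f = field(p_new[inb])
                ok = f > fa_thresh
                d_cand = _principal_dir(tens)
                flip = np.einsum("ij,ij->i", d_cand, d_prev[inb]) < 0
                d_cand[flip] = -d_cand[flip]
                turn_ok = np.einsum("ij,ij->i", d_cand, d_prev[inb]) >= cos_thresh
                keep = ok & turn_ok
                sub = np.where(inb)[0]
                inb[sub[~keep]] = False
                d_new[sub[keep]] = d_cand[keep]
            active = inb
            step_pts = np.full_like(p, np.nan)
            step_pts[active] = p_new[active]
            paths.append(step_pts)
            p[active] = p_new[active]
            d_prev = d_new
        return np.stack(paths, axis=1)  # (n, steps+1, 3)

    fwd = propagate(d0)
    bwd = propagate(-d0)
    streamlines = []
    for i in range(n):
        f_pts = fwd[i][~np.isnan(fwd[i, :, 0])]
        b_pts = bwd[i][~np.isnan(bwd[i, :, 0])]
        pts = np.vstack([b_pts[::-1], f_pts[1:]])
        if len(pts) >= 2:
            streamlines.append(Streamline(points=pts))
    return streamlines


def build_connectome(
    streamlines: list[Streamline],
    atlas: RoiAtlas,
    fa_map: np.ndarray,
    min_length_mm: float = 1.0,
    fa_average: str = "pooled",
) -> Connectome:
    """FA-weighted ROI-pair connectome from streamline endpoints.

    A streamline contributes to pair (A, B) iff the voxel containing one
    endpoint is labeled A, the other B (A != B), and its arc length is at
    least ``min_length_mm``. Edge weight is the mean FA sampled at every
    streamline point (``fa_average="pooled"``, all samples pooled across
    contributing tracts) or the mean of per-streamline mean FA
    (``"per-streamline"``).
    """
    table = atlas.gray_table
    roi_ids = table["label_id"].to_numpy()
    index = {int(lab): i for i, lab in enumerate(roi_ids)}
    n = len(roi_ids)
    counts = np.zeros((n, n), dtype=int)
    sums = np.zeros((n, n))
    nsamp = np.zeros((n, n))
    labels = atlas.label_volume
    vs = atlas.voxel_size
    shape = np.asarray(labels.shape)

    def label_at(p):
        idx = np.floor(p / vs).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            return 0
        return int(labels[tuple(idx)])

    for sl in streamlines:
        if sl.length < min_length_mm or len(sl.points) < 2:
            continue
        la, lb = label_at(sl.points[0]), label_at(sl.points[-1])
        i, j = index.get(la), index.get(lb)
        if i is None or j is None or i == j:
            continue
        idx = np.clip(np.floor(sl.points / vs).astype(int), 0, shape - 1)
        fa_samples = fa_map[idx[:, 0], idx[:, 1], idx[:, 2]]
        if fa_average == "pooled":
            sums[i, j] += fa_samples.sum()
            sums[j, i] += fa_samples.sum()
            nsamp[i, j] += len(fa_samples)
            nsamp[j, i] += len(fa_samples)
        else:
            sums[i, j] += fa_samples.mean()
            sums[j, i] += fa_samples.mean()
            nsamp[i, j] += 1
            nsamp[j, i] += 1
        counts[i, j] += 1
        counts[j, i] += 1
    with np.errstate(invalid="ignore"):
        weights = np.where(counts > 0, sums / np.where(nsamp > 0, nsamp, 1), np.nan)
    return Connectome(weights=weights, counts=counts, roi_ids=roi_ids)


def roi_fa_stats(fa_maps_a, fa_maps_b, atlas: RoiAtlas, rois=None) -> pd.DataFrame:
    """Group comparison of mean FA in white-matter ROIs.

    Parameters
    ----------
    fa_maps_a, fa_maps_b : sequence of ndarray
        Per-subject FA maps of the two groups, aligned to the atlas grid.
    rois : sequence of int, optional
        Label ids to test (defaults to the atlas' white-matter ROIs).

    Returns
    -------
    pandas.DataFrame
        Per-ROI mean FA of each group, t, p, FDR-adjusted q, and Cohen's
        d (pooled SD).
    """
    table = atlas.white_table if rois is None else atlas.roi_table[
        atlas.roi_table["label_id"].isin(rois)
    ]
    rows = []
    for rec in table.itertuples(index=False):
        mask = atlas.label_volume == int(rec.label_id)
        if not mask.any():
            import warnings

            warnings.warn(f"ROI {rec.name!r} has an empty mask; skipped")
            continue
        a = np.array([m[mask].mean() for m in fa_maps_a])
        b = np.array([m[mask].mean() for m in fa_maps_b])
        res = _stats.t_tests(a, b)
        rows.append((rec.label_id, rec.name, a.mean(), b.mean(),
                     res.statistic, res.p, res.d))
    df = pd.DataFrame(rows, columns=["label_id", "name", "mean_fa_a", "mean_fa_b",
                                     "t", "p", "d"])
    if len(df):
        df["q"] = _stats.fdr_bh(df["p"].to_numpy())
    return df


def save_streamlines_jsonl(streamlines, path) -> None:
    """Write streamlines as JSON-lines, one object per track (mm points)."""
    with open(path, "w") as fh:
        for sl in streamlines:
            fh.write(json.dumps({"points": sl.points.tolist(),
                                 "length_mm": sl.length}) + "\n")


def load_streamlines_jsonl(path) -> list[Streamline]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(Streamline(points=np.asarray(json.loads(line)["points"])))
    return out
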