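"""Synthetic region-of-interest atlases.

The default atlas mimics a corticolimbic rat-brain parcellation: 23
bilaterally positioned gray-matter regions (mainly limbic structures with
serotonergic innervation) plus 4 white-matter regions (genu and body of
the corpus callosum, anterior commissure, internal capsule). Regions are
compact boxes placed on a regular lattice, mirrored across the
mid-sagittal plane, so that every left gray region has exactly one right
homolog.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical bilateral gray-matter ROI names (abbreviation conventions of
#: the rat corticolimbic literature).
GRAY_ROI_NAMES = (
    "PFC (dm)",   # dorsomedial prefrontal cortex
    "PFC (vm)",   # ventromedial prefrontal cortex
    "Ins",        # insula
    "FC",         # frontal cortex
    "OFC (v)",    # ventral orbitofrontal cortex
    "OFC (d)",    # dorsal orbitofrontal cortex
    "NAc",        # nucleus accumbens
    "CPu",        # caudate-putamen
    "GP",         # globus pallidus
    "Amy",        # basal amygdaloid nuclei
    "Tha",        # thalamic nuclei
    "Hip (d)",    # dorsal hippocampus
    "Hip (v)",    # ventral hippocampus
    "SN",         # substantia nigra
    "DRN",        # dorsal raphe nuclei
    "VTA",        # ventral tegmental area
    "ViC",        # visual cortex
    "AuC",        # auditory cortex
    "TeC",        # temporal cortex
    "PtC",        # parietal cortex
    "MC",         # motor cortex
    "SmC",        # somatosensory cortex
    "RsC",        # retrosplenial cortex
)

#: White-matter ROI names.
WHITE_ROI_NAMES = (
    "genu CC",
    "body CC",
    "anterior commissure",
    "internal capsule",
)


@dataclass
class RoiAtlas:
    """Integer label volume plus a table describing each region.

    Attributes
    ----------
    label_volume : ndarray of int
        3-D grid, 0 = background, positive integers = ROI labels.
    voxel_size : ndarray of float
        mm per axis (3,).
    roi_table : pandas.DataFrame
        Columns ``label_id, name, hemisphere, homolog_label_id, tissue``.
        Gray-matter rows pair left/right homologs; white-matter rows are
        midline structures (hemisphere ``"both"``, homolog = own label).
    """

    label_volume: np.ndarray
    voxel_size: np.ndarray
    roi_table: pd.DataFrame
    _by_label: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        ids = self.roi_table["label_id"].to_numpy()
        if np.any(ids <= 0) or len(set(ids)) != len(ids):
            raise ValueError("label_ids must be unique and positive")
        self._by_label = {
            int(r.label_id): r for r in self.roi_table.itertuples(index=False)
        }

    @property
    def gray_table(self) -> pd.DataFrame:
        return self.roi_table[self.roi_table["tissue"] == "gray"]

    @property
    def white_table(self) -> pd.DataFrame:
        return self.roi_table[self.roi_table["tissue"] == "white"]

    def homolog(self, label_id: int) -> int:
        """Label of the contralateral homolog (involution)."""
        return int(self._by_label[int(label_id)].homolog_label_id)

    def mask(self, label_id: int) -> np.ndarray:
        return self.label_volume == int(label_id)

    def voxel_count(self, label_id: int) -> int:
        return int(np.count_nonzero(self.label_volume == int(label_id)))

    def roi_centers_mm(self) -> dict[int, np.ndarray]:
        """Center of mass of each ROI in world (mm) coordinates."""
        out = {}
        for lab in self.roi_table["label_id"]:
            idx = np.argwhere(self.label_volume == int(lab))
            out[int(lab)] = (idx.mean(axis=0) + 0.5) * self.voxel_size
        return out


def make_atlas(
    grid_shape=(48, 48, 24),
    voxel_size=0.5,
    n_bilateral: int = 23,
    roi_extent=(3, 3, 3),
    seed: int | None = None,
) -> RoiAtlas:
    """Build a deterministic synthetic bilateral atlas.

    Gray-matter ROIs are ``roi_extent`` boxes arranged column-major on a
    lattice in each hemisphere, mirrored across the mid-plane of axis 0.
    Four white-matter boxes sit on the midline between the hemispheres.

    Parameters
    ----------
    grid_shape : tuple of int
        Label volume dimensions; axis 0 is left-right.
    voxel_size : float or 3-sequence
        mm per axis.
    n_bilateral : int
        Number of bilateral gray-matter ROI pairs (default 23, the full
        corticolimbic name list).
    roi_extent : tuple of int
        Box size of each ROI in voxels.
    seed : int, optional
        Accepted for interface uniformity; placement is lattice-determined
        and identical for any seed.

    Raises
    ------
    ValueError
        If the grid cannot hold ``2 * n_bilateral`` gray boxes plus the 4
        white-matter boxes without overlap.
    """
    if n_bilateral < 1 or n_bilateral > len(GRAY_ROI_NAMES):
        raise ValueError(f"n_bilateral must be in [1, {len(GRAY_ROI_NAMES)}]")
    grid_shape = tuple(int(s) for s in grid_shape)
    ex, ey, ez = (int(e) for e in roi_extent)
    nx, ny, nz = grid_shape
    gap = 1
    # hemisphere slabs: [0, mid-2) left, [mid+2, nx) right; white matter on midline
    mid = nx // 2
    hemi_w = mid - 2
    cols_x = max(hemi_w // (ex + gap), 0)
    cols_y = max(ny // (ey + gap), 0)
    cols_z = max(nz // (ez + gap), 0)
    capacity = cols_x * cols_y * cols_z
    if capacity < n_bilateral or cols_y * cols_z < 4:
        need_x = 2 * (2 + (ex + gap) * int(np.ceil(n_bilateral / max(cols_y * cols_z, 1))))
        raise ValueError(
            f"grid {grid_shape} too small for {n_bilateral} bilateral ROIs; "
            f"needs at least {need_x} voxels along axis 0 at this extent"
        )

    labels = np.zeros(grid_shape, dtype=np.int32)
    rows = []

    def slot(i):
        # column-major lattice position i -> voxel origin within a hemisphere
        ix, rem = divmod(i, cols_y * cols_z)
        iy, iz = divmod(rem, cols_z)
        return ix * (ex + gap), iy * (ey + gap), iz * (ez + gap)

    for i in range(n_bilateral):
        ox, oy, oz = slot(i)
        left_lab = 2 * i + 1
        right_lab = 2 * i + 2
        lx = ox  # left hemisphere grows from x=0
        rx = nx - ex - ox  # mirrored
        labels[lx:lx + ex, oy:oy + ey, oz:oz + ez] = left_lab
        labels[rx:rx + ex, oy:oy + ey, oz:oz + ez] = right_lab
        name = GRAY_ROI_NAMES[i]
        rows.append((left_lab, name, "left", right_lab, "gray"))
        rows.append((right_lab, name, "right", left_lab, "gray"))

    wm_x = mid - ex // 2
    for j, wname in enumerate(WHITE_ROI_NAMES):
        lab = 2 * n_bilateral + 1 + j
        oy = (j % cols_y) * (ey + gap)
        oz = (j // cols_y) * (ez + gap)
        if oz + ez > nz:
            raise ValueError("grid too small along axis 2 for white-matter ROIs")
        labels[wm_x:wm_x + ex, oy:oy + ey, oz:oz + ez] = lab
        rows.append((lab, wname, "both", lab, "white"))

    table = pd.DataFrame(
        rows,
        columns=["label_id", "name", "hemisphere", "homolog_label_id", "tissue"],
    )
    return RoiAtlas(label_volume=labels, voxel_size=voxel_size, roi_table=table)
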