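"""3D spot detection, nuclei segmentation, and FISH distance analysis.

Spots (transcription sites, FISH probe signals) are detected by a 3D
Laplacian-of-Gaussian filter (sign-flipped so bright blobs become
maxima), thresholded at mu + thr*sigma of the filtered frame, and
reduced to connected components whose intensity statistics come from
the *raw* voxel values.  Nuclei are segmented by Otsu thresholding the
log of a Gaussian-smoothed image (the log compensates nonhomogeneous
intranuclear intensity).  Probe-pair distances use mutual nearest
neighbors in physical (micrometer) coordinates, respecting the larger
voxel size along z, with distances over 1 um discarded as aberrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu

__all__ = [
    "ImageStack",
    "Spot",
    "SpotSet",
    "NucleiMask",
    "detect_spots",
    "segment_nuclei",
    "filter_spots_in_nuclei",
    "mutual_nearest_pairs",
    "spot_intensity_normalized",
    "filter_de_novo",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ImageStack:
    """Intensity array, (z, y, x) or (t, z, y, x), with voxel sizes in um."""

    data: np.ndarray
    voxel_xy: float
    voxel_z: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be 3D (z,y,x) or 4D (t,z,y,x)")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.data if self.data.ndim == 3 else self.data[i]


@dataclass(frozen=True)
class Spot:
    center: tuple[float, float, float]  # (z, y, x) in voxel units
    center_um: tuple[float, float, float]  # (z, y, x) in um
    total_intensity: float
    n_voxels: int
    frame: int = 0


@dataclass
class SpotSet:
    spots: list[Spot] = field(default_factory=list)
    voxel_xy: float = 1.0
    voxel_z: float = 1.0

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    def centers_um(self) -> np.ndarray:
        if not self.spots:
            return np.empty((0, 3))
        return np.array([s.center_um for s in self.spots])

    def in_frame(self, i: int) -> "SpotSet":
        return SpotSet(
            [s for s in self.spots if s.frame == i], self.voxel_xy, self.voxel_z
        )


@dataclass
class NucleiMask:
    mask: np.ndarray  # boolean, shaped like the source stack

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


# ---------------------------------------------------------------------------
# Spot detection


def _detect_spots_3d(
    vol: np.ndarray, voxel_xy: float, voxel_z: float,
    log_sigma: float, thr: float, frame: int,
) -> list[Spot]:
    filtered = -ndimage.gaussian_laplace(vol, sigma=log_sigma)
    mu, sigma_f = float(filtered.mean()), float(filtered.std())
    if sigma_f == 0.0:
        return []  # flat frame: the relative threshold is undefined
    binary = filtered >= mu + thr * sigma_f
    labels, n = ndimage.label(binary, structure=_STRUCT_26)
    if n == 0:
        return []
    spots = []
    raw_sums = ndimage.sum_labels(vol, labels, index=range(1, n + 1))
    sizes = ndimage.sum_labels(binary, labels, index=range(1, n + 1))
    for i in range(1, n + 1):
        if raw_sums[i - 1] > 0:
            com = ndimage.center_of_mass(vol * (labels == i))
        else:  # raw signal absent in the mask: fall back to geometry
            com = ndimage.center_of_mass(labels == i)
        z, y, x = (float(c) for c in com)
        spots.append(
            Spot(
                center=(z, y, x),
                center_um=(z * voxel_z, y * voxel_xy, x * voxel_xy),
                total_intensity=float(raw_sums[i - 1]),
                n_voxels=int(sizes[i - 1]),
                frame=frame,
            )
        )
    return spots


def detect_spots(
    stack: ImageStack, log_sigma: float = 1.0, thr: float = 3.0
) -> SpotSet:
    """LoG spot detection with a relative threshold mu + thr*sigma.

    mu and sigma are the mean and standard deviation of the filtered
    frame (computed per frame for movies, with thr common to all);
    26-connected components above threshold become spots whose total
    intensity and intensity-weighted center of mass are read from the
    raw data.
    """
    if stack.data.size == 0:
        raise ValueError("empty image")
    spots: list[Spot] = []
    for i in range(stack.n_frames):
        spots.extend(
            _detect_spots_3d(
                stack.frame(i), stack.voxel_xy, stack.voxel_z,
                log_sigma, thr, frame=i,
            )
        )
    return SpotSet(spots, stack.voxel_xy, stack.voxel_z)


# ---------------------------------------------------------------------------
# Nuclei segmentation


def _segment_volume(vol: np.ndarray, gauss_sigma: float, eps: float) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(vol, sigma=gauss_sigma)
    L = np.log(smoothed + eps)
    out = np.zeros(vol.shape, dtype=bool)
    for z in range(vol.shape[0]):
        sl = L[z]
        if sl.max() == sl.min():
            warnings.warn(
                f"constant slice z={z}: empty mask for that slice",
                stacklevel=3,
            )
            continue
        out[z] = sl >= threshold_otsu(sl)
    return out


def segment_nuclei(
    stack: ImageStack, gauss_sigma: float = 2.0, eps: float = 1.0
) -> NucleiMask:
    """Nuclei mask by per-slice Otsu thresholding of log(smoothed + eps).

    The log transform flattens intranuclear intensity gradients before
    Otsu; the threshold is re-derived in every z-slice (and every
    timepoint for movies).
    """
    if gauss_sigma <= 0:
        raise ValueError("gauss_sigma must be positive")
    if stack.data.ndim == 3:
        return NucleiMask(_segment_volume(stack.data, gauss_sigma, eps))
    mask = np.zeros(stack.data.shape, dtype=bool)
    for t in range(stack.n_frames):
        mask[t] = _segment_volume(stack.data[t], gauss_sigma, eps)
    return NucleiMask(mask)


def filter_spots_in_nuclei(spots: SpotSet, mask: NucleiMask) -> SpotSet:
    """Keep spots whose rounded center voxel falls inside the mask."""
    m = mask.mask
    kept = []
    for s in spots:
        idx = tuple(int(round(c)) for c in s.center)
        if m.ndim == 4:
            idx = (s.frame,) + idx
        if any(i < 0 or i >= n for i, n in zip(idx, m.shape)):
            raise ValueError(f"spot center {idx} outside mask shape {m.shape}")
        if m[idx]:
            kept.append(s)
    return SpotSet(kept, spots.voxel_xy, spots.voxel_z)


# ---------------------------------------------------------------------------
# Mutual-nearest-neighbor distances


def mutual_nearest_pairs(
    A: SpotSet, B: SpotSet, max_dist: float = 1.0
) -> list[tuple[int, int, float]]:
    """Mutual nearest neighbors between two spot sets, in micrometers.

    Distances are Euclidean on physical coordinates (z scaled by its own
    voxel size); a pair is kept iff each spot is the other's nearest
    neighbor and their distance does not exceed ``max_dist`` (default
    1 um, the aberrant-distance cutoff).  Ties resolve to the lowest
    index.  Returns (index_in_A, index_in_B, distance_um) triples.
    """
    if len(A) == 0 or len(B) == 0:
        return []
    pa, pb = A.centers_um(), B.centers_um()
    d = cdist(pa, pb)
    nn_of_a = d.argmin(axis=1)  # argmin takes the lowest index on ties
    nn_of_b = d.argmin(axis=0)
    pairs = []
    for ia, ib in enumerate(nn_of_a):
        if nn_of_b[ib] == ia and d[ia, ib] <= max_dist:
            pairs.append((ia, int(ib), float(d[ia, ib])))
    return pairs


# ---------------------------------------------------------------------------
# Transcription-site intensity and de novo filtering


def spot_intensity_normalized(
    spots: SpotSet,
    background_rois: list[np.ndarray | tuple],
    raw: ImageStack,
) -> np.ndarray:
    """Spot intensities divided by the mean background of the movie.

    ``background_rois`` are index expressions (boolean masks or slice
    tuples) into the raw data, each selecting an area away from any
    transcription spot; the background is the mean of the per-ROI mean
    intensities.
    """
    if not background_rois:
        raise ValueError("need at least one background region")
    means = [float(np.mean(raw.data[roi])) for roi in background_rois]
    background = float(np.mean(means))
    if background == 0:
        raise ZeroDivisionError("zero background intensity")
    return np.array([s.total_intensity / background for s in spots])


def filter_de_novo(
    spots: SpotSet,
    mitosis_frames: tuple[int, int],
    radius: float = 0.5,
) -> SpotSet:
    """Drop post-mitotic spots colocalizing with any mitotic-frame spot.

    Spots in frames within ``mitosis_frames`` (inclusive) define
    persistent (non-de-novo) positions; spots in later frames within
    ``radius`` um of any of them are removed.  The returned set holds
    the surviving post-mitotic ("de novo") spots.
    """
    lo, hi = mitosis_frames
    mitotic = np.array(
        [s.center_um for s in spots if lo <= s.frame <= hi]
    ).reshape(-1, 3)
    post = [s for s in spots if s.frame > hi]
    if mitotic.size == 0:
        return SpotSet(post, spots.voxel_xy, spots.voxel_z)
    kept = []
    for s in post:
        dist = np.sqrt(((mitotic - np.array(s.center_um)) ** 2).sum(axis=1))
        if dist.min() > radius:
            kept.append(s)
    return SpotSet(kept, spots.voxel_xy, spots.voxel_z)
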