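"""MTV delineation methods.

Implements the three delineation families compared in the pipeline plus
the fixed absolute cut:

* **fractional-SUVmax thresholding** (``threshold_segment``) with the
  bladder-masking criterion and an automated surrogate for manual
  adjustment (``grade_and_adjust``);
* **ellipsoid-constrained thresholding** (``ellipsoid_constrained_segment``)
  where an axis-aligned ellipsoid VOI restricts both the SUVmax search
  and the thresholded voxel set;
* **radial-gradient edge detection** (``gradient_segment``) which casts
  rays from the uptake peak, places each ray's boundary at the maximum
  absolute radial derivative and regularises the boundary radii with a
  median continuity filter;
* the **fixed SUV cut** (``fixed_suv_segment``, default SUV > 2.5).

All methods are pure functions of their inputs (no hidden randomness)
and all connected-component operations use 26-connectivity, the common
PET-VOI convention.  Fractional thresholds are inclusive (``>=``, so a
fraction of 1.0 retains the maximum voxel) while the fixed cut is
strict (``>``), matching how the absolute rule is conventionally stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import (
    BLADDER_LABEL,
    OTHER_LABEL,
    BinaryMask,
    LabelVolume,
    ScalarVolume,
    mtv_ml,
)

__all__ = [
    "SegmentationError",
    "MisSeedingError",
    "GradientError",
    "Grade",
    "AdjustmentGrade",
    "Ellipsoid",
    "SegmentationResult",
    "compute_suvmax",
    "threshold_segment",
    "fixed_suv_segment",
    "bladder_masking_required",
    "apply_bladder_mask",
    "grade_and_adjust",
    "ellipsoid_constrained_segment",
    "gradient_segment",
]

#: 26-neighbourhood structuring element.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(ValueError):
    """A delineation method could not produce a volume."""


class MisSeedingError(SegmentationError):
    """The seed voxel falls below the segmentation threshold."""


class GradientError(SegmentationError):
    """The gradient method found no usable edge."""


class Grade(str, Enum):
    """Manual-adjustment burden, graded by the number of affected slices."""

    NONE = "none"
    MINOR = "minor"          # 1-5 slices
    MAJOR = "major"          # 6-20 slices
    TOO_DIFFICULT = "too_difficult"  # >= 21 slices: MTV not measured


@dataclass(frozen=True)
class AdjustmentGrade:
    grade: Grade
    affected_slices: int

    def __post_init__(self):
        n = self.affected_slices
        if n < 0:
            raise ValueError("affected_slices must be >= 0")
        if self.grade is not Grade(self.grade):  # pragma: no cover
            raise ValueError("grade must be a Grade")
        expected = AdjustmentGrade.band(n)
        if self.grade is not expected:
            raise ValueError(f"{n} affected slices implies grade {expected.value}, got {self.grade.value}")

    @staticmethod
    def band(affected_slices: int) -> Grade:
        if affected_slices == 0:
            return Grade.NONE
        if affected_slices <= 5:
            return Grade.MINOR
        if affected_slices <= 20:
            return Grade.MAJOR
        return Grade.TOO_DIFFICULT

    @classmethod
    def from_affected_slices(cls, affected_slices: int) -> "AdjustmentGrade":
        return cls(cls.band(affected_slices), affected_slices)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid VOI in mm coordinates."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def __post_init__(self):
        if len(self.center) != 3 or len(self.semiaxes) != 3:
            raise ValueError("center and semiaxes must be mm triples")
        if any(a <= 0 or not np.isfinite(a) for a in self.semiaxes):
            raise ValueError(f"semiaxes must be positive, got {self.semiaxes}")

    def contains_grid(self, vol) -> np.ndarray:
        """Boolean grid marking voxels whose centre lies inside."""
        x, y, z = vol.axes_mm()
        cx, cy, cz = self.center
        ax, ay, az = self.semiaxes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    def contains_point(self, point) -> bool:
        v = (np.asarray(point, float) - np.asarray(self.center, float)) / np.asarray(self.semiaxes, float)
        return bool((v ** 2).sum() <= 1.0)


@dataclass
class SegmentationResult:
    """One delineation with its provenance.

    ``measured`` is False when adjustment was graded too difficult (the
    MTV is then absent, mirroring clinical practice of not recording it).
    """

    mask: BinaryMask | None
    mtv_ml: float | None
    method: str
    suvmax_used: float | None = None
    fraction: float | None = None
    suv_cut: float | None = None
    bladder_masked: bool = False
    adjustment: AdjustmentGrade | None = None
    measured: bool = True

    def __post_init__(self):
        if not self.measured and self.mtv_ml is not None:
            raise ValueError("an unmeasured result cannot carry an MTV")


def compute_suvmax(pet: ScalarVolume, search: BinaryMask | np.ndarray) -> float:
    """Maximum SUV over a non-empty search region."""
    sel = search.voxels if isinstance(search, BinaryMask) else np.asarray(search, bool)
    if sel.shape != pet.values.shape:
        raise ValueError("search region is not aligned with the PET volume")
    if not sel.any():
        raise ValueError("empty SUVmax search region")
    return float(pet.values[sel].max())


def _sphere_voxels(vol, center_index, radius_mm: float) -> np.ndarray:
    x, y, z = vol.axes_mm()
    c = vol.voxel_to_mm(center_index)
    d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    return d2 <= radius_mm ** 2


def _check_seed(pet, seed):
    seed = tuple(int(s) for s in seed)
    if len(seed) != 3 or any(s < 0 or s >= n for s, n in zip(seed, pet.values.shape)):
        raise ValueError(f"seed {seed} lies outside the grid {pet.values.shape}")
    return seed


def _component(binary: np.ndarray, anchor) -> np.ndarray:
    labeled, _ = ndimage.label(binary, structure=CONNECTIVITY_26)
    return labeled == labeled[anchor]


def _excluded_values(pet, exclusion):
    if exclusion is None:
        return pet.values
    excl = exclusion.voxels if isinstance(exclusion, BinaryMask) else np.asarray(exclusion, bool)
    if excl.shape != pet.values.shape:
        raise ValueError("exclusion mask is not aligned with the PET volume")
    return np.where(excl, 0.0, pet.values)


def threshold_segment(
    pet: ScalarVolume,
    seed,
    fraction: float,
    exclusion: BinaryMask | None = None,
    search_radius_mm: float = 60.0,
    connected: bool = True,
    with_info: bool = False,
):
    """Fractional-SUVmax VOI grown from a seed voxel.

    SUVmax is the maximum of the (exclusion-zeroed) image within a
    sphere of ``search_radius_mm`` around the seed; the VOI is the
    26-connected component of ``{SUV >= fraction * SUVmax}`` containing
    the seed.  With ``connected=False`` the VOI is instead the plain
    intensity cut restricted to the search sphere (the behaviour of some
    clinical tools is unknown, so both variants are exposed).

    Raises :class:`MisSeedingError` when the seed voxel itself falls
    below the threshold, which signals that the click missed the hot
    tumour region.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    seed = _check_seed(pet, seed)
    work = _excluded_values(pet, exclusion)
    sphere = _sphere_voxels(pet, seed, search_radius_mm)
    suvmax = float(work[sphere].max())
    if suvmax <= 0:
        raise SegmentationError("no uptake in the SUVmax search region")
    thr = fraction * suvmax
    if work[seed] < thr:
        raise MisSeedingError(
            f"seed value {work[seed]:.3g} below threshold {thr:.3g} (fraction {fraction})"
        )
    binary = work >= thr
    voxels = _component(binary, seed) if connected else binary & sphere
    mask = BinaryMask(voxels, pet.spacing, pet.origin)
    if with_info:
        return mask, {"suvmax": suvmax, "threshold": thr}
    return mask


def fixed_suv_segment(
    pet: ScalarVolume,
    seed,
    suv_cut: float = 2.5,
    exclusion: BinaryMask | None = None,
    connected: bool = True,
    search_radius_mm: float = 60.0,
    with_info: bool = False,
):
    """Fixed absolute cut: 26-connected component of {SUV > suv_cut}.

    With ``connected=False`` the VOI is the plain cut restricted to a
    sphere of ``search_radius_mm`` around the seed (the non-connected
    variant used when emulating a tool's displayed auto-contour).
    """
    seed = _check_seed(pet, seed)
    work = _excluded_values(pet, exclusion)
    if work[seed] <= suv_cut:
        raise MisSeedingError(f"seed value {work[seed]:.3g} not above the cut {suv_cut}")
    binary = work > suv_cut
    voxels = _component(binary, seed) if connected else binary & _sphere_voxels(pet, seed, search_radius_mm)
    mask = BinaryMask(voxels, pet.spacing, pet.origin)
    if with_info:
        return mask, {"suvmax": float(work[seed]), "threshold": float(suv_cut)}
    return mask


def bladder_masking_required(
    candidate: BinaryMask,
    bladder: BinaryMask,
    slice_axis: int = 2,
    max_overlap_slices: int = 5,
    dominance_fraction: float = 0.5,
) -> bool:
    """Decide whether bladder masking is needed for a trial VOI.

    True when the bladder was effectively outlined instead of tumour
    (more than half the candidate voxels lie in the bladder) or when the
    candidate overlaps the bladder on more than five axial slices.
    """
    if candidate.voxels.shape != bladder.voxels.shape:
        raise ValueError("candidate and bladder masks are not aligned")
    n = candidate.count
    if n == 0:
        return False
    inter = candidate.voxels & bladder.voxels
    if inter.sum() > dominance_fraction * n:
        return True
    per_slice = np.moveaxis(inter, slice_axis, 0).any(axis=(1, 2))
    return int(per_slice.sum()) > max_overlap_slices


def apply_bladder_mask(pet: ScalarVolume, bladder: BinaryMask) -> ScalarVolume:
    """Zero the bladder voxels so they cannot enter SUVmax search or VOIs."""
    if bladder.voxels.shape != pet.values.shape:
        raise ValueError("bladder mask is not aligned with the PET volume")
    values = pet.values.copy()
    values[bladder.voxels] = 0.0
    return ScalarVolume(values, pet.spacing, pet.origin)


def grade_and_adjust(
    mask: BinaryMask,
    labels: LabelVolume,
    slice_axis: int = 2,
) -> tuple[BinaryMask | None, AdjustmentGrade]:
    """Automated surrogate for manual adjustment, with the grading rubric.

    Counts the axial slices on which the VOI overlaps non-tumour
    physiologic labels (bladder/other) and grades the editing burden:
    none (0), minor (1-5), major (6-20), too difficult (>= 21, in which
    case the MTV is not measured and ``None`` is returned).  Otherwise
    the overlapping voxels are removed, the reproducible analogue of a
    human editing them out slice by slice.  Background spill is *not*
    removed - only labelled physiologic structures are edited, as in the
    clinical procedure.
    """
    if mask.voxels.shape != labels.labels.shape:
        raise ValueError("mask and labels are not aligned")
    non_tumour = (labels.labels == BLADDER_LABEL) | (labels.labels == OTHER_LABEL)
    inter = mask.voxels & non_tumour
    per_slice = np.moveaxis(inter, slice_axis, 0).any(axis=(1, 2))
    affected = int(per_slice.sum())
    grade = AdjustmentGrade.from_affected_slices(affected)
    if grade.grade is Grade.TOO_DIFFICULT:
        return None, grade
    if affected == 0:
        return mask, grade
    return BinaryMask(mask.voxels & ~non_tumour, mask.spacing, mask.origin), grade


def ellipsoid_constrained_segment(
    pet: ScalarVolume,
    ellipsoid: Ellipsoid,
    fraction: float | None = None,
    suv_cut: float | None = None,
    with_info: bool = False,
):
    """Thresholding constrained to an ellipsoid VOI drawn around the tumour.

    SUVmax is searched inside the ellipsoid only, and the VOI is the
    26-connected component (within the ellipsoid) of the thresholded set
    containing the in-ellipsoid maximum voxel.  Exactly one of
    ``fraction`` / ``suv_cut`` must be given.  No post-hoc editing is
    applied - with this family of tools no manual adjustment of the
    final contour is possible.
    """
    if (fraction is None) == (suv_cut is None):
        raise ValueError("give exactly one of fraction or suv_cut")
    inside = ellipsoid.contains_grid(pet)
    if not inside.any():
        raise SegmentationError("the ellipsoid contains no voxel centre")
    vals = pet.values
    flat = np.where(inside, vals, -np.inf)
    anchor = np.unravel_index(int(np.argmax(flat)), vals.shape)
    suvmax = float(vals[anchor])
    if fraction is not None:
        if not (0.0 < fraction <= 1.0):
            raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
        if suvmax <= 0:
            raise SegmentationError("no uptake inside the ellipsoid")
        thr = fraction * suvmax
        binary = inside & (vals >= thr)
    else:
        thr = float(suv_cut)
        if suvmax <= thr:
            raise SegmentationError(f"no voxel above the cut {suv_cut} inside the ellipsoid")
        binary = inside & (vals > thr)
    mask = BinaryMask(_component(binary, anchor), pet.spacing, pet.origin)
    if with_info:
        return mask, {"suvmax": suvmax, "threshold": thr, "anchor": anchor}
    return mask


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (golden-spiral sampling)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _hill_climb(values: np.ndarray, seed, max_moves: int = 10_000):
    """Move a seed to a 26-neighbourhood local maximum."""
    pos = tuple(seed)
    shape = values.shape
    for _ in range(max_moves):
        sl = tuple(slice(max(p - 1, 0), min(p + 2, n)) for p, n in zip(pos, shape))
        neigh = values[sl]
        off = np.unravel_index(int(np.argmax(neigh)), neigh.shape)
        cand = tuple(s.start + o for s, o in zip(sl, off))
        if values[cand] <= values[pos]:
            return pos
        pos = cand
    return pos  # pragma: no cover - pathological ramp


def _refine_parabolic(y: np.ndarray, j: int) -> float:
    """Sub-sample refinement of an extremum at index j of y."""
    if j <= 0 or j >= len(y) - 1:
        return float(j)
    denom = y[j - 1] - 2.0 * y[j] + y[j + 1]
    if abs(denom) < 1e-12:
        return float(j)
    off = 0.5 * (y[j - 1] - y[j + 1]) / denom
    return float(j) + float(np.clip(off, -0.5, 0.5))


def gradient_segment(
    pet: ScalarVolume,
    seed,
    n_directions: int = 200,
    continuity_window: int = 8,
    step_voxels: float = 0.5,
    profile_sigma_voxels: float = 0.5,
    psf_fwhm_mm: float = 5.0,
    max_radius_mm: float = 150.0,
) -> BinaryMask:
    """Automated radial-gradient delineation.

    Rays are cast from the local uptake peak over a quasi-uniform sphere
    sampling; the SUV profile along each ray is sampled by trilinear
    interpolation at sub-voxel steps and lightly smoothed; each ray's
    boundary radius is the arg-max of the absolute radial derivative
    beyond the profile peak (with parabolic sub-sample refinement); and
    edge continuity is enforced by twice replacing every radius with the
    median over its ``continuity_window`` nearest directions.  The VOI
    contains the voxels whose centre lies inside the resulting
    star-shaped surface.

    For a blurred convex boundary the radial derivative peaks inward of
    the true edge by approximately ``sigma**2 / r`` (a partial-volume
    curvature effect); each radius is compensated to first order using
    the known reconstruction PSF (``psf_fwhm_mm``, default 5 mm) plus
    the profile pre-smoothing width.
    """
    if n_directions < 50:
        raise ValueError(f"n_directions must be >= 50, got {n_directions}")
    seed = _check_seed(pet, seed)
    vals = pet.values
    if float(np.ptp(vals)) == 0.0:
        raise GradientError("uniform image: no gradient to detect")

    peak = _hill_climb(vals, seed)
    # rays start from the centroid of the connected near-peak region, so
    # flat-topped peaks give the same origin whichever tie the climb hits
    plateau = _component(vals >= 0.995 * vals[peak], peak)
    center = pet.voxel_to_mm(np.argwhere(plateau).mean(axis=0))
    dirs = _fibonacci_sphere(n_directions)
    step_mm = step_voxels * min(pet.spacing)
    n_steps = int(max_radius_mm / step_mm) + 1
    r = np.arange(n_steps) * step_mm

    # sample points in voxel coordinates, flag out-of-grid samples
    pts = center[None, None, :] + r[None, :, None] * dirs[:, None, :]
    vox = (pts - np.asarray(pet.origin)) / np.asarray(pet.spacing)
    upper = np.asarray(vals.shape, float) - 1.0
    in_grid = np.all((vox >= 0.0) & (vox <= upper), axis=2)
    n_valid = np.where(in_grid.all(axis=1), n_steps, np.argmin(in_grid, axis=1))
    profiles = ndimage.map_coordinates(
        vals, vox.reshape(-1, 3).T.clip(0, upper[:, None]), order=1, mode="nearest"
    ).reshape(n_directions, n_steps)

    sigma_samples = profile_sigma_voxels / step_voxels
    radii = np.empty(n_directions)
    for d in range(n_directions):
        nv = int(n_valid[d])
        if nv < 5:
            raise GradientError("ray exits the grid before an edge can be found")
        prof = ndimage.gaussian_filter1d(profiles[d, :nv], sigma_samples, mode="nearest")
        peak_idx = int(np.argmax(prof))
        if peak_idx >= nv - 2:
            raise GradientError("ray exits the grid before an edge can be found")
        # the edge belongs to this lesion: stop the search where the
        # profile rebounds after its descent (the valley before an
        # adjacent structure), so a hotter neighbour's edge is not taken
        stop = nv
        running_min = prof[peak_idx]
        total_drop = prof[peak_idx] - prof[peak_idx:].min()
        for j in range(peak_idx + 1, nv):
            running_min = min(running_min, prof[j])
            drop = prof[peak_idx] - running_min
            if drop > 0.2 * total_drop and prof[j] > running_min + 0.1 * drop:
                stop = j
                break
        deriv = np.gradient(prof, step_mm)
        mag = np.abs(deriv)
        search = mag.copy()
        search[: peak_idx + 1] = -np.inf
        search[stop:] = -np.inf
        j = int(np.argmax(search))
        radii[d] = _refine_parabolic(mag, j) * step_mm

    # first-order curvature compensation for the blur-induced inward shift
    sigma_psf = psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_tot2 = sigma_psf**2 + (profile_sigma_voxels * min(pet.spacing)) ** 2
    radii = radii + sigma_tot2 / np.maximum(radii, np.sqrt(sigma_tot2))

    # continuity of the tumour edge: median over nearest directions, twice
    order = np.argsort(-(dirs @ dirs.T), axis=1)[:, :continuity_window]
    for _ in range(2):
        radii = np.median(radii[order], axis=1)

    # rasterise the star-shaped surface
    rmax = float(radii.max())
    origin = np.asarray(pet.origin, float)
    spacing = np.asarray(pet.spacing, float)
    lo = np.maximum(np.floor((center - rmax - origin) / spacing).astype(int) - 1, 0)
    hi = np.minimum(
        np.ceil((center + rmax - origin) / spacing).astype(int) + 2,
        np.asarray(vals.shape),
    )
    sub_axes = [
        (pet.origin[a] + pet.spacing[a] * np.arange(lo[a], hi[a])) - center[a]
        for a in range(3)
    ]
    dx = sub_axes[0][:, None, None]
    dy = sub_axes[1][None, :, None]
    dz = sub_axes[2][None, None, :]
    dist = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        units = np.stack(np.broadcast_arrays(dx, dy, dz), axis=-1) / dist[..., None]
    units[dist == 0] = np.array([0.0, 0.0, 1.0])
    _, nearest = cKDTree(dirs).query(units.reshape(-1, 3))
    inside_sub = dist.reshape(-1) <= radii[nearest]
    inside_sub = inside_sub.reshape(dist.shape)

    voxels = np.zeros(vals.shape, dtype=bool)
    voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside_sub
    return BinaryMask(voxels, pet.spacing, pet.origin)
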