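"""Synthetic pelvic PET phantoms with ground-truth labels.

The generator emulates the statistical structure of a pre-treatment
cervical-cancer staging cohort: a lobulated ellipsoidal primary tumour
near the grid centre, an adjacent high-uptake bladder separated by a
small tissue gap, optional central necrosis, reconstruction blur
(isotropic Gaussian point-spread function, default 5 mm FWHM as in
ordered-subset reconstructions), and additive post-reconstruction
Gaussian noise in SUV units.  Cohort sampling targets the published
population: MRI tumour volumes log-normal with mean 85.4 ml (SD
69.8 ml), SUVmax normal 15.1 +/- 6.9 truncated at 3, necrosis in 35/81
of tumours, and tumours below 5 ml excluded.

Ground-truth labels are the unblurred rasterised shapes; the necrotic
core carries the tumour label (necrosis counts as tumour in reference
volumes).  Two simulated "readers" are derived from each phantom: reader
1 uses canonical inputs (click at the tumour centre, bounding ellipsoid
with a margin), reader 2 uses jittered inputs - the only source of
inter-reader variance in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import Ellipsoid
from .volumes import BLADDER_LABEL, OTHER_LABEL, TUMOUR_LABEL, LabelVolume, ScalarVolume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "ReaderPerturbation",
    "PhantomGeometryError",
    "make_phantom",
    "rasterize_truth",
    "draw_specs",
    "make_cohort",
    "canonical_reader_inputs",
    "perturb_reader_inputs",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PhantomGeometryError(ValueError):
    """The requested phantom geometry is not realisable."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic case (all lengths in mm)."""

    tumour_center: tuple[float, float, float] = (144.0, 170.0, 144.0)
    tumour_semiaxes: tuple[float, float, float] = (27.3, 27.3, 27.3)
    lobulation_amplitude: float = 0.0
    necrotic_core_fraction: float = 0.0
    tumour_suv: float = 15.1
    necrosis_suv: float = 2.0
    background_suv: float = 1.5
    bladder_center: tuple[float, float, float] | None = None
    bladder_semiaxes: tuple[float, float, float] = (30.0, 35.0, 38.0)
    bladder_suv: float = 20.0
    bowel_centers: tuple[tuple[float, float, float], ...] = ()
    bowel_semiaxes: tuple[tuple[float, float, float], ...] = ()
    bowel_suvs: tuple[float, ...] = ()
    gap_mm: float = 6.0
    psf_fwhm_mm: float = 5.0
    noise_sd_suv: float = 0.5
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.lobulation_amplitude <= 0.5):
            raise ValueError("lobulation_amplitude must lie in [0, 0.5]")
        if not (0.0 <= self.necrotic_core_fraction <= 0.8):
            raise ValueError("necrotic_core_fraction must lie in [0, 0.8]")
        for name in ("tumour_suv", "bladder_suv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("necrosis_suv", "background_suv", "psf_fwhm_mm", "noise_sd_suv", "gap_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tumour_suv <= self.background_suv:
            raise ValueError("tumour_suv must exceed background_suv")
        if any(a <= 0 for a in self.tumour_semiaxes) or any(a <= 0 for a in self.bladder_semiaxes):
            raise ValueError("semiaxes must be positive")
        if not (len(self.bowel_centers) == len(self.bowel_semiaxes) == len(self.bowel_suvs)):
            raise ValueError("bowel_centers, bowel_semiaxes and bowel_suvs must align")
        if any(s < 0 for s in self.bowel_suvs):
            raise ValueError("bowel_suvs must be >= 0")
        if self.bladder_center is None:
            # default geometry: bladder anterior to the tumour (along -y),
            # its surface gap_mm away from the worst-case tumour surface
            tc = self.tumour_center
            off = (
                (1.0 + self.lobulation_amplitude) * self.tumour_semiaxes[1]
                + self.gap_mm
                + self.bladder_semiaxes[1]
            )
            object.__setattr__(self, "bladder_center", (tc[0], tc[1] - off, tc[2]))
        else:
            object.__setattr__(self, "bladder_center", tuple(float(c) for c in self.bladder_center))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Grid physical extent."""
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing))


class _TumourShape:
    """Lobulated ellipsoid: radius modulated by a smooth angular field.

    The modulation is a random low-order combination of degree-2
    solid-harmonic terms, normalised to unit maximum so that
    ``lobulation_amplitude`` is the peak fractional radial perturbation.
    Coefficients derive deterministically from the phantom seed.
    """

    def __init__(self, spec: PhantomSpec):
        self.center = np.asarray(spec.tumour_center, float)
        self.semiaxes = np.asarray(spec.tumour_semiaxes, float)
        self.amplitude = spec.lobulation_amplitude
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), 11]))
        self.coeffs = rng.normal(size=5)
        if self.amplitude > 0:
            probe = _fibonacci_dirs(2048)
            self._norm = float(np.abs(self._raw(probe)).max())
        else:
            self._norm = 1.0

    def _raw(self, u: np.ndarray) -> np.ndarray:
        ux, uy, uz = u[..., 0], u[..., 1], u[..., 2]
        c = self.coeffs
        return (
            c[0] * ux * uy
            + c[1] * uy * uz
            + c[2] * uz * ux
            + c[3] * (ux ** 2 - uy ** 2)
            + c[4] * 0.5 * (3.0 * uz ** 2 - 1.0)
        )

    def modulation(self, u: np.ndarray) -> np.ndarray:
        if self.amplitude == 0:
            return np.zeros(u.shape[:-1])
        return self.amplitude * self._raw(u) / self._norm

    def radius_factor(self, u: np.ndarray) -> np.ndarray:
        """1 + A*f(u): local fractional radius along direction u."""
        return 1.0 + self.modulation(u)

    def contains_points(self, points: np.ndarray, core_fraction: float | None = None) -> np.ndarray:
        """Membership test for an (..., 3) array of mm points."""
        d = np.asarray(points, float) - self.center
        rho = np.sqrt(((d / self.semiaxes) ** 2).sum(axis=-1))
        r = np.sqrt((d ** 2).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            u = d / r[..., None]
        factor = np.where(r > 0, self.radius_factor(np.nan_to_num(u)), 1.0)
        limit = factor if core_fraction is None else core_fraction * factor
        return rho <= limit

    def max_extent(self) -> np.ndarray:
        return (1.0 + self.amplitude) * self.semiaxes


def _fibonacci_dirs(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _grid_points(shape, spacing, origin) -> np.ndarray:
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    x = axes[0][:, None, None, None]
    y = axes[1][None, :, None, None]
    z = axes[2][None, None, :, None]
    zeros = np.zeros(shape)
    return np.stack(
        [x[..., 0] + zeros, y[..., 0] + zeros, z[..., 0] + zeros], axis=-1
    )


def _ellipsoid_grid(shape, spacing, origin, center, semiaxes) -> np.ndarray:
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    x = ((axes[0] - center[0]) / semiaxes[0]) ** 2
    y = ((axes[1] - center[1]) / semiaxes[1]) ** 2
    z = ((axes[2] - center[2]) / semiaxes[2]) ** 2
    return x[:, None, None] + y[None, :, None] + z[None, None, :] <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, LabelVolume]:
    """Render a phantom: PET image in SUV units plus ground-truth labels.

    Pipeline: rasterise the shapes at voxel centres, assign SUVs (the
    necrotic core at ``necrosis_suv``), convolve with the isotropic
    Gaussian PSF, add i.i.d. Gaussian noise and clip at zero.  The label
    volume holds the unblurred truth and is unaffected by PSF/noise
    settings.  Identical spec (including seed) gives bit-identical
    output.
    """
    from scipy import ndimage

    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.spacing)
    origin = (0.0, 0.0, 0.0)

    tumour = _TumourShape(spec)
    ext = tumour.max_extent()
    lo_corner = tumour.center - ext
    hi_corner = tumour.center + ext
    if np.any(lo_corner < 0) or np.any(hi_corner > np.asarray(spec.extent_mm)):
        raise PhantomGeometryError("tumour extends outside the grid")

    pts = _grid_points(shape, spacing, origin)
    tumour_mask = tumour.contains_points(pts)
    core_mask = (
        tumour.contains_points(pts, core_fraction=spec.necrotic_core_fraction)
        if spec.necrotic_core_fraction > 0
        else np.zeros(shape, bool)
    )
    bladder_mask = _ellipsoid_grid(
        shape, spacing, origin, spec.bladder_center, spec.bladder_semiaxes
    )
    if (tumour_mask & bladder_mask).any():
        raise PhantomGeometryError("tumour and bladder interiors overlap before blurring")

    img = np.full(shape, spec.background_suv, dtype=float)
    img[tumour_mask] = spec.tumour_suv
    img[core_mask] = spec.necrosis_suv
    img[bladder_mask] = spec.bladder_suv

    other_mask = np.zeros(shape, bool)
    for b_center, b_semi, b_suv in zip(spec.bowel_centers, spec.bowel_semiaxes, spec.bowel_suvs):
        blob = _ellipsoid_grid(shape, spacing, origin, b_center, b_semi)
        if (blob & (tumour_mask | bladder_mask)).any():
            raise PhantomGeometryError("bowel structure overlaps tumour or bladder")
        img[blob] = b_suv
        other_mask |= blob

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in spacing]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd_suv > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), 23]))
        img = img + rng.normal(0.0, spec.noise_sd_suv, size=shape)
    img = np.clip(img, 0.0, None)

    labels = np.zeros(shape, dtype=np.int16)
    labels[tumour_mask] = TUMOUR_LABEL
    labels[bladder_mask] = BLADDER_LABEL
    labels[other_mask] = OTHER_LABEL
    return (
        ScalarVolume(img, spacing, origin),
        LabelVolume(labels.astype(np.int64), spacing, origin),
    )


def rasterize_truth(
    spec: PhantomSpec,
    spacing: tuple[float, float, float] = (1.25, 1.25, 1.25),
    margin_mm: float = 8.0,
) -> LabelVolume:
    """Rasterise the ground-truth tumour alone on a fine grid.

    Used to emulate the high-resolution MRI frame the reference volume
    is measured on (the PET grid is too coarse for 5 mm slice slabs).
    The grid covers the tumour bounding box plus a margin.
    """
    spacing = tuple(float(s) for s in spacing)
    tumour = _TumourShape(spec)
    ext = tumour.max_extent() + margin_mm
    lo = tumour.center - ext
    shape = tuple(int(np.ceil(2 * e / s)) + 1 for e, s in zip(ext, spacing))
    pts = _grid_points(shape, spacing, tuple(lo))
    labels = tumour.contains_points(pts).astype(np.int64) * TUMOUR_LABEL
    return LabelVolume(labels, spacing, tuple(float(v) for v in lo))


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distributions for a synthetic cohort.

    Defaults reproduce the published cohort statistics: log-normal MRI
    volumes (mean 85.4 ml, SD 69.8 ml) truncated to [5, 450] ml,
    truncated-normal SUVmax 15.1 +/- 6.9 (minimum 3), necrosis
    prevalence 35/81, bladder SUV uniform on [8, 30] so that urinary
    activity frequently exceeds the tumour threshold levels.
    """

    n_cases: int = 0
    volume_mean_ml: float = 85.4
    volume_sd_ml: float = 69.8
    min_volume_ml: float = 5.0
    max_volume_ml: float = 450.0
    suvmax_mean: float = 15.1
    suvmax_sd: float = 6.9
    suvmax_min: float = 3.0
    necrosis_prevalence: float = 35.0 / 81.0
    bladder_suv_range: tuple[float, float] = (8.0, 30.0)
    lobulation_range: tuple[float, float] = (0.05, 0.25)
    necrotic_fraction_range: tuple[float, float] = (0.25, 0.55)
    gap_mm: float = 6.0
    psf_fwhm_mm: float = 5.0
    noise_sd_suv: float = 0.5
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    master_seed: int = 0

    def __post_init__(self):
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if not (0.0 <= self.necrosis_prevalence <= 1.0):
            raise ValueError("necrosis_prevalence must lie in [0, 1]")
        for name in ("volume_mean_ml", "volume_sd_ml", "suvmax_mean", "suvmax_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite")


def _draw_case_spec(cohort: CohortSpec, rng: np.random.Generator) -> PhantomSpec:
    extent = np.asarray([n * s for n, s in zip(cohort.grid_shape, cohort.spacing)])
    t_center = np.array([extent[0] / 2, extent[1] * 0.59, extent[2] / 2])

    # log-normal volume matched to the cohort mean/SD, truncated to range
    sigma2 = np.log(1.0 + (cohort.volume_sd_ml / cohort.volume_mean_ml) ** 2)
    mu = np.log(cohort.volume_mean_ml) - sigma2 / 2.0
    for _ in range(1000):
        vol_ml = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if cohort.min_volume_ml <= vol_ml <= cohort.max_volume_ml:
            break
    else:  # pragma: no cover
        raise RuntimeError("volume sampling failed")

    r0 = 10.0 * (3.0 * vol_ml / (4.0 * np.pi)) ** (1.0 / 3.0)  # ml -> mm radius
    g = rng.uniform(0.75, 1.3, size=3)
    g /= g.prod() ** (1.0 / 3.0)
    semiaxes = tuple(float(v) for v in r0 * g)

    lob = float(rng.uniform(*cohort.lobulation_range))
    has_necrosis = bool(rng.random() < cohort.necrosis_prevalence)
    core_frac = float(rng.uniform(*cohort.necrotic_fraction_range)) if has_necrosis else 0.0
    necrosis_suv = float(rng.uniform(1.0, 2.5))

    for _ in range(1000):
        suvmax = float(rng.normal(cohort.suvmax_mean, cohort.suvmax_sd))
        if suvmax >= cohort.suvmax_min:
            break
    else:  # pragma: no cover
        raise RuntimeError("SUVmax sampling failed")

    b_semiaxes = tuple(
        float(v) for v in np.array([30.0, 35.0, 38.0]) * rng.uniform(0.85, 1.15, size=3)
    )
    b_xz_jitter = rng.uniform(-10.0, 10.0, size=2)
    b_y = t_center[1] - ((1.0 + lob) * semiaxes[1] + cohort.gap_mm + b_semiaxes[1])
    b_center = (
        float(t_center[0] + b_xz_jitter[0]),
        float(b_y),
        float(t_center[2] + b_xz_jitter[1]),
    )

    rng_seed = int(rng.integers(0, 2**31 - 1))
    shape_probe = _TumourShape(
        PhantomSpec(
            tumour_center=tuple(float(v) for v in t_center),
            tumour_semiaxes=semiaxes,
            lobulation_amplitude=lob,
            tumour_suv=suvmax,
            grid_shape=cohort.grid_shape,
            spacing=cohort.spacing,
            rng_seed=rng_seed,
        )
    )
    bowel_c, bowel_s, bowel_u = [], [], []

    # a urine-hot ureter segment lateral to the tumour in most cases: at
    # low thresholds the blurred tumour boundary bridges the few-mm gap
    # and the contour runs up the tube, producing the major (and some
    # too-difficult) manual-adjustment burden seen clinically
    bladder_suv = float(rng.uniform(*cohort.bladder_suv_range))
    if rng.random() < 0.6:
        for _ in range(8):
            side = 1.0 if rng.random() < 0.5 else -1.0
            semi = np.array(
                [rng.uniform(4.0, 6.0), rng.uniform(4.0, 6.0), rng.uniform(15.0, 50.0)]
            )
            off_x = side * ((1.0 + lob) * semiaxes[0] + rng.uniform(4.0, 12.0) + semi[0])
            c = t_center + np.array(
                [off_x, rng.uniform(-15.0, 15.0), rng.uniform(-10.0, 30.0)]
            )
            if not (semi[2] + 6.0 < c[2] < extent[2] - semi[2] - 6.0):
                continue
            probe = c + 1.1 * semi * _fibonacci_dirs(128)
            if shape_probe.contains_points(probe).any():
                continue
            if (
                (((probe - np.asarray(b_center)) / np.asarray(b_semiaxes)) ** 2).sum(-1) < 1.0
            ).any():
                continue
            bowel_c.append(tuple(float(v) for v in c))
            bowel_s.append(tuple(float(v) for v in semi))
            bowel_u.append(float(bladder_suv * rng.uniform(0.6, 1.0)))
            break

    # one pericervical bowel loop in some cases: a mildly avid structure
    # just superior to the tumour that low-threshold contours spill into
    if rng.random() < 0.4:
        for _ in range(8):
            semi = rng.uniform(10.0, 20.0, size=3)
            off_z = (1.0 + lob) * semiaxes[2] + rng.uniform(6.0, 16.0) + semi[2]
            c = t_center + np.array(
                [rng.uniform(-12.0, 12.0), rng.uniform(-12.0, 12.0), off_z]
            )
            if c[2] + semi[2] > extent[2] - 6.0:
                continue
            probe = c + 1.1 * semi * _fibonacci_dirs(128)
            if shape_probe.contains_points(probe).any():
                continue
            if (
                (((probe - np.asarray(b_center)) / np.asarray(b_semiaxes)) ** 2).sum(-1) < 1.0
            ).any():
                continue
            bowel_c.append(tuple(float(v) for v in c))
            bowel_s.append(tuple(float(v) for v in semi))
            bowel_u.append(float(rng.uniform(1.8, 4.5)))
            break

    # distant bowel loops, one per superior-inferior stratum so that their
    # axial extents do not collapse onto the same slices: a runaway
    # auto-contour that floods the soft-tissue background sweeps them all
    # up across well over twenty slices, driving the too-difficult grade
    # exactly as runaway volumes did clinically
    t_clear = (1.0 + lob) * max(semiaxes)
    for z_low in (158.0, 190.0, 222.0, 254.0):
        for _ in range(12):
            c = np.array(
                [
                    rng.uniform(40.0, extent[0] - 40.0),
                    rng.uniform(60.0, extent[1] - 40.0),
                    z_low + rng.uniform(0.0, 8.0),
                ]
            )
            semi = rng.uniform(14.0, 24.0, size=3)
            if c[2] + semi[2] > extent[2] - 4.0:
                semi[2] = extent[2] - 4.0 - c[2]
            if semi[2] < 10.0:
                continue
            m = float(semi.max())
            if np.linalg.norm(c - t_center) < t_clear + m + 5.0:
                continue
            if np.linalg.norm(c - np.asarray(b_center)) < max(b_semiaxes) + m + 5.0:
                continue
            if any(
                np.linalg.norm(c - np.asarray(pc)) < max(ps) + m + 5.0
                for pc, ps in zip(bowel_c, bowel_s)
            ):
                continue
            bowel_c.append(tuple(float(v) for v in c))
            bowel_s.append(tuple(float(v) for v in semi))
            bowel_u.append(float(rng.uniform(2.6, 4.5)))
            break

    return PhantomSpec(
        tumour_center=tuple(float(v) for v in t_center),
        tumour_semiaxes=semiaxes,
        lobulation_amplitude=lob,
        necrotic_core_fraction=core_frac,
        tumour_suv=suvmax,
        necrosis_suv=necrosis_suv,
        bladder_center=b_center,
        bladder_semiaxes=b_semiaxes,
        bladder_suv=bladder_suv,
        bowel_centers=tuple(bowel_c),
        bowel_semiaxes=tuple(bowel_s),
        bowel_suvs=tuple(bowel_u),
        gap_mm=cohort.gap_mm,
        psf_fwhm_mm=cohort.psf_fwhm_mm,
        noise_sd_suv=cohort.noise_sd_suv,
        grid_shape=cohort.grid_shape,
        spacing=cohort.spacing,
        rng_seed=rng_seed,
    )


def _spec_fits(spec: PhantomSpec) -> bool:
    shape_ext = np.asarray(spec.extent_mm)
    tc = np.asarray(spec.tumour_center)
    te = (1.0 + spec.lobulation_amplitude) * np.asarray(spec.tumour_semiaxes)
    if np.any(tc - te < 0) or np.any(tc + te > shape_ext):
        return False
    bc = np.asarray(spec.bladder_center)
    be = np.asarray(spec.bladder_semiaxes)
    return bool(np.all(bc - be >= 0) and np.all(bc + be <= shape_ext))


def draw_specs(cohort: CohortSpec) -> list[PhantomSpec]:
    """Draw per-case phantom specs; deterministic in ``master_seed``.

    Cases whose true volume falls below the exclusion limit (5 ml) or
    whose geometry does not fit the grid are rejected and redrawn.
    """
    specs: list[PhantomSpec] = []
    for i in range(cohort.n_cases):
        rng = np.random.default_rng(np.random.SeedSequence([int(cohort.master_seed), i]))
        for _ in range(100):
            spec = _draw_case_spec(cohort, rng)
            if _spec_fits(spec):
                specs.append(spec)
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not draw a feasible phantom for case {i}")
    return specs


def make_cohort(
    cohort: CohortSpec, render: bool = True
) -> list[tuple[PhantomSpec, ScalarVolume | None, LabelVolume | None]]:
    """Sample a cohort and (optionally) render every phantom."""
    out = []
    for spec in draw_specs(cohort):
        if render:
            pet, labels = make_phantom(spec)
        else:
            pet = labels = None
        out.append((spec, pet, labels))
    return out


@dataclass(frozen=True)
class ReaderPerturbation:
    """Simulated second observer: jittered click and constraining ellipsoid."""

    seed_jitter_mm: float = 2.0
    ellipsoid_jitter: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.seed_jitter_mm < 0 or self.ellipsoid_jitter < 0:
            raise ValueError("jitters must be >= 0")


def canonical_reader_inputs(spec: PhantomSpec) -> tuple[np.ndarray, Ellipsoid]:
    """Reader 1's inputs: click at the tumour centre, bounding ellipsoid.

    The ellipsoid is the tumour's bounding ellipsoid with a 30% margin.
    Observers draw the isocontour to avoid adjacent physiologic
    structures, so along any axis where a structure (bladder, bowel,
    ureter) sits close by, the margin is capped to reach only 60% of the
    way across the gap between the tumour surface and that structure.
    """
    tumour = _TumourShape(spec)
    extents = tumour.max_extent()
    margins = 0.3 * extents
    t_center = np.asarray(spec.tumour_center, float)
    structures = [(np.asarray(spec.bladder_center, float), np.asarray(spec.bladder_semiaxes, float))]
    structures += [
        (np.asarray(c, float), np.asarray(s, float))
        for c, s in zip(spec.bowel_centers, spec.bowel_semiaxes)
    ]
    for s_center, s_semi in structures:
        offset = s_center - t_center
        axis = int(np.argmax(np.abs(offset) - extents - s_semi))
        gap = abs(offset[axis]) - extents[axis] - s_semi[axis]
        if gap < margins[axis]:
            margins[axis] = min(margins[axis], 0.6 * max(gap, 0.0))
    ell = Ellipsoid(
        center=tuple(float(c) for c in t_center),
        semiaxes=tuple(float(e) for e in extents + margins),
    )
    return t_center, ell


def perturb_reader_inputs(
    spec: PhantomSpec, pert: ReaderPerturbation
) -> tuple[np.ndarray, Ellipsoid]:
    """Reader 2's inputs: canonical inputs with deterministic jitter.

    The click is displaced uniformly within ``+/- seed_jitter_mm`` per
    axis (redrawn until it stays inside the true tumour); the ellipsoid
    centre and semiaxes receive fractional jitter of ``ellipsoid_jitter``.
    Zero jitter reproduces reader 1 exactly.
    """
    seed1, ell1 = canonical_reader_inputs(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(pert.rng_seed), 37]))
    tumour = _TumourShape(spec)
    j = pert.seed_jitter_mm
    seed2 = None
    for _ in range(200):
        cand = seed1 + rng.uniform(-j, j, size=3)
        if tumour.contains_points(cand[None, :])[0]:
            seed2 = cand
            break
    if seed2 is None:
        raise ValueError("jittered seed left the tumour; reduce seed_jitter_mm")
    e = pert.ellipsoid_jitter
    semi1 = np.asarray(ell1.semiaxes)
    center2 = np.asarray(ell1.center) + rng.uniform(-e, e, size=3) * semi1
    semi2 = semi1 * (1.0 + rng.uniform(-e, e, size=3))
    return seed2, Ellipsoid(tuple(float(c) for c in center2), tuple(float(s) for s in semi2))
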