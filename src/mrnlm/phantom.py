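"""Digital Jaszczak phantom and pseudo-reconstruction emulator.

The Jaszczak quality-control phantom is a water-filled cylinder (radius
100 mm, height 180 mm) holding six fillable spheres of graded diameter.
Here the spheres carry 18.4 kBq/ml against a 3.6 kBq/ml background (5:1
contrast) on a 2 x 2 x 3 mm grid, matching a standard hot-sphere protocol.

Because actual tomographic reconstruction is out of scope, multiple
iterative reconstructions of the same acquisition are *emulated*: each
pseudo-reconstruction is the noiseless phantom blurred by a point-spread
function and corrupted by spatially correlated Gaussian noise. The blur
and noise magnitude scale with the effective iteration number
(iterations x subsets) relative to a reference of 42 (the 2i:21s clinical
default), qualitatively reproducing the convergence-versus-noise trade-off
of ordered-subset reconstruction: more effective iterations give sharper
but noisier images. Distinct realisation seeds give independent noise on
identical structure, which is exactly what the multiple-reconstruction
filters exploit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import MultiReconSet, Volume
from .errors import GeometryError, ParameterError
from .filters import gaussian_filter
from .metrics import VOIPair

__all__ = [
    "PhantomSpec",
    "ReconSetting",
    "EmulationParams",
    "DEFAULT_TARGET_SETTING",
    "DEFAULT_AUX_SETTINGS",
    "build_phantom",
    "sphere_masks",
    "emulate_reconstruction",
    "generate_dataset",
    "sphere_and_background_masks",
    "masks_to_labels",
    "vois_from_labels",
]


@dataclass(frozen=True)
class ReconSetting:
    """An (iterations, subsets) pair identifying one pseudo-reconstruction."""

    iterations: int
    subsets: int

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.subsets < 1:
            raise ParameterError(
                f"iterations and subsets must be positive, got "
                f"{self.iterations}i:{self.subsets}s"
            )

    @property
    def effective_iterations(self) -> int:
        """iterations x subsets, the usual convergence index of OSEM."""
        return self.iterations * self.subsets

    @property
    def label(self) -> str:
        return f"{self.iterations}i:{self.subsets}s"


DEFAULT_TARGET_SETTING = ReconSetting(2, 21)

#: the twelve auxiliary iteration/subset pairs with effective iteration
#: numbers bracketing the 2i:21s target (subsets divide 168)
DEFAULT_AUX_SETTINGS: tuple[ReconSetting, ...] = tuple(
    ReconSetting(i, s)
    for i, s in [
        (2, 24), (2, 28), (3, 14), (3, 12), (3, 21), (4, 12),
        (4, 8), (5, 8), (5, 7), (5, 6), (6, 7), (7, 6),
    ]
)


def _default_sphere_centers(diameters) -> tuple[tuple[float, float, float], ...]:
    # standard layout: spheres on a 55 mm circle in the central transaxial plane
    n = len(diameters)
    return tuple(
        (55.0 * math.cos(2 * math.pi * k / max(n, 1)),
         55.0 * math.sin(2 * math.pi * k / max(n, 1)),
         0.0)
        for k in range(n)
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and activities of the hot-sphere phantom.

    Distances in mm, activities in kBq/ml. ``sphere_centers_mm`` defaults to
    a 55 mm circle in the central plane, ordered like the diameters
    (smallest first). ``margin_mm`` pads the grid beyond the cylinder;
    ``bg_clearance_mm`` is the minimum distance kept between a background
    VOI and any sphere surface or the cylinder wall.
    """

    cylinder_radius_mm: float = 100.0
    cylinder_height_mm: float = 180.0
    sphere_diameters_mm: tuple[float, ...] = (11.89, 14.43, 17.69, 21.79, 26.82, 33.27)
    background_activity: float = 3.6
    sphere_activity: float = 18.4
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    sphere_centers_mm: tuple[tuple[float, float, float], ...] | None = None
    margin_mm: float = 4.0
    bg_clearance_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.cylinder_radius_mm <= 0 or self.cylinder_height_mm <= 0:
            raise GeometryError("cylinder dimensions must be positive")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ParameterError(f"voxel size must be positive, got {self.voxel_size_mm}")
        if self.background_activity < 0 or self.sphere_activity < 0:
            raise ParameterError("activities must be non-negative")
        diam = tuple(float(d) for d in self.sphere_diameters_mm)
        if diam and self.sphere_activity <= self.background_activity:
            raise ParameterError(
                "hot-sphere phantom needs sphere_activity > background_activity"
            )
        centers = (
            tuple(tuple(float(c) for c in ctr) for ctr in self.sphere_centers_mm)
            if self.sphere_centers_mm is not None
            else _default_sphere_centers(diam)
        )
        if len(centers) != len(diam):
            raise GeometryError(
                f"{len(centers)} sphere centres for {len(diam)} diameters"
            )
        R, H = self.cylinder_radius_mm, self.cylinder_height_mm
        for k, (c, d) in enumerate(zip(centers, diam)):
            r = d / 2.0
            if math.hypot(c[0], c[1]) + r >= R or abs(c[2]) + r >= H / 2.0:
                raise GeometryError(f"sphere {k} (d={d} mm at {c}) is not strictly inside the cylinder")
        for (i, j) in itertools.combinations(range(len(diam)), 2):
            dist = math.dist(centers[i], centers[j])
            if dist < diam[i] / 2.0 + diam[j] / 2.0:
                raise GeometryError(f"spheres {i} and {j} overlap (centre distance {dist:.1f} mm)")
        object.__setattr__(self, "sphere_diameters_mm", diam)
        object.__setattr__(self, "sphere_centers_mm", centers)
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        dx, dy, dz = self.voxel_size_mm
        nx = int(math.ceil(2.0 * (self.cylinder_radius_mm + self.margin_mm) / dx))
        ny = int(math.ceil(2.0 * (self.cylinder_radius_mm + self.margin_mm) / dy))
        nz = int(math.ceil((self.cylinder_height_mm + 2.0 * self.margin_mm) / dz))
        return nx, ny, nz

    def voxel_centers(self):
        """Physical coordinates of voxel centres along each axis (mm,
        origin at the cylinder centre)."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.grid_shape, self.voxel_size_mm)
        )


def _coordinate_grids(spec: PhantomSpec):
    x, y, z = spec.voxel_centers()
    return x[:, None, None], y[None, :, None], z[None, None, :]


def sphere_masks(spec: PhantomSpec) -> list[np.ndarray]:
    """Boolean voxel-centre-in-sphere mask for each sphere."""
    X, Y, Z = _coordinate_grids(spec)
    masks = []
    for (cx, cy, cz), d in zip(spec.sphere_centers_mm, spec.sphere_diameters_mm):
        r2 = (d / 2.0) ** 2
        masks.append((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r2)
    return masks


def build_phantom(spec: PhantomSpec) -> Volume:
    """Noiseless phantom: sphere activity inside spheres, background inside
    the cylinder, zero outside. Voxel membership is decided by the voxel
    centre."""
    X, Y, Z = _coordinate_grids(spec)
    cylinder = (X ** 2 + Y ** 2 <= spec.cylinder_radius_mm ** 2) & (
        np.abs(Z) <= spec.cylinder_height_mm / 2.0
    )
    data = np.where(cylinder, spec.background_activity, 0.0)
    for mask in sphere_masks(spec):
        data[mask] = spec.sphere_activity
    return Volume(data, spec.voxel_size_mm)


@dataclass(frozen=True)
class EmulationParams:
    """Knobs of the pseudo-reconstruction emulator.

    ``psf_fwhm_mm`` is the base resolution blur at the reference effective
    iteration number; ``noise_sigma`` the base noise SD as a fraction of the
    background activity level (estimated as the median positive voxel of
    the noiseless volume). Noise is white Gaussian made spatially
    correlated by a ``noise_correlation_fwhm_mm`` Gaussian kernel, then
    rescaled to the requested SD. A setting with effective iterations E
    scales the noise by (E/ref)^noise_exponent and the blur by
    (ref/E)^blur_exponent: more effective iterations converge further
    (less blur) at the price of more noise. ``seed`` is the master seed
    from which per-realisation seeds are derived.
    """

    psf_fwhm_mm: float = 5.0
    noise_sigma: float = 0.13
    noise_correlation_fwhm_mm: float = 4.0
    effective_iteration_ref: int = 42
    noise_exponent: float = 0.5
    blur_exponent: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise ParameterError(f"psf_fwhm_mm must be >= 0, got {self.psf_fwhm_mm}")
        if self.noise_sigma < 0:
            raise ParameterError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.noise_correlation_fwhm_mm < 0:
            raise ParameterError("noise_correlation_fwhm_mm must be >= 0")
        if self.effective_iteration_ref < 1:
            raise ParameterError("effective_iteration_ref must be >= 1")


def emulate_reconstruction(
    truth: Volume,
    setting: ReconSetting,
    params: EmulationParams,
    realization_seed: int,
) -> Volume:
    """One pseudo-reconstruction: setting-dependent blur plus correlated
    noise, clipped at zero. Deterministic given (setting, params, seed)."""
    ratio = setting.effective_iterations / params.effective_iteration_ref
    blur_fwhm = params.psf_fwhm_mm * ratio ** (-params.blur_exponent)
    noise_scale = params.noise_sigma * ratio ** params.noise_exponent
    blurred = gaussian_filter(truth, blur_fwhm)
    if noise_scale == 0:
        return blurred
    positive = truth.data[truth.data > 0]
    ref_level = float(np.median(positive)) if positive.size else 1.0
    rng = np.random.default_rng(realization_seed)
    field_ = rng.standard_normal(truth.shape)
    if params.noise_correlation_fwhm_mm > 0:
        sigma_vox = [
            params.noise_correlation_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / s
            for s in truth.spacing
        ]
        field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox, mode="reflect")
    field_ /= field_.std()
    data = np.clip(blurred.data + noise_scale * ref_level * field_, 0.0, None)
    return Volume(data, truth.spacing)


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-realisation seed (< 2**31) split from the master seed."""
    state = np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def generate_dataset(
    spec: PhantomSpec,
    target_setting: ReconSetting | None = None,
    aux_settings=None,
    params: EmulationParams | None = None,
) -> MultiReconSet:
    """Target plus auxiliary pseudo-reconstructions of the same phantom.

    The target (index 0) and each auxiliary (index i+1) get distinct seeds
    split from ``params.seed``, so all noise realisations are independent
    while the whole set is bit-reproducible.
    """
    target_setting = target_setting or DEFAULT_TARGET_SETTING
    aux_settings = tuple(aux_settings) if aux_settings is not None else DEFAULT_AUX_SETTINGS
    params = params or EmulationParams()
    if not aux_settings:
        raise ParameterError("at least one auxiliary reconstruction setting is required")
    labels = [s.label for s in aux_settings]
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate auxiliary labels: {labels}")
    truth = build_phantom(spec)
    target = emulate_reconstruction(truth, target_setting, params, derive_seed(params.seed, 0))
    auxiliaries = tuple(
        emulate_reconstruction(truth, s, params, derive_seed(params.seed, i + 1))
        for i, s in enumerate(aux_settings)
    )
    return MultiReconSet(target=target, auxiliaries=auxiliaries, labels=tuple(labels))


# ---------------------------------------------------------------------------
# VOI construction


def _candidate_offsets(spec: PhantomSpec, max_dist_mm: float) -> np.ndarray:
    """Integer voxel offsets sorted by physical distance (then z, y, x):
    the deterministic scan order of the background-VOI search."""
    sx, sy, sz = spec.voxel_size_mm
    ax = np.arange(-int(max_dist_mm / sx), int(max_dist_mm / sx) + 1)
    ay = np.arange(-int(max_dist_mm / sy), int(max_dist_mm / sy) + 1)
    az = np.arange(-int(max_dist_mm / sz), int(max_dist_mm / sz) + 1)
    dx, dy, dz = np.meshgrid(ax, ay, az, indexing="ij")
    dx, dy, dz = dx.ravel(), dy.ravel(), dz.ravel()
    dist = np.sqrt((dx * sx) ** 2 + (dy * sy) ** 2 + (dz * sz) ** 2)
    keep = (dist > 0) & (dist <= max_dist_mm)
    dx, dy, dz, dist = dx[keep], dy[keep], dz[keep], dist[keep]
    order = np.lexsort((dx, dy, dz, dist))
    return np.stack([dx[order], dy[order], dz[order]], axis=1)


def sphere_and_background_masks(spec: PhantomSpec) -> list[VOIPair]:
    """One VOI pair per sphere: the sphere's voxel set, and the same voxel
    set translated to an all-background location.

    The background copy is placed by scanning integer-voxel translations in
    order of increasing physical distance and accepting the first one whose
    translated sphere stays ``bg_clearance_mm`` away from every sphere and
    from the cylinder boundary, and clear of previously placed background
    VOIs. First valid placement wins, so the layout is deterministic.
    """
    masks = sphere_masks(spec)
    R, H = spec.cylinder_radius_mm, spec.cylinder_height_mm
    clear = spec.bg_clearance_mm
    centers = spec.sphere_centers_mm
    radii = [d / 2.0 for d in spec.sphere_diameters_mm]
    spacing = spec.voxel_size_mm
    offsets = _candidate_offsets(spec, max_dist_mm=max(R, H / 2.0) * 1.5)
    placed: list[tuple[tuple[float, float, float], float]] = []
    pairs: list[VOIPair] = []
    for k, (mask, center, r) in enumerate(zip(masks, centers, radii)):
        chosen = None
        for off in offsets:
            c = tuple(center[a] + off[a] * spacing[a] for a in range(3))
            if math.hypot(c[0], c[1]) + r + clear > R:
                continue
            if abs(c[2]) + r + clear > H / 2.0:
                continue
            if any(
                math.dist(c, cj) < r + rj + clear for cj, rj in zip(centers, radii)
            ):
                continue
            if any(math.dist(c, cb) < r + rb + 1e-9 for cb, rb in placed):
                continue
            chosen = (off, c)
            break
        if chosen is None:
            raise GeometryError(f"no valid background placement found for sphere {k}")
        off, c = chosen
        idx = np.argwhere(mask) + np.asarray(off)
        bg = np.zeros_like(mask)
        bg[tuple(idx.T)] = True
        placed.append((c, r))
        pairs.append(VOIPair(signal_mask=mask, background_mask=bg, name=f"sphere{k + 1}"))
    return pairs


def masks_to_labels(vois, shape) -> np.ndarray:
    """Integer label volume: k for signal VOI k (1-based), 100+k for its
    background VOI."""
    labels = np.zeros(shape, dtype=np.int16)
    for k, voi in enumerate(vois, start=1):
        labels[voi.signal_mask] = k
        labels[voi.background_mask] = 100 + k
    return labels


def vois_from_labels(labels: np.ndarray) -> list[VOIPair]:
    """Rebuild VOI pairs from a label volume written by
    :func:`masks_to_labels`."""
    labels = np.asarray(labels)
    ks = sorted(int(v) for v in np.unique(labels) if 0 < v < 100)
    return [
        VOIPair(
            signal_mask=labels == k,
            background_mask=labels == 100 + k,
            name=f"sphere{k}",
        )
        for k in ks
    ]
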