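"""Denoising filters for 3-D emission-tomography volumes.

Implements the conventional non-local means (NLM) filter, its
multiple-reconstruction variant (MR-NLM), the plain auxiliary-image average,
and the Gaussian and bilateral baselines.

Non-local means replaces each voxel ``n`` by a weighted mean of candidate
voxels ``m``::

    V_n = (1/N_n) * sum_m f_m * exp(-||P(v_n) - P(v_m)||^2 / h^2)

where ``P(v)`` is the vector of intensities in the patch around a voxel,
``||.||^2`` the plain sum of squared differences over the patch, ``h`` the
smoothing parameter and ``N_n`` the sum of the weights. In the conventional
filter the candidates are all voxels of a spatial search window centred on
``n`` (clipped to the volume). In MR-NLM the search window is replaced by
the *co-located* patch in each auxiliary reconstruction of the same scene:
every auxiliary contributes exactly one candidate (its centre voxel at
``n``), weighted by the similarity of its patch to the target's patch.

Patch distances are computed on intensities normalised by the target
volume's global maximum so that ``h`` is comparable across acquisitions;
the weighted averaging itself is applied to the raw intensities. Patches
that extend past the volume border use reflect padding; candidate centres
are never taken outside the volume.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import MultiReconSet, Volume
from .errors import ParameterError, ShapeError

__all__ = [
    "PatchSpec",
    "NLMParams",
    "MRNLMParams",
    "BilateralParams",
    "patch_distance2",
    "nlm_weight",
    "nlm_filter",
    "mrnlm_filter",
    "mr_average",
    "gaussian_filter",
    "bilateral_filter",
]

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian kernel
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _check_radii(radius, what: str) -> tuple[int, int, int]:
    r = tuple(int(x) for x in radius)
    if len(r) != 3 or any(x < 0 for x in r) or any(x != y for x, y in zip(r, radius)):
        raise ParameterError(f"{what} must be three non-negative integers, got {radius!r}")
    return r


@dataclass(frozen=True)
class PatchSpec:
    """Per-axis patch half-width in voxels.

    The default ``(2, 2, 0)`` gives the 5x5 in-plane patch applied
    slice-independently within a 3-D volume; fully volumetric patches are
    obtained with a non-zero z radius.
    """

    radius: tuple[int, int, int] = (2, 2, 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "radius", _check_radii(self.radius, "patch radius"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(2 * r + 1 for r in self.radius)  # type: ignore[return-value]

    @property
    def size(self) -> int:
        """Number of voxels |v| in the patch."""
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class NLMParams:
    """Conventional NLM parameters: patch, smoothing h, and search window.

    ``h`` acts on max-normalised intensities; the default 0.3 is calibrated
    for noise around a few percent of the image maximum (see docs/methods.md).
    The default search window (5, 5, 1) spans 11x11x3 voxels.
    """

    h: float = 0.3
    patch: PatchSpec = field(default_factory=PatchSpec)
    search_radius: tuple[int, int, int] = (5, 5, 1)

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ParameterError(f"h must be > 0, got {self.h}")
        object.__setattr__(
            self, "search_radius", _check_radii(self.search_radius, "search radius")
        )


@dataclass(frozen=True)
class MRNLMParams:
    """MR-NLM parameters.

    ``include_target`` controls whether the target image contributes its own
    co-located patch (weight exp(0)=1) as one averaging term alongside the
    auxiliaries.
    """

    h: float = 0.3
    patch: PatchSpec = field(default_factory=PatchSpec)
    include_target: bool = True

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ParameterError(f"h must be > 0, got {self.h}")


@dataclass(frozen=True)
class BilateralParams:
    """Bilateral filter scales: spatial sigma in voxels, intensity sigma in
    max-normalised intensity units."""

    sigma_spatial: float = 3.8
    sigma_intensity: float = 0.35

    def __post_init__(self) -> None:
        if not (self.sigma_spatial > 0 and self.sigma_intensity > 0):
            raise ParameterError(
                f"bilateral sigmas must be > 0, got "
                f"({self.sigma_spatial}, {self.sigma_intensity})"
            )


# ---------------------------------------------------------------------------
# primitives


def _pad_reflect(data: np.ndarray, widths) -> np.ndarray:
    """Reflect-pad per axis ('edge' degenerates correctly for length-1 axes)."""
    out = data
    for ax, w in enumerate(widths):
        if w == 0:
            continue
        pad = [(0, 0)] * out.ndim
        pad[ax] = (w, w)
        mode = "reflect" if out.shape[ax] > 1 else "edge"
        out = np.pad(out, pad, mode=mode)
    return out


def _extract_patch(data: np.ndarray, center, radius) -> np.ndarray:
    padded = _pad_reflect(np.asarray(data, dtype=np.float64), radius)
    sl = tuple(slice(c, c + 2 * r + 1) for c, r in zip(center, radius))
    return padded[sl]


def patch_distance2(
    vol_a: Volume,
    center_a,
    vol_b: Volume,
    center_b,
    patch: PatchSpec,
) -> float:
    """Sum of squared intensity differences between two patches.

    Operates on the raw intensities of the two volumes; symmetric in its
    (volume, centre) arguments. Patches crossing a border use reflect
    padding.
    """
    if vol_a.spacing != vol_b.spacing:
        raise ShapeError(
            f"volumes have different spacings: {vol_a.spacing} vs {vol_b.spacing}"
        )
    for center, vol in ((center_a, vol_a), (center_b, vol_b)):
        c = tuple(int(x) for x in center)
        if len(c) != 3 or any(not (0 <= x < s) for x, s in zip(c, vol.shape)):
            raise IndexError(f"centre {center!r} outside volume of shape {vol.shape}")
    pa = _extract_patch(vol_a.data, tuple(int(x) for x in center_a), patch.radius)
    pb = _extract_patch(vol_b.data, tuple(int(x) for x in center_b), patch.radius)
    return float(np.sum((pa - pb) ** 2))


def nlm_weight(dist2: float, h: float) -> float:
    """Unnormalised NLM weight exp(-dist2 / h^2) in (0, 1].

    Normalisation over the candidate set is the caller's responsibility.
    Very large distances underflow to exactly 0.
    """
    if not h > 0:
        raise ParameterError(f"h must be > 0, got {h}")
    if dist2 < 0:
        raise ParameterError(f"squared distance must be >= 0, got {dist2}")
    with np.errstate(under="ignore"):
        return float(np.exp(-np.float64(dist2) / (np.float64(h) ** 2)))


def _intensity_scale(data: np.ndarray) -> float:
    m = float(data.max())
    return m if m > 0 else 1.0


def _patch_sum(arr: np.ndarray, radius, size: int) -> np.ndarray:
    """Box sum of `arr` over the patch window, same shape as `arr`."""
    if size == 1:
        return arr
    shape = tuple(2 * r + 1 for r in radius)
    return ndimage.uniform_filter(arr, size=shape, mode="constant") * size


def _clip_slices(d, shape):
    """Slices of the voxels n for which candidate n+d stays inside, and of
    the candidates themselves."""
    vsl = tuple(slice(max(0, -dd), n - max(0, dd)) for dd, n in zip(d, shape))
    csl = tuple(slice(s.start + dd, s.stop + dd) for s, dd in zip(vsl, d))
    return vsl, csl


# ---------------------------------------------------------------------------
# filters


def nlm_filter(vol: Volume, params: NLMParams) -> Volume:
    """Conventional non-local means over a clipped spatial search window.

    For every voxel the candidate set is the search window centred there,
    clipped to the volume; the self term carries its natural weight
    exp(0) = 1. Weights are computed on max-normalised intensities; the
    output is a convex combination of raw candidate intensities.
    """
    data = np.ascontiguousarray(vol.data, dtype=np.float64)
    rp = params.patch.radius
    rs = params.search_radius
    shape = data.shape
    scale = _intensity_scale(data)
    f = data / scale
    pad = tuple(p + s for p, s in zip(rp, rs))
    fpad = _pad_reflect(f, pad)
    # view of fpad equivalent to f padded by the patch radius only
    base = tuple(slice(s, s + n + 2 * p) for s, p, n in zip(rs, rp, shape))
    target_patches = fpad[base]
    crop = tuple(slice(p, p + n) for p, n in zip(rp, shape))
    h2 = params.h * params.h
    psize = params.patch.size
    num = np.zeros(shape)
    den = np.zeros(shape)
    offsets = itertools.product(*(range(-r, r + 1) for r in rs))
    for d in offsets:
        shifted = fpad[
            tuple(
                slice(s + dd, s + dd + n + 2 * p)
                for s, dd, n, p in zip(rs, d, shape, rp)
            )
        ]
        diff2 = (target_patches - shifted) ** 2
        dist2 = _patch_sum(diff2, rp, psize)[crop]
        vsl, csl = _clip_slices(d, shape)
        with np.errstate(under="ignore"):
            w = np.exp(-dist2[vsl] / h2)
        num[vsl] += w * (data[csl] - data[vsl])
        den[vsl] += w
    # den >= 1 (self term), but guard underflow pathologies anyway
    safe = np.where(den > 0, den, 1.0)
    out = data + np.where(den > 0, num / safe, 0.0)
    return Volume(out, vol.spacing)


def mrnlm_filter(recons: MultiReconSet, params: MRNLMParams) -> Volume:
    """Multiple-reconstruction NLM: candidates are the co-located patches of
    the auxiliary reconstructions.

    Auxiliary ``j`` contributes its centre-voxel intensity at ``n`` with
    weight ``exp(-||P_target(n) - P_aux_j(n)||^2 / h^2)``; when
    ``include_target`` is set the target's own voxel enters with weight 1.
    If every auxiliary weight underflows (and the target term is excluded),
    the output falls back to the target value.
    """
    if recons.n_aux == 0:
        raise ParameterError("MR-NLM requires at least one auxiliary volume")
    target = np.ascontiguousarray(recons.target.data, dtype=np.float64)
    rp = params.patch.radius
    shape = target.shape
    scale = _intensity_scale(target)
    tpad = _pad_reflect(target / scale, rp)
    crop = tuple(slice(p, p + n) for p, n in zip(rp, shape))
    h2 = params.h * params.h
    psize = params.patch.size
    num = np.zeros(shape)
    den = np.ones(shape) if params.include_target else np.zeros(shape)
    for aux in recons.auxiliaries:
        adata = np.ascontiguousarray(aux.data, dtype=np.float64)
        apad = _pad_reflect(adata / scale, rp)
        dist2 = _patch_sum((tpad - apad) ** 2, rp, psize)[crop]
        with np.errstate(under="ignore"):
            w = np.exp(-dist2 / h2)
        num += w * (adata - target)
        den += w
    safe = np.where(den > 0, den, 1.0)
    out = target + np.where(den > 0, num / safe, 0.0)
    return Volume(out, recons.target.spacing)


def mr_average(recons: MultiReconSet, include_target: bool = True) -> Volume:
    """Plain voxelwise mean of the auxiliaries (and the target when flagged).

    Equals :func:`mrnlm_filter` in the h -> infinity limit.
    """
    if recons.n_aux == 0:
        raise ParameterError("mr_average requires at least one auxiliary volume")
    stack = [np.asarray(a.data, dtype=np.float64) for a in recons.auxiliaries]
    if include_target:
        stack.append(np.asarray(recons.target.data, dtype=np.float64))
    return Volume(np.mean(stack, axis=0), recons.target.spacing)


def gaussian_filter(vol: Volume, fwhm_mm: float) -> Volume:
    """Isotropic-in-mm Gaussian smoothing; ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise ParameterError(f"FWHM must be >= 0, got {fwhm_mm}")
    data = np.ascontiguousarray(vol.data, dtype=np.float64)
    if fwhm_mm == 0:
        return Volume(data, vol.spacing)
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in vol.spacing]
    return Volume(ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect"), vol.spacing)


def bilateral_filter(vol: Volume, params: BilateralParams) -> Volume:
    """Bilateral filter: spatial Gaussian (in voxels) times intensity
    Gaussian (in max-normalised units), truncated at 3 sigma_spatial.

    Each output voxel is a convex combination of the raw intensities within
    the truncated neighbourhood clipped to the volume.
    """
    data = np.ascontiguousarray(vol.data, dtype=np.float64)
    shape = data.shape
    scale = _intensity_scale(data)
    f = data / scale
    r = int(math.ceil(3.0 * params.sigma_spatial))
    inv2sp = 1.0 / (2.0 * params.sigma_spatial ** 2)
    inv2in = 1.0 / (2.0 * params.sigma_intensity ** 2)
    num = np.zeros(shape)
    den = np.zeros(shape)
    for d in itertools.product(range(-r, r + 1), repeat=3):
        d2 = float(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        if d2 > (3.0 * params.sigma_spatial) ** 2:
            continue
        ws = math.exp(-d2 * inv2sp)
        vsl, csl = _clip_slices(d, shape)
        diff = f[csl] - f[vsl]
        with np.errstate(under="ignore"):
            w = ws * np.exp(-(diff * diff) * inv2in)
        num[vsl] += w * (data[csl] - data[vsl])
        den[vsl] += w
    safe = np.where(den > 0, den, 1.0)
    out = data + np.where(den > 0, num / safe, 0.0)
    return Volume(out, vol.spacing)
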