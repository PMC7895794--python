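"""Independent brute-force reference implementations used as oracles.

Each function evaluates the filter definition literally, voxel by voxel
and candidate by candidate, sharing nothing with the package's vectorised
code paths except the documented boundary/normalisation policy (reflect
padding for patches, distances on max-normalised intensities, averaging of
raw intensities).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from mrnlm.core import MultiReconSet, Volume


def _pad(data: np.ndarray, widths) -> np.ndarray:
    out = np.asarray(data, dtype=np.float64)
    for ax, w in enumerate(widths):
        if w == 0:
            continue
        pads = [(w, w) if a == ax else (0, 0) for a in range(out.ndim)]
        out = np.pad(out, pads, mode="reflect" if out.shape[ax] > 1 else "edge")
    return out


def _patch(padded: np.ndarray, center, radius) -> np.ndarray:
    return padded[tuple(slice(c, c + 2 * r + 1) for c, r in zip(center, radius))]


def _scale(data: np.ndarray) -> float:
    m = float(data.max())
    return m if m > 0 else 1.0


def naive_nlm(vol: Volume, h: float, patch_radius, search_radius) -> Volume:
    data = np.asarray(vol.data, dtype=np.float64)
    shape = data.shape
    f = data / _scale(data)
    fp = _pad(f, patch_radius)
    out = np.empty(shape)
    for n in np.ndindex(shape):
        pn = _patch(fp, n, patch_radius)
        num = 0.0
        den = 0.0
        for d in itertools.product(*(range(-r, r + 1) for r in search_radius)):
            m = tuple(c + dd for c, dd in zip(n, d))
            if any(not (0 <= x < s) for x, s in zip(m, shape)):
                continue
            pm = _patch(fp, m, patch_radius)
            w = math.exp(-float(np.sum((pn - pm) ** 2)) / (h * h))
            num += w * data[m]
            den += w
        out[n] = num / den
    return Volume(out, vol.spacing)


def naive_mrnlm(recons: MultiReconSet, h: float, patch_radius, include_target: bool) -> Volume:
    tdata = np.asarray(recons.target.data, dtype=np.float64)
    shape = tdata.shape
    scale = _scale(tdata)
    tp = _pad(tdata / scale, patch_radius)
    apads = [_pad(np.asarray(a.data, dtype=np.float64) / scale, patch_radius) for a in recons.auxiliaries]
    adatas = [np.asarray(a.data, dtype=np.float64) for a in recons.auxiliaries]
    out = np.empty(shape)
    for n in np.ndindex(shape):
        pn = _patch(tp, n, patch_radius)
        num = tdata[n] if include_target else 0.0
        den = 1.0 if include_target else 0.0
        for ap, ad in zip(apads, adatas):
            pm = _patch(ap, n, patch_radius)
            w = math.exp(-float(np.sum((pn - pm) ** 2)) / (h * h))
            num += w * ad[n]
            den += w
        out[n] = num / den if den > 0 else tdata[n]
    return Volume(out, recons.target.spacing)


def naive_bilateral(vol: Volume, sigma_spatial: float, sigma_intensity: float) -> Volume:
    data = np.asarray(vol.data, dtype=np.float64)
    shape = data.shape
    f = data / _scale(data)
    r = int(math.ceil(3.0 * sigma_spatial))
    cutoff2 = (3.0 * sigma_spatial) ** 2
    out = np.empty(shape)
    for n in np.ndindex(shape):
        num = 0.0
        den = 0.0
        for d in itertools.product(range(-r, r + 1), repeat=3):
            d2 = d[0] ** 2 + d[1] ** 2 + d[2] ** 2
            if d2 > cutoff2:
                continue
            m = tuple(c + dd for c, dd in zip(n, d))
            if any(not (0 <= x < s) for x, s in zip(m, shape)):
                continue
            w = math.exp(-d2 / (2.0 * sigma_spatial ** 2)) * math.exp(
                -((f[n] - f[m]) ** 2) / (2.0 * sigma_intensity ** 2)
            )
            num += w * data[m]
            den += w
        out[n] = num / den
    return Volume(out, vol.spacing)
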