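"""Image-quality metrics over volumes of interest (VOIs).

Metrics follow the usual emission-tomography conventions:

* CNR  = |mu_signal - mu_bg| / sqrt((sd_signal^2 + sd_bg^2) / 2)
* SNR  = mean over VOIs of (mu_signal - mu_bg) / sd_bg, with sd_bg the
  standard deviation inside the background VOI of the evaluated image
* phantom bias (%) = 100 (mu_signal - mu_reference) / mu_reference
  against the known true activity, signed
* patient bias (%) = 100 |mu_signal - mu_noisy| / mu_noisy against the
  unfiltered image (magnitude; the sign of the difference is recorded
  separately in reports)

Standard deviations use the sample (n-1) convention throughout. Undefined
metrics (zero denominators) raise :class:`UndefinedMetricError` instead of
returning infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MultiReconSet, Volume
from .errors import ConfigError, ParameterError, ShapeError, UndefinedMetricError
from . import filters as _filters

__all__ = [
    "VOIPair",
    "MetricsReport",
    "cnr",
    "snr",
    "bias_phantom",
    "bias_patient",
    "paired_test",
    "evaluate_methods",
    "reports_to_frame",
]

_DDOF = 1  # sample standard deviation everywhere


@dataclass(frozen=True, eq=False)
class VOIPair:
    """A signal mask and a same-size background mask on a common grid."""

    signal_mask: np.ndarray
    background_mask: np.ndarray
    name: str = "voi"

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal_mask, dtype=bool)
        bg = np.asarray(self.background_mask, dtype=bool)
        if sig.shape != bg.shape:
            raise ShapeError(
                f"VOI {self.name!r}: mask shapes differ ({sig.shape} vs {bg.shape})"
            )
        ns, nb = int(sig.sum()), int(bg.sum())
        if ns < 2 or nb < 2:
            raise ParameterError(
                f"VOI {self.name!r}: masks need >= 2 voxels (got {ns} signal, {nb} background)"
            )
        if ns != nb:
            raise ParameterError(
                f"VOI {self.name!r}: signal ({ns}) and background ({nb}) voxel counts differ"
            )
        if np.any(sig & bg):
            raise ParameterError(f"VOI {self.name!r}: signal and background masks overlap")
        object.__setattr__(self, "signal_mask", sig)
        object.__setattr__(self, "background_mask", bg)

    @property
    def n_voxels(self) -> int:
        return int(self.signal_mask.sum())


def _masked(vol: Volume, mask: np.ndarray) -> np.ndarray:
    if mask.shape != vol.shape:
        raise ShapeError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    return vol.data[mask]


def cnr(vol: Volume, voi: VOIPair) -> float:
    """Contrast-to-noise ratio of one VOI pair on one volume."""
    sig = _masked(vol, voi.signal_mask)
    bg = _masked(vol, voi.background_mask)
    pooled = np.sqrt((sig.var(ddof=_DDOF) + bg.var(ddof=_DDOF)) / 2.0)
    if pooled == 0:
        raise UndefinedMetricError(f"VOI {voi.name!r}: pooled standard deviation is zero")
    return float(abs(sig.mean() - bg.mean()) / pooled)


def snr(vols_and_vois) -> float:
    """Mean over VOIs of (mu_signal - mu_bg) / sd_bg.

    ``vols_and_vois`` is a non-empty sequence of (Volume, VOIPair) pairs,
    allowing pooling across images/patients.
    """
    pairs = list(vols_and_vois)
    if not pairs:
        raise ParameterError("snr needs at least one (volume, VOI) pair")
    terms = []
    for vol, voi in pairs:
        sig = _masked(vol, voi.signal_mask)
        bg = _masked(vol, voi.background_mask)
        sd = bg.std(ddof=_DDOF)
        if sd == 0:
            raise UndefinedMetricError(f"VOI {voi.name!r}: background SD is zero")
        terms.append((sig.mean() - bg.mean()) / sd)
    return float(np.mean(terms))


def bias_phantom(vol: Volume, signal_mask: np.ndarray, reference_activity: float) -> float:
    """Signed percent deviation of the VOI mean from the known true activity."""
    if not reference_activity > 0:
        raise ParameterError(f"reference activity must be > 0, got {reference_activity}")
    mask = np.asarray(signal_mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty signal mask")
    mu = _masked(vol, mask).mean()
    return float(100.0 * (mu - reference_activity) / reference_activity)


def bias_patient(filtered: Volume, noisy: Volume, mask: np.ndarray, signed: bool = False) -> float:
    """Percent deviation of the filtered VOI mean from the unfiltered one.

    Returns the magnitude by default; ``signed=True`` keeps the sign of
    (mu_filtered - mu_noisy).
    """
    if filtered.shape != noisy.shape:
        raise ShapeError("filtered and noisy volumes must share a grid")
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ParameterError("empty mask")
    mu_f = _masked(filtered, m).mean()
    mu_n = _masked(noisy, m).mean()
    if mu_n == 0:
        raise UndefinedMetricError("mean of the unfiltered image over the mask is zero")
    value = 100.0 * (mu_f - mu_n) / mu_n
    return float(value if signed else abs(value))


def paired_test(values_a, values_b) -> float:
    """Two-sided paired t-test p-value on matched per-VOI values.

    All-zero differences return p = 1 by convention (no evidence of any
    difference); identical nonzero differences give p -> 0.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired_test needs two equal-length 1-D sequences")
    if a.size < 2:
        raise ParameterError("paired_test needs at least two matched pairs")
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    if np.all(diff == diff[0]):  # zero-variance, nonzero-mean differences
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# reporting


@dataclass(eq=False)
class MetricsReport:
    """Per-VOI rows plus aggregates for one denoised volume.

    ``rows`` has one record per VOI with columns name, n_voxels,
    mean_signal, mean_bg, sd_signal, sd_bg, cnr, bias, bias_sign. The
    aggregate ``snr`` is the per-VOI mean of (mean_signal - mean_bg)/sd_bg
    and is recomputable from the rows.
    """

    method: str
    rows: pd.DataFrame
    snr: float
    mean_bias: float
    sd_bias: float

    def recomputed_snr(self) -> float:
        r = self.rows
        return float(((r["mean_signal"] - r["mean_bg"]) / r["sd_bg"]).mean())


def _report_for_volume(
    method: str,
    vol: Volume,
    vois,
    truth: Volume | None,
    noisy: Volume | None,
) -> MetricsReport:
    records = []
    for voi in vois:
        sig = _masked(vol, voi.signal_mask)
        bg = _masked(vol, voi.background_mask)
        if truth is not None:
            reference = float(_masked(truth, voi.signal_mask).mean())
            bias = bias_phantom(vol, voi.signal_mask, reference)
            sign = float(np.sign(bias)) if bias != 0 else 0.0
        else:
            assert noisy is not None
            signed = bias_patient(vol, noisy, voi.signal_mask, signed=True)
            bias = abs(signed)
            sign = float(np.sign(signed)) if signed != 0 else 0.0
        records.append(
            {
                "name": voi.name,
                "n_voxels": voi.n_voxels,
                "mean_signal": float(sig.mean()),
                "mean_bg": float(bg.mean()),
                "sd_signal": float(sig.std(ddof=_DDOF)),
                "sd_bg": float(bg.std(ddof=_DDOF)),
                "cnr": cnr(vol, voi),
                "bias": float(bias),
                "bias_sign": sign,
            }
        )
    rows = pd.DataFrame.from_records(records)
    agg_snr = snr([(vol, voi) for voi in vois])
    return MetricsReport(
        method=method,
        rows=rows,
        snr=agg_snr,
        mean_bias=float(rows["bias"].mean()),
        sd_bias=float(rows["bias"].std(ddof=_DDOF)) if len(rows) > 1 else 0.0,
    )


def _apply_method(recons: MultiReconSet, cfg: dict) -> Volume:
    cfg = dict(cfg)
    try:
        method = cfg.pop("method")
    except KeyError:
        raise ConfigError(f"filter config missing 'method': {cfg!r}") from None
    target = recons.target
    if method == "none":
        return target
    if method == "gaussian":
        return _filters.gaussian_filter(target, float(cfg.pop("fwhm_mm", 6.0)))
    if method == "bilateral":
        params = _filters.BilateralParams(
            sigma_spatial=float(cfg.pop("sigma_spatial", 3.8)),
            sigma_intensity=float(cfg.pop("sigma_intensity", 0.35)),
        )
        return _filters.bilateral_filter(target, params)
    if method == "nlm":
        params = _filters.NLMParams(
            h=float(cfg.pop("h", 0.3)),
            patch=_filters.PatchSpec(tuple(cfg.pop("patch_radius", (2, 2, 0)))),
            search_radius=tuple(cfg.pop("search_radius", (5, 5, 1))),
        )
        return _filters.nlm_filter(target, params)
    if method == "mrnlm":
        params = _filters.MRNLMParams(
            h=float(cfg.pop("h", 0.3)),
            patch=_filters.PatchSpec(tuple(cfg.pop("patch_radius", (2, 2, 0)))),
            include_target=bool(cfg.pop("include_target", True)),
        )
        return _filters.mrnlm_filter(recons, params)
    if method == "mr_average":
        return _filters.mr_average(recons, include_target=bool(cfg.pop("include_target", True)))
    raise ConfigError(f"unknown filter method {method!r}")


def evaluate_methods(
    recons: MultiReconSet,
    truth: Volume | None,
    vois,
    method_configs,
    label_suffix: str = "",
) -> list[MetricsReport]:
    """Run each configured filter and measure CNR/SNR/bias per VOI.

    ``truth`` selects the bias convention: when given (phantom runs), bias
    is measured against the true activity in each signal VOI; when ``None``
    (clinical-style runs), against the unfiltered target. An unfiltered
    baseline labelled ``"none"`` is always included first.
    """
    vois = list(vois)
    configs = [dict(c) for c in method_configs]
    for cfg in configs:  # validate labels before any computation
        if cfg.get("method") not in {"none", "gaussian", "bilateral", "nlm", "mrnlm", "mr_average"}:
            raise ConfigError(f"unknown filter method {cfg.get('method')!r}")
    if not any(c.get("method") == "none" for c in configs):
        configs.insert(0, {"method": "none"})
    noisy = recons.target if truth is None else None
    reports = []
    for cfg in configs:
        label = cfg.get("label", cfg["method"]) + label_suffix
        vol = _apply_method(recons, {k: v for k, v in cfg.items() if k != "label"})
        reports.append(_report_for_volume(label, vol, vois, truth, noisy))
    return reports


def reports_to_frame(reports) -> pd.DataFrame:
    """Long-format table: one row per VOI per method."""
    frames = []
    for rep in reports:
        rows = rep.rows.copy()
        rows.insert(0, "method", rep.method)
        rows["snr_aggregate"] = rep.snr
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)
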