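"""Core in-memory containers: volumes and multi-reconstruction sets.

A :class:`Volume` is a 3-D scalar grid of activity values with a physical
voxel spacing in mm; it is the unit every filter and metric operates on.
A :class:`MultiReconSet` bundles one target volume with the co-registered
auxiliary volumes (independent reconstructions of the same scene) consumed
by the multiple-reconstruction filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError

__all__ = ["Volume", "MultiReconSet"]


@dataclass(frozen=True, eq=False)
class Volume:
    """A 3-D scalar image with voxel spacing.

    Parameters
    ----------
    data
        3-D array of activity values (kBq/ml or arbitrary units). Must be
        finite everywhere.
    spacing
        Voxel edge lengths in mm along (x, y, z); all strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ShapeError(f"volume data must be 3-D, got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise ShapeError(f"volume has a zero-sized axis: shape={data.shape}")
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        if not np.all(np.isfinite(data)):
            raise ParameterError("volume data contains NaN or Inf values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ParameterError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        """A new volume on the same grid with different values."""
        return Volume(data, self.spacing)


@dataclass(frozen=True, eq=False)
class MultiReconSet:
    """One target volume plus co-registered auxiliary reconstructions.

    Every auxiliary must share the target's shape and spacing. ``labels``
    identifies each auxiliary (e.g. the ``"3i:14s"`` iteration/subset tag);
    when omitted, positional labels are generated.
    """

    target: Volume
    auxiliaries: tuple[Volume, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        aux = tuple(self.auxiliaries)
        labels = tuple(self.labels) if self.labels else tuple(f"aux{i:02d}" for i in range(len(aux)))
        if len(labels) != len(aux):
            raise ParameterError(
                f"{len(labels)} labels for {len(aux)} auxiliary volumes"
            )
        for lab, vol in zip(labels, aux):
            if vol.shape != self.target.shape:
                raise ShapeError(
                    f"auxiliary {lab!r} shape {vol.shape} != target shape {self.target.shape}"
                )
            if vol.spacing != self.target.spacing:
                raise ShapeError(
                    f"auxiliary {lab!r} spacing {vol.spacing} != target spacing {self.target.spacing}"
                )
        object.__setattr__(self, "auxiliaries", aux)
        object.__setattr__(self, "labels", labels)

    @property
    def n_aux(self) -> int:
        return len(self.auxiliaries)
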