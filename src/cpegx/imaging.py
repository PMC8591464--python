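"""Contralateral parenchymal enhancement (CPE) from registered DCE-MRI.

CPE summarizes delayed enhancement of the fibroglandular (dense parenchymal)
tissue of the breast contralateral to the tumor: for each voxel the relative
signal change between an early and a late post-contrast series,
``(S_late - S_early) / S_early``, is computed, and CPE is the mean of the
top decile of those ratios within the fibroglandular mask.  The statistic is
dimensionless and independent of global intensity scaling.

Registration, bias-field correction, and breast/fibroglandular segmentation
are upstream concerns: this module consumes already-registered volumes and
binary masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DceStudy", "TissueMasks", "CpeValue",
    "enhancement_ratio_map", "compute_cpe", "Standardizer", "standardize",
]

#: fraction of the volume maximum below which an early-phase voxel is treated
#: as having no reliable denominator and excluded rather than clamped
EPS_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class DceStudy:
    """A registered multi-timepoint DCE series.

    Parameters
    ----------
    volumes : list of 3-D float arrays, identical shapes, finite intensities.
        First entry is the pre-contrast series.
    acquisition_times : seconds since contrast injection, strictly increasing;
        first entry is the pre-contrast time (typically 0).
    voxel_spacing : (dx, dy, dz) in millimetres.
    """

    volumes: tuple
    acquisition_times: tuple
    voxel_spacing: tuple = (1.35, 1.35, 1.35)

    def __post_init__(self):
        vols = tuple(np.asarray(v, dtype=float) for v in self.volumes)
        times = tuple(float(t) for t in self.acquisition_times)
        if len(vols) < 3:
            raise ValueError("a DCE study needs >= 3 volumes (pre + early + late)")
        if len(vols) != len(times):
            raise ValueError(
                f"{len(vols)} volumes but {len(times)} acquisition times"
            )
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"acquisition times must be strictly increasing: {times}")
        shape = vols[0].shape
        for i, v in enumerate(vols):
            if v.ndim != 3:
                raise ValueError(f"volume {i} is not 3-D (shape {v.shape})")
            if v.shape != shape:
                raise ValueError(f"volume {i} shape {v.shape} != {shape}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"volume {i} contains non-finite intensities")
        object.__setattr__(self, "volumes", vols)
        object.__setattr__(self, "acquisition_times", times)
        object.__setattr__(self, "voxel_spacing", tuple(float(s) for s in self.voxel_spacing))

    @property
    def shape(self):
        return self.volumes[0].shape

    def volume_at(self, time_s: float, tol: float = 1.0) -> np.ndarray:
        """Volume acquired at ``time_s`` seconds (nearest match within ``tol``)."""
        times = np.asarray(self.acquisition_times)
        idx = int(np.argmin(np.abs(times - time_s)))
        if abs(times[idx] - time_s) > tol:
            raise ValueError(
                f"no series acquired at {time_s} s; available times: "
                f"{list(self.acquisition_times)}"
            )
        return self.volumes[idx]


@dataclass(frozen=True)
class TissueMasks:
    """Breast and fibroglandular binary masks; fibroglandular is a subset."""

    breast_mask: np.ndarray
    fibroglandular_mask: np.ndarray

    def __post_init__(self):
        bm = np.asarray(self.breast_mask, dtype=bool)
        fgt = np.asarray(self.fibroglandular_mask, dtype=bool)
        if bm.shape != fgt.shape:
            raise ValueError("breast and fibroglandular masks have different shapes")
        if np.any(fgt & ~bm):
            raise ValueError("fibroglandular mask must be contained in the breast mask")
        object.__setattr__(self, "breast_mask", bm)
        object.__setattr__(self, "fibroglandular_mask", fgt)


@dataclass(frozen=True)
class CpeValue:
    """CPE with bookkeeping of how many voxels entered the top-decile mean."""

    value: float
    top_fraction: float
    n_voxels_used: int
    n_voxels_mask: int
    n_voxels_excluded: int

    def as_dict(self) -> dict:
        return {
            "cpe": self.value,
            "top_fraction": self.top_fraction,
            "n_used": self.n_voxels_used,
            "n_mask": self.n_voxels_mask,
            "n_excluded": self.n_voxels_excluded,
        }


def enhancement_ratio_map(
    study: DceStudy,
    early_time: float = 90.0,
    late_time: float = 360.0,
    time_tol: float = 1.0,
) -> np.ndarray:
    """Voxelwise delayed-enhancement ratio (S_late - S_early) / S_early.

    Voxels whose early-phase signal falls below a positivity floor
    (``EPS_FLOOR_FRACTION`` x the early volume maximum) are set to NaN
    rather than producing unbounded ratios; `compute_cpe` counts them
    as excluded.

    Returns a float array of ``study.shape`` with NaN marking invalid voxels.
    """
    if late_time <= early_time:
        raise ValueError(f"late_time ({late_time}) must exceed early_time ({early_time})")
    s_early = study.volume_at(early_time, tol=time_tol)
    s_late = study.volume_at(late_time, tol=time_tol)
    floor = EPS_FLOOR_FRACTION * float(np.max(s_early)) if np.max(s_early) > 0 else 0.0
    valid = s_early > floor
    ratio = np.full(s_early.shape, np.nan)
    ratio[valid] = (s_late[valid] - s_early[valid]) / s_early[valid]
    return ratio


def compute_cpe(
    ratio_map: np.ndarray,
    masks: TissueMasks,
    top_fraction: float = 0.10,
) -> CpeValue:
    """Mean of the top-fraction highest ratios within the fibroglandular mask.

    The in-mask ratios are sorted descending (ties broken by voxel linear
    index via a stable sort, which leaves the mean unaffected) and the top
    ``ceil(top_fraction * m)`` of the ``m`` valid voxels are averaged.
    Out-of-mask voxels never influence the result.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    ratio_map = np.asarray(ratio_map, dtype=float)
    fgt = masks.fibroglandular_mask
    if ratio_map.shape != fgt.shape:
        raise ValueError("ratio map and mask shapes differ")
    n_mask = int(fgt.sum())
    if n_mask == 0:
        raise ValueError("fibroglandular mask is empty")
    in_mask = ratio_map[fgt]
    valid = in_mask[np.isfinite(in_mask)]
    n_excluded = n_mask - valid.size
    if valid.size == 0:
        raise ValueError("no valid in-mask voxels (all early-phase signals below floor)")
    n_used = max(1, math.ceil(top_fraction * valid.size))
    # stable descending sort; ties at the cut carry equal values so the mean
    # is order-independent
    top = np.sort(valid, kind="stable")[::-1][:n_used]
    return CpeValue(
        value=float(top.mean()),
        top_fraction=float(top_fraction),
        n_voxels_used=n_used,
        n_voxels_mask=n_mask,
        n_voxels_excluded=n_excluded,
    )


@dataclass
class Standardizer:
    """Standardize to mean 0, sample SD 1; reusable on new values.

    Stores the training mean and SD so that held-out values can be placed
    on the reference scale (one unit = one training SD).
    """

    mean: float = field(default=np.nan)
    sd: float = field(default=np.nan)

    def fit(self, values) -> "Standardizer":
        x = np.asarray(values, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("need a 1-D vector with >= 2 values")
        if np.unique(x).size < 2:
            raise ValueError("cannot standardize a zero-variance vector")
        self.mean = float(x.mean())
        self.sd = float(x.std(ddof=1))
        return self

    def transform(self, values) -> np.ndarray:
        if not np.isfinite(self.mean):
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def fit_transform(self, values) -> np.ndarray:
        return self.fit(values).transform(values)


def standardize(values) -> tuple[np.ndarray, Standardizer]:
    """Convenience wrapper: returns (standardized vector, fitted Standardizer)."""
    st = Standardizer().fit(values)
    return st.transform(values), st
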