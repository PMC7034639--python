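"""Region quantification: TAC extraction, decay correction, SUV, SUV ratios.

The standard uptake value normalizes tissue concentration by injected dose
per gram of body weight:

    SUV = C_tissue [µCi/g] / (injected dose [µCi] / body weight [g])

For tumors the reported statistic is the *upper-quartile mean*: the mean SUV
of the voxels at or above the 75th percentile of the tumor ROI.  This
isolates the high-uptake viable rim from the necrotic core, mirroring how
heterogeneous gliomas are read out in practice.  Normal regions use the
plain ROI mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import DynamicImage, RegionLabelMap, TimeActivityCurve
from .phantom import F18_HALF_LIFE_MIN, SubjectMeta


@dataclass(frozen=True)
class SUVResult:
    region_name: str
    time_min: float
    suv: float
    statistic: str            # "mean" or "upper_quartile_mean"
    n_voxels: int

    def __post_init__(self):
        if self.statistic not in ("mean", "upper_quartile_mean"):
            raise ParameterError(f"unknown SUV statistic {self.statistic!r}")
        if self.suv < 0:
            raise ParameterError("SUV must be non-negative")


@dataclass(frozen=True)
class SUVRatio:
    region_name: str
    reference_name: str
    time_min: float
    ratio: float


def _region_mask(labels: RegionLabelMap, region):
    """Mask for a region name or a union of names (e.g. rim + core = tumor)."""
    names = [region] if isinstance(region, str) else list(region)
    mask = np.zeros(labels.labels.shape, dtype=bool)
    for name in names:
        mask |= labels.mask(name)
    return mask, "+".join(names)


def extract_tac(img: DynamicImage, labels: RegionLabelMap, region) -> TimeActivityCurve:
    """Per-frame arithmetic mean over a region's voxels.

    *region* may be a single name or an iterable of names, in which case the
    voxel union is used (means are therefore voxel-count weighted).
    """
    if img.grid_shape != labels.labels.shape:
        raise ParameterError(
            f"image grid {img.grid_shape} does not match label grid {labels.labels.shape}"
        )
    mask, name = _region_mask(labels, region)
    n = int(mask.sum())
    if n == 0:
        raise ParameterError(f"region {name!r} contains no voxels")
    values = img.voxels[mask].mean(axis=0)
    return TimeActivityCurve(img.frames.midpoints, values, region_name=name, n_voxels=n)


def decay_correct(activity, elapsed_min: float, half_life_min: float = F18_HALF_LIFE_MIN):
    """Correct a measured activity back to the reference time.

    Multiplies by ``2^(elapsed/half_life)``; composing with
    :func:`decay_uncorrect` is the identity.
    """
    if half_life_min <= 0:
        raise ParameterError("half_life_min must be positive")
    if np.any(np.asarray(elapsed_min) < 0):
        raise ParameterError("elapsed_min must be non-negative")
    return activity * 2.0 ** (np.asarray(elapsed_min, dtype=float) / half_life_min)


def decay_uncorrect(activity, elapsed_min: float, half_life_min: float = F18_HALF_LIFE_MIN):
    """Inverse of :func:`decay_correct`: apply physical decay over *elapsed_min*."""
    if half_life_min <= 0:
        raise ParameterError("half_life_min must be positive")
    if np.any(np.asarray(elapsed_min) < 0):
        raise ParameterError("elapsed_min must be non-negative")
    return activity * 2.0 ** (-np.asarray(elapsed_min, dtype=float) / half_life_min)


def compute_suv(concentration, meta: SubjectMeta):
    """SUV = concentration / (injected dose / body weight).  Vectorized."""
    if meta.injected_dose <= 0 or meta.body_weight <= 0:
        raise ParameterError("dose and body weight must be positive")
    return np.asarray(concentration, dtype=float) / (meta.injected_dose / meta.body_weight)


def tumor_suv_upper_quartile(voxel_suvs) -> float:
    """Mean of the voxels at or above the ROI's 75th percentile.

    The percentile uses the linear-interpolation convention
    (rank 0.75·(n−1), 0-based); values tied with the threshold are included.
    The result is never below the plain ROI mean.
    """
    vals = np.asarray(voxel_suvs, dtype=float)
    if vals.size == 0:
        raise ParameterError("upper-quartile SUV of an empty voxel set is undefined")
    q3 = np.percentile(vals, 75.0)
    return float(vals[vals >= q3].mean())


def suv_ratio(region_suv: float, reference_suv: float) -> float:
    """Plain ratio of two SUVs; the reference must be strictly positive."""
    if reference_suv <= 0:
        raise ParameterError("reference SUV must be positive (bad reference region?)")
    return float(region_suv) / float(reference_suv)


def voxel_suvs_at_frame(
    img: DynamicImage, labels: RegionLabelMap, region, frame_index: int, meta: SubjectMeta
) -> np.ndarray:
    """Per-voxel SUVs of a region at one frame."""
    mask, name = _region_mask(labels, region)
    if not mask.any():
        raise ParameterError(f"region {name!r} contains no voxels")
    return np.asarray(compute_suv(img.voxels[mask, frame_index], meta))


def suv_table(
    img: DynamicImage,
    labels: RegionLabelMap,
    meta: SubjectMeta,
    tumor_regions=("tumor_rim", "tumor_core"),
    tumor_name: str = "tumor",
) -> pd.DataFrame:
    """Per-region, per-frame SUV table.

    Normal regions are reported as plain means; the union of *tumor_regions*
    (present in the label map) is additionally reported under *tumor_name*
    with the upper-quartile statistic.
    """
    rows = []
    times = img.frames.midpoints
    for name in labels.region_names:
        tac = extract_tac(img, labels, name)
        suvs = compute_suv(tac.values, meta)
        for t, s in zip(times, suvs):
            rows.append((name, float(t), float(s), "mean", tac.n_voxels))
    present = [r for r in tumor_regions if r in labels.region_names]
    if present:
        mask, _ = _region_mask(labels, present)
        n = int(mask.sum())
        for f, t in enumerate(times):
            uq = tumor_suv_upper_quartile(
                voxel_suvs_at_frame(img, labels, present, f, meta)
            )
            rows.append((tumor_name, float(t), uq, "upper_quartile_mean", n))
    return pd.DataFrame(rows, columns=["region", "time_min", "suv", "statistic", "n_voxels"])
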