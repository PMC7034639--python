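"""On-disk formats and the shared in-memory containers.

The pipeline touches a deliberately small set of artifacts:

* 4D dynamic activity images and 3D integer label maps — NIfTI-1
  (``.nii`` / ``.nii.gz``), read and written with :mod:`nibabel`;
* frame timing tables and region time–activity curves (TACs) — CSV;
* subject metadata and phantom/pipeline configuration — YAML;
* results (Logan fits, statistics, ground truth) — JSON.

Concentrations are µCi/g and activities µCi throughout, matching the
convention of small-animal PET workstations; a kBq conversion constant is
provided but never applied implicitly.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

#: 1 µCi expressed in kBq (exact).
UCI_TO_KBQ = 37.0

TAC_COLUMNS = ("region", "time_min", "mean_uCi_per_g", "n_voxels")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Timing of the dynamic acquisition: per-frame start times and durations.

    Frames must be contiguous (each starts where the previous one ends) and
    non-overlapping; times are minutes post-injection.
    """

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.start_times, dtype=float)
        durs = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", starts)
        object.__setattr__(self, "durations", durs)
        if starts.ndim != 1 or starts.shape != durs.shape:
            raise ParameterError("start_times and durations must be 1-D and equal length")
        if len(starts) == 0:
            raise ParameterError("frame schedule must contain at least one frame")
        if np.any(durs <= 0):
            raise ParameterError("frame durations must be positive")
        if len(starts) > 1:
            if np.any(np.diff(starts) <= 0):
                raise ParameterError("frame start times must be strictly increasing")
            gaps = starts[1:] - (starts[:-1] + durs[:-1])
            if np.any(np.abs(gaps) > 1e-9):
                raise ParameterError("frames must be contiguous and non-overlapping")

    def __len__(self) -> int:
        return len(self.start_times)

    @property
    def midpoints(self) -> np.ndarray:
        return self.start_times + self.durations / 2.0

    @property
    def end_time(self) -> float:
        return float(self.start_times[-1] + self.durations[-1])

    def closest_frame(self, time_min: float) -> int:
        """Index of the frame whose midpoint is closest to *time_min*.

        Ties are broken toward the earlier frame.
        """
        return int(np.argmin(np.abs(self.midpoints - time_min)))

    @classmethod
    def uniform(cls, n_frames: int = 60, frame_min: float = 1.0) -> "FrameSchedule":
        """A uniform schedule; the default is 60 one-minute frames over 0–60 min."""
        starts = np.arange(n_frames, dtype=float) * frame_min
        return cls(starts, np.full(n_frames, float(frame_min)))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Mean concentration of one region at each frame midpoint."""

    times: np.ndarray          # min, frame midpoints, strictly increasing
    values: np.ndarray         # µCi/g
    region_name: str
    n_voxels: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ParameterError("times and values must be 1-D and equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ParameterError(f"TAC times for region {self.region_name!r} must be increasing")
        if not np.all(np.isfinite(v)):
            raise ParameterError(f"TAC values for region {self.region_name!r} must be finite")


@dataclass(frozen=True)
class DynamicImage:
    """4D activity-concentration volume plus its frame schedule.

    ``voxels`` has axis order (x, y, z, frame); values are µCi/g and are
    decay-corrected to injection time unless ``decay_corrected`` is False.
    """

    voxels: np.ndarray
    voxel_size: tuple            # mm per spatial axis
    frames: FrameSchedule
    decay_corrected: bool = True

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "voxel_size", tuple(float(s) for s in self.voxel_size))
        if vox.ndim != 4:
            raise FormatError(f"dynamic image must be 4-D, got {vox.ndim}-D — not dynamic")
        if vox.shape[3] != len(self.frames):
            raise FormatError(
                f"frame axis length {vox.shape[3]} does not match schedule "
                f"with {len(self.frames)} frames"
            )
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise FormatError("voxel_size must be three positive lengths (mm)")
        if not np.all(np.isfinite(vox)):
            raise FormatError("image contains non-finite voxel values")

    @property
    def grid_shape(self) -> tuple:
        return self.voxels.shape[:3]


@dataclass(frozen=True)
class RegionLabelMap:
    """Integer label volume plus the label → region-name table."""

    labels: np.ndarray
    name_table: dict = field(default_factory=dict)

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if np.any(lab != np.round(lab)):
                raise FormatError("label map contains non-integer values")
            lab = lab.astype(np.int64)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "name_table", {int(k): str(v) for k, v in self.name_table.items()})
        if lab.ndim != 3:
            raise FormatError(f"label map must be 3-D, got {lab.ndim}-D")
        present = set(int(v) for v in np.unique(lab)) - {0}
        orphans = sorted(present - set(self.name_table))
        if orphans:
            warnings.warn(
                f"label map contains labels with no name-table entry: {orphans}",
                stacklevel=2,
            )

    @property
    def region_names(self) -> list:
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        return [name for lab, name in sorted(self.name_table.items()) if lab in present]

    def mask(self, region_name: str) -> np.ndarray:
        """Boolean mask of all voxels carrying *region_name*'s label."""
        ids = [lab for lab, name in self.name_table.items() if name == region_name]
        if not ids:
            raise FormatError(f"region {region_name!r} not present in the name table")
        m = np.isin(self.labels, ids)
        return m


# ---------------------------------------------------------------------------
# NIfTI images
# ---------------------------------------------------------------------------

def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def write_dynamic_image(img: DynamicImage, path, frame_csv_path) -> None:
    """Write a 4D image as float32 NIfTI-1 plus its frame-timing CSV."""
    nii = nib.Nifti1Image(img.voxels.astype(np.float32), _affine(img.voxel_size))
    nii.header.set_xyzt_units("mm")
    nib.save(nii, str(path))
    write_frame_schedule(img.frames, frame_csv_path)


def read_dynamic_image(path, frame_csv_path, decay_corrected: bool = True) -> DynamicImage:
    """Load a 4D NIfTI volume and its frame-timing CSV into a DynamicImage."""
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise FormatError(f"{path}: volume is {data.ndim}-D, not dynamic (4-D expected)")
    frames = read_frame_schedule(frame_csv_path)
    if data.shape[3] != len(frames):
        raise FormatError(
            f"{path}: {data.shape[3]} frames in image but {len(frames)} rows in "
            f"{frame_csv_path}"
        )
    voxel_size = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return DynamicImage(data, voxel_size, frames, decay_corrected=decay_corrected)


def write_frame_schedule(frames: FrameSchedule, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_index", "start_min", "duration_min"])
        for i, (s, d) in enumerate(zip(frames.start_times, frames.durations)):
            w.writerow([i, repr(float(s)), repr(float(d))])


def read_frame_schedule(path) -> FrameSchedule:
    starts, durs = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"start_min", "duration_min"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: expected header with start_min,duration_min")
        for lineno, row in enumerate(reader, start=2):
            try:
                starts.append(float(row["start_min"]))
                durs.append(float(row["duration_min"]))
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed frame row {row!r}") from exc
    try:
        return FrameSchedule(np.array(starts), np.array(durs))
    except ParameterError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_label_map(labels: RegionLabelMap, path, names_path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    nii = nib.Nifti1Image(labels.labels.astype(np.uint16), _affine(voxel_size))
    nib.save(nii, str(path))
    with open(names_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "region_name"])
        for lab in sorted(labels.name_table):
            w.writerow([lab, labels.name_table[lab]])


def read_label_map(path, names_path) -> RegionLabelMap:
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj)
    name_table = {}
    with open(names_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"label", "region_name"} <= set(reader.fieldnames):
            raise FormatError(f"{names_path}: expected header with label,region_name")
        for lineno, row in enumerate(reader, start=2):
            try:
                name_table[int(row["label"])] = row["region_name"]
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{names_path}:{lineno}: malformed row {row!r}") from exc
    return RegionLabelMap(data, name_table)


# ---------------------------------------------------------------------------
# TAC tables
# ---------------------------------------------------------------------------

def write_tacs(tacs, path) -> None:
    """Write TACs as long-format CSV (region,time_min,mean_uCi_per_g,n_voxels)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TAC_COLUMNS)
        for tac in tacs:
            for t, v in zip(tac.times, tac.values):
                w.writerow([tac.region_name, repr(float(t)), repr(float(v)), tac.n_voxels])


def read_tacs(path) -> list:
    """Inverse of :func:`write_tacs`; validates per-region time monotonicity."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty TAC file") from exc
    missing = set(TAC_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        return []
    try:
        df["time_min"] = pd.to_numeric(df["time_min"])
        df["mean_uCi_per_g"] = pd.to_numeric(df["mean_uCi_per_g"])
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric TAC value ({exc})") from exc
    bad = df[~np.isfinite(df["mean_uCi_per_g"])]
    if len(bad):
        raise FormatError(f"{path}: non-finite value at row {int(bad.index[0]) + 2}")
    out = []
    for region, grp in df.groupby("region", sort=False):
        try:
            out.append(
                TimeActivityCurve(
                    grp["time_min"].to_numpy(),
                    grp["mean_uCi_per_g"].to_numpy(),
                    region_name=str(region),
                    n_voxels=int(grp["n_voxels"].iloc[0]),
                )
            )
        except ParameterError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return out
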