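"""Synthetic 4D rat-brain phantom with tracer kinetics.

The generator produces dynamic PET volumes of a rat head bearing an
intracerebral 9L glioma, for exercising the quantification pipeline without
any acquired data.  Each labeled region follows reversible compartmental
kinetics driven by a shared sum-of-exponentials plasma bolus:

* most regions are one-tissue compartments, ``dCt/dt = K1*Cp - k2*Ct``,
  with total distribution volume ``DV = K1/k2``;
* the reference region (brainstem) additionally carries a small
  slowly-clearing nonspecific component, so its impulse response is
  ``K1 * [(1-f) * exp(-k2 t) + f * exp(-k2_slow t)]``.  Without such a
  component the tumor-to-reference activity ratio of two shared-input
  one-tissue regions is provably monotone in time, and the transient
  contrast peak seen in vivo at 15–20 min post-injection could not occur.

The tumor is a high-uptake shell (viable rim) around a low-uptake sphere
(necrotic core).  Voxel values are the analytic time-average of the region
TAC over each frame, plus seeded Gaussian noise whose variance scales with
activity over frame duration — a tractable surrogate for reconstructed-image
noise.

The default kinetic table is *calibrated*: plasma scale and region K1/k2
values were chosen so that the noiseless pipeline reproduces the study-level
summary readouts used as simulation ground truth (upper-quartile tumor SUV
1.11 at 20 min, tumor-to-brainstem SUV ratio 2.73, peak contrast in the
15–20 min window, and a 40% tumor DV reduction under the SIRT1 inhibitor
EX-527).  It is a documented fixture, not a physiological measurement.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np

from .errors import ParameterError, SpecError
from .io import DynamicImage, FrameSchedule, RegionLabelMap, TimeActivityCurve

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlasmaInputParams:
    """Arterial input function as a delayed sum of exponentials.

    ``Cp(t) = sum_i amplitudes[i] * exp(-rate_constants[i] * (t - delay))``
    for ``t >= delay`` and 0 before.  Amplitudes are µCi/mL and may be
    negative (to shape the bolus rise) as long as the resulting curve is
    non-negative.
    """

    amplitudes: tuple
    rate_constants: tuple      # 1/min, strictly positive
    delay: float = 0.0         # min

    def __post_init__(self):
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        object.__setattr__(self, "rate_constants", tuple(float(r) for r in self.rate_constants))
        if len(self.amplitudes) != len(self.rate_constants):
            raise ParameterError("amplitudes and rate_constants must have equal length")
        if any(r <= 0 for r in self.rate_constants):
            raise ParameterError("rate_constants must be strictly positive")
        if self.delay < 0:
            raise ParameterError("delay must be non-negative")
        # non-negativity of the curve, checked on a dense grid out to 90 min
        t = np.linspace(0.0, 90.0, 2001)
        c = plasma_input(self, t, _validate=False)
        scale = float(np.max(np.abs(c))) or 1.0
        if float(np.min(c)) < -1e-9 * scale:
            raise ParameterError("plasma input is negative somewhere on [0, 90] min")

    def scaled(self, factor: float) -> "PlasmaInputParams":
        return replace(self, amplitudes=tuple(a * factor for a in self.amplitudes))


@dataclass(frozen=True)
class RegionKinetics:
    """Kinetic parameters of one region.

    ``K1`` (mL·g⁻¹·min⁻¹) and ``k2`` (1/min) define a one-tissue compartment;
    an optional slow washout component (``slow_fraction`` of the impulse
    response amplitude clearing at ``k2_slow``) models nonspecific retention.
    """

    region_name: str
    K1: float
    k2: float
    slow_fraction: float = 0.0
    k2_slow: Optional[float] = None

    def __post_init__(self):
        if self.K1 < 0:
            raise ParameterError(f"{self.region_name}: K1 must be non-negative")
        if self.k2 <= 0:
            raise ParameterError(f"{self.region_name}: k2 must be strictly positive")
        if not 0.0 <= self.slow_fraction < 1.0:
            raise ParameterError(f"{self.region_name}: slow_fraction must be in [0, 1)")
        if self.slow_fraction > 0 and (self.k2_slow is None or self.k2_slow <= 0):
            raise ParameterError(f"{self.region_name}: k2_slow must be positive when used")

    @property
    def dv(self) -> float:
        """Total distribution volume (mL/g): integral of the impulse response."""
        dv = (1.0 - self.slow_fraction) / self.k2
        if self.slow_fraction > 0:
            dv += self.slow_fraction / self.k2_slow
        return self.K1 * dv


@dataclass(frozen=True)
class TreatmentEffect:
    """Fractional change of regional distribution volumes under a drug.

    Fractions multiply the baseline DV; 1.0 means no effect.  The defaults
    mirror the two drug arms of the study design: the SIRT1 inhibitor EX-527
    reduces tumor-specific binding by ~40% without touching off-target
    regions, while the class-IIa HDAC inhibitor MC1568 changes nothing.
    """

    drug_name: str
    tumor_dv_fraction: float = 1.0
    offtarget_dv_fraction: float = 1.0

    def __post_init__(self):
        for name in ("tumor_dv_fraction", "offtarget_dv_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")


#: Default drug arms.
EX527_DEFAULT = TreatmentEffect("EX-527", tumor_dv_fraction=0.6, offtarget_dv_fraction=1.0)
MC1568_DEFAULT = TreatmentEffect("MC1568", tumor_dv_fraction=1.0, offtarget_dv_fraction=1.0)


@dataclass(frozen=True)
class SubjectMeta:
    """Injection bookkeeping needed by the SUV formula."""

    subject_id: str
    injected_dose: float       # µCi, decay-corrected to injection time
    body_weight: float         # g
    injection_time: float = 0.0  # min; defines t = 0

    def __post_init__(self):
        if self.injected_dose <= 0:
            raise ParameterError("injected_dose must be positive")
        if self.body_weight <= 0:
            raise ParameterError("body_weight must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete generative description of one synthetic subject."""

    grid_shape: tuple = (64, 64, 64)
    voxel_size: tuple = (0.5, 0.5, 0.5)       # mm
    region_geometry: dict = field(default_factory=dict)   # name -> descriptor
    region_kinetics: dict = field(default_factory=dict)   # name -> RegionKinetics
    input: PlasmaInputParams = None
    frames: FrameSchedule = None
    noise_level: float = 0.0
    seed: int = 0
    subject: SubjectMeta = None
    treatment: Optional[TreatmentEffect] = None   # provenance; already applied to kinetics
    tumor_regions: tuple = ("tumor_rim", "tumor_core")

    def __post_init__(self):
        if self.noise_level < 0:
            raise SpecError("noise_level must be non-negative")
        missing = set(self.region_geometry) - set(self.region_kinetics)
        if missing:
            raise SpecError(f"regions without kinetics: {sorted(missing)}")

    def ground_truth_dv(self) -> dict:
        """True distribution volume per labeled region (after any treatment)."""
        return {name: self.region_kinetics[name].dv for name in self.region_geometry}


class PhantomResult(NamedTuple):
    image: DynamicImage
    labels: RegionLabelMap
    meta: SubjectMeta
    ground_truth: dict


# ---------------------------------------------------------------------------
# kinetic forward model
# ---------------------------------------------------------------------------

def plasma_input(params: PlasmaInputParams, t, _validate: bool = True):
    """Evaluate the plasma input function at times *t* (min).

    Deterministic and vectorized; negative times are a domain error.
    """
    t = np.asarray(t, dtype=float)
    if _validate and np.any(t < 0):
        raise ParameterError("plasma input is only defined for t >= 0")
    tau = np.clip(t - params.delay, 0.0, None)
    out = np.zeros_like(tau)
    active = (t >= params.delay)
    for a, lam in zip(params.amplitudes, params.rate_constants):
        out = out + np.where(active, a * np.exp(-lam * tau), 0.0)
    return out if out.ndim else float(out)


def _conv_exp(params: PlasmaInputParams, k2: float, t: np.ndarray) -> np.ndarray:
    """Closed-form ``∫₀ᵗ Cp(s)·e^(−k2·(t−s)) ds`` for a sum-of-exponentials Cp.

    Each input term ``a·e^(−λτ)`` contributes ``a·(e^(−λτ) − e^(−k2τ))/(k2−λ)``,
    with the degenerate limit ``a·τ·e^(−k2τ)`` when ``k2 = λ``.
    """
    tau = np.clip(np.asarray(t, dtype=float) - params.delay, 0.0, None)
    out = np.zeros_like(tau)
    for a, lam in zip(params.amplitudes, params.rate_constants):
        if abs(k2 - lam) < 1e-10:
            out = out + a * tau * np.exp(-k2 * tau)
        else:
            out = out + a * (np.exp(-lam * tau) - np.exp(-k2 * tau)) / (k2 - lam)
    return out


def solve_1tcm(kin: RegionKinetics, input: PlasmaInputParams, t_grid) -> TimeActivityCurve:
    """Noiseless, decay-corrected tissue curve for one region.

    For a plain one-tissue region this is ``Ct(t) = K1 ∫₀ᵗ Cp(s) e^(−k2(t−s)) ds``,
    evaluated in closed form.  Regions with a slow washout component get the
    corresponding two-term mixture.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t_grid must be non-negative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ParameterError("t_grid must be strictly increasing")
    ct = (1.0 - kin.slow_fraction) * _conv_exp(input, kin.k2, t)
    if kin.slow_fraction > 0:
        ct = ct + kin.slow_fraction * _conv_exp(input, kin.k2_slow, t)
    return TimeActivityCurve(t, kin.K1 * ct, region_name=kin.region_name)


def frame_averaged_tac(
    kin: RegionKinetics,
    input: PlasmaInputParams,
    frames: FrameSchedule,
    n_sub: int = 21,
) -> TimeActivityCurve:
    """Analytic TAC averaged over each frame interval.

    Uses ``n_sub`` (≥ 20) trapezoid points per frame rather than midpoint
    evaluation, which matters for 1–2 min frames on fast kinetics.
    """
    if n_sub < 2:
        raise ParameterError("n_sub must be at least 2")
    vals = np.empty(len(frames))
    for i, (s, d) in enumerate(zip(frames.start_times, frames.durations)):
        tt = np.linspace(s, s + d, n_sub)
        ct = solve_1tcm(kin, input, tt).values
        vals[i] = np.trapezoid(ct, tt) / d
    return TimeActivityCurve(frames.midpoints, vals, region_name=kin.region_name)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def region_mask(descriptor: dict, grid_shape) -> np.ndarray:
    """Boolean voxel mask for a sphere or spherical-shell descriptor.

    Descriptors use 0-based voxel coordinates:
    ``{"shape": "sphere", "center": (x, y, z), "radius": r}`` or
    ``{"shape": "shell", "center": ..., "inner_radius": ri, "outer_radius": ro}``
    (the shell contains voxels with ``ri < dist <= ro``).
    """
    kind = descriptor.get("shape")
    center = np.asarray(descriptor["center"], dtype=float)
    grids = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    if kind == "sphere":
        r = float(descriptor["radius"])
        return d2 <= r**2
    if kind == "shell":
        ri = float(descriptor["inner_radius"])
        ro = float(descriptor["outer_radius"])
        if ri >= ro:
            raise SpecError("shell inner_radius must be smaller than outer_radius")
        return (d2 > ri**2) & (d2 <= ro**2)
    raise SpecError(f"unknown geometry shape {kind!r}")


def build_label_map(spec: PhantomSpec) -> RegionLabelMap:
    """Rasterize the region geometry; regions must be pairwise disjoint."""
    labels = np.zeros(spec.grid_shape, dtype=np.uint16)
    name_table = {}
    for lab, name in enumerate(sorted(spec.region_geometry), start=1):
        m = region_mask(spec.region_geometry[name], spec.grid_shape)
        if not m.any():
            raise SpecError(f"region {name!r} rasterizes to zero voxels")
        clash = m & (labels != 0)
        if clash.any():
            other = name_table[int(labels[clash][0])]
            raise SpecError(f"region geometry overlap between {name!r} and {other!r}")
        labels[m] = lab
        name_table[lab] = name
    return RegionLabelMap(labels, name_table)


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

def build_phantom(spec: PhantomSpec, apply_decay: bool = False) -> PhantomResult:
    """Generate the 4D image, label map, metadata and ground-truth DVs.

    Each frame voxel holds the region's frame-averaged noiseless TAC plus
    zero-mean Gaussian noise with standard deviation
    ``noise_level * sqrt(Ct / frame_duration)`` (seeded, reproducible).
    Unlabeled voxels are zero.  With ``apply_decay`` the stored values are
    physically decayed (¹⁸F) instead of decay-corrected.
    """
    label_map = build_label_map(spec)
    frames = spec.frames
    rng = np.random.default_rng(spec.seed)

    img = np.zeros(spec.grid_shape + (len(frames),), dtype=np.float64)
    # deterministic region order = label order
    for lab in sorted(label_map.name_table):
        name = label_map.name_table[lab]
        kin = spec.region_kinetics[name]
        tac = frame_averaged_tac(kin, spec.input, frames)
        mask = label_map.labels == lab
        n_vox = int(mask.sum())
        for f in range(len(frames)):
            val = tac.values[f]
            if spec.noise_level > 0 and val > 0:
                sd = spec.noise_level * np.sqrt(val / frames.durations[f])
                img[mask, f] = val + rng.normal(0.0, sd, size=n_vox)
            else:
                img[mask, f] = val

    decay_corrected = True
    if apply_decay:
        factors = 0.5 ** (frames.midpoints / F18_HALF_LIFE_MIN)
        img *= factors[None, None, None, :]
        decay_corrected = False

    image = DynamicImage(
        img.astype(np.float32), spec.voxel_size, frames, decay_corrected=decay_corrected
    )
    return PhantomResult(image, label_map, spec.subject, spec.ground_truth_dv())


def apply_treatment(spec: PhantomSpec, effect: TreatmentEffect) -> PhantomSpec:
    """Return a new spec with regional DVs scaled by the drug effect.

    DV scaling is implemented by scaling K1 while holding k2, so
    delivery-phase kinetics are minimally perturbed.  The original spec is
    untouched.
    """
    unknown = set(spec.tumor_regions) - set(spec.region_kinetics)
    if unknown:
        raise SpecError(f"treatment references unknown tumor regions: {sorted(unknown)}")
    new_kin = {}
    for name, kin in spec.region_kinetics.items():
        frac = (
            effect.tumor_dv_fraction
            if name in spec.tumor_regions
            else effect.offtarget_dv_fraction
        )
        new_kin[name] = replace(kin, K1=kin.K1 * frac)
    return replace(spec, region_kinetics=new_kin, treatment=effect)


def make_cohort(
    n_subjects: int,
    base_spec: PhantomSpec,
    seed: int,
    dose_range=(300.0, 500.0),
    weight_range=(400.0, 500.0),
    jitter_cv: float = 0.05,
) -> list:
    """Simulate a cohort of subjects around a base spec.

    Per subject: injected dose and body weight are drawn uniformly from the
    configured ranges (the plasma input scales with dose/weight, so SUV stays
    comparable across subjects); each region's K1 is jittered by a
    multiplicative factor with the given coefficient of variation (k2 held,
    so DV inherits exactly that CV); noise seeds derive deterministically
    from the master seed.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be at least 1")
    rng = np.random.default_rng(seed)
    base_ratio = base_spec.subject.injected_dose / base_spec.subject.body_weight
    cohort = []
    for i in range(n_subjects):
        dose = float(rng.uniform(*dose_range))
        weight = float(rng.uniform(*weight_range))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        factors = {
            name: float(rng.normal(1.0, jitter_cv)) if jitter_cv > 0 else 1.0
            for name in sorted(base_spec.region_kinetics)
        }
        kin = {
            name: replace(k, K1=k.K1 * max(factors[name], 0.05))
            for name, k in base_spec.region_kinetics.items()
        }
        meta = SubjectMeta(
            subject_id=f"S{i + 1:02d}", injected_dose=dose, body_weight=weight
        )
        spec = replace(
            base_spec,
            region_kinetics=kin,
            input=base_spec.input.scaled((dose / weight) / base_ratio),
            seed=sub_seed,
            subject=meta,
        )
        cohort.append(spec)
    return cohort


# ---------------------------------------------------------------------------
# calibrated defaults
# ---------------------------------------------------------------------------

# Plasma scale chosen so the noiseless default tumor rim reaches an SUV of
# 1.11 at the 20-min frame for the reference subject (400 µCi / 450 g).
_PLASMA_SCALE = 2.1155339164258664

#: Default plasma input: bolus rising over ~1 min (delay 0.25 min) with a
#: fast and a slow washout phase.  The study never sampled blood; this shape
#: is a documented modeling choice, not a measurement.
DEFAULT_PLASMA = PlasmaInputParams(
    amplitudes=tuple(a * _PLASMA_SCALE for a in (1.0, 0.25, -1.25)),
    rate_constants=(0.25, 0.035, 3.0),
    delay=0.25,
)

# Brainstem K1 chosen so the noiseless rim/brainstem SUV ratio is 2.73 at the
# 20-min frame given the shapes below.
_K1_BRAINSTEM = 0.3103401789079571

#: Calibrated regional kinetics.  DV ordering encodes the biology the
#: analysis assumes: viable tumor rim highest, hippocampus and nucleus
#: accumbens elevated, brainstem low (reference), necrotic core lowest.
DEFAULT_KINETICS = {
    "tumor_rim": RegionKinetics("tumor_rim", K1=0.25, k2=0.12),
    "tumor_core": RegionKinetics("tumor_core", K1=0.075, k2=0.12),
    "brainstem": RegionKinetics(
        "brainstem", K1=_K1_BRAINSTEM, k2=0.6, slow_fraction=0.12, k2_slow=0.08
    ),
    "cortex": RegionKinetics("cortex", K1=0.285, k2=0.3),
    "hippocampus": RegionKinetics("hippocampus", K1=0.25, k2=0.2),
    "nucleus_accumbens": RegionKinetics("nucleus_accumbens", K1=0.26, k2=0.2),
    "cerebellum": RegionKinetics("cerebellum", K1=0.25, k2=0.25),
}

#: Default geometry on a 64³ grid of 0.5 mm voxels (0-based voxel indices).
DEFAULT_GEOMETRY = {
    "tumor_rim": {
        "shape": "shell", "center": (20, 32, 36), "inner_radius": 5, "outer_radius": 6
    },
    "tumor_core": {"shape": "sphere", "center": (20, 32, 36), "radius": 5},
    "brainstem": {"shape": "sphere", "center": (32, 18, 20), "radius": 4},
    "cortex": {"shape": "sphere", "center": (44, 32, 42), "radius": 5},
    "hippocampus": {"shape": "sphere", "center": (42, 44, 32), "radius": 4},
    "nucleus_accumbens": {"shape": "sphere", "center": (24, 46, 26), "radius": 3},
    "cerebellum": {"shape": "sphere", "center": (32, 12, 34), "radius": 5},
}

#: Default voxel noise level (unitless multiplier of sqrt(activity/duration)),
#: emulating post-smoothing reconstructed-image noise of roughly 5% at the
#: tumor-rim activity level on 1-min frames.
DEFAULT_NOISE_LEVEL = 0.05


def default_phantom_spec(
    seed: int = 0,
    noise_level: float = DEFAULT_NOISE_LEVEL,
    subject_id: str = "S01",
) -> PhantomSpec:
    """The calibrated baseline subject (no treatment)."""
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size=(0.5, 0.5, 0.5),
        region_geometry=dict(DEFAULT_GEOMETRY),
        region_kinetics=dict(DEFAULT_KINETICS),
        input=DEFAULT_PLASMA,
        frames=FrameSchedule.uniform(60, 1.0),
        noise_level=noise_level,
        seed=seed,
        subject=SubjectMeta(subject_id=subject_id, injected_dose=400.0, body_weight=450.0),
    )


# ---------------------------------------------------------------------------
# (de)serialization helpers
# ---------------------------------------------------------------------------

def spec_to_dict(spec: PhantomSpec) -> dict:
    """Plain-dict form of a spec, suitable for YAML."""
    d = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size": list(spec.voxel_size),
        "region_geometry": {
            name: {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in g.items()}
            for name, g in spec.region_geometry.items()
        },
        "region_kinetics": {
            name: {k: v for k, v in dataclasses.asdict(kin).items() if v is not None}
            for name, kin in spec.region_kinetics.items()
        },
        "input": {
            "amplitudes": list(spec.input.amplitudes),
            "rate_constants": list(spec.input.rate_constants),
            "delay": spec.input.delay,
        },
        "frames": {
            "start_times": [float(s) for s in spec.frames.start_times],
            "durations": [float(d_) for d_ in spec.frames.durations],
        },
        "noise_level": spec.noise_level,
        "seed": int(spec.seed),
        "subject": dataclasses.asdict(spec.subject),
        "tumor_regions": list(spec.tumor_regions),
    }
    if spec.treatment is not None:
        d["treatment"] = dataclasses.asdict(spec.treatment)
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    kin = {}
    for name, kd in d["region_kinetics"].items():
        kd = dict(kd)
        kd.setdefault("region_name", name)
        kin[name] = RegionKinetics(**kd)
    treatment = None
    if d.get("treatment"):
        treatment = TreatmentEffect(**d["treatment"])
    return PhantomSpec(
        grid_shape=tuple(d["grid_shape"]),
        voxel_size=tuple(d["voxel_size"]),
        region_geometry={
            name: {k: (tuple(v) if isinstance(v, list) else v) for k, v in g.items()}
            for name, g in d["region_geometry"].items()
        },
        region_kinetics=kin,
        input=PlasmaInputParams(**d["input"]),
        frames=FrameSchedule(
            np.asarray(d["frames"]["start_times"]), np.asarray(d["frames"]["durations"])
        ),
        noise_level=float(d["noise_level"]),
        seed=int(d["seed"]),
        subject=SubjectMeta(**d["subject"]),
        treatment=treatment,
        tumor_regions=tuple(d.get("tumor_regions", ("tumor_rim", "tumor_core"))),
    )
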