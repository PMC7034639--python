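"""Config-driven orchestration: simulate cohorts, quantify, fit, compare.

The default experiment mirrors the study design the phantom is calibrated
to: a baseline cohort of 6 subjects plus two paired drug arms of 3 subjects
each (EX-527, which reduces tumor DV by 40%, and MC1568, a null control).
Every stage is deterministic given the master seed; the manifest records the
configuration hash and all derived seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PetquantError
from .io import write_dynamic_image, write_label_map, write_tacs
from .kinetics import logan_dvr
from .phantom import (
    EX527_DEFAULT,
    MC1568_DEFAULT,
    PhantomSpec,
    TreatmentEffect,
    apply_treatment,
    build_phantom,
    default_phantom_spec,
    make_cohort,
    spec_to_dict,
)
from .quantify import (
    compute_suv,
    extract_tac,
    suv_ratio,
    suv_table,
    tumor_suv_upper_quartile,
    voxel_suvs_at_frame,
)
from .stats import repeated_measures_compare, summarize_cohort

log = logging.getLogger("petquant.pipeline")

#: Calibration targets the default phantom was built to reproduce.
CALIBRATION_TARGETS = {
    "tumor_uq_suv_20min": 1.11,
    "tumor_brainstem_ratio_20min": 2.73,
    "ex527_dvr_percent_change": -40.0,
}

_POST_SEED_OFFSET = 1_000_003


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the full run needs; maps 1:1 onto the YAML config file."""

    n_baseline: int = 6
    n_ex527: int = 3
    n_mc1568: int = 3
    readout_time_min: float = 20.0
    t_star_min: Optional[float] = 20.0     # None -> automatic selection
    k2prime: Optional[float] = None        # None -> omit the C_ref/k2' term
    noise_level: float = 0.05
    jitter_cv: float = 0.05
    dose_range: tuple = (300.0, 500.0)
    weight_range: tuple = (400.0, 500.0)
    ex527_tumor_dv_fraction: float = 0.6
    mc1568_tumor_dv_fraction: float = 1.0
    seed: int = 1
    reference_region: str = "brainstem"
    save_images: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dose_range"] = list(self.dose_range)
        d["weight_range"] = list(self.weight_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(seed=seed)


def _validate_dict(d: dict) -> list:
    errors = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in d:
        if key not in known:
            errors.append(f"unknown config key {key!r}")

    def num(key, lo=None, hi=None, allow_none=False, integer=False):
        if key not in d:
            return
        v = d[key]
        if v is None:
            if not allow_none:
                errors.append(f"{key}: must not be null")
            return
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            errors.append(f"{key}: expected a number, got {v!r}")
            return
        if integer and int(v) != v:
            errors.append(f"{key}: expected an integer, got {v!r}")
        if lo is not None and v < lo:
            errors.append(f"{key}: must be >= {lo}, got {v}")
        if hi is not None and v > hi:
            errors.append(f"{key}: must be <= {hi}, got {v}")

    num("n_baseline", lo=1, integer=True)
    num("n_ex527", lo=1, integer=True)
    num("n_mc1568", lo=1, integer=True)
    num("readout_time_min", lo=0.0, hi=60.0)
    num("t_star_min", lo=0.0, hi=60.0, allow_none=True)
    num("k2prime", lo=1e-9, allow_none=True)
    num("noise_level", lo=0.0)
    num("jitter_cv", lo=0.0)
    num("ex527_tumor_dv_fraction", lo=0.0, hi=1.0)
    num("mc1568_tumor_dv_fraction", lo=0.0, hi=1.0)
    num("seed", lo=0, integer=True)
    for key in ("dose_range", "weight_range"):
        if key in d:
            v = d[key]
            if (
                not isinstance(v, (list, tuple))
                or len(v) != 2
                or not all(isinstance(x, (int, float)) for x in v)
            ):
                errors.append(f"{key}: expected [low, high]")
            elif v[0] <= 0 or v[1] < v[0]:
                errors.append(f"{key}: must satisfy 0 < low <= high, got {v}")
    if "reference_region" in d:
        from .phantom import DEFAULT_GEOMETRY

        if d["reference_region"] not in DEFAULT_GEOMETRY:
            errors.append(
                f"reference_region: unknown region {d['reference_region']!r}"
            )
    return errors


def validate_config(path) -> PipelineConfig:
    """Load and fully validate a YAML config; all violations are collected.

    Raises :class:`~petquant.errors.ConfigError` carrying the complete error
    list rather than stopping at the first problem.
    """
    try:
        with open(path) as fh:
            d = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError([f"{path}: {exc}"]) from exc
    if d is None:
        d = {}
    if not isinstance(d, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    errors = _validate_dict(d)
    if errors:
        raise ConfigError(errors)
    for key in ("dose_range", "weight_range"):
        if key in d:
            d[key] = tuple(float(x) for x in d[key])
    return PipelineConfig(**d)


# ---------------------------------------------------------------------------
# per-subject analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectReadout:
    """Scalar readouts of one scan at the configured readout time."""

    subject_id: str
    condition: str
    tumor_uq_suv: float
    reference_suv: float
    tumor_ratio: float
    dvr: dict                  # region -> LoganResult
    ground_truth_dv: dict
    suv_by_region: dict        # region -> mean SUV at readout frame


def analyze_subject(spec: PhantomSpec, config: PipelineConfig, condition: str = "baseline"):
    """Build one phantom scan and run the full quantification on it.

    Returns ``(readout, tacs, suv_df)``.
    """
    image, labels, meta, gt = build_phantom(spec)
    fidx = image.frames.closest_frame(config.readout_time_min)

    tumor_present = [r for r in spec.tumor_regions if r in labels.region_names]
    vox = voxel_suvs_at_frame(image, labels, tumor_present, fidx, meta)
    uq = tumor_suv_upper_quartile(vox)

    ref_tac = extract_tac(image, labels, config.reference_region)
    ref_suv = float(compute_suv(ref_tac.values[fidx], meta))
    ratio = suv_ratio(uq, ref_suv)

    tacs = [extract_tac(image, labels, name) for name in labels.region_names]
    tumor_tac = extract_tac(image, labels, tumor_present)
    tumor_tac = replace(tumor_tac, region_name="tumor")
    tacs.append(tumor_tac)

    dvr = {}
    for tac in tacs:
        if tac.region_name == config.reference_region:
            continue
        dvr[tac.region_name] = logan_dvr(
            tac, ref_tac, t_star=config.t_star_min, k2prime=config.k2prime
        )

    suv_df = suv_table(image, labels, meta, tumor_regions=tumor_present)
    suv_by_region = {
        name: float(
            compute_suv(extract_tac(image, labels, name).values[fidx], meta)
        )
        for name in labels.region_names
    }
    readout = SubjectReadout(
        subject_id=meta.subject_id,
        condition=condition,
        tumor_uq_suv=uq,
        reference_suv=ref_suv,
        tumor_ratio=ratio,
        dvr=dvr,
        ground_truth_dv=gt,
        suv_by_region=suv_by_region,
    )
    return readout, tacs, suv_df, (image, labels, meta)


def baseline_cohort_readouts(config: PipelineConfig, n: Optional[int] = None, seed=None):
    """Simulate and quantify the baseline cohort; returns a tidy DataFrame."""
    base = default_phantom_spec(noise_level=config.noise_level)
    cohort = make_cohort(
        n if n is not None else config.n_baseline,
        base,
        seed if seed is not None else config.seed,
        dose_range=config.dose_range,
        weight_range=config.weight_range,
        jitter_cv=config.jitter_cv,
    )
    rows = []
    for spec in cohort:
        r, _, _, _ = analyze_subject(spec, config)
        rows.append(
            {
                "subject": r.subject_id,
                "tumor_uq_suv": r.tumor_uq_suv,
                "reference_suv": r.reference_suv,
                "tumor_ratio": r.tumor_ratio,
                "tumor_dvr": r.dvr["tumor"].dvr_slope,
            }
        )
    return pd.DataFrame(rows)


def paired_arm_readouts(
    config: PipelineConfig, effect: TreatmentEffect, n: int, seed: int
) -> pd.DataFrame:
    """Paired baseline/post scans for one drug arm.

    Each subject keeps its kinetics between conditions (same animal); only
    the treatment scaling and the scan noise realization differ.
    """
    base = default_phantom_spec(noise_level=config.noise_level)
    cohort = make_cohort(
        n,
        base,
        seed,
        dose_range=config.dose_range,
        weight_range=config.weight_range,
        jitter_cv=config.jitter_cv,
    )
    rows = []
    for spec in cohort:
        r_base, _, _, _ = analyze_subject(spec, config, condition="baseline")
        post_spec = apply_treatment(spec, effect)
        post_spec = replace(post_spec, seed=(spec.seed + _POST_SEED_OFFSET) % 2**31)
        r_post, _, _, _ = analyze_subject(post_spec, config, condition=effect.drug_name)
        rows.append(
            {
                "subject": r_base.subject_id,
                "baseline_dvr": r_base.dvr["tumor"].dvr_slope,
                "post_dvr": r_post.dvr["tumor"].dvr_slope,
                "baseline_uq_suv": r_base.tumor_uq_suv,
                "post_uq_suv": r_post.tumor_uq_suv,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute phantom → quantify → kinetics → stats for every arm.

    Writes per-subject TAC/SUV/Logan files, cohort summaries, a stats JSON,
    a run manifest, and a plain-text report under *out_dir*.  Returns the
    manifest dict (also written as ``manifest.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    for sub in ("phantoms", "tacs", "suv", "logan", "stats", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    log.info("run config hash %s, master seed %d", cfg_hash, config.seed)

    arms = {
        "ex527": (
            replace(EX527_DEFAULT, tumor_dv_fraction=config.ex527_tumor_dv_fraction),
            config.n_ex527,
            (config.seed + 101) % 2**31,
        ),
        "mc1568": (
            replace(MC1568_DEFAULT, tumor_dv_fraction=config.mc1568_tumor_dv_fraction),
            config.n_mc1568,
            (config.seed + 202) % 2**31,
        ),
    }

    base_spec = default_phantom_spec(noise_level=config.noise_level)
    cohort = make_cohort(
        config.n_baseline,
        base_spec,
        config.seed,
        dose_range=config.dose_range,
        weight_range=config.weight_range,
        jitter_cv=config.jitter_cv,
    )

    long_rows = []

    def record(arm, readout, tacs, suv_df, raw):
        sid = readout.subject_id
        cond = readout.condition
        stem = f"{arm}_{sid}_{cond}".replace(" ", "_")
        write_tacs(tacs, out / "tacs" / f"{stem}.csv")
        suv_df.to_csv(out / "suv" / f"{stem}.csv", index=False)
        with open(out / "logan" / f"{stem}.json", "w") as fh:
            json.dump(
                {name: res.to_dict() for name, res in readout.dvr.items()}, fh, indent=1
            )
        if config.save_images:
            image, labels, meta = raw
            write_dynamic_image(
                image,
                out / "phantoms" / f"{stem}.nii.gz",
                out / "phantoms" / f"{stem}_frames.csv",
            )
            write_label_map(
                labels,
                out / "phantoms" / f"{stem}_labels.nii.gz",
                out / "phantoms" / f"{stem}_labels.csv",
                voxel_size=image.voxel_size,
            )
        for region, suv in readout.suv_by_region.items():
            long_rows.append(
                {"arm": arm, "subject": sid, "condition": cond,
                 "region": region, "metric": "suv", "value": suv}
            )
        long_rows.append(
            {"arm": arm, "subject": sid, "condition": cond,
             "region": "tumor", "metric": "uq_suv", "value": readout.tumor_uq_suv}
        )
        for region, res in readout.dvr.items():
            long_rows.append(
                {"arm": arm, "subject": sid, "condition": cond,
                 "region": region, "metric": "dvr", "value": res.dvr_slope}
            )

    # baseline arm
    baseline_rows = []
    for spec in cohort:
        try:
            readout, tacs, suv_df, raw = analyze_subject(spec, config)
        except PetquantError as exc:
            raise PetquantError(
                f"baseline stage failed for subject {spec.subject.subject_id}: {exc}"
            ) from exc
        record("baseline", readout, tacs, suv_df, raw)
        baseline_rows.append(readout)
        log.info(
            "baseline %s: tumor UQ SUV %.3f ratio %.3f DVR %.3f",
            readout.subject_id,
            readout.tumor_uq_suv,
            readout.tumor_ratio,
            readout.dvr["tumor"].dvr_slope,
        )

    # drug arms (paired)
    stats_out = {}
    arm_tables = {}
    for arm, (effect, n, arm_seed) in arms.items():
        arm_cohort = make_cohort(
            n,
            base_spec,
            arm_seed,
            dose_range=config.dose_range,
            weight_range=config.weight_range,
            jitter_cv=config.jitter_cv,
        )
        rows = []
        for spec in arm_cohort:
            try:
                r_base, tacs_b, suv_b, raw_b = analyze_subject(spec, config, "baseline")
                post_spec = apply_treatment(spec, effect)
                post_spec = replace(
                    post_spec, seed=(spec.seed + _POST_SEED_OFFSET) % 2**31
                )
                r_post, tacs_p, suv_p, raw_p = analyze_subject(
                    post_spec, config, effect.drug_name
                )
            except PetquantError as exc:
                raise PetquantError(
                    f"{arm} stage failed for subject {spec.subject.subject_id}: {exc}"
                ) from exc
            record(arm, r_base, tacs_b, suv_b, raw_b)
            record(arm, r_post, tacs_p, suv_p, raw_p)
            rows.append(
                {
                    "subject": r_base.subject_id,
                    "baseline_dvr": r_base.dvr["tumor"].dvr_slope,
                    "post_dvr": r_post.dvr["tumor"].dvr_slope,
                    "baseline_uq_suv": r_base.tumor_uq_suv,
                    "post_uq_suv": r_post.tumor_uq_suv,
                }
            )
        df = pd.DataFrame(rows)
        arm_tables[arm] = df
        stats_out[arm] = {
            "dvr": repeated_measures_compare(df["baseline_dvr"], df["post_dvr"]).to_dict(),
            "uq_suv": repeated_measures_compare(
                df["baseline_uq_suv"], df["post_uq_suv"]
            ).to_dict(),
            "n_pairs": int(len(df)),
            "drug": effect.drug_name,
        }

    long_df = pd.DataFrame(long_rows)
    summary = summarize_cohort(
        long_df.rename(columns={"metric": "condition_metric"}).assign(
            condition=lambda d: d["condition"] + ":" + d["condition_metric"]
        )[["subject", "region", "condition", "value"]]
    )
    summary.to_csv(out / "stats" / "summary.csv", index=False)
    long_df.to_csv(out / "stats" / "per_subject.csv", index=False)
    with open(out / "stats" / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=1)

    # report
    mean_uq = float(np.mean([r.tumor_uq_suv for r in baseline_rows]))
    mean_ratio = float(np.mean([r.tumor_ratio for r in baseline_rows]))
    ex_df = arm_tables["ex527"]
    ex_change = 100.0 * (
        ex_df["post_dvr"].mean() - ex_df["baseline_dvr"].mean()
    ) / ex_df["baseline_dvr"].mean()
    report_lines = [
        f"petquant {__version__} run report (config hash {cfg_hash}, seed {config.seed})",
        "",
        f"baseline cohort (n={config.n_baseline}):",
        f"  tumor upper-quartile SUV @ {config.readout_time_min:g} min: "
        f"{mean_uq:.3f}   (calibration target {CALIBRATION_TARGETS['tumor_uq_suv_20min']})",
        f"  tumor/brainstem SUV ratio:                {mean_ratio:.3f}   "
        f"(calibration target {CALIBRATION_TARGETS['tumor_brainstem_ratio_20min']})",
        "",
        f"EX-527 arm (n={len(ex_df)} pairs):",
        f"  tumor DVR change: {ex_change:+.1f}%   "
        f"(calibration target {CALIBRATION_TARGETS['ex527_dvr_percent_change']:+.0f}%)"
        f"   p={stats_out['ex527']['dvr']['p_value']:.4g}",
        f"MC1568 arm (n={len(arm_tables['mc1568'])} pairs):",
        f"  tumor DVR change: "
        f"{stats_out['mc1568']['dvr']['effect_percent']:+.1f}%"
        f"   p={stats_out['mc1568']['dvr']['p_value']:.4g}",
        "",
        "region x condition summary: stats/summary.csv",
    ]
    (out / "report" / "report.txt").write_text("\n".join(report_lines) + "\n")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "master_seed": config.seed,
        "arm_seeds": {arm: arms[arm][2] for arm in arms},
        "subject_seeds": {s.subject.subject_id: s.seed for s in cohort},
        "baseline_mean_tumor_uq_suv": mean_uq,
        "baseline_mean_tumor_ratio": mean_ratio,
        "ex527_dvr_percent_change": float(ex_change),
        "outputs": {
            "stats": "stats/stats.json",
            "summary": "stats/summary.csv",
            "per_subject": "stats/per_subject.csv",
            "report": "report/report.txt",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
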