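"""Synthetic OPG-like cohort generator with a known, recoverable age signal.

Real panoramic-radiograph cohorts for pediatric age estimation are private
clinical data, so this module simulates one: grayscale images whose
tooth-development appearance depends monotonically on age, and numeric
patient-record fields that are linear in age plus Gaussian noise. The
defaults mirror the demographic structure of a pediatric OPG archive —
ages 6-15 years, two sexes with sex-specific mean ages (10.94 male, 11.1
female), a 275:346 male:female ratio, and 15 record fields.

The image model renders the seven left-mandibular permanent teeth. Each
tooth ``t`` has a developmental onset age; its root-completion fraction at
age ``a`` is ``clamp((a - onset_t) / duration_t, 0, 1)``, and the rendered
root length grows with that fraction. With noise off, total rendered tooth
area is non-decreasing in age — the monotone staging signal an image model
is meant to learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "OpgImage",
    "generate_cohort",
    "render_opg",
    "tooth_completion_fractions",
    "write_cohort",
]

N_TEETH = 7  # left mandibular permanent teeth


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated cohort.

    ``record_slopes`` (per-field effect of age, units of the field per
    year) and ``record_noise_sd`` may be scalars or length-
    ``n_record_fields`` vectors; ``None`` slopes default to an evenly
    spaced ramp over [0.5, 1.5] so every field carries age signal of a
    different strength.
    """

    n_patients: int
    age_range: tuple[float, float] = (6.0, 15.0)
    sex_ratio: float = 275 / 621  # fraction male
    male_mean_age: float = 10.94
    female_mean_age: float = 11.1
    age_sd: float = 2.5
    image_height: int = 64
    image_width: int = 64
    n_record_fields: int = 15
    record_slopes: tuple | None = None
    record_noise_sd: float | tuple = 1.0
    image_noise_sd: float = 4.0
    dental_timing_sd: float = 0.75
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        lo, hi = self.age_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("age_range must satisfy min < max")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.n_record_fields < 1:
            raise ValueError("n_record_fields must be >= 1")
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image dimensions must be at least 8x8")
        if self.image_noise_sd < 0 or np.any(np.asarray(self.record_noise_sd) < 0):
            raise ValueError("noise SDs must be non-negative")
        if self.dental_timing_sd < 0:
            raise ValueError("dental_timing_sd must be non-negative")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")

    @property
    def slopes(self) -> np.ndarray:
        if self.record_slopes is None:
            return np.linspace(0.5, 1.5, self.n_record_fields)
        s = np.asarray(self.record_slopes, dtype=float)
        if s.size != self.n_record_fields:
            raise ValueError("record_slopes length must equal n_record_fields")
        return s

    @property
    def intercepts(self) -> np.ndarray:
        return np.linspace(0.0, 5.0, self.n_record_fields)

    @property
    def noise_sds(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.record_noise_sd, dtype=float), (self.n_record_fields,)
        ).copy()


@dataclass(frozen=True)
class PatientRecord:
    """One subject: id, sex, chronological age (years) and record fields."""

    patient_id: str
    sex: str  # "male" | "female"
    age_years: float
    record_fields: np.ndarray

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        object.__setattr__(
            self, "record_fields", np.asarray(self.record_fields, dtype=float)
        )
        if not np.all(np.isfinite(self.record_fields)):
            raise ValueError("record_fields must be finite")


@dataclass(frozen=True)
class OpgImage:
    """Grayscale pixel grid in [0, 255] linked to a patient id."""

    patient_id: str
    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the target mean.

    Truncation is asymmetric for off-centre means, so drawing from a
    normal *centred* on the target would bias the cohort mean; the
    location is calibrated instead (the truncated mean is strictly
    increasing in the location, so the root is unique).
    """
    if not lo < target_mean < hi:
        raise ValueError("target mean must lie inside the age range")

    def truncated_mean_gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return float(brentq(truncated_mean_gap, lo - 10 * sd, hi + 10 * sd, xtol=1e-10))


def _tooth_onsets_durations(age_range: tuple[float, float]) -> tuple[np.ndarray, float]:
    """Per-tooth developmental onsets spanning the age range.

    Duration is a third of the range; the last onset is ``max - duration``
    so every tooth completes by the top of the range, while teeth with
    onset >= min are still at fraction 0 at the bottom of the range.
    """
    lo, hi = age_range
    duration = (hi - lo) / 3.0
    onsets = np.linspace(lo - duration, hi - duration, N_TEETH)
    return onsets, duration


def tooth_completion_fractions(age: float, age_range: tuple[float, float]) -> np.ndarray:
    """Root-completion fraction of each of the seven teeth at ``age``."""
    onsets, duration = _tooth_onsets_durations(age_range)
    return np.clip((age - onsets) / duration, 0.0, 1.0)


def render_opg(
    record: PatientRecord, config: CohortConfig,
    rng: np.random.Generator | None = None,
    staging_age: float | None = None,
) -> OpgImage:
    """Render one synthetic OPG for a patient.

    Seven teeth sit along a simulated mandibular arch: a fixed crown
    (ellipse) per tooth plus a tapering root whose length is the tooth's
    root-completion fraction times the full root length. ``staging_age``
    is the developmental (dental) age driving tooth appearance; it
    defaults to the chronological age. Additive Gaussian pixel noise with
    SD ``config.image_noise_sd`` is applied (drawn from ``rng``), and
    intensities are clipped to [0, 255].
    """
    if not np.isfinite(record.age_years):
        raise ValueError("age must be finite")
    if staging_age is None:
        staging_age = record.age_years
    H, W = config.image_height, config.image_width
    fracs = tooth_completion_fractions(staging_age, config.age_range)

    img = np.full((H, W), 25.0)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    crown_cy = 0.30 * H
    crown_ry = 0.06 * H
    crown_rx = 0.045 * W
    root_len_max = 0.38 * H
    root_w0 = 0.035 * W  # root half-width at the crown, tapering to a point

    for t in range(N_TEETH):
        cx = (t + 1.5) / (N_TEETH + 2) * W
        crown = ((yy - crown_cy) / crown_ry) ** 2 + ((xx - cx) / crown_rx) ** 2 <= 1.0
        img[crown] = 235.0
        root_len = fracs[t] * root_len_max
        if root_len > 0:
            y0 = crown_cy + crown_ry * 0.5
            depth = yy - y0
            taper = 1.0 - depth / root_len_max  # full-length taper profile
            root = (depth >= 0) & (depth <= root_len) & (
                np.abs(xx - cx) <= root_w0 * np.clip(taper, 0.0, 1.0)
            )
            img[root] = 210.0

    # faint mandibular border so the background is not flat
    border = np.abs(yy - 0.85 * H) <= 0.015 * H
    img[border] = 90.0

    if config.image_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        img = img + rng.normal(0.0, config.image_noise_sd, size=img.shape)
    return OpgImage(patient_id=record.patient_id, pixels=np.clip(img, 0.0, 255.0))


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], list[OpgImage]]:
    """Draw a full synthetic cohort (records and images) from ``config``.

    Sex is Bernoulli(``sex_ratio``); age is a sex-specific truncated
    normal on ``age_range``; record field ``j`` is
    ``slope_j * age + intercept_j + N(0, noise_sd_j)``. The image is
    rendered at a *dental* age ``age + N(0, dental_timing_sd)``:
    individuals of the same chronological age differ in developmental
    stage, so the image signal carries biological noise that the record
    fields do not share. Regeneration with the same config (including
    seed) is bit-identical.
    """
    rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.age_range
    n = config.n_patients
    width = max(4, len(str(max(n, 1))))

    is_male = rng.random(n) < config.sex_ratio
    records: list[PatientRecord] = []
    images: list[OpgImage] = []
    slopes, intercepts, noise_sds = config.slopes, config.intercepts, config.noise_sds
    loc_by_sex = {
        True: _truncnorm_loc(config.male_mean_age, config.age_sd, lo, hi),
        False: _truncnorm_loc(config.female_mean_age, config.age_sd, lo, hi),
    } if n else {}
    for i in range(n):
        loc = loc_by_sex[bool(is_male[i])]
        a, b = (lo - loc) / config.age_sd, (hi - loc) / config.age_sd
        age = float(stats.truncnorm.rvs(a, b, loc=loc, scale=config.age_sd, random_state=rng))
        fields = slopes * age + intercepts + rng.normal(0.0, noise_sds)
        rec = PatientRecord(
            patient_id=f"P{i:0{width}d}",
            sex="male" if is_male[i] else "female",
            age_years=age,
            record_fields=fields,
        )
        records.append(rec)
        dental_age = age + rng.normal(0.0, config.dental_timing_sd)
        images.append(render_opg(rec, config, rng, staging_age=dental_age))
    return records, images


def write_cohort(
    records: list[PatientRecord], images: list[OpgImage], out_dir: str | Path
) -> Path:
    """Write PNG images and a CSV manifest; return the manifest path.

    Manifest columns: ``patient_id, sex, age_years, image_path,
    record_1..record_k``; image paths are relative to the manifest's
    directory. Patient ids of records and images must match pairwise.
    """
    if len(records) != len(images):
        raise ValueError("records and images must have equal length")
    for rec, img in zip(records, images):
        if rec.patient_id != img.patient_id:
            raise ValueError(
                f"patient id mismatch: record {rec.patient_id!r} vs image {img.patient_id!r}"
            )
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for rec, img in zip(records, images):
        rel = Path("images") / f"{rec.patient_id}.png"
        arr = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / rel)
        row = {
            "patient_id": rec.patient_id,
            "sex": rec.sex,
            "age_years": rec.age_years,
            "image_path": str(rel),
        }
        for j, v in enumerate(rec.record_fields, start=1):
            row[f"record_{j}"] = v
        rows.append(row)

    if rows:
        manifest = pd.DataFrame(rows)
    else:
        k = 0 if not records else records[0].record_fields.size
        cols = ["patient_id", "sex", "age_years", "image_path"] + [
            f"record_{j}" for j in range(1, k + 1)
        ]
        manifest = pd.DataFrame(columns=cols)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
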