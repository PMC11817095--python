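"""Cohort cleaning and the two normalisations of the pipeline.

Images are min-max scaled per image into [0, 1]; patient-record fields are
Z-score standardised with parameters fitted on the training rows only and
reused on held-out rows, so no test-set statistics leak into the model.
The Z-score uses the population standard deviation (``n`` denominator),
matching the package's population-style metric conventions. Ages (labels)
are never standardised; predictions stay in years.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CleanReport",
    "StandardizationParams",
    "drop_incomplete",
    "minmax_scale_image",
    "zscore_fit_transform",
    "zscore_apply",
]

#: Columns every cohort manifest must carry (record_* columns come after).
MANDATORY_COLUMNS = ("patient_id", "sex", "age_years", "image_path")


@dataclass(frozen=True)
class CleanReport:
    """Outcome of row-wise deletion of incomplete manifest rows."""

    n_input_rows: int
    n_dropped_rows: int
    dropped_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_dropped_rows != len(self.dropped_ids):
            raise ValueError("n_dropped_rows must equal |dropped_ids|")
        if self.n_dropped_rows > self.n_input_rows:
            raise ValueError("cannot drop more rows than were present")


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column mean/SD fitted on the training split.

    ``fitted_on`` records the split the statistics came from; applying the
    same parameters to held-out data is what prevents leakage.
    """

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: str = "train"

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have the same length")
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be non-negative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "sd": self.sd.tolist(),
                "fitted_on": self.fitted_on,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "StandardizationParams":
        d = json.loads(text)
        return cls(mean=np.array(d["mean"]), sd=np.array(d["sd"]), fitted_on=d["fitted_on"])


def drop_incomplete(manifest: pd.DataFrame) -> tuple[pd.DataFrame, CleanReport]:
    """Remove every manifest row with a missing or non-finite field.

    Row order of the survivors is preserved. Non-numeric columns are
    checked for missingness/blank strings; numeric columns additionally
    for NaN/inf.

    Raises
    ------
    ValueError
        If a mandatory manifest column is absent.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing mandatory columns: {missing}")

    bad = manifest.isna().any(axis=1)
    for col in manifest.columns:
        s = manifest[col]
        if pd.api.types.is_numeric_dtype(s):
            bad |= ~np.isfinite(s.fillna(np.nan).astype(float))
        else:
            bad |= s.astype(str).str.strip().eq("")
    kept = manifest.loc[~bad]
    report = CleanReport(
        n_input_rows=int(len(manifest)),
        n_dropped_rows=int(bad.sum()),
        dropped_ids=manifest.loc[bad, "patient_id"].tolist(),
    )
    return kept.reset_index(drop=True), report


def minmax_scale_image(pixels: np.ndarray) -> np.ndarray:
    """Linearly rescale an image's intensities onto [0, 1].

    The minimum and maximum are taken over the whole image, so the output
    attains both 0 and 1 whenever the input is not constant. A constant
    image cannot be rescaled; it maps to all zeros with a warning.
    """
    x = np.asarray(pixels, dtype=float)
    if x.size == 0:
        raise ValueError("image must contain at least one pixel")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn("constant image: min-max scaling returns all zeros", stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def zscore_fit_transform(
    train_fields: np.ndarray, apply_fields: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, StandardizationParams]:
    """Standardise record fields column-wise, fitting on the training rows.

    Returns the standardised training matrix, the standardised apply
    matrix (``None`` if not given), and the fitted parameters. Columns
    with zero variance on train are mapped to zero everywhere (with a
    warning) rather than dividing by zero.
    """
    X = np.asarray(train_fields, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("train_fields must be a 2-D matrix with at least 2 rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    if np.any(sd == 0):
        warnings.warn(
            "zero-variance training column(s) set to 0 after standardisation",
            stacklevel=2,
        )
    params = StandardizationParams(mean=mu, sd=sd)
    out_apply = None if apply_fields is None else zscore_apply(apply_fields, params)
    return zscore_apply(X, params), out_apply, params


def zscore_apply(fields: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Apply previously fitted standardisation parameters to a matrix."""
    X = np.asarray(fields, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.mean.size:
        raise ValueError(
            f"expected a 2-D matrix with {params.mean.size} columns, got shape {X.shape}"
        )
    safe_sd = np.where(params.sd == 0, 1.0, params.sd)
    Z = (X - params.mean) / safe_sd
    Z[:, params.sd == 0] = 0.0
    return Z
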