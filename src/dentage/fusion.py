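"""Per-patient feature containers and early fusion by concatenation.

The fused representation is the image-path feature vector followed by the
record-path feature vector for each patient. Alignment is by explicit
patient-id comparison — mismatched or reordered ids raise instead of being
silently reindexed, because silent misalignment would corrupt every
downstream estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "concatenate_features"]

MODALITIES = ("image", "record", "fused")


@dataclass(frozen=True)
class FeatureMatrix:
    """An n x d matrix of per-patient features with aligned ids."""

    patient_ids: list
    values: np.ndarray
    modality: str
    column_names: list = field(default=None)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "patient_ids", list(self.patient_ids))
        if len(self.patient_ids) != vals.shape[0]:
            raise ValueError("|patient_ids| must equal the number of rows")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("feature values must be finite")
        if self.column_names is None:
            names = [f"f_{j + 1:04d}" for j in range(vals.shape[1])]
            object.__setattr__(self, "column_names", names)
        else:
            object.__setattr__(self, "column_names", list(self.column_names))
            if len(self.column_names) != vals.shape[1]:
                raise ValueError("|column_names| must equal the number of columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def select_columns(self, prefix: str) -> "FeatureMatrix":
        """Project onto the columns whose names start with ``prefix``."""
        idx = [j for j, c in enumerate(self.column_names) if c.startswith(prefix)]
        return FeatureMatrix(
            patient_ids=self.patient_ids,
            values=self.values[:, idx],
            modality=self.modality,
            column_names=[self.column_names[j] for j in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "patient_id", self.patient_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, modality: str) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "patient_id" not in df.columns:
            raise ValueError("feature CSV must have a patient_id column")
        cols = [c for c in df.columns if c != "patient_id"]
        return cls(
            patient_ids=df["patient_id"].astype(str).tolist(),
            values=df[cols].to_numpy(dtype=float) if cols else np.empty((len(df), 0)),
            modality=modality,
            column_names=cols,
        )


def concatenate_features(f_img: FeatureMatrix, f_rec: FeatureMatrix) -> FeatureMatrix:
    """Early fusion: per-patient concatenation of image and record features.

    Column names are prefixed ``img_`` / ``rec_`` so either block can be
    projected back out bit-identically. Patient ids must match pairwise in
    order.
    """
    if f_img.modality != "image" or f_rec.modality != "record":
        raise ValueError("expected an image-modality and a record-modality matrix")
    if f_img.patient_ids != f_rec.patient_ids:
        raise ValueError(
            "patient id mismatch between image and record features; "
            "refusing to reorder silently"
        )
    values = np.hstack([f_img.values, f_rec.values])
    names = [f"img_{c}" for c in f_img.column_names] + [f"rec_{c}" for c in f_rec.column_names]
    return FeatureMatrix(
        patient_ids=f_img.patient_ids, values=values, modality="fused", column_names=names
    )
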