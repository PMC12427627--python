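"""Leakage-safe preprocessing of behavioral phenotype tables.

Fit/apply split of the tabular cleaning pipeline: identifier-column
dropping, per-column median imputation of numeric features, alphabetical
integer encoding of categoricals, and min-max scaling of every feature to
[0, 1].  All statistics (medians, category maps, scaling bounds) are
computed only in ``fit_preprocessor`` and are frozen thereafter, so a state
fitted on a training split can be applied to any other split without
information leaking back.

Also provides diagnosis-label encoding (DX_GROUP 1 = Control -> 0,
2 = ASD -> 1) and cross-modality subject alignment by sorted-id
intersection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessorState",
    "FeatureMatrix",
    "LabelVector",
    "fit_preprocessor",
    "apply_preprocessor",
    "encode_labels",
    "align_modalities",
]

DEFAULT_ID_COLUMNS = ("SUBJ_ID", "ID", "Participant_ID", "Name")
DEFAULT_LABEL_COLUMN = "DX_GROUP"


@dataclass
class PreprocessorState:
    """Frozen fit statistics of the tabular cleaning pipeline."""

    id_columns: list
    medians: dict  # numeric column -> imputation value
    category_maps: dict  # categorical column -> {level: code}
    feature_mins: dict
    feature_maxs: dict
    feature_order: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "id_columns": self.id_columns,
                "medians": self.medians,
                "category_maps": self.category_maps,
                "feature_mins": self.feature_mins,
                "feature_maxs": self.feature_maxs,
                "feature_order": self.feature_order,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessorState":
        d = json.loads(text)
        return cls(**d)


@dataclass
class FeatureMatrix:
    """Subjects x features array with every value in [0, 1]."""

    values: np.ndarray
    feature_names: list
    subject_ids: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class LabelVector:
    """Binary diagnosis labels, 0 = Control, 1 = ASD."""

    y: np.ndarray

    @property
    def onehot(self) -> np.ndarray:
        out = np.zeros((len(self.y), 2))
        out[np.arange(len(self.y)), self.y] = 1.0
        return out

    def __len__(self) -> int:
        return len(self.y)


def fit_preprocessor(
    table: pd.DataFrame,
    id_columns=DEFAULT_ID_COLUMNS,
    label_column: str = DEFAULT_LABEL_COLUMN,
) -> PreprocessorState:
    """Compute imputation, encoding and scaling statistics from a table.

    Identifier columns that do not exist are ignored with a warning; an
    all-missing numeric column is an error (no median exists for it).
    The label column, when present, is excluded from the feature set.
    """
    if table.empty:
        raise ValueError("cannot fit a preprocessor on an empty table")
    present_ids = [c for c in id_columns if c in table.columns]
    missing_ids = [c for c in id_columns if c not in table.columns]
    if missing_ids and tuple(id_columns) != DEFAULT_ID_COLUMNS:
        warnings.warn(f"id columns not found and ignored: {missing_ids}")

    drop = set(present_ids)
    if label_column in table.columns:
        drop.add(label_column)
    feats = table.drop(columns=sorted(drop))

    medians: dict = {}
    category_maps: dict = {}
    mins: dict = {}
    maxs: dict = {}
    for col in feats.columns:
        s = feats[col]
        if pd.api.types.is_numeric_dtype(s):
            observed = s.dropna()
            if observed.empty:
                raise ValueError(f"numeric column {col!r} is entirely missing")
            med = float(observed.median())
            medians[col] = med
            filled = s.fillna(med).astype(float)
            mins[col] = float(filled.min())
            maxs[col] = float(filled.max())
        else:
            levels = sorted(str(v) for v in s.dropna().unique())
            cmap = {lvl: i for i, lvl in enumerate(levels)}
            category_maps[col] = cmap
            codes = s.dropna().astype(str).map(cmap)
            mins[col] = float(codes.min()) if len(codes) else 0.0
            maxs[col] = float(codes.max()) if len(codes) else 0.0
    return PreprocessorState(
        id_columns=present_ids,
        medians=medians,
        category_maps=category_maps,
        feature_mins=mins,
        feature_maxs=maxs,
        feature_order=list(feats.columns),
    )


def apply_preprocessor(
    state: PreprocessorState,
    table: pd.DataFrame,
    subject_id_column: str = "SUBJ_ID",
) -> FeatureMatrix:
    """Impute, encode and scale a table using frozen fit statistics.

    Scaling is (x - min) / (max - min) with clipping to [0, 1]; a constant
    fitted column maps to 0.  An unseen categorical level is mapped to the
    reserved code ``len(category_map)`` (then scaled and clipped), so
    cross-site tables never crash the pipeline.
    """
    missing_cols = [c for c in state.feature_order if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table is missing fitted columns: {missing_cols}")

    n = len(table)
    out = np.empty((n, len(state.feature_order)))
    for j, col in enumerate(state.feature_order):
        s = table[col]
        if col in state.medians:
            v = s.astype(float).fillna(state.medians[col]).to_numpy()
        else:
            cmap = state.category_maps[col]
            reserved = float(len(cmap))
            v = np.array(
                [
                    reserved if pd.isna(x) else float(cmap.get(str(x), reserved))
                    for x in s
                ]
            )
        lo, hi = state.feature_mins[col], state.feature_maxs[col]
        if hi > lo:
            v = (v - lo) / (hi - lo)
        else:
            v = np.zeros_like(v)
        out[:, j] = np.clip(v, 0.0, 1.0)
    ids = (
        list(table[subject_id_column])
        if subject_id_column in table.columns
        else list(range(n))
    )
    return FeatureMatrix(values=out, feature_names=list(state.feature_order),
                         subject_ids=ids)


def encode_labels(dx) -> LabelVector:
    """Map the DX_GROUP coding (1 = Control, 2 = ASD) to 0/1 labels."""
    dx = np.asarray(dx)
    if dx.size == 0:
        raise ValueError("empty DX_GROUP column")
    bad = set(np.unique(dx)) - {1, 2}
    if bad:
        raise ValueError(f"DX_GROUP values outside {{1, 2}}: {sorted(bad)}")
    return LabelVector(y=(dx.astype(np.int64) - 1))


def align_modalities(
    behavioral: FeatureMatrix, mri_ids, labels: LabelVector
):
    """Keep subjects present in both modalities, sorted by subject id.

    Returns ``(behavioral, mri_index, labels)`` where ``mri_index`` gives,
    for each retained subject in sorted-id order, its position in the
    original ``mri_ids`` sequence.
    """
    mri_ids = list(mri_ids)
    beh_pos = {sid: i for i, sid in enumerate(behavioral.subject_ids)}
    mri_pos = {sid: i for i, sid in enumerate(mri_ids)}
    common = sorted(set(beh_pos) & set(mri_pos))
    if not common:
        raise ValueError("no subjects present in both modalities")
    bidx = np.array([beh_pos[s] for s in common])
    midx = np.array([mri_pos[s] for s in common])
    aligned = FeatureMatrix(
        values=behavioral.values[bidx],
        feature_names=behavioral.feature_names,
        subject_ids=common,
    )
    return aligned, midx, LabelVector(y=labels.y[bidx])
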