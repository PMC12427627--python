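"""Synthetic multimodal cohorts for end-to-end testing of the pipeline.

Generates paired behavioral tables and 3-D "structural" volumes with a known
planted class signal, plus a toy brain atlas, so every downstream stage
(preprocessing, additive behavioral network, CNN-GNN encoder, fusion,
hypernetwork classifier) can be exercised and calibrated without any real
neuroimaging download.

The planted structure is deliberately minimal: behavioral features are
standard-normal noise with a mean shift on a chosen subset of features for
the positive (ASD) class; volumes are unit-variance noise with a mean
intensity shift inside a chosen subset of atlas regions.  Missing behavioral
cells are inserted completely at random.  Everything is a deterministic
function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohort",
    "generate_toy_atlas",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass
class SyntheticCohort:
    """A paired behavioral + volumetric cohort with ground-truth record.

    ``behavioral`` uses the phenotype-table convention of a ``SUBJ_ID``
    column, feature columns, and a ``DX_GROUP`` column coded 1 = Control,
    2 = ASD.  ``labels`` is the 0/1 recoding (1 = ASD).  ``truth`` records
    which features / atlas regions carry the planted signal.
    """

    behavioral: pd.DataFrame
    volumes: np.ndarray  # (n, D, H, W)
    atlas: np.ndarray  # (D, H, W) integer labels, 0 = background
    labels: np.ndarray  # (n,) in {0, 1}
    truth: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    @property
    def subject_ids(self) -> list:
        return list(self.behavioral["SUBJ_ID"])


def _grid_splits(shape: tuple, n_rois: int) -> tuple:
    """Pick the most balanced factorization (na, nb, nc) of n_rois that fits.

    Preference order: exact divisibility of each dimension (equal-size
    blocks), then minimal spread between block counts, then lexicographic.
    """
    best = None
    for na in range(1, n_rois + 1):
        if n_rois % na:
            continue
        rem = n_rois // na
        for nb in range(1, rem + 1):
            if rem % nb:
                continue
            nc = rem // nb
            cand = (na, nb, nc)
            if any(c > s for c, s in zip(cand, shape)):
                continue
            divisible = all(s % c == 0 for s, c in zip(shape, cand))
            key = (not divisible, max(cand) - min(cand), cand)
            if best is None or key < best[0]:
                best = (key, cand)
    if best is None:
        raise ValueError(
            f"cannot partition shape {shape} into {n_rois} contiguous blocks"
        )
    return best[1]


def generate_toy_atlas(shape: tuple, n_rois: int, seed: int = 0) -> np.ndarray:
    """Regular grid partition of a 3-D volume into contiguous labeled blocks.

    Labels run 1..n_rois; with this construction every voxel is assigned
    (no background).  The partition is deterministic; ``seed`` is accepted
    for interface symmetry.  The regular-grid layout gives the region
    adjacency a known closed form, which the encoder tests exploit.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 4 for s in shape):
        raise ValueError("shape must be 3-D with each dim >= 4")
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    if n_rois > int(np.prod(shape)):
        raise ValueError("n_rois exceeds the voxel count")
    splits = _grid_splits(shape, n_rois)
    edges = [np.array_split(np.arange(s), c) for s, c in zip(shape, splits)]
    atlas = np.zeros(shape, dtype=np.int32)
    label = 1
    for ia in edges[0]:
        for ib in edges[1]:
            for ic in edges[2]:
                atlas[np.ix_(ia, ib, ic)] = label
                label += 1
    return atlas


def generate_cohort(
    n: int,
    n_features: int = 20,
    behavioral_effect: float = 0.0,
    n_informative_features: int = 5,
    roi_effect: float = 0.0,
    informative_rois: int = 3,
    shape: tuple = (16, 16, 16),
    n_rois: int = 16,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a class-balanced synthetic multimodal cohort.

    Parameters
    ----------
    n : total subject count (classes balanced to within one subject).
    behavioral_effect : mean shift, in noise SD units, added to each of the
        ``n_informative_features`` behavioral features for ASD subjects.
    roi_effect : mean intensity shift inside each of ``informative_rois``
        atlas regions for ASD subjects.
    missing_rate : per-cell probability of a missing behavioral value.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if n_informative_features > n_features:
        raise ValueError("n_informative_features exceeds n_features")
    if informative_rois > n_rois:
        raise ValueError("informative_rois exceeds n_rois")
    if n < 4:
        raise ValueError("need at least 4 subjects")

    rng = np.random.default_rng(seed)
    atlas = generate_toy_atlas(shape, n_rois, seed=seed)

    labels = np.zeros(n, dtype=np.int64)
    labels[: n // 2] = 1  # ceil(n/2) controls, floor(n/2) ASD
    rng.shuffle(labels)

    feat_idx = np.sort(rng.choice(n_features, n_informative_features, replace=False))
    roi_labels = np.sort(rng.choice(np.arange(1, n_rois + 1), informative_rois,
                                    replace=False))

    X = rng.standard_normal((n, n_features))
    X[np.ix_(labels == 1, feat_idx)] += behavioral_effect

    volumes = rng.standard_normal((n,) + tuple(shape))
    roi_mask = np.isin(atlas, roi_labels)
    volumes[labels == 1] += roi_effect * roi_mask

    if missing_rate > 0:
        miss = rng.random((n, n_features)) < missing_rate
        X[miss] = np.nan

    ids = [f"S{i:04d}" for i in range(n)]
    table = pd.DataFrame(X, columns=[f"feat_{j:02d}" for j in range(n_features)])
    table.insert(0, "SUBJ_ID", ids)
    table["DX_GROUP"] = labels + 1  # 1 = Control, 2 = ASD

    truth = {
        "informative_features": feat_idx.tolist(),
        "informative_feature_names": [f"feat_{j:02d}" for j in feat_idx],
        "informative_rois": roi_labels.tolist(),
        "behavioral_effect": float(behavioral_effect),
        "roi_effect": float(roi_effect),
        "missing_rate": float(missing_rate),
        "seed": int(seed),
    }
    return SyntheticCohort(
        behavioral=table, volumes=volumes, atlas=atlas, labels=labels, truth=truth
    )


# IO --------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Persist a cohort: behavioral CSV, NIfTI volumes + atlas, truth JSON."""
    import nibabel as nib

    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    cohort.behavioral.to_csv(out / "behavioral.csv", index=False)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(cohort.atlas.astype(np.int32), affine),
             out / "atlas.nii.gz")
    for sid, vol in zip(cohort.subject_ids, cohort.volumes):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                 out / "volumes" / f"{sid}.nii.gz")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2)


def read_cohort(in_dir) -> SyntheticCohort:
    """Load a cohort written by :func:`write_cohort`."""
    import nibabel as nib

    src = Path(in_dir)
    table = pd.read_csv(src / "behavioral.csv")
    atlas = np.asarray(nib.load(src / "atlas.nii.gz").dataobj).astype(np.int32)
    vols = [
        np.asarray(nib.load(src / "volumes" / f"{sid}.nii.gz").dataobj,
                   dtype=np.float64)
        for sid in table["SUBJ_ID"]
    ]
    truth = {}
    truth_path = src / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    labels = (table["DX_GROUP"].to_numpy() - 1).astype(np.int64)
    return SyntheticCohort(
        behavioral=table, volumes=np.stack(vols), atlas=atlas,
        labels=labels, truth=truth,
    )
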