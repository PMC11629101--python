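"""Reading, validation and normalization of subject x VOI uptake tables.

The tabular currency of the pipeline is the :class:`UptakeMatrix`: one group's
subjects in rows, brain volumes of interest (VOIs) in columns, holding strictly
positive normalized-uptake values.  Tables arrive as TSV/CSV files with a
``subject_id`` first column, or as per-subject rows extracted from a PET volume
with an integer-labelled atlas (:func:`extract_voi_means`).

Intensity normalization divides each subject's row by their whole-brain mean
uptake, so values express regional uptake relative to the brain average.  When
only VOI-level tables exist, the whole-brain mean is the volume-weighted mean
of the VOI values; with weights equal to atlas voxel counts this reproduces the
voxel-level whole-brain mean exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("petnet")

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}


@dataclass(frozen=True)
class UptakeMatrix:
    """One group's subjects x VOIs uptake values.

    Parameters
    ----------
    subject_ids : unique subject identifiers, one per row.
    voi_labels : unique VOI names, one per column.
    values : float array of shape ``(n_subjects, n_vois)``, strictly positive.
    group : group tag, e.g. ``"f-ALS"``.
    normalized : whether rows have been divided by their whole-brain mean.
    """

    subject_ids: tuple[str, ...]
    voi_labels: tuple[str, ...]
    values: np.ndarray
    group: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "voi_labels", tuple(str(v) for v in self.voi_labels))
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x VOIs array")
        if values.shape != (len(self.subject_ids), len(self.voi_labels)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.voi_labels)} VOIs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            dupes = _duplicates(self.subject_ids)
            raise ValueError(f"duplicate subject IDs: {dupes}")
        if len(set(self.voi_labels)) != len(self.voi_labels):
            dupes = _duplicates(self.voi_labels)
            raise ValueError(f"duplicate VOI labels: {dupes}")
        if not np.all(np.isfinite(values)):
            raise ValueError("uptake values contain non-finite entries")
        if np.any(values <= 0):
            i, j = map(int, np.argwhere(values <= 0)[0])
            raise ValueError(
                f"uptake values must be strictly positive; "
                f"subject {self.subject_ids[i]!r}, VOI {self.voi_labels[j]!r} "
                f"has value {values[i, j]}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_vois(self) -> int:
        return len(self.voi_labels)

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame indexed by subject_id."""
        return pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=list(self.voi_labels)
        ).rename_axis("subject_id")


@dataclass(frozen=True)
class AtlasVolume:
    """Integer-labelled 3-D atlas defining the VOIs of a PET volume.

    ``label_array`` holds one integer per voxel, 0 meaning background;
    ``label_table`` maps each nonzero label to its VOI name and fixes the VOI
    column order; ``voxel_volume`` is the voxel size in mm^3.
    """

    label_array: np.ndarray
    label_table: Mapping[int, str]
    voxel_volume: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.label_array)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("label_array must be an integer array")
        if arr.ndim != 3:
            raise ValueError("label_array must be 3-D")
        if arr.min() < 0:
            raise ValueError("atlas labels must be non-negative integers")
        object.__setattr__(self, "label_array", arr)
        table = dict(self.label_table)
        object.__setattr__(self, "label_table", table)
        if 0 in table:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(arr).tolist())
        for lab, name in table.items():
            if lab not in present:
                raise ValueError(f"VOI {name!r} (label {lab}) has no voxels in the atlas")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")

    def voxel_counts(self) -> np.ndarray:
        """Number of voxels per VOI, in label_table order."""
        flat = self.label_array.ravel()
        return np.array([int(np.sum(flat == lab)) for lab in self.label_table])


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def read_uptake_table(
    path: str | Path,
    group: str = "",
    *,
    missing_policy: str = "fail",
) -> UptakeMatrix:
    """Read a subject x VOI uptake table from a TSV/CSV file.

    The file must have a header row; the first column is the subject ID and
    the remaining columns are numeric uptake values.  The delimiter is a comma
    for ``.csv`` files and a tab otherwise.

    Parameters
    ----------
    path : table location.
    group : group tag attached to the result.
    missing_policy : ``"fail"`` (default) raises on any missing cell;
        ``"drop-subject"`` removes subjects with missing values.

    Raises
    ------
    ValueError : on duplicate subject IDs, non-numeric cells, missing data
        under the ``fail`` policy, or fewer than 3 usable subjects.
    """
    if missing_policy not in ("fail", "drop-subject"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected a subject-ID column plus at least one VOI column")

    subject_ids = raw.iloc[:, 0].astype(str).tolist()
    dupes = _duplicates(subject_ids)
    if dupes:
        raise ValueError(f"{path}: duplicate subject IDs: {dupes}")
    voi_labels = [str(c) for c in raw.columns[1:]]

    cells = raw.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(cells.shape, dtype=float)
    missing = np.zeros(cells.shape, dtype=bool)
    for (i, j), cell in np.ndenumerate(cells):
        text = str(cell).strip()
        if text.lower() in _MISSING_TOKENS:
            missing[i, j] = True
            values[i, j] = np.nan
            continue
        try:
            values[i, j] = float(text)
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric value {text!r} for subject "
                f"{subject_ids[i]!r}, VOI {voi_labels[j]!r}"
            ) from None

    if missing.any():
        i, j = map(int, np.argwhere(missing)[0])
        if missing_policy == "fail":
            raise ValueError(
                f"{path}: missing value for subject {subject_ids[i]!r}, "
                f"VOI {voi_labels[j]!r} (missing_policy='fail')"
            )
        keep = ~missing.any(axis=1)
        dropped = [s for s, k in zip(subject_ids, keep) if not k]
        logger.warning("%s: dropped %d subject(s) with missing values: %s", path, len(dropped), dropped)
        subject_ids = [s for s, k in zip(subject_ids, keep) if k]
        values = values[keep]

    if len(subject_ids) < 3:
        raise ValueError(
            f"{path}: {len(subject_ids)} usable subjects; at least 3 are required "
            "for a Pearson correlation network"
        )
    return UptakeMatrix(tuple(subject_ids), tuple(voi_labels), values, group=group, normalized=False)


def write_uptake_table(m: UptakeMatrix, path: str | Path) -> None:
    """Write an UptakeMatrix back to TSV/CSV (delimiter chosen by extension).

    Values are written with shortest round-tripping decimal representation, so
    a read-write-read cycle preserves them bit-exactly.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["subject_id", *m.voi_labels]) + "\n")
        for sid, row in zip(m.subject_ids, m.values):
            fh.write(sep.join([sid, *(repr(float(v)) for v in row)]) + "\n")


def normalize_global_mean(
    m: UptakeMatrix,
    region_volumes: Sequence[float] | np.ndarray | None = None,
) -> UptakeMatrix:
    """Divide each subject's row by their whole-brain mean uptake.

    The whole-brain mean is the volume-weighted mean of the VOI values
    (uniform weights when ``region_volumes`` is None).  With weights equal to
    atlas voxel counts this equals the voxel-level whole-brain mean over the
    union of VOIs.  Already-normalized input is returned unchanged (the
    ``normalized`` flag guard makes the operation idempotent).
    """
    if m.normalized:
        logger.debug("normalize_global_mean: input already normalized; no-op")
        return m
    if region_volumes is None:
        w = np.ones(m.n_vois)
    else:
        w = np.asarray(region_volumes, dtype=float)
        if w.shape != (m.n_vois,):
            raise ValueError(f"region_volumes must have length {m.n_vois}, got shape {w.shape}")
        if np.any(w <= 0):
            raise ValueError("region_volumes must be strictly positive")
    means = m.values @ w / w.sum()
    if np.any(means <= 0):
        i = int(np.argmax(means <= 0))
        raise ValueError(f"nonpositive whole-brain mean for subject {m.subject_ids[i]!r}")
    values = m.values / means[:, None]
    out = replace(m, values=values, normalized=True)
    check = out.values @ w / w.sum()
    if not np.allclose(check, 1.0, rtol=1e-9, atol=0):
        raise AssertionError("post-normalization weighted means deviate from 1")
    return out


def extract_voi_means(pet_volume: np.ndarray, atlas: AtlasVolume) -> np.ndarray:
    """Mean PET value per VOI, in the atlas label_table order.

    Background voxels (label 0) never contribute.  Returns a 1-D array of
    length ``len(atlas.label_table)`` — one subject's uptake row.
    """
    pet = np.asarray(pet_volume, dtype=float)
    if pet.shape != atlas.label_array.shape:
        raise ValueError(
            f"PET volume shape {pet.shape} does not match atlas shape {atlas.label_array.shape}"
        )
    flat_pet = pet.ravel()
    flat_lab = atlas.label_array.ravel()
    out = np.empty(len(atlas.label_table), dtype=float)
    for k, (lab, name) in enumerate(atlas.label_table.items()):
        mask = flat_lab == lab
        if not mask.any():
            raise ValueError(f"VOI {name!r} (label {lab}) has no voxels")
        out[k] = flat_pet[mask].mean()
    return out
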