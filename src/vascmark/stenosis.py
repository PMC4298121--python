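"""Peripheral stenosis scoring over the 27-segment arterial tree.

Visual grades use a five-class scale: class 1 (0% stenosis), 2 (1-50%),
3 (51-75%), 4 (76-99%), 5 (100% / occlusion).  Per patient, Max SC is the
highest class over the available segments and Mean SC the arithmetic mean
over the available segments; unavailable segments are excluded from both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

N_SEGMENTS = 27
CLASSES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class PatientStenosisSummary:
    patient_id: str
    max_sc: int
    mean_sc: float
    n_segments_available: int


def stenosis_class(percent: float) -> int:
    """Map a percent stenosis reading to its class.

    Boundaries are pinned: 0 -> 1, (0, 50] -> 2, (50, 75] -> 3,
    (75, 100) -> 4, 100 -> 5.
    """
    if not 0 <= percent <= 100:
        raise DataError(f"percent stenosis {percent} outside [0, 100]")
    if percent == 0:
        return 1
    if percent <= 50:
        return 2
    if percent <= 75:
        return 3
    if percent < 100:
        return 4
    return 5


def _as_class(reading_type: str, value: float) -> int:
    if reading_type == "percent":
        return stenosis_class(float(value))
    if reading_type == "class":
        cls = int(value)
        if cls not in CLASSES:
            raise DataError(f"stenosis class {value} not in {CLASSES}")
        return cls
    raise DataError(f"unknown reading type {reading_type!r}")


def segment_class(readings) -> int:
    """Highest stenosis class among all readings within one segment.

    ``readings`` is a non-empty iterable of (reading_type, value) pairs with
    reading_type 'percent' or 'class'; bare numbers are taken as percents.
    """
    readings = list(readings)
    if not readings:
        raise DataError("segment has no readings (unavailable)")
    classes = []
    for r in readings:
        if isinstance(r, (int, float)):
            classes.append(stenosis_class(float(r)))
        else:
            kind, value = r
            classes.append(_as_class(kind, value))
    return max(classes)


def patient_summary(classes, patient_id: str = "") -> PatientStenosisSummary:
    """Max SC and Mean SC over the available segments of one patient.

    ``classes`` is an iterable over up to 27 per-segment classes; ``None`` or
    NaN entries mark unavailable segments and are excluded.
    """
    arr = np.asarray(
        [np.nan if c is None else float(c) for c in classes], dtype=float
    )
    if arr.size > N_SEGMENTS:
        raise DataError(f"more than {N_SEGMENTS} segments supplied")
    avail = arr[~np.isnan(arr)]
    if avail.size == 0:
        raise DataError(f"patient {patient_id!r}: no available segments")
    if not np.isin(avail, CLASSES).all():
        raise DataError(f"patient {patient_id!r}: classes must be in {CLASSES}")
    return PatientStenosisSummary(
        patient_id=patient_id,
        max_sc=int(avail.max()),
        mean_sc=float(avail.mean()),
        n_segments_available=int(avail.size),
    )


def summarize_class_matrix(classes: np.ndarray) -> pd.DataFrame:
    """Vectorized per-patient summary of an (n_patients, 27) class matrix.

    NaN marks unavailable segments.  Returns a frame with columns
    max_sc, mean_sc, n_segments_available.
    """
    arr = np.asarray(classes, dtype=float)
    if arr.ndim != 2 or arr.shape[1] > N_SEGMENTS:
        raise DataError(f"class matrix must be (n, <={N_SEGMENTS})")
    n_avail = (~np.isnan(arr)).sum(axis=1)
    if (n_avail == 0).any():
        raise DataError("every patient needs at least one available segment")
    finite = arr[~np.isnan(arr)]
    if not np.isin(finite, CLASSES).all():
        raise DataError(f"classes must be in {CLASSES}")
    with np.errstate(all="ignore"):
        return pd.DataFrame(
            {
                "max_sc": np.nanmax(arr, axis=1).astype(int),
                "mean_sc": np.nanmean(arr, axis=1),
                "n_segments_available": n_avail,
            }
        )


def summarize_grades(table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient summaries from a long-form grade table.

    Expected columns: patient_id, segment_id (1-27), reading_type
    ('percent' | 'class' | 'unavailable'), value.  Multiple readings per
    segment are reduced by :func:`segment_class` first.
    """
    required = {"patient_id", "segment_id", "reading_type", "value"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"grade table missing columns: {sorted(missing)}")
    bad = ~table["segment_id"].isin(range(1, N_SEGMENTS + 1))
    if bad.any():
        raise DataError(
            f"segment_id out of 1..{N_SEGMENTS}: {sorted(table.loc[bad, 'segment_id'].unique())}"
        )
    rows = []
    for pid, group in table.groupby("patient_id", sort=True):
        seg_classes = {}
        for seg_id, seg in group.groupby("segment_id"):
            readings = [
                (rt, v)
                for rt, v in zip(seg["reading_type"], seg["value"])
                if rt != "unavailable"
            ]
            if readings:
                seg_classes[seg_id] = segment_class(readings)
        summary = patient_summary(seg_classes.values(), patient_id=str(pid))
        rows.append(
            {
                "patient_id": str(pid),
                "max_sc": summary.max_sc,
                "mean_sc": summary.mean_sc,
                "n_segments_available": summary.n_segments_available,
            }
        )
    return pd.DataFrame(rows)
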