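"""Rating tables and mean opinion scores.

Human subjects rate each image on the 5-category absolute scale
(Bad=1, Poor=2, Fair=3, Good=4, Excellent=5). The mean opinion score of
image p over a panel of N subjects is the arithmetic mean

    MOS(p) = (1/N) Σ_i S_ip

where S_ip is subject i's score for image p. Subjects who skip an image
simply do not contribute; the record keeps the count of raters that did.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "MOSRecord",
    "RatingsTable",
    "compute_mos",
    "mos_to_frame",
    "read_ratings",
    "write_mos",
]

RATINGS_COLUMNS = ["subject_id", "image_id", "score"]
VALID_SCORES = frozenset({1, 2, 3, 4, 5})


@dataclass(frozen=True)
class MOSRecord:
    """Per-image mean opinion score and the number of contributing raters."""

    image_id: str
    mos: float
    n_raters: int


class RatingsTable:
    """Validated table of integer scores, one per (subject, image) pair."""

    def __init__(self, frame: pd.DataFrame):
        if list(frame.columns) != RATINGS_COLUMNS:
            raise ValidationError(f"ratings columns must be {RATINGS_COLUMNS}")
        if frame.empty:
            raise ValidationError("ratings table is empty")
        frame = frame.copy()
        frame["subject_id"] = frame["subject_id"].astype(str)
        frame["image_id"] = frame["image_id"].astype(str)
        scores = pd.to_numeric(frame["score"], errors="coerce")
        bad = scores.isna() | (scores != scores.round()) | ~scores.isin(list(VALID_SCORES))
        if bad.any():
            first = frame.loc[bad].iloc[0]
            raise ValidationError(
                f"score {first['score']!r} for (subject {first['subject_id']}, "
                f"image {first['image_id']}) is not an integer in 1..5"
            )
        frame["score"] = scores.astype(int)
        dup = frame.duplicated(subset=["subject_id", "image_id"])
        if dup.any():
            pair = frame.loc[dup, ["subject_id", "image_id"]].iloc[0]
            raise ValidationError(
                f"duplicate rating for (subject {pair['subject_id']}, image {pair['image_id']})"
            )
        self.frame = frame.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    @property
    def image_ids(self) -> List[str]:
        return sorted(self.frame["image_id"].unique())

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RatingsTable):
            return NotImplemented
        a = self.frame.sort_values(["subject_id", "image_id"]).reset_index(drop=True)
        b = other.frame.sort_values(["subject_id", "image_id"]).reset_index(drop=True)
        return a.equals(b)


def compute_mos(ratings: RatingsTable, expected_images=None) -> List[MOSRecord]:
    """Average each image's scores over its raters (one record per image).

    If ``expected_images`` is given, every listed image must carry at
    least one rating; otherwise a ValidationError names the missing ones.
    """
    if expected_images is not None:
        missing = sorted(set(map(str, expected_images)) - set(ratings.frame["image_id"]))
        if missing:
            raise ValidationError(f"images with zero ratings: {missing}")
    grouped = ratings.frame.groupby("image_id")["score"]
    records = [
        MOSRecord(image_id=image_id, mos=float(g.mean()), n_raters=int(len(g)))
        for image_id, g in grouped
    ]
    records.sort(key=lambda r: r.image_id)
    return records


def mos_to_frame(records: List[MOSRecord]) -> pd.DataFrame:
    """Tabulate MOS records with columns ``image_id, mos, n_raters``."""
    return pd.DataFrame(
        [(r.image_id, r.mos, r.n_raters) for r in records],
        columns=["image_id", "mos", "n_raters"],
    )


def read_ratings(path) -> RatingsTable:
    """Read a ratings CSV (header ``subject_id,image_id,score``).

    Malformed rows are reported with their 1-based line number in the
    file (the header is line 1).
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty ratings file") from None
        if [h.strip() for h in header] != RATINGS_COLUMNS:
            raise ValidationError(f"{path}: expected header {RATINGS_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            subject_id, image_id, score_txt = (cell.strip() for cell in row)
            try:
                score = int(score_txt)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: score {score_txt!r} is not an integer"
                ) from None
            if score not in VALID_SCORES:
                raise ValidationError(f"{path}:{lineno}: score {score} outside 1..5")
            rows.append((subject_id, image_id, score))
    if not rows:
        raise ValidationError(f"{path}: no rating rows")
    return RatingsTable(pd.DataFrame(rows, columns=RATINGS_COLUMNS))


def write_mos(records: List[MOSRecord], path) -> None:
    """Write MOS records as CSV with header ``image_id,mos,n_raters``."""
    mos_to_frame(records).to_csv(path, index=False)
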