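"""Twin-pair dataset container and delimited-text round trip.

One row per twin pair: ``family_id, zygosity, x1, y1, x2, y2`` and, for
simulated data, an optional ``true_class`` column retained for validation only
(it never enters the likelihood).
"""
from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import OBS_ORDER, ClassLabel, Zygosity

REQUIRED_COLUMNS = ("family_id", "zygosity", *OBS_ORDER)


class DatasetFormatError(ValueError):
    """Malformed dataset file; the message names the offending line numbers
    (1-based, counting the header as line 1)."""


@dataclass(frozen=True)
class TwinDataset:
    """Zygosity-tagged 4-variate twin-pair observations.

    Thin wrapper over a :class:`pandas.DataFrame` that guarantees column
    presence, valid zygosity tokens and absence of missing values.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DatasetFormatError(f"missing required columns: {missing}")

    @property
    def n_pairs(self) -> int:
        return len(self.frame)

    def n_pairs_by_zygosity(self) -> dict[Zygosity, int]:
        counts = self.frame["zygosity"].value_counts()
        return {z: int(counts.get(z.value, 0)) for z in Zygosity}

    def matrix(self, zyg: Zygosity) -> np.ndarray:
        """(N, 4) array of ``(x1, y1, x2, y2)`` for one zygosity group."""
        sub = self.frame[self.frame["zygosity"] == zyg.value]
        return sub[list(OBS_ORDER)].to_numpy(dtype=float)

    def zygosity_mask(self, zyg: Zygosity) -> np.ndarray:
        return (self.frame["zygosity"] == zyg.value).to_numpy()

    @property
    def has_true_class(self) -> bool:
        return "true_class" in self.frame.columns

    def true_labels(self) -> pd.Series:
        if not self.has_true_class:
            raise KeyError("dataset carries no true_class column")
        return self.frame["true_class"]

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path) -> None:
        """Write the comma-separated dialect (12 significant digits)."""
        self.frame.to_csv(path, index=False, float_format="%.12g")

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TwinDataset":
        return cls(_validate_frame(frame.copy()))

    @classmethod
    def from_csv(cls, path) -> "TwinDataset":
        """Read the dialect written by :meth:`to_csv`, with line-level errors."""
        try:
            raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
        except pd.errors.ParserError as exc:  # ragged rows etc.
            raise DatasetFormatError(f"unparseable dataset file: {exc}") from exc
        missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
        if missing:
            raise DatasetFormatError(
                f"header (line 1) is missing required columns: {missing}"
            )
        return cls(_validate_frame(raw))


def _lines(idx: pd.Index) -> list[int]:
    # +2: 1-based and one header line
    return [int(i) + 2 for i in idx[:10]]


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.reset_index(drop=True)
    zyg = frame["zygosity"].astype(str).str.strip().str.upper()
    bad = ~zyg.isin([z.value for z in Zygosity])
    if bad.any():
        raise DatasetFormatError(
            f"unknown zygosity token on line(s) {_lines(frame.index[bad])} "
            f"(expected MZ or DZ)"
        )
    frame["zygosity"] = zyg
    for col in OBS_ORDER:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise DatasetFormatError(
                f"missing or non-numeric {col} on line(s) {_lines(frame.index[bad])}"
            )
        frame[col] = vals.astype(float)
    if "true_class" in frame.columns:
        valid = {c.value for c in ClassLabel}
        labels = frame["true_class"].astype(str).str.strip()
        bad = ~labels.isin(valid)
        if bad.any():
            raise DatasetFormatError(
                f"unknown true_class label on line(s) {_lines(frame.index[bad])}"
            )
        frame["true_class"] = labels
    return frame
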