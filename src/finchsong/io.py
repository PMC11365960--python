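"""WAV and annotation-table I/O.

WAV files are mono RIFF, written as 32-bit float (16-bit PCM is accepted on
read and rescaled to [-1, 1]). Annotations travel as CSV with columns
``onset_s,offset_s,label`` (extra columns preserved) or as Audacity-style
tab-separated label tracks for manual inspection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .segmentation import SyllableSegment

__all__ = [
    "read_wav",
    "write_wav",
    "read_annotations",
    "write_annotations",
    "segments_to_frame",
    "write_audacity_labels",
]

ANNOT_COLUMNS = ("onset_s", "offset_s", "label")


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV as float64 in [-1, 1]; returns (waveform, sample_rate)."""
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    return data, int(sr)


def write_wav(path, w: np.ndarray, sample_rate: int) -> None:
    wavfile.write(path, int(sample_rate), np.asarray(w, dtype=np.float32))


def read_annotations(path) -> pd.DataFrame:
    """Read a segment annotation CSV, validating every row.

    Requires the ``onset_s,offset_s,label`` header; malformed rows (missing
    values, offset <= onset, decreasing onsets) are reported with their line
    number. An empty file with a header yields an empty table.
    """
    df = pd.read_csv(path, dtype={"label": str})
    missing = set(ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if pd.isna(row["onset_s"]) or pd.isna(row["offset_s"]) or pd.isna(row["label"]):
            raise ValueError(f"{path}:{line}: missing value")
        if not (row["offset_s"] > row["onset_s"]):
            raise ValueError(
                f"{path}:{line}: offset {row['offset_s']} must exceed onset {row['onset_s']}"
            )
    return df


def write_annotations(path, table: pd.DataFrame) -> None:
    cols = [c for c in ANNOT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.to_csv(path, index=False, columns=cols)


def segments_to_frame(segments: list[SyllableSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [s.onset for s in segments],
            "offset_s": [s.offset for s in segments],
            "label": [s.label if s.label is not None else "" for s in segments],
        }
    )


def write_audacity_labels(path, segments: list[SyllableSegment]) -> None:
    """Tab-separated onset<TAB>offset<TAB>label, importable in Audacity."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.onset:.6f}\t{s.offset:.6f}\t{s.label or ''}\n")
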