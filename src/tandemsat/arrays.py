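"""The catalog atom: one detected tandem array.

Coordinates are 1-based and inclusive throughout the package (the Tandem
Repeats Finder convention); conversion to 0-based half-open intervals happens
only in BED writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

_CONSENSUS_ALPHABET = set("ACGTN")

CATALOG_COLUMNS = [
    "seq_id", "start", "end", "unit_len", "copy_number",
    "array_len", "percent_matches", "consensus",
]


@dataclass
class TandemArray:
    """One tandem array detected on a source sequence.

    ``start``/``end`` are 1-based inclusive positions on the source
    sequence; ``array_seq`` is the corresponding slice, so
    ``array_len == end - start + 1 == len(array_seq)``.
    """

    source_seq_id: str
    start: int
    end: int
    unit_len: int
    copy_number: float
    consensus: str
    array_seq: str
    percent_matches: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if len(self.array_seq) != self.array_len:
            raise ValueError(
                f"array_seq length {len(self.array_seq)} != span "
                f"{self.array_len} for {self.source_seq_id}:{self.start}")
        if not 1 <= self.unit_len <= 2000:
            raise ValueError(f"unit_len {self.unit_len} outside [1, 2000]")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        bad = set(self.consensus.upper()) - _CONSENSUS_ALPHABET
        if bad:
            raise ValueError(f"consensus contains invalid characters {bad}")

    @property
    def array_len(self) -> int:
        return self.end - self.start + 1

    @property
    def array_id(self) -> str:
        return f"{self.source_seq_id}:{self.start}-{self.end}"


def catalog_to_frame(arrays: Iterable[TandemArray]) -> pd.DataFrame:
    """Tabulate a catalog with the standard column set."""
    rows = [
        {
            "seq_id": a.source_seq_id,
            "start": a.start,
            "end": a.end,
            "unit_len": a.unit_len,
            "copy_number": a.copy_number,
            "array_len": a.array_len,
            "percent_matches": a.percent_matches,
            "consensus": a.consensus,
        }
        for a in arrays
    ]
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def write_catalog(arrays: Iterable[TandemArray], path) -> None:
    catalog_to_frame(arrays).to_csv(path, sep="\t", index=False)


def read_catalog(path, sequences: dict[str, str]) -> list[TandemArray]:
    """Load a catalog TSV, re-slicing array sequences from ``sequences``."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        src = sequences[row.seq_id]
        pm = None if pd.isna(row.percent_matches) else float(row.percent_matches)
        out.append(TandemArray(
            source_seq_id=row.seq_id, start=int(row.start), end=int(row.end),
            unit_len=int(row.unit_len), copy_number=float(row.copy_number),
            consensus=str(row.consensus),
            array_seq=src[int(row.start) - 1:int(row.end)],
            percent_matches=pm,
        ))
    return out
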