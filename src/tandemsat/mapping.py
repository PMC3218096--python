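"""Reference-genome mapping of arrays and locus bookkeeping.

Arrays are aligned to the reference with blastn (both strands); hits on the
same chromosome and strand closer than 150 bp are merged into one locus and
merged loci of 2850 bp or less are discarded — the thresholds the published
screen stated for mapping tandem arrays.  Loci get a cytogenetic band from a
cytoBand-style table and a pericentromeric flag relative to the 3 Mb
centromeric assembly gap at the start of each telocentric chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import blastn_hits
from .arrays import TandemArray
from .config import DEFAULT_CONFIG, PipelineConfig


@dataclass
class GenomeLocus:
    """A mapped occurrence of an array on the reference (1-based
    inclusive)."""
    chrom: str
    start: int
    end: int
    strand: str = "+"
    band: str | None = None
    pericentromeric: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")

    @property
    def hit_len(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BandRecord:
    chrom: str
    start: int          # 1-based inclusive
    end: int
    band_name: str
    stain: str | None = None


@dataclass(frozen=True)
class LocusClass:
    value: str  # single_locus | multi_locus | unplaced

    _ALLOWED = ("single_locus", "multi_locus", "unplaced")

    def __post_init__(self) -> None:
        if self.value not in self._ALLOWED:
            raise ValueError(f"invalid locus class {self.value!r}")


def read_bands(path) -> list[BandRecord]:
    """Read a UCSC cytoBand-like BED table (0-based half-open on disk,
    converted to 1-based inclusive)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            stain = f[4] if len(f) > 4 else None
            out.append(BandRecord(chrom=f[0], start=int(f[1]) + 1,
                                  end=int(f[2]), band_name=f[3],
                                  stain=stain))
    out.sort(key=lambda b: (b.chrom, b.start))
    return out


def map_hits(
    array: TandemArray,
    reference: dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[GenomeLocus]:
    """Merged reference loci of one array (see :func:`map_catalog`)."""
    return map_catalog([array], reference, config)[array.array_id]


def map_catalog(
    arrays: Sequence[TandemArray],
    reference: dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, list[GenomeLocus]]:
    """Map every array to the reference in one blastn pass.

    Per array: hits on the same (chromosome, strand) separated by less than
    ``config.map_merge_gap`` bp are merged; merged loci spanning no more
    than ``config.map_min_hit_len`` bp are discarded.  Loci are returned
    sorted by (chrom, start).
    """
    if not reference:
        raise ValueError("empty reference")
    hits = blastn_hits({a.array_id: a.array_seq for a in arrays},
                       reference, config)
    out: dict[str, list[GenomeLocus]] = {a.array_id: [] for a in arrays}
    for (qid, chrom, strand), grp in hits.groupby(
            ["qseqid", "sseqid", "strand"]):
        loci = _merge_strand_hits(
            list(zip(grp["sstart"], grp["send"])), config.map_merge_gap)
        for s, e in loci:
            if e - s + 1 > config.map_min_hit_len:
                out[qid].append(GenomeLocus(chrom=chrom, start=s, end=e,
                                            strand=strand))
    for loci in out.values():
        loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.strand))
    return out


def _merge_strand_hits(intervals: list[tuple[int, int]],
                       merge_gap: int) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def assign_band(locus: GenomeLocus,
                bands: Sequence[BandRecord]) -> str | None:
    """Band containing the locus midpoint; boundary ties go to the
    lower-coordinate band; None when the midpoint (or chromosome) is not
    covered."""
    mid = (locus.start + locus.end) // 2
    best = None
    for b in bands:
        if b.chrom != locus.chrom:
            continue
        if b.start <= mid <= b.end:
            if best is None or b.start < best.start:
                best = b
    return best.band_name if best else None


def classify_locus_count(loci: Sequence[GenomeLocus]) -> LocusClass:
    """0 loci -> unplaced; 1 -> single_locus; >= 2 -> multi_locus."""
    if len(loci) == 0:
        return LocusClass("unplaced")
    if len(loci) == 1:
        return LocusClass("single_locus")
    return LocusClass("multi_locus")


def is_pericentromeric(
    locus: GenomeLocus,
    gap_len: int = DEFAULT_CONFIG.centromeric_gap_len,
    window: int = DEFAULT_CONFIG.pericentromeric_window,
) -> bool:
    """True when the locus begins within ``window`` bp of the centromeric
    assembly gap occupying coordinates 1..gap_len (mouse telocentric
    geometry: gap at the low-coordinate end of every chromosome)."""
    return locus.start <= gap_len + window


def locus_length_kb(locus: GenomeLocus) -> float:
    """Locus span in kb, one decimal (1-based inclusive arithmetic)."""
    return round((locus.end - locus.start + 1) / 1000, 1)


def loci_frame(loci_by_array: dict[str, list[GenomeLocus]]) -> pd.DataFrame:
    rows = []
    for aid, loci in sorted(loci_by_array.items()):
        for l in loci:
            rows.append({
                "array_id": aid, "chrom": l.chrom, "start": l.start,
                "end": l.end, "strand": l.strand, "band": l.band,
                "length_kb": locus_length_kb(l),
                "pericentromeric": l.pericentromeric,
            })
    return pd.DataFrame(rows, columns=[
        "array_id", "chrom", "start", "end", "strand", "band",
        "length_kb", "pericentromeric"])


def write_loci_bed(loci_by_array: dict[str, list[GenomeLocus]],
                   path) -> None:
    """BED export (0-based half-open)."""
    with open(path, "w") as fh:
        for aid, loci in sorted(loci_by_array.items()):
            for l in loci:
                fh.write(f"{l.chrom}\t{l.start - 1}\t{l.end}\t{aid}\t0\t"
                         f"{l.strand}\n")
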