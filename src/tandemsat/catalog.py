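"""Catalog construction: TRF output ingestion, built-in detection, redundancy
removal and the large-array filter.

The published screen ran Tandem Repeats Finder (TRF) on whole-genome shotgun
assemblies, removed nested/duplicate detections, and kept only arrays of at
least 3 kb.  This module reproduces that flow.  ``parse_trf_dat`` ingests the
TRF ``-d`` table dialect; ``detect_tandem`` is a self-contained periodicity
detector (not a TRF reimplementation) so that synthetic genomes can be
processed without the external binary.
"""

from __future__ import annotations

import io
from typing import Iterable, TextIO

import numpy as np

from .arrays import TandemArray
from .config import DEFAULT_CONFIG, PipelineConfig
from .metrics import consensus_from_seq


class TrfParseError(ValueError):
    """A malformed TRF .dat record (carries the 1-based line number)."""


class CoordinateError(ValueError):
    """TRF coordinates fall outside the supplied source sequence."""


# TRF -d record: start end period copies consensus-size pct-match pct-indel
#                score A C G T entropy consensus sequence
_TRF_FIELDS = 15

_HEADER_PREFIXES = (
    "Tandem Repeats Finder", "Gary Benson", "Program", "Version",
    "Sequence:", "Parameters:",
)


def parse_trf_dat(
    stream: TextIO | str,
    source_seq_id: str,
    source_seq: str,
    *,
    max_unit_len: int = 2000,
) -> list[TandemArray]:
    """Parse a TRF ``-d`` .dat table into :class:`TandemArray` records.

    Array sequences are re-sliced from ``source_seq`` using TRF's 1-based
    inclusive coordinates.  Records whose period exceeds ``max_unit_len``
    (TRF was run with a 2000 bp period cap) are dropped.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[TandemArray] = []
    for lineno, line in enumerate(stream, start=1):
        text = line.strip()
        if not text or text.startswith(_HEADER_PREFIXES):
            continue
        fields = text.split()
        if len(fields) < _TRF_FIELDS:
            raise TrfParseError(
                f"line {lineno}: expected {_TRF_FIELDS} fields, "
                f"got {len(fields)}")
        try:
            start, end = int(fields[0]), int(fields[1])
            period = int(fields[2])
            copies = float(fields[3])
            pct_match = float(fields[5])
            consensus = fields[13].upper()
        except ValueError as exc:
            raise TrfParseError(f"line {lineno}: {exc}") from exc
        if period > max_unit_len:
            continue
        if start < 1 or end > len(source_seq):
            raise CoordinateError(
                f"line {lineno}: {start}-{end} outside {source_seq_id} "
                f"(length {len(source_seq)})")
        out.append(TandemArray(
            source_seq_id=source_seq_id,
            start=start,
            end=end,
            unit_len=period,
            copy_number=copies,
            consensus=consensus,
            array_seq=source_seq[start - 1:end].upper(),
            percent_matches=pct_match,
            provenance={"source": "trf", "line": lineno,
                        "trf_mismatch_weight": 5},
        ))
    return out


def _segments_without_n(seq: str) -> Iterable[tuple[int, str]]:
    """Yield (0-based offset, subsequence) for maximal A/C/G/T runs."""
    start = None
    for i, c in enumerate(seq):
        if c in "ACGT":
            if start is None:
                start = i
        else:
            if start is not None:
                yield start, seq[start:i]
                start = None
    if start is not None:
        yield start, seq[start:]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) spans of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_tandem(
    seq: str,
    max_period: int = 2000,
    config: PipelineConfig = DEFAULT_CONFIG,
    *,
    source_seq_id: str = "seq",
) -> list[TandemArray]:
    """Detect tandem arrays by per-base self-match at candidate periods.

    For each period ``p`` the fraction of positions with
    ``seq[i] == seq[i + p]`` is smoothed over a window and stretches above
    ``config.detect_identity_min`` become candidate arrays; each genomic
    region keeps the smallest period that explains it.  N runs are skipped.
    Returns an empty list when nothing periodic is found.
    """
    seq = seq.upper()
    accepted: list[TandemArray] = []
    for offset, sub in _segments_without_n(seq):
        accepted.extend(
            _detect_in_segment(sub, offset, max_period, config,
                               source_seq_id))
    accepted.sort(key=lambda a: (a.start, a.end, a.unit_len))
    return accepted


def _detect_in_segment(sub: str, offset: int, max_period: int,
                       config: PipelineConfig,
                       source_seq_id: str) -> list[TandemArray]:
    n = len(sub)
    arr = np.frombuffer(sub.encode("ascii"), dtype=np.uint8)
    candidates: list[tuple[int, int, int]] = []  # (start, end0_excl, period)
    thr = config.detect_identity_min
    p_cap = min(max_period, n // 3)
    for p in range(1, p_cap + 1):
        m = (arr[:-p] == arr[p:])
        w = min(max(p, 35), len(m))
        # windowed mean via cumulative sum
        cs = np.concatenate(([0], np.cumsum(m, dtype=np.int32)))
        frac = (cs[w:] - cs[:-w]) / w
        min_span = max(int(np.ceil(config.detect_min_copies * p)),
                       config.detect_min_span)
        runs = _bridge_runs(_runs(frac >= thr), w)
        for ws, we in runs:
            # matched base positions span roughly [ws, we - 1 + w]
            lo, hi = ws, min(we - 1 + w, len(m))
            idx = np.flatnonzero(m[lo:hi])
            if idx.size == 0:
                continue
            s0 = lo + int(idx[0])
            e0 = lo + int(idx[-1]) + p + 1   # exclusive end on the sequence
            if e0 - s0 < min_span:
                continue
            if m[s0:e0 - p].mean() < thr:
                continue
            candidates.append((s0, e0, p))
    out = []
    for s0, e0, p in _select_regions(candidates):
        region_seq = sub[s0:e0]
        out.append(TandemArray(
            source_seq_id=source_seq_id,
            start=offset + s0 + 1,
            end=offset + e0,
            unit_len=p,
            copy_number=round(len(region_seq) / p, 1),
            consensus=consensus_from_seq(region_seq, p),
            array_seq=region_seq,
            provenance={"source": "detect_tandem"},
        ))
    return out


def _bridge_runs(runs: list[tuple[int, int]],
                 max_gap: int) -> list[tuple[int, int]]:
    """Join above-threshold runs separated by short dips (chance local
    divergence inside an otherwise continuous array)."""
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _select_regions(candidates: list[tuple[int, int, int]],
                    span_frac: float = 0.9) -> list[tuple[int, int, int]]:
    """One region per overlapping cluster of candidate detections.

    Detections at different trial periods over the same genomic stretch
    (a period and its multiples, or a marginal small period fragmenting an
    array that a larger period explains cleanly) are grouped by transitive
    overlap; each group keeps the smallest period whose detection spans at
    least ``span_frac`` of the group's maximal extent.
    """
    if not candidates:
        return []
    clusters: list[list[tuple[int, int, int]]] = []
    cur_end = -1
    for cand in sorted(candidates):
        if clusters and cand[0] < cur_end:
            clusters[-1].append(cand)
            cur_end = max(cur_end, cand[1])
        else:
            clusters.append([cand])
            cur_end = cand[1]
    selected = []
    for group in clusters:
        longest = max(e - s for s, e, _ in group)
        best = min(((s, e, p) for s, e, p in group
                    if e - s >= span_frac * longest),
                   key=lambda c: (c[2], -(c[1] - c[0]), c[0]))
        selected.append(best)
    return selected


def remove_redundant(arrays: list[TandemArray]) -> list[TandemArray]:
    """Eliminate nested and duplicate detections.

    Of arrays sharing identical coordinates only the smallest unit size
    survives (ties broken by lexicographic consensus); any array strictly
    contained within a longer one is removed; partially overlapping arrays
    are all kept.  Output is sorted by (start, end, unit_len) and the
    operation is idempotent.
    """
    if not arrays:
        return []
    ids = {a.source_seq_id for a in arrays}
    if len(ids) > 1:
        raise ValueError(f"arrays span multiple source sequences: {ids}")
    # identical spans: keep smallest unit_len, then lexicographic consensus
    by_span: dict[tuple[int, int], TandemArray] = {}
    for a in arrays:
        key = (a.start, a.end)
        b = by_span.get(key)
        if b is None or (a.unit_len, a.consensus) < (b.unit_len, b.consensus):
            by_span[key] = a
    uniq = sorted(by_span.values(), key=lambda a: (a.start, -a.end))
    # strict containment sweep (transitive: compared against every array)
    kept: list[TandemArray] = []
    max_end = 0
    for a in uniq:
        if a.end <= max_end:
            continue          # strictly contained in an earlier, longer span
        kept.append(a)
        max_end = a.end
    kept.sort(key=lambda a: (a.start, a.end, a.unit_len))
    return kept


def filter_large(arrays: Iterable[TandemArray],
                 min_array_len: int = DEFAULT_CONFIG.min_array_len,
                 ) -> list[TandemArray]:
    """Keep arrays of at least ``min_array_len`` bp (default 3 kb)."""
    return [a for a in arrays if a.array_len >= min_array_len]
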