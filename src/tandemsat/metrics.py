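"""Per-array sequence statistics: GC content, consensus monomer and monomer
variability (Var%), plus the unit-length histogram and the three-metric
"cloud" table (monomer length, GC, monomer similarity) used to compare
families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import edlib
import numpy as np
import pandas as pd

from .arrays import TandemArray

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); N and ambiguity codes are excluded from
    the denominator entirely."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    denom = sum(seq.count(b) for b in _BASES)
    if denom == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return (seq.count("G") + seq.count("C")) / denom


def consensus_from_seq(seq: str, unit_len: int) -> str:
    """Per-column majority consensus of the full ``unit_len`` slices of
    ``seq`` (anchored at the sequence start; ties go to the alphabetically
    first base; partial terminal monomers are ignored)."""
    seq = seq.upper()
    if unit_len > len(seq):
        raise ValueError("unit_len exceeds sequence length")
    ncopy = len(seq) // unit_len
    codes = np.frombuffer(seq[:ncopy * unit_len].encode("ascii"),
                          dtype=np.uint8).reshape(ncopy, unit_len)
    counts = np.zeros((4, unit_len), dtype=np.int64)
    for i, base in enumerate(_BASES):
        counts[i] = (codes == ord(base)).sum(axis=0)
    out = []
    for col in range(unit_len):
        if counts[:, col].sum() == 0:
            out.append("N")
        else:
            out.append(_BASES[int(np.argmax(counts[:, col]))])
    return "".join(out)


def consensus_monomer(array: TandemArray) -> str:
    if array.copy_number < 2:
        raise ValueError("consensus requires at least 2 copies")
    return consensus_from_seq(array.array_seq, array.unit_len)


def _slicing_ambiguous(array: TandemArray) -> bool:
    """TRF records whose copy number disagrees with the span suggest
    indels; cutting fixed-size slices would then drift out of frame."""
    return (array.provenance.get("source") == "trf"
            and array.percent_matches is not None
            and abs(array.copy_number * array.unit_len - array.array_len)
            > 0.5 * array.unit_len)


def monomer_variability(array: TandemArray) -> float:
    """Mean percent divergence of the array's monomers from its consensus.

    Each full ``unit_len`` slice is compared to the consensus monomer by
    edit distance; the mean distance is expressed as a percent of the unit
    length.  For TRF-derived arrays with ambiguous slicing the TRF
    ``100 - percent_matches`` statistic is reported instead and flagged in
    provenance.
    """
    if array.copy_number < 2:
        raise ValueError("variability requires at least 2 copies")
    if _slicing_ambiguous(array):
        array.provenance["variability_source"] = "trf_percent_matches"
        return 100.0 - float(array.percent_matches)
    cons = consensus_monomer(array)
    u = array.unit_len
    seq = array.array_seq.upper()
    ncopy = len(seq) // u
    dists = [
        edlib.align(seq[i * u:(i + 1) * u], cons, task="distance")
        ["editDistance"]
        for i in range(ncopy)
    ]
    array.provenance["variability_source"] = "consensus_edit_distance"
    return 100.0 * float(np.mean(dists)) / u


@dataclass(frozen=True)
class ArrayMetrics:
    gc_fraction: float
    variability_pct: float
    monomer_similarity: float
    unit_len: int
    consensus: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.gc_fraction <= 1.0
        assert 0.0 <= self.variability_pct <= 100.0


def compute_metrics(array: TandemArray) -> ArrayMetrics:
    var = monomer_variability(array)
    return ArrayMetrics(
        gc_fraction=gc_content(array.array_seq),
        variability_pct=var,
        monomer_similarity=1.0 - var / 100.0,
        unit_len=array.unit_len,
        consensus=consensus_monomer(array),
    )


def unit_length_histogram(catalog: Iterable[TandemArray],
                          bin: int = 1) -> dict[int, int]:
    """Counts of arrays per unit length (``bin`` groups lengths into
    ``bin``-wide classes keyed by their lower edge)."""
    hist: dict[int, int] = {}
    for a in catalog:
        key = (a.unit_len // bin) * bin if bin > 1 else a.unit_len
        hist[key] = hist.get(key, 0) + 1
    return dict(sorted(hist.items()))


def metric_cloud(catalog: Iterable[TandemArray]
                 ) -> list[tuple[int, float, float]]:
    """One (unit_len, gc_fraction, monomer_similarity) triple per array."""
    out = []
    for a in catalog:
        m = compute_metrics(a)
        out.append((m.unit_len, m.gc_fraction, m.monomer_similarity))
    return out


def metrics_frame(catalog: Iterable[TandemArray]) -> pd.DataFrame:
    """Export-ready metrics table (GC and Var as percents, table style)."""
    rows = []
    for a in catalog:
        m = compute_metrics(a)
        rows.append({
            "array_id": a.array_id,
            "unit_len": m.unit_len,
            "gc_pct": round(100.0 * m.gc_fraction, 1),
            "var_pct": round(m.variability_pct, 1),
        })
    return pd.DataFrame(rows,
                        columns=["array_id", "unit_len", "gc_pct", "var_pct"])
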