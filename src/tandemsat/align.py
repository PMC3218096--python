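"""Local alignment scoring.

Subfamily clustering in the published screen used raw bl2seq (blastn) scores
with a fixed threshold.  The reference semantics here is exact Smith-Waterman
with blastn-style weights (match +2, mismatch -3, a gap of length *k* scoring
``gap_open + k * gap_extend`` = -(5 + 2k) by default), computed with
Biopython's PairwiseAligner; both strands are always searched.  For large
batches the same scoring scheme can be delegated to the blastn binary
(word-seeded, much faster); the heuristic path is an accelerator, not the
definition.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import Align

from .config import DEFAULT_CONFIG, PipelineConfig

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PairScore:
    """Best local-alignment raw score between two sequences (symmetric)."""
    id_a: str
    id_b: str
    raw_score: float
    align_len: int | None = None


def _aligner(config: PipelineConfig) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.match_score = config.match_score
    aln.mismatch_score = config.mismatch_score
    # PairwiseAligner charges open_gap_score for the first gap base;
    # blastn charges gap_open + gap_extend for it.
    aln.open_gap_score = config.gap_open + config.gap_extend
    aln.extend_gap_score = config.gap_extend
    return aln


def local_align_score(
    a: str,
    b: str,
    config: PipelineConfig = DEFAULT_CONFIG,
    *,
    id_a: str = "a",
    id_b: str = "b",
    with_alignment: bool = False,
) -> PairScore:
    """Exact best local alignment raw score over both strands.

    ``with_alignment`` additionally recovers the aligned length of the best
    forward-or-reverse alignment (costs a traceback; skip for large inputs).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner(config)
    a, b = a.upper(), b.upper()
    rc = reverse_complement(b)
    s_fwd = aln.score(a, b)
    s_rev = aln.score(a, rc)
    score = max(s_fwd, s_rev)
    align_len = None
    if with_alignment:
        target = b if s_fwd >= s_rev else rc
        best = aln.align(a, target)[0]
        align_len = best.length
    return PairScore(id_a=id_a, id_b=id_b, raw_score=float(score),
                     align_len=align_len)


# ---------------------------------------------------------------------------
# blastn delegation

_BLAST_OUTFMT = "6 qseqid sseqid qstart qend sstart send length score"
_HIT_COLUMNS = ["qseqid", "sseqid", "qstart", "qend", "sstart", "send",
                "length", "score"]


def _require_blastn() -> str:
    exe = shutil.which("blastn")
    if exe is None:
        raise RuntimeError(
            "blastn executable not found on PATH (required for batch "
            "library annotation and genome mapping)")
    return exe


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def blastn_hits(
    queries: dict[str, str],
    subjects: dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """All blastn HSPs of ``queries`` against ``subjects``.

    Runs blastn with the search parameters of the published screen
    (word size 10, e-value 1e-16, DUST and soft masking off, +2/-3 with
    gap costs 5/2) and returns a table with a ``strand`` column; subject
    coordinates are normalised so ``sstart <= send``.
    """
    exe = _require_blastn()
    with tempfile.TemporaryDirectory(prefix="tandemsat_blast_") as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        _write_fasta(queries, qpath)
        _write_fasta(subjects, spath)
        cmd = [
            exe, "-query", str(qpath), "-subject", str(spath),
            "-task", "blastn", "-word_size", "10",
            "-evalue", "1e-16", "-dust", "no", "-soft_masking", "false",
            "-reward", str(config.match_score),
            "-penalty", str(config.mismatch_score),
            "-gapopen", str(-config.gap_open),
            "-gapextend", str(-config.gap_extend),
            "-max_target_seqs", "10000",
            "-outfmt", _BLAST_OUTFMT,
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"blastn failed: {proc.stderr.strip()}")
        rows = []
        for line in proc.stdout.splitlines():
            f = line.split("\t")
            rows.append({
                "qseqid": f[0], "sseqid": f[1],
                "qstart": int(f[2]), "qend": int(f[3]),
                "sstart": int(f[4]), "send": int(f[5]),
                "length": int(f[6]), "score": float(f[7]),
            })
    df = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    if df.empty:
        df["strand"] = pd.Series(dtype=str)
        return df
    df["strand"] = ["+" if s <= e else "-"
                    for s, e in zip(df["sstart"], df["send"])]
    lo = df[["sstart", "send"]].min(axis=1)
    hi = df[["sstart", "send"]].max(axis=1)
    df["sstart"], df["send"] = lo, hi
    return df


def blastn_pair_scores(
    seqs: dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[frozenset, float]:
    """Best raw score for every unordered pair in ``seqs`` (one blastn
    all-vs-all call; pairs with no reported HSP are absent)."""
    hits = blastn_hits(seqs, seqs, config)
    best: dict[frozenset, float] = {}
    for row in hits.itertuples(index=False):
        if row.qseqid == row.sseqid:
            continue
        key = frozenset((row.qseqid, row.sseqid))
        if row.score > best.get(key, float("-inf")):
            best[key] = row.score
    return best


def merge_intervals(intervals: list[tuple[int, int]],
                    max_gap: int = 0) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals closer than ``max_gap`` bp apart
    (overlapping intervals always merge); order-independent and idempotent."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and (s <= merged[-1][1] or s - merged[-1][1] - 1 < max_gap):
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
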