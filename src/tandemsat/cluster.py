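"""Subfamily clustering and known-repeat annotation.

Arrays are grouped into subfamilies by single-linkage over pairwise local
alignment scores: any pair scoring above the threshold (default 90) falls in
the same subfamily.  Annotation against a repeat-consensus library (Repbase
style entries with satellite / transposable-element class tags) follows the
coverage rule of the published screen: a match counts only when library hits
cover at least 80 % of the array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .align import (PairScore, blastn_hits, blastn_pair_scores,
                    local_align_score, merge_intervals)
from .arrays import TandemArray
from .config import DEFAULT_CONFIG, PipelineConfig


@dataclass
class SubfamilyPartition:
    """Total, disjoint grouping of array ids; labels are the smallest member
    id of each group, so the partition is independent of input order."""
    assignment: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for aid, sub in self.assignment.items():
            out.setdefault(sub, []).append(aid)
        for v in out.values():
            v.sort()
        return out

    def n_subfamilies(self) -> int:
        return len(set(self.assignment.values()))


@dataclass(frozen=True)
class LibraryEntry:
    """One consensus from the known-repeat library."""
    name: str
    seq: str
    class_tag: str = "other"          # satellite | TE | other
    known_family: str | None = None   # e.g. MiSat, MaSat, MTA, L1

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"library entry {self.name} has empty sequence")


@dataclass(frozen=True)
class LibraryMatch:
    entry: LibraryEntry
    coverage: float


class AnnotationTieError(ValueError):
    """Two library entries cover the array equally well."""


def read_library(path) -> list[LibraryEntry]:
    """Load a library FASTA; ``class_tag=`` / ``known_family=`` tokens in
    the description line are honoured."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(
            t.split("=", 1) for t in rec.description.split() if "=" in t)
        entries.append(LibraryEntry(
            name=rec.id,
            seq=str(rec.seq).upper(),
            class_tag=tokens.get("class_tag", "other"),
            known_family=tokens.get("known_family"),
        ))
    names = [e.name for e in entries]
    if len(names) != len(set(names)):
        raise ValueError("duplicate entry names in library")
    return entries


def pairwise_scores(
    arrays: Sequence[TandemArray],
    config: PipelineConfig = DEFAULT_CONFIG,
    method: str = "exact",
) -> list[PairScore]:
    """Raw local-alignment scores for every unordered pair of arrays.

    ``method="exact"`` uses full Smith-Waterman (reference semantics);
    ``method="blast"`` delegates to blastn with identical weights, which is
    the practical choice for catalogs of kilobase-scale arrays.  Pairs for
    which blastn reports no HSP are returned with score 0.
    """
    ids = [a.array_id for a in arrays]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate array ids")
    scores: list[PairScore] = []
    if method == "exact":
        for i, a in enumerate(arrays):
            for b in arrays[i + 1:]:
                scores.append(local_align_score(
                    a.array_seq, b.array_seq, config,
                    id_a=a.array_id, id_b=b.array_id))
    elif method == "blast":
        best = blastn_pair_scores(
            {a.array_id: a.array_seq for a in arrays}, config)
        for i, a in enumerate(arrays):
            for b in arrays[i + 1:]:
                key = frozenset((a.array_id, b.array_id))
                scores.append(PairScore(
                    id_a=a.array_id, id_b=b.array_id,
                    raw_score=best.get(key, 0.0)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return scores


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the lexicographically smaller id as the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_subfamilies(
    arrays: Sequence[TandemArray],
    threshold: float = DEFAULT_CONFIG.cluster_score_threshold,
    config: PipelineConfig = DEFAULT_CONFIG,
    *,
    scores: Sequence[PairScore] | None = None,
    method: str = "exact",
) -> SubfamilyPartition:
    """Single-linkage partition: edges where raw_score > threshold.

    Deterministic regardless of catalog order; each subfamily is labelled
    by its smallest member id.  Pre-computed ``scores`` may be supplied to
    avoid re-aligning.
    """
    if scores is None:
        scores = pairwise_scores(arrays, config, method=method)
    uf = _UnionFind(a.array_id for a in arrays)
    for ps in sorted(scores, key=lambda s: (s.id_a, s.id_b)):
        if ps.raw_score > threshold:
            uf.union(ps.id_a, ps.id_b)
    roots: dict[str, str] = {}
    for a in arrays:
        roots[a.array_id] = uf.find(a.array_id)
    # canonical label: smallest member id of each component
    label: dict[str, str] = {}
    for aid, root in roots.items():
        if root not in label or aid < label[root]:
            label[root] = aid
    return SubfamilyPartition(
        assignment={aid: label[root] for aid, root in roots.items()})


def borderline_pairs(
    scores: Sequence[PairScore],
    threshold: float = DEFAULT_CONFIG.cluster_score_threshold,
    frac: float = DEFAULT_CONFIG.borderline_frac,
) -> list[PairScore]:
    """Pairs scoring within +-frac*threshold of the threshold — the
    deterministic stand-in for the published hand-curation of fuzzy
    subfamily borders (reported, never auto-merged)."""
    lo, hi = threshold * (1 - frac), threshold * (1 + frac)
    return [s for s in scores if lo <= s.raw_score <= hi]


def _tile(seq: str, target_len: int) -> str:
    """Tandem-tile ``seq`` until it is at least ``target_len`` long."""
    reps = -(-target_len // len(seq))
    return seq * max(reps, 1)


def annotate_known(
    array: TandemArray,
    library: Sequence[LibraryEntry],
    coverage_min: float = DEFAULT_CONFIG.library_coverage_min,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> LibraryMatch | None:
    """Best library entry covering at least ``coverage_min`` of the array.

    Each entry is tandem-tiled to the array length, all blastn HSPs are
    collected, overlapping hit intervals on the array are merged and the
    merged length is divided by the array length.  Returns None when no
    entry reaches the coverage floor; raises :class:`AnnotationTieError`
    when two entries tie exactly at the top.
    """
    if not library:
        raise ValueError("library is empty")
    results = annotate_catalog([array], library, coverage_min, config)
    return results[array.array_id]


def annotate_catalog(
    arrays: Sequence[TandemArray],
    library: Sequence[LibraryEntry],
    coverage_min: float = DEFAULT_CONFIG.library_coverage_min,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, LibraryMatch | None]:
    """Vectorised :func:`annotate_known` for a whole catalog (one blastn
    call)."""
    if not library:
        raise ValueError("library is empty")
    max_len = max(a.array_len for a in arrays)
    subjects = {e.name: _tile(e.seq, max_len + len(e.seq))
                for e in library}
    by_name = {e.name: e for e in library}
    hits = blastn_hits({a.array_id: a.array_seq for a in arrays},
                       subjects, config)
    out: dict[str, LibraryMatch | None] = {}
    for a in arrays:
        sub = hits[hits["qseqid"] == a.array_id]
        coverages: dict[str, float] = {}
        for entry_name, grp in sub.groupby("sseqid"):
            ivals = list(zip(grp["qstart"], grp["qend"]))
            covered = sum(e - s + 1 for s, e in merge_intervals(ivals))
            coverages[entry_name] = covered / a.array_len
        qualifying = {n: c for n, c in coverages.items()
                      if c >= coverage_min}
        if not qualifying:
            out[a.array_id] = None
            continue
        best_cov = max(qualifying.values())
        best = sorted(n for n, c in qualifying.items() if c == best_cov)
        if len(best) > 1:
            raise AnnotationTieError(
                f"{a.array_id}: entries {best} tie at coverage "
                f"{best_cov:.3f}")
        out[a.array_id] = LibraryMatch(entry=by_name[best[0]],
                                       coverage=best_cov)
    return out
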