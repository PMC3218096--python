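"""Family/superfamily assignment, subfamily naming, summary tables and FISH
probe design.

The classification scheme has four superfamilies: A (centromeric minor
satellite), B (pericentromeric major satellite), C (heterogeneous tandem
repeats: the strictly pericentromeric TRPC family plus multi-locus,
single-locus and unplaced families) and D (transposable-element-related
families).  Precedence follows the published narrative: known-satellite
library matches first, then TE-class library matches, then position/locus
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays import TandemArray
from .cluster import LibraryMatch, SubfamilyPartition
from .config import DEFAULT_CONFIG, PipelineConfig
from .mapping import LocusClass
from .metrics import consensus_monomer

SUPERFAMILIES = ("A_centromeric", "B_pericentromeric", "C_heterogeneous",
                 "D_TE_related")

_FAMILY_SUPERFAMILY = {
    "MiSat": "A_centromeric",
    "MaSat": "B_pericentromeric",
    "TRPC": "C_heterogeneous",
    "multi_locus": "C_heterogeneous",
    "single_locus": "C_heterogeneous",
    "unplaced": "C_heterogeneous",
}


@dataclass(frozen=True)
class FamilyAssignment:
    array_id: str
    superfamily: str
    family: str
    evidence: tuple[str, ...]
    subfamily: str | None = None

    def __post_init__(self) -> None:
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        if not self.evidence:
            raise ValueError("evidence must be non-empty")
        expected = _FAMILY_SUPERFAMILY.get(self.family)
        if expected is None and not self.family.endswith("_related"):
            raise ValueError(f"unknown family {self.family!r}")
        if expected is not None and expected != self.superfamily:
            raise ValueError(
                f"family {self.family} inconsistent with superfamily "
                f"{self.superfamily}")


def assign_family(
    array: TandemArray,
    library_match: LibraryMatch | None,
    locus_class: LocusClass,
    subfamily_peri_chrom_count: int,
    config: PipelineConfig = DEFAULT_CONFIG,
    *,
    subfamily: str | None = None,
) -> FamilyAssignment:
    """Classify one array.

    Precedence: (1) library match to the minor satellite -> A/MiSat;
    (2) major satellite -> B/MaSat; (3) TE-class library match -> D with
    the family named after the matched element; (4) otherwise C: a
    subfamily with pericentromeric loci on at least
    ``config.trpc_min_peri_chroms`` distinct chromosomes -> TRPC, else the
    locus-count class (multi_locus / single_locus / unplaced).
    """
    aid = array.array_id
    if library_match is not None:
        entry = library_match.entry
        cov = f"coverage={library_match.coverage:.2f}"
        if entry.known_family == "MiSat":
            return FamilyAssignment(aid, "A_centromeric", "MiSat",
                                    (f"library:{entry.name}", cov),
                                    subfamily=subfamily)
        if entry.known_family == "MaSat":
            return FamilyAssignment(aid, "B_pericentromeric", "MaSat",
                                    (f"library:{entry.name}", cov),
                                    subfamily=subfamily)
        if entry.class_tag == "TE":
            fam = f"{entry.known_family or entry.name}_related"
            return FamilyAssignment(aid, "D_TE_related", fam,
                                    (f"library:{entry.name}", cov),
                                    subfamily=subfamily)
    if subfamily_peri_chrom_count >= config.trpc_min_peri_chroms:
        return FamilyAssignment(
            aid, "C_heterogeneous", "TRPC",
            (f"pericentromeric_chromosomes={subfamily_peri_chrom_count}",),
            subfamily=subfamily)
    return FamilyAssignment(
        aid, "C_heterogeneous", locus_class.value,
        (f"locus_class={locus_class.value}",), subfamily=subfamily)


def name_subfamilies(
    partition: SubfamilyPartition,
    arrays: Sequence[TandemArray],
    assignments: Mapping[str, FamilyAssignment],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, str]:
    """Deterministic subfamily names: TR[PC]-<unit><letter>-<suffix>.

    The unit is the subfamily's minimal member unit length; within each
    (prefix, unit) group index letters A, B, ... follow decreasing total
    member array length (ties by smaller subfamily id); "PC" marks
    subfamilies classified into the TRPC family.  Also stored on
    ``partition.names``.
    """
    by_id = {a.array_id: a for a in arrays}
    groups = partition.members()
    info = []
    for sub_id, member_ids in groups.items():
        members = [by_id[m] for m in member_ids]
        unit = min(m.unit_len for m in members)
        total_len = sum(m.array_len for m in members)
        fams = {assignments[m].family for m in member_ids
                if m in assignments}
        prefix = "TRPC" if fams == {"TRPC"} else "TR"
        info.append((prefix, unit, -total_len, sub_id))
    names: dict[str, str] = {}
    counters: dict[tuple[str, int], int] = {}
    for prefix, unit, _, sub_id in sorted(info):
        idx = counters.get((prefix, unit), 0)
        counters[(prefix, unit)] = idx + 1
        names[sub_id] = (f"{prefix}-{unit}{_letters(idx)}-"
                         f"{config.species_suffix}")
    partition.names = names
    return names


def _letters(idx: int) -> str:
    out = ""
    idx += 1
    while idx:
        idx, r = divmod(idx - 1, 26)
        out = chr(ord("A") + r) + out
    return out


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summary_table(
    assignments: Sequence[FamilyAssignment],
) -> pd.DataFrame:
    """Classification summary: one row per (superfamily, family) with array
    counts, percent of the total (half-up, one decimal, recomputed from the
    counts) and the number of distinct subfamilies."""
    if not assignments:
        return pd.DataFrame(columns=["superfamily", "family", "n_arrays",
                                     "percent_of_total", "n_subfamilies"])
    total = len(assignments)
    rows = []
    keys = sorted({(a.superfamily, a.family) for a in assignments})
    for sup, fam in keys:
        members = [a for a in assignments
                   if (a.superfamily, a.family) == (sup, fam)]
        subs = {a.subfamily for a in members if a.subfamily is not None}
        rows.append({
            "superfamily": sup,
            "family": fam,
            "n_arrays": len(members),
            "percent_of_total": _round_half_up(100.0 * len(members) / total),
            "n_subfamilies": len(subs),
        })
    return pd.DataFrame(rows)


def total_large_arrays(per_assembly_counts: Mapping[str, int]) -> int:
    """Combined large-array count across assemblies (the assembly-summary
    total; counts must be non-negative)."""
    if any(v < 0 for v in per_assembly_counts.values()):
        raise ValueError("counts must be non-negative")
    return int(sum(per_assembly_counts.values()))


# ---------------------------------------------------------------------------
# FISH probe design

@dataclass(frozen=True)
class Probe:
    kind: str                 # oligo | long_fragment
    seq: str
    source_array: str
    adapters: tuple[str, str] | None = None


def design_probe(
    array: TandemArray,
    kind: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Probe:
    """Design a FISH probe from one array.

    ``oligo``: the consensus monomer, doubled to a head-to-tail dimer when
    the unit is shorter than ``config.probe_oligo_dimer_below`` bp (the
    short-monomer dimer probe of the published screen).  ``long_fragment``:
    the ~150 bp window of the array maximising mean divergence from the
    consensus tiling (leftmost on ties), flanked by two distinct ~20 bp
    adapters that are verified absent from the array.
    """
    if kind == "oligo":
        cons = consensus_monomer(array)
        seq = cons * 2 if array.unit_len < config.probe_oligo_dimer_below \
            else cons
        return Probe(kind="oligo", seq=seq, source_array=array.array_id)
    if kind != "long_fragment":
        raise ValueError(f"unknown probe kind {kind!r}")
    w = config.probe_fragment_len
    if array.array_len < w:
        raise ValueError(
            f"array {array.array_id} shorter than the {w} bp probe window")
    cons = consensus_monomer(array)
    seq = array.array_seq.upper()
    tiling = (cons * (len(seq) // len(cons) + 1))[:len(seq)]
    mismatch = np.frombuffer(seq.encode(), dtype=np.uint8) != \
        np.frombuffer(tiling.encode(), dtype=np.uint8)
    window_div = np.convolve(mismatch.astype(float),
                             np.ones(w) / w, mode="valid")
    start = int(np.argmax(window_div))     # argmax returns leftmost tie
    core = seq[start:start + w]
    left, right = config.probe_adapters
    for adapter in (left, right):
        if adapter in seq:
            raise ValueError(
                f"adapter {adapter} occurs in array {array.array_id}")
    return Probe(kind="long_fragment", seq=left + core + right,
                 source_array=array.array_id, adapters=(left, right))


def write_probe_fasta(probes: Sequence[Probe], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(probes, 1):
            desc = f"kind={p.kind} source={p.source_array}"
            if p.adapters:
                desc += f" adapter5={p.adapters[0]} adapter3={p.adapters[1]}"
            fh.write(f">probe_{i} {desc}\n{p.seq}\n")
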