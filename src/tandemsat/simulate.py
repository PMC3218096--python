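"""Synthetic tandem-repeat genomes with known truth.

Generates monomers, tandem arrays (optionally with higher-order structure:
an ordered block of diverged monomer variants repeated many times), and
chromosome-scale references that mimic the mouse assembly geometry — every
telocentric chromosome starts with a 3 Mb N gap reserved for the centromere,
arrays are spliced at planted coordinates, and a truth table records where
everything went.  Defaults emulate the published study system: AT-rich
120 bp minor-satellite monomers, the 58+60+58+58 bp major-satellite
heterotetramer (234 bp block), and a 21 bp pericentromeric repeat organised
in variant blocks.

All randomness flows through explicit seeds: identical seeds give
byte-identical sequence and truth outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import LibraryEntry
from .mapping import BandRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_monomer(length: int, target_gc: float, seed: int) -> str:
    """Random monomer with i.i.d. bases; GC probability = ``target_gc``."""
    if length < 4:
        raise ValueError("monomer length must be >= 4")
    rng = _rng(seed)
    p = np.array([(1 - target_gc) / 2, target_gc / 2,
                  target_gc / 2, (1 - target_gc) / 2])
    return bytes(rng.choice(_BASES, size=length, p=p)).decode()


def mutate(seq: str, sub_rate: float, rng: np.random.Generator,
           indel_rate: float = 0.0) -> str:
    """Per-base substitutions (to a different base) and 1 bp indels."""
    out = []
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    for c in seq:
        r = rng.random()
        if indel_rate and r < indel_rate / 2:
            continue                       # 1 bp deletion
        if indel_rate and r < indel_rate:
            out.append(c)                  # 1 bp insertion after this base
            out.append("ACGT"[rng.integers(4)])
            continue
        if rng.random() < sub_rate:
            out.append(others[c][rng.integers(3)])
        else:
            out.append(c)
    return "".join(out)


def make_variants(base: str, n: int, divergence: float, seed: int,
                  length_changes: tuple[int, ...] | None = None,
                  ) -> list[str]:
    """Derive ``n`` monomer variants from a common ancestor.

    Each variant is mutated at ``divergence / 2`` so that the expected
    pairwise divergence between variants is about ``divergence``.
    ``length_changes[i]`` inserts (+) or deletes (-) that many bases in
    variant i, emulating monomer-length jitter such as the 60 bp variant of
    the major-satellite heterotetramer.
    """
    rng = _rng(seed)
    variants = []
    for i in range(n):
        v = mutate(base, divergence / 2, rng)
        delta = length_changes[i] if length_changes else 0
        if delta > 0:
            pos = int(rng.integers(len(v)))
            ins = "".join("ACGT"[rng.integers(4)] for _ in range(delta))
            v = v[:pos] + ins + v[pos:]
        elif delta < 0:
            pos = int(rng.integers(len(v) + delta))
            v = v[:pos] + v[pos - delta:]
        variants.append(v)
    return variants


@dataclass(frozen=True)
class ArraySpec:
    """Recipe for one planted tandem array.

    ``monomers`` is the ordered variant block (a single monomer gives a
    plain tandem, two or more a higher-order repeat whose period is the
    block length); rates are per base per copy.
    """
    monomers: tuple[str, ...]
    block_copies: int
    per_copy_sub_rate: float = 0.0
    per_copy_indel_rate: float = 0.0
    target_gc: float | None = None
    seed: int = 0
    label: str = "array"

    def __post_init__(self) -> None:
        if not self.monomers:
            raise ValueError("at least one monomer required")
        for m in self.monomers:
            if not 4 <= len(m) <= 2000:
                raise ValueError("monomer lengths must be 4-2000 bp")
        for r in (self.per_copy_sub_rate, self.per_copy_indel_rate):
            if not 0.0 <= r < 0.5:
                raise ValueError("rates must be in [0, 0.5)")
        if self.block_copies < 1:
            raise ValueError("block_copies must be >= 1")

    @property
    def block_len(self) -> int:
        return sum(len(m) for m in self.monomers)

    @property
    def unit_len(self) -> int:
        return round(np.mean([len(m) for m in self.monomers]))


def make_array(spec: ArraySpec) -> tuple[str, dict]:
    """Concatenate the variant block ``block_copies`` times, mutating every
    copy independently; returns the sequence and its truth row."""
    rng = _rng(spec.seed)
    copies = []
    for _ in range(spec.block_copies):
        for m in spec.monomers:
            copies.append(mutate(m, spec.per_copy_sub_rate, rng,
                                 spec.per_copy_indel_rate))
    seq = "".join(copies)
    distinct = len(set(spec.monomers)) > 1
    truth = {
        "label": spec.label,
        "unit_len": spec.unit_len,
        "hor_period": float(spec.block_len) if distinct else float("nan"),
        "sub_rate": spec.per_copy_sub_rate,
        "indel_rate": spec.per_copy_indel_rate,
        "gc": (seq.count("G") + seq.count("C")) / len(seq),
        "array_len": len(seq),
    }
    return seq, truth


# ---------------------------------------------------------------------------
# whole-genome plans

@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    gap_len: int = 3_000_000


@dataclass(frozen=True)
class Placement:
    spec: ArraySpec
    chrom: str
    start: int       # 1-based


@dataclass
class GenomePlan:
    chromosomes: list[Chromosome]
    placements: list[Placement]
    band_table: list[BandRecord] = field(default_factory=list)
    filler_gc: float = 0.42
    seed: int = 0


class PlacementError(ValueError):
    pass


def make_genome(plan: GenomePlan
                ) -> tuple[dict[str, str], pd.DataFrame]:
    """Assemble chromosome sequences and the truth table.

    Chromosomes are an N gap followed by composition-matched random filler;
    planted arrays are spliced in at their 1-based start coordinates.
    Placements must fall after the gap and must not overlap.
    """
    rng = _rng(plan.seed)
    chroms = {c.name: c for c in plan.chromosomes}
    built: dict[str, np.ndarray] = {}
    p = np.array([(1 - plan.filler_gc) / 2, plan.filler_gc / 2,
                  plan.filler_gc / 2, (1 - plan.filler_gc) / 2])
    for c in plan.chromosomes:
        filler = rng.choice(_BASES, size=c.length - c.gap_len, p=p)
        built[c.name] = np.concatenate(
            [np.full(c.gap_len, ord("N"), dtype=np.uint8), filler])
    rows = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for pl in plan.placements:
        if pl.chrom not in chroms:
            raise PlacementError(f"unknown chromosome {pl.chrom}")
        seq, truth = make_array(pl.spec)
        start0 = pl.start - 1
        end0 = start0 + len(seq)           # exclusive
        c = chroms[pl.chrom]
        if pl.start <= c.gap_len:
            raise PlacementError(
                f"placement at {pl.chrom}:{pl.start} inside the gap")
        if end0 > c.length:
            raise PlacementError(
                f"placement at {pl.chrom}:{pl.start} exceeds chromosome")
        for s, e in occupied.get(pl.chrom, []):
            if start0 < e and s < end0:
                raise PlacementError(
                    f"overlapping placements on {pl.chrom}")
        occupied.setdefault(pl.chrom, []).append((start0, end0))
        built[pl.chrom][start0:end0] = np.frombuffer(
            seq.encode(), dtype=np.uint8)
        rows.append({
            "chrom": pl.chrom, "start": pl.start, "end": end0,
            **truth,
        })
    seqs = {name: arr.tobytes().decode() for name, arr in built.items()}
    truth_df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "unit_len",
                       "hor_period", "sub_rate", "indel_rate", "gc",
                       "array_len"])
    return seqs, truth_df


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bands_bed(bands: list[BandRecord], path) -> None:
    """cytoBand-style BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for b in sorted(bands, key=lambda b: (b.chrom, b.start)):
            stain = b.stain or "gpos"
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{b.band_name}\t"
                     f"{stain}\n")


# ---------------------------------------------------------------------------
# study-system presets

def misat_like_spec(seed: int, copies: int = 50,
                    sub_rate: float = 0.05,
                    label: str = "MiSat") -> ArraySpec:
    """Single-variant, AT-rich, 120 bp monomer array (centromeric
    minor-satellite-like)."""
    base = make_monomer(120, 0.30, seed)
    return ArraySpec(monomers=(base,), block_copies=copies,
                     per_copy_sub_rate=sub_rate, seed=seed + 1, label=label)


def masat_like_spec(seed: int, copies: int = 30,
                    variant_divergence: float = 0.10,
                    sub_rate: float = 0.01,
                    label: str = "MaSat") -> ArraySpec:
    """Heterotetramer array: four diverged 58/60/58/58 bp monomer variants
    (block 234 bp), the major-satellite higher-order structure."""
    base = make_monomer(58, 0.35, seed)
    v = make_variants(base, 4, variant_divergence, seed + 1,
                      length_changes=(0, 2, 0, 0))
    return ArraySpec(monomers=tuple(v), block_copies=copies,
                     per_copy_sub_rate=sub_rate, seed=seed + 2, label=label)


def trpc_like_spec(seed: int, copies: int = 40, n_variants: int = 8,
                   variant_divergence: float = 0.10,
                   sub_rate: float = 0.01,
                   label: str = "TRPC") -> ArraySpec:
    """Short 21 bp monomers arranged in a repeating block of diverged
    variants (pericentromeric-classical-satellite-like)."""
    base = make_monomer(21, 0.45, seed)
    v = make_variants(base, n_variants, variant_divergence, seed + 1)
    return ArraySpec(monomers=tuple(v), block_copies=copies,
                     per_copy_sub_rate=sub_rate, seed=seed + 2, label=label)


@dataclass
class StudySystem:
    """A complete desk-scale study: contigs to catalog, the anchored
    reference to map against, a known-repeat library, bands and truth."""
    contigs: dict[str, str]          # everything the detector sees
    reference: dict[str, str]        # anchored chromosomes only
    library: list[LibraryEntry]
    bands: list[BandRecord]
    truth: pd.DataFrame              # per planted array, with family labels


def make_study(seed: int, gap_len: int = 3_000_000) -> StudySystem:
    """Plant one array of each of the seven family archetypes.

    Reference chromosomes chr1/chr2 each begin with the centromeric N gap;
    pericentromeric TRPC arrays sit right behind the gap on both
    chromosomes, a major-satellite array behind the gap on chr1, a
    multi-locus array occurs on both chromosome arms, a single-locus array
    once, and a transposable-element-derived array twice.  A gapless
    unanchored contig carries the minor-satellite-like and unplaced arrays
    (they are cataloged but absent from the reference), mirroring the real
    situation where the minor satellite lives only in unassembled
    sequence.
    """
    s = seed * 1000
    misat = misat_like_spec(s + 1, copies=30)
    masat_base = make_monomer(58, 0.35, s + 11)
    masat_v = make_variants(masat_base, 4, 0.10, s + 12,
                            length_changes=(0, 2, 0, 0))
    masat = ArraySpec(monomers=tuple(masat_v), block_copies=16,
                      per_copy_sub_rate=0.02, seed=s + 13, label="MaSat")
    trpc_base = make_monomer(21, 0.45, s + 21)
    trpc_v = tuple(make_variants(trpc_base, 8, 0.10, s + 22))
    trpc_a = ArraySpec(monomers=trpc_v, block_copies=22,
                       per_copy_sub_rate=0.02, seed=s + 23, label="TRPC")
    trpc_b = ArraySpec(monomers=trpc_v, block_copies=20,
                       per_copy_sub_rate=0.02, seed=s + 24, label="TRPC")
    ml_mono = make_monomer(45, 0.50, s + 31)
    ml_a = ArraySpec(monomers=(ml_mono,), block_copies=75,
                     per_copy_sub_rate=0.03, seed=s + 32, label="ML")
    ml_b = ArraySpec(monomers=(ml_mono,), block_copies=70,
                     per_copy_sub_rate=0.03, seed=s + 33, label="ML")
    sl = ArraySpec(monomers=(make_monomer(180, 0.42, s + 41),),
                   block_copies=18, per_copy_sub_rate=0.03, seed=s + 42,
                   label="SL")
    unp = ArraySpec(monomers=(make_monomer(90, 0.55, s + 51),),
                    block_copies=36, per_copy_sub_rate=0.03, seed=s + 52,
                    label="UnP")
    mta_cons = make_monomer(350, 0.45, s + 61)
    te_a = ArraySpec(monomers=(mta_cons,), block_copies=10,
                     per_copy_sub_rate=0.02, seed=s + 62, label="TE")
    te_b = ArraySpec(monomers=(mta_cons,), block_copies=9,
                     per_copy_sub_rate=0.02, seed=s + 63, label="TE")

    # the pericentromeric window spans 300 kb past the gap, so arrays whose
    # classification must rest on locus counts alone are planted beyond it
    g = gap_len
    far = g + 350_000
    chr_len = g + 450_000
    plan = GenomePlan(
        chromosomes=[Chromosome("chr1", chr_len, g),
                     Chromosome("chr2", chr_len, g)],
        placements=[
            Placement(trpc_a, "chr1", g + 1),
            Placement(masat, "chr1", g + 20_000),
            Placement(ml_a, "chr1", far),
            Placement(sl, "chr1", far + 20_000),
            Placement(te_a, "chr1", far + 40_000),
            Placement(trpc_b, "chr2", g + 1),
            Placement(ml_b, "chr2", far),
            Placement(te_b, "chr2", far + 40_000),
        ],
        band_table=[
            BandRecord("chr1", g + 1, g + 50_000, "1A1"),
            BandRecord("chr1", g + 50_001, chr_len, "1A2"),
            BandRecord("chr2", g + 1, g + 50_000, "2A1"),
            BandRecord("chr2", g + 50_001, chr_len, "2A2"),
        ],
        seed=s + 70,
    )
    reference, truth_ref = make_genome(plan)

    # unanchored contig: cataloged, but not part of the mapping reference
    un_plan = GenomePlan(
        chromosomes=[Chromosome("chrUn_contig1", 40_000, 0)],
        placements=[Placement(misat, "chrUn_contig1", 5_000),
                    Placement(unp, "chrUn_contig1", 20_000)],
        seed=s + 80,
    )
    un_seqs, truth_un = make_genome(un_plan)

    library = [
        LibraryEntry(name="SATMIN_like", seq=misat.monomers[0],
                     class_tag="satellite", known_family="MiSat"),
        LibraryEntry(name="GSAT_like", seq="".join(masat_v),
                     class_tag="satellite", known_family="MaSat"),
        LibraryEntry(name="MTA_like", seq=mta_cons,
                     class_tag="TE", known_family="MTA"),
    ]
    label_to_family = {
        "MiSat": "MiSat", "MaSat": "MaSat", "TRPC": "TRPC",
        "ML": "multi_locus", "SL": "single_locus", "UnP": "unplaced",
        "TE": "MTA_related",
    }
    truth = pd.concat([truth_ref, truth_un], ignore_index=True)
    truth["family"] = truth["label"].map(label_to_family)
    contigs = {**reference, **un_seqs}
    return StudySystem(contigs=contigs, reference=reference,
                       library=library, bands=plan.band_table, truth=truth)
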