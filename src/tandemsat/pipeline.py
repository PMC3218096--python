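"""End-to-end orchestration: contigs in, classified catalog out.

Mirrors the published workflow: tandem-array detection per contig,
redundancy removal, the 3 kb filter, per-array metrics, subfamily clustering
at score > 90, known-repeat library annotation with the 80 % coverage rule,
reference mapping with the 2850/150 bp rules, pericentromere flags, and the
final family/superfamily table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .arrays import TandemArray
from .catalog import detect_tandem, filter_large, remove_redundant
from .classify import (FamilyAssignment, assign_family, name_subfamilies,
                       summary_table)
from .cluster import (LibraryEntry, LibraryMatch, SubfamilyPartition,
                      annotate_catalog, cluster_subfamilies, pairwise_scores)
from .config import DEFAULT_CONFIG, PipelineConfig
from .mapping import (BandRecord, GenomeLocus, assign_band,
                      classify_locus_count, is_pericentromeric, map_catalog)


@dataclass
class PipelineResult:
    catalog: list[TandemArray]
    partition: SubfamilyPartition
    annotations: dict[str, LibraryMatch | None]
    loci: dict[str, list[GenomeLocus]]
    assignments: dict[str, FamilyAssignment]
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.assignments.values():
            counts[a.family] = counts.get(a.family, 0) + 1
        return dict(sorted(counts.items()))


def build_catalog(
    contigs: dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
    max_period: int = 2000,
) -> list[TandemArray]:
    """Detect, deduplicate and size-filter arrays over a set of contigs."""
    catalog: list[TandemArray] = []
    for name in sorted(contigs):
        found = detect_tandem(contigs[name], max_period, config,
                              source_seq_id=name)
        catalog.extend(filter_large(remove_redundant(found),
                                    config.min_array_len))
    return catalog


def run_pipeline(
    contigs: dict[str, str],
    reference: dict[str, str],
    library: Sequence[LibraryEntry],
    bands: Sequence[BandRecord] = (),
    config: PipelineConfig = DEFAULT_CONFIG,
    *,
    max_period: int = 2000,
    catalog: Sequence[TandemArray] | None = None,
    cluster_method: str = "blast",
) -> PipelineResult:
    """Run the full annotation pipeline.

    ``contigs`` is everything the detector sees (assembled chromosomes plus
    unanchored contigs); ``reference`` is the anchored assembly used for
    locus mapping.  A pre-built ``catalog`` (e.g. from TRF output) may be
    supplied to skip detection.
    """
    if catalog is None:
        catalog = build_catalog(contigs, config, max_period)
    catalog = list(catalog)
    if not catalog:
        return PipelineResult(catalog=[],
                              partition=SubfamilyPartition(assignment={}),
                              annotations={}, loci={}, assignments={},
                              summary=summary_table([]))
    scores = pairwise_scores(catalog, config, method=cluster_method)
    partition = cluster_subfamilies(
        catalog, config.cluster_score_threshold, config, scores=scores)
    annotations = annotate_catalog(catalog, library,
                                   config.library_coverage_min, config)
    loci = map_catalog(catalog, reference, config)
    for array_loci in loci.values():
        for locus in array_loci:
            locus.pericentromeric = is_pericentromeric(
                locus, config.centromeric_gap_len,
                config.pericentromeric_window)
            if bands:
                locus.band = assign_band(locus, bands)
    # pericentromeric chromosomes per subfamily
    peri_chroms: dict[str, set[str]] = {}
    for aid, sub in partition.assignment.items():
        for locus in loci[aid]:
            if locus.pericentromeric:
                peri_chroms.setdefault(sub, set()).add(locus.chrom)
    assignments: dict[str, FamilyAssignment] = {}
    for array in catalog:
        aid = array.array_id
        sub = partition.assignment[aid]
        assignments[aid] = assign_family(
            array, annotations[aid], classify_locus_count(loci[aid]),
            len(peri_chroms.get(sub, ())), config, subfamily=sub)
    name_subfamilies(partition, catalog, assignments, config)
    summary = summary_table(list(assignments.values()))
    return PipelineResult(catalog=catalog, partition=partition,
                          annotations=annotations, loci=loci,
                          assignments=assignments, summary=summary)


def classification_frame(result: PipelineResult) -> pd.DataFrame:
    """Per-array classification table (array, superfamily, family,
    subfamily name, evidence)."""
    rows = []
    for aid in sorted(result.assignments):
        a = result.assignments[aid]
        sub = result.partition.assignment[aid]
        rows.append({
            "array_id": aid,
            "superfamily": a.superfamily,
            "family": a.family,
            "subfamily": result.partition.names.get(sub, sub),
            "evidence": ";".join(a.evidence),
        })
    return pd.DataFrame(rows, columns=["array_id", "superfamily", "family",
                                       "subfamily", "evidence"])
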