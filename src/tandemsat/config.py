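"""Pipeline-wide numeric parameters.

Every threshold used by the annotation pipeline lives here so that a run is
fully described by one :class:`PipelineConfig` value.  Defaults reproduce the
published mouse large-tandem-repeat screen: arrays shorter than 3 kb are
discarded, subfamilies are merged at a raw local-alignment score above 90,
known-repeat annotation requires 80 % coverage of the array, genome hits
shorter than 2850 bp are dropped and hits closer than 150 bp are merged, and
the pericentromere is defined relative to the 3 Mb assembly gap at the start
of each telocentric chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PipelineConfig:
    """Numeric parameters of the large tandem repeat annotation pipeline.

    Alignment scoring follows the blastn convention: ``match_score`` /
    ``mismatch_score`` are per-base scores and a gap of length *k* scores
    ``gap_open + k * gap_extend`` (both stored as negative numbers, so a
    1 bp gap costs 7 with the defaults).
    """

    # catalog construction
    min_array_len: int = 3000          # bp; arrays below this are dropped
    max_unit_len: int = 2000           # bp; detector period cap

    # subfamily clustering
    cluster_score_threshold: float = 90.0   # raw score; pairs above are merged
    borderline_frac: float = 0.10           # |score - thr| <= frac*thr flagged

    # known-repeat library annotation
    library_coverage_min: float = 0.80  # fraction of array covered by hits

    # reference-genome mapping
    map_min_hit_len: int = 2850        # bp; merged hits <= this are discarded
    map_merge_gap: int = 150           # bp; closer hits merge into one locus

    # self dot-plots
    dotplot_window_small: int = 13
    dotplot_window_large: int = 51
    dotplot_identity_strict: float = 0.90
    dotplot_identity_loose: float = 0.80

    # pericentromere geometry (telocentric chromosomes, gap at coordinate 1)
    centromeric_gap_len: int = 3_000_000
    pericentromeric_window: int = 300_000

    # alignment scoring (blastn-style)
    match_score: int = 2
    mismatch_score: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    # tandem-array detector
    detect_identity_min: float = 0.60  # windowed self-match fraction in-array
    detect_min_copies: float = 3.0     # minimum copies for a detection
    detect_min_span: int = 100         # bp floor for a detection

    # higher-order-repeat detection
    hor_theta: float = 0.25            # base period: peak >= background+theta
    hor_delta: float = 0.10            # HOR: f(HOR) - f(base) >= delta
    hor_max_offset: int = 2200         # bp; spectrum scan limit
    hor_multiple_tol: float = 0.04     # window +-tol*m*p around each multiple

    # classification
    trpc_min_peri_chroms: int = 2      # pericentromeric chromosomes for TRPC
    species_suffix: str = "MM"

    # probe design
    probe_fragment_len: int = 150
    probe_oligo_dimer_below: int = 30  # unit_len below this -> dimer oligo
    probe_adapters: tuple[str, str] = (
        "GTCAGGCTAACTGGTCCAAT",
        "CAGTTCGACGGTTAGACCTA",
    )

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_array_len", "max_unit_len", "map_min_hit_len",
                     "map_merge_gap", "dotplot_window_small",
                     "dotplot_window_large", "centromeric_gap_len",
                     "pericentromeric_window", "hor_max_offset",
                     "probe_fragment_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("library_coverage_min", "dotplot_identity_strict",
                     "dotplot_identity_loose", "detect_identity_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.probe_adapters[0] == self.probe_adapters[1]:
            raise ValueError("probe adapters must be distinct")


DEFAULT_CONFIG = PipelineConfig()
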