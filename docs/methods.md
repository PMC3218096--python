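# Methods

This note documents the models, rules and numerical choices behind
`tandemsat`, and what the synthetic benchmarks do and do not demonstrate.

## Problem and scope

Satellite DNA — megabase-scale tandem arrays of short monomers — dominates
centromeric and pericentromeric heterochromatin but is systematically
under-represented and fragmented in assemblies. The package annotates
*large* tandem arrays (≥ 3 kb) in an assembly: it catalogues them,
measures them, groups them into subfamilies, detects higher-order repeat
(HOR) structure, maps them onto an anchored reference, and classifies them
into the four-superfamily scheme used for the mouse repeat landscape
(A centromeric MiSat, B pericentromeric MaSat, C heterogeneous —
TRPC / multi-locus / single-locus / unplaced — and D TE-related).

Detection on real data is delegated to Tandem Repeats Finder: the
`parse_trf_dat` reader ingests its `-d` table (period cap 2000 bp; TRF's
mismatch weight of 5 is recorded in provenance, not re-implemented). The
built-in `detect_tandem` exists so that synthetic genomes can be processed
with no external detector; it is a periodicity scanner, not a TRF
reimplementation.

## Coordinates

All coordinates are 1-based inclusive (the TRF convention), so a locus
spanning 3,000,001–3,033,629 is 33,629 bp — this is the arithmetic under
which published pericentromeric locus lengths reconcile, and it is pinned
by tests. BED readers/writers convert at the boundary.

## Catalog construction

Redundancy elimination follows two rules, applied transitively: an array
strictly contained within a longer one is removed, and of arrays with
identical coordinates only the smallest unit size survives (ties broken by
lexicographic consensus — the ordering is otherwise undefined). Partially
overlapping arrays are kept as independent. The operation is idempotent
and never mutates records. The large-array filter keeps `array_len ≥
3000`; 2999 bp is out, 3000 bp is in.

`detect_tandem` computes, for each candidate period *p*, the per-base
self-match indicator `s[i] == s[i+p]`, smooths it over a window
`max(p, 35)` bp, and takes stretches above `detect_identity_min`
(default 0.60) spanning at least `max(3p, 100)` bp as candidate regions;
short dips are bridged (chance divergence inside a continuous array).
Candidates across periods that overlap are clustered, and each cluster
keeps the smallest period whose detection spans ≥ 90 % of the cluster's
maximal extent — this stops a marginal small period (e.g. the 58 bp
sub-period of a diverged heterotetramer) from fragmenting an array that
its block period explains cleanly, while still reporting the smallest
adequate unit. N runs are skipped entirely and coordinates are restored
relative to the full sequence. The 0.60/35 bp/100 bp choices balance
false splits against background noise: a random-composition stretch has
self-match fraction ≈ 0.25–0.30, so a 100 bp window above 0.60 is
(binomially) never seen in desk-scale random sequence, while arrays up to
~30 % monomer divergence still pass.

## Per-array metrics

GC content excludes N/ambiguity codes from the denominator (an all-N
sequence is an error, not 0). The consensus monomer is the per-column
majority over full `unit_len` slices anchored at the array start, ties
alphabetical, partial terminal monomers ignored. Monomer variability
(Var%) is the mean unit-level edit distance to the consensus divided by
the unit length — consensus-based rather than all-pairs, matching TRF's
percent-matches semantics and costing O(n) rather than O(n²). For
TRF-derived arrays whose copy number disagrees with the span (indel-rich
arrays where fixed slicing drifts out of frame), `100 − percent_matches`
is reported instead and flagged in provenance; both statistics are thus
available, since the published tables do not state which was used.
Parameter-recovery tests show planted substitution rates of 1–30 % are
recovered within ±3 percentage points.

## Similarity and subfamilies

The pairwise statistic is the raw local-alignment score under blastn
weights: match +2, mismatch −3, a gap of length *k* scoring −(5 + 2*k*).
The published threshold ("score greater than 90") implies ≈ 45 identical
bases minimum. Exact Smith–Waterman (both strands, strand choice by
maximum) is the reference semantics, implemented with Biopython's
PairwiseAligner and cross-checked in tests against an independent
brute-force Gotoh dynamic program; batch scoring for kilobase arrays
delegates to the `blastn` binary with the same weights and the search
parameters of the original screen (word size 10, e-value 1e-16, DUST and
soft masking off). Tests verify the heuristic path makes the same
above/below-threshold decisions as exact DP on clusterable catalogs.

Subfamilies are single-linkage connected components over edges with score
> 90 — deterministic, order-independent, labelled by smallest member id.
Raising the threshold only refines the partition (tested). The published
hand-curation of fuzzy subfamily borders is replaced by a report of
borderline pairs (score within ±10 % of the threshold); nothing is ever
auto-merged.

Library annotation tiles each consensus entry tandemly to the array
length, collects all local hits, merges overlapping hit intervals on the
array and requires merged coverage ≥ 80 %. The best-covering entry wins;
an exact tie between entries is an error surfaced to the caller rather
than an arbitrary pick.

## Higher-order repeats

The detection primitive is the period spectrum
`f(d) = mean_i [s_i == s_{i+d}]`, the algorithmic form of reading
diagonals off a self dot-plot; windowed dot-plot matrices (13 bp
grayscale, 51 bp binary at 90 %/80 % identity) are retained as export
artifacts. The background `b` is the mean self-identity of a
composition-matched shuffle (seeded).

* **Base period** = smallest local spectral peak with `f ≥ b + θ`,
  θ = 0.25. If no peak qualifies and a cataloged unit length is
  available, the best peak within ±10 % of that unit is accepted at
  `b + θ/2` (fallback for indel-riddled arrays with flat spectra).
* **HOR** = smallest multiple *m* ≥ 2 of the base period whose spectral
  peak — searched within ±max(2, 4 %) bp of *m·p* to absorb
  monomer-length jitter — exceeds the base-period value by δ = 0.10.
  Whole HOR blocks must agree distinctly better than adjacent monomers;
  a single-variant array therefore never reports a HOR (0/50 false calls
  in tests).
* **Subunits** = peaks below the base period clearing `b + θ/2` (subunit
  structure is by nature less conserved than the monomer).

The ±4 % multiple window is essential, not cosmetic: the mouse major
satellite heterotetramer is 58+60+58+58 = 234 bp, which is *not* 4×58;
the detector reports the true 234 bp spectral peak with multiplicity 4.
Offsets are scanned to `min(array_len/3, 2200)` bp — slightly above the
2 kb TRF cap, since larger HOR units exist.

δ = 0.10 sets the detection floor: the spectrum contrast between the HOR
peak and the base peak is roughly (inter-variant divergence −
2×per-copy noise), so variant blocks need ≳ 15 % realized inter-variant
divergence at 1–2 % noise to be called reliably. Sensitivity is verified
at 50/50 replicates for 30 % divergence / 1 % noise; blocks diverged only
~8–16 % sit at or below the δ floor by design (they are also invisible to
the eye on a dot-plot at that contrast). The heterotetramer case is
easier than this bound suggests because the 60 bp variant frame-shifts
`f(58)` far below the block peak.

## Mapping and classification

Arrays are mapped with blastn (both strands). Hits on the same
chromosome and strand separated by < 150 bp are merged; merged loci of
≤ 2850 bp are discarded — the only mapping thresholds the original screen
states (given there for TE-related arrays; applied here as the default
for all arrays, config-overridable). Merging is order-independent and
idempotent, and merged loci never overlap on a strand.

Locus classes: 0 loci → unplaced, 1 → single-locus, ≥ 2 → multi-locus.
Pericentromery assumes the mouse telocentric convention — a 3 Mb
assembly gap at the low-coordinate end of each chromosome — and flags
loci starting within 300 kb past the gap; the window is chosen to cover
every published gap-adjacent locus (max start 3,232,335) and is exposed
in config. Cytogenetic bands are assigned by locus midpoint, boundary
ties to the lower-coordinate band.

Family precedence: known-satellite library match (MiSat → A, MaSat → B),
then TE-class library match (→ D, family named after the element), then
position: a subfamily with pericentromeric loci on ≥ 2 distinct
chromosomes is TRPC (generalising the published single instance), else
the locus class decides. Subfamily names are
`TR[PC]-<unit><letter>-MM`: unit = minimal member unit length, letters
within a unit-size group by decreasing total member array length (a
deterministic stand-in for the unstated published ordering), `PC` for
TRPC subfamilies. Summary percentages are recomputed from counts and
rounded half-up to one decimal.

Probe design: `oligo` probes are the consensus monomer, doubled into a
head-to-tail dimer when the unit is < 30 bp; `long_fragment` probes take
the 150 bp window maximising mean divergence from the consensus tiling
(leftmost on ties — the most variable region is the most locus-specific)
and add two distinct 20 bp adapters, verified absent from the array.

## The synthetic study system

`make_study(seed)` emulates the real annotation situation at desk scale:
two anchored chromosomes, each beginning with the 3 Mb centromeric N gap
and carrying ~450 kb of GC-0.42 filler, plus one unanchored gapless
contig. Planted archetypes: a 21 bp 8-variant-block TRPC array directly
behind the gap on both chromosomes; a 58+60+58+58 heterotetramer MaSat
array behind the gap on chr1; a 45 bp multi-locus array on both
chromosome arms beyond the pericentromeric window; 180 bp single-locus
and 350 bp TE-derived arrays; and, on the unanchored contig only, a
120 bp AT-rich MiSat-like array and a 90 bp unplaced array — mirroring
the real finding that the minor satellite lives outside the anchored
assembly. The library carries the generator's own consensus entries
(SATMIN-like, GSAT-like satellite class; MTA-like TE class).

Arrays are built by repeating the variant block and mutating every copy
independently (per-base substitutions; optional 1 bp indels applied per
copy so unit lengths jitter like the 58–60 bp monomer spread). Identical
seeds give byte-identical output.

What passing the 20-seed end-to-end test shows: the pipeline's rules
(detection, 3 kb filter, score-90 clustering, 80 % coverage, 2850/150
mapping, pericentromere logic, precedence) interlock correctly and
recover planted truth exactly at realistic divergences (≤ 10 %).
What it does not show: performance on real assemblies — real satellites
carry higher-order divergence structure, segmental duplications,
assembly collapse and ChrUn fragmentation that the generator deliberately
omits; and detection on real data is TRF's job, not `detect_tandem`'s.

## Problem sizes and budgets

Desk-scale settings used throughout the tests and benchmarks: built-in
detection capped at period 400 on ~1 Mb of non-gap sequence per study
genome; clustering catalogs of ~10 arrays of 3–4 kb; spectra to offset
2200. The acceptance script's arrays are 6–7 kb (30–50 copies), the
sizes at which the spectral rules were calibrated.

## Known limitations

* `detect_tandem` is substitution-oriented; indel-dense arrays shift
  phase and are better handled by TRF upstream (the variability fallback
  and the HOR unit-length fallback mitigate, not cure).
* Exact all-pairs Smith–Waterman is quadratic; catalogs beyond a few
  dozen kilobase arrays should use the blastn scoring path.
* HOR calls below ~15 % inter-variant contrast are deliberately withheld
  (δ floor) rather than guessed.
* Band assignment uses the locus midpoint only; loci spanning band
  boundaries get a single band.
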