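"""Self dot-plots and higher-order repeat (HOR) detection.

A satellite array with a HOR shows the "tartan" pattern in a self dot-plot:
adjacent monomers are diverged variants, but whole multi-monomer blocks
repeat almost perfectly.  The detection primitive here is the per-base period
spectrum f(d) — the fraction of positions matching their neighbour d bases
downstream — which is the algorithmic form of reading diagonals off the
dot-plot.  The base period is the smallest spectral peak clearly above the
shuffled-sequence background; a HOR is called when some multiple of the base
period agrees distinctly better than adjacent monomers do.  Monomer-length
jitter (e.g. the 58/60/58/58 bp major-satellite heterotetramer, block 234 bp)
is absorbed by searching a small window around each multiple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arrays import TandemArray
from .config import DEFAULT_CONFIG, PipelineConfig


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@dataclass
class DotPlot:
    """Windowed self-similarity matrix.

    ``matrix[i, j]`` is the fraction of matching bases between the windows
    starting at ``positions[i]`` and ``positions[j]`` (1-based starts); in
    binary mode cells are 1.0 where that fraction reaches
    ``identity_threshold``.
    """
    window: int
    mode: str
    identity_threshold: float | None
    step: int
    positions: np.ndarray
    matrix: np.ndarray

    def to_pgm(self, path) -> None:
        """Plain-text PGM (P2) grayscale export; darker = more similar."""
        levels = 255
        img = np.rint((1.0 - self.matrix) * levels).astype(int)
        with open(path, "w") as fh:
            n = len(self.positions)
            fh.write(f"P2\n{n} {n}\n{levels}\n")
            for row in img:
                fh.write(" ".join(map(str, row)) + "\n")

    def to_text(self, path) -> None:
        """Binary matrix as 0/1 characters, one row per line."""
        with open(path, "w") as fh:
            for row in self.matrix:
                fh.write("".join("1" if v >= 0.999 else "0" for v in row)
                         + "\n")


def self_dotplot(
    seq: str,
    window: int = DEFAULT_CONFIG.dotplot_window_small,
    mode: str = "grayscale",
    identity_threshold: float | None = None,
    step: int = 1,
) -> DotPlot:
    """Self dot-plot of ``seq`` with a sliding window.

    ``mode="grayscale"`` stores the match fraction per cell;
    ``mode="binary"`` thresholds it at ``identity_threshold`` (required).
    ``step`` subsamples window start positions for long sequences.
    """
    n = len(seq)
    if window > n // 2:
        raise ValueError(f"window {window} > half the sequence length")
    if mode not in ("grayscale", "binary"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "binary" and identity_threshold is None:
        raise ValueError("binary mode requires identity_threshold")
    starts = np.arange(0, n - window + 1, step)
    if len(starts) ** 2 > 30_000_000:
        raise ValueError("dot-plot matrix too large; increase step")
    codes = _codes(seq)
    win = np.lib.stride_tricks.sliding_window_view(codes, window)[starts]
    m = np.empty((len(starts), len(starts)), dtype=np.float32)
    for i in range(len(starts)):
        m[i] = (win == win[i]).mean(axis=1)
    if mode == "binary":
        m = (m >= identity_threshold).astype(np.float32)
    return DotPlot(window=window, mode=mode,
                   identity_threshold=identity_threshold, step=step,
                   positions=starts + 1, matrix=m)


def period_spectrum(seq: str, max_offset: int) -> dict[int, float]:
    """f(d) = mean over i of [seq[i] == seq[i+d]] for d = 1..max_offset."""
    if max_offset >= len(seq):
        raise ValueError("max_offset must be < sequence length")
    codes = _codes(seq)
    return {d: float((codes[:-d] == codes[d:]).mean())
            for d in range(1, max_offset + 1)}


def background_identity(seq: str, max_offset: int, seed: int = 0,
                        n_offsets: int = 50) -> float:
    """Mean self-identity of a composition-matched shuffle of ``seq``
    (sampled over up to ``n_offsets`` offsets)."""
    rng = np.random.default_rng(seed)
    codes = rng.permutation(_codes(seq))
    offsets = np.linspace(1, max_offset, min(n_offsets, max_offset),
                          dtype=int)
    vals = [(codes[:-d] == codes[d:]).mean() for d in np.unique(offsets)]
    return float(np.mean(vals))


@dataclass
class HorReport:
    """Detected periodic structure of one array."""
    base_period: int | None
    hor_period: int | None = None
    hor_multiplicity: int | None = None
    subunit_periods: list[int] = field(default_factory=list)
    spectrum: dict[int, float] = field(default_factory=dict)
    background: float = 0.0


def _peaks(f: np.ndarray) -> np.ndarray:
    """Offsets (1-based) that are local maxima of the spectrum."""
    # f[0] corresponds to offset 1
    left = np.r_[-np.inf, f[:-1]]
    right = np.r_[f[1:], -np.inf]
    return np.flatnonzero((f >= left) & (f >= right)) + 1


def detect_hor(
    array: TandemArray,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> HorReport:
    """Base period and higher-order repeat call for one array.

    The base period is the smallest spectral peak at least
    ``config.hor_theta`` above the shuffled background.  A HOR is reported
    at the smallest multiple m >= 2 of the base period whose spectral value
    (searched within a +-``hor_multiple_tol`` window to tolerate
    monomer-length jitter) exceeds the base-period value by at least
    ``config.hor_delta``; single-variant arrays yield no HOR because whole
    blocks agree no better than adjacent monomers.
    """
    seq = array.array_seq
    max_offset = min(array.array_len // 3, config.hor_max_offset)
    if max_offset < 1:
        raise ValueError("array too short for spectrum analysis")
    spec = period_spectrum(seq, max_offset)
    f = np.array([spec[d] for d in range(1, max_offset + 1)])
    b = background_identity(seq, max_offset, seed=config.rng_seed)
    peaks = _peaks(f)
    above = peaks[f[peaks - 1] >= b + config.hor_theta]
    base: int | None = int(above[0]) if above.size else None
    if base is None and array.unit_len <= max_offset:
        # fall back to the cataloged unit length when the naive spectrum is
        # flat (indel-riddled arrays); accept a weaker local peak there
        lo = max(1, int(array.unit_len * 0.9))
        hi = min(max_offset, int(np.ceil(array.unit_len * 1.1)))
        d = lo + int(np.argmax(f[lo - 1:hi]))
        if f[d - 1] >= b + config.hor_theta / 2:
            base = d
    report = HorReport(base_period=base, spectrum=spec, background=b)
    if base is None:
        return report
    # subunits are by nature less conserved than the base period (e.g. the
    # 28/30 bp halves of a 58 bp monomer), so a weaker bar applies
    report.subunit_periods = [
        int(p) for p in peaks
        if p < base and f[p - 1] >= b + config.hor_theta / 2
    ]
    m = 2
    while m * base <= max_offset:
        center = m * base
        tol = max(2, round(config.hor_multiple_tol * center))
        lo = max(1, center - tol)
        hi = min(max_offset, center + tol)
        d = lo + int(np.argmax(f[lo - 1:hi]))
        if f[d - 1] - f[base - 1] >= config.hor_delta:
            report.hor_period = int(d)
            report.hor_multiplicity = m
            break
        m += 1
    return report
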