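"""Coverage tracks in two modes and a Poisson local-background peak caller.

The caller tests every base against a Poisson null whose rate is the
maximum of the genome-wide rate, the rate in a surrounding local window
and (when supplied) a depth-scaled control rate, corrects tail
probabilities by Benjamini-Hochberg over all tested positions, and merges
significant bases into regions. It is a self-contained MACS-like default;
externally produced peak BED files are accepted everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .alignments import GenomeIndex
from . import intervals as iv

DEFAULT_INSERTION_WINDOW = 25
DEFAULT_LOCAL_WINDOW = 10_000
DEFAULT_Q = 0.05
DEFAULT_MIN_LENGTH = 100
DEFAULT_MERGE_GAP = 50


@dataclass
class CoverageTrack:
    """Per-contig base-resolution depth vectors."""

    depth: dict               # contig -> float64 array of per-base depth
    mode: str                 # 'full_fragment' | 'integration_site'
    total_units: int          # fragments (or insertion events / 2) contributing
    genome: GenomeIndex

    def integral(self) -> float:
        return float(sum(d.sum() for d in self.depth.values()))

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for contig, _ in self.genome.contigs:
                d = self.depth[contig]
                if d.size == 0:
                    continue
                # run-length encode constant-depth steps
                change = np.nonzero(np.diff(d))[0] + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(d)]])
                for s, e in zip(starts, ends):
                    v = d[s]
                    if v != 0:
                        fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")


@dataclass
class Peak:
    """An accessible (or occupied) region with summit and normalized abundance."""

    contig: str
    start: int
    end: int
    summit: int = -1
    count: int = 0
    rpkm: float = 0.0
    qvalue: float = float("nan")
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("peak start must precede end")
        if self.summit < 0:
            self.summit = self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def make_coverage(fragments, genome: GenomeIndex, mode: str = "full_fragment",
                  insertion_window: int = DEFAULT_INSERTION_WINDOW,
                  tn5_shift: bool = False) -> CoverageTrack:
    """Accumulate per-base depth.

    ``full_fragment`` adds 1 over the fragment interval; ``integration_site``
    adds 1 over a +/- ``insertion_window`` bp window around both cut sites
    (fragment start and end), clipped to the contig. An optional Tn5 +4/-5
    shift may be applied to cut sites before windowing (off by default).
    """
    if mode not in ("full_fragment", "integration_site"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    if insertion_window < 1:
        raise ValueError("insertion_window must be >= 1")
    lengths = genome.lengths
    diffs = {c: np.zeros(l + 1, dtype=np.float64) for c, l in genome.contigs}
    n = 0
    for f in fragments:
        if f.contig not in lengths:
            raise ValueError(f"fragment on contig {f.contig!r} outside genome")
        clen = lengths[f.contig]
        if f.end > clen:
            raise ValueError(f"fragment {f.contig}:{f.start}-{f.end} exceeds contig length {clen}")
        d = diffs[f.contig]
        if mode == "full_fragment":
            d[f.start] += 1
            d[f.end] -= 1
        else:
            cuts = (f.start, f.end)
            if tn5_shift:
                cuts = (f.start + 4, f.end - 5)
            for c in cuts:
                s = max(0, c - insertion_window)
                e = min(clen, c + insertion_window)
                if s < e:
                    d[s] += 1
                    d[e] -= 1
        n += 1
    depth = {c: np.cumsum(diffs[c][:-1]) for c, _ in genome.contigs}
    return CoverageTrack(depth=depth, mode=mode, total_units=n, genome=genome)


def _moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean with edge truncation, O(n) via cumulative sums."""
    n = len(x)
    half = window // 2
    cs = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def call_peaks(coverage: CoverageTrack, control: CoverageTrack | None = None,
               q_threshold: float = DEFAULT_Q, min_length: int = DEFAULT_MIN_LENGTH,
               merge_gap: int = DEFAULT_MERGE_GAP,
               local_window: int = DEFAULT_LOCAL_WINDOW) -> list:
    """Call enriched regions against a Poisson local background."""
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must lie in (0, 1)")
    genome = coverage.genome
    if coverage.integral() == 0:
        return []

    rate_global = coverage.integral() / genome.size
    scale = None
    if control is not None and control.integral() > 0:
        scale = coverage.integral() / control.integral()

    pvals = []
    per_contig = {}
    for contig, _ in genome.contigs:
        d = coverage.depth[contig]
        lam = np.maximum(rate_global, _moving_mean(d, local_window))
        if scale is not None:
            # several window sizes on the control so narrow control enrichment
            # is not diluted away
            cd = control.depth[contig]
            for w in (500, 5000, local_window):
                lam = np.maximum(lam, _moving_mean(cd, min(w, local_window)) * scale)
        p = stats.poisson.sf(d - 1, lam)  # P(X >= depth)
        p[d <= 0] = 1.0
        per_contig[contig] = p
        pvals.append(p)

    flat = np.concatenate(pvals)
    q = _bh_adjust(flat)
    peaks = []
    off = 0
    for contig, _ in genome.contigs:
        d = coverage.depth[contig]
        qc = q[off:off + len(d)]
        off += len(d)
        sig = qc < q_threshold
        for s, e in iv.merge(_runs(sig), gap=merge_gap):
            if e - s < min_length:
                continue
            summit = int(s + np.argmax(d[s:e]))  # leftmost argmax by numpy convention
            peaks.append(Peak(contig=contig, start=int(s), end=int(e), summit=summit,
                              qvalue=float(qc[s:e].min()),
                              name=f"peak_{len(peaks) + 1}"))
    return peaks


def _runs(mask: np.ndarray) -> np.ndarray:
    """Maximal runs of True as (start, end) rows."""
    if not mask.any():
        return iv.EMPTY
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return np.column_stack([starts, ends]).astype(np.int64)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def peak_abundance(peaks, fragments) -> list:
    """Fill ``count`` (fragments overlapping >= 1 bp) and RPKM on each peak."""
    total = len(fragments)
    if total == 0:
        raise ValueError("cannot compute RPKM with zero total fragments")
    by_contig_start = {}
    by_contig_end = {}
    for f in fragments:
        by_contig_start.setdefault(f.contig, []).append(f.start)
        by_contig_end.setdefault(f.contig, []).append(f.end)
    for c in by_contig_start:
        by_contig_start[c] = np.sort(by_contig_start[c])
        by_contig_end[c] = np.sort(by_contig_end[c])
    out = []
    for pk in peaks:
        starts = by_contig_start.get(pk.contig)
        if starts is None:
            count = 0
        else:
            ends = by_contig_end[pk.contig]
            n_right = len(starts) - np.searchsorted(starts, pk.end, side="left")
            n_left = np.searchsorted(ends, pk.start, side="right")
            count = int(len(starts) - n_right - n_left)
        rpkm = count / ((pk.length / 1000.0) * (total / 1e6))
        out.append(Peak(contig=pk.contig, start=pk.start, end=pk.end, summit=pk.summit,
                        count=count, rpkm=rpkm, qvalue=pk.qvalue, name=pk.name))
    return out


def write_narrowpeak(peaks, path) -> None:
    """narrowPeak-style BED6+: score = int(10 x RPKM), then summit offset and q."""
    with open(path, "w") as fh:
        for pk in peaks:
            score = int(round(10 * pk.rpkm))
            fh.write(f"{pk.contig}\t{pk.start}\t{pk.end}\t{pk.name or '.'}\t{score}\t.\t"
                     f"{pk.summit - pk.start}\t{pk.qvalue:.6g}\n")


def load_peaks_bed(path) -> list:
    """Read peaks from a BED-like file (3+ columns); extra columns ignored."""
    peaks = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        name = f[3] if len(f) > 3 else ""
        peaks.append(Peak(contig=f[0], start=int(f[1]), end=int(f[2]), name=name))
    return peaks


def merged_peak_intervals(peaks) -> dict:
    """Per-contig merged (start, end) arrays from a peak list."""
    per = {}
    for pk in peaks:
        per.setdefault(pk.contig, []).append((pk.start, pk.end))
    return {c: iv.merge(pairs) for c, pairs in per.items()}
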