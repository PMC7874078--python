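"""Feature enrichment of peaks, anchored signal matrices, and junction tracks.

Enrichment per feature f is log2((S_Pf / S_P) / (S_gf / S_g)): the peak
base pairs falling in the feature, relative to the feature's share of the
genome. Signal matrices profile RPKM-normalized accessibility around genes
(scaled body plus flanks) or around peak summits (fixed window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as iv
from .annotation import FeatureSet, FEATURE_NAMES
from .peaks import CoverageTrack, merged_peak_intervals

NFR_THRESHOLD = 150
NFR_COLOR = (0, 0, 255)          # blue: sub-nucleosomal
NUCLEOSOMAL_COLOR = (255, 0, 0)  # red: nucleosome-spanning


@dataclass
class FeatureEnrichment:
    feature: str
    s_p: int
    s_g: int
    s_pf: int
    s_gf: int
    log2_enrichment: float  # NaN when undefined
    defined: bool


@dataclass
class EnrichmentResult:
    """Per-feature enrichment of a peak set against the genome background."""

    rows: list  # of FeatureEnrichment

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __getitem__(self, feature: str) -> FeatureEnrichment:
        for r in self.rows:
            if r.feature == feature:
                return r
        raise KeyError(feature)


def fold_enrichment(peaks, feature_set: FeatureSet, genome) -> EnrichmentResult:
    """Compute per-feature log2 enrichment of merged peak bp over the genome."""
    if not peaks:
        raise ValueError("no peaks")
    merged = merged_peak_intervals(peaks)
    s_p = sum(iv.total_length(arr) for arr in merged.values())
    s_g = genome.size
    rows = []
    for name in FEATURE_NAMES:
        s_gf = feature_set.sizes[name]
        s_pf = 0
        for contig, pk in merged.items():
            s_pf += iv.total_length(iv.intersect(pk, feature_set.contig_intervals(name, contig)))
        defined = s_p > 0 and s_g > 0 and s_pf > 0 and s_gf > 0
        val = math.log2((s_pf / s_p) / (s_gf / s_g)) if defined else float("nan")
        rows.append(FeatureEnrichment(name, s_p, s_g, s_pf, s_gf, val, defined))
    return EnrichmentResult(rows)


@dataclass
class SignalMatrix:
    """Anchors x bins matrix of RPKM-normalized accessibility."""

    anchors: list            # anchor ids in input order
    matrix: np.ndarray       # shape (n_anchors, n_bins)
    layout: str              # 'gene_scaled' | 'peak_centered'
    bin_width: int
    flank_bins: int          # bins per flank
    body_bins: int           # 0 for peak_centered

    @property
    def metaplot(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def sorted_by_mean(self) -> "SignalMatrix":
        """Rows ranked high-to-low by row mean (heatmap order)."""
        order = np.argsort(-self.matrix.mean(axis=1), kind="stable")
        return SignalMatrix([self.anchors[i] for i in order], self.matrix[order],
                            self.layout, self.bin_width, self.flank_bins, self.body_bins)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, index=self.anchors)
        df.index.name = "anchor"
        df.to_csv(path, sep="\t")

    def metaplot_tsv(self, path) -> None:
        pd.DataFrame({"bin": np.arange(self.matrix.shape[1]),
                      "mean_signal": self.metaplot}).to_csv(path, sep="\t", index=False)


def _window_sums(cumsum: np.ndarray, starts, ends) -> np.ndarray:
    """Depth sums over [start, end) windows, zero outside the contig."""
    n = len(cumsum) - 1
    lo = np.clip(np.asarray(starts), 0, n)
    hi = np.clip(np.asarray(ends), 0, n)
    hi = np.maximum(hi, lo)
    return cumsum[hi] - cumsum[lo]


def signal_matrix(coverage: CoverageTrack, anchors, layout: str = "gene_scaled",
                  flank: int = 1000, bin_width: int = 10,
                  body_bins: int = 100) -> SignalMatrix:
    """Build the anchored signal matrix.

    ``gene_scaled`` anchors need contig/start/end/strand and an id; rows are
    [flank/bin_width upstream][body_bins scaled][flank/bin_width downstream],
    strand-oriented so upstream is leftmost. ``peak_centered`` anchors need a
    summit; rows cover a fixed 2 x flank window. Bin values are RPKM of the
    bin: depth sum / (bin kb) / (million total fragments).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if flank % bin_width != 0:
        raise ValueError("bin_width must divide flank")
    fb = flank // bin_width
    total = coverage.total_units
    norm = (total / 1e6) if total > 0 else 1.0
    cums = {c: np.concatenate([[0.0], np.cumsum(d)]) for c, d in coverage.depth.items()}

    rows, ids = [], []
    if layout == "gene_scaled":
        for g in anchors:
            if g.end - g.start <= 0:
                raise ValueError(f"zero-length body for anchor {getattr(g, 'gene_id', g)}")
            cs = cums[g.contig]
            up_edges = g.start - flank + bin_width * np.arange(fb + 1)
            body_edges = np.rint(np.linspace(g.start, g.end, body_bins + 1)).astype(int)
            down_edges = g.end + bin_width * np.arange(fb + 1)
            parts = []
            for edges, nominal in ((up_edges, float(bin_width)),
                                   (body_edges, (g.end - g.start) / body_bins),
                                   (down_edges, float(bin_width))):
                sums = _window_sums(cs, edges[:-1], edges[1:])
                parts.append(sums / (nominal / 1000.0) / norm)
            row = np.concatenate(parts)
            if g.strand == "-":
                row = row[::-1]
            rows.append(row)
            ids.append(getattr(g, "gene_id", str(len(ids))))
    elif layout == "peak_centered":
        for pk in anchors:
            cs = cums[pk.contig]
            edges = pk.summit - flank + bin_width * np.arange(2 * fb + 1)
            sums = _window_sums(cs, edges[:-1], edges[1:])
            rows.append(sums / (bin_width / 1000.0) / norm)
            ids.append(getattr(pk, "name", "") or f"peak{len(ids)}")
        body_bins = 0
    else:
        raise ValueError(f"unknown layout {layout!r}")

    matrix = np.vstack(rows) if rows else np.zeros((0, 2 * fb + body_bins))
    return SignalMatrix(ids, matrix, layout, bin_width, fb, body_bins)


@dataclass(frozen=True)
class JunctionRecord:
    """A fragment drawn as a two-block junction, color-coded by length class.

    Lengths below the threshold are NFR (blue); the threshold itself is
    assigned to the nucleosomal (red) class.
    """

    contig: str
    start: int
    end: int
    threshold: int = NFR_THRESHOLD

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cls(self) -> str:
        return "nfr" if self.length < self.threshold else "nucleosomal"

    @property
    def color(self) -> tuple:
        return NFR_COLOR if self.cls == "nfr" else NUCLEOSOMAL_COLOR


def junction_track(fragments, threshold: int = NFR_THRESHOLD, paired: bool = True) -> list:
    """One junction per paired-end fragment.

    Callers loading single-end reads must pass ``paired=False``, which is
    rejected: a junction spans a sequenced fragment, not a single read.
    """
    if not paired:
        raise ValueError("junction track requires paired-end fragments")
    return [JunctionRecord(f.contig, f.start, f.end, threshold) for f in fragments]


def junctions_to_bed12(records, path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            rgb = ",".join(map(str, r.color))
            score = min(r.length, 1000)
            block_starts = f"0,{r.length - 1}" if r.length > 1 else "0,0"
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\tjct{i}\t{score}\t.\t"
                     f"{r.start}\t{r.end}\t{rgb}\t2\t1,1\t{block_starts}\n")


def parse_bed12_junctions(path) -> list:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        records.append(JunctionRecord(f[0], int(f[1]), int(f[2])))
    return records


def plot_enrichment(result: EnrichmentResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    df = result.to_frame()
    df = df[df.defined]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(df.feature, df.log2_enrichment)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("log2 fold enrichment")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap_metaplot(sm: SignalMatrix, heatmap_path, metaplot_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    ranked = sm.sorted_by_mean()
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(np.log1p(ranked.matrix), aspect="auto", interpolation="nearest",
              cmap="viridis")
    ax.set_xlabel("bin")
    ax.set_ylabel("anchor (ranked)")
    fig.tight_layout()
    fig.savefig(heatmap_path, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(sm.metaplot)
    ax.set_xlabel("bin")
    ax.set_ylabel("mean signal (RPKM)")
    fig.tight_layout()
    fig.savefig(metaplot_path, dpi=120)
    plt.close(fig)
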