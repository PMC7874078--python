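"""Interval-overlap significance against another peak set, and the relation
between accessibility and RNA-seq expression.

The hypergeometric population is a bin model: the genome divided into
N = floor(S_g / mean peak width) slots, of which the first set occupies
K = n_a; drawing n = n_b slots, the tail P(X >= n_shared) is reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv
from .annotation import promoter_interval
from .peaks import merged_peak_intervals

DEFAULT_N_GROUPS = 10


@dataclass
class OverlapTest:
    n_a: int
    n_b: int
    n_shared: int
    population_bins: int
    p_value: float
    shared_intervals: dict  # contig -> (n,2) array of intersections

    def shared_bed(self, path) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self.shared_intervals):
                for s, e in self.shared_intervals[contig]:
                    fh.write(f"{contig}\t{s}\t{e}\n")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_a": self.n_a, "n_b": self.n_b, "n_shared": self.n_shared,
                       "population_bins": self.population_bins,
                       "p_value": self.p_value}, fh, indent=2)
            fh.write("\n")


def overlap_test(peaks_a, peaks_b, genome, population_bins: int | None = None) -> OverlapTest:
    """Count A peaks sharing >= 1 bp with B and test the count's tail.

    X ~ Hypergeometric(N, K = n_a, n = n_b) with N the genome bin count
    (``population_bins`` overrides the mean-width model); p = P(X >= n_shared).
    """
    ma = merged_peak_intervals(peaks_a)
    mb = merged_peak_intervals(peaks_b)
    n_a = sum(len(v) for v in ma.values())
    n_b = sum(len(v) for v in mb.values())
    if n_a == 0 or n_b == 0:
        raise ValueError("both peak sets must be non-empty")

    n_shared = 0
    shared = {}
    for contig, arr_a in ma.items():
        arr_b = mb.get(contig, iv.EMPTY)
        n_shared += int(iv.overlaps_any(arr_a, arr_b).sum())
        inter = iv.intersect(arr_a, arr_b)
        if len(inter):
            shared[contig] = inter

    if population_bins is None:
        widths = np.concatenate([(v[:, 1] - v[:, 0]) for v in list(ma.values()) + list(mb.values())])
        wbar = widths.mean()
        population_bins = int(genome.size // wbar)
    if population_bins < max(n_a, n_b):
        raise ValueError("genome too small for bin model")

    # P(X >= n_shared); X ~ Hypergeom(M=N, n=K successes, N=draws) in scipy naming
    p = float(stats.hypergeom.sf(n_shared - 1, population_bins, n_a, n_b))
    return OverlapTest(n_a, n_b, n_shared, population_bins, p, shared)


@dataclass
class ExpressionAccessibility:
    table: pd.DataFrame       # gene_id, rpkm, group (1..G, G = most expressed), accessible
    percent_accessible: pd.Series  # indexed by group
    venn: dict                # top/bottom group x accessible counts

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def barplot_tsv(self, path) -> None:
        df = self.percent_accessible.rename("percent_accessible").reset_index()
        df.to_csv(path, sep="\t", index=False)


def expression_accessibility(gene_rpkm, genes, peaks, genome,
                             n_groups: int = DEFAULT_N_GROUPS,
                             promoter_length: int = 1000) -> ExpressionAccessibility:
    """Quantile-group genes by expression and score per-group accessibility.

    A gene is accessible when its body or promoter overlaps >= 1 bp of a
    peak. ``gene_rpkm`` is a mapping or two-column frame (gene_id, rpkm);
    genes absent from the annotation are dropped with a counted warning.
    """
    if isinstance(gene_rpkm, pd.DataFrame):
        expr = dict(zip(gene_rpkm.iloc[:, 0].astype(str), gene_rpkm.iloc[:, 1].astype(float)))
    else:
        expr = {str(k): float(v) for k, v in dict(gene_rpkm).items()}
    by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in expr if gid not in by_id]
    if missing:
        warnings.warn(f"{len(missing)} expression gene ids missing from annotation; excluded")
    scored = [gid for gid in expr if gid in by_id]
    if not scored:
        raise ValueError("no expression gene ids resolvable against the annotation")

    merged = merged_peak_intervals(peaks)
    lengths = genome.lengths
    accessible = {}
    for gid in scored:
        g = by_id[gid]
        spans = [(g.start, g.end)]
        prom = promoter_interval(g, promoter_length, lengths[g.contig])
        if prom is not None:
            spans.append(prom)
        arr = merged.get(g.contig, iv.EMPTY)
        accessible[gid] = bool(iv.overlaps_any(spans, arr).any())

    # rank ascending by (rpkm, gene_id) for deterministic ties; group G = highest
    order = sorted(scored, key=lambda gid: (expr[gid], gid))
    groups = {}
    for gi, chunk in enumerate(np.array_split(np.arange(len(order)), n_groups), start=1):
        for idx in chunk:
            groups[order[idx]] = gi

    table = pd.DataFrame({
        "gene_id": order,
        "rpkm": [expr[g] for g in order],
        "group": [groups[g] for g in order],
        "accessible": [accessible[g] for g in order],
    })
    pct = table.groupby("group")["accessible"].mean() * 100.0
    top, bottom = table[table.group == n_groups], table[table.group == 1]
    venn = {
        "top_accessible": int(top.accessible.sum()),
        "top_inaccessible": int((~top.accessible).sum()),
        "bottom_accessible": int(bottom.accessible.sum()),
        "bottom_inaccessible": int((~bottom.accessible).sum()),
    }
    return ExpressionAccessibility(table, pct, venn)


def genes_overlapping_intervals(genes, shared_intervals, genome,
                                promoter_length: int = 1000):
    """Gene ids whose body (and separately promoter) touch the given intervals."""
    lengths = genome.lengths
    body_hits, promoter_hits = [], []
    for g in genes:
        arr = shared_intervals.get(g.contig)
        if arr is None or len(arr) == 0:
            continue
        if iv.overlaps_any([(g.start, g.end)], arr)[0]:
            body_hits.append(g.gene_id)
        prom = promoter_interval(g, promoter_length, lengths[g.contig])
        if prom is not None and iv.overlaps_any([prom], arr)[0]:
            promoter_hits.append(g.gene_id)
    return body_hits, promoter_hits
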