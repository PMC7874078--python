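"""Differential accessibility: candidate regions, replicate fold/t-test calls,
no-replicate specific peaks, overlap-reproducibility filtering, and
Gaussian-mixture promoter outliers.

Abundance tests run on log2(RPKM + 1); the fold gate uses raw group means
with a pseudocount of 1 so zero-abundance candidates stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from . import intervals as iv
from .peaks import Peak, merged_peak_intervals

DEFAULT_FOLD = 2.0
DEFAULT_P = 0.05
PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class CandidateRegion:
    """A maximal segment of constant membership across the input peak sets."""

    contig: str
    start: int
    end: int
    membership: tuple  # one bool per input peak set


@dataclass
class DifferentialCall:
    region: CandidateRegion
    mean_abundance_g1: float
    mean_abundance_g2: float
    fold_change: float
    p_value: float
    direction: str  # 'up_in_g2' | 'down_in_g2'
    significant: bool


@dataclass
class PromoterCall:
    gene_id: str
    abundance_a: float
    abundance_b: float
    gmm_p: float
    outlier: bool


def candidate_regions(peak_sets) -> list:
    """Sweep-line partition of the union of >= 2 peak sets into segments of
    constant membership (the multi-intersection of the inputs)."""
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    merged = [merged_peak_intervals(ps) if ps and isinstance(ps[0], Peak)
              else {c: iv.merge(arr) for c, arr in ps.items()} if isinstance(ps, dict)
              else merged_peak_intervals(ps)
              for ps in peak_sets]
    contigs = sorted(set().union(*[set(m) for m in merged]))
    out = []
    for contig in contigs:
        sets = [m.get(contig, iv.EMPTY) for m in merged]
        bounds = sorted({int(x) for arr in sets for x in arr.ravel()})
        prev = None
        for s, e in zip(bounds[:-1], bounds[1:]):
            member = tuple(bool(iv.overlaps_any([(s, e)], arr)[0]) for arr in sets)
            if not any(member):
                prev = None
                continue
            if prev is not None and prev.end == s and prev.membership == member:
                prev = CandidateRegion(contig, prev.start, e, member)
                out[-1] = prev
            else:
                prev = CandidateRegion(contig, s, e, member)
                out.append(prev)
    return out


def differential_peaks(candidates, abundance_g1: np.ndarray, abundance_g2: np.ndarray,
                       fold_threshold: float = DEFAULT_FOLD,
                       p_threshold: float = DEFAULT_P) -> list:
    """Welch t-test on log2(RPKM+1) per candidate plus a fold-change gate.

    ``abundance_g1/g2`` are (n_candidates, n_replicates) RPKM matrices with
    >= 2 replicate columns each; significant iff fold >= fold_threshold and
    p < p_threshold.
    """
    a1 = np.atleast_2d(np.asarray(abundance_g1, dtype=float))
    a2 = np.atleast_2d(np.asarray(abundance_g2, dtype=float))
    if a1.shape[1] < 2 or a2.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group for the t-test; "
                         "use specific_peaks_no_replicate for single samples")
    if (a1 < 0).any() or (a2 < 0).any():
        raise ValueError("abundances must be non-negative")
    if len(candidates) != a1.shape[0] or len(candidates) != a2.shape[0]:
        raise ValueError("abundance rows must match candidate count")

    t, p = stats.ttest_ind(np.log2(a1 + 1), np.log2(a2 + 1), axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    m1 = a1.mean(axis=1) + PSEUDOCOUNT
    m2 = a2.mean(axis=1) + PSEUDOCOUNT
    fold = np.maximum(m1, m2) / np.minimum(m1, m2)

    calls = []
    for i, region in enumerate(candidates):
        direction = "up_in_g2" if m2[i] >= m1[i] else "down_in_g2"
        sig = bool(fold[i] >= fold_threshold and p[i] < p_threshold)
        calls.append(DifferentialCall(region, float(a1[i].mean()), float(a2[i].mean()),
                                      float(fold[i]), float(p[i]), direction, sig))
    return calls


def bh_correct(calls, q_threshold: float = DEFAULT_P) -> list:
    """Optional BH-FDR variant of the significance gate (fold gate unchanged)."""
    p = np.array([c.p_value for c in calls])
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(adj, 1.0)
    out = []
    for c, qi in zip(calls, q):
        sig = bool(c.fold_change >= DEFAULT_FOLD and qi < q_threshold)
        out.append(DifferentialCall(c.region, c.mean_abundance_g1, c.mean_abundance_g2,
                                    c.fold_change, float(qi), c.direction, sig))
    return out


def specific_peaks_no_replicate(peaks_a, peaks_b, reproducible_input: bool = False):
    """Peaks unique to each group: no >= 1 bp overlap with the other group.

    ``reproducible_input`` certifies the inputs were reproducibility-filtered
    (e.g. by external IDR or :func:`reproducible_peaks`).
    """
    mb = merged_peak_intervals(peaks_b)
    ma = merged_peak_intervals(peaks_a)
    a_specific = [p for p in peaks_a
                  if not iv.overlaps_any([(p.start, p.end)], mb.get(p.contig, iv.EMPTY))[0]]
    b_specific = [p for p in peaks_b
                  if not iv.overlaps_any([(p.start, p.end)], ma.get(p.contig, iv.EMPTY))[0]]
    return a_specific, b_specific


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def reproducible_peaks(replicate_peak_sets, min_overlap_fraction: float = 0.5) -> list:
    """Overlap-reproducibility filter: keep replicate-1 peaks with reciprocal
    overlap >= the threshold against some peak in every other replicate.

    A documented stand-in for full IDR, which remains pluggable upstream.
    """
    if len(replicate_peak_sets) < 2:
        raise ValueError("need >= 2 replicate peak sets")
    others = []
    for ps in replicate_peak_sets[1:]:
        per = {}
        for p in ps:
            per.setdefault(p.contig, []).append((p.start, p.end))
        others.append(per)
    kept = []
    for p in replicate_peak_sets[0]:
        ok = True
        for per in others:
            if not any(_reciprocal_overlap(p.start, p.end, s, e) >= min_overlap_fraction
                       for s, e in per.get(p.contig, [])):
                ok = False
                break
        if ok:
            kept.append(p)
    return kept


def differential_promoters_gmm(promoter_abundance_pairs, gene_ids=None,
                               n_components_max: int = 3,
                               p_threshold: float = DEFAULT_P,
                               min_component_weight: float = 0.1,
                               random_state: int = 0) -> list:
    """Flag outlier promoters on the bivariate (log2 a+1, log2 b+1) plane.

    Gaussian mixtures with k = 1..n_components_max are fitted (10 restarts,
    fixed seed); k is chosen by BIC among fits whose components all carry
    at least ``min_component_weight`` of the mass — a micro-component is
    itself an outlier cluster and must not absorb the points this test is
    meant to flag. Each gene's tail probability is the chi-square(2)
    survival function at its squared Mahalanobis distance to its most
    responsible component; outlier iff that p < p_threshold.
    """
    pairs = np.asarray(promoter_abundance_pairs, dtype=float).reshape(-1, 2)
    if len(pairs) < 20:
        raise ValueError("need >= 20 genes with finite abundances")
    if not np.isfinite(pairs).all():
        raise ValueError("abundances must be finite")
    X = np.log2(pairs + 1)
    if np.allclose(X, X[0]):
        raise ValueError("zero-variance input")
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(len(X))]

    best = None
    for k in range(1, n_components_max + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full", n_init=10,
                             random_state=random_state, reg_covar=1e-6)
        gm.fit(X)
        if k > 1 and gm.weights_.min() < min_component_weight:
            continue
        bic = gm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, gm)
    gm = best[1]

    resp = gm.predict_proba(X)
    comp = resp.argmax(axis=1)
    d2 = np.empty(len(X))
    for k in range(gm.n_components):
        sel = comp == k
        if not sel.any():
            continue
        diff = X[sel] - gm.means_[k]
        prec = np.linalg.inv(gm.covariances_[k])
        d2[sel] = np.einsum("ij,jk,ik->i", diff, prec, diff)
    gmm_p = stats.chi2.sf(d2, df=2)

    return [PromoterCall(gene_ids[i], float(pairs[i, 0]), float(pairs[i, 1]),
                         float(gmm_p[i]), bool(gmm_p[i] < p_threshold))
            for i in range(len(X))]


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "contig": c.region.contig, "start": c.region.start, "end": c.region.end,
            "mean_g1": c.mean_abundance_g1, "mean_g2": c.mean_abundance_g2,
            "fold_change": c.fold_change, "p_value": c.p_value,
            "direction": c.direction, "significant": c.significant,
        })
    return pd.DataFrame(rows)
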