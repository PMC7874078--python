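"""Deterministic synthetic ATAC-seq fixtures with planted structure.

Generates toy genomes, paired-end fragments (sub-nucleosomal mode plus
nucleosome-periodic modes at a planted spacing, planted accessible regions,
organelle contamination, PCR duplicates), gene annotations, and expression
tables. Every planted quantity is recorded in a truth manifest so tests
consume ground truth only through the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .alignments import Fragment, GenomeIndex, write_fragments_bed
from .annotation import GeneModel
from .peaks import Peak
from . import intervals as iv


@dataclass
class SimulationConfig:
    seed: int = 0
    contigs: tuple = (("chr1", 1_000_000),)        # nuclear contigs
    organelle_contig: tuple = ("chrM", 20_000)
    organelle_fraction: float = 0.0
    duplicate_rate: float = 0.0
    n_fragments: int = 10_000
    nfr_length_mode: int = 60
    nfr_length_scale: float = 50.0
    nucleosome_spacing: int = 190
    nucleosome_length_sd: float = 20.0
    n_nucleosome_modes: int = 3
    mode_weights: tuple | None = None              # nfr + nucleosome modes; auto if None
    planted_accessible_regions: tuple = ()         # of (contig, start, end, multiplier)
    promoter_accessibility_bias: float = 1.0       # multiplier planted at every promoter
    expression_accessibility_slope: float = 0.0
    n_genes: int = 20
    gene_length: int = 2000
    min_fragment_length: int = 20
    max_fragment_length: int = 1000

    def __post_init__(self):
        if not (0 <= self.organelle_fraction <= 1 and 0 <= self.duplicate_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.nucleosome_spacing <= 0:
            raise ValueError("nucleosome_spacing must be positive")
        lengths = dict(self.contigs)
        for contig, s, e, mult in self.planted_accessible_regions:
            if contig not in lengths or not (0 <= s < e <= lengths[contig]):
                raise ValueError(f"planted region {contig}:{s}-{e} outside contigs")
            if mult < 1:
                raise ValueError("planted multipliers must be >= 1")

    def genome(self, include_organelle: bool = True) -> GenomeIndex:
        contigs = tuple(self.contigs)
        if include_organelle and self.organelle_contig is not None:
            contigs = contigs + (tuple(self.organelle_contig),)
        return GenomeIndex(contigs)


def _mode_weights(config: SimulationConfig) -> np.ndarray:
    if config.mode_weights is not None:
        w = np.asarray(config.mode_weights, dtype=float)
    else:
        w = np.array([0.3] + [0.3 * (0.55 ** k) for k in range(config.n_nucleosome_modes)])
    return w / w.sum()


def sample_lengths(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw fragment lengths from the planted mixture."""
    w = _mode_weights(config)
    which = rng.choice(len(w), size=n, p=w)
    lengths = np.empty(n)
    nfr = which == 0
    # two-sided exponential: an "exponential-ish" mode peaking at nfr_length_mode
    lengths[nfr] = rng.laplace(config.nfr_length_mode, config.nfr_length_scale, nfr.sum())
    for k in range(1, len(w)):
        sel = which == k
        lengths[sel] = rng.normal(k * config.nucleosome_spacing,
                                  config.nucleosome_length_sd, sel.sum())
    return np.clip(np.rint(lengths), config.min_fragment_length,
                   config.max_fragment_length).astype(int)


def _planted_regions(config: SimulationConfig, genes) -> list:
    regions = [tuple(r) for r in config.planted_accessible_regions]
    if config.promoter_accessibility_bias > 1 and genes:
        lengths = dict(config.contigs)
        from .annotation import promoter_interval
        for g in genes:
            prom = promoter_interval(g, 1000, lengths[g.contig])
            if prom is not None:
                regions.append((g.contig, prom[0], prom[1],
                                config.promoter_accessibility_bias))
    return regions


def _sample_midpoint(contigs, regions, weights, total_weight, rng):
    """Pick a fragment midpoint: uniform background, boosted inside regions."""
    u = rng.uniform(0, total_weight)
    for contig, clen in contigs:
        if u < clen:
            return contig, int(u)
        u -= clen
    for (contig, s, e, mult), w in zip(regions, weights):
        if u < w:
            return contig, int(s + u / (mult - 1))
        u -= w
    contig, clen = contigs[-1]
    return contig, clen // 2


def generate_fragments(config: SimulationConfig, genes=None):
    """Generate the fragment list and truth record in memory.

    Organelle status is decided per fragment first (probability
    ``organelle_fraction``); nuclear fragments are then duplicated with
    probability ``duplicate_rate`` by copying an earlier nuclear fragment,
    so duplicate removal and organelle removal stay separable. Non-duplicate
    fragments are kept unique in (contig, start, end, strand).
    """
    rng = np.random.default_rng(config.seed)
    contigs = list(config.contigs)
    regions = _planted_regions(config, genes or [])
    region_weights = [(e - s) * (mult - 1) for _, s, e, mult in regions]
    total_weight = sum(l for _, l in contigs) + sum(region_weights)
    lengths = dict(contigs)

    lengths_all = sample_lengths(config, config.n_fragments, rng)
    fragments: list = []
    nuclear_indices: list = []
    seen = set()
    n_org = n_dup = 0
    org_name, org_len = (config.organelle_contig if config.organelle_contig
                         else (None, 0))

    for i in range(config.n_fragments):
        L = int(lengths_all[i])
        if org_name is not None and rng.random() < config.organelle_fraction:
            n_org += 1
            Lc = min(L, org_len)
            start = int(rng.integers(0, max(1, org_len - Lc + 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            fragments.append(Fragment(org_name, start, start + Lc, strand))
            continue
        if nuclear_indices and rng.random() < config.duplicate_rate:
            n_dup += 1
            src = fragments[nuclear_indices[int(rng.integers(0, len(nuclear_indices)))]]
            fragments.append(Fragment(src.contig, src.start, src.end, src.strand))
            continue
        for _ in range(100):  # reject accidental duplicates of planted-unique fragments
            contig, mid = _sample_midpoint(contigs, regions, region_weights,
                                           total_weight, rng)
            clen = lengths[contig]
            Lc = min(L, clen)
            start = int(np.clip(mid - Lc // 2, 0, clen - Lc))
            strand = "+" if rng.random() < 0.5 else "-"
            key = (contig, start, start + Lc, strand)
            if key not in seen:
                break
        seen.add(key)
        nuclear_indices.append(len(fragments))
        fragments.append(Fragment(*key))

    truth = {
        "seed": config.seed,
        "n_fragments": config.n_fragments,
        "n_organelle": n_org,
        "n_duplicates": n_dup,
        "organelle_contig": org_name,
        "planted_regions": [list(r) for r in regions],
        "nucleosome_spacing": config.nucleosome_spacing,
        "nfr_length_mode": config.nfr_length_mode,
        "n_nucleosome_modes": config.n_nucleosome_modes,
        "lengths": [f.length for f in fragments],
    }
    return fragments, truth


def make_genes(config: SimulationConfig) -> list:
    """Evenly spaced two-exon genes with CDS and UTRs on the nuclear contigs."""
    genes = []
    gl = config.gene_length
    idx = 0
    for contig, clen in config.contigs:
        step = max(gl + 4000, clen // max(1, config.n_genes))
        pos = 2000
        while pos + gl <= clen - 2000 and idx < config.n_genes * len(config.contigs):
            s = pos
            strand = "+" if idx % 2 == 0 else "-"
            exons = iv.as_array([(s, s + 2 * gl // 5), (s + 3 * gl // 5, s + gl)])
            cds = iv.as_array([(s + gl // 10, s + 2 * gl // 5),
                               (s + 3 * gl // 5, s + 9 * gl // 10)])
            utr5 = iv.as_array([(s, s + gl // 10)])
            utr3 = iv.as_array([(s + 9 * gl // 10, s + gl)])
            if strand == "-":
                utr5, utr3 = utr3, utr5
            genes.append(GeneModel(f"g{idx:04d}", contig, s, s + gl, strand,
                                   exons, cds, utr5, utr3))
            idx += 1
            pos += step
    if not genes:
        raise ValueError("no genes fit the configured contigs")
    return genes


def write_gtf(genes, path) -> None:
    type_map = {"exon": "exon", "cds": "CDS", "utr5": "five_prime_utr",
                "utr3": "three_prime_utr"}
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(f"{g.contig}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attr}\n")
            for name, arr in (("exon", g.exons), ("cds", g.cds),
                              ("utr5", g.utr5), ("utr3", g.utr3)):
                for s, e in arr:
                    fh.write(f"{g.contig}\tsim\t{type_map[name]}\t{s + 1}\t{e}\t.\t"
                             f"{g.strand}\t.\t{attr}\n")


def write_bam(fragments, genome: GenomeIndex, path, read_length: int = 50) -> None:
    """Minimal paired-end BAM; one proper pair per fragment, MAPQ 60."""
    import pysam
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": n, "LN": l} for n, l in genome.contigs]}
    ref_ids = {n: i for i, (n, _) in enumerate(genome.contigs)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, f in enumerate(fragments):
            rl = min(read_length, f.length)
            first_fwd = f.strand != "-"
            for mate in (1, 2):
                a = pysam.AlignedSegment()
                a.query_name = f"frag{i}"
                a.query_sequence = "A" * rl
                a.reference_id = ref_ids[f.contig]
                a.mapping_quality = 60
                a.cigar = [(0, rl)]
                a.next_reference_id = a.reference_id
                fwd = first_fwd if mate == 1 else not first_fwd
                a.reference_start = f.start if fwd else f.end - rl
                a.next_reference_start = f.end - rl if fwd else f.start
                a.template_length = f.length if fwd else -f.length
                flag = 0x1 | 0x2  # paired, proper pair
                flag |= 0x40 if mate == 1 else 0x80
                if not fwd:
                    flag |= 0x10
                else:
                    flag |= 0x20
                a.flag = flag
                bam.write(a)


def simulate_dataset(config: SimulationConfig, outdir, write_bam_file: bool = False) -> dict:
    """Write the full fixture bundle; returns a manifest dict including paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = make_genes(config)
    fragments, truth = generate_fragments(config, genes)
    genome = config.genome()

    bed = outdir / "fragments.bed"
    write_fragments_bed(fragments, bed)
    gtf = outdir / "genes.gtf"
    write_gtf(genes, gtf)
    sizes = outdir / "chrom.sizes"
    genome.to_chrom_sizes(sizes)
    paths = {"fragments_bed": str(bed), "gtf": str(gtf), "chrom_sizes": str(sizes)}
    if write_bam_file:
        bam = outdir / "fragments.bam"
        write_bam(fragments, genome, bam)
        paths["bam"] = str(bam)

    manifest = {"config": _config_dict(config), "paths": paths, **truth}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["contigs"] = [list(c) for c in config.contigs]
    d["organelle_contig"] = list(config.organelle_contig) if config.organelle_contig else None
    d["planted_accessible_regions"] = [list(r) for r in config.planted_accessible_regions]
    return d


def simulate_expression(genes, genome: GenomeIndex, slope: float, seed: int,
                        promoter_length: int = 1000, peak_width: int = 400):
    """Expression table plus an accessibility-linked promoter peak set.

    RPKM is log-normal; the probability that a gene's promoter receives a
    peak rises linearly with expression rank at the configured slope
    (slope 0: independent; slope 1: ~0.05 at the bottom to ~0.85 at the top).
    Returns ``(expression rows, peaks, truth)``.
    """
    if not genes:
        raise ValueError("empty gene list")
    if not (0 <= slope <= 1):
        raise ValueError("slope must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(genes)
    rpkm = np.exp(rng.normal(2.0, 1.2, n))
    order = np.argsort(rpkm, kind="stable")
    rank_frac = np.empty(n)
    rank_frac[order] = (np.arange(n) + 0.5) / n
    p = np.clip(0.45 + slope * 0.8 * (rank_frac - 0.5), 0.01, 0.99)
    accessible = rng.random(n) < p

    lengths = dict(genome.contigs)
    peaks, accessible_ids = [], []
    from .annotation import promoter_interval
    for g, acc in zip(genes, accessible):
        if not acc:
            continue
        prom = promoter_interval(g, promoter_length, lengths[g.contig])
        if prom is None:
            continue
        mid = (prom[0] + prom[1]) // 2
        s = max(prom[0], mid - peak_width // 2)
        e = min(prom[1], mid + peak_width // 2)
        peaks.append(Peak(contig=g.contig, start=s, end=e, name=f"sim_{g.gene_id}"))
        accessible_ids.append(g.gene_id)

    rows = [{"gene_id": g.gene_id, "rpkm": float(rpkm[i])} for i, g in enumerate(genes)]
    truth = {"seed": seed, "slope": slope, "accessible_genes": accessible_ids}
    return rows, peaks, truth
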