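"""Gene annotation parsing and derivation of the eight genomic feature sets.

Features: promoter, gene_body, exon, intron, utr5, cds, utr3, igr. The IGR
is the genome complement of gene bodies plus promoters. Feature sets carry
their total sizes in bp, used by the enrichment statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import intervals as iv
from .alignments import GenomeIndex

FEATURE_NAMES = ("promoter", "gene_body", "exon", "intron", "utr5", "cds", "utr3", "igr")

DEFAULT_PROMOTER_LENGTH = 1000

_UTR5_TYPES = {"five_prime_utr", "five_prime_UTR", "5UTR", "5'UTR"}
_UTR3_TYPES = {"three_prime_utr", "three_prime_UTR", "3UTR", "3'UTR"}


@dataclass
class GeneModel:
    """A gene collapsed over transcripts (exon union), 0-based half-open."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: np.ndarray
    cds: np.ndarray
    utr5: np.ndarray
    utr3: np.ndarray

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class FeatureSet:
    """Merged interval lists per feature plus their total sizes (S_gf)."""

    features: dict  # feature name -> {contig: (n,2) array}
    sizes: dict     # feature name -> total bp

    def contig_intervals(self, feature: str, contig: str) -> np.ndarray:
        return self.features[feature].get(contig, iv.EMPTY)

    def to_beds(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in FEATURE_NAMES:
            path = outdir / f"{name}.bed"
            with open(path, "w") as fh:
                for contig in sorted(self.features[name]):
                    for s, e in self.features[name][contig]:
                        fh.write(f"{contig}\t{s}\t{e}\t{name}\n")
            paths[name] = path
        return paths

    def sizes_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("feature\tsize_bp\n")
            for name in FEATURE_NAMES:
                fh.write(f"{name}\t{self.sizes[name]}\n")


def _parse_attributes(attr: str, gff3: bool) -> dict:
    out = {}
    if gff3:
        for part in attr.strip().split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                out[k.strip()] = v.strip()
    else:
        for part in attr.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            if " " in part:
                k, v = part.split(" ", 1)
                out[k] = v.strip().strip('"')
    return out


def parse_annotation(path) -> list:
    """Parse GTF or GFF3 into :class:`GeneModel` records.

    Multi-transcript genes are collapsed by exon union; 1-based closed
    coordinates become 0-based half-open here.
    """
    path = Path(path)
    raw = {}  # gene_id -> dict with contig/strand/bounds and feature interval lists
    gff3 = None
    id_to_gene = {}  # GFF3: feature ID -> owning gene id
    pending = []     # GFF3 children seen before their parent (two-pass resolve)

    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GTF/GFF columns")
        contig, _, ftype, start1, end1, _, strand, _, attr = fields[:9]
        if gff3 is None:
            gff3 = "=" in attr and '"' not in attr
        attrs = _parse_attributes(attr, gff3)
        start, end = int(start1) - 1, int(end1)

        if gff3:
            rec_id = attrs.get("ID")
            parent = attrs.get("Parent")
            if ftype == "gene":
                gid = rec_id or attrs.get("gene_id")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene record without ID")
                id_to_gene[rec_id] = gid
                g = raw.setdefault(gid, _new_gene(contig, strand))
                g["start"], g["end"] = start, end
            elif ftype in ("mRNA", "transcript"):
                gid = id_to_gene.get(parent)
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: transcript with unresolvable Parent")
                id_to_gene[rec_id] = gid
            elif ftype in ("exon", "CDS") or ftype in _UTR5_TYPES or ftype in _UTR3_TYPES:
                pending.append((lineno, contig, ftype, start, end, strand, parent))
        else:
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: record without gene_id attribute")
            g = raw.setdefault(gid, _new_gene(contig, strand))
            if ftype in ("gene", "transcript"):
                g["start"] = start if g["start"] is None else min(g["start"], start)
                g["end"] = end if g["end"] is None else max(g["end"], end)
            else:
                _add_feature(g, ftype, start, end)

    if gff3:
        for lineno, contig, ftype, start, end, strand, parent in pending:
            gid = None
            for p in (parent or "").split(","):
                gid = id_to_gene.get(p) or (p if p in raw else None)
                if gid:
                    break
            if gid is None:
                raise ValueError(f"{path}:{lineno}: feature with unresolvable Parent")
            _add_feature(raw[gid], ftype, start, end)

    genes = []
    for gid, g in raw.items():
        exons = iv.merge(g["exon"])
        if g["start"] is None:
            if len(exons) == 0:
                continue
            g["start"], g["end"] = int(exons[0, 0]), int(exons[-1, 1])
        genes.append(GeneModel(
            gene_id=gid, contig=g["contig"], start=g["start"], end=g["end"],
            strand=g["strand"] if g["strand"] in "+-" else "+",
            exons=exons, cds=iv.merge(g["CDS"]),
            utr5=iv.merge(g["utr5"]), utr3=iv.merge(g["utr3"]),
        ))
    genes.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    return genes


def _new_gene(contig, strand):
    return {"contig": contig, "strand": strand, "start": None, "end": None,
            "exon": [], "CDS": [], "utr5": [], "utr3": []}


def _add_feature(g, ftype, start, end):
    if ftype == "exon":
        g["exon"].append((start, end))
    elif ftype == "CDS":
        g["CDS"].append((start, end))
    elif ftype in _UTR5_TYPES:
        g["utr5"].append((start, end))
    elif ftype in _UTR3_TYPES:
        g["utr3"].append((start, end))


def promoter_interval(gene: GeneModel, promoter_length: int, contig_length: int):
    """Strand-aware upstream window, clipped to the contig; may be empty."""
    if gene.strand == "+":
        s, e = gene.start - promoter_length, gene.start
    else:
        s, e = gene.end, gene.end + promoter_length
    s, e = max(0, s), min(contig_length, e)
    return (s, e) if s < e else None


def build_feature_set(genes, genome: GenomeIndex,
                      promoter_length: int = DEFAULT_PROMOTER_LENGTH) -> FeatureSet:
    """Derive the eight merged feature interval sets over the genome."""
    if promoter_length <= 0:
        raise ValueError("promoter_length must be positive")
    lengths = genome.lengths
    per = {name: {} for name in FEATURE_NAMES}

    def add(name, contig, pairs):
        per[name].setdefault(contig, []).extend(pairs)

    any_utr = False
    for g in genes:
        if g.contig not in lengths:
            raise ValueError(f"gene {g.gene_id} on contig {g.contig!r} absent from genome")
        add("gene_body", g.contig, [(g.start, g.end)])
        add("exon", g.contig, map(tuple, g.exons))
        add("cds", g.contig, map(tuple, g.cds))
        add("utr5", g.contig, map(tuple, g.utr5))
        add("utr3", g.contig, map(tuple, g.utr3))
        any_utr = any_utr or len(g.utr5) or len(g.utr3)
        intron = iv.subtract([(g.start, g.end)], g.exons)
        add("intron", g.contig, map(tuple, intron))
        prom = promoter_interval(g, promoter_length, lengths[g.contig])
        if prom is not None:
            add("promoter", g.contig, [prom])

    if genes and not any_utr:
        warnings.warn("annotation carries no UTR records; utr5/utr3 left empty")

    features = {}
    for name in FEATURE_NAMES:
        features[name] = {c: iv.merge(pairs) for c, pairs in per[name].items()}
    # IGR: complement of gene_body union promoter, per contig over the genome
    igr = {}
    for contig, clen in genome.contigs:
        covered = iv.merge(
            np.vstack([features["gene_body"].get(contig, iv.EMPTY),
                       features["promoter"].get(contig, iv.EMPTY)])
            if (contig in features["gene_body"] or contig in features["promoter"])
            else iv.EMPTY)
        igr[contig] = iv.complement(covered, clen)
    features["igr"] = igr

    sizes = {name: sum(iv.total_length(arr) for arr in features[name].values())
             for name in FEATURE_NAMES}
    return FeatureSet(features=features, sizes=sizes)
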