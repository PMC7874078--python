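"""Fragment input, organelle/duplicate filtering, and fragment-size selection.

Coordinates are 0-based half-open everywhere (BED convention); conversion
from 1-based sources happens at the parser boundary.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

#: Contig names treated as organelle-derived by default (case-insensitive
#: exact match); each entry is also tried as a regular expression.
DEFAULT_ORGANELLE_PATTERNS = ("chrM", "MT", "Mt", "Pt", "chrMT", "chloroplast")


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered contig names and lengths; the universe for coverage and enrichment."""

    contigs: tuple  # of (name, length)

    def __post_init__(self):
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        if any(length <= 0 for _, length in self.contigs):
            raise ValueError("contig lengths must be positive")
        if not self.contigs:
            raise ValueError("genome must contain at least one contig")

    @property
    def names(self) -> list:
        return [n for n, _ in self.contigs]

    @property
    def lengths(self) -> dict:
        return dict(self.contigs)

    @property
    def size(self) -> int:
        """Total genome size in bp (the S_g of feature enrichment)."""
        return sum(length for _, length in self.contigs)

    def subset(self, names: Iterable[str]) -> "GenomeIndex":
        keep = set(names)
        return GenomeIndex(tuple((n, l) for n, l in self.contigs if n in keep))

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeIndex":
        contigs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            name, length = line.split()[:2]
            contigs.append((name, int(length)))
        return cls(tuple(contigs))

    def to_chrom_sizes(self, path) -> None:
        Path(path).write_text("".join(f"{n}\t{l}\n" for n, l in self.contigs))


@dataclass(frozen=True)
class Fragment:
    """One sequenced paired-end fragment as a genomic interval."""

    contig: str
    start: int
    end: int
    strand: str = "."  # strand of the first mate; '.' when unknown

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FilterReport:
    """Accounting of the organelle/duplicate filtering step."""

    n_input: int
    n_organelle_removed: int
    n_duplicates_removed: int
    n_retained: int
    organelle_fraction: float

    def __post_init__(self):
        assert self.n_retained == self.n_input - self.n_organelle_removed - self.n_duplicates_removed

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    def to_tsv(self, path) -> None:
        keys = list(self.__dict__)
        Path(path).write_text(
            "\t".join(keys) + "\n" + "\t".join(str(self.__dict__[k]) for k in keys) + "\n"
        )


def load_fragments(path, pairing_mode: str = "paired", min_mapq: int = 10,
                   genome: GenomeIndex | None = None):
    """Load fragments from a BAM/SAM alignment or a 6-column fragment BED.

    Returns ``(fragments, genome_index, n_skipped)`` where ``n_skipped``
    counts reads dropped for pairing/quality reasons (0 for BED input).
    """
    path = Path(path)
    if pairing_mode not in ("paired", "single"):
        raise ValueError(f"unknown pairing mode {pairing_mode!r}")
    if path.suffix.lower() in (".bam", ".sam", ".cram"):
        return _load_alignments(path, pairing_mode, min_mapq)
    frags, genome = load_fragments_bed(path, genome)
    return frags, genome, 0


def _load_alignments(path, pairing_mode, min_mapq):
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise ValueError(f"unreadable alignment file {path}: {exc}") from exc
    with af:
        contigs = tuple(zip(af.references, af.lengths))
        genome = GenomeIndex(contigs)
        fragments = []
        n_skipped = 0
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                n_skipped += 1
                continue
            if read.mapping_quality < min_mapq:
                n_skipped += 1
                continue
            if pairing_mode == "paired":
                if not (read.is_paired and read.is_proper_pair):
                    n_skipped += 1
                    continue
                tlen = read.template_length
                # emit once per pair, from the leftmost mate
                if tlen <= 0:
                    continue
                start = read.reference_start
                end = start + tlen
                if read.is_read1:
                    strand = "-" if read.is_reverse else "+"
                else:
                    strand = "-" if read.mate_is_reverse else "+"
                fragments.append(Fragment(read.reference_name, start, end, strand))
            else:
                fragments.append(Fragment(read.reference_name, read.reference_start,
                                          read.reference_end,
                                          "-" if read.is_reverse else "+"))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} reads (unmapped/unpaired/low MAPQ)")
    return fragments, genome, n_skipped


def load_fragments_bed(path, genome: GenomeIndex | None = None):
    """Read a fragment BED (contig, start, end[, name, length, strand]).

    When no :class:`GenomeIndex` is given, contig lengths are inferred as
    the maximum fragment end per contig (with a warning).
    """
    fragments = []
    maxima: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
        contig, start, end = fields[0], int(fields[1]), int(fields[2])
        strand = fields[5] if len(fields) >= 6 else "."
        fragments.append(Fragment(contig, start, end, strand))
        maxima[contig] = max(maxima.get(contig, 0), end)
    if genome is None:
        warnings.warn("no genome index supplied; inferring contig lengths from fragments")
        genome = GenomeIndex(tuple(sorted(maxima.items())))
    return fragments, genome


def write_fragments_bed(fragments: Sequence[Fragment], path) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\tfrag{i}\t{f.length}\t{f.strand}\n")


def _matches(contig: str, patterns) -> bool:
    for p in patterns:
        if contig.lower() == p.lower():
            return True
        try:
            if re.fullmatch(p, contig):
                return True
        except re.error:
            pass
    return False


def filter_organelle_and_duplicates(fragments: Sequence[Fragment],
                                    organelle_patterns=DEFAULT_ORGANELLE_PATTERNS,
                                    dedup: bool = True):
    """Remove organelle-contig fragments, then collapse exact duplicates.

    Duplicates are fragments identical in (contig, start, end, strand);
    the first occurrence is kept. Returns ``(retained, FilterReport)``.
    """
    if organelle_patterns is not None and len(organelle_patterns) == 0:
        raise ValueError("organelle filtering requested with empty pattern list")
    n_input = len(fragments)
    patterns = organelle_patterns or ()
    seen_contigs = {f.contig for f in fragments}
    if seen_contigs and patterns and all(_matches(c, patterns) for c in seen_contigs):
        raise ValueError("no nuclear contigs remain after organelle filtering")
    nuclear = [f for f in fragments if not _matches(f.contig, patterns)]
    n_org = n_input - len(nuclear)
    if dedup:
        seen = set()
        retained = []
        for f in nuclear:
            key = (f.contig, f.start, f.end, f.strand)
            if key in seen:
                continue
            seen.add(key)
            retained.append(f)
    else:
        retained = nuclear
    n_dup = len(nuclear) - len(retained)
    report = FilterReport(
        n_input=n_input,
        n_organelle_removed=n_org,
        n_duplicates_removed=n_dup,
        n_retained=len(retained),
        organelle_fraction=(n_org / n_input) if n_input else 0.0,
    )
    return retained, report


def select_fragments_by_length(fragments: Sequence[Fragment], cutoff: int,
                               side: str = "at_most"):
    """Keep fragments with length <= cutoff (``at_most``) or > cutoff (``above``)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if side == "at_most":
        out = [f for f in fragments if f.length <= cutoff]
    elif side == "above":
        out = [f for f in fragments if f.length > cutoff]
    else:
        raise ValueError(f"unknown side {side!r}")
    if not out:
        warnings.warn("fragment length selection produced an empty set")
    return out
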