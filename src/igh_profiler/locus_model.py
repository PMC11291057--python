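"""Data model for IGH locus references and gene annotations.

The immunoglobulin heavy-chain (IGH) locus is an ordered array of joining
(J), diversity (D), and variable (V) genes, each flanked by recombination
signal sequences (RSSs) on its recombination-facing side(s):

* V genes carry an RSS 3' of the coding sequence (facing D),
* D genes carry RSSs on both sides,
* J genes carry an RSS 5' of the coding sequence (facing D).

During V(D)J recombination, double-strand breaks occur at these RSSs, so
split-read and deletion breakpoints cluster around them.  Every module in
this package anchors breakpoints to RSS coordinates via this model.

Coordinates are 0-based, half-open throughout.  On the human reference the
IGH genes lie on the minus strand with the J block at the lowest
coordinates, then D, then V; the model supports either strand but the
bundled simulator reproduces the real geometry.  The RSS is stored as a
single representative coordinate: the heptamer edge adjacent to the gene
(numerically the gene boundary itself).
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml


class SegmentClass(str, enum.Enum):
    V = "V"
    D = "D"
    J = "J"


class Functionality(str, enum.Enum):
    functional = "functional"
    ORF = "ORF"
    pseudo = "pseudo"


#: Side of a gene an RSS sits on, in the gene's own 5'->3' frame.
RSS_5P = "5p"
RSS_3P = "3p"

#: Human D genes do not exceed 40 bp; enforced by the simulator and
#: warned about on external annotations.
MAX_D_GENE_LENGTH = 40


class AnnotationError(ValueError):
    """Malformed or invariant-violating annotation input."""


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """One V, D, or J gene with its RSS anchor coordinate(s)."""

    name: str
    segment_class: SegmentClass
    functionality: Functionality
    chrom: str
    start: int
    end: int
    strand: str
    rss5: Optional[int] = None
    rss3: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segment_class",
                           SegmentClass(self.segment_class))
        object.__setattr__(self, "functionality",
                           Functionality(self.functionality))
        if self.start >= self.end:
            raise AnnotationError(f"{self.name}: start must be < end")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.name}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    def rss(self, side: str) -> Optional[int]:
        return self.rss5 if side == RSS_5P else self.rss3

    def rss_positions(self) -> list[tuple[str, int]]:
        out = []
        if self.rss5 is not None:
            out.append((RSS_5P, self.rss5))
        if self.rss3 is not None:
            out.append((RSS_3P, self.rss3))
        return out

    def validate_rss(self) -> None:
        """Check RSS presence/placement for the gene's class and strand.

        rss5 must lie upstream of the gene on its own strand (coordinate
        >= end for '-' genes, <= start for '+'), rss3 downstream.
        """
        cls = self.segment_class
        required = {
            SegmentClass.V: (RSS_3P,),
            SegmentClass.D: (RSS_5P, RSS_3P),
            SegmentClass.J: (RSS_5P,),
        }[cls]
        for side in required:
            if self.rss(side) is None:
                raise AnnotationError(
                    f"{self.name}: {cls.value} gene must carry an {side} RSS"
                )
        if self.strand == "-":
            if self.rss5 is not None and self.rss5 < self.end:
                raise AnnotationError(f"{self.name}: rss5 not upstream of gene")
            if self.rss3 is not None and self.rss3 > self.start:
                raise AnnotationError(f"{self.name}: rss3 not downstream of gene")
        else:
            if self.rss5 is not None and self.rss5 > self.start:
                raise AnnotationError(f"{self.name}: rss5 not upstream of gene")
            if self.rss3 is not None and self.rss3 < self.end:
                raise AnnotationError(f"{self.name}: rss3 not downstream of gene")


class LocusAnnotation:
    """Ordered gene annotation of one IGH reference.

    Parameters
    ----------
    reference_id
        Identifier of the reference genome the coordinates refer to.
    genes
        Gene records; stored sorted by (chrom, start).
    strict_d_length
        If True, D genes longer than :data:`MAX_D_GENE_LENGTH` raise; if
        False (default for external annotations) they only warn.
    """

    def __init__(
        self,
        reference_id: str,
        genes: Iterable[GeneRecord],
        strict_d_length: bool = False,
    ) -> None:
        self.reference_id = reference_id
        self.genes: list[GeneRecord] = sorted(genes, key=lambda g: (g.chrom, g.start))
        self._validate(strict_d_length)
        self._by_name = {g.name: g for g in self.genes}

    def _validate(self, strict_d_length: bool) -> None:
        import warnings

        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise AnnotationError(f"duplicate gene names in annotation: {dup}")
        for g in self.genes:
            g.validate_rss()
            if g.segment_class is SegmentClass.D and g.length > MAX_D_GENE_LENGTH:
                msg = (
                    f"{g.name}: D gene length {g.length} exceeds "
                    f"{MAX_D_GENE_LENGTH} bp"
                )
                if strict_d_length:
                    raise AnnotationError(msg)
                warnings.warn(msg)
        # J block must precede D block, which precedes V block, per chrom.
        order = {SegmentClass.J: 0, SegmentClass.D: 1, SegmentClass.V: 2}
        for chrom in {g.chrom for g in self.genes}:
            ranks = [order[g.segment_class] for g in self.genes if g.chrom == chrom]
            if ranks != sorted(ranks):
                raise AnnotationError(
                    f"{chrom}: gene classes not in J < D < V coordinate order"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def gene(self, name: str) -> GeneRecord:
        return self._by_name[name]

    def by_class(self, cls: SegmentClass) -> list[GeneRecord]:
        return [g for g in self.genes if g.segment_class is cls]

    @property
    def chrom(self) -> str:
        return self.genes[0].chrom

    @property
    def jd_interval(self) -> tuple[int, int]:
        """[leftmost J gene start, rightmost D gene end) on the reference."""
        js = self.by_class(SegmentClass.J)
        ds = self.by_class(SegmentClass.D)
        if not js or not ds:
            raise AnnotationError("jd_interval requires at least one J and one D gene")
        return (min(g.start for g in js), max(g.end for g in ds))

    def locus_rank(self, name: str) -> int:
        """Position of a gene in locus coordinate order."""
        for i, g in enumerate(self.genes):
            if g.name == name:
                return i
        raise KeyError(name)


COLUMNS = ["chrom", "start", "end", "name", "class", "functionality", "strand",
           "rss5", "rss3"]


def load_annotation(path, reference_id: Optional[str] = None) -> LocusAnnotation:
    """Load a locus annotation from the project TSV format.

    The table is BED6-compatible in its first columns: chrom, start, end,
    name, class, functionality, strand, rss5, rss3; missing RSSs are
    encoded as ".".  Raises :class:`AnnotationError` naming the offending
    line on malformed rows.
    """
    path = Path(path)
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(COLUMNS):
                raise AnnotationError(
                    f"{path}:{lineno}: expected {len(COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom, start, end, name, cls, func, strand, rss5, rss3 = fields
                genes.append(
                    GeneRecord(
                        name=name,
                        segment_class=SegmentClass(cls),
                        functionality=Functionality(func),
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        rss5=None if rss5 == "." else int(rss5),
                        rss3=None if rss3 == "." else int(rss3),
                    )
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return LocusAnnotation(reference_id or path.stem, genes)


def write_annotation(annotation: LocusAnnotation, path) -> None:
    """Serialize an annotation to the project TSV format (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(COLUMNS) + "\n")
        for g in annotation.genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.name,
                        g.segment_class.value,
                        g.functionality.value,
                        g.strand,
                        "." if g.rss5 is None else str(g.rss5),
                        "." if g.rss3 is None else str(g.rss3),
                    ]
                )
                + "\n"
            )


class RSSLookupError(LookupError):
    """No RSS of the requested side exists in the annotation."""


def nearest_rss(
    annotation: LocusAnnotation, pos: int, side: str = "any"
) -> tuple[GeneRecord, str, int]:
    """Gene whose RSS coordinate of the requested side is closest to ``pos``.

    Returns ``(gene, rss_side, distance)``.  Ties are broken toward the
    gene with the smaller start coordinate (then the 5' side),
    deterministically.

    Parameters
    ----------
    side
        ``"any"``, ``"5p"`` or ``"3p"``.
    """
    best = None
    for g in annotation.genes:
        for s, coord in g.rss_positions():
            if side != "any" and s != side:
                continue
            d = abs(coord - pos)
            key = (d, g.start, 0 if s == RSS_5P else 1)
            if best is None or key < best[0]:
                best = (key, g, s, d)
    if best is None:
        raise RSSLookupError(f"annotation has no RSS of side {side!r}")
    return best[1], best[2], best[3]


@dataclasses.dataclass
class PanelEntry:
    reference_id: str
    fasta: Optional[Path]
    annotation: LocusAnnotation
    priority: int


class ReferencePanel:
    """Ordered set of reference genomes with IGH annotations.

    Profiling against several references counters reference bias: each
    reference carries IGH genes/haplotypes the others lack, so a read is
    scored against every panel member and the best-fitting one is kept.
    ``priority`` (smaller = preferred) breaks exact ties.
    """

    def __init__(self, entries: Sequence[PanelEntry]) -> None:
        if not entries:
            raise ValueError("reference panel needs at least one entry")
        self.entries = sorted(entries, key=lambda e: e.priority)
        self._by_id = {e.reference_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def annotation(self, reference_id: str) -> LocusAnnotation:
        return self._by_id[reference_id].annotation

    def priority_rank(self, reference_id: str) -> int:
        for i, e in enumerate(self.entries):
            if e.reference_id == reference_id:
                return i
        raise KeyError(reference_id)

    @classmethod
    def from_yaml(cls, path) -> "ReferencePanel":
        """Load a panel config: a YAML list of
        ``{id, fasta, annotation, priority}`` entries; paths are resolved
        relative to the config file."""
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries = []
        for item in raw["references"] if isinstance(raw, dict) else raw:
            ann = load_annotation(
                path.parent / item["annotation"], reference_id=item["id"]
            )
            fasta = item.get("fasta")
            entries.append(
                PanelEntry(
                    reference_id=item["id"],
                    fasta=None if fasta is None else path.parent / fasta,
                    annotation=ann,
                    priority=int(item.get("priority", len(entries))),
                )
            )
        return cls(entries)
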