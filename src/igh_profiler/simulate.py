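"""Synthetic IGH locus, recombined haplotypes, and reads with truth.

The generator builds a toy germline IGH locus that mirrors the geometry of
the real human locus: J genes at the lowest reference coordinates, then the
D block, then the V block, all genes on the minus strand (transcription
runs from the V side toward J).  Consecutive J genes are spaced under
400 bp, D genes are at most 40 bp long, and each gene is flanked by a
fixed 7-mer RSS marker on its recombination-facing side(s) so that split
alignments land sharply at the annotated anchors.

Somatic haplotypes are produced by an event grammar covering the observed
recombination classes (canonical, partial D-J / V-D, multi-D RSS skipping,
J/D/V inversions, and double V-D).  Each somatic molecule is a list of
germline tiles (reference interval + orientation, optionally a literal
junctional-insertion sequence), from which both the molecule sequence and
exact truth alignments for sampled reads are derived.

Reads are emitted as FASTA plus a truth table, and optionally as a SAM
file containing the exact alignment each aligner segment would ideally
produce.  To mimic aligner behaviour, aligned pieces shorter than
``min_segment`` (default 60 bp — e.g. the subsumed D gene of a canonical
event) are left soft-clipped, and same-strand reference gaps shorter than
``deletion_threshold`` (default 2 kb — e.g. skipped spacers between close
D genes) are represented as CIGAR deletions instead of new segments.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._util import revcomp, write_fasta
from .locus_model import (
    Functionality,
    GeneRecord,
    LocusAnnotation,
    SegmentClass,
    write_annotation,
)

RSS_MARKER = "CACAGTG"  # heptamer planted adjacent to each gene

#: V-gene names for the toy locus, left (D-proximal) to right.  The three
#: duplicate-eligible community names are included so duplicate-naming and
#: SV logic can be exercised.
_V_NAMES = [
    "IGHV6-1", "IGHV3-9", "IGHV1-8", "IGHV3-23", "IGHV3-30",
    "IGHV4-34", "IGHV1-69", "IGHV2-70", "IGHV5-51", "IGHV7-81",
]


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the toy locus and read sets."""

    n_v: int = 10
    n_d: int = 5
    n_j: int = 3
    n_pseudo_v: int = 2
    v_len: tuple[int, int] = (280, 300)
    d_len: tuple[int, int] = (16, 36)
    j_len: tuple[int, int] = (48, 60)
    j_spacing: tuple[int, int] = (200, 350)   # < 400 bp between J genes
    d_spacing: tuple[int, int] = (350, 600)
    v_spacing: tuple[int, int] = (1800, 2600)
    left_margin: int = 2500
    right_margin: int = 2500
    jd_gap: int = 4000          # J block to D block
    dv_gap: int = 3000          # D block to V block
    read_len: tuple[int, int] = (8000, 14000)
    error_rate: float = 0.0     # per-base substitution rate
    chrom: str = "igh_toy"
    seed: int = 0


@dataclasses.dataclass(frozen=True)
class TruthJunction:
    """One planted junction, normalized to reference order."""

    left_gene: str
    left_side: str      # "5p" / "3p"
    right_gene: str
    right_side: str
    orientation_change: bool

    def key(self) -> tuple:
        return (self.left_gene, self.left_side, self.right_gene,
                self.right_side, self.orientation_change)


@dataclasses.dataclass(frozen=True)
class Tile:
    """One piece of a somatic molecule.

    Either a germline interval (``start``/``end`` on the reference, with
    orientation) or, when ``ins_seq`` is set, a literal non-templated
    insertion.
    """

    start: int
    end: int
    strand: str = "+"
    ins_seq: Optional[str] = None

    @property
    def length(self) -> int:
        if self.ins_seq is not None:
            return len(self.ins_seq)
        return self.end - self.start


class Molecule:
    """A (possibly recombined) haplotype as a list of tiles."""

    def __init__(self, molecule_id: str, tiles: Sequence[Tile],
                 truth_chain: Sequence[TruthJunction] = ()) -> None:
        self.molecule_id = molecule_id
        self.tiles = list(tiles)
        self.truth_chain = list(truth_chain)
        offs, off = [], 0
        for t in self.tiles:
            offs.append(off)
            off += t.length
        self._offsets = offs
        self.length = off

    def sequence(self, germline: str) -> str:
        parts = []
        for t in self.tiles:
            if t.ins_seq is not None:
                parts.append(t.ins_seq)
            elif t.strand == "+":
                parts.append(germline[t.start : t.end])
            else:
                parts.append(revcomp(germline[t.start : t.end]))
        return "".join(parts)

    def junction_positions(self) -> list[int]:
        """Molecule coordinates of the inter-tile boundaries."""
        return self._offsets[1:]

    def pieces(self, start: int, end: int):
        """Map molecule interval [start, end) to reference pieces.

        Yields ``(mol_start, mol_end, ref_start, ref_end, strand)`` per
        overlapped tile; insertion tiles yield ``ref_start is None``.
        """
        for t, off in zip(self.tiles, self._offsets):
            lo = max(start, off)
            hi = min(end, off + t.length)
            if lo >= hi:
                continue
            if t.ins_seq is not None:
                yield (lo, hi, None, None, "+")
            elif t.strand == "+":
                yield (lo, hi, t.start + (lo - off), t.start + (hi - off), "+")
            else:
                yield (lo, hi, t.end - (hi - off), t.end - (lo - off), "-")


def build_toy_locus(config: SimConfig) -> tuple[str, LocusAnnotation]:
    """Deterministically generate the germline locus and its annotation."""
    for name, (lo, hi) in [("v_len", config.v_len), ("d_len", config.d_len),
                           ("j_len", config.j_len)]:
        if lo > hi or lo <= 0:
            raise ValueError(f"infeasible length range for {name}")
    if config.d_len[1] > 40:
        raise ValueError("D gene length range must stay within 40 bp")
    rng = np.random.default_rng(config.seed)

    genes: list[GeneRecord] = []
    chunks: list[str] = []
    pos = 0

    def emit(seq: str) -> None:
        nonlocal pos
        chunks.append(seq)
        pos += len(seq)

    def rand_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    def emit_gene(name: str, cls: SegmentClass, func: Functionality,
                  length: int) -> None:
        """Genes are on '-' strand: rss3 marker left, rss5 marker right."""
        nonlocal pos
        has_rss3 = cls in (SegmentClass.V, SegmentClass.D)
        has_rss5 = cls in (SegmentClass.J, SegmentClass.D)
        if has_rss3:
            emit(revcomp(RSS_MARKER))
        start = pos
        emit(rand_seq(length))
        end = pos
        if has_rss5:
            emit(RSS_MARKER)
        genes.append(GeneRecord(
            name=name, segment_class=cls, functionality=func,
            chrom=config.chrom, start=start, end=end, strand="-",
            rss5=end if has_rss5 else None,
            rss3=start if has_rss3 else None,
        ))

    emit(rand_seq(config.left_margin))
    for i in range(config.n_j):
        if i:
            emit(rand_seq(int(rng.integers(*config.j_spacing))))
        emit_gene(f"IGHJ{i + 1}", SegmentClass.J, Functionality.functional,
                  int(rng.integers(*config.j_len)))
    emit(rand_seq(config.jd_gap))
    for i in range(config.n_d):
        if i:
            emit(rand_seq(int(rng.integers(*config.d_spacing))))
        emit_gene(f"IGHD{i + 1}-{i + 1}", SegmentClass.D,
                  Functionality.functional, int(rng.integers(*config.d_len)))
    emit(rand_seq(config.dv_gap))
    pseudo_idx = set(range(config.n_v - config.n_pseudo_v, config.n_v))
    for i in range(config.n_v):
        if i:
            emit(rand_seq(int(rng.integers(*config.v_spacing))))
        name = _V_NAMES[i] if i < len(_V_NAMES) else f"IGHV9-{i + 1}"
        func = Functionality.pseudo if i in pseudo_idx else Functionality.functional
        emit_gene(name, SegmentClass.V, func, int(rng.integers(*config.v_len)))
    emit(rand_seq(config.right_margin))

    seq = "".join(chunks)
    ann = LocusAnnotation(config.chrom, genes, strict_d_length=True)
    return seq, ann


@dataclasses.dataclass
class EventSpec:
    """Recombination event to plant.

    ``kind`` is one of canonical, partial_DJ, partial_VD, multi_D,
    inversion_J, inversion_D, inversion_V, double_VD.  Gene roles:

    * canonical: j, d, v
    * partial_DJ: j, d        — D-J joint only, 5' flank of D germline
    * partial_VD: d, v        — V-D joint only, J-D intergenic germline
    * multi_D: j, d_blocks=[(first, last), ...], v — RSS skipping; each
      block [first.rss3 .. last.rss5] is retained as part of the virtual
      "ultralong" D gene
    * inversion_J: j, j2      — span between the two J genes' 5' RSSs
      inverted in place
    * inversion_D: d, d2      — span between the two D genes' 3' RSSs
      inverted in place
    * inversion_V: d, v       — span between D's 5' RSS and V's 3' RSS
      inverted in place
    * double_VD: v2, d, d2, v — no J; inverted v2 joined at d's 3' RSS,
      consecutive-D block [d.rss3 .. d2.rss5], normal V-D joint to v
    """

    kind: str
    j: Optional[str] = None
    d: Optional[str] = None
    v: Optional[str] = None
    j2: Optional[str] = None
    d2: Optional[str] = None
    v2: Optional[str] = None
    d_blocks: Optional[List[Tuple[str, str]]] = None
    insertion: int = 0


def _ins_tiles(spec: EventSpec, rng: np.random.Generator, n_junctions: int):
    if spec.insertion <= 0:
        return [None] * n_junctions
    return ["".join("ACGT"[i] for i in rng.integers(0, 4, spec.insertion))
            for _ in range(n_junctions)]


def apply_event(annotation: LocusAnnotation, locus_len: int, spec: EventSpec,
                molecule_id: Optional[str] = None,
                rng: Optional[np.random.Generator] = None) -> Molecule:
    """Realize an event spec as a somatic molecule with truth junctions.

    Junctions land exactly at the RSS anchors; an optional non-templated
    insertion of ``spec.insertion`` bases is placed at each junction.
    """
    rng = rng or np.random.default_rng(0)
    g = annotation.gene
    L = locus_len
    mid = molecule_id or spec.kind
    k = spec.kind

    def J(lg, ls, rg, rs, flip=False):
        return TruthJunction(lg, ls, rg, rs, flip)

    if k == "canonical":
        j, d, v = g(spec.j), g(spec.d), g(spec.v)
        _check_order(j, d), _check_order(d, v)
        tiles = [Tile(0, j.rss5), Tile(d.rss3, d.rss5), Tile(v.rss3, L)]
        chain = [J(spec.j, "5p", spec.v, "3p")]
    elif k == "partial_DJ":
        j, d = g(spec.j), g(spec.d)
        _check_order(j, d)
        tiles = [Tile(0, j.rss5), Tile(d.rss3, L)]
        chain = [J(spec.j, "5p", spec.d, "3p")]
    elif k == "partial_VD":
        d, v = g(spec.d), g(spec.v)
        _check_order(d, v)
        tiles = [Tile(0, d.rss5), Tile(v.rss3, L)]
        chain = [J(spec.d, "5p", spec.v, "3p")]
    elif k == "multi_D":
        j, v = g(spec.j), g(spec.v)
        blocks = [(g(a), g(b)) for a, b in spec.d_blocks]
        tiles = [Tile(0, j.rss5)]
        chain = [J(spec.j, "5p", spec.d_blocks[0][0], "3p")]
        prev = None
        for (a, b), names in zip(blocks, spec.d_blocks):
            _check_order(j, a)
            if a is not b:
                _check_order(a, b)
            if prev is not None:
                _check_order(prev[0], a)
                chain.append(J(prev[1], "5p", names[0], "3p"))
            tiles.append(Tile(a.rss3, b.rss5))
            prev = (b, names[1])
        _check_order(prev[0], v)
        tiles.append(Tile(v.rss3, L))
        chain.append(J(prev[1], "5p", spec.v, "3p"))
    elif k == "inversion_J":
        ja, jb = g(spec.j), g(spec.j2)
        _check_order(ja, jb)
        tiles = [Tile(0, ja.rss5), Tile(ja.rss5, jb.rss5, "-"),
                 Tile(jb.rss5, L)]
        chain = [J(spec.j, "5p", spec.j2, "5p", True)] * 2
    elif k == "inversion_D":
        da, db = g(spec.d), g(spec.d2)
        _check_order(da, db)
        tiles = [Tile(0, da.rss3), Tile(da.rss3, db.rss3, "-"),
                 Tile(db.rss3, L)]
        chain = [J(spec.d, "3p", spec.d2, "3p", True)] * 2
    elif k == "inversion_V":
        d, v = g(spec.d), g(spec.v)
        _check_order(d, v)
        tiles = [Tile(0, d.rss5), Tile(d.rss5, v.rss3, "-"), Tile(v.rss3, L)]
        chain = [J(spec.d, "5p", spec.v, "3p", True)] * 2
    elif k == "double_VD":
        vb, dlo, dhi, va = g(spec.v2), g(spec.d), g(spec.d2), g(spec.v)
        _check_order(dlo, dhi), _check_order(dhi, va), _check_order(dhi, vb)
        tiles = [Tile(vb.rss3, min(vb.rss3 + 2500, L), "-"),
                 Tile(dlo.rss3, dhi.rss5), Tile(va.rss3, L)]
        chain = [J(spec.d, "3p", spec.v2, "3p", True),
                 J(spec.d2, "5p", spec.v, "3p")]
    else:
        raise ValueError(f"unknown event kind: {spec.kind!r}")

    if spec.insertion > 0:
        inserted: list[Tile] = []
        ins = _ins_tiles(spec, rng, len(tiles) - 1)
        for i, t in enumerate(tiles):
            inserted.append(t)
            if i < len(tiles) - 1 and ins[i] is not None:
                inserted.append(Tile(0, 0, ins_seq=ins[i]))
        tiles = inserted
    return Molecule(mid, tiles, chain)


def _check_order(left: GeneRecord, right: GeneRecord) -> None:
    if left.start >= right.start:
        raise ValueError(
            f"event references genes in wrong locus order: "
            f"{left.name} !< {right.name}"
        )


# ---------------------------------------------------------------------------
# Read simulation


@dataclasses.dataclass(frozen=True)
class TruthSegment:
    """One ideal alignment segment of a simulated read.

    ``read_start``/``read_end`` are in the read's original orientation;
    ``ops`` is the aligned CIGAR core in read orientation as a list of
    (op, length) with op in {"M", "D", "I"}.
    """

    ref_start: int
    ref_end: int
    strand: str
    read_start: int
    read_end: int
    ops: tuple


@dataclasses.dataclass
class SimRead:
    read_id: str
    sequence: str
    molecule_id: str
    segments: List[TruthSegment]
    truth_chain: List[TruthJunction]
    flipped: bool


@dataclasses.dataclass
class CloneSpec:
    """A clone contributing recombination-evidence reads.

    ``n_reads`` reads are sampled so that each spans every planted
    junction with at least ``margin`` aligned bases on both sides.
    """

    event: EventSpec
    n_reads: int
    clone_id: Optional[str] = None


def _segments_for_read(molecule: Molecule, start: int, end: int, flipped: bool,
                       min_segment: int, deletion_threshold: int
                       ) -> List[TruthSegment]:
    """Project a molecule interval into aligner-style truth segments."""
    raw = list(molecule.pieces(start, end))
    # merge same-strand pieces separated by a short reference gap (deletion)
    merged: list[list] = []  # [read_s, read_e, ref_s, ref_e, strand, ops]
    for mlo, mhi, rlo, rhi, strand in raw:
        if rlo is None:
            continue  # junctional insertion: stays unaligned
        rd_s, rd_e = mlo - start, mhi - start
        new_ops = [("M", rhi - rlo)]
        if merged:
            p = merged[-1]
            read_gap = rd_s - p[1]
            if strand == p[4] and read_gap >= 0:
                ref_gap = (rlo - p[3]) if strand == "+" else (p[2] - rhi)
                if 0 <= ref_gap < deletion_threshold:
                    # extend previous segment: insertion for read gap,
                    # deletion for reference gap
                    if read_gap:
                        p[5].append(("I", read_gap))
                    if ref_gap:
                        p[5].append(("D", ref_gap))
                    p[5].extend(new_ops)
                    p[1] = rd_e
                    if strand == "+":
                        p[3] = rhi
                    else:
                        p[2] = rlo
                    continue
        merged.append([rd_s, rd_e, rlo, rhi, strand, new_ops])

    segs = []
    L = end - start
    for rd_s, rd_e, ref_s, ref_e, strand, ops in merged:
        if rd_e - rd_s < min_segment:
            continue
        if flipped:
            rd_s, rd_e = L - rd_e, L - rd_s
            strand = "+" if strand == "-" else "-"
            ops = ops[::-1]
        segs.append(TruthSegment(ref_s, ref_e, strand, rd_s, rd_e, tuple(ops)))
    segs.sort(key=lambda s: s.read_start)
    return segs


def _junctions_covered(molecule: Molecule, start: int, end: int,
                       margin: int) -> List[TruthJunction]:
    out = []
    for pos, junc in zip(molecule.junction_positions(), _chain_at_boundaries(molecule)):
        if junc is None:
            continue
        if pos - start >= margin and end - pos >= margin:
            out.append(junc)
    return out


def _chain_at_boundaries(molecule: Molecule):
    """Associate each tile boundary with its truth junction (insertion
    tiles share their junction with the following boundary)."""
    juncs = list(molecule.truth_chain)
    out = []
    boundary_count = len(molecule.tiles) - 1
    # walk boundaries; an insertion tile consumes no junction on its left
    ji = 0
    for i in range(boundary_count):
        right_tile = molecule.tiles[i + 1]
        left_tile = molecule.tiles[i]
        if left_tile.ins_seq is not None:
            out.append(None)  # boundary after insertion: same junction,
            # already counted at the boundary before the insertion
            continue
        if ji < len(juncs):
            out.append(juncs[ji])
            ji += 1
        else:
            out.append(None)
    return out


def simulate_reads(
    germline: str,
    annotation: LocusAnnotation,
    config: SimConfig,
    clones: Sequence[CloneSpec] = (),
    germline_depth: float = 0.0,
    margin: int = 300,
    min_segment: int = 60,
    deletion_threshold: int = 2000,
    allow_flip: bool = True,
) -> List[SimRead]:
    """Sample reads from the germline and clone molecules.

    Germline reads are drawn uniformly to the requested depth; clone reads
    are placed so that they span all planted junctions with ``margin``
    aligned bases on each side.  Read orientation is random unless
    ``allow_flip`` is False.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = len(germline)
    reads: list[SimRead] = []

    def sample_len() -> int:
        return int(rng.integers(config.read_len[0], config.read_len[1] + 1))

    def make_read(molecule: Molecule, seq: str, start: int, end: int,
                  rid: str) -> SimRead:
        flipped = bool(allow_flip and rng.integers(0, 2))
        sub = seq[start:end]
        if flipped:
            sub = revcomp(sub)
        if config.error_rate > 0:
            sub = _mutate(sub, config.error_rate, rng)
        segs = _segments_for_read(molecule, start, end, flipped,
                                  min_segment, deletion_threshold)
        chain = _junctions_covered(molecule, start, end, margin)
        return SimRead(rid, sub, molecule.molecule_id, segs, chain, flipped)

    if germline_depth > 0:
        mol = Molecule("germline", [Tile(0, L)])
        mean_len = sum(config.read_len) / 2
        n = max(1, int(round(germline_depth * L / mean_len)))
        for i in range(n):
            rl = min(sample_len(), L)
            s = int(rng.integers(0, L - rl + 1))
            reads.append(make_read(mol, germline, s, s + rl, f"germ_{i}"))

    for ci, clone in enumerate(clones):
        cid = clone.clone_id or f"clone{ci}"
        mol = apply_event(annotation, L, clone.event, molecule_id=cid, rng=rng)
        seq = mol.sequence(germline)
        jpos = mol.junction_positions()
        jmin, jmax = min(jpos), max(jpos)
        for i in range(clone.n_reads):
            rl = sample_len()
            span = jmax - jmin + 2 * margin
            if rl < span:
                rl = span + margin
            rl = min(rl, mol.length)
            lo = max(0, jmax + margin - rl)
            hi = min(jmin - margin, mol.length - rl)
            if hi < lo:
                raise ValueError(
                    f"{cid}: molecule too short to span junctions with margin"
                )
            s = int(rng.integers(lo, hi + 1))
            reads.append(make_read(mol, seq, s, s + rl, f"{cid}_{i}"))
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    arr = list(seq)
    for p in pos:
        cur = arr[p]
        choices = [b for b in "ACGT" if b != cur]
        arr[p] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Output writers


def write_reads_fasta(reads: Sequence[SimRead], path) -> None:
    write_fasta(((r.read_id, r.sequence) for r in reads), path)


def write_truth_table(reads: Sequence[SimRead], path) -> None:
    """TSV: read_id, molecule, flipped, planted chain, segment coordinates."""
    from ._util import atomic_open

    with atomic_open(path) as fh:
        fh.write("#read_id\tmolecule\tflipped\tchain\tsegments\n")
        for r in reads:
            chain = ";".join(
                f"{j.left_gene}:{j.left_side}|{j.right_gene}:{j.right_side}"
                f"|{'inv' if j.orientation_change else 'fwd'}"
                for j in r.truth_chain
            ) or "."
            segs = ";".join(
                f"{s.ref_start}-{s.ref_end}:{s.strand}:{s.read_start}-{s.read_end}"
                for s in r.segments
            ) or "."
            fh.write(f"{r.read_id}\t{r.molecule_id}\t{int(r.flipped)}\t"
                     f"{chain}\t{segs}\n")


_CIGAR_CODES = {"M": 0, "I": 1, "D": 2, "S": 4}


def write_truth_sam(reads: Sequence[SimRead], chrom: str, ref_len: int,
                    path) -> None:
    """Emit exact truth alignments (primary + supplementary per read)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": ref_len}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            if not r.segments:
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.read_id
                a.flag = 4
                a.query_sequence = r.sequence
                out.write(a)
                continue
            # longest segment is primary
            order = sorted(range(len(r.segments)),
                           key=lambda i: -(r.segments[i].read_end
                                           - r.segments[i].read_start))
            for rank, i in enumerate(order):
                s = r.segments[i]
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.read_id
                flag = 0
                if s.strand == "-":
                    flag |= 16
                if rank > 0:
                    flag |= 2048
                a.flag = flag
                a.reference_id = 0
                a.reference_start = s.ref_start
                a.mapping_quality = 60
                L = len(r.sequence)
                if s.strand == "+":
                    lead, trail = s.read_start, L - s.read_end
                    ops = list(s.ops)
                    seq = r.sequence
                else:
                    lead, trail = L - s.read_end, s.read_start
                    ops = list(s.ops)[::-1]
                    seq = revcomp(r.sequence)
                cig = []
                if lead:
                    cig.append((_CIGAR_CODES["S"], lead))
                cig += [(_CIGAR_CODES[o], n) for o, n in ops]
                if trail:
                    cig.append((_CIGAR_CODES["S"], trail))
                a.cigartuples = cig
                a.query_sequence = seq
                out.write(a)


def write_locus(germline: str, annotation: LocusAnnotation, outdir,
                name: str = "germline") -> tuple[Path, Path]:
    """Write the germline FASTA + annotation TSV; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fa = outdir / f"{name}.fa"
    tsv = outdir / f"{name}.annotation.tsv"
    write_fasta([(annotation.chrom, germline)], fa)
    write_annotation(annotation, tsv)
    return fa, tsv


def gene_db_from_annotation(germline: str, annotation: LocusAnnotation,
                            allele: str = "01") -> Dict[str, str]:
    """Extract gene sequences as a ``gene*allele`` database.

    Sequences are taken in gene orientation (reverse-complemented for
    '-'-strand genes), as a documented-allele database would store them.
    """
    db = {}
    for g in annotation.genes:
        seq = germline[g.start:g.end]
        if g.strand == "-":
            seq = revcomp(seq)
        db[f"{g.name}*{allele}"] = seq
    return db


def write_panel_yaml(outdir, entries: Sequence[tuple[str, str, str]],
                     name: str = "panel.yaml") -> Path:
    """Write a reference-panel config; entries are (id, fasta, annotation)
    filenames relative to ``outdir`` in priority order."""
    import yaml

    outdir = Path(outdir)
    payload = {
        "references": [
            {"id": rid, "fasta": fa, "annotation": ann, "priority": i}
            for i, (rid, fa, ann) in enumerate(entries)
        ]
    }
    path = outdir / name
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path
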