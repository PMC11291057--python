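"""Detect, deduplicate and classify V(D)J recombination events in reads.

A read overlapping a somatic V(D)J recombination event aligns to the
reference in several contiguous pieces ("segments"); the adjacency between
two segments, or a long internal deletion inside one segment, is a
*junction*.  Because recombination breaks occur at recombination signal
sequences (RSSs), junctions of true events anchor within a small distance
(default 50 bp, inclusive) of annotated RSS coordinates — such junctions
are *confident*.  For deletions between two D genes, where repeat
structure lets the aligner slide the gap, the requirement is instead that
the deletion length matches the germline distance between the two genes'
facing RSSs within 50 bp.

Chains of gene-anchored junctions are classified into the recombination
taxonomy (canonical J-V joint with the D subsumed, partial D-J or V-D
joints, multi-D RSS skipping, J/D/V inversions, double V-D), deduplicated
into events (identity = gene names + RSS sides + orientations, which
absorbs junctional diversity), and summarized per sample by Simpson's
index SI = sum(n_i^2)/N^2 over per-event read counts, with clonality
called monoclonal (SI > 0.25), polyclonal (SI < 0.125) or in-between.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .locus_model import (
    GeneRecord,
    LocusAnnotation,
    ReferencePanel,
    SegmentClass,
    nearest_rss,
)

DEFAULT_RSS_TOLERANCE = 50
DEFAULT_MIN_DELETION = 100

EVENT_CLASSES = (
    "canonical", "partial_DJ", "partial_VD", "multi_D",
    "inversion_J", "inversion_D", "inversion_V", "double_VD",
    "unclassified",
)


@dataclasses.dataclass(frozen=True)
class SplitSegment:
    """One contiguously aligned piece of a read.

    ``read_start``/``read_end`` are in the read's original orientation;
    ``cigar`` is the record's cigartuples (record orientation) retained
    for internal-deletion scanning.
    """

    read_id: str
    reference_id: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str
    mapq: int
    read_length: int
    cigar: Optional[tuple] = None

    def overlaps(self, start: int, end: int) -> bool:
        return self.ref_start < end and start < self.ref_end


@dataclasses.dataclass(frozen=True)
class Anchor:
    """A junction side attributed to its nearest RSS."""

    gene: str
    gene_class: SegmentClass
    side: str          # "5p" / "3p"
    coord: int         # the RSS coordinate
    distance: int      # |breakpoint - RSS|


@dataclasses.dataclass(frozen=True)
class Junction:
    """Adjacency between two segments, or a long internal deletion.

    Anchors are stored in reference order (``left.coord <= right.coord``),
    which makes junction identity independent of read orientation.
    """

    left: Anchor
    right: Anchor
    kind: str                   # "split" | "internal_deletion"
    orientation_change: bool
    read_id: str
    read_breakpoint: int        # read coordinate, original orientation
    confident: bool
    deletion_length: Optional[int] = None

    def key(self) -> tuple:
        return (self.left.gene, self.left.side, self.right.gene,
                self.right.side, self.orientation_change)


# ---------------------------------------------------------------------------
# Alignment ingestion

_REF_CONSUMING = {0, 2, 3, 7, 8}     # M, D, N, =, X
_QUERY_CONSUMING = {0, 1, 4, 7, 8}   # M, I, S, =, X


def _segment_from_record(rec, reference_id: str) -> Optional[SplitSegment]:
    if rec.is_unmapped:
        return None
    if rec.cigartuples is None:
        warnings.warn(f"{rec.query_name}: missing CIGAR, record skipped")
        return None
    lead = trail = aligned = 0
    seen_aligned = False
    for op, ln in rec.cigartuples:
        if op in (4, 5):  # S, H
            if seen_aligned:
                trail += ln
            else:
                lead += ln
        elif op in _QUERY_CONSUMING:
            aligned += ln
            seen_aligned = True
    read_len = lead + aligned + trail
    if rec.is_reverse:
        read_start, read_end = trail, trail + aligned
    else:
        read_start, read_end = lead, lead + aligned
    return SplitSegment(
        read_id=rec.query_name,
        reference_id=reference_id,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        read_start=read_start,
        read_end=read_end,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        read_length=read_len,
        cigar=tuple(rec.cigartuples),
    )


def extract_igh_alignments(
    alignments: Iterable,
    annotation: LocusAnnotation,
    flank: int = 0,
    min_mapq: int = 0,
    reference_id: Optional[str] = None,
) -> Dict[str, List[SplitSegment]]:
    """Collect per-read segment groups overlapping the J-to-D span.

    ``alignments`` is an iterable of pysam records (or a SAM/BAM path).
    Primary and supplementary records are merged per read and sorted by
    read coordinate; secondary records are skipped.  A read is kept iff at
    least one of its segments overlaps ``annotation.jd_interval`` extended
    by ``flank`` — split alignments caused by V-locus structural variation
    therefore fall outside the analysis.
    """
    import pysam

    close = None
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        close = pysam.AlignmentFile(str(alignments), check_sq=False)
        records = close.fetch(until_eof=True)
    else:
        records = alignments
    rid = reference_id or annotation.reference_id

    groups: Dict[str, List[SplitSegment]] = defaultdict(list)
    try:
        for rec in records:
            if rec.is_secondary:
                continue
            seg = _segment_from_record(rec, rid)
            if seg is None or seg.mapq < min_mapq:
                continue
            groups[seg.read_id].append(seg)
    finally:
        if close is not None:
            close.close()

    jd_start, jd_end = annotation.jd_interval
    lo, hi = jd_start - flank, jd_end + flank
    out: Dict[str, List[SplitSegment]] = {}
    for read_id, segs in groups.items():
        if any(s.overlaps(lo, hi) for s in segs):
            out[read_id] = sorted(segs, key=lambda s: (s.read_start, s.read_end))
    return out


# ---------------------------------------------------------------------------
# Junction construction


def _anchor(annotation: LocusAnnotation, pos: int) -> Anchor:
    gene, side, dist = nearest_rss(annotation, pos, "any")
    return Anchor(gene.name, gene.segment_class, side, gene.rss(side), dist)


def _ordered(a: Anchor, b: Anchor) -> Tuple[Anchor, Anchor]:
    return (a, b) if (a.coord, a.gene) <= (b.coord, b.gene) else (b, a)


def junctions_from_segments(
    segments: Sequence[SplitSegment],
    annotation: LocusAnnotation,
    tolerance: int = DEFAULT_RSS_TOLERANCE,
) -> List[Junction]:
    """One junction per adjacent (read-coordinate sorted) segment pair.

    Each side is anchored to its nearest RSS; the junction is confident
    iff both anchor distances are within ``tolerance`` (inclusive).
    """
    out = []
    for a, b in zip(segments, segments[1:]):
        left_edge = a.ref_end if a.strand == "+" else a.ref_start
        right_edge = b.ref_start if b.strand == "+" else b.ref_end
        an_l = _anchor(annotation, left_edge)
        an_r = _anchor(annotation, right_edge)
        lo, hi = _ordered(an_l, an_r)
        out.append(Junction(
            left=lo,
            right=hi,
            kind="split",
            orientation_change=a.strand != b.strand,
            read_id=a.read_id,
            read_breakpoint=(a.read_end + b.read_start) // 2,
            confident=an_l.distance <= tolerance and an_r.distance <= tolerance,
        ))
    return out


def _facing_rss_distance(left: GeneRecord, right: GeneRecord) -> int:
    """Germline distance between the facing RSS anchors of two genes."""
    left_anchor = max(c for _, c in left.rss_positions())
    right_anchor = min(c for _, c in right.rss_positions())
    return right_anchor - left_anchor


def junctions_from_deletions(
    segment: SplitSegment,
    annotation: LocusAnnotation,
    min_deletion: int = DEFAULT_MIN_DELETION,
    tolerance: int = DEFAULT_RSS_TOLERANCE,
) -> List[Junction]:
    """Junctions for long deletions inside one aligned segment.

    A deletion spanning two D genes is confident iff its length matches
    the germline distance between the two genes' facing RSS anchors
    within ``tolerance`` — the aligner may slide the gap within the
    repetitive D locus, so the anchor-proximity rule is relaxed to a
    length rule.  Deletions not flanked by two distinct D genes fall back
    to the standard anchor-distance rule.
    """
    if segment.cigar is None:
        return []
    out = []
    ref = segment.ref_start
    # query position in the read's original orientation
    q = segment.read_start if segment.strand == "+" else segment.read_end
    sign = 1 if segment.strand == "+" else -1
    for op, ln in segment.cigar:
        if op in (4, 5):
            continue
        if op in (0, 7, 8):  # M, =, X
            ref += ln
            q += sign * ln
        elif op == 1:        # I
            q += sign * ln
        elif op in (2, 3):   # D, N
            if ln >= min_deletion:
                an_l = _anchor(annotation, ref)
                an_r = _anchor(annotation, ref + ln)
                gl = annotation.gene(an_l.gene)
                gr = annotation.gene(an_r.gene)
                if (gl.segment_class is SegmentClass.D
                        and gr.segment_class is SegmentClass.D
                        and gl.name != gr.name):
                    expected = _facing_rss_distance(gl, gr)
                    confident = abs(ln - expected) <= tolerance
                else:
                    confident = (an_l.distance <= tolerance
                                 and an_r.distance <= tolerance)
                lo, hi = _ordered(an_l, an_r)
                out.append(Junction(
                    left=lo, right=hi,
                    kind="internal_deletion",
                    orientation_change=False,
                    read_id=segment.read_id,
                    read_breakpoint=q,
                    confident=confident,
                    deletion_length=ln,
                ))
            ref += ln
    return out


def read_junction_chain(
    segments: Sequence[SplitSegment],
    annotation: LocusAnnotation,
    tolerance: int = DEFAULT_RSS_TOLERANCE,
    min_deletion: int = DEFAULT_MIN_DELETION,
) -> List[Junction]:
    """All junctions of one read (splits + internal deletions), in a
    deterministic reference-order chain."""
    juncs = junctions_from_segments(segments, annotation, tolerance)
    for seg in segments:
        juncs.extend(
            junctions_from_deletions(seg, annotation, min_deletion, tolerance)
        )
    juncs.sort(key=lambda j: (j.left.coord, j.right.coord, j.kind))
    return juncs


# ---------------------------------------------------------------------------
# Multi-reference selection


def select_best_reference(
    junction_sets: Mapping[str, Optional[Sequence[Junction]]],
    panel: ReferencePanel,
) -> Tuple[str, List[Junction]]:
    """Pick the panel reference whose alignment best fits its annotation.

    References are ranked by (confident-junction count desc, total anchor
    distance asc, panel priority); a reference the read is absent from
    ranks last.  Deterministic under input reordering.
    """
    best_key, best = None, None
    for entry in panel:
        juncs = junction_sets.get(entry.reference_id)
        if juncs is None:
            key = (1, 0, 0, panel.priority_rank(entry.reference_id))
        else:
            n_conf = sum(1 for j in juncs if j.confident)
            total = sum(j.left.distance + j.right.distance for j in juncs)
            key = (0, -n_conf, total, panel.priority_rank(entry.reference_id))
        if best_key is None or key < best_key:
            best_key = key
            best = (entry.reference_id, list(juncs) if juncs else [])
    if best is None:
        raise ValueError("empty reference panel")
    return best


# ---------------------------------------------------------------------------
# Event classification


def _pair(j: Junction) -> Tuple[Tuple[SegmentClass, str], Tuple[SegmentClass, str]]:
    return ((j.left.gene_class, j.left.side), (j.right.gene_class, j.right.side))


def _classes(j: Junction) -> frozenset:
    return frozenset((j.left.gene_class, j.right.gene_class))


_J, _D, _V = SegmentClass.J, SegmentClass.D, SegmentClass.V


def classify_event(chain: Sequence[Junction]) -> str:
    """Assign an event class to a gene-anchored junction chain.

    The chain must be normalized to reference order (as produced by
    :func:`read_junction_chain`).  Precedence among inversion patterns and
    the double V-D pattern follows the specificity of their signatures:
    same-class inversions first, then double V-D (two V-D joints entering
    consecutive D genes via 3' and 5' RSSs with no J), then V inversion
    (D 5' RSS joined to an inverted V 3' flank).
    """
    if not chain:
        raise ValueError("cannot classify an empty junction chain")

    flips = [j for j in chain if j.orientation_change]
    d_genes = {a.gene for j in chain for a in (j.left, j.right)
               if a.gene_class is _D}
    has_j = any(a.gene_class is _J for j in chain for a in (j.left, j.right))
    vd = [j for j in chain if _classes(j) == frozenset({_D, _V})]

    if flips:
        if any(_classes(j) == frozenset({_J}) for j in flips):
            return "inversion_J"
        if any(_classes(j) == frozenset({_D}) for j in flips):
            return "inversion_D"
        if not has_j and len(vd) >= 2 and len(d_genes) >= 2:
            sides = {a.side for j in vd for a in (j.left, j.right)
                     if a.gene_class is _D}
            if sides == {"5p", "3p"}:
                return "double_VD"
        if any((j.left.gene_class, j.left.side) == (_D, "5p")
               and j.right.gene_class is _V for j in flips):
            return "inversion_V"
        return "unclassified"

    if len(chain) == 1:
        (lc, ls), (rc, rs) = _pair(chain[0])
        if (lc, ls, rc, rs) == (_J, "5p", _V, "3p"):
            return "canonical"
        if (lc, ls, rc, rs) == (_J, "5p", _D, "3p"):
            return "partial_DJ"
        if (lc, ls, rc, rs) == (_D, "5p", _V, "3p"):
            return "partial_VD"
        if (lc, rc) == (_D, _D) and chain[0].left.gene != chain[0].right.gene:
            return "multi_D"
        return "unclassified"

    if not has_j and len(vd) >= 2 and len(d_genes) >= 2:
        sides = {a.side for j in vd for a in (j.left, j.right)
                 if a.gene_class is _D}
        if sides == {"5p", "3p"}:
            return "double_VD"
    if has_j and len(d_genes) >= 1:
        allowed = ({_J, _D}, {_D}, {_D, _V})
        if all(set(_classes(j)) in allowed for j in chain):
            return "multi_D" if len(d_genes) >= 2 else "unclassified"
    return "unclassified"


# ---------------------------------------------------------------------------
# Event grouping and sample profile


@dataclasses.dataclass
class RecombinationEvent:
    """A deduplicated recombination event with its supporting reads."""

    chain: Tuple[tuple, ...]           # normalized junction keys
    event_class: str
    supporting_read_ids: frozenset
    junctions: Tuple[Junction, ...]    # representative chain
    confident: bool

    @property
    def n_reads(self) -> int:
        return len(self.supporting_read_ids)


@dataclasses.dataclass
class EventProfile:
    """Per-sample event summary with clonality."""

    sample_id: str
    events: List[RecombinationEvent]
    n_supporting_reads: int            # reads in confident events
    simpson_index: Optional[float]
    clonality_class: Optional[str]

    def confident_events(self) -> List[RecombinationEvent]:
        return [e for e in self.events if e.confident]


def simpson_index(counts: Sequence[int]) -> float:
    """SI = sum(n_i^2) / N^2 over per-event read counts; in (0, 1]."""
    if not counts:
        raise ValueError("Simpson's index of an empty profile is undefined")
    if any(n <= 0 for n in counts):
        raise ValueError("event read counts must be positive")
    n_total = sum(counts)
    return sum(n * n for n in counts) / (n_total * n_total)


def clonality_class(si: float) -> str:
    """monoclonal (SI > 0.25), polyclonal (SI < 0.125), else in-between.

    Both thresholds are strict, so the boundary values fall in between.
    """
    if not (0 < si <= 1):
        raise ValueError(f"Simpson's index out of range: {si}")
    if si > 0.25:
        return "monoclonal"
    if si < 0.125:
        return "polyclonal"
    return "in_between"


def group_events(
    read_chains: Mapping[str, Sequence[Junction]],
    sample_id: str = "sample",
) -> EventProfile:
    """Merge reads with identical normalized junction chains into events.

    A read contributes confident evidence when every junction of its
    chain is confident; an event is confident when at least one of its
    supporting reads does.  Simpson's index and its read total N are
    computed over reads of confident events only, so that clonality rests
    on the same evidence as gene usage.
    """
    by_key: Dict[tuple, dict] = {}
    for read_id, chain in read_chains.items():
        if not chain:
            continue
        key = tuple(j.key() for j in chain)
        slot = by_key.setdefault(key, {"reads": set(), "confident": False,
                                       "chain": tuple(chain)})
        slot["reads"].add(read_id)
        if all(j.confident for j in chain):
            slot["confident"] = True

    events = []
    for key in sorted(by_key):
        slot = by_key[key]
        events.append(RecombinationEvent(
            chain=key,
            event_class=classify_event(slot["chain"]),
            supporting_read_ids=frozenset(slot["reads"]),
            junctions=slot["chain"],
            confident=slot["confident"],
        ))

    counts = [e.n_reads for e in events if e.confident]
    n_total = sum(counts)
    si = simpson_index(counts) if counts else None
    return EventProfile(
        sample_id=sample_id,
        events=events,
        n_supporting_reads=n_total,
        simpson_index=si,
        clonality_class=clonality_class(si) if si is not None else None,
    )


# ---------------------------------------------------------------------------
# Gene usage


def _first_jd_pair(event: RecombinationEvent) -> Optional[Tuple[str, str]]:
    for j in event.junctions:
        cls = {j.left.gene_class, j.right.gene_class}
        if cls == {_J, _D}:
            jg = j.left.gene if j.left.gene_class is _J else j.right.gene
            dg = j.left.gene if j.left.gene_class is _D else j.right.gene
            return jg, dg
    return None


def gene_usage(profiles: Sequence[EventProfile]):
    """J x V and J x D event-count matrices across samples.

    Canonical events increment (J, V); non-canonical events increment
    (J, D) using the first D-J gene pair of the chain (events without a
    J-D pair, e.g. pure inversions or double V-D, contribute to neither).
    Each event counts once per sample.
    """
    import pandas as pd

    jv: Dict[Tuple[str, str], int] = defaultdict(int)
    jd: Dict[Tuple[str, str], int] = defaultdict(int)
    for profile in profiles:
        for event in profile.confident_events():
            if event.event_class == "canonical":
                j = event.junctions[0]
                jg = j.left.gene if j.left.gene_class is _J else j.right.gene
                vg = j.left.gene if j.left.gene_class is _V else j.right.gene
                jv[(jg, vg)] += 1
            else:
                pair = _first_jd_pair(event)
                if pair is not None:
                    jd[pair] += 1

    def to_frame(d):
        if not d:
            return pd.DataFrame()
        rows = sorted({k[0] for k in d})
        cols = sorted({k[1] for k in d})
        df = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
        for (r, c), n in d.items():
            df.loc[r, c] = n
        return df

    return to_frame(jv), to_frame(jd)


def class_percentages(counts: Mapping[str, int]) -> Dict[str, int]:
    """Percent of events per class, rounded to whole percent."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0 for k in counts}
    return {k: round(100 * v / total) for k, v in counts.items()}


# ---------------------------------------------------------------------------
# Orchestration


def profile_sample(
    alignment_sets: Mapping[str, object],
    panel: ReferencePanel,
    sample_id: str = "sample",
    tolerance: int = DEFAULT_RSS_TOLERANCE,
    min_deletion: int = DEFAULT_MIN_DELETION,
    flank: int = 0,
    min_mapq: int = 0,
) -> Tuple[EventProfile, Dict[str, List[Junction]], Dict[str, str]]:
    """Full read-profiling pass for one sample.

    ``alignment_sets`` maps reference id -> SAM/BAM path (or record
    iterable) of the sample's reads aligned against that reference.  For
    every read the best-fitting reference is selected, then events are
    grouped and clonality computed.

    Returns ``(profile, best_chain_per_read, best_reference_per_read)``.
    """
    per_ref: Dict[str, Dict[str, List[Junction]]] = {}
    for entry in panel:
        src = alignment_sets.get(entry.reference_id)
        if src is None:
            continue
        groups = extract_igh_alignments(
            src, entry.annotation, flank=flank, min_mapq=min_mapq,
            reference_id=entry.reference_id,
        )
        per_ref[entry.reference_id] = {
            rid: read_junction_chain(segs, entry.annotation, tolerance,
                                     min_deletion)
            for rid, segs in groups.items()
        }

    all_reads = sorted({r for chains in per_ref.values() for r in chains})
    best_chains: Dict[str, List[Junction]] = {}
    best_ref: Dict[str, str] = {}
    for rid in all_reads:
        sets = {ref: chains.get(rid) for ref, chains in per_ref.items()}
        ref_id, chain = select_best_reference(sets, panel)
        best_ref[rid] = ref_id
        if chain:
            best_chains[rid] = chain

    profile = group_events(best_chains, sample_id)
    return profile, best_chains, best_ref
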