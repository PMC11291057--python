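"""Read preprocessing ahead of reassembly: split somatic reads, enrich J-D.

Reads carrying somatic V(D)J junctions are split at the junction read
coordinates so that somatic-haplotype evidence cannot seed contigs, while
the germline portions of each read survive.  Junctions between two V
genes are exempt — a non-reference V-V adjacency is potential germline
structural variation, not somatic recombination.  Splitting partitions
the read exactly: no base is lost or duplicated.

Recombination also depletes germline coverage between the J and D genes,
so any processed read overlapping that interval is duplicated once
(``{id}/dup``), roughly doubling local depth and giving the assembler a
stronger germline signal there.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .locus_model import SegmentClass
from .read_profiler import Junction, SplitSegment


@dataclasses.dataclass
class ProcessedRead:
    name: str
    sequence: str
    source_read: str
    read_interval: Tuple[int, int]   # interval of the source read


def qualifying_breakpoints(
    junctions: Sequence[Junction],
    read_length: int,
) -> List[int]:
    """Read coordinates at which to cut.

    A junction qualifies when it is confident (both anchors at RSSs) and
    is not a V-V adjacency.  Unconfident junctions never cut: destroying
    a read over an unanchored joint risks erasing germline SV evidence.
    """
    cuts = []
    for j in junctions:
        if not j.confident:
            continue
        if (j.left.gene_class is SegmentClass.V
                and j.right.gene_class is SegmentClass.V):
            continue
        bp = j.read_breakpoint
        if not (0 <= bp <= read_length):
            raise ValueError(
                f"{j.read_id}: breakpoint {bp} outside read of length "
                f"{read_length}"
            )
        if 0 < bp < read_length:
            cuts.append(bp)
    return sorted(set(cuts))


def split_reads(
    reads: Mapping[str, str],
    junctions_per_read: Mapping[str, Sequence[Junction]],
) -> List[ProcessedRead]:
    """Partition each read at its qualifying junction breakpoints.

    A read with k qualifying junctions becomes k+1 subreads named
    ``{read_id}/part{i}`` (i from 1); reads without qualifying junctions
    pass through unchanged.  The concatenation of a read's subreads
    equals the original sequence.
    """
    out = []
    for read_id, seq in reads.items():
        cuts = qualifying_breakpoints(
            junctions_per_read.get(read_id, ()), len(seq)
        )
        if not cuts:
            out.append(ProcessedRead(read_id, seq, read_id, (0, len(seq))))
            continue
        bounds = [0] + cuts + [len(seq)]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:]), start=1):
            out.append(ProcessedRead(
                f"{read_id}/part{i}", seq[a:b], read_id, (a, b)
            ))
    return out


def subread_placements(
    segments: Sequence[SplitSegment],
    read_interval: Tuple[int, int],
) -> List[Tuple[int, int]]:
    """Reference intervals covered by a slice of a read.

    Each alignment segment overlapping the slice contributes its
    proportionally clipped reference interval (colinear approximation —
    placement only needs interval overlap, not base accuracy).
    """
    a, b = read_interval
    out = []
    for s in segments:
        lo, hi = max(a, s.read_start), min(b, s.read_end)
        if lo >= hi:
            continue
        if s.strand == "+":
            out.append((s.ref_start + (lo - s.read_start),
                        s.ref_start + (hi - s.read_start)))
        else:
            out.append((s.ref_end - (hi - s.read_start),
                        s.ref_end - (lo - s.read_start)))
    return out


class EnrichmentError(RuntimeError):
    pass


def enrich_jd(
    reads: Sequence[ProcessedRead],
    placements: Mapping[str, Sequence[Tuple[int, int]]],
    jd_interval: Tuple[int, int],
    flank: int = 0,
    min_overlap_fraction: Optional[float] = None,
) -> List[ProcessedRead]:
    """Duplicate every read overlapping the J-to-D interval once.

    The copy is named ``{id}/dup`` and emitted right after its source, so
    output order is deterministic.  By default any overlap qualifies;
    ``min_overlap_fraction`` optionally requires that fraction of the
    read to lie inside the interval.  Re-running on already-enriched
    input is refused (duplicate-name guard).
    """
    if any(r.name.endswith("/dup") for r in reads):
        raise EnrichmentError("input already contains /dup reads; "
                              "enrichment is not idempotent by design")
    lo, hi = jd_interval[0] - flank, jd_interval[1] + flank
    out = []
    for r in reads:
        out.append(r)
        ivals = placements.get(r.name, ())
        ov = sum(max(0, min(e, hi) - max(s, lo)) for s, e in ivals)
        if ov <= 0:
            continue
        if min_overlap_fraction is not None and ov < min_overlap_fraction * len(
            r.sequence
        ):
            continue
        out.append(dataclasses.replace(r, name=r.name + "/dup"))
    return out


def preprocess_sample(
    reads: Mapping[str, str],
    chains: Mapping[str, Sequence[Junction]],
    segments_per_read: Mapping[str, Sequence[SplitSegment]],
    jd_interval: Tuple[int, int],
    flank: int = 0,
) -> Tuple[List[ProcessedRead], List[dict]]:
    """Split + enrich in one pass; returns reads and a manifest.

    The manifest maps every output read to its source read and interval.
    """
    processed = split_reads(reads, chains)
    placements = {
        r.name: subread_placements(
            segments_per_read.get(r.source_read, ()), r.read_interval
        )
        for r in processed
    }
    enriched = enrich_jd(processed, placements, jd_interval, flank=flank)
    manifest = [
        {
            "name": r.name,
            "source_read": r.source_read,
            "read_start": r.read_interval[0],
            "read_end": r.read_interval[1],
            "length": len(r.sequence),
        }
        for r in enriched
    ]
    return enriched, manifest
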