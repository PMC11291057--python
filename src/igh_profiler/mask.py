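"""Final assembly cleanup: drop reference-only contigs, hard-mask
unsupported sequence.

Reference-guided assembly patches gaps with guide-reference sequence, so
the output can contain stretches never seen in the sample's reads or de
novo contigs.  Two filters remove that material:

* contigs with no de novo contig alignment of at least
  ``min_support_length`` (default 1 kb) are discarded entirely;
* remaining positions with zero read-alignment depth are replaced by
  ``N`` (sequence length is conserved and the masked intervals are
  reported as BED).

Depth follows ``samtools depth -a -g 0x100 -J`` semantics: every
position is evaluated, secondary alignments are included, and positions
inside a read's deletion count as covered.  Duplicate/QC-fail records
are excluded as samtools does by default.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np


class MaskError(ValueError):
    pass


def support_from_alignments(sam_path, min_support_length: int = 1000
                            ) -> Dict[str, int]:
    """Longest primary-alignment span per target contig.

    Secondary and supplementary records do not count as support; any
    primary alignment spanning at least ``min_support_length`` reference
    bases marks the target contig as supported.
    """
    import pysam

    spans: Dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            span = rec.reference_end - rec.reference_start
            name = rec.reference_name
            spans[name] = max(spans.get(name, 0), span)
    return {k: v for k, v in spans.items() if v >= min_support_length}


def drop_unsupported_contigs(
    assembly: Mapping[str, str],
    denovo: Mapping[str, str],
    workdir,
    min_support_length: int = 1000,
    aligner=None,
) -> Tuple[Dict[str, str], List[str]]:
    """Remove assembly contigs not supported by any de novo contig.

    De novo contigs are aligned to the assembly (minimap2 asm preset by
    default; inject ``aligner(reference_fa, query_fa, out_sam)`` to
    substitute).  Returns (retained contigs, dropped contig names).  An
    empty de novo set drops everything, with a warning.
    """
    from ._util import write_fasta

    if not denovo:
        warnings.warn("empty de novo contig set: all contigs dropped")
        return {}, sorted(assembly)

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ref_fa = workdir / "final_assembly.fa"
    qry_fa = workdir / "denovo_contigs.fa"
    out_sam = workdir / "support.sam"
    write_fasta(sorted(assembly.items()), ref_fa)
    write_fasta(sorted(denovo.items()), qry_fa)

    if aligner is None:
        from .adapters import minimap2_align

        def aligner(ref, qry, out):
            return minimap2_align(ref, qry, out, preset="asm5")

    aligner(ref_fa, qry_fa, out_sam)
    supported = support_from_alignments(out_sam, min_support_length)
    kept = {k: v for k, v in assembly.items() if k in supported}
    dropped = sorted(set(assembly) - set(kept))
    return kept, dropped


def depth_profile(assembly: Mapping[str, str], sam_path) -> Dict[str, np.ndarray]:
    """Per-position depth with deletion-spanning, secondary-inclusive
    semantics (see module docstring)."""
    import pysam

    depth = {name: np.zeros(len(seq), dtype=np.int32)
             for name, seq in assembly.items()}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_duplicate or rec.is_qcfail:
                continue
            name = rec.reference_name
            if name not in depth:
                raise MaskError(
                    f"alignment target {name!r} not present in assembly"
                )
            arr = depth[name]
            ref = rec.reference_start
            for op, ln in rec.cigartuples:
                if op in (0, 2, 7, 8):   # M, D, =, X cover the reference
                    arr[ref:ref + ln] += 1
                    ref += ln
                elif op == 3:            # N: spliced skip, not covered
                    ref += ln
    return depth


def mask_zero_coverage(
    assembly: Mapping[str, str],
    sam_path,
) -> Tuple[Dict[str, str], List[Tuple[str, int, int]]]:
    """Replace zero-depth positions with 'N'.

    Returns the masked contigs (lengths unchanged) and the masked
    intervals as (contig, start, end) BED rows.  Idempotent: masked
    bases stay masked.
    """
    depth = depth_profile(assembly, sam_path)
    masked: Dict[str, str] = {}
    bed: List[Tuple[str, int, int]] = []
    for name in assembly:
        seq = np.frombuffer(assembly[name].upper().encode(), dtype="S1").copy()
        zero = depth[name] == 0
        seq[zero] = b"N"
        masked[name] = seq.tobytes().decode()
        # contiguous zero runs -> BED intervals
        idx = np.flatnonzero(zero)
        if idx.size:
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate(([idx[0]], idx[breaks + 1]))
            ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
            bed.extend((name, int(s), int(e)) for s, e in zip(starts, ends))
    return masked, bed


def write_bed(intervals: Sequence[Tuple[str, int, int]], path) -> None:
    from ._util import atomic_open

    with atomic_open(path) as fh:
        for name, s, e in intervals:
            fh.write(f"{name}\t{s}\t{e}\n")
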