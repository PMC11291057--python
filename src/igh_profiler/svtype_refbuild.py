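"""Genotype common IGH structural variants from contigs and build a
personalized reference.

Seven common structural variants (SVs) segregate in the IGH locus; six
are deletions and one is a complex two-haplotype region where each
haplotype carries its own unique genes.  A de novo contig supports a
deletion when it carries the genes flanking both ends but none of the
interior genes; carrying any interior gene means the non-deleted allele;
a contig not covering the region is "unknown".  The complex SV is typed
by which haplotype's unique genes the contig carries — none or both
means "unknown".

Because assembler phasing occasionally places a contig in the wrong
parental group, allele calls within a group can contradict each other.
Reconciliation tries to restore per-group consistency by swapping
conflicting contigs between the paternal and maternal groups (greedy,
with exhaustive search as fallback for small contig sets); if no
assignment is consistent the conflict is reported for manual action.

The personalized reference is then stitched per haplotype: a backbone
sequence is copied and, for every SV whose called allele differs from
the backbone's, the span between the SV's anchor genes is replaced by a
donor allele sequence; provenance of every output interval is recorded.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import yaml

from .asm_profiler import ContigAnnotation
from .locus_model import LocusAnnotation

ALLELES = ("deleted", "present", "hapA", "hapB", "unknown")


@dataclasses.dataclass(frozen=True)
class SVDefinition:
    sv_id: int
    description: str
    left_anchor: str
    right_anchor: str
    interior: frozenset = frozenset()
    hap_a: frozenset = frozenset()
    hap_b: frozenset = frozenset()

    @property
    def is_complex(self) -> bool:
        return bool(self.hap_a or self.hap_b)

    def __post_init__(self):
        overlap = (self.interior | self.hap_a | self.hap_b) & {
            self.left_anchor, self.right_anchor
        }
        if overlap:
            raise ValueError(
                f"sv{self.sv_id}: anchors overlap interior genes: {overlap}"
            )


@dataclasses.dataclass(frozen=True)
class SVAlleleCall:
    sv_id: int
    contig_id: str
    allele: str

    def __post_init__(self):
        if self.allele not in ALLELES:
            raise ValueError(f"unknown allele type {self.allele!r}")


def load_sv_definitions(path=None) -> List[SVDefinition]:
    """Load SV definitions from YAML; defaults to the bundled catalog of
    the seven common IGH SVs."""
    if path is None:
        path = Path(__file__).parent / "data" / "sv_common.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = []
    for item in raw["svs"]:
        out.append(SVDefinition(
            sv_id=int(item["sv_id"]),
            description=item.get("description", ""),
            left_anchor=item["left_anchor"],
            right_anchor=item["right_anchor"],
            interior=frozenset(item.get("interior", [])),
            hap_a=frozenset(item.get("hap_a", [])),
            hap_b=frozenset(item.get("hap_b", [])),
        ))
    return out


def genotype_sv(annotation: ContigAnnotation, sv: SVDefinition) -> SVAlleleCall:
    """Allele call of one SV on one contig (see module docstring)."""
    genes: Set[str] = set(annotation.gene_names())
    if sv.is_complex:
        a = genes & sv.hap_a
        b = genes & sv.hap_b
        if a and not b:
            allele = "hapA"
        elif b and not a:
            allele = "hapB"
        else:
            allele = "unknown"
    else:
        if genes & sv.interior:
            allele = "present"
        elif sv.left_anchor in genes and sv.right_anchor in genes:
            allele = "deleted"
        else:
            allele = "unknown"
    return SVAlleleCall(sv.sv_id, annotation.contig_id, allele)


def genotype_contigs(
    annotations: Mapping[str, ContigAnnotation],
    svs: Sequence[SVDefinition],
) -> Dict[str, List[SVAlleleCall]]:
    return {
        cid: [genotype_sv(ann, sv) for sv in svs]
        for cid, ann in annotations.items()
        if ann.retained
    }


# ---------------------------------------------------------------------------
# Haplotype reconciliation


@dataclasses.dataclass
class ReconcileResult:
    success: bool
    paternal: List[str]
    maternal: List[str]
    moved: List[str]
    conflicts: List[dict]     # [{sv_id, group, alleles}] when failed


def _group_conflicts(
    contigs: Sequence[str],
    calls: Mapping[str, Sequence[SVAlleleCall]],
) -> List[int]:
    """SV ids with contradictory non-unknown alleles inside one group."""
    per_sv: Dict[int, Set[str]] = {}
    for cid in contigs:
        for call in calls.get(cid, ()):
            if call.allele == "unknown":
                continue
            per_sv.setdefault(call.sv_id, set()).add(call.allele)
    return sorted(sv for sv, alleles in per_sv.items() if len(alleles) > 1)


def reconcile_haplotypes(
    paternal: Sequence[str],
    maternal: Sequence[str],
    calls: Mapping[str, Sequence[SVAlleleCall]],
    n_hits: Optional[Mapping[str, int]] = None,
    exhaustive_limit: int = 10,
) -> ReconcileResult:
    """Restore per-group SV consistency by swapping contigs.

    Greedy phase: contigs involved in a conflicted SV are tried in order
    of fewest gene hits first; a move is kept when it lowers the total
    conflict count.  If conflicts remain and the total number of contigs
    is at most ``exhaustive_limit``, all group assignments are searched
    and the one with the fewest moves (ties: lexicographic) wins.
    Failure returns the conflicting SVs and their allele sets.
    """
    pat, mat = list(paternal), list(maternal)
    n_hits = n_hits or {}
    moved: List[str] = []

    def total_conflicts(p, m):
        return len(_group_conflicts(p, calls)) + len(_group_conflicts(m, calls))

    # greedy swapping
    for _ in range(len(pat) + len(mat)):
        base = total_conflicts(pat, mat)
        if base == 0:
            break
        conflicted_svs = set(_group_conflicts(pat, calls)) | set(
            _group_conflicts(mat, calls)
        )
        candidates = [
            cid for cid in pat + mat
            if any(c.sv_id in conflicted_svs and c.allele != "unknown"
                   for c in calls.get(cid, ()))
        ]
        candidates.sort(key=lambda c: (n_hits.get(c, 0), c))
        improved = False
        for cid in candidates:
            if cid in pat:
                p2, m2 = [x for x in pat if x != cid], mat + [cid]
            else:
                p2, m2 = pat + [cid], [x for x in mat if x != cid]
            if total_conflicts(p2, m2) < base:
                pat, mat = p2, m2
                moved.append(cid)
                improved = True
                break
        if not improved:
            break

    if total_conflicts(pat, mat) == 0:
        return ReconcileResult(True, sorted(pat), sorted(mat), moved, [])

    # exhaustive fallback
    contigs = sorted(paternal) + sorted(maternal)
    if len(contigs) <= exhaustive_limit:
        orig = {c: ("P" if c in set(paternal) else "M") for c in contigs}
        best = None
        for assign in itertools.product("PM", repeat=len(contigs)):
            p = [c for c, g in zip(contigs, assign) if g == "P"]
            m = [c for c, g in zip(contigs, assign) if g == "M"]
            if total_conflicts(p, m):
                continue
            n_moved = sum(1 for c, g in zip(contigs, assign) if orig[c] != g)
            key = (n_moved, assign)
            if best is None or key < best[0]:
                best = (key, p, m,
                        [c for c, g in zip(contigs, assign) if orig[c] != g])
        if best is not None:
            _, p, m, mv = best
            return ReconcileResult(True, sorted(p), sorted(m), mv, [])

    conflicts = []
    for group_name, group in (("paternal", pat), ("maternal", mat)):
        for sv in _group_conflicts(group, calls):
            alleles = sorted({
                c.allele for cid in group for c in calls.get(cid, ())
                if c.sv_id == sv and c.allele != "unknown"
            })
            conflicts.append({"sv_id": sv, "group": group_name,
                              "alleles": alleles})
    return ReconcileResult(False, sorted(pat), sorted(mat), moved, conflicts)


def consensus_calls(
    group: Sequence[str],
    calls: Mapping[str, Sequence[SVAlleleCall]],
) -> Dict[int, str]:
    """Per-SV consensus allele of a consistent contig group."""
    out: Dict[int, str] = {}
    for cid in group:
        for call in calls.get(cid, ()):
            if call.allele == "unknown":
                continue
            prev = out.get(call.sv_id)
            if prev is not None and prev != call.allele:
                raise ValueError(
                    f"group inconsistent for sv{call.sv_id}: "
                    f"{prev} vs {call.allele}"
                )
            out[call.sv_id] = call.allele
    return out


# ---------------------------------------------------------------------------
# Personalized reference


@dataclasses.dataclass(frozen=True)
class DonorSegment:
    """Allele sequence spanning an SV's anchor genes.

    ``left_anchor_end`` / ``right_anchor_start`` delimit, within
    ``sequence``, the span to splice between the backbone anchors.
    """

    source_id: str
    sequence: str
    left_anchor_end: int
    right_anchor_start: int

    def insert(self) -> str:
        return self.sequence[self.left_anchor_end:self.right_anchor_start]


class BuildError(RuntimeError):
    pass


@dataclasses.dataclass
class PersonalizedReference:
    haplotype: str
    sequence: str
    provenance: List[Tuple[int, int, str]]   # (start, end, source_id) tiles

    def validate(self) -> None:
        pos = 0
        for s, e, _ in self.provenance:
            if s != pos or e < s:
                raise BuildError("provenance tiles must tile the sequence")
            pos = e
        if pos != len(self.sequence):
            raise BuildError("provenance does not cover the full sequence")


def build_personalized_reference(
    backbone: str,
    backbone_annotation: LocusAnnotation,
    calls: Mapping[int, str],
    svs: Sequence[SVDefinition],
    donors: Mapping[Tuple[int, str], DonorSegment],
    backbone_alleles: Mapping[int, str],
    haplotype: str = "haplotype",
) -> PersonalizedReference:
    """Stitch a per-haplotype reference from backbone + donor alleles.

    For every SV whose called allele differs from the backbone's, the
    backbone span between the anchor genes (end of left anchor gene to
    start of right anchor gene; the anchors themselves always remain) is
    replaced by the donor allele's corresponding span.  Unknown calls
    keep the backbone.  A called allele without a donor raises
    :class:`BuildError` naming the SV.
    """
    jobs = []
    for sv in sorted(svs, key=lambda s: s.sv_id):
        allele = calls.get(sv.sv_id, "unknown")
        if allele == "unknown" or allele == backbone_alleles.get(sv.sv_id):
            continue
        donor = donors.get((sv.sv_id, allele))
        if donor is None:
            raise BuildError(
                f"no donor sequence for sv{sv.sv_id} allele {allele!r}"
            )
        left = backbone_annotation.gene(sv.left_anchor)
        right = backbone_annotation.gene(sv.right_anchor)
        if left.end > right.start:
            raise BuildError(f"sv{sv.sv_id}: anchors out of order on backbone")
        jobs.append((left.end, right.start, donor))
    jobs.sort()
    for (_, e1, _), (s2, _, _) in zip(jobs, jobs[1:]):
        if s2 < e1:
            raise BuildError("overlapping SV replacement intervals")

    parts: List[str] = []
    prov: List[Tuple[int, int, str]] = []
    cur = 0
    out_pos = 0

    def emit(seq: str, source: str) -> None:
        nonlocal out_pos
        if not seq:
            return
        parts.append(seq)
        prov.append((out_pos, out_pos + len(seq), source))
        out_pos += len(seq)

    for start, end, donor in jobs:
        emit(backbone[cur:start], "backbone")
        emit(donor.insert(), donor.source_id)
        cur = end
    emit(backbone[cur:], "backbone")

    ref = PersonalizedReference(haplotype, "".join(parts), prov)
    ref.validate()
    return ref


# ---------------------------------------------------------------------------
# Report I/O


def write_calls(calls: Mapping[str, Sequence[SVAlleleCall]], path) -> None:
    from ._util import atomic_open

    with atomic_open(path) as fh:
        fh.write("#contig\tsv_id\tallele\n")
        for cid in sorted(calls):
            for call in calls[cid]:
                fh.write(f"{cid}\t{call.sv_id}\t{call.allele}\n")


def write_provenance_bed(ref: PersonalizedReference, path,
                         name: Optional[str] = None) -> None:
    from ._util import atomic_open

    chrom = name or ref.haplotype
    with atomic_open(path) as fh:
        for s, e, src in ref.provenance:
            fh.write(f"{chrom}\t{s}\t{e}\t{src}\n")
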