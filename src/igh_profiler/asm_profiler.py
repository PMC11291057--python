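"""Profile the IGH locus in genome assemblies.

Annotates assembly contigs by aligning a database of documented IGH
gene/allele sequences against them (seeded banded semi-global alignment
via edlib's infix mode, iterating with masking so multi-copy genes are
all found), filters contigs that carry only orphon-like hits (every hit
with more than ``max_mismatch`` = 15 mismatches), disambiguates the
sequence-identical duplicate gene pairs, and classifies assembly
breakpoints:

* **V(D)J breakpoints** — two genes of different segment classes sitting
  within 10 kb on one contig with germline genes missing between them:
  the contig carries a somatically recombined joint.
* **contig ends** — facing ends of adjacent contigs once contigs are
  ordered along the locus; the pair relation is *disjoint* (no shared
  genes), *overlap* (shared boundary genes) or *duplication* (one
  contig's gene set contained in the other's).

A gene inventory (V without pseudogenes, D, J) per haplotype and for the
longest contig summarizes how much of the germline locus the assembly
represents.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import edlib

from ._util import revcomp
from .locus_model import Functionality, LocusAnnotation, SegmentClass

DEFAULT_MAX_MISMATCH = 15
DEFAULT_VDJ_WINDOW = 10_000
#: hits worse than this fraction of gene length are not reported at all
DEFAULT_REPORT_FRACTION = 0.15

#: duplicate gene pairs that are sequence-identical and need positional
#: disambiguation
DUPLICATE_ELIGIBLE = ("IGHV3-23", "IGHV1-69", "IGHV2-70")


@dataclasses.dataclass
class GeneHit:
    """Best-allele alignment of a database gene on a contig."""

    contig_id: str
    gene_name: str
    allele_label: str
    start: int
    end: int
    strand: str
    mismatches: int
    orphon_like: bool = False

    @property
    def segment_class(self) -> SegmentClass:
        m = re.match(r"IGH([VDJ])", self.gene_name)
        if not m:
            raise ValueError(f"cannot infer segment class of {self.gene_name}")
        return SegmentClass(m.group(1))

    @property
    def base_name(self) -> str:
        """Gene name with any positional duplicate suffix removed."""
        for base in DUPLICATE_ELIGIBLE:
            if self.gene_name == base or re.fullmatch(
                re.escape(base) + r"D\d*", self.gene_name
            ):
                return base
        return self.gene_name


@dataclasses.dataclass
class ContigAnnotation:
    contig_id: str
    length: int
    hits: List[GeneHit]
    retained: bool = True

    def gene_names(self, retained_hits_only: bool = True) -> List[str]:
        return [h.gene_name for h in self.hits
                if not (retained_hits_only and h.orphon_like)]


@dataclasses.dataclass(frozen=True)
class Breakpoint:
    kind: str                 # "vdj" | "contig_end"
    left_gene: str
    right_gene: str
    relation: str             # disjoint | overlap | duplication | none
    contig_ids: Tuple[str, ...]


def _parse_db_name(name: str) -> Tuple[str, str]:
    if "*" in name:
        gene, allele = name.split("*", 1)
    else:
        gene, allele = name, "01"
    return gene, allele


def annotate_contigs(
    assembly: Mapping[str, str],
    gene_db: Mapping[str, str],
    report_fraction: float = DEFAULT_REPORT_FRACTION,
    max_copies: int = 8,
) -> Dict[str, ContigAnnotation]:
    """Align every database gene against every contig.

    ``gene_db`` maps ``gene*allele`` names to sequences.  For each gene
    the best-scoring allele/strand placement is reported (edit distance =
    mismatch count); found intervals are masked and the search repeated
    so additional copies up to ``max_copies`` are recovered.  Hits with
    edit distance above ``report_fraction`` of the gene length are not
    reported.  Overlapping hits of different genes are resolved to the
    lower-mismatch gene.
    """
    alleles: Dict[str, List[Tuple[str, str]]] = defaultdict(list)
    for name, seq in gene_db.items():
        gene, allele = _parse_db_name(name)
        alleles[gene].append((allele, seq.upper()))

    annotations: Dict[str, ContigAnnotation] = {}
    for contig_id, contig_seq in assembly.items():
        contig_seq = contig_seq.upper()
        hits: List[GeneHit] = []
        for gene, allele_list in alleles.items():
            k_max = int(report_fraction * max(len(s) for _, s in allele_list))
            work = contig_seq
            for _ in range(max_copies):
                best = None
                for allele, aseq in allele_list:
                    for strand, query in (("+", aseq), ("-", revcomp(aseq))):
                        res = edlib.align(query, work, mode="HW",
                                          task="locations", k=k_max)
                        ed = res["editDistance"]
                        if ed < 0:
                            continue
                        loc = min(res["locations"])
                        cand = (ed, loc[0], strand, allele)
                        if best is None or cand < best:
                            best = cand
                if best is None:
                    break
                ed, s0, strand, allele = best
                # recompute end from the chosen location
                aseq = dict(allele_list)[allele]
                query = aseq if strand == "+" else revcomp(aseq)
                res = edlib.align(query, work, mode="HW", task="locations",
                                  k=k_max)
                loc = min(res["locations"])
                start, end = loc[0], loc[1] + 1
                hits.append(GeneHit(contig_id, gene, allele, start, end,
                                    strand, ed))
                work = work[:start] + "N" * (end - start) + work[end:]
        hits = _resolve_overlaps(hits)
        hits.sort(key=lambda h: (h.start, h.end))
        annotations[contig_id] = ContigAnnotation(
            contig_id, len(contig_seq), hits
        )
    return annotations


def _resolve_overlaps(hits: List[GeneHit]) -> List[GeneHit]:
    """Drop the worse of two different-gene hits covering the same span."""
    keep = []
    for h in sorted(hits, key=lambda h: (h.mismatches, h.end - h.start)):
        clash = False
        for k in keep:
            ov = min(h.end, k.end) - max(h.start, k.start)
            if ov > 0.5 * min(h.end - h.start, k.end - k.start):
                clash = True
                break
        if not clash:
            keep.append(h)
    return keep


def filter_orphons(
    annotations: Mapping[str, ContigAnnotation],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> Dict[str, ContigAnnotation]:
    """Flag orphon-like hits and un-retain contigs carrying only those.

    A hit with more than ``max_mismatch`` mismatches against its closest
    documented allele is orphon-like (homologous copy outside the main
    locus, or a heavily diverged non-functional gene); a hit at exactly
    ``max_mismatch`` is kept.
    """
    out = {}
    for cid, ann in annotations.items():
        hits = [dataclasses.replace(h, orphon_like=h.mismatches > max_mismatch)
                for h in ann.hits]
        retained = any(not h.orphon_like for h in hits) and bool(hits)
        out[cid] = ContigAnnotation(cid, ann.length, hits, retained)
    return out


def assign_duplicate_names(
    annotation: ContigAnnotation,
    germline: Optional[LocusAnnotation] = None,
) -> ContigAnnotation:
    """Disambiguate sequence-identical duplicate genes positionally.

    When a duplicate-eligible gene has several instances on the contig,
    the copy first in locus order keeps the base name and later copies
    get a "D" suffix ("D2", "D3" ... beyond the known pair).  The
    contig's locus direction is inferred from the germline ranks of its
    hits (a reverse-complemented contig carries genes in descending
    rank); without a germline table, ascending contig coordinate is
    assumed.
    """
    flip = False
    if germline is not None:
        ranks = [r for r in (
            _germline_rank(germline, h)
            for h in sorted(annotation.hits, key=lambda h: h.start)
        ) if r is not None]
        down = sum(1 for x, y in zip(ranks, ranks[1:]) if x > y)
        up = sum(1 for x, y in zip(ranks, ranks[1:]) if x < y)
        flip = down > up
    order = sorted(
        range(len(annotation.hits)),
        key=lambda i: annotation.hits[i].start,
        reverse=flip,
    )
    new_hits = list(annotation.hits)
    for base in DUPLICATE_ELIGIBLE:
        idxs = [i for i in order if annotation.hits[i].base_name == base]
        if len(idxs) < 2:
            continue
        for rank, i in enumerate(idxs):
            if rank == 0:
                name = base
            elif rank == 1:
                name = base + "D"
            else:
                name = f"{base}D{rank}"
            new_hits[i] = dataclasses.replace(new_hits[i], gene_name=name)
    return ContigAnnotation(annotation.contig_id, annotation.length,
                            new_hits, annotation.retained)


def detect_vdj_breakpoints(
    annotation: ContigAnnotation,
    germline: LocusAnnotation,
    window: int = DEFAULT_VDJ_WINDOW,
) -> List[Breakpoint]:
    """Find somatic V(D)J joints on a contig.

    Adjacent (non-orphon) hits of different segment classes within
    ``window`` bp flag a breakpoint, provided germline genes are missing
    between them — the germline J-to-D adjacency itself sits within the
    window and must not be flagged.
    """
    if not annotation.retained:
        return []
    hits = [h for h in annotation.hits if not h.orphon_like]
    out = []
    for a, b in zip(hits, hits[1:]):
        if a.segment_class == b.segment_class:
            continue
        gap = b.start - a.end
        if gap > window:
            continue
        if _germline_genes_between(germline, a, b) == 0:
            continue
        out.append(Breakpoint("vdj", a.gene_name, b.gene_name, "none",
                              (annotation.contig_id,)))
    return out


def _germline_rank(germline: LocusAnnotation, hit: GeneHit) -> Optional[int]:
    for name in (hit.gene_name, hit.base_name):
        try:
            return germline.locus_rank(name)
        except KeyError:
            continue
    return None


def _germline_genes_between(germline: LocusAnnotation, a: GeneHit,
                            b: GeneHit) -> int:
    ra, rb = _germline_rank(germline, a), _germline_rank(germline, b)
    if ra is None or rb is None:
        return 0
    return max(0, abs(rb - ra) - 1)


def detect_contig_end_breakpoints(
    annotations: Sequence[ContigAnnotation],
    germline: LocusAnnotation,
) -> Tuple[List[Breakpoint], List[str]]:
    """Breakpoints at facing ends of adjacent contigs of one haplotype.

    Contigs are ordered by the median germline rank of their gene
    content (ties: longer contig first); contigs whose internal gene
    order conflicts with the germline order are reported separately as
    unplaceable.  Each adjacent pair yields one breakpoint whose relation
    is duplication (one gene set contained in the other), overlap
    (shared genes) or disjoint.
    """
    placed, unplaceable = [], []
    for ann in annotations:
        if not ann.retained:
            continue
        ranks = [r for r in (_germline_rank(germline, h)
                             for h in ann.hits if not h.orphon_like)
                 if r is not None]
        if not ranks:
            unplaceable.append(ann.contig_id)
            continue
        mono_up = all(x <= y for x, y in zip(ranks, ranks[1:]))
        mono_dn = all(x >= y for x, y in zip(ranks, ranks[1:]))
        if not (mono_up or mono_dn):
            unplaceable.append(ann.contig_id)
            continue
        med = sorted(ranks)[len(ranks) // 2]
        placed.append((med, -ann.length, ann))

    placed.sort(key=lambda t: t[:2])
    out = []
    for (_, _, a), (_, _, b) in zip(placed, placed[1:]):
        set_a = set(a.gene_names())
        set_b = set(b.gene_names())
        if set_a <= set_b or set_b <= set_a:
            relation = "duplication"
        elif set_a & set_b:
            relation = "overlap"
        else:
            relation = "disjoint"
        left = [h for h in a.hits if not h.orphon_like]
        right = [h for h in b.hits if not h.orphon_like]
        out.append(Breakpoint(
            "contig_end",
            left[-1].gene_name if left else ".",
            right[0].gene_name if right else ".",
            relation,
            (a.contig_id, b.contig_id),
        ))
    return out, unplaceable


def gene_inventory(
    annotations: Mapping[str, ContigAnnotation],
    germline: LocusAnnotation,
) -> dict:
    """Count V (excluding pseudogenes), D and J genes in the assembly.

    Returns overall counts, per-contig counts, the longest retained
    contig's counts, and the germline genes missing from the assembly.
    """
    def functionality(name: str) -> Optional[Functionality]:
        for n in (name, re.sub(r"D\d*$", "", name)):
            try:
                return germline.gene(n).functionality
            except KeyError:
                continue
        return None

    def count(names: Iterable[str]) -> Dict[str, int]:
        c = {"V": 0, "D": 0, "J": 0}
        for name in names:
            m = re.match(r"IGH([VDJ])", name)
            if not m:
                continue
            cls = m.group(1)
            if cls == "V" and functionality(name) is Functionality.pseudo:
                continue
            c[cls] += 1
        return c

    per_contig = {}
    all_names: list[str] = []
    longest = None
    for cid, ann in annotations.items():
        if not ann.retained:
            continue
        names = ann.gene_names()
        per_contig[cid] = count(names)
        all_names.extend(names)
        if longest is None or ann.length > longest[0]:
            longest = (ann.length, cid)

    germline_names = {g.name for g in germline
                      if not (g.segment_class is SegmentClass.V
                              and g.functionality is Functionality.pseudo)}
    missing = sorted(germline_names - set(all_names))
    return {
        "total": count(all_names),
        "per_contig": per_contig,
        "longest_contig": None if longest is None else {
            "contig_id": longest[1],
            "counts": per_contig[longest[1]],
        },
        "missing_genes": missing,
    }


# ---------------------------------------------------------------------------
# Report I/O


def write_contig_annotations(annotations: Mapping[str, ContigAnnotation],
                             path) -> None:
    from ._util import atomic_open

    with atomic_open(path) as fh:
        fh.write("#contig\tstart\tend\tgene\tallele\tstrand\tmismatches\t"
                 "orphon_like\tcontig_retained\n")
        for cid in sorted(annotations):
            ann = annotations[cid]
            for h in ann.hits:
                fh.write(f"{cid}\t{h.start}\t{h.end}\t{h.gene_name}\t"
                         f"{h.allele_label}\t{h.strand}\t{h.mismatches}\t"
                         f"{int(h.orphon_like)}\t{int(ann.retained)}\n")


def write_breakpoints(breakpoints: Sequence[Breakpoint], path) -> None:
    from ._util import atomic_open

    with atomic_open(path) as fh:
        fh.write("#kind\tleft_gene\tright_gene\trelation\tcontigs\n")
        for b in breakpoints:
            fh.write(f"{b.kind}\t{b.left_gene}\t{b.right_gene}\t"
                     f"{b.relation}\t{','.join(b.contig_ids)}\n")


def profile_assembly(
    assembly: Mapping[str, str],
    gene_db: Mapping[str, str],
    germline: LocusAnnotation,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    window: int = DEFAULT_VDJ_WINDOW,
) -> dict:
    """Annotate + filter + rename + breakpoints + inventory in one pass."""
    anns = annotate_contigs(assembly, gene_db)
    anns = filter_orphons(anns, max_mismatch)
    anns = {cid: assign_duplicate_names(a, germline)
            for cid, a in anns.items()}
    vdj = [bp for a in anns.values()
           for bp in detect_vdj_breakpoints(a, germline, window)]
    ends, unplaceable = detect_contig_end_breakpoints(
        list(anns.values()), germline
    )
    return {
        "annotations": anns,
        "vdj_breakpoints": vdj,
        "contig_end_breakpoints": ends,
        "unplaceable_contigs": unplaceable,
        "inventory": gene_inventory(anns, germline),
    }
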