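"""SV genotyping, haplotype reconciliation, personalized reference."""

import itertools
import random

import pytest

from igh_profiler import simulate as sim
from igh_profiler.asm_profiler import (
    ContigAnnotation,
    GeneHit,
    profile_assembly,
)
from igh_profiler.locus_model import Functionality, SegmentClass
from igh_profiler.svtype_refbuild import (
    BuildError,
    DonorSegment,
    SVAlleleCall,
    SVDefinition,
    build_personalized_reference,
    consensus_calls,
    genotype_sv,
    load_sv_definitions,
    reconcile_haplotypes,
)

# toy SV over the D locus: interior D2-2..D4-4, anchored by D1-1 / D5-5
SV_D = SVDefinition(1, "D-locus deletion", "IGHD1-1", "IGHD5-5",
                    interior=frozenset({"IGHD2-2", "IGHD3-3", "IGHD4-4"}))
SV_COMPLEX = SVDefinition(3, "complex V region", "IGHV6-1", "IGHV3-23",
                          hap_a=frozenset({"IGHV3-9"}),
                          hap_b=frozenset({"IGHV1-8"}))


def contig_with(cid, names):
    hits = [GeneHit(cid, n, "01", i * 1000, i * 1000 + 300, "-", 0)
            for i, n in enumerate(names)]
    return ContigAnnotation(cid, len(names) * 1000 + 1000, hits)


def test_deletion_genotyping_rules():
    deleted = contig_with("c1", ["IGHD1-1", "IGHD5-5"])
    present = contig_with("c2", ["IGHD1-1", "IGHD2-2", "IGHD5-5"])
    away = contig_with("c3", ["IGHV3-23", "IGHV4-34"])
    assert genotype_sv(deleted, SV_D).allele == "deleted"
    assert genotype_sv(present, SV_D).allele == "present"
    assert genotype_sv(away, SV_D).allele == "unknown"
    # interior evidence wins even without both flanks
    interior_only = contig_with("c4", ["IGHD3-3"])
    assert genotype_sv(interior_only, SV_D).allele == "present"


def test_complex_genotyping_rules():
    a = contig_with("a", ["IGHV6-1", "IGHV3-9", "IGHV3-23"])
    b = contig_with("b", ["IGHV6-1", "IGHV1-8", "IGHV3-23"])
    both = contig_with("ab", ["IGHV3-9", "IGHV1-8"])
    neither = contig_with("x", ["IGHV6-1", "IGHV3-23"])
    assert genotype_sv(a, SV_COMPLEX).allele == "hapA"
    assert genotype_sv(b, SV_COMPLEX).allele == "hapB"
    assert genotype_sv(both, SV_COMPLEX).allele == "unknown"
    assert genotype_sv(neither, SV_COMPLEX).allele == "unknown"


def test_genotyping_moves_unknown_to_determinate_with_coverage():
    """Extending a non-covering contig into the region resolves the call."""
    short = contig_with("c", ["IGHJ1"])
    assert genotype_sv(short, SV_D).allele == "unknown"
    extended = contig_with("c", ["IGHJ1", "IGHD1-1", "IGHD5-5"])
    assert genotype_sv(extended, SV_D).allele == "deleted"


def test_bundled_sv_catalog_loads():
    svs = load_sv_definitions()
    assert [s.sv_id for s in svs] == [1, 2, 3, 4, 5, 6, 7]
    assert sum(s.is_complex for s in svs) == 1


# ---------------------------------------------------------------------------
# reconciliation


def calls_of(**per_contig):
    """per_contig: contig -> {sv_id: allele}"""
    return {cid: [SVAlleleCall(sv, cid, allele)
                  for sv, allele in d.items()]
            for cid, d in per_contig.items()}


def brute_force_reconcilable(contigs, calls):
    from igh_profiler.svtype_refbuild import _group_conflicts

    for assign in itertools.product([0, 1], repeat=len(contigs)):
        p = [c for c, g in zip(contigs, assign) if g == 0]
        m = [c for c, g in zip(contigs, assign) if g == 1]
        if not _group_conflicts(p, calls) and not _group_conflicts(m, calls):
            return True
    return False


def test_consistent_groups_are_identity():
    calls = calls_of(p1={5: "deleted"}, p2={5: "deleted"},
                     m1={5: "present"})
    res = reconcile_haplotypes(["p1", "p2"], ["m1"], calls)
    assert res.success and res.moved == []
    assert res.paternal == ["p1", "p2"] and res.maternal == ["m1"]


def test_single_swap_resolves_conflict():
    calls = calls_of(p1={5: "deleted"}, p2={5: "present"},
                     m1={5: "present"})
    res = reconcile_haplotypes(["p1", "p2"], ["m1"], calls)
    assert res.success
    assert "p2" in res.maternal


def test_unreconcilable_conflict_reported():
    # two SVs coupled so that contig A conflicts with each of B, C, D:
    # no bipartition into two consistent groups exists
    calls = calls_of(A={1: "deleted", 2: "deleted"},
                     B={1: "present", 2: "present"},
                     C={1: "deleted", 2: "present"},
                     D={1: "present", 2: "deleted"})
    contigs = ["A", "B", "C", "D"]
    assert not brute_force_reconcilable(contigs, calls)
    res = reconcile_haplotypes(["A", "B"], ["C", "D"], calls)
    assert not res.success
    assert {c["sv_id"] for c in res.conflicts} <= {1, 2}
    assert res.conflicts


def test_reconcile_agrees_with_exhaustive_search():
    """On random small instances the success flag equals brute force over
    all contig-to-group assignments."""
    rng = random.Random(17)
    for trial in range(60):
        n = rng.randint(2, 6)
        contigs = [f"c{i}" for i in range(n)]
        calls = {}
        for c in contigs:
            d = {}
            for sv in (1, 2, 3):
                r = rng.random()
                if r < 0.4:
                    continue
                d[sv] = rng.choice(
                    ["deleted", "present"] if sv != 3 else ["hapA", "hapB"])
            calls[c] = [SVAlleleCall(sv, c, al) for sv, al in d.items()]
        half = n // 2
        res = reconcile_haplotypes(contigs[:half], contigs[half:], calls)
        assert res.success == brute_force_reconcilable(contigs, calls), \
            (trial, calls)


# ---------------------------------------------------------------------------
# personalized reference


def test_all_backbone_alleles_identity(germline, annotation):
    ref = build_personalized_reference(
        germline, annotation, calls={1: "present"}, svs=[SV_D], donors={},
        backbone_alleles={1: "present"}, haplotype="pat")
    assert ref.sequence == germline
    assert ref.provenance == [(0, len(germline), "backbone")]


def test_deletion_substitution_drops_interior(germline, annotation, gene_db):
    """Calling the D-locus deletion splices out the interior D genes but
    keeps the anchors; length shrinks by the replaced span."""
    d1 = annotation.gene("IGHD1-1")
    d5 = annotation.gene("IGHD5-5")
    # donor: backbone with the inter-anchor span removed
    donor_seq = germline[d1.start - 500:d1.end] + germline[d5.start:d5.end + 500]
    donor = DonorSegment("donor_del", donor_seq,
                         left_anchor_end=500 + d1.length,
                         right_anchor_start=500 + d1.length)
    ref = build_personalized_reference(
        germline, annotation, calls={1: "deleted"}, svs=[SV_D],
        donors={(1, "deleted"): donor},
        backbone_alleles={1: "present"}, haplotype="pat")
    assert len(ref.sequence) == len(germline) - (d5.start - d1.end)
    assert [src for _, _, src in ref.provenance] == ["backbone", "backbone"]
    inv = profile_assembly({"pat": ref.sequence}, gene_db, annotation)
    names = set(inv["annotations"]["pat"].gene_names())
    assert {"IGHD1-1", "IGHD5-5"} <= names
    assert not names & {"IGHD2-2", "IGHD3-3", "IGHD4-4"}


def test_two_substitutions_give_five_tiles(germline, annotation):
    sv_v = SVDefinition(4, "V deletion", "IGHV1-8", "IGHV3-30",
                        interior=frozenset({"IGHV3-23"}))
    d1 = annotation.gene("IGHD1-1")
    d5 = annotation.gene("IGHD5-5")
    v18 = annotation.gene("IGHV1-8")
    v330 = annotation.gene("IGHV3-30")
    don1 = DonorSegment("don1", germline[d1.start:d1.end] +
                        germline[d5.start:d5.end],
                        d1.length, d1.length)
    don2 = DonorSegment("don2", germline[v18.start:v18.end] +
                        germline[v330.start:v330.end],
                        v18.length, v18.length)
    ref = build_personalized_reference(
        germline, annotation, calls={1: "deleted", 4: "deleted"},
        svs=[SV_D, sv_v],
        donors={(1, "deleted"): don1, (4, "deleted"): don2},
        backbone_alleles={1: "present", 4: "present"})
    # empty donor inserts collapse: backbone/backbone/backbone tiles remain
    assert len(ref.provenance) == 3
    ref.validate()

    don1b = DonorSegment("don1", "X" * 100, 10, 90)
    ref2 = build_personalized_reference(
        germline, annotation, calls={1: "deleted", 4: "deleted"},
        svs=[SV_D, sv_v],
        donors={(1, "deleted"): don1b, (4, "deleted"): don2},
        backbone_alleles={1: "present", 4: "present"})
    assert [src for _, _, src in ref2.provenance] == \
        ["backbone", "don1", "backbone", "backbone"]


def test_missing_donor_raises_naming_sv(germline, annotation):
    with pytest.raises(BuildError, match="sv1"):
        build_personalized_reference(
            germline, annotation, calls={1: "deleted"}, svs=[SV_D],
            donors={}, backbone_alleles={1: "present"})


def test_consensus_calls_rejects_inconsistency():
    calls = calls_of(a={1: "deleted"}, b={1: "present"})
    with pytest.raises(ValueError, match="sv1"):
        consensus_calls(["a", "b"], calls)
    assert consensus_calls(["a"], calls) == {1: "deleted"}
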