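"""Read profiler: junction anchoring, classification, clonality, usage."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from igh_profiler import simulate as sim
from igh_profiler.locus_model import PanelEntry, ReferencePanel, SegmentClass
from igh_profiler.read_profiler import (
    Anchor,
    Junction,
    SplitSegment,
    classify_event,
    clonality_class,
    gene_usage,
    group_events,
    junctions_from_deletions,
    junctions_from_segments,
    select_best_reference,
    simpson_index,
)

from conftest import EVENT_SPECS, profile_from_reads


# ---------------------------------------------------------------------------
# helpers


def seg(read_id, ref_start, ref_end, read_start, read_end, strand="+",
        cigar=None, ref="toy"):
    return SplitSegment(read_id, ref, ref_start, ref_end, read_start,
                        read_end, strand, 60, 20000, cigar)


def make_junction(annotation, lgene, lside, rgene, rside, flip=False,
                  confident=True, read_id="r", bp=1000):
    gl, gr = annotation.gene(lgene), annotation.gene(rgene)
    a = Anchor(lgene, gl.segment_class, lside, gl.rss(lside), 0)
    b = Anchor(rgene, gr.segment_class, rside, gr.rss(rside), 0)
    if a.coord > b.coord:
        a, b = b, a
    return Junction(a, b, "split", flip, read_id, bp, confident)


# ---------------------------------------------------------------------------
# Simpson's index and clonality


def test_simpson_closed_forms():
    assert simpson_index([7, 7]) == 0.5
    assert simpson_index([42]) == 1.0
    for k in (2, 5, 10):
        assert simpson_index([1] * k) == pytest.approx(1 / k)


@given(st.lists(st.integers(min_value=1, max_value=500), min_size=1,
                max_size=30))
def test_simpson_invariants(counts):
    si = simpson_index(counts)
    assert 0 < si <= 1
    shuffled = sorted(counts, reverse=True)
    assert simpson_index(shuffled) == pytest.approx(si)


def test_simpson_rejects_degenerate_input():
    with pytest.raises(ValueError):
        simpson_index([])
    with pytest.raises(ValueError):
        simpson_index([3, 0])


def test_clonality_thresholds_are_strict():
    assert clonality_class(0.5) == "monoclonal"
    assert clonality_class(0.1) == "polyclonal"
    assert clonality_class(0.25) == "in_between"
    assert clonality_class(0.125) == "in_between"
    with pytest.raises(ValueError):
        clonality_class(0.0)
    with pytest.raises(ValueError):
        clonality_class(1.5)


# ---------------------------------------------------------------------------
# junction anchoring


@pytest.mark.parametrize("offset,expect_confident", [
    (0, True), (50, True), (51, False), (80, False),
])
def test_split_confidence_boundary(annotation, offset, expect_confident):
    """The 50 bp RSS tolerance is inclusive; beyond it the junction is
    kept but unconfident."""
    j1 = annotation.gene("IGHJ1")
    v = annotation.gene("IGHV3-23")
    segs = [
        seg("r1", 0, j1.rss5 + offset, 0, 8000),
        seg("r1", v.rss3, v.rss3 + 9000, 8000, 17000),
    ]
    (junc,) = junctions_from_segments(segs, annotation)
    assert junc.confident is expect_confident
    assert {junc.left.gene, junc.right.gene} == {"IGHJ1", "IGHV3-23"}
    assert junc.left.distance in (0, offset)


def test_split_junction_orientation_flag(annotation):
    j1 = annotation.gene("IGHJ1")
    j2 = annotation.gene("IGHJ2")
    segs = [
        seg("r1", 0, j1.rss5, 0, 5000),
        seg("r1", j1.rss5, j2.rss5, 5000, 5600, strand="-"),
    ]
    (junc,) = junctions_from_segments(segs, annotation)
    assert junc.orientation_change


@pytest.mark.parametrize("delta,expect_confident", [
    (0, True), (50, True), (-50, True), (51, False), (-51, False),
])
def test_deletion_length_rule_boundary(annotation, delta, expect_confident):
    """A deletion between two D genes is confident iff its length is
    within 50 bp of the germline distance between the facing RSSs."""
    d2 = annotation.gene("IGHD2-2")
    d4 = annotation.gene("IGHD4-4")
    expected = d4.rss3 - d2.rss5
    dlen = expected + delta
    # alignment: 500M <dlen>D 500M starting so the deletion sits at d2.rss5
    start = d2.rss5 - 500
    cigar = ((0, 500), (2, dlen), (0, 500))
    s = seg("r1", start, start + 1000 + dlen, 0, 1000, cigar=cigar)
    (junc,) = junctions_from_deletions(s, annotation)
    assert junc.kind == "internal_deletion"
    assert junc.deletion_length == dlen
    assert junc.confident is expect_confident


def test_short_deletions_not_inspected(annotation):
    d2 = annotation.gene("IGHD2-2")
    start = d2.rss5 - 500
    cigar = ((0, 500), (2, 99), (0, 500))
    s = seg("r1", start, start + 1099, 0, 1000, cigar=cigar)
    assert junctions_from_deletions(s, annotation) == []


# ---------------------------------------------------------------------------
# reference selection


def panel_of(annotation, ids):
    return ReferencePanel([
        PanelEntry(rid, None, annotation, priority=i)
        for i, rid in enumerate(ids)
    ])


def test_reference_selection_examples(annotation):
    panel = panel_of(annotation, ["A", "B"])
    conf = make_junction(annotation, "IGHJ1", "5p", "IGHV3-23", "3p")
    unconf = make_junction(annotation, "IGHJ1", "5p", "IGHV3-23", "3p",
                           confident=False)
    # more confident junctions wins
    ref, _ = select_best_reference({"A": [conf, conf], "B": [conf]}, panel)
    assert ref == "A"
    # equal confident counts: smaller total distance wins
    far = Junction(
        Anchor("IGHJ1", SegmentClass.J, "5p", 0, 40),
        Anchor("IGHV3-23", SegmentClass.V, "3p", 100, 0),
        "split", False, "r", 0, True)
    ref, _ = select_best_reference({"A": [conf], "B": [far]}, panel)
    assert ref == "A"
    # full tie: panel priority decides
    ref, _ = select_best_reference({"A": [conf], "B": [conf]}, panel)
    assert ref == "A"
    # absent reference ranks last
    ref, _ = select_best_reference({"A": None, "B": [unconf]}, panel)
    assert ref == "B"


def test_reference_selection_matches_exhaustive_ranking(annotation):
    """Selection agrees with an explicitly ranked comparison and is
    stable under input shuffling."""
    rng = random.Random(5)
    ids = ["A", "B", "C"]
    panel = panel_of(annotation, ids)
    for _ in range(50):
        sets = {}
        for rid in ids:
            juncs = []
            for _ in range(rng.randint(0, 3)):
                juncs.append(Junction(
                    Anchor("IGHJ1", SegmentClass.J, "5p", 0,
                           rng.randint(0, 60)),
                    Anchor("IGHV3-23", SegmentClass.V, "3p", 100,
                           rng.randint(0, 60)),
                    "split", False, "r", 0, rng.random() < 0.5))
            sets[rid] = juncs or None

        def rank(rid):
            juncs = sets[rid]
            if juncs is None:
                return (1, 0, 0, ids.index(rid))
            return (0, -sum(j.confident for j in juncs),
                    sum(j.left.distance + j.right.distance for j in juncs),
                    ids.index(rid))

        oracle = min(ids, key=rank)
        chosen, _ = select_best_reference(sets, panel)
        assert chosen == oracle
        shuffled = dict(rng.sample(list(sets.items()), len(sets)))
        assert select_best_reference(shuffled, panel)[0] == oracle


# ---------------------------------------------------------------------------
# classification


def test_classify_single_junction_patterns(annotation):
    mj = lambda *a, **k: make_junction(annotation, *a, **k)
    assert classify_event([mj("IGHJ1", "5p", "IGHV3-23", "3p")]) == "canonical"
    assert classify_event([mj("IGHJ1", "5p", "IGHD3-3", "3p")]) == "partial_DJ"
    assert classify_event([mj("IGHD2-2", "5p", "IGHV1-8", "3p")]) == "partial_VD"
    assert classify_event(
        [mj("IGHD2-2", "5p", "IGHD4-4", "3p")]) == "multi_D"
    assert classify_event(
        [mj("IGHJ1", "5p", "IGHJ2", "5p", flip=True)]) == "inversion_J"
    assert classify_event(
        [mj("IGHD2-2", "3p", "IGHD4-4", "3p", flip=True)]) == "inversion_D"
    assert classify_event(
        [mj("IGHD3-3", "5p", "IGHV3-23", "3p", flip=True)]) == "inversion_V"


def test_classify_multi_junction_patterns(annotation):
    mj = lambda *a, **k: make_junction(annotation, *a, **k)
    chain = [mj("IGHJ2", "5p", "IGHD1-1", "3p"),
             mj("IGHD3-3", "5p", "IGHV5-51", "3p")]
    assert classify_event(chain) == "multi_D"
    chain = [mj("IGHD2-2", "3p", "IGHV1-69", "3p", flip=True),
             mj("IGHD3-3", "5p", "IGHV4-34", "3p")]
    assert classify_event(chain) == "double_VD"
    # a J anywhere forbids double_VD
    chain = [mj("IGHJ1", "5p", "IGHD2-2", "3p"),
             mj("IGHD3-3", "5p", "IGHV4-34", "3p")]
    assert classify_event(chain) == "multi_D"


def test_classify_rejects_empty_chain():
    with pytest.raises(ValueError):
        classify_event([])


def test_unanchored_patterns_are_unclassified(annotation):
    mj = lambda *a, **k: make_junction(annotation, *a, **k)
    assert classify_event([mj("IGHV1-8", "3p", "IGHV3-23", "3p")]) == \
        "unclassified"


# ---------------------------------------------------------------------------
# grouping and usage


def test_identical_chains_merge_into_one_event(annotation):
    j = make_junction(annotation, "IGHJ1", "5p", "IGHV3-23", "3p")
    chains = {f"r{i}": [j] for i in range(10)}
    profile = group_events(chains, "s")
    assert len(profile.events) == 1
    assert profile.events[0].n_reads == 10
    assert profile.simpson_index == 1.0


def test_unconfident_events_excluded_from_si_and_usage(annotation):
    conf = make_junction(annotation, "IGHJ1", "5p", "IGHV3-23", "3p")
    unconf = make_junction(annotation, "IGHJ2", "5p", "IGHV1-8", "3p",
                           confident=False)
    profile = group_events({"r1": [conf], "r2": [conf], "r3": [unconf]}, "s")
    assert len(profile.events) == 2
    assert profile.n_supporting_reads == 2
    assert profile.simpson_index == 1.0
    jv, _ = gene_usage([profile])
    assert jv.to_numpy().sum() == 1


def test_gene_usage_counts_once_per_sample(annotation):
    canon = make_junction(annotation, "IGHJ1", "5p", "IGHV3-23", "3p")
    one = group_events({"r1": [canon], "r2": [canon]}, "s1")
    jv, jd = gene_usage([one])
    assert jv.loc["IGHJ1", "IGHV3-23"] == 1
    # same event in three samples -> cell = 3
    profiles = [group_events({f"{s}r": [canon]}, s) for s in "abc"]
    jv, _ = gene_usage(profiles)
    assert jv.loc["IGHJ1", "IGHV3-23"] == 3


def test_gene_usage_noncanonical_first_jd_pair(annotation):
    mj = lambda *a, **k: make_junction(annotation, *a, **k)
    chain = [mj("IGHJ2", "5p", "IGHD1-1", "3p"),
             mj("IGHD3-3", "5p", "IGHV5-51", "3p")]
    profile = group_events({"r1": chain}, "s")
    jv, jd = gene_usage([profile])
    assert jv.empty
    assert jd.loc["IGHJ2", "IGHD1-1"] == 1


# ---------------------------------------------------------------------------
# alignment extraction (simulator truth path)


def test_v_locus_reads_excluded(germline, annotation):
    """A read contained in the V locus, far from the J-D span, is not
    profiled even if split-aligned there."""
    cfg = sim.SimConfig(seed=23)
    reads = sim.simulate_reads(germline, annotation, cfg,
                               germline_depth=3.0, allow_flip=False)
    _, _, groups = profile_from_reads(reads, annotation)
    jd_end = annotation.jd_interval[1]
    v_reads = {r.read_id for r in reads
               if all(s.ref_start > jd_end for s in r.segments)}
    assert v_reads
    assert not v_reads & set(groups)
    kept = {r.read_id for r in reads
            if any(s.ref_start < jd_end and s.ref_end >
                   annotation.jd_interval[0] for s in r.segments)}
    assert kept <= set(groups) | v_reads


def test_simulated_segments_recovered_exactly(germline, annotation,
                                              sim_config):
    clones = [sim.CloneSpec(EVENT_SPECS["canonical"], 4)]
    reads = sim.simulate_reads(germline, annotation, sim_config, clones)
    _, _, groups = profile_from_reads(reads, annotation)
    for r in reads:
        if r.molecule_id == "germline" or r.read_id not in groups:
            continue
        got = [(s.ref_start, s.ref_end, s.read_start, s.read_end, s.strand)
               for s in groups[r.read_id]]
        want = [(s.ref_start, s.ref_end, s.read_start, s.read_end, s.strand)
                for s in sorted(r.segments, key=lambda s: s.read_start)]
        assert got == want
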