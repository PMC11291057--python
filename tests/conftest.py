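import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from igh_profiler import simulate as sim
from igh_profiler.read_profiler import (
    extract_igh_alignments,
    group_events,
    read_junction_chain,
)


@pytest.fixture(scope="session")
def sim_config():
    return sim.SimConfig(seed=11)


@pytest.fixture(scope="session")
def locus(sim_config):
    """Toy germline locus: (sequence, annotation)."""
    return sim.build_toy_locus(sim_config)


@pytest.fixture(scope="session")
def germline(locus):
    return locus[0]


@pytest.fixture(scope="session")
def annotation(locus):
    return locus[1]


@pytest.fixture(scope="session")
def gene_db(locus):
    return sim.gene_db_from_annotation(*locus)


#: one spec per event class, reused across tests
EVENT_SPECS = {
    "canonical": sim.EventSpec("canonical", j="IGHJ1", d="IGHD2-2",
                               v="IGHV3-23"),
    "partial_DJ": sim.EventSpec("partial_DJ", j="IGHJ2", d="IGHD3-3"),
    "partial_VD": sim.EventSpec("partial_VD", d="IGHD2-2", v="IGHV1-8"),
    "multi_D": sim.EventSpec("multi_D", j="IGHJ1",
                             d_blocks=[("IGHD1-1", "IGHD3-3")],
                             v="IGHV3-30"),
    "multi_D_deletion": sim.EventSpec(
        "multi_D", j="IGHJ2",
        d_blocks=[("IGHD1-1", "IGHD2-2"), ("IGHD4-4", "IGHD4-4")],
        v="IGHV4-34"),
    "inversion_J": sim.EventSpec("inversion_J", j="IGHJ1", j2="IGHJ2"),
    "inversion_D": sim.EventSpec("inversion_D", d="IGHD2-2", d2="IGHD4-4"),
    "inversion_V": sim.EventSpec("inversion_V", d="IGHD3-3", v="IGHV3-23"),
    "double_VD": sim.EventSpec("double_VD", v2="IGHV1-69", d="IGHD2-2",
                               d2="IGHD3-3", v="IGHV4-34"),
}


def profile_from_reads(reads, annotation, sample_id="test"):
    """Run the single-reference profiling path on simulated reads using
    their exact truth alignments."""
    records = sam_records(reads, annotation)
    groups = extract_igh_alignments(records, annotation)
    chains = {
        rid: read_junction_chain(segs, annotation)
        for rid, segs in groups.items()
    }
    chains = {rid: c for rid, c in chains.items() if c}
    profile = group_events(chains, sample_id)
    return profile, chains, groups


def sam_records(reads, annotation, tmpdir=None):
    """Materialize simulated reads as pysam records (via an in-memory
    round-trip through SAM text)."""
    import io
    import tempfile

    import pysam

    with tempfile.TemporaryDirectory() as td:
        path = f"{td}/reads.sam"
        ref_len = max(g.end for g in annotation.genes) + 10_000
        sim.write_truth_sam(reads, annotation.chrom, ref_len, path)
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            return list(fh.fetch(until_eof=True))
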