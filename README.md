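# igh-profiler

Profiling somatic V(D)J recombination and germline IGH assembly quality in
long-read sequencing data from lymphoblastoid cell lines (LCLs).

## The problem

LCLs — EBV-transformed B cells — are the source of many reference-grade
human genomes, but B cells carry pre-existing somatic V(D)J
rearrangements of the immunoglobulin heavy-chain (IGH) locus.  A
sequenced LCL therefore mixes germline and somatically recombined
haplotypes: reads spanning a rearrangement split-align around the
recombination signal sequences (RSSs), assemblies fragment or silently
drop IGH genes, and genotypes of the locus become unreliable.

`igh-profiler` addresses this for PacBio HiFi-class reads and the
assemblies built from them:

* **read profiling** — detect split alignments and long internal
  deletions whose breakpoints anchor near RSSs, deduplicate them into
  recombination events (canonical J–V joints, partial D–J / V–D joints,
  multi-D "RSS skipping", J/D/V inversions, double V–D), and measure
  clonality via Simpson's index

  SI = Σᵢ nᵢ² / N²,

  where nᵢ is the read count of event i and N = Σ nᵢ.  A monoclonal
  diploid line (one dominant event per haplotype) gives SI ≈ 0.5;
  SI > 0.25 is called monoclonal, SI < 0.125 polyclonal.
* **assembly profiling** — annotate IGH genes on contigs against an
  allele database, filter orphon-like hits (> 15 mismatches),
  disambiguate duplicated gene names, classify breakpoints as somatic
  V(D)J joints (different gene classes within 10 kb with germline genes
  skipped) or contig ends (disjoint / overlap / duplication), and
  inventory V (non-pseudo), D and J genes.
* **reassembly preprocessing** — split reads at confident somatic
  junctions (V–V adjacencies exempt, as potential germline SVs),
  duplicate reads over the J–D interval to counter recombination-driven
  depletion, genotype the seven common IGH structural variants from de
  novo contigs, reconcile parental contig groups by swapping, stitch a
  personalized per-haplotype reference from a backbone plus donor
  alleles, and finally hard-mask assembly regions without read or contig
  support.

A bundled simulator builds a toy germline IGH locus with realistic
geometry (J, D, then V blocks on the minus strand; J genes < 400 bp
apart, D genes ≤ 40 bp), applies the full recombination-event grammar,
and emits reads with exact truth alignments — every module is testable
without downloading any external data.

## Worked example

```sh
igh-profiler simulate --out demo --seed 4 --depth 8
igh-profiler read --panel demo/panel.yaml --bam demo/reads.sam \
    --sample DEMO --out demo/profile
```

The simulation plants two clones (a canonical IGHJ1–IGHV3-23 event and a
partial IGHJ2–IGHD3-3 joint, six reads each) in a germline background.
The profiler prints

```
DEMO: 2 events, SI=0.5, clonality=monoclonal
```

and `demo/profile/events.tsv` contains the recovered chains:

```
#sample  event_class  chain                      n_reads  confident
DEMO     canonical    IGHJ1:5p|IGHV3-23:3p|fwd   6        1
DEMO     partial_DJ   IGHJ2:5p|IGHD3-3:3p|fwd    6        1
```

Two events with equal support give SI = (6² + 6²)/12² = 0.5 — the
monoclonal expectation of one dominant event per haplotype.
`demo/profile/profile.json` holds the same numbers plus the chosen
reference per read, and `usage_j_v.tsv` / `usage_j_d.tsv` the gene-usage
matrices.  Profiling the germline FASTA as an "assembly",

```sh
igh-profiler asm --asm demo/germline.fa --genes demo/gene_db.fa \
    --order demo/germline.annotation.tsv --out demo/asm
```

prints `hap1: V=8 D=5 J=3 vdj_bp=0 contig_end_bp=0`: all 8 functional V
genes (the toy locus has 10 V, two of them pseudo), 5 D and 3 J genes,
and no breakpoints — as expected of an intact germline sequence.

## Layout

```
src/igh_profiler/
  locus_model.py      annotation model, RSS lookup, reference panel
  read_profiler.py    junction detection, event classification, clonality
  asm_profiler.py     contig annotation, breakpoints, gene inventory
  preprocess.py       read splitting and J-D enrichment
  svtype_refbuild.py  SV genotyping, reconciliation, reference stitching
  mask.py             contig support filtering, zero-coverage masking
  simulate.py         toy locus, event grammar, reads with truth
  cli.py              igh-profiler subcommands
  adapters.py         minimap2 subprocess adapter
```

See `docs/methods.md` for the model, parameter defaults and design
decisions.
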