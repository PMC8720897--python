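# minitag

Simultaneous multi-sample nanopore amplicon analysis: nested dual-tag
demultiplexing, lowest-common-ancestor (LCA) taxonomy assignment, and
taxa-as-OTU community statistics, with a built-in long-read simulator
that provides ground truth for every stage.

## The problem

Soil microbial surveys need many samples per site, but sequencing each
sample separately is expensive. One answer is to pool everything into a
single MinION run and encode sample identity in the PCR primers
themselves: every sample's amplicon — the bacterial 16S rRNA gene
(27F/1492R, reads 1200–1700 bp) or the fungal ITS region (ITS1F/ITS4,
reads 600–900 bp) — carries a sample-specific **24 bp tag** on the 5′ end
of both primers. A second, nested PCR can prepend an additional **26 bp
tag** to the same primers, so a round-2 primer contains its round-1
primer as an exact suffix. Under the default experimental design this
expands to **80 tagged libraries** (52 round-1, 28 round-2; 38 of them
16S round-1) pooled into one flow cell.

The computational task is the reverse mapping, on long reads with
nanopore-scale error:

1. **Demultiplex** — find tagged primers at *both ends* of each read by
   IUPAC-aware Smith–Waterman local alignment, keep hits covering
   ≥ 90 % of the primer, require both ends to name the same library,
   apply the marker length window, and trim the read to the insert
   between the primers:

   coverage = (aligned primer bases) / (primer length) ≥ 0.90

2. **Assign taxonomy** — search each trimmed insert against a marker
   reference set (blastn, 12-column tabular output). A read is
   assignable when its top hit reaches **100 bits**; the candidate set is
   every hit with bitscore ≥ **0.995 ×** the top bitscore, and the
   assignment is the LCA — the deepest lineage that is a prefix of every
   candidate's lineage.

3. **Community statistics** — each distinct assigned lineage is one OTU.
   Per marker, the OTU table is filtered to the target kingdom (Bacteria
   for 16S, Fungi for ITS) and to taxa with ≥ 2 reads in total, then per
   sample the report gives

   | column | meaning |
   |--------|---------|
   | N      | reads assigned to the sample by demultiplexing |
   | OTU    | retained taxa observed in the sample |
   | Ns     | reads of the sample inside retained taxa |
   | Ns/ng  | Ns per ng of pooled amplicon DNA (default 0.49 ng/sample) |
   | S      | Shannon diversity, S = −Σ pᵢ ln pᵢ |
   | R      | reciprocal Berger–Parker dominance, R = 1 / max pᵢ |

   plus the Bray–Curtis dissimilarity matrix
   d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) for downstream ordination/clustering.

Because the original sequencing run and tag appendices are not publicly
deposited, the package ships a simulator that generates reference sets
evolved along a random taxonomy, community profiles (raw soil,
autoclave-sterilised soil, post-treatment), and tagged noisy reads with
per-read ground truth — so every rule above is testable end to end.

## Worked example

```python
from minitag.pipeline import load_config, run_pipeline, summarize

cfg = load_config(overrides={
    "seed": 11,
    "simulate": {
        "reads_per_library": 60,
        "n_taxa": {"16S": 12, "ITS": 10},
        "design": {
            "single_containers": ("I", "1"),
            "double_containers": (),
            "n_leaf_samples": 1,
        },
    },
})
manifest = run_pipeline(cfg, "runs/demo")
print(summarize("runs/demo")["sample_stats"].round(2))
```

This simulates 5 samples × 2 markers × 2 PCR rounds = 20 libraries with
60 reads each at the default 9 % error rate (3 % each substitution /
insertion / deletion), demultiplexes the pool, assigns taxonomy and
prints:

```
demux: {'assigned': 811, 'barcode_mismatch': 0, 'coverage_fail': 213,
        'length_fail': 0, 'no_forward_hit': 92, 'no_reverse_hit': 84}

              marker   N  OTU  Ns   Ns/ng     S     R
sample
16S-r1-A-I       16S  49   12  49  100.00  2.18  3.50
16S-r1-A-1       16S  38   12  38   77.55  2.26  4.75
16S-r1-B-I       16S  38   12  38   77.55  2.29  4.22
...
ITS-r2-B-1       ITS  44   10  44   89.80  2.05  3.67
ITS-r2-Leaf-1    ITS  43    8  43   87.76  1.81  3.07
```

Reading it: of 1200 simulated reads, 811 carried a recognisable tagged
primer at both ends (the rest lost a primer or fell below 90 % coverage
under 9 % noise — none were mis-assigned); sample `16S-r1-A-I`
contributed N = 49 reads spanning 12 OTUs with Shannon diversity 2.18,
and its most dominant taxon held 1/3.50 ≈ 29 % of its reads.

The same stages are exposed on the command line:

```bash
minitag design --out sheet.tsv                      # 80-library tagged primer sheet
minitag demux --reads pool.fastq --primers sheet.tsv --out demuxed/
minitag run --out runs/full --seed 1                # simulate + full pipeline
minitag summarize --run runs/full
```

## Layout

```
src/minitag/
  io_formats.py    FASTA/FASTQ, 12-column hit tables, lineage TSV
  tag_design.py    core primers, tag generation, design expansion
  align.py         IUPAC-aware affine-gap Smith–Waterman, bitscores
  demux.py         both-ends primer matching, coverage rule, trimming
  taxonomy_lca.py  candidate sets, LCA, blastn wrapper
  community.py     OTU tables, filters, N/OTU/Ns/Ns-per-ng/S/R, Bray–Curtis
  simulator.py     references, communities, noisy tagged reads + truth
  pipeline.py      orchestration, config, manifest
  cli.py           `minitag` entry point
```

See `docs/methods.md` for the model, parameter defaults, and the design
choices behind the demultiplexing rules.
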