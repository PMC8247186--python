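# sclongread

Downstream analysis for **sparse single-cell long-read genome sequencing**
— the kind of data produced by one-adaptor Tn5 tagmentation of single-cell
genomic DNA followed by HiFi/CCS sequencing: a few thousand ~6 kb reads
per cell, mean depth well under 1×, but read lengths long enough to span
structural-variant junctions whole.

The package implements the computational stages that turn per-cell
alignments and call sets into biology:

- **ecDNA detection** (`sclongread.ecdna`) — extrachromosomal circular
  DNA leaves a unique alignment signature: a read passing through the
  circle junction maps back to the linear reference as exactly two
  same-chromosome, same-strand segments in *chiastic* order (the
  read-earlier segment genomically downstream of the read-later one).
  The pipeline detects such reads, removes the two known confounders
  (junctions inside >1 kb tandem repeats; head-to-tail duplications
  established by ≥4-cell DUP consensus within ±100 bp), and merges
  candidates across cells (±50 bp, ≥2 cells). A circle linearized by a
  single transposition event yields a full-length read of exactly the
  circle length, so independent copies give distinct reads of identical
  length — corroborating evidence a tandem repeat cannot produce.
- **Multi-cell SV consensus and benchmarking** (`sclongread.svconsensus`)
  — per-cell filtration (PASS only, ≥2 supporting reads; for bulk ≥4
  reads and support ratio >15%), SURVIVOR-style single-linkage merging
  (same type, breakpoints within 1 kb; translocation breakpoints within
  ±50 kb), distance-based multimatch benchmarking, and the six metrics
  Precision, Recall, F1, FPR, FNR and HM = 2·FPR·FNR/(FPR+FNR).
  Also: the duplication-placement test (100 centromere→telomere windows,
  chi-square against uniform), SNV multi-cell support benchmarking with
  same-alternative-allele matching, per-covered-base SNV FPR, and the
  six-class strand-collapsed mutation spectrum.
- **Windowed CNV profiling** (`sclongread.cnv`) — 1 Mb window read
  ratios, normalization so the genome-wide mean equals the sample ploidy
  (3 for K562-like samples), coefficient of variation against a baseline
  profile, circular binary segmentation with permutation testing, and
  Pearson correlation of segmented profiles with gap windows removed.
- **Synthetic data generator** (`sclongread.simulate`) — emulates the
  whole data-generating process: Poisson Tn5 fragmentation (all fragments
  recovered — the point of one-adaptor chemistry), diploid per-cell
  genomes with planted DEL/INS/DUP/INV/TRA, planted circles tagmented
  copy by copy, copy-number steps, and per-cell private false-positive
  calls. Everything downstream is validated against its machine-readable
  truth.
- **Domain types and I/O** (`sclongread.io_model`) — 0-based half-open
  coordinates everywhere; SAM/BAM with SA tags via pysam; an SV-VCF
  subset (SVTYPE/SVLEN/END, BND pairs reunited through MATEID); BED.

## Worked example

Simulate a small dataset with one planted 5 kb circle and a clonal
deletion, then run the circle pipeline:

```
$ cat sim.yaml
seed: 5
n_chroms: 1
chrom_length_bp: 2000000
n_cells: 3
per_cell_coverage: 3.0
per_cell_fp_calls: 2.0
circles:
  - {chrom: chr1, start: 600000, end: 605000, copies_per_cell: 4}
svs:
  - {svtype: DEL, chrom: chr1, start: 200000, end: 202000}

$ sclongread simulate --config sim.yaml --out data/
wrote dataset for 3 cells to data/

$ sclongread ecdna data/cell*.sam --trf data/trf.bed --out ecdna.tsv
1 nuclear candidates -> ecdna.tsv

$ cat ecdna.tsv
chrom	start	end	n_cells	n_reads	full_length_reads	modal_length
chr1	600000	605000	3	6	6	5000
```

The planted circle is recovered at its exact junction coordinates
(chr1:600000-605000), seen in all 3 cells through 6 junction-crossing
reads, all full-length single-cut reads whose modal length
equals the 5000 bp circle — the same-length evidence that distinguishes
a circle from a tandem repeat; the private false-positive calls, being
chiastic-free, produce no candidates at all.

Benchmarking a call set against itself sanity-checks the metrics:

```
$ sclongread sv-bench data/cell000.sv.vcf data/cell000.sv.vcf --min-indel 0 --out bench.tsv
precision=1.0000 recall=1.0000
```

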