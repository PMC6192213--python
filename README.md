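# spliceval

Evaluation of splice-aware long-read RNA-seq alignments.

Long reads from PacBio and Oxford Nanopore span whole transcripts, so an
RNA-seq aligner must place a single read across several introns — a gapped,
exon-junction-spanning alignment. `spliceval` measures how well a set of
such alignments (SAM) matches either the *known* origins of simulated reads
or gene annotations alone, the two situations a benchmarking study of
spliced aligners faces. It is aimed at people benchmarking or developing
splice-aware aligners and at pipeline authors who want a quantitative sanity
check on long-read RNA-seq alignments.

## Metrics

**Simulated mode** (`eval-sim`). The simulator's MAF records give each
read's source interval on a transcript; lifting that interval through the
annotated exon chain yields the read's true genomic blocks
o₁..o_m. Against the aligner's blocks a₁..a_k:

* **Aligned** — read has a primary alignment.
* **Correct** — same chromosome, k = m, and every block boundary within
  5 bp of its origin boundary (|aᵢ.start − oᵢ.start| ≤ 5 and
  |aᵢ.end − oᵢ.end| ≤ 5): beginning, end *and* inner exon boundaries
  accurately placed.
* **Hit all / Hit one** — every / at least one origin block overlapped by
  ≥ 5 bp by some alignment block.
* **Split reads** — reads aligned to ≥ 2 non-contiguous genomic locations
  (N-gapped and/or supplementary-derived), with Correct/Hit-all/Hit-one
  restated for that subset.
* **Match rate** — fraction of aligned (M/=/X) bases equal to the
  corresponding reference bases.

All percentages are relative to the number of reads in the *input*.

**Real mode** (`eval-real`). With origins unknown, alignments are compared
to annotations: **Exon hit** (some block overlaps an annotated exon by
≥ 5 bp), **Contiguous alignment** (blocks map in order, one per exon, onto
consecutive exons of a single transcript), **Expressed genes** (distinct
genes best-matched by at least one exon-hit read), plus Aligned, match
rate, and per-read aligned query fractions for read-fraction plots.

Both tolerances (5 bp boundary error, 5 bp minimum overlap) are inclusive
and configurable. See `docs/methods.md` for the precise definitions and
edge-case policy.

A bundled generator (`simulate`) builds a toy genome and annotation,
simulates error-prone long reads from spliced transcripts with
expression-weighted sampling, and writes PBSIM-style per-transcript
folders (`<tid>.ref.fa`, `<tid>.fastq`, `<tid>.maf`), a combined FASTQ and
a ground-truth SAM — so the whole metric suite is testable without any
external data, and any aligner's output on `reads.fastq` can be scored
against the same truth.

## Worked example

```bash
spliceval simulate --profile pacbio-roi-like --n-genes 8 --n-reads 200 \
    --seed 42 --out demo
spliceval eval-sim --sam demo/truth.sam --annotation demo/genes.gtf \
    --pbsim-dir demo/reads --reference demo/genome.fa --out demo/sim_report
```

which prints `evaluated 200 reads -> demo/sim_report.json`, with the JSON
containing:

```json
{
  "mean_match_rate": 98.9,
  "n_input_reads": 200,
  "pct_aligned": 100.0,
  "pct_correct": 100.0,
  "pct_hit_all": 100.0,
  "pct_hit_one": 100.0,
  "pct_split": 72.5,
  "pct_correct_split": 72.5,
  "pct_strand_ok": 100.0
}
```

(abridged; counters `n_*` accompany every percentage). Read as: all 200
reads aligned, every alignment placed all exon boundaries within 5 bp of
the truth (here the input *is* the truth SAM, so 100 % is the expected
self-consistency result); 72.5 % of reads span at least one intron, and
the mean match rate of 98.9 % reflects the ~1 % substitution + 1 %
insertion + 1 % deletion error profile (matched bases / aligned bases,
insertions excluded). Scoring a real aligner's SAM instead of `truth.sam`
shows how far it falls from that ceiling. The same dataset in real mode:

```bash
spliceval eval-real --sam demo/truth.sam --annotation demo/genes.gtf \
    --reference demo/genome.fa --out demo/real_report
```

```json
{
  "mean_match_rate": 98.9,
  "n_expressed_genes": 7,
  "pct_aligned": 100.0,
  "pct_contiguous": 100.0,
  "pct_exon_hit": 100.0
}
```

Every read overlaps annotated exons consistently with one transcript's
exon order, and the 200 reads came from 7 of the 8 simulated genes (the
expression weights left one gene unsampled).

Each evaluator also writes `<out>.tsv` with one row per read (flags,
match rate, aligned query fraction) for downstream plotting.

The same pipelines are available as library functions
(`spliceval.evaluate_simulated`, `spliceval.evaluate_real`,
`spliceval.simulate_dataset`) returning per-read evaluations and summary
objects.

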