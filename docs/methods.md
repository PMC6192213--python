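# Methods

## Problem

Splice-aware aligners place long RNA-seq reads (PacBio ROI/subreads, ONT 2D)
across introns, producing gapped alignments whose blocks should correspond to
exons. `spliceval` quantifies how well they do this, in two modes:

* **Simulated mode** — the true origin of every read is known from the
  simulator's MAF records. Each read's transcript-space source interval is
  lifted through the annotated exon chain to a genomic block list, and the
  aligner's placement is compared against it.
* **Real mode** — no per-read truth exists, so alignments are judged by
  concordance with gene annotations alone.

All coordinates are handled internally as 0-based half-open intervals; GTF
(1-based inclusive) and SAM POS (1-based) are converted exactly once, at
parse time.

## Alignment reduction

Each read is reduced to one `AlignmentRecord` built from its primary SAM line:

* Genomic **blocks** come from a CIGAR walk. `M`/`=`/`X`/`D` extend the
  current block; `N` closes it and opens a new one; `I`/`S`/`H` consume no
  reference. A deletion therefore never creates a "split", regardless of
  length — SAM semantics reserve `N` for spliced gaps, and the split-read
  notion here means spliced or chimeric placement.
* Secondary lines (0x100) are ignored. Supplementary lines (0x800) on the
  primary's chromosome and strand are merged into the block list (unions
  taken where they overlap); on a different chromosome or strand the record
  is flagged chimeric and scored on its primary blocks only, keeping
  denominators one-per-read.
* **Aligned query fraction** = (M/=/X/I bases) / (those + soft + hard clip
  lengths). Hard clips count toward read length so fractions are comparable
  across aligners that hard-clip instead of soft-clipping.
* **Match rate** = matching (M/=/X) bases / all (M/=/X) bases, compared
  directly against the reference FASTA. Insertions contribute to neither
  numerator nor denominator (a documented choice; aligner-reported `NM`
  would count them), and deletions have no query base to compare. When no
  FASTA is given, MD tags are used instead; both routes agree exactly on
  files that carry correct MD tags (tested).

## Simulated-mode metrics

Per read, with truth origin blocks `o_1..o_m` and alignment blocks
`a_1..a_k` (both in genomic order):

* `chrom_ok`, `strand_ok` — chromosome and strand match the lifted origin.
  The genomic strand of a read composes the transcript's strand with the
  read's orientation relative to the transcript (equal → `+`). Strand
  correctness is reported as its own percentage, not folded into Correct,
  so either convention is recoverable from the output.
* `hit_one` / `hit_all` — at least one / every origin block is overlapped
  by ≥ `min_overlap` bp (default 5, inclusive) by some alignment block.
  An origin block *shorter* than the threshold counts as hit when fully
  covered; otherwise the criterion would be unsatisfiable for reads that
  start or end within a few bases of a junction.
* `correct` — `chrom_ok`, `k = m`, and every boundary pair
  (`|a_i.start − o_i.start| ≤ tol` and `|a_i.end − o_i.end| ≤ tol`, default
  tol = 5, inclusive) holds. This is the strict definition that includes
  inner exon boundaries, not only the read's first and last coordinate.

The boundary form of `correct` is deliberately independent of the overlap
thresholds: shifting every truth alignment by exactly `tol` leaves Correct
unchanged, while `tol + 1` zeroes it — a sharpness property the tests probe
with the `perturb_truth_sam` harness. A consequence worth noting: for an
adversarial alignment whose origin has a block shorter than
`tol + min_overlap`, Correct can hold while Hit-all does not. On the data
the tool is designed for (truth alignments and aligner outputs over
≥ 30 bp exons) the familiar ordering
`Correct ≤ Hit all ≤ Hit one ≤ Aligned` holds, and the randomized-run tests
exercise it, but it is not a theorem for arbitrary block geometries.

Dataset percentages are all relative to the number of reads in the input
(not the number aligned); split-read sub-statistics (`Correct, split`,
`Split hit all/one`) restrict the numerator to reads with ≥ 2 blocks. Mean
match rate averages over aligned reads with a defined rate. Ratios are kept
exact internally and rounded to one decimal only at serialization.

## Real-mode metrics

Candidate genes are those whose span overlaps the alignment span (interval
tree over gene spans; ≥ 1 bp).

* `exon_hit` — some alignment block overlaps some exon of a candidate gene
  by ≥ `min_overlap` bp (inclusive).
* `contiguous` — there is a transcript of a candidate gene and a window of
  consecutive exons such that the alignment blocks map one-per-exon, in
  order, each overlapping its exon by ≥ `min_overlap` bp. The phrase
  "exons in a sequence" is formalized as this ordered one-block-per-exon
  pairing: it is strict, testable by exhaustive enumeration, and captures
  annotation-concordant spliced alignment. Single-block reads on a single
  exon are contiguous by this definition (window length 1).
* `best_gene` — the candidate maximizing total exonic overlap (exons
  unioned across transcripts so shared exons are not double-counted), ties
  broken by lexicographically smallest gene id. The **expressed genes**
  count is the number of distinct best genes over exon-hit reads, which
  avoids double-counting reads spanning overlapping genes. Exonic overlap
  (not mere gene-body overlap) is required, since a purely intronic read is
  weak evidence of expression.

Intergenic alignments count toward Aligned but no other numerator.

## Ground-truth liftover

A MAF record gives `(transcript, src_start, src_size, strand)` with starts
relative to the 5′ end of the stated strand; minus-strand source
coordinates are normalized to forward at parse time. Lifting walks the exon
chain: for a `-` transcript, transcript coordinate 0 is the genomically
*last* exon base, so the interval is mirrored before the walk and blocks
are always returned in genomic order. The block walk is verified against a
brute-force per-base coordinate map (enumerate every exon base, orient,
slice, re-run-length-encode) on 1,000 random transcripts per run, both
strands, plus a partition property (lifting two halves of an interval
partitions the lift of the whole).

## Synthetic fixture generator

The generator emulates a PBSIM-on-transcripts workflow so every metric is
testable without external data. What it emulates: expression-weighted
sampling of reads from spliced transcripts, aggregate per-base error rates,
MAF ground truth with the PBSIM folder layout
(`reads/<tid>/<tid>.{ref.fa,fastq,maf}`), and a truth SAM. What it does
not: PBSIM's empirical read-length and quality models, signal-level ONT
behaviour, overlapping genes, alternative isoforms per gene, and genome
repeats — so passing tests demonstrate the *evaluator's* correctness, not
that any aligner performs well on real data.

Design and defaults:

* **Geometry** — 20 genes, 1–5 exons of 50–300 bp, introns 50–500 bp,
  intergenic gaps 200–1000 bp, half the genes on the minus strand; values
  chosen as a small-but-structured toy gene complement (yeast-like exon
  counts, compressed lengths) that still produces a high fraction of
  junction-spanning reads.
* **Expression** — per-transcript weights; by default drawn once from an
  exponential distribution as a stand-in for the skewed coverage
  histograms of real expression data; configurable explicitly.
* **Reads** — length from a clamped normal (default mean 500, sd 150,
  min 50; presets mimic PacBio-ROI ~2–3 % and ONT-2D ~15 % total error
  regimes), start uniform along the transcript, antisense with
  probability 0.5 (a strand-symmetric simulator).
* **Errors** — one multinomial draw per reference base among substitution
  (to a uniformly random different base), single-base insertion after the
  position, deletion, or match; applied in a single left-to-right pass
  over the lifted genomic blocks. With i.i.d. per-base draws this is
  distributionally identical to corrupting the transcript-space substring,
  and generating in genomic order lets the truth CIGAR, MD and NM be built
  in the same pass. Under a pure substitution rate *s* the expected match
  rate is exactly 1 − *s*, which the calibration tests recover within
  three binomial standard deviations at ≥ 10⁵ bases.
* **Truth SAM** — each read placed at its lifted origin with an N-gapped
  CIGAR reconstructing every simulated error position, flag 0x10 when the
  composed genomic strand is `-`, constant FASTQ qualities (the evaluator
  never reads qualities), and MD/NM tags so match rate is computable
  without the genome FASTA.
* **Determinism** — one integer seed drives genome, annotation and reads;
  identical config + seed gives byte-identical FASTA/GTF/FASTQ/MAF/SAM.

The `perturb_truth_sam` harness shifts every POS by a constant while
keeping CIGARs, dropping (with a warning) records pushed outside
chromosome bounds; it exists to probe the tolerance boundary.

## Numerical and degenerate-input choices

* Tolerance and overlap comparisons are inclusive (`≤ tol`, `≥ min_overlap`).
* `n_input_reads = 0` is an error; zero *aligned* reads yields 0 % for all
  percentages and an undefined (null) mean match rate.
* Unknown chromosomes in queries return empty results (logged once), not
  errors; a missing reference chromosome makes match rate undefined for
  the affected reads rather than failing the run.
* Duplicate primary SAM lines for one read: first kept, warning logged.
* BED12 transcripts have no gene attribute; the name column doubles as
  gene id, so expressed-gene counts over BED annotations are per-transcript.

## Problem sizes used in tests

The bundled suites run the full pipeline at 10–20 genes and 300–2,000
reads per dataset, 200 randomized small runs for the ordering properties,
1,000 random transcripts for the liftover oracle, and ≥ 10⁵ aligned bases
per error-rate calibration point — sizes chosen so the complete suite
exercises every code path in well under a minute on one CPU.

## Known limitations

* Only PBSIM-style MAF truth is supported; other simulators' truth formats
  (NanoSim, Badread) would need their own parser behind `MafOrigin`.
* GFF3 is not parsed (GTF and BED12 only).
* Chimeric reads are scored by their primary-line blocks; no attempt is
  made to evaluate fusion-like placements.
* MAPQ and base qualities are ignored throughout.
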