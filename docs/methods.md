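# Methods

## Scope and model

`promoterscope` implements a promoter-architecture analysis pipeline for
CAGE and ChIP data, of the kind used to ask how a chromatin factor
distributes across promoter types in *Drosophila*:

1. **TSS re-annotation from CAGE.** Aligned CAGE 5' ends are tallied into
   single-base tag tracks per chromosome and strand, normalized to tags
   per million (TPM), and merged into tag clusters by single-linkage
   chaining: positions on the same chromosome/strand whose
   nearest-neighbour gap is at most `max_gap` (default 40 bp) belong to
   one cluster. Singleton clusters below 5 TPM are discarded, then
   clusters below 12 TPM total are dropped as not expressed. Each
   non-overlapping gene takes the highest-TPM surviving cluster whose
   dominant (max-TPM) position lies within a search window around the
   annotated TSS; that dominant position becomes the gene's re-annotated
   TSS and the cluster total its expression. "Active" promoters are those
   above an expression floor (default 2 TPM, optionally capped at top N).

2. **Promoter classification.** Core-promoter elements are modelled as
   IUPAC consensus strings (or 4×L probability matrices) each with a
   TSS-relative window in which a match may start, scanned on the
   sense-strand sequence only (core elements are orientation-specific).
   Element flags feed a fixed rule table: TATA and TCT promoters need
   only their own element; DPE-type promoters may carry DPE/MTE/PB but no
   TATA, TCT, DRE or Ohler 1/6/7; housekeeping promoters may carry
   DRE/Ohler 1/6/7 but no TATA, TCT or DPR element. Labels are counted
   per label, not as a partition — TATA and TCT can co-occur.

3. **Occupancy quantification.** ChIP-seq fragment coverage is compared
   to input via SES (signal extraction scaling) and expressed as
   `log2((IP + pc) / (r·input + pc))`. ChIP-nexus stop bases are kept
   stranded and RPM-normalized. Both feed strand-oriented TSS-centered
   windows: heatmap matrices (1001 bp), metaprofiles (201 bp, sense and
   antisense), per-promoter scores (max log2 ratio in 501 bp for
   ChIP-seq; summed RPM over both strands in 101 bp for nexus),
   expression quantiles (10 near-equal groups by descending expression)
   and per-class score distributions.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `max_gap` | 40 | bp | tag-cluster chaining distance |
| `singleton_min_tpm` | 5 | TPM | singleton cluster floor |
| `min_cluster_tpm` | 12 | TPM | expressed-cluster floor |
| `min_active_tpm` | 2 | TPM | active-promoter floor |
| `search_upstream` / `search_downstream` | 500 / 300 | bp | re-annotation window around the annotated TSS, in gene orientation; the underlying method leaves this unstated, so it is a package default, exposed in config |
| `heatmap_flank` | 500 | bp | 1001-bp matrix window |
| `chipseq_score_window` | 501 | bp | odd so the TSS is the exact center |
| `nexus_score_window` | 101 | bp | summed-RPM score window |
| `ses_bin_size` | 1000 | bp | SES tiling; the method is bin-size dependent and no canonical value exists, so it is configurable |
| `pseudocount` | 1.0 | raw counts | log2-ratio regularization |
| `min_score_fraction` | 0.8 | — | PWM relative-score threshold |

All "centered at the TSS" windows of odd width `2f+1` span offsets
`−f..+f` with offset 0 on the TSS base; windows of even width are
rejected rather than silently shifted.

## Numerical and design choices

* **Filter order.** Clustering happens first; the singleton rule is then
  applied to clusters with exactly one TSS position, followed by the
  12-TPM expression filter. A 5.0-TPM singleton therefore survives the
  singleton rule but is still removed by the expression filter.
* **Dominant-TSS ties** go to the most upstream member in gene
  orientation (smallest coordinate on `+`, largest on `-`), making
  cluster representatives deterministic.
* **Cluster→gene conflicts**: a cluster eligible for several genes goes
  to the nearest annotated TSS, ties to the leftmost gene on the
  chromosome.
* **SES details.** Bins are ordered by ascending IP sum (ties: ascending
  input sum, then coordinate); `Δ(k) = cumInput(k)/totInput −
  cumIP(k)/totIP`; `k*` is the first maximum and `r =
  cumIP(k*)/cumInput(k*)`. Bins empty in both tracks are dropped before
  ordering — they carry no information, and keeping them would make the
  degenerate-background error fire on the trivially correct `IP = input`
  case. `r` is exactly 1 for identical tracks, scales as `1/c` when the
  input is multiplied by `c`, and is permutation-invariant in the bins.
  Because bins tile from coordinate 0, `r` is *not* exactly invariant
  under mirroring the genome (the bin boundaries move); everything
  downstream of a fixed `r` is.
* **PWM threshold convention.** A hit requires score ≥ `min +
  min_score_fraction·(max − min)` over the attainable log-odds range
  (the relative-score convention of standard PWM scanners), with a 1e-3
  pseudocount added to matrix entries before the log. Fraction 1 keeps
  only perfect matches; fraction 0 keeps every offset.
* **Coordinates** are 0-based half-open internally; BED is native, GTF
  (1-based inclusive) is converted exactly at I/O. CAGE replicates are
  summed before TPM normalization.
* **Antisense display sign.** Stranded metaprofiles are stored
  non-negative; the conventional below-the-axis negation of the
  antisense profile is applied only when exporting.

## The synthetic generator

`promoterscope.synthetic` builds the ground-truth data every stage is
tested against. Promoters (default four classes, shuffled along one
chromosome, 2 kb apart on uniform-ACGT background) carry their
class-defining motif planted at the midpoint of its scan window;
candidate promoter regions are rejection-sampled until scanning finds
*exactly* the planted element flags, so class labels are recoverable by
construction and contaminating motifs are absent. Annotated gene TSSs
are jittered ±200 bp from the truth to exercise re-annotation.
Expression is log-normal (`exp(N(4.6, 1.0))`, i.e. a median around
100 TPM with a wide right tail, matching the order of magnitude of
active-promoter CAGE levels); CAGE tags are multinomial across promoters
proportional to expression with Normal(0, 2 bp) positional dispersion
and a 1% uniform noise floor. ChIP-seq IP reads mix a uniform background
with TSS-centered fragments weighted by per-promoter enrichment
(proportional to expression by default; `constant` and `null` modes
support control experiments). ChIP-nexus stops are planted at
class-dependent offsets — downstream-weighted for TATA (+20/+35) and DPE
(+25/+40), upstream-weighted for TCT (−25/−8) and HK (−30/−12) — with
3 bp dispersion.

What the generator does **not** emulate: realistic genome composition
(uniform base frequencies, no repeats or GC structure), overlapping or
ambiguous promoter classes (real promoters mix elements; rejection
sampling forbids it here), replicate variability, fragment-size
distributions, and mappability artifacts. Passing tests therefore
demonstrate algorithmic correctness and the qualitative published
patterns (quantile-wise occupancy decrease, class-dependent footprint
geometry), not quantitative agreement with any real dataset.

The default motif models are literature-derived consensus sequences;
study-specific motif tables can be dropped in via the YAML config, and
entries marked `source: placeholder` refuse to load so half-configured
comparisons cannot run silently.

## Problem sizes used in tests and the acceptance script

Unit and property tests run at 8–50 promoters per class; the end-to-end
determinism test uses 2,000 promoters with 1e6 CAGE tags, 6e5 ChIP
fragments and 2e5 nexus stops — large enough that every quantile and
class has hundreds of members while the whole suite stays fast. The
acceptance script uses 200 promoters (50 per class), 1e6 CAGE tags and
2e5-read ChIP/nexus libraries. The no-trend control for the quantile
analysis evaluates the Spearman correlation of quantile medians averaged
over five simulation seeds, because a single 10-point correlation has
high sampling variance even under the null.

## Known limitations

* SES is implemented from its defining principle (equalize IP and input
  over the least-enriched bin fraction); no published reference tracks
  exist to compare bit-for-bit, and the estimate carries a small
  (percent-level) finite-depth bias on null data.
* Consensus scanning is exact-match over IUPAC degeneracy; mismatch
  tolerance requires switching that element to PWM mode.
* Gene models must be non-overlapping (enforced, with offenders named);
  overlapping-gene genomes need pre-filtering.
* The CLI consumes aligned, pre-filtered inputs (BED/bedGraph/GTF/
  FASTA); BAM ingestion and read processing are out of scope.
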