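# Methods

This note documents the models, algorithms and design choices behind
seqscrub: what each stage computes, which parameters matter, what the
synthetic-read generator emulates, and where behaviour was genuinely open
and had to be decided.

## Processing model: packs, workers, reproducibility

Input records are read in order and grouped into *packs* of fixed capacity
(default 1,000 records; only the final pack may be short). Each pack is
routed to a worker purely by `pack_index mod worker_count` — with two
workers this is an odd/even split — and transformed by a pure per-pack
function. Outputs are reassembled strictly in ascending pack index.

Because routing is a pure function of the pack index and reassembly is
in-order, the byte content of every output file and every report number is
independent of the worker count and identical across repeated runs. That
contract, not any particular threading mechanism, is what delivers
reproducibility; the scheduler in this package is sequential, with
worker-local statistics kept separate and merged at the end so the
merge-algebra requirements (below) are genuinely exercised.

Two stages are deliberately *not* worker-local:

* **Duplicate marking** is order-sensitive (the first occurrence survives),
  so it runs at the reassembly point, where records appear in input order
  regardless of scheduling.
* **Post-filtering QC** must see only surviving reads (duplicate dropping
  is decided at reassembly), so it accumulates there too. Pre-filtering QC,
  insert-size and adapter counters are worker-local and merged.

Per-pair stage order: UMI extraction → global trim → polyX/polyG → window
cuts → overlap analysis (correction, then adapter clipping; adapter-by-
sequence only when no overlap was found) → filters → duplicate check →
output/merge. Disabled stages are skipped entirely, so changing the
configuration of a disabled stage cannot change output.

## Overlap analysis

For a pair (R1, R2), R1 is aligned against the reverse complement of R2
with substitutions only (no gaps; indel-free short-read overlap is the
standard assumption). The *offset* is the position in R1 coordinates where
reverse-complemented R2 begins:

* `offset >= 0`: fragment longer than either read; insert = offset + len2.
* `offset < 0`: both reads overran the fragment into adapter (read-through);
  insert = overlap length.

Candidate offsets are scanned outward from zero, non-negative before
negative at equal magnitude — a deterministic tie-break that prefers the
longest-overlap explanation. The first candidate whose overlap spans at
least `overlap_len_require` (default 30) bases with at most
`min(overlap_diff_limit, floor(overlap_diff_percent_limit × overlap_len))`
mismatches (defaults 5 and 20%) is accepted. The analysis is computed once
per pair and shared by adapter clipping, base correction, merging and
insert-size estimation — the one-pass principle of the pipeline.

Geometric consequences used throughout: with error-free 150-base reads,
inserts in [overlap_len_require, 270] are recovered exactly; inserts above
`len1 + len2 − overlap_len_require` = 270 cannot be evaluated and are
reported in the *unknown* insert-size category. Note this means the insert
histogram of a library whose true mean is near or above that bound is
truncated at the boundary; the unknown count, not the histogram mode, is
the informative number there.

**Adapter clipping.** A negative offset places the fragment end inside both
reads; everything 3' of it is adapter and is removed (R1 keeps `len2 +
offset` bases, R2 keeps `len1 + offset`). With a non-negative offset
clipping is a no-op. When no overlap is found and an explicit adapter
sequence is configured, a leftmost-match adapter search (≥4 matched bases,
mismatch fraction ≤ 0.2) is used instead.

**Base correction.** At each overlap mismatch, if one mate's base quality
is ≥ Q30 and the other's is < Q15, the low-quality base is replaced by the
strand-consistent base of the high-quality mate and inherits its quality.
Symmetric mismatches are never touched, so correction cannot invent
consensus where the data are ambiguous.

**Merging.** The merged read covers the fragment in R1 orientation. Inside
the overlap the higher-quality base wins (ties go to R1); merged quality is
the max of the two where bases agree and the winner's where they disagree.
Merged length always equals the evaluated insert size. The quality rule is
a documented choice: no posterior recomputation is attempted.

## Trimming and filtering

* **Global trim:** unconditional removal of `trim_front`/`trim_tail` bases.
* **Window cuts** (window 4, mean ≥ Q20 by default, arithmetic mean of
  Phred scores; windows shrink at the read end):
  * *front*: drop 5' bases up to the first window whose mean passes;
  * *tail*: mirror image from the 3' end;
  * *right*: truncate from the start of the first window whose mean fails.
* **polyG/polyX:** a 3'-terminal single-base run of ≥ `min_len` (default
  10) is removed. A run of length L tolerates up to L // 8 mismatching
  bases, but a mismatch only counts as interior to the run when the next 8
  bases toward the 5' end all match — without that condition a run would
  "leak" across its true boundary onto a coincidentally matching prefix
  base. An exact-run mode is available.
* **Filters**, applied in a fixed order with first-failure-wins so the
  per-reason counts partition the reads exactly: low-quality (fraction of
  bases below Q15 exceeding 40%), too-many-N (> 5), too-short (< 15 after
  trimming), too-long (disabled by default). For pairs, the earliest
  failing rule across both mates is the pair's verdict.
* **UMI extraction** moves the leading `umi_len` bases (plus `umi_skip`
  discarded bases) of the designated read(s) into both mates' names as
  `:UMI` (`per_read` joins the two UMIs with `_`); index-based schemes copy
  the UMI from the comment's index field and leave sequences untouched.

Defaults follow the conventions established by widely used FASTQ
preprocessors so that existing pipelines can swap the tool in without
re-tuning thresholds.

## Bloom-filter deduplication

B bit arrays (default 3) of L bits each, with B independent seeded hash
functions (64-bit blake2b keyed by fixed per-array seeds, reduced mod L;
fixed seeds are part of the run-to-run reproducibility contract). A read's
key is its sequence; a pair's key is the two sequences joined by `|`,
hashed exactly like a single-end read. If all B addressed bits are already
set, the read is a duplicate; otherwise all B bits are set and it is
unique.

Properties that follow: bits only transition 0→1, so an exact repeat of a
seen key is *always* flagged (no false negatives); memory is exactly
B × L / 8 bytes regardless of read count; false positives occur with
probability ≈ (1 − (1 − 1/L)^u)^B after u unique insertions. The reported
duplication rate optionally subtracts the accumulated expected
false-positive count (computed online from the running unique count);
read *removal* always uses the raw per-read verdict. Keys are taken from
the sequence after trimming (so adapter-length jitter does not split
duplicates); `dedup_pre_trim` switches to the raw sequence. The
`dup_calc_accuracy` level 1–6 maps to (L, B) from (2^20, 2) up to
(2^32, 4); the library default of L = 2^32, B = 3 costs 1.5 GiB.

## QC statistics

A single pass accumulates per-cycle base counts, per-cycle quality sums
(overall and conditioned on the called base), Q20/Q30/GC tallies, and
counts of all 4^5 5-mers (windows containing N are skipped). The
accumulator merge is a fieldwise sum — associative and commutative — which
is what allows worker-sharded accumulation to equal a single pass exactly.
Cycle indexing is 0-based internally and 1-based in plots.

Overrepresentation analysis samples every s-th read (default 1 in 20,
keyed on the global read index so sampling is scheduler-invariant).
Candidate substrings of lengths {10, 20, 40, 100, read_len/2} are
collected from the first 50 sampled reads and counted across the whole
sample; a sequence is flagged when its count reaches
`max(10, expected × 10)` with `expected = 0.25^len × positions scanned`.
Flagged sequences carry a per-start-cycle hit histogram. Collecting
candidates from a seed window bounds memory; a contaminant present at
appreciable frequency appears in the first 50 sampled reads with
near-certainty.

## Reports

The JSON report is the single source of truth: fixed key order, versioned
schema, counts taken directly from the pipeline counters. The HTML report
renders summary/filtering tables, per-cycle quality and content curves,
the insert-size distribution with its unknown category, and the
overrepresented-sequence table with per-cycle sparklines as self-contained
inline SVG — and embeds the full JSON payload in a
`<script type="application/json">` block, so every number shown is also
machine-readable and the two reports cannot disagree.

## Synthetic-read generator

The generator emulates a modern short-fragment paired-end library and is
the ground truth for every recovery test:

* fragments drawn from a fresh random reference (default 200 kb — long
  enough that independent fragments rarely coincide, so natural duplicate
  collisions stay rare as in a real genome);
* insert sizes ~ Normal(170, 35) truncated at 1: a cfDNA-like distribution
  giving a realistic mix of read-through (~28%), ordinary overlapping, and
  a small unestimable tail;
* 150-cycle reads; R1 is the fragment 5' prefix, R2 the reverse complement
  of the 3' suffix; read-through continues into the TruSeq adapter and
  then random bases;
* per-cycle mean quality decaying linearly 36 → 32 with Gaussian noise
  (sd 2), clipped to [2, 40] — a binned-quality modern-platform profile;
* substitution errors at 0.1% per base by default; error bases get quality
  ~ Normal(8, 2) clipped to [2, 12], reflecting that miscalls are
  low-confidence (this coupling is what the asymmetric-quality correction
  rule exploits);
* optional exact duplicates: with probability `duplication_rate`, a pair is
  a verbatim copy (sequence and qualities) of a uniformly chosen earlier
  pair;
* optional polyG tails and UMIs.

All randomness flows through one seeded generator with a fixed draw order
per pair, so a seed fully determines the corpus and truth table.

What the generator does *not* model — and hence what passing tests do not
demonstrate about real data: indels, quality binning artifacts, optical
duplicate structure, per-tile effects, adapter dimers, and base-composition
bias. Recovery rates measured here are upper bounds for messier libraries.

## Problem sizes and numerical choices

Verification corpora: 50,000 pairs for the reproducibility check (run at
1/2/4/8 workers plus a repeat), 100,000 keys for dedup accuracy against an
exact-set oracle (L = 2^20, B = 3, 20% planted duplication over a 2 Mb
reference), 10,000 pairs for adapter removal at 0.5% error, ~900
constructed pairs spanning every insert size in [40, 260] for offset
recovery, 5,000 pairs for correction/merging, 1,000 reads for the QC
brute-force comparison. These sizes make binomial noise small relative to
every tolerance while keeping the whole verification run a few minutes on
one core.

Numerical conventions: Phred+33 only (Phred+64 inputs are rejected, not
auto-detected — detection heuristics misfire on modern data); arithmetic
mean of Phred scores in window trimming (not error-probability averaging);
gzip output uses a fixed mtime of 0 so compressed outputs are byte-stable;
curve values are rounded to 6–8 decimals in reports; the insert-size peak
reports the smallest size on a tie.

## Known limitations

* Overlap alignment is substitution-only; an indel inside the overlap
  shifts the apparent offset and usually causes a no-overlap verdict.
* Single-end adapter handling requires an explicit adapter sequence; there
  is no consensus-based auto-detection.
* The duplication-rate false-positive correction assumes hash uniformity
  and independence across the B arrays; at extreme fill factors the
  correction under-estimates.
* Merged-read qualities are max/winner values, not recalibrated
  posteriors.
* The sequential scheduler satisfies the reproducibility contract but does
  not itself demonstrate multi-core speedup.
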