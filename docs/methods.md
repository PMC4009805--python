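# Methods

## Overlap alignment

Tag detection uses global-alignment recurrences with linear gap costs
and free end gaps: the first row and column of the DP matrix are zero
and the optimum is taken over the last row and column. Free end gaps
mean a tag may overhang either read end at no cost, which covers both
5' barcodes (tag flush with the read start) and 3' adapter read-through
(only a tag prefix on the read).

Numerical/determinism choices, fixed because the optimum is often tied:

* The optimum cell is chosen by scanning the last row left-to-right,
  then the last column top-to-bottom, taking the first maximum.
* Traceback prefers a diagonal move, then a gap in the read (consume
  tag), then a gap in the tag.
* `N` (letter space) and `.` (color space) score as mismatches against
  every character, including themselves. This is conservative: an
  uncalled position never contributes evidence for a tag.
* Scores are integers throughout; only the acceptance bound below is
  fractional.

`overlap_length` counts alignment columns between the overlap start and
end — matches, mismatches and internal gap columns — and excludes the
free end gaps.

## Acceptance: minimum overlap and similarity threshold

An alignment is accepted iff `overlap_length >= min_overlap` and

```
score >= L*match - T*(L/10)*(match - mismatch)      (L = overlap_length)
```

The functional form was reconstructed from the threshold's documented
behaviour on 7-mer barcodes — threshold 2 tolerates exactly one
substitution over the full barcode, threshold 1 tolerates none — and is
exact for those cases under the default scoring: the bound at L=7 is
4.2 for T=2 (one mismatch scores 5, two score 3) and 5.6 for T=1. The
`T*(L/10)` term makes the tolerated error budget scale linearly with
the overlap, so longer tags earn proportionally more tolerance. T=0
accepts only perfect overlaps.

Defaults, chosen to make the worked 7-mer mapping hold exactly and to
fit Illumina-like error profiles (substitutions dominate indels):

| parameter | adapters | barcodes | why |
|---|---|---|---|
| match / mismatch / gap | 1 / −1 / −6 | 1 / −1 / −6 | gaps ≈ 3 substitutions; indels rare on Illumina |
| min_overlap | 3 | barcode length | adapters must be found as short 3' fragments; barcodes are matched end to end |
| threshold T | 1 | 1 | no tolerated error unless the user opts in |

Barcode and adapter detection are configured independently (separate
scoring, mode, acceptance), so barcode assignment can be strict while
adapter removal stays sensitive.

## Trim modes

`LEFT`/`RIGHT` search the whole read and remove everything from the
match to the 5'/3' end respectively; the positional restriction to a
prefix/suffix is realised through these trim semantics, not by
restricting the DP matrix. Only the TAIL modes restrict the search
region itself, to the first/last *m* positions (*m* = tag length; if
*m* > *n* the region degenerates to the whole read). `ANY` retains the
longer non-matching side; on a tie the 5' side is kept (fixed for
determinism). One adapter pass is performed per read per run; repeated
adapter copies require a second run.

## Filters and processing order

Per read (both mates of a pair independently, except barcode
assignment, which is decided on mate 1 or the separate barcode read):

1. uncalled filter (`max_uncalled`, default 0) — failing reads are
   routed to an `_uncalled` output immediately and skip all tag
   processing;
2. fixed pre-trims (`pre_trim_left/right`, default 0);
3. 3' Phred clipping (`pre_trim_phred`, default off): positions are
   removed from the 3' end up to the first position with quality ≥
   cutoff;
4. barcode assignment (and trim, unless `keep_barcode` or the barcodes
   come from separate barcode reads);
5. adapter detection and trim;
6. 3' truncation to `post_trim_length` (default off);
7. length gate (`min_readlength`, default 18 — shorter reads rarely map
   uniquely);
8. routing.

Each filter is idempotent, and on quality-clean reads the filter stage
is the identity. Trimming may produce empty reads; they are
representable (the record type allows an empty sequence) and are removed
by the gate.

## Demultiplexing

Barcodes are matched with `find_best_tag`; ties on score go to the
barcode listed first in the input FASTA (this generalises the
"prefer the first leader" convention used in splice-leader screens).
The unassigned stream is always materialised, even when empty, so
downstream accounting never has to special-case a missing file. With
separate barcode reads, barcode read *i* labels sequencing read (pair)
*i* positionally and sequencing reads are never trimmed by barcode
matching. For paired-end data with in-read barcodes, only mate 1 is
searched (single-sided barcoding is the common library design).

## Paired-end synchronisation

A pair is dropped from the paired outputs as soon as either mate fails
the length gate, so the `_1` and `_2` files always contain the same ids
in the same order. With `single_reads`, the surviving mate goes to a
`_single` file instead of being discarded; with `write_short`,
sub-gate reads go to `_short` files.

## Color space

SOLiD reads encode 2-base transitions: each color digit is determined
by an adjacent base pair via the standard dibase matrix (identical
bases → 0, symmetric, each row a permutation of {0,1,2,3}), and a read
is one primer base plus *len*−1 colors. Letter-space tags are converted
to their color digits (primer-independent) for matching; tags supplied
as digit strings are used verbatim. Qualities score colors, not
letters.

Trimming a color read's 5' side removes the matched colors **plus the
color at the cut junction**, because that color encodes a transition
from a removed base; the result carries no primer base and re-anchors
only through its remaining transitions. After a 3'-side trim the last
retained color likewise encodes the transition into the first removed
base; it is kept (the record stays primer-anchored and decodable), and
consumers should regard the final color of a 3'-trimmed color read as
junction-contaminated. Both behaviours are package decisions — the
encoding itself does not define a re-anchoring rule.

## Parallelism

Worker parallelism is chunk-based (2,048 reads per chunk) with bounded
submission and an ordered merge, so output files are byte-identical for
any thread count. The contract is determinism, not throughput.

## Synthetic-read generator

`simgen` emulates a demultiplexing experiment: barcodes are planted
round-robin at the 5' end (a multiple of the barcode count gives exact
balance), mutated by a per-position independent error model
(substitution, insertion, deletion, uncalled, each a Bernoulli event),
and followed by a uniform-random insert; `exact_substitutions=k` plants
exactly k substitutions instead, for deterministic error budgets.
`generate_pairs` produces read-through pairs: a random insert length in
[10, read length + 10] by default, with each 36-nt mate padded by
adapter sequence when the insert is short — so adapter trimming
recovers the insert and short inserts fall below the 18-nt gate.
Qualities are a constant Phred 35.

The default barcode set is eight 7-mers with pairwise Hamming
distance ≥ 5, so under the threshold-2 error budget one substitution is
always correctable and two substitutions can never be captured by a
wrong barcode. A distance-3 set would satisfy one-error correction but
not the second guarantee.

What the generator does **not** model: position-dependent quality
ramps, homopolymer and GC biases, chimeras, or real instrument error
profiles. Tests passing on this data therefore demonstrate the
correctness of the alignment, trimming, routing and accounting logic
under controlled error classes — not end-to-end accuracy on a given
real instrument run.

## Verification scale

The test suite and the acceptance script run at desk scale:
10,000-read demultiplexing scenarios, 10,000 synthetic pairs for
pair-sync and determinism checks, a 260,100-pair exhaustive
alignment-oracle sweep over {A,C} sequences up to length 8 against an
independent free-end-gap aligner (Biopython's PairwiseAligner), raw
brute-force enumeration up to length 4, and 10,000-sequence color-space
round trips. These sizes exercise every code path and tie-break while
keeping a full run in tens of seconds.

## Known limitations

* No affine gap penalties; gap cost is linear per gap column.
* One adapter-removal pass per read; tandem adapter copies need a
  second run.
* No paired-end overlap (read-through) inference between mates.
* No dual-index demultiplexing or error-correcting barcode codebooks.
* Output quality encoding always matches the input encoding; no
  re-encoding between offsets.
* The default adapter `min_overlap` of 3 accepts chance 3-mer matches
  (expected in ~1.6% of reads at the extreme 3' position); raise
  `--adapter-min-overlap` or the threshold when spurious trims matter
  more than missed short fragments.
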