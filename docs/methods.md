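# Methods

## The screening problem

An arrayed clone library of `n_plates × plate_format` wells is screened by
sequencing pools instead of individual clones. The library is organised in
*sets* of consecutive plates (default 10); pools never span sets, matching
the practice of barcoding each pool uniquely within its set. Within a set,
every clone belongs to exactly three pools, one per dimension:

* **direct384** — each plate is one plate pool; each row letter pools that
  row across all plates of the set; likewise columns. A k-plate 384-format
  set yields k + 16 + 24 pools (a 96-format set, k + 8 + 12 — the direct
  strategy adapts the row/column pool counts to the plate format).
* **rearray96** — each 384-well plate is split into four quadrants
  re-arrayed into 96-well plates, then pooled as above in 96-format:
  4k + 8 + 12 pools. Fewer clones per plate pool means higher per-clone
  coverage.

The quadrant convention is the interleaved-parity robotic re-array: 0-based
384 well (r, c) goes to quadrant `2·(r mod 2) + (c mod 2) + 1` at 96-well
position `(r div 2, c div 2)`. Any fixed bijection would serve; this one is
the standard interleave and is exercised by an exhaustive round-trip test.
Clone identifiers are always reported in original 384-format coordinates
(`P{plate:02d}{row}{column:02d}`), regardless of strategy.

A pool triple (plate, row, column) intersects in at most one well by
construction; `coordinates_from_pools` resolves it and maps re-arrayed
coordinates back through the inverse quadrant map. The total pool count is
reported per set and never asserted globally.

## Cross-pool matching

Pooled copies of the same insert differ only by per-pool assembly noise,
modelled as substitutions. The matcher is therefore a seed-and-extend
nucleotide aligner without gaps:

* exact k-mer seeds (default k = 15), located via a sorted 2-bit-packed
  index over the forward strands of the subject contigs; queries are
  scanned in both orientations, so minus-strand matches are reported with
  strand "−";
* seeds sharing a (subject, diagonal) are extended once: per-column
  match/mismatch scores (+1/−2) are accumulated outward from the seed and
  extension stops where the running score falls more than the X-drop
  (default 20) below its maximum, ending at that maximum;
* identity = matches / alignment columns; with no gaps, columns equal the
  alignment length. Alignments shorter than `min_aln_len` (default 100 bp)
  are discarded — this makes behaviour independent of database size, which
  an e-value threshold alone is not;
* significance uses the ungapped Karlin–Altschul expect value
  `E = K·m·n·exp(−λS)` with m the query length and n the total indexed
  subject length. λ is the positive root of
  `Σᵢⱼ pᵢpⱼ·exp(λ·s(i,j)) = 1`, solved by Brent root-finding from the
  configured scores and background base frequencies (λ ≈ 1.3327 for +1/−2
  at uniform frequencies). K is a configured constant (default 0.621, the
  standard ungapped nucleotide value for this scoring); it scales E only
  multiplicatively, which is immaterial against the 1e−6 cutoff, so an
  exact series computation was not warranted.

Hits pass at ≥95% identity and E ≤ 1e−6; the best-scoring hit per
(query, subject) pair is kept. Output is deterministic: queries processed
in id order, ties broken on lexicographic subject id. Queries whose own
pool is present in the index are rejected (comparisons are strictly
cross-pool). The matcher's identity is validated against a full
dynamic-programming alignment oracle (Biopython PairwiseAligner) to within
±0.5 percentage points on a seeded mutated-pair panel.

Gapped refinement is deliberately not applied: the generator produces
substitution-only divergence between pool copies, and the e-value reuses
the ungapped statistics. This is a documented approximation; on real
assemblies with indels the matcher would under-call identity near gaps.

## Deconvolution

Plate-pool contigs are the queries (they carry the highest per-pool
coverage and anchor the coordinate system). Per contig:

* **complete** — at least one row-pool and one column-pool hit;
* **partial** — hits in exactly one other dimension;
* **singleton** — no significant hits.

The three statuses partition the plate contigs. For complete contigs,
every (row pool, column pool) pair in the hits forms a candidate well via
the pooling design; the candidate's combined score is the sum of the best
hit score in each dimension, and candidates are ranked by score then
canonical well id ("rank-all" policy). Pool pairs with an empty coordinate
intersection are flagged, not fatal.

Two summary rates are produced per set: the fraction of plate contigs that
are complete, and the per-clone coverage — the fraction of wells recovered
by at least one complete contig with a single candidate.

**Resolution of multi-candidate contigs.** Contigs carrying conserved
sequence shared between clones (in the synthetic library, the fixed domain
markers; in real data, conserved domains of homologous BGCs) accumulate
short high-identity hits into pools of unrelated clones, so they are
rarely strictly unique. These spurious hits are far weaker than the
clone's own full-length overlaps, and the structure is per-dimension: the
true row pool outscores competing row pools by orders of magnitude, and
likewise columns. An assignment is therefore *resolved* when it is unique
**or** the best row pool and best column pool each outscore every
competitor in their dimension by a dominance ratio (default 1.5×) and
their intersection is the top-ranked candidate. Resolved assignments feed
clone records and deduplication; the stricter unique-only coverage is
reported alongside. (A margin on the summed score does not work: the
runner-up candidate shares the true row pool's large score, so the sum
ratio stays near 1.3 even when the column evidence is 20× apart.)

**Deduplication.** Within one well, annotation instances of the same BGC
class collapse to a single record — correcting the count of contigs that
belong to the same clone. Annotations on unresolved contigs cannot be
corrected and remain counted individually. The per-class table reports raw
count, deduplicated count, and the percentage of deduplicated entries with
a well coordinate; the totals row uses the deduplicated weighting, with
the raw-weighted percentage kept in the table's metadata since either
weighting is defensible.

## Screening rules

* Mining pre-filter: contigs strictly longer than 1000 bp.
* Module parsing: a module ends at each carrier domain (ACP or PCP);
  tokens after the last carrier form a final incomplete module. A module
  is complete iff its chemistry's core set is present — PKS {KS, AT, ACP},
  NRPS {C, A, PCP}. Tailoring domains (KR, DH, ER, MT, TE, E) never affect
  completeness. This carrier-terminated segmentation reproduces the
  structure of the worked cluster descriptions (e.g. a 4-module PKS of
  KS-AT-KR-ACP repeats; a NRPS module lacking only its A domain parsed as
  incomplete).
* Viability: a cluster is viable iff it contains ≥3 consecutive complete
  modules. Completing an incomplete module can never revoke viability
  (monotone; property-tested).
* Divergence of a domain from its best database match is 100 − % identity,
  an involution on [0, 100]. Per-clone summaries are arithmetic means over
  the clone's KS/A domains.
* 16S ribotype hits are kept iff e-value < 1e−5, initial alignment
  ≥ 45 bp, and hit length ≥ 300 bp; the phylum label requires ≥75%
  identity, otherwise the hit is kept as "unclassified". The 300-bp rule
  reads the total hit length by default; a toggle applies it to the
  initial alignment instead, since the original phrasing is ambiguous.
* Hit rates are 100·count/library-size, rounded to the requested decimals
  (2 for sub-1% rates, 1 otherwise).

The toy cassette detector recovers planted domain architecture from
synthetic contigs by exact marker scanning on both strands, grouping
occurrences within 600 bp into one annotation. Cluster class follows the
module chemistry mix: PKS-only → "Type I PKS", NRPS-only → "NRPS", mixed →
"Type I PKS-NRPS". It is a stand-in for a gene-level annotator on
simulated data only, and exact matching means a substitution inside a
marker hides that one domain.

## Synthetic library generator

The generator emulates the *post-assembly* state of a pooled screen;
read-level assembly is not simulated mechanistically.

* **Inserts** — one per well; lengths log-normal (arithmetic mean and
  log-dispersion configurable, default mean 6 kb, σ = 0.35) truncated to
  configured bounds; uniform random nucleotides. Real inserts span roughly
  12 kb to >200 kb with a ~113 kb mean; desk-scale runs use kilobase-scale
  inserts, which changes absolute contig sizes but none of the pooling or
  deconvolution logic.
* **Cassettes** — with probability `cassette_rate` a clone receives one
  cassette (PKS, NRPS or hybrid plan with complete modules). Each domain
  token is a fixed 120-bp marker generated once from an internal constant
  seed (the vocabulary is part of the format), separated by 40-bp random
  linkers; the cassette overwrites a uniformly placed window on a random
  strand, preserving insert length.
* **Fragmentation** — per pool and clone, breakpoints are Poisson with
  expected fragment length `E(cov) = base + (plateau − base)·min(cov, c*)/c*`
  (defaults 300 bp, 8 kb, c* = 55), a saturating stand-in for the observed
  "longer contigs with more coverage, up to ~55×" behaviour; no
  quantitative fragmentation model exists to copy, so the shape is
  calibrated qualitatively. Per-clone per-pool depth is Gamma-distributed
  around the pool coverage (shape 6; ∞ = uniform) and drives both
  fragmentation and the contig coverage metadata, so length and coverage
  co-vary and the knee is recoverable from simulated stats. Fragments
  below `min_fragment_len` (default 300 bp) are dropped.
* **Noise and contaminants** — substitutions i.i.d. per base (ε < 0.25);
  optional host/vector contaminant contigs drawn from bundled synthetic
  reference surrogates at a configured fraction per pool.
* **Ground truth** — every non-contaminant contig records its source well
  and interval; cassette and clone tables accompany the contigs. Contig
  ids embed the pool tag and a serial (`S1.plate.03|c000007`) and parse
  back to their pool.
* **Reads (optional)** — paired 2×150 bp with flat Phred qualities, pair
  count `round(depth·L/(2·read_len))` per clone per pool. Platform error
  profiles are out of scope.

Everything is deterministic under the caller's seed; the pipeline derives
independent per-stage substreams from the master seed and logs them.

What passing simulated tests shows — and does not. The simulator gives
exact ground truth for pooling membership, contig origin and cassette
content, so it validates the combinatorics, the matcher's behaviour under
substitution noise, and the deconvolution/deduplication logic. It does not
model chimeric misassembly, repeat-induced cross-clone identity (beyond
the shared domain markers), coverage-dependent assembly failure, or indel
divergence; real-library rates (e.g. the 38% contig / 78% clone figures of
a full-scale screen) are not reproducible at desk scale and are not
asserted.

## Statistics

* Spearman's rho is Pearson on average ranks (tie-corrected), via
  scipy; constant input is an error. Verified against an independent
  rank-Pearson computation to 1e−12.
* Tukey fences: quartiles by linear interpolation between order statistics
  (the convention is stated because the source analysis does not state
  one); fences at Q1/Q3 ± 1.5×IQR; removal is single-pass and points
  removed are strictly outside the fences. Re-running may remove more.
* Kruskal–Wallis: tie-corrected H with the chi-square approximation;
  groups with identical pooled values return H = 0, p = 1. At very small
  samples (4+4) the chi-square p deviates from the exact permutation p by
  up to ~0.03 at intermediate H — an inherent property of the asymptotic
  approximation, shared by all standard implementations; the oracle
  comparison in the tests is exact-permutation based.
* Dunn's post-hoc z tests use pooled mean ranks with the tie-corrected
  variance; multiplicity adjustment is Benjamini–Hochberg by default with
  Holm available. p-values are reported exactly, never truncated to a
  floor like "<2.2e-16".
* The coverage–length profile bins coverage (default 5×), takes the median
  length per bin, estimates the plateau level as the median of the top
  quarter of bins, and places the knee at the first bin whose median
  reaches within 5% of that level. Profiles still climbing at the end are
  flagged "no-plateau"; single-bin profiles "degenerate". The knee is
  descriptive output, never asserted against real data.

## Pipeline and formats

Stages run as design → simulate → (optional read QC) → match →
deconvolute → screen → stats. Every stage writes TSV/FASTA/JSON artifacts
plus a manifest echoing the configuration, derived seeds, per-stage
counters and output checksums; identical configuration and seed give
byte-identical manifests. A stage failure raises a typed error naming the
stage and keeps earlier artifacts.

All interchange intervals are 1-based inclusive; the hits table follows
the conventional tabular alignment column order. FASTA/FASTQ I/O is
Biopython SeqIO (wrapped/unwrapped, LF/CRLF accepted); tables round-trip
byte-identically (TSV floats are re-read with round-trip precision).

Read QC stand-ins: quality trimming is an end-trim at Q ≥ 30 with a 30-bp
minimum length (the simplest contract consistent with "quality-filter,
trim, drop short reads"; sliding-window trimming is not implemented), and
host/vector subtraction is exact k-mer containment (k = 31, both strands):
a sequence is removed when ≥ τ (default 0.5) of its k-mers occur in the
reference set. Both are deterministic replacements for mapping-based
tools with the same keep/remove contract.

## Known limitations

* Ungapped matching and e-values: indel-divergent copies are found but
  clipped at the first gap; identity near gaps is conservative.
* Marker-based cassette detection is exact-match and synthetic-only.
* The dominance ratio (1.5×) for resolving multi-candidate contigs is a
  heuristic chosen for a wide margin between full-overlap scores and
  short conserved-element crosstalk; libraries dominated by near-identical
  repeated inserts would defeat it (and any 3D pooling scheme).
* Per-set matching assumes barcodes isolate sets perfectly; index-hopping
  between pools is not modelled.
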