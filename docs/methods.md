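# Methods

## Problem and model

Telomere-to-telomere assembly curation constantly asks whether an alignment
between two sequences (read/contig vs. reference, contig vs. contig) is real
or an artifact of repeat homology. Inside a family of near-identical repeat
copies, the aligner's mapping quality (MAPQ) is uninformative: a contig
sampled from one copy aligns to every copy with few mismatches and maximal
MAPQ. The copy-specific signal is carried by **rare k-mers**: length-k
subsequences whose genome-wide count is at most R (R = 1: *unique* k-mers).
Within a repeat family the only rare k-mers are windows that overlap positions
where copies differ — exactly the SNP/SV information curators would otherwise
have to call explicitly, at far higher cost.

For each alignment we compute

* `e` — the number of rare k-mers of the target genome whose full window lies
  inside the aligned target interval `[tstart, tend)` (the markers the
  alignment is *expected* to explain), and
* `m` — how many of those markers actually match the query: the window's
  inverse image under the CIGAR is co-linear (no indel inside the window) and
  the query subsequence equals the target window (reverse-complement equality
  on minus-strand alignments). Sequence equality is always re-checked from the
  FASTA, never assumed from `=` operators.

The k-mer mapping quality is

```
KMAPQ = round(60 * m / e)    (half-up, clipped to [0, 60]; e = 0 -> 0)
```

scaled to the familiar 0–60 MAPQ range so that a perfect copy-specific
alignment scores 60 and an alignment contradicted by every marker scores 0.
Half-up rounding is implemented in integer arithmetic
(`(120m + e) // 2e`) so scores are platform-stable. Under the CIGAR path
`m <= e` holds by construction and is enforced; violating it is an internal
error, not a data condition.

**Uninformative alignments.** When `e = 0` the aligned region carries no
markers: a repeat so perfect it cannot be adjudicated either way. Such
alignments are *not* false positives; they are flagged `uninformative`,
score 0, and bypass the KMAPQ threshold in filtering (they are kept and
labeled, never silently removed). They remain subject to the MAPQ threshold.

**Filtering.** An alignment is kept iff `mapq >= min_mapq` and
`kmapq >= min_kmapq` (with the uninformative exception above). The working
threshold used throughout the examples is `min_kmapq = 30`, i.e. an alignment
must explain at least half of its expected markers.

## Rarity and canonicalization choices

* Rarity is computed over the **target/reference FASTA only** ("the whole
  genome"); queries are tested against this set but never change it — a query
  need not be a genome.
* Counting is **canonical**: a k-mer and its reverse complement share one key
  (A<C<G<T matches the 2-bit numeric order, so the numeric minimum of the two
  codes equals the lexicographic minimum). This is required for markers to
  survive minus-strand alignments.
* Windows containing `N` are excluded rather than treated as wildcards.
* Defaults: `k = 21` (standard marker size at which nearly every
  non-repetitive window of a eukaryote-scale genome is unique; configurable
  2–31 so codes fit in 62 bits), `R = 1` (unique k-mers; configurable for the
  looser "small number of times" notion).
* Coordinates are 0-based half-open everywhere (PAF convention).

## Match finding: two paths

**CIGAR path** (used whenever the PAF record carries `cg:Z`): every rare
target position in the interval is projected through the CIGAR onto the
query. A window matches only if it sits inside one maximal indel-free block
(strict co-linearity; a relaxed tolerance is deliberately rejected so a match
always means "the marker itself agrees") and the sequences are equal.
Minus-strand records follow the minimap2 dialect: `qstart/qend` are on the
original query strand, the CIGAR walks the reverse-complemented query against
the forward target, and a frame position `q'` corresponds to original
position `qlen − 1 − q'`.

**Anchored path** (plain 12-column PAF, no CIGAR): candidate anchors are rare
k-mers occurring exactly once in the aligned query interval and exactly once
in the aligned target interval with equal canonical codes; the profile is the
longest strictly monotone chain of anchors (both coordinates increasing on
`+`; target increasing, query decreasing on `−`). Among equal-length chains
the one with the earliest query positions is selected, deterministically
(DP over candidates sorted by query position, first-maximal predecessor).
The CIGAR path is exact and preferred; the anchored path is a fallback and
the path used is recorded per record in the `.rkm` file.

## Synthetic scenario

The generator emulates the situation the method exists for: a genome with
`n_copies` near-identical instances of one ancestral repeat, and a contig
sampled from one copy that aligns to all of them.

* Background and ancestor are i.i.d. uniform A/C/G/T; copies are placed
  non-overlapping with multinomially distributed gaps.
* Each copy receives `Binomial(copy_length, divergence/2)` substitutions and
  `Binomial(copy_length, indel_rate)` 1-bp indels at positions drawn
  **disjoint across copies**, so the expected pairwise substitution rate is
  `divergence` and the pairwise Hamming distance equals the union of the two
  copies' edit lists — making truth CIGARs and NM values exactly recomputable
  from the edit lists alone.
* Truth PAF records are composed through the ancestor coordinate system (no
  aligner involved, so tests are hermetic and seed-reproducible): one record
  per copy, `MAPQ = 60` on all records to reproduce the "aligner quality
  cannot distinguish the copies" premise. An optional documented path scores
  real minimap2 PAF instead.
* Defaults are the reference study conditions used by the acceptance script:
  2 copies of 2.8 kb at 1% divergence, substitutions only, 20 kb genome,
  full-length plus-strand contig from copy 0.

What the simulator does **not** emulate: read-level sequencing error
(HiFi/ONT error profiles), tandem higher-order repeat structure, and
large SVs between copies. Passing tests therefore demonstrate the scoring
machinery and its discrimination logic, not robustness to raw-read noise.

At these conditions the expected markers inside a copy are precisely the
windows covering inter-copy differences (~28 differences × up to 21 windows
each, minus overlaps — typically 400–600 markers per 2.8 kb copy). The
source-copy alignment matches all of them (KMAPQ 60) while the cross-copy
alignment, whose every marker window covers at least one differing base,
matches none (KMAPQ 0): discrimination is essentially deterministic, and the
acceptance run of 100 seeded trials measures it at 100%.

## Problem sizes

Scales were chosen so the whole pipeline is exact and interactive: 2 kb
genomes for brute-force-verified unit oracles, 20 kb genomes / 2.8 kb copies
for the end-to-end scenario, 100 seeded trials for rate estimates. The k-mer
counter is a pure-Python rolling 2-bit encoder (~1 µs/base), ample for these
sizes; genome-scale counting (the published tools' multi-CPU territory) is an
explicit non-goal.

## Rendering

Scenes are built in bp coordinates and serialized to SVG 1.1 text with a
fixed 1200-unit canvas, 80 units per lane, 10-unit sequence bars and linear
per-track scaling, so tests can assert coordinates and byte-identity. Grey
quadrilaterals are alignment areas; red segments connect matching k-mer
pairs (window start positions). On `+` strand the polygon is traversed top
left→right then bottom right→left (a simple trapezoid); on `−` the bottom
corners are emitted in the opposite order so the side edges cross. Zoom is a
`(seq_id, start, end)` region that rescales that track, clips polygons and
drops elements wholly outside; a region equal to the full sequence is the
identity. Global mode orders alignments by `(tname, tstart, qname, qstart)`
and paginates `ceil(n / per_page)` pages.

## Numerical and degenerate-input conventions

* KMAPQ rounding: half-up via integer arithmetic (see above).
* `k` longer than every sequence: empty count map plus a warning, not an
  error.
* Anchored-chain ties: earliest-query-position preference (see above).
* Truth-alignment composition trims boundary indel columns so records never
  start or end in an insertion or deletion.
* Duplicate FASTA ids, empty records, non-alphabetic characters, malformed
  PAF lines/tags/CIGARs, and CIGAR/interval length inconsistencies are all
  hard errors naming the offending record or line.
* IUPAC ambiguity codes other than N are normalized to N on input.

## Known limitations

* The anchored path cannot validate marker agreement at base resolution; a
  rare k-mer present in both intervals but slightly displaced still anchors.
  Prefer CIGAR-bearing PAF (`minimap2 -c`).
* Rarity is global to the target FASTA; scoring a sub-region against an index
  built on a different FASTA is refused only by id/k mismatch, not content.
* `m <= e` can fail on the anchored path in adversarial inputs only if the
  same code occurs once in the interval but at a non-indexed position; codes
  are taken from the index, so this does not arise in practice.
* The SVG layout is a reconstruction suited to scripting and testing, not a
  replica of any interactive viewer's pagination.
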