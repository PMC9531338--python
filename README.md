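# raremark

**Vet alignments in repetitive genomic regions with rare k-mer markers.**

Telomere-to-telomere assembly projects live and die by manual curation of
alignments in repeats: contig assembly, scaffolding, polishing and gap filling
all involve deciding whether an alignment between two sequences is real or a
false positive between near-identical repeat copies. The aligner's MAPQ cannot
make that call — a contig from one copy of an interspersed repeat maps to
*every* copy with MAPQ 60. The copy-specific evidence is in **rare k-mers**:
k-length subsequences occurring at most R times in the whole genome (R = 1:
unique k-mers). raremark is a scriptable toolkit for exactly this workflow:

1. **index** — count canonical k-mers genome-wide and index the rare ones
   (`.rki`);
2. **score** — for each PAF alignment, find which rare k-mers of the aligned
   target interval match the query through the CIGAR, and score

   `KMAPQ = round(60 · m / e)` ∈ [0, 60],

   where `e` is the number of rare k-mers expected in the target interval and
   `m` the number actually matched (each match is one red line in the
   figures); results persist to an indexed `.rkm` file (see `FORMAT.md`);
3. **filter** — keep alignments with `MAPQ ≥ min_mapq` and
   `KMAPQ ≥ min_kmapq`; marker-free (`e = 0`) alignments are kept but flagged
   uninformative;
4. **draw** — deterministic SVG in three modes: a sequence *pair*, *one
   sequence vs. all* its partners, or *global* paginated pages. Grey areas are
   alignments (crossed edges = minus strand), red segments are matching rare
   k-mer pairs;
5. **simulate** — a seed-reproducible repeat-genome generator with exact
   ground-truth alignments, so the whole pipeline can be exercised without
   external data or aligners.

The model, parameter choices and numerical conventions are described in
`docs/methods.md`.

## Worked example

Simulate the canonical trap — two copies of a 2.8 kb interspersed repeat at 1%
divergence, a contig sampled from copy 1 — then index, score, filter and draw:

```sh
raremark simulate --seed 1 -o demo
raremark index demo/ref.fa -o demo/ref.rki
raremark score demo/truth.paf demo/ref.fa demo/contig.fa \
        --index demo/ref.rki -o demo/aln.rkm
raremark filter demo/aln.rkm --min-kmapq 30 -o demo/kept.paf
raremark draw demo/aln.rkm --mode pair --ids contig1,genome1 -o demo/pair.svg
```

which logs

```
[raremark] INFO: simulated 2-copy repeat scenario -> demo
[raremark] INFO: indexed 15548 rare k-mer positions (15548 distinct) -> demo/ref.rki
[raremark] INFO: scored 2 alignments -> demo/aln.rkm
[raremark] INFO: kept 1 / removed 1 alignments; report -> demo/kept.report.tsv
[raremark] INFO: wrote demo/pair.svg
```

and produces this report (`demo/kept.report.tsv`):

```
qname    tname    qstart qend  tstart tend   strand mapq kmapq m    e    uninformative kept
contig1  genome1  0      2800  4745   7545   +      60   60    565  565  0             1
contig1  genome1  0      2800  12296  15096  +      60   0     0    565  0             0
```

Both alignments have MAPQ 60 — the aligner cannot tell the copies apart. But
the alignment to the contig's source copy matches all 565 of its expected rare
k-mer markers (KMAPQ 60), while the alignment to the other copy matches none
(KMAPQ 0): a typical false positive, and the filter removes it
(`demo/kept.removed.paf`) while keeping the real one with `km:i:60 ke:i:565`
tags appended. In `demo/pair.svg` the real alignment is dense with red match
lines; the false one is an empty grey area.

Real data flows through the same commands: align with `minimap2 -c` (the `-c`
keeps the CIGAR, enabling exact per-marker matching; without it an
anchor-chaining fallback is used), then `index`/`score`/`filter`/`draw`
against your reference FASTA.

## Library use

Every subcommand is a thin wrapper over an importable module:
`raremark.kmer_index` (counting, rarity, interval queries),
`raremark.alignment` (PAF I/O, CIGAR projection), `raremark.matching`
(profiles, KMAPQ, filtering), `raremark.rkm_format` (persistence + indexed
lookup), `raremark.render` (SVG scenes), `raremark.synthetic` (simulator).

```python
from raremark import (KmerParams, build_rare_index, read_fasta, read_paf,
                      score_alignments, filter_alignments)

genome = read_fasta("ref.fa")
index = build_rare_index(genome, KmerParams(k=21, max_count=1))
scored = score_alignments(read_paf("aln.paf"), genome, read_fasta("query.fa"), index)
kept, removed = filter_alignments(scored, min_mapq=0, min_kmapq=30)
```

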