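# File formats

All files are plain tab-separated text, 0-based half-open coordinates.

## `.rki` — rare k-mer index

Sidecar of a target FASTA, written by `raremark index` /
`RareKmerIndex.save`.

```
#rki	k=<k>	R=<max_count>
#seq	<seq_id>	<length>          (one per indexed sequence)
<seq_id>	<position>	<code>    (one per rare k-mer occurrence)
```

Rows are sorted by `(seq_id, position)` in FASTA order; `code` is the 2-bit
integer encoding (A=0, C=1, G=2, T=3) of the *canonical* k-mer (lexicographic
minimum of the k-mer and its reverse complement). K-mer strings are never
stored.

## `.rkm` — scored alignments + matching profiles

Written by `raremark score` / `write_rkm`. Gzip-compressed files are accepted
transparently on read.

```
H	k=<k>	R=<R>	version=<package version>	target=<target FASTA name>
A	<m>	<e>	<kmapq>	<uninformative 0|1>	<method cigar|anchored>	<12 PAF columns>	<tags...>
K	<qpos>	<tpos>	<code>
```

* One `A` line per input PAF record, in input order; columns 7+ are the
  verbatim PAF fields (so the original record round-trips byte-identically).
* Each `A` line is followed by exactly `m` `K` lines — one per matching rare
  k-mer pair. `qpos` is on the original query strand, `tpos` on the target,
  `code` is the canonical k-mer code as in `.rki`.

## `.rkm.qidx` / `.rkm.tidx` — offset indexes

```
<seq_id>	<byte offset of an A line>
```

`.qidx` keys by query name, `.tidx` by target name; offsets are strictly
increasing per key and refer to the uncompressed byte stream, so they survive
file copies and allow `lookup()` to seek directly to each alignment block.

## Filtered PAF

`raremark filter` writes kept records to the output PAF and removed records
to a sibling `<output>.removed.paf`. Both carry two appended tags:
`km:i:<kmapq>` and `ke:i:<e>`. The accompanying `.report.tsv` has one row per
input alignment with columns
`qname tname qstart qend tstart tend strand mapq kmapq m e uninformative kept`.
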