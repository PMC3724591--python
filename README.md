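# lolliprot

Lollipop plots of protein mutations, from the command line or as a
Python library.

Sequencing studies routinely produce lists of amino-acid changes, and a
text table hides the single most informative pattern they carry: whether
the changes cluster. Mutations piling up inside one domain — for
example the cysteine substitutions adjacent to the RET transmembrane
segment in Multiple Endocrine Neoplasia 2A — point at a specific
disease mechanism, while an even scatter does not. `lolliprot` renders
a mutation list as a multi-track protein schematic: lollipop markers
per variant (optionally a second, contrasting set), named domain boxes,
post-translational modification (PTM) marks, the reference sequence,
and a per-residue conservation track derived from a multiple sequence
alignment, with zoom into any residue window.

## Conservation score

Given an alignment with a user-designated reference row, every other
sequence is compared to the reference at each reference position. The
score at a position is the exact-match proportion

```
s = n / t
```

where *n* is the number of non-reference sequences carrying the same
amino acid as the reference there and *t* is the total number of
non-reference sequences. `s` ranges over [0, 1]: 0 means no other
sequence matches the reference at that position, 1 means all of them
do. Columns where the reference is gapped have no reference coordinate
and are dropped; a gap in a non-reference sequence counts as a mismatch
rather than shrinking *t*, so unaligned regions read as poorly
conserved.

## Input files

All tabular inputs are TSV; lines starting with `#` are comments and a
single header line is auto-detected. Coordinates are 1-based and
inclusive.

* mutations: `protein  gene  position  ref_aa  alt_aa`
* architecture: `domain_name  start  end`
* PTM sites: one position per line
* alignment: aligned multi-FASTA (e.g. MUSCLE output)

## Worked example

```sh
cat mut.tsv        # RET\tRET\t3\tC\tR / 4 C>Y / 10 C>R
lolliprot plot --mutations mut.tsv --architecture arch.tsv --ptm ptm.tsv \
    --alignment aln.fasta --reference-id human --length 11 --name "RET toy" \
    --show-score --show-reference --out toy.svg --table toy_table.tsv
cat toy_table.tsv
```

prints the annotation table:

```
protein	gene	position	ref	alt	domains	ptm_site	conservation
RET	RET	3	C	R	Extracellular	no	1.000000
RET	RET	4	C	Y	Extracellular	no	0.666667
RET	RET	10	C	R	Kinase	no	1.000000
```

Each row annotates one variant: the domain(s) whose interval contains
its position, whether it falls exactly on a PTM site, and the
conservation score at that residue. Here position 4 scores
0.666667 = 2/3 because two of the three non-reference orthologs retain
the reference cysteine. The per-position profile is available on its
own:

```
$ lolliprot conserve --alignment aln.fasta --reference-id human --length 11 --out prof.tsv
$ head -4 prof.tsv
position	ref_letter	n	t	score
1	M	3	3	1.000000
2	K	3	3	1.000000
3	C	3	3	1.000000
```

`toy.svg` is the figure itself; SVG output is byte-reproducible, and
every marker, domain box and track carries a stable element id so the
figure can be audited programmatically (`lolliprot.count_svg_ids`).

No data at hand? `lolliprot fixture --out-dir inputs/` emits a complete
synthetic RET-like input set (the four domains of the RET worked case,
200 mutations of which 24 form a MEN2A-like cysteine cluster, PTM
sites, and a 7-sequence alignment) to plot immediately:

```sh
lolliprot plot --mutations inputs/mutations.tsv \
    --mutations2 inputs/mutations_clustered.tsv \
    --architecture inputs/architecture.tsv --ptm inputs/ptm.tsv \
    --length 1114 --name RET-like --out ret.svg --zoom 600:700
```

The same pipeline is available from Python via `read_mutation_file`,
`conservation_scores`, `annotate_mutations`, `PlotSpec` and `render`.

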