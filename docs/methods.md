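# Methods

## Coordinate conventions

All residue coordinates are 1-based; intervals (domains, zoom windows)
are inclusive on both ends. A signal peptide "from 1 to 24" therefore
starts at the first residue and spans 24 residues, and a width-1 domain
`(5, 5)` is legal and visible. Bounds checking against the protein
length is likewise inclusive: a domain ending exactly at the declared
length is in range.

## Input parsing

The three tabular formats are tab-separated; blank lines and `#`
comments are skipped. Because conventions differ on header rows, a
single leading header is auto-detected: the first data line is treated
as a header only when its position column is non-integer *and* at least
two data lines follow — a one-line file with a malformed position is
reported as a parse error (with its line number), never silently
swallowed as a header.

The mutation alphabet is the 20 standard amino-acid letters plus `X`
(unknown) for the reference residue, with `*` (stop gained) additionally
allowed as the alternate. Entries whose reference and alternate residue
are identical are almost certainly input mistakes; they are skipped
with a warning rather than aborting a batch run, since the tool plots
amino-acid *changes*. Duplicate positions are preserved — they are real
(recurrent or multi-allelic sites) and are rendered as stacked heads.

Alignments are read with Biopython's FASTA parser; sequences are
uppercased and `.` gaps normalised to `-`. Ragged alignments and
unknown reference identifiers fail immediately, naming the offending or
available identifiers.

## Conservation model

The score at reference position *p* is `s = n/t` with *n* the number of
non-reference sequences matching the reference residue at *p*'s
alignment column and *t* the number of non-reference sequences. Two
modelling choices deserve note:

* **The reference row is excluded from both counts.** Including it
  would floor the score at `1/t` and make the documented endpoint
  `s = 0` ("no other sequences matching") unreachable.
* **t is constant across positions.** The alternative — excluding
  sequences gapped at a column from *t* — would score a column with one
  aligned, matching sequence as perfectly conserved. Treating gaps as
  mismatches instead penalises unaligned regions, which matches the
  visual intent of a conservation track. The per-column variant is
  deliberately not implemented.

Columns where the *reference* is gapped have no reference coordinate
and are dropped from the profile; the gap-aware column map (1-based
residue index → 0-based column) is strictly increasing by construction.
When a protein length is supplied alongside an alignment, the reference
non-gap count must equal it; a mismatch is an error rather than a
silent truncation. Scoring is vectorised (one byte-matrix comparison),
and is tested against an exact-arithmetic per-column count.

No substitution-matrix or entropy weighting is applied: the score is an
exact-match proportion by definition.

## Annotation

A mutation hits a domain when its position lies in the domain's
inclusive interval; all overlapping domains are reported, in
architecture-file order (so permuting the file permutes only the order
within the hit list). PTM overlap is exact position equality. The
exported table lists every mutation — annotated or not — with
semicolon-joined domain names ("none" when empty), yes/no PTM flags,
and the conservation score when a profile was supplied (blank
otherwise).

## Figure layout and rendering

The figure is a stack of disjoint horizontal bands, top to bottom:
title, optional secondary mutation track, primary mutation track,
backbone with domain boxes, PTM marks, reference-sequence letters,
conservation letters, conservation score bars, and the residue-number
axis. The horizontal coordinate of residue *p* is affine in *p* over
the current window (each residue owns a unit-width cell), so ordering
and spacing are exact.

Rendering choices, all configurable through a flat `key = value` file:

* Markers are lollipops (stem plus circular head) labelled
  `<ref><position><alt>`, e.g. `C634R`. Repeated positions stack their
  heads upward in input order.
* Label collisions are resolved deterministically: markers closer than
  3% of the window form a group; singletons label above the head,
  groups of two or three alternate above/below, denser groups rotate
  the labels 90°.
* Domain boxes span `[start − 0.5, end + 0.5]` in residue units (a
  width-1 domain stays visible) and carry centred name labels,
  abbreviated with an ellipsis when wider than the box.
* Zooming restricts the window without filtering the inputs: clipping
  happens at draw time, so a domain straddling a window edge is
  partially drawn, while markers are drawn only when their position is
  in-window.
* Per-residue letter tracks (reference sequence and conservation
  letters) are drawn only when the window is at most 200 residues wide
  — beyond that the glyphs are unreadable and only bloat the file — and
  are otherwise suppressed with a logged notice. The numeric score bar
  track has no such limit. Conservation letters use a 3-bin colour
  scale (s = 1; 0.5 ≤ s < 1; s < 0.5); the bin edges are display
  choices only, the underlying scores are continuous.
* Colours default to blue (primary track), red (secondary), and a fixed
  qualitative palette cycling over domains in file order. PNG defaults:
  150 dpi at 12-inch width.

Vector output is deterministic: a fixed SVG hash salt and stripped date
metadata make repeated renders of the same specification byte-identical,
and every semantic element carries a stable id (`mut-primary-3`,
`domain-0`, `ptm-2`, ...). This turns the figure itself into a testable
artifact — the suite parses the SVG and checks marker counts against
the input mutation list.

## Synthetic data

The generators exist so the whole pipeline is testable without any
database access:

* `simulate_mutations` draws positions uniformly, optionally
  concentrating a configurable fraction inside a hotspot window;
  substitutions are uniform over the 20 letters with ref ≠ alt
  guaranteed.
* `simulate_alignment` draws a uniform-random reference and lets each
  non-reference sequence match it at position *p* with probability
  `q_p` (default 0.9 everywhere, a typical ortholog identity), else
  carry a uniformly chosen different letter; an optional gap rate
  replaces non-reference characters with gaps. Because matches are
  independent Bernoulli draws, the computed score at each position is
  Binomial(t, q_p)/t, which is what the statistical-recovery tests
  check (3-standard-error bands at t = 200).
* `make_ret_like_fixture` emulates the RET case: the four published
  domain intervals (signal peptide 1–24, cadherin 191–270,
  transmembrane 636–653, tyrosine kinase 724–1005), tyrosine-like PTM
  positions, and 200 mutations of which 24 are cysteine substitutions
  confined to residues 600–635 — the MEN2A-like cluster just N-terminal
  of the transmembrane start, always including C634R. The protein
  length defaults to 1114 but is a parameter, not a constant. The
  background mutations avoid cysteine so the clustered subset is
  recoverable by filtering.

Every generator takes a seed and owns its generator instance; identical
seeds give identical artifacts, and distinct internal stream keys keep
the mutation and alignment draws decoupled.

What the synthetic data does *not* emulate: real substitution biases
(transition/transversion structure, CpG hypermutability), realistic
indel placement in alignments, correlated conservation along the
sequence, or the actual licensed disease-mutation catalogue. Passing
tests therefore demonstrate correct bookkeeping, scoring arithmetic and
rendering — not biological realism of the inputs.

## Command-line interface

`plot`, `annotate`, `conserve` and `fixture` expose the pipeline stages
individually. Usage errors (missing required flags) exit 2; data errors
(parse failures, out-of-range positions, unknown reference ids) exit 1
with the problem on standard error. Successful runs write nothing to
standard error; `--verbose` enables progress logging there (this is why
the default log level is warning, not info — a silent success channel
is worth more than chatter).

## Problem sizes in the test-suite

The oracle-equivalence suites use 500 random alignments of at most 10
sequences × 50 columns and 500 random domain/position sets of at most
20 intervals; statistical recovery uses 200 non-reference sequences
over 1000 positions at q = 0.5. These sizes give exact (rational)
comparisons and sub-second-to-few-second runtimes while exercising
every code path the full-size RET example does.

## Known limitations

* Conservation is exact-match only; there is no notion of conservative
  substitution.
* PTM sites are positions only — no modification types or labels.
* Inputs must already be in protein coordinates; there is no VCF/HGVS
  mapping and no retrieval from HGMD/HPRD/RefSeq.
* Label de-collision is heuristic; at extreme densities rotated labels
  may still touch.
* PDF output is not guaranteed byte-reproducible (font subsetting);
  SVG is the canonical audited format.
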