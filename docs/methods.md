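# Methods

## Scope and model of the data

`sangerbatch` processes analysed Sanger chromatograms (AB1/ABIF files):
four per-channel fluorescence signals, called peak positions, base
calls and Phred-style qualities. It matches each trace to a reference
sequence, builds one reference-anchored multiple alignment per
reference, calls a consensus under strict agreement rules, classifies
coding mutations and exports a spreadsheet report. The package is a
batch library + CLI; no re-basecalling is attempted — the instrument's
base calls and qualities are taken as given.

## ABIF dialect

The writer emits a minimal, standards-conformant ABIF file: big-endian,
magic `ABIF`, version 101, a `tdir` root entry at byte 6, 28-byte typed
directory entries with payloads ≤ 4 bytes stored inline. Tags written:
`DATA9–12` (int16 signals in `FWO_` channel order), `FWO_1`,
`PLOC1/2`, `PBAS1/2`, `PCON1/2`. Per-base tags are duplicated under
numbers 1 and 2 because third-party parsers read either
inconsistently; our reader prefers number 2 and falls back to 1.
`PCON` is written char-typed, matching instrument files, so Biopython's
`abi` reader decodes our files (covered by an interoperability test).
Base letters outside ACGT are normalised to N on read.

## Reference handling

FASTA, GenBank, CSV and XLSX (first sheet, columns `id,sequence`) are
accepted. For GenBank the first CDS feature defines the coding
interval (a warning is logged when several exist; spliced `join`
features are rejected rather than silently concatenated). For every
other format the whole sequence is coding: translation starts at the
first codon and a trailing partial codon is dropped at translation
time. Coordinates are 0-based half-open internally and 1-based
inclusive in reports.

## Quality processing

Both filters are opt-in (defaults: off).

* **End trimming** removes each flank up to the outermost run of three
  consecutive bases with quality *strictly above* the trim threshold.
  An interior low-quality stretch between two good runs is kept — the
  rule governs the ends only. Trimming is idempotent and is checked
  against a brute-force run-scan oracle.
* **Quality masking** drops every position with quality *strictly
  below* the mask threshold, so a base exactly at the threshold passes
  both filters.
* N calls are always masked. Masked/trimmed positions are retained in
  memory (`kept=False`) rather than deleted so chromatogram coordinates
  stay valid for reporting.

## Mixed-peak detection

A secondary channel at a called position is reported as a mixed peak
when, relative to the called base's peak:

* its **area ratio** ≥ f and its **height ratio** ≥ f (f default 0.15,
  inclusive boundary — "at least f times");
* the candidate trace is **concave** at the main-peak centre;
* its peak height clears a per-channel **noise gate**.

Areas are integrated over the window bounded by midpoints to the
neighbouring called peaks (rounded toward the centre peak; trace ends
for the outermost peaks). This window is parameter-free and robust to
peak-spacing drift. Height ratio uses the candidate's maximum inside
the window over the main channel's value at the peak centre.

**Concavity.** Curvature is measured as a second difference with
stencil spacing 2 on a 3-sample moving average of the candidate
channel. A raw 3-sample stencil has noise ≈ σ·√6 per sample-noise σ,
which is the same order as the true curvature of a genuine secondary
peak at realistic baseline noise (σ≈10–20 against peak height 1000)
and rejects real mixed peaks; the smoothed wide stencil raises the
signal-to-noise of the curvature estimate roughly tenfold while still
rejecting centre dips from neighbouring-peak shoulders. A channel that
is identically zero in the window is never considered concave.

**Noise gate.** Per channel, the gate is `k × median` of that
channel's signal at called peak centres where it is *not* the called
base — its typical off-peak background (k default 2.0, configurable).
The median is robust as long as genuinely mixed positions are a
minority. This is a documented operationalisation of a
"data-derived threshold"; it is logged with every run.

At most one mixed peak is reported per base (largest area ratio, ties
alphabetical). Detected sets are monotonically shrinking in f. Mixed
peaks are report annotations only; they never alter the consensus.

## Assignment and orientation

If a reference id occurs as a case-insensitive substring of the trace
file name, that reference wins (longest id, then alphabetical).
Otherwise the read is aligned globally to every reference in both
orientations and the best score wins (ties: reference file order). The
same affine-gap scorer (match +2, mismatch −1, gap open −5, gap extend
−1; Biopython convention, a length-k gap costs open + (k−1)·extend) is
used for assignment, orientation and MSA anchoring, so scores are
comparable everywhere; the values are package defaults, logged per
run, not derived from any external source. Orientation is the higher
of forward/reverse-complement scores, ties to forward. A winning score
below 0.5 per kept base flags the assignment low-confidence.

## Multiple alignment and consensus

The builtin MSA is reference-anchored: each read is pairwise-aligned
to the reference; read insertions hanging off the same reference
position share one left-justified column block. Leading/trailing read
gaps are "not covered" (`.`), distinct from deletions (`-`) inside the
aligned span — Sanger reads are routinely shorter than their
reference. A Clustal-Omega-compatible executable is used instead when
present on PATH (`auto`/`external` backends); the builtin path makes
the package hermetic.

Consensus rules per column:

1. a variant (point mutation, insertion, deletion) is called only when
   **all covering reads agree** — one covering read agrees vacuously
   and is visible as single-read evidence in the report colouring;
2. a reference-gap column where only some reads insert — or the
   inserting reads disagree on the base — becomes `?`
   (ambiguous insertion), excluded from coverage, identity and
   translation;
3. any other disagreement keeps the reference base, with coverage
   shown reduced to the agreeing reads.

N and masked positions never count as covering; a `-` inside a read's
span counts as deletion evidence. The implementation is checked
exhaustively against an independent rule-literal oracle on all ≤3-read
column configurations.

**Statistics.** Coverage % = reference positions with ≥1 covering
read / all reference positions. Identity % = covered reference
positions whose consensus equals the reference / covered positions.
The denominator choice (covered positions, not the whole reference) is
deliberate and documented here because coverage and identity are shown
side by side; with zero coverage, identity is reported as 100 with a
vacuity flag.

## Translation and mutation classes

Standard genetic code, translated codon-by-codon from the CDS start;
internal stops render `*` and do not terminate; any codon containing N
gives `X`; `?` columns are removed before codon grouping; a trailing
partial codon is dropped.

Substitutions are classified by comparing the reference codon with the
consensus codon at the same codon index: same amino acid → silent,
stop gained → nonsense, otherwise missense (stop-loss is counted as
missense with a `stop_loss` note). An indel whose length is not
divisible by 3 is a frameshift: every downstream variant until a
compensating indel restores the frame (or the CDS ends) is counted
*only* as frameshift, and translation continues in the shifted frame.
In-frame indels have no class of their own and are reported as
missense with an `inframe_indel` note. Mutation counting is
nucleotide-level: one event per substituted base, one per contiguous
indel.

## Synthetic data generator

`simulate_chromatogram` renders a sequence as one Gaussian peak per
base (default spacing 12 samples, σ 3, amplitude 1000) plus optional
zero-clipped baseline noise (default σ 10), int16-clipped signals and
exact peak locations. Planted events: substitutions, insertions,
deletions, secondary peaks at a chosen amplitude fraction, and locally
degraded qualities. Defaults keep adjacent peaks < 5% overlapping in
area so integrated windows stay clean. `synth_dataset` writes real AB1
files plus reference FASTA/CSV and a truth manifest;
`validation_dataset` is the canonical five-reference study: 120-nt
references, four reads each, 30% reverse-complemented, generic file
names, one planted event per reference covering silent, missense,
nonsense, frameshift and a ratio-0.4 mixed peak (distinct bases are
forced around the deletion site so its alignment placement is
unambiguous).

What the generator does **not** emulate: dye blobs, mobility shifts,
peak-spacing drift, basecaller miscalls correlated with signal shape,
and quality values derived from the signal itself (qualities are
planted, not estimated). Passing tests therefore demonstrate the
correctness of the pipeline's logic under the stated signal model, not
robustness to every artefact of real capillary data.

## Problem sizes and determinism

The validation runs use 5 references × 4 reads of 120 nt — large
enough to exercise every code path (both orientations, score-based
assignment, all mutation classes, mixed-peak mirroring on reversed
traces) while keeping a full run in seconds. All randomness flows
through explicit seeds; reruns are byte-identical at the TSV level
(reports carry no timestamps).

## Known limitations

* MSA-based calling inherits the aligner's indel placement: a deletion
  inside a homopolymer can be reported at any equivalent position, and
  nearby compensating indels may legitimately align as substitutions
  when that scores better.
* No IUPAC ambiguity codes in the consensus; mixed peaks are
  annotations only.
* Spliced (multi-exon) GenBank CDS features are rejected, not joined.
* Quality-weighted consensus voting is out of scope; all covering
  reads vote equally.
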