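# sangerbatch

Batch processing of Sanger sequencing chromatograms: match AB1 trace
files to reference sequences, trim and quality-filter reads, detect
mixed (secondary) chromatogram peaks, build per-reference consensus
sequences under strict agreement rules, classify coding mutations and
export a navigable spreadsheet report.

Sanger sequencing remains the workhorse of sequence validation in
subcloning, protein engineering and antibody discovery. Checking one
chromatogram against its reference by eye takes minutes; checking a
96-well plate is hours of error-prone drudgery. `sangerbatch` is the
computational core of that validation workflow as a library and CLI:
hundreds of traces and references in, one overview table out.

## What it computes

* **ABIF I/O** — reads AB1 files (`DATA9–12`, `FWO_`, `PLOC`, `PBAS`,
  `PCON` tags) and writes them back exactly (round-trip-identical,
  readable by Biopython); references from FASTA, GenBank (CDS feature
  → coding interval), CSV or XLSX.
* **Quality processing** — opt-in end trimming (trim each flank until
  three consecutive bases exceed the threshold) and quality masking
  (drop positions strictly below the threshold); N calls are always
  ignored.
* **Mixed peaks** — a secondary channel is reported when its peak area
  and height are each at least a factor *f* (default 0.15) of the main
  peak's, the trace is concave at the peak centre, and the peak clears
  a per-channel noise gate (*k*× the median off-peak background,
  *k* = 2 by default).
* **Assignment** — by reference id in the file name, else by the best
  global alignment score over all references × both orientations.
* **Consensus** — one reference-anchored MSA per reference; a variant
  is called only when *all* covering reads agree; partial insertions
  become `?` (excluded from coverage/identity/translation); any other
  disagreement keeps the reference base with reduced coverage shown.
* **Mutations** — silent / missense / nonsense by codon comparison;
  indels of length not divisible by 3 frameshift everything downstream
  until a compensating indel, with translation continuing in the new
  frame.
* **Report** — an XLSX workbook (overview sheet with links, one
  alignment sheet and one mismatch/zero-coverage sheet per reference)
  plus a byte-stable plain-TSV mirror.

See `docs/methods.md` for the precise rules, numerical choices and
limitations.

## Worked example

Generate the built-in five-reference validation dataset (four reads
per reference, 30% reverse-complemented, generically named files, one
planted event per reference) and run the pipeline on it:

```python
from pathlib import Path
from sangerbatch.simulate import validation_dataset
from sangerbatch.pipeline import RunConfig, run_pipeline
from sangerbatch.report import summarize

data = Path("demo/data")
validation_dataset(seed=1, dest=data)
result = run_pipeline(RunConfig(traces=data,
                                references=data / "references.csv",
                                output=Path("demo/out")))
print(summarize(result).to_string(index=False))
```

which prints:

```
reference group  coverage_pct  identity_pct  n_silent  n_missense  n_nonsense  n_frameshift  n_traces                             trace_names  low_confidence
     ref1               100.0          99.2         1           0           0             0         4 sample001;sample002;sample003;sample004           False
     ref2               100.0          99.2         0           1           0             0         4 sample005;sample006;sample007;sample008           False
     ref3               100.0          99.2         0           0           1             0         4 sample009;sample010;sample011;sample012           False
     ref4               100.0          99.2         0           0           0             1         4 sample013;sample014;sample015;sample016           False
     ref5               100.0         100.0         0           0           0             0         4 sample017;sample018;sample019;sample020           False
```

Every read covers its full reference (coverage 100%). The planted
events surface as exactly one mutation of the planted class per
reference — the silent GAA→GAG in ref1, the missense GCC→GTC in ref2,
the nonsense TGG→TAG in ref3 and the 1-base deletion (frameshift) in
ref4 each leave one of 123 covered positions differing from the
reference (identity 99.2%). ref5 carries no sequence change (identity
100%) but a planted secondary peak at amplitude ratio 0.4, which shows
up in the per-trace mixed-peak annotations, mirrored in position and
channel on the reverse-complemented trace. All 20 generically named
reads were assigned to the correct reference with the correct
orientation by alignment score alone. `demo/out/` then contains
`report.xlsx` and the `tsv/` mirror.

The same run from the shell:

```sh
sangerbatch simulate --references refs.csv --out demo/data --reads-per-ref 4
sangerbatch run --traces demo/data --references demo/data/references.csv --out demo/out
```

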