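# midakit

Least-squares mass isotopomer distribution analysis for stable-isotope
labelling experiments. midakit converts experimental GC/LC-MS intensity
patterns of labelled metabolites (and fragments) into
natural-abundance-corrected isotopomer-group distributions and absolute
isotope enrichments.

The pipeline:

1. **Binomial natural-abundance model** — the probability that a fragment
   with `n` labelable atoms carries `i` heavy isotopes is
   `C(n, i) · p0^(n−i) · p1^i` (default `p1 = 0.0111` for ¹³C; configurable,
   e.g. 0.00364 for ¹⁵N).
2. **Abundance matrix** — a lower-triangular Toeplitz matrix whose columns
   are shifted copies of the natural-abundance vector, so matrix-vector
   multiplication is convolution.
3. **Least-squares deconvolution** — the observed spectrum is solved
   against the matrix with the Moore–Penrose pseudoinverse; negative fitted
   groups are clamped to zero (raw values stay available for diagnostics).
4. **Enrichment** — molar percentages per isotopomer group, special-notation
   labels (`[000]`, `[XXX] 1`, …, `[111]`), and the absolute enrichment
   `Σᵢ fᵢ·i / n`.

Input records use a `#`-separated plain-text format (`.ls`): one record per
line with five TAB-separated fields —
`name`, `m/e#m/e#…`, `intensity#intensity#…`, metabolite carbons, fragment
carbons. Both dot and comma decimal conventions are supported (`--locale
auto|dot|comma`).

## CLI

```sh
# analyze every record in one or more .ls files
midakit analyze data.ls --format report          # human-readable tables
midakit analyze data.ls --format json -o out.json
midakit analyze data.ls --format csv --spectra-out spectra.tsv

# replay a known fitted abundance vector through the reporting stage
midakit analyze data.ls --fitted "1.01811623727288#0#0#0.436317933953475#"

# generate a synthetic fixture with known ground truth
midakit synth --fractions "0.7#0#0#0.3#" --noise-sd 0.01 --seed 42 -o synth.ls

# merge record files (duplicates collapse to the later occurrence)
midakit merge a.ls b.ls -o merged.ls

# rewrite a file under a different decimal convention
midakit convert german.ls --to-locale dot -o english.ls
```

Useful `analyze` options: `--p1` (heavy-isotope abundance), `--m0`
(monoisotopic-mass override), `--max-heavy-atoms` (mass-window width),
`--extra-carbons` (derivatization-agent carbons folded into the
natural-abundance generator), `--two-stage` (diagnostic second solve with
the matrix rebuilt from stage-one output), `--config file` (key = value
defaults), `-v/-vv` (log condition numbers, excluded peaks, clamped
groups).

## Library

```python
import midakit as mk

record = mk.parse_ls_record(
    "Alanine\t259.15#260.1#261.1#262.1#263.1#264.1#265.1#\t"
    "0.07#8.53#2.3#2.39#44.59#8.79#3.88#\t3\t3"
)
fit = mk.correct_spectrum(record)               # pseudoinverse deconvolution
result = mk.summarize(
    mk.natural_abundance_distribution(3).values, fit.clamped, 3
)
print(result.labelled_percent, result.abs_enrichment_labelled)
```

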