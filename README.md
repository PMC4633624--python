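# mutkit

Tools for quantifying in-vivo mutagenesis in bacteria and phage:
estimating genomic mutation rates from reporter-gene fluctuation assays,
classifying substitution spectra, calling low-frequency mutations from
background-subtracted amplicon deep sequencing, inverting blue/white
plaque counts into per-base rates, and generating fully synthetic
datasets with known ground truth for end-to-end validation.

## Scientific problem

Inducible mutagenesis plasmids raise the genomic substitution rate of
*E. coli* by several orders of magnitude, which is useful for directed
evolution but hard to measure directly. The standard readout is a
fluctuation assay against a selectable reporter: plate cultures on a
selective drug, count resistant colonies, and convert the resistance
frequency into a per-base-pair rate.

With `f` the frequency of resistant mutants, `R` the number of distinct
single-base substitutions in the reporter that confer resistance, and a
culture grown from `N0` to `N` cells, the per-base-pair substitution
rate per generation is

```
mu_bp = f / (R * ln(N / N0))
```

and the per-genome rate is `mu_g = mu_bp * G` for genome length `G`
(4.64 Mbp for *E. coli* MG1655). The package defaults to `R = 77`
(rifampin resistance via *rpoB*) and `N0 = 1.5e7`.

Two complementary readouts are also implemented:

- **Amplicon deep sequencing.** Per-position deviant-base fractions in
  a mutagenized sample are corrected by subtracting a matched
  unmutagenized control; a position is called mutated only when its
  corrected fraction exceeds both the table-wide mean corrected
  fraction and the control fraction plus one control standard
  deviation. Bases below Q30 are masked first. Calls feed a
  12-class strand-specific substitution spectrum.
- **Phage plaque assay.** For phage carrying *lacZ*, the fraction of
  non-blue plaques estimates the probability that at least one
  inactivating substitution hit the gene:
  `P(white) = 1 - exp(-mu_bp * L * g * p)` with target length `L`,
  generations `g`, and inactivating fraction `p` (defaults 3075 bp and
  0.33). Inverting this gives `mu_bp` from plaque counts alone.

## Worked example

A strong mutator culture yields 2005 rifampin-resistant colonies at a
10³ dilution and 1000 viable colonies at a 10⁶ dilution
(`f = 2.005e-3`, `N = 1e9`):

```
$ mutkit estimate-rate --counts counts.tsv --baseline uninduced --out rates.tsv
[mutkit] wrote 2 rate estimates to rates.tsv
$ cat rates.tsv
sample_id  condition  f         mu_bp                  mu_g                fold_vs_baseline  schema_version
s1         induced    0.002005  6.200188002750396e-06  28.768872332761834  1002.5            1
s2         uninduced  2e-06     6.18472618728219e-09   0.028697129508989363 1.0              1
```

i.e. roughly 6.2 × 10⁻⁶ substitutions/bp/generation, or about 29
substitutions per genome per generation — a ~1000-fold induction over
the uninduced baseline.

The same arithmetic in Python:

```python
from mutkit.rates import estimate_mu_bp, genome_rate

mu = estimate_mu_bp(f=2.005e-3, R=77, N=1e9, N0=1.5e7)  # 6.20e-06
genome_rate(mu)                                          # 28.77
```

## Command-line interface

- `mutkit estimate-rate` — colony-count TSV → per-bp and per-genome
  rates, with optional fold change versus a baseline condition.
- `mutkit call-mutations` — sample/control FASTQ (+ alignment-offset
  sidecars) or SAM versus a reference → position table, called
  mutations, substitution spectrum, and, when a truth table is given,
  recall/precision.
- `mutkit spectrum` — substitution TSV → 12-class spectrum table.
- `mutkit phage-rate` — plaque-count TSV → per-bp rate via the
  Poisson inactivation model.
- `mutkit simulate` — YAML config (explicit seed required) → complete
  synthetic dataset: fluctuation counts, reference, mutant clones with
  truth table, reads, plaque counts, and a provenance record.

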