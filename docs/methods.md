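# Methods

This document records the statistical models, default parameters, and
numerical conventions used by `mutkit`, and what the synthetic-data
generators do and do not emulate.

## 1. Fluctuation-assay rate estimation (`mutkit.rates`)

### Model

A culture grows from `N0` to `N` cells. Each replication copies the
genome with per-base-pair substitution rate `mu_bp`. A reporter locus
offers `R` distinct single-base substitutions that confer a selectable
phenotype (drug resistance). Summing mutation opportunities over the
`N - N0 ≈ N` divisions and accounting for lineage expansion, the
expected frequency of resistant cells at saturation is

```
E[f] = mu_bp * R * ln(N / N0)
```

so the point estimator is `mu_bp = f / (R * ln(N/N0))`. This is the
frequency-based (not Luria–Delbrück maximum-likelihood) estimator; it
is simple, unbiased under the continuous-growth model in §5.1, and the
convention for this assay. Its sampling variance is dominated by rare
early ("jackpot") mutations, so rate comparisons should average several
cultures — the simulator and acceptance script use pooled frequencies
over replicate cultures.

### Defaults and provenance of constants

- `R = 77`: number of distinct rpoB single-base substitutions known to
  confer rifampin resistance in *E. coli*.
- `N0 = 1.5e7`: typical inoculum.
- `G = 4.64e6` bp: *E. coli* MG1655 genome length, used by
  `genome_rate` to convert `mu_bp` to substitutions/genome/generation.
- `essential_load(mu_g, fraction)` multiplies the per-genome rate by an
  assumed essential fraction of the genome (plausible range 0.10–0.30,
  exported as `ESSENTIAL_FRACTION_RANGE`) to bound the expected number
  of essential-gene hits per generation.

`marker_frequency` raises on frequencies above 1 rather than clamping:
a frequency above 1 always indicates a unit or dilution error in the
input table, and silently clamping would hide it.

`per_kbp_to_percent` converts a substitution density given per kilobase
pair into percent of positions (divide by 10); densities per kbp are a
common way to report phage-genome mutagenesis outcomes.

## 2. Substitution spectra (`mutkit.spectrum`)

Spectra are kept at full strand-specific resolution: 12 classes
(4 reference bases × 3 alternates). Collapsed 6-class labels pair each
substitution with its reverse complement and are written purine-first
on the left ("G:C→A:T" covers both C→T and G→A). Collapsing is a
presentation step; all arithmetic happens on the 12-class counts, so
the collapsed view is invariant under reverse-complementing the data.

Spectrum distance is total variation over the 12 class fractions,
`0.5 * Σ|p_i - q_i|`, ranging 0 (identical) to 1 (disjoint). It is
symmetric, bounded, and well-defined for sparse spectra, unlike KL
divergence.

## 3. Background-subtracted deep caller (`mutkit.deepcall`)

Amplicon reads from a mutagenized sample and a matched unmutagenized
control are processed identically:

1. **Quality mask.** Bases with Phred quality below `q_min = 30` are
   masked to `N` (Q30 corresponds to 99.9% per-base accuracy). Reads
   with too few unmasked bases are dropped.
2. **Pair dedup.** Reads sharing a name are treated as mates of one
   fragment; overlapping positions are counted once (first mate wins),
   so PCR duplicates of the same fragment pair do not double-count.
3. **Position table.** For each reference position: depth (unmasked
   coverage) and the deviant fraction `dev_frac` = non-reference
   unmasked bases / depth.
4. **Background subtraction.**
   `corrected = max(0, dev_sample - dev_control)` per position.
5. **Call rule.** A position is called mutated iff
   `corrected > mean(corrected)` (mean over all covered positions) and
   `corrected > dev_control + sd(dev_control)`. The control standard
   deviation is a single table-level scalar with `ddof = 1` (sample
   standard deviation): the control positions are a sample from the
   machine's error process, and a scalar threshold avoids per-position
   noise in the threshold itself.
6. The called alternate base is the most frequent non-reference base at
   the position (ties broken alphabetically), feeding
   `spectrum_from_calls`.

This is a deliberately simple, transparent rule — no binomial test or
position-specific error model — matching how amplicon mutagenesis
experiments with a paired negative control are typically scored. Its
detection floor is set by the control's error distribution; with the
default simulation settings (§5.3) clones at 5% frequency are recovered
with recall and precision ≥ 0.9.

Inputs are FASTQ plus a tab-separated sidecar giving each read's
alignment offset on the amplicon (reads are assumed already aligned and
indel-free), or a SAM/BAM whose alignments contain only match
operations; soft-clips and indels are rejected rather than guessed at.

## 4. Phage plaque assay (`mutkit.phage`)

For phage carrying an intact *lacZ* reporter, substitutions accumulate
over `g` generations of propagation at rate `mu_bp`. If a fraction `p`
of possible substitutions in the `L`-bp target inactivates it, the
number of inactivating hits is Poisson with mean `mu_bp * L * g * p`,
so

```
P(non-blue plaque) = 1 - exp(-mu_bp * L * g * p)
```

`rate_from_plaques` inverts this: `mu_bp = -ln(1 - w) / (L * g * p)`
where `w` is the observed fraction of white plus light-blue plaques
(light-blue plaques indicate partial inactivation and are counted as
lacZ⁻). Defaults: `L = 3075` bp (lacZ), `p = 0.33` (roughly one third
of random substitutions in a coding sequence are inactivating —
nonsense plus deleterious missense). `w = 1` (all plaques white) makes
the rate unidentifiable and raises an error.

## 5. Synthetic-data generators (`mutkit.simulate`)

All generators require an explicit seed; there is no global RNG state.
`simulate` subcommands write a `provenance.json` recording the full
configuration so datasets are exactly regenerable.

### 5.1 Fluctuation assay

The default continuous-growth model draws the number of mutation events
per culture as Poisson with mean `mu_bp * R * (N - N0)` and, for each
event, the final mutant lineage size as `N / n` with `n ~ Uniform(N0, N)`
(a mutation arising when the culture has `n` cells founds a lineage
that expands by the remaining factor `N / n`). Under this model
`E[f] = mu_bp * R * ln(N/N0)` holds exactly, so the estimator in §1 is
unbiased against the generator — an intentional property: the
generator's job is to validate the estimator, not to reproduce the full
heavy-tailed Luria–Delbrück distribution. A discrete per-division
model is available behind a flag for studying jackpot behaviour; it is
slower and noisier.

### 5.2 Mutant clone population

`simulate_mutant_population` gives each clone a Poisson
(`mu * L * generations`) number of substitutions. Each substitution is
drawn **class-first**: first a 12-class substitution type from the
input spectrum, then a uniform position among reference bases matching
that class's reference base. The alternative (position-first, then
class conditional on the base found there) makes the realized spectrum
depend on the reference's base composition, so skewed input spectra
would not be recovered even in expectation. Class-first guarantees the
realized spectrum matches the input spectrum in expectation for any
reference composition.

### 5.3 Read simulation and the standard validation condition

`simulate_reads` fragments clone sequences into fixed-length reads at a
target depth and applies per-base errors. Error rates come from a
quality profile — a mixture of (Phred score, weight) states per base,
default `((40, 0.85), (14, 0.15))` — and each base's FASTQ quality
reflects its true error state. This mimics the key property of real
Illumina data that the deep caller depends on: errors concentrate in
bases the instrument itself flags as low-quality, so the Q30 mask
removes most of them. A flat scalar error rate is also supported but
makes 0.1% errors indistinguishable from real 1–5% variants at the
quality level, which no subtraction rule can fully fix.

The standard validation condition (used by `simulate_amplicon_experiment`
defaults, the test suite, and the acceptance script) is: a 200 bp
amplicon, full-length reads, mean depth 1000, one mutant clone at 5%
frequency carrying 10 substitutions, versus an error-only control.
These sizes were chosen so the whole pipeline runs in seconds while the
expected mutant support per site (~50 reads) sits well above the
post-mask noise floor.

### What the generators do not emulate

Indels, structural variants, PCR amplification bias and chimeras,
strand-specific error profiles, quality decline along read cycles,
contamination, and alignment errors. The generators exist to give the
estimators a known ground truth, not to benchmark aligners or error
correction.

## 6. Numerical and formatting conventions

- User-facing coordinates are 1-based inclusive; internal arrays are
  0-based half-open.
- All TSVs carry headers; rate tables carry a `schema_version` column.
- Standard deviations use `ddof = 1` throughout.
- YAML simulation configs must set an explicit `seed`; unknown keys are
  rejected. Numeric strings such as `1.0e8` (which YAML 1.1 parses as
  strings) are coerced using the config dataclass's type hints.
- Amino-acid change calling (`mutkit.clones`) translates whole mutant
  codons jointly, so two substitutions in one codon yield one correct
  amino-acid change rather than two inconsistent ones; rpoB cluster
  windows ((451–754) and (84–401), amino-acid numbering) annotate where
  resistance substitutions fall.

## 7. Limitations

- The frequency estimator ignores Luria–Delbrück skew; for small
  numbers of cultures, an MSS maximum-likelihood estimator would have
  lower variance. Averaging replicate cultures mitigates this.
- The caller's scalar noise threshold assumes roughly homogeneous
  error rates across positions; a strongly position-dependent error
  profile would need per-position control statistics.
- The plaque model treats inactivating hits as independent Poisson
  events and cannot distinguish one hit from many; near-saturating
  mutagenesis (`w → 1`) is outside its usable range.
- `per_kbp_to_percent` is a unit conversion; observed substitution
  densities in propagated phage reflect accumulated generations and
  selection, and are not directly comparable to per-generation rates.
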