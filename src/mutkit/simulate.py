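"""Forward-time synthetic data with known ground truth.

Generators for every input the analysis pipeline consumes:

* fluctuation-assay resistant frequencies under a continuous-growth
  model in which mutation events arise as a Poisson process with
  intensity R*mu per cell division while the population grows from N0
  to N, each mutant lineage growing exponentially alongside the
  culture.  By construction the expected pooled resistant frequency is
  ``mu * R * ln(N / N0)``, so the closed-form frequency estimator is
  unbiased in expectation.  A discrete per-division binomial model is
  available behind a flag for benchmarking.
* clone populations accumulating Poisson-distributed substitutions
  under a chosen 12-class spectrum, with a truth table of every
  introduced substitution;
* Phred-scored amplicon reads at uniform offsets with a per-base
  substitution error model and an offset sidecar;
* blue/white plaque counts under the Poisson inactivation model.

Each generator takes an explicit seed (or ``numpy.random.Generator``)
and is byte-deterministic given seed and parameters.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mutkit import __version__
from mutkit.phage import InactivationModel, PlaqueAssayResult, expected_lacz_minus
from mutkit.spectrum import BASES, STRAND_CLASSES, MutationSpectrum
from mutkit.clones import CloneSubstitution


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is mandatory for every stochastic run")
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Parameters for a full synthetic dataset; the seed is mandatory."""

    seed: int
    true_mu_bp: float = 6.2e-6
    spectrum_weights: dict | None = None  # class "R>A" -> weight
    R: int = 77
    N0: float = 1.5e7
    N: float = 1e9
    n_cultures: int = 24
    generations: int = 20
    read_len: int = 150
    depth: int = 1000
    base_error: float = 1e-3
    L_target: int = 3075
    p_inactivating: float = 0.33
    n_plaques: int = 10000

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class FluctuationAssay:
    """Per-culture resistant frequencies and the pooled frequency."""

    f_per_culture: np.ndarray
    f_pooled: float
    true_mu_bp: float
    R: int
    N0: float
    N: float


def simulate_fluctuation_assay(
    true_mu_bp: float,
    R: int,
    N0: float,
    N: float,
    n_cultures: int,
    seed,
    model: str = "continuous",
) -> FluctuationAssay:
    """Simulate resistant-mutant frequencies in parallel cultures.

    ``model="continuous"``: the number of mutation events in a culture
    is Poisson with mean ``mu*R*(N-N0)`` (one opportunity per net cell
    birth); an event occurring when the population has size n founds a
    lineage of final size N/n, so the expected resistant count is
    ``mu*R*N*ln(N/N0)`` and E[f] = mu*R*ln(N/N0) exactly.

    ``model="discrete"``: generations of synchronous doubling from N0
    to N with Binomial/Poisson mutant draws per division; retains the
    classical Luria-Delbrück bias relative to the frequency estimator.
    """
    if N <= N0 or N0 <= 0:
        raise ValueError("need N > N0 > 0")
    if true_mu_bp < 0:
        raise ValueError("true_mu_bp must be non-negative")
    rng = _rng(seed)
    expected_events = true_mu_bp * R * (N - N0)
    if 0 < expected_events < 1e-3:
        warnings.warn(
            "expected mutation events per culture < 1e-3: frequency "
            "estimator will be unstable",
            stacklevel=2,
        )
    fs = np.zeros(n_cultures)
    if model == "continuous":
        for i in range(n_cultures):
            k = rng.poisson(expected_events)
            if k:
                sizes = rng.uniform(N0, N, size=k)
                fs[i] = min(1.0, float(np.sum(N / sizes)) / N)
    elif model == "discrete":
        n_gen = max(1, round(math.log2(N / N0)))
        for i in range(n_cultures):
            n, mutants = N0, 0.0
            for _ in range(n_gen):
                new = rng.poisson(n * true_mu_bp * R)
                mutants = 2 * mutants + new
                n *= 2
            fs[i] = min(1.0, mutants / n)
    else:
        raise ValueError(f"unknown growth model {model!r}")
    return FluctuationAssay(
        f_per_culture=fs,
        f_pooled=float(fs.mean()),
        true_mu_bp=true_mu_bp,
        R=R,
        N0=N0,
        N=N,
    )


def _spectrum_probs(spectrum: MutationSpectrum | dict | None) -> np.ndarray:
    """Sampling probabilities over the 12 classes, canonical order."""
    if spectrum is None:
        return np.full(len(STRAND_CLASSES), 1 / len(STRAND_CLASSES))
    if isinstance(spectrum, MutationSpectrum):
        fr = spectrum.fractions
        probs = np.array([fr[c] for c in STRAND_CLASSES], dtype=float)
    else:
        probs = np.array(
            [float(spectrum.get(f"{r}>{a}", 0.0)) for r, a in STRAND_CLASSES]
        )
    total = probs.sum()
    if total <= 0:
        raise ValueError("spectrum has no positive weight")
    return probs / total


def simulate_mutant_population(
    ref_seq: str,
    true_mu_bp: float,
    generations: float,
    spectrum: MutationSpectrum | dict | None,
    n_clones: int,
    seed,
) -> tuple[list[str], pd.DataFrame]:
    """Clone sequences mutated under a spectrum, plus the truth table.

    Each clone accumulates ``Poisson(mu * L * generations)``
    substitutions.  A substitution is generated by drawing its class
    from the spectrum and then a uniform not-yet-mutated position among
    sites carrying that class's reference base, so the realized class
    distribution matches the requested spectrum for any reference
    composition.  The truth table (columns: clone, position, ref, alt;
    1-based) lists every introduced substitution.
    """
    ref = ref_seq.upper()
    rng = _rng(seed)
    probs = _spectrum_probs(spectrum)
    by_base = {
        b: np.nonzero(np.frombuffer(ref.encode(), dtype="S1") == b.encode())[0]
        for b in BASES
    }
    lam = true_mu_bp * len(ref) * generations
    clones: list[str] = []
    rows: list[dict] = []
    for ci in range(n_clones):
        k = rng.poisson(lam)
        seq = list(ref)
        used: set[int] = set()
        for _ in range(k):
            for _attempt in range(1000):
                cls = STRAND_CLASSES[rng.choice(len(STRAND_CLASSES), p=probs)]
                pool = by_base[cls[0]]
                if len(pool) == 0:
                    continue
                pos = int(pool[rng.integers(len(pool))])
                if pos not in used:
                    break
            else:
                raise RuntimeError(
                    "could not place a substitution; reference too short "
                    "or spectrum incompatible with its composition"
                )
            used.add(pos)
            seq[pos] = cls[1]
            rows.append(
                {
                    "clone": f"clone{ci}",
                    "position": pos + 1,
                    "ref": cls[0],
                    "alt": cls[1],
                }
            )
        clones.append("".join(seq))
    truth = pd.DataFrame(rows, columns=["clone", "position", "ref", "alt"])
    return clones, truth


def truth_substitutions(truth: pd.DataFrame) -> dict[str, list[CloneSubstitution]]:
    """Truth table rows as per-clone substitution records."""
    out: dict[str, list[CloneSubstitution]] = {}
    for row in truth.itertuples(index=False):
        out.setdefault(row.clone, []).append(
            CloneSubstitution(int(row.position), row.ref, row.alt)
        )
    for subs in out.values():
        subs.sort(key=lambda s: s.position)
    return out


#: default per-base quality profile: mostly high-confidence bases plus a
#: low-quality tail that a Q>=30 filter masks, as on a real short-read run
DEFAULT_QUALITY_PROFILE: tuple[tuple[int, float], ...] = ((40, 0.85), (14, 0.15))


def simulate_reads(
    sequences: Sequence[str],
    read_len: int,
    depth: float,
    base_error,
    seed,
    ids: Sequence[str] | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Phred-scored reads at uniform offsets with substitution errors.

    ``depth`` is the target mean per-position coverage pooled over the
    clone population: ``round(depth * L / read_len)`` reads are drawn,
    each from a uniformly chosen source sequence at a uniform offset.

    ``base_error`` is either a flat per-base error probability or a
    per-base Phred profile — a sequence of ``(phred, weight)`` pairs
    from which each base's quality is drawn independently, with error
    probability ``10**(-q/10)``.  Either way, each erroneous base is
    replaced by a uniform different base and the Phred string encodes
    the error probability actually used.

    Returns FASTQ-ready records plus a sidecar table (read, source,
    offset; offset 0-based).
    """
    if not sequences:
        raise ValueError("no source sequences")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("source sequences must share one length")
    if read_len > L:
        raise ValueError("read_len exceeds sequence length")
    rng = _rng(seed)
    if ids is None:
        ids = [f"clone{i}" for i in range(len(sequences))]

    if isinstance(base_error, (int, float)):
        if not 0.0 <= base_error < 1.0:
            raise ValueError("base_error must lie in [0, 1)")
        flat_q = (
            60
            if base_error == 0
            else min(60, round(-10 * math.log10(base_error)))
        )
        phreds, weights = None, None
    else:
        profile = [(int(q), float(w)) for q, w in base_error]
        phreds = np.array([q for q, _ in profile])
        weights = np.array([w for _, w in profile])
        weights = weights / weights.sum()

    n_reads = max(1, round(depth * L / read_len))
    src = rng.integers(len(sequences), size=n_reads)
    offs = rng.integers(0, L - read_len + 1, size=n_reads)
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    records: list[SeqRecord] = []
    rows: list[dict] = []
    for i in range(n_reads):
        s, o = int(src[i]), int(offs[i])
        read = np.frombuffer(
            sequences[s][o : o + read_len].encode(), dtype="S1"
        ).copy()
        if phreds is None:
            quals = np.full(read_len, flat_q)
            err_p = float(base_error)
            err = rng.random(read_len) < err_p if err_p > 0 else None
        else:
            quals = phreds[rng.choice(len(phreds), size=read_len, p=weights)]
            err = rng.random(read_len) < 10.0 ** (-quals / 10.0)
        if err is not None and err.any():
            cur = np.searchsorted(base_arr, read[err])
            shift = rng.integers(1, 4, size=int(err.sum()))
            read[err] = base_arr[(cur + shift) % 4]
        name = f"read{i}"
        rec = SeqRecord(Seq(read.tobytes().decode()), id=name, description="")
        rec.letter_annotations["phred_quality"] = quals.tolist()
        records.append(rec)
        rows.append({"read": name, "source": ids[s], "offset": o})
    sidecar = pd.DataFrame(rows, columns=["read", "source", "offset"])
    return records, sidecar


def simulate_spiked_population(
    ref_seq: str,
    n_sites: int,
    clone_fraction: float,
    spectrum: MutationSpectrum | dict | None,
    seed,
) -> tuple[list[str], pd.DataFrame]:
    """A population with one mutant clone at a known frequency.

    The mutant carries exactly ``n_sites`` substitutions (positions
    uniform without replacement, alternate bases per spectrum given the
    reference base, renormalised); the population holds
    ``round(1/clone_fraction)`` clones of which one is the mutant, so
    every mutated site has true frequency ``clone_fraction``.  Used as
    the standard truth set for scoring caller recall/precision.
    """
    if not 0 < clone_fraction <= 1:
        raise ValueError("clone_fraction must lie in (0, 1]")
    ref = ref_seq.upper()
    if n_sites > len(ref):
        raise ValueError("more sites requested than reference positions")
    rng = _rng(seed)
    probs = _spectrum_probs(spectrum)
    positions = rng.choice(len(ref), size=n_sites, replace=False)
    seq = list(ref)
    rows = []
    for pos in sorted(int(p) for p in positions):
        r = ref[pos]
        w = np.array(
            [p if cls[0] == r else 0.0 for cls, p in zip(STRAND_CLASSES, probs)]
        )
        if w.sum() == 0:  # spectrum has no class for this base: uniform alts
            alts = [b for b in BASES if b != r]
            alt = alts[int(rng.integers(3))]
        else:
            cls = STRAND_CLASSES[int(rng.choice(len(STRAND_CLASSES), p=w / w.sum()))]
            alt = cls[1]
        seq[pos] = alt
        rows.append({"clone": "mutant", "position": pos + 1, "ref": r, "alt": alt})
    n_clones = max(2, round(1 / clone_fraction))
    clones = ["".join(seq)] + [ref] * (n_clones - 1)
    truth = pd.DataFrame(rows, columns=["clone", "position", "ref", "alt"])
    return clones, truth


def simulate_amplicon_experiment(
    seed,
    ref_len: int = 200,
    n_sites: int = 10,
    clone_fraction: float = 0.05,
    depth: float = 1000,
    read_len: int | None = None,
    quality_profile=DEFAULT_QUALITY_PROFILE,
    spectrum: MutationSpectrum | dict | None = None,
) -> dict:
    """Standard amplicon truth set for scoring the mutation caller.

    Builds a random amplicon reference, a spiked mutant population
    (``n_sites`` substitutions at frequency ``clone_fraction``), and
    Phred-profiled reads for the mutagenized sample and an
    unmutagenized control.  Defaults give full-length amplicon reads at
    1000x coverage.  Returns a dict with keys ``ref``, ``clones``,
    ``truth``, ``sample_reads``, ``sample_offsets``, ``control_reads``,
    ``control_offsets``.
    """
    rng = _rng(seed)
    s = [int(x) for x in rng.integers(0, 2**31 - 1, size=4)]
    if read_len is None:
        read_len = ref_len
    ref = random_reference(ref_len, seed=s[0])
    clones, truth = simulate_spiked_population(
        ref, n_sites, clone_fraction, spectrum, seed=s[1]
    )
    sample_reads, sample_offsets = simulate_reads(
        clones, read_len, depth, quality_profile, seed=s[2]
    )
    control_reads, control_offsets = simulate_reads(
        [ref], read_len, depth, quality_profile, seed=s[3]
    )
    return {
        "ref": ref,
        "clones": clones,
        "truth": truth,
        "sample_reads": sample_reads,
        "sample_offsets": sample_offsets,
        "control_reads": control_reads,
        "control_offsets": control_offsets,
    }


def simulate_plaque_assay(
    true_mu_bp: float, model: InactivationModel, n_plaques: int, seed
) -> PlaqueAssayResult:
    """Plaque counts with lacZ-minus plaques drawn Binomial(n, p).

    p is the Poisson inactivation model's expected lacZ-minus fraction;
    all lacZ-minus plaques are reported as white (the assay model only
    uses the combined white + light-blue fraction).
    """
    if n_plaques <= 0:
        raise ValueError("n_plaques must be positive")
    rng = _rng(seed)
    p = expected_lacz_minus(true_mu_bp, model)
    k = int(rng.binomial(n_plaques, p))
    return PlaqueAssayResult(n_blue=n_plaques - k, n_light_blue=0, n_white=k)


def random_reference(length: int, seed, gc: float = 0.5) -> str:
    """A random reference sequence with the given GC content."""
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def write_provenance(path, config: SimulationConfig) -> None:
    """Record config, seed and package version next to generated data."""
    payload = {"package": "mutkit", "version": __version__, "config": asdict(config)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
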