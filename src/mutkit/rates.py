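"""Reporter-based mutation-rate estimation and rate arithmetic.

A fluctuation-style reporter assay grows cultures from an initial
population ``N0`` (the size at which a resistant mutant first becomes
observable) to a final size ``N`` and measures the resistant-mutant
frequency ``f`` by selective plating.  With ``R`` distinct nucleotide
sites in the reporter gene conferring resistance, the per-base-pair
substitution rate is

    mu_bp = f / (R * ln(N / N0))

and the per-genome rate is ``mu_G = mu_bp * genome_len``.  Defaults
follow the E. coli MG1655 rifampin/rpoB reporter: R = 77 known
resistance sites, N0 = 1.5e7, genome length 4.64e6 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: number of distinct rpoB sites known to confer rifampin resistance
DEFAULT_R = 77
#: population size at which resistance is first observable
DEFAULT_N0 = 1.5e7
#: E. coli MG1655 genome length (bp)
MG1655_GENOME_BP = 4.64e6
#: fraction of the E. coli genome estimated to be essential (low, high)
ESSENTIAL_FRACTION_RANGE = (0.10, 0.30)


@dataclass(frozen=True)
class ReporterAssayResult:
    """Colony counts and dilutions from one selective/nonselective plating."""

    colonies_selective: int
    dilution_selective: float
    colonies_nonselective: int
    dilution_nonselective: float

    def __post_init__(self) -> None:
        if self.colonies_selective < 0 or self.colonies_nonselective < 0:
            raise ValueError("colony counts must be non-negative")
        if self.dilution_selective <= 0 or self.dilution_nonselective <= 0:
            raise ValueError("dilution factors must be positive")

    @property
    def population_size(self) -> float:
        """Total viable cells implied by the nonselective plate."""
        return self.colonies_nonselective * self.dilution_nonselective

    @property
    def f(self) -> float:
        """Resistant-mutant frequency after dilution correction.

        A value above 1 indicates a dilution bookkeeping mistake and is
        an error, never clamped.
        """
        return marker_frequency(
            self.colonies_selective,
            self.colonies_nonselective,
            self.dilution_selective,
            self.dilution_nonselective,
        )


@dataclass(frozen=True)
class RateEstimate:
    """A per-bp substitution rate with its full provenance."""

    mu_bp: float
    R: int
    N: float
    N0: float
    f: float
    genome_len: float = MG1655_GENOME_BP

    @property
    def mu_g(self) -> float:
        """Substitutions per genome per generation."""
        return genome_rate(self.mu_bp, self.genome_len)


def estimate_mu_bp(
    f: float, R: int = DEFAULT_R, N: float = 1e9, N0: float = DEFAULT_N0
) -> float:
    """Per-bp substitution rate from a resistant-mutant frequency.

    Closed form ``f / (R * ln(N / N0))``; no iteration.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"frequency f must lie in [0, 1], got {f}")
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    if N0 <= 0 or N <= N0:
        raise ValueError(
            f"need N > N0 > 0 for defined growth, got N={N}, N0={N0}"
        )
    return f / (R * math.log(N / N0))


def estimate_rate(
    assay: ReporterAssayResult,
    R: int = DEFAULT_R,
    N0: float = DEFAULT_N0,
    genome_len: float = MG1655_GENOME_BP,
) -> RateEstimate:
    """Full estimate from one reporter assay; N comes from the
    nonselective plate."""
    f = assay.f
    N = assay.population_size
    mu = estimate_mu_bp(f, R=R, N=N, N0=N0)
    return RateEstimate(mu_bp=mu, R=R, N=N, N0=N0, f=f, genome_len=genome_len)


def genome_rate(mu_bp: float, genome_len: float = MG1655_GENOME_BP) -> float:
    """Substitutions per genome per generation: ``mu_bp * genome_len``."""
    if mu_bp < 0 or genome_len <= 0:
        raise ValueError("mu_bp must be >= 0 and genome_len > 0")
    return mu_bp * genome_len


def fold_change(numerator: float, denominator: float) -> float:
    """Ratio of two rates (e.g. induced over uninduced)."""
    if denominator <= 0:
        raise ValueError("fold change undefined for non-positive denominator")
    return numerator / denominator


def dynamic_range(induced: float, uninduced: float) -> float:
    """Induced-over-uninduced rate ratio (alias for :func:`fold_change`)."""
    return fold_change(induced, uninduced)


def essential_load(mu_g: float, essential_fraction: float) -> float:
    """Expected mutations per generation landing in essential genes."""
    if not 0.0 <= essential_fraction <= 1.0:
        raise ValueError("essential_fraction must lie in [0, 1]")
    if mu_g < 0:
        raise ValueError("mu_g must be non-negative")
    return mu_g * essential_fraction


def marker_frequency(
    counts_marker: int,
    counts_total: int,
    dilution_marker: float = 1.0,
    dilution_total: float = 1.0,
) -> float:
    """Dilution-corrected marker frequency from two plate counts.

    Generic form of the resistant / blue-colony fraction:
    ``(counts_marker * dilution_marker) / (counts_total * dilution_total)``.
    """
    if counts_marker < 0 or counts_total < 0:
        raise ValueError("counts must be non-negative")
    if dilution_marker <= 0 or dilution_total <= 0:
        raise ValueError("dilutions must be positive")
    denom = counts_total * dilution_total
    if denom == 0:
        raise ValueError("marker frequency undefined: zero total population")
    freq = counts_marker * dilution_marker / denom
    if freq > 1.0:
        raise ValueError(
            f"marker frequency {freq:.3g} > 1: inconsistent counts/dilutions"
        )
    return freq


def per_kbp_to_percent(subs_per_kbp: float) -> float:
    """Substitution density per kbp expressed as percent of positions.

    2.3 substitutions per kbp ⇔ 0.23% of bases substituted.
    """
    if subs_per_kbp < 0:
        raise ValueError("density must be non-negative")
    return subs_per_kbp / 1000.0 * 100.0
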