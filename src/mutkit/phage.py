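"""Blue/white plaque inactivation assay model.

A reporter cassette (lacZ) carried by a phage is inactivated by
substitutions accumulated during propagation; plaques are scored blue
(functional), light blue or white (lacZ-minus).  Under a Poisson hit
model with per-bp rate mu, target length L, g generations of
propagation, and probability p that a substitution in the target
inactivates it, the expected lacZ-minus fraction is

    1 - exp(-mu * L * g * p)

which is invertible for mu below saturation.  p is an explicit user
assumption (default 0.33), surfaced in every report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: default lacZ target length (bp) — length of a standard lacZ ORF
DEFAULT_LACZ_LENGTH = 3075
#: default probability that a substitution in the target inactivates it
DEFAULT_P_INACTIVATING = 0.33


@dataclass(frozen=True)
class InactivationModel:
    """Poisson-hit model linking a per-bp rate to a lacZ-minus fraction."""

    L_target: int = DEFAULT_LACZ_LENGTH
    generations: float = 1.0
    p_inactivating: float = DEFAULT_P_INACTIVATING

    def __post_init__(self) -> None:
        if self.L_target < 1:
            raise ValueError("L_target must be >= 1 bp")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 < self.p_inactivating <= 1.0:
            raise ValueError("p_inactivating must lie in (0, 1]")


@dataclass(frozen=True)
class PlaqueAssayResult:
    """Plaque counts from one blue/white screen."""

    n_blue: int
    n_light_blue: int
    n_white: int

    def __post_init__(self) -> None:
        if min(self.n_blue, self.n_light_blue, self.n_white) < 0:
            raise ValueError("plaque counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_blue + self.n_light_blue + self.n_white

    @property
    def lacz_minus_fraction(self) -> float:
        """White-or-light-blue plaques as a fraction of all plaques."""
        if self.total == 0:
            raise ValueError("lacZ-minus fraction undefined: zero plaques")
        return (self.n_white + self.n_light_blue) / self.total


def expected_lacz_minus(mu_bp: float, model: InactivationModel) -> float:
    """Expected lacZ-minus plaque fraction at per-bp rate ``mu_bp``."""
    if mu_bp < 0:
        raise ValueError("mu_bp must be non-negative")
    return 1.0 - math.exp(
        -mu_bp * model.L_target * model.generations * model.p_inactivating
    )


def rate_from_plaques(
    result: PlaqueAssayResult | float, model: InactivationModel
) -> float:
    """Invert the Poisson hit model: per-bp rate from a lacZ-minus fraction.

    Accepts either a :class:`PlaqueAssayResult` or a bare fraction.
    A fraction of 1 saturates the assay and the rate is unidentifiable.
    """
    frac = (
        result.lacz_minus_fraction
        if isinstance(result, PlaqueAssayResult)
        else float(result)
    )
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {frac}")
    if frac == 1.0:
        raise ValueError("assay saturated (fraction = 1): rate unidentifiable")
    denom = model.L_target * model.generations * model.p_inactivating
    if denom == 0:
        raise ValueError("model with zero generations cannot be inverted")
    return -math.log(1.0 - frac) / denom


def summarize_plaques(
    n_blue: int, n_light_blue: int, n_white: int
) -> PlaqueAssayResult:
    """Build a result from raw counts; total must be positive."""
    result = PlaqueAssayResult(n_blue, n_light_blue, n_white)
    if result.total == 0:
        raise ValueError("no plaques counted")
    return result
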