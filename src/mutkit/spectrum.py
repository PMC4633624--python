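"""Substitution classes and mutational spectra.

A point substitution on double-stranded DNA can be described
strand-specifically (12 ordered ref→alt classes over {A,C,G,T}) or
collapsed over strand complementarity into 6 base-pair classes.  Spectra
are count vectors over the 12 strand-specific classes; the 6-class view
is derived by summing complementary pairs.

Collapsed labels are written purine:pyrimidine first, e.g. ``G:C→A:T``
for the C→T / G→A transition pair; the alternate ordering ``C:G→T:A``
is accepted as a synonym on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

BASES = ("A", "C", "G", "T")
PURINES = frozenset("AG")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: the 12 strand-specific substitution classes, in a fixed canonical order
STRAND_CLASSES: tuple[tuple[str, str], ...] = tuple(
    (r, a) for r in BASES for a in BASES if r != a
)

_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


class InvalidSubstitutionError(ValueError):
    """A (ref, alt) pair is not a valid DNA substitution."""


def _validate_pair(ref_base: str, alt_base: str) -> None:
    if ref_base not in BASES or alt_base not in BASES:
        raise InvalidSubstitutionError(
            f"bases must be upper-case A/C/G/T, got ({ref_base!r}, {alt_base!r})"
        )
    if ref_base == alt_base:
        raise InvalidSubstitutionError(
            f"ref and alt are identical ({ref_base}); not a substitution"
        )


def collapsed_label(ref_base: str, alt_base: str) -> str:
    """Canonical 6-class base-pair label for a substitution.

    The pair is oriented so the reference purine comes first, e.g. both
    C→T and G→A map to ``G:C→A:T``.
    """
    _validate_pair(ref_base, alt_base)
    if ref_base in PURINES:
        r, a = ref_base, alt_base
    else:
        r, a = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    return f"{r}:{COMPLEMENT[r]}→{a}:{COMPLEMENT[a]}"


#: the 6 collapsed base-pair classes, in canonical order
COLLAPSED_CLASSES: tuple[str, ...] = tuple(
    dict.fromkeys(collapsed_label(r, a) for r, a in STRAND_CLASSES)
)


def parse_collapsed_label(label: str) -> str:
    """Normalise a collapsed-class label, accepting synonym orderings.

    ``C:G→T:A`` and ``G:C→A:T`` name the same class; ``->`` is accepted
    for the arrow.
    """
    text = label.strip().replace("->", "→")
    try:
        left, right = text.split("→")
        r1, r2 = left.split(":")
        a1, a2 = right.split(":")
    except ValueError as exc:
        raise InvalidSubstitutionError(f"cannot parse class label {label!r}") from exc
    for x, y in ((r1, r2), (a1, a2)):
        if x not in BASES or y not in BASES or COMPLEMENT[x] != y:
            raise InvalidSubstitutionError(
                f"{label!r}: {x}:{y} is not a complementary base pair"
            )
    return collapsed_label(r1, a1)


@dataclass(frozen=True)
class MutationClass:
    """One of the 12 strand-specific substitution classes."""

    ref_base: str
    alt_base: str
    collapsed_label: str

    @property
    def is_transition(self) -> bool:
        return (self.ref_base, self.alt_base) in _TRANSITIONS

    @property
    def is_transversion(self) -> bool:
        return not self.is_transition

    def __str__(self) -> str:
        return f"{self.ref_base}→{self.alt_base}"


def classify_substitution(
    ref_base: str, alt_base: str, collapse: bool = False
) -> MutationClass | str:
    """Classify a single-nucleotide substitution.

    Returns the strand-specific :class:`MutationClass` (which always
    carries its collapsed label); with ``collapse=True`` the canonical
    6-class label string is returned instead.

    Raises :class:`InvalidSubstitutionError` for identical bases or
    characters outside A/C/G/T (ambiguity codes are rejected, never
    silently skipped).
    """
    _validate_pair(ref_base, alt_base)
    label = collapsed_label(ref_base, alt_base)
    if collapse:
        return label
    return MutationClass(ref_base, alt_base, label)


@dataclass
class MutationSpectrum:
    """Counts of substitutions over the 12 strand-specific classes."""

    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {c: 0 for c in STRAND_CLASSES}
    )

    def __post_init__(self) -> None:
        full = {c: 0 for c in STRAND_CLASSES}
        for key, n in self.counts.items():
            if key not in full:
                raise InvalidSubstitutionError(f"unknown class {key!r}")
            if n < 0:
                raise ValueError(f"negative count for class {key}")
            full[key] = int(n)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[tuple[str, str], float]:
        t = self.total
        if t == 0:
            return {c: 0.0 for c in STRAND_CLASSES}
        return {c: n / t for c, n in self.counts.items()}

    def collapsed_counts(self) -> dict[str, int]:
        """6-class counts: sums of the two complementary strand classes."""
        out = {lbl: 0 for lbl in COLLAPSED_CLASSES}
        for (r, a), n in self.counts.items():
            out[collapsed_label(r, a)] += n
        return out

    def collapsed_fractions(self) -> dict[str, float]:
        t = self.total
        cc = self.collapsed_counts()
        if t == 0:
            return {lbl: 0.0 for lbl in cc}
        return {lbl: n / t for lbl, n in cc.items()}

    def add(self, ref_base: str, alt_base: str, n: int = 1) -> None:
        _validate_pair(ref_base, alt_base)
        self.counts[(ref_base, alt_base)] += n

    def reverse_complement(self) -> "MutationSpectrum":
        """Spectrum after complementing every (ref, alt) pair."""
        return MutationSpectrum(
            {(COMPLEMENT[r], COMPLEMENT[a]): n for (r, a), n in self.counts.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: class, ref, alt, collapsed label, count, fraction."""
        fr = self.fractions
        rows = [
            {
                "class": f"{r}→{a}",
                "ref": r,
                "alt": a,
                "collapsed": collapsed_label(r, a),
                "count": self.counts[(r, a)],
                "fraction": fr[(r, a)],
            }
            for r, a in STRAND_CLASSES
        ]
        return pd.DataFrame(rows)


def spectrum_from_pairs(pairs: Sequence[tuple[str, str]]) -> MutationSpectrum:
    """Tally a list of (ref, alt) substitutions into a spectrum.

    An invalid pair raises :class:`InvalidSubstitutionError` naming the
    offending 0-based index.
    """
    spec = MutationSpectrum()
    for i, (ref, alt) in enumerate(pairs):
        try:
            spec.add(ref, alt)
        except InvalidSubstitutionError as exc:
            raise InvalidSubstitutionError(f"pair {i}: {exc}") from exc
    return spec


def spectrum_distance(a: MutationSpectrum, b: MutationSpectrum) -> float:
    """Total-variation distance between two spectra's 12-class fractions.

    ``½·Σ|a_i − b_i|``, in [0, 1].  Undefined (raises ValueError) if
    either spectrum is empty.
    """
    if a.total == 0 or b.total == 0:
        raise ValueError("spectrum distance undefined for an empty spectrum")
    fa, fb = a.fractions, b.fractions
    return 0.5 * sum(abs(fa[c] - fb[c]) for c in STRAND_CLASSES)


def read_substitutions_tsv(path) -> list[tuple[int, str, str]]:
    """Read a substitution table (columns: position, ref, alt; 1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    missing = {"position", "ref", "alt"} - set(df.columns)
    if missing:
        raise ValueError(f"substitution TSV missing columns: {sorted(missing)}")
    return [
        (int(row.position), row.ref, row.alt)
        for row in df.itertuples(index=False)
    ]


def write_spectrum_tsv(spectrum: MutationSpectrum, path) -> None:
    spectrum.to_frame().to_csv(path, sep="\t", index=False)
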