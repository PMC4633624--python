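"""Substitution extraction from single-clone reporter sequences.

Supports the classic rifampin-resistance workflow: Sanger-sequence a
fixed-length reporter amplicon (e.g. an rpoB fragment spanning the two
resistance clusters) from each resistant clone, diff it against the
wild-type reference, window the substitutions to the resistance
clusters, and name the amino-acid changes (e.g. ``S531F``).

Coordinates are 1-based on the reference in all user-facing records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from mutkit.spectrum import BASES, InvalidSubstitutionError

#: rpoB rifampin-resistance cluster windows in amino-acid coordinates,
#: cluster I then cluster II
RPOB_CLUSTER_WINDOWS: tuple[tuple[int, int], ...] = ((451, 754), (84, 401))


@dataclass(frozen=True)
class CloneSubstitution:
    """A single substitution observed in one clone.

    ``position`` is 1-based on the reference nucleotide sequence.
    ``codon_index`` is the 1-based amino-acid number after the numbering
    offset; ``aa_change`` is like ``S531F``, or ``""`` for synonymous,
    or ``None`` when not yet annotated. ``in_cds`` is False for
    substitutions flagged as falling outside complete codons.
    """

    position: int
    ref_base: str
    alt_base: str
    codon_index: int | None = None
    aa_change: str | None = None
    in_cds: bool = True


def _check_dna(seq: str, name: str) -> None:
    bad = set(seq.upper()) - set(BASES)
    if bad:
        raise InvalidSubstitutionError(
            f"{name} contains non-ACGT characters: {sorted(bad)}"
        )


def diff_clone(
    clone_seq: str, ref_seq: str, mode: str = "positional"
) -> list[CloneSubstitution]:
    """Report every mismatch between a clone and the reference.

    ``mode="positional"`` (default) compares base-by-base and requires
    equal lengths, as for fixed-length amplicons.  ``mode="align"`` runs
    a global alignment (match +1, mismatch -1, gap -2) solely to detect
    indels, which are rejected: clones carrying indels are out of scope
    and raise a ValueError.
    """
    clone = clone_seq.upper()
    ref = ref_seq.upper()
    _check_dna(ref, "reference")
    _check_dna(clone, "clone")
    if mode == "positional":
        if len(clone) != len(ref):
            raise ValueError(
                f"length mismatch ({len(clone)} vs {len(ref)}): use "
                "mode='align' to check for indels"
            )
    elif mode == "align":
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        aln = aligner.align(ref, clone)[0]
        ref_aln, clone_aln = str(aln[0]), str(aln[1])
        if "-" in ref_aln or "-" in clone_aln:
            raise ValueError("clone alignment contains indels; clone rejected")
        clone = clone_aln
        ref = ref_aln
    else:
        raise ValueError(f"unknown diff mode {mode!r}")
    return [
        CloneSubstitution(position=i + 1, ref_base=r, alt_base=c)
        for i, (r, c) in enumerate(zip(ref, clone))
        if r != c
    ]


def apply_substitutions(ref_seq: str, subs: Iterable[CloneSubstitution]) -> str:
    """Reconstruct a clone sequence from the reference and its diff."""
    seq = list(ref_seq.upper())
    for s in subs:
        if not 1 <= s.position <= len(seq):
            raise ValueError(f"position {s.position} outside reference")
        if seq[s.position - 1] != s.ref_base:
            raise ValueError(
                f"reference base at {s.position} is {seq[s.position - 1]}, "
                f"record says {s.ref_base}"
            )
        seq[s.position - 1] = s.alt_base
    return "".join(seq)


def call_aa_changes(
    subs: Sequence[CloneSubstitution],
    ref_seq: str,
    cds_start: int = 1,
    numbering_offset: int = 0,
) -> list[CloneSubstitution]:
    """Annotate substitutions with codon indices and amino-acid changes.

    ``cds_start`` is the 1-based reference position of the first codon
    base; ``numbering_offset`` is added to the local codon number so a
    sequenced fragment can carry the gene's published residue numbering.
    Multiple substitutions in one codon are translated jointly.
    Substitutions before ``cds_start`` or past the last complete codon
    are flagged (``in_cds=False``), not dropped.
    """
    ref = ref_seq.upper()
    n_codons = (len(ref) - (cds_start - 1)) // 3
    by_codon: dict[int, list[CloneSubstitution]] = {}
    flagged: list[tuple[int, CloneSubstitution]] = []
    for i, s in enumerate(subs):
        local = (s.position - cds_start) // 3  # 0-based codon number
        if s.position < cds_start or local >= n_codons:
            flagged.append((i, replace(s, in_cds=False)))
        else:
            by_codon.setdefault(local, []).append((i, s))

    out: list[tuple[int, CloneSubstitution]] = list(flagged)
    for local, items in by_codon.items():
        start = cds_start - 1 + 3 * local  # 0-based
        ref_codon = ref[start : start + 3]
        mut = list(ref_codon)
        for _, s in items:
            off = s.position - 1 - start
            if ref_codon[off] != s.ref_base:
                raise ValueError(
                    f"reference base at {s.position} is {ref_codon[off]}, "
                    f"record says {s.ref_base}"
                )
            mut[off] = s.alt_base
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq("".join(mut)).translate())
        codon_index = local + 1 + numbering_offset
        change = "" if ref_aa == alt_aa else f"{ref_aa}{codon_index}{alt_aa}"
        for i, s in items:
            out.append(
                (i, replace(s, codon_index=codon_index, aa_change=change))
            )
    out.sort(key=lambda t: t[0])
    return [s for _, s in out]


def window_to_clusters(
    subs: Sequence[CloneSubstitution],
    windows: Sequence[tuple[int, int]] = RPOB_CLUSTER_WINDOWS,
) -> list[CloneSubstitution]:
    """Keep substitutions whose codon index falls in any window.

    Windows are inclusive amino-acid ranges (after the numbering
    offset); they must be non-empty and non-overlapping.  Input order is
    preserved. Substitutions lacking a codon index are dropped.
    """
    for lo, hi in windows:
        if lo > hi:
            raise ValueError(f"empty window ({lo}, {hi})")
    ordered = sorted(windows)
    for (l1, h1), (l2, h2) in zip(ordered, ordered[1:]):
        if l2 <= h1:
            raise ValueError(f"overlapping windows ({l1},{h1}) and ({l2},{h2})")
    return [
        s
        for s in subs
        if s.codon_index is not None
        and any(lo <= s.codon_index <= hi for lo, hi in windows)
    ]


def substitutions_to_frame(subs: Sequence[CloneSubstitution]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of substitution records."""
    return pd.DataFrame(
        [
            {
                "position": s.position,
                "ref": s.ref_base,
                "alt": s.alt_base,
                "codon_index": s.codon_index,
                "aa_change": s.aa_change,
                "in_cds": s.in_cds,
            }
            for s in subs
        ],
        columns=["position", "ref", "alt", "codon_index", "aa_change", "in_cds"],
    )
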