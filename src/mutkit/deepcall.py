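"""Background-subtracted amplicon deep-sequencing mutation calling.

The procedure targets amplicon sequencing of a fixed reference (e.g. a
lacZ cassette carried by a phage): reads are quality-filtered by
masking bases below a Phred threshold (Q >= 30 by default, i.e. >= 99.9%
base accuracy), per-position deviation fractions are computed for a
mutagenized sample and an unmutagenized control, the control fraction is
subtracted position-wise (floored at zero) to give the "corrected
fraction mutated", and a position is called mutated when its corrected
fraction exceeds BOTH the sample-wide mean corrected fraction AND the
control fraction plus one standard deviation of the control's
per-position fractions.

Reads are substitution-only and carry 0-based reference offsets, either
from the synthetic generator's sidecar table or from a SAM file of
gapless alignments.  Paired reads sharing a name count once per
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from mutkit.spectrum import BASES, MutationSpectrum

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class AmpliconRead:
    """A read with a known 0-based offset on the amplicon reference.

    Masked (quality-filtered) bases are represented as ``N`` and are
    excluded from all counts.
    """

    name: str
    sequence: str
    offset: int
    quality: list[int] | None = None


@dataclass
class FilterStats:
    n_reads_in: int = 0
    n_reads_kept: int = 0
    n_bases_in: int = 0
    n_bases_masked: int = 0


def load_fastq_with_offsets(fastq_path, sidecar_path) -> list[AmpliconRead]:
    """Read a FASTQ plus its offset sidecar TSV (columns: read, offset).

    Every read must have an offset row; a missing or malformed record
    raises a ValueError naming it.
    """
    offsets = pd.read_csv(sidecar_path, sep="\t")
    if not {"read", "offset"} <= set(offsets.columns):
        raise ValueError("offset sidecar needs columns 'read' and 'offset'")
    table = dict(zip(offsets["read"].astype(str), offsets["offset"].astype(int)))
    reads = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        if rec.id not in table:
            raise ValueError(f"read {rec.id!r} has no offset in sidecar")
        reads.append(
            AmpliconRead(
                name=rec.id,
                sequence=str(rec.seq).upper(),
                offset=table[rec.id],
                quality=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def reads_from_records(records, sidecar: pd.DataFrame) -> list[AmpliconRead]:
    """Pair in-memory FASTQ records with their offset sidecar table."""
    offsets = dict(
        zip(sidecar["read"].astype(str), sidecar["offset"].astype(int))
    )
    reads = []
    for rec in records:
        if rec.id not in offsets:
            raise ValueError(f"read {rec.id!r} has no offset in sidecar")
        reads.append(
            AmpliconRead(
                name=rec.id,
                sequence=str(rec.seq).upper(),
                offset=offsets[rec.id],
                quality=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def run_caller(
    sample_reads: Sequence[AmpliconRead],
    control_reads: Sequence[AmpliconRead],
    ref_seq: str,
    q_min: int = 30,
) -> tuple["PositionCallTable", list["CalledMutation"]]:
    """Full pipeline: filter both samples, correct, and call."""
    sample, _ = quality_filter(sample_reads, q_min=q_min)
    control, _ = quality_filter(control_reads, q_min=q_min)
    table = corrected_fraction(
        per_position_fractions(sample, ref_seq),
        per_position_fractions(control, ref_seq),
    )
    return table, call_mutations(table)


def load_sam(path) -> list[AmpliconRead]:
    """Read substitution-only alignments from a SAM file.

    Alignments with indels or clipping are rejected (the caller handles
    amplicon reads of a fixed reference only); unmapped reads are
    skipped.
    """
    reads = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if any(op not in (0, 7, 8) for op, _ in (aln.cigartuples or [])):
                raise ValueError(
                    f"read {aln.query_name!r}: alignment is not substitution-only"
                )
            qual = (
                list(aln.query_qualities)
                if aln.query_qualities is not None
                else None
            )
            reads.append(
                AmpliconRead(
                    name=aln.query_name,
                    sequence=aln.query_sequence.upper(),
                    offset=aln.reference_start,
                    quality=qual,
                )
            )
    return reads


def quality_filter(
    reads: Iterable[AmpliconRead], q_min: int = 30, min_unmasked: int = 1
) -> tuple[list[AmpliconRead], FilterStats]:
    """Mask bases below the Phred threshold; drop depleted reads.

    Q >= 30 keeps only bases with error probability <= 1e-3 (>= 99.9%
    accuracy).  Reads whose unmasked length falls below ``min_unmasked``
    are dropped.  Reads without quality strings pass through unmasked.
    """
    if q_min < 0:
        raise ValueError("q_min must be non-negative")
    stats = FilterStats()
    kept: list[AmpliconRead] = []
    for read in reads:
        stats.n_reads_in += 1
        stats.n_bases_in += len(read.sequence)
        if read.quality is None:
            seq = read.sequence
        else:
            if len(read.quality) != len(read.sequence):
                raise ValueError(
                    f"read {read.name!r}: quality length != sequence length"
                )
            seq = "".join(
                b if q >= q_min else "N"
                for b, q in zip(read.sequence, read.quality)
            )
            stats.n_bases_masked += sum(1 for c in seq if c == "N") - sum(
                1 for c in read.sequence if c == "N"
            )
        if sum(1 for c in seq if c != "N") >= min_unmasked:
            stats.n_reads_kept += 1
            kept.append(
                AmpliconRead(read.name, seq, read.offset, read.quality)
            )
    return kept, stats


@dataclass
class PositionTable:
    """Per-position base counts and deviation fractions for one sample."""

    ref_seq: str
    base_counts: np.ndarray  # (L, 4) counts of A/C/G/T observations
    depth: np.ndarray  # (L,) unmasked observations
    dev_count: np.ndarray  # (L,) non-reference observations
    dev_frac: np.ndarray  # (L,) dev_count / depth, 0 where depth == 0

    @property
    def covered(self) -> np.ndarray:
        return self.depth > 0


def _fragment_arrays(read: AmpliconRead) -> tuple[np.ndarray, np.ndarray]:
    """0-based reference positions and base indices of unmasked bases."""
    seq = np.frombuffer(read.sequence.encode(), dtype="S1")
    keep = seq != b"N"
    pos = read.offset + np.nonzero(keep)[0]
    idx = np.searchsorted(
        np.frombuffer(b"ACGT", dtype="S1"), seq[keep]
    )
    return pos, idx


def per_position_fractions(
    reads: Sequence[AmpliconRead], ref_seq: str, dedupe_pairs: bool = True
) -> PositionTable:
    """Count per-position observations and deviation fractions.

    Reads must not overhang the reference.  With ``dedupe_pairs`` (the
    default), reads sharing a name — mates of one fragment — contribute
    at most one observation per position, the first mate winning where
    they overlap.
    """
    ref = ref_seq.upper()
    L = len(ref)
    counts = np.zeros((L, 4), dtype=np.int64)

    # group mates of the same fragment so overlaps count once
    if dedupe_pairs:
        by_name: dict[str, list[AmpliconRead]] = {}
        for r in reads:
            by_name.setdefault(r.name, []).append(r)
        groups = list(by_name.values())
    else:
        groups = [[r] for r in reads]

    for group in groups:
        seen: dict[int, int] = {}
        for read in group:
            if read.offset < 0 or read.offset + len(read.sequence) > L:
                raise ValueError(
                    f"read {read.name!r} overhangs the reference "
                    f"(offset {read.offset}, length {len(read.sequence)})"
                )
            if not set(read.sequence) <= {"A", "C", "G", "T", "N"}:
                raise ValueError(
                    f"read {read.name!r} contains non-ACGT/N characters"
                )
            pos, idx = _fragment_arrays(read)
            if len(group) == 1:
                np.add.at(counts, (pos, idx), 1)
            else:
                for p, b in zip(pos.tolist(), idx.tolist()):
                    seen.setdefault(p, b)
        if len(group) > 1 and seen:
            pos = np.fromiter(seen.keys(), dtype=np.int64)
            idx = np.fromiter(seen.values(), dtype=np.int64)
            np.add.at(counts, (pos, idx), 1)

    depth = counts.sum(axis=1)
    ref_idx = np.array([_BASE_INDEX[b] for b in ref], dtype=np.int64)
    ref_count = counts[np.arange(L), ref_idx]
    dev = depth - ref_count
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, dev / np.maximum(depth, 1), 0.0)
    return PositionTable(ref, counts, depth, dev, frac)


@dataclass
class PositionCallTable:
    """Sample-vs-control corrected fractions and mutation calls."""

    ref_seq: str
    depth_sample: np.ndarray
    dev_frac_sample: np.ndarray
    dev_frac_control: np.ndarray
    corrected_frac: np.ndarray  # max(0, sample - control)
    mean_corrected: float
    sd_control: float
    sample_base_counts: np.ndarray
    called: np.ndarray = field(default=None)  # set by call_mutations

    def to_frame(self) -> pd.DataFrame:
        L = len(self.ref_seq)
        called = (
            self.called
            if self.called is not None
            else np.zeros(L, dtype=bool)
        )
        return pd.DataFrame(
            {
                "position": np.arange(1, L + 1),
                "ref": list(self.ref_seq),
                "depth": self.depth_sample,
                "dev_frac_sample": self.dev_frac_sample,
                "dev_frac_control": self.dev_frac_control,
                "corrected_frac": self.corrected_frac,
                "called": called,
            }
        )


def corrected_fraction(
    sample: PositionTable, control: PositionTable
) -> PositionCallTable:
    """Background-subtract the control's per-position deviation fractions.

    ``corrected = max(0, dev_frac_sample - dev_frac_control)``; negative
    differences are floored at zero.  ``mean_corrected`` is the mean
    corrected fraction over all positions; ``sd_control`` is the sample
    standard deviation of the control's per-position fractions.
    """
    if sample.ref_seq != control.ref_seq:
        raise ValueError("sample and control tables cover different references")
    corrected = np.maximum(0.0, sample.dev_frac - control.dev_frac)
    n = len(corrected)
    mean_corrected = float(corrected.mean()) if n else 0.0
    sd = float(np.std(control.dev_frac, ddof=1)) if n > 1 else 0.0
    return PositionCallTable(
        ref_seq=sample.ref_seq,
        depth_sample=sample.depth,
        dev_frac_sample=sample.dev_frac,
        dev_frac_control=control.dev_frac,
        corrected_frac=corrected,
        mean_corrected=mean_corrected,
        sd_control=sd,
        sample_base_counts=sample.base_counts,
    )


@dataclass(frozen=True)
class CalledMutation:
    """A called position with its dominant alternate base (1-based)."""

    position: int
    ref_base: str
    alt_base: str
    corrected_frac: float


def call_mutations(table: PositionCallTable) -> list[CalledMutation]:
    """Apply the two-part call rule and return called positions.

    A position is called when its corrected fraction is greater than the
    table-wide mean corrected fraction AND greater than the control
    fraction plus one control standard deviation.  The dominant
    alternate base (most-observed non-reference base in the sample, ties
    broken alphabetically) accompanies each call for spectrum building.
    """
    L = len(table.ref_seq)
    if L == 0:
        raise ValueError("cannot call mutations on an empty table")
    called = (table.corrected_frac > table.mean_corrected) & (
        table.corrected_frac > table.dev_frac_control + table.sd_control
    )
    table.called = called
    calls: list[CalledMutation] = []
    for i in np.nonzero(called)[0]:
        ref = table.ref_seq[i]
        counts = table.sample_base_counts[i].copy()
        counts[_BASE_INDEX[ref]] = -1
        alt = BASES[int(np.argmax(counts))]  # argmax ties -> first (A<C<G<T)
        calls.append(
            CalledMutation(
                position=int(i) + 1,
                ref_base=ref,
                alt_base=alt,
                corrected_frac=float(table.corrected_frac[i]),
            )
        )
    return calls


def spectrum_from_calls(calls: Sequence[CalledMutation]) -> MutationSpectrum:
    """Tally called positions' (ref, dominant alt) into a spectrum."""
    spec = MutationSpectrum()
    for c in calls:
        spec.add(c.ref_base, c.alt_base)
    return spec
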