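"""Double-stranded 38-nt oligonucleotide units for barcode-tag assembly.

Barcode tags are built by random blunt-end ligation of a small pool of
38-nt double-stranded oligonucleotide units (labelled ``a``-``j`` by
convention).  Each unit is a concatenation of four short
"pyrosequencing-friendly" sub-barcodes: sequences chosen so that no
homopolymer run exceeds two bases and no dinucleotide tract repeats more
than twice, which keeps flowgram-style basecalling unambiguous.

The published oligo sequences themselves are not distributed; this module
ships a constrained generator plus a frozen default set produced by it
under a fixed seed (see :func:`default_oligo_set`).
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import edlib
from Bio import SeqIO

OLIGO_LENGTH = 38
DNA_ALPHABET = frozenset("ACGT")
DEFAULT_SUB_LENGTHS = (10, 9, 9, 10)
DEFAULT_OLIGO_SEED = 1903
DEFAULT_LABELS = tuple("abcdefghij")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class OligoConstraintError(ValueError):
    """A sequence violates the unit design constraints."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an upper-case ACGT string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def max_homopolymer_run(sequence: str) -> int:
    """Length of the longest single-base run in ``sequence``."""
    best = 0
    for _, group in itertools.groupby(sequence):
        best = max(best, sum(1 for _ in group))
    return best


def max_dinucleotide_repeats(sequence: str) -> int:
    """Largest number of consecutive repeats of any two-base motif.

    Only heterodimeric motifs (e.g. ``AT`` in ``ATATAT``) are counted;
    homodimers are already covered by the homopolymer rule.
    """
    best = 0
    n = len(sequence)
    for i in range(n - 1):
        if sequence[i] == sequence[i + 1]:
            continue
        motif = sequence[i : i + 2]
        r = 1
        while sequence[i + 2 * r : i + 2 * r + 2] == motif:
            r += 1
        best = max(best, r)
    return best


def validate_oligo_sequence(
    sequence: str,
    *,
    max_homopolymer: int = 2,
    max_dinucleotide: int = 2,
) -> None:
    """Raise :class:`OligoConstraintError` unless ``sequence`` is a valid unit."""
    if len(sequence) != OLIGO_LENGTH:
        raise OligoConstraintError(
            f"oligo unit must be {OLIGO_LENGTH} nt, got {len(sequence)}"
        )
    if not set(sequence) <= DNA_ALPHABET:
        bad = sorted(set(sequence) - DNA_ALPHABET)
        raise OligoConstraintError(f"non-ACGT characters in oligo: {bad}")
    run = max_homopolymer_run(sequence)
    if run > max_homopolymer:
        raise OligoConstraintError(
            f"homopolymer run of {run} exceeds maximum {max_homopolymer}"
        )
    reps = max_dinucleotide_repeats(sequence)
    if reps > max_dinucleotide:
        raise OligoConstraintError(
            f"dinucleotide tract of {reps} repeats exceeds maximum {max_dinucleotide}"
        )
    if sequence == reverse_complement(sequence):
        raise OligoConstraintError("palindromic oligo: reverse complement equals forward")


@dataclass(frozen=True)
class OligoUnit:
    """One 38-nt double-stranded ligation unit.

    Parameters
    ----------
    label:
        Single-letter identifier (``a``-``j`` for the default pool).
    sequence:
        The 38-nt top-strand sequence.
    sub_barcodes:
        The four contiguous sub-barcodes whose concatenation is ``sequence``.
    """

    label: str
    sequence: str
    sub_barcodes: tuple[str, ...]

    def __post_init__(self) -> None:
        validate_oligo_sequence(self.sequence)
        if len(self.sub_barcodes) != 4:
            raise OligoConstraintError(
                f"oligo {self.label!r}: expected 4 sub-barcodes, got {len(self.sub_barcodes)}"
            )
        if "".join(self.sub_barcodes) != self.sequence:
            raise OligoConstraintError(
                f"oligo {self.label!r}: sub-barcodes do not concatenate to the sequence"
            )

    @property
    def reverse_complement(self) -> str:
        return reverse_complement(self.sequence)

    def oriented(self, orientation: str) -> str:
        """Top-strand sequence contributed when ligated in ``'F'`` or ``'R'``."""
        if orientation == "F":
            return self.sequence
        if orientation == "R":
            return self.reverse_complement
        raise ValueError(f"orientation must be 'F' or 'R', got {orientation!r}")


def _partition(sequence: str, sub_lengths: Sequence[int]) -> tuple[str, ...]:
    if sum(sub_lengths) != len(sequence):
        raise OligoConstraintError(
            f"sub-barcode lengths {tuple(sub_lengths)} do not sum to {len(sequence)}"
        )
    parts, pos = [], 0
    for length in sub_lengths:
        parts.append(sequence[pos : pos + length])
        pos += length
    return tuple(parts)


def load_oligo_set(
    records: Iterable,
    *,
    sub_lengths: Sequence[int] = DEFAULT_SUB_LENGTHS,
) -> list[OligoUnit]:
    """Validate an oligo pool from ``(label, sequence)`` pairs or SeqRecords.

    Rejects length or tract violations, duplicate labels and duplicate
    sequences, where a sequence equal to another's reverse complement also
    counts as a duplicate (the two would be indistinguishable after
    double-stranded ligation).
    """
    units: list[OligoUnit] = []
    seen_labels: set[str] = set()
    seen_seqs: dict[str, str] = {}
    for record in records:
        if hasattr(record, "seq"):  # Bio.SeqRecord
            label, seq = record.id, str(record.seq).upper()
            lengths = _sub_lengths_from_description(getattr(record, "description", ""), sub_lengths)
        else:
            label, seq = record[0], str(record[1]).upper()
            lengths = tuple(record[2]) if len(record) > 2 else tuple(sub_lengths)
        if label in seen_labels:
            raise OligoConstraintError(f"duplicate oligo label {label!r}")
        validate_oligo_sequence(seq)
        rc = reverse_complement(seq)
        for variant in (seq, rc):
            if variant in seen_seqs:
                raise OligoConstraintError(
                    f"oligo {label!r} duplicates the sequence of {seen_seqs[variant]!r} "
                    "(forward or reverse complement)"
                )
        seen_labels.add(label)
        seen_seqs[seq] = label
        seen_seqs[rc] = label
        units.append(OligoUnit(label=label, sequence=seq, sub_barcodes=_partition(seq, lengths)))
    if not units:
        raise OligoConstraintError("empty oligo set")
    return units


def _sub_lengths_from_description(description: str, default: Sequence[int]) -> tuple[int, ...]:
    for token in description.split():
        if token.startswith("sub_lengths="):
            return tuple(int(x) for x in token.split("=", 1)[1].split(","))
    return tuple(default)


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def _junction_safe(left: str, right: str, max_homopolymer: int, max_dinucleotide: int) -> bool:
    """True if concatenating ``left + right`` creates no tract across the seam.

    A homopolymer or dinucleotide violation crossing the junction is fully
    contained in the last five bases of ``left`` plus the first five of
    ``right``; violations inside either half would already have failed the
    per-unit check.
    """
    window = left[-5:] + right[:5]
    return (
        max_homopolymer_run(window) <= max_homopolymer
        and max_dinucleotide_repeats(window) <= max_dinucleotide
    )


def generate_oligo_set(
    n: int = 10,
    *,
    seed: int = DEFAULT_OLIGO_SEED,
    labels: Sequence[str] | None = None,
    min_sub_distance: int = 3,
    max_homopolymer: int = 2,
    max_dinucleotide: int = 2,
) -> list[OligoUnit]:
    """Generate ``n`` compliant 38-nt units by constrained rejection sampling.

    Each unit is four sub-barcodes of 8-10 nt (summing to 38).  Bases are
    drawn one at a time from the alphabet choices that keep homopolymer runs
    and dinucleotide tracts within bounds; whole units are rejected if
    palindromic, if any pair of sub-barcodes in the growing pool comes
    closer than ``min_sub_distance`` edits, or if the unit duplicates an
    accepted sequence on either strand.  Units are additionally required to
    be junction-safe: concatenating any two pool members in any order and
    orientation (as random blunt-end ligation will) cannot create a tract
    violation across the junction.
    """
    if labels is None:
        labels = [chr(ord("a") + i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("need exactly one label per oligo")
    rng = random.Random(seed)
    compositions = [
        c
        for c in itertools.product((8, 9, 10), repeat=4)
        if sum(c) == OLIGO_LENGTH
    ]
    accepted: list[OligoUnit] = []
    accepted_subs: list[str] = []
    accepted_seqs: set[str] = set()
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise RuntimeError("oligo generation did not converge; relax constraints")
        seq_chars: list[str] = []
        for _ in range(OLIGO_LENGTH):
            choices = []
            for base in "ACGT":
                tail = "".join(seq_chars[-5:]) + base
                if max_homopolymer_run(tail) > max_homopolymer:
                    continue
                if max_dinucleotide_repeats(tail) > max_dinucleotide:
                    continue
                choices.append(base)
            seq_chars.append(rng.choice(choices))
        seq = "".join(seq_chars)
        if seq == reverse_complement(seq):
            continue
        if seq in accepted_seqs or reverse_complement(seq) in accepted_seqs:
            continue
        subs = _partition(seq, rng.choice(compositions))
        pool = accepted_subs + list(subs)
        ok = True
        for i, a in enumerate(subs):
            others = accepted_subs + [s for j, s in enumerate(subs) if j != i]
            if any(_edit_distance(a, b) < min_sub_distance for b in others):
                ok = False
                break
        if not ok:
            continue
        oriented_pool = [x for u in accepted for x in (u.sequence, reverse_complement(u.sequence))]
        oriented_pool += [seq, reverse_complement(seq)]
        candidate_oriented = (seq, reverse_complement(seq))
        for x in oriented_pool:
            for y in oriented_pool:
                if x not in candidate_oriented and y not in candidate_oriented:
                    continue  # pairs of already-accepted units were vetted earlier
                if not _junction_safe(x, y, max_homopolymer, max_dinucleotide):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        accepted.append(OligoUnit(label=labels[len(accepted)], sequence=seq, sub_barcodes=subs))
        accepted_subs = pool
        accepted_seqs.add(seq)
        accepted_seqs.add(reverse_complement(seq))
    return accepted


def write_oligo_fasta(units: Iterable[OligoUnit], path) -> None:
    with open(path, "w") as handle:
        for unit in units:
            lengths = ",".join(str(len(s)) for s in unit.sub_barcodes)
            handle.write(f">{unit.label} sub_lengths={lengths}\n{unit.sequence}\n")


def default_oligo_set() -> list[OligoUnit]:
    """The frozen ten-unit pool (labels ``a``-``j``) shipped with the package."""
    ref = resources.files("mobactag").joinpath("data/default_oligos.fasta")
    with resources.as_file(ref) as path:
        return load_oligo_set(SeqIO.parse(str(path), "fasta"))
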