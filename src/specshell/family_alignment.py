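"""Family multiple-sequence-alignment handling.

Parses a pre-computed protein family alignment (aligned FASTA or Clustal),
maps alignment columns onto the ungapped numbering of a designated reference
sequence, scores per-column polymorphism, computes the pairwise percent
identity matrix, and removes sequences carrying large deletions.

The alignment itself is an *input*: this module never builds or refines one.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import AlignIO

GAP = "-"
#: 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity codes tolerated on input.  They are tallied in column profiles
#: but can never, on their own, make a column count as polymorphic.
AMBIGUOUS_RESIDUES = frozenset("BJXZ")
VALID_RESIDUES = STANDARD_RESIDUES | AMBIGUOUS_RESIDUES


class AlignmentFormatError(ValueError):
    """Raised when an alignment file violates basic shape/content rules."""


@dataclass(frozen=True)
class FamilyAlignment:
    """An aligned protein family with one sequence designated as reference.

    Parameters
    ----------
    records
        ``(identifier, aligned_sequence)`` pairs in file order.  Sequences are
        upper-case, use ``-`` as the gap symbol and must all share one length.
    reference_id
        Identifier of the record whose ungapped positions define the
        family-wide residue numbering.
    """

    records: tuple[tuple[str, str], ...]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentFormatError("alignment contains no sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"aligned sequences have unequal lengths: {sorted(lengths)}"
            )
        matches = [rid for rid, _ in self.records if rid == self.reference_id]
        if len(matches) == 0:
            raise KeyError(f"reference_id {self.reference_id!r} not in alignment")
        if len(matches) > 1:
            raise AlignmentFormatError(
                f"reference_id {self.reference_id!r} names {len(matches)} records"
            )
        for rid, seq in self.records:
            bad = set(seq) - VALID_RESIDUES - {GAP}
            if bad:
                raise AlignmentFormatError(
                    f"illegal characters {sorted(bad)} in record {rid!r}"
                )

    @property
    def column_count(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def reference_sequence(self) -> str:
        """Aligned (gapped) reference sequence."""
        return dict(self.records)[self.reference_id]

    def reference_column_map(self) -> dict[int, int]:
        """Map 1-based ungapped reference position -> 0-based column index."""
        out: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(self.reference_sequence):
            if ch != GAP:
                pos += 1
                out[pos] = col
        return out

    def reference_residue(self, position: int) -> str:
        """Reference residue letter at an ungapped 1-based position."""
        col = self.reference_column_map().get(position)
        if col is None:
            raise KeyError(f"reference has no ungapped position {position}")
        return self.reference_sequence[col]

    def subset(self, ids: Iterable[str]) -> "FamilyAlignment":
        """Restrict to the given identifiers (reference always kept)."""
        keep = set(ids) | {self.reference_id}
        return FamilyAlignment(
            records=tuple((rid, s) for rid, s in self.records if rid in keep),
            reference_id=self.reference_id,
        )

    def drop(self, ids: Iterable[str]) -> "FamilyAlignment":
        """Manually exclude identifiers (e.g. poor-quality sequences)."""
        bad = set(ids)
        if self.reference_id in bad:
            raise ValueError("cannot drop the reference sequence")
        return FamilyAlignment(
            records=tuple((rid, s) for rid, s in self.records if rid not in bad),
            reference_id=self.reference_id,
        )


@dataclass(frozen=True)
class ColumnProfile:
    """Residue composition of one alignment column, in reference numbering.

    ``residue_counts`` excludes gaps; ``occupancy`` is the non-gap fraction.
    ``is_polymorphic`` is True iff at least two distinct *standard* residues
    each reach the minimum count and the column occupancy reaches the minimum
    occupancy (ambiguity codes are tallied but never qualify).
    """

    reference_position: int
    reference_residue: str
    residue_counts: dict[str, int] = field(compare=False)
    occupancy: float = 0.0
    is_polymorphic: bool = False

    @property
    def observed_residues(self) -> set[str]:
        return set(self.residue_counts)


@dataclass(frozen=True)
class IdentityMatrix:
    """Pairwise percent identity over mutually non-gap columns.

    ``values[i, j]`` is in [0, 100]; pairs sharing zero non-gap columns are
    NaN and listed in ``undefined_pairs``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    undefined_pairs: tuple[tuple[str, str], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

_FORMAT_ALIASES = {
    "fasta": "fasta",
    "aligned-fasta": "fasta",
    "afa": "fasta",
    "clustal": "clustal",
    "aln": "clustal",
}


def read_alignment(path, format: str = "fasta", reference_id: str | None = None) -> FamilyAlignment:
    """Read an aligned FASTA or Clustal file into a :class:`FamilyAlignment`.

    ``.`` gap characters are normalised to ``-`` and sequences upper-cased.
    ``reference_id`` defaults to the first record.
    """
    fmt = _FORMAT_ALIASES.get(format.lower())
    if fmt is None:
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    records = tuple(
        (rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in msa
    )
    if reference_id is None:
        reference_id = records[0][0]
    return FamilyAlignment(records=records, reference_id=reference_id)


def write_alignment(aln: FamilyAlignment, path) -> None:
    """Write the alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n{seq}\n")


def filter_large_deletions(aln: FamilyAlignment, min_coverage: float = 0.7) -> FamilyAlignment:
    """Drop records gapped over too much of the reference-occupied columns.

    Coverage of a record is its non-gap fraction over the columns where the
    reference is non-gap.  Records with coverage < ``min_coverage`` are
    removed; the reference itself is always retained.
    """
    if not 0.0 < min_coverage <= 1.0:
        raise ValueError("min_coverage must be in (0, 1]")
    ref_cols = list(aln.reference_column_map().values())
    if not ref_cols:
        raise AlignmentFormatError("reference sequence is entirely gapped")
    kept = []
    for rid, seq in aln.records:
        cov = sum(seq[c] != GAP for c in ref_cols) / len(ref_cols)
        if rid == aln.reference_id or cov >= min_coverage:
            kept.append((rid, seq))
    return FamilyAlignment(records=tuple(kept), reference_id=aln.reference_id)


def column_profiles(
    aln: FamilyAlignment,
    min_variant_count: int = 1,
    min_occupancy: float = 0.5,
    include_ids: Iterable[str] | None = None,
) -> list[ColumnProfile]:
    """Profile every ungapped reference position of the alignment.

    A column is polymorphic iff >=2 distinct standard residues each appear at
    least ``min_variant_count`` times and occupancy >= ``min_occupancy``.
    ``include_ids`` restricts the counted records (the reference residue is
    still read from the reference sequence); by default all records count.
    """
    if min_variant_count < 1:
        raise ValueError("min_variant_count must be >= 1")
    counted = aln.records
    if include_ids is not None:
        wanted = set(include_ids)
        counted = tuple(r for r in aln.records if r[0] in wanted)
    n_records = len(counted)
    profiles = []
    ref_seq = aln.reference_sequence
    for position, col in aln.reference_column_map().items():
        counts = Counter(seq[col] for _, seq in counted)
        counts.pop(GAP, None)
        occupancy = sum(counts.values()) / n_records if n_records else 0.0
        qualifying = [
            res
            for res, n in counts.items()
            if res in STANDARD_RESIDUES and n >= min_variant_count
        ]
        profiles.append(
            ColumnProfile(
                reference_position=position,
                reference_residue=ref_seq[col],
                residue_counts=dict(sorted(counts.items())),
                occupancy=occupancy,
                is_polymorphic=len(qualifying) >= 2 and occupancy >= min_occupancy,
            )
        )
    return profiles


def identity_matrix(aln: FamilyAlignment) -> IdentityMatrix:
    """Percent identity for every sequence pair, over shared non-gap columns."""
    if len(aln.records) < 2:
        raise ValueError("identity matrix requires >= 2 sequences")
    seqs = np.array([list(seq) for _, seq in aln.records])
    nongap = seqs != GAP
    n = len(aln.records)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            total = int(shared.sum())
            if total == 0:
                undefined.append((aln.records[i][0], aln.records[j][0]))
                continue
            same = int((seqs[i][shared] == seqs[j][shared]).sum())
            values[i, j] = values[j, i] = 100.0 * same / total
    return IdentityMatrix(
        ids=tuple(aln.ids), values=values, undefined_pairs=tuple(undefined)
    )


def profiles_to_frame(profiles: list[ColumnProfile]) -> pd.DataFrame:
    """Tabulate column profiles for TSV export."""
    return pd.DataFrame(
        {
            "position": [p.reference_position for p in profiles],
            "reference_residue": [p.reference_residue for p in profiles],
            "observed_residues": [
                "".join(sorted(p.residue_counts)) for p in profiles
            ],
            "occupancy": [p.occupancy for p in profiles],
            "is_polymorphic": [p.is_polymorphic for p in profiles],
        }
    )
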