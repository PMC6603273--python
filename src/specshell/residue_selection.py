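"""Candidate specificity-residue nomination.

The candidate rule is a pure set intersection: a position is nominated iff it
sits in the ligand shell (mapped into target numbering) *and* its alignment
column is polymorphic across the family.  Shell positions whose columns are
conserved are reported as excluded, never silently dropped -- a conserved
substrate-contact residue is itself informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .family_alignment import ColumnProfile


class SelectionConsistencyError(ValueError):
    """A shell position has no alignment column profile."""


@dataclass(frozen=True)
class CandidateReport:
    """Partition of the mapped ligand shell by alignment polymorphism.

    ``selected`` holds ``(position, reference_residue, observed_residues)``
    for polymorphic shell positions; ``excluded_conserved`` holds
    ``(position, reference_residue)`` for conserved ones; ``unmapped_shell``
    lists template-side shell residues with no correspondence partner.
    """

    selected: tuple[tuple[int, str, str], ...]
    excluded_conserved: tuple[tuple[int, str], ...]
    unmapped_shell: tuple[int, ...] = ()

    @property
    def selected_positions(self) -> list[int]:
        return [p for p, _, _ in self.selected]

    @property
    def excluded_positions(self) -> list[int]:
        return [p for p, _ in self.excluded_conserved]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"position": p, "reference_residue": r, "observed_residues": obs,
             "status": "selected"}
            for p, r, obs in self.selected
        ] + [
            {"position": p, "reference_residue": r, "observed_residues": r,
             "status": "excluded_conserved"}
            for p, r in self.excluded_conserved
        ]
        return pd.DataFrame(rows, columns=["position", "reference_residue",
                                           "observed_residues", "status"])


def select_candidates(
    shell_positions: set[int],
    profiles: list[ColumnProfile],
    unmapped_shell: tuple[int, ...] | list[int] = (),
) -> CandidateReport:
    """Split shell positions into polymorphic candidates and conserved rest.

    Every shell position must carry a profile; ordering is by position so the
    report is deterministic.
    """
    by_pos = {p.reference_position: p for p in profiles}
    missing = sorted(set(shell_positions) - set(by_pos))
    if missing:
        raise SelectionConsistencyError(
            f"shell positions without column profiles: {missing}"
        )
    selected = []
    excluded = []
    for pos in sorted(shell_positions):
        prof = by_pos[pos]
        if prof.is_polymorphic:
            selected.append(
                (pos, prof.reference_residue, "".join(sorted(prof.residue_counts)))
            )
        else:
            excluded.append((pos, prof.reference_residue))
    return CandidateReport(
        selected=tuple(selected),
        excluded_conserved=tuple(excluded),
        unmapped_shell=tuple(sorted(unmapped_shell)),
    )
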