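"""Mutant-panel design from natural variation.

Given candidate positions and their alignment column profiles, enumerates
single-residue substitutions that mimic the variation observed across the
family, supports curated manual additions (residues chosen for structural
reasons rather than observed in the family), and assembles named combination
variants (e.g. a double mutant plus triples extending it).

Names use the standard "T257G" convention -- wild-type letter, reference
position, new letter -- and combinations join singles with "/"; every name
parses back to its substitution map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .family_alignment import STANDARD_RESIDUES, ColumnProfile

_SINGLE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class PanelDesignError(ValueError):
    """Invalid, colliding or duplicate substitution design."""


@dataclass(frozen=True)
class SubstitutionVariant:
    """One variant: a map of reference positions to (wildtype, new) residues."""

    substitutions: tuple[tuple[int, str, str], ...]  # (position, wt, new)
    name: str
    origin: str  # "natural" | "manual" | "combination"

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.substitutions]
        if len(positions) != len(set(positions)):
            raise PanelDesignError(f"{self.name}: repeated position")
        for pos, wt, new in self.substitutions:
            if wt == new:
                raise PanelDesignError(f"{self.name}: {wt}{pos}{new} is a no-op")
            if new not in STANDARD_RESIDUES or wt not in STANDARD_RESIDUES:
                raise PanelDesignError(f"{self.name}: non-standard residue")
        if self.origin == "combination" and len(self.substitutions) < 2:
            raise PanelDesignError(f"{self.name}: combination needs >= 2 substitutions")

    @property
    def substitution_map(self) -> dict[int, tuple[str, str]]:
        return {p: (wt, new) for p, wt, new in self.substitutions}

    @property
    def canonical_name(self) -> str:
        """Slash-joined single-substitution names, sorted by position."""
        return "/".join(
            f"{wt}{pos}{new}" for pos, wt, new in sorted(self.substitutions)
        )

    def apply_to(self, sequence: str) -> str:
        """Apply the substitutions to an ungapped reference sequence."""
        chars = list(sequence)
        for pos, wt, new in self.substitutions:
            if pos < 1 or pos > len(chars):
                raise PanelDesignError(f"position {pos} outside sequence")
            if chars[pos - 1] != wt:
                raise PanelDesignError(
                    f"sequence has {chars[pos - 1]} at {pos}, expected {wt}"
                )
            chars[pos - 1] = new
        return "".join(chars)


def single(pos: int, wt: str, new: str, origin: str = "natural",
           name: str | None = None) -> SubstitutionVariant:
    """Convenience constructor for a single-substitution variant."""
    return SubstitutionVariant(
        substitutions=((pos, wt, new),), name=name or f"{wt}{pos}{new}", origin=origin
    )


def parse_variant_name(name: str, wildtype_by_position: dict[int, str] | None = None
                       ) -> tuple[tuple[int, str, str], ...]:
    """Parse "T257G" or "T257G/G259A" back into a substitution tuple.

    If ``wildtype_by_position`` is given, the encoded wild-type letters are
    checked against it.
    """
    subs = []
    for part in name.split("/"):
        m = _SINGLE_RE.match(part)
        if not m:
            raise PanelDesignError(f"cannot parse substitution {part!r}")
        wt, pos, new = m.group(1), int(m.group(2)), m.group(3)
        if wildtype_by_position is not None and wildtype_by_position.get(pos) != wt:
            raise PanelDesignError(
                f"{part}: wild type at {pos} is "
                f"{wildtype_by_position.get(pos)}, not {wt}"
            )
        subs.append((pos, wt, new))
    return tuple(subs)


@dataclass
class VariantPanel:
    """An ordered, duplicate-free collection of substitution variants."""

    variants: list[SubstitutionVariant] = field(default_factory=list)

    def __contains__(self, variant: SubstitutionVariant) -> bool:
        return any(v.substitution_map == variant.substitution_map for v in self.variants)

    def add(self, variant: SubstitutionVariant) -> None:
        if variant in self:
            raise PanelDesignError(f"duplicate variant {variant.name}")
        self.variants.append(variant)

    def names(self) -> list[str]:
        return [v.name for v in self.variants]

    def restrict(self, include: list[str]) -> "VariantPanel":
        """Overlay a curated include-list (by name) on the enumeration."""
        wanted = set(include)
        unknown = wanted - set(self.names())
        if unknown:
            raise PanelDesignError(f"include-list names not in panel: {sorted(unknown)}")
        return VariantPanel([v for v in self.variants if v.name in wanted])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [v.name for v in self.variants],
                "substitutions": [v.canonical_name for v in self.variants],
                "n_substitutions": [len(v.substitutions) for v in self.variants],
                "origin": [v.origin for v in self.variants],
            }
        )

    def to_fasta(self, reference_sequence: str, reference_id: str, path) -> None:
        """Write mutated full-length protein sequences, reference first."""
        with open(path, "w") as fh:
            fh.write(f">{reference_id}\n{reference_sequence}\n")
            for v in self.variants:
                fh.write(f">{reference_id}_{v.name}\n{v.apply_to(reference_sequence)}\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def natural_substitutions(
    position: int, profile: ColumnProfile, wildtype: str
) -> list[SubstitutionVariant]:
    """One single variant per distinct residue observed at the position,
    excluding the wild type, sorted alphabetically by new residue."""
    if profile.reference_position != position:
        raise PanelDesignError(
            f"profile is for position {profile.reference_position}, not {position}"
        )
    if profile.reference_residue != wildtype:
        raise PanelDesignError(
            f"reference residue at {position} is {profile.reference_residue}, "
            f"not {wildtype}"
        )
    observed = sorted(
        res for res in profile.residue_counts
        if res in STANDARD_RESIDUES and res != wildtype
    )
    return [single(position, wildtype, res, origin="natural") for res in observed]


def enumerate_panel(
    profiles: list[ColumnProfile], positions: list[int]
) -> VariantPanel:
    """Natural-variation panel over the given candidate positions."""
    by_pos = {p.reference_position: p for p in profiles}
    panel = VariantPanel()
    for pos in positions:
        prof = by_pos.get(pos)
        if prof is None:
            raise PanelDesignError(f"no profile for position {pos}")
        for v in natural_substitutions(pos, prof, prof.reference_residue):
            panel.add(v)
    return panel


def add_manual_substitutions(
    panel: VariantPanel,
    additions: list[tuple[int, str, str]],  # (position, new residue, note)
    wildtype_by_position: dict[int, str],
) -> VariantPanel:
    """Append curated substitutions (origin="manual"); duplicates rejected."""
    for pos, new, _note in additions:
        wt = wildtype_by_position.get(pos)
        if wt is None:
            raise PanelDesignError(f"no wild-type residue known for position {pos}")
        if new == wt:
            raise PanelDesignError(f"{wt}{pos}{new} does not change the residue")
        panel.add(single(pos, wt, new, origin="manual"))
    return panel


def build_combinations(
    base: list[tuple[int, str, str]],
    extensions: list[tuple[int, str, str]],
    names: dict[str, str],
) -> list[SubstitutionVariant]:
    """Build the base combination plus one extended variant per extension.

    ``base`` substitutions must be pairwise position-disjoint and every
    extension disjoint from the base.  ``names`` maps canonical
    slash-joined substitution strings to aliases (e.g. "GA", "GAM").
    """
    base_positions = [p for p, _, _ in base]
    if len(base_positions) != len(set(base_positions)):
        raise PanelDesignError("base substitutions collide on a position")
    out = []

    def _named(subs: tuple[tuple[int, str, str], ...]) -> SubstitutionVariant:
        canonical = "/".join(f"{wt}{p}{new}" for p, wt, new in sorted(subs))
        return SubstitutionVariant(
            substitutions=tuple(sorted(subs)),
            name=names.get(canonical, canonical),
            origin="combination",
        )

    out.append(_named(tuple(base)))
    for ext in extensions:
        if ext[0] in base_positions:
            raise PanelDesignError(
                f"extension at position {ext[0]} collides with the base"
            )
        out.append(_named(tuple(base) + (ext,)))
    return out
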