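"""Packaged worked-example data for the MAM/IPMS enzyme family.

Methylthioalkylmalate synthases (MAMs) catalyse the condensation step of the
glucosinolate chain-elongation cycle; their substrate-pocket residues control
how many elongation rounds a 2-oxo acid substrate undergoes.  The constants
here encode the published natural variation at the five substrate-proximal
positions of *A. thaliana* MAM1 (numbering along ungapped MAM1) observed
across Brassicaceae MAM/IPMS homologues, and the curated variant panel built
from it.  They drive the README worked example and the regression tests; the
full-family pipeline takes real alignments and structures as inputs.
"""

from __future__ import annotations

from .family_alignment import FamilyAlignment

#: Substrate-proximal positions (within 8 A of the bound 2-oxo acid in the
#: superposed structures), in MAM1 numbering.
SHELL_POSITIONS: tuple[int, ...] = (186, 229, 257, 259, 290)

#: The one shell position invariant across all MAM synthases.
CONSERVED_SHELL_POSITION: int = 229

#: Residues observed at the four polymorphic shell positions across
#: representative MAM/IPMS homologues (rows with two residues denote
#: species-specific alternatives and expand to two sequences).
NATURAL_VARIATION: dict[str, dict[int, str]] = {
    "AtIPMS":     {186: "H", 257: "N", 259: "P", 290: "S"},
    "AtMAM1":     {186: "L", 257: "T", 259: "G", 290: "A"},
    "AtMAM2":     {186: "L", 257: "N", 259: "A", 290: "S"},
    "AtMAM3":     {186: "M", 257: "G", 259: "A", 290: "A"},
    "AtbMAM1":    {186: "L", 257: "S", 259: "G", 290: "A"},
    "Al/AcMAMb":  {186: "I/L", 257: "G", 259: "A", 290: "T"},
    "Cs/CrMAM3a": {186: "T", 257: "G", 259: "A", 290: "A"},
    "Al/AcMAM3c": {186: "C", 257: "C", 259: "A", 290: "S"},
    "Cs/CrMAM3b": {186: "G/I", 257: "G", 259: "A", 290: "G"},
}

#: Substitutions not observed in the family but chosen for structural
#: reasons (position, new residue, note).
MANUAL_ADDITIONS: list[tuple[int, str, str]] = [
    (257, "V", "structural: small hydrophobic"),
    (257, "D", "structural: acidic"),
]

#: Canonical aliases of the combination variants: the common MAMb-clade
#: double mutant plus the two triples mimicking long-chain MAM3s.
COMBINATION_BASE: list[tuple[int, str, str]] = [(257, "T", "G"), (259, "G", "A")]
COMBINATION_EXTENSIONS: list[tuple[int, str, str]] = [(186, "L", "M"), (290, "A", "G")]
COMBINATION_NAMES: dict[str, str] = {
    "T257G/G259A": "GA",
    "L186M/T257G/G259A": "GAM",
    "T257G/G259A/A290G": "GAG",
}

REFERENCE_ID = "AtMAM1"


def natural_variation_alignment(length: int = 300) -> FamilyAlignment:
    """Expand the natural-variation matrix into a gap-free family alignment.

    Every column outside the five shell positions is invariant ("A"); the
    conserved shell position carries "G" in all rows, matching the family;
    homologue rows listing two alternative residues become two sequences.
    AtMAM1 is the numbering reference.
    """
    if length < max(SHELL_POSITIONS):
        raise ValueError(f"length must be >= {max(SHELL_POSITIONS)}")
    records = []
    for name, residues in NATURAL_VARIATION.items():
        alternatives = [residues]
        for pos, res in residues.items():
            if "/" in res:
                alternatives = [
                    {**r, pos: option} for r in alternatives for option in res.split("/")
                ]
        for i, variant in enumerate(alternatives):
            seq = ["A"] * length
            seq[CONSERVED_SHELL_POSITION - 1] = "G"
            for pos, res in variant.items():
                seq[pos - 1] = res
            rid = name if len(alternatives) == 1 else f"{name}.{i + 1}"
            records.append((rid.replace("/", "_"), "".join(seq)))
    reference_id = REFERENCE_ID
    return FamilyAlignment(records=tuple(records), reference_id=reference_id)
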