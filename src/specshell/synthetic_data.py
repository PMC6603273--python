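"""Seeded synthetic-data generators with known ground truth.

The study's raw inputs (family alignment, structures, MRM area tables) are
not deposited anywhere, so every pipeline stage is exercised on generated
data whose truth is known by construction:

* family alignments with planted polymorphic columns, planted conserved
  columns and planted large-deletion sequences;
* a ligand-bearing template structure plus a rigid-transformed (optionally
  coordinate-noised) copy, with planted shell membership: chosen residues
  placed at controlled minimum distances from the ligand;
* long-format MRM tables (metabolite and proteomics) drawn from known
  ground-truth concentrations / expression factors under multiplicative
  log-normal noise, the standard noise model for LC-MS peak intensities.

Identical spec + seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .family_alignment import FamilyAlignment
from .structure_shell import Atom, Residue, Structure

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class SpecError(ValueError):
    """Generator parameters out of range."""


# ---------------------------------------------------------------------------
# Family alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentSpec:
    """Planted-truth family alignment parameters.

    ``polymorphic_positions`` maps a 1-based reference position to the set of
    residues circulating there (must include >= 2 letters); every other
    column is strictly conserved.  ``deletion_coverages`` plants extra
    sequences whose non-gap fraction over the reference columns equals the
    given values (for testing the large-deletion filter).
    """

    n_sequences: int = 57
    length: int = 300
    polymorphic_positions: dict[int, str] = field(default_factory=dict)
    deletion_coverages: tuple[float, ...] = ()
    reference_id: str = "REF"

    def validate(self) -> None:
        if self.n_sequences < 2 or self.length < 1:
            raise SpecError("need >= 2 sequences and length >= 1")
        for pos, residues in self.polymorphic_positions.items():
            if not 1 <= pos <= self.length:
                raise SpecError(f"planted position {pos} outside 1..{self.length}")
            if len(set(residues)) < 2:
                raise SpecError(f"position {pos}: needs >= 2 distinct residues")
        for cov in self.deletion_coverages:
            if not 0 <= cov <= 1:
                raise SpecError("deletion coverage must be in [0, 1]")


def gen_alignment(
    spec: AlignmentSpec, seed: int | np.random.Generator = 0
) -> tuple[FamilyAlignment, dict]:
    """Generate a gap-free family alignment plus planted truth.

    The reference carries the first residue of each planted set; each planted
    column is dealt so that every listed residue appears at least once.
    Returns ``(alignment, truth)`` where truth holds the planted polymorphic
    positions and the identifiers of the planted deletion sequences.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    consensus = _AA[rng.integers(0, len(_AA), size=spec.length)].copy()
    rows = np.tile(consensus, (spec.n_sequences, 1))
    for pos, residues in sorted(spec.polymorphic_positions.items()):
        letters = sorted(set(residues))
        # reference keeps the first planted letter; the family columns carry
        # each planted letter at least once, remainder drawn uniformly
        rows[0, pos - 1] = letters[0]
        n_family = spec.n_sequences - 1
        if n_family < len(letters):
            raise SpecError(
                f"position {pos}: {len(letters)} planted residues need "
                f">= {len(letters)} non-reference sequences"
            )
        col = letters + [
            letters[int(i)] for i in rng.integers(0, len(letters), n_family - len(letters))
        ]
        rng.shuffle(col)
        rows[1:, pos - 1] = col

    records = [(spec.reference_id, "".join(rows[0]))]
    records += [
        (f"SEQ{i:03d}", "".join(rows[i])) for i in range(1, spec.n_sequences)
    ]

    deletion_ids = []
    for j, cov in enumerate(spec.deletion_coverages):
        n_keep = int(round(cov * spec.length))
        seq = list(records[1 + (j % (spec.n_sequences - 1))][1])
        gap_cols = rng.permutation(spec.length)[: spec.length - n_keep]
        for c in gap_cols:
            seq[c] = "-"
        rid = f"DEL{j:02d}"
        deletion_ids.append(rid)
        records.append((rid, "".join(seq)))

    aln = FamilyAlignment(records=tuple(records), reference_id=spec.reference_id)
    truth = {
        "polymorphic_positions": sorted(spec.polymorphic_positions),
        "planted_residues": {
            p: sorted(set(r)) for p, r in spec.polymorphic_positions.items()
        },
        "deletion_ids": deletion_ids,
        "deletion_coverages": dict(zip(deletion_ids, spec.deletion_coverages)),
    }
    return aln, truth


# ---------------------------------------------------------------------------
# Structure pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureSpec:
    """Planted-truth structure-pair parameters.

    ``shell_distances`` maps residue number -> intended minimum distance (A)
    from the ligand centroid side; all other residues sit at
    >= ``background_min_distance``.  The surrogate copy is the template's
    polymer under ``rotation_deg`` about z plus ``translation``, with
    isotropic Gaussian coordinate noise of ``noise_sigma`` A.
    """

    n_residues: int = 40
    shell_distances: dict[int, float] = field(default_factory=dict)
    background_min_distance: float = 12.0
    rotation_deg: float = 30.0
    translation: tuple[float, float, float] = (5.0, -3.0, 2.0)
    noise_sigma: float = 0.0
    ligand_name: str = "AKG"
    chain_id: str = "A"

    def validate(self) -> None:
        if self.n_residues < max([0, *self.shell_distances], default=0):
            raise SpecError("planted shell residue number outside structure")
        if any(d <= 0 for d in self.shell_distances.values()):
            raise SpecError("planted distances must be positive")
        if self.background_min_distance <= max(
            self.shell_distances.values(), default=0.0
        ):
            raise SpecError("background distance must exceed planted shell distances")


def _rotation_matrix_z(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def gen_structure_pair(
    spec: StructureSpec, seed: int | np.random.Generator = 0
) -> tuple[Structure, Structure, dict]:
    """Generate (template-with-ligand, transformed surrogate, truth).

    The ligand is a single hetero atom at the origin, so each residue's
    planted distance is exact.  Polymer residues are single-CA residues
    placed on random directions at controlled radii; shell residues at their
    planted distances, the rest at ``background_min_distance`` plus a random
    offset.  Truth records planted shell membership and the rigid transform.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _direction() -> np.ndarray:
        v = rng.standard_normal(3)
        return v / np.linalg.norm(v)

    residues = []
    for i in range(1, spec.n_residues + 1):
        if i in spec.shell_distances:
            radius = spec.shell_distances[i]
        else:
            radius = spec.background_min_distance + rng.uniform(0.0, 20.0)
        xyz = _direction() * radius
        residues.append(
            Residue(
                chain_id=spec.chain_id, number=i, insertion_code="", name="ALA",
                atoms=(Atom("CA", "C", tuple(xyz), "polymer"),),
                record_class="polymer",
            )
        )
    ligand = Residue(
        chain_id=spec.chain_id, number=spec.n_residues + 1, insertion_code="",
        name=spec.ligand_name,
        atoms=(Atom("C1", "C", (0.0, 0.0, 0.0), "hetero"),),
        record_class="hetero",
    )
    template = Structure(residues=tuple(residues) + (ligand,), name="template")

    R = _rotation_matrix_z(spec.rotation_deg)
    t = np.asarray(spec.translation, dtype=float)
    surrogate_res = []
    for r in residues:
        xyz = R @ np.asarray(r.atoms[0].coord) + t
        if spec.noise_sigma > 0:
            xyz = xyz + rng.normal(0.0, spec.noise_sigma, size=3)
        surrogate_res.append(
            Residue(
                chain_id=r.chain_id, number=r.number, insertion_code="",
                name=r.name, atoms=(Atom("CA", "C", tuple(xyz), "polymer"),),
                record_class="polymer",
            )
        )
    surrogate = Structure(residues=tuple(surrogate_res), name="surrogate")
    truth = {
        "shell_positions": sorted(spec.shell_distances),
        "shell_distances": dict(sorted(spec.shell_distances.items())),
        "rotation": R,
        "translation": t,
        "noise_sigma": spec.noise_sigma,
    }
    return template, surrogate, truth


# ---------------------------------------------------------------------------
# MRM tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MrmSpec:
    """Planted-truth targeted-LC-MS table parameters.

    ``concentrations`` maps strain -> analyte -> true concentration (same
    units as the internal-standard concentration after dilution correction).
    Defaults mirror the study design: 3 biological x 3 technical replicates,
    a 10 ug/ml internal-standard mix and a combined 25-fold sample dilution.
    ``noise_cv`` is the coefficient of variation of the multiplicative
    log-normal noise applied independently to each analyte and standard area.
    """

    concentrations: dict[str, dict[str, float]] = field(default_factory=dict)
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    is_concentration: float = 10.0
    dilution_factor: float = 25.0
    noise_cv: float = 0.10
    base_is_area: float = 1e5

    def validate(self) -> None:
        if not self.concentrations:
            raise SpecError("no strains/concentrations given")
        if self.noise_cv < 0:
            raise SpecError("noise_cv must be >= 0")
        if self.is_concentration <= 0 or self.dilution_factor <= 0:
            raise SpecError("standard concentration and dilution must be positive")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(() if size is None else size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def gen_mrm_table(
    spec: MrmSpec, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, dict]:
    """Generate a long-format metabolite MRM area table plus truth.

    Areas are constructed so the internal-standard quantification recovers
    the planted concentrations exactly at zero noise:
    ``area = conc / (is_conc * dilution) * is_area`` with per-measurement
    log-normal factors on both areas at ``noise_cv``.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for strain, analytes in spec.concentrations.items():
        for b in range(1, spec.n_bio_reps + 1):
            for t in range(1, spec.n_tech_reps + 1):
                for analyte, conc in analytes.items():
                    is_area = spec.base_is_area * float(
                        _lognormal_factor(rng, spec.noise_cv, None)
                    )
                    if conc == 0:
                        area = 0.0
                    else:
                        area = (
                            conc
                            / (spec.is_concentration * spec.dilution_factor)
                            * spec.base_is_area
                            * float(_lognormal_factor(rng, spec.noise_cv, None))
                        )
                    rows.append(
                        {
                            "strain": strain, "bio_rep": f"B{b}",
                            "tech_rep": f"T{t}", "analyte": analyte,
                            "area": area, "is_area": is_area,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = {
        "concentrations": {s: dict(a) for s, a in spec.concentrations.items()},
        "is_concentration": spec.is_concentration,
        "dilution_factor": spec.dilution_factor,
        "noise_cv": spec.noise_cv,
    }
    return table, truth


@dataclass(frozen=True)
class ProteomicsSpec:
    """Planted-truth proteomics table parameters.

    ``expression`` maps strain -> protein -> expression factor relative to
    the reference strain (factor 0 plants an undetected light peptide).  The
    housekeeping protein is present in every strain at ``housekeeping_level``.
    """

    expression: dict[str, dict[str, float]] = field(default_factory=dict)
    reference_strain: str = "REFSTRAIN"
    housekeeping_protein: str = "ICD"
    housekeeping_level: float = 1.0
    n_bio_reps: int = 3
    noise_cv: float = 0.10
    base_heavy_area: float = 5e4
    base_light_area: float = 2e4

    def validate(self) -> None:
        if self.reference_strain not in self.expression:
            raise SpecError("reference strain missing from expression map")
        if self.housekeeping_level <= 0:
            raise SpecError("housekeeping level must be positive")


def gen_proteomics_table(
    spec: ProteomicsSpec, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, dict]:
    """Generate a light/heavy peptide area table plus planted truth.

    Quantifier peptide names are ``PEP_<protein>``.  Light areas scale with
    the planted expression factor (zero factor -> NaN light area, the
    undetected case); heavy areas fluctuate around the spike level.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proteins = sorted({p for m in spec.expression.values() for p in m})
    rows = []
    for strain, levels in spec.expression.items():
        for b in range(1, spec.n_bio_reps + 1):
            # per-sample extraction yield: scales every light peptide together
            sample_factor = float(_lognormal_factor(rng, spec.noise_cv, None))
            for protein in [spec.housekeeping_protein, *proteins]:
                if protein == spec.housekeeping_protein:
                    factor = spec.housekeeping_level
                else:
                    factor = levels.get(protein, 0.0)
                heavy = spec.base_heavy_area * float(
                    _lognormal_factor(rng, spec.noise_cv, None)
                )
                if factor == 0:
                    light = np.nan
                else:
                    light = (
                        spec.base_light_area * factor * sample_factor
                        * float(_lognormal_factor(rng, spec.noise_cv, None))
                    )
                rows.append(
                    {
                        "strain": strain, "bio_rep": f"B{b}",
                        "peptide": f"PEP_{protein}", "protein": protein,
                        "light_area": light, "heavy_area": heavy,
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "expression": {s: dict(m) for s, m in spec.expression.items()},
        "reference_strain": spec.reference_strain,
        "housekeeping_protein": spec.housekeeping_protein,
    }
    return table, truth
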