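"""Structure superposition and ligand-proximity residue shells.

Reads PDB-format coordinates, rigidly superimposes two structures with the
Kabsch algorithm guided by an alignment-derived residue correspondence,
and selects the polymer residues whose heavy atoms lie within a distance
cutoff of a bound ligand -- the "ligand shell" that seeds the
specificity-residue search.

Distances are minimum heavy-atom/heavy-atom Euclidean distances in Angstrom;
hydrogens, waters and monoatomic ions never join a shell.  Coordinates stay
in the file's frame: no crystallographic symmetry expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Raised for empty, malformed or unusable structure input."""


class CorrespondenceError(ValueError):
    """Raised when a residue correspondence cannot support an operation."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    record_class: str  # "polymer" | "hetero"

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: tuple[Atom, ...]
    record_class: str  # "polymer" | "hetero"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array(
            [a.coord for a in self.atoms if not a.is_hydrogen], dtype=float
        ).reshape(-1, 3)


@dataclass(frozen=True)
class Structure:
    """Parsed atomic coordinates grouped into chains of residues."""

    residues: tuple[Residue, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError("structure contains no atoms")
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise StructureError("duplicate residue keys within a chain")
        for r in self.residues:
            for a in r.atoms:
                if not np.all(np.isfinite(a.coord)):
                    raise StructureError(f"non-finite coordinates in residue {r.key}")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.record_class == "polymer"]

    def hetero_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.record_class == "hetero"]

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain_id, number, icode):
                return r
        raise KeyError(f"no residue {chain_id}/{number}{icode}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply x -> R x + t to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_res = []
        for r in self.residues:
            new_atoms = tuple(
                Atom(a.name, a.element, tuple(R @ np.asarray(a.coord) + t), a.record_class)
                for a in r.atoms
            )
            new_res.append(
                Residue(r.chain_id, r.number, r.insertion_code, r.name, new_atoms, r.record_class)
            )
        return Structure(residues=tuple(new_res), name=self.name)


@dataclass(frozen=True)
class ResidueCorrespondence:
    """Residue-number pairing between two structures (e.g. from a pairwise
    alignment's mutually non-gap columns).  ``pairs`` maps position_a (mobile
    side) to position_b (fixed side)."""

    pairs: tuple[tuple[int, int], ...]
    source: str = ""

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(a_side) != len(set(a_side)) or len(b_side) != len(set(b_side)):
            raise CorrespondenceError("a position appears more than once per side")

    def a_to_b(self) -> dict[int, int]:
        return dict(self.pairs)

    def b_to_a(self) -> dict[int, int]:
        return {b: a for a, b in self.pairs}


def correspondence_from_pairwise_alignment(
    seq_a: str, seq_b: str, source: str = "pairwise alignment"
) -> ResidueCorrespondence:
    """Build a correspondence from two aligned (gapped) sequences.

    Positions are 1-based ungapped residue numbers per side; only mutually
    non-gap columns contribute pairs.
    """
    if len(seq_a) != len(seq_b):
        raise CorrespondenceError("aligned sequences differ in length")
    pairs = []
    pos_a = pos_b = 0
    for ca, cb in zip(seq_a, seq_b):
        if ca != "-":
            pos_a += 1
        if cb != "-":
            pos_b += 1
        if ca != "-" and cb != "-":
            pairs.append((pos_a, pos_b))
    return ResidueCorrespondence(pairs=tuple(pairs), source=source)


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid transform (mobile -> fixed) and its residual RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class LigandShell:
    """Polymer residues within ``cutoff`` Angstrom of the selected ligand."""

    cutoff: float
    ligand_key: tuple[str, int, str]
    ligand_name: str
    members: tuple[tuple[tuple[str, int, str], float], ...]  # (residue key, min dist)
    member_names: dict[tuple[str, int, str], str] = field(default_factory=dict, compare=False)

    @property
    def member_numbers(self) -> set[int]:
        return {key[1] for key, _ in self.members}


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_structure(path, name: str = "") -> Structure:
    """Parse a PDB file (ATOM/HETATM records) into a :class:`Structure`.

    Polymer vs hetero follows the record type via Bio.PDB's hetero field;
    alternate locations resolve to the highest-occupancy conformer (ties:
    first encountered).  Only the first model of multi-model files is read.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            model = next(parser.get_structure(name or "s", path).get_models())
        except StopIteration:
            raise StructureError(f"{path}: no model/atoms found") from None
        except ValueError as exc:
            raise StructureError(f"{path}: malformed PDB records: {exc}") from exc
    residues = []
    for chain in model:
        for res in chain:
            hetfield, resseq, icode = res.id
            record_class = "polymer" if hetfield == " " else "hetero"
            atoms = tuple(
                Atom(
                    name=atom.get_name(),
                    element=(atom.element or "").strip().upper(),
                    coord=tuple(float(c) for c in atom.get_coord()),
                    record_class=record_class,
                )
                # .get_unpacked_list() would return all altlocs; iterating the
                # residue yields each DisorderedAtom's selected child, which
                # Bio.PDB keeps as the highest-occupancy conformer.
                for atom in res
            )
            residues.append(
                Residue(
                    chain_id=chain.id,
                    number=int(resseq),
                    insertion_code=icode.strip(),
                    name=res.get_resname().strip(),
                    atoms=atoms,
                    record_class=record_class,
                )
            )
    if not residues:
        raise StructureError(f"{path}: no atoms found")
    return Structure(residues=tuple(residues), name=name)


def write_structure(struct: Structure, path) -> None:
    """Write a minimal PDB file (ATOM/HETATM/TER/END) at 3-decimal precision."""
    with open(path, "w") as fh:
        serial = 1
        last_chain = None
        for r in struct.residues:
            if last_chain is not None and r.chain_id != last_chain:
                fh.write("TER\n")
            last_chain = r.chain_id
            record = "ATOM  " if r.record_class == "polymer" else "HETATM"
            for a in r.atoms:
                x, y, z = a.coord
                atom_name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"{record}{serial:5d} {atom_name:<4s}{'':1s}{r.name:>3s} "
                    f"{r.chain_id:1s}{r.number:4d}{r.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_transform(mobile_xyz: np.ndarray, fixed_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation R and translation t minimising
    ``|| (R @ mobile + t) - fixed ||`` over paired points; returns (R, t, rmsd).

    The reflection case (det < 0) is corrected by flipping the sign of the
    smallest singular direction, so det(R) = +1 always.
    """
    P = np.asarray(mobile_xyz, dtype=float)
    Q = np.asarray(fixed_xyz, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise CorrespondenceError(f"need >= 3 paired points, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 => points (near-)collinear: rotation about the axis undetermined
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise CorrespondenceError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return R, t, rmsd


def kabsch_superpose(
    mobile: Structure,
    fixed: Structure,
    corr: ResidueCorrespondence,
    atom_name: str = "CA",
    mobile_chain: str | None = None,
    fixed_chain: str | None = None,
) -> Superposition:
    """Superimpose ``mobile`` onto ``fixed`` over corresponding residues.

    Uses the named atom (alpha-carbon by default) of each corresponded
    residue; pairs missing the atom on either side are dropped, and
    ``n_atoms`` reports how many were used.
    """
    mob_chain = mobile_chain or mobile.chains[0]
    fix_chain = fixed_chain or fixed.chains[0]
    mob_by_num = {
        r.number: r for r in mobile.polymer_residues() if r.chain_id == mob_chain
    }
    fix_by_num = {
        r.number: r for r in fixed.polymer_residues() if r.chain_id == fix_chain
    }
    P, Q = [], []
    for a, b in corr.pairs:
        ra, rb = mob_by_num.get(a), fix_by_num.get(b)
        if ra is None or rb is None:
            continue
        aa, ab = ra.atom(atom_name), rb.atom(atom_name)
        if aa is None or ab is None:
            continue
        P.append(aa.coord)
        Q.append(ab.coord)
    if len(P) < 3:
        raise CorrespondenceError(
            f"only {len(P)} usable correspondence pairs with atom {atom_name!r}"
        )
    R, t, rmsd = kabsch_transform(np.array(P), np.array(Q))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(P))


# ---------------------------------------------------------------------------
# Ligand shell
# ---------------------------------------------------------------------------

def _is_monoatomic_ion(res: Residue) -> bool:
    return len([a for a in res.atoms if not a.is_hydrogen]) <= 1


def ligand_shell(
    struct: Structure,
    ligand_name: str | None = None,
    ligand_chain: str | None = None,
    ligand_number: int | None = None,
    cutoff: float = 8.0,
) -> LigandShell:
    """Residues with any heavy atom within ``cutoff`` A of the ligand.

    The selector (name and/or chain and/or residue number) must match exactly
    one hetero residue.  Membership uses the minimum over all heavy-atom
    pairs, compared inclusively (min distance == cutoff is *in*).  Waters and
    monoatomic ions are excluded from membership.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    matches = [
        r
        for r in struct.hetero_residues()
        if (ligand_name is None or r.name == ligand_name)
        and (ligand_chain is None or r.chain_id == ligand_chain)
        and (ligand_number is None or r.number == ligand_number)
    ]
    if len(matches) != 1:
        raise StructureError(
            f"ligand selector matched {len(matches)} hetero residues (need exactly 1)"
        )
    ligand = matches[0]
    lig_xyz = ligand.heavy_coords()
    if lig_xyz.size == 0:
        raise StructureError("ligand has no heavy atoms")
    tree = cKDTree(lig_xyz)
    members = []
    names = {}
    for r in struct.residues:
        if r.key == ligand.key:
            continue
        if r.record_class == "hetero" and (
            r.name in WATER_NAMES or _is_monoatomic_ion(r)
        ):
            continue
        if r.record_class != "polymer":
            continue
        xyz = r.heavy_coords()
        if xyz.size == 0:
            continue
        dmin = float(tree.query(xyz)[0].min())
        if dmin <= cutoff:
            members.append((r.key, dmin))
            names[r.key] = r.name
    members.sort(key=lambda m: m[0])
    return LigandShell(
        cutoff=cutoff,
        ligand_key=ligand.key,
        ligand_name=ligand.name,
        members=tuple(members),
        member_names=names,
    )


def map_shell_to_target(
    shell: LigandShell, corr: ResidueCorrespondence
) -> tuple[set[int], list[int]]:
    """Translate shell residue numbers (template side) into target numbering.

    ``corr`` pairs template positions (side a) with target positions (side b).
    Returns ``(mapped_target_positions, unmapped_template_positions)``.
    """
    lookup = corr.a_to_b()
    mapped: set[int] = set()
    unmapped: list[int] = []
    for (chain, number, icode), _dist in shell.members:
        if number in lookup:
            mapped.add(lookup[number])
        else:
            unmapped.append(number)
    return mapped, sorted(set(unmapped))
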