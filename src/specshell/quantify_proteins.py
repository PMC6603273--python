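"""Relative protein quantification from light/heavy proteotypic peptides.

Each target protein is monitored through a quantifier tryptic peptide whose
synthetic isotope-labelled ("heavy") counterpart is spiked at a fixed amount.
The endogenous ("light") to heavy area ratio is normalised to a housekeeping
protein (isocitrate dehydrogenase in the bacterial host) within each sample,
then expressed relative to a designated reference strain::

    value(strain, protein) = [L/H(protein, strain) / L/H(HK, strain)]
                             / [L/H(protein, ref) / L/H(HK, ref)]

Undetected light peptides count as zero -- an absent protein is a real zero,
not missing data.  Because each protein has its own peptide with its own
response factor, values are comparable across strains for one protein but
never across proteins; the interface refuses cross-protein ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass

PROTON_MASS = 1.00727646688


class StandardError_(ValueError):
    """Invalid heavy-standard area (must be positive)."""


class NormalisationError(ValueError):
    """Housekeeping ratio is zero/undefined in some strain."""


# ---------------------------------------------------------------------------
# Ratios and relative quantification
# ---------------------------------------------------------------------------

def light_heavy_ratio(light_area: float | None, heavy_area: float) -> float:
    """Endogenous/standard peptide area ratio; missing light counts as 0."""
    if heavy_area is None or not heavy_area > 0:
        raise StandardError_(f"heavy (standard) area must be > 0, got {heavy_area}")
    if light_area is None or (isinstance(light_area, float) and np.isnan(light_area)):
        return 0.0
    if light_area < 0:
        raise ValueError("light area must be non-negative")
    return float(light_area) / float(heavy_area)


@dataclass(frozen=True)
class RelativeQuant:
    strain: str
    protein: str
    value: float          # NaN when undefined (reference ratio zero)
    defined: bool
    n_replicates: int


def relative_quant(
    table: pd.DataFrame,
    housekeeping_protein: str,
    reference_strain: str,
    quantifier_peptides: dict[str, str] | None = None,
) -> list[RelativeQuant]:
    """Housekeeping- and reference-normalised protein levels per strain.

    ``table`` is long-format with columns ``strain, bio_rep, peptide,
    protein, light_area, heavy_area``.  If ``quantifier_peptides`` maps
    protein -> peptide, only those rows are used (one quantifier per protein);
    otherwise each protein must have a single peptide.

    Normalisation happens within each biological replicate, reference
    relativisation against the reference strain's mean normalised ratio, and
    replicates are averaged last.  A protein absent from the reference strain
    (mean reference ratio zero) gives an undefined value (NaN, flagged).
    """
    required = {"strain", "bio_rep", "peptide", "protein", "light_area", "heavy_area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns {sorted(missing)}")
    df = table.copy()
    if quantifier_peptides is not None:
        keep = df.apply(
            lambda r: quantifier_peptides.get(r["protein"]) == r["peptide"], axis=1
        )
        df = df[keep]
    else:
        multi = df.groupby("protein")["peptide"].nunique()
        bad = multi[multi > 1]
        if not bad.empty:
            raise ValueError(
                f"multiple peptides per protein without a quantifier map: "
                f"{sorted(bad.index)}"
            )
    if df.empty:
        raise ValueError("no quantifier rows in table")
    if reference_strain not in set(df["strain"]):
        raise ValueError(f"reference strain {reference_strain!r} absent")

    df["ratio"] = [
        light_heavy_ratio(la, ha) for la, ha in zip(df["light_area"], df["heavy_area"])
    ]

    # within-replicate housekeeping normalisation
    hk = df[df["protein"] == housekeeping_protein].set_index(["strain", "bio_rep"])[
        "ratio"
    ]
    zero_hk = hk[hk <= 0]
    if not zero_hk.empty:
        raise NormalisationError(
            f"housekeeping ratio is zero in samples: {list(zero_hk.index)}"
        )
    df = df[df["protein"] != housekeeping_protein].copy()
    df["normalised"] = [
        r / hk.loc[(s, b)]
        for r, s, b in zip(df["ratio"], df["strain"], df["bio_rep"])
    ]

    results: list[RelativeQuant] = []
    for protein, sub in df.groupby("protein", sort=False):
        ref_mean = sub.loc[sub["strain"] == reference_strain, "normalised"].mean()
        for strain, ssub in sub.groupby("strain", sort=False):
            vals = ssub["normalised"].to_numpy(dtype=float)
            if not np.isfinite(ref_mean) or ref_mean == 0:
                results.append(
                    RelativeQuant(strain, protein, float("nan"), False, len(vals))
                )
                continue
            results.append(
                RelativeQuant(
                    strain, protein, float(vals.mean() / ref_mean), True, len(vals)
                )
            )
    return results


def relative_quant_frame(results: list[RelativeQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain": [r.strain for r in results],
            "protein": [r.protein for r in results],
            "value": [r.value for r in results],
            "defined": [r.defined for r in results],
            "n_replicates": [r.n_replicates for r in results],
        }
    )


def cross_protein_ratio(*_args, **_kwargs):
    """Refused: peptide response factors differ between proteins, so levels
    of different proteins are not on a common scale."""
    raise NotImplementedError(
        "cross-protein comparisons are not meaningful with per-protein "
        "proteotypic standards; compare strains within one protein instead"
    )


# ---------------------------------------------------------------------------
# Proteotypic peptide panel audit
# ---------------------------------------------------------------------------

#: (protein, peptide, is_quantifier) triples for the chain-elongation
#: pathway enzymes and the host housekeeping anchor (ICD).  Quantifier
#: peptides (one per protein) drive the relative quantification; the rest
#: serve as detection witnesses.
CHAIN_ELONGATION_PEPTIDES: tuple[tuple[str, str, bool], ...] = (
    ("BCAT4", "TGEETLAAK", False),
    ("BCAT4", "LYETLSDIQTGR", True),
    ("BCAT4", "SITNYZPVWIPLAEAK", False),
    ("BCAT4", "GNVVSTPTIAGTILPGVTR", False),
    ("MAM1", "SGNASLEEVVMALK", False),
    ("MAM1", "STYEILSPEDIGIVK", False),
    ("MAM1", "DGEQSPGGSLTPPQK", False),
    ("MAM1", "SLGFNDIQFGZEDGGR", True),
    ("MAM3", "GESLMDGVYTK", False),
    ("MAM3", "ALVVNGAEISSEK", False),
    ("MAM3", "SGNAPLEEVVMALK", False),
    ("MAM3", "STYEILSPEDVGIVK", True),
    ("MAM3", "DGEQSPGAALTPPQK", False),
    ("IPMS2", "GTYEIMSPEEIGLER", True),
    ("IPMI-LSU1", "FILDGEMPSYLQAK", True),
    ("IPMI-LSU1", "VWMDVYALPVPGAGGK", False),
    ("IPMI-SSU3", "LGSFALNGLPK", False),
    ("IPMI-SSU3", "EDGSSLLINHTTR", False),
    ("IPMI-SSU3", "NCVATGEIFPLESEVR", True),
    ("IPMDH1", "LSDAILLGAIGGYK", True),
    ("IPMDH1", "AGSLEGLEFDFK", False),
    ("IPMDH1", "IEDAVVDALNK", False),
    ("ICD", "GPLTTPVGGGIR", True),
)


def quantifier_map(
    peptides: tuple[tuple[str, str, bool], ...] = CHAIN_ELONGATION_PEPTIDES,
) -> dict[str, str]:
    """Protein -> quantifier-peptide map from a peptide panel."""
    out: dict[str, str] = {}
    for protein, pep, is_q in peptides:
        if is_q:
            if protein in out:
                raise ValueError(f"{protein}: more than one quantifier peptide")
            out[protein] = pep
    return out

@dataclass(frozen=True)
class PeptideAudit:
    peptide: str
    protein: str
    mz: float | None            # [M+2H]2+ by default; None when mass undefined
    violations: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    @property
    def passes(self) -> bool:
        return not self.violations and not self.warnings


def tryptic_peptides(sequence: str) -> list[str]:
    """In-silico tryptic digest: cleave after K/R except before P."""
    peptides, start = [], 0
    for i, ch in enumerate(sequence):
        if ch in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    return peptides


def peptide_mz(sequence: str, charge: int = 2) -> float:
    """Monoisotopic m/z of a peptide at the given positive charge."""
    m = _pt_mass.fast_mass(sequence, charge=0)
    return (m + charge * PROTON_MASS) / charge


def audit_peptide(
    peptide: str,
    protein: str = "",
    max_mz: float = 1250.0,
    charge: int = 2,
) -> PeptideAudit:
    """Check a proteotypic peptide against the selection preferences.

    Preferences: (1) m/z below ``max_mz`` at the given charge; (2) exactly one
    K/R, at the C-terminus (a clean single tryptic cleavage site); (3) no
    methionine or cysteine (oxidation-prone).  Violations are reported, not
    fatal -- panels in practice keep some preference-violating peptides when
    a protein offers nothing better.  Non-standard letters (B/J/X/Z) make the
    mass undefined; the peptide is excluded from the m/z check with a warning.
    """
    violations: list[str] = []
    warns: list[str] = []
    nonstandard = sorted(set(peptide) & set("BJXZOU"))
    mz = None
    if nonstandard:
        warns.append(
            f"non-standard letters {nonstandard}: mass undefined, m/z check skipped"
        )
    else:
        mz = peptide_mz(peptide, charge=charge)
        if mz >= max_mz:
            violations.append(f"m/z {mz:.1f} >= {max_mz:g}")
    n_kr = sum(peptide.count(x) for x in "KR")
    if n_kr != 1 or peptide[-1] not in "KR":
        violations.append("cleavage-site rule: needs exactly one K/R, C-terminal")
    if set(peptide) & set("MC"):
        violations.append("contains methionine or cysteine")
    return PeptideAudit(
        peptide=peptide, protein=protein, mz=mz,
        violations=tuple(violations), warnings=tuple(warns),
    )


def audit_panel(
    peptides: list[tuple[str, str]], max_mz: float = 1250.0, charge: int = 2
) -> pd.DataFrame:
    """Audit a list of ``(protein, peptide)`` pairs; returns a report frame."""
    rows = []
    for protein, pep in peptides:
        a = audit_peptide(pep, protein, max_mz=max_mz, charge=charge)
        rows.append(
            {
                "protein": protein,
                "peptide": pep,
                "mz": a.mz,
                "violations": "; ".join(a.violations),
                "warnings": "; ".join(a.warnings),
                "passes": a.passes,
            }
        )
    return pd.DataFrame(rows)
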