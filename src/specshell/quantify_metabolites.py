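"""Targeted-MRM metabolite quantification and product-profile statistics.

Converts peak areas into concentrations against stable-isotope-labelled
internal standards::

    concentration = (area / internal_standard_area)
                    * internal_standard_concentration * dilution_factor

then summarises per-strain product profiles (composition by precursor
amino acid, elongation-round distribution), computes fold changes between
strains, and compares strains with one-way ANOVA, per-strain contrasts
against the grand mean, and Tukey's HSD.

Detection semantics: a zero/missing area is *not detected*; a quantifiable
signal below the configured limit of quantification is *below LOQ* and
contributes zero to totals while keeping its detection flag; a nonzero area
with a zero internal-standard area is *unquantifiable* and never silently
becomes zero concentration.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PRECURSORS = ("methionine", "leucine", "phenylalanine", "other")
#: elongation-round bins used for the product-length distribution
ROUND_BINS = ("1", "2", ">=3")

QUANTIFIED = "quantified"
BELOW_LOQ = "below_loq"
NOT_DETECTED = "not_detected"
UNQUANTIFIABLE = "unquantifiable"


class PanelError(ValueError):
    """Unknown analyte or inconsistent panel definition."""


@dataclass(frozen=True)
class AnalyteEntry:
    analyte: str
    precursor: str
    elongation_rounds: int
    internal_standard: str
    loq: float = 0.0
    class_label: str | None = None  # aromatic | indolic | aliphatic (GLS panels)

    def __post_init__(self) -> None:
        if self.precursor not in PRECURSORS:
            raise PanelError(f"{self.analyte}: unknown precursor {self.precursor!r}")
        if self.elongation_rounds < 0:
            raise PanelError(f"{self.analyte}: negative elongation rounds")
        expected = _rounds_from_name(self.analyte)
        if expected is not None and expected != self.elongation_rounds:
            raise PanelError(
                f"{self.analyte}: name implies {expected} elongation rounds, "
                f"entry says {self.elongation_rounds}"
            )


_PREFIX_ROUNDS = {"": 1, "D": 2, "Tri": 3, "Tetra": 4, "Penta": 5, "Hexa": 6,
                  "Hepta": 7, "Octa": 8, "Nona": 9}
_ELONGATED_NAME = re.compile(
    r"^(D|Tri|Tetra|Penta|Hexa|Hepta|Octa|Nona)?(HM|HL|HPhe)$"
)


def _rounds_from_name(name: str) -> int | None:
    """Elongation rounds encoded in homo-amino-acid shorthand (HM=1, DHM=2,
    ... HeptaHM=7; HL=1, DHL=2; HPhe=1); None for names outside the scheme."""
    m = _ELONGATED_NAME.match(name)
    if not m:
        return None
    return _PREFIX_ROUNDS[m.group(1) or ""]


@dataclass(frozen=True)
class AnalytePanel:
    """The set of monitored analytes with grouping and quantification info."""

    entries: tuple[AnalyteEntry, ...]

    def __post_init__(self) -> None:
        names = [e.analyte for e in self.entries]
        if len(names) != len(set(names)):
            raise PanelError("duplicate analyte names in panel")

    def __getitem__(self, analyte: str) -> AnalyteEntry:
        for e in self.entries:
            if e.analyte == analyte:
                return e
        raise PanelError(f"analyte {analyte!r} not in panel")

    def __contains__(self, analyte: str) -> bool:
        return any(e.analyte == analyte for e in self.entries)

    @property
    def analytes(self) -> list[str]:
        return [e.analyte for e in self.entries]

    def by_class(self, class_label: str) -> list[AnalyteEntry]:
        return [e for e in self.entries if e.class_label == class_label]


def chain_elongation_panel(loq: dict[str, float] | None = None) -> AnalytePanel:
    """The elongated-amino-acid panel monitored in the bacterial cultures.

    Methionine homologues elongated one to seven times, leucine homologues
    one to three, and homophenylalanine; each analyte is quantified against
    its isotope-labelled parent amino acid.  LOQ values are configuration
    (instrument-specific), defaulting to 0.
    """
    loq = loq or {}
    spec = [
        ("HM", "methionine", 1), ("DHM", "methionine", 2),
        ("TriHM", "methionine", 3), ("TetraHM", "methionine", 4),
        ("PentaHM", "methionine", 5), ("HexaHM", "methionine", 6),
        ("HeptaHM", "methionine", 7),
        ("HL", "leucine", 1), ("DHL", "leucine", 2), ("TriHL", "leucine", 3),
        ("HPhe", "phenylalanine", 1),
    ]
    standards = {"methionine": "Met-13C15N", "leucine": "Leu-13C15N",
                 "phenylalanine": "Phe-13C15N"}
    return AnalytePanel(entries=tuple(
        AnalyteEntry(name, prec, rounds, internal_standard=standards[prec],
                     loq=loq.get(name, 0.0))
        for name, prec, rounds in spec
    ))


def glucosinolate_panel(loq: dict[str, float] | None = None) -> AnalytePanel:
    """The leaf glucosinolate panel: one aromatic, three indolic and nine
    aliphatic desulfo-glucosinolates, all quantified against the
    p-hydroxybenzyl glucosinolate internal standard.

    Aliphatic side-chain length encodes the elongation round count (a C(n)
    methylthio/methylsulfinyl chain arises from n-2 methionine elongations);
    short chain = rounds 1-3, long chain = rounds >= 4.  Indolic and aromatic
    glucosinolates come from unelongated tryptophan (rounds 0) and
    once-elongated phenylalanine respectively.
    """
    loq = loq or {}
    aliphatic = [
        ("3-methylthiopropyl", 1), ("3-methylsulfinylpropyl", 1),
        ("4-methylthiobutyl", 2), ("4-methylsulfinylbutyl", 2),
        ("5-methylsulfinylpentyl", 3),
        ("7-methylthioheptyl", 5), ("7-methylsulfinylheptyl", 5),
        ("8-methylthiooctyl", 6), ("8-methylsulfinyloctyl", 6),
    ]
    indolic = ["indol-3-ylmethyl", "N-methoxy-indol-3-ylmethyl",
               "4-methoxy-indol-3-ylmethyl"]
    entries = [
        AnalyteEntry(name, "methionine", rounds, "p-hydroxybenzyl-GLS",
                     loq=loq.get(name, 0.0), class_label="aliphatic")
        for name, rounds in aliphatic
    ]
    entries += [
        AnalyteEntry(name, "other", 0, "p-hydroxybenzyl-GLS",
                     loq=loq.get(name, 0.0), class_label="indolic")
        for name in indolic
    ]
    entries.append(
        AnalyteEntry("2-phenylethyl", "phenylalanine", 1, "p-hydroxybenzyl-GLS",
                     loq=loq.get("2-phenylethyl", 0.0), class_label="aromatic")
    )
    return AnalytePanel(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantRecord:
    strain: str
    biological_replicate: str
    technical_replicate: str
    analyte: str
    area: float
    internal_standard_area: float
    concentration: float | None
    status: str


def quantify(
    area: float,
    internal_standard_area: float,
    is_concentration: float,
    dilution_factor: float,
    loq: float = 0.0,
) -> tuple[float | None, str]:
    """Concentration of one measurement, with its detection status.

    Returns ``(concentration, status)``; concentration is None unless
    ``status == "quantified"``.
    """
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    if area is None or (isinstance(area, float) and math.isnan(area)) or area == 0:
        return None, NOT_DETECTED
    if area < 0 or internal_standard_area < 0:
        raise ValueError("peak areas must be non-negative")
    if internal_standard_area == 0:
        return None, UNQUANTIFIABLE
    conc = (area / internal_standard_area) * is_concentration * dilution_factor
    if conc < loq:
        return None, BELOW_LOQ
    return conc, QUANTIFIED


def quantify_table(
    table: pd.DataFrame,
    panel: AnalytePanel,
    is_concentration: float,
    dilution_factor: float,
) -> pd.DataFrame:
    """Vectorised :func:`quantify` over a long-format MRM area table.

    Expects columns ``strain, bio_rep, tech_rep, analyte, area, is_area``;
    returns a copy with ``concentration`` and ``status`` columns added.
    Every analyte must be in the panel.
    """
    required = {"strain", "bio_rep", "tech_rep", "analyte", "area", "is_area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns {sorted(missing)}")
    unknown = set(table["analyte"]) - set(panel.analytes)
    if unknown:
        raise PanelError(f"analytes not in panel: {sorted(unknown)}")
    out = table.copy()
    concs, statuses = [], []
    for analyte, area, is_area in zip(out["analyte"], out["area"], out["is_area"]):
        conc, status = quantify(
            area, is_area, is_concentration, dilution_factor, loq=panel[analyte].loq
        )
        concs.append(conc)
        statuses.append(status)
    out["concentration"] = pd.array(concs, dtype="Float64")
    out["status"] = statuses
    return out


def _effective_concentration(df: pd.DataFrame) -> pd.Series:
    """Concentration used in totals: below-LOQ and not-detected count as 0."""
    conc = df["concentration"].astype(float)
    return conc.where(df["status"] == QUANTIFIED, 0.0)


def collapse_technical_replicates(quantified: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates within each biological replicate.

    Returns one row per (strain, bio_rep, analyte) with the mean effective
    concentration; all cross-replicate statistics run on this level.
    """
    df = quantified.copy()
    df["_conc"] = _effective_concentration(df)
    grouped = (
        df.groupby(["strain", "bio_rep", "analyte"], sort=False)["_conc"]
        .mean()
        .reset_index()
        .rename(columns={"_conc": "concentration"})
    )
    return grouped


# ---------------------------------------------------------------------------
# Product profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileSummary:
    """Per-strain product-profile summary.

    ``group_totals``: mean (over biological replicates) summed concentration
    per precursor group, strains x groups.  ``group_percentages``: the same
    rows normalised to 100 (NaN for strains with zero total, listed in
    ``zero_total_strains``).  ``round_distribution``: percentage of total
    production elongated once, twice, or three-plus times.
    """

    group_totals: pd.DataFrame
    group_percentages: pd.DataFrame
    round_distribution: pd.DataFrame
    zero_total_strains: tuple[str, ...] = ()


def profile(quantified: pd.DataFrame, panel: AnalytePanel) -> ProfileSummary:
    """Build composition and elongation-round summaries per strain."""
    unknown = set(quantified["analyte"]) - set(panel.analytes)
    if unknown:
        raise PanelError(f"analytes not in panel: {sorted(unknown)}")
    per_rep = collapse_technical_replicates(quantified)
    per_rep["precursor"] = [panel[a].precursor for a in per_rep["analyte"]]
    per_rep["rounds"] = [panel[a].elongation_rounds for a in per_rep["analyte"]]
    per_rep["round_bin"] = np.select(
        [per_rep["rounds"] == 1, per_rep["rounds"] == 2],
        [ROUND_BINS[0], ROUND_BINS[1]],
        default=ROUND_BINS[2],
    )

    def _mean_group_total(key: str) -> pd.DataFrame:
        per_rep_totals = (
            per_rep.groupby(["strain", "bio_rep", key], sort=False)["concentration"]
            .sum()
            .unstack(key, fill_value=0.0)
        )
        return per_rep_totals.groupby("strain", sort=False).mean()

    totals = _mean_group_total("precursor")
    grand = totals.sum(axis=1)
    zero_strains = tuple(grand.index[grand == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        percentages = totals.div(grand, axis=0) * 100.0
    percentages.loc[list(zero_strains)] = np.nan

    rounds = _mean_group_total("round_bin")
    rounds = rounds.reindex(columns=[b for b in ROUND_BINS if b in rounds.columns])
    with np.errstate(invalid="ignore", divide="ignore"):
        rounds_pct = rounds.div(rounds.sum(axis=1), axis=0) * 100.0

    return ProfileSummary(
        group_totals=totals,
        group_percentages=percentages,
        round_distribution=rounds_pct,
        zero_total_strains=zero_strains,
    )


def fold_change(
    quantified: pd.DataFrame,
    strain_numerator: str,
    strain_denominator: str,
    analyte: str | None = None,
) -> float:
    """Ratio of mean production (numerator/denominator strain).

    Means are over biological replicates of the per-replicate total
    concentration (all analytes, or one analyte when given).  A zero
    denominator yields NaN with a warning.
    """
    per_rep = collapse_technical_replicates(quantified)
    if analyte is not None:
        per_rep = per_rep[per_rep["analyte"] == analyte]
    totals = (
        per_rep.groupby(["strain", "bio_rep"], sort=False)["concentration"].sum()
    )
    means = totals.groupby("strain").mean()
    for s in (strain_numerator, strain_denominator):
        if s not in means.index:
            raise KeyError(f"strain {s!r} absent from table")
    denom = means[strain_denominator]
    if denom == 0:
        warnings.warn(
            f"fold change undefined: {strain_denominator} total is zero",
            RuntimeWarning,
        )
        return float("nan")
    return float(means[strain_numerator] / denom)


# ---------------------------------------------------------------------------
# Strain comparison statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrainComparison:
    """One-way ANOVA + grand-mean contrasts + Tukey HSD for one response."""

    anova: pd.DataFrame           # F, p, df_between, df_within
    grand_mean_contrasts: pd.DataFrame  # per strain: effect, t, p
    tukey_pairs: pd.DataFrame     # pairwise: diff, q, p_adj, reject
    degenerate: bool = False      # zero within-group variance everywhere


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    """Classic one-way fixed-effects ANOVA from sums of squares.

    Returns ``(F, p, df_between, df_within)``; F is NaN when the within-group
    variance is exactly zero (degenerate input).
    """
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_obs = np.concatenate(groups)
    grand = all_obs.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, len(all_obs) - k
    if ss_within == 0:
        return float("nan"), float("nan"), df_b, df_w
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p, df_b, df_w


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey's HSD over all group pairs via the studentized-range law.

    For unbalanced designs the Tukey-Kramer harmonic standard error is used.
    Returns a frame with columns ``group_a, group_b, diff, q, p_adj, reject``.
    """
    names = list(groups)
    k = len(names)
    if k < 2:
        raise ValueError("need >= 2 groups")
    ns = {g: len(v) for g, v in groups.items()}
    df_w = sum(ns.values()) - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            diff = float(groups[a].mean() - groups[b].mean())
            se = math.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                q = float("inf") if diff != 0 else 0.0
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_w))
            rows.append(
                {"group_a": a, "group_b": b, "diff": diff, "q": q,
                 "p_adj": p_adj, "reject": p_adj < alpha}
            )
    return pd.DataFrame(rows)


def grand_mean_contrasts(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Each group mean contrasted against the grand mean of all observations.

    Uses the pooled within-group mean square; the contrast mean_i - grand
    has variance MSE * (1/n_i - 1/N) under the one-way model.
    """
    names = list(groups)
    k = len(names)
    all_obs = np.concatenate(list(groups.values()))
    N = len(all_obs)
    grand = all_obs.mean()
    df_w = N - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_w
    rows = []
    for g in names:
        n_i = len(groups[g])
        effect = float(groups[g].mean() - grand)
        var = mse * (1.0 / n_i - 1.0 / N)
        if var <= 0:
            t = p = float("nan")
        else:
            t = effect / math.sqrt(var)
            p = float(2.0 * stats.t.sf(abs(t), df_w))
        rows.append({"strain": g, "effect": effect, "t": t, "p": p})
    return pd.DataFrame(rows)


def compare_strains(
    quantified: pd.DataFrame, analyte: str, alpha: float = 0.05
) -> StrainComparison:
    """Full strain comparison for one analyte at biological-replicate level."""
    per_rep = collapse_technical_replicates(quantified)
    per_rep = per_rep[per_rep["analyte"] == analyte]
    groups = {
        strain: sub["concentration"].to_numpy(dtype=float)
        for strain, sub in per_rep.groupby("strain", sort=False)
    }
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 strains with >= 2 biological replicates each")
    F, p, df_b, df_w = one_way_anova(list(groups.values()))
    degenerate = math.isnan(F)
    anova = pd.DataFrame(
        [{"analyte": analyte, "F": F, "p": p, "df_between": df_b, "df_within": df_w}]
    )
    return StrainComparison(
        anova=anova,
        grand_mean_contrasts=grand_mean_contrasts(groups),
        tukey_pairs=tukey_hsd(groups, alpha=alpha),
        degenerate=degenerate,
    )


def simulate_tukey_fwer(
    n_datasets: int,
    n_groups: int,
    n_per_group: int,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> float:
    """Family-wise error rate of Tukey's HSD under the null, by simulation.

    Draws ``n_datasets`` balanced normal datasets with equal group means and
    reports the fraction in which any pair is declared different at
    ``alpha``.  With a balanced design the family rejects iff the maximum
    studentized range statistic exceeds the critical value, so the whole
    simulation vectorises.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k, n = n_groups, n_per_group
    df_w = k * (n - 1)
    q_crit = stats.studentized_range.ppf(1.0 - alpha, k, df_w)
    data = rng.standard_normal((n_datasets, k, n))
    means = data.mean(axis=2)
    mse = data.var(axis=2, ddof=1).mean(axis=1)
    q_max = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(mse / n)
    return float(np.mean(q_max > q_crit))
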