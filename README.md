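# specshell

Specificity-determining residue nomination and targeted-LC-MS quantification
for enzyme-family engineering.

## The problem

Enzyme families often contain close homologues with very different substrate
preferences. The motivating case is the methylthioalkylmalate synthase (MAM)
family of Brassicaceae: MAM enzymes catalyse the condensation step of the
iterative glucosinolate chain-elongation cycle, and a handful of
substrate-pocket residues decide which 2-oxo acid substrates are accepted and
how many elongation rounds they undergo. Finding those residues, and testing
them by mimicking the family's natural variation in a mutant panel, takes
four computational steps that this package implements as a reusable pipeline:

1. **Structure shell** — superimpose a template structure onto a
   ligand-bound relative (Kabsch least-squares rotation `R`, translation
   `t`, residual RMSD) and collect every polymer residue with a heavy atom
   within a cutoff (default 8 Å) of the ligand.
2. **Alignment polymorphism** — profile every column of a family multiple
   sequence alignment in the numbering of a reference sequence; a column is
   polymorphic iff ≥ 2 distinct standard residues each reach a minimum count
   and the column occupancy reaches a minimum.
3. **Candidate selection** — the nominated specificity residues are the
   intersection: shell ∩ polymorphic. Conserved shell residues are reported
   as exclusions.
4. **Mutant panel design** — one single substitution per residue observed in
   the family at each candidate position (plus curated manual additions),
   and named combination variants (a double mutant and triples extending
   it).

The downstream readout is quantitative: strains carrying the variants are
profiled by targeted LC–MS. Metabolite concentrations come from
stable-isotope internal standards,

```
conc = (area / IS_area) · IS_conc · dilution_factor
```

with explicit below-LOQ / not-detected / unquantifiable states, per-strain
composition by precursor amino acid and elongation-round distribution, fold
changes between strains, and one-way ANOVA + grand-mean contrasts + Tukey
HSD for strain comparison. Relative protein expression comes from
light/heavy proteotypic-peptide ratios normalised to a housekeeping protein
and a reference strain, with undetected peptides counted as true zeros.

Because no raw study data are deposited anywhere, the package ships seeded
synthetic-data generators (`specshell.synthetic_data`) that emulate every
input class with planted ground truth; all tests run against those.

## Worked example

The packaged worked example (`specshell.datasets`) expands the published
natural-variation matrix of the MAM/IPMS family at the five
substrate-proximal positions of *A. thaliana* MAM1 into a family alignment:

```python
import specshell as sp
from specshell import datasets as ds

aln = ds.natural_variation_alignment()
profiles = sp.column_profiles(aln)
report = sp.select_candidates(set(ds.SHELL_POSITIONS), profiles)
print("selected:", report.selected)
print("excluded:", report.excluded_conserved)
```

prints

```
selected: ((186, 'L', 'CGHILMT'), (257, 'T', 'CGNST'), (259, 'G', 'AGP'), (290, 'A', 'AGST'))
excluded: ((229, 'G'),)
```

— four polymorphic candidates (with the residues circulating at each) and
one conserved exclusion: position 229 is within the shell but invariant
(glycine) across the family, so mutating it cannot mimic natural variation.
Panel design then enumerates 15 natural single substitutions, adds the two
curated ones and builds the combinations:

```python
panel = sp.enumerate_panel(profiles, report.selected_positions)
wt = {p: aln.reference_residue(p) for p in report.selected_positions}
sp.add_manual_substitutions(panel, ds.MANUAL_ADDITIONS, wt)
combos = sp.build_combinations(ds.COMBINATION_BASE, ds.COMBINATION_EXTENSIONS,
                               ds.COMBINATION_NAMES)
print("singles:", ", ".join(panel.names()))
print("combinations:", [(c.name, c.canonical_name) for c in combos])
```

```
singles: L186C, L186G, L186H, L186I, L186M, L186T, T257C, T257G, T257N, T257S, G259A, G259P, A290G, A290S, A290T, T257V, T257D
combinations: [('GA', 'T257G/G259A'), ('GAM', 'L186M/T257G/G259A'), ('GAG', 'T257G/G259A/A290G')]
```

Quantifying a synthetic two-strain MRM table (10 % noise, planted
concentrations) and profiling it:

```python
table, truth = sp.gen_mrm_table(sp.MrmSpec(concentrations={
    "MAM1": {"HM": 40.0, "DHM": 120.0, "TriHM": 10.0, "HL": 25.0, "HPhe": 20.0},
    "GA":   {"HM": 30.0, "DHM": 40.0, "TriHM": 15.0, "TetraHM": 5.0,
             "HL": 10.0, "HPhe": 18.0},
}, noise_cv=0.10), seed=11)
q = sp.quantify_table(table, sp.chain_elongation_panel(), 10.0, 25.0)
summary = sp.profile(q, sp.chain_elongation_panel())
print(summary.group_percentages.round(1))
print(summary.round_distribution.round(1))
```

```
precursor  methionine  leucine  phenylalanine
strain
MAM1             78.7     11.9            9.4
GA               75.5      8.5           16.0
round_bin     1     2   >=3
strain
MAM1       40.2  55.4   4.4
GA         48.5  33.8  17.7
```

The composition table gives each strain's percentage of total production per
precursor amino acid (rows sum to 100); the round table shows how much of
each strain's production was elongated once, twice, or three-plus times —
here the planted double mutant shifts production toward longer products,
the behaviour the combination variants are designed to probe.

A thin CLI mirrors the pipeline: `specshell align-profile`, `shell`,
`select`, `design`, `quantify`, `protquant`, `simulate` (see `--help`).

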