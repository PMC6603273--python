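# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Alignment polymorphism

Alignment columns are reported in **reference numbering**: 1-based positions
along the ungapped designated reference sequence. Columns where the
reference is gapped carry no reference position and are excluded from the
profile report, so the number of profiles always equals the reference's
ungapped length.

A column is **polymorphic** iff at least two distinct standard residues each
appear at least `min_variant_count` times (default 1) and the column's
occupancy (non-gap fraction) is at least `min_occupancy` (default 0.5). The
defaults are deliberately permissive: the biological question is "does the
family tolerate more than one residue here at all", and the worked-example
matrix classifies correctly under them. Ambiguity codes (B, J, X, Z) are
tallied in the residue counts — they occur in real sequence data — but never
count toward the two qualifying residues, since they encode uncertainty, not
variation.

**Large deletions** are filtered by coverage: a record is dropped when its
non-gap fraction over the reference-occupied columns falls below
`min_coverage` (default 0.7). The source procedure states the filter but no
cutoff; 0.7 removes genuinely truncated sequences while tolerating ragged
termini. The filter is idempotent and never removes the reference. Records
known to be poor quality can additionally be excluded by an explicit id list
(`FamilyAlignment.drop`); no automatic quality inference is attempted.

**Percent identity** is computed over mutually non-gap columns only; pairs
sharing zero such columns are NaN and listed as undefined rather than being
given a fake 0.

## Structure shell

PDB input is parsed with Bio.PDB and converted to a light immutable
container. Polymer vs hetero follows the record type; alternate locations
resolve to the highest-occupancy conformer (ties: first encountered); only
the first model of multi-model files is used. Coordinates stay in the file's
frame — no crystallographic symmetry expansion — so shells near packing
interfaces may miss symmetry-mate contacts.

**Superposition** uses the Kabsch algorithm: SVD of the covariance of the
centred paired coordinates, with the standard determinant sign fix so the
returned rotation is always proper (det = +1) even for mirror-image inputs.
Pairing comes from a residue correspondence derived from the mutually
non-gap columns of a pairwise alignment; α-carbons are used by default, and
pairs missing the named atom on either side are dropped (`n_atoms` reports
the count actually used). Fewer than 3 usable pairs, or a (near-)collinear
point set — detected by the second singular value falling below 1e-10 of the
first — raise errors rather than returning an ill-conditioned rotation.
The test suite checks the SVD route against two independent oracles: Horn's
closed-form quaternion eigen-method and a quaternion-parameterised numerical
minimiser.

**Ligand shell** membership uses the minimum over all heavy-atom pairs
(residue atom × ligand atom); hydrogens are ignored, and the comparison is
inclusive (min distance == cutoff is in). Waters and monoatomic ions are
never members. The 8 Å default reflects the scale at which second-shell
residues can still reshape a substrate pocket. Shell positions are mapped
into target numbering through the correspondence; unmapped members are
reported separately rather than dropped.

The pipeline superimposes and shells the *template* structure directly. The
original analysis used a homology model of the target built on that
template; model building is out of scope here, so shell positions on the
template side are carried to the target purely through the alignment
correspondence. Shells computed this way can differ from model-based shells
where the target's side chains rearrange.

## Candidate selection and panel design

Selection is a pure set intersection — shell positions that are polymorphic
are selected, the rest excluded — with no scoring or ranking; the criterion
is binary (close to the substrate, and variable in the family). Which
records count toward polymorphism is configurable (`include_ids`), defaulting
to all records.

Variant naming follows the standard `T257G` convention; combination names
join singles with `/` and may carry configured aliases (`GA`, `GAM`, `GAG`).
Every generated name parses back to its substitution map (property-tested).
Panels support curated include-lists because published panels are curated,
not exhaustive; manual substitutions (chosen for structural reasons rather
than observed) are tracked with `origin="manual"`. Combination builders
refuse position collisions.

## Metabolite quantification

`conc = (area / IS_area) · IS_conc · dilution_factor`. The dilution factor
is one explicit combined number per analysis rather than a chain of
inferred mixing steps, because "1:10" style conventions are ambiguous
(1 + 9 vs 1 + 10); callers state what they did. Detection states:

* `not_detected` — zero/missing analyte area; contributes 0 to totals.
* `below_loq` — quantifiable signal below the configured limit of
  quantification; contributes 0 to totals but keeps its detection flag.
* `unquantifiable` — nonzero analyte area with zero internal-standard area;
  never silently converted to a number.

LOQ values are instrument properties and therefore configuration, defaulting
to 0 (everything detected is quantified).

Technical replicates are averaged within each biological replicate before
any cross-replicate statistic; biological replicates are the experimental
unit (default design: 3 × 3). Composition percentages are per-strain group
totals normalised to 100; strains with zero total are flagged rather than
divided. Elongation-round bins are {1, 2, ≥3}. Fold changes are ratios of
means across biological replicates; a zero denominator yields NaN with a
warning.

The packaged panels encode the two analyte families: the chain-elongated
amino acids (methionine homologues HM…HeptaHM, leucine homologues
HL/DHL/TriHL, homophenylalanine), each quantified against its isotope-
labelled parent amino acid, and the 13-entry leaf glucosinolate panel
(9 aliphatic, 3 indolic, 1 aromatic) quantified against *p*-hydroxybenzyl
glucosinolate, with aliphatic chain length encoding the elongation-round
count (short chain = rounds 1–3, long chain = rounds ≥ 4). Panel entries
validate that names and round counts agree.

## Strain comparison statistics

One-way fixed-effects ANOVA from sums of squares (F is NaN with a
`degenerate` flag when the within-group variance is exactly zero).
Per-strain contrasts against the grand mean use the pooled mean square:
`Var(mean_i − grand) = MSE·(1/n_i − 1/N)`. Tukey's HSD computes
`q = |mean_i − mean_j| / sqrt(MSE/2 · (1/n_i + 1/n_j))` (Tukey–Kramer for
unbalanced designs) with adjusted p-values from the studentized-range
distribution (scipy). Calibration is verified by simulation: under a
balanced null the family rejects iff the maximum studentized range exceeds
the critical value, which vectorises over 10,000 datasets in well under a
second; the family-wise error lands within Monte-Carlo error of the nominal
0.05. The simulation uses 4 groups of 3 — the replicate scale of the
motivating experiments.

## Protein quantification

`value(strain, protein) = [L/H(protein)/L/H(HK)]_strain ÷
[L/H(protein)/L/H(HK)]_reference`, normalised within each biological
replicate, reference-relativised against the reference strain's mean
normalised ratio, and averaged last. Undetected light peptides are true
zeros (an absent protein, not missing data). A protein absent from the
reference strain has no defined relative level — values are NaN and flagged,
not zero. Rescaling invariances are pinned by tests: a common light+heavy
rescale in one strain cancels, a strain-wide heavy-only rescale also cancels
through the housekeeping normalisation, and a single protein's heavy-only
rescale changes that protein's value by exactly the inverse factor.
Cross-protein comparisons are refused by the interface: each protein's
peptide has its own response factor, so different proteins are not on a
common scale.

The peptide-panel auditor checks the standard selection preferences —
[M+2H]²⁺ m/z < 1250 (monoisotopic masses via pyteomics), exactly one
C-terminal K/R (clean tryptic cleavage; the in-silico digest cleaves after
K/R except before P), and no Met/Cys — but reports violations instead of
rejecting, because practical panels keep preference-violating peptides when
a protein offers nothing better. Non-standard letters make the mass
undefined; such peptides are excluded from the m/z check with a warning.

## Synthetic data

Generators are deterministic given spec + seed. They emulate:

* family alignments with planted polymorphic columns (each planted residue
  guaranteed to occur) and planted low-coverage sequences — but not
  phylogenetic correlation between sequences, realistic substitution
  processes, or alignment errors;
* structure pairs as single-Cα residues on random directions at controlled
  radii from a one-atom ligand at the origin, under a known rigid transform
  plus optional isotropic Gaussian coordinate noise — but not side chains,
  secondary structure or realistic packing. The post-fit RMSD under noise σ
  on n points concentrates around σ·sqrt(3 − 6/n), which the tests check by
  Monte-Carlo;
* MRM tables with unit-mean multiplicative log-normal noise (the standard
  model for LC–MS peak intensities) applied independently to analyte and
  standard areas, plus a per-sample extraction-yield factor common to all
  light peptides in the proteomics tables — but not retention-time drift,
  matrix effects, censoring at the detection limit, or correlated
  transitions.

Passing planted-truth tests therefore demonstrates correctness of the
computations, not robustness to every artefact of real chromatography or
real alignments.

Default generator conditions mirror the motivating study design: 57-sequence
families with 4 planted polymorphic positions, 3 biological × 3 technical
replicates, a 10 μg/ml internal-standard mix, a combined 25-fold dilution,
10 % CV noise, and planted 5-fold (total) and 20-fold (single-analyte)
strain ratios.

## Problem sizes

The verification runs use 1,000 random configurations for the superposition
oracle, 57 × 300 synthetic alignments, 60-residue structure pairs, 9
measurements per strain/analyte for quantification recovery, and 10,000
null datasets for Tukey calibration — sizes at which every check is exact or
tightly banded while the whole suite stays fast.

## Known limitations

* No homology-model construction, mmCIF input, symmetry expansion, or
  energy calculations; the template stands in for the target structure.
* Published RMSD figures for model-on-structure superpositions depend on the
  model-building tool and atom set and are not regression targets here.
* Polymorphism thresholds are heuristics; families with strong sampling bias
  (many near-duplicate sequences) will overcount variant support — no
  sequence weighting is applied.
* LOQ handling treats below-LOQ signals as zero in totals; if below-LOQ
  analytes dominate a strain, composition percentages are accordingly
  conservative.
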