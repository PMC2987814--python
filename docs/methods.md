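# Methods

This note records the models, conventions and numerical choices behind
`ensval`, and what the synthetic-data generator does and does not emulate.

## Ensemble model and input handling

An ensemble is an ordered list of conformers over one harmonized atom
table (chain, author residue number, residue type, PDB v3 atom name).
Multi-model PDB input is parsed with gemmi; a file without MODEL records
is a single conformer. Models whose atom sets differ are reconciled by
intersection with a logged warning, so that every evaluator sees the same
atoms in every conformer. Proton names are normalized to the v3 dialect
(HB2/HB3): leading-digit names are rotated (`1HB` → `HB1`), `HN` → `H`,
and a per-residue table of methylene/amine groups maps the v2 1/2
numbering to v3 2/3. Restraint selectors written in the v2 dialect are
resolved through the same mapping as a fallback when the literal name
matches nothing. Residue numbers are taken verbatim from the file
(author numbering, as X-PLOR restraints reference it); parameter records
that reference residues or atoms absent from the ensemble are skipped
with a warning, never fatally, because experimental data sets routinely
overlap the construct only partially.

The NMR-STAR reader is a purpose-built tokenizer/loop parser covering the
categories this tool consumes — chemical shifts, S² order parameters,
RDCs and ³J couplings, in both 2.1-style flat tags and 3.1-style
`category.tag` names. It is not a general STAR implementation: save-frame
structure is ignored, unrecognized loops are skipped with a note, and
values `.`/`?` are treated as missing. Restraint files are parsed from
`assign (sel)(sel) d dminus dplus` statements with `!` comments removed;
selectors keep the X-PLOR wildcards (`#` digits, `*` any, `%` one
character) and an OR of clauses becomes a compound selector. The
published ambiguity filter is reproduced literally: every *physical line*
whose tokens include the word "or" (case-insensitive, word-boundary) is
removed before statements are joined and counted.

## Distance averaging and violations

Two averaging stages are deliberately kept distinct:

* intramolecular (pseudoatom) pooling within one conformer, always r⁻⁶:
  d_eff = (mean over atom pairs of d⁻⁶)⁻¹ᐟ⁶;
* ensemble averaging across conformers, r⁻⁶ by default or r⁻³ on
  request: d_eff = (mean over conformers of d⁻ⁿ)⁻¹ᐟⁿ.

For the two-pair, ten-model reference case the two-stage form equals
pooling all twenty distances at once, because every model contributes the
same number of pairs; the implementation always uses the two-stage form.
Generalized-mean ordering (r⁻⁶ ≤ r⁻³ ≤ arithmetic mean, equality iff all
distances are equal) is enforced as a property test.

Only upper-bound violations (d_eff − (d + d⁺) > 0) are reported by
default since NOE bounds are predominantly upper limits; lower-bound
checking sits behind a flag. Ambiguous ("or") restraints are excluded
from violation statistics by default and can instead be pooled r⁻⁶ over
all branches. The violation histogram uses a 0.1 Å bin width by default
(configurable; no canonical width exists).

## Probability-of-identity scoring

Each conformer is compared with the restraint list through distance
histograms per sequence-separation class k = |i − j|, k from 3 to 30 by
default, bins of 0.5 Å over [0, 15 Å]. For class k the probability of
identity is the histogram intersection Σ_bins min(h_target, h_realized)
of the normalized target-distance and realized-distance histograms, and
the score is the unweighted mean over classes that contain at least one
in-range restraint. Wildcard or compound selections contribute their
r⁻⁶-pooled effective distance to the realized histogram, consistent with
the violation analysis. Because the query restraints and the scored
conformers describe the same chain, no cross-length weighting is needed.
This is a fully specified, configurable variant of the
probability-of-identity family of scores; the class range, bin width and
distance cap are declared parameters rather than tuned constants, and
whether classes should be weighted is left as configuration (unweighted
by default).

## S² order parameters

S² = ½(3 Σₐᵦ ⟨μₐ μᵦ⟩² − 1), where μ is the unit bond vector (N–H or
Cα–Hα) and ⟨·⟩ the uniform average over conformers — the Lipari–Szabo
order parameter of a discrete orientation set. S² is intrinsically an
ensemble quantity; no per-conformer S² exists, so the per-model
correlation diagnostic does not apply to it. The ensemble is evaluated
exactly as submitted: S² is invariant under one common rotation but not
under per-conformer rotations, so an un-superposed ensemble legitimately
yields low values. Values below −10⁻⁹ trigger a warning that the input
is probably not superposed. Superposition (Kabsch least-squares over a
backbone N/CA/C mask by default) and mean pairwise RMSD are provided as
separate, explicitly invoked utilities; the pairwise convention
(mean ± sd over all conformer pairs) was chosen because a mean with a
spread matches a pairwise distribution, whereas RMSD-to-mean-structure
yields a single number per conformer.

## Chemical shifts, couplings, RDCs

Shifts: a pluggable per-conformer predictor returns (residue, nucleus,
ppm) rows; supported nuclei are Cα, Cβ, Hα, amide H, amide N. The
built-in baseline is a random-coil table plus fixed secondary-structure
offsets keyed on φ/ψ — deterministic and rotation-invariant, adequate for
exercising the averaging and statistics machinery, and explicitly *not* a
substitute-quality empirical predictor. Glycine's two Hα predictions are
averaged into one Hα before ensemble averaging (under uniform weights the
order of the two averages is irrelevant). A predictor failure on any
conformer aborts the run naming the model, rather than silently
averaging over fewer conformers.

Couplings: J(φ) = A cos²(φ+Δ) + B cos(φ+Δ) + C on each conformer's φ,
then the arithmetic mean. The four φ-derived coupling types ship with
literature Karplus coefficients (³J_HNHα 7.09/−1.42/1.55, Δ = −60°;
³J_HαC′ 3.72/−2.18/1.28, Δ = +120°; ³J_HNCβ 3.06/−0.74/0.13, Δ = +60°;
³J_HNC′ 4.29/−1.01/0.00, Δ = 180°) as an editable mapping — the
coefficients are configuration, not constants baked into the algorithm.

RDCs: the forward model is D = D_max μᵀ S μ with S the traceless
symmetric alignment (Saupe) tensor and D_max computed from gyromagnetic
ratios and standard bond lengths (N–H 1.02 Å, C–H 1.09 Å, C–C 1.525 Å,
C–N 1.329 Å); the absolute scale divides out of fits but keeps values in
Hz. In SVD mode the five independent tensor components are solved by
least squares per conformer, requiring ≥ 5 observations and a full-rank
design (degenerate bond orientations are reported as such). Each
conformer gets its own tensor — never one tensor for the whole ensemble —
and the per-conformer back-calculated values are arithmetically averaged.
First-principles steric alignment is an external-command hook with a
simple file exchange (per-conformer PDB and pair template in, per-bond
values out); it is not re-implemented here. When steric mode is selected
without a configured external tool, the run falls back to SVD with a
logged notice.

## Correspondence statistics

Statistics are computed only over records present on both the
experimental and the calculated side; unmatched records never enter any
number, and the matched count is reported. R is the Pearson
product-moment correlation (undefined below three pairs or at zero
variance, reported as not-computable rather than faked). The Q-factor is
the square-root convention q = sqrt(Σ(P_calc − P_exp)²/ΣP_exp²), matching
common RDC-validation usage so reported values are comparable across
tools; the un-rooted variant is available behind a flag. RMSD is
root-mean-square (not mean absolute) deviation. The per-model diagnostic
reports each conformer's correlation with experiment alongside the mean
per-model correlation and the correlation of the ensemble average; an
ensemble value above every per-model value is the signature that
averaging itself improves agreement.

## Synthetic-data generator

The generator builds ideal-geometry backbones (fixed bond lengths and
angles from standard tables, trans peptide bonds, user φ/ψ, protons and
Cβ placed by ideal tetrahedral geometry, L-configuration) and emits the
same three file formats the tool consumes. Observables are synthesized
from the generated coordinates through the same physical conventions the
evaluators use: exact dyadic S², Karplus couplings on the realized φ,
RDCs from a prescribed alignment tensor per conformer then averaged,
baseline-predictor shifts, and restraints placed at the realized
ensemble-averaged distances with a configurable margin (0.5 Å default).
Optional Gaussian noise per observable kind is drawn from a single seeded
generator; one seed governs every stochastic element.

Conformational variation comes from per-conformer torsion lists and/or
rigid per-conformer rotations. Two rotation modes exist for a numerical
reason worth recording: coordinates are quantized to the PDB precision of
0.001 Å before observables are computed, so that ground truth matches
what any consumer reads back from the file. Continuous random rotations
do not commute with that quantization, which breaks the exact
self-consistency of per-conformer SVD refitting at the 10⁻⁴ level. The
default `axis_aligned` mode therefore draws rotations from the 24 proper
axis-permutation matrices, which commute with rounding exactly; under it
the full pipeline reproduces every synthesized observable to floating
point (the closed-loop test requires R = 1 and q ≤ 10⁻⁸ for every
parameter type). The `random` mode provides continuous orientational
scatter whose magnitude dials the target S² level, for studies where
exactness is not required.

Default study conditions: a 12-residue mixed sequence containing glycine,
10 conformers (a typical deposited solution-ensemble size), helical
torsions in the N-terminal half and extended ones in the C-terminal half
(so shift offsets and φ-dependent couplings vary along the chain), zero
noise unless requested.

What the generator does not emulate: side chains beyond Cβ, realistic
packing or solvent, distance-dependent NOE intensities, predictor error
structure, conformer-shape-dependent alignment (the synthesis tensor is
common to all conformers). Passing closed-loop tests therefore
demonstrates that the parsing/averaging/statistics pipeline is
arithmetically faithful — not that any predictor is accurate for real
proteins.

## Numerical choices and degenerate inputs

Torsions use the IUPAC sign convention (α-helical φ negative); the first
residue's φ is undefined and skipped. Effective-distance inputs must be
positive; empty selector resolutions mark the restraint unresolved,
excluded and counted. Superposition requires ≥ 3 non-collinear masked
atoms; collinear geometry is a reported numerical error. The SVD fit
treats a design matrix of rank < 5 as an error naming the deficiency.
Conformers are always weighted uniformly in every average. Runs are
deterministic given their configuration; output tables keep a fixed
column schema regardless of which parameter categories are present, and
skipped records are logged with a greppable `SKIPPED`/`UNRESOLVED` tag.

## Known limitations

* The NMR-STAR subset covers the four consumed categories only; exotic
  tag dialects may be skipped (with a note) rather than parsed.
* The built-in shift predictor is a baseline; quantitative shift
  validation of real ensembles requires an external predictor hook.
* Steric-alignment RDC back-calculation requires an external program;
  only the SVD mode is native.
* Two acceptance checks depend on deposited restraint/coordinate files
  (PDB 1D3Z, 2JZZ) that are not redistributed with the package; without
  them those tests fail with an explanatory message.
* Time-averaged restraint interpretations and composite quality scores
  are deliberately out of scope.
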