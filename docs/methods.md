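# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `afmissense`.

## Problem setting

Given a catalog of clinically labeled missense variants in hereditary-cancer
genes and AlphaFold models of the corresponding proteins, the pipeline asks
how well structure-derived per-variant descriptors separate pathogenic from
benign substitutions. Three descriptor families are handled: the AlphaFold
per-residue confidence score pLDDT (read from the PDB B-factor column,
range 0–100), relative solvent accessibility rASA, and predicted stability
changes ΔΔG from five external tools. Labels are consumed, never derived:
clinical classification itself (ACMG criteria, ClinVar assertions) is out of
scope.

## Variant curation

Protein changes are parsed from compact (`H101Q`) or HGVS-protein
(`p.His101Gln`) notation; one- and three-letter forms are canonicalized to
identical records. Stop-gain and frameshift notation is classified as
truncating, not parsed as a substitution; synonymous notation is rejected
with a distinct error so data problems stay visible.

Curation filters (all configurable via `FilterConfig`):

- **review stars ≥ 2** for ClinVar records. ClinVar review-status strings
  map to stars by the documented scheme (practice guideline 4, expert panel
  3, multiple concordant submitters 2, single submitter or conflicting 1);
  unknown strings conservatively map to 0. Cohort records have no ClinVar
  review status and bypass this filter.
- **condition keywords** ("cancer", "tumor", "tumour"): case-insensitive
  substring match on the free-text condition, no tokenization.
- **variant class** kept: missense (default).
- **labels dropped**: VUS and conflicting. The five-level label is stored;
  for evaluation likely_benign/likely_pathogenic fold into benign/pathogenic.
- **MAF < 0.01** when an allele frequency is present; absent frequencies are
  treated as rare and kept (logged), because panel cohort variants are
  typically unobserved in population databases.

Merging deduplicates on (UniProt accession, position, wild-type, mutant).
Duplicates collapse to one record preferring the ClinVar label — the
preference only affects provenance when labels agree, and any disagreement
is emitted in an explicit conflict list, never silently resolved. Two
records asserting different wild-type residues at the same position raise a
data-integrity error. Wild-type validation checks the recorded residue
against the 1-based position of the UniProt sequence.

Summary percentages use round-half-away-from-zero at integer and
one-decimal precision; a zero denominator yields 0 with a flag rather than
an exception.

## Fragment tiling and stitching

Proteome-scale AlphaFold predictions of chains longer than one prediction
window ship as overlapping fragments F1…Fn. The tiling model: F1 starts at
residue 1, each fragment starts one stride after the previous, every
fragment ends at `min(start + window − 1, L)`, and the count is
`ceil((L − window)/stride) + 1` for L > window. Window 1,400 and stride 200
are defaults inferred from the published fragment geometry of the two large
panel proteins (3,418 residues → 12 fragments, F12 = 2201–3418, 1,218 long,
consecutive overlaps 1,200; 3,056 residues → 10 fragments, F1–F7 overlap
200); both are parameters, not constants.

Stitching walks the selected fragments in sequence order. For each
consecutive pair the later fragment is rigidly mapped onto the assembled
chain by a Kabsch least-squares superposition of the overlap Cα atoms
(pairing by residue index; pairs missing a Cα are skipped). The duplicated
overlap residues are dropped from the *later* fragment, keeping the earlier
fragment's coordinates — a deterministic choice that preserves the
N-terminal frame. Joining is positional: chain continuity is asserted but no
covalent-geometry regularization is applied at the seam. pLDDT values are
carried through untouched. Overlaps shorter than `min_overlap` (default 200)
are an error; a join RMSD above the QC threshold (default 5 Å) warns and
proceeds, recording the join, because the sensible fallback for a
badly-fitting fragment set (re-prediction) is outside this package's scope.

Kabsch superposition is computed via SVD of the cross-covariance of centered
point sets with the determinant correction that excludes reflections; fewer
than 3 pairs or (near-)collinear geometry raises a degeneracy error. Tests
cross-check the minimized RMSD against a multi-start Nelder–Mead rotation
search and `scipy`'s independent implementation.

## Solvent accessibility

SASA uses the Shrake–Rupley test-point method with a deterministic
golden-spiral (Fibonacci) point set — chosen over random placement so results
are exactly reproducible and convergence is oracle-checkable. Defaults:
probe 1.4 Å, 960 points per atom, heavy atoms only (AlphaFold models carry
no hydrogens), element van der Waals radii from a bundled Bondi-style table.
A test point is blocked when *strictly* inside a neighbour's expanded
sphere, so tangent spheres do not occlude; exactly coincident equal-radius
atoms collapse to a single sphere whose area is assigned to the first.

At 960 points, total SASA is rotation/translation-invariant to well under
0.5%; individual residue values carry a few percent of point-discretization
noise (they converge to < 1% against a 4,000-point run).

rASA divides residue SASA by a per-amino-acid reference maximum. The bundled
default scale is the Tien et al. (2013) theoretical set. Note the systematic
offset between scales: with heavy-atom Bondi radii an ideal-geometry exposed
residue evaluates to roughly 0.82–0.87 of the Tien theoretical maximum
(which derives from a different radius set and a conformational search), so
self-consistency checks compare against a converged run of this package's
own engine on the same geometry rather than across scales. rASA is not
clamped above 1 (terminal residues legitimately exceed it); values above 1.2
warn. Burial uses a strict `rasa < 0.7` comparison; the threshold is
configurable and the inclusivity choice is documented here because the
boundary convention is not externally fixed.

## Stability-score harmonization

Predictor registry: mCSM, MAESTRO, CUPSAT (structure input), SAAFEC-SEQ,
MUpro (sequence input). All except MAESTRO natively report negative ΔΔG as
destabilizing; MAESTRO reports negative as stabilizing. The unified
convention is **positive = stabilizing, negative = destabilizing**, i.e.
MAESTRO values are negated and the rest pass through. The convention is a
single flag (`SignConvention`) so the opposite choice is a one-argument
change, and harmonization is an involution for MAESTRO / identity otherwise —
properties the tests assert. Scores keep predictor-native kcal/mol-scale
units with no cross-tool rescaling, since the downstream evaluation is
rank-based and scale-free. Table ingestion accepts the tools' CSV/TSV
exports through per-role column aliases (overridable per call); rows with
unparseable variants or non-numeric values are reported, never silently
dropped.

## Discrimination analysis

AUROC is the Mann–Whitney statistic U/(n₁n₀) with ties counted ½, computed
from midranks — identical (to machine precision, asserted over random tied
instances) to the trapezoidal area under the stepwise ROC curve the package
also produces. Confidence intervals use the DeLong placement-component
variance estimator (verified to 1e-9 against R's pROC on a frozen dataset);
a seeded stratified bootstrap is available as an alternative. The p-value
against AUC = 0.5 is the two-sided normal approximation of the Mann–Whitney
test (scipy, tie-corrected). Degenerate input (all scores identical) returns
AUC 0.5 with a flagged zero-width CI rather than an error.

Orientations are fixed by field convention — pLDDT higher→pathogenic, rASA
lower→pathogenic, harmonized ΔΔG lower→pathogenic — with an auto mode that
flips to AUC ≥ 0.5 and records the flip. Auto-flipping never changes
|AUC − 0.5|.

Missing descriptor values are excluded pairwise per descriptor, with class
sizes reported per cell; nothing is imputed. Correlations are
pairwise-complete Spearman by default (robust to the tools' different
scales), Pearson optional, label-stratified on request; cells with fewer
than 3 complete pairs are flagged absent.

Subset filters: confidence keeps pLDDT ≥ threshold (inclusive, default 50);
burial keeps rASA < threshold (strict, default 0.7). They are exposed
independently and compose, because published analyses are ambiguous about
whether one or both defined the "confident" subset. Subset evaluation
commutes with pre-filtering the data (asserted).

## Synthetic data generator

The generator draws labeled tables with exact class counts (default 445
pathogenic / 647 benign, the evaluated catalog's class sizes) and the joint
structure the analysis assumes:

- **pLDDT**: pathogenic ~ truncated normal (88, 6) on [0, 100]; benign a
  two-component truncated-normal mixture, weight 0.45 on a low-confidence
  mode (38, 8) and 0.55 on (88, 6). These defaults reproduce the qualitative
  published shape (pathogenic variants confined to confident positions,
  benign bimodal); no quantitative parameters are published, so the values
  are illustrative and config-exposed, chosen once.
- **designed-AUC mode**: setting `plddt_design_auc` replaces the mixture
  with a binormal design (pathogenic shifted by √2·Φ⁻¹(AUC) standard
  deviations) squashed into [0, 100] by a strictly monotone normal-CDF map —
  rank-preserving, so the expected empirical AUC equals the design exactly.
- **ΔΔG**: per-predictor binormal designs on the harmonized scale
  (pathogenic shifted toward negative/destabilizing). Default designed AUCs
  are the published total-set discrimination of the five tools (mCSM 0.719,
  SAAFEC 0.711, MAESTRO 0.650, CUPSAT 0.614, MUpro 0.534).
- **rASA**: a logistic decay in pLDDT (midpoint 70, steepness 0.08) plus
  Gaussian noise (sd 0.15), clipped at 0. Only the decreasing direction is a
  contract; the functional form is a modelling convenience.

What the generator does *not* emulate: per-gene label proportions, sequence
composition, covariance between ΔΔG predictors beyond their common label
dependence, and realistic protein geometry. Passing tests therefore
demonstrate correctness of the pipeline's statistics and geometry handling,
not performance claims about real catalogs.

Synthetic structures are helically twisted chains with exact 3.8 Å
consecutive Cα spacing (radius 2.3 Å, 100°/residue, rise solved from the
chord length) plus approximate N and C backbone atoms — valid, non-collinear
PDB-writable fixtures for superposition, stitching and SASA. The fragment
perturber applies an independent uniform random rotation and N(0, 20 Å)
translation per fragment (a zero-rotation mode exists for identity checks).

## Unimodality test

The bimodality contract on benign pLDDT is checked with a dip-type
statistic: the sup-norm distance between the empirical CDF and the nearest
glued greatest-convex-minorant / least-concave-majorant envelope, minimized
over the mode position (computed with an incremental convex-hull sweep from
both ends). The p-value is Monte-Carlo calibrated against the uniform null —
the least favourable unimodal case — with a seeded generator, so the test is
exact by construction for this statistic. This envelope formulation was
chosen over a port of the classic modal-interval iteration for transparency
and testability; for well-separated mixtures it is decisively significant
and for unimodal samples it is not, which is the property the tests rely on.

## Problem sizes and determinism

Defaults are desk-scale by design: SASA fixtures of 10–25 residues at 960
points, stitching recovery on a 600-residue chain, 100-replicate design
recovery at n = 1,092, a 2,000-point dip test with 199 null replicates. The
full test suite runs in well under a minute on one CPU. Every stochastic
routine takes an explicit seed (numpy `default_rng`); identical
(config, seed) pairs reproduce tables bit-for-bit and hence identical
evaluation reports.

## Known limitations

- PDB only; no mmCIF, no AlphaFold DB download client, no structure
  prediction, and no seam-geometry minimization after stitching.
- ΔΔG predictors are ingested, never run; their output dialects are handled
  by column aliases that may need a per-site override.
- DeLong CIs are asymptotic; at very small class counts the bootstrap flag
  is the safer choice.
- rASA depends on the reference scale; cross-scale comparisons of absolute
  rASA values are not meaningful (see the offset note above).
- The generator's distribution parameters are qualitative defaults, not
  fitted to any dataset; conclusions about real-data discrimination require
  real catalogs and real predictor outputs.
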