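# Methods

## The construction grammar

A dendrimer is specified by a core block, an ordered layer sequence
(innermost first) of branch blocks, and a terminal form. Growth
alternates two reactions, and the composition calculus mirrors them
exactly:

* **TEC capping** (allyl → ammonium): anti-Markovnikov addition of
  cysteamine hydrochloride across every terminal allyl group. The
  reaction is atom-economic, so the full cap composition (C2H8ClNS,
  113.60 g/mol) is added per end group and nothing is removed. Every
  terminal amine is carried as its ammonium chloride salt.
* **Amide coupling** (ammonium → next layer): condensation of the next
  block's focal carboxylic acid with each peripheral ammonium group.
  Per attachment the capped-site/block pair loses H2O (the amide bond)
  plus HCl (from the salt). The coupling delta is a per-block property,
  so registries with different coupling chemistry remain expressible.

The composition of a perfect structure is computed by a recursion over
"sites": a site entering layer *i* contributes cap + block − delta plus
`multiplicity` child sites; a terminal site contributes one cap
(ammonium form) or nothing (allyl form — the allyl groups already belong
to the parent block). The recursion is cross-checked in the tests
against an independent brute-force oracle that books atoms reaction by
reaction through the stepwise synthesis.

**Block registry.** The shipped defaults are reconstructed from the
described structures, since no source formulae are available, and are
pinned by the reported masses: AB3 = C19H26O3Si (330.50 g/mol, reported
330), AB6 = C31H46O4Si2 (538.88, reported 539), cap = C2H8ClNS, core
precursor (tetraallylsilane) = C12H20Si. With the
every-amine-as-hydrochloride convention these reproduce the reported
17,107 g/mol for G2-3-6-N (computed 17,106.4, within the ±1 g/mol
comparison tolerance), the generation-3 extremes 32.7 and 201.2 kDa,
and the 3.9:1 G1-3-A : BtO-AB3 separation mass ratio. The companion
4.9:1 ratio for G1-6-A : AB6 evaluates to 4.80 under these compositions;
the discrepancy is noted and not forced, as its sibling value
reproduces exactly. Atomic weights are the IUPAC 2021 conventional
standard atomic weights; monoisotopic masses use principal-isotope
masses. Masses are kept at full precision internally and rounded to
integers only for comparison with reported values.

**Naming.** Labels follow `G<generation>-<layer tokens, inner to
outer>-<A|N>`; layer order is innermost-first, matching the synthesis
narrative in which G2-3-6 is built upon G1-3. Parsing is the exact
inverse of naming and reports the character position of any defect.
Enumeration orders sequences lexicographically by layer-name tuple so
output is deterministic.

**Defects.** A defect variant may miss terminal caps and/or whole branch
subtrees. A missing cap removes one cap composition; a missing branch
leaves its attachment site as an intact capped (ammonium chloride) end
group and removes the block with everything downstream. Because the
retained salt can contain atoms (Cl) the perfect site lost during
coupling, additions are accumulated before the single subtraction.
Mixed defects compose additively; adducts (Na+, matrix) are not
modelled. The cap-defect ladder is arithmetic with rung spacing equal to
the cap mass, which is how end-group completeness is read off mass
spectra.

**SMILES.** Structures are emitted by recursive substitution of
attachment-annotated fragments stored in the registry (the amide linkage
`NC(=O)` is grammar logic; everything else is block data). Chloride
counterions are appended as separate components, one per charged
terminus. The guarantee is syntactic validity and exact atom-count
agreement with the composition calculus; tests audit this with rdkit as
an independent parser. Canonicalisation is not attempted.

## The nanofiltration model

Transmission is defined as the instantaneous filtrate-to-retentate
concentration ratio, r = c_f/c_r. The model treats r as constant within
a cycle; solvent dependence enters only through user-supplied values.
For dead-end concentration from V0 to f·V0, the instantaneous mass
balance dm/dV = r·m/V integrates to the retained fraction **f^r** — this
closed form is derived here from the transmission definition and is
cross-checked in the tests against a 10⁴-step numerical integration
(agreement < 10⁻⁶ relative). Batch simulation applies f^r per cycle per
species and books permeated mass, so conservation holds to machine
precision; continuous (constant-volume) diafiltration follows
m = m0·exp(−r·Vf/Vr) and agrees with batch cycling in the fine-cycle
limit (< 1% at f = 0.99). Cycle planning inverts the geometric decay:
n = ⌈ln(target)/(r·ln f)⌉, with a guard against float-rounding
overshoot.

The inverse estimator recovers rᵢ = ln(mᵢ/mᵢ₋₁)/ln f per cycle. Because
"mean transmission" over a multi-form impurity pool is ambiguous, both
the unweighted per-cycle mean (default, headline value) and a
mass-loss-weighted mean are reported.

The transmission-test simulator reproduces the stirred-cell sampling
scheme (9 mL at 5 mg/mL; permeate and discard 2.7 mL; collect a 0.25 mL
filtrate sample; draw 50 µL of retentate; re-dilute and repeat). The
filtrate sample concentration is the window average over its collection
interval, so the sampled c_f/c_r carries a small finite-window bias
(≈ 2% relative at r = 0.1 under the default volumes); tests assert
recovery within 0.005 absolute.

Transmissions above 1 are physically suspect but conceivable
(concentration-polarisation artifacts), so they warn rather than raise.
Membrane MWCO (1/3/10 kDa presets) is metadata only; the model never
predicts r from it, and no flux, fouling or osmotic-pressure physics is
included.

## Solution-property analytics

Rg is the square root of the mass-weighted mean squared distance from
the centre of mass. Rmax is the maximal distance from the *unweighted*
centre of geometry — the two reference points differ deliberately,
following the quantities' respective definitions (Rg is a mass
distribution measure; Rmax estimates a geometric radius). Both are
invariant under rigid motions and satisfy Rg ≤ Rmax.

The shape factor ρ = Rg/Rh uses the hard-sphere reference
√(3/5) ≈ 0.775; a classifier annotates values against it with a ±0.05
band. Inputs may mix simulated Rg with measured Rh (as done when
combining molecular-dynamics and light-scattering data); no solvation
correction is attempted, and the operation is source-agnostic.

Stokes–Einstein conversions use scipy's CODATA Boltzmann constant and SI
units; temperature and viscosity are required arguments with no baked-in
defaults. The diffusion scaling exponent *b* comes from unweighted OLS
of ln D on ln N (scipy.stats.linregress), returning the slope, its
standard error and R²; at least three records with distinct atom counts
are required. Mn, Mw and Đ = Mw/Mn are computed from (mass, number
abundance) pairs; Đ ≥ 1 with equality iff monodisperse.

## Synthetic data

All noise is multiplicative log-normal (the measured quantities are
positive); sigma is the standard deviation of the log, default 0.05
(0.02 for diffusion series, reflecting the tighter scatter of NMR-
derived D values). Each generator derives an independent stream from the
global seed keyed by generator name, is bit-reproducible under a fixed
seed, and reduces exactly to its closed form at sigma = 0:

* **Filtration series**: mᵢ = m0·f^(r·i) × noise.
* **Diffusion series**: D = a·N^b × noise; default atom counts are taken
  from the perfect structures' formulae (e.g. 417/1413/4401 for the
  homolayered AB3 ammonium line), with prefactor 3×10⁻⁹ m²/s giving
  D ≈ 10⁻¹⁰–10⁻⁹ m²/s, the magnitude observed for nanometre-scale
  solutes in methanol.
* **Sphere clouds**: exact uniform sampling in a ball via normalised
  Gaussian directions and radial-CDF radii R·u^(1/3) (no rejection).
  Rg → √(3/5)·R; note Rmax is centroid-referenced, so it can exceed R by
  the centroid's finite-sample offset (~R/√n).
* **Defect ensembles**: per molecule, missing caps ~ Binomial(N_PG, p);
  masses from the defect ladder. The resulting dispersity matches the
  binomial-moment closed form Đ = 1 + N·p(1−p)·m_cap²/E[M]², which at
  the ~1% defect level observed in mass spectra stays below 1.0001 —
  defect rates of that order are invisible to Đ.

What the generators do *not* emulate: baseline drift and peak overlap in
NMR quantification, ionisation bias and adduct formation in mass
spectrometry, aggregation, and solvent-composition-dependent
transmission within a run. Passing tests therefore demonstrate the
correctness of the calculus and the estimators under the stated noise
models, not robustness to those instrument artifacts.

## Numerical choices and problem sizes

Tolerances in the test suite follow from theory, not tuning: Monte-Carlo
Rg at 10⁵ points is asserted within 0.5% (sampling SE ≈ 0.07%);
transmission recovery at sigma = 0.05 over 10 cycles within 0.02 (SE
≈ 0.003); scaling-exponent recovery at sigma = 0.02 within 0.03;
dispersity agreement with the binomial closed form within three
chi-square standard errors of the sample variance. Degenerate inputs
(empty clouds, non-positive masses or concentrations, impossible defect
counts, f outside (0,1)) raise ValueError with messages naming the
offending quantity; ladder ties cannot occur (rung spacing is a fixed
positive mass). Simulation sizes throughout (≤ 10⁵ points, ≤ 4000
molecules, ≤ 300 cycles) keep every script and the full suite within
seconds while leaving sampling error well below the asserted bounds.

## Design notes

* Domain types are frozen dataclasses with explicit constructor
  validation; the CLI is click-based. Registry files are YAML.
* The XYZ reader/writer is intentionally minimal (element + coordinates)
  and maps symbols to masses through the package's own atomic-weight
  table so geometric and mass calculations share one source of truth.
* rdkit is used only in tests, as an independent SMILES parser for the
  atom-count audit; it is not a runtime dependency.
* The `analysis/` scripts are thin narrative drivers over the library;
  all computation lives in `src/pamcas` and is imported by the tests and
  the acceptance script.
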