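# Methods

`asymcat` models the featurization and machine-learning benchmarking of a
chiral-catalyst screening campaign: 192 Rh precatalysts of the form
[Rh(L)(NBD)]⁺ (L = chiral mono- or bidentate P/N-donor ligand, NBD =
norbornadiene) tested against five prochiral olefins (SM1–SM5) in 96-well
hydrogenation plates. This note records the models, conventions and design
choices; every empirical statement here is one the test suite or
`scripts/acceptance.py` computes.

## Complex partitioning

Bonds are perceived from interatomic distances: atoms *i*, *j* are bonded
iff *d(i,j)* ≤ 1.20 · (r_cov(i) + r_cov(j)) with Cordero single-bond
covalent radii (shipped as `data/covalent_radii.csv`). Deleting the unique
metal atom splits the complex into connected components. Components holding
a P or N atom within 2.8 Å of the metal (an explicit cutoff covering Rh–P
and Rh–N bonds with margin) form the ligand — several such components are
unioned with a logged warning, which handles e.g. two monophosphines; the
metal-bound component whose heavy atoms are all carbon is the auxiliary
diene; any other metal-bound component raises rather than guessing. The
two coordinating atoms of a bidentate ligand are distinguished by their
NBO partial charge: *max donor* = most positive, *min donor* = least, with
ties resolved to the smaller atom index (the one documented non-geometric
tie-break). Monodentate ligands fill both roles with their single donor.

## Steric and geometric descriptors

**Percent buried volume.** %V_bur = 100 · V(probe sphere ∩ ∪ scaled vdW
spheres of the chosen atoms) / V(probe sphere), evaluated on a cubic grid.
Conventions: Bondi van der Waals radii × 1.17, hydrogens included, sphere
radius 3.5 Å and grid spacing 0.05 Å unless stated otherwise. These are the
dominant community conventions for this descriptor; they are package
constants, not guesses re-derived per call. The grid estimator rasterizes
atom spheres into their bounding sub-boxes, so cost scales with occupied
volume; determinism follows from the fixed grid. Quadrant-resolved values
use a right-handed frame with +z along metal→donor-midpoint and the
xz-plane containing the max donor (for monodentate ligands, where that
direction is degenerate, the lowest-index ligand atom more than 15° off
axis serves as reference). The mean of the four quadrants equals the total
within grid-partition jitter (≤ 0.2).

**Exact cone angle.** The minimal apex angle of a cone at the metal
containing every ligand-atom vdW sphere (unscaled Bondi radii, the
convention of the exact-cone-angle literature). For a candidate axis **n**
the required half-angle is max_i [∠(**n**, **v**_i) + asin(r_i/d_i)]; the
axis is optimized by a 4096-point Fibonacci-sphere scan followed by
Nelder–Mead refinement. Against a 10⁶-direction brute-force scan the
optimizer agrees to within 0.1° and never exceeds the scan's value.

**Sterimol.** L, B1, B5 relative to the attach→first axis, measured from
the attachment atom, using unscaled Bondi radii with hydrogen at 1.10 Å —
the classic Verloop choice, which the single-substituent closed form
(L = 1.09 + 1.10 for an axial H) pins down. B1 is found by a 0.1°
rotational scan of supporting half-planes perpendicular to the axis; the
width function is smooth, so the scan resolves B1 well below the 0.01 Å
test tolerance.

**NBD dihedral.** The two metal-facing olefins of the auxiliary diene are
identified as the two disjoint bonded C–C pairs whose midpoints lie nearest
the metal. The descriptor is the signed four-point dihedral
min-donor – metal – midpoint₁ – midpoint₂ (IUPAC sign convention). The two
midpoints are ordered by distance to the min donor, a purely geometric rule
that makes the value invariant under atom renumbering while still flipping
sign for mirror-image complexes — the one descriptor that sees chirality.

## The 34-descriptor schema

The catalyst vector has 15 steric (S1–S15), 8 geometric (G1–G8) and 11
electronic (E1–E11) entries. The exact membership is a frozen schema chosen
to satisfy every anchored label: S1–S3 metal-centered %V_bur at 3.5/4.5/6.0
Å, S4 the hydrogen-excluded metal value, S5–S8 the four quadrants at the
metal (3.5 Å), S9–S11 max-donor-centered, S12 donor-midpoint-centered
(3.5 Å), S13–S14 min-donor-centered at 4.5/6.0 Å and **S15** the min-donor
value at 3.5 Å; G1 bite angle, G2 exact cone angle, G3 NBD dihedral, **G4**
d(metal, min donor), G5 d(metal, max donor), G6 donor–donor distance, G7/G8
metal–olefin-midpoint distances (nearer first); E1–E6 from the complex
single point (gap, min/max donor NBO charge, min-donor lone-pair occupancy,
**E5** = metal NBO charge, max-donor occupancy) and E7–E11 from the
free-ligand single point (**E7** = min-donor lone-pair occupancy, E8
max-donor occupancy, E9/**E10** min/max-donor NBO charge, E11 gap).
Electronic values are ingested from JSON sidecars rather than computed —
the package featurizes geometries, it does not run quantum chemistry. The
upstream redundancy pruning that produced a 34-descriptor set from a larger
pool mixed data-driven filtering with expert judgment and is deliberately
not re-run; the schema is implemented directly as the reproducible
contract.

## Substrate fingerprints

For the olefin C1=C2 (located geometrically: bonded C–C pairs at ≤ 1.40 Å;
ambiguous inputs require an explicit hint) the four substituent anchors
R1–R4 are enumerated per carbon in (descending atomic number, ascending
index) order, hydrogens included. The fingerprint is 6 buried volumes
(3.5 Å sphere on each of C1, C2, R1–R4; occupying set = the whole molecule
minus the center atom, measuring crowding around each position) plus
sterimol B1/B5/L for each C–R pairing, where the substituent subset is the
branch reachable from R without crossing its olefin carbon. 3D geometries
come from seeded ETKDG distance-geometry embedding, with (`dft_fp`-style)
or without (`smiles_fp`-style) MMFF94 relaxation — two genuinely different
featurizations of the same molecule, mirroring the refined-structure vs
quick-embedding distinction.

## HTE design and targets

The plate design ships as package data: 17 condition rows over SM1–SM5,
solvents methanol/DCE, 25–50 °C, 5–30 bar, 1–16 h, summing to 3552 wells =
37 plates. The modeling subset keeps one uniform condition per substrate
(methanol; 25 °C/5 bar/1 h for SM1–SM3, 50 °C/5 bar/16 h for SM4–SM5):
exactly 960 points. Enantioselectivity is modeled as
ΔΔG‡ = R·T·ln((1+ee)/(1−ee)) in kJ/mol at the well temperature (positive
sign favors the (+)-ee enantiomer; the inverse is a tanh, exact to 1e-10).
Reactivity is binary: high iff conversion ≥ 0.8 (boundary inclusive) for
out-of-domain models, or ≥ the per-substrate median for in-domain models.

## Synthetic study conditions

The generator is first-class, tested code; its defaults *are* the study
conditions.

**Toy complexes** place Rh at the origin, donors at 2.30 Å realizing a
requested bite angle (feasible 60–140°), a CH₂ or C₂H₄ backbone, alkyl arms
of requested bulk (methyl/ethyl/tert-butyl) and a rigid seven-carbon
norbornadiene-like cage trans to the donors, hydrogens filled by local
valence geometry. Ground-truth atom roles are returned for oracle tests.
For wide bite angles the backbone carbons fall within bonding distance of
Rh; this is tolerated — they belong to the donor-bearing component, so
partitioning is unaffected, and chemical realism is explicitly not the
goal, only geometric validity for the descriptor code. Sidecars draw from
plausible DFT ranges (gaps 2–6 eV, P charges +0.4…+1.0, N charges
−0.7…−0.3, occupancies 1.5–2.0).

**Outcomes** follow a latent-factor model: each ligand has a selectivity
skill g and an activity a, standard normal; substrate s sees
z = λ_s·g + √(1−λ_s²)·ε with loadings λ = 0.92 (selectivity) / 0.89
(activity) for SM1–SM3 and 0 for SM4–SM5. Those loadings are the inversion
of the bivariate-normal rank-correlation relation Spearman ≈ (6/π)
asin(ρ/2) at the published targets (≈ 0.83 for ΔΔG‡, ≈ 0.77 for conversion
among related substrates). ΔΔG‡ = clip(scale·z + shift) with scale 5 kJ/mol
on SM1–SM3 (range −15…15) and scale 2, shift +1 on SM4–SM5 (range −5…7);
ee follows by the inverse Gibbs relation. Conversion =
clip(logistic(6·(z + 0.6)) + N(0, 0.02²)), a steep squashing that yields
the bimodal, high-skewed distribution (≈ 64% of wells above 0.8 in
expectation). Non-modeling condition rows get small activity offsets
relative to the substrate's selected condition (slower in DCE, further
along at 16 h, higher pressure or temperature). Two signal modes:
`identity_driven` draws the latents independently of any descriptor (the
null world in which random descriptors must tie with real ones), and
`descriptor_driven` makes the latents linear in a sparse set of true
synthetic descriptors plus 30% noise (the world in which featurization
should win in-domain). Descriptor tables, outcome latents and
random-descriptor controls use separately tagged RNG streams derived from
the user seed, so a table generated at seed *s* can never accidentally
encode the outcome latents drawn at the same seed.

What the generator does **not** emulate: real ligand chemistry (descriptor
values are drawn from plausible marginal ranges, not computed from shared
structures, so descriptor–descriptor correlations are absent), solvent or
pressure mechanism, plate position effects, and measurement censoring.
Passing tests therefore demonstrate that the pipeline's *mechanisms* —
identity memorization out-of-domain, planted-signal recovery in-domain,
chance-correlation inflation — behave correctly, not that any model would
reach specific scores on the real campaign.

## ML harness

Seven out-of-domain cases (targets SM3/SM2/SM1 from the two related
substrates — cases 1–3; the same plus SM4/SM5 in training — cases 4–6;
SM4 from SM3+SM5 — case 7), each with the feature row
[ligand features ‖ substrate features]. Partial out-of-domain moves a
seed-deterministic random half of the target substrate's catalysts into
training; in-domain uses catalyst features only with an 80:20 catalyst
split (test size = ⌈0.2·n⌉, the scikit-learn convention). No
target-substrate catalyst ever straddles the train/test boundary; this is
asserted on every split. The learner is a random forest grid-searched over
trees {100, 300}, depth {3, 5, 10}, min-leaf {1, 3} with 5-fold CV on the
training rows, scored by balanced accuracy (classification) or R²
(regression) — a small, standard, fully config-overridable grid. One-hot
ligand features are the exception to the depth cap: those trees grow until
the leaves are pure, since a shallow tree can consult only a handful of
indicator columns. Enumerating representations × cases × targets (×3
splits where applicable) yields 168 fully-OOD, 504 partially-OOD and 90
in-domain runs; random-descriptor controls are enumerated separately.
Importances are impurity-based, normalized to sum to one; perfectly
correlated columns share their importance, which is tested rather than
hidden.

The Monte-Carlo subset study draws, per catalyst fraction (90%…10%), many
random subsets, splits each 80:20, and fits a forest (50 trees — the
effect under study is small-test-set variance, not ensemble size) on the
descriptor features, recording the test R² distribution, its maximum and
optional membership logs. On null-signal data the maximum at fraction 0.1
far exceeds the median at 0.9: the chance-correlation trap of small
datasets.

## PCA maps

Descriptor tables are standardized (the columns mix %, degrees, Å and eV;
constant columns are rejected with instruction to remove them) before PCA.
Component signs follow a fixed rule — the largest-|loading| feature is made
positive — so score plots are reproducible across reruns and row orders.
Cross-sections take PC1 of each descriptor category separately, with its
explained-variance share.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 192-ligand × 5-substrate
campaign for all statistical checks; geometry oracles use 10⁶-point
Monte-Carlo and 10⁶-direction brute-force scans; out-of-domain benchmarks
average 5 generator seeds and the in-domain planted-signal check 3; the
Monte-Carlo study uses 1000 splits at fractions 0.9 and 0.1. Batch
featurization tests use a 5-ligand library at 0.1 Å grid spacing, the
documented accuracy/cost trade-off for tests (descriptor-grade runs use
0.05 Å). Degenerate inputs fail loudly throughout: engulfed cone apex,
zero-length sterimol axis, collinear dihedral points, single-class
training targets, constant PCA columns.

## Known limitations

* Electronic descriptors are only as good as the supplied sidecars; no
  quantum-chemistry files are parsed.
* Bond perception is a pure distance rule; haptic interactions beyond the
  diene-midpoint heuristic and multi-metal complexes are out of scope.
* The %V_bur grid estimator carries ≤ ~0.3 grid jitter under rigid
  rotation at the default spacing; quadrant sums match totals to ≤ 0.2.
* The synthetic world contains exactly the structure listed above; real
  campaigns are harder in ways the generator does not pretend to capture.
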