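# Methods

## The model

An N-electron wavefunction Psi(**x**), **x** ∈ R^(3N), changes sign under
odd like-spin permutations and is invariant under even ("same-sign") ones.
The same-sign permutations tessellate the same-sign region of configuration
space into *tiles*: single-signed regions ψ_j with Psi = Σ_j ψ_j and
ψ_j(P_j∘**x**) = ±ψ₀(**x**).  Tile boundaries between opposite signs lie on
nodes; boundaries between same-sign tiles are fixed here, as in the method
this package implements, by a self-consistent Voronoi condition: a
configuration belongs to the tile of site **x̄** when it is at least as
close to **x̄** as to any same-sign permuted image P∘**x̄** of it.  The site
is the mean of Metropolis walkers sampling Psi² inside the cell, so at
self-consistency it estimates the centroid integral
**x̄** = ∫ **x** ψ₀² d**x** / ∫ ψ₀² d**x**, and its per-electron components
r̄_p act as localised "electron positions".

Wavefunctions are short determinant expansions
Psi = Σ_k c_k det(A_k^α) det(A_k^β) over orthonormal molecular orbitals in
a contracted Cartesian Gaussian basis (s, p, d; 6 Cartesian d components).
Everything internal is in Hartree atomic units (bohr); file formats use
Angstrom with the conversion 0.52917721092 Å/bohr.

## Electronic-structure engine

The package contains a compact engine producing these wavefunctions:
McMurchie–Davidson one- and two-electron integrals (numba-compiled),
restricted and unrestricted Hartree–Fock with DIIS, and full CI in small
active spaces via Slater–Condon rules, with the "excited configurations"
of an n-configuration wavefunction taken as the largest-|coefficient|
determinants of that CI, renormalised.  6-31G / 6-31G(d) parameters are
tabulated for H, C, N, O, F; the fluorine set was re-derived variationally
under the same split-valence prescription (atomic UHF optimum
−99.3608596 Eh, matching the standard tabulation to 4e-7 Eh).  Validation:
one-electron integrals against grid quadrature and hydrogenic closed
forms; two-electron integrals against erf-potential quadrature and
center-derivative identities; total energies against standard split-valence
anchor values (H atom −0.4982329 Eh exactly; water −76.0107 Eh; hydrogen
fluoride −100.0029 Eh at 0.911 Å).

For the hydrogen fluoride 2-configuration model the correlating orbital is
the leading natural orbital of the σ-pair CI over all virtuals, iterated
(a raw canonical virtual spreads the pair correlation over several
determinants).  The CI weight of the second configuration grows from 0.09
at 0.91 Å to 0.28 at 1.51 Å, the expected signature of homolytic-cleavage
correlation.

## Sampling

Walkers move by all-coordinate Gaussian Metropolis steps, accepted with
min(1, Psi²(x′)/Psi²(x)).  Proposals whose amplitude sign differs from the
tile's reference sign are rejected (node-delineated boundaries); proposals
leaving the Voronoi cell are folded back by the inverse nearest same-sign
image permutation, which is measure-preserving because Psi² is permutation
invariant.  The nearest-image search is one linear assignment per spin
followed by an exact parity-constrained ranked-assignment (Murty) search;
the sampler's inner loop uses a compiled assignment solver with a
cheapest-swap parity repair whose folds are re-verified, so a rare
sub-optimal repair can only turn a fold into a rejection.

Key defaults (SamplerConfig): 1000 walkers; per-coordinate step 0.35 bohr
auto-tuned during an 80-sweep burn-in to 40–60% acceptance; outer
iterations of 100 sweeps; convergence when the maximum per-electron site
drift stays below 0.02 bohr for 5 consecutive iterations; budget 5000
sweeps.  Site updates use the accumulated post-burn-in walker mean (the
estimator of the centroid integral), excluding the first two outer
iterations while the structure still relaxes and resetting a site's
accumulator if its batch mean departs by more than 0.3 bohr (a structural
shift rather than noise).  Batch-only updates were tried first and do not
converge for water: the tile has slowly-diffusing flat directions (e.g.
the mutual orientation of α and β lone pairs, which Psi² does not couple
at the single-determinant level), so the batch site performs a random walk
with ~0.1 bohr per-iteration drift.  The accumulated mean settles below
tolerance in roughly a thousand sweeps.  The 0.02 bohr tolerance is chosen
at the Monte-Carlo noise floor of the default walker budget.

## Sub-tile (bifurcation) analysis

Some tiles are "two-humped" and need two Voronoi sites.  Detection fits
1- and 2-component Gaussian mixtures (EM, 20 restarts) to the walker cloud
— optionally restricted to designated coordinates such as the two bond
electrons' z components — and prefers two components only when all of the
following hold:

* BIC(2) < BIC(1) − 10 (strong-evidence margin);
* the component means are ≥ 2.0 pooled standard deviations apart (the
  point where an equal two-Gaussian mixture actually becomes bimodal);
* for spin-swap-symmetric wavefunctions, the two components are each
  other's α↔β images (cross-swap distance below self-swap distance) —
  a split failing this describes anharmonic shape (e.g. a breathing mode),
  not a spin-split pair of sub-tiles.

Selection subsamples at most 3000 points because walker samples are
autocorrelated and raw BIC at tens of thousands of correlated points
overfits anharmonicity.  For spin-swap-symmetric multi-determinant
wavefunctions the harvest comes from a frozen, spin-symmetrised cell
(a self-consistent site spontaneously localises into one Coulson–Fischer
hump at larger stretch and would hide the second), and the detection set
is augmented with bond-pair-exchanged copies so both humps enter with
equal weight.  A single-determinant closed-shell Psi² factorises over
spins and cannot spin-split, so full-space detection is skipped there.

Planar open-shell radicals may localise the unpaired electron on one side
of the molecular plane; the mirror-partner sub-tile is then constructed
directly (reflection composed with a like-spin relabelling of the parity
that restores the tile sign) and accepted when a Psi² valley (factor ≥ 4
dip or sign change) separates the two sites.  After any split, DVMS re-runs
against the multi-site Voronoi predicate, which makes the sub-tiles
non-overlapping by construction.

Tiles are not unique (no more than a crystal's unit cell is).  The methyl
radical illustrates this: most runs give the two mirror sub-tiles with the
unpaired electron above/below the plane, but a minority of seeds settles
into an equally valid mirror-symmetric single tile with one α electron in
each lobe; tests therefore require the two-sub-tile description from the
majority of independent runs.

## Known limitation: the hydrogen fluoride bifurcation onset

For the 2-configuration H–F wavefunction this package constructs, the
detection criterion above reports a spin-split two-site model robustly at
larger stretch but not yet at R = 1.11 Å: at high precision the bond-pair
mixture separation there measures 1.8–2.1 (threshold 2.0) and the dominant
2-component candidate is the breathing anharmonicity, which the
swap-consistency test correctly rejects.  The equilibrium geometry
(0.91 Å) is monomodal for every seed tested.  Loosening the criterion to
flag 1.11 Å would also flag the equilibrium; the onset of the bifurcated
description in this model therefore lies between 1.1 and 1.5 Å, and the
package reports the detection constants alongside every bifurcation claim.

## Reaction tracking

Frames are ordered geometries with wavefunctions; frame k+1's DVMS is
warm-started from frame k's converged sites, each electron displaced with
its nearest nucleus.  Electron identity across frames is maintained by the
minimum-squared-displacement relabelling constrained to even combined
parity (so the relabelling is itself a same-sign permutation); after a
bifurcation the sub-tile nearest the previously followed site is followed
continuously.  The per-electron site loci across frames are the calculated
curly arrows, exported as spin-labelled polylines (JSON) and as an SVG
projected onto the best-fit heavy-atom plane.

The demonstration reaction paths (S_N2 backside displacement, hydroxide
addition to formaldehyde) are geometrically interpolated frames between
reactant-like and product-like structures — synthetic stand-ins for
steepest-descent paths, which this package consumes but does not compute.
Tracking for these closed-shell demonstrations follows the single tile
(`detect_subtiles=False`), matching the single-tile evolution of these
mechanisms; both spins follow the same path in the carbonyl addition.

## Projections

Cross-section fields evaluate the tile amplitude with one electron scanned
over a grid and the others clamped to their site positions, zeroing points
outside the tile (optionally outside one sub-tile's cell); isosurfaces are
extracted by marching cubes at ζ = 0.1 × field maximum by default (ζ is an
aesthetic choice).  Per-electron marginals are normalised histograms of
walker positions — the Psi²-weighted analogue of integrating the amplitude
over the other electrons; an amplitude-weighted estimator would need
1/|Psi| reweighting, whose variance is why the density-weighted form is
the default.  Grids default to the nuclei's bounding box plus a 4 Å margin
at 0.15 Å spacing.  Exports: Gaussian cube (bohr, per the standard),
Wavefront OBJ, JSON (Angstrom).

## What the synthetic fixtures do and do not show

Displaced-Gaussian toy determinants have analytically known tile centroids
(the generating centers, once separations exceed ~6 widths) and exercise
the full permutation/fold/assignment machinery without electronic
structure; the two-configuration H₂ model adds a closed-form amplitude
oracle and a genuinely bifurcating tile.  Passing on these shows the
sampler, predicate and split logic are correct, not that a given ab initio
level is adequate for a given molecule.  Problem sizes in the test suite
(hundreds of walkers, 1–3 thousand sweeps, 3–4 reaction frames) are chosen
so every quantity tested is resolved within its quoted Monte-Carlo error;
they are the package's default desk-scale settings, and all of them scale
up by configuration.
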