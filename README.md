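# dvms — wavefunction tiles and calculated curly arrows

Chemists draw reaction mechanisms as curly arrows: localised electron pairs
moving between bonds and lone pairs.  Molecular-orbital wavefunctions do not
come with localised electrons, but the antisymmetry of an N-electron
wavefunction forces Psi(**x**) to repeat itself across 3N-dimensional space:
under any like-spin permutation P of even parity, Psi(P∘**x**) = Psi(**x**).
The wavefunction therefore decomposes into *tiles* — non-overlapping,
single-signed hyper-regions that regenerate the full wavefunction under
permutation, like unit cells of a crystal.  One tile pins down an identity
for every electron, and its average electron positions behave exactly like
the localised bonds and lone pairs of a Lewis structure.

This package implements **Dynamic Voronoi Metropolis Sampling (DVMS)** of
wavefunction tiles, and everything needed to use it on real molecules:

* a self-contained restricted/unrestricted Hartree–Fock + small-CASCI
  engine (6-31G and 6-31G(d) bases for H, C, N, O, F) producing
  multi-determinant wavefunctions Psi(**x**) = Σ_k c_k det(A_k^α)det(A_k^β);
* Metropolis walkers sampling Psi² in 3N dimensions, confined to one tile:
  each walker must stay closer to the mean walker position **x̄** (the
  "Voronoi site") than to any same-sign permuted image P∘**x̄** — a Voronoi
  tessellation over even like-spin permutations, solved by linear
  assignment with an exact parity-constrained (Murty) search;
* self-consistent convergence of **x̄** = ∫ **x** ψ₀² d**x** / ∫ ψ₀² d**x**
  (the sites are the per-electron mean positions r̄_p);
* bifurcation analysis: expectation–maximisation Gaussian-mixture detection
  of "two-humped" tiles (stretched bonds, the methyl radical's unpaired
  electron) and splitting into non-overlapping sub-tiles ψ₀ = Σ_m φ₀^m;
* projections: per-electron sites, isosurface cross-sections
  S_p = { r_p | ψ₀(r̄₁, …, r_p, …, r̄_N) = ζ }, marginal densities, and the
  dipole identity Σ_A Z_A R_A − Σ_p r̄_p ≈ ⟨Psi|μ|Psi⟩;
* reaction-coordinate tracking: warm-started DVMS along ordered geometry
  frames with electron identity maintained by optimal even relabelling —
  the locus of each r̄_p across frames is a *calculated curly arrow*
  (exported as JSON and SVG).

Demonstration systems (water, methyl radical, hydrogen fluoride under
stretch, the S_N2 displacement FCH₃ + OH⁻ → F⁻ + CH₃OH, nucleophilic
hydroxide addition to formaldehyde) are generated from formulas at run
time; small pre-built wavefunction containers ship with the package.

## Worked example: the electronic structure of water

```python
from dvms.fixtures import packaged_fixture
from dvms.sampler import SamplerConfig, run_dvms
from dvms.projection import electron_sites, dipole_check

wf = packaged_fixture("water_rhf_631gd")          # RHF/6-31G(d) container
cfg = SamplerConfig(n_walkers=600, max_sweeps=2500, seed=11)
sites, cloud, diag = run_dvms(wf, cfg)
print(f"converged={diag.converged} after {diag.sweeps_total} sweeps")
for e in electron_sites(sites[0]):
    p = e.position
    print(f"e{e.index:2d} {e.spin:5s} at ({p[0]:+6.3f}, {p[1]:+6.3f}, {p[2]:+6.3f}) A")
```

prints (oxygen at the origin, hydrogens at ±y toward +z):

```
converged=True after 1580 sweeps
e 0 alpha at (+0.065, +0.510, +0.393) A
e 1 alpha at (-0.019, -0.575, +0.405) A
e 2 alpha at (+0.046, -0.023, +0.055) A
e 3 alpha at (-0.401, +0.077, -0.133) A
e 4 alpha at (+0.286, -0.024, -0.292) A
e 5 beta  at (+0.039, +0.639, +0.436) A
e 6 beta  at (+0.249, +0.045, -0.302) A
e 7 beta  at (-0.060, +0.076, +0.025) A
e 8 beta  at (-0.487, -0.105, -0.158) A
e 9 beta  at (+0.056, -0.425, +0.351) A
```

The ten electrons localise into the textbook Lewis structure: an α/β pair
on each O–H bond (±y), a core pair at the oxygen, and two lone pairs
pointing away from the hydrogens above and below the molecular plane.
Averaged over four independent runs, the site-based dipole
Σ_A Z_A R_A − Σ_p r̄_p is (0.08, −0.03, 0.77) ± (0.16, 0.11, 0.06) a.u.
against the quantum-mechanical expectation (0, 0, 0.87) a.u. —
the identity holds within the Monte-Carlo error of the mean
(`dipole_check(sites[0], wf)` reports both).

Sub-tile analysis and reaction tracking work the same way; see
`dvms.subtiles.run_dvms_with_subtiles` (methyl radical, stretched H–F) and
`dvms.tracking.track_reaction` / `export_arrows` (S_N2 and carbonyl
addition paths in `dvms.demos`).

## Command line

```bash
dvms fixtures recipe.yaml --out wavefunctions/    # build containers
dvms run manifest.yaml --seed 7                   # converge one tile
dvms subtiles manifest.yaml                       # + bifurcation analysis
dvms project manifest.yaml                        # sites, cube, OBJ meshes
dvms track  trajectory.yaml                       # per-frame sites
dvms arrows trajectory.yaml                       # curly-arrow JSON + SVG
```

Manifests are YAML; paths resolve relative to the manifest, outputs are
JSON/CSV/cube/OBJ/SVG with geometry in Angstrom.  Identical invocations
with the same `--seed` are byte-identical.

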