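"""Projections of converged tiles into 3-dimensional representations.

Three views of a tile: per-electron mean positions (the projection of the
3N-vector x-bar onto vectors r-bar_p), isosurface cross-sections S_p =
{ r_p | psi_0(r-bar_1, ..., r_p, ..., r-bar_N) = zeta } with all other
electrons clamped to their site positions, and per-electron marginal
densities phi_p estimated by histogramming the walker cloud.  Also the
dipole identity: nuclear charges at R_A minus electron sites r-bar_p
reproduce the quantum-mechanical dipole expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import marching_cubes

from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM
from .permutations import in_tile
from .sampler import VoronoiSite

__all__ = [
    "ElectronSite", "ScalarField", "IsoSurface", "electron_sites",
    "make_grid", "cross_section_field", "extract_isosurface",
    "marginal_density", "dipole_check", "write_cube", "write_obj",
]


@dataclass
class ElectronSite:
    """Average position r-bar_p of one electron in a tile (Angstrom)."""

    index: int
    spin: str                    # "alpha" | "beta"
    position: np.ndarray         # (3,) Angstrom


@dataclass
class ScalarField:
    """Values on a regular right-handed 3D grid (Angstrom geometry)."""

    origin: np.ndarray           # (3,) Angstrom
    spacing: float               # Angstrom
    values: np.ndarray           # (nx, ny, nz)

    def axis_points(self, d):
        n = self.values.shape[d]
        return self.origin[d] + self.spacing * np.arange(n)


@dataclass
class IsoSurface:
    vertices: np.ndarray         # (nv, 3) Angstrom
    faces: np.ndarray            # (nf, 3) int
    isovalue: float
    electron_index: int


def electron_sites(site: VoronoiSite) -> list:
    """Project a 3N site onto per-electron 3D sites, bohr -> Angstrom."""
    out = []
    for p, pos in enumerate(site.positions):
        spin = "alpha" if p < site.n_alpha else "beta"
        out.append(ElectronSite(p, spin, pos * ANGSTROM_PER_BOHR))
    return out


def make_grid(geometry, margin=4.0, spacing=0.15):
    """Cubic grid enclosing the nuclei with a margin (Angstrom units)."""
    xyz = geometry.coords_angstrom()
    lo = xyz.min(axis=0) - margin
    hi = xyz.max(axis=0) + margin
    ns = np.ceil((hi - lo) / spacing).astype(int) + 1
    return lo, spacing, tuple(ns)


def _grid_points(origin, spacing, shape):
    ax = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)


def cross_section_field(wf, sites, electron_index, origin=None, spacing=0.15,
                        shape=None, margin=4.0, clamp_to_tile=True,
                        owner_only=False, chunk=20000) -> ScalarField:
    """Tile amplitude with electron p scanned over a grid, others clamped.

    ``sites``: a VoronoiSite or list of them (sub-tiles); the scan clamps
    the other electrons to the FIRST site's positions.  With
    ``clamp_to_tile`` points where the scanned configuration leaves the tile
    are zeroed, so the surface is the tile's rather than the raw
    wavefunction's; ``owner_only`` additionally zeroes points owned by a
    different sub-tile, restricting the section to the first site's cell.
    """
    if isinstance(sites, VoronoiSite):
        sites = [sites]
    site = sites[0]
    na, nb = site.n_alpha, site.n_beta
    if origin is None or shape is None:
        origin, spacing, shape = make_grid(wf.geometry, margin, spacing)
    pts = _grid_points(np.asarray(origin, float), spacing, shape)
    pts_bohr = pts * BOHR_PER_ANGSTROM
    vals = np.empty(len(pts))
    base = site.positions
    sites_arr = [s.positions for s in sites]
    for lo in range(0, len(pts), chunk):
        hi = min(lo + chunk, len(pts))
        configs = np.broadcast_to(base, (hi - lo,) + base.shape).copy()
        configs[:, electron_index, :] = pts_bohr[lo:hi]
        vals[lo:hi] = wf.amplitude_many(configs)
        if clamp_to_tile:
            from .sampler import _resolve_membership
            inside, owner, _ = _resolve_membership(configs,
                                                   np.stack(sites_arr),
                                                   na, nb)
            bad = ~inside
            if owner_only:
                bad |= owner != 0
            vals[lo:hi][bad] = 0.0
    return ScalarField(np.asarray(origin, float), spacing,
                       vals.reshape(shape))


def extract_isosurface(field: ScalarField, isovalue=None,
                       electron_index=-1) -> IsoSurface:
    """Marching-cubes mesh at ``isovalue`` (default 0.1 x field maximum).

    The isovalue zeta is an aesthetic choice; it must lie strictly between
    the field minimum and maximum.
    """
    v = field.values
    if isovalue is None:
        isovalue = 0.1 * float(v.max())
    if not (v.min() < isovalue < v.max()):
        raise ValueError(
            f"isovalue {isovalue} outside field range [{v.min()}, {v.max()}]")
    verts, faces, _, _ = marching_cubes(v, level=isovalue)
    verts = verts * field.spacing + field.origin
    return IsoSurface(verts, faces, float(isovalue), electron_index)


def marginal_density(samples, electron_index, origin=None, spacing=0.15,
                     shape=None, geometry=None, margin=4.0) -> ScalarField:
    """Per-electron marginal density phi_p from walker samples.

    3D histogram of electron p's positions over >= 1e4 samples, normalised
    to unit integral: the Psi^2-weighted marginal of the tile (the
    density-weighted analogue of integrating the amplitude over the other
    electrons' coordinates).
    """
    samples = np.asarray(samples, float)
    if origin is None or shape is None:
        if geometry is None:
            raise ValueError("need either a grid spec or a geometry")
        origin, spacing, shape = make_grid(geometry, margin, spacing)
    origin = np.asarray(origin, float)
    r = samples[:, electron_index, :] * ANGSTROM_PER_BOHR
    edges = [origin[d] - 0.5 * spacing + spacing * np.arange(shape[d] + 1)
             for d in range(3)]
    hist, _ = np.histogramdd(r, bins=edges)
    total = hist.sum()
    if total > 0:
        hist = hist / (total * spacing ** 3)
    return ScalarField(origin, spacing, hist)


def dipole_check(model_or_sites, wf, n_samples_note=None):
    """Site-based dipole vs quantum expectation dipole (atomic units).

    Site dipole: sum_A Z_A R_A - sum_m w_m sum_p r-bar_p^m.  Expectation
    dipole from the one-particle density matrix of the wavefunction.
    Returns (site_dipole, expectation_dipole, discrepancy vector).
    """
    from .engine import expectation_dipole
    if isinstance(model_or_sites, VoronoiSite):
        sites, weights = [model_or_sites], np.ones(1)
    elif isinstance(model_or_sites, (list, tuple)):
        sites = list(model_or_sites)
        weights = np.full(len(sites), 1.0 / len(sites))
    else:                        # SubTileModel
        sites, weights = model_or_sites.sites, model_or_sites.weights
    geom = wf.geometry
    nuc = (geom.numbers[:, None] * geom.coords).sum(axis=0)
    elec = sum(w * s.positions.sum(axis=0) for w, s in zip(weights, sites))
    mu_sites = nuc - elec
    mu_exp = expectation_dipole(wf)
    return mu_sites, mu_exp, mu_sites - mu_exp


# --------------------------------------------------------------------------
# exports
# --------------------------------------------------------------------------

def write_cube(path, field: ScalarField, geometry, comment="DVMS field"):
    """Gaussian cube file (bohr, per the cube convention)."""
    o = field.origin * BOHR_PER_ANGSTROM
    h = field.spacing * BOHR_PER_ANGSTROM
    nx, ny, nz = field.values.shape
    with open(path, "w") as f:
        f.write(f"{comment}\nvalues on grid; lengths in bohr\n")
        f.write(f"{len(geometry.symbols):5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}\n")
        f.write(f"{nx:5d} {h:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        f.write(f"{ny:5d} {0.0:12.6f} {h:12.6f} {0.0:12.6f}\n")
        f.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {h:12.6f}\n")
        for z, pos in zip(geometry.numbers, geometry.coords):
            f.write(f"{z:5d} {float(z):12.6f} "
                    f"{pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}\n")
        flat = field.values.ravel()
        for i in range(0, len(flat), 6):
            f.write(" ".join(f"{v:13.5e}" for v in flat[i:i + 6]) + "\n")


def write_obj(path, surface: IsoSurface, comment="DVMS isosurface"):
    """Wavefront OBJ mesh (vertices in Angstrom)."""
    with open(path, "w") as f:
        f.write(f"# {comment}\n# isovalue {surface.isovalue}\n")
        for v in surface.vertices:
            f.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for tri in surface.faces:
            f.write(f"f {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")
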