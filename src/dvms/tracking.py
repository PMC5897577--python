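"""Tile tracking along reaction coordinates and curly-arrow export.

The locus of a Voronoi site's per-electron positions across reaction
frames is a calculated curly arrow: it links "electron positions" from
reactants to products.  Each frame's DVMS run is warm-started from the
previous frame's converged sites (displaced rigidly with the nearest
nucleus); electron identity is maintained between frames by an optimal
even relabelling, and once a tile bifurcates, one designated sub-tile is
followed continuously.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .sampler import (
    SamplerConfig, VoronoiSite, match_site_labels, run_dvms, sample_tile,
)
from .subtiles import SubTileModel, run_dvms_with_subtiles
from .units import ANGSTROM_PER_BOHR

__all__ = ["ReactionFrame", "CurlyArrowPath", "track_reaction",
           "match_electron_labels", "export_arrows", "arrows_to_svg"]

log = logging.getLogger(__name__)


@dataclass
class ReactionFrame:
    index: int
    coordinate: float
    geometry: object
    model: SubTileModel
    followed: int                       # designated sub-tile index
    converged: bool
    diagnostics: object = None


@dataclass
class CurlyArrowPath:
    """Spin-labelled per-electron polyline across frames (Angstrom)."""

    electron_index: int
    spin: str
    points: np.ndarray                  # (n_frames, 3)

    @property
    def displacement(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


def match_electron_labels(previous: np.ndarray, current: np.ndarray,
                          n_alpha: int, n_beta: int):
    """Even relabelling aligning ``current`` site electrons to ``previous``.

    Minimum total squared displacement per spin, parity-repaired so the
    relabelling is itself a same-sign permutation.  Returns (relabelled
    positions, SpinPermutation).
    """
    return match_site_labels(previous, current, n_alpha, n_beta)


def _rigid_warm_start(site: VoronoiSite, old_geom, new_geom) -> VoronoiSite:
    """Displace each site electron with its nearest nucleus's motion."""
    d = site.positions[:, None, :] - old_geom.coords[None, :, :]
    nearest = np.einsum("pak,pak->pa", d, d).argmin(axis=1)
    shift = new_geom.coords[nearest] - old_geom.coords[nearest]
    return VoronoiSite(site.positions + shift, site.n_alpha, site.n_beta,
                       site.sign)


def track_reaction(wavefunctions, config: SamplerConfig, coordinates=None,
                   feature=None, harvest_sweeps=40,
                   detect_subtiles=True) -> list:
    """Converge DVMS frame by frame along an ordered reaction path.

    ``wavefunctions``: ordered CIWavefunction list (consistent atom order);
    ``coordinates``: optional monotone reaction-coordinate values (default
    frame index).  Returns ReactionFrame list.  Non-converged frames are
    flagged and tracking continues from the last converged sites.
    """
    if len(wavefunctions) < 2:
        raise ValueError("need >= 2 frames")
    coords = list(coordinates) if coordinates is not None \
        else list(range(len(wavefunctions)))
    frames = []
    sites = None
    followed_site = None
    last_geom = None
    for k, wf in enumerate(wavefunctions):
        cfg = replace(config, seed=config.seed + 1000 * k)
        if sites is not None:
            sites = [_rigid_warm_start(s, last_geom, wf.geometry)
                     for s in sites]
        if not detect_subtiles and (sites is None or len(sites) == 1):
            ss, cloud, diag = run_dvms(wf, cfg, sites)
            samples, owners = sample_tile(
                wf, ss, cloud, cfg, harvest_sweeps,
                np.random.default_rng(cfg.seed + 13))
            model = SubTileModel(ss, np.ones(1),
                                 np.zeros(len(samples), int), bic={},
                                 feature="disabled")
        elif sites is None or len(sites) == 1:
            model, samples, diag = run_dvms_with_subtiles(
                wf, cfg, sites0=sites, feature=feature,
                harvest_sweeps=harvest_sweeps)
        else:
            ss, cloud, diag = run_dvms(wf, cfg, sites)
            samples, owners = sample_tile(
                wf, ss, cloud, cfg, harvest_sweeps,
                np.random.default_rng(cfg.seed + 13))
            weights = np.array([(owners == m).mean() for m in range(len(ss))])
            model = SubTileModel(ss, weights, owners, bic={},
                                 feature=str(feature))
        # designate the followed sub-tile: nearest to the previous one
        if followed_site is None or model.n_components == 1:
            followed = 0
        else:
            dists = []
            for s in model.sites:
                aligned, _ = match_site_labels(
                    followed_site.positions, s.positions,
                    wf.n_alpha, wf.n_beta)
                dists.append(np.linalg.norm(aligned
                                            - followed_site.positions))
            followed = int(np.argmin(dists))
        converged = bool(getattr(diag, "converged", True))
        if not converged:
            log.warning("frame %d not converged; continuing", k)
        frames.append(ReactionFrame(k, coords[k], wf.geometry, model,
                                    followed, converged, diag))
        sites = model.sites
        followed_site = model.sites[followed]
        last_geom = wf.geometry
    return frames


def export_arrows(frames, n_alpha, n_beta,
                  displacement_threshold=0.0) -> list:
    """CurlyArrowPath per electron from the followed sites of a track.

    Electron labels are chained frame to frame by optimal even relabelling,
    so each polyline follows one physical electron slot.  Electrons whose
    total displacement is below ``displacement_threshold`` (Angstrom) are
    dropped (e.g. to suppress unchanged core electrons).
    """
    if len(frames) < 2:
        raise ValueError("need >= 2 frames")
    chain = [frames[0].model.sites[frames[0].followed].positions]
    for fr in frames[1:]:
        cur = fr.model.sites[fr.followed].positions
        aligned, _ = match_site_labels(chain[-1], cur, n_alpha, n_beta)
        chain.append(aligned)
    chain = np.stack(chain) * ANGSTROM_PER_BOHR     # (F, N, 3)
    out = []
    for p in range(n_alpha + n_beta):
        spin = "alpha" if p < n_alpha else "beta"
        path = CurlyArrowPath(p, spin, chain[:, p, :].copy())
        if path.displacement >= displacement_threshold:
            out.append(path)
    return out


def arrows_to_json(paths, file_or_path, coordinates=None):
    payload = {
        "schema_version": 1,
        "units": "angstrom",
        "reaction_coordinate": list(coordinates) if coordinates is not None
        else None,
        "arrows": [{"electron": p.electron_index, "spin": p.spin,
                    "frames": p.points.tolist()} for p in paths],
    }
    if hasattr(file_or_path, "write"):
        json.dump(payload, file_or_path, indent=1)
    else:
        with open(file_or_path, "w") as f:
            json.dump(payload, f, indent=1)


def _projection_plane(geometry):
    """Principal plane of the heavy atoms (all atoms if none heavy)."""
    xyz = geometry.coords_angstrom()
    heavy = xyz[geometry.numbers > 1]
    if len(heavy) < 3:
        heavy = xyz
    c = heavy.mean(axis=0)
    u, s, vt = np.linalg.svd(heavy - c, full_matrices=False)
    basis = vt[:2] if len(vt) >= 2 else np.eye(3)[:2]
    return c, basis


def arrows_to_svg(paths, geometries, path, scale=55.0, margin=30.0):
    """2D SVG of the curly arrows, projected onto the best-fit plane of the
    final frame's heavy atoms; alpha red, beta blue; start marker triangle,
    end marker square; reactant geometry black, product grey."""
    c, basis = _projection_plane(geometries[-1])

    def proj(x3):
        return (np.atleast_2d(x3) - c) @ basis.T

    pts = np.concatenate([proj(p.points) for p in paths] +
                         [proj(g.coords_angstrom()) for g in geometries])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)

    def to_px(q):
        q = (q - lo) / span
        return (margin + q[:, 0] * scale * span[0] / span.max() * 10,
                margin + (1 - q[:, 1]) * scale * span[1] / span.max() * 10)

    W = margin * 2 + scale * 10 * span[0] / span.max()
    H = margin * 2 + scale * 10 * span[1] / span.max()
    colors = {"alpha": "#cc2222", "beta": "#2244cc"}
    lines = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{W:.0f}" '
             f'height="{H:.0f}" viewBox="0 0 {W:.0f} {H:.0f}">',
             f'<!-- units: angstrom, projected onto heavy-atom plane -->']
    for g, col in ((geometries[0], "#000000"), (geometries[-1], "#999999")):
        px, py = to_px(proj(g.coords_angstrom()))
        for x, y, z in zip(px, py, g.numbers):
            r = 3.0 + z
            lines.append(f'<circle cx="{x:.1f}" cy="{y:.1f}" r="{r:.1f}" '
                         f'fill="none" stroke="{col}" stroke-width="1.5"/>')
    for p in paths:
        px, py = to_px(proj(p.points))
        d = "M " + " L ".join(f"{x:.1f} {y:.1f}" for x, y in zip(px, py))
        col = colors[p.spin]
        lines.append(f'<path d="{d}" fill="none" stroke="{col}" '
                     f'stroke-width="2" opacity="0.8"/>')
        x0, y0 = px[0], py[0]
        lines.append(f'<polygon points="{x0:.1f},{y0 - 5:.1f} '
                     f'{x0 - 4:.1f},{y0 + 3:.1f} {x0 + 4:.1f},{y0 + 3:.1f}" '
                     f'fill="{col}"/>')
        x1, y1 = px[-1], py[-1]
        lines.append(f'<rect x="{x1 - 3.5:.1f}" y="{y1 - 3.5:.1f}" '
                     f'width="7" height="7" fill="{col}"/>')
    lines.append("</svg>")
    with open(path, "w") as f:
        f.write("\n".join(lines))
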