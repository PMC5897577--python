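"""Bifurcation detection and sub-tile splitting.

Some tiles are "two-humped" (stretched bonds, the methyl radical's unpaired
electron): a single site misrepresents them and the tile is better written
as a sum of non-overlapping sub-tiles, each with its own Voronoi site.
Bimodality is detected by expectation-maximisation Gaussian-mixture fits to
the walker cloud and Bayesian-information-criterion model selection; after a
split, sampling against the multi-site Voronoi predicate keeps the sub-tiles
non-overlapping by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .sampler import (
    SamplerConfig, VoronoiSite, WalkerCloud, run_dvms, sample_tile,
)

__all__ = ["SubTileModel", "select_component_count", "split_sites",
           "run_dvms_with_subtiles"]

# BIC margin ("strong evidence" convention): prefer 2 components only when
# BIC(2) < BIC(1) - DELTA.
BIC_MARGIN = 10.0
N_EM_RESTARTS = 20
MIN_COMPONENT_FRACTION = 0.05
# walker samples are autocorrelated; selection uses at most this many,
# drawn uniformly, so the BIC's sample-size term is not inflated
MAX_SELECTION_POINTS = 3000
# minimum Mahalanobis separation of the two component means (pooled
# covariance): guards against splitting a merely anharmonic single hump
MIN_SEPARATION = 2.0


@dataclass
class SubTileModel:
    """1 or 2 Voronoi sites with walker assignments and selection scores."""

    sites: list                              # VoronoiSite per component
    weights: np.ndarray
    assignments: np.ndarray                  # per-walker component index
    bic: dict                                # {1: ..., 2: ...}
    margin: float = BIC_MARGIN
    separation: float = float("nan")
    degenerate_split: bool = False
    feature: str = "all"
    method: str = "em"                       # em | broken-symmetry
    asymmetry: float = float("nan")          # spin-swap site asymmetry, bohr

    @property
    def n_components(self) -> int:
        return len(self.sites)


def _features(samples: np.ndarray, feature):
    """Designated coordinate subset of (W, N, 3) samples, flattened.

    ``feature``: None/"all" for the full 3N coordinates; a list of electron
    indices for their full 3D positions; or a list of (electron, axis)
    pairs for single coordinates (e.g. the z components of the two bond
    electrons).
    """
    W = len(samples)
    if feature is None or feature == "all":
        return samples.reshape(W, -1)
    feature = list(feature)
    if feature and isinstance(feature[0], (tuple, list)):
        cols = [samples[:, int(e), int(ax)] for e, ax in feature]
        return np.stack(cols, axis=1)
    idx = np.atleast_1d(np.asarray(feature, int))
    return samples[:, idx, :].reshape(W, -1)


def _mean_separation(gm) -> float:
    """Mahalanobis distance between the two component means under the
    pooled covariance."""
    d = gm.means_[1] - gm.means_[0]
    pooled = 0.5 * (gm.covariances_[0] + gm.covariances_[1])
    return float(np.sqrt(d @ np.linalg.solve(pooled, d)))


def select_component_count(samples, feature=None, seed=0,
                           margin=BIC_MARGIN, n_restarts=N_EM_RESTARTS,
                           max_points=MAX_SELECTION_POINTS,
                           min_separation=MIN_SEPARATION):
    """1 or 2, by EM Gaussian-mixture fits and a BIC margin.

    ``samples``: (W, N, 3) walker configurations (W >= 200); ``feature``
    optionally restricts to designated electron indices (e.g. the two bond
    electrons).  Two components are reported only when BIC(2) beats BIC(1)
    by ``margin`` AND the component means are at least ``min_separation``
    pooled standard deviations apart.  Deterministic given ``seed``.
    Returns (M, scores dict).
    """
    X = _features(np.asarray(samples, float), feature)
    if len(X) < 200:
        raise ValueError("need >= 200 walkers for model selection")
    if len(X) > max_points:
        sub = np.random.default_rng(seed).choice(len(X), max_points,
                                                 replace=False)
        X = X[sub]
    scores = {}
    models = {}
    for m in (1, 2):
        gm = GaussianMixture(n_components=m, covariance_type="full",
                             n_init=n_restarts if m > 1 else 1,
                             random_state=seed, reg_covar=1e-6)
        gm.fit(X)
        if not gm.converged_:
            raise RuntimeError(f"EM failed to converge for {m} component(s)")
        scores[m] = float(gm.bic(X))
        models[m] = gm
    sep = _mean_separation(models[2])
    m_sel = 2 if (scores[2] < scores[1] - margin
                  and sep >= min_separation) else 1
    return m_sel, {"bic": scores, "margin": margin, "separation": sep,
                   "models": models}


def split_sites(samples, n_alpha, n_beta, sign=1, feature=None, seed=0,
                m=2) -> SubTileModel:
    """Hard-assign walkers to ``m`` mixture components; one site each.

    Sites are means of the full 3N coordinates of the assigned walkers (the
    mixture may have been fitted on a coordinate subset).  A component
    capturing < 5% of walkers flags a degenerate split and falls back to a
    single site.
    """
    samples = np.asarray(samples, float)
    X = _features(samples, feature)
    W = len(samples)
    if m == 1:
        site = VoronoiSite(samples.mean(axis=0), n_alpha, n_beta, sign)
        return SubTileModel([site], np.ones(1), np.zeros(W, int),
                            bic={}, feature=str(feature))
    gm = GaussianMixture(n_components=m, covariance_type="full",
                         n_init=N_EM_RESTARTS, random_state=seed,
                         reg_covar=1e-6)
    labels = gm.fit_predict(X)
    weights = np.array([(labels == k).mean() for k in range(m)])
    if weights.min() < MIN_COMPONENT_FRACTION:
        site = VoronoiSite(samples.mean(axis=0), n_alpha, n_beta, sign)
        model = SubTileModel([site], np.ones(1), np.zeros(W, int), bic={},
                             feature=str(feature))
        model.degenerate_split = True
        return model
    sites = [VoronoiSite(samples[labels == k].mean(axis=0),
                         n_alpha, n_beta, sign) for k in range(m)]
    return SubTileModel(sites, weights, labels, bic={}, feature=str(feature))


def _swap_consistency(gm, feature, n_alpha):
    """Spin-swap structure of a 2-component mixture fit.

    ``swap`` exchanges alpha and beta roles in the feature space.  Returns
    ||m1 - swap(m2)|| / ||m1 - swap(m1)||: below 1 the components are each
    other's swap images (a genuine spin-split pair of sub-tiles), at or
    above 1 each component is essentially its own swap image (e.g. a
    breathing-mode split of an anharmonic single hump).  None when the
    feature space has no well-defined swap.
    """
    m1, m2 = gm.means_
    if feature is None or feature == "all":
        n = len(m1) // 3
        perm = np.r_[np.arange(n_alpha, n), np.arange(n_alpha)]
        cols = (perm[:, None] * 3 + np.arange(3)).ravel()
    else:
        feature = list(feature)
        if not (feature and isinstance(feature[0], (tuple, list))):
            return None
        pairs = [(int(e), int(ax)) for e, ax in feature]
        if len(pairs) == 2 and pairs[0][1] == pairs[1][1] and \
                (pairs[0][0] < n_alpha) != (pairs[1][0] < n_alpha):
            # one alpha + one beta coordinate (a bond pair): the swap
            # exchanges the two features
            cols = np.array([1, 0])
        else:
            return None
    sep = np.linalg.norm(m1 - m2)
    if sep < 1e-12:
        return 0.0
    cross = np.linalg.norm(m1 - m2[cols])       # comp2's swap image vs comp1
    self1 = np.linalg.norm(m1 - m1[cols])       # comp1 vs its own swap image
    # < 1: the components are each other's swap images (spin-split pair);
    # >= 1: each component is its own swap image (e.g. a breathing split)
    return float(cross / max(self1, 1e-12))


def _spin_swap_symmetric(wf) -> bool:
    """True when exchanging all alpha and beta positions leaves Psi
    unchanged (equal spin counts, swap-closed determinant list)."""
    if wf.n_alpha != wf.n_beta:
        return False
    detset = {(d.alpha, d.beta) for d in wf.determinants}
    return all((b, a) in detset for (a, b) in detset)


def _swap_spins(positions, na):
    return np.concatenate([positions[na:], positions[:na]])


# a converged site further than this (per electron, bohr) from its aligned
# spin-swapped/mirrored image is treated as a spontaneously localised
# sub-tile
BROKEN_SYMMETRY_THRESHOLD = 0.5
# ... provided the straight path between the two sites crosses a density
# valley at least this deep (two humps need a dip between them; a flat
# degenerate direction, e.g. uncorrelated alpha/beta lone-pair orientations
# in a closed-shell tile, does not)
BARRIER_FACTOR = 4.0


def _density_barrier(wf, pos1, pos2, sign, factor=BARRIER_FACTOR, npts=33,
                     moved=None):
    """True when Psi^2 dips by > ``factor`` (or changes sign) between two
    site configurations.

    Only the electrons in ``moved`` (default: all) are interpolated; the
    rest stay at ``pos1``.  Restricting the path to the correlated pair
    avoids spurious Pauli zeros from uninvolved like-spin electrons
    crossing on the straight line.
    """
    t = np.linspace(0.0, 1.0, npts)[:, None, None]
    if moved is None:
        configs = (1.0 - t) * pos1[None] + t * pos2[None]
    else:
        configs = np.broadcast_to(pos1, (npts,) + pos1.shape).copy()
        configs[:, moved, :] = ((1.0 - t) * pos1[None]
                                + t * pos2[None])[:, moved, :]
    s, l = wf.amplitude_signlog(configs)
    if np.any(s[1:-1] != sign):
        return True
    end = min(l[0], l[-1])
    return bool(l[1:-1].min() < end - 0.5 * np.log(factor))
# atoms within this distance (bohr) of their best-fit plane count as planar
PLANARITY_TOLERANCE = 0.05


def _molecular_plane(geometry):
    """(point, normal) of the best-fit atomic plane, or None if non-planar."""
    xyz = geometry.coords
    c = xyz.mean(axis=0)
    if len(xyz) < 3:
        return None
    u, s, vt = np.linalg.svd(xyz - c, full_matrices=False)
    # genuinely planar, not linear: a linear molecule's mirror images are
    # mere reorientations, not sub-tiles
    if s[-1] > PLANARITY_TOLERANCE * max(1.0, s[0]) or \
            s[-2] <= PLANARITY_TOLERANCE * max(1.0, s[0]):
        return None
    return c, vt[-1]


def mirror_image_site(wf, site, plane_point, plane_normal):
    """The reflection-partner sub-tile site of a localised site.

    Reflecting a configuration through a molecular symmetry plane maps
    Psi -> +/-Psi; composing with a like-spin relabelling of matching
    parity restores the tile's sign, so the mirrored site is a same-sign
    structure.  Returns the aligned mirrored VoronoiSite and the alignment
    residual (bohr, max per electron) between the original site and its
    image -- ~0 when the site is itself mirror symmetric.
    """
    from .permutations import _best_parity_assignment, _spin_cost
    n = plane_normal / np.linalg.norm(plane_normal)
    y = site.positions - 2.0 * ((site.positions - plane_point) @ n)[:, None] * n
    s_ref, _ = wf.amplitude_signlog(y)
    if s_ref == 0:
        return None, float("inf")
    # parity of the relabelling must cancel the reflection's sign factor
    parity = 1 if int(s_ref) == site.sign else -1
    na, nb = site.n_alpha, site.n_beta
    Ca = _spin_cost(y, site.positions, 0, na).T
    Cb = _spin_cost(y, site.positions, na, na + nb).T
    try:
        pa, pb, _ = _best_parity_assignment(Ca, Cb, parity)
    except ValueError:
        return None, float("inf")
    perm = np.concatenate([pa, na + pb]).astype(int)
    aligned = y[perm]
    resid = float(np.linalg.norm(aligned - site.positions, axis=1).max())
    mirrored = VoronoiSite(aligned, na, nb, site.sign)
    s_chk, _ = wf.amplitude_signlog(aligned)
    if int(s_chk) != site.sign:
        return None, float("inf")
    return mirrored, resid


def run_dvms_with_subtiles(wf, config: SamplerConfig, sites0=None,
                           feature=None, harvest_sweeps=40,
                           polish_fraction=0.5, selection_points=None):
    """Full pipeline: converge one site, test bimodality, split and polish.

    Returns (SubTileModel, samples, diagnostics).  When the EM/BIC selector
    chooses two components, the cloud is split and DVMS re-run against the
    two-site Voronoi predicate so the sub-tiles become non-overlapping.

    For spin-swap-symmetric wavefunctions two safeguards apply: a site that
    has spontaneously localised far from its spin-swapped image is reported
    directly as a two-component model (the swapped image being the second
    sub-tile), and otherwise the site is spin-symmetrised and briefly
    re-converged before harvesting, so a cloud stuck in one hump is not
    mistaken for a unimodal tile.
    """
    from .sampler import match_site_labels
    from dataclasses import replace

    sites, cloud, diag = run_dvms(wf, config, sites0)
    na, nb = wf.n_alpha, wf.n_beta
    asym = float("nan")
    # spin-split humps require opposite-spin correlation, i.e. more than
    # one determinant: a closed-shell single-determinant Psi^2 factorises
    # over spins, so its spin-swap site asymmetry is always a flat
    # degenerate direction, never a bifurcation
    # detection examines the instantaneous (batch) site: a momentarily
    # localised cloud signals broken symmetry that the accumulated mean
    # washes out
    batch = diag.batch_positions[0] if getattr(diag, "batch_positions",
                                               None) else sites[0].positions
    swap_symmetric = _spin_swap_symmetric(wf) and len(wf.determinants) > 1
    if len(sites) == 1 and swap_symmetric:
        # symmetrise the stable accumulated site (a spontaneously
        # localised site would hide the second hump) and harvest by free
        # same-sign sampling folded into the symmetric cell: exact for the
        # tile distribution and free of boundary hysteresis in the slow
        # bond-exchange coordinate
        acc = sites[0].positions
        swapped = _swap_spins(acc, na)
        aligned, _ = match_site_labels(acc, swapped, na, nb)
        asym = float(np.linalg.norm(acc - aligned, axis=1).max())
        sym_pos = 0.5 * (acc + aligned)
        sites = [VoronoiSite(sym_pos, na, nb, sites[0].sign)]
        # re-equilibrate a fresh cloud in the frozen symmetric cell: it
        # cannot re-localise, so both humps stay reachable for detection
        from .sampler import initialize_walkers, metropolis_sweep
        sym_cfg = replace(config, seed=config.seed + 2)
        rng_sym = np.random.default_rng(sym_cfg.seed)
        cloud = initialize_walkers(wf, sites, sym_cfg, rng_sym)
        step = diag.step_size or config.step_size
        for _ in range(2 * config.burn_in_sweeps):
            metropolis_sweep(cloud, wf, sites, step, rng_sym,
                             config.fold_policy)
    if len(sites) == 1 and wf.n_alpha != wf.n_beta:
        # spontaneously mirror-broken site of a planar open-shell radical
        # (the out-of-plane unpaired electron of e.g. methyl)
        plane = _molecular_plane(wf.geometry)
        if plane is not None:
            batch_site = VoronoiSite(batch, na, nb, sites[0].sign)
            mirrored, resid = mirror_image_site(wf, batch_site, *plane)
            trigger = False
            if mirrored is not None and resid > BROKEN_SYMMETRY_THRESHOLD:
                # unlike the spin-swap case no pair-count guard applies:
                # mirroring an open-shell site legitimately moves the spin
                # density's companion electrons too; the nodal barrier is
                # the discriminator
                d_m = np.linalg.norm(batch - mirrored.positions, axis=1)
                path_m = np.where(d_m > 0.25)[0]
                trigger = _density_barrier(
                    wf, batch, mirrored.positions,
                    sites[0].sign, moved=path_m)
            if trigger:
                asym = resid
                pair = [batch_site, mirrored]
                polish_cfg = replace(
                    config,
                    max_sweeps=max(200,
                                   int(config.max_sweeps * polish_fraction)),
                    init_jitter=0.25, seed=config.seed + 1)
                sites2, cloud2, diag2 = run_dvms(wf, polish_cfg, pair)
                samples2, owners2 = sample_tile(
                    wf, sites2, cloud2, polish_cfg, harvest_sweeps,
                    np.random.default_rng(config.seed + 13))
                weights = np.array([(owners2 == m).mean()
                                    for m in range(len(sites2))])
                model = SubTileModel(sites2, weights, owners2, bic={},
                                     feature=str(feature),
                                     method="broken-symmetry",
                                     asymmetry=resid)
                return model, samples2, diag2
    rng = np.random.default_rng(config.seed + 104729)
    samples, owners = sample_tile(wf, sites, cloud, config,
                                  harvest_sweeps, rng)
    if callable(feature):             # e.g. bond-pair indices from the site
        feature = feature(sites[0])
    if feature is None and len(wf.determinants) == 1 \
            and _spin_swap_symmetric(wf):
        # no opposite-spin correlation -> no spin-split humps; the full-3N
        # mixture fit of a large cloud would only read its anharmonicity
        model = SubTileModel([sites[0]], np.ones(1),
                             np.zeros(len(samples), int), bic={},
                             feature="none (single-determinant "
                                     "closed shell)", asymmetry=asym)
        return model, samples, diag
    sel_kw = {}
    if selection_points:
        sel_kw["max_points"] = selection_points
    det_samples = samples
    bond_pair = (swap_symmetric and isinstance(feature, (list, tuple))
                 and len(feature) == 2
                 and isinstance(feature[0], (tuple, list))
                 and (feature[0][0] < na) != (feature[1][0] < na))
    if bond_pair:
        # exchanging the alpha/beta bond electrons is a symmetry of the
        # tile family; augmenting with swapped copies guarantees both
        # humps enter detection with equal weight however unevenly the
        # finite cloud covered them
        e1, e2 = int(feature[0][0]), int(feature[1][0])
        sw = samples.copy()
        sw[:, [e1, e2]] = sw[:, [e2, e1]]
        det_samples = np.concatenate([samples, sw])
    m_sel, scores = select_component_count(det_samples, feature=feature,
                                           seed=config.seed, **sel_kw)
    if m_sel == 2 and swap_symmetric:
        # genuine sub-tiles of a spin-swap-symmetric tile are each other's
        # alpha<->beta images; a split violating that is anharmonic shape,
        # not bifurcation
        ratio = _swap_consistency(scores["models"][2], feature, na)
        scores["swap_ratio"] = ratio
        if ratio is not None and ratio > 1.0:
            m_sel = 1
    if m_sel == 1:
        model = SubTileModel([sites[0]], np.ones(1),
                             np.zeros(len(samples), int),
                             bic=scores["bic"], feature=str(feature),
                             separation=scores["separation"],
                             asymmetry=asym)
        return model, samples, diag
    split = split_sites(det_samples, wf.n_alpha, wf.n_beta, sites[0].sign,
                        feature=feature, seed=config.seed)
    split.separation = scores["separation"]
    split.asymmetry = asym
    if split.degenerate_split:
        split.bic = scores["bic"]
        return split, samples, diag
    # polish with the two-site predicate
    polish_cfg = replace(
        config,
        max_sweeps=max(200, int(config.max_sweeps * polish_fraction)),
        init_jitter=0.25,        # tight re-seeding: do not cross basins
        seed=config.seed + 1)
    sites2, cloud2, diag2 = run_dvms(wf, polish_cfg, split.sites)
    samples2, owners2 = sample_tile(wf, sites2, cloud2, polish_cfg,
                                    harvest_sweeps,
                                    np.random.default_rng(config.seed + 13))
    weights = np.array([(owners2 == k).mean() for k in range(len(sites2))])
    model = SubTileModel(sites2, weights, owners2, bic=scores["bic"],
                         feature=str(feature),
                         separation=scores["separation"], asymmetry=asym)
    return model, samples2, diag2
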