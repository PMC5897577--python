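"""Dynamic Voronoi Metropolis Sampling.

A cloud of 3N-dimensional walkers samples Psi^2 by plain Metropolis moves
while confined to one wavefunction tile: each walker must stay closer to the
site x-bar (the average walker position) than to any same-sign permuted
image of it.  Sites and tile boundaries are converged self-consistently by
alternating Metropolis sweeps with site updates; the site estimates the
centroid integral  x-bar = Int x psi_0^2 dx / Int psi_0^2 dx  because the
confined walkers are Psi^2-distributed over the tile.

Proposals that leave the cell are folded back by the inverse nearest-image
permutation (measure-preserving, since Psi^2 is permutation invariant);
proposals whose amplitude sign differs from the tile's reference sign are
rejected, which pins the node-delineated boundaries between opposite-sign
tiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._lap import resolve_batch
from .permutations import (
    _best_even_assignment, _spin_cost, apply_permutation, fold_into_tile,
    in_tile, nearest_same_sign_image,
)
from .wavefunction import CIWavefunction

__all__ = [
    "VoronoiSite", "WalkerCloud", "SamplerConfig", "ConvergenceDiagnostics",
    "SiteStarvationError", "initialize_walkers", "metropolis_sweep",
    "update_sites", "run_dvms", "sample_tile", "site_uncertainty",
    "match_site_labels",
]

log = logging.getLogger(__name__)


class SiteStarvationError(RuntimeError):
    """A Voronoi site owns no walkers."""


@dataclass
class VoronoiSite:
    """A 3N-dimensional Voronoi site x-bar defining one (sub-)tile."""

    positions: np.ndarray        # (N, 3) bohr
    n_alpha: int
    n_beta: int
    sign: int = 1

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        if len(self.positions) != self.n_alpha + self.n_beta:
            raise ValueError("site size does not match spin layout")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite site")
        if self.sign not in (-1, 1):
            raise ValueError("site sign must be +1 or -1")

    def electron_positions(self) -> np.ndarray:
        return self.positions


@dataclass
class WalkerCloud:
    """Metropolis walkers with cached amplitudes and tile ownership."""

    positions: np.ndarray        # (W, N, 3)
    log_psi: np.ndarray          # (W,)
    sign: np.ndarray             # (W,)
    owner: np.ndarray            # (W,) site index
    n_alpha: int
    n_beta: int

    @property
    def size(self) -> int:
        return len(self.positions)


@dataclass
class SamplerConfig:
    n_walkers: int = 1000
    step_size: float = 0.35               # bohr, per coordinate
    burn_in_sweeps: int = 80
    sweeps_per_iteration: int = 100
    max_sweeps: int = 5000
    drift_tolerance: float = 0.02         # bohr, max per-electron site drift
    patience: int = 5
    seed: int = 0
    fold_policy: str = "fold"             # fold | reject
    autotune_step: bool = True
    target_acceptance: tuple = (0.4, 0.6)
    init_jitter: float = 0.75             # bohr, walker seeding spread

    def __post_init__(self):
        if self.n_walkers < 1 or self.sweeps_per_iteration < 1:
            raise ValueError("counts must be >= 1")
        if self.step_size <= 0 or self.drift_tolerance <= 0:
            raise ValueError("step size and tolerance must be positive")
        if self.fold_policy not in ("fold", "reject"):
            raise ValueError("fold_policy must be 'fold' or 'reject'")


@dataclass
class ConvergenceDiagnostics:
    drift: list = field(default_factory=list)          # per outer iteration
    acceptance: list = field(default_factory=list)
    fold_fraction: list = field(default_factory=list)
    sweeps_total: int = 0
    outer_iterations: int = 0
    converged: bool = False
    step_size: float = 0.0
    # instantaneous (final-iteration batch) site positions: these reveal a
    # momentarily localised cloud that the accumulated mean averages out
    batch_positions: list = field(default_factory=list)


# --------------------------------------------------------------------------
# batched tile predicates
# --------------------------------------------------------------------------

def _site_array(sites):
    return np.stack([s.positions for s in sites])


def _batch_costs(X, site, na, nb):
    """Identity cost and per-spin assignment lower bound for every walker."""
    da = X[:, :na, None, :] - site[None, None, :na, :]
    Ca = np.einsum("wijk,wijk->wij", da, da)
    db = X[:, na:, None, :] - site[None, None, na:, :]
    Cb = np.einsum("wijk,wijk->wij", db, db)
    ident = (np.einsum("wii->w", Ca) if na else 0.0) + \
            (np.einsum("wii->w", Cb) if nb else 0.0)
    lower = (Ca.min(axis=2).sum(axis=1) if na else 0.0) + \
            (Cb.min(axis=2).sum(axis=1) if nb else 0.0)
    return ident, lower


def _screen_in_tile(X, sites_arr, na, nb):
    """Vectorised sufficient test of tile membership.

    Returns (proved_inside, owner): where proved_inside is True, the
    identity image of sites_arr[owner] certainly achieves the global
    minimum; elsewhere the exact scalar path must decide.
    """
    M = len(sites_arr)
    idents = np.empty((M, len(X)))
    lowers = np.empty((M, len(X)))
    for m in range(M):
        idents[m], lowers[m] = _batch_costs(X, sites_arr[m], na, nb)
    id_best = idents.min(axis=0)
    owner = idents.argmin(axis=0)
    lb = lowers.min(axis=0)
    return id_best <= lb, owner


def _resolve_membership(X, sites_arr, na, nb):
    """Exact-or-verified tile membership for a batch.

    Fast screen first; survivors go through the compiled assignment
    resolver.  Returns (inside, owner, perms) with perms the relabelling
    that folds outside configurations into the tile (identity elsewhere);
    folded results are verified by the caller.
    """
    W = len(X)
    ok, owner = _screen_in_tile(X, sites_arr, na, nb)
    inside = ok.copy()
    perms = np.broadcast_to(np.arange(na + nb), (W, na + nb)).copy()
    fail = np.where(~ok)[0]
    if len(fail):
        ins2, own2, perms2 = resolve_batch(X[fail], np.asarray(sites_arr),
                                           na)
        inside[fail] = ins2
        owner[fail] = own2
        perms[fail] = perms2
    return inside, owner, perms


# --------------------------------------------------------------------------
# sampler operations
# --------------------------------------------------------------------------

def _heuristic_site(wf: CIWavefunction, rng) -> VoronoiSite:
    """Seed a site by nuclear-charge-weighted electron placement with spin
    alternation, jittered until the amplitude is nonzero."""
    geom = wf.geometry
    z = geom.numbers.astype(int)
    order = np.argsort(-z)
    slots = []                      # (atom index) per electron, heavy first
    remaining = z.copy()
    while remaining.sum() > 0:
        for ai in order:
            if remaining[ai] > 0:
                slots.append(ai)
                remaining[ai] -= 1
    # ions: surplus electrons go to the heaviest atom, missing ones come
    # off the tail of the round-robin list
    while len(slots) < wf.n_electrons:
        slots.append(int(order[0]))
    slots = slots[: wf.n_electrons]
    # interleave: even positions alpha, odd beta, then patch counts
    alpha, beta = slots[0::2], slots[1::2]
    while len(alpha) > wf.n_alpha:
        beta.append(alpha.pop())
    while len(alpha) < wf.n_alpha:
        alpha.append(beta.pop())
    atoms = np.array(alpha + beta)
    base = geom.coords[atoms]
    for _ in range(200):
        pos = base + 0.4 * rng.standard_normal(base.shape)
        s, _ = wf.amplitude_signlog(pos)
        if s != 0:
            return VoronoiSite(pos, wf.n_alpha, wf.n_beta, int(s))
    raise RuntimeError("could not seed a nonzero-amplitude site")


def _fold_positions(X, perms):
    """Relabel each configuration: y[k, perms[k, i]] = X[k, i]."""
    y = np.empty_like(X)
    rows = np.arange(len(X))[:, None]
    y[rows, perms] = X
    return y


def initialize_walkers(wf: CIWavefunction, sites, config: SamplerConfig,
                       rng) -> WalkerCloud:
    """Walkers seeded around the sites and folded into the tile."""
    na, nb = wf.n_alpha, wf.n_beta
    W = config.n_walkers
    M = len(sites)
    base = np.stack([sites[m % M].positions for m in range(W)])
    X = base + config.init_jitter * rng.standard_normal(base.shape)
    sites_arr = _site_array(sites)
    ref_sign = sites[0].sign
    sign = np.zeros(W)
    log_psi = np.full(W, -np.inf)
    owner = np.zeros(W, dtype=int)
    good = np.zeros(W, dtype=bool)
    for attempt in range(200):
        bad = np.where(~good)[0]
        if len(bad) == 0:
            break
        if attempt:
            X[bad] = (base[bad] + config.init_jitter
                      * rng.standard_normal(X[bad].shape))
        inside, own, perms = _resolve_membership(X[bad], sites_arr, na, nb)
        folded = _fold_positions(X[bad], perms)
        ins2, own2, _ = _resolve_membership(folded[~inside], sites_arr,
                                            na, nb)
        X[bad] = np.where(inside[:, None, None], X[bad], folded)
        own[~inside] = own2
        settled = inside.copy()
        settled[~inside] = ins2
        s, l = wf.amplitude_signlog(X[bad])
        ok = settled & (s == ref_sign)
        sign[bad], log_psi[bad], owner[bad] = s, l, own
        good[bad] = ok
    else:
        raise RuntimeError("failed to seed walkers with the tile's sign")
    return WalkerCloud(X, log_psi, sign, owner, na, nb)


def metropolis_sweep(cloud: WalkerCloud, wf: CIWavefunction, sites,
                     step: float, rng, fold_policy="fold"):
    """One all-coordinate Gaussian Metropolis sweep restricted to the tile.

    Returns (acceptance fraction, fold fraction).  Detailed balance with
    respect to Psi^2 on the tile: symmetric proposals, sign-flip rejection,
    measure-preserving folds.
    """
    na, nb = cloud.n_alpha, cloud.n_beta
    W = cloud.size
    sites_arr = _site_array(sites)
    ref_sign = sites[0].sign
    prop = cloud.positions + step * rng.standard_normal(cloud.positions.shape)
    s_p, l_p = wf.amplitude_signlog(prop)
    valid = s_p == ref_sign
    owner_p = np.zeros(W, dtype=int)
    folded = 0
    idx = np.where(valid)[0]
    if len(idx):
        inside, own, perms = _resolve_membership(prop[idx], sites_arr,
                                                 na, nb)
        owner_p[idx] = own
        out = np.where(~inside)[0]
        if len(out) and fold_policy == "fold":
            y = _fold_positions(prop[idx[out]], perms[out])
            # verify folds (the compiled parity repair is not certified
            # optimal); a failed fold becomes a rejection
            ins2, own2, _ = _resolve_membership(y, sites_arr, na, nb)
            ok2 = np.where(ins2)[0]
            w_ok = idx[out[ok2]]
            prop[w_ok] = y[ok2]
            owner_p[w_ok] = own2[ok2]
            valid[idx[out[~ins2]]] = False
            folded = len(ok2)
        elif len(out):
            valid[idx[out]] = False
    with np.errstate(invalid="ignore"):
        log_ratio = 2.0 * (l_p - cloud.log_psi)
    log_ratio[~np.isfinite(cloud.log_psi)] = np.inf
    accept = valid & (np.log(rng.random(W)) < log_ratio)
    cloud.positions[accept] = prop[accept]
    cloud.log_psi[accept] = l_p[accept]
    cloud.sign[accept] = s_p[accept]
    cloud.owner[accept] = owner_p[accept]
    return float(accept.mean()), folded / max(1, W)


def update_sites(cloud: WalkerCloud, sites, position_sums=None, counts=None):
    """New sites from the unweighted mean of owned walker coordinates.

    With ``position_sums``/``counts`` (accumulated over several sweeps), the
    batch mean over the whole iteration is used instead of the instantaneous
    cloud.
    """
    M = len(sites)
    if position_sums is None:
        position_sums = np.zeros((M,) + cloud.positions.shape[1:])
        counts = np.zeros(M)
        for m in range(M):
            mask = cloud.owner == m
            position_sums[m] = cloud.positions[mask].sum(axis=0)
            counts[m] = mask.sum()
    out = []
    for m in range(M):
        if counts[m] == 0:
            raise SiteStarvationError(f"site {m} owns no walkers")
        out.append(VoronoiSite(position_sums[m] / counts[m],
                               cloud.n_alpha, cloud.n_beta, sites[m].sign))
    return out


def run_dvms(wf: CIWavefunction, config: SamplerConfig, sites0=None):
    """Self-consistent DVMS: returns (sites, cloud, diagnostics).

    Alternates blocks of Metropolis sweeps with batch site updates until the
    largest per-electron site drift stays below ``drift_tolerance`` for
    ``patience`` consecutive updates, or the sweep budget is exhausted
    (flagged non-converged, not raised).  Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if sites0 is None:
        sites = [_heuristic_site(wf, rng)]
    else:
        sites = [s for s in sites0]
    # reference sign consistency
    for s in sites:
        amp_sign, _ = wf.amplitude_signlog(s.positions)
        if amp_sign != 0:
            s.sign = int(amp_sign)
    sign0 = sites[0].sign
    for s in sites:
        s.sign = sign0
    cloud = initialize_walkers(wf, sites, config, rng)
    diag = ConvergenceDiagnostics()
    step = config.step_size
    # burn-in with step autotuning
    for sweep in range(config.burn_in_sweeps):
        acc, _ = metropolis_sweep(cloud, wf, sites, step, rng,
                                  config.fold_policy)
        diag.sweeps_total += 1
        if config.autotune_step and sweep % 5 == 4:
            lo, hi = config.target_acceptance
            if acc < lo:
                step *= 0.8
            elif acc > hi:
                step *= 1.25
        if sweep % 10 == 9:
            try:
                sites = update_sites(cloud, sites)
            except SiteStarvationError:
                pass
    diag.step_size = step
    streak = 0
    # the site estimates the centroid integral, so it accumulates over all
    # post-burn-in sweeps; the accumulator resets for a site whose batch
    # mean departs from the accumulated mean (a genuine structural shift,
    # not sampling noise)
    acc_sums = None
    acc_counts = None
    RESET_DISTANCE = 0.3        # bohr, per electron
    SETTLE_ITERATIONS = 2       # early iterations excluded: still relaxing
    while diag.sweeps_total < config.max_sweeps:
        M = len(sites)
        pos_sums = np.zeros((M,) + cloud.positions.shape[1:])
        counts = np.zeros(M)
        acc_sum = fold_sum = 0.0
        for _ in range(config.sweeps_per_iteration):
            acc, ff = metropolis_sweep(cloud, wf, sites, step, rng,
                                       config.fold_policy)
            acc_sum += acc
            fold_sum += ff
            diag.sweeps_total += 1
            for m in range(M):
                mask = cloud.owner == m
                pos_sums[m] += cloud.positions[mask].sum(axis=0)
                counts[m] += mask.sum()
        if (counts == 0).any() and M > 1:
            # sub-tile merge: a starved site's region is covered by the rest
            keep = counts > 0
            log.warning("dropping %d starved site(s)", int((~keep).sum()))
            sites = [s for s, k in zip(sites, keep) if k]
            remap = np.cumsum(keep) - 1
            cloud.owner = remap[cloud.owner]
            acc_sums = acc_counts = None
            streak = 0
            continue
        if counts.min() == 0:
            raise SiteStarvationError("site owns no walkers")
        if diag.outer_iterations < SETTLE_ITERATIONS:
            # batch update while the structure still relaxes
            acc_sums = pos_sums.copy()
            acc_counts = counts.copy()
        elif acc_sums is None:
            acc_sums = pos_sums.copy()
            acc_counts = counts.copy()
        else:
            batch = pos_sums / counts[:, None, None]
            running = acc_sums / acc_counts[:, None, None]
            for m in range(M):
                if np.linalg.norm(batch[m] - running[m],
                                  axis=1).max() > RESET_DISTANCE:
                    acc_sums[m] = pos_sums[m]
                    acc_counts[m] = counts[m]
                else:
                    acc_sums[m] += pos_sums[m]
                    acc_counts[m] += counts[m]
        diag.batch_positions = [pos_sums[m] / counts[m] for m in range(M)]
        new_sites = [VoronoiSite(acc_sums[m] / acc_counts[m],
                                 cloud.n_alpha, cloud.n_beta, sites[m].sign)
                     for m in range(M)]
        drift = max(
            float(np.linalg.norm(n.positions - o.positions, axis=1).max())
            for n, o in zip(new_sites, sites))
        sites = new_sites
        diag.outer_iterations += 1
        diag.drift.append(drift)
        diag.acceptance.append(acc_sum / config.sweeps_per_iteration)
        diag.fold_fraction.append(fold_sum / config.sweeps_per_iteration)
        log.info("iter %d: drift %.4f bohr, acceptance %.2f",
                 diag.outer_iterations, drift, diag.acceptance[-1])
        streak = streak + 1 if drift < config.drift_tolerance else 0
        if streak >= config.patience:
            diag.converged = True
            break
    return sites, cloud, diag


def sample_tile(wf, sites, cloud, config, n_sweeps, rng=None):
    """Harvest Psi^2 samples from the converged tile.

    Returns (samples (W*n_sweeps, N, 3), owners (W*n_sweeps,)); sites are
    held fixed while sampling.
    """
    rng = np.random.default_rng(config.seed + 7919) if rng is None else rng
    step = config.step_size
    chunks, owners = [], []
    for _ in range(n_sweeps):
        metropolis_sweep(cloud, wf, sites, step, rng, config.fold_policy)
        chunks.append(cloud.positions.copy())
        owners.append(cloud.owner.copy())
    return np.concatenate(chunks), np.concatenate(owners)


def _free_sweep(cloud: WalkerCloud, wf, ref_sign, step, rng):
    """Metropolis sweep constrained only by the amplitude sign (no Voronoi
    cell): walkers sample the whole same-sign region."""
    prop = cloud.positions + step * rng.standard_normal(cloud.positions.shape)
    s_p, l_p = wf.amplitude_signlog(prop)
    valid = s_p == ref_sign
    with np.errstate(invalid="ignore"):
        log_ratio = 2.0 * (l_p - cloud.log_psi)
    log_ratio[~np.isfinite(cloud.log_psi)] = np.inf
    accept = valid & (np.log(rng.random(cloud.size)) < log_ratio)
    cloud.positions[accept] = prop[accept]
    cloud.log_psi[accept] = l_p[accept]
    cloud.sign[accept] = s_p[accept]
    return float(accept.mean())


def sample_tile_folded(wf, site, config, n_sweeps, rng=None,
                       equilibration=None):
    """Harvest tile samples by free same-sign Psi^2 sampling + exact folds.

    Tiles tessellate the same-sign region, and folding by the nearest
    same-sign image is measure preserving, so folding every unconfined
    sample into ``site``'s cell reproduces the tile-restricted
    distribution exactly -- with far better mixing than cell-confined
    dynamics (no boundary hysteresis in slowly-exchanging coordinates).
    """
    rng = np.random.default_rng(config.seed + 7919) if rng is None else rng
    na, nb = site.n_alpha, site.n_beta
    cloud = initialize_walkers(wf, [site], config, rng)
    step = config.step_size
    equilibration = (2 * config.burn_in_sweeps if equilibration is None
                     else equilibration)
    for _ in range(equilibration):
        _free_sweep(cloud, wf, site.sign, step, rng)
    chunks = []
    for _ in range(n_sweeps):
        _free_sweep(cloud, wf, site.sign, step, rng)
        chunks.append(cloud.positions.copy())
    raw = np.concatenate(chunks)
    sites_arr = np.asarray([site.positions])
    folded = raw.copy()
    # iterate folds: the compiled parity repair is near-exact; one or two
    # rounds land essentially every sample in the cell
    for _ in range(3):
        inside, _, perms = _resolve_membership(folded, sites_arr, na, nb)
        out = np.where(~inside)[0]
        if len(out) == 0:
            break
        folded[out] = _fold_positions(folded[out], perms[out])
    return folded


# --------------------------------------------------------------------------
# cross-run statistics
# --------------------------------------------------------------------------

def match_site_labels(reference: np.ndarray, other: np.ndarray,
                      n_alpha: int, n_beta: int):
    """Even relabelling of ``other`` minimising distance to ``reference``.

    Returns (relabelled copy, SpinPermutation).  The relabelling is itself a
    same-sign permutation, so it leaves Psi at the site unchanged.
    """
    Ca = _spin_cost(other, reference, 0, n_alpha).T
    Cb = _spin_cost(other, reference, n_alpha, n_alpha + n_beta).T
    pa, pb, _ = _best_even_assignment(Ca, Cb)
    perm = np.concatenate([pa, n_alpha + pb]).astype(int)
    from .permutations import SpinPermutation
    sp = SpinPermutation(tuple(pa), tuple(pb))
    return other[perm].copy(), sp


def site_uncertainty(site_runs, n_alpha, n_beta):
    """Component-wise standard error of the mean across independent runs.

    ``site_runs``: list of (N, 3) site position arrays from >= 2 runs,
    matched by optimal even relabelling against the first run.
    """
    if len(site_runs) < 2:
        raise ValueError("need >= 2 independent runs")
    ref = np.asarray(site_runs[0], float)
    aligned = [ref]
    for s in site_runs[1:]:
        m, _ = match_site_labels(ref, np.asarray(s, float), n_alpha, n_beta)
        aligned.append(m)
    stack = np.stack(aligned)
    return stack.std(axis=0, ddof=1) / np.sqrt(len(aligned)), stack.mean(axis=0)
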