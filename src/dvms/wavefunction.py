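"""Multi-determinant electronic wavefunctions and their pointwise evaluation.

The central object is :class:`CIWavefunction`: a molecular geometry, a
contracted Gaussian basis, a molecular-orbital coefficient matrix and a short
configuration-interaction expansion

    Psi(x) = sum_k c_k det(A_k^alpha) det(A_k^beta),

where ``A_k^sigma`` is the Slater matrix of occupied sigma-spin orbital values
at the sigma-spin electron positions of the 3N-dimensional configuration
``x``.  Everything here works in bohr; conversion to/from Angstrom happens at
the I/O boundary.

Electron configurations are plain ``(N, 3)`` float arrays (batches:
``(W, N, 3)``); by convention the first ``n_alpha`` rows are alpha-spin
electrons and the remainder beta-spin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .units import BOHR_PER_ANGSTROM, ANGSTROM_PER_BOHR

__all__ = [
    "ELEMENT_NUMBERS",
    "Geometry",
    "BasisShell",
    "Determinant",
    "CIWavefunction",
    "cartesian_components",
    "evaluate_basis",
    "evaluate_amplitude",
    "density",
]

ELEMENT_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}
ELEMENT_SYMBOLS = {z: s for s, z in ELEMENT_NUMBERS.items()}

MAX_ANGULAR_MOMENTUM = 3  # s, p, d, f

# Amplitudes with |Psi| below this are treated as exact zeros for sign logic,
# keeping sign decisions out of the denormal range.
AMPLITUDE_ZERO_THRESHOLD = 1e-300
LOG_ZERO_THRESHOLD = math.log(AMPLITUDE_ZERO_THRESHOLD)


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass
class Geometry:
    """Nuclear frame: element symbols, charges and positions in bohr."""

    symbols: list
    coords: np.ndarray          # (n_atoms, 3) bohr
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) != len(self.coords):
            raise ValueError("symbol/coordinate count mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite nuclear coordinates")
        if any(z < 1 for z in self.numbers):
            raise ValueError("atomic number must be >= 1")
        if self.n_electrons < 1:
            raise ValueError("geometry carries no electrons")

    @property
    def numbers(self) -> np.ndarray:
        return np.array([ELEMENT_NUMBERS[s] for s in self.symbols], dtype=int)

    @property
    def n_electrons(self) -> int:
        return int(self.numbers.sum()) - self.charge

    @classmethod
    def from_angstrom(cls, symbols, coords_angstrom, charge=0, multiplicity=1):
        coords = np.asarray(coords_angstrom, float) * BOHR_PER_ANGSTROM
        return cls(list(symbols), coords, charge, multiplicity)

    def coords_angstrom(self) -> np.ndarray:
        return self.coords * ANGSTROM_PER_BOHR

    def nuclear_repulsion(self) -> float:
        e = 0.0
        z = self.numbers
        for i in range(len(z)):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(self.coords[i] - self.coords[j])
        return e


# --------------------------------------------------------------------------
# basis shells
# --------------------------------------------------------------------------

@dataclass
class BasisShell:
    """One contracted Cartesian Gaussian shell on an atomic center.

    ``exponents`` are in bohr^-2; ``coefficients`` multiply individually
    normalised Cartesian primitives.  A contraction normalisation is applied
    on top so every contracted component has unit norm.
    """

    center: int
    l: int
    exponents: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        self.exponents = np.atleast_1d(np.asarray(self.exponents, float))
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, float))
        if self.l < 0 or self.l > MAX_ANGULAR_MOMENTUM:
            raise NotImplementedError(
                f"angular momentum l={self.l} unsupported (max l=3)")
        if len(self.exponents) == 0 or len(self.exponents) != len(self.coefficients):
            raise ValueError("shell needs matching, non-empty primitive lists")
        if np.any(self.exponents <= 0):
            raise ValueError("primitive exponents must be positive")

    @property
    def n_cartesian(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


_DFACT = [1.0, 1.0, 3.0, 15.0, 105.0]  # (2n-1)!! for n = 0..4


def _double_factorial(n: int) -> float:
    # (2n-1)!!
    return _DFACT[n] if n < len(_DFACT) else _DFACT[-1] * math.prod(
        range(2 * len(_DFACT) - 1, 2 * n, 2))


def cartesian_components(l: int):
    """Monomial powers (i, j, k) of an l-shell, in lexicographic order.

    s: (000); p: x, y, z; d: xx, xy, xz, yy, yz, zz; f: xxx ... zzz.
    """
    return [(i, j, l - i - j) for i in range(l, -1, -1) for j in range(l - i, -1, -1)]


def primitive_norm(a: float, l: int) -> float:
    """Norm of the pure-power primitive x^l exp(-a r^2); component-specific
    double-factorial factors are applied separately."""
    return (2.0 * a / math.pi) ** 0.75 * (4.0 * a) ** (l / 2.0)


def shell_contraction_norm(shell: BasisShell) -> float:
    """Scale making each contracted component unit-normalised.

    The double-factorial factors of a component cancel between the primitive
    norms and the self-overlap, so one scalar serves the whole shell.
    """
    a = shell.exponents[:, None]
    b = shell.exponents[None, :]
    c = shell.coefficients
    na = primitive_norm(shell.exponents, shell.l)
    s = (np.outer(c * na, c * na)
         * (math.pi / (a + b)) ** 1.5 / (2.0 * (a + b)) ** shell.l)
    return 1.0 / math.sqrt(float(s.sum()))


def _component_norm_factors(l: int) -> np.ndarray:
    comps = cartesian_components(l)
    return np.array([
        1.0 / math.sqrt(_double_factorial(i) * _double_factorial(j)
                        * _double_factorial(k))
        for (i, j, k) in comps])


# Spherical (pure) d functions in terms of the 6 Cartesian d monomials
# (xx, xy, xz, yy, yz, zz); rows ordered m = -2, -1, 0, +1, +2.
_SPH_D_MONOMIAL = np.array([
    [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],      # xy
    [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],      # yz
    [-0.5, 0.0, 0.0, -0.5, 0.0, 1.0],    # (2z^2 - x^2 - y^2)/2
    [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],      # xz
    [0.5 * math.sqrt(3.0), 0.0, 0.0, -0.5 * math.sqrt(3.0), 0.0, 0.0],  # (x²-y²)√3/2
])


def _spherical_d_transform() -> np.ndarray:
    """(5, 6) matrix from unit-normalised Cartesian d components to
    unit-normalised real spherical d functions."""
    comps = cartesian_components(2)
    # overlap metric of degree-2 monomial Gaussians at reference exponent 1/2
    def mono_overlap(c1, c2):
        i, j, k = (c1[0] + c2[0], c1[1] + c2[1], c1[2] + c2[2])
        if i % 2 or j % 2 or k % 2:
            return 0.0
        return (_double_factorial(i // 2) * _double_factorial(j // 2)
                * _double_factorial(k // 2))
    metric = np.array([[mono_overlap(a, b) for b in comps] for a in comps])
    cart_norm = np.sqrt(np.diag(metric))
    out = np.zeros((5, 6))
    for m in range(5):
        v = _SPH_D_MONOMIAL[m]
        v = v / math.sqrt(v @ metric @ v)          # unit-norm combination
        out[m] = v * cart_norm                     # act on normalised cartesians
    return out


_SPH_D = _spherical_d_transform()


def n_basis_functions(shells, cartesian=True) -> int:
    n = 0
    for sh in shells:
        if cartesian or sh.l < 2:
            n += sh.n_cartesian
        elif sh.l == 2:
            n += 5
        else:
            raise NotImplementedError("spherical functions beyond d unsupported")
    return n


def evaluate_basis(shells, geometry: Geometry, points, cartesian=True) -> np.ndarray:
    """Values of every contracted basis function at ``points`` (bohr).

    Returns an array of shape ``points.shape[:-1] + (nbf,)``.  Contractions
    are primitive-summed; each Cartesian component is individually
    normalised.  With ``cartesian=False``, d shells are emitted as the five
    real spherical combinations (order m = -2..+2).
    """
    pts = np.asarray(points, float)
    lead = pts.shape[:-1]
    pts = pts.reshape(-1, 3)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite evaluation point")
    cols = []
    for sh in shells:
        d = pts - geometry.coords[sh.center]
        r2 = np.einsum("ij,ij->i", d, d)
        nc = shell_contraction_norm(sh)
        radial = np.zeros(len(pts))
        for a, c in zip(sh.exponents, sh.coefficients):
            radial += c * primitive_norm(a, sh.l) * np.exp(-a * r2)
        radial *= nc
        comps = cartesian_components(sh.l)
        factors = _component_norm_factors(sh.l)
        block = np.empty((len(pts), len(comps)))
        for ci, ((i, j, k), f) in enumerate(zip(comps, factors)):
            mono = np.ones(len(pts))
            if i: mono = mono * d[:, 0] ** i
            if j: mono = mono * d[:, 1] ** j
            if k: mono = mono * d[:, 2] ** k
            block[:, ci] = f * mono * radial
        if not cartesian and sh.l == 2:
            block = block @ _SPH_D.T
        elif not cartesian and sh.l > 2:
            raise NotImplementedError("spherical functions beyond d unsupported")
        cols.append(block)
    out = np.concatenate(cols, axis=1)
    return out.reshape(lead + (out.shape[-1],))


# --------------------------------------------------------------------------
# determinants and the CI wavefunction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Determinant:
    """Occupied orbital indices per spin, strictly increasing."""

    alpha: tuple
    beta: tuple

    def __post_init__(self):
        object.__setattr__(self, "alpha", tuple(int(i) for i in self.alpha))
        object.__setattr__(self, "beta", tuple(int(i) for i in self.beta))
        for occ in (self.alpha, self.beta):
            if any(b <= a for a, b in zip(occ, occ[1:])):
                raise ValueError("occupation lists must be strictly increasing")
            if any(i < 0 for i in occ):
                raise ValueError("negative orbital index")


@dataclass
class CIWavefunction:
    """A (possibly multi-determinant) electronic wavefunction Psi(x)."""

    geometry: Geometry
    shells: list
    mo_coefficients: np.ndarray          # (nbf, nmo), columns are orbitals
    determinants: list
    ci_coefficients: np.ndarray
    n_alpha: int
    n_beta: int
    cartesian: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mo_coefficients = np.asarray(self.mo_coefficients, float)
        self.ci_coefficients = np.asarray(self.ci_coefficients, float)
        if not np.all(np.isfinite(self.mo_coefficients)):
            raise ValueError("non-finite MO coefficients")
        if len(self.determinants) != len(self.ci_coefficients):
            raise ValueError("determinant/coefficient count mismatch")
        if len(self.determinants) == 0:
            raise ValueError("empty determinant expansion")
        norm = float(np.sum(self.ci_coefficients ** 2))
        if abs(norm - 1.0) > 1e-8:
            raise ValueError(f"CI coefficients not normalised (sum c^2 = {norm})")
        nmo = self.mo_coefficients.shape[1]
        for det in self.determinants:
            if len(det.alpha) != self.n_alpha or len(det.beta) != self.n_beta:
                raise ValueError("determinant occupation does not match spin layout")
            if det.alpha and max(det.alpha) >= nmo:
                raise ValueError("alpha occupation exceeds orbital count")
            if det.beta and max(det.beta) >= nmo:
                raise ValueError("beta occupation exceeds orbital count")
        if self.n_alpha + self.n_beta != self.geometry.n_electrons:
            raise ValueError("spin layout inconsistent with electron count")
        nbf = n_basis_functions(self.shells, self.cartesian)
        if self.mo_coefficients.shape[0] != nbf:
            raise ValueError(
                f"MO matrix has {self.mo_coefficients.shape[0]} rows, "
                f"basis has {nbf} functions")

    @property
    def n_electrons(self) -> int:
        return self.n_alpha + self.n_beta

    # -- evaluation --------------------------------------------------------

    def basis_values(self, points) -> np.ndarray:
        return evaluate_basis(self.shells, self.geometry, points, self.cartesian)

    def amplitude_signlog(self, configs) -> tuple:
        """Batched amplitude in (sign, log|Psi|) form.

        ``configs``: array (W, N, 3) or (N, 3), bohr.  Returns arrays
        ``(sign, logabs)`` of shape (W,); sign is 0 where Psi vanishes
        (logabs = -inf there).
        """
        x = np.asarray(configs, float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1] != self.n_electrons or x.shape[2] != 3:
            raise ValueError(
                f"configuration shape {x.shape[1:]} does not match "
                f"{self.n_electrons} electrons")
        bas = self.basis_values(x)          # (W, N, nbf)
        na = self.n_alpha
        signs = np.zeros(x.shape[0])
        logs = np.full(x.shape[0], -np.inf)
        # accumulate sum_k c_k s_k exp(l_k) with per-walker max-log factoring
        det_signs = []
        det_logs = []
        for det in self.determinants:
            s = np.ones(x.shape[0])
            l = np.zeros(x.shape[0])
            if na:
                A = bas[:, :na, :] @ self.mo_coefficients[:, list(det.alpha)]
                sa, la = np.linalg.slogdet(A)
                s, l = s * sa, l + la
            if self.n_beta:
                B = bas[:, na:, :] @ self.mo_coefficients[:, list(det.beta)]
                sb, lb = np.linalg.slogdet(B)
                s, l = s * sb, l + lb
            det_signs.append(s)
            det_logs.append(l)
        det_signs = np.array(det_signs)     # (K, W)
        det_logs = np.array(det_logs)
        with np.errstate(invalid="ignore"):
            lmax = det_logs.max(axis=0)
        ok = np.isfinite(lmax)
        if np.any(ok):
            contrib = (self.ci_coefficients[:, None] * det_signs[:, ok]
                       * np.exp(det_logs[:, ok] - lmax[ok]))
            total = contrib.sum(axis=0)
            nz = np.abs(total) > 0
            li = np.full(total.shape, -np.inf)
            li[nz] = lmax[ok][nz] + np.log(np.abs(total[nz]))
            si = np.sign(total)
            idx = np.where(ok)[0]
            logs[idx] = li
            signs[idx] = si
        # denormal guard
        dead = logs < LOG_ZERO_THRESHOLD
        signs[dead] = 0.0
        logs[dead] = -np.inf
        if not np.all(np.isfinite(logs[signs != 0])):
            raise FloatingPointError("non-finite amplitude")
        if single:
            return signs[0], logs[0]
        return signs, logs

    def amplitude_many(self, configs) -> np.ndarray:
        s, l = self.amplitude_signlog(configs)
        with np.errstate(over="raise"):
            return s * np.exp(np.where(np.isfinite(l), l, -np.inf))

    def amplitude(self, x) -> float:
        return float(self.amplitude_many(np.asarray(x, float)[None])[0])

    def density_many(self, configs) -> np.ndarray:
        return self.amplitude_many(configs) ** 2

    def density(self, x) -> float:
        return self.amplitude(x) ** 2


def evaluate_amplitude(wf: CIWavefunction, x) -> float:
    """Signed amplitude Psi(x) at a single 3N-dimensional configuration."""
    return wf.amplitude(x)


def density(wf: CIWavefunction, x) -> float:
    """Probability density Psi(x)^2; exactly zero on nodes."""
    return wf.density(x)
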