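"""Reaction-coordinate demonstration systems.

Synthetic reaction paths for the demonstration reactions: geometrically
interpolated frames between reactant-like and product-like structures
(stand-ins for steepest-descent reaction-path geometries, which this
package consumes but does not compute).  Each builder returns an ordered
list of Geometry frames; wavefunctions come from the engine adapter at the
levels used throughout (single determinant for the S_N2 displacement, two
configurations for nucleophilic carbonyl addition).
"""

from __future__ import annotations

import math

import numpy as np

from .fixtures import build_from_engine
from .wavefunction import Geometry

__all__ = ["sn2_path", "carbonyl_addition_path", "hf_dissociation_path",
           "sn2_wavefunctions", "carbonyl_addition_wavefunctions"]


def _lerp(a, b, t):
    return a + (b - a) * t


def sn2_path(n_frames=3) -> list:
    """FCH3 + OH- -> F- + CH3OH backside-attack frames (charge -1).

    Collinear F-C-O axis along z with Walden inversion of the methyl
    umbrella; C-F stretches 1.40 -> 3.20 A while C-O contracts
    2.60 -> 1.42 A.  A synthetic interpolated path, not a computed
    steepest-descent one.
    """
    frames = []
    for k in range(n_frames):
        t = k / (n_frames - 1) if n_frames > 1 else 0.0
        d_cf = _lerp(1.40, 3.20, t)
        d_co = _lerp(2.60, 1.42, t)
        # umbrella: H z-offset flips sign (inversion), r(CH) fixed
        z_h = _lerp(0.35, -0.38, t)
        r_h = math.sqrt(max(1.09 ** 2 - z_h ** 2, 0.3))
        atoms = [("F", [0.0, 0.0, -d_cf]), ("C", [0.0, 0.0, 0.0])]
        for j in range(3):
            th = 2.0 * math.pi * j / 3.0
            atoms.append(("H", [r_h * math.cos(th), r_h * math.sin(th), z_h]))
        # hydroxide: O on axis, its H tilted off-axis beyond O
        oh = 0.97
        ang = math.radians(105.0)
        atoms.append(("O", [0.0, 0.0, d_co]))
        atoms.append(("H", [oh * math.sin(ang), 0.0,
                            d_co + oh * math.cos(math.pi - ang)]))
        frames.append(Geometry.from_angstrom(
            [a for a, _ in atoms], [p for _, p in atoms], charge=-1))
    return frames


def sn2_wavefunctions(n_frames=3, basis_name="6-31g(d)"):
    """Single-determinant wavefunctions along the S_N2 path."""
    return [build_from_engine(g, basis_name, n_configs=1)
            for g in sn2_path(n_frames)]


def carbonyl_addition_path(n_frames=3) -> list:
    """H2CO + OH- -> H2C(OH)O- attack frames (charge -1).

    The hydroxide oxygen approaches the carbonyl carbon roughly along the
    obtuse attack angle while the C=O bond lengthens and the carbon
    pyramidalises.  Synthetic interpolated frames.
    """
    frames = []
    for k in range(n_frames):
        t = k / (n_frames - 1) if n_frames > 1 else 0.0
        d_co = _lerp(1.21, 1.33, t)          # carbonyl C=O
        d_cnu = _lerp(2.60, 1.45, t)         # C...O(H) forming bond
        pyr = _lerp(0.0, 0.45, t)            # carbon pyramidalisation (A)
        # formaldehyde in the xz plane, C at origin, O along +z
        atoms = [("C", [0.0, 0.0, 0.0]), ("O", [0.0, 0.0, d_co])]
        hx = 0.94
        hz = -0.54 + 0.10 * t
        atoms.append(("H", [hx, 0.0, hz]))
        atoms.append(("H", [-hx, 0.0, hz]))
        # nucleophile approaches from +y, tilted toward -z
        ang = math.radians(107.0)
        nu = np.array([0.0,
                       d_cnu * math.sin(ang),
                       -d_cnu * math.cos(ang)])
        atoms.append(("O", nu.tolist()))
        oh = 0.97
        atoms.append(("H", (nu + [0.0, oh * 0.45, -oh * 0.89]).tolist()))
        # pyramidalise: push C toward the nucleophile side
        atoms[0] = ("C", [0.0, pyr * 0.4, 0.0])
        frames.append(Geometry.from_angstrom(
            [a for a, _ in atoms], [p for _, p in atoms], charge=-1))
    return frames


def carbonyl_addition_wavefunctions(n_frames=3, basis_name="6-31g(d)",
                                    n_configs=2):
    """Two-configuration wavefunctions along the carbonyl addition path
    (frontier pi/pi* pair active)."""
    return [build_from_engine(g, basis_name, n_configs=n_configs)
            for g in carbonyl_addition_path(n_frames)]


def hf_dissociation_path(r_values=(0.91, 1.11, 1.31, 1.51)):
    """H-F bond-length scan geometries (Angstrom)."""
    return [Geometry.from_angstrom(["F", "H"], [[0, 0, 0], [0, 0, r]])
            for r in r_values]
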