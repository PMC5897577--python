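"""Wavefunction containers and structure file formats.

The self-describing container holds geometry (Angstrom), basis shells,
MO coefficients (rows = basis functions), the determinant expansion and
spin counts.  JSON for small systems and HDF5 for large ones; both
round-trip bit-exactly.  A Molden reader imports geometry/basis/orbitals
from other programs, with determinants supplied via a sidecar table.
"""

from __future__ import annotations

import json

import numpy as np

from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM
from .wavefunction import (
    BasisShell, CIWavefunction, Determinant, Geometry,
)

__all__ = [
    "save_wavefunction", "load_wavefunction", "read_xyz",
    "read_xyz_trajectory", "write_xyz", "read_molden", "write_molden",
]

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# container
# --------------------------------------------------------------------------

def _wf_to_dict(wf: CIWavefunction) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "units": "angstrom (geometry); basis exponents bohr^-2",
        "geometry": {
            "symbols": list(wf.geometry.symbols),
            "xyz_angstrom": wf.geometry.coords_angstrom().tolist(),
            "charge": wf.geometry.charge,
            "multiplicity": wf.geometry.multiplicity,
        },
        "basis": [{"center": int(sh.center), "l": int(sh.l),
                   "exponents": sh.exponents.tolist(),
                   "coefficients": sh.coefficients.tolist()}
                  for sh in wf.shells],
        "orbitals": {"coefficients": wf.mo_coefficients.tolist(),
                     "convention": "rows = basis functions"},
        "ci": {"determinants": [{"alpha": list(d.alpha), "beta": list(d.beta)}
                                for d in wf.determinants],
               "coefficients": wf.ci_coefficients.tolist()},
        "meta": {**wf.meta, "n_alpha": wf.n_alpha, "n_beta": wf.n_beta,
                 "cartesian": wf.cartesian},
    }


def _wf_from_dict(d: dict) -> CIWavefunction:
    g = d["geometry"]
    geom = Geometry.from_angstrom(g["symbols"], g["xyz_angstrom"],
                                  g.get("charge", 0),
                                  g.get("multiplicity", 1))
    shells = [BasisShell(b["center"], b["l"], b["exponents"],
                         b["coefficients"]) for b in d["basis"]]
    meta = dict(d.get("meta", {}))
    na = int(meta.pop("n_alpha"))
    nb = int(meta.pop("n_beta"))
    cart = bool(meta.pop("cartesian", True))
    dets = [Determinant(tuple(x["alpha"]), tuple(x["beta"]))
            for x in d["ci"]["determinants"]]
    return CIWavefunction(geom, shells,
                          np.asarray(d["orbitals"]["coefficients"], float),
                          dets, np.asarray(d["ci"]["coefficients"], float),
                          na, nb, cartesian=cart, meta=meta)


def save_wavefunction(wf: CIWavefunction, path):
    """Write a container; format chosen by extension (.json or .h5/.hdf5)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as f:
            json.dump(_wf_to_dict(wf), f)
        return
    if not (path.endswith(".h5") or path.endswith(".hdf5")):
        raise ValueError("container path must end in .json, .h5 or .hdf5")
    import h5py
    with h5py.File(path, "w") as f:
        g = f.create_group("geometry")
        g.create_dataset("symbols",
                         data=np.array(wf.geometry.symbols, dtype="S4"))
        g.create_dataset("Z", data=wf.geometry.numbers)
        g.create_dataset("xyz_angstrom", data=wf.geometry.coords_angstrom())
        g.attrs["charge"] = wf.geometry.charge
        g.attrs["multiplicity"] = wf.geometry.multiplicity
        b = f.create_group("basis")
        b.create_dataset("center", data=np.array([s.center for s in wf.shells]))
        b.create_dataset("l", data=np.array([s.l for s in wf.shells]))
        nprim = np.array([len(s.exponents) for s in wf.shells])
        b.create_dataset("n_primitives", data=nprim)
        b.create_dataset("exponents",
                         data=np.concatenate([s.exponents for s in wf.shells]))
        b.create_dataset("coefficients",
                         data=np.concatenate([s.coefficients for s in wf.shells]))
        o = f.create_group("orbitals")
        o.create_dataset("coefficients", data=wf.mo_coefficients)
        o.attrs["convention"] = "rows = basis functions"
        c = f.create_group("ci")
        c.create_dataset("alpha", data=np.array([d.alpha for d in wf.determinants]))
        c.create_dataset("beta",
                         data=np.array([d.beta for d in wf.determinants])
                         if wf.n_beta else np.zeros((len(wf.determinants), 0), int))
        c.create_dataset("coefficients", data=wf.ci_coefficients)
        m = f.create_group("meta")
        m.attrs["n_alpha"] = wf.n_alpha
        m.attrs["n_beta"] = wf.n_beta
        m.attrs["cartesian"] = wf.cartesian
        m.attrs["schema_version"] = SCHEMA_VERSION
        for k, v in wf.meta.items():
            try:
                m.attrs[k] = v
            except TypeError:
                m.attrs[k] = str(v)


def load_wavefunction(path) -> CIWavefunction:
    path = str(path)
    if path.endswith(".json"):
        with open(path) as f:
            return _wf_from_dict(json.load(f))
    import h5py
    with h5py.File(path, "r") as f:
        g = f["geometry"]
        geom = Geometry.from_angstrom(
            [s.decode() for s in g["symbols"][()]],
            g["xyz_angstrom"][()], int(g.attrs["charge"]),
            int(g.attrs["multiplicity"]))
        nprim = f["basis/n_primitives"][()]
        exps = f["basis/exponents"][()]
        coefs = f["basis/coefficients"][()]
        shells, pos = [], 0
        for c, l, n in zip(f["basis/center"][()], f["basis/l"][()], nprim):
            shells.append(BasisShell(int(c), int(l),
                                     exps[pos:pos + n], coefs[pos:pos + n]))
            pos += n
        alpha = f["ci/alpha"][()]
        beta = f["ci/beta"][()]
        dets = [Determinant(tuple(a), tuple(b)) for a, b in zip(alpha, beta)]
        meta = {k: v for k, v in f["meta"].attrs.items()
                if k not in ("n_alpha", "n_beta", "cartesian",
                             "schema_version")}
        return CIWavefunction(geom, shells, f["orbitals/coefficients"][()],
                              dets, f["ci/coefficients"][()],
                              int(f["meta"].attrs["n_alpha"]),
                              int(f["meta"].attrs["n_beta"]),
                              cartesian=bool(f["meta"].attrs["cartesian"]),
                              meta=meta)


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------

def read_xyz(path, charge=0, multiplicity=1) -> Geometry:
    return read_xyz_trajectory(path, charge, multiplicity)[0]


def read_xyz_trajectory(path, charge=0, multiplicity=1) -> list:
    """All frames of a (multi-frame) XYZ file, coordinates in Angstrom.

    A comment line containing ``charge=<int>`` / ``multiplicity=<int>`` (or
    ``rc=<float>`` for a reaction-coordinate value, stored on the geometry
    via the returned (geometry, rc) convention) overrides the defaults.
    """
    frames = []
    with open(path) as f:
        lines = f.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nat = int(lines[i].split()[0])
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        ch, mult = charge, multiplicity
        for tok in comment.replace(",", " ").split():
            if tok.startswith("charge="):
                ch = int(tok.split("=")[1])
            elif tok.startswith("multiplicity="):
                mult = int(tok.split("=")[1])
        syms, xyz = [], []
        for ln in lines[i + 2: i + 2 + nat]:
            parts = ln.split()
            syms.append(parts[0])
            xyz.append([float(x) for x in parts[1:4]])
        frames.append(Geometry.from_angstrom(syms, xyz, ch, mult))
        i += 2 + nat
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return frames


def write_xyz(path, geometries, comments=None):
    geometries = ([geometries] if isinstance(geometries, Geometry)
                  else list(geometries))
    with open(path, "w") as f:
        for k, g in enumerate(geometries):
            c = comments[k] if comments else \
                f"charge={g.charge} multiplicity={g.multiplicity}"
            f.write(f"{len(g.symbols)}\n{c}\n")
            for s, p in zip(g.symbols, g.coords_angstrom()):
                f.write(f"{s:2s} {p[0]:15.8f} {p[1]:15.8f} {p[2]:15.8f}\n")


# --------------------------------------------------------------------------
# Molden
# --------------------------------------------------------------------------

_L_LETTER = {"s": 0, "p": 1, "d": 2, "f": 3}


def read_molden(path, determinants=None, ci_coefficients=None,
                n_alpha=None, n_beta=None) -> CIWavefunction:
    """Geometry, basis and orbitals from a Molden file.

    Assumes Cartesian d functions ([6D], this package's convention) unless
    a [5D] flag is present (spherical d, order m = -2..+2).  Occupations
    default to the aufbau single determinant closed shell; a determinant
    sidecar can be passed explicitly.
    """
    with open(path) as f:
        text = f.read()
    lines = text.splitlines()

    def section(tag):
        out, active = [], False
        for ln in lines:
            s = ln.strip()
            if s.lower().startswith("[" + tag.lower() + "]"):
                active = True
                continue
            if s.startswith("[") and active:
                break
            if active and s:
                out.append(ln)
        return out

    ang_units = "angs" in text.lower().split("[atoms]")[1][:20].lower() \
        if "[atoms]" in text.lower() else True
    atoms = section("Atoms")
    syms, xyz = [], []
    for ln in atoms:
        p = ln.split()
        syms.append(p[0].capitalize())
        xyz.append([float(x) for x in p[3:6]])
    xyz = np.asarray(xyz)
    if not ang_units:
        xyz = xyz * ANGSTROM_PER_BOHR
    cartesian = "[5d" not in text.lower()
    gto = section("GTO")
    shells = []
    iatom = None
    i = 0
    while i < len(gto):
        parts = gto[i].split()
        if len(parts) >= 1 and parts[0].isdigit() and \
                (len(parts) == 1 or parts[-1] == "0" or len(parts) == 2):
            iatom = int(parts[0]) - 1
            i += 1
            continue
        letter = parts[0].lower()
        if letter in _L_LETTER:
            nprim = int(parts[1])
            exps, coefs = [], []
            for k in range(nprim):
                p = gto[i + 1 + k].replace("D", "E").replace("d", "e").split()
                exps.append(float(p[0]))
                coefs.append(float(p[1]))
            shells.append(BasisShell(iatom, _L_LETTER[letter], exps, coefs))
            i += 1 + nprim
        else:
            i += 1
    geom = Geometry.from_angstrom(syms, xyz)
    mo = section("MO")
    cols, occs, spins = [], [], []
    cur = None
    for ln in mo:
        s = ln.strip()
        low = s.lower()
        if low.startswith(("sym=", "ene=")):
            continue
        if low.startswith("spin="):
            spins.append(low.split("=")[1].strip())
            cur = []
            cols.append(cur)
            continue
        if low.startswith("occup="):
            occs.append(float(low.split("=")[1]))
            continue
        parts = s.split()
        if len(parts) == 2 and cur is not None:
            cur.append((int(parts[0]) - 1, float(parts[1])))
    nbf = max(max(i for i, _ in c) for c in cols) + 1
    C = np.zeros((nbf, len(cols)))
    for j, c in enumerate(cols):
        for i, v in c:
            C[i, j] = v
    if determinants is None:
        nelec = geom.n_electrons
        if n_alpha is None:
            n_alpha = (nelec + (geom.multiplicity - 1)) // 2
            n_beta = nelec - n_alpha
        determinants = [Determinant(tuple(range(n_alpha)),
                                    tuple(range(n_beta)))]
        ci_coefficients = np.array([1.0])
    return CIWavefunction(geom, shells, C, determinants,
                          np.asarray(ci_coefficients, float),
                          n_alpha, n_beta, cartesian=cartesian,
                          meta={"source": "molden"})


def write_molden(path, wf: CIWavefunction, occupations=None):
    """Minimal Molden writer (Cartesian d, [6D]); for round-trip tests and
    interchange of the orbital part (determinant data travels separately)."""
    letters = {0: "s", 1: "p", 2: "d", 3: "f"}
    occ = occupations
    if occ is None:
        occ = np.zeros(wf.mo_coefficients.shape[1])
        d0 = wf.determinants[0]
        for i in d0.alpha:
            occ[i] += 1
        for i in d0.beta:
            occ[i] += 1
    with open(path, "w") as f:
        f.write("[Molden Format]\n[6D]\n[Atoms] Angs\n")
        for k, (s, p) in enumerate(zip(wf.geometry.symbols,
                                       wf.geometry.coords_angstrom())):
            from .wavefunction import ELEMENT_NUMBERS
            f.write(f"{s:3s} {k + 1:4d} {ELEMENT_NUMBERS[s]:4d} "
                    f"{p[0]:15.8f} {p[1]:15.8f} {p[2]:15.8f}\n")
        f.write("[GTO]\n")
        for k in range(len(wf.geometry.symbols)):
            f.write(f"{k + 1} 0\n")
            for sh in wf.shells:
                if sh.center != k:
                    continue
                f.write(f" {letters[sh.l]} {len(sh.exponents)} 1.00\n")
                for a, c in zip(sh.exponents, sh.coefficients):
                    f.write(f"   {a:.10e}  {c:.10e}\n")
            f.write("\n")
        f.write("[MO]\n")
        for j in range(wf.mo_coefficients.shape[1]):
            f.write(f"Sym= A\nEne= 0.0\nSpin= Alpha\nOccup= {occ[j]:.1f}\n")
            for i in range(wf.mo_coefficients.shape[0]):
                f.write(f"  {i + 1:4d}  {wf.mo_coefficients[i, j]:.12e}\n")
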