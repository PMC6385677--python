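"""File formats: XYZ geometries, Molden frequency files, Hessian text, HDF5 studies.

All readers return atomic units (bohr); XYZ files are in angstrom on disk as
usual.  The trajectory container is an HDF5 file with one group per ensemble
and per-trajectory datasets (times, r, v, cc), plus a JSON manifest attribute.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from modetime.dynamics import Trajectory
from modetime.harmonic import ATOMIC_MASSES, MolecularSystem, PhaseSpaceEnsemble
from modetime.units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_hessian_txt",
    "write_hessian_txt",
    "read_molden_frequencies",
    "basis_from_molden",
    "write_molden_frequencies",
    "load_system",
    "write_ensemble_table",
    "save_study",
    "load_study",
]


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read an XYZ file; returns (symbols, flat coordinates in bohr)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: expected an atom count") from None
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise ValueError(
            f"{path}: header declares {n} atoms but only {len(body)} atom lines found"
        )
    symbols, coords = [], []
    for k, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {k + 3}: expected 'symbol x y z'")
        sym = parts[0].capitalize()
        if sym not in ATOMIC_MASSES:
            raise ValueError(f"{path}: line {k + 3}: unknown element {parts[0]!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ValueError(f"{path}: line {k + 3}: non-numeric coordinate") from None
        symbols.append(sym)
        coords.append(xyz)
    return symbols, np.asarray(coords).ravel() * ANGSTROM_TO_BOHR


def write_xyz(
    path: str | Path,
    symbols: list[str],
    coords_bohr: np.ndarray,
    comment: str = "",
) -> None:
    coords = np.asarray(coords_bohr).reshape(-1, 3) * BOHR_TO_ANGSTROM
    lines = [str(len(symbols)), comment]
    for sym, (x, y, z) in zip(symbols, coords):
        lines.append(f"{sym:<3} {x: 18.12f} {y: 18.12f} {z: 18.12f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_hessian_txt(path: str | Path) -> np.ndarray:
    """Read a whitespace-separated square Hessian (hartree/bohr^2)."""
    vals = np.loadtxt(path)
    flat = np.asarray(vals).ravel()
    n = int(round(np.sqrt(flat.size)))
    if n * n != flat.size:
        raise ValueError(f"{path}: {flat.size} values do not form a square matrix")
    return flat.reshape(n, n)


def write_hessian_txt(path: str | Path, hessian: np.ndarray) -> None:
    np.savetxt(path, hessian, fmt="% .16e")


def read_molden_frequencies(path: str | Path) -> dict:
    """Parse the [FREQ], [FR-COORD] and [FR-NORM-COORD] sections of a Molden file.

    Returns a dict with ``frequencies_cm`` (negative values flag imaginary
    modes, following the usual Molden convention), ``symbols``, ``coords``
    (bohr, flat) and ``modes`` (3N x n_modes Cartesian displacements).
    """
    lines = Path(path).read_text().splitlines()
    sections: dict[str, list[str]] = {}
    current = None
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("["):
            current = stripped.split("]")[0].strip("[] ").upper()
            sections[current] = []
        elif current is not None and stripped:
            sections[current].append(stripped)

    for required in ("FREQ", "FR-COORD", "FR-NORM-COORD"):
        if required not in sections:
            raise ValueError(f"{path}: missing [{required}] section")

    freqs = np.array([float(tok) for tok in sections["FREQ"]])
    symbols, coords = [], []
    for row in sections["FR-COORD"]:
        parts = row.split()
        symbols.append(parts[0].capitalize())
        coords.append([float(p) for p in parts[1:4]])
    coords = np.asarray(coords).ravel()  # FR-COORD is in bohr by convention

    n3 = coords.size
    mode_rows: list[list[float]] = []
    modes: list[np.ndarray] = []
    for row in sections["FR-NORM-COORD"]:
        if row.lower().startswith("vibration"):
            if mode_rows:
                modes.append(np.asarray(mode_rows).ravel())
            mode_rows = []
        else:
            mode_rows.append([float(p) for p in row.split()])
    if mode_rows:
        modes.append(np.asarray(mode_rows).ravel())
    if len(modes) != freqs.size:
        raise ValueError(
            f"{path}: {freqs.size} frequencies but {len(modes)} normal-coordinate blocks"
        )
    for k, m in enumerate(modes):
        if m.size != n3:
            raise ValueError(f"{path}: vibration {k + 1} has {m.size} values, expected {n3}")
    return {
        "frequencies_cm": freqs,
        "symbols": symbols,
        "coords": coords,
        "modes": np.column_stack(modes) if modes else np.zeros((n3, 0)),
    }


def basis_from_molden(path: str | Path) -> "NormalModeBasis":
    """Build a normal-mode basis directly from a Molden frequency file.

    The Cartesian displacement of each vibration is mass-weighted and
    normalised; negative frequencies mark the (single) imaginary mode, which
    is placed at index 0 with the remaining modes in ascending order.  The
    displacements are taken as given — no re-orthogonalisation is applied —
    so mildly non-orthogonal input modes carry through.
    """
    from modetime.harmonic import NormalModeBasis
    from modetime.units import AMU_TO_ME, HARTREE_TO_WAVENUMBER

    data = read_molden_frequencies(path)
    masses_me = np.repeat(
        np.array([ATOMIC_MASSES[s] for s in data["symbols"]]) * AMU_TO_ME, 3
    )
    disp = data["modes"]
    if disp.shape[1] == 0:
        raise ValueError(f"{path}: no vibrational modes found")
    vecs = np.sqrt(masses_me)[:, None] * disp
    norms = np.linalg.norm(vecs, axis=0)
    if np.any(norms < 1e-12):
        raise ValueError(f"{path}: zero-norm normal-mode displacement")
    vecs = vecs / norms

    freqs_cm = data["frequencies_cm"]
    imag = freqs_cm < 0
    if imag.sum() > 1:
        raise ValueError(
            f"{path}: found {int(imag.sum())} imaginary-frequency modes; at most one is allowed"
        )
    freqs = np.abs(freqs_cm) / HARTREE_TO_WAVENUMBER
    order = np.argsort(np.where(imag, -np.inf, freqs), kind="stable")
    freqs, imag, vecs = freqs[order], imag[order], vecs[:, order]
    flips = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    flips[flips == 0] = 1.0
    return NormalModeBasis(
        frequencies=freqs,
        is_imaginary=imag,
        mode_vectors=vecs * flips,
        masses_me=masses_me,
        ref_geometry=data["coords"].copy(),
    )


def write_molden_frequencies(
    path: str | Path, basis: "NormalModeBasis", symbols: list[str]
) -> None:
    """Write a basis as a Molden frequency file (bohr, signed cm^-1)."""
    lines = ["[Molden Format]", "[FREQ]"]
    for f_cm, im in zip(basis.frequencies_cm, basis.is_imaginary):
        lines.append(f"{-f_cm if im else f_cm:.4f}")
    lines.append("[FR-COORD]")
    for sym, (x, y, z) in zip(symbols, basis.ref_geometry.reshape(-1, 3)):
        lines.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    lines.append("[FR-NORM-COORD]")
    inv_sqm = 1.0 / np.sqrt(basis.masses_me)
    for k in range(basis.n_modes):
        lines.append(f"vibration {k + 1}")
        cart = (inv_sqm * basis.mode_vectors[:, k]).reshape(-1, 3)
        for x, y, z in cart:
            lines.append(f" {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_system(
    xyz_path: str | Path, hessian_path: str | Path
) -> MolecularSystem:
    """Assemble a MolecularSystem from an XYZ file and a Hessian text file."""
    symbols, coords = read_xyz(xyz_path)
    hessian = read_hessian_txt(hessian_path)
    masses = np.array([ATOMIC_MASSES[s] for s in symbols])
    return MolecularSystem(
        atom_symbols=symbols, masses=masses, geometry=coords, hessian=hessian
    )


def write_ensemble_table(path: str | Path, ensemble: PhaseSpaceEnsemble) -> None:
    """One row per sample: r_0..r_{M-1}, v_0..v_{M-1} in au."""
    m = ensemble.r.shape[1]
    header = " ".join([f"r_{i}" for i in range(m)] + [f"v_{i}" for i in range(m)])
    np.savetxt(path, np.hstack([ensemble.r, ensemble.v]), header=header)


def save_study(
    path: str | Path, study: dict[str, list[Trajectory]], manifest: dict | None = None
) -> None:
    """Write a study (ensembles of trajectories) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(manifest or {})
        for label, trajs in study.items():
            grp = f.create_group(label)
            for i, t in enumerate(trajs):
                g = grp.create_group(f"traj_{i:04d}")
                g.create_dataset("times", data=t.times)
                g.create_dataset("r", data=t.r_frames)
                g.create_dataset("v", data=t.v_frames)
                g.create_dataset("cc", data=t.cc_distance)
                g.attrs["dt"] = t.dt
                g.attrs["dissociated"] = t.dissociated


def load_study(path: str | Path) -> tuple[dict[str, list[Trajectory]], dict]:
    """Read back a study written by :func:`save_study`."""
    study: dict[str, list[Trajectory]] = {}
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs.get("manifest", "{}"))
        for label in f:
            trajs = []
            for name in sorted(f[label]):
                g = f[label][name]
                trajs.append(
                    Trajectory(
                        times=g["times"][...],
                        r_frames=g["r"][...],
                        v_frames=g["v"][...],
                        cc_distance=g["cc"][...],
                        dt=float(g.attrs["dt"]),
                        dissociated=bool(g.attrs["dissociated"]),
                    )
                )
            study[label] = trajs
    return study, manifest
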