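"""Seeded generators of self-contained synthetic input sets.

``build_synthetic_system`` constructs a molecule whose Hessian has a
prescribed vibrational spectrum: a random orthonormal basis of the
translation/rotation-free subspace is given the target eigenvalues (one
negative for the reaction coordinate) and transformed back to Cartesian
second derivatives.  The resulting system is synthetic — its geometry is
random and its modes are not those of any real molecule — but it is exactly
consistent: normal-mode analysis recovers the prescribed frequencies.

``make_fixture`` writes ready-to-run input sets (geometry, Hessian, config)
for the test-suite and the documentation examples.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from modetime.harmonic import (
    ATOMIC_MASSES,
    MolecularSystem,
    _tr_subspace,
)
from modetime.io import write_hessian_txt, write_xyz
from modetime.units import AMU_TO_ME, HARTREE_TO_WAVENUMBER

__all__ = [
    "DIOXETANE_LIKE_FREQS_CM",
    "build_synthetic_system",
    "build_diatomic",
    "make_fixture",
]

# a transition-state-like spectrum for an 8-atom ring: one imaginary mode
# (negative by convention), four slow skeletal deformations (the
# barrier-coupled modes in the default study: they must be slow against the
# ~8 fs barrier-attempt cycle for their phases to gate the escape), and a
# block of fast framework/C-H modes that stay uncoupled
DIOXETANE_LIKE_FREQS_CM = np.array(
    [
        -400.0,
        200.0, 260.0, 340.0, 420.0,
        800.0, 900.0, 1000.0, 1100.0, 1200.0, 1300.0, 1400.0,
        1500.0, 1600.0, 1700.0,
        2900.0, 3000.0, 3100.0,
    ]
)

_COMPOSITIONS = {8: ["C", "C", "O", "O", "H", "H", "H", "H"]}
_COMPOSITIONS[20] = ["C"] * 6 + ["O"] * 2 + ["H"] * 12


def _random_geometry(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """A random non-degenerate 3-D arrangement with ~2.5 bohr spacing."""
    pts = rng.uniform(-1.0, 1.0, size=(n_atoms, 3))
    # spread atoms apart to avoid accidental collinearity
    return (pts * 2.5 * n_atoms ** (1.0 / 3.0)).ravel()


def build_synthetic_system(
    n_atoms: int = 8,
    freqs_cm: np.ndarray | None = None,
    seed: int = 0,
) -> MolecularSystem:
    """A synthetic molecule whose Hessian has the prescribed spectrum.

    ``freqs_cm`` uses the Molden sign convention: negative means imaginary.
    Default: the 18-mode transition-state-like spectrum for 8 atoms; for other
    atom counts a spread of frequencies is generated (first mode imaginary).
    """
    if freqs_cm is None:
        if n_atoms == 8:
            freqs_cm = DIOXETANE_LIKE_FREQS_CM
        else:
            n_modes = 3 * n_atoms - 6
            rng0 = np.random.default_rng(seed)
            real = np.sort(rng0.uniform(250.0, 3100.0, size=n_modes - 1))
            freqs_cm = np.concatenate([[-420.0], real])
    freqs_cm = np.asarray(freqs_cm, dtype=float)
    n_modes = 3 * n_atoms - 6
    if freqs_cm.size != n_modes:
        raise ValueError(f"need {n_modes} frequencies for {n_atoms} atoms")

    symbols = _COMPOSITIONS.get(n_atoms)
    if symbols is None:
        symbols = ["C"] * n_atoms
    masses = np.array([ATOMIC_MASSES[s] for s in symbols])

    rng = np.random.default_rng(seed)
    geometry = _random_geometry(n_atoms, rng)
    masses_me = masses * AMU_TO_ME

    tr = _tr_subspace(geometry, masses_me)
    if tr.shape[1] != 6:
        raise RuntimeError("random geometry degenerate; different seed required")
    # orthonormal basis of the vibrational complement
    proj = np.eye(3 * n_atoms) - tr @ tr.T
    u, s, _ = np.linalg.svd(proj)
    comp = u[:, : 3 * n_atoms - 6]
    # random rotation inside the complement so mode vectors are non-trivial
    q, _ = np.linalg.qr(rng.standard_normal((n_modes, n_modes)))
    modes = comp @ q

    w_au = np.abs(freqs_cm) / HARTREE_TO_WAVENUMBER
    evals = np.sign(freqs_cm) * w_au**2
    h_mw = modes @ (evals[:, None] * modes.T)
    sqm = np.sqrt(np.repeat(masses_me, 3))
    hessian = h_mw * np.outer(sqm, sqm)
    hessian = 0.5 * (hessian + hessian.T)

    return MolecularSystem(
        atom_symbols=symbols, masses=masses, geometry=geometry, hessian=hessian
    )


def build_diatomic(
    force_constant: float = 0.35,
    mass_amu: float = 12.0107,
    separation: float = 2.5,
) -> MolecularSystem:
    """A homonuclear diatomic along z with analytic frequency sqrt(k/mu)."""
    symbols = ["C", "C"]
    masses = np.array([mass_amu, mass_amu])
    geometry = np.array([0.0, 0.0, 0.0, 0.0, 0.0, separation])
    h = np.zeros((6, 6))
    k = force_constant
    h[2, 2] = h[5, 5] = k
    h[2, 5] = h[5, 2] = -k
    return MolecularSystem(
        atom_symbols=symbols, masses=masses, geometry=geometry, hessian=h
    )


_TINY_STUDY_CONFIG = {
    "seed": 0,
    "n_trajectories": 10,
    "dt_au": 10.0,
    "max_time_fs": 250.0,
    "stride": 5,
    "with_velocities": True,
    "bnn": {"hidden_layers": [16], "epochs": 40, "batch_size": 64},
    "interpret_modes": [6, 8],
    "interpret_n": 20,
}


def make_fixture(kind: str, seed: int = 0, outdir: str | Path = ".") -> dict[str, Path]:
    """Write a self-contained input set; returns the paths written.

    Kinds: ``toy-diatomic`` (analytic oscillator), ``surrogate-18mode``
    (8-atom synthetic transition state), ``tiny-study`` (the same system plus
    a config for a 10-trajectory end-to-end run).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if kind == "toy-diatomic":
        system = build_diatomic()
    elif kind in ("surrogate-18mode", "tiny-study"):
        system = build_synthetic_system(8, seed=seed)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    paths["xyz"] = outdir / "geometry.xyz"
    write_xyz(paths["xyz"], system.atom_symbols, system.geometry, comment=f"{kind} seed={seed}")
    paths["hessian"] = outdir / "hessian.txt"
    write_hessian_txt(paths["hessian"], system.hessian)

    if kind == "tiny-study":
        cfg = dict(_TINY_STUDY_CONFIG)
        cfg["seed"] = seed
        cfg["geometry"] = str(paths["xyz"])
        cfg["hessian"] = str(paths["hessian"])
        paths["config"] = outdir / "config.yaml"
        paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
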