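"""Normal-mode analysis at a stationary or transition-state geometry.

The vibrational basis is obtained by diagonalising the mass-weighted Hessian
after explicit projection of the translational and rotational (Eckart) subspace
at the reference geometry.  Projection, rather than discarding the six smallest
eigenvalues, is robust at a transition state where one eigenvalue is negative.

Conventions
-----------
* Internal units are atomic (bohr, hartree, electron masses, au time).
* Mode vectors are columns of an orthonormal matrix ``L`` in mass-weighted
  Cartesian space; mode coordinates are ``r = L^T M^{1/2} (x - x_ref)``.
* At most one imaginary-frequency mode is accepted; if present it is the
  reaction coordinate and is forced to index 0.  Remaining modes are ordered
  by ascending real frequency.
* Mode-vector signs are fixed by making each column's largest-magnitude
  component positive, so feature signs are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from modetime.units import AMU_TO_ME, HARTREE_TO_WAVENUMBER

__all__ = [
    "ATOMIC_MASSES",
    "MolecularSystem",
    "NormalModeBasis",
    "PhaseSpaceSample",
    "PhaseSpaceEnsemble",
    "normal_mode_analysis",
    "to_mode_coordinates",
    "from_mode_coordinates",
    "mode_report",
]

# average atomic masses (amu) for the elements this pipeline encounters
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00794,
    "D": 2.014102,
    "He": 4.002602,
    "Li": 6.941,
    "B": 10.811,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "F": 18.998403,
    "Ne": 20.1797,
    "Na": 22.989769,
    "Mg": 24.3050,
    "Si": 28.0855,
    "P": 30.973762,
    "S": 32.065,
    "Cl": 35.453,
    "Ar": 39.948,
    "Br": 79.904,
    "I": 126.90447,
}


@dataclass
class MolecularSystem:
    """A molecule defined by symbols, masses, geometry and a Hessian.

    Parameters
    ----------
    atom_symbols : list of str
        Element labels, length N.
    masses : (N,) array
        Atomic masses in amu.
    geometry : (3N,) array
        Cartesian reference geometry in bohr.
    hessian : (3N, 3N) array
        Second derivatives of the energy in hartree/bohr^2.
    """

    atom_symbols: list[str]
    masses: np.ndarray
    geometry: np.ndarray
    hessian: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.geometry = np.asarray(self.geometry, dtype=float).ravel()
        self.hessian = np.asarray(self.hessian, dtype=float)
        n = len(self.atom_symbols)
        if n < 2:
            raise ValueError(f"need at least 2 atoms, got {n}")
        if self.masses.shape != (n,):
            raise ValueError("masses length does not match atom count")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if self.geometry.shape != (3 * n,):
            raise ValueError(
                f"geometry has {self.geometry.size} values, expected {3 * n}"
            )
        if self.hessian.shape != (3 * n, 3 * n):
            raise ValueError(
                f"hessian shape {self.hessian.shape} does not match 3N={3 * n}"
            )
        scale = max(np.abs(self.hessian).max(), 1.0)
        asym = np.abs(self.hessian - self.hessian.T).max()
        if asym > 1e-8 * scale:
            raise ValueError(f"hessian not symmetric (max asymmetry {asym:.3e})")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_symbols)


@dataclass
class NormalModeBasis:
    """Vibrational normal modes of a :class:`MolecularSystem`.

    ``frequencies`` stores the magnitude of the angular frequency in au;
    ``is_imaginary`` flags the (single, optional) barrier mode.  The reaction
    coordinate, if present, is mode 0 (``rc_index``).
    """

    frequencies: np.ndarray
    is_imaginary: np.ndarray
    mode_vectors: np.ndarray
    masses_me: np.ndarray
    ref_geometry: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.mode_vectors.shape[1]

    @property
    def rc_index(self) -> int | None:
        """Index of the reaction coordinate (imaginary mode), or None."""
        return 0 if bool(self.is_imaginary[0]) else None

    @property
    def frequencies_cm(self) -> np.ndarray:
        """Frequency magnitudes in cm^-1."""
        return self.frequencies * HARTREE_TO_WAVENUMBER

    def sampleable_frequencies(self) -> np.ndarray:
        """Frequencies of the real (Wigner-sampleable) modes, in au."""
        return self.frequencies[~self.is_imaginary]


@dataclass
class PhaseSpaceSample:
    """Mass-weighted normal-mode positions and velocities (au) for one sample."""

    r: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.r.shape != self.v.shape:
            raise ValueError("r and v must have the same shape")
        if not (np.all(np.isfinite(self.r)) and np.all(np.isfinite(self.v))):
            raise ValueError("phase-space sample contains non-finite values")


@dataclass
class PhaseSpaceEnsemble:
    """A stack of phase-space samples: ``r`` and ``v`` are (n_samples, n_modes)."""

    r: np.ndarray
    v: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))
        if self.r.shape != self.v.shape:
            raise ValueError("r and v must have the same shape")

    def __len__(self) -> int:
        return self.r.shape[0]

    def __getitem__(self, i: int) -> PhaseSpaceSample:
        return PhaseSpaceSample(self.r[i], self.v[i])


def _tr_subspace(geometry: np.ndarray, masses_me: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the mass-weighted translation/rotation subspace.

    Returns a (3N, k) matrix with k = 6 (nonlinear) or 5 (linear); rank is
    detected from the singular values so linear molecules need no special flag.
    """
    coords = geometry.reshape(-1, 3)
    n = coords.shape[0]
    sqm = np.sqrt(masses_me)
    com = (masses_me[:, None] * coords).sum(axis=0) / masses_me.sum()
    rel = coords - com

    vecs = np.zeros((3 * n, 6))
    for a in range(3):  # translations
        vecs[a::3, a] = sqm
    for a, axis in enumerate(np.eye(3)):  # infinitesimal rotations
        rot = np.cross(np.broadcast_to(axis, rel.shape), rel)
        vecs[:, 3 + a] = (sqm[:, None] * rot).ravel()

    u, s, _ = np.linalg.svd(vecs, full_matrices=False)
    rank = int(np.sum(s > 1e-8 * s[0]))
    return u[:, :rank]


def normal_mode_analysis(
    system: MolecularSystem,
    linear: bool = False,
    freq_floor: float = 1e-6,
) -> NormalModeBasis:
    """Diagonalise the projected mass-weighted Hessian.

    Parameters
    ----------
    system : MolecularSystem
    linear : bool
        Declare the molecule linear (3N-5 expected modes).  Used only for
        validation; the translation/rotation rank is detected numerically.
    freq_floor : float
        Minimum |frequency| (au) a reported mode may have.  A smaller value
        among the retained modes indicates a projection failure.

    Returns
    -------
    NormalModeBasis
        With the single imaginary mode (if any) at index 0 and the remaining
        modes in ascending frequency order.
    """
    masses_me = np.repeat(system.masses * AMU_TO_ME, 3)
    sqm = np.sqrt(masses_me)
    h_mw = system.hessian / np.outer(sqm, sqm)
    h_mw = 0.5 * (h_mw + h_mw.T)

    tr = _tr_subspace(system.geometry, np.asarray(system.masses) * AMU_TO_ME)
    n_tr = tr.shape[1]
    expected_tr = 5 if linear else 6
    if n_tr != expected_tr:
        raise ValueError(
            f"detected {n_tr} translation/rotation vectors, expected {expected_tr}"
        )

    proj = np.eye(h_mw.shape[0]) - tr @ tr.T
    h_proj = proj @ h_mw @ proj
    h_proj = 0.5 * (h_proj + h_proj.T)
    evals, evecs = np.linalg.eigh(h_proj)

    # drop the n_tr eigenpairs closest to zero (the projected-out subspace)
    drop = np.argsort(np.abs(evals))[:n_tr]
    keep = np.setdiff1d(np.arange(evals.size), drop)
    evals, evecs = evals[keep], evecs[:, keep]

    imag = evals < 0
    n_imag = int(imag.sum())
    if n_imag > 1:
        raise ValueError(
            f"found {n_imag} imaginary-frequency modes; at most one is allowed"
        )

    freqs = np.sqrt(np.abs(evals))
    if np.any(freqs < freq_floor):
        bad = int(np.sum(freqs < freq_floor))
        raise ValueError(
            f"{bad} vibrational mode(s) below the frequency floor {freq_floor:g} au; "
            "translation/rotation projection is incomplete"
        )

    # imaginary mode first, then ascending frequency; stable sort keeps original
    # eigenvector order on ties
    order = np.argsort(np.where(imag, -np.inf, freqs), kind="stable")
    freqs, imag, evecs = freqs[order], imag[order], evecs[:, order]

    # sign convention: largest-magnitude component positive
    flips = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flips[flips == 0] = 1.0
    evecs = evecs * flips

    return NormalModeBasis(
        frequencies=freqs,
        is_imaginary=imag,
        mode_vectors=evecs,
        masses_me=masses_me,
        ref_geometry=np.asarray(system.geometry, dtype=float).copy(),
    )


def to_mode_coordinates(
    basis: NormalModeBasis,
    positions: np.ndarray,
    velocities: np.ndarray | None = None,
) -> PhaseSpaceSample:
    """Project Cartesian positions/velocities onto the vibrational modes.

    ``r = L^T M^{1/2} (x - x_ref)`` and ``v = L^T M^{1/2} dx/dt``; the
    translational and rotational components are discarded by construction.
    """
    x = np.asarray(positions, dtype=float).ravel()
    if x.shape != basis.ref_geometry.shape:
        raise ValueError(
            f"positions have {x.size} values, expected {basis.ref_geometry.size}"
        )
    sqm = np.sqrt(basis.masses_me)
    r = basis.mode_vectors.T @ (sqm * (x - basis.ref_geometry))
    if velocities is None:
        v = np.zeros_like(r)
    else:
        xd = np.asarray(velocities, dtype=float).ravel()
        if xd.shape != x.shape:
            raise ValueError("velocities shape does not match positions")
        v = basis.mode_vectors.T @ (sqm * xd)
    return PhaseSpaceSample(r=r, v=v)


def from_mode_coordinates(
    basis: NormalModeBasis, sample: PhaseSpaceSample
) -> tuple[np.ndarray, np.ndarray]:
    """Map a mode-space sample back to Cartesian bohr positions and velocities.

    Exact left-inverse of :func:`to_mode_coordinates` on the vibrational
    subspace: ``x = x_ref + M^{-1/2} L r``.
    """
    if sample.r.shape[-1] != basis.n_modes:
        raise ValueError(
            f"sample has {sample.r.shape[-1]} modes, basis has {basis.n_modes}"
        )
    inv_sqm = 1.0 / np.sqrt(basis.masses_me)
    x = basis.ref_geometry + inv_sqm * (basis.mode_vectors @ sample.r)
    xd = inv_sqm * (basis.mode_vectors @ sample.v)
    return x, xd


def mode_report(basis: NormalModeBasis) -> str:
    """Tabular text report: mode index, frequency in cm^-1, imaginary flag."""
    lines = [f"{'mode':>4}  {'freq/cm^-1':>12}  {'imaginary':>9}"]
    for i, (f_cm, im) in enumerate(zip(basis.frequencies_cm, basis.is_imaginary)):
        lines.append(f"{i:>4}  {f_cm:>12.2f}  {'yes' if im else 'no':>9}")
    return "\n".join(lines)
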