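"""Wigner sampling of vibrational initial conditions.

For a harmonic mode of angular frequency ``w`` (au, hbar = 1, mass-weighted
coordinates) the ground-state Wigner function is a product of Gaussians:
``r ~ N(0, 1/(2w))`` and ``v ~ N(0, w/2)``, giving the zero-point energy
``<E> = w/2``.

The first excited state's Wigner function is negative near the origin and is
not a samplable density.  We instead draw ``r`` and ``v`` independently from
the quantum marginals ``|psi_1(r)|^2`` and ``|phi_1(v)|^2``; the position
marginal is proportional to ``r^2 exp(-w r^2)``, which is exactly the law of a
random sign times the norm of a 3-vector of iid ``N(0, 1/(2w))`` draws, so it
is sampled exactly (no tabulation).  Both marginals of the true Wigner function
are matched, and ``<E> = 3w/2``.

The reaction coordinate (imaginary mode) is never Wigner-sampled: it starts at
``r = 0`` and only receives a kinetic-energy kick (1 kcal/mol by default)
directed toward products.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from modetime.harmonic import NormalModeBasis, PhaseSpaceEnsemble
from modetime.units import KCALMOL_TO_HARTREE

__all__ = [
    "VibrationalStateSpec",
    "sample_wigner_ground",
    "sample_wigner_excited",
    "apply_rc_kick",
    "sample_ensemble",
    "spec_subseed",
]


@dataclass
class VibrationalStateSpec:
    """Specification of a vibrational-state ensemble.

    Parameters
    ----------
    quanta : dict or None
        Map mode index -> excitation level.  Only levels 0/1 are supported and
        the reaction coordinate may not be excited.  None or empty means the
        vibrational ground state.
    ensemble_size : int
        Number of phase-space samples (default 250).
    kick_energy : float
        Kinetic energy (kcal/mol) given along the reaction coordinate.
    kick_sign : int
        Direction of the kick; +1 points toward the product side of the
        surrogate potential.
    """

    quanta: dict[int, int] | None = None
    ensemble_size: int = 250
    seed: int = 0
    kick_energy: float = 1.0
    kick_sign: int = +1

    def __post_init__(self) -> None:
        self.quanta = dict(self.quanta or {})
        for mode, q in self.quanta.items():
            if q not in (0, 1):
                raise ValueError(
                    f"mode {mode}: only first excitations are supported, got quanta={q}"
                )

    @property
    def excited_modes(self) -> tuple[int, ...]:
        return tuple(sorted(m for m, q in self.quanta.items() if q == 1))

    def label(self) -> str:
        if not self.excited_modes:
            return "ground"
        return "+".join(f"mode{m}" for m in self.excited_modes)


def _check_sampleable(basis: NormalModeBasis) -> np.ndarray:
    """Indices of modes to Wigner-sample (all real modes)."""
    bad = np.flatnonzero(basis.is_imaginary[1:]) + 1
    if bad.size:
        raise ValueError(
            f"imaginary frequency on non-reaction-coordinate mode(s) {bad.tolist()}"
        )
    return np.flatnonzero(~basis.is_imaginary)


def sample_wigner_ground(
    basis: NormalModeBasis, n: int, seed: int
) -> PhaseSpaceEnsemble:
    """Sample ``n`` vibrational-ground-state phase-space points.

    Each real mode is drawn from its ground-state Wigner Gaussians; the
    reaction coordinate gets ``r = v = 0`` (the kick is applied separately).
    """
    return sample_wigner_excited(
        basis, VibrationalStateSpec(quanta={}, ensemble_size=n, seed=seed, kick_energy=0.0)
    )


def sample_wigner_excited(
    basis: NormalModeBasis, spec: VibrationalStateSpec
) -> PhaseSpaceEnsemble:
    """Sample an ensemble for the vibrational state described by ``spec``.

    Unexcited modes follow the ground-state Wigner Gaussians; modes with one
    quantum follow the ``v = 1`` quantum marginals (see module docstring).  The
    kick is *not* applied here; use :func:`apply_rc_kick` or
    :func:`sample_ensemble`.
    """
    sampleable = _check_sampleable(basis)
    rc = basis.rc_index
    for m in spec.excited_modes:
        if m == rc:
            raise ValueError("the reaction coordinate cannot be vibrationally excited")
        if m < 0 or m >= basis.n_modes:
            raise ValueError(f"excited mode {m} out of range for {basis.n_modes} modes")

    n = spec.ensemble_size
    n_modes = basis.n_modes
    r = np.zeros((n, n_modes))
    v = np.zeros((n, n_modes))
    root = np.random.SeedSequence(spec.seed)
    # one child stream per mode: streams are independent of ensemble composition
    streams = root.spawn(n_modes)
    for m in sampleable:
        rng = np.random.Generator(np.random.PCG64(streams[m]))
        w = basis.frequencies[m]
        sig_r = np.sqrt(1.0 / (2.0 * w))
        sig_v = np.sqrt(w / 2.0)
        if m in spec.excited_modes:
            r[:, m] = _sample_excited_marginal(rng, sig_r, n)
            v[:, m] = _sample_excited_marginal(rng, sig_v, n)
        else:
            r[:, m] = rng.normal(0.0, sig_r, size=n)
            v[:, m] = rng.normal(0.0, sig_v, size=n)
    return PhaseSpaceEnsemble(r=r, v=v, meta={"spec": spec})


def _sample_excited_marginal(
    rng: np.random.Generator, sigma: float, n: int
) -> np.ndarray:
    """Draw from the density proportional to ``u^2 exp(-u^2 / (2 sigma^2))``.

    Exact sampling: the magnitude is the norm of a 3-vector of iid
    ``N(0, sigma^2)`` components (a scaled chi-3 variate); the sign is uniform.
    """
    mag = np.linalg.norm(rng.normal(0.0, sigma, size=(n, 3)), axis=1)
    sign = rng.integers(0, 2, size=n) * 2 - 1
    return sign * mag


def apply_rc_kick(
    ensemble: PhaseSpaceEnsemble,
    energy: float,
    sign: int = +1,
    rc_index: int = 0,
) -> PhaseSpaceEnsemble:
    """Set the reaction-coordinate velocity to carry ``energy`` kcal/mol.

    The kick *sets* ``v_rc = sign * sqrt(2 E)`` (mass-weighted au); applying it
    twice is idempotent.  ``r_rc`` is left unchanged.
    """
    if energy < 0:
        raise ValueError(f"kick energy must be non-negative, got {energy}")
    if sign not in (-1, +1):
        raise ValueError("kick sign must be +1 or -1")
    e_h = energy * KCALMOL_TO_HARTREE
    v = ensemble.v.copy()
    v[:, rc_index] = sign * np.sqrt(2.0 * e_h)
    return PhaseSpaceEnsemble(r=ensemble.r.copy(), v=v, meta=dict(ensemble.meta))


def sample_ensemble(
    basis: NormalModeBasis, spec: VibrationalStateSpec
) -> PhaseSpaceEnsemble:
    """Wigner-sample ``spec`` and apply its reaction-coordinate kick."""
    ens = sample_wigner_excited(basis, spec)
    if basis.rc_index is None:
        return ens
    return apply_rc_kick(ens, spec.kick_energy, spec.kick_sign, basis.rc_index)


def spec_subseed(seed: int, spec: VibrationalStateSpec) -> int:
    """Derive a per-ensemble seed from a study seed and the spec's content.

    Content-based (not position-based) derivation means two identical specs
    in one study receive identical ensembles, and a predicted and a
    propagated study run from the same seed share their initial conditions.
    """
    key = f"{spec.label()}|{spec.kick_energy}|{spec.kick_sign}|{spec.ensemble_size}"
    digest = zlib.crc32(key.encode())
    return int(
        np.random.SeedSequence([int(seed), digest]).generate_state(1)[0] % (2**31)
    )
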