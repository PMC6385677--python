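"""Surrogate dissociation dynamics in mass-weighted normal-mode coordinates.

This module stands in for on-the-fly electronic-structure dynamics: a model
potential with a barrier along the reaction coordinate, a harmonic bath, and a
sparse linear coupling that modulates the barrier height, integrated with
velocity Verlet.  The coupling plants a known set of causally relevant modes,
so downstream feature-relevance inference has a recoverable ground truth.

Potential
---------
With ``q0`` the reaction coordinate and ``q_i`` the bath modes (all
mass-weighted, au)::

    V(q) = A * g(q0) * (1 + sum_i lambda_i q_i) + sum_i 1/2 w_i^2 q_i^2
           + 1/2 w_wall^2 q0^2   (q0 < 0 only)

    g(q0) = (q0/s)^2 * exp(1 - (q0/s)^2)   for q0 >= 0, else 0

``g`` vanishes at the starting point ``q0 = 0``, peaks at ``q0 = s`` (the
barrier top, height ``A`` when the bath is at rest) and decays to the plateau
beyond, so a trajectory kicked toward products must cross a barrier whose
instantaneous height fluctuates with the coupled bath modes.  The harmonic
wall at ``q0 < 0`` confines the system on the product side of the preceding
(already crossed) transition state, so failed attempts are reflected back
instead of re-crossing; the potential is C^1 at ``q0 = 0``.

The C-C bond length is a linear readout of the reaction coordinate,
``cc = d_TS + slope * q0``; dissociation is declared when it exceeds 2.4 A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from modetime.harmonic import NormalModeBasis, PhaseSpaceEnsemble, PhaseSpaceSample
from modetime.units import AU_TIME_TO_FS, KCALMOL_TO_HARTREE
from modetime.wigner import VibrationalStateSpec, sample_ensemble, spec_subseed

__all__ = [
    "SurrogatePotential",
    "Trajectory",
    "evaluate_potential",
    "propagate",
    "propagate_ensemble",
    "generate_study",
    "default_study_potential",
    "trajectory_energy",
    "DISSOCIATION_THRESHOLD",
]

DISSOCIATION_THRESHOLD = 2.4  # angstrom; twice the carbon van der Waals radius


@dataclass
class SurrogatePotential:
    """Parameters of the surrogate dissociation potential.

    Attributes
    ----------
    barrier_height : float
        ``A`` in hartree; height of the unmodulated barrier above the plateau.
    barrier_width : float
        ``s`` in mass-weighted au; the barrier top sits at ``q0 = s``.
    wall_frequency : float
        Angular frequency (au) of the confining wall at ``q0 < 0``.
    d_ts : float
        C-C distance (angstrom) at the starting (transition-state) geometry.
    dist_slope : float
        Angstrom of C-C stretch per unit mass-weighted ``q0``.
    bath_frequencies : (M-1,) array
        Angular frequency (au) of each bath mode.
    couplings : (M-1,) array
        ``lambda_i`` (per au); nonzero entries are the planted relevant modes.
    plateau_energy : float
        Constant energy offset (hartree) of the dissociated plateau.
    """

    barrier_height: float
    barrier_width: float
    wall_frequency: float
    d_ts: float
    dist_slope: float
    bath_frequencies: np.ndarray
    couplings: np.ndarray
    plateau_energy: float = 0.0

    def __post_init__(self) -> None:
        self.bath_frequencies = np.asarray(self.bath_frequencies, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be non-negative")
        if self.barrier_width <= 0:
            raise ValueError("barrier_width must be positive")
        if self.dist_slope <= 0:
            raise ValueError("dist_slope must be positive")
        if self.couplings.shape != self.bath_frequencies.shape:
            raise ValueError("couplings and bath_frequencies must have equal length")

    @property
    def n_modes(self) -> int:
        return 1 + self.bath_frequencies.size

    @property
    def planted_modes(self) -> tuple[int, ...]:
        """Mode indices (in the full numbering, rc = 0) with nonzero coupling."""
        return tuple(int(i) + 1 for i in np.flatnonzero(self.couplings))

    def cc_distance(self, q0: np.ndarray) -> np.ndarray:
        """C-C bond length (angstrom) as a function of the reaction coordinate."""
        return self.d_ts + self.dist_slope * np.asarray(q0)


@dataclass
class Trajectory:
    """A propagated trajectory on a uniform time grid.

    ``times`` are in fs; ``r_frames``/``v_frames`` are (n_frames, n_modes) in
    mass-weighted au; ``cc_distance`` in angstrom.
    """

    times: np.ndarray
    r_frames: np.ndarray
    v_frames: np.ndarray
    cc_distance: np.ndarray
    dt: float
    dissociated: bool

    def __post_init__(self) -> None:
        if self.times.size < 1:
            raise ValueError("trajectory must contain at least one frame")
        steps = np.diff(self.times)
        if steps.size and (np.any(steps <= 0) or np.ptp(steps) > 1e-9):
            raise ValueError("times must increase with a constant step")
        if not np.all(np.isfinite(self.cc_distance)):
            raise ValueError("cc_distance contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.times.size


def evaluate_potential(
    potential: SurrogatePotential, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Energy (hartree) and analytic gradient (hartree/au) at ``q``.

    ``q`` may be a single (M,) point or a batch (..., M); the energy has the
    batch shape and the gradient the shape of ``q``.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != potential.n_modes:
        raise ValueError(
            f"q has {q.shape[-1]} modes, potential has {potential.n_modes}"
        )
    q0 = q[..., 0]
    qb = q[..., 1:]
    s = potential.barrier_width
    a_h = potential.barrier_height
    w2 = potential.bath_frequencies**2
    lam = potential.couplings

    pos = q0 > 0
    x = np.where(pos, q0, 0.0) / s
    expo = np.exp(1.0 - x * x)
    g = x * x * expo
    gp = np.where(pos, (2.0 * q0 / s**2) * (1.0 - x * x) * expo, 0.0)

    q0_neg = np.where(pos, 0.0, q0)
    mod = 1.0 + qb @ lam
    energy = (
        potential.plateau_energy
        + a_h * g * mod
        + 0.5 * potential.wall_frequency**2 * q0_neg**2
        + 0.5 * (qb * qb) @ w2
    )
    grad = np.empty_like(q)
    grad[..., 0] = a_h * gp * mod + potential.wall_frequency**2 * q0_neg
    grad[..., 1:] = a_h * g[..., None] * lam + w2 * qb
    return energy, grad


def trajectory_energy(potential: SurrogatePotential, traj: Trajectory) -> np.ndarray:
    """Total (kinetic + potential) energy per frame, hartree."""
    e_pot, _ = evaluate_potential(potential, traj.r_frames)
    return e_pot + 0.5 * np.sum(traj.v_frames**2, axis=1)


def secular_energy_drift(potential: SurrogatePotential, traj: Trajectory) -> float:
    """Secular energy change (hartree) over the trajectory.

    The instantaneous energy of a symplectic one-step integrator oscillates
    with amplitude O((w dt)^2) about the conserved shadow energy without
    growing; drift is therefore measured as the least-squares linear trend of
    E(t) times the trajectory duration, which suppresses the bounded
    oscillation of every mode whose period is short against the run length.
    """
    e = trajectory_energy(potential, traj)
    slope = np.polyfit(traj.times, e, 1)[0]
    return float(abs(slope) * (traj.times[-1] - traj.times[0]))


def propagate(
    potential: SurrogatePotential,
    initial: PhaseSpaceSample,
    dt: float = 10.0,
    max_time: float = 250.0,
    stop_margin: float = 2.5,
    threshold: float = DISSOCIATION_THRESHOLD,
) -> Trajectory:
    """Integrate one trajectory with velocity Verlet.

    Parameters
    ----------
    dt : float
        Time step in au (default 10 au, about 0.24 fs).
    max_time : float
        Maximum simulated time in fs.
    stop_margin : float
        Extra fs recorded beyond the first crossing of ``threshold``.
    threshold : float
        C-C dissociation threshold in angstrom.
    """
    ens = PhaseSpaceEnsemble(r=initial.r[None, :], v=initial.v[None, :])
    return propagate_ensemble(
        potential, ens, dt=dt, max_time=max_time,
        stop_margin=stop_margin, threshold=threshold,
    )[0]


def propagate_ensemble(
    potential: SurrogatePotential,
    ensemble: PhaseSpaceEnsemble,
    dt: float = 10.0,
    max_time: float = 250.0,
    stop_margin: float = 2.5,
    threshold: float = DISSOCIATION_THRESHOLD,
) -> list[Trajectory]:
    """Velocity-Verlet integration of a whole ensemble in lock-step.

    All trajectories advance together (vectorised over the ensemble axis);
    each one's recorded history ends ``stop_margin`` fs after its own first
    threshold crossing, or at ``max_time``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = ensemble.r.astype(float).copy()
    v = ensemble.v.astype(float).copy()
    n = r.shape[0]
    dt_fs = dt * AU_TIME_TO_FS
    max_steps = int(math.floor(max_time / dt_fs + 1e-9))
    margin_frames = int(math.ceil(stop_margin / dt_fs - 1e-9))

    _, grad = evaluate_potential(potential, r)
    cc = potential.cc_distance(r[:, 0])
    rs, vs, ccs = [r.copy()], [v.copy()], [cc.copy()]
    cross = np.where(cc > threshold, 0, -1)

    for step in range(1, max_steps + 1):
        v_half = v - 0.5 * dt * grad
        r = r + dt * v_half
        if not np.all(np.isfinite(r)):
            bad = int(np.flatnonzero(~np.isfinite(r).all(axis=1))[0])
            raise FloatingPointError(
                f"non-finite state at frame {step} (trajectory {bad})"
            )
        _, grad = evaluate_potential(potential, r)
        v = v_half - 0.5 * dt * grad
        cc = potential.cc_distance(r[:, 0])
        rs.append(r.copy())
        vs.append(v.copy())
        ccs.append(cc.copy())
        newly = (cross < 0) & (cc > threshold)
        cross[newly] = step
        if np.all((cross >= 0) & (step >= cross + margin_frames)):
            break

    r_all = np.stack(rs)  # (frames, n, modes)
    v_all = np.stack(vs)
    cc_all = np.stack(ccs)
    n_recorded = r_all.shape[0]
    times = np.arange(n_recorded) * dt_fs

    out = []
    for i in range(n):
        end = n_recorded if cross[i] < 0 else min(n_recorded, cross[i] + margin_frames + 1)
        out.append(
            Trajectory(
                times=times[:end].copy(),
                r_frames=r_all[:end, i, :].copy(),
                v_frames=v_all[:end, i, :].copy(),
                cc_distance=cc_all[:end, i].copy(),
                dt=dt_fs,
                dissociated=bool(cross[i] >= 0),
            )
        )
    return out


def default_study_potential(
    basis: NormalModeBasis,
    planted_modes: tuple[int, ...] = (1, 2, 3, 4),
    effect_sizes: tuple[float, ...] = (0.65, 0.50, 0.55, 0.50),
    barrier_height_kcal: float = 1.45,
    barrier_width: float = 12.0,
    wall_frequency: float = 1.0e-2,
    d_ts: float = 1.55,
    dist_slope: float = 0.06,
) -> SurrogatePotential:
    """Build the default planted-relevance potential on top of a mode basis.

    ``effect_sizes`` are dimensionless: each planted mode's coupling is
    ``c * sqrt(2 w)`` so that a one-standard-deviation ground-state
    displacement of that mode modulates the barrier height by the fraction
    ``c``, independently of the mode's frequency.
    """
    if basis.rc_index != 0:
        raise ValueError("basis must carry the reaction coordinate at mode 0")
    if len(effect_sizes) != len(planted_modes):
        raise ValueError("one effect size per planted mode required")
    bath_w = basis.frequencies[1:]
    lam = np.zeros_like(bath_w)
    for mode, c in zip(planted_modes, effect_sizes):
        if not 1 <= mode < basis.n_modes:
            raise ValueError(f"planted mode {mode} out of range")
        lam[mode - 1] = c * np.sqrt(2.0 * bath_w[mode - 1])
    return SurrogatePotential(
        barrier_height=barrier_height_kcal * KCALMOL_TO_HARTREE,
        barrier_width=barrier_width,
        wall_frequency=wall_frequency,
        d_ts=d_ts,
        dist_slope=dist_slope,
        bath_frequencies=bath_w,
        couplings=lam,
    )


def generate_study(
    basis: NormalModeBasis,
    potential: SurrogatePotential,
    specs: list[VibrationalStateSpec],
    seed: int,
    dt: float = 10.0,
    max_time: float = 250.0,
    stop_margin: float = 2.5,
    threshold: float = DISSOCIATION_THRESHOLD,
) -> dict[str, list[Trajectory]]:
    """Sample, kick and propagate one trajectory ensemble per state spec.

    Each spec receives a sub-seed derived deterministically from ``seed`` and
    the spec's content, so the whole study is reproducible bitwise and a
    duplicate spec receives an identical ensemble.  Returns a map from
    ``spec.label()`` to the list of trajectories.
    """
    if basis.n_modes != potential.n_modes:
        raise ValueError(
            f"basis has {basis.n_modes} modes, potential has {potential.n_modes}"
        )
    study: dict[str, list[Trajectory]] = {}
    for spec in specs:
        spec_i = replace(spec, seed=spec_subseed(seed, spec))
        ens = sample_ensemble(basis, spec_i)
        try:
            study[spec.label()] = propagate_ensemble(
                potential, ens, dt=dt, max_time=max_time,
                stop_margin=stop_margin, threshold=threshold,
            )
        except FloatingPointError as err:
            raise FloatingPointError(f"ensemble '{spec.label()}': {err}") from err
    return study
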