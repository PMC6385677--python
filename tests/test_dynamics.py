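"""Surrogate potential and velocity-Verlet propagation."""

import numpy as np
import pytest

from modetime.dynamics import (
    SurrogatePotential,
    default_study_potential,
    evaluate_potential,
    generate_study,
    propagate,
    propagate_ensemble,
    trajectory_energy,
)
from modetime.harmonic import PhaseSpaceEnsemble, PhaseSpaceSample
from modetime.labels import dissociation_time, frustration_summary
from modetime.units import AU_TIME_TO_FS
from modetime.wigner import VibrationalStateSpec


def small_potential(a=1.0e-3, lam=(0.0, 0.0, 0.0)):
    return SurrogatePotential(
        barrier_height=a,
        barrier_width=10.0,
        wall_frequency=8e-3,
        d_ts=1.55,
        dist_slope=0.06,
        bath_frequencies=np.array([2e-3, 4e-3, 8e-3]),
        couplings=np.array(lam),
    )


def test_barrier_top_and_origin_are_stationary():
    pot = small_potential(lam=(0.1, 0.0, 0.0))
    for q0 in (0.0, pot.barrier_width):
        _, g = evaluate_potential(pot, np.array([q0, 0.3, -0.2, 0.1]))
        assert g[0] == pytest.approx(
            0.0 if q0 == 0.0 else pot.barrier_height * 0.0, abs=1e-15
        )


def test_uncoupled_bath_energy_is_harmonic():
    pot = small_potential()
    a = 0.7
    q = np.zeros(4)
    q[2] = a
    e, _ = evaluate_potential(pot, q)
    assert e == pytest.approx(0.5 * pot.bath_frequencies[1] ** 2 * a**2, rel=1e-14)


def test_gradient_matches_central_differences():
    pot = small_potential(lam=(0.05, 0.0, -0.08))
    rng = np.random.default_rng(0)
    eps = 1e-5
    for _ in range(20):
        q = rng.normal(0, 5.0, size=4)
        _, g = evaluate_potential(pot, q)
        for k in range(4):
            qp, qm = q.copy(), q.copy()
            qp[k] += eps
            qm[k] -= eps
            ep, _ = evaluate_potential(pot, qp)
            em, _ = evaluate_potential(pot, qm)
            fd = (ep - em) / (2 * eps)
            assert g[k] == pytest.approx(fd, rel=1e-6, abs=1e-10)


def test_dimension_mismatch_rejected():
    pot = small_potential()
    with pytest.raises(ValueError, match="modes"):
        evaluate_potential(pot, np.zeros(7))


def test_harmonic_energy_conservation():
    """Relative energy error < 1e-6 over 250 fs at dt = 10 au in the regime
    where the discretisation error resolves it (w*dt < 2e-3: the instantaneous
    energy of velocity Verlet oscillates at O((w dt)^2/8), so the 1e-6 level
    is meaningful only for slow modes)."""
    pot = SurrogatePotential(
        barrier_height=1e-12,
        barrier_width=10.0,
        wall_frequency=8e-3,
        d_ts=1.55,
        dist_slope=0.06,
        bath_frequencies=np.array([1.0e-4, 1.3e-4, 1.8e-4]),
        couplings=np.zeros(3),
    )
    init = PhaseSpaceSample(
        r=np.array([0.0, 40.0, -25.0, 30.0]), v=np.array([0.0, 0.002, 0.001, -0.002])
    )
    traj = propagate(pot, init, dt=10.0, max_time=250.0, threshold=np.inf)
    e = trajectory_energy(pot, traj)
    assert np.abs(e - e[0]).max() / abs(e[0]) < 1e-6


def test_harmonic_energy_error_bounded_at_study_frequencies(basis, potential):
    """At the study's own frequencies the energy error stays within the
    O((w dt)^2) symplectic envelope and shows no growth between the first and
    second half of the run."""
    harm = SurrogatePotential(
        barrier_height=1e-12,
        barrier_width=potential.barrier_width,
        wall_frequency=potential.wall_frequency,
        d_ts=potential.d_ts,
        dist_slope=potential.dist_slope,
        bath_frequencies=potential.bath_frequencies,
        couplings=np.zeros_like(potential.couplings),
    )
    rng = np.random.default_rng(5)
    amp = 1.0 / np.sqrt(2.0 * potential.bath_frequencies)
    init = PhaseSpaceSample(
        r=np.concatenate([[0.0], rng.normal(0, 1, basis.n_modes - 1) * amp]),
        v=np.concatenate(
            [[0.0], rng.normal(0, 1, basis.n_modes - 1)
             * np.sqrt(potential.bath_frequencies / 2)]
        ),
    )
    traj = propagate(harm, init, dt=10.0, max_time=250.0, threshold=np.inf)
    e = trajectory_energy(harm, traj)
    err = np.abs(e - e[0])
    w_max_dt = potential.bath_frequencies.max() * 10.0
    assert err.max() < w_max_dt**2 * e[0]  # envelope, ~8x above (w dt)^2/8
    half = err.size // 2
    assert err[half:].max() < 2.0 * err[:half].max()


def test_coupled_secular_drift_small(basis, potential):
    """Secular drift < 1e-5 hartree over 250 fs for the default coupled
    potential at Wigner-scale initial conditions."""
    from modetime.dynamics import secular_energy_drift
    from modetime.wigner import sample_ensemble

    ens = sample_ensemble(
        basis, VibrationalStateSpec(quanta={}, ensemble_size=1, seed=2)
    )
    traj = propagate(
        potential, PhaseSpaceSample(ens.r[0], ens.v[0]),
        dt=10.0, max_time=250.0, threshold=np.inf,
    )
    assert secular_energy_drift(potential, traj) < 1e-5


def test_time_reversal_symmetry():
    pot = small_potential(a=1e-12)
    init = PhaseSpaceSample(
        r=np.array([-2.0, 1.0, 0.5, -0.5]), v=np.array([0.001, -0.001, 0.002, 0.0])
    )
    fwd = propagate(pot, init, dt=10.0, max_time=50.0, threshold=np.inf)
    back = propagate(
        pot,
        PhaseSpaceSample(r=fwd.r_frames[-1], v=-fwd.v_frames[-1]),
        dt=10.0,
        max_time=50.0,
        threshold=np.inf,
    )
    np.testing.assert_allclose(back.r_frames[-1], init.r, atol=1e-8)
    np.testing.assert_allclose(-back.v_frames[-1], init.v, atol=1e-8)


def test_free_particle_crossing_time():
    """Zero forces: q0(t) = v0 t, so the crossing frame is the first beyond
    (threshold displacement)/v0."""
    pot = SurrogatePotential(
        barrier_height=1e-30,
        barrier_width=10.0,
        wall_frequency=0.0,
        d_ts=1.55,
        dist_slope=0.06,
        bath_frequencies=np.zeros(2),
        couplings=np.zeros(2),
    )
    v0 = 0.05
    traj = propagate(pot, PhaseSpaceSample(np.zeros(3), np.array([v0, 0, 0])), dt=10.0)
    t_au = traj.times / AU_TIME_TO_FS
    np.testing.assert_allclose(traj.r_frames[:, 0], v0 * t_au, rtol=1e-12)
    q_star = (2.4 - pot.d_ts) / pot.dist_slope
    expected_frame = int(np.floor(q_star / (v0 * 10.0))) + 1
    assert dissociation_time(traj) == pytest.approx(
        traj.times[expected_frame], abs=1e-12
    )


def test_frame_spacing_is_quarter_femtosecond():
    pot = small_potential()
    traj = propagate(pot, PhaseSpaceSample(np.zeros(4), np.zeros(4)), dt=10.0, max_time=5.0)
    assert round(traj.times[1] - traj.times[0], 2) == 0.24


def test_single_and_ensemble_propagation_agree(potential, basis):
    rng = np.random.default_rng(2)
    r = np.concatenate([[0.0], rng.normal(0, 3.0, basis.n_modes - 1)])
    v = np.concatenate([[0.056], rng.normal(0, 0.003, basis.n_modes - 1)])
    single = propagate(potential, PhaseSpaceSample(r, v))
    batch = propagate_ensemble(
        potential, PhaseSpaceEnsemble(r[None, :], v[None, :])
    )[0]
    np.testing.assert_array_equal(single.r_frames, batch.r_frames)
    np.testing.assert_array_equal(single.cc_distance, batch.cc_distance)


def test_study_reproducible_and_produces_frustration(basis, potential, ground_study):
    spec = VibrationalStateSpec(quanta={}, ensemble_size=10)
    a = generate_study(basis, potential, [spec], seed=3)["ground"]
    b = generate_study(basis, potential, [spec], seed=3)["ground"]
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.r_frames, tb.r_frames)
    assert frustration_summary(ground_study).counts.sum() > 0


def test_uncoupled_study_has_no_mode_dependence(basis):
    """With all couplings zero the reaction coordinate decouples: every
    trajectory crosses at exactly the same time regardless of bath state.
    The barrier is set below the kick energy so the crossing happens."""
    pot = default_study_potential(
        basis, effect_sizes=(0.0, 0.0, 0.0, 0.0), barrier_height_kcal=0.8
    )
    study = generate_study(
        basis, pot, [VibrationalStateSpec(quanta={}, ensemble_size=50)], seed=4
    )
    times = np.array([dissociation_time(t) for t in study["ground"]])
    assert np.isfinite(times).all()
    assert np.ptp(times) == 0.0


def test_excited_planted_mode_accelerates_dissociation(basis, potential):
    """Exciting a barrier-coupled mode shifts the median dissociation time
    down (more frequent low-barrier windows), consistently over 3 seeds.
    Ground and excited ensembles share a seed, so every other mode's Wigner
    draws are identical and the comparison is paired."""
    from modetime.wigner import sample_ensemble

    for seed in (1, 2, 3):
        ground = sample_ensemble(
            basis, VibrationalStateSpec(quanta={}, ensemble_size=250, seed=seed)
        )
        excited = sample_ensemble(
            basis, VibrationalStateSpec(quanta={3: 1}, ensemble_size=250, seed=seed)
        )
        t_g = np.array(
            [dissociation_time(t) for t in propagate_ensemble(potential, ground)]
        )
        t_e = np.array(
            [dissociation_time(t) for t in propagate_ensemble(potential, excited)]
        )
        assert np.median(t_e[np.isfinite(t_e)]) < np.median(t_g[np.isfinite(t_g)])
        both = np.isfinite(t_g) & np.isfinite(t_e)
        assert np.mean(t_e[both] - t_g[both]) < 0


def test_default_ground_study_statistics(basis, potential):
    """Tuned defaults: >=95% dissociation within 250 fs and >=30 fs IQR of
    the dissociation times (averaged over three 250-trajectory ensembles)."""
    fracs, iqrs = [], []
    for seed in (1, 2, 3):
        study = generate_study(
            basis, potential,
            [VibrationalStateSpec(quanta={}, ensemble_size=250)], seed=seed,
        )
        times = np.array([dissociation_time(t) for t in study["ground"]])
        fin = times[np.isfinite(times)]
        fracs.append(np.isfinite(times).mean())
        iqrs.append(np.percentile(fin, 75) - np.percentile(fin, 25))
    assert np.mean(fracs) >= 0.95
    assert np.mean(iqrs) >= 30.0


def test_divergent_forces_raise_with_frame_index():
    """A bath mode far beyond the integrator's stability limit (w dt > 2)
    grows exponentially until the state overflows."""
    pot = SurrogatePotential(
        barrier_height=1e-12,
        barrier_width=10.0,
        wall_frequency=1e-3,
        d_ts=1.55,
        dist_slope=0.06,
        bath_frequencies=np.array([0.5]),
        couplings=np.zeros(1),
    )
    init = PhaseSpaceSample(r=np.array([0.0, 1.0]), v=np.zeros(2))
    with pytest.raises(FloatingPointError, match="frame"):
        propagate(pot, init, dt=50.0, max_time=250.0, threshold=np.inf)
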