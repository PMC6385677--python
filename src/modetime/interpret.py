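"""Hypothesis testing with a trained model: excited-ensemble half-times.

A trained posterior replaces the dynamics: for an ensemble of Wigner-sampled
initial conditions (ground or vibrationally excited), the model predicts the
individual dissociation times, and the ensemble half-time is the ceil(n/2)-th
smallest prediction.  Scanning single and pairwise excitations reveals which
nuclear coordinates accelerate or delay dissociation; z-scores normalise each
pairwise column to expose second-order effects.  Confidence intervals are
percentile bootstrap over the n predicted times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from modetime.bnn import BNNResults
from modetime.dynamics import SurrogatePotential, generate_study
from modetime.harmonic import NormalModeBasis
from modetime.labels import dissociation_time, half_time
from modetime.wigner import VibrationalStateSpec, sample_ensemble, spec_subseed

__all__ = [
    "HalfTimeTable",
    "PairwiseScan",
    "ComparisonReport",
    "predict_half_times",
    "simulate_half_times",
    "pairwise_scan",
    "mode_zscores",
    "compare_to_simulation",
]


@dataclass
class HalfTimeTable:
    """Half-times (fs) with bootstrap 95% confidence intervals per ensemble."""

    labels: list[str]
    half_times: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reference: str = "ground"
    source: str = "predicted"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ensemble": self.labels,
                "half_time_fs": self.half_times,
                "ci95_low": self.ci_low,
                "ci95_high": self.ci_high,
                "is_reference": [lb == self.reference for lb in self.labels],
            }
        )

    def __getitem__(self, label: str) -> float:
        return float(self.half_times[self.labels.index(label)])


@dataclass
class PairwiseScan:
    """Symmetric matrix of predicted half-times for double excitations.

    ``modes`` are the scanned mode indices (the reaction coordinate is never
    excited); ``h[i, j]`` is the half-time with modes[i] and modes[j] both
    singly excited, and the diagonal holds the single-excitation half-times.
    """

    modes: np.ndarray
    h: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.h,
            index=[f"mode{m}" for m in self.modes],
            columns=[f"mode{m}" for m in self.modes],
        )


@dataclass
class ComparisonReport:
    """Predicted-vs-simulated half-time errors.

    ``rmsd_other``/``rmsd_ratio`` are filled when a second model's table is
    supplied: the ratio is other/primary, so values above 1 mean the primary
    model is closer to the simulation.
    """

    labels: list[str]
    predicted: np.ndarray
    simulated: np.ndarray
    errors: np.ndarray
    rmsd: float
    kendall_tau: float
    rmsd_other: float | None = None
    rmsd_ratio: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ensemble": self.labels,
                "predicted_fs": self.predicted,
                "simulated_fs": self.simulated,
                "error_fs": self.errors,
            }
        )


def _bootstrap_ci(
    values: np.ndarray, seed: int, n_boot: int = 2000, level: float = 0.95
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = values.size
    stats = np.empty(n_boot)
    for b in range(n_boot):
        stats[b] = half_time(values[rng.integers(0, n, size=n)])
    alpha = (1.0 - level) / 2.0
    finite = stats[np.isfinite(stats)]
    if finite.size < n_boot // 2:
        return float("inf"), float("inf")
    return float(np.quantile(finite, alpha)), float(np.quantile(finite, 1 - alpha))


def predict_half_times(
    results: BNNResults,
    basis: NormalModeBasis,
    specs: list[VibrationalStateSpec],
    n: int = 250,
    seed: int = 0,
    n_draws: int | None = None,
) -> HalfTimeTable:
    """Predict the dissociation half-time of each vibrational-state ensemble.

    For each spec: sample ``n`` initial conditions (Wigner + kick), build the
    model's features from them, predict the mean dissociation times, and take
    the ensemble half-time with a bootstrap 95% CI.
    """
    with_v = results.posterior.n_features == 2 * basis.n_modes
    if not with_v and results.posterior.n_features != basis.n_modes:
        raise ValueError(
            f"posterior expects {results.posterior.n_features} features; "
            f"basis provides {basis.n_modes} (or twice that with velocities)"
        )
    labels, hts, lo, hi = [], [], [], []
    for spec in specs:
        spec_n = replace(spec, ensemble_size=n)
        sub = spec_subseed(seed, spec_n)
        ens = sample_ensemble(basis, replace(spec_n, seed=sub))
        feats = np.hstack([ens.r, ens.v]) if with_v else ens.r
        times, _ = results.predict(feats, n_draws=n_draws, seed=sub)
        labels.append(spec.label())
        hts.append(half_time(times))
        ci = _bootstrap_ci(times, seed=sub + 1)
        lo.append(ci[0])
        hi.append(ci[1])
    return HalfTimeTable(
        labels=labels,
        half_times=np.array(hts),
        ci_low=np.array(lo),
        ci_high=np.array(hi),
        source="predicted",
    )


def simulate_half_times(
    basis: NormalModeBasis,
    potential: SurrogatePotential,
    specs: list[VibrationalStateSpec],
    n: int = 250,
    seed: int = 0,
    **propagate_kwargs,
) -> HalfTimeTable:
    """Half-times of actually propagated ensembles (the numerical experiment)."""
    study = generate_study(
        basis, potential, [replace(s, ensemble_size=n) for s in specs],
        seed=seed, **propagate_kwargs,
    )
    labels, hts, lo, hi = [], [], [], []
    for i, spec in enumerate(specs):
        times = np.array([dissociation_time(t) for t in study[spec.label()]])
        labels.append(spec.label())
        hts.append(half_time(times))
        ci = _bootstrap_ci(times, seed=seed + 7919 * (i + 1))
        lo.append(ci[0])
        hi.append(ci[1])
    return HalfTimeTable(
        labels=labels,
        half_times=np.array(hts),
        ci_low=np.array(lo),
        ci_high=np.array(hi),
        source="simulated",
    )


def pairwise_scan(
    results: BNNResults,
    basis: NormalModeBasis,
    n: int = 250,
    seed: int = 0,
    n_draws: int = 25,
    modes: list[int] | None = None,
) -> PairwiseScan:
    """Predicted half-times for all unordered pairs of singly excited modes.

    The reaction coordinate is excluded.  Each pair is evaluated once and
    mirrored, so the matrix is symmetric by construction; the diagonal holds
    the single-excitation half-times.
    """
    if modes is None:
        modes = [m for m in range(basis.n_modes) if m != basis.rc_index]
    modes = np.asarray(modes, dtype=int)
    specs = []
    cells = []
    for a in range(modes.size):
        specs.append(VibrationalStateSpec(quanta={int(modes[a]): 1}))
        cells.append((a, a))
        for b in range(a + 1, modes.size):
            specs.append(
                VibrationalStateSpec(quanta={int(modes[a]): 1, int(modes[b]): 1})
            )
            cells.append((a, b))
    table = predict_half_times(results, basis, specs, n=n, seed=seed, n_draws=n_draws)
    h = np.full((modes.size, modes.size), np.nan)
    for (a, b), val in zip(cells, table.half_times):
        h[a, b] = val
        h[b, a] = val
    return PairwiseScan(modes=modes, h=h)


def mode_zscores(scan: PairwiseScan) -> np.ndarray:
    """Column-normalised z-scores of the pairwise half-time matrix.

    ``z[m, n] = (H[m, n] - mean_m' H[m', n]) / std_m' H[m', n]`` with the
    statistics over the whole column ``n`` (population std): how exciting
    mode ``m`` shifts the half-time obtained with mode ``n`` already excited.
    Each column has mean 0 and variance 1 by construction; a column with zero
    spread is degenerate and flagged with NaN.
    """
    h = scan.h
    if np.any(np.isnan(h)):
        raise ValueError("pairwise matrix is incomplete")
    z = np.full_like(h, np.nan)
    for n_col in range(h.shape[1]):
        col = h[:, n_col]
        sd = col.std()
        if sd < 1e-12:
            continue  # degenerate column stays NaN
        z[:, n_col] = (col - col.mean()) / sd
    return z


def compare_to_simulation(
    predicted: HalfTimeTable,
    simulated: HalfTimeTable,
    other_predicted: HalfTimeTable | None = None,
) -> ComparisonReport:
    """Per-ensemble error and overall RMSD of predicted vs simulated half-times.

    When a second model's predictions are supplied the report also carries its
    RMSD and the ratio other/primary.
    """
    if predicted.labels != simulated.labels:
        raise ValueError("predicted and simulated tables cover different ensembles")
    err = predicted.half_times - simulated.half_times
    rmsd = float(np.sqrt(np.mean(err**2)))
    tau = kendalltau(predicted.half_times, simulated.half_times).statistic
    rmsd_other = ratio = None
    if other_predicted is not None:
        if other_predicted.labels != simulated.labels:
            raise ValueError("second table covers different ensembles")
        err2 = other_predicted.half_times - simulated.half_times
        rmsd_other = float(np.sqrt(np.mean(err2**2)))
        ratio = rmsd_other / rmsd if rmsd > 0 else float("inf")
    return ComparisonReport(
        labels=list(predicted.labels),
        predicted=predicted.half_times.copy(),
        simulated=simulated.half_times.copy(),
        errors=err,
        rmsd=rmsd,
        kendall_tau=float(tau),
        rmsd_other=rmsd_other,
        rmsd_ratio=ratio,
    )
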