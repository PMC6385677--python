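"""Bayesian neural network regression of time-to-dissociation.

Model
-----
A feedforward network ``y = f_act(w x + b)`` applied layer by layer, with a
linear output unit, regresses the (standardized) time remaining until
dissociation on the (standardized) normal-mode features.  Every weight and
bias carries a Laplace(0, prior_scale) prior — the Bayesian analogue of L1
regularisation — which prunes connections from irrelevant inputs and makes
first-layer coefficient magnitudes interpretable as feature relevances.

Inference is mean-field variational: each parameter gets an independent
Gaussian ``q(theta) = N(mu, sigma^2)``, and the evidence lower bound

    ELBO = E_q[ log N(y | f(x; theta), sigma_n^2) ] - KL(q || p)

is maximised with Adam over ``mu``, ``log sigma`` and the homoscedastic noise
scale ``sigma_n``.  The likelihood term uses a single reparameterised draw per
step; the KL against the Laplace prior is analytic:

    KL(N(mu, s^2) || Laplace(0, b)) = -log(s sqrt(2 pi e)) + log(2 b) + E|w|/b
    E|w| = s sqrt(2/pi) exp(-mu^2 / 2 s^2) + mu erf(mu / (s sqrt(2)))

Predictive means and uncertainties come from Monte-Carlo forward passes with
weights drawn from the variational posterior; the reported standard deviation
is the spread of the network output (parameter uncertainty), de-standardized
to fs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from modetime.curation import CuratedDataset

__all__ = [
    "BNNConfig",
    "BNNPosterior",
    "EvaluationMetrics",
    "RelevanceProfile",
    "DissociationTimeBNN",
    "BNNResults",
    "train",
    "hyperparameter_search",
    "ACTIVATIONS",
]

_SQRT_2_PI = np.sqrt(2.0 / np.pi)


def _tanh(x):
    return np.tanh(x)


def _tanh_grad(x, y):
    return 1.0 - y * y


def _rectifier(x):
    return np.maximum(x, 0.0)


def _rectifier_grad(x, y):
    return (x > 0).astype(float)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _sigmoid_grad(x, y):
    return y * (1.0 - y)


ACTIVATIONS = {
    "tanh": (_tanh, _tanh_grad),
    "rectifier": (_rectifier, _rectifier_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
}


@dataclass
class BNNConfig:
    """Hyperparameters of the network and its variational optimisation."""

    hidden_layers: tuple[int, ...] = (64, 32)
    activation: str = "tanh"
    prior_scale: float = 0.7
    learn_rate: float = 3e-3
    epochs: int = 900
    batch_size: int = 256
    n_posterior_draws: int = 100
    seed: int = 0
    init_sigma: float = 0.05
    noise_init: float = 0.2
    average_tail: float = 0.15  # fraction of final epochs averaged (Polyak)

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(int(h) for h in self.hidden_layers)
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden-layer widths must be >= 1")
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        if self.n_posterior_draws < 1:
            raise ValueError("n_posterior_draws must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; choose from {sorted(ACTIVATIONS)}"
            )

    def to_dict(self) -> dict:
        return {
            "hidden_layers": list(self.hidden_layers),
            "activation": self.activation,
            "prior_scale": self.prior_scale,
            "learn_rate": self.learn_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "n_posterior_draws": self.n_posterior_draws,
            "seed": self.seed,
            "init_sigma": self.init_sigma,
            "noise_init": self.noise_init,
            "average_tail": self.average_tail,
        }


@dataclass
class BNNPosterior:
    """Variational location/scale parameters for every weight and bias.

    ``w_mu[l]`` has shape (n_in, n_out) for layer ``l``; scales are stored as
    ``log sigma``.  Standardization constants travel with the posterior so
    predictions can be issued from raw features.
    """

    w_mu: list[np.ndarray]
    w_logsig: list[np.ndarray]
    b_mu: list[np.ndarray]
    b_logsig: list[np.ndarray]
    log_noise: float
    activation: str
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    feature_names: list[str]

    @property
    def n_layers(self) -> int:
        return len(self.w_mu)

    @property
    def n_features(self) -> int:
        return self.w_mu[0].shape[0]


@dataclass
class EvaluationMetrics:
    """Accuracy of predictive means against labels, in fs."""

    rmsd: float
    mad: float
    r2: float
    n: int

    def __str__(self) -> str:
        r2 = "undefined" if np.isnan(self.r2) else f"{self.r2:.3f}"
        return f"RMSD {self.rmsd:.2f} fs, MAD {self.mad:.2f} fs, r^2 {r2} (n={self.n})"


@dataclass
class RelevanceProfile:
    """First-layer coefficient-magnitude distributions per input feature."""

    magnitudes: np.ndarray  # (n_features, n_hidden): |location| of weight j->h
    summary: np.ndarray  # median over hidden neurons, per feature
    feature_names: list[str]

    def ranking(self) -> np.ndarray:
        """Feature indices sorted by decreasing relevance summary."""
        return np.argsort(-self.summary, kind="stable")

    def mode_summary(self, n_modes: int) -> np.ndarray:
        """Mode-level relevance: the larger of a mode's r/v feature summaries.

        A normal mode counts as relevant when *either* its position or its
        velocity feature carries weight, mirroring how position-only and
        position+velocity models are read side by side.
        """
        by_name = dict(zip(self.feature_names, self.summary))
        out = np.empty(n_modes)
        for i in range(n_modes):
            vals = [by_name.get(f"r_{i}", 0.0), by_name.get(f"v_{i}", 0.0)]
            out[i] = max(vals)
        return out

    def mode_ranking(self, n_modes: int) -> np.ndarray:
        """Mode indices sorted by decreasing mode-level relevance."""
        return np.argsort(-self.mode_summary(n_modes), kind="stable")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.magnitudes, index=self.feature_names)
        df.columns = [f"neuron_{h}" for h in range(self.magnitudes.shape[1])]
        df.insert(0, "median_magnitude", self.summary)
        return df


def _init_params(
    n_features: int, config: BNNConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Flat parameter list: [w_mu, w_logsig, b_mu, b_logsig] per layer + log_noise."""
    sizes = [n_features, *config.hidden_layers, 1]
    params: list[np.ndarray] = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        w_mu = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))
        params += [
            w_mu,
            np.full((n_in, n_out), np.log(config.init_sigma)),
            np.zeros(n_out),
            np.full(n_out, np.log(config.init_sigma)),
        ]
    params.append(np.array([np.log(config.noise_init)]))
    return params


def _unpack(params: list[np.ndarray]) -> tuple[list, list, list, list, float]:
    n_layers = (len(params) - 1) // 4
    w_mu = [params[4 * l] for l in range(n_layers)]
    w_ls = [params[4 * l + 1] for l in range(n_layers)]
    b_mu = [params[4 * l + 2] for l in range(n_layers)]
    b_ls = [params[4 * l + 3] for l in range(n_layers)]
    return w_mu, w_ls, b_mu, b_ls, float(params[-1][0])


def _forward(x, weights, biases, act):
    """Forward pass; returns output (n,) and per-layer (pre-act, post-act) cache."""
    f, _ = ACTIVATIONS[act]
    h = x
    cache = []
    n_layers = len(weights)
    for l, (w, b) in enumerate(zip(weights, biases)):
        z = h @ w + b
        a = z if l == n_layers - 1 else f(z)
        cache.append((h, z, a))
        h = a
    return h[:, 0], cache


def _backward(dout, cache, weights, act):
    """Gradient of a scalar loss wrt weights, biases and input activations."""
    _, fgrad = ACTIVATIONS[act]
    n_layers = len(weights)
    dw = [None] * n_layers
    db = [None] * n_layers
    delta = dout[:, None]  # (n, 1) gradient wrt output layer activation
    for l in range(n_layers - 1, -1, -1):
        h, z, a = cache[l]
        if l != n_layers - 1:
            delta = delta * fgrad(z, a)
        dw[l] = h.T @ delta
        db[l] = delta.sum(axis=0)
        delta = delta @ weights[l].T
    return dw, db


def _kl_and_grads(mu, logsig, prior_b):
    """Analytic KL(N(mu, s)||Laplace(0, b)) summed over the array, with grads."""
    s = np.exp(logsig)
    z = mu / (s * np.sqrt(2.0))
    e_abs = s * _SQRT_2_PI * np.exp(-(z**2)) + mu * erf(z)
    kl = -logsig - 0.5 * np.log(2.0 * np.pi * np.e) + np.log(2.0 * prior_b) + e_abs / prior_b
    dmu = erf(z) / prior_b
    dlogsig = -1.0 + s * _SQRT_2_PI * np.exp(-(z**2)) / prior_b
    return float(kl.sum()), dmu, dlogsig


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class DissociationTimeBNN:
    """Model object: a Laplace-prior BNN bound to a curated dataset.

    Parameters
    ----------
    dataset : CuratedDataset
        Standardization constants are taken from its training split.
    config : BNNConfig, optional

    Examples
    --------
    >>> model = DissociationTimeBNN(dataset, BNNConfig(hidden_layers=(48,)))
    >>> results = model.fit()
    >>> print(results.evaluate("test"))
    """

    def __init__(self, dataset: CuratedDataset, config: BNNConfig | None = None):
        if dataset.y_train.size == 0:
            raise ValueError("training split is empty")
        self.dataset = dataset
        self.config = config or BNNConfig()

    @classmethod
    def from_dataframe(
        cls,
        frames: pd.DataFrame,
        config: BNNConfig | None = None,
        seed: int = 0,
        **assemble_kwargs,
    ) -> "DissociationTimeBNN":
        """Build the model straight from a labelled-frames table."""
        from modetime.curation import assemble

        return cls(assemble(frames, seed=seed, **assemble_kwargs), config)

    def fit(self, seed: int | None = None) -> "BNNResults":
        """Maximise the ELBO with Adam; returns a results object.

        Deterministic for a fixed seed (default: ``config.seed``).
        """
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        ds = self.dataset
        x = ds.standardize_x(ds.x_train)
        y = ds.standardize_y(ds.y_train)
        n, d = x.shape
        rng = np.random.default_rng(cfg.seed)
        params = _init_params(d, cfg, rng)
        opt = _Adam(params, cfg.learn_rate)
        prior_b = cfg.prior_scale
        n_layers = (len(params) - 1) // 4
        history = []
        # Polyak averaging: accumulate the variational parameters over the
        # final epochs so the reported posterior is free of the stochastic-
        # gradient jitter of any single end state
        tail_start = max(0, cfg.epochs - max(1, int(round(cfg.average_tail * cfg.epochs))))
        averaged = [np.zeros_like(p) for p in params]
        n_averaged = 0

        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                scale = n / idx.size  # minibatch -> full-data likelihood scale

                w_mu, w_ls, b_mu, b_ls, log_noise = _unpack(params)
                eps_w = [rng.standard_normal(m.shape) for m in w_mu]
                eps_b = [rng.standard_normal(m.shape) for m in b_mu]
                weights = [m + np.exp(ls) * e for m, ls, e in zip(w_mu, w_ls, eps_w)]
                biases = [m + np.exp(ls) * e for m, ls, e in zip(b_mu, b_ls, eps_b)]

                pred, cache = _forward(xb, weights, biases, cfg.activation)
                err = pred - yb
                noise_var = np.exp(2.0 * log_noise)
                nll = scale * (
                    0.5 * np.sum(err**2) / noise_var
                    + idx.size * (log_noise + 0.5 * np.log(2 * np.pi))
                )
                dpred = scale * err / noise_var
                dw, db = _backward(dpred, cache, weights, cfg.activation)
                d_log_noise = scale * (
                    -np.sum(err**2) / noise_var + idx.size
                )

                grads = []
                kl_total = 0.0
                for l in range(n_layers):
                    kl_w, kmu_w, kls_w = _kl_and_grads(w_mu[l], w_ls[l], prior_b)
                    kl_b, kmu_b, kls_b = _kl_and_grads(b_mu[l], b_ls[l], prior_b)
                    kl_total += kl_w + kl_b
                    sig_w, sig_b = np.exp(w_ls[l]), np.exp(b_ls[l])
                    grads += [
                        dw[l] + kmu_w,
                        dw[l] * eps_w[l] * sig_w + kls_w,
                        db[l] + kmu_b,
                        db[l] * eps_b[l] * sig_b + kls_b,
                    ]
                grads.append(np.array([d_log_noise]))

                loss = (nll + kl_total) / n
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"variational optimisation diverged at epoch {epoch}"
                    )
                grads = [g / n for g in grads]
                opt.step(params, grads)
                epoch_loss += loss * idx.size / n
            history.append(epoch_loss)
            if epoch >= tail_start:
                for acc, p in zip(averaged, params):
                    acc += p
                n_averaged += 1

        params = [acc / n_averaged for acc in averaged]
        w_mu, w_ls, b_mu, b_ls, log_noise = _unpack(params)
        posterior = BNNPosterior(
            w_mu=w_mu, w_logsig=w_ls, b_mu=b_mu, b_logsig=b_ls,
            log_noise=log_noise, activation=cfg.activation,
            x_mean=ds.x_mean.copy(), x_scale=ds.x_scale.copy(),
            y_mean=ds.y_mean, y_scale=ds.y_scale,
            feature_names=list(ds.feature_names),
        )
        return BNNResults(self, posterior, np.asarray(history), cfg)


def train(dataset: CuratedDataset, config: BNNConfig) -> tuple[BNNPosterior, np.ndarray]:
    """Functional wrapper: fit a model and return (posterior, loss history)."""
    res = DissociationTimeBNN(dataset, config).fit()
    return res.posterior, res.history


def posterior_predict(
    posterior: BNNPosterior,
    features: np.ndarray,
    n_draws: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and standard deviation (fs) for raw features.

    Performs ``n_draws`` forward passes with parameters sampled from the
    variational posterior; the spread reflects parameter uncertainty.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != posterior.n_features:
        raise ValueError(
            f"features have {x.shape[1]} columns, posterior expects {posterior.n_features}"
        )
    xs = (x - posterior.x_mean) / posterior.x_scale
    rng = np.random.default_rng(seed)
    outs = np.empty((n_draws, x.shape[0]))
    for k in range(n_draws):
        weights = [
            m + np.exp(ls) * rng.standard_normal(m.shape)
            for m, ls in zip(posterior.w_mu, posterior.w_logsig)
        ]
        biases = [
            m + np.exp(ls) * rng.standard_normal(m.shape)
            for m, ls in zip(posterior.b_mu, posterior.b_logsig)
        ]
        outs[k], _ = _forward(xs, weights, biases, posterior.activation)
    mean = outs.mean(axis=0) * posterior.y_scale + posterior.y_mean
    std = outs.std(axis=0) * posterior.y_scale
    return mean, std


class BNNResults:
    """Fitted-model results: posterior, diagnostics, relevance, persistence."""

    def __init__(
        self,
        model: DissociationTimeBNN | None,
        posterior: BNNPosterior,
        history: np.ndarray,
        config: BNNConfig,
    ):
        self.model = model
        self.posterior = posterior
        self.history = history
        self.config = config

    def predict(
        self, features: np.ndarray, n_draws: int | None = None, seed: int = 0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and uncertainty (fs) for raw (unstandardized) features."""
        n_draws = n_draws or self.config.n_posterior_draws
        return posterior_predict(self.posterior, features, n_draws, seed)

    def evaluate(
        self,
        split: str | tuple[np.ndarray, np.ndarray] = "test",
        n_draws: int | None = None,
        seed: int = 0,
    ) -> EvaluationMetrics:
        """RMSD, MAD and r^2 of predictive means on a split or (x, y) pair."""
        if isinstance(split, str):
            if self.model is None:
                raise ValueError("results were loaded without a dataset; pass (x, y)")
            x, y = self.model.dataset.split(split)
        else:
            x, y = split
        if y.size == 0:
            raise ValueError("evaluation split is empty")
        pred, _ = self.predict(x, n_draws=n_draws, seed=seed)
        err = pred - y
        rmsd = float(np.sqrt(np.mean(err**2)))
        mad = float(np.mean(np.abs(err)))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(err**2)) / ss_tot
        return EvaluationMetrics(rmsd=rmsd, mad=mad, r2=r2, n=int(y.size))

    def coefficient_magnitudes(self) -> RelevanceProfile:
        """Per-feature distribution of first-layer |weight location| values.

        The across-neuron median summarises each input feature's relevance;
        Laplace priors shrink connections from irrelevant inputs toward zero,
        so larger magnitudes indicate more influential features.
        """
        mags = np.abs(self.posterior.w_mu[0])  # (n_features, n_hidden)
        return RelevanceProfile(
            magnitudes=mags,
            summary=np.median(mags, axis=1),
            feature_names=list(self.posterior.feature_names),
        )

    def overfitting_bound(self) -> float:
        """Norm-based generalisation-gap bound (fs) from Rademacher complexity.

        Uses the layer-product bound for k-layer networks with 1-Lipschitz
        activations: ``2 (prod_l B_l) X_max / sqrt(m)`` where ``B_l`` is the
        largest 1-norm of a neuron's incoming weight locations in layer ``l``,
        ``X_max`` the largest standardized input infinity-norm and ``m`` the
        training-set size; scaled to fs by the label scale.  A diagnostic, not
        a tight estimate.
        """
        if self.model is None:
            raise ValueError("overfitting_bound requires the training dataset")
        ds = self.model.dataset
        m = ds.y_train.size
        x_max = float(np.abs(ds.standardize_x(ds.x_train)).max())
        prod = 1.0
        for w in self.posterior.w_mu:
            prod *= float(np.abs(w).sum(axis=0).max())
        return 2.0 * prod * x_max / np.sqrt(m) * self.posterior.y_scale

    def summary(self) -> str:
        """Human-readable fit summary table."""
        cfg = self.config
        lines = [
            "Dissociation-time BNN (Laplace prior, mean-field VI)",
            "=" * 52,
            f"architecture      : {self.posterior.n_features} -> "
            + " -> ".join(map(str, cfg.hidden_layers))
            + " -> 1",
            f"activation        : {cfg.activation}",
            f"prior scale       : {cfg.prior_scale}",
            f"epochs / batch    : {cfg.epochs} / {cfg.batch_size}",
            f"final ELBO loss   : {self.history[-1]:.4f} (per frame)",
            f"noise scale       : {np.exp(self.posterior.log_noise) * self.posterior.y_scale:.2f} fs",
        ]
        if self.model is not None:
            for split in ("train", "val", "test"):
                x, y = self.model.dataset.split(split)
                if y.size:
                    lines.append(f"{split:<18}: {self.evaluate(split)}")
            lines.append(f"overfit bound     : {self.overfitting_bound():.2f} fs")
        top = self.coefficient_magnitudes()
        rank = top.ranking()[:6]
        names = [top.feature_names[i] for i in rank]
        lines.append("top features      : " + ", ".join(names))
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialise posterior + config to a single .npz archive."""
        post = self.posterior
        arrays = {}
        for l in range(post.n_layers):
            arrays[f"w_mu_{l}"] = post.w_mu[l]
            arrays[f"w_logsig_{l}"] = post.w_logsig[l]
            arrays[f"b_mu_{l}"] = post.b_mu[l]
            arrays[f"b_logsig_{l}"] = post.b_logsig[l]
        manifest = {
            "n_layers": post.n_layers,
            "log_noise": post.log_noise,
            "activation": post.activation,
            "y_mean": post.y_mean,
            "y_scale": post.y_scale,
            "feature_names": post.feature_names,
            "config": self.config.to_dict(),
        }
        np.savez(
            path,
            manifest=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
            x_mean=post.x_mean,
            x_scale=post.x_scale,
            history=self.history,
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "BNNResults":
        with np.load(path) as data:
            manifest = json.loads(bytes(data["manifest"]).decode())
            nl = manifest["n_layers"]
            post = BNNPosterior(
                w_mu=[data[f"w_mu_{l}"] for l in range(nl)],
                w_logsig=[data[f"w_logsig_{l}"] for l in range(nl)],
                b_mu=[data[f"b_mu_{l}"] for l in range(nl)],
                b_logsig=[data[f"b_logsig_{l}"] for l in range(nl)],
                log_noise=manifest["log_noise"],
                activation=manifest["activation"],
                x_mean=data["x_mean"],
                x_scale=data["x_scale"],
                y_mean=manifest["y_mean"],
                y_scale=manifest["y_scale"],
                feature_names=manifest["feature_names"],
            )
            cfg_d = manifest["config"]
            cfg_d["hidden_layers"] = tuple(cfg_d["hidden_layers"])
            return cls(None, post, data["history"].copy(), BNNConfig(**cfg_d))


def hyperparameter_search(
    space: dict[str, list],
    dataset: CuratedDataset,
    budget: int = 10,
    seed: int = 0,
) -> tuple[BNNConfig, pd.DataFrame]:
    """Random search over BNNConfig fields, scored by validation MAD.

    ``space`` maps config field names to candidate value lists.  Returns the
    best configuration and a leaderboard sorted by score; candidates whose
    optimisation diverged are recorded with an infinite score.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    best_cfg, best_score = None, np.inf
    for trial in range(budget):
        choice = {k: v[rng.integers(len(v))] for k, v in space.items()}
        cfg = BNNConfig(**choice, seed=int(rng.integers(2**31)))
        try:
            res = DissociationTimeBNN(dataset, cfg).fit()
            score = res.evaluate("val").mad
        except RuntimeError:
            score = np.inf
        rows.append({"trial": trial, **choice, "val_mad": score})
        if score < best_score:
            best_cfg, best_score = cfg, score
    if best_cfg is None or not np.isfinite(best_score):
        raise RuntimeError("all hyperparameter-search candidates diverged")
    board = pd.DataFrame(rows).sort_values("val_mad").reset_index(drop=True)
    return best_cfg, board
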