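"""1-D denoising diffusion over segmented heartbeats, used to rebalance the
class distribution.

Forward process: a Markov chain q(x_t | x_{t-1}) = N(sqrt(1-beta_t) x_{t-1},
beta_t I) with strictly increasing variances beta_1 < ... < beta_T, whose
closed-form marginal is x_t = sqrt(abar_t) x_0 + sqrt(1-abar_t) eps with
abar_t the cumulative product of (1-beta_s).  At large T, abar_T ~ 0 and x_T
is pure noise.

Reverse process: ancestral sampling with a learned noise predictor
eps_theta(x_t, t); the reverse mean is mu = (x_t - beta_t/sqrt(1-abar_t) *
eps_theta) / sqrt(alpha_t) and sigma_t^2 is beta_t (default) or the posterior
variance beta_t (1-abar_{t-1})/(1-abar_t).

The predictor is a small 1-D convolutional network whose input stacks the
noisy signal with fixed sinusoidal position features (so a translation-
invariant conv stack can represent position-dependent beat morphology) and a
broadcast sinusoidal embedding of the timestep.  Training minimizes the
simplified epsilon-prediction MSE.  Beats are z-standardized per dataset
before diffusion and de-standardized after sampling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io import Beat
from .nn.functional import mse


@dataclass
class NoiseSchedule:
    """Forward-process variances and derived quantities."""

    betas: np.ndarray
    sigma_kind: str = "beta"  # "beta" | "posterior"

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 1 or self.betas.size < 2:
            raise ValueError("need at least two diffusion steps")
        if np.any(self.betas <= 0) or np.any(self.betas >= 1):
            raise ValueError("betas must lie in (0, 1)")
        if np.any(np.diff(self.betas) <= 0):
            raise ValueError("betas must be strictly increasing")
        if self.sigma_kind not in ("beta", "posterior"):
            raise ValueError("sigma_kind must be 'beta' or 'posterior'")
        self.alphas = 1.0 - self.betas
        self.alpha_bars = np.cumprod(self.alphas)

    @property
    def T(self) -> int:
        return self.betas.size

    def sigma(self, t: int) -> float:
        """Reverse-step standard deviation at step t (1-based)."""
        b = self.betas[t - 1]
        if self.sigma_kind == "beta" or t == 1:
            return float(np.sqrt(b))
        abar_prev = self.alpha_bars[t - 2]
        abar = self.alpha_bars[t - 1]
        return float(np.sqrt(b * (1 - abar_prev) / (1 - abar)))


def make_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.02,
                  kind: str = "linear", sigma_kind: str = "beta") -> NoiseSchedule:
    """Linear beta schedule (the canonical default)."""
    if T < 2:
        raise ValueError("T must be >= 2")
    if not 0 < beta_start < beta_end < 1:
        raise ValueError("need 0 < beta_start < beta_end < 1")
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    return NoiseSchedule(np.linspace(beta_start, beta_end, T), sigma_kind)


def forward_sample(x0: np.ndarray, t: int, schedule: NoiseSchedule,
                   seed_or_rng=None):
    """Single-shot draw of x_t ~ q(x_t | x_0) via the closed-form marginal."""
    if not 1 <= t <= schedule.T:
        raise ValueError(f"t must lie in [1, {schedule.T}]")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    x0 = np.asarray(x0, dtype=float)
    eps = rng.standard_normal(x0.shape)
    abar = schedule.alpha_bars[t - 1]
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps


def forward_chain(x0: np.ndarray, t: int, schedule: NoiseSchedule, rng):
    """Iterate q(x_s | x_{s-1}) s = 1..t step by step (reference path for the
    distributional-equivalence check)."""
    x = np.asarray(x0, dtype=float)
    for s in range(t):
        b = schedule.betas[s]
        x = np.sqrt(1.0 - b) * x + np.sqrt(b) * rng.standard_normal(x.shape)
    return x


# ---------------------------------------------------------------------------
# noise-prediction network
# ---------------------------------------------------------------------------

@dataclass
class DdpmTrainConfig:
    steps: int = 400
    batch_size: int = 16
    lr: float = 1e-3
    hidden: int = 48
    kernel: int = 9
    n_pos: int = 16   # sinusoidal position feature channels
    n_time: int = 8   # sinusoidal timestep embedding channels


def _position_features(length: int, n_feat: int) -> np.ndarray:
    """Fixed sinusoidal position channels, shape (n_feat, length)."""
    pos = np.arange(length) / max(1, length - 1)
    feats = [pos]
    k = 1
    while len(feats) < n_feat:
        feats.append(np.sin(2 * np.pi * k * pos))
        if len(feats) < n_feat:
            feats.append(np.cos(2 * np.pi * k * pos))
        k += 1
    return np.stack(feats[:n_feat])


def _time_features(t: np.ndarray, T: int, n_feat: int) -> np.ndarray:
    """Sinusoidal embedding of normalized timesteps, shape (len(t), n_feat)."""
    frac = np.asarray(t, dtype=float)[:, None] / T
    k = np.arange(1, n_feat // 2 + 1)[None, :]
    emb = np.concatenate([np.sin(np.pi * k * frac), np.cos(np.pi * k * frac)], axis=1)
    return emb[:, :n_feat]


class DenoiserModel(nn.Module):
    """eps_theta(x_t, t) over fixed-length signals; output shape == input."""

    def __init__(self, length: int, cfg: DdpmTrainConfig, seed: int = 0):
        super().__init__()
        self.length = length
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c_in = 1 + cfg.n_pos + cfg.n_time
        self.net = nn.Sequential(
            nn.Conv1d(c_in, cfg.hidden, cfg.kernel, rng),
            nn.ReLU(),
            nn.Conv1d(cfg.hidden, cfg.hidden, cfg.kernel, rng),
            nn.ReLU(),
            nn.Conv1d(cfg.hidden, 1, cfg.kernel, rng),
        )
        self._pos = _position_features(length, cfg.n_pos)
        # set once training sees data; identity until then
        self.norm_mean = 0.0
        self.norm_std = 1.0

    def predict_eps(self, x_t: np.ndarray, t: np.ndarray, T: int) -> np.ndarray:
        """Forward pass on standardized x_t, shape (N, L) -> (N, L)."""
        n, length = x_t.shape
        pos = np.broadcast_to(self._pos, (n, *self._pos.shape))
        tf = _time_features(t, T, self.cfg.n_time)[:, :, None]
        tf = np.broadcast_to(tf, (n, self.cfg.n_time, length))
        inp = np.concatenate([x_t[:, None, :], pos, tf], axis=1)
        return self.net(inp)[:, 0, :]

    def backward_eps(self, grad: np.ndarray) -> None:
        g = np.zeros((grad.shape[0], 1, grad.shape[1]))
        g[:, 0, :] = grad
        self.net.backward(g)


def train_denoiser(beats, schedule: NoiseSchedule,
                   cfg: DdpmTrainConfig | None = None, seed: int = 0):
    """Train the epsilon-prediction MSE objective on one class of beats.

    Returns ``(model, loss_trace)``; the trace holds the per-step training
    loss.  Deterministic given the seed.
    """
    beats = list(beats)
    if not beats:
        raise ValueError("need at least one beat")
    cfg = cfg or DdpmTrainConfig()
    data = np.stack([np.asarray(b.samples, dtype=float) for b in beats])
    mean, std = float(data.mean()), float(data.std())
    std = std if std > 0 else 1.0
    data = (data - mean) / std

    model = DenoiserModel(data.shape[1], cfg, seed=seed)
    model.norm_mean, model.norm_std = mean, std
    rng = np.random.default_rng(seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    trace = []
    for _ in range(cfg.steps):
        idx = rng.integers(0, data.shape[0], size=cfg.batch_size)
        x0 = data[idx]
        t = rng.integers(1, schedule.T + 1, size=cfg.batch_size)
        eps = rng.standard_normal(x0.shape)
        abar = schedule.alpha_bars[t - 1][:, None]
        x_t = np.sqrt(abar) * x0 + np.sqrt(1 - abar) * eps
        pred = model.predict_eps(x_t, t, schedule.T)
        loss, grad = mse(pred, eps)
        opt.zero_grad()
        model.backward_eps(grad)
        opt.step()
        trace.append(loss)
    return model, np.asarray(trace)


def sample(model: DenoiserModel, schedule: NoiseSchedule, n: int,
           seed: int = 0) -> np.ndarray:
    """Ancestral sampling x_T -> x_0; returns (n, length) in millivolts."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    model.eval()
    x = rng.standard_normal((n, model.length))
    for t in range(schedule.T, 0, -1):
        eps = model.predict_eps(x, np.full(n, t), schedule.T)
        a = schedule.alphas[t - 1]
        abar = schedule.alpha_bars[t - 1]
        mean = (x - schedule.betas[t - 1] / np.sqrt(1 - abar) * eps) / np.sqrt(a)
        x = mean
        if t > 1:
            x = x + schedule.sigma(t) * rng.standard_normal(x.shape)
    model.train()
    return x * model.norm_std + model.norm_mean


# ---------------------------------------------------------------------------
# class balancing
# ---------------------------------------------------------------------------

@dataclass
class BalancePlan:
    """Per-class target counts; majority classes are downsampled, minority
    classes are topped up with synthetic beats."""

    targets: dict
    seed: int = 0


def make_balance_plan(beats, target: int | None = None, seed: int = 0) -> BalancePlan:
    """Near-balance helper: every class is driven to the median class count
    (or an explicit target)."""
    counts: dict = {}
    for b in beats:
        counts[b.label] = counts.get(b.label, 0) + 1
    if target is None:
        target = int(np.median(sorted(counts.values())))
    return BalancePlan({label: target for label in counts}, seed)


def balance_dataset(beats, plan: BalancePlan, models: dict | None = None,
                    schedule: NoiseSchedule | None = None) -> list:
    """Apply a balance plan: seeded uniform downsampling of majority classes,
    DDPM synthesis for minority classes (original minority beats all kept).

    ``models`` maps class label -> trained :class:`DenoiserModel` and is only
    required for classes whose target exceeds their current count.
    """
    beats = list(beats)
    by_class: dict = {}
    for b in beats:
        by_class.setdefault(b.label, []).append(b)
    missing = set(by_class) - set(plan.targets)
    if missing:
        raise ValueError(f"plan does not cover classes: {sorted(missing)}")
    rng = np.random.default_rng(plan.seed)
    out = []
    for label in sorted(by_class):
        group = by_class[label]
        target = int(plan.targets[label])
        if target <= len(group):
            keep = rng.choice(len(group), size=target, replace=False)
            out.extend(group[i] for i in sorted(keep))
        else:
            out.extend(group)
            n_new = target - len(group)
            if models is None or label not in models:
                raise ValueError(f"no denoiser model for minority class {label!r}")
            if schedule is None:
                raise ValueError("a noise schedule is required for synthesis")
            synth = sample(models[label], schedule, n_new,
                           seed=plan.seed * 7919 + hash(label) % 10007)
            r_idx = group[0].r_index
            out.extend(
                Beat(row, label, f"SYN-{label}-{i:05d}", r_index=r_idx,
                     source="synthetic")
                for i, row in enumerate(synth))
    return out
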