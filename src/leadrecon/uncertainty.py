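"""Monte Carlo-dropout uncertainty and reliability analysis.

With the two dropout layers (after the BiLSTM block and after the fusion
concatenation, rate 0.2) kept active at inference, N stochastic forward
passes yield per-time-point predictive statistics:

* sigma(t): population standard deviation (divisor N) over the passes,
* sigma_norm(t): sigma divided by its temporal maximum per lead (in [0,1];
  identically zero by convention when sigma is identically zero),
* e(t): relative reconstruction error |pred - ref| / (|ref| + eps), with a
  small eps guarding near-zero reference samples (a signed variant is
  available by flag).

Reliability is assessed by pooling all (record x time) points per lead:
the Pearson correlation between sigma_norm and e, and quartile-binned mean
relative error over sigma_norm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluate import pearson_r
from .model import TrainedModel
from .synth import ParameterError, TARGET_LEADS

#: default number of stochastic forward passes
DEFAULT_N_PASSES = 1000
#: default stability constant for the relative error, in mV
DEFAULT_EPSILON = 1e-3


@dataclass
class McSampleStack:
    """N stochastic forward passes for one input window."""

    samples: np.ndarray  # (N, 11, T) mV
    mean: np.ndarray  # (11, T) mV
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2 or self.samples.shape[0] != self.n:
            raise ParameterError("need N >= 2 stochastic passes")
        if not np.allclose(self.mean, self.samples.mean(axis=0)):
            raise ParameterError("stack mean does not match its samples")


@dataclass
class UncertaintyProfile:
    sigma: np.ndarray  # (11, T), mV, >= 0
    sigma_norm: np.ndarray | None = None  # (11, T), unitless in [0, 1]

    @property
    def max_sigma_location(self) -> np.ndarray:
        """Per-lead time index of the sigma maximum."""
        return self.sigma.argmax(axis=1)


@dataclass
class ErrorProfile:
    e: np.ndarray  # (11, T), unitless
    epsilon: float


def mc_predict(model: TrainedModel, lead1: np.ndarray,
               meta: np.ndarray | None = None, n_passes: int = DEFAULT_N_PASSES,
               seed: int = 0) -> McSampleStack:
    """Run N stochastic forward passes with only the MC dropout sites active."""
    if n_passes < 2:
        raise ParameterError("n_passes must be >= 2")
    x = np.asarray(lead1, dtype=float)
    if x.ndim == 1:
        x = x[None, None, :]
    elif x.ndim == 2:
        x = x[None, :, :]
    m = None
    if model.metadata_dim > 0:
        m = np.asarray(meta, dtype=float)
        if m.ndim == 1:
            m = m[None, :]
    rng = np.random.default_rng(seed)
    # one batched pass per MC sample: replicate the input so every replica
    # draws an independent dropout mask
    reps = 32  # replicate the window inside each forward for throughput
    samples = []
    remaining = n_passes
    while remaining > 0:
        k = min(reps, remaining)
        xb = np.repeat(x, k, axis=0)
        mb = np.repeat(m, k, axis=0) if m is not None else None
        out = model.net.forward(xb, mb, "mc", rng)
        samples.append(out)
        remaining -= k
    stack = np.concatenate(samples, axis=0)
    return McSampleStack(samples=stack, mean=stack.mean(axis=0),
                         n=n_passes, seed=seed)


def predictive_std(stack: McSampleStack) -> UncertaintyProfile:
    """Population (divisor-N) standard deviation over the MC passes."""
    sigma = np.sqrt(np.mean((stack.samples - stack.mean) ** 2, axis=0))
    return UncertaintyProfile(sigma=sigma)


def normalize_std(profile: UncertaintyProfile) -> UncertaintyProfile:
    """Divide each lead's sigma(t) by its temporal maximum.

    Leads with sigma identically zero map to sigma_norm identically zero.
    """
    sigma = profile.sigma
    peak = sigma.max(axis=-1, keepdims=True)
    safe = np.where(peak > 0, peak, 1.0)
    profile.sigma_norm = np.where(peak > 0, sigma / safe, 0.0)
    return profile


def relative_error(pred: np.ndarray, ref: np.ndarray,
                   epsilon: float = DEFAULT_EPSILON,
                   signed: bool = False) -> ErrorProfile:
    """Relative error e(t) = |pred - ref| / (|ref| + eps) per lead and time.

    ``signed=True`` keeps the sign of (pred - ref) in the numerator.
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ParameterError("shape mismatch")
    num = (pred - ref) if signed else np.abs(pred - ref)
    return ErrorProfile(e=num / (np.abs(ref) + epsilon), epsilon=epsilon)


def _pool(profiles: list[UncertaintyProfile], errors: list[ErrorProfile]
          ) -> tuple[np.ndarray, np.ndarray]:
    """Pool (record x time) points per lead -> (leads, n_points) arrays."""
    if len(profiles) != len(errors) or not profiles:
        raise ParameterError("need matching, non-empty profile/error lists")
    s = np.concatenate([p.sigma_norm for p in profiles], axis=-1)
    e = np.concatenate([er.e for er in errors], axis=-1)
    if s.shape != e.shape:
        raise ParameterError("profile/error shapes disagree")
    return s, e


def uncertainty_error_correlation(profiles: list[UncertaintyProfile],
                                  errors: list[ErrorProfile],
                                  lead_names=TARGET_LEADS,
                                  per_record: bool = False) -> dict[str, float]:
    """Per-lead Pearson R between sigma_norm(t) and e(t).

    Default pools every (record x time) pair per lead; ``per_record=True``
    instead correlates within each record and averages the per-record
    coefficients.  Leads with zero variance on either side report NaN.
    """
    if per_record:
        out = {}
        for j, name in enumerate(lead_names):
            vals = [pearson_r(p.sigma_norm[j], er.e[j])
                    for p, er in zip(profiles, errors)]
            out[name] = float(np.nanmean(vals))
        return out
    s, e = _pool(profiles, errors)
    return {name: pearson_r(s[j], e[j]) for j, name in enumerate(lead_names)}


def quantile_error_table(profiles: list[UncertaintyProfile],
                         errors: list[ErrorProfile],
                         n_bins: int = 4) -> list[dict[str, float]]:
    """Mean +- SD of relative error per sigma_norm quantile bin (Q1 lowest).

    Points from all leads, records and times are pooled; bin edges are the
    empirical quantiles of sigma_norm, with boundary ties resolved by the
    stable ordering of np.argsort.
    """
    s, e = _pool(profiles, errors)
    s, e = s.ravel(), e.ravel()
    if s.size < n_bins:
        raise ParameterError("fewer pooled points than bins")
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    table = []
    for i, idx in enumerate(bins):
        table.append({
            "quantile": f"Q{i + 1}",
            "mean_error": float(e[idx].mean()),
            "sd_error": float(e[idx].std()),
            "mean_sigma_norm": float(s[idx].mean()),
            "n": int(idx.size),
        })
    return table


def render_heatmap(pred: np.ndarray, ref: np.ndarray, sigma_norm: np.ndarray,
                   out_path: str | Path, lead_names=TARGET_LEADS,
                   leads: list[str] | None = None, fs: float = 100.0) -> Path:
    """Reliability map: traces over a time-axis background colored by sigma_norm.

    One panel per requested lead; blue marks low, red high uncertainty.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    leads = leads or ["II"]
    rows = [list(lead_names).index(name) for name in leads]
    t = np.arange(pred.shape[-1]) / fs
    fig, axes = plt.subplots(len(rows), 1, figsize=(10, 2.5 * len(rows)),
                             squeeze=False)
    for ax, name, j in zip(axes[:, 0], leads, rows):
        lo = min(pred[j].min(), ref[j].min())
        hi = max(pred[j].max(), ref[j].max())
        pad = 0.1 * (hi - lo + 1e-9)
        ax.pcolormesh(t, np.array([lo - pad, hi + pad]),
                      sigma_norm[j][None, :-1],
                      cmap="coolwarm", vmin=0.0, vmax=1.0, shading="flat")
        ax.plot(t, ref[j], color="0.4", lw=1.0, label="reference")
        ax.plot(t, pred[j], color="black", lw=1.0, label="predicted")
        ax.set_ylabel(f"{name} [mV]")
        ax.legend(loc="upper right", fontsize=7)
    axes[-1, 0].set_xlabel("time [s]")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
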