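"""Bias-corrected bootstrap inference for DEA scores.

Two resampling schemes are provided as first-class citizens:

* ``smoothed`` — the homogeneous smoothed bootstrap of Simar and Wilson:
  pseudo-efficiencies are drawn from a reflected, kernel-smoothed estimate of
  the score distribution and turned into a pseudo reference technology by
  radially inflating the observed inputs; each original DMU is then re-scored
  against the pseudo technology.
* ``naive`` — resampling whole DMUs with replacement to form the reference
  set, preserving the joint input-output structure, and re-scoring the
  original DMUs against it.

For every DMU the replicate scores theta*_b give the bias estimate
``mean(theta*) - theta_hat`` and the bias-corrected score
``2 * theta_hat - mean(theta*)``. Two interval styles are available:
``percentile`` (empirical quantiles of theta*, which bracket the *biased*
score) and ``bias-corrected-basic`` (``2*theta_hat - Q``, the reflection that
brackets the underlying true score). Quantiles use linear interpolation
between order statistics (numpy's default, the type-7 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import dea
from .errors import DegenerateSampleError, SolverError

__all__ = [
    "BootstrapConfig",
    "BootstrapEstimate",
    "smoothed_bootstrap",
    "naive_bootstrap",
    "reflection_bandwidth",
    "bias_correct",
    "derive_seed",
]


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 2000
    alpha: float = 0.05
    scheme: str = "smoothed"  # smoothed | naive
    seed: int = 0
    ci_style: str = "percentile"  # percentile | bias-corrected-basic
    #: replicates assembled into one block-diagonal LP call
    replicate_chunk: int = 25
    #: abort if more than this fraction of replicates fails to solve
    max_dropped_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.scheme not in {"smoothed", "naive"}:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.ci_style not in {"percentile", "bias-corrected-basic"}:
            raise ValueError(f"unknown ci_style {self.ci_style!r}")


@dataclass
class BootstrapEstimate:
    label: str
    theta_hat: float
    bias: float
    theta_tilde: float
    ci_low: float
    ci_high: float
    b_effective: int
    clamped: bool = False


def derive_seed(master: int, *keys) -> int:
    """Deterministic child seed (< 2**31) for a named stream."""
    material = [int(master) & 0x7FFFFFFF]
    for k in keys:
        material.extend(str(k).encode())
    ss = np.random.SeedSequence(material)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def reflection_bandwidth(scores: np.ndarray) -> float:
    """Normal-reference bandwidth on the reflected sample {theta, 2 - theta}.

    h = 0.9 * min(sd, IQR / 1.349) * (2n)^(-1/5)
    """
    scores = np.asarray(scores, dtype=float)
    if np.unique(scores).size < 2:
        raise DegenerateSampleError(
            "bandwidth undefined for a zero-spread score sample"
        )
    n = scores.size
    refl = np.concatenate([scores, 2.0 - scores])
    sd = refl.std(ddof=1)
    q75, q25 = np.percentile(refl, [75, 25])
    spread = min(sd, (q75 - q25) / 1.349)
    if spread <= 0:  # pathological but possible with heavy ties
        spread = sd
    return 0.9 * spread * (2 * n) ** (-0.2)


def bias_correct(
    theta_hat: float,
    bootstrap_scores: np.ndarray,
    alpha: float = 0.05,
    ci_style: str = "percentile",
    label: str = "",
) -> BootstrapEstimate:
    """Aggregate one DMU's replicate scores into a bias-corrected estimate."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    bs = np.asarray(bootstrap_scores, dtype=float)
    bs = bs[np.isfinite(bs)]
    if bs.size == 0:
        raise ValueError("no bootstrap scores")
    mean_star = bs.mean()
    bias = mean_star - theta_hat
    theta_tilde = 2.0 * theta_hat - mean_star
    q_lo, q_hi = np.quantile(bs, [alpha / 2.0, 1.0 - alpha / 2.0])
    if ci_style == "percentile":
        lo, hi = float(q_lo), float(q_hi)
    elif ci_style == "bias-corrected-basic":
        lo, hi = 2.0 * theta_hat - float(q_hi), 2.0 * theta_hat - float(q_lo)
    else:
        raise ValueError(f"unknown ci_style {ci_style!r}")
    clamped = lo <= 0 or hi > 1
    lo = min(max(lo, np.finfo(float).tiny), 1.0)
    hi = min(max(hi, lo), 1.0)
    return BootstrapEstimate(
        label=label,
        theta_hat=float(theta_hat),
        bias=float(bias),
        theta_tilde=float(theta_tilde),
        ci_low=lo,
        ci_high=hi,
        b_effective=int(bs.size),
        clamped=bool(clamped),
    )


def _deterministic_scores(dmus: dea.DMUSet, rts: str) -> np.ndarray:
    theta, statuses = dea.radial_scores(
        dmus.inputs, dmus.outputs, dmus.inputs, dmus.outputs, rts
    )
    bad = [lab for lab, st in zip(dmus.labels, statuses) if st != "optimal"]
    if bad:
        raise SolverError(f"deterministic scores failed for {bad}")
    return theta


def _replicate_loop(dmus, rts, config, make_ref):
    """Shared driver: build B pseudo reference sets, re-score, aggregate."""
    n = dmus.n
    boot = np.empty((config.B, n))
    ok = np.ones((config.B, n), dtype=bool)
    chunk = max(1, config.replicate_chunk)
    b = 0
    while b < config.B:
        k = min(chunk, config.B - b)
        refs = [make_ref() for _ in range(k)]
        theta, good = dea.radial_scores_multi(
            dmus.inputs, dmus.outputs, refs, rts
        )
        boot[b : b + k] = theta
        ok[b : b + k] = good & np.isfinite(theta)
        b += k
    keep = ok.all(axis=1)
    dropped = int((~keep).sum())
    if dropped > max(config.max_dropped_frac * config.B, 0):
        raise SolverError(
            f"{dropped}/{config.B} bootstrap replicates failed to solve"
        )
    return boot[keep]


def _aggregate(dmus, theta_hat, boot, config):
    return [
        bias_correct(
            float(theta_hat[i]), boot[:, i], config.alpha, config.ci_style,
            label=dmus.labels[i],
        )
        for i in range(dmus.n)
    ]


def smoothed_bootstrap(
    dmus: dea.DMUSet, rts: str, config: BootstrapConfig
) -> list[BootstrapEstimate]:
    """Homogeneous smoothed (Simar-Wilson) bootstrap.

    Steps per replicate: draw pseudo-scores from the kernel-smoothed reflected
    score sample with the variance correction, map back into (0, 1], inflate
    inputs by theta_hat / theta_star to form the pseudo technology, and
    re-solve the DEA program of every original DMU against it.
    """
    if dmus.n < 2:
        raise DegenerateSampleError("smoothed bootstrap needs at least 2 DMUs")
    rng = np.random.default_rng(config.seed)
    theta_hat = _deterministic_scores(dmus, rts)

    if np.unique(np.round(theta_hat, 12)).size < 2:
        # zero spread: the smoothed distribution collapses onto theta_hat and
        # every pseudo technology reproduces the original one
        boot = np.tile(theta_hat, (config.B, 1))
        return _aggregate(dmus, theta_hat, boot, config)

    h = reflection_bandwidth(theta_hat)
    refl = np.concatenate([theta_hat, 2.0 - theta_hat])
    var_refl = refl.var(ddof=1)
    n = dmus.n

    def make_ref():
        beta = rng.choice(refl, size=n, replace=True)
        tilde = beta + h * rng.standard_normal(n)
        tilde = beta.mean() + (tilde - beta.mean()) / np.sqrt(1.0 + h * h / var_refl)
        star = np.where(tilde > 1.0, 2.0 - tilde, tilde)
        star = np.abs(star)  # reflect at 0; mass there is negligible
        star = np.clip(star, 1e-9, 1.0)
        X_star = dmus.inputs * (theta_hat / star)
        return X_star, dmus.outputs

    boot = _replicate_loop(dmus, rts, config, make_ref)
    return _aggregate(dmus, theta_hat, boot, config)


def naive_bootstrap(
    dmus: dea.DMUSet, rts: str, config: BootstrapConfig
) -> list[BootstrapEstimate]:
    """DMU-level resampling with replacement; originals re-scored per draw."""
    if dmus.n < 2:
        raise DegenerateSampleError("naive bootstrap needs at least 2 DMUs")
    rng = np.random.default_rng(config.seed)
    theta_hat = _deterministic_scores(dmus, rts)
    n = dmus.n

    def make_ref():
        idx = rng.integers(0, n, size=n)
        return dmus.inputs[:, idx], dmus.outputs[:, idx]

    if rts != "crs":
        warnings.warn(
            "naive resampling under VRS/NIRS can leave DMUs outside the "
            "resampled hull; failed replicates are dropped and counted",
            stacklevel=2,
        )
    boot = _replicate_loop(dmus, rts, config, make_ref)
    return _aggregate(dmus, theta_hat, boot, config)


def run_bootstrap(dmus: dea.DMUSet, rts: str, config: BootstrapConfig):
    """Dispatch on ``config.scheme``."""
    fn = smoothed_bootstrap if config.scheme == "smoothed" else naive_bootstrap
    return fn(dmus, rts, config)
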