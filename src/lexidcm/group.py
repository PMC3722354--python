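"""Group-level inference: random-effects Bayesian model selection, Bayesian
model averaging of connection gains, and the sampling-based proportion test.

Per-subject log model evidences (variational free energies) feed a
variational Dirichlet estimate of the population model frequencies; model
exceedance probabilities come from Monte-Carlo sampling of the fitted
Dirichlet.  Connection gains are then pooled by repeated sampling: draw a
model per subject from its (group-reweighted) posterior model probabilities,
draw a parameter vector from that model's Gaussian posterior, convert to
per-connection gains (connections unmodulated in the drawn model contribute
the null gain 1), and pool draws across subjects and repetitions.  Each
pooled gain is finally tested against 1 with the Gaussian-sampling proportion
test: if more than 90% of 10,000 draws fall on one side of 1, the connection
is judged significantly stronger (gain > 1) or weaker (gain < 1) in the
modulated condition, with Bayes factor P/(1-P).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

from .inversion import DCMPosterior

__all__ = [
    "EvidenceMatrix",
    "RfxResult",
    "BMAResult",
    "ProportionTestResult",
    "rfx_bms",
    "bma_gains",
    "proportion_test",
    "bayes_factor",
]


@dataclass
class EvidenceMatrix:
    """Log model evidences: subjects x models (nats)."""

    free_energies: np.ndarray
    subject_ids: list[str]
    model_ids: list[int]

    def __post_init__(self) -> None:
        self.free_energies = np.atleast_2d(np.asarray(self.free_energies, float))
        if not np.all(np.isfinite(self.free_energies)):
            raise ValueError("non-finite free energies")
        n, k = self.free_energies.shape
        if n < 1 or k < 1:
            raise ValueError("need >= 1 subject and >= 1 model")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvidenceMatrix":
        wide = df.pivot(index="subject", columns="model_index", values="free_energy")
        return cls(wide.to_numpy(), [str(s) for s in wide.index], [int(m) for m in wide.columns])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.subject_ids):
            for j, m in enumerate(self.model_ids):
                rows.append(
                    {"subject": s, "model_index": m, "free_energy": self.free_energies[i, j]}
                )
        return pd.DataFrame(rows)


@dataclass
class RfxResult:
    alpha: np.ndarray  # Dirichlet parameters over models
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    subject_model_probs: np.ndarray  # subjects x models
    n_samples: int
    seed: int


def rfx_bms(
    evidence: EvidenceMatrix,
    alpha0: float = 1.0,
    n_samples: int = 10_000,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> RfxResult:
    """Variational Dirichlet estimation of population model frequencies.

    Iterates the standard fixed point: per-subject model responsibilities
    proportional to exp(F_nk + digamma(alpha_k) - digamma(sum alpha)), then
    alpha = alpha0 + summed responsibilities.  Exceedance probabilities are
    Monte-Carlo frequencies with which each model's sampled frequency is the
    largest, over seeded draws from the fitted Dirichlet.
    """
    F = evidence.free_energies
    n, K = F.shape
    alpha = np.full(K, alpha0)
    if K == 1:
        g = np.ones((n, 1))
        return RfxResult(alpha + n, np.ones(1), np.ones(1), g, n_samples, seed)
    for _ in range(max_iter):
        logu = F + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        logu = logu - logu.max(axis=1, keepdims=True)
        g = np.exp(logu)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=K) / n_samples
    return RfxResult(
        alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance_probabilities=xp,
        subject_model_probs=g,
        n_samples=n_samples,
        seed=seed,
    )


@dataclass
class BMAResult:
    """Pooled posterior gain statistics per connection."""

    connections: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_samples: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"connection": self.connections, "mean_gain": self.mean, "sd_gain": self.sd}
        )


def _gain_draws(post: DCMPosterior, connections: list[str], rng) -> np.ndarray:
    theta = rng.multivariate_normal(post.mean, post.cov, method="cholesky")
    conn_param = {}
    for pname, conns in post.gain_map.items():
        for cn in conns:
            conn_param[cn] = pname
    idx = {nm: i for i, nm in enumerate(post.param_names)}
    out = np.ones(len(connections))
    for i, cn in enumerate(connections):
        pname = conn_param.get(cn)
        if pname is not None:
            out[i] = np.exp(theta[idx[pname]])
    return out


def bma_gains(
    posteriors: dict[tuple[str, int], DCMPosterior],
    subject_ids: list[str],
    model_ids: list[int],
    subject_model_probs: np.ndarray,
    connections: list[str],
    n_samples: int = 10_000,
    seed: int = 0,
) -> BMAResult:
    """Random-effects Bayesian model averaging of connection gains.

    ``posteriors`` must cover every (subject, model) pair.  Each sampling
    round draws one model per subject from ``subject_model_probs`` (the
    group-reweighted per-subject model probabilities from :func:`rfx_bms`)
    and one gain vector from the drawn model's Gaussian posterior; draws are
    pooled across subjects and rounds (at least ``n_samples`` in total).
    """
    for s in subject_ids:
        for m in model_ids:
            if (s, m) not in posteriors:
                raise KeyError(f"missing posterior for subject {s!r}, model {m}")
    n_subj = len(subject_ids)
    rounds = int(np.ceil(n_samples / n_subj))
    rng = np.random.default_rng(seed)
    pools = np.empty((rounds * n_subj, len(connections)))
    row = 0
    for _ in range(rounds):
        for i, s in enumerate(subject_ids):
            k = rng.choice(len(model_ids), p=subject_model_probs[i])
            post = posteriors[(s, model_ids[k])]
            pools[row] = _gain_draws(post, connections, rng)
            row += 1
    return BMAResult(
        connections=list(connections),
        mean=pools.mean(axis=0),
        sd=pools.std(axis=0, ddof=1),
        n_samples=pools.shape[0],
        seed=seed,
    )


@dataclass
class ProportionTestResult:
    p_exceed: float
    direction: str  # stronger_trained | stronger_untrained
    significant: bool
    bayes_factor: float
    n_samples: int
    seed: int


def proportion_test(
    mean_gain: float,
    sd_gain: float,
    n_samples: int = 10_000,
    threshold: float = 0.9,
    seed: int = 0,
) -> ProportionTestResult:
    """Sampling-based test of a pooled gain against the null value 1.

    Draws ``n_samples`` Gaussian samples at the pooled mean and SD;
    P_exceed is the larger of the fractions above and below 1, significant
    when it exceeds ``threshold``.  A gain above 1 marks the connection
    stronger in the modulated (trained-word) condition.
    """
    if sd_gain < 0:
        raise ValueError("sd must be nonnegative")
    if sd_gain == 0:
        frac_gt = 1.0 if mean_gain > 1 else 0.0
        frac_lt = 1.0 if mean_gain < 1 else 0.0
        if mean_gain == 1:
            frac_gt = frac_lt = 0.5
    else:
        rng = np.random.default_rng(seed)
        samples = rng.normal(mean_gain, sd_gain, n_samples)
        frac_gt = float(np.mean(samples > 1.0))
        frac_lt = 1.0 - frac_gt
    if frac_gt >= frac_lt:
        p, direction = frac_gt, "stronger_trained"
    else:
        p, direction = frac_lt, "stronger_untrained"
    return ProportionTestResult(
        p_exceed=p,
        direction=direction,
        significant=p > threshold,
        bayes_factor=bayes_factor(p),
        n_samples=n_samples,
        seed=seed,
    )


def bayes_factor(p: float) -> float:
    """Posterior odds P/(1-P); a posterior probability of 0.9 maps to 9."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if p == 1.0:
        import warnings

        warnings.warn("posterior probability of 1 gives an infinite Bayes factor")
        return float("inf")
    return p / (1.0 - p)
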