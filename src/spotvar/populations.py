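"""Two-population decomposition of per-spot diffusivities.

High-cholesterol bilayers show a bimodal distribution of spot-to-spot
diffusion coefficients: a slow (S) and a fast (F) sub-population.  This
module fits a two-component Gaussian mixture to log10(D) by
expectation-maximization with a deterministic percentile initialization,
and scores the separation with Ashman's D.

Diffusivities spread multiplicatively, so the mixture lives on log10(D);
component S is always the one with the lower mean D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusivitySample",
    "PopulationSplit",
    "fit_two_component",
    "bimodality_index",
    "histogram_table",
    "DegenerateSplitError",
]


class DegenerateSplitError(ValueError):
    """The sample does not support a two-component decomposition."""


@dataclass(frozen=True)
class DiffusivitySample:
    """One diffusivity measurement (um^2/s) with an optional region label
    (e.g. 'I'/'II') used only for validation."""

    D: float
    region_hint: str | None = None

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive")


@dataclass
class PopulationSplit:
    """Two-component mixture on log10(D); component 0 is S (slower)."""

    means: tuple[float, float]  # log10(um^2/s)
    sds: tuple[float, float]
    weights: tuple[float, float]
    assignments: np.ndarray  # 0 = S, 1 = F per sample
    bimodality: float = float("nan")
    degenerate: bool = False
    n_iter: int = 0
    log_likelihood: float = float("nan")

    @property
    def means_linear(self) -> tuple[float, float]:
        """Component means back on the D scale (um^2/s)."""
        return (10.0 ** self.means[0], 10.0 ** self.means[1])


def _log_norm_pdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))


def fit_two_component(
    samples: "list[DiffusivitySample] | np.ndarray",
    max_iter: int = 500,
    tol: float = 1e-8,
    min_sd: float = 1e-6,
) -> PopulationSplit:
    """EM fit of a two-component Gaussian mixture on log10(D).

    Initialization is deterministic: component means at the 25th and 75th
    percentiles, equal weights, shared sample SD.  Iteration stops when
    the log-likelihood improves by less than ``tol`` or after
    ``max_iter`` rounds.  Samples are assigned to the component with the
    larger responsibility.  All-equal data cannot separate and returns a
    flagged single-component fallback.
    """
    D = np.array(
        [s.D if isinstance(s, DiffusivitySample) else float(s) for s in samples]
    )
    if len(D) < 10:
        raise ValueError("need at least 10 samples")
    if np.any(D <= 0):
        raise ValueError("diffusivities must be positive")
    x = np.log10(D)
    if np.ptp(x) == 0:
        return PopulationSplit(
            means=(float(x[0]), float(x[0])),
            sds=(0.0, 0.0),
            weights=(1.0, 0.0),
            assignments=np.zeros(len(x), dtype=int),
            degenerate=True,
        )
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[0] == mu[1]:
        spread = max(np.std(x), min_sd)
        mu = np.array([mu[0] - 0.5 * spread, mu[0] + 0.5 * spread])
    sd = np.full(2, max(np.std(x), min_sd))
    pi = np.array([0.5, 0.5])
    ll_prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = np.stack(
            [np.log(pi[k]) + _log_norm_pdf(x, mu[k], sd[k]) for k in range(2)]
        )
        m = logp.max(axis=0)
        log_total = m + np.log(np.exp(logp - m).sum(axis=0))
        resp = np.exp(logp - log_total)
        ll = float(log_total.sum())
        if ll - ll_prev < tol and n_iter > 1:
            ll_prev = ll
            break
        ll_prev = ll
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        pi = nk / len(x)
        mu = (resp @ x) / nk
        for k in range(2):
            var = (resp[k] @ (x - mu[k]) ** 2) / nk[k]
            sd[k] = max(np.sqrt(var), min_sd)
    order = np.argsort(mu)  # component 0 = S (lower mean D)
    mu, sd, pi = mu[order], sd[order], pi[order]
    logp = np.stack(
        [np.log(pi[k]) + _log_norm_pdf(x, mu[k], sd[k]) for k in range(2)]
    )
    assignments = np.argmax(logp, axis=0)
    split = PopulationSplit(
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        weights=(float(pi[0]), float(pi[1])),
        assignments=assignments,
        n_iter=n_iter,
        log_likelihood=ll_prev,
    )
    split.bimodality = bimodality_index(split)
    return split


def histogram_table(samples, bins: int = 20) -> "pd.DataFrame":
    """Histogram of diffusivities in both views used for plotting:
    raw D (um^2/s) bin edges/counts and the same on log10(D).

    Returns a DataFrame with columns ``D_left, D_right, count,
    log10_left, log10_right`` (log edges are the log of the raw edges of
    a log-spaced binning, so the two views describe the same bars).
    """
    import pandas as pd

    D = np.array(
        [s.D if isinstance(s, DiffusivitySample) else float(s) for s in samples]
    )
    if np.any(D <= 0):
        raise ValueError("diffusivities must be positive")
    x = np.log10(D)
    edges = np.linspace(x.min(), x.max() + 1e-12, bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return pd.DataFrame(
        {
            "D_left": 10.0 ** edges[:-1],
            "D_right": 10.0 ** edges[1:],
            "count": counts,
            "log10_left": edges[:-1],
            "log10_right": edges[1:],
        }
    )


def bimodality_index(split: PopulationSplit) -> float:
    """Ashman's D: ``sqrt(2) |mu1 - mu2| / sqrt(sd1^2 + sd2^2)``.

    Values above 2 indicate a cleanly bimodal distribution.
    """
    if split.degenerate:
        raise DegenerateSplitError(
            "bimodality undefined for a degenerate single-component split"
        )
    mu1, mu2 = split.means
    s1, s2 = split.sds
    denom = np.sqrt(s1 ** 2 + s2 ** 2)
    if denom == 0:
        return 0.0 if mu1 == mu2 else float("inf")
    return float(np.sqrt(2.0) * abs(mu1 - mu2) / denom)
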