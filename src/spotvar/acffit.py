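"""Fit autocorrelation curves with the 2D diffusion model and convert
between transit time, spot size and diffusivity.

Model
-----
``G(tau) = G0 / (1 + (tau/tau_D)^alpha) + baseline``

with amplitude ``G0 ~ 1/N`` (``N`` the mean number of fluorophores in the
spot), transit time ``tau_D`` (half-decay time for ``alpha = 1``) and an
anomaly exponent ``alpha`` that is fixed at 1 on the diffusion-law path
and freed only for diagnostics.

The diffusion-law conversions rest on the FWHM convention of
:mod:`spotvar.signal`:

``tau_D = d^2 / (8 D ln2)``    (transit time through a spot of FWHM d)

so ``D = d^2 / (8 ln2 tau_D)`` per spot, and a reference bilayer of known
``D_ref`` calibrates the spot diameter ``d = sqrt(8 ln2 D_ref tau_D)``.

Units at this interface: ``tau_D`` in ms, ``d`` in nm, ``D`` in um^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model, Parameters

from .signal import CorrelationCurve

__all__ = [
    "AcfModelParams",
    "AcfFitResult",
    "AcfFitError",
    "model_acf",
    "fit_acf",
    "half_decay_time",
    "spot_diffusivity",
    "calibrate_spot",
    "EIGHT_LN2",
]

EIGHT_LN2 = 8.0 * np.log(2.0)


class AcfFitError(ValueError):
    """Curve cannot be fitted (no decay, too few points, ...)."""


@dataclass(frozen=True)
class AcfModelParams:
    """Parameters of the 2D ACF model (tau_D in ms)."""

    G0: float
    tau_D: float
    alpha: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.G0 <= 0:
            raise ValueError("G0 must be positive")
        if self.tau_D <= 0:
            raise ValueError("tau_D must be positive")
        if not 0 < self.alpha <= 2:
            raise ValueError("alpha must lie in (0, 2]")


@dataclass
class AcfFitResult:
    params: AcfModelParams
    standard_errors: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")
    converged: bool = False
    model: str = "G0/(1+(tau/tau_D)^alpha)+baseline"


def model_acf(lag_ms, p: AcfModelParams):
    """Evaluate the ACF model at lag(s) in ms."""
    lag_ms = np.asarray(lag_ms, dtype=float)
    if np.any(lag_ms < 0):
        raise ValueError("lags must be non-negative")
    out = p.G0 / (1.0 + (lag_ms / p.tau_D) ** p.alpha) + p.baseline
    return out if out.ndim else float(out)


def _acf_func(lag_ms, G0, tau_D, alpha, baseline):
    return G0 / (1.0 + (lag_ms / tau_D) ** alpha) + baseline


def fit_acf(
    curve: CorrelationCurve,
    fix_alpha: bool = True,
    fit_baseline: bool = True,
    max_lag_factor: float | None = 20.0,
    anchor_amplitude: bool = False,
) -> AcfFitResult:
    """Weighted nonlinear least-squares fit of the 2D ACF model.

    Initialization: ``G0`` from G at the smallest lag, ``tau_D`` from the
    first lag where G drops below half of that, ``alpha = 1``, baseline
    from the mean of the last decade of lags.  Weights are ``1/sem`` when
    the curve carries per-lag standard errors, else uniform.  A curve with
    no half-decay crossing is refused with :class:`AcfFitError`.

    ``max_lag_factor`` restricts the fit to lags up to that multiple of
    the half-decay lag.  The free-plane model overestimates G at lags
    where the tracer has explored a region comparable to the sample (or
    simulation box), so curves from bounded geometries are fitted on the
    decaying part only; ``None`` fits the full curve.

    With ``anchor_amplitude`` the zero-lag amplitude is pinned to a
    short-lag linear extrapolation of the measured curve instead of
    floating.  For a single-timescale decay this is equivalent to the
    free fit; for multi-scale decays (hindered diffusion) it makes the
    extracted tau_D the half-decay time of the full correlation
    amplitude — the spot-variation convention on which the sign of the
    diffusion-law intercept rests.
    """
    lag_ms = curve.lags * 1e3
    G = curve.G
    if len(G) < 8:
        raise AcfFitError("need at least 8 lag points")
    g0 = G[0]
    if g0 <= 0:
        raise AcfFitError("non-positive G at the smallest lag")
    below = np.nonzero(G < 0.5 * g0)[0]
    if len(below) == 0:
        raise AcfFitError(
            "curve never decays below half its initial value; "
            "no transit time can be extracted"
        )
    tau0 = lag_ms[below[0]]
    if max_lag_factor is not None:
        keep = lag_ms <= max_lag_factor * tau0
        if keep.sum() >= 8:
            lag_ms, G = lag_ms[keep], G[keep]
            curve = CorrelationCurve(
                lag_ms * 1e-3, G,
                None if curve.sem is None else np.asarray(curve.sem)[keep],
            )
    last_decade = lag_ms >= lag_ms[-1] / 10.0
    base0 = float(np.mean(G[last_decade]))

    model = Model(_acf_func, independent_vars=["lag_ms"])
    params = Parameters()
    params.add("tau_D", value=tau0, min=lag_ms[0] * 1e-3, max=lag_ms[-1] * 1e3)
    params.add("alpha", value=1.0, min=0.05, max=2.0, vary=not fix_alpha)
    params.add("baseline", value=base0 if fit_baseline else 0.0,
               vary=fit_baseline)
    if anchor_amplitude:
        # zero-lag amplitude from a short-lag linear extrapolation
        k = min(6, max(2, int(np.searchsorted(lag_ms, 0.2 * tau0)) + 2))
        coef = np.polyfit(lag_ms[:k], G[:k], 1)
        amp = float(coef[1])
        if amp <= 0:
            raise AcfFitError("non-positive extrapolated amplitude")
        params.add("amp", value=amp, vary=False)
        params.add("G0", expr="amp - baseline", min=0.0)
    else:
        params.add("G0", value=max(g0 - base0, 1e-12), min=0.0)
    weights = None
    if curve.sem is not None:
        sem = np.asarray(curve.sem, dtype=float)
        good = sem > 0
        weights = np.where(good, 1.0 / np.where(good, sem, 1.0), 0.0)
    res = model.fit(G, params, lag_ms=lag_ms, weights=weights)
    fitted = AcfModelParams(
        G0=float(res.params["G0"].value),
        tau_D=float(res.params["tau_D"].value),
        alpha=float(res.params["alpha"].value),
        baseline=float(res.params["baseline"].value),
    )
    errors: dict[str, float] = {}
    if res.success:
        for name in ("G0", "tau_D", "alpha", "baseline"):
            se = res.params[name].stderr
            if se is not None:
                errors[name] = float(se)
    return AcfFitResult(
        params=fitted,
        standard_errors=errors,
        residual_norm=float(np.sqrt(np.sum(res.residual ** 2))),
        converged=bool(res.success),
    )


def half_decay_time(curve: CorrelationCurve, n_amp: int = 4) -> float:
    """Model-free transit time: the lag (ms) at which G falls to half its
    zero-lag amplitude.

    The amplitude is a linear extrapolation of the first ``n_amp``
    channels to zero lag; the crossing is interpolated linearly between
    the bracketing channels.  This is the definitional transit time of
    the spot-variation diffusion law and remains meaningful when the
    decay mixes several timescales (hindered diffusion), where a
    single-component model fit would split the difference between the
    fast and slow branches.
    """
    lag_ms = curve.lags * 1e3
    G = curve.G
    if len(G) < max(n_amp, 4):
        raise AcfFitError("too few lag points for a half-decay estimate")
    coef = np.polyfit(lag_ms[:n_amp], G[:n_amp], 1)
    amp = float(coef[1])
    if amp <= 0:
        raise AcfFitError("non-positive extrapolated amplitude")
    half = 0.5 * amp
    below = np.nonzero(G < half)[0]
    if len(below) == 0:
        raise AcfFitError(
            "curve never decays below half its amplitude; "
            "no transit time can be extracted"
        )
    i = int(below[0])
    if i == 0:
        return float(lag_ms[0])
    # linear interpolation between the bracketing channels
    g1, g2 = G[i - 1], G[i]
    x1, x2 = lag_ms[i - 1], lag_ms[i]
    return float(x1 + (g1 - half) * (x2 - x1) / (g1 - g2))


def spot_diffusivity(tau_D_ms: float, d_nm: float) -> float:
    """Per-spot diffusivity ``D = d^2 / (8 ln2 tau_D)`` in um^2/s,
    assuming free diffusion (zero diffusion-law intercept)."""
    if tau_D_ms <= 0 or d_nm <= 0:
        raise ValueError("tau_D and d must be positive")
    # nm^2/ms -> um^2/s carries a factor 1e-6 * 1e3 = 1e-3
    return d_nm ** 2 / (EIGHT_LN2 * tau_D_ms) * 1e-3


def calibrate_spot(tau_D_ms: float, D_ref: float) -> float:
    """Spot FWHM in nm from the transit time measured on a reference
    bilayer of known diffusivity: ``d = sqrt(8 ln2 D_ref tau_D)``."""
    if tau_D_ms <= 0 or D_ref <= 0:
        raise ValueError("tau_D and D_ref must be positive")
    return float(np.sqrt(EIGHT_LN2 * D_ref * tau_D_ms * 1e-3) * 1e3)
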