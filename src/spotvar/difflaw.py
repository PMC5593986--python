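"""FCS diffusion-law analysis: transit time versus spot area.

For a spot of FWHM ``d`` the transit time follows

``tau_D = d^2 / (8 D_eff ln2) + t0``

a straight line in ``d^2`` whose slope gives the effective diffusivity
``D_eff`` and whose intercept ``t0`` diagnoses the transport mechanism:
``t0 = 0`` for free Brownian motion, ``t0 > 0`` for transient trapping in
nanodomains, ``t0 < 0`` for meshwork- or gel-hindered diffusion.  When the
mechanism changes with length scale the law is piecewise linear; the spot
diameter at which the two regime lines meet is the dynamical crossover
``xi``.  For a regime with ``t0 < 0`` the extrapolated line crosses
``tau_D = 0`` at ``d = omega``, an estimate of the hindering domain size:

``omega = sqrt(8 ln2 D_eff |t0|)``  (valid only for ``t0 < 0``).

Units at this interface: ``d`` in nm, ``tau_D`` and ``t0`` in ms,
``D_eff`` in um^2/s, ``xi`` and ``omega`` in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .acffit import EIGHT_LN2

__all__ = [
    "DiffusionLawPoint",
    "RegimeFit",
    "DiffusionLawFit",
    "fit_line",
    "fit_crossover",
    "classify_regime",
    "domain_size",
    "DomainSizeError",
]

FREE = "free"
TRAPPED = "trapped_nanodomain"
GEL_MESHWORK = "gel_meshwork"


class DomainSizeError(ValueError):
    """Domain size requested outside its validity range (t0 >= 0)."""


@dataclass(frozen=True)
class DiffusionLawPoint:
    """One (spot FWHM, transit time) measurement."""

    d: float  # nm
    tau_D: float  # ms
    tau_se: float | None = None  # ms

    def __post_init__(self) -> None:
        if self.d <= 0 or self.tau_D <= 0:
            raise ValueError("d and tau_D must be positive")
        if self.tau_se is not None and self.tau_se < 0:
            raise ValueError("tau_se must be non-negative")


@dataclass
class RegimeFit:
    """Weighted straight-line fit of tau_D on d^2 for one regime."""

    slope: float  # ms / nm^2
    t0: float  # ms
    se_slope: float
    se_t0: float
    n_points: int
    d2_range: tuple[float, float]  # nm^2
    rss: float = 0.0

    @property
    def D_eff(self) -> float:
        """Effective diffusivity from the slope (um^2/s); NaN when the
        slope is non-positive."""
        if self.slope <= 0:
            return float("nan")
        return 1e-3 / (EIGHT_LN2 * self.slope)

    def predict(self, d2) -> np.ndarray:
        return self.slope * np.asarray(d2, float) + self.t0


@dataclass
class DiffusionLawFit:
    """Result of single-versus-segmented diffusion-law fitting."""

    regimes: list[RegimeFit]
    labels: list[str]
    xi: float | None = None  # nm, present iff two regimes
    xi_rule: str | None = None  # 'intersection' or 'midpoint'
    omega: float | None = None  # nm, present iff some regime has t0 < 0
    omega_se: float | None = None
    selection: dict = field(default_factory=dict)

    @property
    def segmented(self) -> bool:
        return len(self.regimes) == 2


def _wls_line(x, y, w, sigma_known):
    """Weighted least squares y = t0 + slope*x with analytic covariance.

    With ``sigma_known`` the weights are 1/sigma^2 and the covariance is
    used as-is; otherwise it is scaled by the reduced chi-square.
    """
    S = w.sum()
    Sx = (w * x).sum()
    Sxx = (w * x * x).sum()
    Sy = (w * y).sum()
    Sxy = (w * x * y).sum()
    delta = S * Sxx - Sx * Sx
    slope = (S * Sxy - Sx * Sy) / delta
    t0 = (Sxx * Sy - Sx * Sxy) / delta
    resid = y - (t0 + slope * x)
    rss = float((w * resid * resid).sum())
    var_slope = S / delta
    var_t0 = Sxx / delta
    n = len(x)
    if not sigma_known:
        scale = rss / (n - 2) if n > 2 else 0.0
        var_slope *= scale
        var_t0 *= scale
    return slope, t0, float(np.sqrt(var_slope)), float(np.sqrt(var_t0)), rss


def _prepare(points):
    pts = sorted(points, key=lambda p: p.d)
    d2 = np.array([p.d ** 2 for p in pts])
    tau = np.array([p.tau_D for p in pts])
    ses = [p.tau_se for p in pts]
    if all(s is not None and s > 0 for s in ses):
        w = 1.0 / np.array(ses, float) ** 2
        sigma_known = True
    else:
        w = np.ones_like(tau)
        sigma_known = False
    return pts, d2, tau, w, sigma_known


def fit_line(points: "list[DiffusionLawPoint]") -> RegimeFit:
    """Single weighted linear fit of tau_D on d^2.

    Weights are 1/tau_se^2 when every point carries a standard error
    (covariance then treated as known-sigma), uniform otherwise
    (covariance scaled by the reduced chi-square).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for a regime fit")
    _, d2, tau, w, sigma_known = _prepare(points)
    slope, t0, se_s, se_t, rss = _wls_line(d2, tau, w, sigma_known)
    return RegimeFit(
        slope=slope, t0=t0, se_slope=se_s, se_t0=se_t,
        n_points=len(points), d2_range=(float(d2.min()), float(d2.max())),
        rss=rss,
    )


def classify_regime(fit: RegimeFit, k_sigma: float = 2.0,
                    atol: float = 1e-9) -> str:
    """Label a regime from the significance of its intercept.

    ``|t0| <= k_sigma * se_t0`` -> free Brownian; significantly positive
    -> trapping nanodomains; significantly negative -> gel/meshwork
    hindrance.  Intercepts below ``atol`` (ms) are free regardless of
    their formal significance — they are rounding residue of exact data,
    ten orders of magnitude below any physical intercept.  A degenerate
    ``se_t0 = 0`` with nonzero t0 is classified by sign.
    """
    if not np.isfinite(fit.se_t0):
        raise ValueError("se_t0 must be finite")
    if abs(fit.t0) <= atol:
        return FREE
    if fit.se_t0 == 0 and fit.t0 != 0:
        import warnings

        warnings.warn("se_t0 is zero; classifying by the sign of t0 alone")
        return TRAPPED if fit.t0 > 0 else GEL_MESHWORK
    if abs(fit.t0) <= k_sigma * fit.se_t0:
        return FREE
    return TRAPPED if fit.t0 > 0 else GEL_MESHWORK


def domain_size(D_eff: float, t0_ms: float) -> float:
    """Domain size ``omega = sqrt(8 ln2 D_eff |t0|)`` in nm.

    Only defined for a negative intercept: the fitted line then crosses
    tau_D = 0 at d = omega.  A non-negative ``t0`` is refused.
    """
    if t0_ms >= 0:
        raise DomainSizeError(
            "domain size is defined only for t0 < 0 (the diffusion-law "
            "line must cross tau_D = 0 at positive spot area)"
        )
    if D_eff <= 0:
        raise ValueError("D_eff must be positive")
    # um^2/s * ms -> um^2 carries 1e-3; um -> nm carries 1e3
    return float(np.sqrt(EIGHT_LN2 * D_eff * abs(t0_ms) * 1e-3) * 1e3)


def _domain_size_se(reg: RegimeFit) -> float:
    """First-order propagation of se_slope and se_t0 into omega.

    omega^2 = |t0|/slope (in nm^2 with tau in ms), so
    d(omega)/omega = 0.5*sqrt((se_t0/t0)^2 + (se_slope/slope)^2)
    (covariance between slope and intercept neglected).
    """
    om = domain_size(reg.D_eff, reg.t0)
    rel = 0.5 * np.sqrt(
        (reg.se_t0 / reg.t0) ** 2 + (reg.se_slope / reg.slope) ** 2
    )
    return float(om * rel)


def fit_crossover(
    points: "list[DiffusionLawPoint]",
    min_per_segment: int = 3,
    alpha: float = 0.05,
    k_sigma: float = 2.0,
    partition_correction: bool = True,
) -> DiffusionLawFit:
    """Fit the diffusion law allowing one dynamical crossover.

    All contiguous partitions of the d^2-sorted points with at least
    ``min_per_segment`` points per side are searched exhaustively; each
    side is fitted by an independent weighted line and the partition with
    the smallest total weighted RSS wins (ties broken toward balanced
    point counts).  The segmented model is accepted over the single line
    by an F-test at level ``alpha``; with ``partition_correction`` the
    level is Bonferroni-divided by the number of candidate partitions to
    keep the false-crossover rate at ``alpha`` despite the search.  BIC
    for both models is recorded alongside.

    The crossover ``xi`` is the d-coordinate of the two regime lines'
    intersection when that intersection falls inside the data span;
    otherwise the midpoint (in d) between the two boundary points is used.
    The rule that fired is recorded.  ``omega`` is attached when a regime
    has a significantly negative intercept (preferring the large-d regime
    if both qualify).
    """
    n = len(points)
    if n < 2 * min_per_segment:
        raise ValueError(
            f"need >= {2 * min_per_segment} points for crossover search"
        )
    pts, d2, tau, w, sigma_known = _prepare(points)
    single = fit_line(pts)

    best = None
    n_candidates = 0
    for split in range(min_per_segment, n - min_per_segment + 1):
        n_candidates += 1
        lo = fit_line(pts[:split])
        hi = fit_line(pts[split:])
        rss = lo.rss + hi.rss
        balance = abs(2 * split - n)
        key = (rss, balance)
        if best is None or key < best[0]:
            best = (key, split, lo, hi)
    _, split, lo, hi = best
    rss1, rss2 = single.rss, lo.rss + hi.rss
    df2 = n - 4
    if df2 <= 0:
        raise ValueError("too few points for the segmented F-test")
    scale = float((w * tau * tau).sum())
    if rss1 <= 1e-20 * scale:
        # the single line is already exact to rounding: no crossover
        p_value = 1.0
        f_stat = 0.0
    elif rss2 <= 1e-20 * scale:
        p_value = 0.0
        f_stat = float("inf")
    else:
        f_stat = ((rss1 - rss2) / 2.0) / (rss2 / df2)
        p_value = float(stats.f.sf(f_stat, 2, df2))
    level = alpha / n_candidates if partition_correction else alpha
    accept = p_value < level

    # BIC from the weighted Gaussian log-likelihood (up to a constant)
    def _bic(rss, k):
        if rss <= 0:
            return float("-inf")
        return n * np.log(rss / n) + k * np.log(n)

    selection = {
        "rss_single": rss1,
        "rss_segmented": rss2,
        "f_stat": f_stat,
        "p_value": p_value,
        "alpha": alpha,
        "alpha_effective": level,
        "n_candidate_partitions": n_candidates,
        "bic_single": _bic(rss1, 2),
        "bic_segmented": _bic(rss2, 4),
        "selected": "segmented" if accept else "single",
        "split_index": split if accept else None,
    }

    if not accept:
        fit = DiffusionLawFit(
            regimes=[single],
            labels=[classify_regime(single, k_sigma)],
            selection=selection,
        )
        if fit.labels[0] == GEL_MESHWORK and single.t0 < 0:
            fit.omega = domain_size(single.D_eff, single.t0)
            fit.omega_se = _domain_size_se(single)
        return fit

    # crossover from the intersection of the two independent lines
    xi_rule = "midpoint"
    xi = None
    if lo.slope != hi.slope:
        x_star = (hi.t0 - lo.t0) / (lo.slope - hi.slope)
        if d2.min() <= x_star <= d2.max() and x_star > 0:
            xi = float(np.sqrt(x_star))
            xi_rule = "intersection"
    if xi is None:
        xi = 0.5 * (pts[split - 1].d + pts[split].d)

    labels = [classify_regime(lo, k_sigma), classify_regime(hi, k_sigma)]
    fit = DiffusionLawFit(
        regimes=[lo, hi], labels=labels, xi=xi, xi_rule=xi_rule,
        selection=selection,
    )
    for reg, label in ((hi, labels[1]), (lo, labels[0])):
        if label == GEL_MESHWORK and reg.t0 < 0 and fit.omega is None:
            fit.omega = domain_size(reg.D_eff, reg.t0)
            fit.omega_se = _domain_size_se(reg)
    return fit
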