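"""Kinetic fits and preferred-crossing-angle inference.

The chirality-resolved unlinking times of single DNA crossings are
exponentially distributed with characteristic times tau_L (positive,
left-handed crossings) and tau_R (negative).  If a single
angle-dependent step is rate limiting, the ratio tau_L/tau_R equals the
ratio P_R(alpha0)/P_L(alpha0) of the crossing-angle probability
densities at the enzyme's preferred angle alpha0, which is therefore
the root of the log-ratio curve -- the package's headline computation.
Also provides exponential dwell fits with right-censoring,
Michaelis-Menten-like rate-vs-concentration fits, and the inverse
dwell-vs-crossing-number fit of distributive supercoil relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .crossing import AngleDistribution, distribution_from_angles

__all__ = [
    "ExponentialFit",
    "PreferredAngleResult",
    "MMFit",
    "NoSolutionError",
    "AmbiguousRootError",
    "fit_exponential",
    "tau_ratio",
    "infer_preferred_angle",
    "combine_geometries",
    "fit_michaelis_menten",
    "fit_inverse_dwell",
    "angle_from_rate_ratio",
]


class NoSolutionError(RuntimeError):
    """The rate ratio lies outside the attainable density-ratio range."""


class AmbiguousRootError(RuntimeError):
    """The log-ratio curve crosses the target more than once."""

    def __init__(self, roots):
        self.roots = list(roots)
        super().__init__(f"multiple candidate roots: {self.roots}")


@dataclass(frozen=True)
class ExponentialFit:
    """Single-exponential dwell/unlinking-time fit P(t) = exp(-t/tau)/tau."""

    tau_s: float
    se_s: float
    n: int
    censored_n: int = 0
    method: str = "mle"

    def __post_init__(self) -> None:
        if self.tau_s <= 0 or self.se_s < 0 or self.n < 1:
            raise ValueError("invalid exponential fit")


@dataclass(frozen=True)
class PreferredAngleResult:
    """Inferred preferred crossing angle with error decomposition."""

    alpha0_deg: float
    stat_err_deg: float
    syst_err_deg: float
    ratio_used: float
    method: str = ""
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha0_deg < 180.0):
            raise ValueError("alpha0 out of (0, 180)")

    @property
    def total_err_deg(self) -> float:
        return float(np.hypot(self.stat_err_deg, self.syst_err_deg))


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten-like fit V0 = Vmax E / (Kd_app + E)."""

    vmax: float
    kd_app: float
    se_vmax: float
    se_kd: float
    covariance: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.kd_app <= 0:
            raise ValueError("vmax and kd_app must be positive")

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.vmax * conc / (self.kd_app + conc)


# ---------------------------------------------------------------------------
# exponential times
# ---------------------------------------------------------------------------

def fit_exponential(times_s, censored_times_s=(), method: str = "mle",
                    bins: int = 12) -> ExponentialFit:
    """Characteristic time of exponentially distributed waiting times.

    The default maximum-likelihood estimator handles right-censored
    observations (crossings abandoned before unlinking):
    tau = (sum of all times) / n_uncensored, se = tau / sqrt(n_unc).
    ``method="binned-lsq"`` reproduces the histogram least-squares fit
    used for display, without censoring support.
    """
    t = np.asarray(times_s, dtype=float)
    c = np.asarray(censored_times_s, dtype=float)
    if len(t) < 5:
        raise ValueError("need >= 5 uncensored times")
    if np.any(t <= 0) or (len(c) and np.any(c <= 0)):
        raise ValueError("times must be positive")
    if method == "mle":
        tau = (t.sum() + c.sum()) / len(t)
        return ExponentialFit(float(tau), float(tau / np.sqrt(len(t))),
                              len(t), len(c), "mle")
    if method == "binned-lsq":
        counts, edges = np.histogram(t, bins=bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0

        def model(x, tau):
            return np.exp(-x / tau) / tau

        popt, pcov = curve_fit(model, centers[keep], counts[keep],
                               p0=[t.mean()], maxfev=10000)
        return ExponentialFit(float(popt[0]), float(np.sqrt(pcov[0, 0])),
                              len(t), 0, "binned-lsq")
    raise ValueError(f"unknown method {method!r}")


def tau_ratio(fit_L: ExponentialFit, fit_R: ExponentialFit):
    """rho = tau_L / tau_R with first-order error propagation."""
    rho = fit_L.tau_s / fit_R.tau_s
    se = rho * np.hypot(fit_L.se_s / fit_L.tau_s, fit_R.se_s / fit_R.tau_s)
    return float(rho), float(se)


# ---------------------------------------------------------------------------
# preferred-angle root finding
# ---------------------------------------------------------------------------

def _log_ratio_root(centers, log_ratio, target):
    """Roots of the piecewise-linear log-ratio curve at ``target``."""
    roots = []
    for i in range(len(centers) - 1):
        y0, y1 = log_ratio[i] - target, log_ratio[i + 1] - target
        if not (np.isfinite(y0) and np.isfinite(y1)):
            continue
        if y0 == 0.0:
            roots.append(centers[i])
        elif y0 * y1 < 0:
            roots.append(
                centers[i] + (centers[i + 1] - centers[i]) * y0 / (y0 - y1)
            )
    return roots


#: slope (per degree) below which the log-ratio curve counts as flat
_SLOPE_FLOOR = 0.004


def _solve_alpha0(P_L: AngleDistribution, P_R: AngleDistribution,
                  rho: float, support_min_count: int = 5,
                  max_root_span_deg: float = 30.0,
                  extrapolation_margin: float = 0.75):
    """alpha0 and local log-ratio slope from two binned densities.

    The raw piecewise-linear interpolation is used when it crosses the
    target once.  Sampling noise can make the curve wiggle through the
    target repeatedly; the theoretical log ratio of mirror-related
    chiral distributions is smooth and monotone (exactly linear for
    Gaussian shapes), so in that case a count-weighted linear
    regression of the log ratio supplies the crossing.  The same
    regression extrapolates a target that falls at most
    ``extrapolation_margin`` log units beyond the supported range
    (finite sampling truncates the tails before the theoretical curve
    does); further outside raises NoSolutionError.  A regression root
    far outside the hull of the raw crossings raises an ambiguity
    error; a flat curve matching the target (the symmetric, rho = 1
    case) resolves to the weighted centre of the support.
    """
    if not np.allclose(P_L.bin_edges_deg, P_R.bin_edges_deg):
        raise ValueError("distributions must share bins")
    ok = (P_L.counts >= support_min_count) & (P_R.counts >= support_min_count)
    if ok.sum() < 3:
        raise NoSolutionError("insufficient overlapping support")
    centers = P_L.bin_centers_deg[ok]
    log_ratio = np.log(P_R.density[ok]) - np.log(P_L.density[ok])
    target = np.log(rho)
    if (target < log_ratio.min() - extrapolation_margin
            or target > log_ratio.max() + extrapolation_margin):
        raise NoSolutionError(
            f"log ratio {target:.3f} outside attainable range "
            f"[{log_ratio.min():.3f}, {log_ratio.max():.3f}]"
        )
    roots = _log_ratio_root(centers, log_ratio, target)
    weights = np.minimum(P_L.counts[ok], P_R.counts[ok]).astype(float)
    wsum = weights.sum()
    xbar = float(np.dot(weights, centers) / wsum)
    ybar = float(np.dot(weights, log_ratio) / wsum)
    sxx = float(np.dot(weights, (centers - xbar) ** 2))
    slope_fit = float(np.dot(weights, (centers - xbar)
                             * (log_ratio - ybar)) / sxx) if sxx else 0.0

    if not roots:
        # target beyond the measured tails: extrapolate the regression
        if abs(slope_fit) < _SLOPE_FLOOR:
            raise NoSolutionError("flat log-ratio curve away from target")
        alpha0 = xbar + (target - ybar) / slope_fit
        span = centers.max() - centers.min()
        if not (centers.min() - 0.25 * span
                <= alpha0 <= centers.max() + 0.25 * span):
            raise NoSolutionError(
                "extrapolated root too far outside the supported range"
            )
        return float(alpha0), float(slope_fit)

    if len(roots) == 1:
        alpha0 = float(roots[0])
        k = int(np.argmin(np.abs(centers - alpha0)))
        k0, k1 = max(0, k - 2), min(len(centers) - 1, k + 2)
        denom = centers[k1] - centers[k0]
        slope = ((log_ratio[k1] - log_ratio[k0]) / denom
                 if denom else slope_fit)
        return alpha0, float(slope)

    if abs(slope_fit) < _SLOPE_FLOOR:
        resid_sd = float(np.sqrt(
            np.dot(weights, (log_ratio - ybar) ** 2) / wsum
        ))
        if abs(ybar - target) <= max(resid_sd, 0.05):
            return xbar, slope_fit   # flat curve through the target
        raise NoSolutionError("flat log-ratio curve away from the target")

    alpha0 = xbar + (target - ybar) / slope_fit
    if not (centers.min() - 2.0 <= alpha0 <= centers.max() + 2.0):
        raise NoSolutionError("regression root outside the supported range")
    if roots and not (min(roots) - max_root_span_deg
                      <= alpha0 <= max(roots) + max_root_span_deg):
        raise AmbiguousRootError(roots)
    return float(alpha0), float(slope_fit)


def infer_preferred_angle(
    P_L: AngleDistribution,
    P_R: AngleDistribution,
    rho: float,
    se_rho: float = 0.0,
    n_bootstrap: int = 200,
    seed: int = 0,
    systematic: bool = True,
    method: str = "",
    geometry: dict | None = None,
) -> PreferredAngleResult:
    """Preferred crossing angle alpha0 from tau_L/tau_R = P_R/P_L.

    The root of log[P_R(alpha)/P_L(alpha)] = log(rho) is found by
    monotone piecewise-linear interpolation over bins where both
    densities have support.  The statistical error combines the
    propagated rate-ratio uncertainty (through the local log-ratio
    slope) with a bootstrap over the raw per-frame angles; the
    systematic error is the spread of alpha0 under re-binning (x0.5,
    x2) and, when the underlying juxtaposition events are available,
    threshold (+-2 nm) and equilibration-fraction perturbations.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    alpha0, slope = _solve_alpha0(P_L, P_R, rho)

    stat = 0.0
    if se_rho > 0 and slope != 0:
        stat += (se_rho / rho / abs(slope)) ** 2
    rng = np.random.default_rng(seed)
    if (n_bootstrap and P_L.angles_deg is not None
            and P_R.angles_deg is not None):
        bw = float(np.diff(P_L.bin_edges_deg)[0])
        boots = []
        for _ in range(n_bootstrap):
            aL = rng.choice(P_L.angles_deg, size=len(P_L.angles_deg))
            aR = rng.choice(P_R.angles_deg, size=len(P_R.angles_deg))
            try:
                a0, _ = _solve_alpha0(
                    distribution_from_angles(aL, bin_deg=bw),
                    distribution_from_angles(aR, bin_deg=bw),
                    rho,
                )
                boots.append(a0)
            except (NoSolutionError, AmbiguousRootError):
                continue
        if len(boots) >= max(10, n_bootstrap // 4):
            stat += float(np.var(boots))
    stat_err = float(np.sqrt(stat))

    syst_err = 0.0
    if systematic:
        alts = []
        bw = float(np.diff(P_L.bin_edges_deg)[0])
        for factor in (0.5, 2.0):
            if P_L.angles_deg is None or P_R.angles_deg is None:
                continue
            try:
                a0, _ = _solve_alpha0(
                    distribution_from_angles(P_L.angles_deg,
                                             bin_deg=bw * factor),
                    distribution_from_angles(P_R.angles_deg,
                                             bin_deg=bw * factor),
                    rho,
                )
                alts.append(a0)
            except (NoSolutionError, AmbiguousRootError):
                continue
        for dist_pair in _threshold_perturbations(P_L, P_R):
            try:
                a0, _ = _solve_alpha0(dist_pair[0], dist_pair[1], rho)
                alts.append(a0)
            except (NoSolutionError, AmbiguousRootError):
                continue
        if alts:
            syst_err = float(np.max(np.abs(np.asarray(alts) - alpha0)))

    return PreferredAngleResult(
        alpha0_deg=alpha0,
        stat_err_deg=stat_err,
        syst_err_deg=syst_err,
        ratio_used=float(rho),
        method=method,
        geometry=geometry or {},
    )


def _threshold_perturbations(P_L, P_R):
    """Re-derive distribution pairs at threshold +-2 nm and with the
    first 20% of events dropped, where event tables are available."""
    out = []
    evL = P_L.meta.get("events")
    evR = P_R.meta.get("events")
    thr = P_L.meta.get("threshold_nm")
    if evL is None or evR is None or thr is None:
        return out
    bw = float(np.diff(P_L.bin_edges_deg)[0])

    def rebuild(ev, new_thr, drop_frac=0.0):
        sel = ev[ev["min_distance_nm"] <= new_thr]
        if drop_frac:
            sel = sel.iloc[int(drop_frac * len(sel)):]
        return distribution_from_angles(sel["angle_deg"].to_numpy(),
                                        bin_deg=bw)

    for d_thr in (-2.0, 2.0):
        try:
            out.append((rebuild(evL, thr + d_thr), rebuild(evR, thr + d_thr)))
        except Exception:
            continue
    try:
        out.append((rebuild(evL, thr, 0.2), rebuild(evR, thr, 0.2)))
    except Exception:
        pass
    return out


def combine_geometries(results):
    """Unweighted mean and SEM of alpha0 across tether geometries."""
    results = list(results)
    if len(results) < 2:
        raise ValueError("need >= 2 geometries to combine")
    a = np.array([r.alpha0_deg for r in results])
    return float(a.mean()), float(a.std(ddof=1) / np.sqrt(len(a)))


# ---------------------------------------------------------------------------
# rate-law fits
# ---------------------------------------------------------------------------

def fit_michaelis_menten(conc, rates) -> MMFit:
    """Nonlinear least squares of V0 = Vmax E / (Kd_app + E)."""
    conc = np.asarray(conc, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if len(conc) < 4:
        raise ValueError("need >= 4 concentration points")

    def model(E, vmax, kd):
        return vmax * E / (kd + E)

    p0 = [rates.max() * 1.2, np.median(conc)]
    popt, pcov = curve_fit(model, conc, rates, p0=p0, maxfev=20000)
    vmax, kd = popt
    if not (conc.min() / 100.0 <= kd <= conc.max() * 100.0):
        raise RuntimeError(
            f"Kd_app {kd:.3g} outside data range x100: flagged fit"
        )
    se = np.sqrt(np.diag(pcov))
    return MMFit(float(vmax), float(kd), float(se[0]), float(se[1]), pcov)


def fit_inverse_dwell(n_crossings, dwell_s):
    """Least-squares c of dwell = c / n (dwell inversely proportional to
    the number of DNA crossings); returns (c, se, diagnostics)."""
    n = np.asarray(n_crossings, dtype=float)
    t = np.asarray(dwell_s, dtype=float)
    if len(n) < 1 or np.any(t <= 0) or np.any(n <= 0):
        raise ValueError("need positive crossing counts and dwells")
    x = 1.0 / n
    c = float(np.dot(x, t) / np.dot(x, x))
    resid = t - c * x
    dof = max(1, len(n) - 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / np.dot(x, x)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return c, se, {"r_squared": r2, "residuals_s": resid}


def angle_from_rate_ratio(distribution_pairs, rate_ratio: float):
    """Preferred-angle interval from an ATPase or relaxation rate ratio.

    ``distribution_pairs`` is one (P_plus, P_minus) pair or a sequence
    of pairs (e.g. supercoiled-plasmid crossing-angle distributions at
    several superhelical densities).  Each pair is solved with the same
    log-ratio machinery as :func:`infer_preferred_angle` using
    rate_ratio = P_minus(alpha0)/P_plus(alpha0); the (min, max) of the
    roots is returned.
    """
    if isinstance(distribution_pairs, tuple) and len(distribution_pairs) == 2 \
            and isinstance(distribution_pairs[0], AngleDistribution):
        distribution_pairs = [distribution_pairs]
    roots = []
    for P_plus, P_minus in distribution_pairs:
        a0, _ = _solve_alpha0(P_plus, P_minus, rate_ratio)
        roots.append(a0)
    return float(min(roots)), float(max(roots))
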