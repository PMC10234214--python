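"""Constitutive rheology of jammed, wholly-cellular bioinks.

Two steady/oscillatory constitutive models are implemented and fitted:

* a thixotropic Herschel-Bulkley law for steady shear,

      sigma(gdot) = sigma0 / (1 + lam * gdot) + K * gdot**n,

  where ``sigma0`` is the intrinsic (shear-independent) yield stress of the
  intact, jammed aggregate packing, ``lam`` is a structural-reconstruction
  timescale that competes with shear-induced break-up (``lam > 0`` can make
  the steady flow curve non-monotonic), and ``K``/``n`` describe the
  power-law, shear-thinning branch at high rates; and

* a five-parameter fractional Jeffrey model (FJM) for small-amplitude
  oscillatory shear: two spring-pots (fractional elements of orders
  ``alpha`` >= ``beta`` with quasi-properties ``V`` [Pa s^alpha] and ``G``
  [Pa s^beta]) in series, in parallel with a Newtonian dashpot ``eta0``
  that captures residual, non-cellular media.  Its complex modulus is

      G*(w) = V(iw)^a * G(iw)^b / (V(iw)^a + G(iw)^b) + i*w*eta0,

  whose real and imaginary parts give the storage and loss moduli.

Helpers extract the quantities a bioprinting rheologist reports: yield
stress (from the fit), critical strain from an amplitude sweep, loss
tangent tan(delta) = G''/G', exponential recovery timescales after flow
cessation, and the single-point parallel-plate (rim-stress) correction.

All fitting is deterministic: multi-start nonlinear least squares on a
fixed lattice of initial guesses, in log-residual space because moduli and
stresses span decades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import FitFailureError, NoYieldError

__all__ = [
    "HBThixoParams",
    "FJMParams",
    "FlowCurve",
    "OscillatorySweep",
    "RecoveryTrace",
    "FitDiagnostics",
    "RecoveryFit",
    "hb_thixo_stress",
    "hb_thixo_viscosity",
    "hb_thixo_nonmonotonic",
    "fit_hb_thixo",
    "fjm_moduli",
    "fjm_complex_modulus",
    "fit_fjm",
    "critical_strain",
    "fit_recovery",
    "parallel_plate_correct",
    "check_hysteresis",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class HBThixoParams:
    """Thixotropic Herschel-Bulkley parameters.

    sigma0 : Pa, intrinsic yield stress (>= 0)
    lam    : s, structural reconstruction timescale (>= 0)
    K      : Pa s^n, consistency (>= 0)
    n      : flow index, 0 < n <= 2
    """

    sigma0: float
    lam: float
    K: float
    n: float

    def __post_init__(self):
        if self.sigma0 < 0 or self.lam < 0 or self.K < 0:
            raise ValueError("sigma0, lam and K must be non-negative")
        if not 0 < self.n <= 2:
            raise ValueError("flow index n must be in (0, 2]")


@dataclass(frozen=True)
class FJMParams:
    """Fractional Jeffrey model parameters.

    V, G   : quasi-properties of the alpha / beta spring-pots
             (Pa s^alpha and Pa s^beta), both > 0
    alpha  : fractional order of the more viscous spring-pot
    beta   : fractional order of the more elastic spring-pot
    eta0   : Pa s, Newtonian dashpot in parallel (>= 0)

    Invariant: 0 <= beta <= alpha <= 1.
    """

    V: float
    G: float
    alpha: float
    beta: float
    eta0: float = 0.0

    def __post_init__(self):
        if self.V <= 0 or self.G <= 0:
            raise ValueError("quasi-properties V and G must be positive")
        if not 0.0 <= self.beta <= self.alpha <= 1.0:
            raise ValueError("orders must satisfy 0 <= beta <= alpha <= 1")
        if self.eta0 < 0:
            raise ValueError("eta0 must be non-negative")


# ---------------------------------------------------------------------------
# observation containers


def _as_positive_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if np.any(arr <= 0):
        raise ValueError(f"{name} must be strictly positive")
    return arr


@dataclass(frozen=True)
class FlowCurve:
    """Steady-shear observations: stress versus shear rate."""

    shear_rates: np.ndarray
    stresses: np.ndarray
    corrected: bool = False

    def __post_init__(self):
        rates = _as_positive_array(self.shear_rates, "shear_rates")
        stresses = np.asarray(self.stresses, dtype=float)
        if stresses.shape != rates.shape:
            raise ValueError("shear_rates and stresses must have equal length")
        d = np.diff(rates)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("shear_rates must be strictly monotone")
        object.__setattr__(self, "shear_rates", rates)
        object.__setattr__(self, "stresses", stresses)


@dataclass(frozen=True)
class OscillatorySweep:
    """Oscillatory observations: G', G'' versus frequency (rad/s) or
    strain amplitude (dimensionless fraction)."""

    abscissa: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray
    mode: str = "frequency"

    def __post_init__(self):
        if self.mode not in ("frequency", "amplitude"):
            raise ValueError("mode must be 'frequency' or 'amplitude'")
        x = _as_positive_array(self.abscissa, "abscissa")
        gp = np.asarray(self.g_prime, dtype=float)
        gpp = np.asarray(self.g_double_prime, dtype=float)
        if gp.shape != x.shape or gpp.shape != x.shape:
            raise ValueError("abscissa and moduli must have equal length")
        if np.any(gp < 0) or np.any(gpp < 0):
            raise ValueError("moduli must be non-negative")
        object.__setattr__(self, "abscissa", x)
        object.__setattr__(self, "g_prime", gp)
        object.__setattr__(self, "g_double_prime", gpp)


@dataclass(frozen=True)
class RecoveryTrace:
    """Storage modulus versus time after flow cessation."""

    time: np.ndarray
    g_prime: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        g = np.asarray(self.g_prime, dtype=float)
        if t.ndim != 1 or t.shape != g.shape or t.size == 0:
            raise ValueError("time and g_prime must be equal-length 1-D arrays")
        if t[0] < 0 or np.any(np.diff(t) < 0):
            raise ValueError("time must be non-decreasing from 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "g_prime", g)


@dataclass
class FitDiagnostics:
    """Bookkeeping returned alongside fitted parameters."""

    residual_norm: float
    n_points: int
    n_starts: int
    conf_intervals: dict = field(default_factory=dict)
    tan_delta: np.ndarray | None = None


@dataclass(frozen=True)
class RecoveryFit:
    g_inf: float
    g0: float
    tau_r: float
    tau_identifiable: bool
    residual_norm: float


# ---------------------------------------------------------------------------
# thixotropic Herschel-Bulkley


def hb_thixo_stress(rate, params: HBThixoParams):
    """Steady shear stress sigma0/(1 + lam*gdot) + K*gdot**n (Pa).

    ``rate`` may be a scalar or array of strictly positive shear rates.
    """
    gdot = np.asarray(rate, dtype=float)
    if np.any(gdot <= 0):
        raise ValueError("shear rate must be strictly positive")
    sigma = params.sigma0 / (1.0 + params.lam * gdot) + params.K * gdot**params.n
    return float(sigma) if np.isscalar(rate) else sigma


def hb_thixo_viscosity(rate, params: HBThixoParams):
    """Steady shear viscosity eta = sigma / gdot (Pa s)."""
    return hb_thixo_stress(rate, params) / np.asarray(rate, dtype=float)


def _hb_dstress(gdot: np.ndarray, p: HBThixoParams) -> np.ndarray:
    """d sigma / d gdot."""
    return (
        -p.sigma0 * p.lam / (1.0 + p.lam * gdot) ** 2
        + p.n * p.K * gdot ** (p.n - 1.0)
    )


def hb_thixo_nonmonotonic(
    params: HBThixoParams, rate_window: tuple[float, float]
) -> tuple[bool, float | None]:
    """Detect a non-monotonic steady flow curve within a rate window.

    Returns ``(True, rate_at_stress_minimum)`` when the derivative of the
    flow curve changes sign inside the window (the signature of a
    positive reconstruction timescale ``lam``), else ``(False, None)``.

    The derivative is negative exactly where
    ``h(g) = ln(n K g^(n-1) (1 + lam g)^2) - ln(sigma0 lam) < 0``;
    ``h`` is unimodal in ``g`` (its minimum sits at
    ``g* = (1 - n) / (lam (1 + n))`` when ``n < 1``, at the left edge
    otherwise), so the negative region is a single interval whose
    endpoints are bracketed and refined by root finding.  The returned
    rate is the global stress minimiser over the window (an interior
    stationary point or, for a curve still descending at the window edge,
    that edge).
    """
    lo, hi = float(rate_window[0]), float(rate_window[1])
    if lo <= 0 or hi <= lo:
        raise ValueError("rate window must be positive with min < max")
    p = params
    if p.lam == 0 or p.sigma0 == 0 or p.K == 0:
        # derivative strictly positive (or strictly negative for K == 0):
        # monotone either way
        return False, None

    def h(g: float) -> float:
        return (
            np.log(p.n * p.K)
            + (p.n - 1.0) * np.log(g)
            + 2.0 * np.log1p(p.lam * g)
            - np.log(p.sigma0 * p.lam)
        )

    g_star = (1.0 - p.n) / (p.lam * (1.0 + p.n)) if p.n < 1.0 else lo
    g_min = min(max(g_star, lo), hi)
    if h(g_min) >= 0.0:
        return False, None  # derivative non-negative throughout
    g1 = lo if h(lo) < 0 else optimize.brentq(h, lo, g_min, xtol=1e-15, rtol=1e-15)
    g2 = hi if h(hi) < 0 else optimize.brentq(h, g_min, hi, xtol=1e-15, rtol=1e-15)
    if g1 == lo and g2 == hi:
        return False, None  # derivative negative throughout: monotone fall
    candidates = [lo, hi]
    if g2 < hi:
        candidates.append(g2)
    best = min(candidates, key=lambda g: hb_thixo_stress(g, p))
    return True, float(best)


_HB_N_GRID = (0.2, 0.5, 0.8, 1.2)
_HB_LAM_GRID = (0.0, 1.0)


def fit_hb_thixo(curve: FlowCurve) -> tuple[HBThixoParams, FitDiagnostics]:
    """Fit the thixotropic Herschel-Bulkley law to a steady flow curve.

    Least squares on log-stress residuals (stresses span decades), with
    non-negativity bounds on sigma0, lam, K and n in (0, 2].  Eight
    deterministic starts on a coarse (n, lam) lattice; the best residual
    wins.  Returns parameters plus diagnostics with approximate 95%
    confidence half-widths from the Jacobian.
    """
    gdot = curve.shear_rates
    sigma = curve.stresses
    if gdot.size < 6:
        raise FitFailureError("need at least 6 points to fit 4 parameters")
    if np.log10(gdot.max() / gdot.min()) < 1.5:
        raise FitFailureError("shear rates must span at least 1.5 decades")
    if np.any(sigma <= 0):
        raise FitFailureError("stresses must be positive for a log-space fit")
    if np.ptp(sigma) < 1e-12 * sigma.max():
        raise FitFailureError(
            "stress is constant across rates; model parameters are not "
            "identifiable", {"stress": float(sigma[0])}
        )

    log_sigma = np.log(sigma)
    scale = float(np.median(sigma))

    def residuals(theta):
        s0, lam, K, n = theta
        model = s0 / (1.0 + lam * gdot) + K * gdot**n
        return np.log(np.maximum(model, 1e-300)) - log_sigma

    lb = [0.0, 0.0, 0.0, 1e-3]
    ub = [np.inf, np.inf, np.inf, 2.0]
    best = None
    for n0 in _HB_N_GRID:
        for lam0 in _HB_LAM_GRID:
            x0 = [scale / 2.0, lam0, scale / 2.0, n0]
            try:
                sol = optimize.least_squares(
                    residuals, x0, bounds=(lb, ub), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("all fit starts failed to converge")
    s0, lam, K, n = best.x
    params = HBThixoParams(sigma0=float(s0), lam=float(lam), K=float(K), n=float(n))
    diag = FitDiagnostics(
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_points=int(gdot.size),
        n_starts=len(_HB_N_GRID) * len(_HB_LAM_GRID),
        conf_intervals=_jacobian_intervals(best, ("sigma0", "lam", "K", "n")),
    )
    return params, diag


def _jacobian_intervals(sol, names) -> dict:
    """Approximate 95% confidence half-widths from the fit Jacobian."""
    m, k = sol.jac.shape
    dof = max(m - k, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        half = 1.96 * np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        half = np.full(k, np.nan)
    return {name: float(h) for name, h in zip(names, half)}


# ---------------------------------------------------------------------------
# fractional Jeffrey model


def fjm_complex_modulus(omega, params: FJMParams):
    """Complex modulus G*(w) of the fractional Jeffrey model.

    Two spring-pots in series, Newtonian dashpot in parallel:
    ``G* = V(iw)^a G(iw)^b / (V(iw)^a + G(iw)^b) + i w eta0``.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w <= 0):
        raise ValueError("angular frequency must be strictly positive")
    za = params.V * (1j * w) ** params.alpha
    zb = params.G * (1j * w) ** params.beta
    g = za * zb / (za + zb) + 1j * w * params.eta0
    return complex(g) if np.isscalar(omega) else g


def fjm_moduli(omega, params: FJMParams):
    """Storage and loss moduli (G', G'') of the fractional Jeffrey model.

    Explicit trigonometric form: with ``A = V w^alpha`` and
    ``B = G w^beta``,

        den = A^2 + B^2 + 2 A B cos(pi (alpha - beta) / 2)
        G'  = (A B^2 cos(pi alpha/2) + A^2 B cos(pi beta/2)) / den
        G'' = (A B^2 sin(pi alpha/2) + A^2 B sin(pi beta/2)) / den
              + eta0 * w

    which is the real/imaginary decomposition of
    :func:`fjm_complex_modulus`.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w <= 0):
        raise ValueError("angular frequency must be strictly positive")
    a, b = params.alpha, params.beta
    A = params.V * w**a
    B = params.G * w**b
    den = A**2 + B**2 + 2.0 * A * B * np.cos(np.pi * (a - b) / 2.0)
    num_p = A * B**2 * np.cos(np.pi * a / 2.0) + A**2 * B * np.cos(np.pi * b / 2.0)
    num_pp = A * B**2 * np.sin(np.pi * a / 2.0) + A**2 * B * np.sin(np.pi * b / 2.0)
    gp = num_p / den
    gpp = num_pp / den + params.eta0 * w
    if np.isscalar(omega):
        return float(gp), float(gpp)
    return gp, gpp


_FJM_ALPHA_GRID = (0.3, 0.7)
_FJM_RATIO_GRID = (0.25, 0.75)
_FJM_ETA_GRID = (0.0, 1.0)


def fit_fjm(sweep: OscillatorySweep) -> tuple[FJMParams, FitDiagnostics]:
    """Fit the five FJM parameters to a frequency sweep.

    Joint least squares on summed squared log-residuals of G' and G''
    under the order constraint 0 <= beta <= alpha <= 1 (enforced by the
    parameterisation beta = alpha * t, t in [0, 1]).  Deterministic
    multi-start over a coarse (alpha, t, eta0) lattice.  Diagnostics carry
    tan(delta) = G''/G' of the fit at each frequency.
    """
    if sweep.mode != "frequency":
        raise ValueError("fit_fjm requires a frequency-mode sweep")
    w = sweep.abscissa
    gp, gpp = sweep.g_prime, sweep.g_double_prime
    if w.size < 8:
        raise FitFailureError("need at least 8 frequencies to fit 5 parameters")
    if np.any(gp <= 0) or np.any(gpp <= 0):
        raise FitFailureError("both moduli must be positive for a log-space fit")

    log_gp, log_gpp = np.log(gp), np.log(gpp)
    g_scale = float(np.median(gp))
    eta_scale = float(np.median(gpp / w))

    def unpack(theta):
        logV, logG, alpha, t, eta0 = theta
        return FJMParams(
            V=float(np.exp(logV)), G=float(np.exp(logG)),
            alpha=float(alpha), beta=float(alpha * t), eta0=float(eta0),
        )

    def residuals(theta):
        p = unpack(theta)
        mp, mpp = fjm_moduli(w, p)
        return np.concatenate([
            np.log(np.maximum(mp, 1e-300)) - log_gp,
            np.log(np.maximum(mpp, 1e-300)) - log_gpp,
        ])

    lb = [-60.0, -60.0, 1e-6, 0.0, 0.0]
    ub = [60.0, 60.0, 1.0, 1.0, np.inf]
    best = None
    for a0 in _FJM_ALPHA_GRID:
        for t0 in _FJM_RATIO_GRID:
            for e0 in _FJM_ETA_GRID:
                x0 = [np.log(g_scale), np.log(g_scale), a0, t0, e0 * eta_scale]
                try:
                    sol = optimize.least_squares(
                        residuals, x0, bounds=(lb, ub), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
                    )
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("all FJM fit starts failed to converge")
    params = unpack(best.x)
    mp, mpp = fjm_moduli(w, params)
    diag = FitDiagnostics(
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_points=int(w.size),
        n_starts=len(_FJM_ALPHA_GRID) * len(_FJM_RATIO_GRID) * len(_FJM_ETA_GRID),
        conf_intervals=_jacobian_intervals(
            best, ("logV", "logG", "alpha", "beta_ratio", "eta0")
        ),
        tan_delta=mpp / mp,
    )
    return params, diag


# ---------------------------------------------------------------------------
# derived rheological quantities


def critical_strain(sweep: OscillatorySweep, drop_frac: float = 0.1) -> float:
    """Yield strain from an amplitude sweep.

    The linear plateau is the median G' over the lowest decade of strain;
    the critical strain is the (log-)interpolated strain at which G' first
    falls below ``(1 - drop_frac) * plateau``.  Raises :class:`NoYieldError`
    if G' never drops that far.  Invariant under rescaling both moduli.
    """
    if sweep.mode != "amplitude":
        raise ValueError("critical_strain requires an amplitude-mode sweep")
    if not 0.0 < drop_frac <= 0.5:
        raise ValueError("drop_frac must be in (0, 0.5]")
    strain = sweep.abscissa
    gp = sweep.g_prime
    order = np.argsort(strain)
    strain, gp = strain[order], gp[order]
    plateau = float(np.median(gp[strain <= strain[0] * 10.0]))
    target = (1.0 - drop_frac) * plateau
    below = np.nonzero(gp < target)[0]
    if below.size == 0:
        raise NoYieldError(
            f"G' never drops below {1 - drop_frac:.0%} of its plateau"
        )
    i = below[0]
    if i == 0:
        return float(strain[0])
    # log-linear interpolation between the bracketing amplitudes
    x0, x1 = np.log(strain[i - 1]), np.log(strain[i])
    y0, y1 = gp[i - 1], gp[i]
    frac = (y0 - target) / (y0 - y1)
    return float(np.exp(x0 + frac * (x1 - x0)))


def fit_recovery(trace: RecoveryTrace) -> RecoveryFit:
    """Fit exponential recovery G'(t) = g_inf - (g_inf - g0) exp(-t/tau).

    After flow cessation the storage modulus of a thixotropic slurry
    rebuilds toward its intact value ``g_inf`` from the sheared value
    ``g0`` with timescale ``tau_r``.  A flat trace is degenerate:
    ``g_inf = g0`` and ``tau_r`` is flagged unidentifiable.
    """
    t, g = trace.time, trace.g_prime
    if t.size < 5:
        raise FitFailureError("need at least 5 time points")
    if np.ptp(g) < 1e-12 * max(abs(g).max(), 1.0):
        return RecoveryFit(
            g_inf=float(g[0]), g0=float(g[0]), tau_r=float("nan"),
            tau_identifiable=False, residual_norm=0.0,
        )

    span = max(t[-1] - t[0], 1e-12)

    def model(theta):
        g_inf, g0, log_tau = theta
        return g_inf - (g_inf - g0) * np.exp(-t / np.exp(log_tau))

    def residuals(theta):
        return model(theta) - g

    best = None
    for tau0 in (span / 10.0, span / 3.0, span):
        x0 = [float(g[-1]), float(g[0]), np.log(tau0)]
        try:
            sol = optimize.least_squares(
                residuals, x0, method="lm", xtol=1e-14, ftol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("recovery fit failed to converge")
    g_inf, g0, log_tau = best.x
    return RecoveryFit(
        g_inf=float(g_inf), g0=float(g0), tau_r=float(np.exp(log_tau)),
        tau_identifiable=True,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
    )


def parallel_plate_correct(curve: FlowCurve) -> FlowCurve:
    """Single-point rim-stress correction for plate-plate geometry.

    In a parallel-plate rheometer the shear rate varies with radius, so
    the apparent (rim) stress overstates the true stress of a
    shear-thinning material.  The standard single-point correction is

        sigma_true = sigma_apparent * (3 + d ln sigma_a / d ln gdot) / 4,

    with the local log-log slope from central differences (one-sided at
    the ends).  Newtonian data (slope 1) are left exactly unchanged.
    The returned curve carries ``corrected=True``; correcting twice is an
    error.
    """
    if curve.corrected:
        raise ValueError("flow curve is already parallel-plate corrected")
    if curve.shear_rates.size < 4:
        raise ValueError("need at least 4 points to estimate local slopes")
    if np.any(curve.stresses <= 0):
        raise ValueError("stresses must be positive for a log-log slope")
    ln_g = np.log(curve.shear_rates)
    ln_s = np.log(curve.stresses)
    slope = np.gradient(ln_s, ln_g)
    factor = (3.0 + slope) / 4.0
    return FlowCurve(
        shear_rates=curve.shear_rates.copy(),
        stresses=curve.stresses * factor,
        corrected=True,
    )


def check_hysteresis(
    descending: FlowCurve, ascending: FlowCurve, tol: float = 0.1
) -> tuple[bool, float]:
    """Compare descending- and ascending-rate sweeps point by point.

    Steady-shear protocols run the rate down and then back up; agreement
    of the two branches certifies the absence of history (hysteresis)
    artifacts.  Returns ``(flagged, median_relative_discrepancy)`` where
    ``flagged`` is True when the median relative discrepancy at matched
    rates exceeds ``tol`` (default 10%).
    """
    down = dict(zip(np.round(np.log10(descending.shear_rates), 9),
                    descending.stresses))
    up = dict(zip(np.round(np.log10(ascending.shear_rates), 9),
                  ascending.stresses))
    common = sorted(set(down) & set(up))
    if not common:
        raise ValueError("sweeps share no common shear rates")
    rel = np.array([
        abs(down[k] - up[k]) / max(abs(down[k]), abs(up[k])) for k in common
    ])
    med = float(np.median(rel))
    return med > tol, med
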