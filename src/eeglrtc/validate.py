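"""Three-stage validation of LRTC estimates.

1. Surrogate test — the DFA exponents of the analysed windows must
   differ from those of sample-shuffled (whitened) copies.
2. Long- vs short-range dependence — per window, an ARMA(p, 0) fit to
   the raw series competes by AIC with an "ARFIMA" fit obtained by
   fractionally differencing the window with ``d = H - 0.5`` and fitting
   ARMA(p, 0) to the residual; AR order is selected independently per
   branch over p = 1..10.
3. Power-law linearity — candidate models (polynomials of order 1-5,
   exponential, logarithmic, root) are fitted to the log2-log2
   fluctuation plot and compared by AIC/BIC; the exponent is trusted
   when the linear model wins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import lfilter
from scipy.stats import mannwhitneyu

from .datatypes import FluctuationFunction
from .dfa import dfa_exponent_batch
from .errors import FitError, ParameterError, SampleSizeError

logger = logging.getLogger(__name__)

__all__ = ["surrogate_test", "frac_diff", "frac_diff_weights", "fit_arma",
           "select_orders", "compare_arma_arfima", "mldfa",
           "r_squared_linear", "SurrogateReport", "ArfimaComparison",
           "MLDFAReport"]

MAX_AR_ORDER = 10
D_CLAMP = 0.49


@dataclass
class SurrogateReport:
    h_original: np.ndarray
    h_shuffled: np.ndarray
    p_value: float
    n_windows: int


@dataclass
class ArfimaComparison:
    preferred: list            # per-window "ARMA" / "ARFIMA"
    aic_arma: np.ndarray
    aic_arfima: np.ndarray
    p_arma: np.ndarray
    p_arfima: np.ndarray
    d: np.ndarray
    pct_arfima_preferred: float
    n_failed: int = 0


@dataclass
class MLDFAReport:
    aic: dict
    bic: dict
    loglik: dict
    coeffs: dict
    best_by_aic: str
    best_by_bic: str
    is_linear_best: bool
    quad_lin_ratio: float | None = None
    r_squared: float = field(default=np.nan)


def surrogate_test(windows: np.ndarray, n_shuffles_per_window: int = 1,
                   sizes=None, seed=None) -> SurrogateReport:
    """Mann-Whitney comparison of window DFA exponents against exponents
    of sample-shuffled surrogates of the same windows."""
    w = np.asarray(windows, dtype=float)
    if w.ndim != 2:
        raise ParameterError("windows must be 2-D (n_windows, n_samples)")
    if w.shape[0] < 20:
        raise SampleSizeError("need at least 20 windows for the surrogate test")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    h_orig, _ = dfa_exponent_batch(w, sizes)
    shuffled = np.concatenate([
        rng.permuted(w, axis=1) for _ in range(n_shuffles_per_window)
    ])
    h_shuf, _ = dfa_exponent_batch(shuffled, sizes)
    a = h_orig[np.isfinite(h_orig)]
    b = h_shuf[np.isfinite(h_shuf)]
    p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return SurrogateReport(h_orig, h_shuf, p, w.shape[0])


def frac_diff_weights(n: int, d: float) -> np.ndarray:
    """Binomial weights of (1 - B)^d: w0 = 1, w_j = w_{j-1} (j-1-d)/j."""
    w = np.empty(n)
    w[0] = 1.0
    for j in range(1, n):
        w[j] = w[j - 1] * (j - 1 - d) / j
    return w


def frac_diff(x: np.ndarray, d: float) -> np.ndarray:
    """Apply (1 - B)^d with weights truncated at the series start."""
    if abs(d) >= 1.0:
        raise ParameterError("|d| must be < 1")
    x = np.asarray(x, dtype=float)
    if d == 0.0:
        return x.copy()
    return lfilter(frac_diff_weights(len(x), d), [1.0], x)


def fit_arma(x: np.ndarray, p: int, q: int = 0, method: str = "burg"):
    """Gaussian ARMA(p, q) fit with constant mean.

    Returns ``(loglik, aic, params)`` with ``aic = 2k - 2 loglik`` and
    ``k = p + q + 2`` (constant + innovation variance). The likelihood
    is the exact Gaussian likelihood evaluated through the state-space
    representation; by default the parameters come from the fast Burg
    estimator, ``method="statespace"`` switches to full MLE.
    """
    from statsmodels.tsa.arima.model import ARIMA

    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0:
        raise FitError("constant series has degenerate innovation variance")
    if not (1 <= p <= MAX_AR_ORDER) or q != 0:
        raise ParameterError(f"p must be 1..{MAX_AR_ORDER} and q = 0")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(x, order=(p, 0, q), trend="c").fit(method=method)
    except Exception as exc:  # pragma: no cover - estimator-dependent
        if method != "statespace":
            logger.warning("ARMA(%d,%d) %s fit failed (%s); "
                           "falling back to statespace", p, q, method, exc)
            return fit_arma(x, p, q, method="statespace")
        raise FitError(f"ARMA({p},{q}) fit failed: {exc}") from exc
    llf = float(res.llf)
    if not np.isfinite(llf):
        raise FitError(f"ARMA({p},{q}) produced non-finite likelihood")
    k = p + q + 2
    return llf, 2.0 * k - 2.0 * llf, np.asarray(res.params)


def select_orders(x: np.ndarray, max_p: int = MAX_AR_ORDER,
                  method: str = "burg"):
    """AIC-minimising AR order over p = 1..max_p with q = 0.

    Returns ``(p_star, aic_star, loglik_star)``.
    """
    best = None
    for p in range(1, max_p + 1):
        try:
            llf, aic, _ = fit_arma(x, p, 0, method=method)
        except FitError as exc:
            logger.debug("order %d skipped: %s", p, exc)
            continue
        if best is None or aic < best[1]:
            best = (p, aic, llf)
    if best is None:
        raise FitError("all AR orders failed to fit")
    return best


def compare_arma_arfima(windows: np.ndarray, h_estimates=None,
                        sizes=None, count_d_parameter: bool = False,
                        method: str = "burg") -> ArfimaComparison:
    """Per-window AIC contest between a short-memory ARMA fit of the raw
    window and a long-memory fit of the fractionally differenced window.

    ``d = H - 0.5`` is plugged in from the DFA estimate (clamped to
    (-0.49, 0.49)); since d is not likelihood-estimated it is, by
    default, not counted as an extra AIC parameter
    (``count_d_parameter=True`` restores the conservative count).
    The fractional differencing operator is unit-Jacobian, so the two
    branches' Gaussian likelihoods are directly comparable.
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim != 2:
        raise ParameterError("windows must be 2-D (n_windows, n_samples)")
    if h_estimates is None:
        h_estimates, _ = dfa_exponent_batch(w, sizes)
    h_estimates = np.asarray(h_estimates, dtype=float)
    d = np.clip(h_estimates - 0.5, -D_CLAMP, D_CLAMP)

    preferred, aic_a, aic_f, p_a, p_f = [], [], [], [], []
    n_failed = 0
    for i in range(w.shape[0]):
        if not np.isfinite(d[i]):
            n_failed += 1
            continue
        try:
            pa, aa, _ = select_orders(w[i], method=method)
            z = frac_diff(w[i], float(d[i]))
            pf, af, _ = select_orders(z, method=method)
        except FitError as exc:
            logger.warning("window %d excluded: %s", i, exc)
            n_failed += 1
            continue
        if count_d_parameter:
            af += 2.0
        preferred.append("ARFIMA" if af < aa else "ARMA")
        aic_a.append(aa)
        aic_f.append(af)
        p_a.append(pa)
        p_f.append(pf)
    n_ok = len(preferred)
    pct = (100.0 * sum(1 for v in preferred if v == "ARFIMA") / n_ok
           if n_ok else np.nan)
    return ArfimaComparison(preferred, np.asarray(aic_a), np.asarray(aic_f),
                            np.asarray(p_a), np.asarray(p_f), d, pct,
                            n_failed)


# ---------------------------------------------------------------------------
# ML-DFA: model competition on the log-log fluctuation plot
# ---------------------------------------------------------------------------

def _gauss_loglik(resid: np.ndarray, scale: float = 1.0) -> float:
    m = len(resid)
    s2 = float((resid ** 2).mean())
    # floor the variance at numerical-noise level so that machine-precision
    # fits are ranked by parsimony instead of by rounding dust
    floor = (1e-8 * max(1.0, scale)) ** 2
    s2 = max(s2, floor)
    return -0.5 * m * (np.log(2.0 * np.pi * s2) + 1.0)


def _fit_poly(u, v, order):
    c = np.polyfit(u, v, order)
    return c, v - np.polyval(c, u)


def _fit_log(u, v):
    a = np.column_stack([np.ones_like(u), np.log(u)])
    c, *_ = np.linalg.lstsq(a, v, rcond=None)
    return c, v - a @ c


def _fit_root(u, v):
    a = np.column_stack([np.ones_like(u), np.sqrt(u)])
    c, *_ = np.linalg.lstsq(a, v, rcond=None)
    return c, v - a @ c


def _fit_exp(u, v):
    def model(uu, a, b, c):
        return a + b * np.exp(np.clip(c * uu, -500, 50))

    scale = max(1.0, float(np.ptp(u)))
    p0 = (float(v.min()), float(np.ptp(v) + 1e-3), 0.5 / scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coef, _ = curve_fit(model, u, v, p0=p0, maxfev=20000)
    return coef, v - model(u, *coef)


def mldfa(flucs: FluctuationFunction) -> MLDFAReport:
    """Compare candidate shapes of the log2-log2 fluctuation plot.

    AIC = 2k - 2 logL and BIC = k ln m - 2 logL with k = number of model
    coefficients + 1 (residual variance) and m = number of grid points.
    """
    u = np.log2(np.asarray(flucs.sizes, dtype=float))
    v = np.log2(np.asarray(flucs.f, dtype=float))
    m = len(u)
    if m < 8:
        raise ParameterError("need at least 8 grid points for ML-DFA")
    if np.ptp(u) == 0.0:
        raise ParameterError("constant abscissa: singular design")

    candidates = {}
    for order in range(1, 6):
        candidates[f"poly{order}"] = (order + 1,
                                      lambda uu, vv, o=order: _fit_poly(uu, vv, o))
    candidates["logarithmic"] = (2, _fit_log)
    candidates["root"] = (2, _fit_root)
    candidates["exponential"] = (3, _fit_exp)

    aic, bic, llk, coeffs = {}, {}, {}, {}
    for name, (n_coef, fitter) in candidates.items():
        try:
            c, resid = fitter(u, v)
        except Exception as exc:
            logger.debug("ML-DFA candidate %s failed: %s", name, exc)
            continue
        ll = _gauss_loglik(resid, float(np.std(v)))
        k = n_coef + 1
        aic[name] = 2.0 * k - 2.0 * ll
        bic[name] = k * np.log(m) - 2.0 * ll
        llk[name] = ll
        coeffs[name] = np.asarray(c)
    if not aic:
        raise FitError("no ML-DFA candidate could be fitted")

    best_aic = min(aic, key=aic.get)
    best_bic = min(bic, key=bic.get)
    is_linear = best_aic == "poly1"
    ratio = None
    if best_aic == "poly2":
        quad, lin = coeffs["poly2"][0], coeffs["poly2"][1]
        ratio = abs(quad) / abs(lin) if lin != 0.0 else np.inf
    return MLDFAReport(aic, bic, llk, coeffs, best_aic, best_bic,
                       is_linear, ratio, r_squared_linear(flucs))


def r_squared_linear(flucs: FluctuationFunction) -> float:
    """R^2 of the OLS line on (log2 n, log2 F)."""
    u = np.log2(np.asarray(flucs.sizes, dtype=float))
    v = np.log2(np.asarray(flucs.f, dtype=float))
    if len(u) < 3:
        raise ParameterError("need at least 3 points")
    c, resid = _fit_poly(u, v, 1)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((v - v.mean()) ** 2).sum())
    if ss_tot == 0.0:
        if ss_res == 0.0:
            return 1.0
        raise ParameterError("zero variance in log2 F with nonzero residuals")
    return 1.0 - ss_res / ss_tot
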