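"""Levin-Lin-Chu (LLC) pooled panel unit-root test and stationarity enforcement.

The LLC test pools bias-adjusted augmented-Dickey-Fuller regressions
across the members of a balanced panel under a common-autoregressive-root
assumption.  Per panel member i the two auxiliary regressions

    dy_t  on  {dy_{t-1..t-L}, deterministic terms}   -> residual e_hat
    y_{t-1} on the same regressors                   -> residual v_hat

are run, the residuals standardized by the per-member ADF residual scale,
and all members' standardized pairs pooled into one no-intercept
regression e = delta * v + err.  Its t-statistic t_delta diverges to
-infinity under stationarity but is not centered at zero under the unit
root; the moment-adjusted statistic

    t* = (t_delta - N * T_bar * S_N * sigma_eps^-2 * SE(delta) * mu*) / sigma*

is asymptotically standard normal, where S_N is the mean ratio of
long-run to short-run innovation SDs (Bartlett-kernel long-run variance)
and (mu*, sigma*) are adjustment moments.  The test is one-sided: small
(left-tail) t* rejects the unit root.

Adjustment moments come in two modes.  ``simulated`` (default) calibrates
(mu*, sigma*) at run time by Monte-Carlo under the unit-root null with the
same (N, effective T, lag order, deterministic spec) as the data —
appropriate here because the study design's T=9 lies far outside the range
any published lookup covers.  ``tabulated`` uses a plug-in constant table;
the built-in one was itself calibrated by large-replicate Monte-Carlo
under the null (see ``DEFAULT_MOMENTS``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import PanelDataset, _difference_many

__all__ = [
    "UnitRootResult",
    "adf_components",
    "llc_test",
    "ensure_stationary",
    "DEFAULT_MOMENTS",
]

DETERMINISTIC_SPECS = ("none", "intercept", "trend")

#: built-in adjustment moments, keyed (deterministic_spec, effective T).
#: Calibrated by Monte-Carlo under the driftless random-walk null
#: (50 panel members, 20000 replicates per entry); see docs/methods.md.
#: Entries are (mu_star, sigma_star).  Populated for the effective lengths
#: this package's own experiments use; nearest-T lookup otherwise.
DEFAULT_MOMENTS: dict[tuple[str, int], tuple[float, float]] = {
    ("intercept", 8): (-1.1627, 1.3668),
    ("intercept", 24): (-0.7323, 0.9009),
    ("intercept", 39): (-0.6442, 0.8426),
    ("intercept", 46): (-0.6275, 0.8344),
    ("intercept", 49): (-0.6197, 0.8302),
    ("none", 8): (0.0062, 1.2394),
    ("none", 49): (-0.0114, 1.0286),
    ("trend", 8): (-1.2245, 2.1816),
    ("trend", 49): (-0.6254, 0.8234),
}


@dataclass(frozen=True)
class UnitRootResult:
    """Outcome of one LLC panel unit-root test."""

    variable: str
    deterministic_spec: str
    lags_per_panel: tuple[int, ...]
    pooled_delta: float
    t_delta: float
    t_star: float
    mu_star: float
    sigma_star: float
    p_value: float
    alpha: float
    reject_unit_root: bool
    moments_mode: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.sigma_star <= 0:
            raise ValueError("sigma_star must be positive")


def _residuals(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    if design.shape[1] == 0:
        return y
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _det_terms(n: int, deterministic: str) -> np.ndarray:
    if deterministic == "none":
        return np.empty((n, 0))
    if deterministic == "intercept":
        return np.ones((n, 1))
    if deterministic == "trend":
        return np.column_stack([np.ones(n), np.arange(n, dtype=float)])
    raise ValueError(
        f"unknown deterministic spec {deterministic!r}; use one of {DETERMINISTIC_SPECS}"
    )


def adf_components(series: np.ndarray, lags: int = 0,
                   deterministic: str = "intercept"):
    """Per-member ADF orthogonalization step of the LLC procedure.

    Regresses dy_t and y_{t-1} (t = lags+1 .. T-1) on the lagged
    differences dy_{t-1..t-lags} plus deterministic terms, and standardizes
    both residual series by sigma_hat, the residual scale of the ADF
    regression e_hat = delta_i * v_hat + err (RSS divided by the number of
    pooled observations, following the original procedure).

    Returns
    -------
    (e_tilde, v_tilde, sigma_hat)
        Aligned standardized residual series of length T - lags - 1 and the
        scale used.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("zero variance: series is constant")
    t_len = y.size
    n_obs = t_len - lags - 1
    if n_obs < 3:
        raise ValueError(
            f"too few observations: T={t_len} leaves {n_obs} usable points "
            f"with lags={lags} (need >= 3)"
        )
    dy = np.diff(y)
    # regressand rows correspond to t = lags+1 .. T-1
    target_dy = dy[lags:]
    target_lv = y[lags:-1]
    lag_cols = [dy[lags - l:-l] for l in range(1, lags + 1)]
    design = np.column_stack(lag_cols + [_det_terms(n_obs, deterministic)]) \
        if lag_cols else _det_terms(n_obs, deterministic)
    e_hat = _residuals(target_dy, design)
    v_hat = _residuals(target_lv, design)
    denom = v_hat @ v_hat
    if denom == 0:
        raise ValueError("zero variance: lagged-level residual is identically zero")
    delta_i = (v_hat @ e_hat) / denom
    rss = e_hat - delta_i * v_hat
    sigma = np.sqrt((rss @ rss) / n_obs)
    if sigma == 0:
        raise ValueError("zero variance: perfect ADF fit, cannot standardize")
    return e_hat / sigma, v_hat / sigma, sigma


def _long_run_sd_ratio(series: np.ndarray, deterministic: str, sigma_eps: float) -> float:
    """Bartlett-kernel long-run SD of dy over the ADF residual SD."""
    dy = np.diff(np.asarray(series, dtype=float))
    m = dy.size
    if deterministic != "none":
        dy = dy - dy.mean()
    # Bartlett truncation ceil(3.21 * T^(1/3)), capped at T - 3
    trunc = min(int(np.ceil(3.21 * (m + 1) ** (1 / 3))), max(m - 2, 0))
    lrv = dy @ dy / m
    for l in range(1, trunc + 1):
        w = 1.0 - l / (trunc + 1.0)
        lrv += 2.0 * w * (dy[l:] @ dy[:-l]) / m
    lrv = max(lrv, 1e-12)  # kernel estimates can dip negative at tiny T
    return float(np.sqrt(lrv) / sigma_eps)


def _auto_lags(t_len: int) -> int:
    # no room for ADF lag augmentation in short panels
    return 0 if t_len < 15 else int(np.floor(t_len ** (1 / 3)))


def _llc_statistic(y: np.ndarray, lags: int, deterministic: str):
    """Pooled LLC regression pieces for an (N, T) array.

    Returns (delta, t_delta, bias_factor) where ``bias_factor`` multiplies
    mu_star in the t* adjustment: N * T_bar * S_N * sigma_eps^-2 * SE(delta).
    """
    n, t_len = y.shape
    e_all, v_all, ratios = [], [], []
    for i in range(n):
        e_t, v_t, sigma = adf_components(y[i], lags, deterministic)
        e_all.append(e_t)
        v_all.append(v_t)
        ratios.append(_long_run_sd_ratio(y[i], deterministic, sigma))
    e = np.concatenate(e_all)
    v = np.concatenate(v_all)
    t_bar = t_len - lags - 1
    delta = (v @ e) / (v @ v)
    resid = e - delta * v
    sigma_eps2 = (resid @ resid) / (n * t_bar)
    se = np.sqrt(sigma_eps2 / (v @ v))
    t_delta = delta / se
    s_n = float(np.mean(ratios))
    bias_factor = n * t_bar * s_n * se / sigma_eps2
    return float(delta), float(t_delta), float(bias_factor), t_bar


_MOMENT_CACHE: dict[tuple, tuple[float, float]] = {}


def simulate_moments(n: int, t_len: int, lags: int, deterministic: str,
                     n_rep: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo adjustment moments (mu*, sigma*) under the unit-root null.

    Simulates ``n_rep`` panels of N independent driftless Gaussian random
    walks of length T, computes (t_delta, bias_factor) for each, and solves
    for the (mu*, sigma*) that standardize t*:

        mu*    = mean(t_delta) / mean(bias_factor)
        sigma* = SD(t_delta - bias_factor * mu*)

    Deterministic for a fixed seed; results are cached per
    (N, T, lags, deterministic, n_rep, seed) within the process.
    """
    key = (n, t_len, lags, deterministic, n_rep, seed)
    if key in _MOMENT_CACHE:
        return _MOMENT_CACHE[key]
    rng = np.random.default_rng(seed)
    t_stats = np.empty(n_rep)
    factors = np.empty(n_rep)
    for r in range(n_rep):
        walks = np.cumsum(rng.standard_normal((n, t_len)), axis=1)
        _, t_stats[r], factors[r], _ = _llc_statistic(walks, lags, deterministic)
    mu = float(t_stats.mean() / factors.mean())
    sigma = float(np.std(t_stats - factors * mu, ddof=1))
    _MOMENT_CACHE[key] = (mu, sigma)
    return mu, sigma


def _tabulated_moments(deterministic: str, t_bar: int,
                       table: dict | None) -> tuple[float, float]:
    table = table if table is not None else DEFAULT_MOMENTS
    candidates = {t: ms for (det, t), ms in table.items() if det == deterministic}
    if not candidates:
        raise ValueError(
            f"no tabulated moments available for deterministic={deterministic!r}; "
            "supply moments_table= or use moments_mode='simulated'"
        )
    nearest = min(candidates, key=lambda t: abs(t - t_bar))
    return candidates[nearest]


def llc_test(panel: PanelDataset, variable: str,
             deterministic: str = "intercept",
             lags: int | str = "auto",
             alpha: float = 0.05,
             moments_mode: str = "simulated",
             seed: int = 0,
             n_moment_reps: int = 2000,
             moments_table: dict | None = None) -> UnitRootResult:
    """LLC panel unit-root test for one variable of a balanced panel.

    H0: every panel member's series has a unit root (common root delta=0 in
    the pooled ADF representation); H1: all members share a stationary
    root.  Left-tail standard-normal p-value on the moment-adjusted t*.

    Parameters
    ----------
    lags
        ADF augmentation lags per member; ``"auto"`` picks 0 for T < 15
        else floor(T^(1/3)).
    moments_mode
        ``"simulated"`` (default) — calibrate (mu*, sigma*) under the null
        with matched (N, effective T, lags, deterministic) using
        ``n_moment_reps`` replicates seeded by ``seed``; ``"tabulated"`` —
        look up the plug-in table (``moments_table`` or the built-in
        simulation-calibrated ``DEFAULT_MOMENTS``).
    """
    if moments_mode not in ("simulated", "tabulated"):
        raise ValueError(f"unknown moments_mode {moments_mode!r}")
    y = panel.series(variable)
    n, t_len = y.shape
    lag_order = _auto_lags(t_len) if lags == "auto" else int(lags)
    if t_len - lag_order - 1 < 3:
        raise ValueError(
            f"lags={lag_order} too large for T={t_len} (needs T - lags - 1 >= 3)"
        )
    try:
        delta, t_delta, bias_factor, t_bar = _llc_statistic(y, lag_order, deterministic)
    except ValueError as err:
        # attribute per-member failures to the offending subject
        for i in range(n):
            try:
                adf_components(y[i], lag_order, deterministic)
            except ValueError as inner:
                raise ValueError(
                    f"variable {variable!r}, subject {panel.subjects[i]!r}: {inner}"
                ) from err
        raise

    if moments_mode == "simulated":
        mu, sig = simulate_moments(n, t_len, lag_order, deterministic,
                                   n_rep=n_moment_reps, seed=seed)
    else:
        mu, sig = _tabulated_moments(deterministic, t_bar, moments_table)

    t_star = (t_delta - bias_factor * mu) / sig
    p = float(stats.norm.cdf(t_star))
    return UnitRootResult(
        variable=variable, deterministic_spec=deterministic,
        lags_per_panel=(lag_order,) * n,
        pooled_delta=delta, t_delta=t_delta, t_star=float(t_star),
        mu_star=mu, sigma_star=sig, p_value=p, alpha=alpha,
        reject_unit_root=p < alpha, moments_mode=moments_mode,
    )


def ensure_stationary(panel: PanelDataset,
                      variables: list[str] | None = None,
                      alpha: float = 0.05,
                      max_diff: int = 2,
                      on_failure: str = "flag",
                      **llc_options):
    """Difference each variable until the LLC test rejects its unit root.

    Runs :func:`llc_test` per variable; any variable whose unit root is not
    rejected is first-differenced (which truncates the whole panel by one
    time point to keep it balanced) and retested, up to ``max_diff``
    rounds.  Returns ``(panel, log)`` where ``log`` maps each variable to a
    dict with the differencing order applied, the final test result, and a
    ``stationary`` flag.

    ``on_failure="flag"`` (default) records still-nonstationary variables
    in the log and continues; ``"raise"`` aborts instead.
    """
    if on_failure not in ("flag", "raise"):
        raise ValueError(f"unknown on_failure {on_failure!r}")
    variables = list(variables) if variables is not None else list(panel.variables)
    orders = {v: 0 for v in variables}
    log: dict[str, dict] = {}
    current = panel
    for round_no in range(max_diff + 1):
        pending = []
        for v in variables:
            if v in log:
                continue
            res = llc_test(current, v, alpha=alpha, **llc_options)
            if res.reject_unit_root:
                log[v] = {"diff_order": orders[v], "stationary": True, "result": res}
            elif round_no == max_diff:
                msg = (f"variable {v!r} still nonstationary after "
                       f"{orders[v]} difference(s) (max_diff={max_diff})")
                if on_failure == "raise":
                    raise RuntimeError(msg)
                log[v] = {"diff_order": orders[v], "stationary": False,
                          "result": res, "warning": msg}
            else:
                pending.append(v)
        if not pending:
            break
        current = _difference_many(current, pending, order=1)
        for v in pending:
            orders[v] += 1
    return current, log
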