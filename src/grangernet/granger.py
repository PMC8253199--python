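"""Pairwise panel Granger non-causality tests with half-panel-jackknife
bias correction.

For an ordered variable pair (cause x, effect y) on a balanced panel of N
subjects and T time points, the test fits the homogeneous dynamic panel
regression

    y_it = alpha_i + rho_1 y_{i,t-1} + ... + rho_p y_{i,t-p}
                   + beta_1 x_{i,t-1} + ... + beta_p x_{i,t-p} + eps_it

by pooled OLS after the within transformation (subtracting subject means,
which absorbs the fixed effects alpha_i).  With small T the within
estimator of a dynamic panel carries the O(1/T) Nickell bias; the
half-panel jackknife (HPJ) removes its leading term by combining the
full-window estimate with estimates from the first and last halves of the
effective time range:

    theta_HPJ = 2 * theta_full - (theta_first_half + theta_second_half) / 2

Granger non-causality (H0: beta_1 = ... = beta_p = 0) is then tested by a
Wald statistic on the beta subvector of theta_HPJ, using either a
subject-clustered sandwich variance (chi-square p-value, df = p) or a
subject-resampling bootstrap null distribution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import PanelDataset

__all__ = [
    "GrangerPairResult",
    "within_demean",
    "pooled_within_ols",
    "hpj_estimate",
    "granger_test",
    "pairwise_matrix",
    "PairwiseError",
]


class SingularDesignError(ValueError):
    """Raised when the within-transformed regressor matrix is rank-deficient."""


@dataclass(frozen=True)
class GrangerPairResult:
    """One directed cause -> effect panel Granger test.

    ``theta_within`` and ``theta_hpj`` are laid out as the p own-lag
    coefficients rho_1..rho_p followed by the p cross-lag coefficients
    beta_1..beta_p; the Wald statistic tests the beta block.
    """

    cause: str
    effect: str
    lag_order: int
    theta_within: np.ndarray
    theta_hpj: np.ndarray
    wald: float
    df: int
    p_value: float
    n_effective: int
    variance_mode: str

    def __post_init__(self):
        if self.cause == self.effect:
            raise ValueError("cause and effect must differ")
        if self.wald < 0:
            raise ValueError("Wald statistic must be non-negative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.df != self.lag_order:
            raise ValueError("df must equal the lag order")

    @property
    def beta_hpj(self) -> np.ndarray:
        return self.theta_hpj[self.lag_order:]


def within_demean(groups: list[np.ndarray]) -> list[np.ndarray]:
    """Subtract each group's (subject's) mean; grouping preserved.

    The within transformation absorbs subject fixed effects before pooled
    estimation; each returned group has mean exactly zero to numerical
    precision.
    """
    out = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if arr.size == 0:
            raise ValueError("empty group in within_demean")
        out.append(arr - arr.mean(axis=0))
    return out


def _window_rows(t_len: int, p: int, time_window: tuple[int, int] | None):
    """Regressand time indices t (p <= t < T) selected by the window."""
    lo, hi = (p, t_len) if time_window is None else time_window
    if not (p <= lo < hi <= t_len):
        raise ValueError(f"invalid time window [{lo}, {hi}) for p={p}, T={t_len}")
    return np.arange(lo, hi)


def _design(y: np.ndarray, x: np.ndarray, p: int,
            time_window: tuple[int, int] | None):
    """Within-demeaned stacked regressand and design for the pooled fit.

    y, x : (N, T) arrays.  Columns: y lags 1..p then x lags 1..p, each
    demeaned within subject over the selected window rows.
    """
    n, t_len = y.shape
    rows = _window_rows(t_len, p, time_window)
    if rows.size < 2 * p + 1:
        raise ValueError(
            f"window of {rows.size} periods cannot identify {2 * p} lag "
            "coefficients plus fixed effects"
        )
    yd = y[:, rows]
    cols = [y[:, rows - l] for l in range(1, p + 1)]
    cols += [x[:, rows - l] for l in range(1, p + 1)]
    design = np.stack(cols, axis=2)                       # (N, W, 2p)
    yd = yd - yd.mean(axis=1, keepdims=True)
    design = design - design.mean(axis=1, keepdims=True)
    return yd, design


def pooled_within_ols(y: np.ndarray, x: np.ndarray, p: int = 1,
                      time_window: tuple[int, int] | None = None,
                      names: tuple[str, str] = ("effect", "cause")):
    """Pooled within-estimator for the bivariate dynamic panel regression.

    Parameters
    ----------
    y, x
        (N, T) effect and cause series per subject.
    p
        Lag order; the design has p own lags of y then p lags of x.
    time_window
        Optional (lo, hi) half-open range of regressand times t (defaults
        to the full effective range p..T-1); lags reach back before the
        window's start, and the within transformation demeans over the
        window only.

    Returns
    -------
    (theta, xtx, stacked)
        OLS solution (length 2p), the pooled cross-product matrix, and the
        per-subject demeaned (regressand, design) pair for variance work.

    Raises
    ------
    SingularDesignError
        If a regressor is constant after demeaning (naming the offending
        variable) or the pooled design is otherwise rank-deficient.
    """
    yd, design = _design(np.asarray(y, float), np.asarray(x, float), p, time_window)
    flat_x = design.reshape(-1, 2 * p)
    flat_y = yd.reshape(-1)
    col_ss = (flat_x ** 2).sum(axis=0)
    scale = max(float(flat_y @ flat_y), 1.0)
    dead = np.nonzero(col_ss <= 1e-14 * scale)[0]
    if dead.size:
        which = names[0] if dead[0] < p else names[1]
        raise SingularDesignError(
            f"regressor for variable {which!r} (lag {dead[0] % p + 1}) is "
            "constant within subjects; design is singular"
        )
    xtx = flat_x.T @ flat_x
    xty = flat_x.T @ flat_y
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularDesignError(
            f"pooled within design is numerically singular (cond={cond:.2e})"
        )
    theta = np.linalg.solve(xtx, xty)
    return theta, xtx, (yd, design)


def hpj_estimate(theta_full: np.ndarray, theta_first: np.ndarray,
                 theta_second: np.ndarray) -> np.ndarray:
    """Half-panel-jackknife combination 2*full - (first + second)/2.

    Removes the leading O(1/T) (Nickell) bias of the within estimator.
    """
    a = np.asarray(theta_full, float)
    b = np.asarray(theta_first, float)
    c = np.asarray(theta_second, float)
    if not (a.shape == b.shape == c.shape):
        raise ValueError(
            f"coefficient vectors must share a shape; got {a.shape}, {b.shape}, {c.shape}"
        )
    return 2.0 * a - 0.5 * (b + c)


def _influence(theta: np.ndarray, xtx: np.ndarray, yd: np.ndarray,
               design: np.ndarray) -> np.ndarray:
    """Per-subject influence B * X_i' A_i u_i with residuals at theta.

    A_i is the bias-reduced (CR2-style) residual adjustment, the
    Moore-Penrose inverse square root of M_i - X_i (X'X)^-1 X_i' with
    M_i = I - 11'/W the within-demeaning projector: without it the plain
    clustered sandwich understates the error variance badly at small T
    because each subject loses a mean plus a share of the slopes.
    """
    n, w, k2 = design.shape
    resid = yd - np.einsum("nwk,k->nw", design, theta)
    bread = np.linalg.inv(xtx)
    m_proj = np.eye(w) - np.full((w, w), 1.0 / w)
    scores = np.empty((n, k2))
    for i in range(n):
        s_mat = m_proj - design[i] @ bread @ design[i].T
        vals, vecs = np.linalg.eigh(s_mat)
        inv_sqrt = np.where(vals > 1e-10, 1.0 / np.sqrt(np.clip(vals, 1e-10, None)), 0.0)
        a_i = (vecs * inv_sqrt) @ vecs.T
        scores[i] = design[i].T @ (a_i @ resid[i])
    return scores @ bread.T


def _hpj_clustered_cov(fits: dict) -> np.ndarray:
    """Subject-clustered sandwich covariance of the HPJ combination.

    The HPJ estimator is the linear combination 2*full - (first+second)/2
    of three pooled OLS fits sharing subjects, so its per-subject influence
    is the same combination of the three fits' influences,
    psi_i = 2 B_f s_i^f - (B_a s_i^a + B_b s_i^b)/2.  Each window's
    residuals enter at that window's own OLS solution (the CR2 adjustment
    is derived for own-window residuals; evaluating elsewhere re-inflates
    the small-T bias).  Influences are centered across subjects and the
    small-sample factor N/(N-1) applied.
    """
    psi = (2.0 * _influence(*fits["full"])
           - 0.5 * (_influence(*fits["a"]) + _influence(*fits["b"])))
    psi = psi - psi.mean(axis=0)
    n = psi.shape[0]
    return psi.T @ psi * (n / (n - 1.0))


def _halves(t_len: int, p: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """First/last floor((T-p)/2) regressand periods; middle period dropped
    when T - p is odd, keeping the halves balanced and disjoint."""
    eff = t_len - p
    h = eff // 2
    return (p, p + h), (t_len - h, t_len)


def _fit_hpj(y: np.ndarray, x: np.ndarray, p: int):
    t_len = y.shape[1]
    win_a, win_b = _halves(t_len, p)
    theta_full, xtx_f, stacked_f = pooled_within_ols(y, x, p)
    theta_a, xtx_a, stacked_a = pooled_within_ols(y, x, p, time_window=win_a)
    theta_b, xtx_b, stacked_b = pooled_within_ols(y, x, p, time_window=win_b)
    theta_hpj = hpj_estimate(theta_full, theta_a, theta_b)
    fits = {"full": (theta_full, xtx_f, *stacked_f),
            "a": (theta_a, xtx_a, *stacked_a),
            "b": (theta_b, xtx_b, *stacked_b)}
    return theta_full, theta_hpj, fits


def _wald(theta_hpj: np.ndarray, cov: np.ndarray, p: int) -> float:
    beta = theta_hpj[p:]
    vbb = cov[p:, p:]
    w = float(beta @ np.linalg.solve(vbb, beta))
    return max(w, 0.0)


def granger_test(panel: PanelDataset, cause: str, effect: str,
                 p: int = 1, variance_mode: str = "clustered",
                 n_boot: int = 499, seed: int = 0) -> GrangerPairResult:
    """Panel Granger non-causality test for one ordered pair.

    H0: no lag of ``cause`` helps predict ``effect`` beyond the effect's
    own lags (beta_1 = ... = beta_p = 0).  Coefficients are the HPJ
    bias-corrected within estimates; inference is by Wald statistic with

    - ``variance_mode="clustered"`` (default): subject-clustered sandwich
      variance (small-sample factor N/(N-1)) evaluated at the HPJ point
      estimate; chi-square p-value with df = p.
    - ``variance_mode="bootstrap"``: subject-resampling bootstrap with
      ``n_boot`` seeded draws; each resample's Wald statistic is computed
      on the recentered coefficient (beta* - beta_hat), and the p-value is
      the null tail fraction (1 + #{W* >= W}) / (n_boot + 1).
    """
    if cause == effect:
        raise ValueError(f"cause and effect must differ (both {cause!r})")
    if variance_mode not in ("clustered", "bootstrap"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    y = panel.series(effect)
    x = panel.series(cause)
    t_len = y.shape[1]
    if t_len - p < 4 or (t_len - p) // 2 < 2 * p + 1:
        raise ValueError(
            f"T={t_len} too small for lag order p={p}: each jackknife half "
            f"needs at least {2 * p + 1} periods (T >= {7 * p + 2})"
        )
    try:
        theta_full, theta_hpj, fits = _fit_hpj(y, x, p)
    except SingularDesignError as err:
        raise SingularDesignError(
            f"pair {cause!r} -> {effect!r}: {err}"
        ) from err

    cov = _hpj_clustered_cov(fits)
    wald = _wald(theta_hpj, cov, p)

    if variance_mode == "clustered":
        p_value = float(stats.chi2.sf(wald, df=p))
    else:
        rng = np.random.default_rng(seed)
        n = y.shape[0]
        beta_hat = theta_hpj[p:]
        exceed = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                _, th_b, fits_b = _fit_hpj(y[idx], x[idx], p)
            except SingularDesignError:
                continue
            cov_b = _hpj_clustered_cov(fits_b)
            centered = th_b.copy()
            centered[p:] -= beta_hat
            if _wald(centered, cov_b, p) >= wald:
                exceed += 1
        p_value = (1.0 + exceed) / (n_boot + 1.0)

    n_eff = y.shape[0] * (t_len - p)
    return GrangerPairResult(
        cause=cause, effect=effect, lag_order=p,
        theta_within=theta_full, theta_hpj=theta_hpj,
        wald=wald, df=p, p_value=p_value,
        n_effective=n_eff, variance_mode=variance_mode,
    )


class PairwiseError(RuntimeError):
    """Aggregates per-pair test failures with their messages."""

    def __init__(self, failures: list[tuple[str, str, str]]):
        self.failures = failures
        lines = "; ".join(f"{c}->{e}: {msg}" for c, e, msg in failures)
        super().__init__(f"{len(failures)} pairwise test(s) failed: {lines}")


def pairwise_matrix(panel: PanelDataset, variables: list[str] | None = None,
                    p: int = 1, variance_mode: str = "clustered",
                    n_boot: int = 499, seed: int = 0,
                    on_error: str = "raise"):
    """All V(V-1) ordered-pair Granger tests, row-major in variable order.

    Per-pair errors are collected; with ``on_error="raise"`` (default) a
    single :class:`PairwiseError` listing every failing pair is raised
    after the sweep, with ``"collect"`` the function returns
    ``(results, failures)`` instead.

    With bootstrap variance each pair gets an independent seeded stream
    derived from ``seed`` and the pair's position, so permuting the
    variable list permutes but does not change the (cause, effect,
    p_value) triples.
    """
    if on_error not in ("raise", "collect"):
        raise ValueError(f"unknown on_error {on_error!r}")
    variables = list(variables) if variables is not None else list(panel.variables)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables for pairwise testing")
    results: list[GrangerPairResult] = []
    failures: list[tuple[str, str, str]] = []
    base = np.random.SeedSequence(seed)
    for cause in variables:
        for effect in variables:
            if cause == effect:
                continue
            pair_key = zlib.crc32(f"{cause}\x1f{effect}".encode())
            pair_seed = int(
                np.random.SeedSequence(
                    entropy=base.entropy, spawn_key=(pair_key,)
                ).generate_state(1)[0] & 0x7FFFFFFF
            )
            try:
                results.append(
                    granger_test(panel, cause, effect, p=p,
                                 variance_mode=variance_mode,
                                 n_boot=n_boot, seed=pair_seed)
                )
            except (ValueError, np.linalg.LinAlgError) as err:
                failures.append((cause, effect, str(err)))
    if failures and on_error == "raise":
        raise PairwiseError(failures)
    if on_error == "collect":
        return results, failures
    return results
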