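"""Naka-Rushton intensity-response fitting and the shuffle-null encoding test.

The intensity-response function is the Naka-Rushton saturating sigmoid of
log light intensity E (log photons cm^-2 s^-1):

    R(E) = Rmax * 10^(nE) / (10^(nE) + 10^(nK))

where Rmax is the predicted maximum response, n the slope and K the
semi-saturation (sensitivity).  A unit is intensity-encoding when the RMSE
of its fitted sigmoid is smaller (strictly) than the 5th percentile of a
null RMSE distribution obtained by refitting after shuffling the responses
along the intensity axis (100 shuffles give 0.01 probability resolution).

The module is organised statsmodels-style: ``IntensityResponseModel`` holds
the data, ``fit()`` returns an ``IntensityResponseResults`` carrying the
parameter estimates, their standard errors, the RMSE, and methods for the
encoding test, threshold intensity, dynamic range, ``summary()`` and
``plot()``.  Thin functional wrappers (``fit_naka_rushton``,
``classify_intensity_encoding`` ...) cover script use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares

from .stats import TestResult, paired_perm_ttest

__all__ = [
    "naka_rushton",
    "SigmoidFit",
    "EncodingTest",
    "IntensityResponseModel",
    "IntensityResponseResults",
    "fit_naka_rushton",
    "rmse",
    "classify_intensity_encoding",
    "threshold_intensity",
    "dynamic_range",
    "pooled_intensity_response",
    "ramp_phase_fit",
    "transition_lag",
    "pre_post_transition_compare",
]

LN10 = np.log(10.0)


def naka_rushton(E, Rmax: float, n: float, K: float):
    """Naka-Rushton response at log intensity E.

    Evaluated in the overflow-safe form Rmax / (1 + 10^(n (K - E))); equals
    Rmax/2 at E = K, tends to Rmax as E -> +inf and to 0 as E -> -inf, and
    is strictly increasing in E for n > 0.
    """
    if n <= 0:
        raise ValueError("slope n must be positive")
    E = np.asarray(E, dtype=float)
    out = Rmax / (1.0 + 10.0 ** (n * (K - E)))
    return out if out.ndim else float(out)


@dataclass
class SigmoidFit:
    """Fitted Naka-Rushton parameters for one unit (or pooled curve).

    ``direction`` is +1 for responses increasing with intensity and -1 for
    decreasing ones (such responses are negated before fitting, so Rmax, n,
    K always describe an increasing sigmoid).
    """

    Rmax: float
    n: float
    K: float
    direction: int = 1
    rmse: float = float("nan")
    converged: bool = True

    def predict(self, E):
        """Fitted (signed) response at log intensity E."""
        return self.direction * naka_rushton(E, self.Rmax, self.n, self.K)


@dataclass
class EncodingTest:
    """Shuffle-null RMSE test outcome."""

    rmse_real: float
    rmse_null: np.ndarray
    percentile5: float
    encoding_flag: bool
    unreliable: bool = False
    n_shuffles: int = 100
    seed: int | None = None


def _residuals_and_jac(params, E, y):
    Rmax, n, K = params
    s = 10.0 ** (n * (K - E))
    denom = 1.0 + s
    f = Rmax / denom
    resid = f - y
    g = Rmax * s / denom**2 * LN10
    jac = np.column_stack([1.0 / denom, -g * (K - E), -g * n])
    return resid, jac


def _ls_fit(E: np.ndarray, y: np.ndarray):
    """Bounded least squares of an increasing Naka-Rushton to (E, y)."""
    scale = max(float(np.max(np.abs(y))), 1e-6)
    x0 = np.array([scale, 1.0, float(np.median(E))])
    lb = np.array([0.0, 0.05, E.min() - 3.0])
    ub = np.array([10.0 * scale, 10.0, E.max() + 3.0])
    res = least_squares(
        lambda p: _residuals_and_jac(p, E, y)[0],
        x0,
        jac=lambda p: _residuals_and_jac(p, E, y)[1],
        bounds=(lb, ub),
        method="trf",
        x_scale=np.array([scale, 1.0, 1.0]),
    )
    return res


def fit_naka_rushton(intensities, responses) -> SigmoidFit:
    """Least-squares Naka-Rushton fit of mean responses vs log intensity.

    Requires at least four intensity points.  Response direction is
    detected by the sign of the Spearman correlation (ties count as
    increasing); decreasing responses are negated before fitting and
    reported with direction -1.  A failed optimisation yields
    converged=False and infinite RMSE so the unit is excluded downstream.
    """
    E = np.asarray(intensities, dtype=float)
    y = np.asarray(responses, dtype=float)
    if E.shape != y.shape or E.ndim != 1:
        raise ValueError("intensities and responses must be equal-length 1-D")
    if len(E) < 4:
        raise ValueError("need at least 4 intensity points")
    if np.ptp(y) == 0:
        rho = 0.0
    else:
        rho = sps.spearmanr(E, y).statistic
    direction = -1 if (np.isfinite(rho) and rho < 0) else 1
    y_fit = direction * y
    try:
        res = _ls_fit(E, y_fit)
        ok = res.success and np.all(np.isfinite(res.x))
    except Exception:
        res, ok = None, False
    if not ok:
        return SigmoidFit(Rmax=np.nan, n=np.nan, K=np.nan, direction=direction,
                          rmse=np.inf, converged=False)
    Rmax, n, K = res.x
    return SigmoidFit(
        Rmax=float(Rmax), n=float(n), K=float(K), direction=direction,
        rmse=float(np.sqrt(np.mean(res.fun**2))), converged=True,
    )


def _batch_rank(Y: np.ndarray) -> np.ndarray:
    """Row-wise ranks with midrank ties (vectorized Spearman support)."""
    order = np.argsort(Y, axis=1, kind="stable")
    ranks = np.empty_like(Y)
    rows = np.arange(Y.shape[0])[:, None]
    ranks[rows, order] = np.arange(Y.shape[1], dtype=float)
    # midrank correction, applied only to rows that actually contain ties
    sorted_rows = np.take_along_axis(Y, order, axis=1)
    tied = np.any(np.diff(sorted_rows, axis=1) == 0, axis=1)
    for i in np.flatnonzero(tied):
        vals, inv, cnt = np.unique(Y[i], return_inverse=True, return_counts=True)
        sums = np.zeros(len(vals))
        np.add.at(sums, inv, ranks[i])
        ranks[i] = sums[inv] / cnt[inv]
    return ranks


def _batch_directions(E: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Sign of the Spearman correlation per row (ties/zero -> +1)."""
    ranks = _batch_rank(Y)
    re = np.argsort(np.argsort(E)).astype(float)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    ec = re - re.mean()
    num = rc @ ec
    return np.where(num < 0, -1, 1).astype(int)


def _batch_fit_rmse(E: np.ndarray, Y: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """RMSE of bounded Naka-Rushton least squares, batched over rows of Y.

    A projected Levenberg-Marquardt sharing one iteration loop across all
    problems: per problem, a damped 3x3 Gauss-Newton step is taken, clipped
    to the parameter bounds, and accepted only when it lowers the cost.
    Deterministic; used by the encoding test so the real curve and every
    shuffle go through the identical fitting routine.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    d = _batch_directions(E, Y)
    Yf = Y * d[:, None]
    B, m = Yf.shape
    scale = np.maximum(np.max(np.abs(Yf), axis=1), 1e-6)
    theta = np.column_stack([scale, np.ones(B), np.full(B, np.median(E))])
    lb = np.column_stack([np.zeros(B), np.full(B, 0.05), np.full(B, E.min() - 3.0)])
    ub = np.column_stack([10.0 * scale, np.full(B, 10.0), np.full(B, E.max() + 3.0)])

    def cost_resid(th):
        s = 10.0 ** (th[:, 1:2] * (th[:, 2:3] - E[None, :]))
        denom = 1.0 + s
        f = th[:, 0:1] / denom
        r = f - Yf
        return (r * r).sum(axis=1), r, s, denom

    cost, resid, s, denom = cost_resid(theta)
    lam = np.full(B, 1e-3)
    for _ in range(n_iter):
        g = theta[:, 0:1] * s / denom**2 * LN10
        J = np.stack(
            [1.0 / denom, -g * (theta[:, 2:3] - E[None, :]), -g * theta[:, 1:2]], axis=2
        )
        JtJ = np.einsum("bij,bik->bjk", J, J)
        Jtr = np.einsum("bij,bi->bj", J, resid)
        diag = np.einsum("bjj->bj", JtJ).copy()
        diag = np.maximum(diag, 1e-12)
        A = JtJ + lam[:, None, None] * diag[:, :, None] * np.eye(3)
        try:
            delta = -np.linalg.solve(A, Jtr[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            delta = -np.linalg.solve(A + 1e-8 * np.eye(3), Jtr[:, :, None])[:, :, 0]
        trial = np.clip(theta + delta, lb, ub)
        new_cost, new_resid, new_s, new_denom = cost_resid(trial)
        accept = new_cost < cost
        theta = np.where(accept[:, None], trial, theta)
        cost = np.where(accept, new_cost, cost)
        resid = np.where(accept[:, None], new_resid, resid)
        s = np.where(accept[:, None], new_s, s)
        denom = np.where(accept[:, None], new_denom, denom)
        lam = np.where(accept, lam / 3.0, lam * 2.0)
        lam = np.clip(lam, 1e-10, 1e8)
    return np.sqrt(cost / m)


def rmse(fit: SigmoidFit, intensities, responses) -> float:
    """Root mean square error of a fit against (possibly reordered) data."""
    E = np.asarray(intensities, dtype=float)
    y = np.asarray(responses, dtype=float)
    return float(np.sqrt(np.mean((fit.predict(E) - y) ** 2)))


def classify_intensity_encoding(
    intensities,
    responses,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> tuple[SigmoidFit, EncodingTest]:
    """Fit the sigmoid and run the shuffle-null RMSE encoding test.

    The null is built by randomly permuting the responses along the
    intensity axis ``n_shuffles`` times (permutations drawn uniformly with
    replacement; the identity is allowed) and refitting each shuffle.  The
    unit is flagged intensity-encoding when the real RMSE is strictly below
    the 5th percentile of the null RMSEs.  The test is marked unreliable
    when more than 20% of null fits fail to converge.
    """
    E = np.asarray(intensities, dtype=float)
    y = np.asarray(responses, dtype=float)
    fit = fit_naka_rushton(E, y)
    rng = np.random.default_rng(seed)
    shuffles = np.array([rng.permutation(y) for _ in range(n_shuffles)])
    # one shared fitting routine for the real curve and every shuffle keeps
    # the comparison exchangeable under the null
    rmses = _batch_fit_rmse(E, np.vstack([y[None, :], shuffles]))
    rmse_real = float(rmses[0])
    null = rmses[1:]
    n_fail = int(np.sum(~np.isfinite(null)))
    p5 = float(np.percentile(null, 5, method="lower"))
    flag = bool(fit.converged and rmse_real < p5)
    test = EncodingTest(
        rmse_real=rmse_real, rmse_null=null, percentile5=p5,
        encoding_flag=flag, unreliable=n_fail > 0.2 * n_shuffles,
        n_shuffles=n_shuffles, seed=seed,
    )
    return fit, test


def classify_intensity_encoding_batch(
    intensities,
    responses: np.ndarray,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Encoding flags for many units at once (shared batched fitter).

    ``responses`` is units x intensities.  Statistically identical to
    calling :func:`classify_intensity_encoding` per unit — same shuffle
    null, same strict 5th-percentile rule — but all units' real and
    shuffled curves are fitted in a single batched least-squares pass,
    which is what makes population-scale calibration runs cheap.
    """
    E = np.asarray(intensities, dtype=float)
    Y = np.atleast_2d(np.asarray(responses, dtype=float))
    n_units, n_int = Y.shape
    rng = np.random.default_rng(seed)
    stacked = np.empty((n_units * (1 + n_shuffles), n_int))
    for u in range(n_units):
        base = u * (1 + n_shuffles)
        stacked[base] = Y[u]
        for s in range(n_shuffles):
            stacked[base + 1 + s] = Y[u, rng.permutation(n_int)]
    rmses = _batch_fit_rmse(E, stacked).reshape(n_units, 1 + n_shuffles)
    real = rmses[:, 0]
    p5 = np.percentile(rmses[:, 1:], 5, axis=1, method="lower")
    return real < p5


def threshold_intensity(fit: SigmoidFit, criterion: float = 0.1) -> float:
    """Intensity at which the fitted response reaches ``criterion`` spikes/s.

    Exact inverse of the Naka-Rushton function:
    E* = K + (1/n) log10(criterion / (Rmax - criterion)).
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if criterion >= fit.Rmax:
        raise ValueError("criterion must be below the fitted Rmax")
    return float(fit.K + np.log10(criterion / (fit.Rmax - criterion)) / fit.n)


def dynamic_range(fit: SigmoidFit) -> tuple[float, float]:
    """Dynamic range [E10, E90] of the fitted sigmoid.

    The cumulative integral of dR/dE is proportional to R itself, so the
    10% and 90% mass quantiles of the derivative are where R crosses
    0.1*Rmax and 0.9*Rmax; the interval has closed form
    K -/+ log10(9)/n and width (2/n) log10(9).
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    half = np.log10(9.0) / fit.n
    return (float(fit.K - half), float(fit.K + half))


# ---------------------------------------------------------------------------
# Model / Results


class IntensityResponseModel:
    """Intensity-response model for one unit (or a pooled population curve).

    Parameters
    ----------
    intensities
        Log light intensities (log photons cm^-2 s^-1), >= 4 values.
    responses
        Mean steady-state (or early-window) firing rate at each intensity,
        baseline-subtracted by default.
    baseline_subtracted
        Bookkeeping flag recording which response mode the data are in.
    """

    def __init__(self, intensities, responses, baseline_subtracted: bool = True):
        self.intensities = np.asarray(intensities, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if self.intensities.shape != self.responses.shape:
            raise ValueError("intensities and responses must align")
        if len(self.intensities) < 4:
            raise ValueError("need at least 4 intensity points")
        self.baseline_subtracted = baseline_subtracted

    @classmethod
    def from_window_rates(cls, rates_by_intensity, baseline_subtract: bool = True,
                          window: str = "steady"):
        """Build from per-intensity WindowRates (mean over reps).

        ``window`` selects FR2 ("steady") or FR1 ("early"); with
        ``baseline_subtract`` the per-rep baseline FR0 is removed first.
        """
        E, y = [], []
        for e_log in sorted(rates_by_intensity):
            wr = rates_by_intensity[e_log]
            resp = wr.fr2 if window == "steady" else wr.fr1
            vals = resp - wr.fr0 if baseline_subtract else resp
            E.append(e_log)
            y.append(float(np.mean(vals)))
        return cls(E, y, baseline_subtracted=baseline_subtract)

    def fit(self) -> "IntensityResponseResults":
        sig = fit_naka_rushton(self.intensities, self.responses)
        return IntensityResponseResults(self, sig)


@dataclass
class IntensityResponseResults:
    """Results of a Naka-Rushton fit, statsmodels-style."""

    model: IntensityResponseModel
    sigmoid: SigmoidFit
    _encoding: EncodingTest | None = field(default=None, repr=False)

    @property
    def params(self) -> dict[str, float]:
        return {"Rmax": self.sigmoid.Rmax, "n": self.sigmoid.n, "K": self.sigmoid.K}

    @property
    def direction(self) -> int:
        return self.sigmoid.direction

    @property
    def rmse(self) -> float:
        return self.sigmoid.rmse

    @property
    def converged(self) -> bool:
        return self.sigmoid.converged

    def bse(self) -> dict[str, float]:
        """Approximate standard errors from the Gauss-Newton covariance."""
        E = self.model.intensities
        y = self.direction * self.model.responses
        resid, jac = _residuals_and_jac(
            np.array([self.sigmoid.Rmax, self.sigmoid.n, self.sigmoid.K]), E, y
        )
        dof = max(len(E) - 3, 1)
        sigma2 = float(resid @ resid) / dof
        try:
            cov = sigma2 * np.linalg.inv(jac.T @ jac)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        return dict(zip(("Rmax", "n", "K"), map(float, se)))

    def predict(self, E):
        return self.sigmoid.predict(E)

    def encoding_test(self, n_shuffles: int = 100, seed: int | None = None) -> EncodingTest:
        """Run (and cache) the shuffle-null RMSE encoding test."""
        if self._encoding is None:
            _, self._encoding = classify_intensity_encoding(
                self.model.intensities, self.model.responses,
                n_shuffles=n_shuffles, seed=seed,
            )
        return self._encoding

    def threshold_intensity(self, criterion: float = 0.1) -> float:
        return threshold_intensity(self.sigmoid, criterion)

    def dynamic_range(self) -> tuple[float, float]:
        return dynamic_range(self.sigmoid)

    def summary(self) -> str:
        se = self.bse()
        lines = [
            "Naka-Rushton intensity-response fit",
            "=" * 47,
            f"{'n points':<22}{len(self.model.intensities):>25d}",
            f"{'direction':<22}{'enhanced (+1)' if self.direction == 1 else 'suppressed (-1)':>25}",
            f"{'converged':<22}{str(self.converged):>25}",
            f"{'RMSE (spikes/s)':<22}{self.rmse:>25.4f}",
            "-" * 47,
            f"{'param':<10}{'estimate':>18}{'std err':>18}",
        ]
        for k, v in self.params.items():
            lines.append(f"{k:<10}{v:>18.4f}{se[k]:>18.4f}")
        if self.converged and 0.1 < self.sigmoid.Rmax:
            lines.append("-" * 47)
            lines.append(f"{'threshold @0.1 Hz':<22}{self.threshold_intensity(0.1):>25.3f}")
            lo, hi = self.dynamic_range()
            lines.append(f"{'dynamic range':<22}{f'[{lo:.3f}, {hi:.3f}]':>25}")
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Data points and fitted curve vs log intensity."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        E = self.model.intensities
        ax.plot(E, self.model.responses, "o", label="data")
        grid = np.linspace(E.min() - 0.5, E.max() + 0.5, n_grid)
        ax.plot(grid, self.predict(grid), "-", label="Naka-Rushton fit")
        ax.set_xlabel("log intensity (log photons cm$^{-2}$ s$^{-1}$)")
        ax.set_ylabel("response (spikes/s)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# population pooling and ramp analysis


def pooled_intensity_response(unit_responses, directions=None):
    """Population mean +/- SEM response per intensity, sign-rectified.

    ``unit_responses`` is units x intensities (baseline-subtracted).  Units
    whose response decreases with intensity are negated before averaging so
    that enhanced and suppressed populations reinforce rather than cancel.
    Directions default to the sign of each unit's Spearman correlation with
    the column index (ties count as enhanced).
    """
    resp = np.atleast_2d(np.asarray(unit_responses, dtype=float))
    n_units, n_int = resp.shape
    if directions is None:
        idx = np.arange(n_int)
        directions = np.ones(n_units, dtype=int)
        for i in range(n_units):
            if np.ptp(resp[i]) == 0:
                continue
            rho = sps.spearmanr(idx, resp[i]).statistic
            if np.isfinite(rho) and rho < 0:
                directions[i] = -1
    else:
        directions = np.asarray(directions, dtype=int)
    rect = resp * directions[:, None]
    mean = rect.mean(axis=0)
    sem = rect.std(axis=0, ddof=1) / np.sqrt(n_units) if n_units > 1 else np.zeros(n_int)
    return mean, sem


def ramp_phase_fit(
    ramp_rates: np.ndarray,
    protocol,
    phase: str = "ascending",
    bin_s: float = 1.0,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> tuple[SigmoidFit, EncodingTest]:
    """Sigmoid fit + encoding test of FR vs instantaneous intensity in one phase.

    ``ramp_rates`` is reps x bins over the full bi-phasic epoch at ``bin_s``
    resolution; the mean trace is split at the phase transition and the
    chosen phase's rates are fitted against the log intensity at each bin
    centre.
    """
    if protocol.ramp is None:
        raise ValueError("protocol is not a ramp protocol")
    if phase not in ("ascending", "descending"):
        raise ValueError("phase must be 'ascending' or 'descending'")
    mean_trace = np.atleast_2d(np.asarray(ramp_rates, dtype=float)).mean(axis=0)
    phase_s = protocol.ramp["phase_s"]
    n_phase = int(round(phase_s / bin_s))
    centers = (np.arange(len(mean_trace)) + 0.5) * bin_s
    if phase == "ascending":
        sel = slice(0, n_phase)
    else:
        sel = slice(n_phase, 2 * n_phase)
    E = np.asarray(protocol.ramp_intensity(centers[sel]), dtype=float)
    y = mean_trace[sel]
    order = np.argsort(E)
    return classify_intensity_encoding(E[order], y[order], n_shuffles=n_shuffles, seed=seed)


def transition_lag(
    mean_trace: np.ndarray,
    direction: int = 1,
    bin_s: float = 1.0,
    phase_s: float = 30.0,
) -> tuple[float, bool]:
    """Lag (s) between the intensity peak and the FR extremum of a ramp trace.

    The extremum is the maximum of the mean trace for enhanced units and the
    minimum for suppressed ones; the lag is the extremum's bin start time
    minus the phase-transition time.  Returns (lag, censored); censored is
    True when the extremum sits on the first or last bin, where the true
    extremum may lie outside the trace.
    """
    trace = np.asarray(mean_trace, dtype=float) * direction
    i = int(np.argmax(trace))
    censored = i in (0, len(trace) - 1)
    lag = i * bin_s - phase_s
    return float(lag), censored


def pre_post_transition_compare(
    ramp_traces: np.ndarray,
    bin_s: float = 1.0,
    phase_s: float = 30.0,
    window_s: float = 7.0,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Paired test of per-unit FR before vs after the ramp's intensity peak.

    For each unit, mean FR over [phase_s - window_s, phase_s) is compared to
    [phase_s, phase_s + window_s) with a paired permutation t-test across
    units.  With light-history (hysteresis) effects, the post-transition
    window sees higher intensity-equivalent drive and FR is higher.
    """
    traces = np.atleast_2d(np.asarray(ramp_traces, dtype=float))
    i_t = int(round(phase_s / bin_s))
    w = int(round(window_s / bin_s))
    pre = traces[:, i_t - w:i_t].mean(axis=1)
    post = traces[:, i_t:i_t + w].mean(axis=1)
    return paired_perm_ttest(post, pre, n_perm=n_perm, seed=seed)
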