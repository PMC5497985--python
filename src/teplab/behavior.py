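"""Scoring of the four behavioral tasks.

* Stop-signal: SSRT by the mean method (mean correct-go RT minus mean SSD),
  appropriate for staircase-tracked designs that converge to 50 % stop
  success. An integration-method estimator is available behind a flag.
* Delay discounting: hyperbolic subjective value V = A / (1 + kD) with a
  logistic-choice likelihood; k is searched on a log-spaced grid and
  polished by bounded local optimization, jointly with the decision-noise
  slope beta.
* Speeded arithmetic: accuracy over all presented trials (late or omitted
  responses count as errors by default; a timely-only denominator is
  available); subjects with fewer than 3 accurate-and-timely trials are
  flagged for discard.
* Recognition memory: proportion correct among four alternatives (chance
  0.25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import EstimatorError

# ---------------------------------------------------------------------------
# Stop-signal task


@dataclass
class SSTResult:
    ssrt: float  # ms
    mean_go_rt: float  # ms, correct go trials
    mean_ssd: float  # ms
    go_error_rate: float  # wrong-cue or omitted among go trials
    stop_success_rate: float
    n_go: int = 0
    n_stop: int = 0


def estimate_ssrt(log: pd.DataFrame, method: str = "mean") -> SSTResult:
    """Stop-signal RT from a trial log.

    ``log`` columns: trial_type ('go'|'stop'), responded (bool), rt (ms,
    NaN when no response), correct_cue (bool), ssd (ms, stop trials only).

    ``method='mean'``: SSRT = mean correct-go RT - mean SSD.
    ``method='integration'``: SSRT = nth-percentile go RT - mean SSD with
    n = observed stop-failure rate.
    """
    go = log[log["trial_type"] == "go"]
    stop = log[log["trial_type"] == "stop"]
    if len(stop) == 0:
        raise EstimatorError("no stop trials; SSRT undefined")
    correct_go = go[go["responded"] & go["correct_cue"]]
    if len(correct_go) == 0:
        raise EstimatorError("no responded go trials; SSRT undefined")
    mean_go_rt = float(correct_go["rt"].mean())
    mean_ssd = float(stop["ssd"].mean())
    stop_success = float((~stop["responded"]).mean())
    if method == "mean":
        ssrt = mean_go_rt - mean_ssd
    elif method == "integration":
        p_respond = 1.0 - stop_success
        rts = np.sort(go.loc[go["responded"], "rt"].to_numpy(float))
        ssrt = float(np.quantile(rts, np.clip(p_respond, 0.0, 1.0))) - mean_ssd
    else:
        raise EstimatorError(f"unknown SSRT method {method!r}")
    n_go = len(go)
    go_errors = int((~(go["responded"] & go["correct_cue"])).sum())
    return SSTResult(
        ssrt=ssrt,
        mean_go_rt=mean_go_rt,
        mean_ssd=mean_ssd,
        go_error_rate=go_errors / n_go if n_go else float("nan"),
        stop_success_rate=stop_success,
        n_go=n_go,
        n_stop=len(stop),
    )


# ---------------------------------------------------------------------------
# Delay discounting


def discounted_value(amount, delay, k):
    """Hyperbolic subjective value V = amount / (1 + k * delay).

    ``amount`` > 0 (currency), ``delay`` >= 0 (days), ``k`` >= 0 (1/day).
    Accepts scalars or arrays.
    """
    amount = np.asarray(amount, dtype=float)
    delay = np.asarray(delay, dtype=float)
    if np.any(amount <= 0):
        raise EstimatorError("amounts must be > 0")
    if np.any(delay < 0):
        raise EstimatorError("delays must be >= 0")
    if np.any(np.asarray(k) < 0):
        raise EstimatorError("k must be >= 0")
    v = amount / (1.0 + k * delay)
    return float(v) if v.ndim == 0 else v


@dataclass
class DiscountingFit:
    k: float  # 1/day
    beta: float  # decision-noise slope, 1/currency
    log_likelihood: float  # nats, <= 0
    converged: bool


def _choice_nll(log_params, imm, delayed, delay, chose_delayed):
    k = np.exp(log_params[0])
    beta = np.exp(log_params[1])
    dv = delayed / (1.0 + k * delay) - imm
    z = beta * dv
    # log sigma(z) = -log(1 + e^-z), computed stably
    ll = np.where(chose_delayed, -np.logaddexp(0.0, -z), -np.logaddexp(0.0, z))
    return -ll.sum()


def fit_hyperbolic_k(
    log: pd.DataFrame,
    bounds: tuple[float, float] = (1e-5, 1.0),
    grid_size: int = 41,
    beta_bounds: tuple[float, float] = (1e-4, 1e3),
) -> DiscountingFit:
    """Maximum-likelihood hyperbolic discounting fit.

    ``log`` columns: immediate_amount, delayed_amount, delay, chose_delayed.
    P(delayed) = logistic(beta * (V_delayed - V_immediate)). A log-spaced
    grid over k (joint with a coarse beta grid) seeds a bounded L-BFGS-B
    polish in log space. A fit pinned to a k bound is flagged not-converged
    (one-sided choice sets carry no interior optimum).
    """
    if len(log) == 0:
        raise EstimatorError("empty choice log")
    imm = log["immediate_amount"].to_numpy(float)
    delayed = log["delayed_amount"].to_numpy(float)
    delay = log["delay"].to_numpy(float)
    chose = log["chose_delayed"].to_numpy(bool)
    if np.any(imm <= 0) or np.any(delayed <= 0) or np.any(delay < 0):
        raise EstimatorError("amounts must be > 0 and delays >= 0")

    k_grid = np.geomspace(bounds[0], bounds[1], grid_size)
    beta_grid = np.geomspace(max(beta_bounds[0], 1e-3), min(beta_bounds[1], 50.0), 13)
    best = (np.inf, k_grid[0], beta_grid[0])
    for k in k_grid:
        for b in beta_grid:
            nll = _choice_nll(np.log([k, b]), imm, delayed, delay, chose)
            if nll < best[0]:
                best = (nll, k, b)

    res = optimize.minimize(
        _choice_nll,
        x0=np.log([best[1], best[2]]),
        args=(imm, delayed, delay, chose),
        method="L-BFGS-B",
        bounds=[tuple(np.log(bounds)), tuple(np.log(beta_bounds))],
    )
    log_k, log_beta = res.x
    k_hat = float(np.exp(log_k))
    beta_hat = float(np.exp(log_beta))
    pinned = (
        k_hat <= bounds[0] * (1 + 1e-6)
        or k_hat >= bounds[1] * (1 - 1e-6)
        or chose.all()
        or (~chose).all()
    )
    return DiscountingFit(
        k=k_hat,
        beta=beta_hat,
        log_likelihood=float(-res.fun),
        converged=bool(res.success) and not pinned,
    )


# ---------------------------------------------------------------------------
# Speeded arithmetic


@dataclass
class ArithmeticResult:
    accuracy: float
    mean_rt: float  # ms, timely responses
    n_valid: int  # timely responses
    discarded: bool  # fewer than min_valid accurate-and-timely trials


def score_arithmetic(
    log: pd.DataFrame,
    deadline_ms: float = 2000.0,
    min_valid: int = 3,
    denominator: str = "all",
) -> ArithmeticResult:
    """Score the speeded greater/smaller-than-4 task.

    ``log`` columns: correct_side, response_side (NaN = omission), rt (ms).
    A trial is timely when a response arrives within ``deadline_ms``;
    ``denominator='all'`` counts late/omitted trials as errors,
    ``denominator='timely'`` scores among timely trials only.
    """
    if len(log) == 0:
        raise EstimatorError("empty arithmetic log")
    responded = log["response_side"].notna().to_numpy()
    rt = log["rt"].to_numpy(float)
    timely = responded & (rt <= deadline_ms)
    correct = timely & (log["response_side"] == log["correct_side"]).to_numpy()
    n_correct_timely = int(correct.sum())
    if denominator == "all":
        accuracy = n_correct_timely / len(log)
    elif denominator == "timely":
        accuracy = n_correct_timely / timely.sum() if timely.any() else 0.0
    else:
        raise EstimatorError(f"unknown denominator convention {denominator!r}")
    return ArithmeticResult(
        accuracy=float(accuracy),
        mean_rt=float(rt[timely].mean()) if timely.any() else float("nan"),
        n_valid=int(timely.sum()),
        discarded=n_correct_timely < min_valid,
    )


# ---------------------------------------------------------------------------
# Recognition memory


@dataclass
class MemoryResult:
    accuracy: float  # chance level 0.25 (four alternatives)
    mean_rt: float
    n_valid: int


def score_memory(log: pd.DataFrame) -> MemoryResult:
    """Proportion of trials where the chosen alternative is the correct one."""
    if len(log) == 0:
        raise EstimatorError("empty memory log")
    correct = (log["chosen_alternative"] == log["correct_alternative"]).to_numpy()
    rt = log["rt"].to_numpy(float) if "rt" in log.columns else np.full(len(log), np.nan)
    return MemoryResult(
        accuracy=float(correct.mean()),
        mean_rt=float(np.nanmean(rt)) if np.isfinite(rt).any() else float("nan"),
        n_valid=len(log),
    )
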