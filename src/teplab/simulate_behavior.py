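"""Synthetic behavioral trial logs with known ground truth.

Stop-signal trials follow the independent race model: on a stop trial the
response escapes iff the sampled go RT is below SSD + ssrt_true; the SSD is
staircase-tracked (success -> +step, failure -> -step, floored at 0), which
drives stop success toward 50 %. Stop trials are deterministically
interleaved (exactly one per block of round(1/stop_fraction) trials, at a
seeded position within each block) so the nominal stop fraction is exact.

Discounting choices are logistic in the hyperbolic value difference; the
default item set is the 27-item monetary-choice grid (immediate amounts
11-80, delayed 25-85, delays 7-186 days). Arithmetic and memory trials are
Bernoulli with per-subject success probabilities and plausible RTs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import discounted_value
from .errors import EstimatorError, SpecError
from .truth import SubjectTruth

#: 27-item monetary-choice questionnaire: (immediate, delayed, delay_days).
KIRBY_ITEMS: tuple[tuple[float, float, int], ...] = (
    (54, 55, 117), (55, 75, 61), (19, 25, 53), (31, 85, 7), (14, 25, 19),
    (47, 50, 160), (15, 35, 13), (25, 60, 14), (78, 80, 162), (40, 55, 62),
    (11, 30, 7), (67, 75, 119), (34, 35, 186), (27, 50, 21), (69, 85, 91),
    (49, 60, 89), (80, 85, 157), (24, 35, 29), (33, 80, 14), (28, 30, 179),
    (34, 50, 30), (25, 30, 80), (41, 75, 20), (54, 60, 111), (54, 80, 30),
    (22, 25, 136), (20, 55, 7),
)


def default_choice_set(repeats: int = 1) -> list[tuple[float, float, float]]:
    """The 27-item grid repeated ``repeats`` times."""
    return [item for _ in range(repeats) for item in KIRBY_ITEMS]


def simulate_stop_signal(
    truth: SubjectTruth,
    n_trials: int = 400,
    stop_fraction: float = 0.25,
    ssd_initial: float = 250.0,
    ssd_step: float = 50.0,
    seed: int = 0,
    p_go_error: float = 0.02,
) -> pd.DataFrame:
    """Race-model stop-signal log with staircase SSD tracking.

    Columns: trial_index, trial_type, cue, ssd, responded, rt, correct_cue.
    """
    if not 0.0 < stop_fraction < 1.0:
        raise SpecError("stop_fraction must be in (0, 1)")
    if ssd_step <= 0:
        raise SpecError("ssd_step must be > 0")
    rng = np.random.default_rng(seed)
    block = int(round(1.0 / stop_fraction))
    is_stop = np.zeros(n_trials, dtype=bool)
    for start in range(0, n_trials - block + 1, block):
        is_stop[start + rng.integers(block)] = True

    ssd = float(ssd_initial)
    rows = []
    for i in range(n_trials):
        cue = "x" if rng.random() < 0.5 else "o"
        go_rt = max(50.0, rng.normal(truth.go_rt_mean, truth.go_rt_sd))
        if is_stop[i]:
            responded = go_rt < ssd + truth.ssrt_true
            rows.append(
                dict(
                    trial_index=i,
                    trial_type="stop",
                    cue=cue,
                    ssd=ssd,
                    responded=responded,
                    rt=go_rt if responded else np.nan,
                    correct_cue=bool(responded and rng.random() >= p_go_error),
                )
            )
            ssd = ssd + ssd_step if not responded else max(0.0, ssd - ssd_step)
        else:
            rows.append(
                dict(
                    trial_index=i,
                    trial_type="go",
                    cue=cue,
                    ssd=np.nan,
                    responded=True,
                    rt=go_rt,
                    correct_cue=bool(rng.random() >= p_go_error),
                )
            )
    return pd.DataFrame(rows)


def simulate_discounting(
    truth: SubjectTruth,
    choice_set: list[tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic-choice hyperbolic discounting log.

    Columns: immediate_amount, delayed_amount, delay, chose_delayed.
    P(delayed) = logistic(choice_beta * (V_delayed - V_immediate)).
    """
    if choice_set is None:
        choice_set = default_choice_set()
    if len(choice_set) == 0:
        raise EstimatorError("empty choice set")
    rng = np.random.default_rng(seed)
    imm = np.array([c[0] for c in choice_set], dtype=float)
    delayed = np.array([c[1] for c in choice_set], dtype=float)
    delay = np.array([c[2] for c in choice_set], dtype=float)
    v_delayed = discounted_value(delayed, delay, truth.k_true)
    v_imm = imm  # immediate reward: delay 0
    from scipy.special import expit

    p_delayed = expit(truth.choice_beta * (v_delayed - v_imm))
    chose = rng.random(len(choice_set)) < p_delayed
    return pd.DataFrame(
        dict(
            immediate_amount=imm,
            delayed_amount=delayed,
            delay=delay,
            chose_delayed=chose,
        )
    )


def simulate_arithmetic(
    truth: SubjectTruth,
    n_trials: int = 40,
    seed: int = 0,
    rt_mean: float = 900.0,
    rt_sd: float = 300.0,
    p_omit: float = 0.02,
) -> pd.DataFrame:
    """Speeded greater/smaller-than-4 task log.

    Columns: trial_index, problem_result, correct_side, response_side, rt.
    RTs can exceed the 2000 ms deadline (then scored as late); omissions
    leave response_side empty.
    """
    rng = np.random.default_rng(seed)
    results = rng.choice([1, 2, 3, 5, 6, 7, 8], size=n_trials)
    correct_side = np.where(results > 4, "right", "left")
    rows = []
    for i in range(n_trials):
        if rng.random() < p_omit:
            rows.append(
                dict(
                    trial_index=i,
                    problem_result=int(results[i]),
                    correct_side=correct_side[i],
                    response_side=np.nan,
                    rt=np.nan,
                )
            )
            continue
        correct = rng.random() < truth.p_arith
        side = correct_side[i] if correct else ("left" if correct_side[i] == "right" else "right")
        rt = max(200.0, rng.normal(rt_mean, rt_sd))
        rows.append(
            dict(
                trial_index=i,
                problem_result=int(results[i]),
                correct_side=correct_side[i],
                response_side=side,
                rt=rt,
            )
        )
    return pd.DataFrame(rows)


def simulate_memory(
    truth: SubjectTruth,
    n_trials: int = 20,
    seed: int = 0,
    rt_mean: float = 1500.0,
    rt_sd: float = 400.0,
) -> pd.DataFrame:
    """Four-alternative recognition log.

    Columns: trial_index, correct_alternative, chosen_alternative, rt.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_trials):
        correct = int(rng.integers(1, 5))
        if rng.random() < truth.p_mem:
            chosen = correct
        else:
            chosen = int(rng.choice([a for a in range(1, 5) if a != correct]))
        rows.append(
            dict(
                trial_index=i,
                correct_alternative=correct,
                chosen_alternative=chosen,
                rt=max(300.0, rng.normal(rt_mean, rt_sd)),
            )
        )
    return pd.DataFrame(rows)
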