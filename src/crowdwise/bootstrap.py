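"""Question-level bootstrap error bars.

The sampling unit of uncertainty in a fixed-panel estimation experiment
is the question: subjects are the same across questions, but the set of
quantities asked is one draw from a notional population of questions.
Error bars therefore come from resampling whole questions with
replacement.  Each of ``n_exp`` effective experiments redraws N_Q of the
N_Q question ids, recomputes the statistic, and the upper (lower) bar is
the smallest half-width containing a fraction C of the resampled values
above (below) the full-data value — asymmetric by construction, suited
to skewed statistics.  C defaults to 0.683, by analogy with one
Gaussian standard error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapCI:
    """A statistic with asymmetric question-resampling error bars."""

    x0: float
    b_minus: float
    b_plus: float
    n_exp: int
    confidence: float

    @property
    def interval(self) -> tuple[float, float]:
        return (self.x0 - self.b_minus, self.x0 + self.b_plus)


def _one_sided_bar(devs: np.ndarray, confidence: float) -> float:
    """Nearest-rank C-quantile of a one-sided deviation set."""
    if devs.size == 0:
        return 0.0
    devs = np.sort(devs)
    k = int(np.ceil(confidence * devs.size))
    return float(devs[max(k, 1) - 1])


def bootstrap_ci(
    records: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    n_exp: int = 1000,
    confidence: float = 0.683,
    seed: int = 0,
    question_col: str = "question_id",
    max_retries: int = 10,
) -> BootstrapCI:
    """Bootstrap a scalar statistic of the records over questions.

    ``statistic`` maps a record table to a float and is evaluated on the
    full data (giving x0) and on ``n_exp`` resamples in which the N_Q
    distinct questions are redrawn with replacement (a drawn question
    contributes all its records, possibly several times).  A resample on
    which the statistic is undefined (NaN) is redrawn up to
    ``max_retries`` times; the redraw rate is logged.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    qids = records[question_col].unique()
    if len(qids) < 2:
        raise ValueError("need at least 2 distinct questions to bootstrap")
    x0 = float(statistic(records))
    if np.isnan(x0):
        raise ValueError("statistic is undefined on the full data")

    index_of = {q: np.flatnonzero((records[question_col] == q).to_numpy()) for q in qids}
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(20,)))
    xs = np.empty(n_exp)
    n_redraws = 0
    for i in range(n_exp):
        for _ in range(max_retries + 1):
            chosen = rng.choice(qids, size=len(qids), replace=True)
            idx = np.concatenate([index_of[q] for q in chosen])
            val = float(statistic(records.iloc[idx]))
            if not np.isnan(val):
                break
            n_redraws += 1
        else:
            raise RuntimeError("statistic undefined on every redrawn resample")
        xs[i] = val
    if n_redraws:
        logger.info("bootstrap redrew %d undefined resamples", n_redraws)

    above = xs[xs > x0] - x0
    below = x0 - xs[xs < x0]
    if above.size == 0 or below.size == 0:
        warnings.warn(
            "one-sided deviation set empty; the corresponding error bar is 0",
            stacklevel=2,
        )
    return BootstrapCI(
        x0=x0,
        b_minus=_one_sided_bar(below, confidence),
        b_plus=_one_sided_bar(above, confidence),
        n_exp=n_exp,
        confidence=confidence,
    )
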