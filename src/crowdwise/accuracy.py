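"""Collective and individual estimation accuracy.

Both metrics act on log-normalised estimates X = log10(E / T), so 0 is
perfect.  Collective accuracy is |median(X)| — how close the crowd's
median sits to the truth; individual accuracy is median(|X|) — how close
a typical individual sits.  Medians use the standard midpoint convention
for even counts.  Stratified variants split records by the sign of the
distance D = M - X_p and by S relative to its within-condition median.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRATA = ("all", "D_neg", "D_pos", "S_low", "S_high")

#: Replacement split point when a condition's median S is exactly 0.
ZERO_MEDIAN_THRESHOLD = 0.001


def collective_accuracy(x) -> float:
    """|median(X)| — distance of the crowd's median from the truth."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("collective accuracy of an empty sample is undefined")
    return float(abs(np.median(x)))


def individual_accuracy(x) -> float:
    """median(|X|) — typical individual distance from the truth."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("individual accuracy of an empty sample is undefined")
    return float(np.median(np.abs(x)))


def _stratum_masks(g: pd.DataFrame) -> dict[str, np.ndarray]:
    d = g["distance"].to_numpy(dtype=float)
    s = g["sensitivity"].to_numpy(dtype=float)
    med = float(np.median(s))
    if med == 0.0:
        med = ZERO_MEDIAN_THRESHOLD
    return {
        "all": np.ones(len(g), dtype=bool),
        "D_neg": d < 0,
        "D_pos": d > 0,
        "S_low": s < med,
        "S_high": s >= med,
    }


def stratified_accuracy(records: pd.DataFrame) -> pd.DataFrame:
    """Accuracy per (treatment, tau, phase, stratum).

    D = 0 records are excluded from the D-sign strata.  The S split uses
    the condition's median of S — strictly below versus at-or-above —
    replaced by 0.001 when the median is exactly 0 (a median sitting on
    the point mass makes the raw split meaningless).  Empty strata are
    omitted with a log note.
    """
    rows = []
    for (tr, tau), g in records.groupby(["treatment", "tau"], sort=True):
        masks = _stratum_masks(g)
        for stratum, mask in masks.items():
            sub = g[mask]
            if len(sub) == 0:
                logger.info("empty stratum %s for treatment=%s tau=%s", stratum, tr, tau)
                continue
            for phase, col in (("personal", "x_personal"), ("second", "x_second")):
                x = sub[col].to_numpy(dtype=float)
                rows.append(
                    {
                        "treatment": tr,
                        "tau": int(tau),
                        "phase": phase,
                        "stratum": stratum,
                        "collective": collective_accuracy(x),
                        "individual": individual_accuracy(x),
                        "n": len(sub),
                    }
                )
    return pd.DataFrame(rows)
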