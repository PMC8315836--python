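"""Agent-based model of social information integration.

Each agent answers a question, receives the (geometric-mean) central
tendency ``M`` of ``tau`` peers' log-normalised estimates, and produces a
second estimate as a barycentre ``X_s = (1 - S) X_p + S M``, where the
sensitivity to social influence ``S`` follows a hurdle law: with
probability ``P_0`` the agent keeps its estimate (``S = 0``), otherwise
``S`` is Gaussian with mean ``m_g(tau)`` and s.d. ``sigma_g(tau)``.

The mean sensitivity combines an exponential saturation in the number of
shared estimates with a V-shaped (cusp) dependence on the distance
``D = M - X_p``:

    <S>(tau, D) = alpha_inf - (1 - eps)^(tau-1) (alpha_inf - alpha_1)
                  + beta_(+/-) |D - D0|,

with slope ``beta_minus`` left of the vertex ``D0`` and ``beta_plus``
right of it.  ``m_g`` and ``sigma_g`` follow the same saturation form at
the same shared rate ``eps``, and the Gaussian-branch probability is
``P_g = <S> / m_g`` clipped to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Design, Question, _child_rng, sample_truncated_laplace

_PARAM_FIELDS = (
    "epsilon",
    "mg1",
    "mg_inf",
    "sg1",
    "sg_inf",
    "alpha1",
    "alpha_inf",
    "d0",
    "beta_minus",
    "beta_plus",
)


@dataclass(frozen=True)
class TreatmentParams:
    """The ten behavioural parameters of one display treatment."""

    epsilon: float       # shared saturation rate, in (0, 1)
    mg1: float           # m_g at tau = 1
    mg_inf: float        # saturation value of m_g
    sg1: float           # sigma_g at tau = 1
    sg_inf: float        # saturation value of sigma_g
    alpha1: float        # cusp bottom at tau = 1
    alpha_inf: float     # saturation value of the cusp bottom
    d0: float            # vertex of the cusp in D
    beta_minus: float    # cusp slope for D < d0
    beta_plus: float     # cusp slope for D > d0

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError(f"epsilon must lie in (0, 1), got {self.epsilon}")
        if self.sg1 <= 0 or self.sg_inf <= 0:
            raise ValueError("sigma_g values must be positive")
        if self.beta_minus < 0 or self.beta_plus < 0:
            raise ValueError("cusp slopes must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TreatmentParams":
        data = json.loads(text)
        unknown = set(data) - set(_PARAM_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        return cls(**{k: float(data[k]) for k in _PARAM_FIELDS})


def load_preset(name: str) -> TreatmentParams:
    """Load the packaged parameter set for ``sorted``, ``unsorted`` or
    ``aggregated`` (the calibrated empirical values per treatment)."""
    ref = resources.files("crowdwise.presets").joinpath(f"{name}.json")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(f"no preset named {name!r}") from None
    return TreatmentParams.from_json(text)


def load_presets() -> dict[str, TreatmentParams]:
    return {t: load_preset(t) for t in ("sorted", "unsorted", "aggregated")}


# ---------------------------------------------------------------------------
# Behavioural laws
# ---------------------------------------------------------------------------

def saturating(tau, y1: float, y_inf: float, epsilon: float):
    """Exponential saturation Y(tau) = Y_inf - (1 - eps)^(tau - 1) (Y_inf - Y_1)."""
    tau = np.asarray(tau, dtype=float)
    return y_inf - (1.0 - epsilon) ** (tau - 1.0) * (y_inf - y1)


def mean_sensitivity(params: TreatmentParams, tau, D):
    """Expected sensitivity <S>(tau, D): saturating baseline plus cusp term."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 1):
        raise ValueError("tau must be >= 1")
    D = np.asarray(D, dtype=float)
    alpha = saturating(tau, params.alpha1, params.alpha_inf, params.epsilon)
    beta = np.where(D < params.d0, params.beta_minus, params.beta_plus)
    return alpha + beta * np.abs(D - params.d0)


def gaussian_probability(params: TreatmentParams, tau, D):
    """Probability of the Gaussian branch, P_g = <S>(tau, D) / m_g(tau).

    The raw ratio can leave [0, 1] for extreme |D - d0|; it is clipped,
    the minimal fix that keeps E[S] = P_g m_g well defined.
    """
    mg = saturating(tau, params.mg1, params.mg_inf, params.epsilon)
    if np.any(np.asarray(mg) <= 0):
        raise ValueError("m_g(tau) must be positive")
    return np.clip(mean_sensitivity(params, tau, D) / mg, 0.0, 1.0)


def draw_sensitivity(params: TreatmentParams, tau, D, rng: np.random.Generator):
    """Hurdle draw of S: 0 with probability 1 - P_g, else Normal(m_g, sigma_g)."""
    tau = np.asarray(tau, dtype=float)
    D = np.asarray(D, dtype=float)
    pg = gaussian_probability(params, tau, D)
    mg = saturating(tau, params.mg1, params.mg_inf, params.epsilon)
    sg = saturating(tau, params.sg1, params.sg_inf, params.epsilon)
    gaussian = rng.uniform(size=pg.shape) < pg
    s = np.where(gaussian, rng.normal(np.broadcast_to(mg, pg.shape), np.broadcast_to(sg, pg.shape)), 0.0)
    return s if s.shape else float(s)


def update_estimate(x_personal, social_mean, sensitivity):
    """Second estimate as the barycentre X_s = (1 - S) X_p + S M."""
    x_personal = np.asarray(x_personal, dtype=float)
    social_mean = np.asarray(social_mean, dtype=float)
    sensitivity = np.asarray(sensitivity, dtype=float)
    return (1.0 - sensitivity) * x_personal + sensitivity * social_mean


# ---------------------------------------------------------------------------
# Full-experiment simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Outcome of repeated simulated experiments.

    ``records`` concatenates the per-run estimate tables (with a ``run``
    column) when record keeping is on; the two summary tables are always
    populated and are exact recomputations from the records.
    """

    records: pd.DataFrame | None
    sensitivity_summary: pd.DataFrame   # mean S per (treatment, tau, stratum)
    accuracy_summary: pd.DataFrame      # run-averaged accuracy per (treatment, tau, phase)
    n_runs: int


def _design_arrays(design: Design) -> dict[str, np.ndarray]:
    cells = design.cells
    pairs = cells[["group_id", "question_id", "tau", "treatment", "block"]].drop_duplicates(
        ["group_id", "question_id"]
    )
    return {
        "group": pairs["group_id"].to_numpy(),
        "question": pairs["question_id"].to_numpy(),
        "tau": pairs["tau"].to_numpy(int),
        "treatment": pairs["treatment"].to_numpy(),
        "block": pairs["block"].to_numpy(int),
    }


def _accuracy_by_condition(frame: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (tr, tau), g in frame.groupby(["treatment", "tau"], sort=True):
        for phase, col in (("personal", "x_personal"), ("second", "x_second")):
            x = g[col].to_numpy()
            rows.append((tr, int(tau), phase, abs(float(np.median(x))), float(np.median(np.abs(x)))))
    return pd.DataFrame(rows, columns=["treatment", "tau", "phase", "collective", "individual"])


def simulate(
    design: Design,
    questions: Sequence[Question],
    params: Mapping[str, TreatmentParams],
    n_runs: int = 10_000,
    seed: int = 0,
    keep_records: bool = True,
    max_redraws: int = 100,
) -> SimulationResult:
    """Run ``n_runs`` simulated experiments on the given design.

    Per run and per (group, question): personal estimates X_p are drawn
    from the question's truncated Laplace law; every agent receives the
    mean M of ``tau`` freshly drawn peers (never itself); S follows the
    hurdle law of that group's treatment; X_s is the barycentre.  The
    physical bound X_s > -log10(T) is enforced by redrawing S for the
    rare violating agent (possible only when S falls outside [0, 1]),
    with S set to 0 after ``max_redraws`` failed attempts.

    ``keep_records=False`` drops the per-record tables and keeps only the
    summary accumulators, which makes very large ``n_runs`` cheap.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    missing = set(design.cells["treatment"].unique()) - set(params)
    if missing:
        raise KeyError(f"missing treatment parameters for: {sorted(missing)}")

    qmap = {q.question_id: q for q in questions}
    arr = _design_arrays(design)
    n_gq = len(arr["tau"])                      # (group, question) pairs
    N = design.group_size
    centers = np.array([qmap[q].center for q in arr["question"]])
    widths = np.array([qmap[q].width for q in arr["question"]])
    lowers = np.array([qmap[q].lower_bound for q in arr["question"]])
    truths = np.array([qmap[q].true_value for q in arr["question"]])
    taus = arr["tau"]

    # peer candidate table: for subject s, the other N-1 subjects
    cand = np.array([[j for j in range(N) if j != s] for s in range(N)])

    # per-record static columns, repeated N times per (group, question)
    rec_static = {
        "group_id": np.repeat(arr["group"], N),
        "subject_id": np.concatenate(
            [[f"{g}S{s + 1:02d}" for s in range(N)] for g in arr["group"]]
        ),
        "treatment": np.repeat(arr["treatment"], N),
        "question_id": np.repeat(arr["question"], N),
        "block": np.repeat(arr["block"], N),
        "tau": np.repeat(taus, N),
        "true_value": np.repeat(truths, N),
    }
    tau_flat = rec_static["tau"]
    treat_flat = rec_static["treatment"]
    lower_flat = np.repeat(lowers, N)
    params_of = {t: params[t] for t in np.unique(treat_flat)}

    run_frames: list[pd.DataFrame] = []
    sens_acc: dict[tuple, np.ndarray] = {}
    acc_frames: list[pd.DataFrame] = []

    for run in range(n_runs):
        rng = _child_rng(seed, 10, run)
        xp = sample_truncated_laplace(
            centers[:, None], widths[:, None], lowers[:, None], (n_gq, N), rng
        )
        # each agent averages the first tau entries of a private shuffle of
        # the other N-1 agents' estimates
        order = np.argsort(rng.random((n_gq, N, N - 1)), axis=2)
        peer_idx = np.take_along_axis(np.broadcast_to(cand, (n_gq, N, N - 1)), order, axis=2)
        peer_x = np.take_along_axis(
            np.broadcast_to(xp[:, None, :], (n_gq, N, N)), peer_idx, axis=2
        )
        csum = np.cumsum(peer_x, axis=2)
        M = csum[np.arange(n_gq), :, taus - 1] / taus[:, None]

        xp_flat = xp.reshape(-1)
        m_flat = M.reshape(-1)
        d_flat = m_flat - xp_flat
        s_flat = np.empty_like(xp_flat)
        for tr, p in params_of.items():
            mask = treat_flat == tr
            s_flat[mask] = draw_sensitivity(p, tau_flat[mask], d_flat[mask], rng)
        xs_flat = update_estimate(xp_flat, m_flat, s_flat)

        # enforce the physical lower bound on the second estimate
        bad = xs_flat <= lower_flat
        attempts = 0
        while bad.any() and attempts < max_redraws:
            for tr, p in params_of.items():
                mask = bad & (treat_flat == tr)
                if mask.any():
                    s_flat[mask] = draw_sensitivity(p, tau_flat[mask], d_flat[mask], rng)
            xs_flat = update_estimate(xp_flat, m_flat, s_flat)
            bad = xs_flat <= lower_flat
            attempts += 1
        if bad.any():
            s_flat[bad] = 0.0
            xs_flat[bad] = xp_flat[bad]

        frame = pd.DataFrame(
            {
                **rec_static,
                "x_personal": xp_flat,
                "social_mean": m_flat,
                "x_second": xs_flat,
                "sensitivity": s_flat,
                "distance": d_flat,
                "run": run,
            }
        )
        for (tr, tau), g in frame.groupby(["treatment", "tau"], sort=True):
            s = g["sensitivity"].to_numpy()
            d = g["distance"].to_numpy()
            for stratum, mask in (("all", slice(None)), ("D_neg", d < 0), ("D_pos", d > 0)):
                key = (tr, int(tau), stratum)
                tot = sens_acc.setdefault(key, np.zeros(2))
                sub = s[mask]
                tot += (sub.sum(), sub.size)
        acc_frames.append(_accuracy_by_condition(frame))
        if keep_records:
            run_frames.append(frame)

    sens = pd.DataFrame(
        [(tr, tau, st, v[0] / v[1] if v[1] else np.nan, int(v[1]))
         for (tr, tau, st), v in sorted(sens_acc.items())],
        columns=["treatment", "tau", "stratum", "mean_s", "n"],
    )
    acc = (
        pd.concat(acc_frames)
        .groupby(["treatment", "tau", "phase"], sort=True, as_index=False)
        .mean()
    )
    return SimulationResult(
        records=pd.concat(run_frames, ignore_index=True) if keep_records else None,
        sensitivity_summary=sens,
        accuracy_summary=acc,
        n_runs=n_runs,
    )
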