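"""Synthetic estimation-task experiments.

Generates the full balanced design of a group estimation experiment —
groups of subjects assigned to one of three social-information display
treatments (``sorted``, ``unsorted``, ``aggregated``) answering a series
of quiz-style quantitative questions — together with synthetic personal
estimates carrying the statistical structure the downstream analysis
assumes.

All estimates live in log space normalised by the truth: for a raw
estimate ``E`` of a quantity with true value ``T``, the working variable
is ``X = log10(E / T)``, the deviation from the truth in orders of
magnitude.  Per question, ``X`` follows a Laplace distribution of centre
``c`` (the median) and width ``w`` (mean absolute deviation from the
median), truncated below at ``-log10(T)`` because raw estimates cannot
fall below 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TREATMENTS = ("sorted", "unsorted", "aggregated")

#: Default number of groups per display treatment.
N_GROUPS_PER_TREATMENT = 6
#: Default group size N.
GROUP_SIZE = 12
#: Default numbers of shared estimates (tau levels).
TAU_LEVELS = (1, 3, 5, 7, 9, 11)
#: Default number of questions.
N_QUESTIONS = 42

#: Column order of the on-disk estimate-record table.
RECORD_COLUMNS = [
    "group_id",
    "subject_id",
    "treatment",
    "question_id",
    "block",
    "tau",
    "true_value",
    "x_personal",
    "social_mean",
    "x_second",
    "sensitivity",
    "distance",
]


@dataclass(frozen=True)
class Question:
    """A quantity to estimate and the Laplace law of its log-normalised estimates."""

    question_id: str
    true_value: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.true_value > 0:
            raise ValueError(f"true_value must be positive, got {self.true_value}")
        if not self.width > 0:
            raise ValueError(f"width must be positive, got {self.width}")

    @property
    def log_truth(self) -> float:
        return float(np.log10(self.true_value))

    @property
    def lower_bound(self) -> float:
        """Truncation bound of X: raw estimates are at least 1, so X > -log10(T)."""
        return -self.log_truth


@dataclass(frozen=True)
class QuestionConfig:
    """Distributions from which per-question Laplace parameters are drawn.

    Defaults encode the underestimation bias seen in human estimation
    data: the centre ``c`` of the log-normalised estimate distribution
    has a negative mean, i.e. the median estimate falls below the truth.
    """

    center_mean: float = -0.3
    center_sd: float = 0.35
    width_low: float = 0.3
    width_high: float = 0.8
    log_truth_low: float = 2.0
    log_truth_high: float = 9.0

    def __post_init__(self) -> None:
        if self.width_low <= 0 or self.width_high <= 0:
            raise ValueError("question widths must be positive")
        if self.width_high < self.width_low:
            raise ValueError("width_high must be >= width_low")
        if self.center_sd < 0:
            raise ValueError("center_sd must be non-negative")


@dataclass(frozen=True)
class Design:
    """A complete balanced experimental design.

    ``cells`` has one row per (group, subject, question) with columns
    group_id, subject_id, treatment, question_id, block, tau and
    peer_ids (tuple of same-group subject ids shown to the subject).
    """

    cells: pd.DataFrame
    n_groups: int
    group_size: int
    tau_levels: tuple[int, ...]
    n_questions: int

    @property
    def n_subjects(self) -> int:
        return self.n_groups * self.group_size


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent child stream per (purpose, index) so adding one purpose
    or group never perturbs the draws of another."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# Questions
# ---------------------------------------------------------------------------

def generate_questions(
    n_questions: int = N_QUESTIONS,
    config: QuestionConfig | None = None,
    seed: int = 0,
) -> list[Question]:
    """Draw a synthetic question list.

    Each question gets a true value ``T`` (log10 T uniform over the
    configured range), a centre ``c`` (normal) and a width ``w``
    (uniform), the parameters of its Laplace estimate distribution.
    """
    if n_questions < 1:
        raise ValueError(f"n_questions must be >= 1, got {n_questions}")
    cfg = config or QuestionConfig()
    rng = _child_rng(seed, 0)
    log_t = rng.uniform(cfg.log_truth_low, cfg.log_truth_high, n_questions)
    centers = rng.normal(cfg.center_mean, cfg.center_sd, n_questions)
    widths = rng.uniform(cfg.width_low, cfg.width_high, n_questions)
    return [
        Question(
            question_id=f"Q{i + 1:03d}",
            true_value=float(10.0 ** log_t[i]),
            center=float(centers[i]),
            width=float(widths[i]),
        )
        for i in range(n_questions)
    ]


def questions_to_frame(questions: Sequence[Question]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "question_id": [q.question_id for q in questions],
            "true_value": [q.true_value for q in questions],
            "center": [q.center for q in questions],
            "width": [q.width for q in questions],
        }
    )


def questions_from_frame(frame: pd.DataFrame) -> list[Question]:
    return [
        Question(str(r.question_id), float(r.true_value), float(r.center), float(r.width))
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Balanced design
# ---------------------------------------------------------------------------

def _random_latin_square(k: int, rng: np.random.Generator) -> np.ndarray:
    """A random k x k Latin square via row/column/symbol shuffles of the
    cyclic square.  Not uniform over all Latin squares, but every row and
    column constraint holds exactly, which is all the balance needs."""
    base = (np.arange(k)[:, None] + np.arange(k)[None, :]) % k
    rows = rng.permutation(k)
    cols = rng.permutation(k)
    symbols = rng.permutation(k)
    return symbols[base[rows][:, cols]]


def build_design(
    n_groups_per_treatment: int = N_GROUPS_PER_TREATMENT,
    group_size: int = GROUP_SIZE,
    tau_levels: Sequence[int] = TAU_LEVELS,
    n_questions: int = N_QUESTIONS,
    seed: int = 0,
) -> Design:
    """Build the balanced treatment/tau/question design.

    Balance constraints, all enforced exactly:

    * each group sees one treatment only (between-groups);
    * within a group, questions are split into blocks of ``len(tau_levels)``
      and every block contains each tau exactly once;
    * across the groups of one treatment, every question is asked at each
      tau exactly ``n_groups_per_treatment / len(tau_levels)`` times — with
      the defaults, exactly once per (question, treatment, tau).

    The construction stacks random Latin squares into a question x group
    rectangle per treatment, so the constraints hold by construction and
    infeasible requests fail fast instead of yielding a silently
    unbalanced design.
    """
    tau_levels = tuple(int(t) for t in tau_levels)
    k = len(tau_levels)
    if n_questions % k != 0:
        raise ValueError(
            f"n_questions ({n_questions}) must be divisible by the number of "
            f"tau levels ({k})"
        )
    if group_size <= max(tau_levels):
        raise ValueError(
            f"group_size ({group_size}) must exceed the largest tau "
            f"({max(tau_levels)})"
        )
    if n_groups_per_treatment % k != 0:
        raise ValueError(
            f"n_groups_per_treatment ({n_groups_per_treatment}) must be a "
            f"multiple of the number of tau levels ({k}) for cross-group balance"
        )
    n_blocks = n_questions // k
    taus = np.asarray(tau_levels)

    rows = []
    group_counter = 0
    for t_idx, treatment in enumerate(TREATMENTS):
        rng = _child_rng(seed, 1, t_idx)
        # question x group tau assignment: stack Latin squares so each row
        # (question) is a permutation of tau_levels across each band of k
        # groups and each column (group) carries each tau n_questions/k times.
        blocks_of_squares = []
        for _ in range(n_questions // k):
            blocks_of_squares.append(
                np.concatenate(
                    [_random_latin_square(k, rng) for _ in range(n_groups_per_treatment // k)],
                    axis=1,
                )
            )
        rect = np.concatenate(blocks_of_squares, axis=0)  # (n_questions, n_groups_per_treatment)
        rect = rect[rng.permutation(n_questions)]
        tau_of = taus[rect]  # tau per (question index, local group)

        for local_g in range(n_groups_per_treatment):
            group_id = f"G{group_counter + 1:02d}"
            group_counter += 1
            grng = _child_rng(seed, 2, group_counter)
            # blocks: one question of each tau per block, shuffled within block
            order_within = {}
            for tau in tau_levels:
                q_idx = np.flatnonzero(tau_of[:, local_g] == tau)
                grng.shuffle(q_idx)
                order_within[tau] = q_idx
            for b in range(n_blocks):
                block_questions = [order_within[tau][b] for tau in tau_levels]
                grng.shuffle(block_questions)
                for qi in block_questions:
                    tau = int(tau_of[qi, local_g])
                    for s in range(group_size):
                        subject_id = f"{group_id}S{s + 1:02d}"
                        others = [f"{group_id}S{j + 1:02d}" for j in range(group_size) if j != s]
                        peers = tuple(grng.choice(others, size=tau, replace=False))
                        rows.append(
                            (
                                group_id,
                                subject_id,
                                treatment,
                                f"Q{qi + 1:03d}",
                                b + 1,
                                tau,
                                peers,
                            )
                        )

    cells = pd.DataFrame(
        rows,
        columns=["group_id", "subject_id", "treatment", "question_id", "block", "tau", "peer_ids"],
    )
    return Design(
        cells=cells,
        n_groups=n_groups_per_treatment * len(TREATMENTS),
        group_size=group_size,
        tau_levels=tau_levels,
        n_questions=n_questions,
    )


# ---------------------------------------------------------------------------
# Personal estimates
# ---------------------------------------------------------------------------

def sample_truncated_laplace(
    center: float | np.ndarray,
    width: float | np.ndarray,
    lower: float | np.ndarray,
    size: int | tuple[int, ...] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Laplace(center, width) draws restricted to (lower, inf) by inverse CDF
    on the truncated support — exact, no rejection loop."""
    u_low = stats.laplace.cdf(lower, loc=center, scale=width)
    u = rng.uniform(u_low, 1.0, size=size)
    return stats.laplace.ppf(u, loc=center, scale=width)


def draw_personal_estimates(
    questions: Sequence[Question],
    design: Design,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill ``x_personal`` for every design cell.

    Each subject's log-normalised personal estimate is drawn from the
    question's Laplace(c, w) truncated to X > -log10(T); one subject gives
    one estimate per question regardless of tau.
    """
    qmap = {q.question_id: q for q in questions}
    missing = set(design.cells["question_id"]) - set(qmap)
    if missing:
        raise KeyError(f"design references unknown question ids: {sorted(missing)}")

    records = design.cells.copy()
    records["true_value"] = records["question_id"].map(lambda qid: qmap[qid].true_value)

    # one draw per (subject, question): subjects answer each question once
    pairs = records[["subject_id", "question_id"]].drop_duplicates()
    rng = _child_rng(seed, 3)
    centers = pairs["question_id"].map(lambda qid: qmap[qid].center).to_numpy()
    widths = pairs["question_id"].map(lambda qid: qmap[qid].width).to_numpy()
    lowers = pairs["question_id"].map(lambda qid: qmap[qid].lower_bound).to_numpy()
    pairs = pairs.assign(
        x_personal=sample_truncated_laplace(centers, widths, lowers, len(pairs), rng)
    )
    records = records.merge(pairs, on=["subject_id", "question_id"], how="left")
    return records


def assign_social_info(records: pd.DataFrame, design: Design, seed: int = 0) -> pd.DataFrame:
    """Fill ``social_mean`` and ``display_payload`` from the peer sets.

    ``social_mean`` M is the arithmetic mean of the peers' X values —
    identically log10 of the geometric mean of their raw estimates,
    normalised by the truth.  The payload mirrors what each treatment
    shows on screen: the peer X values ascending (sorted), randomly
    permuted (unsorted), or the pair (M, tau) (aggregated).
    """
    if records["x_personal"].isna().any():
        raise ValueError("all personal estimates must be present before assigning social info")
    if max(design.tau_levels) >= design.group_size:
        raise ValueError("tau must be smaller than the group size")

    x_of = {
        (r.subject_id, r.question_id): r.x_personal
        for r in records[["subject_id", "question_id", "x_personal"]]
        .drop_duplicates()
        .itertuples(index=False)
    }
    rng = _child_rng(seed, 4)
    out = records.copy()
    social_mean = np.empty(len(out))
    payloads: list[str] = []
    for i, r in enumerate(out.itertuples(index=False)):
        peer_x = np.array([x_of[(p, r.question_id)] for p in r.peer_ids])
        m = float(peer_x.mean())
        social_mean[i] = m
        if r.treatment == "sorted":
            payload = {"estimates": sorted(peer_x.tolist())}
        elif r.treatment == "unsorted":
            payload = {"estimates": rng.permutation(peer_x).tolist()}
        else:
            payload = {"mean": m, "tau": int(r.tau)}
        payloads.append(json.dumps(payload))
    out["social_mean"] = social_mean
    out["display_payload"] = payloads
    out["distance"] = out["social_mean"] - out["x_personal"]
    return out


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_records(records: pd.DataFrame, path) -> None:
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    extra = [c for c in ("display_payload",) if c in records.columns]
    records[cols + extra].to_csv(path, index=False, float_format="%.12g")


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)
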