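"""Probabilistic associative learning (ProAL) task: schedules, trials, scoring.

The task pairs an auditory cue (low/high tone) with a visual outcome
(male/female face).  Within each block the contingency between cue and
outcome is constant; across blocks it jumps between 90/10, 70/30 and 50/50,
so the learner experiences a volatile environment.  The single tracked
quantity is ``p_match``, the probability that the reference association
"high tone -> female face" (equivalently "low tone -> male face") holds on
a trial; the binary input ``u`` fed to the learning models indicates whether
it held.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CUE_LOW = "low_tone"
CUE_HIGH = "high_tone"
OUTCOME_MALE = "male"
OUTCOME_FEMALE = "female"
MISSING = "missing"

#: Contingency levels used in the task (plus their complements).
CONTINGENCY_LEVELS = (0.9, 0.7, 0.5)


class InfeasibleScheduleError(ValueError):
    """No block composition satisfies the requested constraints."""


class UndefinedAccuracyError(ValueError):
    """Accuracy is undefined because every response is missing."""


@dataclass(frozen=True)
class Block:
    length: int
    p_match: float


@dataclass(frozen=True)
class TaskSchedule:
    """Ordered block structure of one session.

    ``p_match`` of each block is the probability that the reference
    association holds on a trial of that block.
    """

    blocks: tuple[Block, ...]

    @property
    def session_length(self) -> int:
        return sum(b.length for b in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def p_match_per_trial(self) -> np.ndarray:
        return np.repeat([b.p_match for b in self.blocks],
                         [b.length for b in self.blocks])

    def block_index_per_trial(self) -> np.ndarray:
        """1-based block index for every trial."""
        return np.repeat(np.arange(1, self.n_blocks + 1),
                         [b.length for b in self.blocks])

    def validate(self, length_range: tuple[int, int] = (11, 17),
                 levels: Iterable[float] = CONTINGENCY_LEVELS) -> None:
        lo, hi = length_range
        allowed = {round(p, 10) for lv in levels for p in (lv, 1.0 - lv)}
        for b in self.blocks:
            if not lo <= b.length <= hi:
                raise ValueError(f"block length {b.length} outside [{lo}, {hi}]")
            if round(b.p_match, 10) not in allowed:
                raise ValueError(f"p_match {b.p_match} not an allowed level")


@dataclass
class TrialRecord:
    """One trial: cue, outcome, the binary match indicator and the response.

    ``u`` is 1 iff the reference association held, i.e. it is a deterministic
    function of (cue, outcome): high tone + female, or low tone + male.
    """

    trial_index: int  # 1-based
    block_index: int  # 1-based
    cue: str
    outcome: str
    u: int
    response: str = MISSING

    @property
    def correct(self) -> bool | None:
        if self.response == MISSING:
            return None
        return self.response == self.outcome


def match_indicator(cue: str, outcome: str) -> int:
    """1 iff (cue, outcome) agrees with the reference association."""
    if cue == CUE_HIGH:
        return int(outcome == OUTCOME_FEMALE)
    return int(outcome == OUTCOME_MALE)


_CANONICAL_LENGTHS = (15, 16, 11, 17, 14, 16, 15, 13, 17, 16)
_CANONICAL_P = (0.5, 0.9, 0.1, 0.7, 0.3, 0.9, 0.5, 0.1, 0.7, 0.5)


def canonical_schedule() -> TaskSchedule:
    """The fixed default 150-trial, 10-block session.

    Block lengths range over 11-17 and contingencies over the 90/10, 70/30,
    50/50 levels and their complements.
    """
    return TaskSchedule(tuple(Block(l, p) for l, p in
                              zip(_CANONICAL_LENGTHS, _CANONICAL_P)))


def sample_schedule(rng_seed: int, n_blocks: int = 10,
                    length_range: tuple[int, int] = (11, 17),
                    levels: Sequence[float] = CONTINGENCY_LEVELS,
                    session_length: int = 150) -> TaskSchedule:
    """Draw a random schedule satisfying all structural invariants.

    Lengths are a uniform-ish random composition of ``session_length`` into
    ``n_blocks`` parts within ``length_range``; each block's ``p_match`` is
    drawn uniformly from the levels and their complements.

    Raises
    ------
    InfeasibleScheduleError
        if no composition of ``session_length`` into ``n_blocks`` parts
        within ``length_range`` exists.
    """
    lo, hi = length_range
    if not (n_blocks * lo <= session_length <= n_blocks * hi):
        raise InfeasibleScheduleError(
            f"cannot compose {session_length} trials into {n_blocks} blocks "
            f"of length in [{lo}, {hi}]")
    rng = np.random.default_rng(rng_seed)
    # distribute the surplus one trial at a time among blocks below the cap
    lengths = np.full(n_blocks, lo)
    for _ in range(session_length - n_blocks * lo):
        room = np.flatnonzero(lengths < hi)
        lengths[room[rng.integers(len(room))]] += 1
    choices = sorted({round(p, 10) for lv in levels for p in (lv, 1.0 - lv)})
    p_match = rng.choice(choices, size=n_blocks)
    sched = TaskSchedule(tuple(Block(int(l), float(p))
                               for l, p in zip(lengths, p_match)))
    sched.validate(length_range, levels)
    return sched


def generate_trials(schedule: TaskSchedule, rng_seed: int) -> list[TrialRecord]:
    """Sample one session of trials (responses left missing).

    Cues are fair-coin i.i.d.; the outcome is chosen so that
    ``P(u = 1) = p_match`` of the trial's block, with ``u`` the match
    indicator of (cue, outcome).
    """
    rng = np.random.default_rng(rng_seed)
    p = schedule.p_match_per_trial()
    blocks = schedule.block_index_per_trial()
    n = schedule.session_length
    cues = rng.integers(2, size=n)  # 1 = high tone
    u = (rng.random(n) < p).astype(int)
    trials = []
    for k in range(n):
        cue = CUE_HIGH if cues[k] else CUE_LOW
        if cue == CUE_HIGH:
            outcome = OUTCOME_FEMALE if u[k] else OUTCOME_MALE
        else:
            outcome = OUTCOME_MALE if u[k] else OUTCOME_FEMALE
        trials.append(TrialRecord(trial_index=k + 1, block_index=int(blocks[k]),
                                  cue=cue, outcome=outcome, u=int(u[k])))
    return trials


def score_responses(trials: Sequence[TrialRecord]) -> tuple[float, int]:
    """Return ``(accuracy_percent, n_missing)``.

    Accuracy is 100 x (correct responses) / (non-missing responses).
    """
    n_missing = sum(1 for t in trials if t.response == MISSING)
    answered = [t for t in trials if t.response != MISSING]
    if not answered:
        raise UndefinedAccuracyError("all responses missing; accuracy undefined")
    acc = 100.0 * sum(t.correct for t in answered) / len(answered)
    return acc, n_missing


# ---------------------------------------------------------------------------
# delimited-text interchange

TRIAL_COLUMNS = ["subject_id", "trial", "block", "cue", "outcome", "u", "response"]


def trials_to_frame(trials: Sequence[TrialRecord], subject_id: str) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": subject_id,
        "trial": [t.trial_index for t in trials],
        "block": [t.block_index for t in trials],
        "cue": [t.cue for t in trials],
        "outcome": [t.outcome for t in trials],
        "u": [t.u for t in trials],
        "response": ["" if t.response == MISSING else t.response for t in trials],
    })


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    missing = {name for name in TRIAL_COLUMNS if name not in df.columns}
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    unknown = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if unknown:
        raise ValueError(f"trial table has unknown columns: {unknown}")
    out = []
    for row in df.itertuples(index=False):
        resp = row.response
        if resp is None or (isinstance(resp, float) and np.isnan(resp)) or resp == "":
            resp = MISSING
        out.append(TrialRecord(trial_index=int(row.trial), block_index=int(row.block),
                               cue=str(row.cue), outcome=str(row.outcome),
                               u=int(row.u), response=str(resp)))
    return out


def schedule_to_dict(schedule: TaskSchedule) -> dict:
    return {"blocks": [{"length": b.length, "p_match": b.p_match}
                       for b in schedule.blocks]}


def schedule_from_dict(d: dict) -> TaskSchedule:
    return TaskSchedule(tuple(Block(int(b["length"]), float(b["p_match"]))
                              for b in d["blocks"]))
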