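"""Three-day cycles, cycle entropy H, and cycle symptom score SC.

EMA prompts are grouped into consecutive non-overlapping blocks of
``cycle_length_days`` days (default 3, i.e. 9 prompts per cycle at 3 prompts
per day).  Within a cycle the checked activities form a probability
distribution; its Shannon entropy H (base 2) is the static rhythmic marker.
A cycle is valid only when fewer than 3 of its 9 prompts are missing; missing
prompts are pooled into one reserved "missing" category of the distribution.
SC is the mean of the summed five symptom items over the cycle's answered
prompts (each prompt sum in 5..35).
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MISSING_LABEL
from .ema import EMARecord

_PROB_TOL = 1e-9


class DegenerateCycleError(ValueError):
    """A valid cycle whose activity distribution has no mass (every answered
    prompt reported zero activities and no prompt is missing)."""


class UndefinedScoreError(ValueError):
    """SC requested for a cycle with no answered prompts."""


@dataclass(frozen=True)
class Cycle:
    """One block of consecutive study days for one participant."""

    participant_id: str
    group: str
    cycle_index: int  # 1-based
    n_expected_prompts: int
    n_missing: int
    valid: bool
    activity_distribution: dict[str, float] | None
    H: float | None
    SC: float | None


def shannon_entropy(distribution: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy, in bits, of a discrete probability distribution.

    H(X) = -sum_x p(x) log2 p(x), with 0 log 0 = 0.

    Raises
    ------
    ValueError
        If probabilities are negative or do not sum to 1 within tolerance.
    """
    if isinstance(distribution, Mapping):
        p = np.asarray(list(distribution.values()), dtype=float)
    else:
        p = np.asarray(distribution, dtype=float)
    if p.size == 0:
        raise ValueError("empty distribution")
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def activity_distribution(
    cycle_records: Sequence[EMARecord],
    n_expected_prompts: int,
    denominator: str = "tokens",
) -> dict[str, float]:
    """Probability distribution of activities reported within one cycle.

    Counts each distinct activity across the cycle's answered prompts, plus
    one count per missing prompt under the reserved missing label, and
    normalizes.  With ``denominator="tokens"`` (default) the divisor is the
    total activity-token count, which generalizes the single-select worked
    case (divide by 9) to multi-select prompts while keeping the
    probabilities summing to 1.  ``denominator="prompts"`` divides by the
    number of prompts instead and then renormalizes.
    """
    if denominator not in ("tokens", "prompts"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    counts: Counter[str] = Counter()
    n_missing = 0
    for rec in cycle_records:
        if rec.answered:
            counts.update(rec.activities)
        else:
            n_missing += 1
    n_missing += n_expected_prompts - len(cycle_records)
    if n_missing:
        counts[MISSING_LABEL] = n_missing
    total = sum(counts.values())
    if total == 0:
        raise DegenerateCycleError(
            "cycle has no activity tokens and no missing prompts"
        )
    if denominator == "tokens":
        dist = {a: c / total for a, c in counts.items()}
    else:
        dist = {a: c / n_expected_prompts for a, c in counts.items()}
        s = sum(dist.values())
        dist = {a: v / s for a, v in dist.items()}
    return dist


def cycle_symptom_score(cycle_records: Sequence[EMARecord]) -> float:
    """Mean per-prompt symptom sum (range 5..35) over answered prompts."""
    sums = [rec.symptom_sum for rec in cycle_records if rec.answered]
    if not sums:
        raise UndefinedScoreError("no answered prompts in cycle")
    return float(np.mean(sums))


def build_cycles(
    records: Sequence[EMARecord],
    cycle_length_days: int = 3,
    prompts_per_day: int = 3,
    max_missing: int = 2,
    denominator: str = "tokens",
) -> list[Cycle]:
    """Partition one participant's records into consecutive cycles.

    Days are split into non-overlapping ``cycle_length_days``-day blocks
    starting at day 1; a trailing partial block is discarded.  Each cycle
    carries its missingness count; H and SC are computed only for valid
    cycles (``n_missing <= max_missing``).
    """
    if not records:
        return []
    pid = records[0].participant_id
    group = records[0].group
    if any(r.participant_id != pid for r in records):
        raise ValueError("build_cycles expects records of a single participant")
    n_expected = cycle_length_days * prompts_per_day
    max_day = max(r.day for r in records)
    n_cycles = max_day // cycle_length_days
    by_cycle: dict[int, list[EMARecord]] = {i: [] for i in range(1, n_cycles + 1)}
    for r in records:
        ci = (r.day - 1) // cycle_length_days + 1
        if ci in by_cycle:
            by_cycle[ci].append(r)
    cycles: list[Cycle] = []
    for ci in range(1, n_cycles + 1):
        recs = by_cycle[ci]
        n_answered = sum(1 for r in recs if r.answered)
        n_missing = n_expected - n_answered
        valid = n_missing <= max_missing
        dist = H = sc = None
        if valid:
            dist = activity_distribution(recs, n_expected, denominator)
            H = shannon_entropy(dist)
            sc = cycle_symptom_score(recs)
        cycles.append(
            Cycle(
                participant_id=pid,
                group=group,
                cycle_index=ci,
                n_expected_prompts=n_expected,
                n_missing=n_missing,
                valid=valid,
                activity_distribution=dist,
                H=H,
                SC=sc,
            )
        )
    return cycles


@dataclass(frozen=True)
class ParticipantSeries:
    """Ordered cycles of one participant with the inclusion flag.

    A participant enters the dynamic analyses only with at least
    ``min_valid_cycles`` (default 3) valid cycles — enough to observe at
    least two states of the Markov chain.
    """

    participant_id: str
    group: str
    cycles: tuple[Cycle, ...]
    min_valid_cycles: int = 3

    @property
    def valid_cycles(self) -> tuple[Cycle, ...]:
        return tuple(c for c in self.cycles if c.valid)

    @property
    def included(self) -> bool:
        return len(self.valid_cycles) >= self.min_valid_cycles


def build_participant_series(
    records: Sequence[EMARecord],
    cycle_length_days: int = 3,
    prompts_per_day: int = 3,
    max_missing: int = 2,
    min_valid_cycles: int = 3,
    denominator: str = "tokens",
) -> dict[str, ParticipantSeries]:
    """Group records by participant and build each one's cycle series."""
    by_pid: dict[str, list[EMARecord]] = {}
    for r in records:
        by_pid.setdefault(r.participant_id, []).append(r)
    out: dict[str, ParticipantSeries] = {}
    for pid, recs in by_pid.items():
        cycles = build_cycles(
            recs, cycle_length_days, prompts_per_day, max_missing, denominator
        )
        out[pid] = ParticipantSeries(
            participant_id=pid,
            group=recs[0].group,
            cycles=tuple(cycles),
            min_valid_cycles=min_valid_cycles,
        )
    return out


def cycles_table(series: Mapping[str, ParticipantSeries]) -> pd.DataFrame:
    """Tidy per-cycle table: participant, group, cycle, missingness, H, SC."""
    rows = []
    for ps in series.values():
        for c in ps.cycles:
            rows.append(
                {
                    "participant_id": c.participant_id,
                    "group": c.group,
                    "cycle_index": c.cycle_index,
                    "n_missing": c.n_missing,
                    "valid": c.valid,
                    "H": c.H if c.H is not None else math.nan,
                    "SC": c.SC if c.SC is not None else math.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "group",
            "cycle_index",
            "n_missing",
            "valid",
            "H",
            "SC",
        ],
    )


def person_H_decomposition(cycle_table: pd.DataFrame) -> pd.DataFrame:
    """Within/between decomposition of H over valid cycles.

    Adds, per cycle row, the participant's mean H (``person_mean_H``,
    between-person predictor) and the deviation of the cycle's H from it
    (``centered_H``, within-person predictor).  Centered values sum to ~0
    within each participant.
    """
    df = cycle_table[cycle_table["valid"]].copy()
    means = df.groupby("participant_id")["H"].transform("mean")
    df["person_mean_H"] = means
    df["centered_H"] = df["H"] - means
    return df
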