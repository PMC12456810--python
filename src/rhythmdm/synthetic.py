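"""Synthetic EMA cohort generator with known ground-truth dynamics.

The generator emulates the study protocol — 3 prompts/day over 30 days, 39
checkbox activities with multi-select, five 1-7 symptom items summed to a
5-35 score, per-prompt missingness — while every participant's cycle-to-cycle
dynamics follow a *known* group-specific transition matrix over the nine
(ΔH, ΔSC) states.  That makes every downstream stage testable without the
access-restricted study data: the latent state sequence is returned alongside
the records, so state classification, transition-matrix estimation, and the
group statistics can all be checked against ground truth.

Generation is constructive rather than merely stochastic: each participant
carries an "entropy ladder" of activity-count compositions whose realized
entropies are strictly increasing, and an integer ladder of cycle symptom
totals.  An up (U) latent label moves one rung up the relevant ladder, down
(D) one rung down, and flat (F) reuses the previous cycle's realized
multiset exactly — so at zero missingness the realized (ΔH, ΔSC) signs agree
with the latent labels by construction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import markov
from .catalog import ActivityCatalog, load_default_catalog
from .ema import EMARecord, write_ema

_ROW_TOL = 1e-12


class GenerationError(RuntimeError):
    """The latent trajectory demands an impossible realization (e.g. the
    entropy is forced past the top of the ladder)."""


@dataclass(frozen=True)
class LatentTrajectory:
    """Ground-truth state sequence of one synthetic participant.

    ``states[t]`` (1-based Box-state index) labels the transition between
    cycle t and cycle t+1; the sequence has length n_cycles - 1.
    """

    participant_id: str
    group: str
    states: tuple[int, ...]


class CohortSpec(BaseModel, arbitrary_types_allowed=True):
    """Study-condition parameters of a synthetic cohort.

    Defaults mirror the protocol: 30 days at 3 prompts/day (10 cycles of 9
    prompts), the 39-activity catalog, and modest per-prompt missingness.
    """

    n_participants_per_group: dict[str, int]
    n_days: int = Field(30, ge=3)
    prompts_per_day: int = Field(3, ge=1)
    activity_labels: tuple[str, ...] | None = None
    true_transition_matrix_per_group: dict[str, list[list[float]]]
    missingness_rate: float = Field(0.1, ge=0.0, lt=1.0)
    block_missingness: bool = False
    symptom_noise_sd: float = Field(2.0, ge=0.0)
    multi_select_probs: tuple[float, float, float] = (0.8, 0.15, 0.05)
    seed: int = 0

    @field_validator("n_participants_per_group")
    @classmethod
    def _positive_counts(cls, v):
        for g, n in v.items():
            if n < 1:
                raise ValueError(f"group {g!r} needs >= 1 participant")
        return v

    @model_validator(mode="after")
    def _check_matrices(self):
        for g in self.n_participants_per_group:
            if g not in self.true_transition_matrix_per_group:
                raise ValueError(f"no true transition matrix for group {g!r}")
        for g, m in self.true_transition_matrix_per_group.items():
            arr = np.asarray(m, dtype=float)
            if arr.shape != (markov.N_STATES, markov.N_STATES):
                raise ValueError(f"matrix for {g!r} must be 9x9")
            if np.any(arr < 0):
                raise ValueError(f"matrix for {g!r} has negative entries")
            if np.max(np.abs(arr.sum(axis=1) - 1.0)) > _ROW_TOL:
                raise ValueError(f"rows of matrix for {g!r} must sum to 1")
        p = np.asarray(self.multi_select_probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("multi_select_probs must be a distribution")
        return self

    @property
    def groups(self) -> list[str]:
        return list(self.n_participants_per_group)

    @property
    def n_cycles(self) -> int:
        return self.n_days // 3

    def catalog(self) -> ActivityCatalog:
        if self.activity_labels is None:
            return load_default_catalog()
        return ActivityCatalog(tuple(self.activity_labels))

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def example_group_matrices() -> dict[str, list[list[float]]]:
    """Three distinct, well-conditioned 9x9 chains for the example scenario.

    The control chain concentrates probability on flips between UF and DF
    (entropy changes with steady symptom reports); the schizophrenia chain
    spreads mass toward the symptom-coupled corner states (UU, UD, DU, DD);
    the bipolar chain is their midpoint.  These choices reproduce the
    qualitative group structure the pipeline is meant to detect and make the
    groups' analytic mean expected hit times clearly distinct.
    """
    n = markov.N_STATES
    labels = markov.STATE_LABELS
    uf, df = labels.index("UF"), labels.index("DF")
    corners = [labels.index(s) for s in ("UU", "UD", "DU", "DD")]

    control = np.full((n, n), 0.30 / (n - 2))
    control[:, uf] = 0.35
    control[:, df] = 0.35
    for i in (uf, df):
        control[i] = 0.20 / (n - 2)
        control[i, uf if i == df else df] = 0.60
        control[i, i] = 0.20
    control /= control.sum(axis=1, keepdims=True)

    scz = np.full((n, n), 0.28 / (n - 4))
    for j in corners:
        scz[:, j] = 0.18
    scz /= scz.sum(axis=1, keepdims=True)

    bipolar = 0.5 * control + 0.5 * scz
    return {
        "control": control.tolist(),
        "bipolar": bipolar.tolist(),
        "schizophrenia": scz.tolist(),
    }


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Cohort spec matching the study conditions: group sizes 45 controls,
    192 bipolar, 153 schizophrenia; 30 days x 3 prompts."""
    params = dict(
        n_participants_per_group={
            "control": 45,
            "bipolar": 192,
            "schizophrenia": 153,
        },
        true_transition_matrix_per_group=example_group_matrices(),
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)


# ---------------------------------------------------------------------------
# constructive realization helpers


def _capped_composition(total: int, caps: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random composition of ``total`` over len(caps) cells, cell i <= caps[i]."""
    caps = np.asarray(caps, dtype=int)
    if total > caps.sum():
        raise ValueError("composition infeasible")
    alloc = np.zeros(len(caps), dtype=int)
    remaining = total
    while remaining > 0:
        free = caps - alloc
        idx = np.where(free > 0)[0]
        add = rng.multinomial(remaining, free[idx] / free[idx].sum())
        add = np.minimum(add, free[idx])
        alloc[idx] += add
        remaining = total - int(alloc.sum())
    return alloc


def _entropy_ladder(
    n_tokens: int, max_count: int, n_piles_max: int, seed_key: Sequence[int]
) -> list[tuple[float, tuple[int, ...]]]:
    """Strictly increasing ladder of (entropy, count-multiset) rungs.

    Candidate compositions of ``n_tokens`` activity tokens (each pile capped
    at ``max_count`` so tokens can be dealt to distinct prompts) are
    generated, deduplicated, and sorted by the Shannon entropy of
    counts/n_tokens; rungs closer than 1e-6 bits are merged so consecutive
    rungs differ by a detectable entropy gap.
    """
    rng = np.random.default_rng(list(seed_key))
    k_min = -(-n_tokens // max_count)  # ceil
    k_max = min(n_tokens, n_piles_max)
    seen: set[tuple[int, ...]] = set()
    for k in range(k_min, k_max + 1):
        base, rem = divmod(n_tokens, k)
        if base + 1 <= max_count:
            vec = tuple(sorted([base + 1] * rem + [base] * (k - rem), reverse=True))
            if all(v > 0 for v in vec):
                seen.add(vec)
        for _ in range(30):
            caps = np.full(k, max_count - 1)
            vec = 1 + _capped_composition(n_tokens - k, caps, rng)
            seen.add(tuple(sorted(vec.tolist(), reverse=True)))
    rungs: list[tuple[float, tuple[int, ...]]] = []
    for vec in seen:
        p = np.asarray(vec, dtype=float) / n_tokens
        h = float(-(p * np.log2(p)).sum())
        rungs.append((h, vec))
    rungs.sort(key=lambda r: r[0])
    out: list[tuple[float, tuple[int, ...]]] = []
    for h, vec in rungs:
        if not out or h - out[-1][0] >= 1e-6:
            out.append((h, vec))
    return out


def _deal_tokens(
    activity_counts: list[tuple[str, int]],
    capacities: np.ndarray,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Deal activity tokens into prompts so no prompt repeats an activity.

    Feasible whenever every activity count <= number of prompts and the
    total token count equals the total prompt capacity; the greedy
    largest-remaining-capacity rule below then always succeeds.
    """
    n_prompts = len(capacities)
    rem = np.asarray(capacities, dtype=int).copy()
    out: list[list[str]] = [[] for _ in range(n_prompts)]
    for act, cnt in sorted(activity_counts, key=lambda ac: -ac[1]):
        order = np.lexsort((rng.random(n_prompts), -rem))
        chosen = [i for i in order if rem[i] > 0][:cnt]
        if len(chosen) < cnt:
            raise GenerationError(
                f"cannot place activity {act!r} x{cnt} into {n_prompts} prompts"
            )
        for i in chosen:
            out[i].append(act)
            rem[i] -= 1
    return out


def _prompt_sums(
    total: int, n_prompts: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Integer per-prompt symptom sums in 5..35 with an exact grand total."""
    mu = total / n_prompts
    vals = np.clip(np.rint(rng.normal(mu, sd, n_prompts)).astype(int), 5, 35)
    diff = total - int(vals.sum())
    step = 1 if diff > 0 else -1
    guard = 0
    while diff != 0:
        i = int(rng.integers(n_prompts))
        if 5 <= vals[i] + step <= 35:
            vals[i] += step
            diff -= step
        guard += 1
        if guard > 100_000:  # pragma: no cover - bounded totals make this unreachable
            raise GenerationError("could not balance prompt sums")
    return vals


def _split_items(total: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Split a prompt sum (5..35) into five item ratings each in 1..7."""
    extra = _capped_composition(total - 5, np.full(5, 6), rng)
    return tuple((1 + extra).tolist())


_DIR_STEP = {"U": +1, "F": 0, "D": -1}


def _state_dirs(state: int) -> tuple[str, str]:
    label = markov.STATE_LABELS[state - 1]
    return label[0], label[1]


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[EMARecord], list[LatentTrajectory]]:
    """Generate EMA records plus the latent ground-truth trajectories.

    Identical spec (including seed) yields byte-identical output.
    """
    catalog = spec.catalog()
    labels = list(catalog)
    n_ppc = spec.prompts_per_day * 3  # prompts per 3-day cycle
    n_cycles = spec.n_cycles
    if n_cycles < 2:
        raise ValueError("need at least 6 days (2 cycles) to generate dynamics")
    sc_total_min, sc_total_max = 5 * n_ppc, 35 * n_ppc

    root = np.random.SeedSequence(spec.seed)
    records: list[EMARecord] = []
    trajectories: list[LatentTrajectory] = []
    ladder_cache: dict[int, list[tuple[float, tuple[int, ...]]]] = {}

    for g_idx, group in enumerate(spec.groups):
        P_true = np.asarray(spec.true_transition_matrix_per_group[group], float)
        pi = markov.stationary_distribution(P_true)
        n_part = spec.n_participants_per_group[group]
        for p_idx in range(n_part):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            pid = f"{group}_{p_idx:04d}"

            # latent chain: states[t] labels the cycle t -> t+1 transition
            states = [int(rng.choice(markov.N_STATES, p=pi)) + 1]
            for _ in range(n_cycles - 2):
                row = P_true[states[-1] - 1]
                states.append(int(rng.choice(markov.N_STATES, p=row)) + 1)
            trajectories.append(
                LatentTrajectory(pid, group, tuple(states))
            )

            # per-participant prompt token template (multi-select pattern)
            tokens_per_prompt = rng.choice(
                [1, 2, 3], size=n_ppc, p=np.asarray(spec.multi_select_probs)
            )
            T = int(tokens_per_prompt.sum())
            if T not in ladder_cache:
                ladder_cache[T] = _entropy_ladder(
                    T, max_count=n_ppc, n_piles_max=len(labels),
                    seed_key=(spec.seed, 99173, T),
                )
            ladder = ladder_cache[T]
            pref = rng.permutation(len(labels))

            # realize the entropy/symptom ladders cycle by cycle
            # start mid-ladder / mid-range so the +-1-rung and +-delta moves
            # demanded by a 10-cycle trajectory cannot run out of headroom
            rung = len(ladder) // 2
            sc_total = int(rng.integers(150, 211)) * n_ppc // 9
            sc_total = min(max(sc_total, sc_total_min + 10), sc_total_max - 10)

            cycle_acts: list[list[list[str]]] = []  # per cycle, per prompt
            cycle_sums: list[np.ndarray] = []

            def realize_activities(r: int) -> list[list[str]]:
                _, counts = ladder[r]
                acts = [labels[pref[i]] for i in range(len(counts))]
                return _deal_tokens(
                    list(zip(acts, counts)), tokens_per_prompt, rng
                )

            cycle_acts.append(realize_activities(rung))
            cycle_sums.append(
                _prompt_sums(sc_total, n_ppc, spec.symptom_noise_sd, rng)
            )

            for t, state in enumerate(states, start=1):
                h_dir, s_dir = _state_dirs(state)
                # entropy rung move
                dr = _DIR_STEP[h_dir]
                if dr == 0:
                    # reuse the previous multiset so the entropy ties exactly
                    prompts = _permute_same_capacity(
                        cycle_acts[-1], tokens_per_prompt, rng
                    )
                else:
                    rung_new = rung + dr
                    if not (0 <= rung_new < len(ladder)):
                        raise GenerationError(
                            f"participant {pid}: entropy forced past the "
                            f"ladder at cycle {t + 1} (rung {rung_new} of "
                            f"{len(ladder)})"
                        )
                    rung = rung_new
                    prompts = realize_activities(rung)
                cycle_acts.append(prompts)

                # symptom total move
                ds = _DIR_STEP[s_dir]
                if ds == 0:
                    sums = rng.permutation(cycle_sums[-1])
                else:
                    delta = int(rng.integers(3, 13))
                    if ds > 0:
                        delta = min(delta, sc_total_max - sc_total)
                    else:
                        delta = min(delta, sc_total - sc_total_min)
                    if delta < 1:
                        raise GenerationError(
                            f"participant {pid}: symptom total forced past "
                            f"its bounds at cycle {t + 1}"
                        )
                    sc_total += ds * delta
                    sums = _prompt_sums(
                        sc_total, n_ppc, spec.symptom_noise_sd, rng
                    )
                cycle_sums.append(sums)

            # missingness mask over all prompts
            n_days_used = n_cycles * 3
            if spec.block_missingness:
                day_missing = rng.random(n_days_used) < spec.missingness_rate
                missing = np.repeat(day_missing, spec.prompts_per_day)
            else:
                missing = (
                    rng.random(n_days_used * spec.prompts_per_day)
                    < spec.missingness_rate
                )

            # emit records
            k = 0
            for c in range(n_cycles):
                for j in range(n_ppc):
                    day = c * 3 + j // spec.prompts_per_day + 1
                    prompt = j % spec.prompts_per_day + 1
                    if missing[k]:
                        records.append(
                            EMARecord(pid, group, day, prompt, False)
                        )
                    else:
                        records.append(
                            EMARecord(
                                pid,
                                group,
                                day,
                                prompt,
                                True,
                                activities=frozenset(cycle_acts[c][j]),
                                symptom_items=_split_items(
                                    int(cycle_sums[c][j]), rng
                                ),
                            )
                        )
                    k += 1
    return records, trajectories


def _permute_same_capacity(
    prompts: list[list[str]],
    capacities: np.ndarray,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Shuffle prompt contents among prompts holding equal token counts,
    leaving the cycle's pooled activity multiset (hence its entropy) intact."""
    out = [None] * len(prompts)
    for cap in np.unique(capacities):
        idx = np.where(capacities == cap)[0]
        perm = rng.permutation(idx)
        for src, dst in zip(idx, perm):
            out[dst] = prompts[src]
    return [list(p) for p in out]


def write_cohort(
    records: Iterable[EMARecord],
    trajectories: Iterable[LatentTrajectory],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the cohort CSV (EMA schema) and the ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "cohort.csv"
    truth_path = out_dir / "ground_truth.json"
    write_ema(records, csv_path)
    truth = {
        tr.participant_id: {"group": tr.group, "states": list(tr.states)}
        for tr in trajectories
    }
    truth_path.write_text(json.dumps(truth, indent=1), encoding="utf-8")
    return csv_path, truth_path


# ---------------------------------------------------------------------------
# auxiliary synthetic tables for the statistical contracts

SITES = ("UTD", "Miami", "UCSD")
GENDERS = ("Men", "Women")
ETHNORACIAL = ("Asian", "Black", "Hispanic", "Other", "White")
EDUCATION = ("HS or less", "Some college", "College degree or higher")


def generate_covariates(
    trajectories: Sequence[LatentTrajectory], seed: int = 0
) -> "pd.DataFrame":
    """Demographic covariate table (site, age, gender, ethnoracial group,
    educational attainment) for the adjusted models, one row per
    participant."""
    import pandas as pd

    rng = np.random.default_rng([seed, 424243])
    rows = []
    for tr in trajectories:
        rows.append(
            {
                "participant_id": tr.participant_id,
                "group": tr.group,
                "site": SITES[int(rng.integers(len(SITES)))],
                "age": int(rng.integers(18, 66)),
                "gender": GENDERS[int(rng.integers(len(GENDERS)))],
                "ethnoracial": ETHNORACIAL[int(rng.integers(len(ETHNORACIAL)))],
                "education": EDUCATION[int(rng.integers(len(EDUCATION)))],
            }
        )
    return pd.DataFrame(rows)


def generate_interviewer_scores(
    participant_ids: Sequence[str],
    seed: int = 0,
    marker_values: "pd.Series | None" = None,
    log_effect: float = 0.0,
) -> "pd.DataFrame":
    """Interviewer-rated symptom scores (PANSS-style subscale totals).

    Scores are gamma-distributed around subscale-typical means: positive
    symptoms (range 7-49), reduced emotional experience (3-21), reduced
    emotional expression (4-28).  By default they are independent of the
    rhythmic markers (a null generator); passing ``marker_values`` and a
    nonzero ``log_effect`` injects a log-linear association with the
    standardized marker for power/recovery experiments.
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 550011])
    n = len(participant_ids)
    if marker_values is not None and log_effect != 0.0:
        z = np.asarray(marker_values, dtype=float)
        z = (z - z.mean()) / (z.std() or 1.0)
        shift = log_effect * z
    else:
        shift = np.zeros(n)
    out = {"participant_id": list(participant_ids)}
    for name, mean, lo, hi in (
        ("positive_symptoms", 15.0, 7, 49),
        ("emotional_experience", 6.0, 3, 21),
        ("emotional_expression", 6.0, 4, 28),
    ):
        shape = 8.0
        vals = rng.gamma(shape, mean * np.exp(shift) / shape, size=n)
        out[name] = np.clip(vals, lo, hi)
    return pd.DataFrame(out)
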