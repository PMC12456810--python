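"""Markov-chain rhythmic markers over the 9-state (ΔH, ΔSC) space.

Between consecutive valid cycles, the direction of change of cycle entropy H
and of the cycle symptom score SC — up (U), flat (F), or down (D) — is
combined into one of nine states:

    UU, UF, UD, FU, FF, FD, DU, DF, DD        (indices 1..9)

Per participant, transitions between successive states are counted in a 9x9
matrix; a pseudocount of 0.1 is added to every cell before row normalization
so the chain is strictly positive (hence irreducible and with finite hit
times).  From the smoothed matrix we derive the dynamic markers: expected
hit times (EHT) to each state from each start state, their per-target means
(MEHT), and the matrix entropy MH (sum of the row distributions' Shannon
entropies).  Group-level chains pool participants' counts and drive a
cumulative-sum inverse-CDF random walk whose occupancy approximates the
stationary distribution.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cycles import shannon_entropy

#: Ordered labels of the 9 joint (ΔH, ΔSC) states.
STATE_LABELS = ("UU", "UF", "UD", "FU", "FF", "FD", "DU", "DF", "DD")
N_STATES = 9

_DIRS = ("U", "F", "D")


class InsufficientDataError(ValueError):
    """Participant has too few valid cycles for the dynamic markers."""


def state_index(label: str) -> int:
    """1-based index of a state label in the canonical order."""
    return STATE_LABELS.index(label) + 1


def _direction(delta: float, tol: float) -> str:
    if delta > tol:
        return "U"
    if delta < -tol:
        return "D"
    return "F"


def classify_deltas(
    H_series: Sequence[float],
    SC_series: Sequence[float],
    flat_tol_H: float = 1e-9,
    flat_tol_SC: float = 1e-9,
) -> np.ndarray:
    """Map consecutive (ΔH, ΔSC) pairs to 1-based state indices.

    A change larger than the flat tolerance is U, smaller than its negative
    is D, otherwise F.  The default tolerances treat only (numerically)
    exact ties as flat.

    Raises
    ------
    InsufficientDataError
        With fewer than 3 aligned cycle values (fewer than 2 transitions'
        worth of states cannot support a chain).
    """
    H = np.asarray(H_series, dtype=float)
    SC = np.asarray(SC_series, dtype=float)
    if H.shape != SC.shape:
        raise ValueError("H and SC series must be aligned")
    if flat_tol_H < 0 or flat_tol_SC < 0:
        raise ValueError("flat tolerances must be nonnegative")
    if H.size < 3:
        raise InsufficientDataError(
            f"need >= 3 valid cycles to observe >= 2 states, got {H.size}"
        )
    states = []
    for t in range(1, H.size):
        h_dir = _direction(H[t] - H[t - 1], flat_tol_H)
        s_dir = _direction(SC[t] - SC[t - 1], flat_tol_SC)
        states.append(state_index(h_dir + s_dir))
    return np.asarray(states, dtype=int)


def count_transitions(states: Sequence[int], n_states: int = N_STATES) -> np.ndarray:
    """Count matrix of observed transitions; counts sum to len(states) - 1."""
    s = np.asarray(states, dtype=int)
    if s.size < 2:
        raise InsufficientDataError("need >= 2 states to count a transition")
    if s.min() < 1 or s.max() > n_states:
        raise ValueError(f"state indices must lie in 1..{n_states}")
    counts = np.zeros((n_states, n_states), dtype=int)
    np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1)
    return counts


def smooth_and_normalize(counts: np.ndarray, pseudo: float = 0.1) -> np.ndarray:
    """Add a pseudocount to every cell and row-normalize.

    P(i,j) = (counts(i,j) + pseudo) / sum_k (counts(i,k) + pseudo); the
    result is strictly positive with rows summing to 1, so every state is
    reachable and all hit times are finite.
    """
    if pseudo <= 0:
        raise ValueError("pseudo count must be positive")
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("counts must be a square matrix")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    sm = c + pseudo
    return sm / sm.sum(axis=1, keepdims=True)


def expected_hit_times(P: np.ndarray, target: int) -> np.ndarray:
    """Expected first-hit times to ``target`` (1-based) from every state.

    Solves h(i) = 1 + sum_{k != target} P(i,k) h(k) with h(target) = 0 as a
    dense linear system.  For strictly positive P the system is nonsingular
    and all entries are finite.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    j = target - 1
    keep = [i for i in range(n) if i != j]
    Q = P[np.ix_(keep, keep)]
    A = np.eye(n - 1) - Q
    h = np.linalg.solve(A, np.ones(n - 1))
    out = np.zeros(n)
    out[keep] = h
    return out


def hit_time_matrix(P: np.ndarray) -> np.ndarray:
    """EHT matrix: entry (i, j) is the expected steps from i to first hit j."""
    n = P.shape[0]
    eht = np.zeros((n, n))
    for j in range(1, n + 1):
        eht[:, j - 1] = expected_hit_times(P, j)
    return eht


def mean_hit_times(EHT: np.ndarray, include_self: bool = True) -> np.ndarray:
    """MEHT(j): mean over start states of the expected hit time to j.

    With ``include_self`` (default) the zero self-hit term enters the mean,
    i.e. MEHT(j) = mean_i EHT(i, j) over all 9 start states.
    """
    EHT = np.asarray(EHT, dtype=float)
    if include_self:
        return EHT.mean(axis=0)
    n = EHT.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return np.array([EHT[mask[:, j], j].mean() for j in range(n)])


def matrix_entropy(P: np.ndarray) -> float:
    """MH: sum over rows of the row distribution's Shannon entropy (bits)."""
    P = np.asarray(P, dtype=float)
    return float(sum(shannon_entropy(row) for row in P))


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary (leading left-eigenvector) distribution of the chain."""
    P = np.asarray(P, dtype=float)
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()


def inverse_cdf_state(row: Sequence[float], u: float) -> int:
    """State selected by cumulative-sum inverse sampling (1-based).

    The cumulative sum of the row distribution is scanned left to right and
    the first state whose cumulative value is >= u is returned, so intervals
    are closed on the right (u = 0.56 against cumsum (0.2, 0.6, 1.0) selects
    state 2; u exactly 0.2 selects state 1).
    """
    cum = np.cumsum(np.asarray(row, dtype=float))
    return int(np.searchsorted(cum, u, side="left")) + 1


def random_walk(
    P: np.ndarray,
    n_steps: int = 100_000,
    start: int = 1,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Simulate the cumulative-sum random walk and return occupancy.

    At each step a uniform number u in [0, 1] is drawn and the next state is
    the first whose cumulative row probability reaches u; the walk restarts
    each step from the row of the previously selected state.  Occupancy is
    the fraction of the ``n_steps`` selected states spent in each state;
    walk_entropy is the Shannon entropy (bits) of that occupancy
    distribution.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if not (1 <= start <= n):
        raise ValueError(f"start state must lie in 1..{n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cum = np.cumsum(P, axis=1)
    us = rng.random(n_steps)
    visits = np.zeros(n, dtype=np.int64)
    state = start - 1
    for t in range(n_steps):
        state = int(np.searchsorted(cum[state], us[t], side="left"))
        visits[state] += 1
    occupancy = visits / n_steps
    occ_nz = occupancy[occupancy > 0]
    walk_entropy = float(-(occ_nz * np.log2(occ_nz)).sum())
    return occupancy, walk_entropy


def sample_path(
    P: np.ndarray,
    n_steps: int,
    start: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sample a state path (1-based indices, excluding the start state)."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    P = np.asarray(P, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cum = np.cumsum(P, axis=1)
    us = rng.random(n_steps)
    path = np.empty(n_steps, dtype=int)
    state = start - 1
    for t in range(n_steps):
        state = int(np.searchsorted(cum[state], us[t], side="left"))
        path[t] = state + 1
    return path


@dataclass(frozen=True)
class TransitionModel:
    """Per-participant (or pooled) chain and its derived dynamic markers."""

    counts: np.ndarray
    P: np.ndarray
    EHT: np.ndarray
    MEHT: np.ndarray
    MH: float

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudo: float = 0.1,
        include_self_hit: bool = True,
    ) -> "TransitionModel":
        P = smooth_and_normalize(counts, pseudo)
        EHT = hit_time_matrix(P)
        return cls(
            counts=np.asarray(counts),
            P=P,
            EHT=EHT,
            MEHT=mean_hit_times(EHT, include_self_hit),
            MH=matrix_entropy(P),
        )

    @classmethod
    def from_states(
        cls,
        states: Sequence[int],
        pseudo: float = 0.1,
        include_self_hit: bool = True,
    ) -> "TransitionModel":
        return cls.from_counts(count_transitions(states), pseudo, include_self_hit)


@dataclass(frozen=True)
class GroupChain:
    """Pooled chain for one diagnostic group plus its random-walk summary."""

    group: str
    model: TransitionModel
    walk_occupancy: np.ndarray
    walk_entropy: float
    n_steps: int
    seed: int | None


def aggregate_group(
    counts_per_participant: Iterable[np.ndarray],
    pseudo: float = 0.1,
    mode: str = "pool_counts",
    include_self_hit: bool = True,
) -> TransitionModel:
    """Aggregate participants' chains into one group-level model.

    ``pool_counts`` (default) sums the raw count matrices elementwise and
    then smooths, weighting participants by their observed transitions.
    ``average_P`` instead averages the participants' smoothed matrices.
    """
    counts_list = [np.asarray(c) for c in counts_per_participant]
    if not counts_list:
        raise ValueError("cannot aggregate an empty group")
    if mode == "pool_counts":
        pooled = np.sum(counts_list, axis=0)
        return TransitionModel.from_counts(pooled, pseudo, include_self_hit)
    if mode == "average_P":
        Ps = [smooth_and_normalize(c, pseudo) for c in counts_list]
        P = np.mean(Ps, axis=0)
        EHT = hit_time_matrix(P)
        return TransitionModel(
            counts=np.sum(counts_list, axis=0),
            P=P,
            EHT=EHT,
            MEHT=mean_hit_times(EHT, include_self_hit),
            MH=matrix_entropy(P),
        )
    raise ValueError(f"unknown aggregation mode {mode!r}")
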