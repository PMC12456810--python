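"""Model/results interface over the marker pipeline.

``RhythmicMarkers`` is constructed from EMA records (or a CSV / DataFrame in
the EMA schema) plus a :class:`~rhythmdm.config.PipelineConfig`; ``fit()``
runs cycles → entropy → state classification → per-participant chains →
group aggregation and returns an :class:`RDMResults` carrying the cycle
table, the per-participant marker (RDM) table, the exclusion report, and
the pooled group chains.  The downstream statistical contracts and the
random-walk simulation hang off the results object.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cycles as cyc
from . import markov, stats
from .catalog import ActivityCatalog, load_default_catalog
from .config import PipelineConfig
from .ema import EMARecord, read_ema

_WALK_STREAM = 731001  # named substream tags for seed derivation
_SCORE_STREAM = 731002


@dataclass(frozen=True)
class ParticipantRDM:
    """Per-participant chain and static markers."""

    participant_id: str
    group: str
    n_valid_cycles: int
    mean_H: float
    mean_self_symptoms: float
    model: markov.TransitionModel


class RhythmicMarkers:
    """Rhythmic-marker model over a long-format EMA cohort."""

    def __init__(
        self,
        records: Sequence[EMARecord],
        config: PipelineConfig | None = None,
        catalog: ActivityCatalog | None = None,
    ):
        self.records = list(records)
        self.config = config or PipelineConfig()
        self.catalog = catalog or load_default_catalog()

    @classmethod
    def from_csv(
        cls,
        path,
        config: PipelineConfig | None = None,
        catalog: ActivityCatalog | None = None,
    ) -> "RhythmicMarkers":
        catalog = catalog or load_default_catalog()
        return cls(read_ema(path, catalog), config=config, catalog=catalog)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        config: PipelineConfig | None = None,
        catalog: ActivityCatalog | None = None,
    ) -> "RhythmicMarkers":
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        catalog = catalog or load_default_catalog()
        return cls(read_ema(buf, catalog), config=config, catalog=catalog)

    # -- fitting ----------------------------------------------------------

    def _participant_states(
        self, series: cyc.ParticipantSeries
    ) -> tuple[np.ndarray | None, str | None]:
        """State indices for one participant, or (None, reason) if excluded."""
        cfg = self.config
        vc = series.valid_cycles
        if len(vc) < cfg.min_valid_cycles:
            return None, (
                f"only {len(vc)} valid cycles "
                f"(need >= {cfg.min_valid_cycles})"
            )
        H = [c.H for c in vc]
        SC = [c.SC for c in vc]
        if cfg.delta_gap_mode == "skip":
            states = markov.classify_deltas(
                H, SC, cfg.flat_tol_H, cfg.flat_tol_SC
            )
            return states, None
        # strict mode: break the series at gaps in cycle index
        runs: list[list[cyc.Cycle]] = []
        for c in vc:
            if runs and c.cycle_index == runs[-1][-1].cycle_index + 1:
                runs[-1].append(c)
            else:
                runs.append([c])
        all_states: list[np.ndarray] = []
        for run in runs:
            if len(run) < 3:
                continue
            all_states.append(
                markov.classify_deltas(
                    [c.H for c in run],
                    [c.SC for c in run],
                    cfg.flat_tol_H,
                    cfg.flat_tol_SC,
                )
            )
        if not all_states or sum(len(s) for s in all_states) < 2:
            return None, "no gap-free run long enough for >= 2 states"
        return all_states, None

    def fit(self) -> "RDMResults":
        cfg = self.config
        series = cyc.build_participant_series(
            self.records,
            cycle_length_days=cfg.cycle_length_days,
            prompts_per_day=cfg.prompts_per_day,
            max_missing=cfg.max_missing_per_cycle,
            min_valid_cycles=cfg.min_valid_cycles,
            denominator=cfg.denominator,
        )
        cycle_table = cyc.cycles_table(series)
        participants: dict[str, ParticipantRDM] = {}
        exclusions: list[dict] = []
        for pid, ps in series.items():
            states, reason = self._participant_states(ps)
            if states is None:
                exclusions.append(
                    {
                        "participant_id": pid,
                        "group": ps.group,
                        "n_valid_cycles": len(ps.valid_cycles),
                        "reason": reason,
                    }
                )
                continue
            if isinstance(states, list):  # strict mode: counts per run
                counts = sum(
                    markov.count_transitions(s) for s in states if len(s) >= 2
                )
                tm = markov.TransitionModel.from_counts(
                    counts, cfg.pseudo_count, cfg.include_self_hit
                )
            else:
                tm = markov.TransitionModel.from_states(
                    states, cfg.pseudo_count, cfg.include_self_hit
                )
            vc = ps.valid_cycles
            participants[pid] = ParticipantRDM(
                participant_id=pid,
                group=ps.group,
                n_valid_cycles=len(vc),
                mean_H=float(np.mean([c.H for c in vc])),
                mean_self_symptoms=float(np.mean([c.SC for c in vc])),
                model=tm,
            )
        group_chains = self._aggregate_groups(participants)
        return RDMResults(
            model=self,
            series=series,
            cycle_table=cycle_table,
            participants=participants,
            exclusions=pd.DataFrame(
                exclusions,
                columns=["participant_id", "group", "n_valid_cycles", "reason"],
            ),
            group_chains=group_chains,
        )

    def _aggregate_groups(
        self, participants: Mapping[str, ParticipantRDM]
    ) -> dict[str, markov.GroupChain]:
        cfg = self.config
        by_group: dict[str, list[np.ndarray]] = {}
        for p in participants.values():
            by_group.setdefault(p.group, []).append(p.model.counts)
        chains: dict[str, markov.GroupChain] = {}
        for group in sorted(by_group):
            tm = markov.aggregate_group(
                by_group[group], cfg.pseudo_count, cfg.aggregation,
                cfg.include_self_hit,
            )
            rng = np.random.default_rng([cfg.seed, _WALK_STREAM, len(chains)])
            occ, went = markov.random_walk(
                tm.P, cfg.n_walk_steps, cfg.walk_start_state, rng
            )
            chains[group] = markov.GroupChain(
                group=group,
                model=tm,
                walk_occupancy=occ,
                walk_entropy=went,
                n_steps=cfg.n_walk_steps,
                seed=cfg.seed,
            )
        return chains


class RDMResults:
    """Fitted rhythmic markers: tables, chains, statistics, simulation."""

    def __init__(
        self,
        model: RhythmicMarkers,
        series: Mapping[str, cyc.ParticipantSeries],
        cycle_table: pd.DataFrame,
        participants: Mapping[str, ParticipantRDM],
        exclusions: pd.DataFrame,
        group_chains: Mapping[str, markov.GroupChain],
    ):
        self.model = model
        self.config = model.config
        self.series = dict(series)
        self.cycle_table = cycle_table
        self.participants = dict(participants)
        self.exclusions = exclusions
        self.group_chains = dict(group_chains)

    # -- tables -----------------------------------------------------------

    @property
    def rdm_table(self) -> pd.DataFrame:
        """Per-participant marker table: mean H, MH, and the nine MEHTs."""
        rows = []
        for p in self.participants.values():
            row = {
                "participant_id": p.participant_id,
                "group": p.group,
                "n_valid_cycles": p.n_valid_cycles,
                "mean_H": p.mean_H,
                "mean_self_symptoms": p.mean_self_symptoms,
                "MH": p.model.MH,
            }
            for j, s in enumerate(markov.STATE_LABELS):
                row[f"MEHT_{s}"] = float(p.model.MEHT[j])
            rows.append(row)
        return pd.DataFrame(rows)

    def decomposed_cycles(self) -> pd.DataFrame:
        """Valid cycles of included participants with the within/between H
        decomposition (person_mean_H, centered_H) attached."""
        included = set(self.participants)
        tab = self.cycle_table[
            self.cycle_table["participant_id"].isin(included)
        ]
        return cyc.person_H_decomposition(tab)

    # -- statistics -------------------------------------------------------

    def within_between(self, **kwargs):
        """Gamma mixed model of SC on person-mean and centered H."""
        return stats.fit_within_between_model(self.decomposed_cycles(), **kwargs)

    def symptom_associations(
        self, interviewer_scores: pd.DataFrame, covariates: pd.DataFrame, **kw
    ) -> list[stats.RegressionResult]:
        return stats.fit_rdm_symptom_models(
            self.rdm_table, interviewer_scores, covariates, **kw
        )

    def group_differences(
        self, covariates: pd.DataFrame, **kw
    ) -> list[stats.RegressionResult]:
        return stats.fit_group_differences(self.rdm_table, covariates, **kw)

    # -- simulation -------------------------------------------------------

    def simulate_walk(
        self,
        group: str,
        n_steps: int | None = None,
        seed: int | None = None,
    ) -> markov.GroupChain:
        """Re-run the cumulative-sum random walk for one group's chain."""
        chain = self.group_chains[group]
        n = n_steps or self.config.n_walk_steps
        rng = np.random.default_rng(
            [seed if seed is not None else self.config.seed, _WALK_STREAM]
        )
        occ, went = markov.random_walk(
            chain.model.P, n, self.config.walk_start_state, rng
        )
        return markov.GroupChain(
            group=group,
            model=chain.model,
            walk_occupancy=occ,
            walk_entropy=went,
            n_steps=n,
            seed=seed if seed is not None else self.config.seed,
        )

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of cohort accounting and group-level markers."""
        lines = []
        lines.append("Rhythmic digital markers — fit summary")
        lines.append("=" * 54)
        n_total = len(self.series)
        n_inc = len(self.participants)
        lines.append(
            f"Participants: {n_total} total, {n_inc} included, "
            f"{n_total - n_inc} excluded (< {self.config.min_valid_cycles} "
            "valid cycles)"
        )
        lines.append(
            f"Cycle: {self.config.cycle_length_days} days x "
            f"{self.config.prompts_per_day} prompts; valid with <= "
            f"{self.config.max_missing_per_cycle} of "
            f"{self.config.prompts_per_cycle} missing"
        )
        lines.append(f"Config hash: {self.config.config_hash()}  seed: {self.config.seed}")
        lines.append("")
        tab = self.rdm_table
        if len(tab):
            lines.append(
                f"{'group':<15}{'n':>5}{'mean H':>9}{'MH':>8}"
                f"{'walk H':>8}  MEHT range"
            )
            lines.append("-" * 54)
            for group, chain in self.group_chains.items():
                sub = tab[tab["group"] == group]
                meht = chain.model.MEHT
                lines.append(
                    f"{group:<15}{len(sub):>5}"
                    f"{sub['mean_H'].mean():>9.3f}"
                    f"{sub['MH'].mean():>8.2f}"
                    f"{chain.walk_entropy:>8.4f}"
                    f"  {meht.min():.2f}-{meht.max():.2f}"
                )
        return "\n".join(lines)

    def save(self, out_dir) -> dict[str, Path]:
        """Write cycle/RDM/exclusion tables (CSV) and group chains (JSON).

        Every file records the config hash and seed for provenance.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = {"config_hash": self.config.config_hash(), "seed": self.config.seed}
        paths: dict[str, Path] = {}

        def _csv(name: str, df: pd.DataFrame) -> None:
            p = out / f"{name}.csv"
            df2 = df.copy()
            for k, v in stamp.items():
                df2[k] = v
            df2.to_csv(p, index=False)
            paths[name] = p

        _csv("cycles", self.cycle_table)
        _csv("rdm", self.rdm_table)
        _csv("exclusions", self.exclusions)
        chains = {
            g: {
                "P": c.model.P.tolist(),
                "counts": np.asarray(c.model.counts).tolist(),
                "MEHT": c.model.MEHT.tolist(),
                "MH": c.model.MH,
                "walk_occupancy": c.walk_occupancy.tolist(),
                "walk_entropy": c.walk_entropy,
                "n_steps": c.n_steps,
                **stamp,
            }
            for g, c in self.group_chains.items()
        }
        p = out / "group_chains.json"
        p.write_text(json.dumps(chains, indent=1), encoding="utf-8")
        paths["group_chains"] = p
        return paths
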