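import numpy as np
import pytest
from hypothesis import settings

import rhythmdm as r

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return r.load_default_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """Three small groups with the example dynamics, mild missingness."""
    spec = r.default_cohort_spec(
        seed=42,
        missingness_rate=0.05,
        n_participants_per_group={
            "control": 10,
            "bipolar": 10,
            "schizophrenia": 10,
        },
    )
    records, trajectories = r.generate_cohort(spec)
    return spec, records, trajectories


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-missingness cohort: realized dynamics equal latent dynamics."""
    spec = r.default_cohort_spec(
        seed=7,
        missingness_rate=0.0,
        n_participants_per_group={"control": 8, "schizophrenia": 8},
    )
    records, trajectories = r.generate_cohort(spec)
    return spec, records, trajectories


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    _, records, _ = small_cohort
    cfg = r.PipelineConfig(seed=3, n_walk_steps=2000)
    return r.RhythmicMarkers(records, config=cfg).fit()


def make_answered(pid, group, day, prompt, activities=("Watching TV",), sums=(2, 2, 2, 2, 2)):
    return r.EMARecord(
        participant_id=pid,
        group=group,
        day=day,
        prompt=prompt,
        answered=True,
        activities=frozenset(activities),
        symptom_items=tuple(sums),
    )


def make_missing(pid, group, day, prompt):
    return r.EMARecord(
        participant_id=pid, group=group, day=day, prompt=prompt, answered=False
    )


@pytest.fixture
def simple_participant():
    """30 days x 3 prompts, single activity per prompt, fully answered."""
    recs = []
    for day in range(1, 31):
        for prompt in range(1, 4):
            act = "Watching TV" if (day + prompt) % 2 else "Preparing food"
            recs.append(
                make_answered("p1", "control", day, prompt, (act,), (1, 2, 1, 2, 1))
            )
    return recs
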