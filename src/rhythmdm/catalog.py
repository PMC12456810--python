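"""The 39-item activity catalog used by the EMA surveys.

Each EMA prompt asks which of 39 everyday activities the participant is
currently engaged in (multiple may be checked).  The canonical catalog ships
with the package as a plain-text fixture, one label per line, in fixed order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

#: Reserved label under which missing prompts are pooled when a cycle's
#: activity distribution is formed (missing observations are treated as one
#: distinct activity).
MISSING_LABEL = "__missing__"

N_ACTIVITIES = 39


@dataclass(frozen=True)
class ActivityCatalog:
    """Ordered collection of canonical activity labels.

    Parameters
    ----------
    labels : tuple of str
        Exactly 39 unique activity labels in canonical order.
    """

    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.labels) != N_ACTIVITIES:
            raise ValueError(
                f"activity catalog must have exactly {N_ACTIVITIES} labels, "
                f"got {len(self.labels)}"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("activity catalog labels must be unique")
        if MISSING_LABEL in self.labels:
            raise ValueError(f"{MISSING_LABEL!r} is reserved")

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def load_default_catalog() -> ActivityCatalog:
    """Load the packaged 39-activity catalog fixture."""
    text = resources.files("rhythmdm.data").joinpath("activities.txt").read_text(
        encoding="utf-8"
    )
    labels = tuple(line.strip() for line in text.splitlines() if line.strip())
    return ActivityCatalog(labels)
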