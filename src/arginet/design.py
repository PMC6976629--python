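"""Sample design: sample -> condition -> replicate bookkeeping.

The study design is a fully crossed layout of myeloid precursor cultures:
M-CSF alone or with RANKL, with arginine manipulated by recombinant
arginase (depletion), arginine-free medium (starvation) or re-addition
(rescue), four biological replicates per condition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidDesignError, UnknownConditionError

#: The seven culture conditions of the reference study.
STUDY_CONDITIONS = (
    "M-CSF",
    "RANKL",
    "RANKL/Arg-Depletion",
    "RANKL/Arg-Starvation",
    "RANKL/Arg-Rescue",
    "M-CSF/Arg-Starvation",
    "M-CSF/Arg-Rescue",
)

DEFAULT_REPLICATES = 4


@dataclass(frozen=True)
class SampleDesign:
    """Immutable sample sheet.

    ``table`` has columns ``sample_id``, ``condition``, ``replicate``;
    sample ids are unique and every condition carries at least two
    replicates.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "replicate"}
        if not required.issubset(self.table.columns):
            raise InvalidDesignError(
                f"design table needs columns {sorted(required)}"
            )
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise InvalidDesignError(f"duplicate sample ids: {sorted(set(dupes))}")
        counts = self.table.groupby("condition", sort=False).size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise InvalidDesignError(f"conditions with <2 replicates: {bad}")
        if (self.table["replicate"] < 1).any():
            raise InvalidDesignError("replicate indices must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        return list(dict.fromkeys(self.table["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        if condition not in set(self.table["condition"]):
            raise UnknownConditionError(f"condition {condition!r} not in design")
        sel = self.table["condition"] == condition
        return self.table.loc[sel, "sample_id"].tolist()

    def n_replicates(self, condition: str) -> int:
        return len(self.samples_for(condition))

    def __len__(self) -> int:
        return len(self.table)


def make_design(conditions: list[str], replicates: int = DEFAULT_REPLICATES) -> SampleDesign:
    """Build a balanced design with ``replicates`` samples per condition.

    Sample ids are ``<condition>_r<k>`` with ``/`` and spaces replaced so
    the ids stay filesystem- and TSV-header-safe.
    """
    if replicates < 2:
        raise InvalidDesignError("need at least 2 replicates per condition")
    if not conditions:
        raise InvalidDesignError("condition list is empty")
    if len(set(conditions)) != len(conditions):
        raise InvalidDesignError("condition labels must be distinct")
    rows = []
    for cond in conditions:
        safe = cond.replace("/", ".").replace(" ", "_")
        for r in range(1, replicates + 1):
            rows.append({"sample_id": f"{safe}_r{r}", "condition": cond, "replicate": r})
    return SampleDesign(pd.DataFrame(rows))
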