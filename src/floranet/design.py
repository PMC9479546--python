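"""Sample sheet handling for the two-sex staged floral design.

A study profiles male and female flower buds at successive differentiation
stages (by default M1..M4 and F1..F4) with replicated libraries per stage.
Samples are named ``<stage>_<replicate>`` (M1_1, M1_2, ..., F4_3).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

DEFAULT_STAGES: tuple[str, ...] = ("M1", "M2", "M3", "M4", "F1", "F2", "F3", "F4")

_STAGE_RE = re.compile(r"^([MF])(\d+)$")


class DesignError(ValueError):
    """Raised for malformed or inconsistent sample sheets."""


@dataclass
class SampleDesign:
    """Mapping of sample ids to stage, replicate and sex.

    Parameters
    ----------
    table:
        DataFrame with columns ``sample_id``, ``stage``, ``replicate``.
        A ``sex`` column ('M' or 'F') is derived from the stage prefix.
    allowed_stages:
        Stage labels accepted by validation; defaults to M1..M4, F1..F4.
    """

    table: pd.DataFrame
    allowed_stages: tuple[str, ...] = field(default=DEFAULT_STAGES)

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"sample_id", "stage", "replicate"}
        missing = required - set(t.columns)
        if missing:
            raise DesignError(f"sample sheet missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate sample ids: {dupes}")
        bad = [s for s in t["stage"] if s not in self.allowed_stages]
        if bad:
            raise DesignError(
                f"unknown stage label(s) {sorted(set(bad))}; "
                f"allowed labels are {list(self.allowed_stages)}"
            )
        t["replicate"] = t["replicate"].astype(int)
        t["sex"] = [_STAGE_RE.match(s).group(1) for s in t["stage"]]
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_sample_ids(cls, sample_ids, allowed_stages=DEFAULT_STAGES) -> "SampleDesign":
        """Parse ``<stage>_<replicate>`` sample names into a design."""
        rows = []
        for sid in sample_ids:
            stage, _, rep = str(sid).rpartition("_")
            if not stage or not rep.isdigit():
                raise DesignError(f"cannot parse sample id {sid!r} as <stage>_<replicate>")
            rows.append({"sample_id": sid, "stage": stage, "replicate": int(rep)})
        return cls(pd.DataFrame(rows), allowed_stages=allowed_stages)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def stages(self) -> list[str]:
        """Stages in first-appearance order."""
        return list(dict.fromkeys(self.table["stage"]))

    def samples_of(self, stage: str) -> list[str]:
        if stage not in set(self.table["stage"]):
            raise DesignError(f"stage {stage!r} absent from design")
        return self.table.loc[self.table["stage"] == stage, "sample_id"].tolist()

    def stage_of(self, sample_id: str) -> str:
        hit = self.table.loc[self.table["sample_id"] == sample_id, "stage"]
        if hit.empty:
            raise DesignError(f"sample {sample_id!r} absent from design")
        return hit.iloc[0]

    def require_replicates(self, minimum: int = 2) -> None:
        counts = self.table.groupby("stage").size()
        thin = counts[counts < minimum]
        if not thin.empty:
            raise DesignError(
                f"stages with fewer than {minimum} replicates: {thin.to_dict()}"
            )

    def cross_validate_samples(self, sample_ids) -> None:
        """Fail if the design references samples absent from a data matrix."""
        missing = set(self.sample_ids) - set(sample_ids)
        if missing:
            raise DesignError(f"design references samples absent from data: {sorted(missing)}")
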