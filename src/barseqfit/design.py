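"""Experiment design: which samples are Time0 controls and which are conditions."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .config import ValidationError

DESIGN_COLUMNS = ["sample", "role", "time0_group", "condition", "replicate"]


class ExperimentDesign:
    """Assignment of BarSeq samples to Time0 groups and growth conditions.

    Each row describes one sequenced sample: its id, its role (``Time0`` for
    the pre-selection control aliquot, ``condition`` for a post-selection
    sample), the Time0 group it belongs to (condition samples are compared
    against the summed Time0 samples of their group), the condition name and
    a replicate index.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"design table missing required column(s): {missing}")
        frame = frame[DESIGN_COLUMNS].reset_index(drop=True)
        if frame["sample"].duplicated().any():
            dup = frame.loc[frame["sample"].duplicated(), "sample"].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        bad_role = ~frame["role"].isin(["Time0", "condition"])
        if bad_role.any():
            raise ValidationError(
                f"sample {frame.loc[bad_role, 'sample'].iloc[0]!r}: role must be "
                "'Time0' or 'condition'"
            )
        t0_groups = set(frame.loc[frame["role"] == "Time0", "time0_group"])
        for _, row in frame[frame["role"] == "condition"].iterrows():
            if row["time0_group"] not in t0_groups:
                raise ValidationError(
                    f"condition sample {row['sample']!r} has Time0 group "
                    f"{row['time0_group']!r} with no Time0 sample"
                )
        self.frame = frame

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample"])

    @property
    def condition_samples(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "condition"]

    @property
    def time0_samples(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "Time0"]

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.condition_samples["condition"]))

    def time0_of_group(self, group: str) -> list[str]:
        t0 = self.frame[(self.frame["role"] == "Time0") & (self.frame["time0_group"] == group)]
        return list(t0["sample"])

    @classmethod
    def build(
        cls,
        conditions: Sequence[str],
        n_time0: int = 3,
        replicates: int = 1,
        time0_group: str = "T0set1",
        extra_time0_groups: Iterable[tuple[str, int]] = (),
    ) -> "ExperimentDesign":
        """Convenience constructor: one primary Time0 group plus condition
        replicates, optionally extra Time0-only groups (useful for null
        comparisons)."""
        rows = []
        for i in range(n_time0):
            rows.append((f"{time0_group}.T0r{i + 1}", "Time0", time0_group, "Time0", i + 1))
        for group, n in extra_time0_groups:
            for i in range(n):
                rows.append((f"{group}.T0r{i + 1}", "Time0", group, "Time0", i + 1))
        for cond in conditions:
            for r in range(replicates):
                rows.append((f"{cond}.r{r + 1}", "condition", time0_group, cond, r + 1))
        return cls(pd.DataFrame(rows, columns=DESIGN_COLUMNS))
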