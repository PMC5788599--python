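"""Paired replicate designs for label-free LC-MS/MS experiments.

A study design is a set of runs, each labelled with a condition
(``control`` or ``treated``), a biological replicate index and a
technical replicate index.  The designs handled here are *completely
paired*: every (biological, technical) replicate slot that was measured
under one condition was also measured under the other, so a paired test
can match run ``treated_b1_t3`` with run ``control_b1_t3``.  The default
study shape is 2 biological x 5 technical replicates per condition
(20 runs in total, ten abundance measurements per condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CONTROL = "control"
TREATED = "treated"
CONDITIONS = (CONTROL, TREATED)

#: Columns every design table must carry.
DESIGN_COLUMNS = ["run_id", "condition", "bio_rep", "tech_rep"]


@dataclass(frozen=True)
class SampleDesign:
    """A completely paired two-condition run layout.

    Parameters
    ----------
    runs : pandas.DataFrame
        One row per LC-MS/MS run with columns ``run_id``, ``condition``,
        ``bio_rep`` and ``tech_rep``.
    label : str
        Free-text label for the sample (e.g. a cell-line name).
    """

    runs: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        validate_design(self.runs)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def run_ids(self) -> list[str]:
        return list(self.runs["run_id"])

    def runs_for(self, condition: str) -> pd.DataFrame:
        """Runs of one condition, ordered by (bio_rep, tech_rep).

        The ordering defines the pairing used by the paired t-test: the
        i-th control run is the partner of the i-th treated run.
        """
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        sub = self.runs[self.runs["condition"] == condition]
        return sub.sort_values(["bio_rep", "tech_rep"], kind="mergesort")

    def paired_run_ids(self) -> tuple[list[str], list[str]]:
        """(control run ids, treated run ids) aligned by replicate slot."""
        return (
            list(self.runs_for(CONTROL)["run_id"]),
            list(self.runs_for(TREATED)["run_id"]),
        )


def validate_design(runs: pd.DataFrame) -> None:
    """Check design invariants; raise ``ValueError`` on violation.

    Enforced invariants: required columns present, run identifiers
    unique, conditions restricted to {control, treated}, and complete
    pairing (every (bio, tech) slot appears under both conditions
    exactly once).
    """
    missing = [c for c in DESIGN_COLUMNS if c not in runs.columns]
    if missing:
        raise ValueError(f"design table lacks columns: {missing}")
    if runs["run_id"].duplicated().any():
        dupes = sorted(runs.loc[runs["run_id"].duplicated(), "run_id"])
        raise ValueError(f"duplicate run identifiers: {dupes}")
    bad = set(runs["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions in design: {sorted(bad)}")
    slots = runs.pivot_table(
        index=["bio_rep", "tech_rep"], columns="condition",
        values="run_id", aggfunc="count", fill_value=0,
    )
    for cond in CONDITIONS:
        if cond not in slots.columns:
            slots[cond] = 0
    unpaired = slots[(slots[CONTROL] != 1) | (slots[TREATED] != 1)]
    if len(unpaired):
        raise ValueError(
            "design is not completely paired; offending (bio_rep, tech_rep) "
            f"slots: {list(unpaired.index)}"
        )


def generate_design(n_bio: int, n_tech: int, label: str = "") -> SampleDesign:
    """Build the standard paired design: 2 conditions x n_bio x n_tech runs.

    Deterministic; run identifiers are ``{condition}_b{bio}_t{tech}``.

    Raises
    ------
    ValueError
        If ``n_bio`` or ``n_tech`` is not a positive integer.
    """
    if n_bio < 1 or n_tech < 1:
        raise ValueError("n_bio and n_tech must be >= 1")
    rows = [
        {
            "run_id": f"{cond}_b{b}_t{t}",
            "condition": cond,
            "bio_rep": b,
            "tech_rep": t,
        }
        for cond in CONDITIONS
        for b in range(1, int(n_bio) + 1)
        for t in range(1, int(n_tech) + 1)
    ]
    return SampleDesign(runs=pd.DataFrame(rows), label=label)
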