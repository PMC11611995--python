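"""Scoring and summaries for the six-task praxis battery.

The battery follows the Birmingham Cognitive Screen praxis tasks: gesture
production, meaningless gesture imitation, gesture recognition, single- and
multi-object use, and complex figure copy.  Raw item scores are standardised
to percent of the task maximum; two independent coders are averaged; a
patient is classified as impaired on a task when their percent score falls
strictly below the task's normative cut-off.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

TASK_COLUMNS = [
    "meaningless",
    "production",
    "recognition",
    "single_object",
    "multi_object",
    "figure_copy",
]


@dataclass(frozen=True)
class TaskDefinition:
    """One praxis task: item structure, maximum raw score, cut-off.

    Production and the object-use tasks score each gesture on a 0/1/2
    Likert scale; recognition is scored 0/1 per item.  Note the battery
    description calls the 20-point task "meaningless gesture recognition"
    in one place; it is the meaningless gesture *imitation* task (the
    recognition task is the 6-point one) and is treated as such here.
    """

    name: str
    n_items: int
    max_points_per_item: int
    max_total: int
    cutoff_percent: float

    def __post_init__(self) -> None:
        if self.max_total <= 0:
            raise ValueError(f"{self.name}: max_total must be positive")
        if not 0 < self.cutoff_percent < 100:
            raise ValueError(f"{self.name}: cutoff must be in (0, 100)")


PRAXIS_TASKS: dict[str, TaskDefinition] = {
    "meaningless": TaskDefinition("meaningless", 10, 2, 20, 75.0),
    "production": TaskDefinition("production", 6, 2, 12, 75.0),
    "recognition": TaskDefinition("recognition", 6, 1, 6, 83.0),
    "single_object": TaskDefinition("single_object", 6, 2, 12, 85.0),
    "multi_object": TaskDefinition("multi_object", 6, 2, 12, 85.0),
    "figure_copy": TaskDefinition("figure_copy", 47, 1, 47, 83.0),
}


@dataclass(frozen=True)
class RaterSheet:
    """One coder's item-level scores for one patient on one task."""

    patient: str
    task: str
    item_scores: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_scores", tuple(self.item_scores))


def score_task(sheet: RaterSheet, task: TaskDefinition) -> float:
    """Percent score: 100 * (sum of item scores) / task maximum."""
    if sheet.task != task.name:
        raise ValueError(
            f"sheet is for task {sheet.task!r}, definition is {task.name!r}"
        )
    if len(sheet.item_scores) != task.n_items:
        raise ValueError(
            f"patient {sheet.patient}, task {task.name}: expected "
            f"{task.n_items} items, got {len(sheet.item_scores)}"
        )
    for i, s in enumerate(sheet.item_scores):
        if not 0 <= s <= task.max_points_per_item:
            raise ValueError(
                f"patient {sheet.patient}, task {task.name}, item {i + 1}: "
                f"score {s} outside 0..{task.max_points_per_item}"
            )
    return 100.0 * sum(sheet.item_scores) / task.max_total


def average_coders(
    sheet_a: RaterSheet, sheet_b: RaterSheet, task: TaskDefinition
) -> float:
    """Final task score: mean of the two coders' percent scores."""
    if (sheet_a.patient, sheet_a.task) != (sheet_b.patient, sheet_b.task):
        raise ValueError(
            f"coder sheets disagree: {sheet_a.patient}/{sheet_a.task} vs "
            f"{sheet_b.patient}/{sheet_b.task}"
        )
    return 0.5 * (score_task(sheet_a, task) + score_task(sheet_b, task))


def cohens_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa for two coders' categorical codes.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement from the coders' marginal products.  Returns
    1.0 in the degenerate perfect-agreement case p_e = 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.size != b.size:
        raise ValueError("label sequences must be non-empty and equal length")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = np.mean(a == b)
    p_e = sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def zscore_column(scores) -> np.ndarray:
    """Standard scores with the sample (n-1) standard deviation."""
    x = np.asarray(scores, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("zscore needs at least 2 distinct values")
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd


def correlation_matrix(
    table: pd.DataFrame, tasks: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlations between task columns.

    Constant columns yield missing (NaN) entries rather than zeros.
    """
    tasks = list(tasks) if tasks is not None else TASK_COLUMNS
    if len(table) < 3:
        raise ValueError("correlation matrix needs at least 3 patients")
    return table[tasks].corr(method="pearson")


def below_cutoff_count(
    scores, cutoff: float, patient_ids=None
) -> tuple[int, list[str]]:
    """Patients scoring strictly below the cut-off (score == cutoff passes)."""
    if not 0 < cutoff < 100:
        raise ValueError(f"cutoff must be in (0, 100), got {cutoff}")
    x = np.asarray(scores, dtype=float)
    if patient_ids is None:
        patient_ids = [str(i) for i in range(x.size)]
    below = x < cutoff
    return int(below.sum()), [p for p, b in zip(patient_ids, below) if b]


def load_reference_table() -> pd.DataFrame:
    """The packaged 29-patient behavioural fixture (percent scores and
    demographics as printed in the source study's tables).

    Note the printed group summaries do not all recompute exactly from the
    rounded per-patient percentages: the multi-object below-cut-off count
    recomputes to 7 (5 printed) and the gender tally to 19 M / 10 F
    (18/11 printed).  The per-patient values here are the printed ones.
    """
    ref = importlib.resources.files("praxmap.data") / "table2_behaviour.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def summarise_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-task mean, sample SD, cut-off and below-cut-off count."""
    rows = []
    for task in TASK_COLUMNS:
        cutoff = PRAXIS_TASKS[task].cutoff_percent
        n_below, who = below_cutoff_count(
            table[task], cutoff, table["patient_id"].tolist()
        )
        rows.append(
            {
                "task": task,
                "mean": table[task].mean(),
                "sd": table[task].std(ddof=1),
                "cutoff": cutoff,
                "n_below_cutoff": n_below,
                "below_cutoff_patients": ",".join(who),
            }
        )
    return pd.DataFrame(rows).set_index("task")
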