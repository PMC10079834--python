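"""Record-level quality control for chamber deployments.

Deployments are removed when the closure duration falls outside the
plausible window (chamber malfunction), when any recorded mole fraction is
negative (instrument malfunction), or when cavity temperature/pressure
readings fall outside the analyzer's plausible operating range.  A removal
is attributed to the first failing rule in that order; all gases of a
deployment are dropped together because a single analyzer serves them all.
Both-model-high-uncertainty rejections from flux fitting are merged into
the summary as their own row, so the overall removed fraction can be read
with or without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fluxfit import Deployment

RULE_DURATION = "duration_out_of_range"
RULE_NEGATIVE = "negative_concentration"
RULE_CAVITY = "cavity_out_of_range"
RULE_UNCERTAIN = "both_models_high_uncertainty"


@dataclass
class QCRules:
    """Thresholds for the record-level filters.

    Defaults: 9-11 min closures; cavity temperature 30-50 degC (303.15 to
    323.15 K) and pressure 15-25 kPa around a reduced-pressure cavity set
    point.  All ranges are configurable because 'erroneous' has no
    universal bounds.
    """

    min_duration_s: float = 540.0
    max_duration_s: float = 660.0
    cavity_temp_range_k: Tuple[float, float] = (303.15, 323.15)
    cavity_press_range_kpa: Tuple[float, float] = (15.0, 25.0)

    def __post_init__(self) -> None:
        if self.min_duration_s >= self.max_duration_s:
            raise ValueError("min duration must be < max duration")
        for lo, hi in (self.cavity_temp_range_k, self.cavity_press_range_kpa):
            if lo >= hi:
                raise ValueError("range bounds must satisfy min < max")


@dataclass
class QCSummary:
    n_input: int = 0
    n_removed_by_rule: dict = field(default_factory=dict)
    n_output: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.n_removed_by_rule.values())

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "n_removed": n} for rule, n in self.n_removed_by_rule.items()
        ]
        rows.append({"rule": "TOTAL", "n_removed": self.n_removed})
        df = pd.DataFrame(rows)
        df["n_input"] = self.n_input
        df["fraction_of_input"] = df["n_removed"] / self.n_input if self.n_input else 0.0
        return df


def _first_failing_rule(group: Sequence[Deployment], rules: QCRules) -> Optional[str]:
    dur = max(d.duration_s for d in group)
    if not (rules.min_duration_s <= dur <= rules.max_duration_s):
        return RULE_DURATION
    for d in group:
        if np.any(d.mole_fraction_ppm < 0) or not np.all(
            np.isfinite(d.mole_fraction_ppm)
        ):
            return RULE_NEGATIVE
    tlo, thi = rules.cavity_temp_range_k
    plo, phi = rules.cavity_press_range_kpa
    for d in group:
        if np.any((d.cavity_temp_k < tlo) | (d.cavity_temp_k > thi)):
            return RULE_CAVITY
        if np.any((d.cavity_press_kpa < plo) | (d.cavity_press_kpa > phi)):
            return RULE_CAVITY
    return None


def filter_deployments(
    deployments: Iterable[Deployment],
    rules: Optional[QCRules] = None,
    rejected_by_fitting: Optional[Sequence] = None,
) -> Tuple[List[Deployment], QCSummary]:
    """Apply the record-level filters.

    Returns the kept deployments (all gas traces of surviving deployment
    ids) and a summary attributing each removed deployment id to the first
    rule it failed.  ``rejected_by_fitting`` takes the (deployment_id, gas)
    rejections emitted by model selection so that both accountings appear
    in one report; those are counted as measurement periods, not
    re-filtered here.
    """
    rules = rules or QCRules()
    deployments = list(deployments)
    # group gas traces by deployment id: one analyzer, one verdict
    by_id: dict = {}
    order: List[str] = []
    for d in deployments:
        if d.deployment_id not in by_id:
            order.append(d.deployment_id)
        by_id.setdefault(d.deployment_id, []).append(d)

    summary = QCSummary(n_input=len(order))
    counts = {RULE_DURATION: 0, RULE_NEGATIVE: 0, RULE_CAVITY: 0}
    kept: List[Deployment] = []
    for dep_id in order:
        group = by_id[dep_id]
        rule = _first_failing_rule(group, rules)
        if rule is None:
            kept.extend(group)
        else:
            counts[rule] += 1
    summary.n_removed_by_rule = counts
    if rejected_by_fitting is not None:
        uncertain_ids = {r[0] if isinstance(r, tuple) else r for r in rejected_by_fitting}
        summary.n_removed_by_rule[RULE_UNCERTAIN] = len(uncertain_ids)
    summary.n_output = summary.n_input - summary.n_removed
    return kept, summary


def summarize_qc(summary: QCSummary) -> pd.DataFrame:
    """Machine-readable per-rule report (also suitable for logging)."""
    return summary.to_frame()
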