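"""Sequential trial-exclusion rules and retention reporting.

Rules are applied in a fixed order, each trial attributed to the first
rule that removes it: (1) the first trials of the first block (prone to
learning effects); (2) trials either player answered incorrectly; (3)
communicator reaction times over 8 s; (4) per-subject interquartile-range
outliers on the main kinematic parameters; (5) trials without a valid
detected movement (segmentation flags).  Quartiles use the linear
interpolation convention between order statistics — the rule is
convention-sensitive, so the convention is recorded in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SCREENED = ("rtc_ms", "mtf_ms", "ht_ms", "mtb_ms", "tl_cm", "pv_cms")

RULES = ("first_trials", "errors", "reaction_time", "iqr_outlier", "invalid_movement")


@dataclass(frozen=True)
class ExclusionConfig:
    drop_first_trials: int = 2  # first block only
    rt_max_s: float = 8.0
    iqr_multiplier: float = 3.0
    screened_parameters: tuple[str, ...] = DEFAULT_SCREENED
    require_correct: bool = True

    def __post_init__(self) -> None:
        if self.rt_max_s <= 0:
            raise ValueError("rt_max_s must be positive")
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be positive")


@dataclass
class ExclusionReport:
    n_total: int
    counts: dict[str, int]
    retained_ids: list
    per_condition_retention: dict[str, dict[str, float]] = field(default_factory=dict)
    quartile_convention: str = "linear interpolation between order statistics"

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    @property
    def retention_pct(self) -> float:
        return 100.0 * self.n_retained / self.n_total

    def percentages(self) -> dict[str, float]:
        return {k: 100.0 * v / self.n_total for k, v in self.counts.items()}

    def to_json(self, path=None) -> str:
        payload = {
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "retention_pct": self.retention_pct,
            "excluded_counts": self.counts,
            "excluded_pct": self.percentages(),
            "per_condition_retention_pct": self.per_condition_retention,
            "quartile_convention": self.quartile_convention,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def log_lines(self) -> list[str]:
        lines = [f"exclusion: {self.n_total} trials in"]
        for rule in RULES:
            n = self.counts.get(rule, 0)
            lines.append(f"  {rule}: {n} excluded ({100.0 * n / self.n_total:.1f}%)")
        lines.append(
            f"  retained: {self.n_retained} ({self.retention_pct:.1f}%)"
        )
        return lines


def apply_exclusions(
    trials: pd.DataFrame,
    cfg: ExclusionConfig = ExclusionConfig(),
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion rules to a trial table.

    ``trials`` needs one row per trial with columns ``subject``, ``block``,
    ``trial_in_block`` (or ``trial_index``), ``communicator_correct``,
    ``addressee_correct``, ``valid_movement``, and the screened kinematic
    parameter columns.  Returns the retained rows (original order) and an
    :class:`ExclusionReport`.
    """
    unknown = [p for p in cfg.screened_parameters if p not in trials.columns]
    if unknown:
        raise ValueError(f"unknown screened parameter(s): {unknown}")
    df = trials.reset_index(drop=True)
    excluded_by = pd.Series(index=df.index, dtype=object)

    def mark(mask: pd.Series, rule: str) -> None:
        fresh = mask & excluded_by.isna()
        excluded_by[fresh] = rule

    # 1. first trials of the first block, per subject
    first_block = df["block"] == df.groupby("subject")["block"].transform("min")
    order_col = "trial_in_block" if "trial_in_block" in df.columns else "trial_index"
    mark(first_block & (df[order_col] < cfg.drop_first_trials), "first_trials")

    # 2. communication errors (either player wrong)
    if cfg.require_correct:
        mark(
            ~(df["communicator_correct"].astype(bool) & df["addressee_correct"].astype(bool)),
            "errors",
        )

    # 3. excessive communicator reaction time
    mark(df["rtc_ms"] > cfg.rt_max_s * 1e3, "reaction_time")

    # 4. per-subject IQR outlier screen on each screened parameter,
    #    quartiles computed over that subject's still-surviving trials
    surviving = excluded_by.isna()
    outlier = pd.Series(False, index=df.index)
    for _, idx in df[surviving].groupby("subject").groups.items():
        sub = df.loc[idx]
        for param in cfg.screened_parameters:
            vals = sub[param].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size < 4:
                continue
            q1, q3 = np.percentile(finite, [25, 75], method="linear")
            iqr = q3 - q1
            lo, hi = q1 - cfg.iqr_multiplier * iqr, q3 + cfg.iqr_multiplier * iqr
            bad = (sub[param] < lo) | (sub[param] > hi)
            outlier.loc[idx[bad.to_numpy()]] = True
    mark(outlier, "iqr_outlier")

    # 5. invalid movements flagged by segmentation
    mark(~df["valid_movement"].astype(bool), "invalid_movement")

    retained = df[excluded_by.isna()]
    counts = {rule: int((excluded_by == rule).sum()) for rule in RULES}

    per_condition = {}
    for factor in ("action", "addressee", "sign"):
        if factor in df.columns:
            total = df.groupby(factor).size()
            kept = retained.groupby(factor).size().reindex(total.index, fill_value=0)
            per_condition[factor] = (100.0 * kept / total).round(3).to_dict()

    id_col = "trial_id" if "trial_id" in df.columns else None
    retained_ids = retained[id_col].tolist() if id_col else retained.index.tolist()
    report = ExclusionReport(
        n_total=len(df),
        counts=counts,
        retained_ids=retained_ids,
        per_condition_retention=per_condition,
    )
    return retained, report
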