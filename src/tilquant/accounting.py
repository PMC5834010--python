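"""Cohort accounting: patients and samples through the analytic stages.

Tracks the flow from the trial's primary-analysis population through the
baseline density analysis (patients with a digitised pre-treatment slide
and outcome data) to the matched pre/post change analysis, with pCR counts
at each stage and exclusion reasons where known.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .errors import ValidationError


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


@dataclass
class CohortFlow:
    """Stage counts of the analytic flow."""

    n_primary_analysis: int
    n_baseline_included: int
    n_matched_pre_post: int
    n_pcr_primary: int
    n_pcr_baseline: int
    n_pcr_matched: int
    exclusion_reasons: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def validate(self) -> "CohortFlow":
        if not (self.n_matched_pre_post <= self.n_baseline_included <= self.n_primary_analysis):
            raise ValidationError(
                "stage counts must be nested: matched <= baseline <= primary"
            )
        for n_pcr, denom, name in (
            (self.n_pcr_primary, self.n_primary_analysis, "primary"),
            (self.n_pcr_baseline, self.n_baseline_included, "baseline"),
            (self.n_pcr_matched, self.n_matched_pre_post, "matched"),
        ):
            if not (0 <= n_pcr <= denom):
                raise ValidationError(f"pCR count exceeds the {name} denominator")
        expected = {
            "baseline": self.n_primary_analysis - self.n_baseline_included,
            "matched": self.n_baseline_included - self.n_matched_pre_post,
        }
        for stage, reasons in self.exclusion_reasons.items():
            total = sum(reasons.values())
            if stage in expected and total != expected[stage]:
                raise ValidationError(
                    f"exclusions at stage {stage!r} sum to {total}, "
                    f"expected {expected[stage]}"
                )
        return self

    def percentages(self) -> dict[str, int]:
        """Integer percentages as printed in trial flow reports.

        Inclusion rates use the primary-analysis n as denominator; pCR
        rates use their own stage n.
        """
        def pct(num: int, den: int) -> int:
            return round_half_away(100.0 * num / den) if den else 0

        return {
            "baseline_included_pct": pct(self.n_baseline_included, self.n_primary_analysis),
            "matched_pre_post_pct": pct(self.n_matched_pre_post, self.n_primary_analysis),
            "pcr_primary_pct": pct(self.n_pcr_primary, self.n_primary_analysis),
            "pcr_baseline_pct": pct(self.n_pcr_baseline, self.n_baseline_included),
            "pcr_matched_pct": pct(self.n_pcr_matched, self.n_matched_pre_post),
        }

    def to_frame(self) -> pd.DataFrame:
        pcts = self.percentages()
        rows = [
            ("primary analysis", self.n_primary_analysis, 100, self.n_pcr_primary,
             pcts["pcr_primary_pct"]),
            ("baseline density analysis", self.n_baseline_included,
             pcts["baseline_included_pct"], self.n_pcr_baseline, pcts["pcr_baseline_pct"]),
            ("matched pre/post analysis", self.n_matched_pre_post,
             pcts["matched_pre_post_pct"], self.n_pcr_matched, pcts["pcr_matched_pct"]),
        ]
        return pd.DataFrame(rows, columns=["stage", "n", "pct_of_primary",
                                           "n_pcr", "pcr_pct"])


def cohort_accounting(records: pd.DataFrame,
                      exclusion_reasons: Optional[Mapping] = None) -> CohortFlow:
    """Derive the analytic flow from per-patient availability flags.

    ``records`` must carry boolean columns has_baseline_slide and
    has_post_slide plus the binary pcr outcome.  A patient enters the
    change analysis only if they are in the baseline analysis.
    """
    for col in ("pcr", "has_baseline_slide", "has_post_slide"):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
    base = records["has_baseline_slide"].astype(bool)
    post = records["has_post_slide"].astype(bool)
    if (post & ~base).any():
        raise ValidationError("patients with a matched post slide but no baseline slide")
    matched = base & post
    flow = CohortFlow(
        n_primary_analysis=len(records),
        n_baseline_included=int(base.sum()),
        n_matched_pre_post=int(matched.sum()),
        n_pcr_primary=int(records["pcr"].sum()),
        n_pcr_baseline=int(records.loc[base, "pcr"].sum()),
        n_pcr_matched=int(records.loc[matched, "pcr"].sum()),
        exclusion_reasons=dict(exclusion_reasons or {}),
    )
    return flow.validate()
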