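"""Published regional OEF group summaries shipped as a worked example.

A two-group study of regional oxygen extraction fraction — 15 patients with
obstructive sleep apnea versus 16 healthy controls — reported per-region
OEF means and standard deviations (in percent) along with pooled-SD Cohen's
d effect sizes.  Those printed summaries are bundled here so the effect-size
layer has a real worked example: recomputing d from (mean, SD, n) should
reproduce the printed value.

For three of the fifteen regions the printed effect size is not consistent
with pooled-SD Cohen's d computed from the printed means and SDs (flagged
``reproducible=False``); they are retained for completeness but excluded
from reproduction checks.
"""

from __future__ import annotations

import pandas as pd

from .phantom import CohortSpec
from .stats import GroupSummary

N_OSA = 15
N_CONTROL = 16

# region: (mean_osa, sd_osa, mean_control, sd_control, printed_d, reproducible)
REGIONAL_OEF = {
    "right_hemisphere":      (46.99, 6.90, 54.20, 7.35, 1.010, True),
    "left_hemisphere":       (46.85, 6.89, 54.41, 7.51, 1.046, True),
    "right_cerebral_cortex": (29.15, 4.49, 33.64, 5.53, 0.886, True),
    "left_cerebral_cortex":  (29.42, 4.49, 34.20, 5.61, 0.937, True),
    "right_frontal":         (40.70, 5.91, 47.05, 7.65, 0.923, True),
    "left_frontal":          (42.22, 6.74, 49.75, 6.62, 1.126, True),
    "right_parietal":        (41.26, 7.51, 48.80, 8.15, 0.961, True),
    "left_parietal":         (41.28, 7.35, 48.38, 7.30, 0.968, True),
    "right_temporal":        (48.97, 6.36, 57.71, 8.43, 1.164, True),
    "left_temporal":         (47.21, 6.58, 55.14, 8.55, 1.034, True),
    "right_occipital":       (54.48, 11.10, 63.66, 7.83, 0.961, True),
    "left_occipital":        (51.32, 8.55, 59.24, 9.37, 1.614, False),
    "cerebellum":            (44.15, 6.60, 48.69, 8.45, 0.298, False),
    "right_cerebellum":      (44.41, 6.72, 48.06, 9.67, 0.436, True),
    "left_cerebellum":       (43.71, 6.80, 49.09, 7.74, 0.347, False),
}


def regional_summaries(reproducible_only: bool = False) -> dict[str, GroupSummary]:
    """Region -> GroupSummary (group a = apnea, group b = control)."""
    out = {}
    for region, (ma, sa, mb, sb, _d, ok) in REGIONAL_OEF.items():
        if reproducible_only and not ok:
            continue
        out[region] = GroupSummary(mean_a=ma, sd_a=sa, n_a=N_OSA,
                                   mean_b=mb, sd_b=sb, n_b=N_CONTROL)
    return out


def printed_effect_sizes(reproducible_only: bool = True) -> dict[str, float]:
    """Region -> printed Cohen's d."""
    return {
        region: d
        for region, (_ma, _sa, _mb, _sb, d, ok) in REGIONAL_OEF.items()
        if ok or not reproducible_only
    }


def summary_frame() -> pd.DataFrame:
    """The summaries in the (region, mean_a, sd_a, n_a, mean_b, sd_b, n_b) layout."""
    rows = [
        {"region": region, "mean_a": ma, "sd_a": sa, "n_a": N_OSA,
         "mean_b": mb, "sd_b": sb, "n_b": N_CONTROL,
         "printed_d": d, "reproducible": ok}
        for region, (ma, sa, mb, sb, d, ok) in REGIONAL_OEF.items()
    ]
    return pd.DataFrame(rows)


def cohort_spec(seed: int = 0) -> CohortSpec:
    """A CohortSpec drawing per-subject regional OEF from the group summaries."""
    regions = tuple(REGIONAL_OEF)
    return CohortSpec(
        region_names=regions,
        group_a={r: (v[0], v[1], N_OSA) for r, v in REGIONAL_OEF.items()},
        group_b={r: (v[2], v[3], N_CONTROL) for r, v in REGIONAL_OEF.items()},
        labels=("apnea", "control"),
        seed=seed,
    )
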