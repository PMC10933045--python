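"""Composite nutritional-supplementation endpoint (FT/WL).

Positive iff a feeding tube was placed within 90 days after radiotherapy
completion, or body weight dropped strictly more than 10% below baseline
in that window.  Baseline weight is the record closest to RT start within
a ±2-week window.
"""

from __future__ import annotations

BASELINE_WINDOW_DAYS = 14
FOLLOWUP_DAYS = 90
WEIGHT_LOSS_FRACTION = 0.10


class IneligibleCaseError(ValueError):
    """No baseline weight within ±2 weeks of RT start."""


def baseline_weight(
    weight_records: list[tuple[float, float]], rt_start_day: float = 0.0
) -> float:
    """Weight (kg) recorded closest to RT start within the ±2-week window.

    ``weight_records``: (day, kg) pairs; days share the axis of
    ``rt_start_day``.  Ties on |day - start| resolve to the earlier record.
    """
    eligible = [
        (abs(day - rt_start_day), day, kg)
        for day, kg in weight_records
        if abs(day - rt_start_day) <= BASELINE_WINDOW_DAYS
    ]
    if not eligible:
        raise IneligibleCaseError(
            f"no weight record within ±{BASELINE_WINDOW_DAYS} days of RT start"
        )
    eligible.sort(key=lambda t: (t[0], t[1]))
    return eligible[0][2]


def extract_endpoint(
    ft_days: list[float],
    weight_records: list[tuple[float, float]],
    rt_end_day: float,
    rt_start_day: float = 0.0,
) -> bool:
    """FT/WL endpoint for one case.

    True iff a feeding-tube day lies in ``(rt_end, rt_end + 90]`` or the
    minimum weight in that window is below ``0.9 x baseline`` (strict
    >10% loss).
    """
    base = baseline_weight(weight_records, rt_start_day)
    lo, hi = rt_end_day, rt_end_day + FOLLOWUP_DAYS
    ft = any(lo < d <= hi for d in ft_days)
    window_weights = [kg for day, kg in weight_records if lo < day <= hi]
    wl = bool(window_weights) and min(window_weights) < (1.0 - WEIGHT_LOSS_FRACTION) * base
    return ft or wl
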