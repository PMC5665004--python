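"""Project performance and cost analytics.

Digitiser throughput is summarised with the classic three-point (PERT)
estimator over observed minutes-per-specimen: from a best case *a* (the
minimum), a most likely *m* (the median) and a worst case *b* (the 90th
percentile of observed times),

    E  = (a + 4m + b) / 6        SD = (b - a) / 6

per workflow stage (preparation, imaging, transcription).  The project total
is the sum of the *unrounded* per-stage estimates; per-stage shares are each
stage's fraction of that total.  All printed figures are rounded half-up:
two decimals for times and money, whole numbers for percents.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

STAGES = ("preparation", "imaging", "transcription")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.845 -> 0.85 at 2 dp), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ThreePointTiming:
    """(a, m, b) minutes-per-specimen observations for one stage."""

    a: float  # minimum, best case
    m: float  # median, most likely
    b: float  # 90th percentile, worst case
    stage: str = ""

    def __post_init__(self):
        if not (0 < self.a <= self.m <= self.b):
            raise ValueError(f"need 0 < a <= m <= b, got ({self.a}, {self.m}, {self.b})")


def _pert_raw(a: float, m: float, b: float) -> float:
    return (a + 4 * m + b) / 6.0


def pert_estimate(a: float, m: float, b: float) -> float:
    """Three-point base estimate E = (a + 4m + b)/6, rounded to 2 dp."""
    if not (0 < a <= m <= b):
        raise ValueError(f"need 0 < a <= m <= b, got ({a}, {m}, {b})")
    return round_half_up(_pert_raw(a, m, b), 2)


def pert_sd(a: float, b: float) -> float:
    """Three-point spread SD = (b - a)/6, rounded to 2 dp."""
    if a > b:
        raise ValueError(f"need a <= b, got ({a}, {b})")
    return round_half_up((b - a) / 6.0, 2)


@dataclass(frozen=True)
class ProjectEstimate:
    per_stage: dict[str, float]  # rounded per-stage E
    total: float  # rounded sum of unrounded per-stage E
    shares: dict[str, int]  # percent of total per stage


def project_estimate(timings: dict[str, ThreePointTiming]) -> ProjectEstimate:
    """Combine the three stage estimates into the project per-specimen time.

    The total sums the unrounded stage estimates before rounding (so the
    printed stage values need not add up to the printed total exactly);
    shares are round-half-up percents of the unrounded total.
    """
    missing = [s for s in STAGES if s not in timings]
    if missing:
        raise ValueError(f"missing stage(s): {', '.join(missing)}")
    raw = {s: _pert_raw(timings[s].a, timings[s].m, timings[s].b) for s in STAGES}
    total_raw = sum(raw.values())
    return ProjectEstimate(
        per_stage={s: round_half_up(v, 2) for s, v in raw.items()},
        total=round_half_up(total_raw, 2),
        shares={s: int(round_half_up(100.0 * v / total_raw, 0)) for s, v in raw.items()},
    )


def timings_from_log(log: pd.DataFrame, min_obs: int = 10) -> dict[str, ThreePointTiming]:
    """Derive (a, m, b) per stage from a raw event log.

    ``log`` needs columns ``stage`` and ``seconds`` (one row per specimen
    handled).  a is the minimum, m the linearly interpolated median, b the
    linearly interpolated 90th percentile, all converted to minutes.
    """
    out: dict[str, ThreePointTiming] = {}
    for stage, grp in log.groupby("stage"):
        secs = grp["seconds"].to_numpy(dtype=float)
        if len(secs) < min_obs:
            raise ValueError(
                f"stage {stage!r} has only {len(secs)} observation(s); need {min_obs}"
            )
        minutes = secs / 60.0
        out[str(stage)] = ThreePointTiming(
            a=float(minutes.min()),
            m=float(np.quantile(minutes, 0.5)),
            b=float(np.quantile(minutes, 0.9)),
            stage=str(stage),
        )
    return out


@dataclass(frozen=True)
class CostSummary:
    lines: dict[str, float]
    total: float
    n_specimens: int
    per_specimen_total: float
    per_specimen_digitisers: float
    per_specimen_georeferencing: float


def cost_report(
    lines: dict[str, float],
    n_specimens: int,
    digitiser_key: str = "digitiser_salaries",
    georeferencing_key: str = "georeferencing",
) -> CostSummary:
    """Totals and cost-per-specimen variants from project line items."""
    if n_specimens <= 0:
        raise ValueError("n_specimens must be positive")
    if any(v < 0 for v in lines.values()):
        raise ValueError("cost amounts must be non-negative")
    total = sum(lines.values())
    return CostSummary(
        lines=dict(lines),
        total=round_half_up(total, 2),
        n_specimens=n_specimens,
        per_specimen_total=round_half_up(total / n_specimens, 2),
        per_specimen_digitisers=round_half_up(lines.get(digitiser_key, 0.0) / n_specimens, 2),
        per_specimen_georeferencing=round_half_up(
            lines.get(georeferencing_key, 0.0) / n_specimens, 2
        ),
    )
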