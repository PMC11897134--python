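"""Phase classification from aggregation propensity and clustering degree.

Two threshold presets are built in:

* ``all_atom_revised`` — boundaries appropriate to all-atom simulations of
  short aromatic peptides: fibers have AP > 1.6 and CD > 0.9; condensates
  have 1.2 < AP < 1.6 and CD > 0.5.
* ``coarse_grained_cited`` — the older coarse-grained dipeptide boundaries:
  fibers AP > 3 and CD > 0.9; condensates 1 < AP < 3 and CD > 0.5.

The two rule regions do not tile the (AP, CD) plane.  Points below the
condensate lower bounds are *dispersed*; points in uncovered regions (for
example AP above the fiber bound but CD between 0.5 and 0.9, or metrics
exactly on a boundary — all inequalities are strict) are labelled
*ambiguous* rather than silently coerced into a phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ArgumentError, DataError
from .structure import PhaseMetrics, Trajectory, phase_metrics


@dataclass(frozen=True)
class ThresholdSet:
    """Classification boundaries on AP and CD (all strict inequalities)."""

    name: str
    ap_fiber_min: float
    cd_fiber_min: float
    ap_cond_min: float
    ap_cond_max: float
    cd_cond_min: float

    def __post_init__(self) -> None:
        for f in ("ap_fiber_min", "cd_fiber_min", "ap_cond_min", "ap_cond_max", "cd_cond_min"):
            if getattr(self, f) <= 0:
                raise ArgumentError(f"{f} must be positive")


ALL_ATOM_REVISED = ThresholdSet(
    name="all_atom_revised",
    ap_fiber_min=1.6, cd_fiber_min=0.9,
    ap_cond_min=1.2, ap_cond_max=1.6, cd_cond_min=0.5,
)

COARSE_GRAINED_CITED = ThresholdSet(
    name="coarse_grained_cited",
    ap_fiber_min=3.0, cd_fiber_min=0.9,
    ap_cond_min=1.0, ap_cond_max=3.0, cd_cond_min=0.5,
)

PRESETS: dict[str, ThresholdSet] = {
    t.name: t for t in (ALL_ATOM_REVISED, COARSE_GRAINED_CITED)
}


@dataclass
class PhaseLabel:
    """Categorical phase outcome with the rules that fired."""

    label: str  # fiber | condensate | dispersed | ambiguous
    matched_rules: list[str] = field(default_factory=list)
    thresholds_used: str = ALL_ATOM_REVISED.name
    metrics: PhaseMetrics | None = None


def classify_phase(
    metrics: PhaseMetrics,
    thresholds: ThresholdSet = ALL_ATOM_REVISED,
) -> PhaseLabel:
    """Map (AP, CD) to fiber / condensate / dispersed / ambiguous.

    Fiber wins when both fiber rules hold; otherwise condensate when the AP
    window and CD bound hold; otherwise dispersed when the metrics fall
    below the condensate lower bounds; anything else is ambiguous.
    """
    ap, cd = metrics.ap, metrics.cd
    if math.isnan(ap) or math.isnan(cd):
        raise DataError("NaN metric passed to classifier")
    t = thresholds
    matched: list[str] = []
    if ap > t.ap_fiber_min and cd > t.cd_fiber_min:
        matched.append(f"ap > {t.ap_fiber_min} and cd > {t.cd_fiber_min}")
        label = "fiber"
    elif t.ap_cond_min < ap < t.ap_cond_max and cd > t.cd_cond_min:
        matched.append(
            f"{t.ap_cond_min} < ap < {t.ap_cond_max} and cd > {t.cd_cond_min}"
        )
        label = "condensate"
    elif ap <= t.ap_cond_min or cd <= t.cd_cond_min:
        matched.append(f"ap <= {t.ap_cond_min} or cd <= {t.cd_cond_min}")
        label = "dispersed"
    else:
        label = "ambiguous"
    return PhaseLabel(
        label=label, matched_rules=matched,
        thresholds_used=t.name, metrics=metrics,
    )


def classify_trajectory(
    traj: Trajectory,
    thresholds: ThresholdSet = ALL_ATOM_REVISED,
    **metric_params,
) -> PhaseLabel:
    """Compute phase metrics for a trajectory and classify them.

    Keyword arguments are forwarded to
    :func:`phasekit.structure.phase_metrics`; the returned label carries
    the full metrics row.
    """
    m = phase_metrics(traj, **metric_params)
    return classify_phase(m, thresholds)
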