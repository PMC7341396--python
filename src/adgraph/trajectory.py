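"""Classification of stage trajectories of subnetwork attributes.

A trajectory is the 4-vector of group means of one (network, metric) AUC
across the ordered disease stages NC -> EMCI -> LMCI -> AD.  Two evolving
patterns are of primary interest:

* TEMPERATURE_INVERSION — the value rises from NC, peaks at EMCI, and
  declines through LMCI to AD (an inverted U), named after the
  meteorological phenomenon where temperature deviates from the usual
  fall with altitude;
* MONOTONOUS_DECLINE — the value falls steadily from NC to AD, matching
  the intuitive picture of progressive functional loss.

A U_SHAPED label (interior minimum with recovery at the end) and a
catch-all OTHER complete the scheme.  Because group means are noisy, all
comparisons use a tolerance ``tol``; by default tol is noise-scaled —
0.25 x the pooled standard error of the four stage means — so the rule
adapts to the data rather than to an arbitrary absolute band.  This
quantitative criterion is this package's own; visual inspection of
trajectory plots is the traditional alternative.

Networks whose five metrics agree (by majority) on a pattern are grouped
into "homogeneous evolving subnetworks".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .synthetic import STAGES

__all__ = [
    "Pattern",
    "PatternLabel",
    "StageTrajectory",
    "default_tolerance",
    "classify_pattern",
    "group_homogeneous",
]


class Pattern(str, Enum):
    TEMPERATURE_INVERSION = "TEMPERATURE_INVERSION"
    MONOTONOUS_DECLINE = "MONOTONOUS_DECLINE"
    U_SHAPED = "U_SHAPED"
    OTHER = "OTHER"


@dataclass(frozen=True)
class PatternLabel:
    label: Pattern
    peak_stage: str | None

    def __post_init__(self) -> None:
        if self.label is Pattern.TEMPERATURE_INVERSION and self.peak_stage != "EMCI":
            raise ValueError("temperature inversion implies a peak at EMCI")


@dataclass(frozen=True)
class StageTrajectory:
    """Group means (and standard errors) of one feature across the 4 stages."""

    feature: tuple[str, str]
    values: tuple[float, float, float, float]
    dispersion: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.values) != len(STAGES):
            raise ValueError(f"need {len(STAGES)} stage values, got {len(self.values)}")


def default_tolerance(dispersion, scale: float = 0.25) -> float:
    """Noise-scaled tolerance: ``scale`` x pooled SE of the stage means."""
    se = np.asarray(dispersion, dtype=float)
    return float(scale * np.sqrt(np.mean(se**2)))


def classify_pattern(trajectory: StageTrajectory, tol: float | None = None) -> PatternLabel:
    """Label one stage trajectory.

    Parameters
    ----------
    trajectory
        Four ordered group means (NC, EMCI, LMCI, AD), optionally with
        standard errors.
    tol
        Comparison tolerance; a rise must exceed ``tol`` to count, and a
        decline step may backslide by at most ``tol``.  ``None`` uses the
        noise-scaled default (requires ``dispersion``); pass an absolute
        number for absolute-tolerance mode, 0 for strict comparisons.

    Rules (v = stage means):

    * TEMPERATURE_INVERSION: v2 - v1 > tol, v2 is the maximum, and both
      decline steps v2->v3->v4 fall (backsliding < tol allowed);
    * MONOTONOUS_DECLINE: every step falls (backsliding < tol allowed)
      and the total drop v1 - v4 exceeds tol;
    * U_SHAPED: interior minimum with an initial fall and a final rise
      beyond tol;
    * OTHER: anything else.
    """
    v = np.asarray(trajectory.values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError(f"non-finite trajectory values: {trajectory.values}")
    if tol is None:
        if trajectory.dispersion is None:
            raise ValueError("tol=None needs a trajectory with dispersion (standard errors)")
        tol = default_tolerance(trajectory.dispersion)
    if tol < 0:
        raise ValueError("tol must be >= 0")

    rises = np.diff(v)  # rises[i] = v[i+1] - v[i]
    if (rises[0] > tol and int(np.argmax(v)) == 1
            and rises[1] < tol and rises[2] < tol and (v[1] - v[3]) > tol):
        return PatternLabel(Pattern.TEMPERATURE_INVERSION, "EMCI")
    if (rises < tol).all() and (v[0] - v[3]) > tol:
        return PatternLabel(Pattern.MONOTONOUS_DECLINE, "NC")
    amin = int(np.argmin(v))
    if amin in (1, 2) and (v[0] - v[amin]) > tol and rises[2] > tol:
        return PatternLabel(Pattern.U_SHAPED, None)
    return PatternLabel(Pattern.OTHER, None)


def group_homogeneous(labels: dict[tuple[str, str], PatternLabel]) -> dict[str, Pattern]:
    """Aggregate per-(network, metric) labels into one pattern per network.

    Each network gets the majority pattern across its metrics; a tie for
    the majority yields OTHER.  Networks sharing a pattern form the
    homogeneous evolving groups.

    Returns
    -------
    dict network -> Pattern
    """
    by_network: dict[str, list[Pattern]] = {}
    for (network, _metric), label in labels.items():
        by_network.setdefault(network, []).append(label.label)
    out: dict[str, Pattern] = {}
    for network, pats in by_network.items():
        counts = Counter(pats).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            out[network] = Pattern.OTHER
        else:
            out[network] = counts[0][0]
    return out
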