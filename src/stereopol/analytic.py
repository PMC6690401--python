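"""Closed-form expected interocular correlation.

Treating the stereogram as a population of aligned pixel pairs with
probabilities (d, m, u, d_m, d_u, x) — see
:class:`stereopol.corrstats.PixelPairStats` — the expected Pearson
correlation has a closed form for each polarity condition:

  mixed polarity:  r_mixed = m * d_m / d
  same polarity:   r_same  = (m*d_m + u*(2*d_u - 1) - d^2) / (d * (1 - d))

When dots are scattered freely (overlap allowed), the dot probability of the
partner pixel of an unmatched dot is just d, forcing d_u = 1/(2 - d) and
collapsing both expressions to

  r_Ov = 1 - u / (d * (2 - d)),

i.e. with overlap the two polarities have identical expected correlation.
When overlap is forbidden, d_u is pushed toward its floor of 1/2 (noise dots
can land only on background), and in the limiting case d_u = 1/2

  r_mixed = 1 - u / (2d)        r_same = 1 - u / (2d(1 - d)),

so the same-polarity correlation is strictly lower: the stimulus-construction
artefact behind the psychophysical mixed-polarity advantage.

These functions are pure arithmetic with validated domains; all stochastic
validation against the Monte-Carlo generator lives in the test suite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .corrstats import PixelPairStats


class Polarity(enum.Enum):
    MIXED = "mixed"
    SAME = "same"


class Regime(enum.Enum):
    GENERAL = "general"
    OVERLAP = "overlap"
    LIMIT_NO_OVERLAP = "limit_no_overlap"


@dataclass(frozen=True)
class AnalyticPrediction:
    r_mixed: float
    r_same: float
    regime: Regime
    inputs: PixelPairStats | None = None


def _check_d(d: float) -> None:
    if not 0.0 < d < 1.0:
        raise ValueError(f"dot probability d must lie strictly in (0, 1); got {d}")


def expected_r(stats: PixelPairStats, polarity: Polarity) -> float:
    """Expected Pearson correlation for the given pixel-pair statistics."""
    _check_d(stats.d)
    if polarity is Polarity.MIXED:
        return stats.m * stats.d_m / stats.d
    if polarity is Polarity.SAME:
        num = stats.m * stats.d_m + stats.u * (2.0 * stats.d_u - 1.0) - stats.d**2
        return num / (stats.d * (1.0 - stats.d))
    raise ValueError(f"unknown polarity {polarity}")


def predict(stats: PixelPairStats) -> AnalyticPrediction:
    """Both polarity predictions for one set of pixel-pair statistics."""
    return AnalyticPrediction(
        r_mixed=expected_r(stats, Polarity.MIXED),
        r_same=expected_r(stats, Polarity.SAME),
        regime=Regime.GENERAL,
        inputs=stats,
    )


def du_overlap(d: float) -> float:
    """P(dot | unmatched pair) when dots are scattered freely: 1 / (2 - d)."""
    if not 0.0 <= d < 1.0:
        raise ValueError(f"d must lie in [0, 1); got {d}")
    return 1.0 / (2.0 - d)


def r_overlap(u: float, d: float) -> float:
    """Expected correlation (both polarities) in the free-scatter regime:
    1 - u / (d * (2 - d))."""
    _check_d(d)
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"unmatched probability u must lie in [0, 1]; got {u}")
    return 1.0 - u / (d * (2.0 - d))


def r_limit_no_overlap(u: float, d: float, polarity: Polarity) -> float:
    """Expected correlation in the limiting no-overlap case d_u = 1/2 (noise
    dots land only on double background)."""
    _check_d(d)
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"unmatched probability u must lie in [0, 1]; got {u}")
    if polarity is Polarity.MIXED:
        return 1.0 - u / (2.0 * d)
    if polarity is Polarity.SAME:
        return 1.0 - u / (2.0 * d * (1.0 - d))
    raise ValueError(f"unknown polarity {polarity}")
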