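"""Period-class labelling for oscillating genes.

Transcripts detected as rhythmic in high-resolution liver time courses fall
into a ~24 h (circadian) class and two ultradian harmonic classes at ~12 h
and ~8 h.  The windows used here are the conventional ones: 24 +/- 4 h,
12 +/- 2 h and 8 +/- 1 h.  Both window ends are treated as inclusive, so a
transcript with a fitted period of exactly 9 h is an 8-h-class gene.
"""

from __future__ import annotations

from enum import Enum


class PeriodClass(str, Enum):
    """Oscillation-period class of a gene."""

    P8 = "P8"
    P12 = "P12"
    P24 = "P24"
    NONE = "NONE"


#: closed [lo, hi] windows, in hours; mutually disjoint
PERIOD_WINDOWS: dict[PeriodClass, tuple[float, float]] = {
    PeriodClass.P24: (20.0, 28.0),
    PeriodClass.P12: (10.0, 14.0),
    PeriodClass.P8: (7.0, 9.0),
}


def classify_period(period_hours: float) -> PeriodClass:
    """Map a fitted oscillation period (hours) to its class.

    Parameters
    ----------
    period_hours
        Fitted period length in hours; must be strictly positive.

    Returns
    -------
    PeriodClass
        ``P24`` for periods in [20, 28], ``P12`` for [10, 14], ``P8`` for
        [7, 9], ``NONE`` otherwise.
    """
    if not period_hours > 0:
        raise ValueError(f"period must be positive, got {period_hours!r}")
    for cls, (lo, hi) in PERIOD_WINDOWS.items():
        if lo <= period_hours <= hi:
            return cls
    return PeriodClass.NONE
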