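"""Quantification of sucrose-gradient A254 absorbance traces.

A polysome profile is a UV-absorbance (254 nm) readout along a sucrose
density gradient: free mRNPs and ribosomal subunits sediment near the top,
monosomes in the middle, and polysomes — mRNAs carrying two or more
ribosomes — at the bottom.  The fraction of total absorbance found in the
polysomal region is the standard bulk estimate of translational activity.

This module handles the arithmetic of that estimate: blank-gradient
baseline subtraction, trapezoidal area-under-curve, the polysomal-area
percentage, and replicate-level differences between treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GradientTrace",
    "FractionScheme",
    "UndefinedMetricError",
    "subtract_baseline",
    "area",
    "fraction_areas",
    "polysomal_area_pct",
    "pct_difference",
    "PctDifference",
]


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined for this input (e.g. 0/0)."""


@dataclass(frozen=True)
class GradientTrace:
    """An A254 sedimentation profile sampled along the gradient.

    Parameters
    ----------
    positions:
        Strictly increasing gradient depth coordinates (arbitrary units,
        top of the gradient first).
    absorbance:
        A254 readings at ``positions`` (AU).
    """

    positions: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if pos.ndim != 1 or ab.ndim != 1 or pos.size != ab.size:
            raise ValueError("positions and absorbance must be 1-D and equal length")
        if pos.size < 2:
            raise ValueError("a trace needs at least 2 points")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(ab))):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "absorbance", ab)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])


# Ribosome count -> fraction index (1..12).  Count 0 is the free-mRNP
# region at the top, the monosome sits in fraction 3 (still non-polysomal),
# and counts >= 2 sediment into the polysomal fractions 5..12.
_DEFAULT_COUNT_MAP = {0: 1, 1: 3, 2: 5, 3: 6, 4: 7, 5: 8, 6: 9, 7: 10, 8: 11}
_DEFAULT_COUNT_CAP = 9  # counts >= cap all land in the deepest fraction


@dataclass(frozen=True)
class FractionScheme:
    """Partition of the gradient domain into fractions and pools.

    ``boundaries`` holds ``n_fractions + 1`` increasing positions; fraction
    ``f`` spans ``[boundaries[f-1], boundaries[f]]``.  ``pools`` names the
    contiguous index ranges pooled for RNA extraction: non-polysomal (NP),
    small polysomes (SP) and large polysomes (LP).  ``count_map`` places a
    given per-mRNA ribosome count into a fraction, used by the synthetic
    generator and by fraction-resolved metrics.
    """

    boundaries: np.ndarray
    pools: dict = field(
        default_factory=lambda: {"NP": (1, 4), "SP": (5, 8), "LP": (9, 12)}
    )
    polysome_start_fraction: int = 5
    count_map: dict = field(default_factory=lambda: dict(_DEFAULT_COUNT_MAP))
    count_cap: int = _DEFAULT_COUNT_CAP

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("boundaries must be a 1-D array of >= 2 values")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)
        n = self.n_fractions
        covered = sorted(
            f for lo, hi in self.pools.values() for f in range(lo, hi + 1)
        )
        if covered != list(range(1, n + 1)):
            raise ValueError("pools must be disjoint and jointly cover all fractions")
        poly = sorted(
            f
            for name in ("SP", "LP")
            if name in self.pools
            for f in range(self.pools[name][0], self.pools[name][1] + 1)
        )
        if poly and poly[0] != self.polysome_start_fraction:
            raise ValueError("SP∪LP must start at polysome_start_fraction")

    @classmethod
    def default(cls, domain: tuple[float, float] = (0.0, 12.0), n_fractions: int = 12) -> "FractionScheme":
        """Twelve equal-width fractions with NP=1-4, SP=5-8, LP=9-12."""
        return cls(boundaries=np.linspace(domain[0], domain[1], n_fractions + 1))

    @property
    def n_fractions(self) -> int:
        return int(self.boundaries.size - 1)

    @property
    def polysomal_fractions(self) -> range:
        return range(self.polysome_start_fraction, self.n_fractions + 1)

    def fraction_for_count(self, n: int) -> int:
        """Fraction index receiving an mRNA carrying ``n`` ribosomes."""
        if n < 0:
            raise ValueError("ribosome count must be >= 0")
        if n >= self.count_cap:
            return self.n_fractions
        try:
            return self.count_map[n]
        except KeyError:
            raise ValueError(f"count {n} not covered by the fraction scheme") from None

    def fraction_span(self, f: int) -> tuple[float, float]:
        if not 1 <= f <= self.n_fractions:
            raise ValueError(f"fraction index {f} out of range")
        return float(self.boundaries[f - 1]), float(self.boundaries[f])

    def fraction_center(self, f: int) -> float:
        lo, hi = self.fraction_span(f)
        return 0.5 * (lo + hi)


def subtract_baseline(trace: GradientTrace, blank: GradientTrace) -> GradientTrace:
    """Subtract a blank-gradient trace, clipping negative values to zero.

    The blank is linearly interpolated onto the trace's positions; its
    domain must cover the trace's.  Clipping reflects that A254 is
    nonnegative and keeps downstream area percentages inside [0, 100].
    """
    t_lo, t_hi = trace.domain
    b_lo, b_hi = blank.domain
    if b_lo > t_lo or b_hi < t_hi:
        raise ValueError("blank trace domain does not cover the sample trace")
    interp = np.interp(trace.positions, blank.positions, blank.absorbance)
    corrected = np.clip(trace.absorbance - interp, 0.0, None)
    return GradientTrace(trace.positions, corrected)


def _interp_at(trace: GradientTrace, x: float) -> float:
    return float(np.interp(x, trace.positions, trace.absorbance))


def area(trace: GradientTrace, lo: float, hi: float) -> float:
    """Trapezoidal integral of absorbance over [lo, hi].

    Endpoints interior to a sampling step are handled by linear
    interpolation, so the rule is exact for piecewise-linear traces and
    exactly additive over adjacent intervals.
    """
    d_lo, d_hi = trace.domain
    if lo >= hi:
        raise ValueError("need lo < hi")
    if lo < d_lo - 1e-12 or hi > d_hi + 1e-12:
        raise ValueError(f"[{lo}, {hi}] outside trace domain [{d_lo}, {d_hi}]")
    lo = max(lo, d_lo)
    hi = min(hi, d_hi)
    inside = (trace.positions > lo) & (trace.positions < hi)
    xs = np.concatenate(([lo], trace.positions[inside], [hi]))
    ys = np.concatenate(
        ([_interp_at(trace, lo)], trace.absorbance[inside], [_interp_at(trace, hi)])
    )
    return float(np.trapezoid(ys, xs))


def fraction_areas(trace: GradientTrace, scheme: FractionScheme) -> np.ndarray:
    """Area under the trace within each fraction, index order 1..n."""
    return np.array(
        [area(trace, *scheme.fraction_span(f)) for f in range(1, scheme.n_fractions + 1)]
    )


def polysomal_area_pct(trace: GradientTrace, scheme: FractionScheme) -> float:
    """Percentage of total trace area in the polysomal fractions.

    The trace should already be baseline-subtracted; total area is used as
    the denominator to correct for uneven gradient loading.

    Raises
    ------
    UndefinedMetricError
        If the total area is not positive (0/0 is flagged, never 0).
    """
    lo = scheme.boundaries[0]
    hi = scheme.boundaries[-1]
    total = area(trace, lo, hi)
    if total <= 0:
        raise UndefinedMetricError("total trace area is 0; polysomal % undefined")
    poly_lo = scheme.fraction_span(scheme.polysome_start_fraction)[0]
    return 100.0 * area(trace, poly_lo, hi) / total


@dataclass(frozen=True)
class PctDifference:
    """Treated-minus-control difference of polysomal-area percentages."""

    difference: float
    sd: float
    pvalue: float
    n_treated: int
    n_control: int


def pct_difference(treated, control) -> PctDifference:
    """Mean difference of replicate percentages with propagated SD.

    ``sd`` is the propagated sample SD, sqrt(sd_t^2 + sd_c^2) — the SD of a
    hypothetical single treated-minus-control difference, matching the
    mean ± SD convention used for replicate gradient summaries.  A
    two-sided two-sample t p-value (pooled variance) is attached.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("need at least 2 replicates per arm")
    diff = float(t.mean() - c.mean())
    sd = float(np.sqrt(t.var(ddof=1) + c.var(ddof=1)))
    if t.var(ddof=1) == 0 and c.var(ddof=1) == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(stats.ttest_ind(t, c, equal_var=True).pvalue)
    return PctDifference(diff, sd, p, t.size, c.size)
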