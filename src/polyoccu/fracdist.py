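"""Fraction-resolved transcript distributions and ribosome-density metrics.

For a single transcript measured across the 12 gradient fractions one can
separate two quantities that a bulk polysome/monosome ratio conflates:

* polysomal occupancy — the share of the transcript's copies engaged in
  polysomes (``pl_pct``), and
* ribosome density — how many ribosomes those engaged copies carry,
  proxied by the abundance-weighted mean fraction index within the
  polysomal region (deeper fractions = more ribosomes per mRNA).

A transcript can gain occupancy while losing density: more of its copies
are being translated, each by fewer ribosomes.  ``scenario_classify``
turns the (occupancy delta, density delta) sign pattern into a mechanistic
label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradient import FractionScheme, UndefinedMetricError

__all__ = [
    "FractionProfile",
    "DensityMetrics",
    "normalize_profile",
    "np_pl_split",
    "density_metrics",
    "scenario_classify",
]


@dataclass(frozen=True)
class FractionProfile:
    """Per-gene abundance across gradient fractions, with normalizers.

    ``spike_signal`` is the signal of the exogenous luciferase spike-in for
    the same sample; ``trace_area`` the polysomal A254 area of the gradient
    the fractions came from.  Both are used by :func:`normalize_profile`.
    """

    gene_id: str
    abundances: np.ndarray
    spike_signal: float = 1.0
    trace_area: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        if a.ndim != 1:
            raise ValueError("abundances must be 1-D")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("abundances must be finite and >= 0")
        object.__setattr__(self, "abundances", a)


@dataclass(frozen=True)
class DensityMetrics:
    """Occupancy / density summary of one fraction profile."""

    np_pct: float
    pl_pct: float
    weighted_index: float
    peak_fraction: int


def _values(profile) -> np.ndarray:
    if isinstance(profile, FractionProfile):
        return profile.abundances
    return np.asarray(profile, dtype=float)


def normalize_profile(profile: FractionProfile) -> np.ndarray:
    """Divide each fraction by the spike signal and the gradient area.

    Removes per-sample differences in extraction yield (spike) and in
    gradient loading (A254 area); the result is comparable across samples.
    """
    if profile.spike_signal <= 0:
        raise ValueError("spike_signal must be > 0")
    if profile.trace_area <= 0:
        raise ValueError("trace_area must be > 0")
    return profile.abundances / profile.spike_signal / profile.trace_area


def np_pl_split(profile, scheme: FractionScheme) -> tuple[float, float]:
    """(np_pct, pl_pct): signal split between non-polysomal and polysomal
    fractions, scaled so NP + PL = 100%.  Scale invariant, so raw or
    normalized profiles give the same split."""
    a = _values(profile)
    if a.size != scheme.n_fractions:
        raise ValueError("profile length does not match the fraction scheme")
    total = a.sum()
    if total <= 0:
        raise UndefinedMetricError("all-zero profile: NP/PL split undefined")
    start = scheme.polysome_start_fraction
    pl = a[start - 1 :].sum()
    np_pct = 100.0 * (total - pl) / total
    return np_pct, 100.0 - np_pct


def density_metrics(profile, scheme: FractionScheme) -> DensityMetrics:
    """Occupancy split plus density metrics over the polysomal region.

    ``weighted_index`` is the abundance-weighted mean fraction index over
    polysomal fractions; ``peak_fraction`` the modal polysomal fraction
    (ties broken toward the lowest index).
    """
    a = _values(profile)
    np_pct, pl_pct = np_pl_split(a, scheme)
    start = scheme.polysome_start_fraction
    poly = a[start - 1 :]
    if poly.sum() <= 0:
        raise UndefinedMetricError("no polysomal signal: density metrics undefined")
    idx = np.arange(start, scheme.n_fractions + 1, dtype=float)
    weighted = float((idx * poly).sum() / poly.sum())
    peak = int(idx[int(np.argmax(poly))])  # argmax returns first maximum
    return DensityMetrics(np_pct, pl_pct, weighted, peak)


def scenario_classify(
    control: DensityMetrics,
    treated: DensityMetrics,
    occ_tol: float = 1.0,
    dens_tol: float = 0.25,
) -> str:
    """Label the occupancy/density change pattern between two conditions.

    Deltas within tolerance (``occ_tol`` percentage points of PL%,
    ``dens_tol`` fraction-index units) count as no change.  Labels:

    * ``initiation_up`` — occupancy up and density up: more initiation
      loads more copies with more ribosomes each.
    * ``occupancy_up_density_down`` — more copies engaged, each carrying
      fewer ribosomes: release from sequestration with unchanged or slower
      per-copy loading, elongation stall with reduced initiation, or
      ribosome runoff.
    * ``repression`` — both down.
    * ``no_change`` / ``other`` — neither or a mixed/partial pattern.
    """
    d_occ = treated.pl_pct - control.pl_pct
    d_dens = treated.weighted_index - control.weighted_index
    occ_up, occ_down = d_occ > occ_tol, d_occ < -occ_tol
    dens_up, dens_down = d_dens > dens_tol, d_dens < -dens_tol
    if not (occ_up or occ_down) and not (dens_up or dens_down):
        return "no_change"
    if occ_up and dens_down:
        return "occupancy_up_density_down"
    if occ_up and dens_up:
        return "initiation_up"
    if occ_down and dens_down:
        return "repression"
    return "other"
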