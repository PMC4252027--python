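"""Three-level differential analysis of translatome experiments.

Sucrose-gradient microarray/RNA designs measure every gene at two levels:
steady-state mRNA (SL, total RNA) and polysomal mRNA (PL, RNA from the
pooled polysome fractions).  Three contrasts follow:

* ``SL`` — transcriptional response: treated vs control at steady state.
* ``PL`` — polysome-association response: treated vs control in polysomes.
* ``RO`` — polysomal occupancy, the ratio PL/SL: a change in RO means the
  polysome association changed beyond what the transcript's abundance
  change explains, i.e. translational regulation.

On the log2 scale the three are linked by construction:
``log2FC_RO = log2FC_PL − log2FC_SL`` (exact on balanced designs).

Per-gene tests use a two-sample t on log2 intensities (pooled variance by
default; Welch optional), p-values are Benjamini–Hochberg adjusted per
contrast, and genes are called with the padj ≤ 0.05 & |log2FC| ≥ 1
(two-fold) rule.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "spike_normalize",
    "internal_standard_normalize",
    "differential",
    "benjamini_hochberg",
    "occupancy_contrast",
    "three_contrast_analysis",
    "classify",
]

_SAMPLE_RE = re.compile(
    r"^(?P<condition>[^.]+)\.(?P<light>[^.]+)\.(?P<level>[^.]+)\.(?P<replicate>\d+)$"
)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples intensity matrix with a sample annotation table.

    ``values`` is indexed by gene id with one column per sample; ``samples``
    is indexed by sample name with columns ``condition`` (control/sucrose),
    ``light`` (light/dark), ``level`` (steady_state/polysomal) and
    ``replicate`` (int).  ``log2`` flags the scale of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log2: bool = False
    spike: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("values columns and sample annotation index differ")
        missing = {"condition", "light", "level", "replicate"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample annotation lacks columns: {sorted(missing)}")
        if not self.log2 and (self.values.to_numpy() <= 0).any():
            raise ValueError("linear-scale intensities must be strictly positive")

    @classmethod
    def from_columns(cls, values: pd.DataFrame, log2: bool = False, spike=None) -> "ExpressionMatrix":
        """Parse ``condition.light.level.rep`` sample names into annotations."""
        rows = []
        for name in values.columns:
            m = _SAMPLE_RE.match(str(name))
            if m is None:
                raise ValueError(f"sample name {name!r} is not condition.light.level.rep")
            d = m.groupdict()
            d["replicate"] = int(d["replicate"])
            rows.append(d)
        samples = pd.DataFrame(rows, index=values.columns)
        return cls(values=values, samples=samples, log2=log2, spike=spike)

    def to_log2(self) -> "ExpressionMatrix":
        if self.log2:
            return self
        return replace(self, values=np.log2(self.values), log2=True)

    def select(self, **criteria) -> list[str]:
        """Sample names matching annotation criteria, replicate-sorted."""
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        names = self.samples.index[mask]
        return list(names[np.argsort(self.samples.loc[names, "replicate"].to_numpy())])


def spike_normalize(matrix: ExpressionMatrix, spike_signal: pd.Series | None = None) -> ExpressionMatrix:
    """Normalize each sample by its exogenous spike-in signal.

    Each sample's (linear) intensities are divided by its spike signal,
    then rescaled by the geometric mean of all spike signals so overall
    magnitudes are preserved.  Removes sample-to-sample differences in RNA
    recovery that a fixed-amount spike (e.g. 50 pg luciferase RNA per
    sample) is designed to capture.
    """
    if matrix.log2:
        raise ValueError("spike normalization operates on linear intensities")
    spikes = spike_signal if spike_signal is not None else matrix.spike
    if spikes is None:
        raise ValueError("no spike signal provided")
    spikes = spikes.reindex(matrix.values.columns)
    if spikes.isna().any() or (spikes <= 0).any():
        raise ValueError("spike signals must be present and > 0 for every sample")
    gm = float(np.exp(np.log(spikes.to_numpy(dtype=float)).mean()))
    scaled = matrix.values.div(spikes, axis=1) * gm
    return replace(matrix, values=scaled, spike=pd.Series(gm, index=spikes.index))


def internal_standard_normalize(
    peak_areas: pd.DataFrame,
    standard_ids,
    sample_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalize GC-MS peak areas by an internal-standard PCA score and sample weight.

    The per-sample normalization factor is the projection of each sample's
    internal-standard profile onto the first principal component of the
    mean-centered standards submatrix (the t1 score direction), sign-fixed
    to correlate positively with mean standard intensity and rescaled to
    geometric mean 1.  A pure size effect (standards proportional between
    samples) is removed exactly; identical standard profiles reduce to
    division by sample weight alone.  Degenerate standards (zero variance)
    or nonpositive scores fall back to mean-of-standards normalization
    with a warning.
    """
    std = [s for s in standard_ids if s in peak_areas.columns]
    if len(std) < 2:
        raise ValueError("need >= 2 internal standards present in the table")
    if peak_areas.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    x = peak_areas[std].to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    factors = None
    if np.linalg.norm(centered) > 1e-12 * max(1.0, np.linalg.norm(x)):
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        w = vt[0]
        scores = x @ w  # uncentered projection keeps the size component
        if np.corrcoef(scores, x.mean(axis=1))[0, 1] < 0:
            scores = -scores
        if np.all(scores > 0):
            factors = scores
    if factors is None:
        warnings.warn(
            "degenerate internal-standard matrix; falling back to mean-of-standards",
            stacklevel=2,
        )
        factors = x.mean(axis=1)
        if np.any(factors <= 0):
            raise ValueError("internal-standard intensities must be positive")
    factors = factors / np.exp(np.mean(np.log(factors)))
    out = peak_areas.div(pd.Series(factors, index=peak_areas.index), axis=0)
    if sample_weights is not None:
        weights = sample_weights.reindex(peak_areas.index)
        if weights.isna().any() or (weights <= 0).any():
            raise ValueError("sample weights must be present and > 0")
        out = out.div(weights, axis=0)
    return out


def _group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    return values.mean(axis=1), values.var(axis=1, ddof=1), values.shape[1]


def _t_test(
    treated: np.ndarray, control: np.ndarray, var_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided two-sample t-test on rows; handles the
    zero-variance degeneracies explicitly (equal means → p=1, unequal
    means → exact separation, p=0)."""
    m_t, v_t, n_t = _group_stats(treated)
    m_c, v_c, n_c = _group_stats(control)
    diff = m_t - m_c
    if var_mode == "pooled":
        sp2 = ((n_t - 1) * v_t + (n_c - 1) * v_c) / (n_t + n_c - 2)
        se = np.sqrt(sp2 * (1 / n_t + 1 / n_c))
        df = np.full_like(diff, n_t + n_c - 2)
    elif var_mode == "welch":
        se = np.sqrt(v_t / n_t + v_c / n_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v_t / n_t + v_c / n_c) ** 2 / (
                (v_t / n_t) ** 2 / (n_t - 1) + (v_c / n_c) ** 2 / (n_c - 1)
            )
    else:
        raise ValueError(f"unknown var_mode {var_mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    return diff, p


def differential(
    matrix: ExpressionMatrix,
    level: str,
    treated: str = "sucrose",
    control: str = "control",
    light: str = "light",
    var_mode: str = "pooled",
) -> pd.DataFrame:
    """Per-gene log2 fold change and p-value for one level's contrast.

    log2FC = mean(treated) − mean(control) on log2 intensities; p from a
    two-sided two-sample t-test.  ``var_mode='pooled'`` (default) assumes
    equal group variances — exact at the small replicate numbers typical
    here — while ``'welch'`` drops that assumption at the cost of a
    conservative small-sample approximation.
    """
    m = matrix.to_log2()
    t_cols = m.select(condition=treated, light=light, level=level)
    c_cols = m.select(condition=control, light=light, level=level)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("each group needs >= 2 replicates")
    lfc, p = _t_test(
        m.values[t_cols].to_numpy(dtype=float),
        m.values[c_cols].to_numpy(dtype=float),
        var_mode,
    )
    return pd.DataFrame({"log2fc": lfc, "pvalue": p}, index=m.values.index)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def occupancy_contrast(
    matrix: ExpressionMatrix,
    treated: str = "sucrose",
    control: str = "control",
    light: str = "light",
    levels: tuple[str, str] = ("polysomal", "steady_state"),
    var_mode: str = "pooled",
    mode: str = "ratio",
) -> pd.DataFrame:
    """Per-gene polysomal-occupancy (RO = PL/SL) log2 fold change and p.

    ``mode='ratio'`` (default) forms the per-replicate log2 occupancy
    o_ij = log2(PL_ij) − log2(SL_ij) on replicate-matched samples and runs
    the two-sample t on o.  ``mode='interaction'`` instead tests the 2×2
    condition × level interaction contrast on the four group means with a
    pooled variance estimate, which does not require replicate pairing.
    Either way log2FC_RO = log2FC_PL − log2FC_SL on balanced designs.
    """
    m = matrix.to_log2()
    pl_level, sl_level = levels
    groups = {}
    for cond in (treated, control):
        pl_cols = m.select(condition=cond, light=light, level=pl_level)
        sl_cols = m.select(condition=cond, light=light, level=sl_level)
        if mode == "ratio":
            pl_reps = list(m.samples.loc[pl_cols, "replicate"])
            sl_reps = list(m.samples.loc[sl_cols, "replicate"])
            if pl_reps != sl_reps:
                raise ValueError(
                    f"unmatched replicate structure for {cond}: PL reps {pl_reps} "
                    f"vs SL reps {sl_reps}"
                )
        groups[cond] = (
            m.values[pl_cols].to_numpy(dtype=float),
            m.values[sl_cols].to_numpy(dtype=float),
        )
    if mode == "ratio":
        o_t = groups[treated][0] - groups[treated][1]
        o_c = groups[control][0] - groups[control][1]
        _, p = _t_test(o_t, o_c, var_mode)
        # fold change from the level-wise group means so that
        # log2FC_RO == log2FC_PL - log2FC_SL holds bit-exactly
        lfc = (groups[treated][0].mean(axis=1) - groups[control][0].mean(axis=1)) - (
            groups[treated][1].mean(axis=1) - groups[control][1].mean(axis=1)
        )
    elif mode == "interaction":
        est = np.zeros(m.values.shape[0])
        var_num = np.zeros_like(est)
        ss = np.zeros_like(est)
        df = 0
        for cond, sign in ((treated, 1.0), (control, -1.0)):
            for arr, lsign in zip(groups[cond], (1.0, -1.0)):
                mean, var, n = _group_stats(arr)
                est += sign * lsign * mean
                var_num += 1.0 / n
                ss += (n - 1) * var
                df += n - 1
        sp2 = ss / df
        se = np.sqrt(sp2 * var_num)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / se
            p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where((se == 0) & (est == 0), 1.0, p)
        p = np.where((se == 0) & (est != 0), 0.0, p)
        lfc = est
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame({"log2fc": lfc, "pvalue": p}, index=m.values.index)


def three_contrast_analysis(
    matrix: ExpressionMatrix,
    treated: str = "sucrose",
    control: str = "control",
    light: str = "light",
    var_mode: str = "pooled",
    ro_mode: str = "ratio",
) -> pd.DataFrame:
    """SL, PL and RO contrasts with per-contrast BH adjustment.

    Returns one row per gene with ``log2fc_X``, ``pvalue_X`` and
    ``padj_X`` for X in {SL, PL, RO}.
    """
    out = {}
    for name, level in (("SL", "steady_state"), ("PL", "polysomal")):
        res = differential(matrix, level, treated, control, light, var_mode)
        out[f"log2fc_{name}"] = res["log2fc"]
        out[f"pvalue_{name}"] = res["pvalue"]
        out[f"padj_{name}"] = benjamini_hochberg(res["pvalue"].to_numpy())
    ro = occupancy_contrast(matrix, treated, control, light, var_mode=var_mode, mode=ro_mode)
    out["log2fc_RO"] = ro["log2fc"]
    out["pvalue_RO"] = ro["pvalue"]
    out["padj_RO"] = benjamini_hochberg(ro["pvalue"].to_numpy())
    return pd.DataFrame(out, index=matrix.values.index)


def classify(
    diff: pd.DataFrame,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
    ro_lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Assign a regulation class per gene from the three-contrast result.

    significant(X) ⇔ padj_X ≤ padj_max and |log2FC_X| ≥ the fold gate
    (``ro_lfc_min`` for RO, ``lfc_min`` for SL/PL).  Precedence:
    ``RO_changed`` > ``concordant`` (SL and PL) > ``SL_only`` /
    ``PL_only`` > ``unchanged``.  Directions (+1/−1/0) are reported for
    each significant contrast.
    """
    for col in ("padj_SL", "padj_PL", "padj_RO", "log2fc_SL", "log2fc_PL", "log2fc_RO"):
        if col not in diff.columns:
            raise ValueError(f"missing contrast column {col!r}")

    def sig(name: str, gate: float) -> pd.Series:
        return (diff[f"padj_{name}"] <= padj_max) & (diff[f"log2fc_{name}"].abs() >= gate)

    s_sl, s_pl, s_ro = sig("SL", lfc_min), sig("PL", lfc_min), sig("RO", ro_lfc_min)
    cls = pd.Series("unchanged", index=diff.index)
    cls[s_sl] = "SL_only"
    cls[s_pl] = "PL_only"
    cls[s_sl & s_pl] = "concordant"
    cls[s_ro] = "RO_changed"
    out = pd.DataFrame({"class": cls})
    for name, s in (("SL", s_sl), ("PL", s_pl), ("RO", s_ro)):
        out[f"dir_{name}"] = np.where(s, np.sign(diff[f"log2fc_{name}"]), 0).astype(int)
    return out
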