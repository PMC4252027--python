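"""Synthetic translatome data with mechanistic ground truth.

The generator is built around a *two-pool ribosome-loading model*.  Each
mRNA copy of a gene is either sequestered (probability ``s``) — withdrawn
from the translatable pool, carrying zero ribosomes — or active, in which
case it carries ``min(Poisson(λ), C)`` ribosomes, where the capacity
``C = floor(CDS length / ribosome footprint)`` caps how many ribosomes
physically fit on the coding sequence.

Two parameters give the model two independently tunable observables:

* polysomal occupancy — the fraction of copies engaged in polysomes,
  driven up by lowering ``s`` or raising ``λ``;
* ribosome density — ribosomes per engaged copy, driven by ``λ`` alone.

A single-parameter Poisson model cannot decouple them (both observables
are increasing in ``λ``); the two-pool form is the minimal model in which
releasing transcripts from sequestration while initiation slows produces
the pattern of interest: occupancy up, density down.

Mechanistic treatment scenarios are expressed as parameter shifts
(:class:`ScenarioSpec`), an experiment design mixes them across genes, and
:func:`simulate_experiment` emits every input kind the analysis modules
consume — expression matrices, fraction profiles, A254 traces — together
with a per-gene truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fracdist import FractionProfile
from .gradient import FractionScheme, GradientTrace, area

__all__ = [
    "TranscriptModel",
    "ScenarioSpec",
    "SCENARIOS",
    "ExperimentDesign",
    "SimulatedExperiment",
    "simulate_loading",
    "counts_to_profile",
    "synthesize_trace",
    "simulate_experiment",
    "simulate_transcripts",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TranscriptModel:
    """Kinetic parameters of one gene under the two-pool loading model.

    Parameters
    ----------
    cds_len_codons:
        Coding-sequence length in codons; with ``footprint_codons`` it
        sets the ribosome capacity ``C``.
    loading_intensity:
        λ ≥ 0, mean ribosomes loaded per *active* copy before capacity
        truncation.  Summarizes the initiation/elongation balance.
    sequestered_fraction:
        s ∈ [0, 1], probability that a copy is withdrawn from the
        translatable pool (zero ribosomes).
    abundance:
        mRNA copies per cell-equivalent (sets steady-state signal).
    """

    gene_id: str
    cds_len_codons: int
    loading_intensity: float
    sequestered_fraction: float
    abundance: float
    footprint_codons: int = 10

    def __post_init__(self) -> None:
        if self.cds_len_codons < 1 or self.footprint_codons < 1:
            raise ValueError("lengths must be positive integers")
        if not 0.0 <= self.sequestered_fraction <= 1.0:
            raise ValueError("sequestered_fraction must lie in [0, 1]")
        if self.loading_intensity < 0:
            raise ValueError("loading_intensity must be >= 0")
        if self.abundance <= 0:
            raise ValueError("abundance must be > 0")
        if self.capacity < 1:
            raise ValueError("capacity floor(cds/footprint) must be >= 1")

    @property
    def capacity(self) -> int:
        return self.cds_len_codons // self.footprint_codons

    def p_engaged(self, min_ribosomes: int = 1) -> float:
        """P(a copy carries >= ``min_ribosomes``); capacity truncation
        leaves lower-tail probabilities unchanged for thresholds <= C."""
        if min_ribosomes > self.capacity:
            return 0.0
        lam, s = self.loading_intensity, self.sequestered_fraction
        return (1.0 - s) * float(stats.poisson.sf(min_ribosomes - 1, lam))

    def mean_ribosomes(self) -> float:
        """(1−s) · E[min(Poisson(λ), C)] per copy."""
        lam, s, c = self.loading_intensity, self.sequestered_fraction, self.capacity
        # E[min(X, C)] = sum_{k=0}^{C-1} P(X > k)
        e_trunc = float(stats.poisson.sf(np.arange(c), lam).sum())
        return (1.0 - s) * e_trunc


_SCENARIO_NAMES = (
    "null",
    "transcriptional",
    "concordant",
    "initiation_up",
    "sequestration_release",
    "elongation_stall",
    "runoff",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """A mechanistic treatment effect as parameter shifts.

    ``delta_log2_abundance`` moves transcription, ``delta_lambda`` the
    loading intensity and ``delta_s`` the sequestered fraction.  Optional
    ``lambda_control`` / ``s_control`` pin the control regime for the
    class instead of drawing it from the global priors (used e.g. for the
    sequestration-release class, which targets poorly translated,
    partly sequestered transcripts).
    """

    name: str
    delta_log2_abundance: float = 0.0
    delta_lambda: float = 0.0
    delta_s: float = 0.0
    lambda_control: float | None = None
    s_control: float | None = None

    def __post_init__(self) -> None:
        if self.name not in _SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.name == "null" and (
            self.delta_log2_abundance or self.delta_lambda or self.delta_s
        ):
            raise ValueError("the null scenario must have all deltas = 0")
        if self.name == "sequestration_release" and not (
            self.delta_s < 0 and self.delta_lambda <= 0
        ):
            raise ValueError(
                "sequestration_release requires delta_s < 0 and delta_lambda <= 0"
            )


#: Default magnitudes per scenario.  The sequestration-release defaults
#: (s 0.6→0.2, λ 3→2) are the regime in which occupancy rises while
#: density falls: the engaged fraction (1−s)(1−e^{−λ}) climbs from 0.380
#: to 0.692 while ribosomes per engaged copy λ/(1−e^{−λ}) drop from 3.16
#: to 2.31.
SCENARIOS: dict[str, ScenarioSpec] = {
    "null": ScenarioSpec("null"),
    "transcriptional": ScenarioSpec("transcriptional", delta_log2_abundance=1.5),
    "concordant": ScenarioSpec("concordant", delta_log2_abundance=2.0),
    "initiation_up": ScenarioSpec("initiation_up", delta_lambda=1.5),
    "sequestration_release": ScenarioSpec(
        "sequestration_release",
        delta_lambda=-1.0,
        delta_s=-0.4,
        lambda_control=3.0,
        s_control=0.6,
    ),
    "elongation_stall": ScenarioSpec("elongation_stall", delta_lambda=1.0),
    "runoff": ScenarioSpec("runoff", delta_lambda=-1.5),
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic treated-vs-control translatome experiment."""

    n_genes: int
    class_mixture: dict = field(default_factory=lambda: {"null": 1.0})
    n_replicates: int = 3
    noise_sd_log2: float = 0.2
    spike_true: float = 1000.0
    sample_scale_sd_log2: float = 0.0
    n_copies: int = 1000
    seed: int = 0
    scenarios: dict | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.noise_sd_log2 < 0 or self.sample_scale_sd_log2 < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.spike_true <= 0:
            raise ValueError("spike_true must be > 0")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture sums to {total}, not 1")
        for name in self.class_mixture:
            if name not in self.resolved_scenarios():
                raise ValueError(f"no ScenarioSpec for mixture class {name!r}")

    def resolved_scenarios(self) -> dict:
        merged = dict(SCENARIOS)
        if self.scenarios:
            merged.update(self.scenarios)
        return merged


def simulate_loading(model: TranscriptModel, n_copies: int, seed) -> np.ndarray:
    """Ribosome counts for ``n_copies`` copies of one gene.

    Copies are sequestered independently with probability ``s`` (count
    forced to 0); active copies draw Poisson(λ) clamped at the capacity
    ``C``.  Deterministic given the seed / generator.
    """
    if not isinstance(n_copies, (int, np.integer)) or isinstance(n_copies, bool):
        raise ValueError("n_copies must be an integer")
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = _rng(seed)
    active = rng.random(n_copies) >= model.sequestered_fraction
    counts = np.zeros(n_copies, dtype=np.int64)
    n_active = int(active.sum())
    if n_active:
        draws = rng.poisson(model.loading_intensity, n_active)
        counts[active] = np.minimum(draws, model.capacity)
    return counts


def counts_to_profile(
    counts: np.ndarray,
    scheme: FractionScheme,
    gene_id: str = "gene",
    spike_signal: float = 1.0,
    trace_area: float = 1.0,
    scale: float = 1.0,
) -> FractionProfile:
    """Bin per-copy ribosome counts into a 12-fraction profile.

    Conservation holds exactly: the profile sums to ``n_copies * scale``.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    hist = np.zeros(scheme.n_fractions, dtype=float)
    for n, m in zip(*np.unique(counts, return_counts=True)):
        hist[scheme.fraction_for_count(int(n)) - 1] += m
    return FractionProfile(gene_id, hist * scale, spike_signal, trace_area)


def _class_histogram(population) -> np.ndarray:
    """Aggregate #copies carrying n ribosomes over a population.

    ``population`` is either a list of (TranscriptModel, count-vector)
    pairs or an already-aggregated histogram indexed by ribosome count.
    """
    if isinstance(population, np.ndarray) and population.ndim == 1:
        return population.astype(float)
    hists = []
    for _, counts in population:
        counts = np.asarray(counts)
        hists.append(np.bincount(counts))
    if not hists:
        return np.zeros(0)
    size = max(h.size for h in hists)
    out = np.zeros(size)
    for h in hists:
        out[: h.size] += h
    return out


def synthesize_trace(
    population,
    peak_width: float = 0.25,
    baseline: float = 0.02,
    n_points: int = 600,
    scheme: FractionScheme | None = None,
    subunit_area_frac: float = 1.2,
) -> GradientTrace:
    """Render a population of loaded mRNAs as an A254 absorbance trace.

    A254 mass is dominated by rRNA, so each ribosome class ``n >= 1``
    contributes a Gaussian peak with area proportional to ``n`` times the
    number of copies carrying ``n`` ribosomes, centered at the midpoint of
    the gradient fraction that class sediments into (monotone in ``n``).
    A free-subunit (40S/60S) peak near the top carries
    ``subunit_area_frac`` times the total mRNA-bound ribosome mass; the
    default of 1.2 reflects that in plant extracts the free-subunit and
    monosome region holds a bit over half of the UV-absorbing material,
    putting roughly 40% of total area in the polysomal fractions for a
    typical unstressed population.  Free mRNPs (n = 0) contribute no A254
    mass.
    """
    if peak_width <= 0:
        raise ValueError("peak_width must be > 0")
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    scheme = scheme or FractionScheme.default()
    lo, hi = float(scheme.boundaries[0]), float(scheme.boundaries[-1])
    x = np.linspace(lo, hi, n_points)
    y = np.full(n_points, float(baseline))
    hist = _class_histogram(population)

    def add_peak(center: float, peak_area: float) -> None:
        if peak_area <= 0:
            return
        amp = peak_area / (peak_width * math.sqrt(2.0 * math.pi))
        y[:] += amp * np.exp(-0.5 * ((x - center) / peak_width) ** 2)

    total_mass = 0.0
    for n in range(1, hist.size):
        mass = float(n * hist[n])
        total_mass += mass
        add_peak(scheme.fraction_center(scheme.fraction_for_count(n)), mass)
    if total_mass > 0 and subunit_area_frac > 0:
        add_peak(scheme.fraction_center(2), subunit_area_frac * total_mass)
    return GradientTrace(x, y)


@dataclass(frozen=True)
class SimulatedExperiment:
    """Bundle of everything one simulated experiment produced."""

    matrix: object  # diffreg.ExpressionMatrix
    profiles: dict  # sample name -> DataFrame (fraction_1..12, spike, trace_area)
    traces: dict  # sample name -> GradientTrace (baseline-subtracted)
    truth: pd.DataFrame
    design: ExperimentDesign
    scheme: FractionScheme

    def profile(self, sample: str, gene: str) -> FractionProfile:
        row = self.profiles[sample].loc[gene]
        n = self.scheme.n_fractions
        return FractionProfile(
            gene,
            row.iloc[:n].to_numpy(dtype=float),
            float(row["spike"]),
            float(row["trace_area"]),
        )


def _allocate_classes(mixture: dict, n_genes: int) -> list[str]:
    """Deterministic largest-remainder allocation of genes to scenarios."""
    names = sorted(mixture)
    exact = {k: mixture[k] * n_genes for k in names}
    counts = {k: int(math.floor(exact[k])) for k in names}
    short = n_genes - sum(counts.values())
    by_remainder = sorted(names, key=lambda k: (-(exact[k] - counts[k]), k))
    for k in by_remainder[:short]:
        counts[k] += 1
    out: list[str] = []
    for k in names:
        out.extend([k] * counts[k])
    return out


def _gene_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # Counter-based substreams: draws for one unit never depend on how
    # many other units exist or in what order they are generated.
    return np.random.default_rng(np.random.SeedSequence([seed, stream, index]))


def simulate_experiment(
    design: ExperimentDesign,
    scheme: FractionScheme | None = None,
    profiles: bool = True,
    traces: bool = True,
) -> SimulatedExperiment:
    """Simulate a full treated-vs-control translatome experiment.

    For each gene, control parameters are drawn from documented priors
    (CDS length uniform over 100–800 codons, λ uniform over [1.5, 4] with
    s = 0.25 — about 70% of copies ribosome-associated — and log-normal
    abundance), the treated parameters apply the gene's scenario shifts,
    and measured intensities get multiplicative log-normal noise per
    replicate.  Steady-state signal is proportional to abundance;
    polysomal signal to abundance times the probability that a copy
    sediments into the polysomal fractions (counts >= 2 under the default
    scheme).  Fully reproducible from ``design.seed``.
    """
    from .diffreg import ExpressionMatrix  # local import to avoid a cycle

    scheme = scheme or FractionScheme.default()
    specs = design.resolved_scenarios()
    classes = _allocate_classes(design.class_mixture, design.n_genes)
    width = max(4, len(str(design.n_genes)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, design.n_genes + 1)]

    poly_min = min(
        n for n in range(0, scheme.count_cap + 1) if scheme.fraction_for_count(n) >= scheme.polysome_start_fraction
    )

    conditions = ("control", "sucrose")
    reps = range(1, design.n_replicates + 1)
    matrix_cols = [
        f"{cond}.light.{level}.{r}"
        for cond in conditions
        for level in ("steady_state", "polysomal")
        for r in reps
    ]
    profile_samples = [f"{cond}.light.{r}" for cond in conditions for r in reps]

    # Per-sample handling factors (RNA recovery) — captured by the spike.
    srng = _gene_rng(design.seed, 2, 0)
    if design.sample_scale_sd_log2 > 0:
        g = 2.0 ** srng.normal(0.0, design.sample_scale_sd_log2, len(matrix_cols))
    else:
        g = np.ones(len(matrix_cols))
    spikes = pd.Series(design.spike_true * g, index=matrix_cols)

    truth_rows = []
    values = np.empty((design.n_genes, len(matrix_cols)))
    profile_blocks = {s: [] for s in profile_samples} if profiles else None
    class_hists = {s: np.zeros(64) for s in profile_samples} if traces else None

    for i, (gene, cls) in enumerate(zip(gene_ids, classes)):
        spec: ScenarioSpec = specs[cls]
        rng = _gene_rng(design.seed, 0, i)

        if cls == "sequestration_release":
            cds_len = int(rng.integers(100, 301))
        else:
            cds_len = int(rng.integers(100, 801))
        lam_c = spec.lambda_control if spec.lambda_control is not None else float(
            rng.uniform(1.5, 4.0)
        )
        s_c = spec.s_control if spec.s_control is not None else 0.25
        abund_c = float(rng.lognormal(math.log(200.0), 0.8))

        lam_t = max(lam_c + spec.delta_lambda, 0.0)
        s_t = float(np.clip(s_c + spec.delta_s, 0.0, 1.0))
        abund_t = abund_c * 2.0 ** spec.delta_log2_abundance

        m_c = TranscriptModel(gene, cds_len, lam_c, s_c, abund_c)
        m_t = TranscriptModel(gene, cds_len, lam_t, s_t, abund_t)
        occ_c = m_c.p_engaged(poly_min)
        occ_t = m_t.p_engaged(poly_min)

        if occ_c > 0 and occ_t > 0:
            d_pl = spec.delta_log2_abundance + float(np.log2(occ_t) - np.log2(occ_c))
        else:  # a fully silent condition has no defined polysomal ratio
            d_pl = float("nan")
        truth_rows.append(
            {
                "gene_id": gene,
                "scenario": cls,
                "true_dlog2_sl": spec.delta_log2_abundance,
                "true_dlog2_pl": d_pl,
                "true_dlog2_ro": d_pl - spec.delta_log2_abundance,
                "lambda_control": lam_c,
                "lambda_treated": lam_t,
                "s_control": s_c,
                "s_treated": s_t,
                "abundance_control": abund_c,
                "cds_len_codons": cds_len,
                "occ_control": occ_c,
                "occ_treated": occ_t,
            }
        )

        base = []
        for cond in conditions:
            abund, occ = (abund_c, occ_c) if cond == "control" else (abund_t, occ_t)
            for level in ("steady_state", "polysomal"):
                sig = abund if level == "steady_state" else max(abund * occ, 1e-12)
                base.extend([sig] * design.n_replicates)
        eps = (
            rng.normal(0.0, design.noise_sd_log2, len(matrix_cols))
            if design.noise_sd_log2 > 0
            else np.zeros(len(matrix_cols))
        )
        values[i] = np.asarray(base) * 2.0 ** eps * g

        if profiles or traces:
            lrng = _gene_rng(design.seed, 1, i)
            for cond in conditions:
                model = m_c if cond == "control" else m_t
                for r in reps:
                    counts = simulate_loading(model, design.n_copies, lrng)
                    sample = f"{cond}.light.{r}"
                    if traces:
                        h = np.bincount(counts, minlength=class_hists[sample].size)
                        if h.size > class_hists[sample].size:
                            class_hists[sample] = np.pad(
                                class_hists[sample], (0, h.size - class_hists[sample].size)
                            )
                        class_hists[sample][: h.size] += h
                    if profiles:
                        prof = counts_to_profile(
                            counts,
                            scheme,
                            gene,
                            scale=model.abundance / design.n_copies,
                        )
                        profile_blocks[sample].append(prof.abundances)

    matrix = ExpressionMatrix.from_columns(
        pd.DataFrame(values, index=gene_ids, columns=matrix_cols), log2=False, spike=spikes
    )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")

    trace_out: dict = {}
    poly_areas: dict = {}
    if traces:
        for sample in profile_samples:
            tr = synthesize_trace(class_hists[sample], scheme=scheme, baseline=0.0)
            trace_out[sample] = tr
            poly_lo = scheme.fraction_span(scheme.polysome_start_fraction)[0]
            poly_areas[sample] = area(tr, poly_lo, float(scheme.boundaries[-1]))

    profile_out: dict = {}
    if profiles:
        ncols = scheme.n_fractions
        for sample in profile_samples:
            df = pd.DataFrame(
                np.vstack(profile_blocks[sample]),
                index=gene_ids,
                columns=[f"fraction_{f}" for f in range(1, ncols + 1)],
            )
            df["spike"] = design.spike_true
            df["trace_area"] = poly_areas.get(sample, 1.0)
            profile_out[sample] = df

    return SimulatedExperiment(matrix, profile_out, trace_out, truth, design, scheme)


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list("ACGT"), size=length, p=probs)) if length else ""


def simulate_transcripts(
    truth: pd.DataFrame,
    seed: int,
    utr5_gc: float = 0.35,
    target_utr5_gc: float = 0.50,
    target_scenarios: tuple = ("sequestration_release",),
    planted_motif: str | None = "GGAGAG",
    plant_prob: float = 0.8,
):
    """Synthetic UTR/CDS sequences matching a truth table.

    Genes in ``target_scenarios`` emulate the reported signature of
    translationally controlled transcripts: shorter CDS (already encoded
    in the truth table's CDS lengths), GC-richer 5′UTRs, and — optionally
    — a planted instance of a degenerate motif in the 5′UTR with
    probability ``plant_prob``.  Returns ``(annotations, planted)`` where
    ``annotations`` maps gene id to a :class:`~polyoccu.seqfeat.TranscriptAnnotation`
    and ``planted`` is a boolean Series.
    """
    from .seqfeat import TranscriptAnnotation  # avoid import cycle

    annotations = {}
    planted = {}
    for i, (gene, row) in enumerate(truth.iterrows()):
        rng = _gene_rng(seed, 3, i)
        is_target = row["scenario"] in target_scenarios
        gc = target_utr5_gc if is_target else utr5_gc
        utr5 = _random_seq(rng, int(rng.integers(30, 301)), gc)
        utr3 = _random_seq(rng, int(rng.integers(50, 401)), 0.30)
        n_codons = int(row["cds_len_codons"])
        body = rng.choice(_SENSE_CODONS, size=max(n_codons - 2, 0))
        cds = "ATG" + "".join(body) + "TGA"
        plant = bool(is_target and planted_motif and rng.random() < plant_prob)
        if plant:
            pos = int(rng.integers(0, max(len(utr5) - len(planted_motif), 0) + 1))
            utr5 = utr5[:pos] + planted_motif + utr5[pos + len(planted_motif):]
        annotations[gene] = TranscriptAnnotation(gene, utr5, cds, utr3)
        planted[gene] = plant
    return annotations, pd.Series(planted)
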