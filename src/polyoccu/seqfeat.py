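"""Transcript sequence features of translationally regulated genes.

Computes, per transcript region (5′UTR / CDS / 3′UTR / full transcript):
length, GC content, Wright's effective number of codons (Nc), upstream
open reading frames (uORFs) in the 5′UTR, and the −5..+8 start-codon
context; plus rank-based target-vs-background comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TranscriptAnnotation",
    "UORF",
    "region_features",
    "effective_number_of_codons",
    "find_uorfs",
    "start_context",
    "compare_features",
    "feature_table",
]

_VALID = set("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")

# Standard genetic code, codon -> amino acid (stops excluded below).
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

# Degeneracy class of each amino acid (number of synonymous codons).
_AA_DEGENERACY: dict[str, int] = {}
for _codon, _aa in _CODE.items():
    _AA_DEGENERACY[_aa] = _AA_DEGENERACY.get(_aa, 0) + 1
# Family sizes per degeneracy class and Wright's weights 9/F2 + 1/F3 + 5/F4 + 3/F6
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}


def _check_bases(seq: str, region: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid character(s) {sorted(bad)} in {region}")


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript split into 5′UTR, CDS and 3′UTR nucleotide strings.

    Concatenating utr5 + cds + utr3 gives transcript coordinates
    (1-based).  The CDS must be >= 3 nt and divisible by 3 unless
    ``lenient=True``, which flags rather than silently truncates.
    """

    gene_id: str
    utr5: str
    cds: str
    utr3: str
    lenient: bool = False

    def __post_init__(self) -> None:
        for name in ("utr5", "cds", "utr3"):
            seq = getattr(self, name).upper()
            _check_bases(seq, name)
            object.__setattr__(self, name, seq)
        if not self.lenient and (len(self.cds) < 3 or len(self.cds) % 3 != 0):
            raise ValueError(
                f"{self.gene_id}: CDS length {len(self.cds)} is not a positive "
                "multiple of 3 (set lenient=True to keep the record flagged)"
            )

    @property
    def transcript(self) -> str:
        return self.utr5 + self.cds + self.utr3


def _gc(seq: str) -> float:
    unambig = sum(seq.count(b) for b in "ACGT")
    if unambig == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / unambig


def region_features(ann: TranscriptAnnotation) -> dict:
    """Length (nt) and GC fraction per region and for the full transcript.

    GC is computed over unambiguous bases only; an empty region has
    length 0 and undefined (NaN) GC.
    """
    out = {}
    for name, seq in (
        ("utr5", ann.utr5),
        ("cds", ann.cds),
        ("utr3", ann.utr3),
        ("transcript", ann.transcript),
    ):
        out[f"len_{name}"] = len(seq)
        out[f"gc_{name}"] = _gc(seq)
    return out


def effective_number_of_codons(cds: str, min_codons_per_aa: int = 2) -> float:
    """Wright's effective number of codons (Nc) of a coding sequence.

    For each amino acid with n >= ``min_codons_per_aa`` observed codons,
    the homozygosity estimate is F̂ = (n·Σp̂² − 1)/(n − 1).  Nc sums the
    inverse class means, 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, where class k
    averages F̂ over amino acids with k synonymous codons.  A class with
    no usable amino acid borrows the mean F̂ of the classes that are
    observed.  The result is clamped to [20, 61]; NaN if no class is
    observed at all.  Stop codons are excluded.
    """
    cds = cds.upper()
    _check_bases(cds, "cds")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    counts: dict[str, dict[str, int]] = {}
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = _CODE.get(codon)
        if aa is None:  # stop codon or ambiguous base
            continue
        counts.setdefault(aa, {})
        counts[aa][codon] = counts[aa].get(codon, 0) + 1

    f_by_class: dict[int, list[float]] = {k: [] for k in _CLASS_SIZES}
    for aa, codon_counts in counts.items():
        deg = _AA_DEGENERACY[aa]
        if deg == 1:
            continue  # Met, Trp carry no bias information
        n = sum(codon_counts.values())
        if n < min_codons_per_aa:
            continue
        p2 = sum((c / n) ** 2 for c in codon_counts.values())
        f_hat = (n * p2 - 1.0) / (n - 1.0)
        if f_hat > 0:  # F̂ = 0 cannot be inverted; treat as unobserved
            f_by_class[deg].append(f_hat)

    class_means = {k: float(np.mean(v)) for k, v in f_by_class.items() if v}
    if not class_means:
        return float("nan")
    fallback = float(np.mean(list(class_means.values())))
    nc = 2.0
    for k, n_fam in _CLASS_SIZES.items():
        nc += n_fam / class_means.get(k, fallback)
    return float(np.clip(nc, 20.0, 61.0))


@dataclass(frozen=True)
class UORF:
    """An upstream ORF; 1-based inclusive coordinates in the 5′UTR
    (``end`` may extend into the CDS when it overlaps the main ORF)."""

    start: int
    end: int
    n_codons: int  # codons including the ATG, excluding the stop
    overlaps_cds: bool


def find_uorfs(
    utr5: str,
    cds: str = "",
    min_codons: int = 1,
    allow_overlap: bool = False,
) -> list[UORF]:
    """Scan a 5′UTR (5′→3′) for upstream open reading frames.

    Every ATG opens a candidate; it becomes a uORF when an in-frame stop
    codon lies entirely within the 5′UTR (or, with ``allow_overlap``,
    downstream within the CDS).  ``min_codons`` counts the start codon, so
    the default of 1 accepts an ATG immediately followed by a stop.
    Candidates nested in the same frame sharing a stop with an
    already-reported, longer uORF are reported once (outermost start).
    Lowercase input is normalized; codons containing N never match.
    """
    utr5 = utr5.upper()
    cds = cds.upper()
    _check_bases(utr5, "utr5")
    _check_bases(cds, "cds")
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    search = utr5 + (cds if allow_overlap else "")
    out: list[UORF] = []
    claimed: set[tuple[int, int]] = set()  # (frame, stop start) already reported
    for i in range(len(utr5) - 2):
        if utr5[i : i + 3] != "ATG":
            continue
        frame = i % 3
        stop_at = None
        for j in range(i + 3, len(search) - 2, 3):
            if search[j : j + 3] in STOP_CODONS:
                stop_at = j
                break
        if stop_at is None:
            continue
        if not allow_overlap and stop_at + 3 > len(utr5):
            continue
        n_codons = (stop_at - i) // 3
        if n_codons < min_codons:
            continue
        if (frame, stop_at) in claimed:
            continue
        claimed.add((frame, stop_at))
        out.append(
            UORF(
                start=i + 1,
                end=stop_at + 3,
                n_codons=n_codons,
                overlaps_cds=stop_at + 3 > len(utr5),
            )
        )
    return out


def start_context(ann: TranscriptAnnotation) -> str:
    """The 13-nt −5..+8 context around the main start codon.

    Position +1 is the A of the CDS ATG (there is no position 0);
    −5..−1 are the last five 5′UTR bases, +1..+8 the first eight CDS
    bases.  Shortfalls are padded with 'N' (left for the UTR, right for a
    CDS shorter than 8 nt, with a warning).
    """
    left = ann.utr5[-5:].rjust(5, "N")
    if len(ann.cds) < 8:
        warnings.warn(f"{ann.gene_id}: CDS shorter than 8 nt; right-padding context")
    right = ann.cds[:8].ljust(8, "N")
    return left + right


def feature_table(annotations: dict, uorf_kwargs: dict | None = None) -> pd.DataFrame:
    """Per-gene feature vector table for a set of annotations."""
    rows = {}
    for gene, ann in annotations.items():
        feats = region_features(ann)
        feats["nc"] = effective_number_of_codons(ann.cds) if len(ann.cds) % 3 == 0 else float("nan")
        uorfs = find_uorfs(ann.utr5, ann.cds, **(uorf_kwargs or {}))
        feats["n_uorfs"] = len(uorfs)
        feats["start_context"] = start_context(ann)
        rows[gene] = feats
    return pd.DataFrame.from_dict(rows, orient="index")


_CONTINUOUS = (
    "len_transcript",
    "len_cds",
    "len_utr5",
    "len_utr3",
    "gc_transcript",
    "gc_cds",
    "gc_utr5",
    "gc_utr3",
    "nc",
)


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Exact null distribution where feasible; tie- and continuity-corrected
    # normal approximation otherwise.
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_features(
    target: pd.DataFrame,
    background: pd.DataFrame,
    min_defined: int = 5,
) -> pd.DataFrame:
    """Target-vs-background tests per feature.

    Continuous features (lengths, GC, Nc) use the two-sided Wilcoxon
    rank-sum test; uORF presence (n_uorfs >= 1) uses a one-tailed
    Fisher's exact test for enrichment in the target set.  Features with
    fewer than ``min_defined`` defined values on either side are skipped
    with a warning.
    """
    rows = []
    for feat in _CONTINUOUS:
        if feat not in target.columns or feat not in background.columns:
            continue
        x = target[feat].dropna().to_numpy(dtype=float)
        y = background[feat].dropna().to_numpy(dtype=float)
        if x.size < min_defined or y.size < min_defined:
            warnings.warn(f"feature {feat!r}: fewer than {min_defined} defined values; skipped")
            continue
        u, p = _ranksum(x, y)
        rows.append(
            {
                "feature": feat,
                "test": "wilcoxon_ranksum",
                "statistic": u,
                "pvalue": p,
                "median_target": float(np.median(x)),
                "median_background": float(np.median(y)),
            }
        )
    if "n_uorfs" in target.columns and "n_uorfs" in background.columns:
        k_t = int((target["n_uorfs"] >= 1).sum())
        k_b = int((background["n_uorfs"] >= 1).sum())
        table = [[k_t, len(target) - k_t], [k_b, len(background) - k_b]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "feature": "has_uorf",
                "test": "fisher_one_tailed",
                "statistic": float(k_t),
                "pvalue": float(p),
                "median_target": k_t / max(len(target), 1),
                "median_background": k_b / max(len(background), 1),
            }
        )
    return pd.DataFrame(rows)
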