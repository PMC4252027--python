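"""Degenerate consensus motif scanning and enrichment.

Motifs are written in bracket notation — literal bases plus bracketed
alternative sets, e.g. ``[GA][GA]AGA[GA]`` — and scanned exactly against
sense-strand transcript regions (every offset, overlapping hits counted,
``N`` never matches).  Enrichment of a motif in a target gene list versus
the background is a one-tailed Fisher's exact test on the 2×2 table of
genes with/without a hit, with fold enrichment
``(k_target/n_target) / (k_bg/n_bg)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MotifPattern",
    "EnrichmentResult",
    "parse_consensus",
    "scan",
    "motif_enrichment",
    "enrichment_table",
]


@dataclass(frozen=True)
class MotifPattern:
    consensus: str
    positions: tuple  # tuple of frozensets of allowed bases

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def regex(self) -> str:
        return "".join(
            next(iter(s)) if len(s) == 1 else "[" + "".join(sorted(s)) + "]"
            for s in self.positions
        )


def parse_consensus(consensus: str) -> MotifPattern:
    """Parse a bracket-notation consensus into per-position base sets.

    Raises ``ValueError`` naming the offending position for unbalanced or
    empty brackets and characters outside ACGT.
    """
    if not consensus:
        raise ValueError("empty consensus")
    positions = []
    i = 0
    while i < len(consensus):
        ch = consensus[i]
        if ch == "[":
            j = consensus.find("]", i)
            if j < 0:
                raise ValueError(f"unbalanced '[' at position {i + 1}")
            inner = consensus[i + 1 : j]
            if not inner:
                raise ValueError(f"empty bracket at position {i + 1}")
            bad = set(inner) - set("ACGT")
            if bad:
                raise ValueError(
                    f"invalid character(s) {sorted(bad)} in bracket at position {i + 1}"
                )
            positions.append(frozenset(inner))
            i = j + 1
        elif ch == "]":
            raise ValueError(f"unbalanced ']' at position {i + 1}")
        elif ch in "ACGT":
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(f"invalid character {ch!r} at position {i + 1}")
    return MotifPattern(consensus, tuple(positions))


def scan(seqs, pattern: MotifPattern) -> tuple[dict, set]:
    """Count motif hits per gene on the given (sense) strand.

    Returns ``(per-gene hit count, set of genes with >= 1 hit)``.  All
    overlapping occurrences count; positions holding ``N`` never match.
    """
    rx = re.compile(f"(?=(?:{pattern.regex}))")
    counts: dict = {}
    hits: set = set()
    for gene, seq in seqs.items():
        n = sum(1 for _ in rx.finditer(seq.upper()))
        counts[gene] = n
        if n:
            hits.add(gene)
    return counts, hits


@dataclass(frozen=True)
class EnrichmentResult:
    """2×2 enrichment of a motif in the target list vs the background."""

    k_target: int
    n_target: int
    k_bg: int
    n_bg: int
    fold: float
    pvalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.k_target <= self.n_target and 0 <= self.k_bg <= self.n_bg):
            raise ValueError("need 0 <= k <= n on both sides")


def motif_enrichment(
    k_target: int,
    n_target: int,
    k_bg: int,
    n_bg: int,
    background_includes_target: bool = False,
) -> EnrichmentResult:
    """One-tailed Fisher enrichment of hits in the target gene list.

    By default the background counts exclude the target genes, so the
    hypergeometric population is the union of both lists (size
    ``n_target + n_bg`` with ``k_target + k_bg`` hit genes).  With
    ``background_includes_target`` the background IS the population.  The
    p-value is the upper hypergeometric tail P(X >= k_target); fold is
    the ratio of hit rates (infinite when the background rate is zero and
    the target rate is not).
    """
    if n_target <= 0 or n_bg <= 0:
        raise ValueError("n_target and n_bg must be > 0")
    if not (0 <= k_target <= n_target and 0 <= k_bg <= n_bg):
        raise ValueError("need 0 <= k <= n on both sides")
    if background_includes_target:
        pop, successes = n_bg, k_bg
        if k_target > k_bg or n_target > n_bg:
            raise ValueError("target must be a subset of an inclusive background")
    else:
        pop, successes = n_target + n_bg, k_target + k_bg
    p = float(stats.hypergeom.sf(k_target - 1, pop, successes, n_target))
    rate_t = k_target / n_target
    rate_b = k_bg / n_bg
    fold = float("inf") if rate_b == 0 and rate_t > 0 else (
        float("nan") if rate_b == 0 else rate_t / rate_b
    )
    return EnrichmentResult(k_target, n_target, k_bg, n_bg, fold, min(p, 1.0))


def enrichment_table(
    seqs_by_region: dict,
    patterns,
    target_genes,
    background_includes_target: bool = False,
) -> pd.DataFrame:
    """Motif-by-region enrichment table for a target gene list.

    ``seqs_by_region`` maps region name (e.g. ``utr5``, ``cds``) to a
    ``{gene: sequence}`` mapping; genes lacking a region are simply not
    scanned there, so denominators are per-region gene counts.  For each
    (motif, region) the gene-level 2×2 enrichment is computed; total
    occurrence counts are reported alongside.
    """
    targets = set(target_genes)
    rows = []
    for consensus in patterns:
        pattern = consensus if isinstance(consensus, MotifPattern) else parse_consensus(consensus)
        for region, seqs in seqs_by_region.items():
            counts, hit_genes = scan(seqs, pattern)
            genes = set(seqs)
            t_genes = genes & targets
            b_genes = genes if background_includes_target else genes - targets
            k_t = len(hit_genes & t_genes)
            k_b = len(hit_genes & b_genes)
            if not t_genes or not b_genes:
                continue
            res = motif_enrichment(
                k_t, len(t_genes), k_b, len(b_genes), background_includes_target
            )
            rows.append(
                {
                    "consensus": pattern.consensus,
                    "region": region,
                    "target_hit_genes": k_t,
                    "target_genes": len(t_genes),
                    "background_hit_genes": k_b,
                    "background_genes": len(b_genes),
                    "target_occurrences": int(sum(counts[g] for g in t_genes)),
                    "background_occurrences": int(sum(counts[g] for g in b_genes)),
                    "fold_enrichment": res.fold,
                    "pvalue": res.pvalue,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["consensus", "region"]).reset_index(drop=True)
    return df
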