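"""Readers and writers for the plain-text formats the pipeline uses.

Traces are two-column CSV (position, a254); expression matrices are TSV
with ``condition.light.level.rep`` sample columns; fraction profiles and
truth tables are TSV; transcript regions travel as FASTA with record ids
``<gene>.utr5`` / ``<gene>.cds`` / ``<gene>.utr3``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffreg import ExpressionMatrix
from .gradient import FractionScheme, GradientTrace
from .seqfeat import TranscriptAnnotation

__all__ = [
    "read_trace",
    "write_trace",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_profiles",
    "write_profiles",
    "read_annotations",
    "write_annotations",
    "read_scheme",
]


def read_trace(path) -> GradientTrace:
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "position" not in cols or "a254" not in cols:
        raise ValueError(f"{path}: expected columns 'position' and 'a254'")
    return GradientTrace(df["position"].to_numpy(float), df["a254"].to_numpy(float))


def write_trace(trace: GradientTrace, path) -> None:
    pd.DataFrame({"position": trace.positions, "a254": trace.absorbance}).to_csv(
        path, index=False, float_format="%.8g"
    )


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    if matrix.spike is not None:
        df.loc["__spike__"] = matrix.spike.reindex(df.columns)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.8g")


def read_expression_matrix(path, log2: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    spike = None
    if "__spike__" in df.index:
        spike = df.loc["__spike__"]
        df = df.drop(index="__spike__")
    return ExpressionMatrix.from_columns(df, log2=log2, spike=spike)


def write_profiles(profiles: dict, path) -> None:
    """One TSV for all samples: sample, gene, fraction_1.., spike, trace_area."""
    frames = []
    for sample, df in sorted(profiles.items()):
        block = df.copy()
        block.insert(0, "sample", sample)
        frames.append(block)
    pd.concat(frames).to_csv(path, sep="\t", index_label="gene_id", float_format="%.8g")


def read_profiles(path) -> dict:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return {s: g.drop(columns="sample") for s, g in df.groupby("sample", sort=True)}


def write_annotations(annotations: dict, path) -> None:
    records = []
    for gene in sorted(annotations):
        ann: TranscriptAnnotation = annotations[gene]
        for region in ("utr5", "cds", "utr3"):
            seq = getattr(ann, region)
            if seq:
                records.append(SeqRecord(Seq(seq), id=f"{gene}.{region}", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_annotations(path, lenient: bool = False) -> dict:
    regions: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, region = rec.id.rpartition(".")
        if region not in ("utr5", "cds", "utr3") or not gene:
            raise ValueError(f"record id {rec.id!r} is not <gene>.<utr5|cds|utr3>")
        regions.setdefault(gene, {})[region] = str(rec.seq)
    return {
        gene: TranscriptAnnotation(
            gene,
            parts.get("utr5", ""),
            parts.get("cds", ""),
            parts.get("utr3", ""),
            lenient=lenient,
        )
        for gene, parts in sorted(regions.items())
    }


def read_scheme(path) -> FractionScheme:
    """Fraction scheme from YAML: boundaries, pools, polysome_start_fraction."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    kwargs = {"boundaries": np.asarray(cfg["boundaries"], dtype=float)}
    if "pools" in cfg:
        kwargs["pools"] = {k: tuple(v) for k, v in cfg["pools"].items()}
    if "polysome_start_fraction" in cfg:
        kwargs["polysome_start_fraction"] = int(cfg["polysome_start_fraction"])
    if "count_map" in cfg:
        kwargs["count_map"] = {int(k): int(v) for k, v in cfg["count_map"].items()}
    if "count_cap" in cfg:
        kwargs["count_cap"] = int(cfg["count_cap"])
    return FractionScheme(**kwargs)
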