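"""Gene-dosage expression outlier analysis.

Per-gene expression Z-scores are computed over the whole cohort (cases and
controls scaled together), genes are matched to CNV calls by genomic
position, and pairs in which both the expression Z and the CNV depth score
exceed |2| in the dosage-concordant direction are flagged as outlier
pairs. The direction of expression change across all usable pairs is
summarised by its Pearson correlation with the call sign (+1 duplication,
-1 deletion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .caller import CnvCall


@dataclass
class ExpressionZ:
    """Gene x sample outlier Z-scores over the full cohort."""

    z: pd.DataFrame  # NaN rows at masked (non-expressed / zero-variance) genes
    expressed: pd.Series  # boolean, True where the gene row is usable
    n_samples_scaled: int


def expression_zscores(
    expr_counts: pd.DataFrame, min_expression: float = 1.0
) -> ExpressionZ:
    """Standardise each gene's counts across all samples (mean 0, sd 1, n-1).

    Genes with median count below ``min_expression`` are masked as not
    detectably expressed; zero-variance genes are masked with a warning.
    Scaling is over every sample at once, so each case's outlier score is
    measured against the mixed case+control reference.
    """
    if expr_counts.shape[1] < 2:
        raise ValueError("expression scaling needs at least two samples")
    values = expr_counts.to_numpy(dtype=float)
    expressed = np.median(values, axis=1) >= min_expression
    sd = values.std(axis=1, ddof=1)
    zero_var = expressed & (sd == 0)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} constant gene(s) masked", RuntimeWarning, stacklevel=2
        )
        expressed = expressed & (sd > 0)
    z = np.full_like(values, np.nan)
    if expressed.any():
        mu = values[expressed].mean(axis=1, keepdims=True)
        z[expressed] = (values[expressed] - mu) / sd[expressed, None]
    return ExpressionZ(
        z=pd.DataFrame(z, index=expr_counts.index, columns=expr_counts.columns),
        expressed=pd.Series(expressed, index=expr_counts.index, name="expressed"),
        n_samples_scaled=expr_counts.shape[1],
    )


def validate_gene_models(genes: pd.DataFrame) -> pd.DataFrame:
    """Gene model table: chrom, start, end, gene_id (BED-like, sorted, unique)."""
    required = {"chrom", "start", "end", "gene_id"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene models need columns {sorted(required)}")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids")
    return genes


@dataclass
class DosagePair:
    """One (CNV call, overlapping gene) pair with both outlier scores."""

    call: CnvCall
    gene_id: str
    sample: str
    expr_z: float | None  # None when the gene is not detectably expressed
    cnv_sign: int  # +1 dup, -1 del
    cnv_score: float  # mean SVD-ZRPKM of the call in this sample
    usable: bool
    outlier_pair: bool = False


def match_genes_to_calls(
    calls: list[CnvCall],
    genes: pd.DataFrame,
    exprz: ExpressionZ,
    flank_bp: int = 0,
) -> list[DosagePair]:
    """Join calls to genes in or adjacent to them (within ``flank_bp``).

    Emits one pair per (call, gene) whose interval overlaps the call
    extended by the flank on both sides. Genes absent from the expression
    matrix or masked as not expressed yield unusable pairs (null Z) that
    are kept for bookkeeping but excluded from outlier statistics.
    """
    validate_gene_models(genes)
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples():
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end), str(row.gene_id)
        )
    z = exprz.z
    pairs: list[DosagePair] = []
    for call in calls:
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(call.start - flank_bp, call.end + flank_bp))
        for iv in hits:
            gene_id = iv.data
            usable = (
                gene_id in z.index
                and call.sample in z.columns
                and bool(exprz.expressed.get(gene_id, False))
            )
            expr_z = float(z.at[gene_id, call.sample]) if usable else None
            pairs.append(
                DosagePair(
                    call=call,
                    gene_id=gene_id,
                    sample=call.sample,
                    expr_z=expr_z,
                    cnv_sign=call.sign,
                    cnv_score=call.mean_score,
                    usable=usable,
                )
            )
    return pairs


def flag_outlier_pairs(
    pairs: list[DosagePair],
    z_cutoff: float = 2.0,
    require_same_sign: bool = True,
) -> tuple[list[DosagePair], pd.DataFrame]:
    """Set ``outlier_pair`` and summarise outlier genes per call.

    A pair is an outlier when |expression Z| > cutoff and |CNV score| >
    cutoff, and (by default) the expression change points the same way as
    the copy-number change. The per-call summary counts expressed genes,
    outlier genes and direction-consistent outliers, supporting
    statements like "all N genes in the interval are down-regulated".
    """
    for pair in pairs:
        if not pair.usable or pair.expr_z is None:
            pair.outlier_pair = False
            continue
        beyond = abs(pair.expr_z) > z_cutoff and abs(pair.cnv_score) > z_cutoff
        if require_same_sign:
            beyond = beyond and np.sign(pair.expr_z) == pair.cnv_sign
        pair.outlier_pair = bool(beyond)

    rows = []
    by_call: dict[int, list[DosagePair]] = {}
    order: list[CnvCall] = []
    for pair in pairs:
        key = id(pair.call)
        if key not in by_call:
            by_call[key] = []
            order.append(pair.call)
        by_call[key].append(pair)
    for call in order:
        group = by_call[id(call)]
        usable = [p for p in group if p.usable]
        outliers = [p for p in usable if p.outlier_pair]
        consistent = [
            p for p in usable if p.expr_z is not None
            and abs(p.expr_z) > z_cutoff and np.sign(p.expr_z) == p.cnv_sign
        ]
        rows.append(
            {
                "sample": call.sample,
                "chrom": call.chrom,
                "start": call.start,
                "end": call.end,
                "type": call.type,
                "n_genes": len(group),
                "n_expressed": len(usable),
                "n_outlier_pairs": len(outliers),
                "n_direction_consistent": len(consistent),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "start", "end", "type",
            "n_genes", "n_expressed", "n_outlier_pairs", "n_direction_consistent",
        ],
    )
    return pairs, summary


def dosage_direction_correlation(pairs: list[DosagePair]) -> tuple[float, int, float]:
    """Pearson r between expression Z and call sign over usable pairs.

    Returns (r, n, two-sided p). Requires at least three usable pairs;
    warns when only one call sign is represented, since the correlation
    is then driven by a degenerate design.
    """
    usable = [p for p in pairs if p.usable and p.expr_z is not None]
    if len(usable) < 3:
        raise ValueError("need at least three usable pairs for a correlation")
    z = np.array([p.expr_z for p in usable], dtype=float)
    sign = np.array([p.cnv_sign for p in usable], dtype=float)
    if len(set(sign)) == 1:
        warnings.warn(
            "all pairs share one CNV sign; correlation design is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan"), len(usable), float("nan")
    r, p = stats.pearsonr(z, sign)
    return float(r), len(usable), float(p)
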