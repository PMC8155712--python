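"""Ortholog expression comparison: counting, normalization, DEG calling.

Counts of RNA-seq 5' ends within each gene body are normalized with
median-of-ratios size factors (reference = per-gene geometric mean across
samples), and differential expression between two strains is called on
log2-transformed normalized counts with a Benjamini-Hochberg-adjusted
two-sample test.  A gene is a DEG when its fold change exceeds 2-fold
(|log2 FC| > 1) and the adjusted p-value is below 0.01.

The default test pools the log-scale variance across genes (a
common-dispersion z-test); per-gene Welch t is available as
``method="welch"``.  Fold change and log transforms use a 0.5 pseudocount.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import AnnotationSet, EndCountTrack

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5


def count_matrix(
    tracks_a: Sequence[EndCountTrack],
    tracks_b: Sequence[EndCountTrack],
    annotation_a: AnnotationSet,
    annotation_b: AnnotationSet,
    pairs: Sequence,
) -> pd.DataFrame:
    """Per-ortholog-pair, per-sample sums of raw 5'-end counts in the gene
    body (strand-aware).  Columns are ``A_<rep>`` / ``B_<rep>``."""
    for t in list(tracks_a) + list(tracks_b):
        if t.normalized:
            raise ValueError("count_matrix requires raw (unnormalized) tracks")
        if t.total() == 0:
            logger.warning("track %s/%s is empty", t.library_type, t.replicate_id)
    rows = []
    index = []
    for pair in pairs:
        gene_a_id, gene_b_id = pair.gene_a, pair.gene_b
        if gene_a_id not in annotation_a:
            raise KeyError(f"pair gene {gene_a_id!r} absent from annotation A")
        if gene_b_id not in annotation_b:
            raise KeyError(f"pair gene {gene_b_id!r} absent from annotation B")
        ga, gb = annotation_a.get(gene_a_id), annotation_b.get(gene_b_id)
        row = [_gene_count(t, ga) for t in tracks_a] + \
              [_gene_count(t, gb) for t in tracks_b]
        rows.append(row)
        index.append(gene_a_id)
    columns = [f"A_{t.replicate_id}" for t in tracks_a] + \
              [f"B_{t.replicate_id}" for t in tracks_b]
    return pd.DataFrame(rows, index=index, columns=columns, dtype=np.int64)


def _gene_count(track: EndCountTrack, gene) -> int:
    counts = track.counts(gene.strand)
    return int(sum(v for p, v in counts.items() if gene.start <= p < gene.end))


def size_factors_median_of_ratios(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq definition).

    Reference = per-gene geometric mean over samples, restricted to genes
    with nonzero counts in every sample; factor = median over genes of
    count / reference.
    """
    counts = matrix.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = counts[all_nonzero]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


@dataclass
class DEGRecord:
    pair_id: str
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    is_deg: bool


def call_degs(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc_min: float = 1.0,
    alpha: float = 0.01,
    method: str = "pooled",
    size_factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Differential expression of strain A over strain B.

    Returns a DataFrame indexed by pair id with columns
    ``log2_fold_change``, ``p_value``, ``adjusted_p``, ``is_deg``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("sample groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("at least 2 replicates per group are required")
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(matrix[group_a + group_b])
    norm = matrix[group_a + group_b].to_numpy(dtype=float) / \
        size_factors[group_a + group_b].to_numpy()
    na, nb = len(group_a), len(group_b)
    a, b = norm[:, :na], norm[:, na:]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))

    la, lb = np.log2(a + PSEUDOCOUNT), np.log2(b + PSEUDOCOUNT)
    diff = la.mean(axis=1) - lb.mean(axis=1)
    var_a, var_b = la.var(axis=1, ddof=1), lb.var(axis=1, ddof=1)
    if method == "pooled":
        # common log-scale variance across genes: the shared-dispersion
        # simplification standing in for a full NB model
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        s2 = float(np.mean(pooled))
        se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
        z = diff / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    elif method == "welch":
        se2 = var_a / na + var_b / nb
        se2[se2 == 0] = np.finfo(float).tiny
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (var_a / na) ** 2 / max(na - 1, 1) + (var_b / nb) ** 2 / max(nb - 1, 1)
            + np.finfo(float).tiny
        )
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        raise ValueError(f"unknown test method {method!r}")
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    is_deg = (np.abs(lfc) > lfc_min) & (padj < alpha)
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": pvals,
            "adjusted_p": padj,
            "is_deg": is_deg,
        },
        index=matrix.index,
    )


def qpcr_fold_change(
    ct_table: pd.DataFrame,
    reference_gene: str,
    conditions: Tuple[str, str],
) -> pd.Series:
    """2^(-ddCt) fold changes between two conditions.

    ``ct_table`` is genes x conditions of (mean) Ct values; dCt is computed
    against the reference gene per condition and ddCt between the two
    conditions.  Genes with a missing Ct are skipped with a warning.
    """
    c1, c2 = conditions
    for c in conditions:
        if c not in ct_table.columns:
            raise KeyError(f"condition {c!r} not in Ct table")
    if reference_gene not in ct_table.index:
        raise KeyError(f"reference gene {reference_gene!r} not in Ct table")
    ref = ct_table.loc[reference_gene, [c1, c2]]
    if ref.isna().any():
        raise ValueError("reference gene has missing Ct values")
    out = {}
    for gene, row in ct_table.iterrows():
        if gene == reference_gene:
            continue
        if pd.isna(row[c1]) or pd.isna(row[c2]):
            logger.warning("gene %s skipped: missing Ct value", gene)
            continue
        dct1 = row[c1] - ref[c1]
        dct2 = row[c2] - ref[c2]
        out[gene] = 2.0 ** (-(dct1 - dct2))
    return pd.Series(out, name="fold_change")
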