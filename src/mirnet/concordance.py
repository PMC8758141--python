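"""Pathway-restricted fold-change concordance between DE datasets.

Given several DE tables (e.g. a perturbation transcriptome and disease
cohorts) and a pathway gene set, compute the pairwise Pearson correlation of
log2 fold changes over the genes the pair shares, plus a gene × dataset
fold-change table suitable for heatmap plotting. Genes missing from either
dataset of a pair are pairwise-deleted; a pair sharing fewer than 3 genes is
flagged missing rather than correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DifferentialExpressionTable, GeneSet

log = logging.getLogger(__name__)

__all__ = ["ConcordanceMatrix", "pairwise_fc_correlation", "fc_heatmap_table"]

MIN_SHARED_GENES = 3


@dataclass
class ConcordanceMatrix:
    """Symmetric matrices of pairwise correlation r, test p-value, and
    shared-gene counts, indexed by dataset id. Missing pairs are NaN."""

    dataset_ids: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n_genes: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.dataset_ids):
            for b in self.dataset_ids[i + 1 :]:
                rows.append(
                    {
                        "dataset_a": a,
                        "dataset_b": b,
                        "r": self.r.at[a, b],
                        "p_value": self.p.at[a, b],
                        "n_genes": int(self.n_genes.at[a, b]),
                    }
                )
        return pd.DataFrame(rows, columns=["dataset_a", "dataset_b", "r", "p_value", "n_genes"])


def pairwise_fc_correlation(
    tables: list[DifferentialExpressionTable],
    gene_set: GeneSet,
    dataset_ids: list[str] | None = None,
    method: str = "pearson",
) -> ConcordanceMatrix:
    """Pairwise correlation of log2 fold changes over ``gene_set``.

    ``method`` is ``"pearson"`` (default) or ``"spearman"``. The diagonal is
    exactly 1 with the dataset's own pathway-gene count.
    """
    if len(tables) < 2:
        raise ValueError("need at least two DE tables")
    if len(gene_set) == 0:
        raise ValueError("gene_set is empty")
    if dataset_ids is None:
        dataset_ids = [f"dataset_{i + 1}" for i in range(len(tables))]
    if len(dataset_ids) != len(tables):
        raise ValueError("dataset_ids must match tables in length")
    corr = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]

    ids = list(dataset_ids)
    r = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    p = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    n = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    vecs = []
    for table in tables:
        genes = sorted(gene_set.genes & table.universe)
        vecs.append(table.frame.loc[genes, "log2_fc"])
    for i, a in enumerate(ids):
        n.at[a, a] = len(vecs[i])
        for j in range(i + 1, len(ids)):
            b = ids[j]
            shared = vecs[i].index.intersection(vecs[j].index)
            n.at[a, b] = n.at[b, a] = len(shared)
            if len(shared) < MIN_SHARED_GENES:
                log.warning(
                    "pair (%s, %s) shares only %d pathway genes (<%d); flagged missing",
                    a, b, len(shared), MIN_SHARED_GENES,
                )
                r.at[a, b] = r.at[b, a] = np.nan
                p.at[a, b] = p.at[b, a] = np.nan
                continue
            res = corr(vecs[i].loc[shared], vecs[j].loc[shared])
            r.at[a, b] = r.at[b, a] = float(res.statistic)
            p.at[a, b] = p.at[b, a] = float(res.pvalue)
    return ConcordanceMatrix(ids, r, p, n)


def fc_heatmap_table(
    tables: list[DifferentialExpressionTable],
    gene_set: GeneSet,
    dataset_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Gene × dataset table of log2 fold changes over ``gene_set``.

    Rows are the pathway genes present in at least one dataset; cells where
    a gene is absent from a dataset are NaN. Ready for any heatmap tool.
    """
    if dataset_ids is None:
        dataset_ids = [f"dataset_{i + 1}" for i in range(len(tables))]
    cols = {}
    for ds_id, table in zip(dataset_ids, tables):
        genes = sorted(gene_set.genes & table.universe)
        cols[ds_id] = table.frame.loc[genes, "log2_fc"]
    out = pd.DataFrame(cols)
    out.index.name = "gene_id"
    if out.empty:
        log.warning("gene_set %r shares no genes with any dataset", gene_set.name)
    return out.sort_index()
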