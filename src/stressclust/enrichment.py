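"""Pathway over-representation per expression group.

Enrichment of an annotation term in a gene group is scored with the exact
upper-tail hypergeometric probability P(X >= k) for drawing k annotated
genes in a group of n from a universe of N containing K annotated genes,
followed by Benjamini-Hochberg FDR control across the terms tested for that
group (per-group by default; a joint mode is available).  Reports mirror
the source analysis style: the top seven terms by significance, reordered
so terms with more gene "hits" in the group are listed first.

The universe defaults to the genes present on the expression matrix after
probeset collapsing, not the whole genome.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParseError, StressclustError

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05


def hypergeometric_enrich(group: set, pathway: set, universe: set) -> dict:
    """Exact over-representation record for one (group, pathway) pair.

    ``pathway`` is intersected with ``universe`` before counting; ``group``
    must be a subset of ``universe``.  p is the exact upper tail
    P(X >= k) with no normal approximation.
    """
    if not universe:
        raise StressclustError("empty universe")
    if not group <= universe:
        raise StressclustError("group is not a subset of the universe")
    K = len(pathway & universe)
    n = len(group)
    N = len(universe)
    k = len(group & pathway & universe)
    # hypergeom.sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return {"k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)}


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise StressclustError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_annotations(path) -> pd.DataFrame:
    """Read a (gene, pathway[, pathway_name]) TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns (gene, pathway[, pathway_name])")
    df = df.iloc[:, :3]
    df.columns = ["gene", "pathway", "pathway_name"][: df.shape[1]]
    if "pathway_name" not in df.columns:
        df["pathway_name"] = df["pathway"]
    return df


def enrich_groups(group_table: pd.DataFrame, annotations: pd.DataFrame,
                  universe: set | None = None,
                  joint_fdr: bool = False) -> pd.DataFrame:
    """Hypergeometric enrichment of every annotated pathway in every group.

    ``group_table`` is the labeled per-gene table (index = gene, column
    ``group``); genes with a null group are part of the universe but of no
    target set.  BH correction is applied within each group by default
    (``joint_fdr=True`` pools all tests).
    """
    if universe is None:
        universe = set(group_table.index)
    names = annotations.drop_duplicates("pathway").set_index("pathway")["pathway_name"]
    pathway_genes = {pw: set(sub["gene"]) for pw, sub in annotations.groupby("pathway")}
    records = []
    for label, sub in group_table.dropna(subset=["group"]).groupby("group"):
        group = set(sub.index) & universe
        for pw, genes in sorted(pathway_genes.items()):
            rec = hypergeometric_enrich(group, genes, universe)
            rec.update(group=label, pathway=pw, pathway_name=names.get(pw, pw))
            records.append(rec)
    if not records:
        return pd.DataFrame(columns=["group", "pathway", "pathway_name",
                                     "k", "K", "n", "N", "p_value", "q_value"])
    df = pd.DataFrame.from_records(records)
    if joint_fdr:
        df["q_value"] = bh_fdr(df["p_value"])
    else:
        df["q_value"] = df.groupby("group")["p_value"].transform(bh_fdr)
    logger.info("enrichment: %d group x pathway tests", len(df))
    return df[["group", "pathway", "pathway_name", "k", "K", "n", "N",
               "p_value", "q_value"]]


def top_pathways(records: pd.DataFrame, k: int = 7,
                 fdr: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Top-k report for one group: select by q, then reorder by hit count.

    Significant records (q < fdr) are ranked by (q, p, pathway id), the k
    best kept, and that selection is reordered descending by the number of
    group genes hitting the pathway — the convention of listing the most
    gene-rich of the top terms first.
    """
    sig = records[records["q_value"] < fdr]
    sel = sig.sort_values(["q_value", "p_value", "pathway"]).head(k)
    return sel.sort_values(["k", "pathway"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)
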