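"""Translation-efficiency classification and cross-study concordance.

Translation efficiency (TE) is ribosome-footprint read density over matched
RNA-seq density for the same gene.  Genes are classed UP / DOWN / NS from a
differential-TE table (log2 fold change + BH-adjusted p): adjusted p >= 0.05
is non-significant, otherwise the sign of the fold change decides.  For
synthetic data the module also ships a deliberately simple per-gene test
(Welch t on replicate log2 TE, BH-adjusted) so end-to-end runs need no
external count-model fitter; real analyses ingest an external table
(e.g. a DESeq2 TE contrast) instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

CLASS_NS = "NS"
CLASS_UP = "UP"
CLASS_DOWN = "DOWN"

#: counts pseudocount used before log-ratios in the synthetic-mode test
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class TEResult:
    """One gene's translation-efficiency change and class label."""

    gene_id: str
    log2fc_te: float
    padj: float
    class_label: str
    flags: frozenset[str] = frozenset()


def rpkm(counts: float, feature_length: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length <= 0:
        raise ValueError(f"feature_length must be positive, got {feature_length}")
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    return counts / (feature_length / 1e3) / (library_size / 1e6)


def translation_efficiency(ribo_density: float, rna_density: float) -> float:
    """TE = ribosome-footprint density / RNA density."""
    if rna_density <= 0:
        raise ValueError("TE undefined for zero RNA density")
    return ribo_density / rna_density


def classify_gene(padj: float | None, log2fc_te: float) -> tuple[str, frozenset[str]]:
    """Apply the UP/DOWN/NS rule; returns (label, flags).

    Adjusted p >= 0.05 (or missing) -> NS; below 0.05 the fold-change sign
    decides.  A significant gene with exactly zero fold change has no sign
    and stays NS, flagged ``ZERO_FC``.
    """
    if padj is None or (isinstance(padj, float) and np.isnan(padj)):
        return CLASS_NS, frozenset({"UNTESTED"})
    if not 0.0 <= padj <= 1.0:
        raise ValueError(f"padj {padj} outside [0, 1]")
    if padj >= 0.05:
        return CLASS_NS, frozenset()
    if log2fc_te > 0:
        return CLASS_UP, frozenset()
    if log2fc_te < 0:
        return CLASS_DOWN, frozenset()
    return CLASS_NS, frozenset({"ZERO_FC"})


def classify_table(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Classify a differential-TE table (gene_id, log2fc_te, padj).

    ``alpha`` only relabels when differing from the canonical 0.05 rule;
    the boundary always goes to NS.
    """
    out = df.copy()
    labels = []
    for padj, fc in zip(out["padj"], out["log2fc_te"]):
        if pd.isna(padj) or padj >= alpha:
            labels.append(CLASS_NS)
        elif fc > 0:
            labels.append(CLASS_UP)
        elif fc < 0:
            labels.append(CLASS_DOWN)
        else:
            labels.append(CLASS_NS)
    out["class_label"] = labels
    return out


def cross_study_concordance(
    fc_a: Mapping[str, float] | pd.Series,
    fc_b: Mapping[str, float] | pd.Series,
    reads_a: pd.DataFrame | None = None,
    reads_b: pd.DataFrame | None = None,
) -> tuple[float, int]:
    """Spearman rho between two per-transcript fold-change tables.

    Transcripts with zero reads in any condition of either study (rows of
    the optional per-condition read tables containing a zero) are discarded
    before correlating.  Returns (rho, n) on the surviving intersection.
    """
    a = pd.Series(fc_a, dtype=float)
    b = pd.Series(fc_b, dtype=float)

    def _nonzero_ids(reads: pd.DataFrame | None, ids: pd.Index) -> pd.Index:
        if reads is None:
            return ids
        keep = reads.loc[(reads > 0).all(axis=1)].index
        return ids.intersection(keep)

    shared = a.index.intersection(b.index)
    shared = _nonzero_ids(reads_a, shared)
    shared = _nonzero_ids(reads_b, shared)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} transcripts shared after zero-read filtering"
        )
    rho, _ = sps.spearmanr(a.loc[shared], b.loc[shared])
    return float(rho), len(shared)


def _log2_te_matrix(
    ribo: np.ndarray, rna: np.ndarray, lib_ribo: np.ndarray, lib_rna: np.ndarray
) -> np.ndarray:
    """Per-replicate log2 TE from count matrices (genes x replicates)."""
    ribo_d = (ribo + PSEUDOCOUNT) / lib_ribo
    rna_d = (rna + PSEUDOCOUNT) / lib_rna
    return np.log2(ribo_d) - np.log2(rna_d)


def simple_te_test(
    counts: pd.DataFrame,
    control: str = "vehicle",
    treated: str = "treated",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test on replicate log2 TE, BH-adjusted.

    ``counts`` is long format with columns gene_id, condition, replicate,
    ribo, rna.  Library sizes are the per-sample column sums over the
    catalog.  Returns a classified table (gene_id, log2fc_te, pvalue, padj,
    class_label).  Requires >= 2 replicates per condition.
    """
    for col in ("gene_id", "condition", "replicate", "ribo", "rna"):
        if col not in counts.columns:
            raise ValueError(f"counts table lacks column {col!r}")

    def _pivot(col: str) -> pd.DataFrame:
        return counts.pivot_table(
            index="gene_id", columns=["condition", "replicate"], values=col
        )

    ribo = _pivot("ribo")
    rna = _pivot("rna")
    for cond in (control, treated):
        if cond not in ribo.columns.get_level_values(0):
            raise ValueError(f"condition {cond!r} absent from counts table")
        if ribo[cond].shape[1] < 2:
            raise ValueError(
                f"condition {cond!r} has a single replicate; supply an "
                "external differential-TE table instead"
            )

    def _log2te(cond: str) -> np.ndarray:
        r = ribo[cond].to_numpy(float)
        m = rna[cond].to_numpy(float)
        return _log2_te_matrix(r, m, r.sum(axis=0), m.sum(axis=0))

    te_ctl = _log2te(control)
    te_trt = _log2te(treated)
    tstat, pval = sps.ttest_ind(te_trt, te_ctl, axis=1, equal_var=False)
    log2fc = te_trt.mean(axis=1) - te_ctl.mean(axis=1)
    pval = np.where(np.isnan(pval), 1.0, pval)
    _, padj, _, _ = multipletests(pval, method="fdr_bh")
    out = pd.DataFrame(
        {
            "gene_id": ribo.index,
            "log2fc_te": log2fc,
            "pvalue": pval,
            "padj": padj,
        }
    ).reset_index(drop=True)
    return classify_table(out, alpha=alpha)
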