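"""Reference-gene normalization, subgroup clustering, tissue-specific
block detection and qPCR/RNA-seq agreement.

FPKM values are first divided, per sample, by the mean FPKM of a set of
reference (housekeeping) genes in that sample — removing sample-level
scale — then each gene row is standardized to mean 0 / sd 1 across
samples (the ``scale()`` convention, sd with n-1 denominator).
Standardized rows are clustered agglomeratively into k subgroups, and
each subgroup is tested for tissue specificity: its dominant tissue is
the one with the highest mean standardized expression, and the subgroup
is flagged tissue-specific when the margin over the runner-up tissue
reaches a threshold (default 0.5 sd).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy import stats

from bhlh_survey.io_formats import ExpressionMatrix, ValidationError

logger = logging.getLogger("bhlh_survey")


@dataclass
class NormalizedMatrix:
    """Two-stage normalized expression: reference-divided then row-standardized.

    ``intermediate`` holds the stage-1 (reference-divided) values;
    ``values`` the row-standardized result.  Constant rows cannot be
    standardized and are flagged (values set to 0).
    """

    values: pd.DataFrame
    intermediate: pd.DataFrame
    sample_tissue: dict[str, str]
    constant_genes: list[str] = field(default_factory=list)


def normalize(matrix: ExpressionMatrix, reference_ids: Sequence[str]) -> NormalizedMatrix:
    """Divide each sample by its reference-gene mean, then standardize rows.

    Reference genes are excluded from the output.  A sample whose
    reference mean is zero or NaN is an error naming the sample.
    """
    missing = [r for r in reference_ids if r not in matrix.values.index]
    if missing:
        raise ValidationError(f"reference genes absent from matrix: {missing}")
    if not reference_ids:
        raise ValidationError("at least one reference gene required")
    ref_mean = matrix.values.loc[list(reference_ids)].mean(axis=0)
    bad = [s for s in matrix.sample_ids
           if not np.isfinite(ref_mean[s]) or ref_mean[s] == 0]
    if bad:
        raise ValidationError(f"zero or undefined reference mean in sample(s): {bad}")
    intermediate = matrix.values.drop(index=list(reference_ids)).div(ref_mean, axis=1)

    means = intermediate.mean(axis=1)
    sds = intermediate.std(axis=1, ddof=1)
    constant = sds[(sds == 0) | ~np.isfinite(sds)].index.tolist()
    if constant:
        logger.warning("normalize: %d constant gene row(s) set to 0: %s",
                       len(constant), constant[:5])
    safe_sd = sds.replace(0, np.nan)
    values = intermediate.sub(means, axis=0).div(safe_sd, axis=0)
    values.loc[constant] = 0.0
    return NormalizedMatrix(
        values=values, intermediate=intermediate,
        sample_tissue=dict(matrix.sample_tissue), constant_genes=constant,
    )


@dataclass
class SubgroupClustering:
    """Gene -> subgroup id (1..k) with the underlying dendrogram."""

    assignments: dict[str, int]
    linkage_matrix: np.ndarray
    k: int

    def genes_in(self, subgroup: int) -> list[str]:
        return [g for g, s in self.assignments.items() if s == subgroup]


def cluster_subgroups(
    nm: NormalizedMatrix,
    k: int = 14,
    linkage: str = "complete",
    metric: str = "euclidean",
) -> SubgroupClustering:
    """Agglomerative clustering of standardized gene rows into k subgroups.

    Subgroup ids are relabeled 1..k in order of first appearance along
    the input gene order, which makes labels deterministic.
    """
    genes = list(nm.values.index)
    if k > len(genes):
        raise ValidationError(f"k={k} exceeds number of genes ({len(genes)})")
    X = nm.values.to_numpy()
    Z = hierarchy.linkage(X, method=linkage, metric=metric)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for label in raw:
        if label not in relabel:
            relabel[label] = len(relabel) + 1
    assignments = {g: relabel[l] for g, l in zip(genes, raw)}
    got = len(set(assignments.values()))
    if got != k:
        logger.warning("cluster_subgroups: requested k=%d, obtained %d "
                       "(distance ties)", k, got)
    return SubgroupClustering(assignments=assignments, linkage_matrix=Z, k=k)


@dataclass(frozen=True)
class TissueBlock:
    """Tissue-specificity call for one expression subgroup."""

    subgroup: int
    dominant_tissue: str
    margin: float          # dominant mean - runner-up mean, in sd units
    specific: bool


def detect_blocks(
    clustering: SubgroupClustering,
    nm: NormalizedMatrix,
    margin_threshold: float = 0.5,
) -> list[TissueBlock]:
    """Call the dominant tissue of each subgroup and flag specific ones.

    For each subgroup, the mean standardized value is computed per tissue
    (over all member genes and all samples of the tissue); the dominant
    tissue is the argmax and the margin its lead over the runner-up.
    """
    tissues = sorted(set(nm.sample_tissue.values()))
    if len(tissues) < 2:
        raise ValidationError("need at least 2 tissues for block detection")
    samples_by_tissue = {
        t: [s for s in nm.values.columns if nm.sample_tissue[s] == t]
        for t in tissues
    }
    blocks = []
    for subgroup in sorted(set(clustering.assignments.values())):
        genes = clustering.genes_in(subgroup)
        sub = nm.values.loc[genes]
        tissue_means = {
            t: float(sub[cols].to_numpy().mean())
            for t, cols in samples_by_tissue.items() if cols
        }
        ordered = sorted(tissue_means.items(), key=lambda kv: (-kv[1], kv[0]))
        dominant, top = ordered[0]
        runner_up = ordered[1][1]
        margin = max(top - runner_up, 0.0)
        blocks.append(TissueBlock(
            subgroup=subgroup, dominant_tissue=dominant,
            margin=margin, specific=margin >= margin_threshold,
        ))
    return blocks


def qpcr_agreement(
    fpkm: ExpressionMatrix,
    qpcr: ExpressionMatrix,
    scale: str = "log2",
) -> pd.DataFrame:
    """Per-gene Pearson correlation between RNA-seq FPKM and qPCR values.

    Computed on log2(x+1)-transformed unstandardized values by default
    (``scale="raw"`` skips the transform); two-sided p from the
    t-distribution with n-2 df.  Genes with fewer than 3 shared samples
    are skipped with a warning.
    """
    shared_genes = [g for g in fpkm.gene_ids if g in set(qpcr.gene_ids)]
    shared_samples = [s for s in fpkm.sample_ids if s in set(qpcr.sample_ids)]
    rows = []
    for gene in shared_genes:
        x = fpkm.values.loc[gene, shared_samples].to_numpy(dtype=float)
        y = qpcr.values.loc[gene, shared_samples].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            logger.warning("qpcr_agreement: gene %s skipped (<3 shared samples)", gene)
            continue
        x, y = x[ok], y[ok]
        if scale == "log2":
            x, y = np.log2(x + 1), np.log2(y + 1)
        r, p = stats.pearsonr(x, y)
        rows.append((gene, float(r), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["gene", "r", "p", "n_samples"])
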