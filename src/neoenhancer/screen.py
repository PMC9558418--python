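"""Tumor-versus-every-normal-tissue overexpression screen.

For each gene, the tumor group is tested against every normal tissue type
separately (one-sided, tumor greater).  P-values are Benjamini-Hochberg
adjusted across the full gene x tissue family, and a gene is called only
when it clears *every* tissue: a single failing tissue vetoes the call.
A minimum log2 margin over the highest-expressing normal tissue is also
required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenParams",
    "GeneScreenResult",
    "screen_overexpressed",
    "filter_surface",
]


@dataclass(frozen=True)
class ScreenParams:
    """Screen configuration.

    ``min_delta`` is the required log2 margin of the tumor mean over the
    highest normal-tissue mean (default 1 = 2-fold).  Tissues with fewer
    than ``min_tissue_n`` samples are excluded with a warning.
    """

    test: str = "welch_t"
    alpha: float = 0.05
    min_delta: float = 1.0
    min_tissue_n: int = 3

    def __post_init__(self) -> None:
        if self.test not in ("welch_t", "mann_whitney"):
            raise ValueError(f"unknown test {self.test!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")


@dataclass
class GeneScreenResult:
    gene_id: str
    tumor_mean: float
    p_by_tissue: dict[str, float]
    q_by_tissue: dict[str, float]
    max_normal_mean: float
    max_normal_tissue: str
    delta_vs_max: float
    called: bool


def screen_overexpressed(
    matrix: pd.DataFrame,
    labels: pd.Series | dict,
    tumor_label: str = "EwS",
    params: ScreenParams = ScreenParams(),
) -> list[GeneScreenResult]:
    """Run the all-tissue-veto overexpression screen.

    ``matrix`` is genes x samples of log2 intensities; ``labels`` maps each
    sample (column) to ``tumor_label`` or a normal tissue-type name.

    Returns one :class:`GeneScreenResult` per testable gene.  A gene is
    ``called`` iff for every tissue the one-sided adjusted p is below alpha,
    the tumor mean exceeds the tissue mean, and the margin over the highest
    tissue mean is at least ``min_delta``.
    """
    labels = pd.Series(labels)
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    unlabeled = [c for c in matrix.columns if c not in labels.index]
    if unlabeled:
        raise ValueError(f"unlabeled samples: {unlabeled[:5]}")
    labels = labels.loc[matrix.columns]

    tumor_cols = labels.index[labels == tumor_label]
    if len(tumor_cols) == 0:
        raise ValueError(f"no samples labelled {tumor_label!r}")
    tissue_names = sorted(set(labels) - {tumor_label})
    if len(tissue_names) < 2:
        raise ValueError("need at least 2 normal tissue types")

    kept_tissues = []
    for t in tissue_names:
        n = int((labels == t).sum())
        if n < params.min_tissue_n:
            warnings.warn(
                f"tissue {t!r} has {n} < {params.min_tissue_n} samples; excluded",
                stacklevel=2,
            )
        else:
            kept_tissues.append(t)
    if len(kept_tissues) < 2:
        raise ValueError("fewer than 2 tissue types remain after size filtering")

    # all-constant rows have undefined p-values; skip them up front
    values = matrix.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"skipping {int(constant.sum())} all-constant gene row(s)", stacklevel=2
        )
    genes = matrix.index[~constant]
    tumor = matrix.loc[genes, tumor_cols].to_numpy(dtype=float)

    n_genes = len(genes)
    pmat = np.ones((n_genes, len(kept_tissues)))
    tissue_means = np.empty((n_genes, len(kept_tissues)))
    for j, t in enumerate(kept_tissues):
        cols = labels.index[labels == t]
        block = matrix.loc[genes, cols].to_numpy(dtype=float)
        tissue_means[:, j] = block.mean(axis=1)
        if params.test == "welch_t":
            res = stats.ttest_ind(
                tumor, block, axis=1, equal_var=False, alternative="greater"
            )
            p = res.pvalue
        else:
            res = stats.mannwhitneyu(tumor, block, axis=1, alternative="greater")
            p = res.pvalue
        pmat[:, j] = np.where(np.isfinite(p), p, 1.0)

    # BH over the full gene x tissue family
    qmat = stats.false_discovery_control(pmat.ravel(), method="bh").reshape(pmat.shape)

    tumor_mean = tumor.mean(axis=1)
    max_idx = tissue_means.argmax(axis=1)
    max_normal = tissue_means[np.arange(n_genes), max_idx]
    delta = tumor_mean - max_normal

    results: list[GeneScreenResult] = []
    for i, g in enumerate(genes):
        all_sig = bool((qmat[i] < params.alpha).all())
        all_greater = bool((tumor_mean[i] > tissue_means[i]).all())
        called = all_sig and all_greater and delta[i] >= params.min_delta
        results.append(
            GeneScreenResult(
                gene_id=str(g),
                tumor_mean=float(tumor_mean[i]),
                p_by_tissue={t: float(pmat[i, j]) for j, t in enumerate(kept_tissues)},
                q_by_tissue={t: float(qmat[i, j]) for j, t in enumerate(kept_tissues)},
                max_normal_mean=float(max_normal[i]),
                max_normal_tissue=kept_tissues[int(max_idx[i])],
                delta_vs_max=float(delta[i]),
                called=called,
            )
        )
    return results


def filter_surface(
    results: list[GeneScreenResult],
    surface: dict[str, bool] | set[str] | list[str],
) -> pd.DataFrame:
    """Intersect called genes with surface-protein flags.

    Genes absent from ``surface`` are treated as not surface.  Candidates
    are ranked by ``delta_vs_max`` descending.
    """
    if isinstance(surface, dict):
        flagged = {g for g, f in surface.items() if f}
    else:
        flagged = set(surface)
    rows = [
        {
            "gene_id": r.gene_id,
            "tumor_mean": r.tumor_mean,
            "max_normal_mean": r.max_normal_mean,
            "delta_vs_max": r.delta_vs_max,
        }
        for r in results
        if r.called and r.gene_id in flagged
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "tumor_mean", "max_normal_mean", "delta_vs_max"])
    return df.sort_values("delta_vs_max", ascending=False, kind="mergesort").reset_index(drop=True)
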