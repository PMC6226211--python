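"""Enrichment-based baseline predictors and Benjamini-Hochberg adjustment.

Two baselines bracket the main scoring model:

* **direct enrichment** — hypergeometric term enrichment among each
  compound's 20 strongest *negative* chemical-genetic interactions, using an
  annotation matrix built over the strain universe (no genetic interaction
  network involved);
* **gene-target enrichment** — the same test applied to the genes carrying
  each compound's top-n gene similarity scores (largest first), over the
  query-gene universe.

Selection keeps every gene tying the n-th score, and the enrichment factor
and hypergeometric tail are evaluated at the *nominal* n as printed in the
defining equations; a strict-n variant with seeded random tie-breaking is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import AnnotationMatrix, ChemGenProfileSet

#: Baseline selection size used throughout the comparisons.
DEFAULT_TOP_N = 20

#: The selection-size sweep explored for gene-target enrichment.
TOP_N_SWEEP = (10, 20, 50, 100, 200, 300, 400, 600, 800)


@dataclass
class EnrichmentResult:
    """Per-(condition, term) enrichment factors and hypergeometric p-values."""

    n_top: int
    top_mask: pd.DataFrame  # binary condition x gene selection
    enrichment: pd.DataFrame  # condition x term enrichment factors
    p: pd.DataFrame  # condition x term upper-tail hypergeometric p


def top_n_mask(
    scores: pd.DataFrame,
    n_top: int,
    direction: str = "largest",
    *,
    strict: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binary mask of each row's top-n scores.

    ``direction="largest"`` selects scores >= the n-th largest;
    ``"most-negative"`` selects scores <= the n-th smallest. Ties at the
    threshold are all included unless ``strict`` is set, in which case a
    seeded random subset of the tied genes pads the selection to exactly n.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > scores.shape[1]:
        raise ValueError("n_top exceeds the gene universe size")
    values = scores.to_numpy(dtype=float)
    if direction == "most-negative":
        values = -values
    elif direction != "largest":
        raise ValueError(f"unknown direction {direction!r}")
    threshold = np.partition(values, values.shape[1] - n_top, axis=1)[
        :, values.shape[1] - n_top][:, None]
    mask = values >= threshold
    if strict:
        rng = np.random.default_rng(seed)
        for i in range(mask.shape[0]):
            extra = mask[i].sum() - n_top
            if extra > 0:
                tied = np.flatnonzero(mask[i] & (values[i] == threshold[i, 0]))
                drop = rng.choice(tied, size=extra, replace=False)
                mask[i, drop] = False
    return pd.DataFrame(mask.astype(np.int8), index=scores.index,
                        columns=scores.columns)


def enrichment_scores(
    mask: pd.DataFrame, ann: AnnotationMatrix, n_top: int
) -> EnrichmentResult:
    """Hypergeometric enrichment of each term in each row's selected genes.

    With universe size N, term size K, nominal selection size n and overlap
    k: enrichment factor E = k N / (K n) and p = P(X >= k) for X
    hypergeometric(N, K, n).
    """
    if not mask.columns.equals(ann.gene_ids):
        if set(mask.columns) != set(ann.gene_ids):
            raise ValueError("mask gene universe differs from annotation universe")
        mask = mask[ann.gene_ids]
    n_genes = mask.shape[1]
    sizes = ann.term_sizes.to_numpy()
    assert (sizes > 0).all(), "size filtering must remove empty terms first"
    overlap = mask.to_numpy(dtype=float) @ ann.membership.to_numpy(dtype=float)
    enrichment = overlap * n_genes / (sizes[None, :] * n_top)
    p = hypergeom.sf(overlap - 1, n_genes, sizes[None, :], n_top)
    shape = dict(index=mask.index, columns=ann.term_ids)
    return EnrichmentResult(
        n_top=n_top,
        top_mask=mask,
        enrichment=pd.DataFrame(enrichment, **shape),
        p=pd.DataFrame(p, **shape),
    )


def gene_target_enrichment(
    sim: pd.DataFrame, ann: AnnotationMatrix, n_top: int = DEFAULT_TOP_N, **kwargs
) -> EnrichmentResult:
    """Enrichment among the genes with the largest similarity scores."""
    mask = top_n_mask(sim, n_top, "largest", **kwargs)
    return enrichment_scores(mask, ann, n_top)


def direct_enrichment(
    cg: ChemGenProfileSet,
    strain_ann: AnnotationMatrix,
    n_top: int = DEFAULT_TOP_N,
    **kwargs,
) -> EnrichmentResult:
    """Enrichment among each condition's strongest negative interactions.

    Works directly on the chemical-genetic z-scores against a strain-universe
    annotation matrix, bypassing the genetic interaction network.
    """
    scores = cg.scores.T  # conditions x strains
    mask = top_n_mask(scores[strain_ann.gene_ids], n_top, "most-negative", **kwargs)
    return enrichment_scores(mask, strain_ann, n_top)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
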