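"""Compound-gene similarity scores and their aggregation to processes.

The core scoring model: genetic interaction query profiles are L2
column-normalized (G'), and each chemical-genetic profile is scored against
each query by the plain inner product

    S = C^T G'.

Only the genetic side is normalized, so a gene-target score reflects both the
direction of the chemical-genetic profile (its similarity to the query) and
its overall strength. Scores are then summed over a term's annotated genes,

    X = S B,

giving one compound-process score per (condition, term).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (AnnotationMatrix, ChemGenProfileSet,
                         GeneticInteractionMatrix)
from .errors import AlignmentError

log = logging.getLogger(__name__)


def l2_normalize_queries(gi: GeneticInteractionMatrix) -> GeneticInteractionMatrix:
    """Divide each query column by its Euclidean norm.

    Zero-norm columns cannot be normalized; those queries are dropped with a
    warning (callers must re-check annotation term sizes afterwards).
    """
    values = gi.scores.to_numpy(dtype=float)
    norms = np.linalg.norm(values, axis=0)
    zero = norms == 0
    if zero.any():
        dropped = gi.scores.columns[zero].tolist()
        log.warning("dropping %d zero-norm query column(s): %s",
                    len(dropped), dropped[:5])
        values = values[:, ~zero]
        columns = gi.scores.columns[~zero]
        norms = norms[~zero]
    else:
        columns = gi.scores.columns
    normalized = pd.DataFrame(values / norms, index=gi.scores.index,
                              columns=columns)
    return GeneticInteractionMatrix(normalized, normalized=True)


def similarity_scores(
    cg: ChemGenProfileSet, gi_norm: GeneticInteractionMatrix
) -> pd.DataFrame:
    """Inner products of every condition profile with every normalized query.

    Returns a conditions x queries DataFrame; linear in the chemical-genetic
    profiles (scaling a condition scales its whole score row).
    """
    if not gi_norm.normalized:
        raise ValueError("genetic interaction matrix must be L2-normalized first")
    if not cg.strain_ids.equals(gi_norm.strain_ids):
        raise AlignmentError("strain order mismatch; run align_strains first")
    values = cg.scores.to_numpy(dtype=float).T @ gi_norm.scores.to_numpy(dtype=float)
    return pd.DataFrame(values, index=cg.condition_ids, columns=gi_norm.query_ids)


def process_scores(sim: pd.DataFrame, ann: AnnotationMatrix) -> pd.DataFrame:
    """Sum each condition's gene similarity scores within each term.

    Returns a conditions x terms DataFrame. Every annotated gene must be a
    column of ``sim`` (the annotation matrix is built on the query universe).
    """
    missing = ann.gene_ids.difference(sim.columns)
    if len(missing) > 0:
        raise AlignmentError(
            f"annotation universe has gene(s) absent from similarity scores: "
            f"{missing.tolist()[:5]}")
    values = sim[ann.gene_ids].to_numpy(dtype=float) @ ann.membership.to_numpy(dtype=float)
    return pd.DataFrame(values, index=sim.index, columns=ann.term_ids)
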