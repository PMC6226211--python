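"""Benchmarking machinery: simulated profiles, ranks, PR curves, AUPR.

Simulated chemical-genetic profiles are genetic interaction query profiles
with added Gaussian noise (per-strain variance a fixed multiple of that
strain's variance across the genetic interaction matrix); each simulated
profile inherits the term annotations of its parent query, giving a gold
standard at screen scale without any wet-lab data.

All prediction lists use one total order: p-value ascending, then z-score
(or enrichment factor) descending, then term id ascending — the last key is
a deterministic tie-break so ranks are reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import overlap_index
from .containers import AnnotationMatrix, ChemGenProfileSet, GeneticInteractionMatrix

log = logging.getLogger(__name__)

#: Simulated-profile defaults: replicates per query and noise variance
#: multiplier relative to each strain's variance in the genetic network.
DEFAULT_REPLICATES = 3
DEFAULT_VARIANCE_MULTIPLIER = 2.0

#: Gene-overlap threshold at which two terms count as interchangeable when
#: computing effective ranks.
DEFAULT_EFFECTIVE_RANK_OVERLAP = 0.4


@dataclass
class SimulatedProfileSet:
    """Noisy copies of query profiles posing as compound treatments."""

    profiles: ChemGenProfileSet
    parent_query: pd.Series  # profile id -> source query gene
    inherited_terms: pd.Series  # profile id -> frozenset of gold term ids


def simulate_profiles(
    gi: GeneticInteractionMatrix,
    replicates: int = DEFAULT_REPLICATES,
    variance_multiplier: float = DEFAULT_VARIANCE_MULTIPLIER,
    seed: int = 0,
    ann: AnnotationMatrix | None = None,
) -> SimulatedProfileSet:
    """Simulate one treatment profile per (query, replicate).

    Each profile is its parent query column plus independent Gaussian noise
    whose per-strain variance is ``variance_multiplier`` times the sample
    variance of that strain's row of the genetic interaction matrix. With
    ``ann`` given, profiles inherit their parent's term annotations.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if variance_multiplier < 0:
        raise ValueError("variance_multiplier must be >= 0")
    values = gi.scores.to_numpy(dtype=float)
    n_m, n_q = values.shape
    strain_sd = np.sqrt(variance_multiplier * values.var(axis=1, ddof=1))
    rng = np.random.default_rng(seed)
    base = np.repeat(values, replicates, axis=1)
    noise = rng.standard_normal(base.shape) * strain_sd[:, None]
    parents = np.repeat(gi.query_ids.to_numpy(), replicates)
    ids = pd.Index(
        [f"sim_{q}_{r}" for q in gi.query_ids for r in range(replicates)])
    scores = pd.DataFrame(base + noise, index=gi.strain_ids, columns=ids)
    types = pd.Series("treatment", index=ids, name="type")
    if ann is not None:
        by_query = {q: ann.membership.columns[ann.membership.loc[q] == 1]
                    for q in gi.query_ids if q in ann.gene_ids.to_numpy()}
        terms = pd.Series(
            [frozenset(by_query.get(q, ())) for q in parents], index=ids)
    else:
        terms = pd.Series([frozenset()] * len(ids), index=ids)
    return SimulatedProfileSet(
        profiles=ChemGenProfileSet(scores, types),
        parent_query=pd.Series(parents, index=ids, name="parent_query"),
        inherited_terms=terms,
    )


def rank_terms(p_row: pd.Series, z_row: pd.Series) -> pd.Index:
    """Term ids sorted by the canonical total order (p asc, z desc, id asc)."""
    # stable sort on a pre-sorted index implements the id tie-break
    frame = pd.DataFrame({"p": p_row, "z": z_row}).sort_index()
    frame = frame.sort_values(["p", "z"], ascending=[True, False],
                              kind="mergesort")
    return frame.index


def top_prediction_pr(
    p_final: pd.DataFrame,
    z_final: pd.DataFrame,
    gold: pd.Series,
) -> pd.DataFrame:
    """Precision-recall over each profile's single top prediction.

    Each profile contributes its top-ranked term; profiles are then sorted by
    that prediction's (p asc, z desc) and the running precision
    (TP / (TP + FP)) and recall (TP count) are accumulated. ``gold`` maps
    profile id -> set of gold-standard term ids; profiles with an empty gold
    set are excluded with a warning.
    """
    records = []
    for cond in p_final.index:
        gold_terms = gold.get(cond, frozenset())
        if not gold_terms:
            continue
        order = rank_terms(p_final.loc[cond], z_final.loc[cond])
        top = order[0]
        records.append((cond, top, p_final.at[cond, top], z_final.at[cond, top],
                        top in gold_terms))
    skipped = p_final.shape[0] - len(records)
    if skipped:
        log.warning("excluded %d profile(s) without gold annotations", skipped)
    if not records:
        raise ValueError("no profiles with gold annotations")
    table = pd.DataFrame(
        records, columns=["profile_id", "top_term", "p", "z", "hit"])
    table = table.sort_values(["p", "z"], ascending=[True, False],
                              kind="mergesort").reset_index(drop=True)
    tp = table["hit"].cumsum()
    table["precision"] = tp / np.arange(1, len(table) + 1)
    table["recall"] = tp
    return table


def top1_accuracy(pr_table: pd.DataFrame) -> float:
    """Fraction of profiles whose top prediction is a gold annotation."""
    return float(pr_table["hit"].mean())


def gold_rank_significance(
    p_row: pd.Series,
    z_row: pd.Series,
    gold_term: str,
    n_shuffles: int = 10_000,
    seed: int = 0,
    *,
    chunk_size: int = 512,
) -> tuple[int, float]:
    """Rank of the gold term and its shuffle-based empirical p-value.

    The observed rank uses the canonical total order. For significance, the
    (p, z) pairs are randomly reassigned to terms (without replacement) and
    the gold term's rank recomputed; the empirical p is the fraction of
    shuffles achieving the observed rank or better (<=).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    order = rank_terms(p_row, z_row)
    observed = int(order.get_loc(gold_term)) + 1
    p = p_row.to_numpy(dtype=float)
    z = z_row.to_numpy(dtype=float)
    n = p.size
    gold_pos = int(p_row.index.get_loc(gold_term))
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_shuffles:
        m = min(chunk_size, n_shuffles - done)
        perms = rng.permuted(
            np.broadcast_to(np.arange(n), (m, n)).copy(), axis=1)
        p_perm = p[perms]
        z_perm = z[perms]
        pg = p_perm[:, gold_pos][:, None]
        zg = z_perm[:, gold_pos][:, None]
        better = (p_perm < pg) | ((p_perm == pg) & (z_perm > zg))
        tied = (p_perm == pg) & (z_perm == zg)
        ranks = better.sum(axis=1) + tied[:, :gold_pos].sum(axis=1) + 1
        hits += int((ranks <= observed).sum())
        done += m
    return observed, hits / n_shuffles


def effective_rank(
    p_row: pd.Series,
    z_row: pd.Series,
    gold_term: str,
    ann: AnnotationMatrix,
    threshold: float = DEFAULT_EFFECTIVE_RANK_OVERLAP,
) -> int:
    """Best rank among terms sufficiently similar to the gold term.

    A term qualifies when the overlap index of its gene set with the gold
    term's gene set is >= ``threshold``; the gold term itself always
    qualifies (overlap 1).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    gold_genes = ann.genes_of(gold_term)
    order = rank_terms(p_row, z_row)
    for rank, term in enumerate(order, start=1):
        genes = ann.genes_of(term)
        if term == gold_term:
            return rank
        if genes and overlap_index(genes, gold_genes) >= threshold:
            return rank
    raise KeyError(f"gold term {gold_term!r} not in the prediction universe")


def average_precision(labels) -> float:
    """Average precision of a sorted binary relevance list.

    Mean, over the positives, of the precision at each positive (the
    step-function AUPR convention).
    """
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValueError("need at least one positive")
    tp = labels.cumsum()
    precision = tp / np.arange(1, labels.size + 1)
    return float(precision[labels].mean())


def per_term_aupr(
    p_col: pd.Series, z_col: pd.Series, positives: set
) -> float:
    """AUPR of one term's profile ranking, normalized by a random classifier.

    Profiles are sorted by the term's (p asc, z desc, profile id asc); a
    profile is a positive if annotated to the term. The raw average
    precision is divided by positives/total, so 1.0 means chance.
    """
    order = rank_terms(p_col, z_col)  # same total order, over profile ids
    labels = np.array([pid in positives for pid in order])
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("term has no positive profiles")
    return average_precision(labels) / (n_pos / labels.size)


def braun_blanquet(fp_a, fp_b) -> float:
    """Intersection size divided by the size of the larger set."""
    a, b = set(fp_a), set(fp_b)
    if not a or not b:
        raise ValueError("braun_blanquet is undefined for empty sets")
    return len(a & b) / max(len(a), len(b))
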