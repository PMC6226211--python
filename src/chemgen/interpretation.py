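"""Importance scores: which strains drive a compound's process prediction.

For a compound and a predicted term, a mean genetic interaction profile is
taken across the term's L2-normalized query profiles whose inner product
with the compound's chemical-genetic profile reaches a threshold (default
2), and the importance profile is the Hadamard (elementwise) product of
that mean profile with the compound's chemical-genetic profile. A strain's
importance is positive exactly when its chemical-genetic and mean genetic
interactions agree in sign, so importance profiles summarize where the two
interaction types are concordant for a given prediction.

The module also aggregates importance profiles across compounds: fractions
of interactions that contribute to top predictions, and a hypergeometric
overrepresentation test for strains that interact strongly yet contribute
nothing (general-stress responders rather than mode-of-action signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import AnnotationMatrix, GeneticInteractionMatrix
from .enrichment import bh_adjust

#: Default thresholds mirroring the screen-scale analysis: query inner
#: product >= 2 qualifies a profile for the mean; contribution cutoffs
#: (|cg| >= 2.5, importance >= +0.1); "strong" cutoffs (|cg| >= 5, >= +0.5);
#: overrepresentation region: cg z < -5 with |importance| <= 0.1.
DEFAULT_INNER_PRODUCT_THRESHOLD = 2.0
DEFAULT_CG_CUTOFF = 2.5
DEFAULT_IMPORTANCE_CUTOFF = 0.1
STRONG_CG_CUTOFF = 5.0
STRONG_IMPORTANCE_CUTOFF = 0.5
DEFAULT_REGION_BAND = 0.1
DEFAULT_BACKGROUND_Z = -5.0


@dataclass
class ImportanceProfile:
    """Per-strain contribution of one compound to one term prediction."""

    compound_id: str
    term_id: str
    mean_gi_profile: pd.Series  # per-strain mean of qualifying query profiles
    importance: pd.Series  # mean_gi_profile * chemical-genetic profile
    contributing_queries: list[str]
    inner_product_threshold: float
    empty: bool  # True when no annotated query reached the threshold


def importance_profile(
    cg_profile: pd.Series,
    gi_norm: GeneticInteractionMatrix,
    ann: AnnotationMatrix,
    term_id: str,
    threshold: float = DEFAULT_INNER_PRODUCT_THRESHOLD,
) -> ImportanceProfile:
    """Importance scores of one compound's prediction to one term."""
    if term_id not in ann.term_ids:
        raise KeyError(f"term {term_id!r} not in the annotation matrix")
    if not gi_norm.normalized:
        raise ValueError("genetic interaction matrix must be L2-normalized")
    annotated = [q for q in ann.genes_of(term_id) if q in gi_norm.query_ids]
    annotated = sorted(annotated)
    cg = cg_profile.reindex(gi_norm.strain_ids)
    inner = cg.to_numpy() @ gi_norm.scores[annotated].to_numpy()
    qualifying = [q for q, s in zip(annotated, inner) if s >= threshold]
    name = str(cg_profile.name)
    if not qualifying:
        empty = pd.Series(np.nan, index=gi_norm.strain_ids)
        return ImportanceProfile(name, term_id, empty, empty, [], threshold, True)
    mean_gi = gi_norm.scores[qualifying].mean(axis=1)
    return ImportanceProfile(
        compound_id=name,
        term_id=term_id,
        mean_gi_profile=mean_gi,
        importance=mean_gi * cg,
        contributing_queries=qualifying,
        inner_product_threshold=threshold,
        empty=False,
    )


def importance_records(profiles: list[ImportanceProfile],
                       cg_profiles: pd.DataFrame) -> pd.DataFrame:
    """Long table of per-strain scores for a batch of importance profiles.

    ``cg_profiles`` is strains x conditions; one row per (compound, term,
    strain) with the chemical-genetic score, mean genetic interaction and
    importance. Empty profiles contribute no rows.
    """
    frames = []
    for prof in profiles:
        if prof.empty:
            continue
        frames.append(pd.DataFrame({
            "compound_id": prof.compound_id,
            "term_id": prof.term_id,
            "strain_id": prof.importance.index,
            "cg_score": cg_profiles[prof.compound_id].reindex(
                prof.importance.index).to_numpy(),
            "mean_gi": prof.mean_gi_profile.to_numpy(),
            "importance": prof.importance.to_numpy(),
        }))
    if not frames:
        return pd.DataFrame(columns=["compound_id", "term_id", "strain_id",
                                     "cg_score", "mean_gi", "importance"])
    return pd.concat(frames, ignore_index=True)


def contribution_summary(
    records: pd.DataFrame,
    cg_cutoff: float = DEFAULT_CG_CUTOFF,
    importance_cutoff: float = DEFAULT_IMPORTANCE_CUTOFF,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fractions of chemical-genetic interactions that contribute.

    An *interaction* is a strain with |cg_score| >= ``cg_cutoff``; it
    *contributes* when its importance is >= ``importance_cutoff`` (one-sided:
    contribution means sign agreement). Returns a per-compound table
    (fractions overall and split by interaction sign) and pooled counts
    across compounds. Compounds with zero interactions at the cutoff are
    excluded from the per-compound table but counted in pooled denominators.
    """
    if cg_cutoff <= 0 or importance_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    rec = records.copy()
    rec["interaction"] = rec["cg_score"].abs() >= cg_cutoff
    rec["negative"] = rec["cg_score"] <= -cg_cutoff
    rec["positive"] = rec["cg_score"] >= cg_cutoff
    rec["contributing"] = rec["interaction"] & (rec["importance"] >= importance_cutoff)
    rows = []
    pooled = {"n_interactions": 0, "n_contributing": 0,
              "n_negative": 0, "n_negative_contributing": 0,
              "n_positive": 0, "n_positive_contributing": 0}
    for compound, grp in rec.groupby("compound_id", sort=True):
        n_int = int(grp["interaction"].sum())
        n_con = int(grp["contributing"].sum())
        n_neg = int(grp["negative"].sum())
        n_neg_c = int((grp["negative"] & grp["contributing"]).sum())
        n_pos = int(grp["positive"].sum())
        n_pos_c = int((grp["positive"] & grp["contributing"]).sum())
        pooled["n_interactions"] += n_int
        pooled["n_contributing"] += n_con
        pooled["n_negative"] += n_neg
        pooled["n_negative_contributing"] += n_neg_c
        pooled["n_positive"] += n_pos
        pooled["n_positive_contributing"] += n_pos_c
        if n_int == 0:
            continue
        rows.append({
            "compound_id": compound,
            "n_interactions": n_int,
            "fraction_contributing": n_con / n_int,
            "fraction_negative_contributing": n_neg_c / n_neg if n_neg else np.nan,
            "fraction_positive_contributing": n_pos_c / n_pos if n_pos else np.nan,
        })
    return pd.DataFrame(rows), pd.Series(pooled)


def strain_overrepresentation(
    records: pd.DataFrame,
    z_cutoff: float = DEFAULT_BACKGROUND_Z,
    band: float = DEFAULT_REGION_BAND,
    significance: float = 0.05,
) -> pd.DataFrame:
    """Strains overrepresented among strong-but-uninformative interactions.

    Background: observations (one per compound/top-term/strain) with
    chemical-genetic z < ``z_cutoff``. Region: background observations whose
    importance lies within +/-``band`` (strong sensitivity, no contribution).
    Each strain's in-region count is tested against the pooled region with an
    upper-tail hypergeometric test; p-values are BH-adjusted across strains.
    """
    if z_cutoff >= 0:
        raise ValueError("z_cutoff must be negative")
    if band <= 0:
        raise ValueError("band must be positive")
    background = records[records["cg_score"] < z_cutoff]
    if background.empty:
        raise ValueError("empty background: no strong negative interactions")
    in_region = background["importance"].abs() <= band
    n_total = len(background)
    n_region = int(in_region.sum())
    rows = []
    for strain, grp in background.groupby("strain_id", sort=True):
        k = int(in_region.loc[grp.index].sum())
        draws = len(grp)
        p = float(hypergeom.sf(k - 1, n_total, n_region, draws))
        rows.append({"strain_id": strain, "n_background": draws,
                     "n_in_region": k, "p": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adjusted"] <= significance
    return table.sort_values("p").reset_index(drop=True)
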