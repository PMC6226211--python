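"""Synthetic screens with planted compound-process signal.

The generator builds the three pipeline inputs from scratch:

* a modular genetic interaction network — queries in the same functional
  module share a latent per-strain signature, so within-module profile
  correlation is controlled exactly (shared-factor model);
* a one-term-per-module annotation matrix;
* a chemical-genetic screen in which *active* compounds are scaled, noisy
  copies of randomly chosen query profiles (their truth is the parent
  query's terms), while inactive compounds and solvent controls are pure
  unit-variance noise (the profiles are z-scores, so a unit-variance
  Gaussian is the natural null).

Module signatures are sparse-interactor mixtures: a small fraction of
strains are strong *negative* interactors of the module, the remaining
strains carry a small positive balance so the signature has zero mean and
unit variance. This mimics real interaction profiles, in which the strong
entries are overwhelmingly negative (synergistic fitness defects), and is
what lets the planted fixture reproduce the dominance of negative
chemical-genetic interactions in strong predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AnnotationMatrix, ChemGenProfileSet, GeneticInteractionMatrix

#: Fixture defaults: a screen small enough for a laptop-scale end-to-end run
#: yet large enough for rank and FDR statistics to be meaningful.
DEFAULT_N_STRAINS = 100
DEFAULT_N_QUERIES = 60
DEFAULT_N_MODULES = 10
DEFAULT_WITHIN_MODULE_CORR = 0.7
DEFAULT_N_ACTIVE = 50
DEFAULT_N_INACTIVE = 50
DEFAULT_N_CONTROLS = 50
DEFAULT_NOISE_SD = 0.5

#: Amplitude applied to a parent query profile when planting an active
#: compound; with unit-variance query entries this yields z-score-scale
#: interactions (strong strains reach |z| >= 5).
DEFAULT_SIGNAL_SCALE = 5.0

MIN_MODULE_SIZE = 4

#: Fraction of strains that are strong (negative) interactors of a module,
#: and the Gaussian jitter applied around the two mixture levels.
DEFAULT_INTERACTOR_FRACTION = 0.05
_SIGNATURE_JITTER = 0.2


def _module_signatures(rng: np.random.Generator, n_strains: int,
                       n_modules: int, interactor_fraction: float) -> np.ndarray:
    """Zero-mean, unit-variance signatures with negative strong entries.

    With interactor fraction f, interactors sit near -sqrt((1-f)/f) and the
    rest near +sqrt(f/(1-f)) (the levels that balance the mean at 0 and the
    variance at 1), each jittered by a small Gaussian; the final matrix is
    rescaled to exact unit variance.
    """
    f = interactor_fraction
    neg_level = -np.sqrt((1 - f) / f)
    pos_level = np.sqrt(f / (1 - f))
    interactor = rng.random((n_strains, n_modules)) < f
    levels = np.where(interactor, neg_level, pos_level)
    jitter = rng.standard_normal((n_strains, n_modules)) * _SIGNATURE_JITTER
    return (levels + jitter) / np.sqrt(1.0 + _SIGNATURE_JITTER ** 2)


def generate_genetic_network(
    n_strains: int = DEFAULT_N_STRAINS,
    n_queries: int = DEFAULT_N_QUERIES,
    n_modules: int = DEFAULT_N_MODULES,
    within_module_corr: float = DEFAULT_WITHIN_MODULE_CORR,
    seed: int = 0,
    interactor_fraction: float = DEFAULT_INTERACTOR_FRACTION,
) -> tuple[GeneticInteractionMatrix, AnnotationMatrix]:
    """Modular genetic interaction network plus its module annotations.

    Query j in module m is sqrt(corr) * signature_m + sqrt(1-corr) * noise,
    so two queries in the same module have profile correlation ``corr`` and
    queries in different modules are uncorrelated. Module sizes are
    n_queries/n_modules with any remainder spread over the first modules.
    """
    if not 0 <= within_module_corr < 1:
        raise ValueError("within_module_corr must be in [0, 1)")
    base, extra = divmod(n_queries, n_modules)
    sizes = [base + (1 if m < extra else 0) for m in range(n_modules)]
    if min(sizes) < MIN_MODULE_SIZE:
        raise ValueError(
            f"module size {min(sizes)} below the minimum term size "
            f"{MIN_MODULE_SIZE}; use fewer modules or more queries")
    rng = np.random.default_rng(seed)
    signatures = _module_signatures(rng, n_strains, n_modules,
                                    interactor_fraction)
    module_of = np.repeat(np.arange(n_modules), sizes)
    # query-specific deviations follow the same sparse-negative law as the
    # shared signatures: strong entries of real profiles are negative whether
    # they are module-wide or idiosyncratic
    noise = _module_signatures(rng, n_strains, n_queries, interactor_fraction)
    values = (np.sqrt(within_module_corr) * signatures[:, module_of]
              + np.sqrt(1.0 - within_module_corr) * noise)
    strains = pd.Index([f"strain{i:03d}" for i in range(n_strains)])
    queries = pd.Index([f"q{j:03d}" for j in range(n_queries)])
    gi = GeneticInteractionMatrix(pd.DataFrame(values, index=strains,
                                               columns=queries))
    terms = pd.Index([f"M{m:02d}" for m in range(n_modules)])
    membership = pd.DataFrame(0, index=queries, columns=terms, dtype=np.int8)
    for j, m in enumerate(module_of):
        membership.iloc[j, m] = 1
    names = pd.Series([f"module {m} signature" for m in range(n_modules)],
                      index=terms)
    return gi, AnnotationMatrix(membership, names)


def generate_strain_annotations(
    gi: GeneticInteractionMatrix,
    ann: AnnotationMatrix,
    n_per_module: int = 10,
) -> AnnotationMatrix:
    """Strain-universe annotations for the direct-enrichment baseline.

    Each module term is assigned the ``n_per_module`` strains with the most
    negative mean interaction across the module's queries — the strains a
    perturbation of that module hits hardest.
    """
    membership = pd.DataFrame(0, index=gi.strain_ids, columns=ann.term_ids,
                              dtype=np.int8)
    for term in ann.term_ids:
        queries = [q for q in ann.genes_of(term) if q in gi.query_ids]
        means = gi.scores[queries].mean(axis=1)
        top = means.nsmallest(n_per_module).index
        membership.loc[top, term] = 1
    return AnnotationMatrix(membership, ann.term_names)


@dataclass
class ScreenTruth:
    """Ground truth for a synthetic screen."""

    table: pd.DataFrame  # condition_id, active, parent_query, terms ("|"-joined)

    def active_terms(self) -> pd.Series:
        """condition id -> frozenset of planted term ids (actives only)."""
        active = self.table[self.table["active"]]
        return pd.Series(
            [frozenset(t.split("|")) if t else frozenset()
             for t in active["terms"]],
            index=active["condition_id"].to_numpy())


def generate_screen(
    gi: GeneticInteractionMatrix,
    ann: AnnotationMatrix,
    n_active: int = DEFAULT_N_ACTIVE,
    n_inactive: int = DEFAULT_N_INACTIVE,
    n_controls: int = DEFAULT_N_CONTROLS,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    signal_scale: float = DEFAULT_SIGNAL_SCALE,
) -> tuple[ChemGenProfileSet, ScreenTruth]:
    """Chemical-genetic screen with ``n_active`` planted compounds.

    Each active compound copies a randomly chosen query column scaled by
    ``signal_scale`` and adds Gaussian noise with standard deviation
    ``noise_sd`` times the scaled column's standard deviation. Inactive
    compounds and solvent controls are independent unit-variance noise.
    """
    if min(n_active, n_inactive, n_controls) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_m = gi.scores.shape[0]
    columns: list[np.ndarray] = []
    ids: list[str] = []
    types: list[str] = []
    truth_rows = []
    parents = rng.choice(gi.query_ids.to_numpy(), size=n_active, replace=True)
    gene_sets = {t: ann.genes_of(t) for t in ann.term_ids}
    for i, parent in enumerate(parents):
        signal = signal_scale * gi.scores[parent].to_numpy()
        sd = noise_sd * signal.std(ddof=1)
        profile = signal + rng.standard_normal(n_m) * sd
        cid = f"cmpd_active_{i:04d}"
        columns.append(profile)
        ids.append(cid)
        types.append("treatment")
        terms = sorted(t for t, genes in gene_sets.items() if parent in genes)
        truth_rows.append((cid, True, parent, "|".join(terms)))
    for i in range(n_inactive):
        cid = f"cmpd_inactive_{i:04d}"
        columns.append(rng.standard_normal(n_m))
        ids.append(cid)
        types.append("treatment")
        truth_rows.append((cid, False, "", ""))
    for i in range(n_controls):
        cid = f"dmso_{i:04d}"
        columns.append(rng.standard_normal(n_m))
        ids.append(cid)
        types.append("control")
        truth_rows.append((cid, False, "", ""))
    if not columns:
        raise ValueError("screen has no conditions")
    scores = pd.DataFrame(np.column_stack(columns), index=gi.strain_ids,
                          columns=pd.Index(ids))
    cg = ChemGenProfileSet(scores, pd.Series(types, index=pd.Index(ids)))
    truth = ScreenTruth(pd.DataFrame(
        truth_rows, columns=["condition_id", "active", "parent_query", "terms"]))
    return cg, truth
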