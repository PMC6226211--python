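"""End-to-end orchestration: align -> normalize -> resample -> score ->
significance -> combine -> FDR -> tables.

`run_predict` is the library entry point used by both the CLI and the test
fixtures; it takes in-memory containers plus a `PredictConfig` and returns a
`PredictionResult` bundling every intermediate a downstream analysis needs
(similarity matrices, combined statistics per profile type, both FDR maps,
and writers for the on-disk tables).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotations as ann_mod
from .containers import (AnnotationMatrix, ChemGenProfileSet,
                         GeneticInteractionMatrix, align_strains)
from .errors import ConfigError
from .fdr import (FdrMap, apply_fdr, best_p_per_profile, build_fdr_map,
                  count_discoveries, fdr_summary, pool_observed_p)
from .resampling import generate_resampled_profiles
from .scoring import l2_normalize_queries, process_scores, similarity_scores
from .significance import CombinedStats, combine_statistics, control_statistics, \
    within_statistics

log = logging.getLogger(__name__)

PROFILE_TYPES = ("treatment", "control", "resampled")


@dataclass
class PredictConfig:
    """Tunable parameters of a prediction run (screen-scale defaults)."""

    n_resampled: int = 50_000
    n_permutations: int = 10_000
    min_term_size: int = 4
    max_term_size: int = 200
    fdr_cap: float = 1.0
    seed: int = 0

    def manifest(self) -> dict:
        return asdict(self)


@dataclass
class PredictionResult:
    """Everything a prediction run computes."""

    config: PredictConfig
    cg: ChemGenProfileSet  # aligned, including resampled columns
    gi_norm: GeneticInteractionMatrix
    ann: AnnotationMatrix
    similarity: dict[str, pd.DataFrame]  # per profile type
    scores: dict[str, pd.DataFrame]
    combined: dict[str, CombinedStats]
    fdr_maps: dict[str, FdrMap]  # keys: control, resampled
    fdr_treatment: dict[str, pd.DataFrame]

    def predictions_table(self) -> pd.DataFrame:
        """Treatment predictions in the standard output schema."""
        table = self.combined["treatment"].to_frame()
        table.insert(2, "term_name",
                     self.ann.term_names.reindex(table["term_id"]).to_numpy())
        table.insert(3, "score",
                     self.scores["treatment"].stack().to_numpy())
        for key in ("control", "resampled"):
            table[f"fdr_{key}"] = self.fdr_treatment[key].stack().to_numpy()
        return table

    def discovery_counts(self, cutoffs=(0.0, 0.05, 0.10, 0.25),
                         control_type: str = "resampled") -> pd.Series:
        """Treatments discovered at each FDR cutoff (default: resampled map)."""
        ptop = best_p_per_profile(self.combined["treatment"].p_final)
        fmap = self.fdr_maps[control_type]
        return pd.Series({c: count_discoveries(fmap, ptop, c) for c in cutoffs})

    def summary_table(self) -> pd.DataFrame:
        ptops = {t: best_p_per_profile(self.combined[t].p_final)
                 for t in PROFILE_TYPES}
        return fdr_summary(self.fdr_maps, ptops)


def run_predict(
    cg: ChemGenProfileSet,
    gi: GeneticInteractionMatrix,
    ann: AnnotationMatrix,
    config: PredictConfig | None = None,
) -> PredictionResult:
    """Run the full prediction pipeline on in-memory inputs.

    ``cg`` must carry treatment and control conditions; resampled profiles
    are generated here. ``ann`` is the raw annotation matrix over the query
    universe; queries dropped during normalization are dropped from it and
    term sizes re-filtered before scoring.
    """
    config = config or PredictConfig()
    log.info("prediction run with %s", config.manifest())
    cg, gi = align_strains(cg, gi)
    if not (cg.condition_types == "control").any():
        raise ConfigError("no experimental control conditions in the screen")
    gi_norm = l2_normalize_queries(gi)
    ann = ann_mod.filter_term_sizes(
        ann.restrict_genes(gi_norm.query_ids),
        config.min_term_size, config.max_term_size)
    if len(ann.term_ids) == 0:
        raise ConfigError("no terms left after size filtering")

    resampled = generate_resampled_profiles(cg, config.n_resampled, config.seed)
    full = cg.with_resampled(resampled)

    similarity: dict[str, pd.DataFrame] = {}
    scores: dict[str, pd.DataFrame] = {}
    for ptype in PROFILE_TYPES:
        sub = full.subset(ptype)
        similarity[ptype] = similarity_scores(sub, gi_norm)
        scores[ptype] = process_scores(similarity[ptype], ann)

    combined: dict[str, CombinedStats] = {}
    for i, ptype in enumerate(PROFILE_TYPES):
        stats = {
            "control": control_statistics(scores[ptype], scores["control"],
                                          "control"),
            "resampled": control_statistics(scores[ptype], scores["resampled"],
                                            "resampled"),
            "within": within_statistics(similarity[ptype], ann,
                                        config.n_permutations,
                                        seed=config.seed + 1 + i),
        }
        combined[ptype] = combine_statistics(stats)

    p_all = pool_observed_p(*(combined[t].p_final for t in PROFILE_TYPES))
    ptop = {t: best_p_per_profile(combined[t].p_final) for t in PROFILE_TYPES}
    fdr_maps = {
        key: build_fdr_map(ptop["treatment"], ptop[key], p_all, key,
                           cap=config.fdr_cap)
        for key in ("control", "resampled")
    }
    fdr_treatment = {key: apply_fdr(fmap, combined["treatment"].p_final)
                     for key, fmap in fdr_maps.items()}
    return PredictionResult(
        config=config, cg=full, gi_norm=gi_norm, ann=ann,
        similarity=similarity, scores=scores, combined=combined,
        fdr_maps=fdr_maps, fdr_treatment=fdr_treatment,
    )


def write_outputs(result: PredictionResult, out_dir: str | Path,
                  float_format: str = "%.6g") -> dict[str, Path]:
    """Write the standard output tables and a run manifest.

    Files: predictions.tsv (per condition-term), fdr_summary.tsv (per
    p-value threshold), combined p/z dumps per profile type, manifest.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pred = result.predictions_table()
    paths["predictions"] = out_dir / "predictions.tsv"
    pred.to_csv(paths["predictions"], sep="\t", index=False,
                float_format=float_format)

    paths["fdr_summary"] = out_dir / "fdr_summary.tsv"
    result.summary_table().to_csv(paths["fdr_summary"], sep="\t", index=False,
                                  float_format=float_format)

    for ptype in PROFILE_TYPES:
        for name, frame in (("p", result.combined[ptype].p_final),
                            ("z", result.combined[ptype].z_final)):
            path = out_dir / f"{name}_combined_{ptype}.tsv"
            frame.to_csv(path, sep="\t")
            paths[f"{name}_{ptype}"] = path

    manifest = result.config.manifest()
    manifest.update({
        "n_strains": int(result.cg.n_strains),
        "n_treatment": result.cg.n_conditions("treatment"),
        "n_control": result.cg.n_conditions("control"),
        "n_resampled": result.cg.n_conditions("resampled"),
        "n_queries": int(result.gi_norm.n_queries),
        "n_terms": int(len(result.ann.term_ids)),
    })
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote %d output files to %s", len(paths), out_dir)
    return paths
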