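"""Resampled chemical-genetic profile null.

Solvent controls capture plate- and measurement-level noise but not the extra
per-strain variance that appears only under treatment with bioactive compound.
The resampled null captures it: each entry of a resampled profile is drawn
independently, uniformly with replacement, from that strain's interaction
scores across the *treatment* conditions. A resampled profile therefore has
realistic marginal score distributions per strain while destroying any
coherent cross-strain signature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ChemGenProfileSet
from .errors import AlignmentError

#: Screen-scale default size of the resampled null cohort.
DEFAULT_N_RESAMPLED = 50_000

RESAMPLED_PREFIX = "resampled"


def generate_resampled_profiles(
    cg: ChemGenProfileSet, n_resampled: int, seed: int
) -> ChemGenProfileSet:
    """Draw a cohort of resampled null profiles from the treatment columns.

    Entry (i, j) of the output is an independently drawn member of strain i's
    treatment-score multiset. One seeded generator is consumed in row-major
    order, so results are reproducible for a fixed seed and generator
    algorithm (PCG64).
    """
    if n_resampled < 1:
        raise ValueError("n_resampled must be >= 1")
    if (cg.condition_types == "treatment").any():
        treat = cg.subset("treatment")
    else:
        raise AlignmentError("no treatment conditions to resample from")
    values = treat.scores.to_numpy()
    n_m, n_alpha = values.shape
    rng = np.random.default_rng(seed)
    choice = rng.integers(0, n_alpha, size=(n_m, n_resampled))
    resampled = np.take_along_axis(values, choice, axis=1)
    ids = pd.Index(
        [f"{RESAMPLED_PREFIX}_{j:06d}" for j in range(n_resampled)])
    scores = pd.DataFrame(resampled, index=treat.strain_ids, columns=ids)
    types = pd.Series("resampled", index=ids, name="type")
    return ChemGenProfileSet(scores, types)
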