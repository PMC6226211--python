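"""Empirical false discovery rate estimation from control discovery rates.

A profile is "discovered" at a p-value threshold if its best (smallest)
combined process p-value passes the threshold. The FDR at a threshold is the
fraction of control profiles discovered divided by the fraction of treatment
profiles discovered, evaluated over the grid of every observed p-value and
then made monotone nondecreasing in p by a reverse cumulative minimum
(values at a looser threshold can never be beaten by a stricter one).

Two maps are built per run: one against solvent-control profiles and one
against resampled profiles. The resampled map is typically the more
conservative because resampled profiles carry treatment-specific per-strain
variance that solvent controls lack; high-confidence discovery defaults to
the resampled map, but both are always reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: FDR cutoffs used for the standard discovery summary.
SUMMARY_CUTOFFS = (0.0, 0.05, 0.10, 0.25)


@dataclass
class FdrMap:
    """Monotone step-function mapping observed p-values to FDR estimates."""

    control_type: str
    p_all: np.ndarray  # sorted unique observed p-values
    r_star: np.ndarray  # raw control/treatment discovery-rate ratio
    r: np.ndarray  # monotone (reverse cumulative min), capped

    def lookup(self, p: np.ndarray) -> np.ndarray:
        """FDR at each p via the step function (exact grid hits expected)."""
        p = np.asarray(p, dtype=float)
        idx = np.searchsorted(self.p_all, p, side="right") - 1
        if (idx < 0).any():
            log.warning("p-value(s) below the FDR map grid; clamped to first step")
            idx = np.clip(idx, 0, None)
        return self.r[idx]


def best_p_per_profile(p_matrix: pd.DataFrame) -> pd.Series:
    """Each profile's smallest combined process p-value."""
    if p_matrix.shape[1] == 0:
        raise ValueError("p matrix has no terms")
    return p_matrix.min(axis=1)


def pool_observed_p(*p_matrices: pd.DataFrame) -> np.ndarray:
    """Sorted unique union of every entry of the given combined p matrices."""
    values = np.concatenate([m.to_numpy(dtype=float).ravel() for m in p_matrices])
    return np.unique(values)


def build_fdr_map(
    ptop_treatment: pd.Series | np.ndarray,
    ptop_control: pd.Series | np.ndarray,
    p_all: np.ndarray,
    control_type: str,
    cap: float = 1.0,
) -> FdrMap:
    """Estimate FDR at every observed p-value threshold.

    r*[i] = frac(control best-p <= p_all[i]) / frac(treatment best-p <= p_all[i]),
    with 0/0 -> 0 and x/0 (x > 0) -> cap; r is the reverse cumulative minimum
    of r*, capped at ``cap``.
    """
    treat = np.sort(np.asarray(ptop_treatment, dtype=float))
    ctrl = np.sort(np.asarray(ptop_control, dtype=float))
    if treat.size == 0 or ctrl.size == 0:
        raise ValueError("need at least one treatment and one control profile")
    p_all = np.asarray(p_all, dtype=float)
    frac_treat = np.searchsorted(treat, p_all, side="right") / treat.size
    frac_ctrl = np.searchsorted(ctrl, p_all, side="right") / ctrl.size
    with np.errstate(divide="ignore", invalid="ignore"):
        r_star = frac_ctrl / frac_treat
    r_star = np.where(frac_treat == 0, np.where(frac_ctrl == 0, 0.0, cap), r_star)
    r_star = np.minimum(r_star, cap)
    r = np.minimum.accumulate(r_star[::-1])[::-1]
    return FdrMap(control_type=control_type, p_all=p_all, r_star=r_star, r=r)


def apply_fdr(fdr_map: FdrMap, p_matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise FDR lookup for a combined p matrix."""
    values = fdr_map.lookup(p_matrix.to_numpy(dtype=float))
    return pd.DataFrame(values, index=p_matrix.index, columns=p_matrix.columns)


def count_discoveries(
    fdr_map: FdrMap, ptop: pd.Series | np.ndarray, fdr_cutoff: float
) -> int:
    """Number of profiles whose best prediction passes an FDR cutoff."""
    ptop = np.asarray(ptop, dtype=float)
    passing = fdr_map.p_all[fdr_map.r <= fdr_cutoff]
    if passing.size == 0:
        return 0
    return int((ptop <= passing.max()).sum())


def fdr_summary(
    maps: dict[str, FdrMap],
    ptops: dict[str, pd.Series],
) -> pd.DataFrame:
    """Machine-readable discovery-rate table over the full p-value grid.

    One row per observed p-value threshold: the number of treatment, solvent
    control and resampled profiles discovered, and the two FDR estimates.
    ``maps`` has keys ``control``/``resampled``; ``ptops`` has keys
    ``treatment``/``control``/``resampled``.
    """
    p_all = maps["resampled"].p_all
    out = {"p_threshold": p_all}
    for name, ptop in ptops.items():
        sorted_p = np.sort(np.asarray(ptop, dtype=float))
        out[f"n_{name}_discovered"] = np.searchsorted(sorted_p, p_all, side="right")
    out["fdr_control"] = maps["control"].r
    out["fdr_resampled"] = maps["resampled"].r
    return pd.DataFrame(out)
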