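"""Z-scores and empirical p-values from three nulls, conservatively combined.

Every compound-process score is judged against three null distributions:

* **control** — the term's scores across solvent-control profiles;
* **resampled** — the term's scores across resampled null profiles;
* **within** — the compound's own gene-similarity score distribution,
  assessed by permuting the gene labels of its similarity row.

Each null yields a z-score and an empirical p-value (a count fraction; the
``<=`` in the count means a score tying the best null score still pays
1/n in p). The three (z, p) pairs are combined by taking the *largest*
(least significant) p-value; p ties are broken by the *smallest* z. The
combined pair is therefore the most conservative of the three readings, and
it is computed for every profile type — treatments and both control types —
because the downstream FDR machinery compares their discovery rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AnnotationMatrix

#: Combination order; also the deterministic tie-break order when both the
#: p-values and the z-scores tie exactly.
SOURCES = ("control", "resampled", "within")

#: Large finite stand-in for +/- infinite z when a null has zero variance.
Z_SENTINEL = 1e30


@dataclass
class SourceStats:
    """One null's verdict on every (condition, term) pair.

    ``counts`` holds the integer numerators of the empirical p-values
    (denominator ``denominator``), so p-values stay exact rationals.
    ``zero_variance`` flags entries where the null spread was 0 and the
    z-score is the +/-``Z_SENTINEL`` convention (0 when the numerator is 0).
    """

    source: str
    z: pd.DataFrame
    p: pd.DataFrame
    counts: pd.DataFrame
    denominator: int
    zero_variance: pd.DataFrame


@dataclass
class CombinedStats:
    """Per-(condition, term) combined statistics plus their three sources."""

    per_source: dict[str, SourceStats]
    source: pd.DataFrame
    z_final: pd.DataFrame
    p_final: pd.DataFrame
    p_numerator: pd.DataFrame
    p_denominator: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (condition, term)."""
        rows = self.p_final.stack()
        out = pd.DataFrame({
            "condition_id": rows.index.get_level_values(0),
            "term_id": rows.index.get_level_values(1),
            "z": self.z_final.stack().to_numpy(),
            "p_count_numerator": self.p_numerator.stack().to_numpy(),
            "p_count_denominator": self.p_denominator.stack().to_numpy(),
            "p": rows.to_numpy(),
            "source": self.source.stack().to_numpy(),
        })
        return out.reset_index(drop=True)


def _z_with_sentinel(numerator: np.ndarray, spread: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(numerator / spread) with the zero-variance sentinel convention."""
    zero = spread == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = numerator / spread
    if np.any(zero):
        z = np.where(zero & (numerator == 0), 0.0, z)
        z = np.where(zero & (numerator != 0), np.sign(numerator) * Z_SENTINEL, z)
    return z, np.broadcast_to(zero, z.shape).copy()


def control_statistics(
    x_obs: pd.DataFrame, x_null: pd.DataFrame, source: str
) -> SourceStats:
    """Score observed process scores against a cohort of null profiles.

    z uses the null cohort's per-term mean and sample (n-1) standard
    deviation; the empirical p for an entry is the fraction of null profiles
    whose score for that term is >= the observed score.
    """
    n_b = x_null.shape[0]
    if n_b < 2:
        raise ValueError("need at least 2 null profiles for a standard deviation")
    null = x_null.to_numpy(dtype=float)
    obs = x_obs.to_numpy(dtype=float)
    u = null.mean(axis=0)
    v = null.std(axis=0, ddof=1)
    z, zero = _z_with_sentinel(obs - u, v)
    # counts: per term, #{k : obs <= null_k}; via sorted columns
    order = np.sort(null, axis=0)
    counts = np.empty_like(obs, dtype=np.int64)
    for t in range(null.shape[1]):
        counts[:, t] = n_b - np.searchsorted(order[:, t], obs[:, t], side="left")
    shape = dict(index=x_obs.index, columns=x_obs.columns)
    return SourceStats(
        source=source,
        z=pd.DataFrame(z, **shape),
        p=pd.DataFrame(counts / n_b, **shape),
        counts=pd.DataFrame(counts, **shape),
        denominator=n_b,
        zero_variance=pd.DataFrame(zero, **shape),
    )


def within_statistics(
    sim: pd.DataFrame,
    ann: AnnotationMatrix,
    n_permutations: int,
    seed: int,
    *,
    chunk_size: int = 64,
) -> SourceStats:
    """Score each term's mean gene similarity against the profile's own scores.

    z compares the term mean to the condition's overall mean and sample
    standard deviation of gene similarity scores (scaled by sqrt(term size)).
    The empirical p counts, over seeded within-row permutations of the
    similarity scores, how often the permuted term score reaches the observed
    one. Each condition row is permuted independently; permutations are drawn
    with replacement from the permutation group.
    """
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    s = sim[ann.gene_ids].to_numpy(dtype=float)
    b = ann.membership.to_numpy(dtype=float)
    n_cond, n_q = s.shape
    d = b.sum(axis=0)
    x = s @ b
    w = s.mean(axis=1, keepdims=True)
    y = s.std(axis=1, ddof=1, keepdims=True) if n_q > 1 else np.zeros((n_cond, 1))
    z, zero = _z_with_sentinel(x / d - w, y / np.sqrt(d))

    rng = np.random.default_rng(seed)
    counts = np.zeros((n_cond, b.shape[1]), dtype=np.int64)
    for start in range(0, n_cond, chunk_size):
        rows = s[start:start + chunk_size]
        m = rows.shape[0]
        tiled = np.repeat(rows[:, None, :], n_permutations, axis=1)
        rng.permuted(tiled, axis=2, out=tiled)
        perm_x = tiled @ b  # (m, n_permutations, n_terms)
        counts[start:start + m] = (
            x[start:start + m, None, :] <= perm_x).sum(axis=1)
    shape = dict(index=sim.index, columns=ann.term_ids)
    return SourceStats(
        source="within",
        z=pd.DataFrame(z, **shape),
        p=pd.DataFrame(counts / n_permutations, **shape),
        counts=pd.DataFrame(counts, **shape),
        denominator=n_permutations,
        zero_variance=pd.DataFrame(zero, **shape),
    )


def combine_statistics(stats: dict[str, SourceStats]) -> CombinedStats:
    """Keep, per (condition, term), the least significant null's verdict.

    The winning source has the largest p; among p ties the smallest z wins
    (and exact (p, z) ties fall back to the fixed order of ``SOURCES``).
    """
    missing = set(SOURCES) - set(stats)
    if missing:
        raise ValueError(f"missing source statistics: {sorted(missing)}")
    first = stats[SOURCES[0]]
    index, columns = first.p.index, first.p.columns
    p = np.stack([stats[s].p.to_numpy(dtype=float) for s in SOURCES])
    z = np.stack([stats[s].z.to_numpy(dtype=float) for s in SOURCES])
    num = np.stack([stats[s].counts.to_numpy() for s in SOURCES])
    den = np.array([stats[s].denominator for s in SOURCES])

    p_final = p.max(axis=0)
    z_masked = np.where(p == p_final[None, :, :], z, np.inf)
    winner = z_masked.argmin(axis=0)

    take = np.take_along_axis
    z_final = take(z, winner[None], axis=0)[0]
    numerator = take(num, winner[None], axis=0)[0]
    denominator = den[winner]
    source = np.array(SOURCES, dtype=object)[winner]
    shape = dict(index=index, columns=columns)
    return CombinedStats(
        per_source=stats,
        source=pd.DataFrame(source, **shape),
        z_final=pd.DataFrame(z_final, **shape),
        p_final=pd.DataFrame(p_final, **shape),
        p_numerator=pd.DataFrame(numerator, **shape),
        p_denominator=pd.DataFrame(denominator, **shape),
    )
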