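"""Typed matrix containers and labeled-TSV / GMT readers and writers.

Two kinds of interaction matrices flow through the pipeline and share their
row (strain) axis:

* chemical-genetic interaction profiles — z-scores of mutant-strain abundance
  under a condition (compound treatment or solvent control), strains x
  conditions, with a per-condition type label;
* genetic interaction profiles — double-mutant epsilon scores, strains x
  query genes.

On disk both are UTF-8 tab-separated matrices with one header row of column
identifiers and a first column of row identifiers; strains are rows. Gene-set
annotations use the GMT dialect (term_id, term_name, member ids). Condition
types travel in a two-column sidecar TSV (condition_id, type).

All entries must be finite: missing values are rejected at load (the scoring
model assumes dense matrices), with an explicit ``impute_zero`` escape hatch
that converts NaN to 0 with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

log = logging.getLogger(__name__)

#: Valid condition-type labels for chemical-genetic profiles.
CONDITION_TYPES = ("treatment", "control", "resampled")


def _check_unique(ids: pd.Index, axis: str, where: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {axis} identifier(s) {dup[:5]} in {where}")


def _check_finite(values: np.ndarray, index: pd.Index, columns: pd.Index,
                  where: str) -> None:
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-finite value at row {index[i]!r}, column {columns[j]!r} in {where}"
        )


@dataclass
class ChemGenProfileSet:
    """Chemical-genetic interaction z-scores, strains x conditions.

    Parameters
    ----------
    scores
        Strains (rows) by conditions (columns); every entry finite.
    condition_types
        Maps each condition id to ``treatment``, ``control`` or ``resampled``.
    """

    scores: pd.DataFrame
    condition_types: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.scores.index, "strain", "ChemGenProfileSet")
        _check_unique(self.scores.columns, "condition", "ChemGenProfileSet")
        if self.scores.size == 0:
            raise FormatError("empty chemical-genetic matrix")
        values = np.asarray(self.scores.values, dtype=float)
        _check_finite(values, self.scores.index, self.scores.columns,
                      "ChemGenProfileSet")
        self.condition_types = self.condition_types.reindex(self.scores.columns)
        if self.condition_types.isna().any():
            missing = self.condition_types.index[self.condition_types.isna()]
            raise FormatError(
                f"no condition type for condition(s) {missing.tolist()[:5]}"
            )
        unknown = set(self.condition_types) - set(CONDITION_TYPES)
        if unknown:
            raise FormatError(f"unknown condition type(s) {sorted(unknown)}")

    # -- label accessors -------------------------------------------------
    @property
    def strain_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def condition_ids(self) -> pd.Index:
        return self.scores.columns

    @property
    def n_strains(self) -> int:
        return self.scores.shape[0]

    def n_conditions(self, condition_type: str | None = None) -> int:
        if condition_type is None:
            return self.scores.shape[1]
        return int((self.condition_types == condition_type).sum())

    def subset(self, condition_type: str) -> "ChemGenProfileSet":
        """Restrict to conditions of one type (order preserved)."""
        keep = self.condition_types.index[self.condition_types == condition_type]
        if len(keep) == 0:
            raise AlignmentError(f"no conditions of type {condition_type!r}")
        return ChemGenProfileSet(self.scores[keep], self.condition_types[keep])

    def with_resampled(self, resampled: "ChemGenProfileSet") -> "ChemGenProfileSet":
        """Append resampled null profiles (same strains, same order)."""
        if not self.strain_ids.equals(resampled.strain_ids):
            raise AlignmentError("resampled profiles have mismatched strains")
        scores = pd.concat([self.scores, resampled.scores], axis=1)
        types = pd.concat([self.condition_types, resampled.condition_types])
        return ChemGenProfileSet(scores, types)


@dataclass
class GeneticInteractionMatrix:
    """Genetic interaction scores, strains x query genes.

    ``normalized`` is True iff every query column has unit Euclidean norm
    (enforced to 1e-9); raw matrices carry the screen's epsilon scores.
    """

    scores: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.scores.index, "strain", "GeneticInteractionMatrix")
        _check_unique(self.scores.columns, "query", "GeneticInteractionMatrix")
        if self.scores.size == 0:
            raise FormatError("empty genetic interaction matrix")
        values = np.asarray(self.scores.values, dtype=float)
        _check_finite(values, self.scores.index, self.scores.columns,
                      "GeneticInteractionMatrix")
        if self.normalized:
            norms = np.linalg.norm(values, axis=0)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise FormatError("normalized flag set but columns are not unit norm")

    @property
    def strain_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def query_ids(self) -> pd.Index:
        return self.scores.columns

    @property
    def n_queries(self) -> int:
        return self.scores.shape[1]


@dataclass
class AnnotationMatrix:
    """Binary gene (or strain) x term membership with display names.

    The row universe is the query-gene set for bioprocess prediction, or the
    strain set for the direct-enrichment baseline.
    """

    membership: pd.DataFrame
    term_names: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_unique(self.membership.index, "gene", "AnnotationMatrix")
        _check_unique(self.membership.columns, "term", "AnnotationMatrix")
        values = np.asarray(self.membership.values)
        if not np.isin(values, (0, 1)).all():
            raise FormatError("annotation membership must be binary")
        self.membership = self.membership.astype(np.int8)
        if self.term_names is None:
            self.term_names = pd.Series(self.membership.columns,
                                        index=self.membership.columns)
        else:
            self.term_names = self.term_names.reindex(self.membership.columns)
            self.term_names = self.term_names.fillna(
                pd.Series(self.membership.columns, index=self.membership.columns))

    @property
    def gene_ids(self) -> pd.Index:
        return self.membership.index

    @property
    def term_ids(self) -> pd.Index:
        return self.membership.columns

    @property
    def term_sizes(self) -> pd.Series:
        return self.membership.sum(axis=0).astype(int)

    def genes_of(self, term_id: str) -> frozenset:
        col = self.membership[term_id]
        return frozenset(col.index[col == 1])

    def gene_sets(self) -> dict[str, frozenset]:
        return {t: self.genes_of(t) for t in self.term_ids}

    def restrict_genes(self, genes: Sequence[str]) -> "AnnotationMatrix":
        """Restrict the gene universe (term columns kept, sizes shrink)."""
        keep = [g for g in self.gene_ids if g in set(genes)]
        return AnnotationMatrix(self.membership.loc[keep], self.term_names)


# ---------------------------------------------------------------------------
# labeled-TSV I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
    # pandas silently renames duplicate header fields, so check them raw
    _check_unique(pd.Index(header), "column", str(path))
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if raw.size == 0:
        raise FormatError(f"empty matrix in {path}")
    _check_unique(pd.Index(raw.index), "row", str(path))
    _check_unique(pd.Index(raw.columns), "column", str(path))
    try:
        values = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad.argmax()]
                raise FormatError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}")
        raise
    return values


def read_labeled_matrix(
    path: str | Path,
    *,
    rows_are_strains: bool = True,
    kind: str = "chemgen",
    condition_types: pd.Series | str | Path | None = None,
    impute_zero: bool = False,
) -> ChemGenProfileSet | GeneticInteractionMatrix:
    """Read a labeled TSV matrix into a typed container.

    Parameters
    ----------
    rows_are_strains
        The on-disk convention puts strains on rows; pass False to transpose
        a nonconforming file.
    kind
        ``"chemgen"`` (requires ``condition_types``) or ``"genetic"``.
    condition_types
        Sidecar mapping (or path to a two-column TSV) from condition id to
        ``treatment``/``control``.
    impute_zero
        Convert NaN cells to 0 with a warning instead of failing.
    """
    values = _read_table(path)
    if not rows_are_strains:
        values = values.T
    if values.isna().any().any():
        if impute_zero:
            n = int(values.isna().sum().sum())
            log.warning("imputing %d missing value(s) in %s with 0", n, path)
            values = values.fillna(0.0)
        else:
            stacked = values.isna().stack()
            row, col = stacked.index[stacked.argmax()]
            raise FormatError(
                f"missing cell at row {row!r}, column {col!r} in {path} "
                f"(use impute_zero to convert to 0)")
    if kind == "genetic":
        return GeneticInteractionMatrix(values)
    if kind != "chemgen":
        raise ValueError(f"unknown matrix kind {kind!r}")
    if condition_types is None:
        raise FormatError("chemical-genetic matrices need a condition-type table")
    if isinstance(condition_types, (str, Path)):
        condition_types = read_condition_types(condition_types)
    return ChemGenProfileSet(values, condition_types)


def write_labeled_matrix(frame, path: str | Path) -> None:
    """Write a labeled matrix TSV at full double precision (round-trip safe)."""
    scores = frame.scores if hasattr(frame, "scores") else frame
    scores.to_csv(path, sep="\t")


def read_condition_types(path: str | Path) -> pd.Series:
    """Read the condition-type sidecar TSV (columns: condition_id, type)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"condition-type table {path} needs 2 columns")
    ids = pd.Index(table.iloc[:, 0])
    _check_unique(ids, "condition", str(path))
    return pd.Series(table.iloc[:, 1].values, index=ids, name="type")


def write_condition_types(types: pd.Series, path: str | Path) -> None:
    frame = pd.DataFrame({"condition_id": types.index, "type": types.values})
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path, universe: Iterable[str]) -> AnnotationMatrix:
    """Load a GMT file into an annotation matrix over a fixed gene universe.

    One term per line: ``term_id <TAB> term_name <TAB> member...``. Members
    outside ``universe`` are silently dropped (count logged); terms left with
    zero members are retained so size filtering stays a separate, explicit
    step.
    """
    universe = pd.Index(dict.fromkeys(universe))
    term_ids: list[str] = []
    term_names: list[str] = []
    columns: list[np.ndarray] = []
    in_universe = set(universe)
    dropped = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 fields")
            term_id, term_name, *members = fields
            if term_id in term_ids:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            kept = [m for m in dict.fromkeys(members) if m in in_universe]
            dropped += len(set(members)) - len(kept)
            col = np.zeros(len(universe), dtype=np.int8)
            col[universe.get_indexer(kept)] = 1
            if not kept:
                log.warning("term %s has no members in the gene universe", term_id)
            term_ids.append(term_id)
            term_names.append(term_name)
            columns.append(col)
    if not term_ids:
        raise FormatError(f"no terms in {path}")
    if dropped:
        log.info("dropped %d gene memberships outside the universe", dropped)
    membership = pd.DataFrame(
        np.column_stack(columns), index=universe, columns=pd.Index(term_ids))
    return AnnotationMatrix(membership, pd.Series(term_names, index=term_ids))


def write_gene_sets(ann: AnnotationMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for term in ann.term_ids:
            members = ann.membership.index[ann.membership[term] == 1]
            name = ann.term_names[term]
            handle.write("\t".join([term, str(name), *members]) + "\n")


# ---------------------------------------------------------------------------
# strain alignment
# ---------------------------------------------------------------------------

def align_strains(
    cg: ChemGenProfileSet, gi: GeneticInteractionMatrix
) -> tuple[ChemGenProfileSet, GeneticInteractionMatrix]:
    """Restrict both matrices to their shared strains, in the cg file order.

    The genetic interaction compendium is screened on more strains than any
    one chemical-genetic screen; both sides are cut to the intersection and
    reordered identically so inner products line up row by row. Idempotent.
    """
    shared = cg.strain_ids.intersection(gi.strain_ids)
    if len(shared) == 0:
        raise AlignmentError("chemical-genetic and genetic matrices share no strains")
    # canonical order: cg file order restricted to the intersection
    order = [s for s in cg.strain_ids if s in set(shared)]
    dropped_cg = cg.n_strains - len(order)
    dropped_gi = len(gi.strain_ids) - len(order)
    if dropped_cg or dropped_gi:
        log.info("alignment dropped %d chemical-genetic and %d genetic strains",
                 dropped_cg, dropped_gi)
    cg_out = ChemGenProfileSet(cg.scores.loc[order], cg.condition_types)
    gi_out = GeneticInteractionMatrix(gi.scores.loc[order], gi.normalized)
    return cg_out, gi_out
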