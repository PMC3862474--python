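"""Mirrortree co-evolution scoring.

A protein pair is scored by restricting both ortholog families to their
common species, computing each family's condensed pairwise evolutionary
distance vector over that shared species order, and taking the Pearson
correlation r of the two vectors.  High r means the two families'
distance matrices mirror each other — the co-evolution signal used to
predict interaction.

Pairs with fewer common species than the configured minimum (default
15, a standard dataset filter) and pairs whose distance vectors have no
variance (e.g. a family of identical orthologs, for which r is
undefined) are flagged rather than scored, and excluded downstream.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .distances import (
    OrthologAlignment,
    UndefinedDistanceError,
    distance_matrix,
    mean_identity,
)

__all__ = [
    "DEFAULT_MIN_COMMON",
    "DegenerateVarianceError",
    "PairScore",
    "common_species",
    "pearson",
    "score_pair",
    "score_all",
    "SCORE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Minimum number of common species for a pair to be scored.
DEFAULT_MIN_COMMON = 15


class DegenerateVarianceError(ValueError):
    """Pearson correlation is undefined: a vector has zero variance."""


def common_species(align_a: OrthologAlignment, align_b: OrthologAlignment) -> list[str]:
    """Sorted intersection of the two families' species labels."""
    return sorted(set(align_a.rows) & set(align_b.rows))


def pearson(x, y) -> float:
    """Pearson's correlation coefficient of two paired vectors.

    r = sum((x - xbar)(y - ybar)) / sqrt(sum((x - xbar)^2) sum((y - ybar)^2))

    Raises :class:`DegenerateVarianceError` when either vector has zero
    variance (r undefined) and ValueError for length mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateVarianceError("zero variance in a distance vector")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class PairScore:
    """Mirrortree score for one protein pair, with provenance."""

    protein_a: str
    protein_b: str
    status: str  # scored | too-few-species | degenerate-variance | missing-alignment
    r: float | None = None
    n_common: int = 0
    model: str | None = None
    conservation: float | None = None


def score_pair(
    align_a: OrthologAlignment,
    align_b: OrthologAlignment,
    model: str = "jtt",
    min_common: int = DEFAULT_MIN_COMMON,
) -> PairScore:
    """Score one protein pair for co-evolution.

    Both alignments are restricted to their common species (one shared
    lexicographic order, so the two condensed vectors are aligned entry
    by entry).  Distance entries that are saturated or undefined for
    either family are dropped from both vectors symmetrically; if fewer
    than 3 usable entries remain, or a vector has no variance, the pair
    is flagged ``degenerate-variance``.

    The pair's ``conservation`` is the mean of the two families'
    mean-pairwise-identity values over the common species.
    """
    if min_common < 3:
        raise ValueError("min_common must be at least 3")
    shared = common_species(align_a, align_b)
    base = PairScore(
        protein_a=align_a.protein_id,
        protein_b=align_b.protein_id,
        status="too-few-species",
        n_common=len(shared),
        model=model,
    )
    if len(shared) < min_common:
        return base
    sub_a = align_a.restrict(shared)
    sub_b = align_b.restrict(shared)
    try:
        base.conservation = 0.5 * (mean_identity(sub_a) + mean_identity(sub_b))
    except UndefinedDistanceError:
        base.conservation = None
    da = distance_matrix(sub_a, model, on_error="nan").values
    db = distance_matrix(sub_b, model, on_error="nan").values
    usable = ~np.isnan(da) & ~np.isnan(db)
    if usable.sum() < 3:
        base.status = "degenerate-variance"
        return base
    try:
        base.r = pearson(da[usable], db[usable])
    except DegenerateVarianceError:
        base.status = "degenerate-variance"
        return base
    base.status = "scored"
    return base


SCORE_COLUMNS = [
    "protein_a",
    "protein_b",
    "label",
    "r",
    "n_common",
    "conservation",
    "model",
    "status",
]


def score_all(
    pair_table: pd.DataFrame,
    alignment_store: Mapping[str, OrthologAlignment],
    model: str = "jtt",
    min_common: int = DEFAULT_MIN_COMMON,
) -> pd.DataFrame:
    """Score every pair in a pair table.

    ``pair_table`` needs columns ``protein_a`` and ``protein_b``; a
    ``label`` column is carried through (default ``unknown``).  Pairs
    whose alignments are missing from the store get status
    ``missing-alignment`` and the run continues.  Returns a DataFrame
    with :data:`SCORE_COLUMNS`.
    """
    records = []
    for row in pair_table.itertuples(index=False):
        label = getattr(row, "label", "unknown")
        aln_a = alignment_store.get(row.protein_a)
        aln_b = alignment_store.get(row.protein_b)
        if aln_a is None or aln_b is None:
            missing = row.protein_a if aln_a is None else row.protein_b
            logger.warning("no alignment for protein %r; pair skipped", missing)
            ps = PairScore(
                protein_a=row.protein_a,
                protein_b=row.protein_b,
                status="missing-alignment",
                model=model,
            )
        else:
            ps = score_pair(aln_a, aln_b, model=model, min_common=min_common)
        records.append(
            {
                "protein_a": ps.protein_a,
                "protein_b": ps.protein_b,
                "label": label,
                "r": np.nan if ps.r is None else ps.r,
                "n_common": ps.n_common,
                "conservation": np.nan if ps.conservation is None else ps.conservation,
                "model": model,
                "status": ps.status,
            }
        )
    table = pd.DataFrame(records, columns=SCORE_COLUMNS)
    counts = Counter(table["status"]) if len(table) else {}
    logger.info(
        "scored %d pairs: %s",
        len(table),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())) or "empty table",
    )
    return table
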