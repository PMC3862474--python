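"""Evaluation of mirrortree scores as a binary interaction classifier.

Covers the assessment machinery around the score itself: construction
of shuffled non-interacting control pairs, score densities per class,
ROC curves and AUC, the Matthews correlation coefficient (MCC) swept
over score thresholds with peak selection, sensitivity/specificity,
binning of scores by sequence conservation, and stratification of pairs
by evolutionary span (clade coverage or time since last common
ancestor).

Classification direction: a pair is predicted interacting when its
score r is at or above the threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn import metrics as _skmetrics

__all__ = [
    "CapacityError",
    "ROCResult",
    "MCCCurve",
    "SpanStratification",
    "filter_scored",
    "make_negatives",
    "roc",
    "mcc",
    "mcc_curve",
    "bin_by_conservation",
    "assign_clade_category",
    "stratify_by_span",
    "span_vs_score",
    "density_summary",
]

logger = logging.getLogger(__name__)

POSITIVE = "interacting"
NEGATIVE = "noninteracting"


class CapacityError(RuntimeError):
    """The input cannot supply the requested number of negative pairs."""


def _check_labels(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    labels = set(table["label"])
    if not labels <= {POSITIVE, NEGATIVE}:
        raise ValueError(f"unexpected labels: {sorted(labels - {POSITIVE, NEGATIVE})}")
    if labels != {POSITIVE, NEGATIVE}:
        raise ValueError("both interacting and noninteracting pairs are required")
    y = (table["label"] == POSITIVE).to_numpy()
    scores = table["r"].to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise ValueError("score table contains unscored (NaN) rows; filter first")
    return y, scores


def filter_scored(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only successfully scored rows (status == 'scored')."""
    if "status" in table.columns:
        kept = table[table["status"] == "scored"].copy()
    else:
        kept = table[~table["r"].isna()].copy()
    dropped = len(table) - len(kept)
    if dropped:
        logger.info("excluding %d unscored pairs from evaluation", dropped)
    return kept


# ---------------------------------------------------------------------------
# Negative-set construction


def make_negatives(
    interacting_pairs: Iterable[tuple[str, str]] | pd.DataFrame,
    n_out: int,
    seed,
    retry_factor: int = 100,
) -> pd.DataFrame:
    """Shuffled non-interacting control pairs.

    Protein ids are drawn with replacement from those appearing in the
    interacting set and paired at random; self-pairs, pairs present in
    the interacting set (either orientation) and duplicates are
    discarded.  Draws stop after ``retry_factor * n_out`` attempts, at
    which point a :class:`CapacityError` reports that the input is too
    small to supply ``n_out`` distinct negatives.
    """
    if n_out < 1:
        raise ValueError("n_out must be at least 1")
    if isinstance(interacting_pairs, pd.DataFrame):
        pairs = list(
            zip(interacting_pairs["protein_a"], interacting_pairs["protein_b"])
        )
    else:
        pairs = list(interacting_pairs)
    proteins = sorted({p for ab in pairs for p in ab})
    if len(proteins) < 2:
        raise ValueError("need at least 2 distinct proteins")
    forbidden = {frozenset(ab) for ab in pairs}
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    budget = retry_factor * n_out
    while len(out) < n_out and budget > 0:
        budget -= 1
        a, b = rng.choice(len(proteins), size=2)
        if a == b:
            continue
        key = frozenset((proteins[a], proteins[b]))
        if key in forbidden or key in seen:
            continue
        seen.add(key)
        out.append((proteins[a], proteins[b]))
    if len(out) < n_out:
        raise CapacityError(
            f"could only form {len(out)} of {n_out} distinct non-interacting "
            f"pairs from {len(proteins)} proteins"
        )
    return pd.DataFrame(out, columns=["protein_a", "protein_b"]).assign(label=NEGATIVE)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    """An ROC curve and its area.

    ``thresholds`` are descending score cutoffs; the curve runs from
    (0, 0) to (1, 1) with ties grouped into single threshold steps, so
    the trapezoidal area equals the Mann-Whitney concordance estimate
    with ties counted one half.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc(table: pd.DataFrame) -> ROCResult:
    """ROC curve of the scores, predicting interacting when r >= cutoff."""
    y, scores = _check_labels(table)
    fpr, tpr, thr = _skmetrics.roc_curve(y, scores, drop_intermediate=False)
    return ROCResult(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_skmetrics.auc(fpr, tpr))
    )


# ---------------------------------------------------------------------------
# MCC


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); defined as 0
    when any denominator factor vanishes.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp + fp + tn + fn == 0:
        raise ValueError("confusion matrix is empty")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


@dataclass
class MCCCurve:
    """MCC, sensitivity and specificity swept over score thresholds."""

    thresholds: np.ndarray
    mcc: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    peak_threshold: float
    peak_mcc: float


def mcc_curve(table: pd.DataFrame, thresholds: Sequence[float] | None = None) -> MCCCurve:
    """Sweep classification thresholds and record MCC and the rates.

    At each threshold t a pair is predicted interacting when r >= t.
    ``peak_threshold`` is the threshold maximizing the MCC, ties broken
    toward the smallest threshold (favoring sensitivity).
    """
    y, scores = _check_labels(table)
    if thresholds is None:
        thresholds = np.unique(scores)
    thresholds = np.asarray(thresholds, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    mccs = np.empty(thresholds.size)
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        mccs[i] = mcc(tp, fp, tn, fn)
        sens[i] = tp / n_pos
        spec[i] = tn / n_neg
    peak = int(np.argmax(mccs))  # first occurrence = smallest threshold
    return MCCCurve(
        thresholds=thresholds,
        mcc=mccs,
        sensitivity=sens,
        specificity=spec,
        peak_threshold=float(thresholds[peak]),
        peak_mcc=float(mccs[peak]),
    )


# ---------------------------------------------------------------------------
# Conservation binning


def bin_by_conservation(table: pd.DataFrame, width: float = 0.02) -> pd.DataFrame:
    """Summarize scores in half-open conservation bins [k*w, (k+1)*w).

    Returns one row per (bin, label) with the pair count, mean score and
    standard deviation of scores (absent for single-pair bins).  Empty
    bins are omitted.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    work = table.dropna(subset=["conservation", "r"]).copy()
    work["_bin"] = np.floor(work["conservation"].to_numpy() / width).astype(int)
    rows = []
    for (k, label), grp in work.groupby(["_bin", "label"], sort=True):
        rows.append(
            {
                "bin_low": k * width,
                "bin_high": (k + 1) * width,
                "label": label,
                "n": len(grp),
                "mean_r": grp["r"].mean(),
                "sd_r": grp["r"].std(ddof=1) if len(grp) > 1 else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["bin_low", "bin_high", "label", "n", "mean_r", "sd_r"]
    )


# ---------------------------------------------------------------------------
# Evolutionary-span stratification


def assign_clade_category(
    species: Iterable[str], clade_paths: Mapping[str, Sequence[str]]
) -> str:
    """Innermost clade containing every species of a pair.

    ``clade_paths`` maps each species to its nested clade memberships,
    innermost first (e.g. chordates, metazoa, eukaryota).  Raises
    KeyError for unknown species and ValueError when no common clade
    exists.
    """
    species = list(species)
    if not species:
        raise ValueError("empty species set")
    paths = []
    for sp in species:
        if sp not in clade_paths:
            raise KeyError(sp)
        paths.append(list(clade_paths[sp]))
    for clade in paths[0]:
        if all(clade in p for p in paths[1:]):
            return clade
    raise ValueError(f"species {species} share no clade")


@dataclass
class SpanStratification:
    """Pairs partitioned by the clade span of their common species."""

    categories: list[str]
    tables: dict[str, pd.DataFrame]
    roc: dict[str, ROCResult | None]
    excluded: list[tuple[str, str]] = field(default_factory=list)


def stratify_by_span(
    table: pd.DataFrame,
    species_sets: Mapping[tuple[str, str], Iterable[str]],
    clade_paths: Mapping[str, Sequence[str]],
    category_order: Sequence[str] | None = None,
) -> SpanStratification:
    """Partition score rows by the clade coverage of each pair.

    Each pair goes to the innermost clade that contains all of its
    common species.  Pairs with species missing from ``clade_paths``
    are excluded with a log entry.  A per-category ROC is computed when
    the category holds both labels, else recorded as None.
    """
    assignments: dict[str, list[int]] = {}
    excluded: list[tuple[str, str]] = []
    for idx, row in table.iterrows():
        key = (row["protein_a"], row["protein_b"])
        try:
            cat = assign_clade_category(species_sets[key], clade_paths)
        except (KeyError, ValueError) as exc:
            logger.warning("pair %s excluded from stratification: %s", key, exc)
            excluded.append(key)
            continue
        assignments.setdefault(cat, []).append(idx)
    if category_order is None:
        category_order = sorted(assignments)
    tables = {
        cat: table.loc[assignments[cat]].copy()
        for cat in category_order
        if cat in assignments
    }
    rocs: dict[str, ROCResult | None] = {}
    for cat, sub in tables.items():
        try:
            rocs[cat] = roc(sub)
        except ValueError:
            logger.info("category %r has a single label; ROC skipped", cat)
            rocs[cat] = None
    return SpanStratification(
        categories=list(tables), tables=tables, roc=rocs, excluded=excluded
    )


def span_vs_score(
    table: pd.DataFrame,
    species_sets: Mapping[tuple[str, str], Iterable[str]],
    lca_times: Mapping[frozenset, float],
    ) -> pd.DataFrame:
    """Score summaries grouped by evolutionary span.

    A pair's span is the largest time since last common ancestor (Myr)
    over all pairs of its common species.  Returns per (span, label)
    the pair count, mean score and standard deviation.  Pairs with a
    missing divergence time are excluded with a log entry.
    """
    spans = []
    for row in table.itertuples(index=False):
        key = (row.protein_a, row.protein_b)
        species = sorted(species_sets[key])
        try:
            span = max(
                lca_times[frozenset(p)] for p in itertools.combinations(species, 2)
            )
        except KeyError as exc:
            logger.warning("pair %s excluded: no divergence time for %s", key, exc)
            continue
        spans.append({"span_myr": span, "label": row.label, "r": row.r})
    if not spans:
        return pd.DataFrame(columns=["span_myr", "label", "n", "mean_r", "sd_r"])
    work = pd.DataFrame(spans)
    rows = []
    for (span, label), grp in work.groupby(["span_myr", "label"], sort=True):
        rows.append(
            {
                "span_myr": span,
                "label": label,
                "n": len(grp),
                "mean_r": grp["r"].mean(),
                "sd_r": grp["r"].std(ddof=1) if len(grp) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["span_myr", "label", "n", "mean_r", "sd_r"])


# ---------------------------------------------------------------------------
# Densities


def density_summary(
    table: pd.DataFrame,
    bandwidth: float | str | None = "silverman",
    grid_size: int = 512,
) -> dict[str, dict]:
    """Gaussian kernel density of scores per label on [-1, 1].

    Returns, per label, the evaluation grid, the density values and the
    mode (grid point of highest density).  Bandwidth defaults to
    Silverman's rule.  Raises ValueError when a class has fewer than
    two scores (or zero spread, for which a KDE is undefined).
    """
    out: dict[str, dict] = {}
    grid = np.linspace(-1.0, 1.0, grid_size)
    for label, grp in table.groupby("label"):
        scores = grp["r"].dropna().to_numpy(dtype=float)
        if scores.size < 2:
            raise ValueError(f"need at least 2 scores for label {label!r}")
        if np.ptp(scores) == 0.0:
            raise ValueError(f"scores for label {label!r} are all identical")
        kde = gaussian_kde(scores, bw_method=bandwidth)
        dens = kde(grid)
        out[label] = {
            "grid": grid,
            "density": dens,
            "mode": float(grid[int(np.argmax(dens))]),
        }
    return out
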