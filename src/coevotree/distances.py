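"""Evolutionary distances between aligned amino-acid sequences.

Four pairwise distance measures are provided:

* ``p`` — observed fraction of differing residues (p-distance);
* ``kimura`` — Kimura's closed-form correction of the p-distance,
  ``d = -ln(1 - D - 0.2 D**2)``;
* ``categories`` — mean per-column physico-chemical group-substitution
  cost (0 within a group, 0.457 between groups);
* ``jtt`` / ``pam001`` — pairwise maximum-likelihood distances under the
  Jones-Taylor-Thornton or Dayhoff PAM empirical replacement model.

All measures use pairwise gap deletion: an alignment column contributes
to a pair's distance only if neither sequence has a gap or ambiguity
code there.  Ambiguous residues (B, Z, X) are treated as missing data.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "AMINO_ACIDS",
    "SaturationError",
    "UndefinedDistanceError",
    "InvalidResidueError",
    "SubstitutionModel",
    "load_model",
    "OrthologAlignment",
    "CondensedDistances",
    "p_distance",
    "kimura_distance",
    "categories_distance",
    "ml_distance",
    "distance_matrix",
    "mean_identity",
    "DISTANCE_MODELS",
]

#: Canonical amino acids in PHYLIP (protdist) order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Characters treated as missing data: the gap character plus the
#: standard ambiguity codes.
_MISSING = set("-.?BZX")

# Physico-chemical categories: sulfhydryl; small/neutral; acidic (with
# amides); basic; hydrophobic; aromatic.
_CATEGORY_GROUPS = ("C", "STAPG", "DENQ", "HRK", "VLIM", "FYW")
_GROUP_OF = {aa: g for g, members in enumerate(_CATEGORY_GROUPS) for aa in members}

#: Cost of substituting a residue of one group for one of another.
BETWEEN_GROUP_COST = 0.457

#: Kimura's correction diverges at D = (-1 + sqrt(1.8)) / 0.4.
KIMURA_SATURATION = (-1.0 + np.sqrt(1.8)) / 0.4

#: Upper bound for the ML distance search, in substitutions per site.
ML_T_MAX = 10.0


class SaturationError(ValueError):
    """Distance is beyond the measure's usable range."""


class UndefinedDistanceError(ValueError):
    """No alignment column is comparable for this sequence pair."""


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the amino-acid alphabet."""


def encode_sequence(seq: str) -> np.ndarray:
    """Map an aligned sequence to integer codes; missing data become -1.

    Raises :class:`InvalidResidueError` for characters that are neither
    canonical amino acids, gaps, nor ambiguity codes.
    """
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        if ch in _AA_INDEX:
            out[i] = _AA_INDEX[ch]
        elif ch in _MISSING:
            out[i] = -1
        else:
            raise InvalidResidueError(
                f"invalid residue {ch!r} at position {i + 1}"
            )
    return out


# ---------------------------------------------------------------------------
# Substitution models


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible empirical amino-acid replacement model.

    The rate matrix is built from published exchangeabilities ``s(i,j)``
    and stationary frequencies ``pi`` as ``Q_ij = s_ij * pi_j`` and
    scaled so the expected rate at stationarity is one substitution per
    site per unit time.  The transition matrix ``P(t) = expm(Q t)`` is
    evaluated from a cached eigendecomposition of the symmetrized rate
    matrix (reversibility guarantees a real spectrum).
    """

    name: str
    rate_matrix: np.ndarray
    frequencies: np.ndarray
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, default=None)

    @classmethod
    def from_exchangeabilities(
        cls, name: str, exchangeabilities: np.ndarray, frequencies: np.ndarray
    ) -> "SubstitutionModel":
        s = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        pi = pi / pi.sum()
        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(pi, np.diag(q))
        q /= mu
        # Symmetrize: B = D^1/2 Q D^-1/2 with D = diag(pi).
        sqrt_pi = np.sqrt(pi)
        b = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        w, u = np.linalg.eigh((b + b.T) / 2.0)
        left = u / sqrt_pi[:, None]
        right = u.T * sqrt_pi[None, :]
        return cls(name=name, rate_matrix=q, frequencies=pi, _eig=(w, left, right))

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) with rows indexed by ancestral, columns by derived state."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        w, left, right = self._eig
        p = (left * np.exp(w * t)[np.newaxis, :]) @ right
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)


def _read_model_file(filename: str) -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("coevotree.data").joinpath(filename).read_text()
    rows = [
        [float(x) for x in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    tri, freqs = rows[:19], np.array(rows[19])
    s = np.zeros((20, 20))
    for i, row in enumerate(tri, start=1):
        s[i, : len(row)] = row
    s = s + s.T
    return s, freqs


@functools.lru_cache(maxsize=None)
def load_model(name: str) -> SubstitutionModel:
    """Load a named replacement model (``jtt`` or ``pam001``)."""
    key = name.lower()
    if key not in ("jtt", "pam001"):
        raise ValueError(f"unknown substitution model {name!r}")
    s, freqs = _read_model_file(f"{key}.txt")
    return SubstitutionModel.from_exchangeabilities(key, s, freqs)


# ---------------------------------------------------------------------------
# Alignment containers


@dataclass
class OrthologAlignment:
    """Aligned sequences of one protein's orthologs, keyed by species."""

    protein_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no sequences")
        self.rows = {sp: seq.upper() for sp, seq in self.rows.items()}
        lengths = {len(seq) for seq in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"alignment {self.protein_id!r} has ragged sequence lengths {sorted(lengths)}"
            )
        if 0 in lengths:
            raise ValueError(f"alignment {self.protein_id!r} has zero-length sequences")

    @property
    def species(self) -> list[str]:
        """Species labels in sorted order."""
        return sorted(self.rows)

    @property
    def n_species(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def restrict(self, species: Sequence[str]) -> "OrthologAlignment":
        """Sub-alignment over the given species."""
        missing = [sp for sp in species if sp not in self.rows]
        if missing:
            raise KeyError(f"species absent from {self.protein_id!r}: {missing}")
        return OrthologAlignment(
            protein_id=self.protein_id, rows={sp: self.rows[sp] for sp in species}
        )

    def encoded(self) -> np.ndarray:
        """(n_species, length) integer matrix in sorted species order."""
        return np.stack([encode_sequence(self.rows[sp]) for sp in self.species])


@dataclass
class CondensedDistances:
    """The n(n-1)/2 pairwise distances of one ortholog set.

    ``values[k]`` is the distance between ``species[i]`` and
    ``species[j]`` for the k-th pair in lexicographic (i, j) order,
    i < j.  Entries may be NaN when computed with ``on_error="nan"``.
    """

    species: list[str]
    values: np.ndarray
    model: str

    def __post_init__(self) -> None:
        n = len(self.species)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n * (n - 1) // 2,):
            raise ValueError("condensed vector length must be n(n-1)/2")

    def pair_labels(self) -> list[tuple[str, str]]:
        n = len(self.species)
        return [
            (self.species[i], self.species[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]

    def as_square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.values)


# ---------------------------------------------------------------------------
# Pairwise measures


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return encode_sequence(seq)


def p_distance(seq_a, seq_b) -> float:
    """Fraction of differing residues over comparable columns.

    Columns where either sequence has a gap or ambiguity code are
    excluded for this pair only (pairwise deletion).
    """
    a, b = _as_codes(seq_a), _as_codes(seq_b)
    if a.shape != b.shape:
        raise ValueError("aligned sequences must have equal length")
    comparable = (a >= 0) & (b >= 0)
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable columns")
    return float(((a != b) & comparable).sum()) / n


def kimura_distance(d_obs: float) -> float:
    """Kimura's protein distance ``-ln(1 - D - 0.2 D**2)``.

    Diverges as the observed difference D approaches ~0.8541; beyond
    that a :class:`SaturationError` is raised.
    """
    if d_obs < 0:
        raise ValueError("observed difference must be nonnegative")
    arg = 1.0 - d_obs - 0.2 * d_obs * d_obs
    if arg <= 0.0:
        raise SaturationError(
            f"observed difference D={d_obs:.4f} is at or beyond the "
            f"saturation point D={KIMURA_SATURATION:.4f}"
        )
    return -float(np.log(arg))


def categories_distance(seq_a, seq_b) -> float:
    """Mean per-column group-substitution cost.

    Residues are lumped into six physico-chemical groups (sulfhydryl;
    small/neutral; acidic; basic; hydrophobic; aromatic); a column costs
    0 if both residues fall in the same group and 0.457 otherwise.
    """
    a, b = _as_codes(seq_a), _as_codes(seq_b)
    if a.shape != b.shape:
        raise ValueError("aligned sequences must have equal length")
    comparable = (a >= 0) & (b >= 0)
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable columns")
    ga = _GROUP_CODES[a[comparable]]
    gb = _GROUP_CODES[b[comparable]]
    return BETWEEN_GROUP_COST * float((ga != gb).sum()) / n


_GROUP_CODES = np.array([_GROUP_OF[a] for a in AMINO_ACIDS], dtype=np.int8)


# ---------------------------------------------------------------------------
# Maximum-likelihood distances


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """20x20 matrix of residue-pair counts over comparable columns.

    The count matrix is symmetrized: under a reversible model the
    likelihood is unchanged (pi_a P_ab(t) = pi_b P_ba(t)), and the
    resulting distance becomes exactly symmetric in its arguments.
    """
    comparable = (a >= 0) & (b >= 0)
    flat = a[comparable].astype(np.int64) * 20 + b[comparable]
    n = np.bincount(flat, minlength=400).reshape(20, 20).astype(float)
    return (n + n.T) / 2.0


def _log_likelihood(counts: np.ndarray, model: SubstitutionModel, t: float) -> float:
    p = model.transition_matrix(t)
    joint = model.frequencies[:, None] * p
    mask = counts > 0
    with np.errstate(divide="ignore"):
        ll = counts[mask] * np.log(joint[mask])
    return float(ll.sum())


def _ml_from_counts(
    counts: np.ndarray, model: SubstitutionModel, t_max: float = ML_T_MAX
) -> float:
    n = counts.sum()
    if n == 0:
        raise UndefinedDistanceError("no comparable columns")
    if np.trace(counts) == n:
        return 0.0
    res = minimize_scalar(
        lambda t: -_log_likelihood(counts, model, t),
        bounds=(1e-9, t_max),
        method="bounded",
        options={"xatol": 1e-8},
    )
    t_hat = float(res.x)
    if t_hat > t_max * (1.0 - 1e-3):
        raise SaturationError(
            f"ML distance estimate reached the search bound t_max={t_max}"
        )
    return t_hat


def ml_distance(seq_a, seq_b, model: SubstitutionModel | str) -> float:
    """Pairwise maximum-likelihood distance under an empirical model.

    Maximizes ``sum_columns log(pi(a) * P(t)[a, b])`` over the branch
    length t by bounded scalar search on ``[0, 10]`` substitutions per
    site.  Identical sequences return exactly 0.  Reversibility of the
    model makes the estimate symmetric in its arguments.
    """
    if isinstance(model, str):
        model = load_model(model)
    a, b = _as_codes(seq_a), _as_codes(seq_b)
    if a.shape != b.shape:
        raise ValueError("aligned sequences must have equal length")
    return _ml_from_counts(_pair_counts(a, b), model)


def _ml_batch(
    counts_stack: np.ndarray, model: SubstitutionModel, t_max: float = ML_T_MAX
) -> np.ndarray:
    """ML distances for a stack of count matrices (K, 20, 20).

    A shared coarse grid of branch lengths locates each pair's
    likelihood peak; a bounded scalar search then refines each estimate
    within its bracketing grid interval.  Saturated pairs (peak at the
    bound) come back as NaN.
    """
    k = counts_stack.shape[0]
    out = np.zeros(k)
    totals = counts_stack.sum(axis=(1, 2))
    diag = np.trace(counts_stack, axis1=1, axis2=2)
    undefined = totals == 0
    identical = ~undefined & (diag == totals)
    todo = np.flatnonzero(~undefined & ~identical)
    out[undefined] = np.nan
    if todo.size == 0:
        return out

    grid = np.concatenate([[1e-9], np.geomspace(1e-4, t_max, 80)])
    lls = np.empty((todo.size, grid.size))
    log_pi = np.log(model.frequencies)
    for g, t in enumerate(grid):
        p = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            log_joint = log_pi[:, None] + np.log(p)
        log_joint[np.isneginf(log_joint)] = -1e30
        lls[:, g] = np.einsum("kij,ij->k", counts_stack[todo], log_joint)
    best = np.argmax(lls, axis=1)

    for idx, gi in zip(todo, best):
        if gi == grid.size - 1:
            out[idx] = np.nan  # saturated: peak at the search bound
            continue
        lo = grid[max(gi - 1, 0)]
        hi = grid[gi + 1]
        res = minimize_scalar(
            lambda t: -_log_likelihood(counts_stack[idx], model, t),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        out[idx] = float(res.x)
    return out


# ---------------------------------------------------------------------------
# Whole-alignment operations

DISTANCE_MODELS = ("p", "kimura", "categories", "jtt", "pam001")


def distance_matrix(
    alignment: OrthologAlignment, model_name: str, on_error: str = "raise"
) -> CondensedDistances:
    """All n(n-1)/2 pairwise distances of an ortholog set.

    Parameters
    ----------
    alignment:
        Ortholog alignment with at least two species.
    model_name:
        One of ``p``, ``kimura``, ``categories``, ``jtt``, ``pam001``.
    on_error:
        ``"raise"`` (default) propagates saturation/undefined-distance
        errors tagged with the offending species pair; ``"nan"`` records
        NaN for that pair instead, letting callers drop entries.
    """
    if model_name not in DISTANCE_MODELS:
        raise ValueError(f"unknown distance model {model_name!r}")
    if on_error not in ("raise", "nan"):
        raise ValueError("on_error must be 'raise' or 'nan'")
    species = alignment.species
    n = len(species)
    if n < 2:
        raise ValueError("distance matrix requires at least 2 species")
    enc = alignment.encoded()
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    if model_name in ("jtt", "pam001"):
        model = load_model(model_name)
        counts = np.stack([_pair_counts(enc[i], enc[j]) for i, j in pairs])
        values = _ml_batch(counts, model)
        if on_error == "raise" and np.isnan(values).any():
            i, j = pairs[int(np.flatnonzero(np.isnan(values))[0])]
            raise SaturationError(
                f"ML distance undefined or saturated for species pair "
                f"({species[i]!r}, {species[j]!r})"
            )
        return CondensedDistances(species=species, values=values, model=model_name)

    measure = {
        "p": p_distance,
        "kimura": lambda a, b: kimura_distance(p_distance(a, b)),
        "categories": categories_distance,
    }[model_name]
    values = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        try:
            values[k] = measure(enc[i], enc[j])
        except (SaturationError, UndefinedDistanceError) as exc:
            if on_error == "raise":
                raise type(exc)(
                    f"{exc} [species pair ({species[i]!r}, {species[j]!r})]"
                ) from exc
            values[k] = np.nan
    return CondensedDistances(species=species, values=values, model=model_name)


def mean_identity(alignment: OrthologAlignment) -> float:
    """Degree of conservation: mean pairwise fraction identity.

    The mean over all n(n-1)/2 sequence pairs of ``1 - p_distance``.
    """
    cd = distance_matrix(alignment, "p", on_error="nan")
    vals = cd.values[~np.isnan(cd.values)]
    if vals.size == 0:
        raise UndefinedDistanceError(
            f"no comparable sequence pair in alignment {alignment.protein_id!r}"
        )
    return float(np.mean(1.0 - vals))
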