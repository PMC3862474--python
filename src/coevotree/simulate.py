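"""Synthetic co-evolution benchmarks.

Generates labeled pairs of ortholog families with a known degree of
evolutionary coupling.  All families share one ultrametric species tree
(a Yule tree rescaled to a chosen depth).  Each protein of a pair
evolves independently from its own random root sequence, but the two
proteins' per-branch evolutionary rates are drawn from a bivariate
lognormal whose log-scale correlation — the *coupling* — is the dial
between interacting (correlated lineage-specific rates) and
non-interacting (independent rates) pairs.  Coupling 1 means the two
proteins speed up and slow down in perfect lockstep on every branch;
coupling 0 means their rate variation is unrelated.

The multiplier distribution has log-mean ``-rate_sd**2 / 2`` so the
expected multiplier is 1 and effective branch lengths are unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import AMINO_ACIDS, OrthologAlignment, SubstitutionModel, load_model

__all__ = [
    "Phylogeny",
    "SimulationConfig",
    "SimulatedBenchmark",
    "sample_tree",
    "sample_rate_multipliers",
    "discrete_gamma_rates",
    "evolve_pair",
    "generate_benchmark",
    "write_fixture",
]


@dataclass
class Phylogeny:
    """A rooted binary ultrametric tree over labeled species.

    Nodes are integers: leaves ``0..n-1`` (sorted by label), internal
    nodes ``n..2n-2`` with the root last.  ``branch_lengths[v]`` is the
    length of the branch above node ``v`` in expected substitutions per
    site; the root carries no branch (length 0).
    """

    parent: np.ndarray
    branch_lengths: np.ndarray
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def path_lengths(self) -> np.ndarray:
        """Root-to-tip path length for each leaf."""
        depths = np.zeros(self.n_nodes)
        for v in self._preorder()[1:]:
            depths[v] = depths[self.parent[v]] + self.branch_lengths[v]
        return depths[: self.n_leaves]

    @property
    def depth(self) -> float:
        return float(self.path_lengths().max())

    def _preorder(self) -> list[int]:
        children: dict[int, list[int]] = {}
        for v, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(v)
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(children.get(v, [])))
        return order

    def to_newick(self) -> str:
        children: dict[int, list[int]] = {}
        for v, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(v)

        def fmt(v: int) -> str:
            if v < self.n_leaves:
                return f"{self.leaf_labels[v]}:{self.branch_lengths[v]:.10g}"
            inner = ",".join(fmt(c) for c in children[v])
            if v == self.root:
                return f"({inner})"
            return f"({inner}):{self.branch_lengths[v]:.10g}"

        return fmt(self.root) + ";"


def sample_tree(n_species: int, depth: float, seed) -> Phylogeny:
    """Sample an ultrametric Yule (pure-birth) tree.

    Speciations occur forward in time at rate 1 per lineage; after the
    n-th lineage appears the present is set one more exponential waiting
    time later, and all branch lengths are rescaled so that every
    root-to-tip path equals ``depth``.
    """
    if n_species < 3:
        raise ValueError("n_species must be at least 3")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)

    n_nodes = 2 * n_species - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    birth = np.zeros(n_nodes)

    # Grow the tree with temporary ids, then canonicalize: leaves
    # 0..n-1 in label order, internal nodes next, root last.
    tmp_parent: dict[int, int] = {0: -1}
    tmp_birth: dict[int, float] = {0: 0.0}
    active: list[int] = []
    next_tmp = 1
    t = 0.0
    # Root splits immediately into two lineages at time 0.
    for _ in range(2):
        tmp_parent[next_tmp] = 0
        tmp_birth[next_tmp] = 0.0
        active.append(next_tmp)
        next_tmp += 1
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        split = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            tmp_parent[next_tmp] = split
            tmp_birth[next_tmp] = t
            active.append(next_tmp)
            next_tmp += 1
    present = t + rng.exponential(1.0 / n_species)

    width = len(str(n_species))
    labels = [f"sp{i + 1:0{width}d}" for i in range(n_species)]
    leaf_tmp = sorted(active)
    internal_tmp = sorted(set(tmp_parent) - set(leaf_tmp) - {0})
    remap = {tv: i for i, tv in enumerate(leaf_tmp)}
    remap.update({tv: n_species + k for k, tv in enumerate(internal_tmp)})
    remap[0] = n_nodes - 1  # the first split is the root

    for tv, tp in tmp_parent.items():
        v = remap[tv]
        parent[v] = remap[tp] if tp >= 0 else -1
        birth[v] = tmp_birth[tv]

    end_time = np.full(n_nodes, present)
    for tv, tp in tmp_parent.items():
        if tv not in leaf_tmp:
            # An internal node's branch ends when it splits, i.e. at the
            # birth time of its children.
            kids = [cv for cv, cp in tmp_parent.items() if cp == tv]
            if kids:
                end_time[remap[tv]] = tmp_birth[kids[0]]
    lengths = np.maximum(end_time - birth, 0.0)
    lengths[parent < 0] = 0.0
    lengths *= depth / present

    return Phylogeny(parent=parent, branch_lengths=lengths, leaf_labels=labels)


def sample_rate_multipliers(
    rng: np.random.Generator, n: int, coupling: float, rate_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch lognormal rate multipliers for the two proteins.

    Log multipliers are built from a shared and an idiosyncratic
    standard-normal component, ``z = sqrt(rho) z0 + sqrt(1-rho) e``,
    giving exact log-scale correlation ``rho``; with ``rho = 1`` the two
    proteins' multipliers coincide branch by branch.  Log-mean
    ``-rate_sd**2/2`` makes E[multiplier] = 1.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    if rate_sd < 0:
        raise ValueError("rate_sd must be nonnegative")
    z0 = rng.standard_normal(n)
    ea = rng.standard_normal(n)
    eb = rng.standard_normal(n)
    a = np.sqrt(coupling)
    b = np.sqrt(1.0 - coupling)
    mu = -0.5 * rate_sd**2
    za = rate_sd * (a * z0 + b * ea) + mu
    zb = rate_sd * (a * z0 + b * eb) + mu
    return np.exp(za), np.exp(zb)


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean-one discrete-gamma site-rate categories (equal weights).

    Category rates are the gamma quantile midpoints, renormalized to
    mean exactly 1.  Larger ``alpha`` means less rate variation across
    sites; ``alpha = inf`` would be a single rate for every site.
    """
    from scipy.stats import gamma as _gamma

    if alpha <= 0:
        raise ValueError("alpha must be positive")
    q = (2 * np.arange(n_categories) + 1) / (2 * n_categories)
    rates = _gamma.ppf(q, a=alpha, scale=1.0 / alpha)
    return rates / rates.mean()


def _evolve_sequences(
    tree: Phylogeny,
    multipliers: np.ndarray,
    seq_length: int,
    model: SubstitutionModel,
    rng: np.random.Generator,
    site_rates: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate one protein down the tree; returns (n_leaves, L) codes.

    ``site_rates`` (length L) scales each column's substitution rate,
    modeling conserved cores versus variable surface positions.
    """
    states = np.empty((tree.n_nodes, seq_length), dtype=np.int64)
    root = tree.root
    states[root] = rng.choice(20, size=seq_length, p=model.frequencies)
    if site_rates is None:
        site_rates = np.ones(seq_length)
    rate_values = np.unique(site_rates)
    for v in tree._preorder()[1:]:
        t_eff = tree.branch_lengths[v] * multipliers[v]
        u = rng.random(seq_length)
        parent_states = states[tree.parent[v]]
        out = states[v]
        for rate in rate_values:
            sites = site_rates == rate
            p = model.transition_matrix(t_eff * rate)
            cum = np.cumsum(p, axis=1)
            cum[:, -1] = 1.0
            out[sites] = (cum[parent_states[sites]] < u[sites, None]).sum(axis=1)
    return states[: tree.n_leaves]


def _codes_to_alignment(
    protein_id: str, tree: Phylogeny, codes: np.ndarray
) -> OrthologAlignment:
    rows = {
        label: "".join(AMINO_ACIDS[c] for c in codes[i])
        for i, label in enumerate(tree.leaf_labels)
    }
    return OrthologAlignment(protein_id=protein_id, rows=rows)


def evolve_pair(
    tree: Phylogeny,
    coupling: float,
    rate_sd: float,
    seq_length: int,
    model: SubstitutionModel | str,
    seed,
    protein_ids: tuple[str, str] = ("protA", "protB"),
    site_rate_alpha: float | None = 1.0,
    n_rate_categories: int = 4,
) -> tuple[OrthologAlignment, OrthologAlignment]:
    """Simulate a protein pair with coupled lineage-specific rates.

    Each protein starts from its own root sequence drawn from the
    model's stationary frequencies and evolves down the shared tree; the
    branch length seen by protein P on branch b is
    ``branch_length(b) * m_P(b)`` with the multipliers drawn by
    :func:`sample_rate_multipliers`.  Sites additionally evolve at
    discrete-gamma rates (shape ``site_rate_alpha``, independently
    assigned per protein; ``None`` disables heterogeneity), so deep
    alignments retain a conserved core instead of decaying uniformly to
    random.  Alignments are gap-free with exactly ``seq_length``
    columns.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be at least 1")
    if isinstance(model, str):
        model = load_model(model)
    rng = np.random.default_rng(seed)
    m_a, m_b = sample_rate_multipliers(rng, tree.n_nodes, coupling, rate_sd)
    if site_rate_alpha is None:
        rates_a = rates_b = None
    else:
        cats = discrete_gamma_rates(site_rate_alpha, n_rate_categories)
        rates_a = cats[rng.integers(len(cats), size=seq_length)]
        rates_b = cats[rng.integers(len(cats), size=seq_length)]
    codes_a = _evolve_sequences(tree, m_a, seq_length, model, rng, rates_a)
    codes_b = _evolve_sequences(tree, m_b, seq_length, model, rng, rates_b)
    return (
        _codes_to_alignment(protein_ids[0], tree, codes_a),
        _codes_to_alignment(protein_ids[1], tree, codes_b),
    )


@dataclass
class SimulationConfig:
    """Conditions for one synthetic benchmark.

    Defaults describe a benchmark spanning deep eukaryote-like
    divergence: 20 species, root-to-tip depth 2 substitutions/site,
    strongly coupled interacting pairs (``coupling = 0.9``), moderate
    lineage-specific rate variation (``rate_sd = 0.25``, i.e. a
    coefficient of variation of about 25% for branch rates), moderate
    among-site rate variation (discrete gamma, shape 1), 300-column
    alignments, and 30 pairs per class.
    """

    n_species: int = 20
    depth: float = 2.0
    coupling: float = 0.9
    rate_sd: float = 0.25
    seq_length: int = 300
    n_interacting: int = 30
    n_noninteracting: int = 30
    substitution_model: str = "jtt"
    site_rate_alpha: float | None = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be at least 3")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.rate_sd < 0:
            raise ValueError("rate_sd must be nonnegative")
        if self.seq_length < 1:
            raise ValueError("seq_length must be at least 1")
        if self.n_interacting < 0 or self.n_noninteracting < 0:
            raise ValueError("pair counts must be nonnegative")


@dataclass
class SimulatedBenchmark:
    """Synthetic ortholog families with known interaction labels."""

    tree: Phylogeny
    alignments: dict[str, OrthologAlignment]
    pair_table: pd.DataFrame  # columns protein_a, protein_b, label
    config: SimulationConfig


def generate_benchmark(config: SimulationConfig) -> SimulatedBenchmark:
    """Generate a labeled benchmark on one shared species tree.

    Interacting pairs get the configured coupling; non-interacting pairs
    get coupling 0.  Each pair's random stream is derived from the
    master seed and the pair's index, so individual pairs are
    reproducible in isolation.
    """
    tree = sample_tree(config.n_species, config.depth, seed=config.seed)
    alignments: dict[str, OrthologAlignment] = {}
    rows = []
    jobs = [("interacting", config.coupling, k) for k in range(config.n_interacting)]
    jobs += [("noninteracting", 0.0, k) for k in range(config.n_noninteracting)]
    for label, coupling, k in jobs:
        tag = "I" if label == "interacting" else "N"
        ids = (f"{tag}{k:03d}a", f"{tag}{k:03d}b")
        pair_seed = np.random.SeedSequence(
            entropy=config.seed, spawn_key=(0 if tag == "I" else 1, k)
        )
        aln_a, aln_b = evolve_pair(
            tree,
            coupling,
            config.rate_sd,
            config.seq_length,
            config.substitution_model,
            seed=pair_seed,
            protein_ids=ids,
            site_rate_alpha=config.site_rate_alpha,
        )
        alignments[ids[0]] = aln_a
        alignments[ids[1]] = aln_b
        rows.append({"protein_a": ids[0], "protein_b": ids[1], "label": label})
    pair_table = pd.DataFrame(rows, columns=["protein_a", "protein_b", "label"])
    return SimulatedBenchmark(
        tree=tree, alignments=alignments, pair_table=pair_table, config=config
    )


def write_fixture(benchmark: SimulatedBenchmark, directory) -> list[str]:
    """Write a benchmark as FASTA files + pair table + config echo.

    Returns the manifest: one aligned multi-FASTA per protein (record id
    = species label, description = protein id), ``pairs.tsv``,
    ``config.txt`` and ``tree.nwk``, as a list of paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for pid, aln in benchmark.alignments.items():
        path = directory / f"{pid}.fasta"
        with open(path, "w") as fh:
            for sp in aln.species:
                fh.write(f">{sp} {pid}\n{aln.rows[sp]}\n")
        manifest.append(str(path))
    pairs_path = directory / "pairs.tsv"
    benchmark.pair_table.to_csv(pairs_path, sep="\t", index=False)
    manifest.append(str(pairs_path))
    config_path = directory / "config.txt"
    with open(config_path, "w") as fh:
        for key, value in asdict(benchmark.config).items():
            fh.write(f"{key}={value}\n")
    manifest.append(str(config_path))
    tree_path = directory / "tree.nwk"
    tree_path.write_text(benchmark.tree.to_newick() + "\n")
    manifest.append(str(tree_path))
    return manifest
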