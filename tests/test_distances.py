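"""Distance measures: closed forms, oracles, and model properties."""

import numpy as np
import pytest

from coevotree.distances import (
    AMINO_ACIDS,
    KIMURA_SATURATION,
    InvalidResidueError,
    OrthologAlignment,
    SaturationError,
    UndefinedDistanceError,
    categories_distance,
    distance_matrix,
    kimura_distance,
    load_model,
    mean_identity,
    ml_distance,
    p_distance,
)

GROUPS = ("C", "STAPG", "DENQ", "HRK", "VLIM", "FYW")
GROUP_OF = {aa: i for i, members in enumerate(GROUPS) for aa in members}


def naive_p_distance(a, b):
    diff = comp = 0
    for x, y in zip(a, b):
        if x in AMINO_ACIDS and y in AMINO_ACIDS:
            comp += 1
            diff += x != y
    return diff / comp


def naive_categories(a, b):
    cost = comp = 0
    for x, y in zip(a, b):
        if x in AMINO_ACIDS and y in AMINO_ACIDS:
            comp += 1
            cost += 0.0 if GROUP_OF[x] == GROUP_OF[y] else 0.457
    return cost / comp


class TestModels:
    @pytest.mark.parametrize("name", ["jtt", "pam001"])
    def test_rate_matrix_properties(self, name):
        model = load_model(name)
        q, pi = model.rate_matrix, model.frequencies
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert abs(pi.sum() - 1.0) < 1e-12
        # expected substitution rate at stationarity is 1 per site
        assert abs(-np.dot(pi, np.diag(q)) - 1.0) < 1e-12
        # detailed balance pi_i q_ij = pi_j q_ji
        assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)

    @pytest.mark.parametrize("name", ["jtt", "pam001"])
    def test_transition_matrix_is_stochastic(self, name):
        model = load_model(name)
        for t in (0.0, 0.1, 1.0, 5.0):
            p = model.transition_matrix(t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
            assert (p >= 0).all()
        assert np.allclose(model.transition_matrix(0.0), np.eye(20), atol=1e-10)


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACDE", "ACDE", 0.0),
            ("ACDE", "ACDF", 0.25),
            ("AC-E", "ACDE", 0.0),  # gap column excluded pairwise
            ("ACXE", "ACDE", 0.0),  # ambiguity treated as missing
        ],
    )
    def test_examples(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_columns(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("--A", "AC-")

    def test_invalid_residue_named(self):
        with pytest.raises(InvalidResidueError, match="position 2"):
            p_distance("AOC", "ACC")

    def test_matches_naive_loop(self, rng):
        alphabet = list(AMINO_ACIDS) + ["-", "X"]
        for _ in range(100):
            a = "".join(rng.choice(alphabet, size=30))
            b = "".join(rng.choice(alphabet, size=30))
            try:
                expected = naive_p_distance(a, b)
            except ZeroDivisionError:
                continue
            assert p_distance(a, b) == pytest.approx(expected, abs=1e-12)


class TestKimura:
    def test_closed_form(self):
        assert kimura_distance(0.0) == 0.0
        assert kimura_distance(0.2) == pytest.approx(0.23319, abs=1e-5)
        for d in np.linspace(0.0, 0.85, 40):
            assert kimura_distance(d) == pytest.approx(
                -np.log(1 - d - 0.2 * d * d), abs=1e-12
            )

    def test_monotone_and_inflating(self):
        grid = np.linspace(0.01, 0.84, 50)
        vals = [kimura_distance(d) for d in grid]
        assert np.all(np.diff(vals) > 0)
        assert all(v > d for v, d in zip(vals, grid))

    @pytest.mark.parametrize("d", [0.9, KIMURA_SATURATION, 1.0])
    def test_saturation(self, d):
        with pytest.raises(SaturationError):
            kimura_distance(d)


class TestCategories:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ST", "TS", 0.0),  # both small/neutral
            ("C", "F", 0.457),  # sulfhydryl vs aromatic
            ("AA", "AF", 0.2285),
        ],
    )
    def test_examples(self, a, b, expected):
        assert categories_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_naive_loop(self, rng):
        for _ in range(100):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=25))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=25))
            assert categories_distance(a, b) == pytest.approx(
                naive_categories(a, b), abs=1e-12
            )


def simulate_pair_at_distance(model, t, length, rng):
    """Two sequences separated by branch length t under the model."""
    anc = rng.choice(20, size=length, p=model.frequencies)
    p = model.transition_matrix(t)
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    der = (cum[anc] < u[:, None]).sum(axis=1)
    a = "".join(AMINO_ACIDS[c] for c in anc)
    b = "".join(AMINO_ACIDS[c] for c in der)
    return a, b


class TestMLDistance:
    def test_identical_is_zero(self):
        assert ml_distance("ACDEFGHIKL", "ACDEFGHIKL", "jtt") == 0.0

    def test_symmetry(self, rng):
        model = load_model("jtt")
        a, b = simulate_pair_at_distance(model, 0.8, 400, rng)
        assert ml_distance(a, b, model) == pytest.approx(
            ml_distance(b, a, model), abs=1e-6
        )

    def test_recovers_branch_length(self, rng):
        model = load_model("jtt")
        a, b = simulate_pair_at_distance(model, 0.5, 20000, rng)
        assert ml_distance(a, b, model) == pytest.approx(0.5, abs=0.03)

    def test_pam_differs_from_jtt(self, rng):
        model = load_model("jtt")
        a, b = simulate_pair_at_distance(model, 0.6, 2000, rng)
        assert ml_distance(a, b, "jtt") != pytest.approx(
            ml_distance(a, b, "pam001"), abs=1e-4
        )


class TestDistanceMatrix:
    def test_vector_lengths(self, rng):
        from tests.conftest import random_alignment

        for n, expected in [(2, 1), (15, 105)]:
            aln = random_alignment(rng, "px", [f"s{i}" for i in range(n)])
            cd = distance_matrix(aln, "p")
            assert cd.values.shape == (expected,)

    def test_identical_rows_all_zero(self):
        aln = OrthologAlignment("px", {s: "ACDEF" for s in ("a", "b", "c")})
        for model in ("p", "kimura", "categories", "jtt"):
            assert np.allclose(distance_matrix(aln, model).values, 0.0)

    def test_saturation_tagged_and_nan_mode(self):
        # two maximally different rows: p = 1 saturates the Kimura measure
        aln = OrthologAlignment("px", {"a": "AAAA", "b": "CCCC", "c": "AAAA"})
        with pytest.raises(SaturationError, match="'a'.*'b'|'b'"):
            distance_matrix(aln, "kimura")
        cd = distance_matrix(aln, "kimura", on_error="nan")
        assert np.isnan(cd.values).sum() == 2  # a-b and b-c saturate

    def test_species_order_is_sorted(self, rng):
        from tests.conftest import random_alignment

        aln = random_alignment(rng, "px", ["zeb", "ant", "moo"])
        assert distance_matrix(aln, "p").species == ["ant", "moo", "zeb"]


class TestMeanIdentity:
    def test_identical_rows(self):
        aln = OrthologAlignment("px", {s: "ACDEF" for s in ("a", "b")})
        assert mean_identity(aln) == 1.0

    def test_three_rows_mean(self):
        # identities: a-b 1.0, a-c 0.8, b-c 0.8 -> mean 0.8667
        aln = OrthologAlignment(
            "px", {"a": "AAAAA", "b": "AAAAA", "c": "AAAAC"}
        )
        assert mean_identity(aln) == pytest.approx(0.86667, abs=1e-4)
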