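"""Classifier evaluation: ROC/AUC, MCC, negatives, binning, strata."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevotree.evaluation import (
    CapacityError,
    assign_clade_category,
    bin_by_conservation,
    density_summary,
    make_negatives,
    mcc,
    mcc_curve,
    roc,
    span_vs_score,
    stratify_by_span,
)


def score_table(pos, neg, **extra):
    rows = [{"r": s, "label": "interacting", **extra} for s in pos]
    rows += [{"r": s, "label": "noninteracting", **extra} for s in neg]
    df = pd.DataFrame(rows)
    df.insert(0, "protein_a", [f"a{i}" for i in range(len(df))])
    df.insert(1, "protein_b", [f"b{i}" for i in range(len(df))])
    return df


def mann_whitney_auc(pos, neg):
    """Concordant-pair estimate with ties counted one half."""
    pos, neg = np.asarray(pos), np.asarray(neg)
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestMakeNegatives:
    def test_capacity_error_single_pair(self):
        with pytest.raises(CapacityError):
            make_negatives([("A", "B")], n_out=1, seed=0)

    def test_admissible_pairs_only(self):
        interacting = [("A", "B"), ("C", "D")]
        negs = make_negatives(interacting, n_out=2, seed=1)
        admissible = {
            frozenset(p) for p in [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]
        }
        drawn = {frozenset((r.protein_a, r.protein_b)) for r in negs.itertuples()}
        assert drawn <= admissible
        assert len(drawn) == 2  # no duplicates

    def test_seed_determinism(self):
        interacting = [(f"p{i}", f"q{i}") for i in range(20)]
        n1 = make_negatives(interacting, n_out=15, seed=5)
        n2 = make_negatives(interacting, n_out=15, seed=5)
        pd.testing.assert_frame_equal(n1, n2)

    def test_excludes_interacting_both_orientations(self):
        interacting = [("A", "B"), ("B", "C"), ("C", "A")]
        # triangle: only self/interacting pairs exist among {A,B,C}
        with pytest.raises(CapacityError):
            make_negatives(interacting, n_out=1, seed=0, retry_factor=50)


class TestROC:
    def test_perfect_separation(self):
        res = roc(score_table([0.9, 0.8, 0.7], [0.5, 0.4]))
        assert res.auc == 1.0
        assert res.fpr[0] == 0.0 and res.tpr[-1] == 1.0

    def test_partial_overlap_example(self):
        # concordant pairs: 3 of 4 -> AUC 0.75
        res = roc(score_table([0.9, 0.8], [0.85, 0.2]))
        assert res.auc == pytest.approx(0.75)

    def test_null_scores(self, rng):
        pos = rng.random(500)
        neg = rng.random(500)
        assert roc(score_table(pos, neg)).auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        table = score_table([0.9, 0.8], [])
        with pytest.raises(ValueError):
            roc(table)

    def test_curve_monotone(self, rng):
        res = roc(score_table(rng.random(50), rng.random(50)))
        assert np.all(np.diff(res.fpr) >= 0)
        assert np.all(np.diff(res.tpr) >= 0)

    def test_auc_equals_mann_whitney(self, rng):
        for _ in range(100):
            pos = np.round(rng.random(int(rng.integers(2, 30))), 2)
            neg = np.round(rng.random(int(rng.integers(2, 30))), 2)
            assert roc(score_table(pos, neg)).auc == pytest.approx(
                mann_whitney_auc(pos, neg), abs=1e-9
            )

    def test_label_swap_flips_auc(self, rng):
        pos, neg = rng.random(30), rng.random(30)
        assert roc(score_table(pos, neg)).auc == pytest.approx(
            1.0 - roc(score_table(neg, pos)).auc, abs=1e-12
        )


class TestMCC:
    @pytest.mark.parametrize(
        "tp,fp,tn,fn,expected",
        [
            (10, 0, 10, 0, 1.0),
            (10, 10, 10, 10, 0.0),
            (90, 20, 80, 10, 0.7035),
            (0, 0, 10, 10, 0.0),  # zero denominator factor (tp+fp = 0)
        ],
    )
    def test_examples(self, tp, fp, tn, fn, expected):
        assert mcc(tp, fp, tn, fn) == pytest.approx(expected, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mcc(0, 0, 0, 0)

    @given(
        tp=st.integers(0, 500),
        fp=st.integers(0, 500),
        tn=st.integers(0, 500),
        fn=st.integers(0, 500),
    )
    @settings(max_examples=300, derandomize=True)
    def test_bounded(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        assert abs(mcc(tp, fp, tn, fn)) <= 1.0

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for _ in range(50):
            y = rng.integers(0, 2, size=60)
            pred = rng.integers(0, 2, size=60)
            tp = int(((y == 1) & (pred == 1)).sum())
            fp = int(((y == 0) & (pred == 1)).sum())
            tn = int(((y == 0) & (pred == 0)).sum())
            fn = int(((y == 1) & (pred == 0)).sum())
            assert mcc(tp, fp, tn, fn) == pytest.approx(
                matthews_corrcoef(y, pred), abs=1e-12
            )


class TestMCCCurve:
    def test_perfect_separation_peak(self):
        curve = mcc_curve(score_table([0.9, 0.8], [0.5, 0.4]))
        assert curve.peak_mcc == 1.0
        assert 0.5 < curve.peak_threshold <= 0.8

    def test_low_threshold_rates(self):
        curve = mcc_curve(
            score_table([0.9, 0.8], [0.5, 0.4]), thresholds=[0.0]
        )
        assert curve.sensitivity[0] == 1.0
        assert curve.specificity[0] == 0.0

    def test_null_peak_small(self, rng):
        curve = mcc_curve(score_table(rng.random(500), rng.random(500)))
        assert curve.peak_mcc < 0.15

    def test_rate_monotonicity(self, rng):
        curve = mcc_curve(score_table(rng.random(40), rng.random(40)))
        assert np.all(np.diff(curve.sensitivity) <= 0)
        assert np.all(np.diff(curve.specificity) >= 0)

    def test_label_swap_negates_mcc(self, rng):
        pos, neg = rng.random(25), rng.random(25)
        thr = np.linspace(0.1, 0.9, 9)
        fwd = mcc_curve(score_table(pos, neg), thresholds=thr)
        rev = mcc_curve(score_table(neg, pos), thresholds=thr)
        assert np.allclose(fwd.mcc, -rev.mcc, atol=1e-12)


class TestConservationBins:
    def test_single_bin(self):
        table = score_table([0.9, 0.8], [0.5], conservation=0.5)
        bins = bin_by_conservation(table, width=0.02)
        assert set(zip(bins["bin_low"].round(6), bins["bin_high"].round(6))) == {
            (0.5, 0.52)
        }

    def test_singleton_bin_sd_absent(self):
        table = score_table([0.9], [0.5], conservation=0.5)
        table.loc[1, "conservation"] = 0.7
        bins = bin_by_conservation(table, width=0.02)
        assert bins["sd_r"].isna().all()

    def test_bin_count_bounded_by_range(self, rng):
        cons = rng.uniform(0.3, 0.9, size=200)
        table = score_table(rng.random(100), rng.random(100))
        table["conservation"] = cons
        bins = bin_by_conservation(table, width=0.02)
        assert bins[["bin_low", "bin_high"]].drop_duplicates().shape[0] <= 31


CLADES = {
    "hum": ["chordates", "metazoa", "eukaryota"],
    "mus": ["chordates", "metazoa", "eukaryota"],
    "dme": ["metazoa", "eukaryota"],
    "sce": ["eukaryota"],
}


class TestSpanStratification:
    def test_innermost_containment(self):
        assert assign_clade_category(["hum", "mus"], CLADES) == "chordates"
        assert assign_clade_category(["hum", "dme"], CLADES) == "metazoa"
        assert assign_clade_category(["hum", "dme", "sce"], CLADES) == "eukaryota"

    def test_unknown_species(self):
        with pytest.raises(KeyError):
            assign_clade_category(["hum", "xenon"], CLADES)

    def test_partition(self):
        table = score_table([0.9, 0.8, 0.7], [0.6, 0.5, 0.4])
        keys = list(zip(table["protein_a"], table["protein_b"]))
        species = [
            ["hum", "mus"], ["hum", "dme"], ["hum", "sce"],
            ["hum", "mus"], ["mus", "dme"], ["dme", "sce"],
        ]
        strat = stratify_by_span(table, dict(zip(keys, species)), CLADES)
        assert sum(len(t) for t in strat.tables.values()) == len(table)
        assert set(strat.categories) == {"chordates", "metazoa", "eukaryota"}

    def test_missing_species_excluded(self):
        table = score_table([0.9], [0.5])
        keys = list(zip(table["protein_a"], table["protein_b"]))
        species = [["hum", "ghost"], ["hum", "mus"]]
        strat = stratify_by_span(table, dict(zip(keys, species)), CLADES)
        assert len(strat.excluded) == 1
        assert sum(len(t) for t in strat.tables.values()) == 1


class TestSpanVsScore:
    TIMES = {
        frozenset(("hum", "mus")): 90.0,
        frozenset(("hum", "sce")): 1500.0,
        frozenset(("mus", "sce")): 1500.0,
    }

    def test_single_pair_span(self):
        table = score_table([0.9], [0.5])
        keys = list(zip(table["protein_a"], table["protein_b"]))
        species = {keys[0]: ["hum", "mus"], keys[1]: ["hum", "mus", "sce"]}
        out = span_vs_score(table, species, self.TIMES)
        assert set(out["span_myr"]) == {90.0, 1500.0}

    def test_missing_time_excluded(self):
        table = score_table([0.9], [0.5])
        keys = list(zip(table["protein_a"], table["protein_b"]))
        species = {keys[0]: ["hum", "dme"], keys[1]: ["hum", "mus"]}
        out = span_vs_score(table, species, self.TIMES)
        assert len(out) == 1


class TestDensity:
    def test_normalization_and_mode(self, rng):
        pos = 0.7 + 0.05 * rng.standard_normal(200)
        neg = 0.2 + 0.05 * rng.standard_normal(200)
        dens = density_summary(score_table(pos, neg))
        for label, d in dens.items():
            total = np.trapezoid(d["density"], d["grid"])
            assert total == pytest.approx(1.0, abs=0.01)
        assert dens["interacting"]["mode"] > dens["noninteracting"]["mode"]

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            density_summary(score_table([0.9], [0.5, 0.4]))
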