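"""Discrimination and threshold tests: Mann-Whitney oracle, DeLong CI sanity,
confusion-matrix arithmetic, sweep monotonicity, nomination counts."""

import numpy as np
import pandas as pd
import pytest

from endoclass.evaluate import (
    carrier_fraction_large_effect,
    delong_auc_ci,
    fit_discrimination,
    nominate_variants,
    nominated_fractions,
    rank_auc,
    sd_threshold_sweep,
    summarize_by_consequence,
    threshold_characteristics,
)


def pairwise_concordance(scores, labels):
    """Brute-force AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def effects_frame(betas, keys=None):
    keys = keys or [f"v{i}" for i in range(len(betas))]
    return pd.DataFrame({"variant_key": keys, "beta": betas})


def assertions_frame(categories, keys=None):
    keys = keys or [f"v{i}" for i in range(len(categories))]
    return pd.DataFrame({"variant_key": keys, "category": categories})


class TestAUC:
    def test_perfect_separation(self):
        eff = effects_frame([50.0] * 5 + [0.0] * 5)
        asr = assertions_frame(["pathogenic"] * 5 + ["benign"] * 5)
        out = fit_discrimination(eff, asr)
        assert out.auc == 1.0

    def test_all_ties_gives_half(self):
        eff = effects_frame([7.0] * 10)
        asr = assertions_frame(["pathogenic"] * 4 + ["likely_benign"] * 6)
        out = fit_discrimination(eff, asr)
        assert out.auc == pytest.approx(0.5)

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(6, 40))
            scores = rng.choice([0.0, 1.0, 2.5, -1.0, 2.5], size=n)
            labels = rng.random(n) < 0.4
            if labels.sum() == 0 or (~labels).sum() == 0:
                continue
            assert rank_auc(scores, labels) == pytest.approx(
                pairwise_concordance(scores, labels), abs=1e-10)

    def test_trapezoid_roc_equals_rank_auc(self):
        """AUC integrated from the ROC curve equals the rank-based AUC."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(8, 60))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.random(n) < 0.5
            if labels.sum() == 0 or (~labels).sum() == 0:
                continue
            eff = effects_frame(scores)
            asr = assertions_frame(np.where(labels, "pathogenic", "benign"))
            out = fit_discrimination(eff, asr)
            trapezoid = np.trapezoid(out.roc_points[:, 1], out.roc_points[:, 0])
            assert trapezoid == pytest.approx(out.auc, abs=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        base = rank_auc(scores, labels)
        assert rank_auc(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)
        assert rank_auc(3 * scores + 7, labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_raises(self):
        eff = effects_frame([1.0, 2.0])
        asr = assertions_frame(["pathogenic", "pathogenic"])
        with pytest.raises(ValueError):
            fit_discrimination(eff, asr)

    def test_only_asserted_variants_included(self):
        eff = effects_frame([50.0, 0.0, 99.0])
        asr = assertions_frame(["pathogenic", "benign"], keys=["v0", "v1"])
        out = fit_discrimination(eff, asr)
        assert out.n_variants == 2  # v2 has no assertion

    def test_positive_set_grouping(self):
        eff = effects_frame([50.0, 30.0, 0.0, 1.0])
        asr = assertions_frame(
            ["pathogenic", "likely_pathogenic", "benign", "likely_benign"])
        only = fit_discrimination(eff, asr, "pathogenic_only")
        plus = fit_discrimination(eff, asr, "pathogenic_plus_likely")
        assert only.n_variants == 3 and plus.n_variants == 4
        assert plus.n_positive == 2

    def test_delong_ci_brackets_auc_and_shrinks(self):
        rng = np.random.default_rng(3)
        small = rng.normal(size=30)
        lab_small = np.r_[np.ones(15), np.zeros(15)].astype(bool)
        big = rng.normal(size=600)
        lab_big = np.r_[np.ones(300), np.zeros(300)].astype(bool)
        a1, lo1, hi1 = delong_auc_ci(small + lab_small, lab_small)
        a2, lo2, hi2 = delong_auc_ci(big + lab_big, lab_big)
        assert lo1 <= a1 <= hi1 and lo2 <= a2 <= hi2
        assert (hi2 - lo2) < (hi1 - lo1)


class TestThresholdCharacteristics:
    def test_threshold_below_everything(self):
        eff = effects_frame([5.0, 8.0, 3.0, 4.0])
        asr = assertions_frame(["pathogenic", "pathogenic", "benign", "likely_benign"])
        ch = threshold_characteristics(eff, asr, threshold=0.0)
        assert ch.sensitivity == 1.0 and ch.specificity == 0.0

    def test_hand_built_confusion_matrix(self):
        """TP=3 FN=1 FP=2 TN=4 -> sens 0.75, spec 2/3, PPV 0.6, NPV 0.8."""
        betas = [10, 11, 12, 1,      # pathogenic: 3 above threshold 5, 1 below
                 9, 8, 2, 1, 0, 3]   # benign-side: 2 above, 4 below
        cats = ["pathogenic"] * 4 + ["benign"] * 3 + ["likely_benign"] * 3
        ch = threshold_characteristics(effects_frame(betas),
                                       assertions_frame(cats), threshold=5.0)
        assert (ch.tp, ch.fn, ch.fp, ch.tn) == (3, 1, 2, 4)
        assert ch.sensitivity == pytest.approx(0.75)
        assert ch.specificity == pytest.approx(2 / 3)
        assert ch.ppv == pytest.approx(0.6)
        assert ch.npv == pytest.approx(0.8)

    def test_margins_sum_to_class_sizes(self):
        rng = np.random.default_rng(4)
        betas = rng.normal(size=50)
        cats = rng.choice(["pathogenic", "benign", "likely_benign", "vus"], size=50)
        eff, asr = effects_frame(betas), assertions_frame(cats)
        n_pos = int((cats == "pathogenic").sum())
        n_neg = int(np.isin(cats, ["benign", "likely_benign"]).sum())
        for thr in [-1.0, 0.0, 0.5, 2.0]:
            ch = threshold_characteristics(eff, asr, thr)
            assert ch.tp + ch.fn == n_pos
            assert ch.tn + ch.fp == n_neg

    def test_no_pathogenic_variants_sensitivity_undefined(self):
        eff = effects_frame([1.0, 2.0])
        asr = assertions_frame(["benign", "benign"])
        ch = threshold_characteristics(eff, asr, threshold=1.5)
        assert np.isnan(ch.sensitivity)
        assert any("sensitivity" in note for note in ch.notes)

    def test_boundary_is_inclusive(self):
        # effect size equal to the threshold counts as test-positive
        eff = effects_frame([5.0, 4.999])
        asr = assertions_frame(["pathogenic", "benign"])
        ch = threshold_characteristics(eff, asr, threshold=5.0)
        assert ch.tp == 1 and ch.tn == 1


class TestSweep:
    def _hand_set(self):
        betas = [30, 20, 12, 5, 25, 2, 1, 18, 3, 16, 8, 0]
        cats = ["pathogenic", "pathogenic", "pathogenic", "pathogenic",
                "benign", "benign", "likely_benign", "likely_benign",
                "vus", "vus", "conflicting", "absent"]
        return effects_frame(betas), assertions_frame(cats)

    def test_monotone_in_sd_multiple(self):
        eff, asr = self._hand_set()
        sweep = sd_threshold_sweep(eff, asr, trait_sd_value=10.0,
                                   sd_grid=[0.25, 0.5, 1.0, 2.0])
        sens = sweep["sensitivity"].to_numpy()
        spec = sweep["specificity"].to_numpy()
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_threshold_is_multiple_of_trait_sd(self):
        eff, asr = self._hand_set()
        sweep = sd_threshold_sweep(eff, asr, trait_sd_value=33.4, sd_grid=[0.5])
        assert sweep.loc[0, "threshold"] == pytest.approx(16.7)

    def test_every_cell_matches_brute_force(self):
        """Every sweep cell on a hand-built 12-variant set equals direct
        counting over the table."""
        eff, asr = self._hand_set()
        grid = [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0]
        sweep = sd_threshold_sweep(eff, asr, trait_sd_value=10.0, sd_grid=grid)
        table = eff.merge(asr, on="variant_key")
        for i, mult in enumerate(grid):
            thr = mult * 10.0
            pos = table["category"] == "pathogenic"
            neg = table["category"].isin(["benign", "likely_benign"])
            above = table["beta"] >= thr
            assert sweep.loc[i, "sensitivity"] == pytest.approx(
                (pos & above).sum() / pos.sum())
            assert sweep.loc[i, "specificity"] == pytest.approx(
                (neg & ~above).sum() / neg.sum())
            vus = table["category"] == "vus"
            assert sweep.loc[i, "nominated_fraction_vus"] == pytest.approx(
                (vus & above).sum() / vus.sum())

    def test_empty_grid_rejected(self):
        eff, asr = self._hand_set()
        with pytest.raises(ValueError):
            sd_threshold_sweep(eff, asr, 10.0, sd_grid=[])


class TestNomination:
    def test_all_vus_above_threshold(self):
        eff = effects_frame([20.0, 30.0])
        asr = assertions_frame(["vus", "vus"])
        noms = nominate_variants(eff, asr, threshold=10.0)
        assert nominated_fractions(noms)["vus"] == 1.0

    def test_no_nomination_categories_empty(self):
        eff = effects_frame([20.0])
        asr = assertions_frame(["pathogenic"])
        noms = nominate_variants(eff, asr, threshold=10.0)
        assert noms.empty

    def test_unreported_variants_nominated_as_absent(self):
        eff = effects_frame([20.0, 1.0], keys=["v0", "v1"])
        asr = assertions_frame(["pathogenic"], keys=["v0"])  # v1 not in ClinVar
        noms = nominate_variants(eff, asr, threshold=10.0)
        assert noms["category"].tolist() == ["absent"]
        assert not noms["nominated"].iloc[0]

    def test_fractions_match_brute_force(self):
        rng = np.random.default_rng(5)
        betas = rng.normal(10, 8, size=20)
        cats = rng.choice(["vus", "conflicting", "absent", "benign"], size=20)
        eff, asr = effects_frame(betas), assertions_frame(cats)
        noms = nominate_variants(eff, asr, threshold=12.0)
        fracs = nominated_fractions(noms)
        for cat in ["vus", "conflicting", "absent"]:
            mask = cats == cat
            if mask.sum() == 0:
                assert cat not in fracs
            else:
                assert fracs[cat] == pytest.approx(
                    (betas[mask] >= 12.0).mean())


class TestCarrierFraction:
    def _geno(self, columns):
        return pd.DataFrame(columns, index=[f"S{i}" for i in
                                            range(len(next(iter(columns.values()))))])

    def test_every_vus_large_effect(self):
        geno = self._geno({"v0": [1.0, 0, 0], "v1": [0, 1.0, 0]})
        eff = effects_frame([20.0, 25.0], keys=["v0", "v1"])
        asr = assertions_frame(["vus", "vus"], keys=["v0", "v1"])
        assert carrier_fraction_large_effect(geno, eff, asr, 10.0) == 1.0

    def test_no_carriers_undefined(self):
        geno = self._geno({"v0": [0.0, 0.0]})
        eff = effects_frame([20.0], keys=["v0"])
        asr = assertions_frame(["vus"], keys=["v0"])
        assert np.isnan(carrier_fraction_large_effect(geno, eff, asr, 10.0))

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(6)
        n, m = 200, 30
        geno = self._geno({f"v{j}": rng.choice([0.0, 1.0], n, p=[0.95, 0.05])
                           for j in range(m)})
        betas = rng.normal(10, 10, m)
        cats = rng.choice(["vus", "conflicting", "benign", "pathogenic"], m)
        eff = effects_frame(betas, keys=list(geno.columns))
        asr = assertions_frame(cats, keys=list(geno.columns))
        thr = 15.0
        got = carrier_fraction_large_effect(geno, eff, asr, thr)
        # independent recount
        numer = denom = 0
        for i in range(n):
            row = geno.iloc[i]
            vc_keys = [f"v{j}" for j in range(m) if cats[j] in ("vus", "conflicting")]
            carries = any(row[k] > 0 for k in vc_keys)
            large = any(row[f"v{j}"] > 0 and betas[j] >= thr
                        for j in range(m) if cats[j] in ("vus", "conflicting"))
            denom += carries
            numer += carries and large
        assert got == pytest.approx(numer / denom)


class TestConsequenceSummary:
    def _variants(self, consequences, keys=None):
        keys = keys or [f"v{i}" for i in range(len(consequences))]
        return pd.DataFrame({"variant_key": keys, "consequence": consequences})

    def test_all_below_threshold(self):
        eff = effects_frame([1.0, 2.0])
        var = self._variants(["missense", "stop_gained"])
        out = summarize_by_consequence(eff, var, threshold=10.0)
        assert (out["large_effect_proportion"] == 0).all()

    def test_single_class(self):
        eff = effects_frame([20.0])
        var = self._variants(["synonymous"])
        out = summarize_by_consequence(eff, var, threshold=10.0)
        assert len(out) == 1 and out.iloc[0]["class"] == "synonymous"

    def test_mixed_set_matches_hand_counts(self):
        betas = [20, 1, 15, 0, 30, 2]
        conseq = ["frameshift", "stop_gained", "missense",
                  "missense", "synonymous", "synonymous"]
        out = summarize_by_consequence(
            effects_frame(betas), self._variants(conseq),
            threshold=10.0, second_threshold=25.0).set_index("class")
        assert out.loc["lof", "large_effect_proportion"] == pytest.approx(0.5)
        assert out.loc["missense_indel", "large_effect_proportion"] == pytest.approx(0.5)
        assert out.loc["synonymous", "large_effect_proportion"] == pytest.approx(0.5)
        assert out.loc["synonymous", "large_effect_proportion_2"] == pytest.approx(0.5)
        assert out.loc["lof", "large_effect_proportion_2"] == pytest.approx(0.0)

    def test_unknown_label_warned_and_classed_other(self):
        eff = effects_frame([5.0])
        var = self._variants(["mystery"])
        with pytest.warns(UserWarning, match="mystery"):
            out = summarize_by_consequence(eff, var, threshold=1.0)
        assert out.iloc[0]["class"] == "other"
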