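"""The site taxonomy: chromatin state, dependency, pioneer mode,
cobinding, codependency and partner-binding labels."""

import numpy as np
import pandas as pd
import pytest

from pioneerlink import classify as cm
from pioneerlink.classify import ClassificationThresholds
from pioneerlink.differential import RegionCountMatrix
from pioneerlink.pipeline import classification_stage, differential_stage

THR = ClassificationThresholds()


def sites(coords, prefix="s"):
    return pd.DataFrame(
        {
            "chrom": [c[0] for c in coords],
            "start": [c[1] for c in coords],
            "end": [c[2] for c in coords],
            "name": [f"{prefix}{i}" for i in range(len(coords))],
        }
    )


def diff_table(ids, log2fc, q):
    return pd.DataFrame(
        {
            "base_mean": 100.0,
            "log2fc": log2fc,
            "se": 0.1,
            "p": q,
            "q": q,
        },
        index=pd.Index(ids, name="region_id"),
    )


class TestChromatinState:
    def test_single_base_overlap_is_open(self):
        tf = sites([("chr1", 0, 10)])
        atac = sites([("chr1", 9, 50)], prefix="a")
        assert cm.classify_chromatin_state(tf, atac)[0] == "open"

    def test_no_overlap_is_closed(self):
        tf = sites([("chr1", 0, 10)])
        atac = sites([("chr1", 10, 50)], prefix="a")
        assert cm.classify_chromatin_state(tf, atac)[0] == "closed"


class TestDependency:
    def test_called_decrease_is_opens_and_increase_is_represses(self):
        diff = diff_table(["s0", "s1", "s2"], [-1.0, 1.0, 0.1], [0.01, 0.01, 0.01])
        out = cm.classify_dependency(["s0", "s1", "s2"], diff, THR)
        assert out.tolist() == ["opens", "represses", "static"]

    def test_missing_site_raises_with_site_name(self):
        diff = diff_table(["s0"], [-1.0], [0.01])
        with pytest.raises(ValueError, match="s9"):
            cm.classify_dependency(["s9"], diff, THR)

    def test_shrinking_q_max_never_grows_dependent_set(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(200)]
        diff = diff_table(ids, rng.normal(0, 1, 200), rng.random(200))
        loose = cm.classify_dependency(ids, diff, ClassificationThresholds(q_max_dependency=0.5))
        tight = cm.classify_dependency(ids, diff, ClassificationThresholds(q_max_dependency=0.05))
        loose_dep = set(loose[loose != "static"].index)
        tight_dep = set(tight[tight != "static"].index)
        assert tight_dep <= loose_dep


class TestPioneerMode:
    def make(self, dependency, ko_peak, ko_signal):
        dep = pd.Series([dependency], index=pd.Index(["s0"], name="site_id"))
        return dict(
            dependency=dep,
            ko_peak=pd.Series([ko_peak], index=dep.index),
            ko_signal=pd.Series([ko_signal], index=dep.index),
            wt_open_reference=np.linspace(100, 300, 101),  # 10% quantile = 120
        )

    def test_no_ko_peak_and_low_signal_is_classical(self):
        out = cm.classify_pioneer_mode(**self.make("opens", False, 5.0), thresholds=THR)
        assert out.iloc[0] == "classical_pioneer"

    def test_ko_peak_with_residual_signal_is_permissive(self):
        out = cm.classify_pioneer_mode(**self.make("opens", True, 100.0), thresholds=THR)
        assert out.iloc[0] == "permissive"

    def test_low_signal_but_ko_peak_still_permissive_when_required(self):
        out = cm.classify_pioneer_mode(**self.make("opens", True, 5.0), thresholds=THR)
        assert out.iloc[0] == "permissive"
        relaxed = ClassificationThresholds(require_no_ko_peak=False)
        out2 = cm.classify_pioneer_mode(**self.make("opens", True, 5.0), thresholds=relaxed)
        assert out2.iloc[0] == "classical_pioneer"

    def test_static_site_rejected(self):
        with pytest.raises(ValueError, match="static"):
            cm.classify_pioneer_mode(**self.make("static", False, 5.0), thresholds=THR)

    def test_repressive_site_with_wt_peak_is_permissive(self):
        args = self.make("represses", True, 250.0)
        out = cm.classify_pioneer_mode(
            **args,
            thresholds=THR,
            wt_peak=pd.Series([True], index=args["dependency"].index),
            wt_signal=pd.Series([200.0], index=args["dependency"].index),
            ko_open_reference=np.linspace(100, 300, 101),
        )
        assert out.iloc[0] == "permissive"


class TestPreboundConsistency:
    def test_full_overlap_gives_one(self):
        early = diff_table(["s0", "s1"], [-2.0, -2.0], [0.001, 0.001])
        dep = pd.Series(["opens", "opens"], index=pd.Index(["s0", "s1"], name="site_id"))
        frac, flags = cm.prebound_consistency(early, dep, THR)
        assert frac == 1.0 and flags.all()

    def test_disjoint_sets_give_zero(self):
        early = diff_table(["s0"], [-2.0], [0.001])
        dep = pd.Series(["static"], index=pd.Index(["s0"], name="site_id"))
        frac, _ = cm.prebound_consistency(early, dep, THR)
        assert frac == 0.0

    def test_empty_denominator_reports_missing(self):
        early = diff_table(["s0"], [0.0], [0.9])
        dep = pd.Series(["opens"], index=pd.Index(["s0"], name="site_id"))
        frac, flags = cm.prebound_consistency(early, dep, THR)
        assert np.isnan(frac) and len(flags) == 0


class TestCoboundAndCodependent:
    def test_cobound_is_peak_overlap(self):
        tf = sites([("chr1", 0, 10), ("chr1", 100, 110)])
        rem = sites([("chr1", 5, 50)], prefix="r")
        assert cm.flag_cobound(tf, rem).tolist() == [True, False]

    def cob(self, flags):
        return pd.Series(flags, index=pd.Index([f"s{i}" for i in range(len(flags))], name="site_id"))

    def test_concordant_down_at_relaxed_q_is_codependent(self):
        ko = diff_table(["s0"], [-1.0], [0.3])
        inh = diff_table(["s0"], [-0.1], [0.9])  # threshold-free: sign only
        out = cm.codependent_sites(self.cob([True]), ko, inh, THR)
        assert out.iloc[0]

    def test_discordant_directions_not_codependent(self):
        ko = diff_table(["s0"], [-1.0], [0.3])
        inh = diff_table(["s0"], [0.4], [0.9])
        assert not cm.codependent_sites(self.cob([True]), ko, inh, THR).iloc[0]

    def test_cobinding_required(self):
        ko = diff_table(["s0"], [-1.0], [0.3])
        inh = diff_table(["s0"], [-0.4], [0.9])
        assert not cm.codependent_sites(self.cob([False]), ko, inh, THR).iloc[0]

    def test_zero_inhibitor_fold_change_counts_as_discordant(self):
        ko = diff_table(["s0"], [-1.0], [0.3])
        inh = diff_table(["s0"], [0.0], [0.9])
        assert not cm.codependent_sites(self.cob([True]), ko, inh, THR).iloc[0]

    def test_missing_site_raises(self):
        ko = diff_table(["s0"], [-1.0], [0.3])
        inh = diff_table(["other"], [-1.0], [0.3])
        with pytest.raises(ValueError, match="s0"):
            cm.codependent_sites(self.cob([True]), ko, inh, THR)


class TestPartnerBinding:
    def test_absent_and_unchanged_labels(self):
        rng = np.random.default_rng(1)
        site_set = sites([("chr1", 0, 200), ("chr1", 1_000, 1_200)])
        counts = pd.DataFrame(
            rng.poisson(150, size=(2, 6)),
            index=["s0", "s1"],
            columns=["c0", "c1", "c2", "k0", "k1", "k2"],
        )
        rcm = RegionCountMatrix(counts)
        # perturbed peaks only over s1
        perturbed_peaks = sites([("chr1", 1_000, 1_200)], prefix="p")
        out = cm.partner_binding_change(
            rcm, ["c0", "c1", "c2"], ["k0", "k1", "k2"], perturbed_peaks, site_set, THR
        )
        assert out.loc["s0"] == "absent"
        assert out.loc["s1"] == "unchanged"


class TestFcCorrelation:
    def test_identical_vectors_give_one(self):
        a = diff_table(["s0", "s1", "s2"], [1.0, -1.0, 0.5], [0.1, 0.1, 0.1])
        assert cm.accessibility_fc_correlation(a, a, ["s0", "s1", "s2"]) == pytest.approx(1.0)

    def test_negated_vectors_give_minus_one(self):
        a = diff_table(["s0", "s1", "s2"], [1.0, -1.0, 0.5], [0.1, 0.1, 0.1])
        b = a.copy()
        b["log2fc"] = -b["log2fc"]
        assert cm.accessibility_fc_correlation(a, b, ["s0", "s1", "s2"]) == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(1_000)]
        a = diff_table(ids, rng.normal(size=1_000), np.full(1_000, 0.5))
        b = diff_table(ids, rng.normal(size=1_000), np.full(1_000, 0.5))
        assert abs(cm.accessibility_fc_correlation(a, b, ids)) < 0.1

    def test_zero_variance_reports_missing(self):
        a = diff_table(["s0", "s1", "s2"], [1.0, 1.0, 1.0], [0.1, 0.1, 0.1])
        b = diff_table(["s0", "s1", "s2"], [1.0, -1.0, 0.5], [0.1, 0.1, 0.1])
        assert np.isnan(cm.accessibility_fc_correlation(a, b, ["s0", "s1", "s2"]))


class TestThresholds:
    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError):
            ClassificationThresholds(ko_signal_quantile=0.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            ClassificationThresholds(fc_min=0.0)


class TestTaxonomyOnBundle:
    def test_every_site_gets_exactly_one_label_per_axis(self, small_bundle):
        diffs = differential_stage(small_bundle)
        classification, _ = classification_stage(small_bundle, diffs, THR)
        assert len(classification) == len(small_bundle.truth_sites)
        assert classification["chromatin_state"].isin(["open", "closed"]).all()
        assert classification["dependency"].isin(
            ["opens", "represses", "static", "not_assessed"]
        ).all()
        assert classification["mode"].isin(
            ["classical_pioneer", "permissive", "not_applicable"]
        ).all()
        # dependency assessed exactly on open sites
        closed = classification["chromatin_state"] == "closed"
        assert (classification.loc[closed, "dependency"] == "not_assessed").all()
        assert (classification.loc[~closed, "dependency"] != "not_assessed").all()
        # mode only on dependent sites
        dependent = classification["dependency"].isin(["opens", "represses"])
        assert (classification.loc[~dependent, "mode"] == "not_applicable").all()
        assert (classification.loc[dependent, "mode"] != "not_applicable").all()

    def test_classification_invariant_to_site_order(self, small_bundle):
        tf = small_bundle.peaks["tf"]
        atac = small_bundle.peaks["atac_wt_late"]
        rem = small_bundle.peaks["remodeler_control"]
        shuffled = tf.sample(frac=1.0, random_state=0)
        a = pd.Series(cm.classify_chromatin_state(tf, atac), index=tf["name"])
        b = pd.Series(cm.classify_chromatin_state(shuffled, atac), index=shuffled["name"])
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())
        ca = pd.Series(cm.flag_cobound(tf, rem), index=tf["name"])
        cb = pd.Series(cm.flag_cobound(shuffled, rem), index=shuffled["name"])
        pd.testing.assert_series_equal(ca.sort_index(), cb.sort_index())

    def test_chromosome_renaming_consistency(self, small_bundle):
        tf = small_bundle.peaks["tf"].copy()
        atac = small_bundle.peaks["atac_wt_late"].copy()
        before = cm.classify_chromatin_state(tf, atac)
        mapping = {"chr1": "alias_A", "chr2": "alias_B"}
        tf["chrom"] = tf["chrom"].map(mapping)
        atac["chrom"] = atac["chrom"].map(mapping)
        after = cm.classify_chromatin_state(tf, atac)
        assert np.array_equal(before, after)
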