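import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import twinmeth as tm
from twinmeth.core_io import BetaMatrix, IntensityPair, ProbeAnnotation, QcMetrics, TwinDesign
from twinmeth.preprocess import _quantile_normalize


def _design(n_pairs, age_wave=10):
    rows = []
    for i in range(n_pairs):
        pid = f"p{i}"
        rows.append((f"{pid}a", pid, "affected", "discordant", age_wave))
        rows.append((f"{pid}u", pid, "unaffected", "discordant", age_wave))
    return TwinDesign(
        pd.DataFrame(rows, columns=["sample_id", "pair_id", "role", "group", "age_wave"])
    )


def _qc(detp, samples, probes=None):
    detp = np.asarray(detp, dtype=float)
    probes = probes or [f"cg{i}" for i in range(detp.shape[0])]
    index = pd.Index(probes, name="probe_id")
    return QcMetrics(
        pd.DataFrame(detp, index=index, columns=samples),
        pd.DataFrame(np.full(detp.shape, 14), index=index, columns=samples),
    )


class TestSampleFilter:
    def test_clean_metrics_retain_everyone(self):
        design = _design(2)
        metrics = _qc(np.full((100, 4), 0.001), ["p0a", "p0u", "p1a", "p1u"])
        report = tm.filter_samples(metrics, design)
        assert report.n_samples_retained == 4
        assert report.removed_samples.empty

    def test_failing_sample_takes_co_twin_along(self):
        design = _design(2)
        detp = np.full((100, 4), 0.001)
        detp[:6, 0] = 0.9  # 6% failing calls for p0a
        report = tm.filter_samples(_qc(detp, ["p0a", "p0u", "p1a", "p1u"]), design)
        assert len(report.removed_samples) == 2
        reasons = dict(zip(report.removed_samples["sample_id"], report.removed_samples["reason"]))
        assert reasons == {"p0a": "own failure", "p0u": "co-twin removal"}
        assert report.removed_samples.set_index("sample_id").loc["p0u", "partner"] == "p0a"

    def test_both_twins_failing_are_both_own_failures(self):
        design = _design(2)
        detp = np.full((100, 4), 0.001)
        detp[:6, 0] = 0.9
        detp[:6, 1] = 0.9
        report = tm.filter_samples(_qc(detp, ["p0a", "p0u", "p1a", "p1u"]), design)
        assert list(report.removed_samples["reason"]) == ["own failure", "own failure"]

    def test_low_bead_counts_also_fail(self):
        design = _design(2)
        metrics = _qc(np.full((100, 4), 0.001), ["p0a", "p0u", "p1a", "p1u"])
        beads = metrics.bead_count.copy()
        beads.iloc[:6, 0] = 2
        report = tm.filter_samples(QcMetrics(metrics.detection_p, beads), design)
        assert set(report.removed_samples["sample_id"]) == {"p0a", "p0u"}

    def test_filter_is_idempotent(self):
        design = _design(3)
        detp = np.full((200, 6), 0.001)
        detp[:15, 2] = 0.5
        samples = ["p0a", "p0u", "p1a", "p1u", "p2a", "p2u"]
        metrics = _qc(detp, samples)
        report1 = tm.filter_samples(metrics, design)
        kept = report1.retained_samples
        report2 = tm.filter_samples(
            metrics.subset(samples=kept), design.subset_samples(kept)
        )
        assert report2.removed_samples.empty
        assert report2.retained_samples == kept


class TestProbeFilter:
    def _annotation(self, probes, chroms=None, cross=None, snp=None):
        n = len(probes)
        return ProbeAnnotation(
            pd.DataFrame(
                {
                    "chromosome": chroms or ["1"] * n,
                    "position": range(1, n + 1),
                    "design_type": ["II"] * n,
                    "gene_labels": [[] for _ in range(n)],
                    "cross_reactive": cross or [False] * n,
                    "snp_control": snp or [False] * n,
                },
                index=pd.Index(probes, name="probe_id"),
            )
        )

    def test_clean_autosomal_probes_all_retained(self):
        probes = [f"cg{i}" for i in range(5)]
        beta = BetaMatrix(
            pd.DataFrame(np.full((5, 2), 0.5), index=pd.Index(probes, name="probe_id"),
                         columns=["s1", "s2"])
        )
        report = tm.filter_probes(self._annotation(probes), beta)
        assert report.retained_probes == probes

    def test_flagged_and_sex_probes_removed(self):
        probes = [f"cg{i}" for i in range(10)]
        chroms = ["1"] * 9 + ["X"]
        cross = [True, True] + [False] * 8
        beta = BetaMatrix(
            pd.DataFrame(np.full((10, 2), 0.5), index=pd.Index(probes, name="probe_id"),
                         columns=["s1", "s2"])
        )
        report = tm.filter_probes(self._annotation(probes, chroms, cross), beta)
        assert report.n_probes_retained == 7
        reasons = report.removed_probes.set_index("probe_id")["reason"]
        assert reasons["cg0"] == "cross-reactive"
        assert reasons["cg9"] == "sex chromosome"

    def test_snp_controls_removed_from_testing(self, small_study):
        report = tm.filter_probes(small_study.annotation, small_study.beta_age10)
        removed = report.removed_probes.set_index("probe_id")["reason"]
        assert all(removed.loc[p] == "snp control" for p in small_study.snp_control_probe_ids)
        assert len(small_study.snp_control_probe_ids) == 65

    def test_missingness_rule_and_idempotence(self):
        probes = ["cg0", "cg1", "cg2"]
        values = pd.DataFrame(
            [[0.5, 0.5], [np.nan, 0.5], [0.2, 0.8]],
            index=pd.Index(probes, name="probe_id"),
            columns=["s1", "s2"],
        )
        beta = BetaMatrix(values)
        report = tm.filter_probes(self._annotation(probes), beta)
        assert report.retained_probes == ["cg0", "cg2"]
        again = tm.filter_probes(
            self._annotation(report.retained_probes), beta.subset(probes=report.retained_probes)
        )
        assert again.removed_probes.empty

    def test_unannotated_probe_is_an_error(self):
        beta = BetaMatrix(
            pd.DataFrame([[0.5]], index=pd.Index(["cgZ"], name="probe_id"), columns=["s1"])
        )
        with pytest.raises(ValueError, match="missing from annotation"):
            tm.filter_probes(self._annotation(["cgA"]), beta)


class TestMonozygosity:
    def _snp_beta(self, values, samples):
        probes = [f"rs{i}" for i in range(values.shape[0])]
        return BetaMatrix(
            pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
        )

    def test_identical_twins_pass_with_zero_discordance(self):
        design = _design(1)
        vals = np.tile(np.linspace(0.05, 0.95, 12)[:, None], (1, 2))
        report = tm.confirm_monozygosity(self._snp_beta(vals, ["p0a", "p0u"]), design)
        assert report.loc["p0", "discordance"] == 0.0
        assert bool(report.loc["p0", "passed"])

    def test_unrelated_genotypes_fail(self):
        """Independently drawn trimodal genotype profiles disagree on ~half
        the markers, far above the 0.1 discordance bound."""
        rng = np.random.default_rng(4)
        design = _design(1)
        levels = np.array([0.05, 0.5, 0.95])
        vals = levels[rng.integers(0, 3, size=(65, 2))]
        report = tm.confirm_monozygosity(self._snp_beta(vals, ["p0a", "p0u"]), design)
        assert not bool(report.loc["p0", "passed"])

    def test_failing_pair_is_flagged_not_removed(self):
        rng = np.random.default_rng(1)
        design = _design(4)
        samples = [s for i in range(4) for s in (f"p{i}a", f"p{i}u")]
        vals = np.tile(rng.choice([0.05, 0.5, 0.95], size=(20, 1)), (1, 8))
        vals[:, 6] = rng.choice([0.05, 0.5, 0.95], size=20)  # pair p3 mismatched
        report = tm.confirm_monozygosity(self._snp_beta(vals, samples), design)
        assert report["passed"].sum() == 3
        assert len(report) == 4

    def test_too_few_markers_rejected(self):
        design = _design(1)
        vals = np.full((5, 2), 0.5)
        with pytest.raises(ValueError, match=">= 10 SNP control probes"):
            tm.confirm_monozygosity(self._snp_beta(vals, ["p0a", "p0u"]), design)


class TestDasen:
    def _intensities(self, meth, unmeth, design_types):
        probes = [f"cg{i}" for i in range(len(design_types))]
        index = pd.Index(probes, name="probe_id")
        cols = [f"s{j}" for j in range(np.asarray(meth).shape[1])]
        pair = IntensityPair(
            pd.DataFrame(np.asarray(meth, dtype=float), index=index, columns=cols),
            pd.DataFrame(np.asarray(unmeth, dtype=float), index=index, columns=cols),
        )
        ann = ProbeAnnotation(
            pd.DataFrame(
                {
                    "chromosome": "1",
                    "position": range(1, len(probes) + 1),
                    "design_type": design_types,
                    "gene_labels": [[] for _ in probes],
                    "cross_reactive": False,
                    "snp_control": False,
                },
                index=index,
            )
        )
        return pair, ann

    def test_hand_computed_quantile_normalization(self):
        """2 samples x 4 type-II probes: rank-wise reference means."""
        x = np.array([[2.0, 8.0], [4.0, 2.0], [6.0, 4.0], [8.0, 6.0]])
        # sorted columns: [2,4,6,8] and [2,4,6,8] -> reference [2,4,6,8]
        expected = np.array([[2.0, 8.0], [4.0, 2.0], [6.0, 4.0], [8.0, 6.0]])
        result = _quantile_normalize(pd.DataFrame(x))
        np.testing.assert_allclose(result.to_numpy(), expected)
        y = np.array([[1.0, 30.0], [3.0, 10.0], [5.0, 20.0], [7.0, 40.0]])
        # reference = mean of sorted cols = [(1+10)/2,(3+20)/2,(5+30)/2,(7+40)/2]
        ref = np.array([5.5, 11.5, 17.5, 23.5])
        expected_y = np.column_stack([ref, ref[[2, 0, 1, 3]]])
        np.testing.assert_allclose(_quantile_normalize(pd.DataFrame(y)).to_numpy(), expected_y)

    def test_ties_average_reference_values(self):
        x = np.array([[1.0, 5.0], [1.0, 6.0], [3.0, 7.0]])
        result = _quantile_normalize(pd.DataFrame(x)).to_numpy()
        # column 0 has a tie at rank 1.5: both entries get the mean of the
        # first two reference values
        ref = (np.sort(x, axis=0)).mean(axis=1)
        assert result[0, 0] == result[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_sorted_vectors_identical_across_samples_per_stratum(self):
        rng = np.random.default_rng(0)
        types = ["I"] * 10 + ["II"] * 30
        pair, ann = self._intensities(
            rng.lognormal(8, 0.4, (40, 5)), rng.lognormal(8, 0.4, (40, 5)), types
        )
        out = tm.dasen_normalize(pair, ann)
        for frame in (out.methylated, out.unmethylated):
            for mask in (np.array(types) == "I", np.array(types) == "II"):
                block = frame.to_numpy()[mask]
                sorted_cols = np.sort(block, axis=0)
                for j in range(1, block.shape[1]):
                    np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_rank_order_preserved_within_stratum(self):
        rng = np.random.default_rng(3)
        types = ["II"] * 25 + ["I"] * 8
        pair, ann = self._intensities(
            rng.lognormal(8, 0.5, (33, 3)), rng.lognormal(8, 0.5, (33, 3)), types
        )
        out = tm.dasen_normalize(pair, ann)
        mask = np.array(types) == "II"
        before = pair.methylated.to_numpy()[mask]
        after = out.methylated.to_numpy()[mask]
        for j in range(3):
            assert np.array_equal(np.argsort(before[:, j]), np.argsort(after[:, j]))

    def test_background_shift_aligns_type_i_quantile(self):
        rng = np.random.default_rng(9)
        types = ["I"] * 50 + ["II"] * 50
        base = rng.lognormal(8, 0.3, (100, 2))
        meth = base.copy()
        meth[:50] += 500.0  # type I background
        pair, ann = self._intensities(meth, base, types)
        out = tm.dasen_normalize(pair, ann)
        m = out.methylated.to_numpy()
        q_i = np.quantile(m[:50], 0.05, axis=0)
        q_ii = np.quantile(m[50:], 0.05, axis=0)
        np.testing.assert_allclose(q_i, q_ii, rtol=0.12)

    def test_stratum_with_too_few_probes_rejected(self):
        pair, ann = self._intensities([[1.0, 2.0]], [[1.0, 2.0]], ["I"])
        with pytest.raises(ValueError, match="stratum"):
            tm.dasen_normalize(pair, ann)


class TestComputeBeta:
    def test_worked_values(self):
        pair, _ = TestDasen()._intensities(
            [[300.0], [100.0], [0.0]], [[100.0], [100.0], [0.0]], ["II", "II", "II"]
        )
        beta = tm.compute_beta(pair, offset=100.0)
        np.testing.assert_allclose(beta.values.to_numpy().ravel(), [0.6, 1 / 3, 0.0])
        equal = tm.compute_beta(
            TestDasen()._intensities([[50.0]], [[50.0]], ["II"])[0], offset=0.0
        )
        assert equal.values.iloc[0, 0] == pytest.approx(0.5)

    @given(
        m=st.floats(min_value=0, max_value=1e6),
        m2=st.floats(min_value=0, max_value=1e6),
        u=st.floats(min_value=0, max_value=1e6),
    )
    def test_monotone_in_methylated_signal(self, m, m2, u):
        lo, hi = sorted([m, m2])
        pair_lo, _ = TestDasen()._intensities([[lo]], [[u]], ["II"])
        pair_hi, _ = TestDasen()._intensities([[hi]], [[u]], ["II"])
        assert (
            tm.compute_beta(pair_lo).values.iloc[0, 0]
            <= tm.compute_beta(pair_hi).values.iloc[0, 0]
        )

    def test_negative_intensity_rejected(self):
        probes = pd.Index(["cg0"], name="probe_id")
        with pytest.raises(ValueError, match="negative"):
            IntensityPair(
                pd.DataFrame([[-1.0]], index=probes, columns=["s"]),
                pd.DataFrame([[1.0]], index=probes, columns=["s"]),
            )
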