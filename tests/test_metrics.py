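import numpy as np
import pytest

from memtopo import (
    MetricRecord,
    MetricTimecourse,
    UncertainValue,
    aggregate_window,
    contact_relative_enrichment,
    enrichment,
    enrichment_uncertain,
    membrane_bound,
    normalize_to_max,
    relative_enrichment,
    relative_membrane_bound,
)


def masks_6x6():
    whole = np.zeros((6, 6), dtype=bool)
    whole[0, :] = True
    whole[5, :] = True  # 12 membrane pixels
    region = np.zeros((6, 6), dtype=bool)
    region[0, :4] = True  # 4 px
    return region, whole


class TestNormalizeToMax:
    def test_membrane_max_becomes_one(self):
        region, whole = masks_6x6()
        img = np.ones((6, 6))
        img[0, 0] = 200.0
        out = normalize_to_max(img, whole)
        assert out[0, 0] == pytest.approx(1.0)
        assert out[whole].max() == pytest.approx(1.0)

    def test_enrichment_invariant_under_normalisation(self):
        region, whole = masks_6x6()
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 10, (6, 6))
        e1 = enrichment(img, region, whole)
        e2 = enrichment(normalize_to_max(img, whole), region, whole)
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_zero_membrane_errors(self):
        region, whole = masks_6x6()
        with pytest.raises(ValueError):
            normalize_to_max(np.zeros((6, 6)), whole)


class TestEnrichment:
    def test_uniform_image_gives_one(self):
        region, whole = masks_6x6()
        assert enrichment(np.full((6, 6), 3.3), region, whole) == pytest.approx(1.0)

    def test_toy_arithmetic(self):
        region, whole = masks_6x6()
        img = np.zeros((6, 6))
        img[whole] = 2.5  # membrane mean 5 after region pixels are set:
        img[region] = 10.0
        # membrane mean = (4*10 + 8*2.5) / 12 = 5.0; region mean = 10
        assert enrichment(img, region, whole) == pytest.approx(2.0)

    def test_scale_invariance(self):
        region, whole = masks_6x6()
        rng = np.random.default_rng(1)
        img = rng.uniform(0.1, 5, (6, 6))
        assert enrichment(img * 3, region, whole) == pytest.approx(
            enrichment(img, region, whole), rel=1e-12
        )

    def test_whole_membrane_exactly_one(self):
        _, whole = masks_6x6()
        rng = np.random.default_rng(2)
        img = rng.uniform(1, 9, (6, 6))
        out = enrichment_uncertain(img, whole, whole)
        assert (out.value, out.sem) == (1.0, 0.0)

    def test_empty_region_errors(self):
        _, whole = masks_6x6()
        with pytest.raises(ValueError, match="empty"):
            enrichment(np.ones((6, 6)), np.zeros((6, 6), dtype=bool), whole)

    def test_zero_membrane_mean_errors(self):
        region, whole = masks_6x6()
        with pytest.raises(ValueError):
            enrichment(np.zeros((6, 6)), region, whole)


class TestRelativeEnrichment:
    def test_identity_for_reference_itself(self):
        assert relative_enrichment(1.2, 1.2) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert relative_enrichment(1.5, 1.2) == pytest.approx(1.25)

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError):
            relative_enrichment(1.0, 0.0)


class TestContactMetrics:
    def _setup(self, contact_val, noncontact_val):
        whole = np.zeros((6, 6), dtype=bool)
        whole[0, :] = whole[5, :] = True
        contact = np.zeros((6, 6), dtype=bool)
        contact[0, :3] = True
        noncontact = np.zeros((6, 6), dtype=bool)
        noncontact[0, 3:] = True
        img = np.ones((6, 6))
        img[contact] = contact_val
        img[noncontact] = noncontact_val
        return img, contact, noncontact, whole

    def test_uniform_image_gives_one(self):
        img, c, n, w = self._setup(1.0, 1.0)
        assert contact_relative_enrichment(img, c, n, w) == pytest.approx(1.0)

    def test_arithmetic_12_over_8(self):
        img, c, n, w = self._setup(12.0, 8.0)
        assert contact_relative_enrichment(img, c, n, w) == pytest.approx(1.5)

    def test_membrane_mean_cancels(self):
        img, c, n, w = self._setup(12.0, 8.0)
        assert contact_relative_enrichment(img, c, n, w) == pytest.approx(
            img[c].mean() / img[n].mean()
        )

    def test_membrane_bound_equal_means_zero(self):
        img, c, n, w = self._setup(4.0, 4.0)
        assert membrane_bound(img, c, n, w).value == pytest.approx(0.0)

    def test_membrane_bound_sign_and_magnitude(self):
        img, c, n, w = self._setup(12.0, 8.0)
        e_c = enrichment(img, c, w)
        e_n = enrichment(img, n, w)
        mb = membrane_bound(img, c, n, w)
        assert mb.value == pytest.approx(e_c - e_n)
        assert mb.value > 0

    def test_empty_submask_errors(self):
        img, c, n, w = self._setup(1.0, 1.0)
        with pytest.raises(ValueError):
            contact_relative_enrichment(img, np.zeros_like(c), n, w)


class TestRelativeMembraneBound:
    def test_unit_reference_identity(self):
        mb = UncertainValue(0.6, 0.5)
        out = relative_membrane_bound(mb, UncertainValue(1.0, 0.0))
        assert (out.value, out.sem) == (pytest.approx(0.6), pytest.approx(0.5))

    def test_worked_example(self):
        out = relative_membrane_bound(UncertainValue(0.6, 0.5), UncertainValue(1.2, 0.1))
        assert out.value == pytest.approx(0.5)
        assert out.sem == pytest.approx(0.4188, abs=0.001)

    def test_zero_numerator_convention(self):
        out = relative_membrane_bound(UncertainValue(0.0, 0.3), UncertainValue(1.5, 0.1))
        assert out.value == 0.0
        assert out.sem == pytest.approx(0.2)

    def test_missing_reference_instructs_configuration(self):
        with pytest.raises(ValueError, match="caax_reference_enrichment"):
            relative_membrane_bound(UncertainValue(0.6, 0.5), None)


def make_timecourse(values_by_t, metric="relative_enrichment", region="protrusion",
                    role="protein", interval=4.0, t0=0):
    tc = MetricTimecourse(frame_interval_s=interval, t0_frame=t0)
    for frame, (t_s, v) in enumerate(values_by_t):
        tc.append(MetricRecord(frame, t_s, region, metric, UncertainValue(v, 0.0), role))
    return tc


class TestAggregateWindow:
    def test_constant_metric(self):
        tc = make_timecourse([(0, 1.3), (4, 1.3), (8, 1.3)])
        out, skipped = aggregate_window(tc, "relative_enrichment", "protrusion",
                                        "protein", (0, 60))
        assert (out.value, out.sem, skipped) == (pytest.approx(1.3), 0.0, 0)

    def test_arithmetic_with_sem(self):
        tc = make_timecourse([(0, 1.0), (4, 2.0), (8, 3.0)])
        out, _ = aggregate_window(tc, "relative_enrichment", "protrusion",
                                  "protein", (0, 60))
        assert out.value == pytest.approx(2.0)
        assert out.sem == pytest.approx(0.5774, abs=1e-4)

    def test_window_inclusive_at_60s(self):
        tc = make_timecourse([(0, 1.0), (60, 3.0), (75, 99.0)], interval=15.0)
        out, _ = aggregate_window(tc, "relative_enrichment", "protrusion",
                                  "protein", (0, 60))
        assert out.value == pytest.approx(2.0)

    def test_missing_values_skipped_and_counted(self):
        tc = make_timecourse([(0, 1.0), (4, float("nan")), (8, 3.0)])
        out, skipped = aggregate_window(tc, "relative_enrichment", "protrusion",
                                        "protein", (0, 60))
        assert out.value == pytest.approx(2.0)
        assert skipped == 1

    def test_no_frames_in_window_errors(self):
        tc = make_timecourse([(100.0, 1.0)])
        with pytest.raises(ValueError):
            aggregate_window(tc, "relative_enrichment", "protrusion", "protein", (0, 60))

    def test_undefined_t0_errors(self):
        tc = make_timecourse([(0, 1.0)])
        tc.t0_frame = None
        with pytest.raises(ValueError):
            aggregate_window(tc, "relative_enrichment", "protrusion", "protein", (0, 60))


class TestMetricRecordValidation:
    def test_contact_metric_requires_region_class(self):
        with pytest.raises(ValueError):
            MetricRecord(0, 0.0, "protrusion_contact", "contact_relative_enrichment",
                         UncertainValue(1.0), "protein")
        MetricRecord(0, 0.0, "protrusion", "contact_relative_enrichment",
                     UncertainValue(1.0), "protein")

    def test_unknown_region_metric(self):
        with pytest.raises(ValueError):
            MetricRecord(0, 0.0, "nucleus", "enrichment", UncertainValue(1.0), "protein")
        with pytest.raises(ValueError):
            MetricRecord(0, 0.0, "body", "fancy_metric", UncertainValue(1.0), "protein")

    def test_dataframe_roundtrip_columns(self):
        tc = make_timecourse([(0, 1.0), (4, 2.0)])
        df = tc.to_dataframe()
        assert list(df["value"]) == [1.0, 2.0]
        assert {"frame", "t_s", "region", "metric", "channel_role", "sem"} <= set(df.columns)
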