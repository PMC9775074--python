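"""Scoring rules: timed-score inversion, z-composite arithmetic,
education-adjusted diagnostic classification, marker transforms."""

import numpy as np
import pandas as pd
import pytest

from alps_glymph import cohort_scoring as sc
import alps_glymph as ag


@pytest.fixture
def four_subjects():
    return pd.DataFrame(
        {
            "wms_vr_dr": [10.0, 12.0, 8.0, 6.0],
            "avlt_dr": [8.0, 9.0, 5.0, 4.0],
            "bnt": [26.0, 27.0, 22.0, 20.0],
            "cvf": [18.0, 20.0, 14.0, 12.0],
            "tmt_a": [40.0, 30.0, 60.0, 90.0],
            "tmt_b": [90.0, 80.0, 150.0, 200.0],
            "scwt_b": [50.0, 45.0, 70.0, 95.0],
            "scwt_c": [85.0, 80.0, 120.0, 160.0],
            "cdt": [9.0, 10.0, 7.0, 5.0],
            "vrt": [10.0, 11.0, 7.0, 4.0],
        }
    )


class TestInvertTimedScores:
    def test_negation_convention(self, four_subjects):
        out = sc.invert_timed_scores(four_subjects)
        assert out.loc[0, "tmt_a_inv"] == -40.0
        # order reverses: the slower subject scores lower
        assert out.loc[1, "tmt_a_inv"] > out.loc[0, "tmt_a_inv"]

    def test_non_timed_columns_untouched(self, four_subjects):
        out = sc.invert_timed_scores(four_subjects)
        pd.testing.assert_series_equal(out["bnt"], four_subjects["bnt"])

    def test_reciprocal_mode_preserves_ranking(self, four_subjects):
        neg = sc.invert_timed_scores(four_subjects, mode="negate")
        rec = sc.invert_timed_scores(four_subjects, mode="reciprocal")
        assert (
            neg["tmt_b_inv"].rank() == rec["tmt_b_inv"].rank()
        ).all()

    def test_non_positive_time_rejected(self, four_subjects):
        bad = four_subjects.copy()
        bad.loc[2, "scwt_b"] = 0.0
        with pytest.raises(ValueError, match="scwt_b"):
            sc.invert_timed_scores(bad)


class TestZTransformAndComposite:
    def test_whole_sample_standardization_identity(self, four_subjects):
        out = sc.z_transform_and_composite(four_subjects)
        for test in ("wms_vr_dr", "tmt_a_inv"):
            z = out[f"z_{test}"]
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_composites_match_hand_computed_means(self, four_subjects):
        """Each composite equals the hand-worked mean of its two z-scores."""
        out = sc.z_transform_and_composite(four_subjects)

        def z(col):
            x = four_subjects[col] if not col.endswith("_inv") else -four_subjects[col[:-4]]
            return (x - x.mean()) / x.std(ddof=1)

        hand = {
            "episodic_memory": (z("wms_vr_dr") + z("avlt_dr")) / 2,
            "language": (z("bnt") + z("cvf")) / 2,
            "processing_speed": (z("tmt_a_inv") + z("scwt_b_inv")) / 2,
            "executive": (z("tmt_b_inv") + z("scwt_c_inv")) / 2,
            "visuospatial": (z("cdt") + z("vrt")) / 2,
        }
        for domain, expected in hand.items():
            assert np.allclose(out[f"z_{domain}"], expected), domain

    def test_subject_at_reference_mean_scores_zero(self):
        df = pd.DataFrame({"wms_vr_dr": [5.0, 7.0, 9.0], "avlt_dr": [2.0, 4.0, 6.0]})
        out = sc.z_transform_and_composite(df)
        assert out.loc[1, "z_episodic_memory"] == pytest.approx(0.0, abs=1e-12)

    def test_z_transform_idempotent_in_distribution(self, four_subjects):
        once = sc.z_transform_and_composite(four_subjects)
        renamed = once[[f"z_{t}" for t in ("wms_vr_dr", "avlt_dr")]].rename(
            columns={"z_wms_vr_dr": "wms_vr_dr", "z_avlt_dr": "avlt_dr"}
        )
        twice = sc.z_transform_and_composite(renamed)
        assert np.allclose(twice["z_wms_vr_dr"], renamed["wms_vr_dr"])

    def test_missing_constituent_propagates_to_composite(self, four_subjects):
        df = four_subjects.copy()
        df.loc[2, "avlt_dr"] = np.nan
        out = sc.z_transform_and_composite(df)
        assert np.isnan(out.loc[2, "z_episodic_memory"])
        assert np.isfinite(out.loc[0, "z_episodic_memory"])

    def test_zero_variance_reference_rejected(self):
        df = pd.DataFrame({"wms_vr_dr": [5.0, 5.0, 5.0], "avlt_dr": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="wms_vr_dr"):
            sc.z_transform_and_composite(df)

    def test_nc_reference_leaves_nc_mean_zero(self, default_cohort):
        out = sc.z_transform_and_composite(default_cohort, reference="nc_group")
        nc = out[out["group"] == "NC"]
        assert nc["z_bnt"].mean() == pytest.approx(0.0, abs=1e-10)


class TestClassifyCognition:
    @pytest.mark.parametrize(
        "mmse, moca, cdr, adl, education, expected",
        [
            # dementia: MMSE at/below the education-adjusted cutoff with CDR >= 1
            (19, 10, 1.0, 10, 8, "VaD"),
            (24, 10, 1.0, 12, 8, "VaD"),   # boundary: 24 <= 24
            (25, 10, 1.0, 12, 8, "unclassifiable"),  # above cutoff, CDR 1
            (17, 8, 2.0, 14, 0, "VaD"),    # illiteracy cutoff 17
            (18, 8, 2.0, 14, 0, "unclassifiable"),
            (20, 9, 1.0, 10, 6, "VaD"),    # 1-6 years cutoff 20
            # MCI: MMSE above cutoff, MoCA at/below cutoff, CDR 0.5, ADL 8
            (28, 20, 0.5, 8, 10, "MCI"),
            (28, 24, 0.5, 8, 10, "MCI"),   # boundary: 24 <= 24
            (28, 25, 0.5, 8, 10, "unclassifiable"),  # MoCA above cutoff at CDR 0.5
            (28, 19, 0.5, 8, 6, "MCI"),    # 1-6 years MoCA cutoff 19
            (28, 13, 0.5, 8, 0, "MCI"),    # illiteracy MoCA cutoff 13
            (28, 20, 0.5, 9, 10, "unclassifiable"),  # ADL != 8
            # normal screening profile
            (29, 26, 0.0, 8, 10, "non-CI"),
            (25, 25, 0.0, 8, 10, "non-CI"),  # both just above cutoffs
            (29, 24, 0.0, 8, 10, "unclassifiable"),  # MoCA at cutoff, CDR 0
            (29, 26, 0.5, 8, 10, "unclassifiable"),  # normal scores but CDR 0.5
            (21, 20, 0.0, 8, 6, "non-CI"),  # above cutoff 20, MoCA above 19
            (21, 19, 0.5, 8, 6, "MCI"),
        ],
    )
    def test_rule_grid(self, mmse, moca, cdr, adl, education, expected):
        record = {"mmse": mmse, "moca": moca, "cdr": cdr, "adl": adl, "education": education}
        assert sc.classify_cognition(record) == expected

    def test_partition_every_record_gets_exactly_one_label(self, rng):
        labels = {"VaD", "MCI", "non-CI", "unclassifiable"}
        for _ in range(500):
            rec = {
                "mmse": int(rng.integers(0, 31)),
                "moca": int(rng.integers(0, 31)),
                "cdr": float(rng.choice([0, 0.5, 1, 2, 3])),
                "adl": int(rng.integers(8, 20)),
                "education": int(rng.integers(0, 20)),
            }
            assert sc.classify_cognition(rec) in labels

    def test_missing_fields_listed(self):
        with pytest.raises(ValueError, match="moca"):
            sc.classify_cognition({"mmse": 28, "cdr": 0, "adl": 8, "education": 10})

    def test_synthetic_labels_recovered_at_default_noise(self, default_cohort):
        """The generated screening scores reproduce the intended group for
        >= 95% of subjects at the default label-noise level."""
        out = sc.classification_agreement(default_cohort)
        assert out["label_agrees"].mean() >= 0.95
        # disagreements, if any, are flagged rather than dropped
        assert len(out) == len(default_cohort)

    def test_one_line_21_moca_check(self):
        # MoCA 20 with 10 years of education is below the >24 cutoff: MCI profile
        rec = {"mmse": 28, "moca": 20, "cdr": 0.5, "adl": 8, "education": 10}
        assert sc.classify_cognition(rec) == "MCI"


class TestTransformMarkers:
    def test_zero_count_maps_to_zero(self):
        df = pd.DataFrame({"li_count": [0], "cmb_count": [0], "wmh_volume": [0.0]})
        out = sc.transform_markers(df)
        assert out.loc[0, "log_li"] == 0.0
        assert out.loc[0, "log_cmb"] == 0.0
        assert out.loc[0, "log_wmh"] == 0.0

    def test_log10_with_offset(self):
        df = pd.DataFrame({"wmh_volume": [9.0], "li_count": [9], "cmb_count": [99]})
        out = sc.transform_markers(df)
        assert out.loc[0, "log_wmh"] == pytest.approx(1.0)
        assert out.loc[0, "log_li"] == pytest.approx(1.0)
        assert out.loc[0, "log_cmb"] == pytest.approx(2.0)

    def test_epvs_coded_binary(self):
        df = pd.DataFrame({"epvs_bg": [True, False]})
        out = sc.transform_markers(df)
        assert out["epvs"].tolist() == [1, 0]

    def test_negative_marker_rejected(self):
        with pytest.raises(ValueError, match="wmh_volume"):
            sc.transform_markers(pd.DataFrame({"wmh_volume": [-1.0]}))
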