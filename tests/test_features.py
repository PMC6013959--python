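"""Feature pipeline: windowed value expressions, note-section selection,
bag-of-words filtering, 1-of-K + min-max encoding, and the total-KL
variable filter with its brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from readmitnet.cohort import LabeledAdmission, label_readmissions
from readmitnet.features import (FeatureSpec, MinMaxZeroEncoder, TotalKLDivergenceSelector,
                                 Expression, Window, build_bow, encode_and_scale,
                                 extract_windowed_features, select_note_sections,
                                 total_kl_divergence)
from readmitnet.synthetic import NoteSection
from conftest import make_stay


def _labeled(rec, prior=0):
    return LabeledAdmission(record=rec, is_countable=True,
                            cumulative_prior_30day_readmissions=prior)


# -- windows ------------------------------------------------------------------

def test_lab_event_outside_admit_week_not_counted():
    rec = make_stay(admit=0, discharge=20,
                    lab_events=[("L1", 8, True),   # day 8: outside [0, 7]
                                ("L1", 3, True),   # inside admit-side window
                                ("L1", 15, True),  # inside discharge-side window
                                ("L1", 2, False)])  # normal result never counts
    t = extract_windowed_features([_labeled(rec)])
    assert t.loc[0, "lab_L1_admit7"] == 1.0
    assert t.loc[0, "lab_L1_dis7"] == 1.0


def test_diagnosis_within_two_years_binary():
    rec = make_stay(admit=1000, discharge=1005,
                    diagnosis_codes=[("D1", 1005 - 365), ("D2", 1005 - 900)])
    t = extract_windowed_features([_labeled(rec)])
    assert t.loc[0, "dx_D1"] == 1.0
    assert "dx_D2" not in t.columns  # outside the 2-year window for every row


def test_medication_counts_within_stay():
    rec = make_stay(admit=0, discharge=10,
                    medication_events=[("M1", 1), ("M1", 2), ("M1", 9), ("M2", 11)])
    t = extract_windowed_features([_labeled(rec)])
    assert t.loc[0, "rx_M1"] == 3.0
    assert "rx_M2" not in t.columns


def test_code_lookup_mapping_and_passthrough():
    rec = make_stay(admit=0, discharge=5,
                    medication_events=[("drugA", 1), ("drugB", 2)])
    t = extract_windowed_features([_labeled(rec)],
                                  lookups={"medications": {"drugA": "ATC1"}})
    assert t.loc[0, "rx_ATC1"] == 1.0
    assert t.loc[0, "rx_drugB"] == 1.0  # unmapped codes pass through


def test_unknown_lookup_data_type_errors():
    with pytest.raises(ValueError, match="unknown data type"):
        extract_windowed_features([_labeled(make_stay())], lookups={"potions": {}})


def test_cumulative_readmission_feature_present():
    t = extract_windowed_features([_labeled(make_stay(), prior=3)])
    assert t.loc[0, "adm_cumulative_prior_30day_readmissions"] == 3.0
    assert t.loc[0, "adm_length_of_stay"] == 5.0


def test_feature_spec_rejects_off_table_combinations():
    FeatureSpec("los", "admissions", Window.admit_to_discharge, Expression.continuous)
    with pytest.raises(ValueError):
        FeatureSpec("bad", "diagnoses", Window.admit_plus_7d, Expression.continuous)
    with pytest.raises(ValueError, match="unknown data type"):
        FeatureSpec("bad", "potions", Window.admit_to_discharge, Expression.continuous)


# -- note sections and BOW ----------------------------------------------------

def _note_stay(sections, admit=0):
    ns = [NoteSection("discharge_summary", s, admit + 1, list(toks))
          for s, toks in sections.items()]
    return make_stay(admit=admit, discharge=admit + 5, note_sections=ns)


@pytest.mark.parametrize("present,total,kept", [(5, 10, True), (4, 10, False),
                                                (10, 10, True)])
def test_section_presence_threshold(present, total, kept):
    labeled = []
    for i in range(total):
        secs = {"course": ["a"]}
        if i < present:
            secs["extra"] = ["b"]
        labeled.append(_labeled(_note_stay(secs, admit=i * 100)))
    retained = select_note_sections(labeled)
    assert ("extra" in retained["discharge_summary"]) is kept


def test_empty_notes_give_empty_selection():
    assert select_note_sections([_labeled(make_stay())]) == {}


def test_bow_corpus_frequency_filter():
    docs = [["rare"] * 5 + ["kept"] * 3, ["kept"] * 3]
    bow = build_bow(docs)  # total counts: rare=5 (dropped), kept=6
    assert "w_cnt_rare" not in bow.columns
    assert bow["w_cnt_kept"].tolist() == [3.0, 3.0]
    assert bow["w_bin_kept"].tolist() == [1.0, 1.0]


def test_bow_empty_document_is_all_zero():
    bow = build_bow([["tok"] * 6, []])
    assert bow.iloc[1].sum() == 0.0


def test_bow_normalizer_hook():
    docs = [["UPPER"] * 6, ["upper"] * 6]
    bow = build_bow(docs)
    assert bow["w_cnt_upper"].tolist() == [6.0, 6.0]
    drop_all = build_bow(docs, normalizer=lambda t: None)
    assert drop_all.shape[1] == 0


# -- encoding and scaling -----------------------------------------------------

def test_minmax_affine_endpoints():
    fm = encode_and_scale(pd.DataFrame({"x": [2.0, 4.0, 6.0]}))
    assert fm.values[:, 0].tolist() == [0.0, 0.5, 1.0]


def test_one_of_k_expansion():
    fm = encode_and_scale(pd.DataFrame({"c": ["A", "B", "C"]}))
    assert fm.columns == ["c=A", "c=B", "c=C"]
    assert fm.values[1].tolist() == [0.0, 1.0, 0.0]


def test_all_missing_column_becomes_zeros():
    fm = encode_and_scale(pd.DataFrame({"x": [np.nan, np.nan], "y": [1.0, 2.0]}))
    assert fm.values[:, 0].tolist() == [0.0, 0.0]


def test_scaling_idempotence(small_cohort):
    labeled = label_readmissions(small_cohort)[:150]
    raw = extract_windowed_features(labeled)
    first = encode_and_scale(raw)
    second = encode_and_scale(pd.DataFrame(first.values, columns=first.columns))
    np.testing.assert_allclose(first.values, second.values, atol=1e-12)
    assert first.values.min() >= 0.0 and first.values.max() <= 1.0


def test_transform_clips_unseen_values_to_unit_interval():
    enc = MinMaxZeroEncoder().fit(pd.DataFrame({"x": [0.0, 10.0]}))
    out = enc.transform(pd.DataFrame({"x": [-5.0, 20.0]}))
    assert out.ravel().tolist() == [0.0, 1.0]


# -- total KL divergence ------------------------------------------------------

def test_kl_hand_value_binary_08_vs_02():
    """Class rates 0.8 vs 0.2 give D = 2 * 0.6 * ln 4 ~= 1.6636."""
    col = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8, dtype=float)
    y = np.array([1] * 10 + [0] * 10)
    rep = total_kl_divergence(col[:, None], y)
    assert rep.divergence[0] == pytest.approx(2 * 0.6 * math.log(4), abs=1e-4)


def test_kl_identical_distributions_near_zero():
    col = np.array([1, 0] * 10, dtype=float)
    y = np.array([1, 1, 0, 0] * 5)
    rep = total_kl_divergence(col[:, None], y)
    assert rep.divergence[0] == pytest.approx(0.0, abs=1e-6)


def test_kl_threshold_and_mask_match_brute_force(rng):
    """tau = mean + sd/2 and the keep mask recomputed independently."""
    X = (rng.random((80, 8)) < rng.random(8)).astype(float)
    y = (rng.random(80) < 0.4).astype(int)
    rep = total_kl_divergence(X, y)
    D = []
    for j in range(8):
        p = (X[y == 1, j].sum() + 1e-9) / ((y == 1).sum() + 2e-9)
        q = (X[y == 0, j].sum() + 1e-9) / ((y == 0).sum() + 2e-9)
        kl = lambda a, b: a * math.log(a / b) + (1 - a) * math.log((1 - a) / (1 - b))
        D.append(kl(p, q) + kl(q, p))
    D = np.array(D)
    tau = D.mean() + 0.5 * D.std()
    np.testing.assert_allclose(rep.divergence, D, rtol=1e-6)
    assert rep.threshold == pytest.approx(tau, rel=1e-6)
    np.testing.assert_array_equal(rep.keep_mask, D >= tau)


def test_kl_symmetry_under_label_swap(rng):
    X = rng.random((60, 5))
    y = (rng.random(60) < 0.5).astype(int)
    a = total_kl_divergence(X, y).divergence
    b = total_kl_divergence(X, 1 - y).divergence
    np.testing.assert_allclose(a, b, rtol=1e-9)
    assert (a >= 0).all()


def test_kl_filter_shift_invariance():
    """Adding a constant to every divergence shifts tau equally, leaving the
    keep decisions unchanged."""
    D = np.array([0.1, 0.5, 0.9, 0.2, 0.05])
    for c in (0.0, 1.0, 10.0):
        Dc = D + c
        tau = Dc.mean() + 0.5 * Dc.std()
        np.testing.assert_array_equal(Dc >= tau, D >= D.mean() + 0.5 * D.std())


def test_kl_single_class_errors():
    with pytest.raises(ValueError):
        total_kl_divergence(np.zeros((4, 2)), np.ones(4))


def test_kl_selector_ranks_planted_signal_above_noise(rng):
    n = 2000
    y = (rng.random(n) < 0.3).astype(int)
    signal = (rng.random(n) < np.where(y == 1, 0.7, 0.2)).astype(float)
    noise = (rng.random((n, 5)) < 0.4).astype(float)
    X = np.column_stack([signal, noise])
    sel = TotalKLDivergenceSelector().fit(X, y)
    assert sel.divergence_[0] > sel.divergence_[1:].max()
    assert sel.get_support()[0]
    assert sel.transform(X).shape[1] == sel.get_support().sum()


def test_pipeline_retains_planted_columns(small_cohort):
    """End-to-end: planted diagnosis/event signal earns higher divergence
    than the bulk of pure-noise columns."""
    labeled = label_readmissions(small_cohort)
    raw = extract_windowed_features(labeled)
    countable = [l for l in labeled if l.is_countable]
    yv = np.array([l.label for l in countable])
    fm = encode_and_scale(raw, yv)
    rep = total_kl_divergence(fm.values, fm.labels)
    # covariate 0 (weight 1.5) materializes as diagnosis code C000
    j = fm.columns.index("dx_C000")
    assert rep.divergence[j] > np.median(rep.divergence)
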