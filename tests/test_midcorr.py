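"""Natural-abundance correction matrices and MID recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pyrtrace.chem import FragmentSpec, isotopologue_distribution, parse_formula
from pyrtrace.midcorr import (
    MID,
    MeasuredDistribution,
    build_correction_matrix,
    convolve_mid,
    correct_area_table,
    correct_mid,
)

from conftest import enumerate_isotopologue_distribution


@pytest.fixture(scope="module")
def lactate_cm(library):
    return build_correction_matrix(library["lactate"])


class TestBuildCorrectionMatrix:
    def test_no_natural_abundance_gives_identity(self, zero_abundance_table):
        frag = FragmentSpec("bare", parse_formula("C3"), 3, 100.0, 4)
        cm = build_correction_matrix(frag, zero_abundance_table)
        assert cm.matrix == pytest.approx(np.eye(4), abs=1e-15)

    def test_column0_is_unlabeled_pattern(self, library, table, lactate_cm):
        pat = isotopologue_distribution(library["lactate"].formula, table,
                                        5).probs
        assert lactate_cm.matrix[:, 0] == pytest.approx(pat, abs=1e-15)

    def test_column3_is_reduced_formula_shifted(self, table, lactate_cm):
        # fixing 3 carbons as 13C removes them from the convolution and
        # shifts the pattern up 3 channels
        want = enumerate_isotopologue_distribution(
            parse_formula("C8H25O3Si2"), table, 2)
        assert lactate_cm.matrix[:3, 3] == pytest.approx(0.0, abs=0.0)
        assert lactate_cm.matrix[3:, 3] == pytest.approx(want, abs=1e-9)

    def test_columns_sum_below_one(self, library):
        for met in ("pyruvate", "glucose_C456", "succinate"):
            cm = build_correction_matrix(library[met])
            assert (cm.matrix >= 0).all()
            assert (cm.matrix.sum(axis=0) <= 1 + 1e-12).all()


class TestCorrectMid:
    def test_unlabeled_input(self, library, lactate_cm):
        meas = MeasuredDistribution(library["lactate"],
                                    lactate_cm.matrix[:, 0])
        mid = correct_mid(meas, lactate_cm)
        assert mid.fractions == pytest.approx([1, 0, 0, 0], abs=1e-9)

    def test_two_state_mixture(self, library, lactate_cm):
        areas = 0.6 * lactate_cm.matrix[:, 0] + 0.4 * lactate_cm.matrix[:, 3]
        mid = correct_mid(MeasuredDistribution(library["lactate"], areas),
                          lactate_cm)
        assert mid.fractions == pytest.approx([0.6, 0, 0, 0.4], abs=1e-9)

    def test_noisy_recovery(self, library, lactate_cm):
        rng = np.random.default_rng(11)
        true = np.array([0.5, 0.3, 0.1, 0.1])
        clean = lactate_cm.matrix @ true
        noisy = clean * rng.lognormal(0, 0.01, size=len(clean))
        mid = correct_mid(MeasuredDistribution(library["lactate"], noisy),
                          lactate_cm)
        assert mid.fractions == pytest.approx(true, abs=0.02)

    def test_scale_invariance(self, library, lactate_cm):
        areas = lactate_cm.matrix @ np.array([0.25, 0.25, 0.25, 0.25])
        a = correct_mid(MeasuredDistribution(library["lactate"], areas),
                        lactate_cm)
        b = correct_mid(MeasuredDistribution(library["lactate"], areas * 37.0),
                        lactate_cm)
        assert a.fractions == pytest.approx(b.fractions, abs=1e-12)

    def test_monotone_noise_response(self, library, lactate_cm):
        true = np.array([0.4, 0.2, 0.2, 0.2])
        clean = lactate_cm.matrix @ true
        errs = []
        for cv in (0.0, 0.01, 0.05):
            rng = np.random.default_rng(5)
            err = 0.0
            for _ in range(40):
                noisy = clean * rng.lognormal(0, cv, size=len(clean)) \
                    if cv else clean
                mid = correct_mid(
                    MeasuredDistribution(library["lactate"], noisy),
                    lactate_cm)
                err += np.abs(mid.fractions - true).mean()
            errs.append(err / 40)
        assert errs[0] < errs[1] < errs[2]

    def test_all_zero_measurement_rejected(self, library):
        with pytest.raises(ValueError):
            MeasuredDistribution(library["lactate"], np.zeros(5))

    def test_rank_deficient_matrix_raises(self, library, lactate_cm):
        broken = type(lactate_cm)(library["lactate"],
                                  np.zeros_like(lactate_cm.matrix))
        meas = MeasuredDistribution(library["lactate"], np.ones(5))
        with pytest.raises(np.linalg.LinAlgError):
            correct_mid(meas, broken)


class TestConvolveMid:
    def test_pure_m0_gives_column0(self, lactate_cm):
        out = convolve_mid(np.array([1.0, 0, 0, 0]), lactate_cm)
        assert out.areas == pytest.approx(lactate_cm.matrix[:, 0], abs=0.0)

    def test_identity_table_pads_mid(self, zero_abundance_table):
        frag = FragmentSpec("bare", parse_formula("C3"), 3, 100.0, 4)
        cm = build_correction_matrix(frag, zero_abundance_table)
        mid = np.array([0.1, 0.2, 0.3, 0.4])
        assert convolve_mid(mid, cm).areas == pytest.approx(mid, abs=1e-15)

    def test_linear_combination(self, lactate_cm):
        out = convolve_mid(np.array([0.6, 0, 0, 0.4]), lactate_cm)
        want = 0.6 * lactate_cm.matrix[:, 0] + 0.4 * lactate_cm.matrix[:, 3]
        assert out.areas == pytest.approx(want, abs=1e-15)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
           st.sampled_from(["pyruvate", "lactate", "glucose_C456"]))
    def test_round_trip_recovers_mid(self, library, raw, met):
        mid = np.array(raw) / np.sum(raw)
        cm = build_correction_matrix(library[met])
        back = correct_mid(convolve_mid(mid, cm), cm)
        assert back.fractions == pytest.approx(mid, abs=1e-9)
        assert back.fractions.sum() == pytest.approx(1.0, abs=1e-12)


class TestCorrectAreaTable:
    def test_tidy_round_trip(self, library):
        import pandas as pd
        cm = build_correction_matrix(library["pyruvate"])
        mid = np.array([0.55, 0.05, 0.05, 0.35])
        areas = (cm.matrix @ mid) * 2.3e6
        df = pd.DataFrame({
            "sample_id": "s1", "metabolite": "pyruvate",
            "channel_index": np.arange(5), "area": areas,
        })
        out = correct_area_table(df)
        assert list(out["isotopologue"]) == ["M0", "M1", "M2", "M3"]
        assert out["fraction"].to_numpy() == pytest.approx(mid, abs=1e-9)

    def test_unknown_metabolite_raises(self):
        import pandas as pd
        df = pd.DataFrame({"sample_id": ["s1"], "metabolite": ["nonesuch"],
                           "channel_index": [0], "area": [1.0]})
        with pytest.raises(KeyError):
            correct_area_table(df)
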