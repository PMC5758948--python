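import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import acodopt
from acodopt.snr import (NegativeResponseWarning, effects_table,
                         level_mean_snr, optimal_formulation, round_half_up,
                         snr_ltb, snr_ltb_from_moments, snr_ntb, snr_stb,
                         snr_table)

from conftest import SNR_BGP, SNR_BMP, SNR_CODS, BGP_MEAN, BGP_SD


# --- per-run S/N ----------------------------------------------------------

@pytest.mark.parametrize("values, expected", [
    ([140.11], 42.93),            # single-replicate run: 20*log10(y)
    ([100.0, 200.0], 42.04),      # -10*log10((1e-4 + 2.5e-5)/2)
    ([1.0], 0.0),
])
def test_snr_ltb_examples(values, expected):
    assert round_half_up(snr_ltb(values)) == pytest.approx(expected)


def test_snr_ltb_squaring_discards_sign_with_warning():
    """A negative response scores like its absolute value, loudly."""
    with pytest.warns(NegativeResponseWarning):
        val = snr_ltb([-263.42])
    assert round_half_up(val) == 48.41
    assert val == snr_ltb([263.42])


def test_snr_ltb_negative_policies():
    with pytest.warns(NegativeResponseWarning):
        lit = snr_ltb([-50.0, 100.0], negative_policy="literal")
    excl = snr_ltb([-50.0, 100.0], negative_policy="exclude")
    assert excl == snr_ltb([100.0])
    floor = snr_ltb([-50.0, 100.0], negative_policy="floor", floor_eps=1e-6)
    assert floor < lit  # the floored tiny value dominates 1/y^2


def test_snr_ltb_errors():
    with pytest.raises(ValueError):
        snr_ltb([])
    with pytest.raises(ZeroDivisionError):
        snr_ltb([10.0, 0.0])


@pytest.mark.parametrize("mean, sd, expected", [
    (167.39, 16.92, 44.34),
    (240.01, 5.25, 47.60),
])
def test_snr_moment_approximation_examples(mean, sd, expected):
    assert round_half_up(snr_ltb_from_moments(mean, sd)) == expected


@given(m=st.floats(0.1, 1e5))
@settings(max_examples=100, deadline=None)
def test_moment_approximation_zero_sd_equals_single_value(m):
    assert snr_ltb_from_moments(m, 0.0) == pytest.approx(snr_ltb([m]))
    assert snr_ltb_from_moments(m, 0.0) == pytest.approx(20 * math.log10(m))


def test_moment_approximation_rejects_nonpositive_mean():
    with pytest.raises(ValueError):
        snr_ltb_from_moments(0.0, 1.0)
    with pytest.raises(ValueError):
        snr_ltb_from_moments(-10.0, 1.0)


def test_snr_stb_examples():
    assert snr_stb([1.0]) == pytest.approx(0.0)
    assert snr_stb([10.0]) == pytest.approx(-20.0)


def test_snr_ntb_example():
    # sample with mean 10, sd 1 -> 10*log10(100/1) = 20 dB
    vals = [9.0, 10.0, 11.0]
    assert np.std(vals, ddof=1) == pytest.approx(1.0)
    assert snr_ntb(vals) == pytest.approx(20.0)


@given(
    values=st.lists(st.floats(0.1, 1e4), min_size=1, max_size=6),
    c=st.floats(0.01, 100.0),
)
@settings(max_examples=150, deadline=None)
def test_snr_ltb_scale_equivariance(values, c):
    """Scaling every replicate by c adds exactly 20*log10(c) dB."""
    base = snr_ltb(values)
    scaled = snr_ltb([c * v for v in values])
    assert scaled == pytest.approx(base + 20 * math.log10(c), abs=1e-8)


def test_snr_ltb_increasing_in_each_magnitude():
    vals = [50.0, 80.0, 120.0]
    base = snr_ltb(vals)
    for i in range(3):
        bumped = list(vals)
        bumped[i] *= 1.1
        assert snr_ltb(bumped) > base


# --- level means and effects ---------------------------------------------

def test_level_mean_examples_from_printed_snr(printed_snr, design):
    b3 = level_mean_snr(printed_snr, design, "B", 3, "bgp_ml_per_gvs")
    a1 = level_mean_snr(printed_snr, design, "A", 1, "bgp_ml_per_gvs")
    assert round_half_up(b3) == 31.00
    assert round_half_up(a1) == 37.21


def test_level_mean_matches_brute_force_oracle(design):
    """Grouped mean equals an independently coded group-by on random tables."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        snr = pd.DataFrame(
            rng.normal(35.0, 8.0, (9, 2)),
            index=pd.RangeIndex(1, 10, name="run_id"),
            columns=["r1", "r2"],
        )
        for f in "ABCD":
            for level in (1, 2, 3):
                for resp in ("r1", "r2"):
                    acc, n = 0.0, 0
                    for run in range(1, 10):
                        if design.levels(run)["ABCD".index(f)] == level:
                            acc += snr.loc[run, resp]
                            n += 1
                    assert n == 3
                    assert level_mean_snr(snr, design, f, level, resp) == (
                        pytest.approx(acc / n)
                    )


def test_constant_snr_table_gives_constant_level_means(design):
    snr = pd.DataFrame({"r": [7.5] * 9}, index=pd.RangeIndex(1, 10))
    for f in "ABCD":
        for level in (1, 2, 3):
            assert level_mean_snr(snr, design, f, level, "r") == 7.5


def test_effects_ranks_reproduce_published_order(printed_effects):
    assert printed_effects.ranks("bgp_ml_per_gvs") == {
        "A": 4, "B": 1, "C": 3, "D": 2}
    assert printed_effects.ranks("bmp_ml_per_gvs") == {
        "A": 4, "B": 1, "C": 3, "D": 2}
    assert printed_effects.ranks("cods_removal_pct") == {
        "A": 4, "B": 2, "C": 1, "D": 3}


def test_effects_balance_identity(printed_snr, design, printed_effects):
    """Mean of the nine S/N values equals the mean of any factor's level means."""
    for resp in printed_snr.columns:
        overall = printed_snr[resp].mean()
        for f in "ABCD":
            level_means = [printed_effects.level_mean(resp, f, l)
                           for l in (1, 2, 3)]
            assert np.mean(level_means) == pytest.approx(overall)


def test_effects_constant_table_tie_breaking(design):
    snr = pd.DataFrame({"r": [5.0] * 9}, index=pd.RangeIndex(1, 10))
    eff = effects_table(snr, design)
    assert eff.ranks("r") == {"A": 1, "B": 2, "C": 3, "D": 4}
    assert optimal_formulation(eff, "r").designation == "A1B1C1D1"
    assert (eff.table["range"] == 0).all()


def test_effects_requires_complete_table(design):
    snr = pd.DataFrame({"r": [5.0] * 8}, index=pd.RangeIndex(1, 9))
    with pytest.raises(ValueError):
        effects_table(snr, design)


def test_optimal_formulations_match_study(printed_effects):
    assert optimal_formulation(
        printed_effects, "bgp_ml_per_gvs").designation == "A2B1C2D1"
    assert optimal_formulation(
        printed_effects, "bmp_ml_per_gvs").designation == "A2B1C2D1"
    assert optimal_formulation(
        printed_effects, "cods_removal_pct").designation == "A1B3C3D3"


def test_snr_table_from_run_table_reconstructs_bgp_cells(run_table):
    """Moment reconstruction lands within 0.02 dB of every published BGP cell."""
    with pytest.warns(NegativeResponseWarning):
        table = snr_table(run_table)
    got = table["bgp_ml_per_gvs"].to_numpy()
    assert np.max(np.abs(got - SNR_BGP)) < 0.02


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(2.675) == 2.68
    assert round_half_up(31.005) == 31.01
    assert round_half_up(-2.675) == -2.68
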