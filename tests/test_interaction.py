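"""Hill block and two-drug combination models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtddi.interaction import (
    CHANNELS,
    ChannelInhibitionVector,
    HillParams,
    InteractionModel,
    block_from_concentration,
    combine_bliss,
    combine_channels,
    combine_loewe,
    combine_sum,
    hill_inhibition,
    load_drug_table,
)

fractions = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
open_fractions = st.floats(min_value=1e-6, max_value=1.0 - 1e-6)


class TestHill:
    @pytest.mark.parametrize(
        "conc, ic50, n, expected",
        [
            (1.0, 1.0, 1.0, 0.5),     # midpoint of the curve
            (0.0, 1.0, 1.0, 0.0),     # no drug, no block
            (0.0, 7.3, 2.4, 0.0),
            (3.0, 1.0, 2.0, 0.9),     # 9 / (1 + 9)
        ],
    )
    def test_examples(self, conc, ic50, n, expected):
        assert hill_inhibition(conc, HillParams(ic50, n)) == pytest.approx(expected, abs=1e-12)

    def test_midpoint_is_half_for_any_params(self):
        for ic50 in (0.01, 1.0, 300.0):
            for n in (0.5, 1.0, 3.7):
                assert hill_inhibition(ic50, HillParams(ic50, n)) == pytest.approx(0.5)

    def test_strictly_increasing_and_bounded(self):
        params = HillParams(2.0, 1.7)
        concs = np.logspace(-4, 4, 60)
        vals = [hill_inhibition(c, params) for c in concs]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_rejects_bad_concentration(self, bad):
        with pytest.raises(ValueError):
            hill_inhibition(bad, HillParams(1.0))

    @pytest.mark.parametrize("ic50, n", [(0.0, 1.0), (-2.0, 1.0), (1.0, 0.0), (1.0, -1.0)])
    def test_rejects_bad_params(self, ic50, n):
        with pytest.raises(ValueError):
            HillParams(ic50, n)


class TestCombiners:
    @pytest.mark.parametrize(
        "fn, ea, eb, expected",
        [
            (combine_sum, 0.2, 0.3, 0.5),
            (combine_sum, 0.7, 0.6, 1.0),
            (combine_sum, 0.0, 0.4, 0.4),
            (combine_bliss, 0.5, 0.5, 0.75),
            (combine_bliss, 0.3, 0.0, 0.3),
            (combine_bliss, 1.0, 0.6, 1.0),
            (combine_loewe, 0.5, 0.5, 0.5 / 0.75),
            (combine_loewe, 0.4, 0.0, 0.4),
            (combine_loewe, 0.9, 0.9, 0.18 / 0.19),
        ],
    )
    def test_examples(self, fn, ea, eb, expected):
        assert fn(ea, eb) == pytest.approx(expected, abs=1e-12)

    def test_loewe_full_block_continuity(self):
        # 0/0 corner defined as 1 by continuity
        assert combine_loewe(1.0, 1.0) == 1.0
        assert combine_loewe(1.0 - 1e-9, 1.0 - 1e-9) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("fn", [combine_sum, combine_bliss, combine_loewe])
    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan")])
    def test_rejects_out_of_range(self, fn, bad):
        with pytest.raises(ValueError):
            fn(bad, 0.5)
        with pytest.raises(ValueError):
            fn(0.5, bad)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(open_fractions, open_fractions)
    def test_ordering_loewe_bliss_sum(self, ea, eb):
        # strict interior ordering: dose addition <= independence <= capped sum
        assert combine_loewe(ea, eb) <= combine_bliss(ea, eb) <= combine_sum(ea, eb)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(fractions, fractions)
    def test_symmetry_and_bounds(self, ea, eb):
        for fn in (combine_sum, combine_bliss, combine_loewe):
            v1, v2 = fn(ea, eb), fn(eb, ea)
            assert v1 == v2
            assert 0.0 <= v1 <= 1.0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(fractions)
    def test_identity_with_zero_partner(self, e):
        for fn in (combine_sum, combine_bliss, combine_loewe):
            assert fn(e, 0.0) == e

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(fractions, fractions, st.floats(min_value=0.0, max_value=0.2))
    def test_monotone_in_each_argument(self, ea, eb, bump):
        ea2 = min(ea + bump, 1.0)
        for fn in (combine_sum, combine_bliss, combine_loewe):
            assert fn(ea2, eb) >= fn(ea, eb) - 1e-12

    def test_loewe_hill_dose_addition_closed_form(self):
        # for n = 1 and a shared IC50, Loewe combination of the individual
        # blocks equals the Hill block of the summed dose, exactly
        params = HillParams(ic50=1.3, hill_n=1.0)
        grid = np.logspace(-3, 2, 25)
        for ca in grid:
            for cb in grid:
                ea = hill_inhibition(ca, params)
                eb = hill_inhibition(cb, params)
                assert combine_loewe(ea, eb) == pytest.approx(
                    hill_inhibition(ca + cb, params), abs=1e-12
                )


class TestChannelVector:
    def test_identity_against_zero_vector(self):
        zero = ChannelInhibitionVector()
        b = ChannelInhibitionVector(IKr=0.3, IKs=0.1, INa=0.6, ICaL=0.9)
        for model in InteractionModel:
            assert combine_channels(zero, b, model) == b

    def test_elementwise_bliss(self):
        a = ChannelInhibitionVector(IKr=0.5)
        out = combine_channels(a, a, InteractionModel.BLISS)
        assert out.IKr == pytest.approx(0.75)
        assert (out.IKs, out.INa, out.ICaL) == (0.0, 0.0, 0.0)

    def test_sum_caps_every_channel(self):
        a = ChannelInhibitionVector(IKr=0.6, IKs=0.6, INa=0.6, ICaL=0.6)
        out = combine_channels(a, a, InteractionModel.SUM)
        assert out.as_array().tolist() == [1.0, 1.0, 1.0, 1.0]

    def test_rejects_out_of_range_entries(self):
        with pytest.raises(ValueError):
            ChannelInhibitionVector(IKr=1.5)
        with pytest.raises(ValueError):
            ChannelInhibitionVector.from_mapping({"IK1": 0.5})


class TestDrugTable:
    def test_load_and_block(self, tmp_path):
        path = tmp_path / "drugs.csv"
        path.write_text(
            "drug,channel,ic50_uM,hill_n\n"
            "drugA,IKr,1.0,1.0\n"
            "drugA,ICaL,10.0,2.0\n"
        )
        table = load_drug_table(path)
        assert set(table["drugA"]) == {"IKr", "ICaL"}
        block = block_from_concentration(1.0, table["drugA"])
        assert block.IKr == pytest.approx(0.5)
        # missing channels mean no block
        assert block.IKs == 0.0 and block.INa == 0.0

    def test_rejects_unknown_channel(self, tmp_path):
        path = tmp_path / "drugs.csv"
        path.write_text("drug,channel,ic50_uM,hill_n\ndrugA,IK1,1.0,1.0\n")
        with pytest.raises(ValueError, match="IK1"):
            load_drug_table(path)

    def test_rejects_missing_columns(self, tmp_path):
        path = tmp_path / "drugs.csv"
        path.write_text("drug,channel\ndrugA,IKr\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_drug_table(path)
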