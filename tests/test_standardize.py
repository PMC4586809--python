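import numpy as np
import pandas as pd
import pytest

import arealdisp as ad
from arealdisp.standardize import StandardizationError

from conftest import make_panel


def panel_from_counts(y, n, cancer="c", group=None, area=None):
    """One-year panel from parallel count/population arrays."""
    k = len(y)
    group = group if group is not None else [0] * k
    area = area if area is not None else [f"a{i}" for i in range(k)]
    df = pd.DataFrame(
        {
            "cancer": cancer,
            "area_id": area,
            "year": 2000,
            "group": group,
            "count": y,
            "population": n,
        }
    )
    return ad.ArealPanel(df)


class TestStatewideRates:
    def test_pooled_rate(self):
        panel = panel_from_counts([60, 40], [4000, 6000])
        rates = ad.statewide_rates(panel)
        assert rates["rate"].iloc[0] == pytest.approx(100 / 10_000)

    def test_groups_rated_independently(self):
        panel = panel_from_counts([10, 30], [1000, 1000], group=[0, 1], area=["a0", "a0"])
        rates = ad.statewide_rates(panel).set_index("group")["rate"]
        assert rates[0] == pytest.approx(0.01)
        assert rates[1] == pytest.approx(0.03)

    def test_zero_person_years_rejected(self):
        panel = panel_from_counts([0, 0], [0, 0])
        with pytest.raises(StandardizationError):
            ad.statewide_rates(panel)

    def test_all_zero_counts_give_zero_rate_and_undefined_sirs(self):
        panel = panel_from_counts([0, 0], [100, 200])
        rates = ad.statewide_rates(panel)
        assert (rates["rate"] == 0).all()
        table = ad.sir(panel, ad.expected_counts(panel, rates))
        assert not table.data["defined"].any()


class TestExpectedCounts:
    def test_cellwise_product(self):
        panel = panel_from_counts([5, 0], [1000, 0])
        rates = pd.DataFrame({"cancer": ["c"], "group": [0], "rate": [0.01]})
        e = ad.expected_counts(panel, rates).values.to_numpy()
        assert e == pytest.approx([10.0, 0.0])

    def test_missing_rate_key_rejected(self):
        panel = panel_from_counts([1, 1], [10, 10], group=[0, 1], area=["a0", "a0"])
        rates = pd.DataFrame({"cancer": ["c"], "group": [0], "rate": [0.01]})
        with pytest.raises(StandardizationError):
            ad.expected_counts(panel, rates)

    def test_conservation_on_random_panel(self):
        panel = make_panel(n_areas=6, n_years=3, seed=3, covariates=False)
        rates = ad.statewide_rates(panel)
        e = ad.expected_counts(panel, rates)
        df = panel.data.assign(e=e.values.to_numpy())
        for (_, _), sub in df.groupby(["cancer", "group"]):
            assert sub["e"].sum() == pytest.approx(sub["count"].sum(), rel=1e-12)


class TestSir:
    def test_examples(self):
        panel = panel_from_counts([10, 0, 3], [100, 100, 0])
        rates = pd.DataFrame({"cancer": ["c"], "group": [0], "rate": [0.1]})
        table = ad.sir(panel, ad.expected_counts(panel, rates))
        out = table.data
        assert out["sir"].iloc[0] == pytest.approx(1.0)
        assert out["sir"].iloc[1] == pytest.approx(0.0)
        assert not out["defined"].iloc[2]

    def test_scale_invariance(self):
        panel = make_panel(n_areas=5, n_years=2, seed=8, covariates=False)
        scaled = ad.ArealPanel(
            panel.data.assign(
                count=panel.data["count"] * 7, population=panel.data["population"] * 7
            )
        )
        s1 = ad.sir(panel, ad.expected_counts(panel, ad.statewide_rates(panel)))
        s2 = ad.sir(scaled, ad.expected_counts(scaled, ad.statewide_rates(scaled)))
        np.testing.assert_allclose(
            s1.data["sir"].to_numpy(), s2.data["sir"].to_numpy(), rtol=1e-12
        )

    def test_monotone_in_count(self):
        panel = panel_from_counts([4, 9], [100, 100])
        rates = pd.DataFrame({"cancer": ["c"], "group": [0], "rate": [0.05]})
        e = ad.expected_counts(panel, rates)
        bumped = ad.ArealPanel(panel.data.assign(count=[5, 9]))
        s0 = ad.sir(panel, e).data["sir"].iloc[0]
        s1 = ad.sir(bumped, e).data["sir"].iloc[0]
        assert s1 > s0


class TestSirRatio:
    def _table(self, y_f, e_f, y_r, e_r):
        k = len(y_f)
        df = pd.DataFrame(
            {
                "cancer": "c",
                "area_id": [f"a{i}" for i in range(k)] * 2,
                "year": 2000,
                "group": [1] * k + [0] * k,
                "count": list(y_f) + list(y_r),
                "population": 100,
                "expected": list(e_f) + list(e_r),
            }
        )
        df["sir"] = df["count"] / df["expected"]
        df["defined"] = df["expected"] > 0
        return ad.SirTable(df)

    def test_symmetry_gives_unity(self):
        t = self._table([3, 5], [4, 4], [3, 5], [4, 4])
        assert ad.sir_ratio_by_year(t)["sir_ratio"].iloc[0] == pytest.approx(1.0)

    def test_doubled_focal_sirs_give_two(self):
        t = self._table([6, 10], [4, 4], [3, 5], [4, 4])
        assert ad.sir_ratio_by_year(t)["sir_ratio"].iloc[0] == pytest.approx(2.0)

    def test_two_county_hand_computation(self):
        # focal: y=(2,0), e=(1,1); reference: y=(1,1), e=(1,1)
        # mean SIR_focal = (2+0)/2 = 1, mean SIR_ref = 1, ratio 1
        t = self._table([2, 0], [1, 1], [1, 1], [1, 1])
        out = ad.sir_ratio_by_year(t)
        assert out["mean_sir_focal"].iloc[0] == pytest.approx(1.0)
        assert out["mean_sir_reference"].iloc[0] == pytest.approx(1.0)
        assert out["sir_ratio"].iloc[0] == pytest.approx(1.0)

    def test_mean_of_ratios_option(self):
        t = self._table([2, 2], [1, 1], [1, 4], [1, 1])
        out = ad.sir_ratio_by_year(t, method="mean-of-ratios")
        assert out["sir_ratio"].iloc[0] == pytest.approx((2 / 1 + 2 / 4) / 2)

    def test_single_group_rejected(self):
        panel = panel_from_counts([1, 1], [10, 10])
        table = ad.sir(panel, ad.expected_counts(panel, ad.statewide_rates(panel)))
        with pytest.raises(StandardizationError):
            ad.sir_ratio_by_year(table)


def test_site_distribution_shares():
    out = ad.site_distribution({"x": 30, "y": 70})
    shares = out.set_index("site")["percent"]
    assert shares["x"] == pytest.approx(30.0)
    assert shares["y"] == pytest.approx(70.0)
    assert out.set_index("site")["count"]["__total__"] == 100
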