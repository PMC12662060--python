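"""Severity indices: breakdowns, BRI, prevalence, density, BSI, mortality."""

import numpy as np
import pytest

from reefbleach.errors import UndefinedIndexError
from reefbleach.indices import (
    bri,
    bsi,
    category_breakdown,
    density,
    mortality_change,
    prevalence,
    site_bri,
    summary_tables,
)
from reefbleach.survey_io import CATEGORY_CODES, SiteDesign, SurveyDesign
from conftest import make_dataset


def breakdown_from_counts(counts, period="during"):
    """A one-site dataset realising the given C1..C6 counts."""
    rows = [
        ("S", "S1", period, "q1", "Acropora", code, n)
        for code, n in zip(CATEGORY_CODES, counts)
        if n > 0
    ]
    ds = make_dataset(rows)
    return category_breakdown(ds, period=period)


class TestCategoryBreakdown:
    def test_counts_to_percentages(self):
        bd = breakdown_from_counts((10, 5, 5, 0, 0, 0))
        assert bd.n_total == 20
        assert bd.percentages == (50.0, 25.0, 25.0, 0.0, 0.0, 0.0)

    def test_single_dead_colony(self):
        bd = breakdown_from_counts((0, 0, 0, 0, 0, 1))
        assert bd.percentages == (0.0, 0.0, 0.0, 0.0, 0.0, 100.0)

    def test_empty_stratum_is_flagged_not_an_error(self, toy_dataset):
        bd = category_breakdown(toy_dataset, period="after")
        assert bd.empty
        assert bd.n_total == 0
        assert bd.percentages is None

    def test_percentages_sum_to_100(self, small_dataset):
        bd = category_breakdown(small_dataset, period="during")
        assert sum(bd.percentages) == pytest.approx(100.0)


class TestBRI:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((100, 0, 0, 0, 0, 0), 0.0),  # all healthy
            ((0, 0, 0, 0, 0, 100), 100.0),  # all dead
            ((10, 5, 5, 0, 0, 0), 15.0),  # (0*50 + 1*25 + 2*25)/5
            ((0, 0, 0, 0, 100, 0), 80.0),  # all extreme: 4*100/5
        ],
    )
    def test_hand_computed_values(self, counts, expected):
        assert bri(breakdown_from_counts(counts)) == pytest.approx(expected)

    def test_empty_breakdown_raises(self, toy_dataset):
        with pytest.raises(UndefinedIndexError):
            bri(category_breakdown(toy_dataset, period="after"))

    def test_bounds_on_random_breakdowns(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            counts = rng.integers(0, 40, size=6)
            if counts.sum() == 0:
                continue
            assert 0.0 <= bri(breakdown_from_counts(tuple(counts))) <= 100.0

    def test_monotone_under_worsening(self):
        """Moving any colony to a higher-weight category never lowers BRI."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            counts = rng.integers(0, 20, size=6)
            counts[0] += 1  # ensure non-empty and movable
            base = bri(breakdown_from_counts(tuple(counts)))
            src = rng.choice(np.flatnonzero(counts[:5]))
            dst = rng.integers(src + 1, 6)
            worse = counts.copy()
            worse[src] -= 1
            worse[dst] += 1
            assert bri(breakdown_from_counts(tuple(worse))) >= base - 1e-9


class TestSiteBRI:
    def test_pooled_half_dead_site(self):
        rows = [
            ("S", "S1", "during", "q1", "Acropora", "C1", 50),
            ("S", "S1", "during", "q1", "Galaxea", "C6", 50),
        ]
        assert site_bri(make_dataset(rows), "S", "during") == pytest.approx(50.0)

    def test_all_healthy_site_is_zero(self):
        rows = [("S", "S1", "during", "q1", "Acropora", "C1", 30)]
        assert site_bri(make_dataset(rows), "S", "during") == 0.0

    def test_pooling_identity(self, small_dataset):
        """Site BRI = colony-weighted mean of genus BRIs (index linearity)."""
        for site in small_dataset.design.site_names:
            for period in small_dataset.periods:
                sub = small_dataset.subset(site=site, period=period)
                if sub.empty:
                    continue
                acc = n_tot = 0.0
                for genus in sub["genus"].unique():
                    bd = category_breakdown(
                        small_dataset, site=site, period=period, genus=genus
                    )
                    acc += bri(bd) * bd.n_total
                    n_tot += bd.n_total
                assert site_bri(small_dataset, site, period) == pytest.approx(
                    acc / n_tot
                )


class TestPrevalence:
    def test_hand_computed(self):
        assert prevalence(breakdown_from_counts((10, 5, 5, 0, 0, 0))) == 50.0

    def test_all_healthy_zero(self):
        assert prevalence(breakdown_from_counts((30, 0, 0, 0, 0, 0))) == 0.0

    def test_dead_in_denominator_only(self):
        # 10 healthy, 10 bleached, 20 dead: prevalence counts the dead in
        # the denominator but not the numerator.
        assert prevalence(breakdown_from_counts((10, 10, 0, 0, 0, 20))) == 25.0

    def test_partition_of_shares(self, small_dataset):
        """prevalence + healthy share + dead share = 100."""
        bd = category_breakdown(small_dataset, period="during")
        healthy = bd.percentages[0]
        dead = bd.percentages[5]
        assert prevalence(bd) + healthy + dead == pytest.approx(100.0)


class TestDensity:
    def test_constant_quadrats(self):
        design = SurveyDesign((SiteDesign("S", ("S1",), quadrats_per_station=20),))
        rows = [
            ("S", "S1", "during", f"q{i}", "Acropora", "C1", 15) for i in range(20)
        ]
        mean, se = density(make_dataset(rows, design), period="during")
        assert (mean, se) == (15.0, 0.0)

    def test_two_quadrats_hand_computed(self):
        design = SurveyDesign((SiteDesign("S", ("S1",), quadrats_per_station=2),))
        rows = [
            ("S", "S1", "during", "q1", "Acropora", "C1", 10),
            ("S", "S1", "during", "q2", "Acropora", "C1", 20),
        ]
        mean, se = density(make_dataset(rows, design), period="during")
        assert mean == pytest.approx(15.0)
        assert se == pytest.approx(5.0)

    def test_unsurveyed_quadrats_count_as_zero(self):
        design = SurveyDesign((SiteDesign("S", ("S1",), quadrats_per_station=4),))
        rows = [("S", "S1", "during", "q1", "Acropora", "C1", 8)]
        mean, _ = density(make_dataset(rows, design), period="during")
        assert mean == pytest.approx(2.0)  # 8 colonies over 4 designed quadrats

    def test_quadrat_area_scales_density(self):
        design = SurveyDesign(
            (SiteDesign("S", ("S1",), quadrats_per_station=2, quadrat_area_m2=4.0),)
        )
        rows = [
            ("S", "S1", "during", "q1", "Acropora", "C1", 10),
            ("S", "S1", "during", "q2", "Acropora", "C1", 20),
        ]
        mean, _ = density(make_dataset(rows, design), period="during")
        assert mean == pytest.approx(15.0 / 4.0)

    def test_empty_stratum_errors(self):
        design = SurveyDesign((SiteDesign("S", ("S1",),),))
        ds = make_dataset([("S", "S1", "during", "q1", "Acropora", "C1", 1)], design)
        with pytest.raises(UndefinedIndexError):
            density(ds, site="Nowhere", period="during")


class TestBSI:
    def test_two_genera_no_exclusion(self):
        # A: 60 colonies, half C1 half C6 -> BRI 50; B: 40 colonies,
        # half C1 half C2 -> BRI 10.  D in percent: (60, 40).
        rows = [
            ("S", "S1", "during", "q1", "Acropora", "C1", 30),
            ("S", "S1", "during", "q1", "Acropora", "C6", 30),
            ("S", "S1", "during", "q1", "Galaxea", "C1", 20),
            ("S", "S1", "during", "q1", "Galaxea", "C2", 20),
        ]
        value, n_genera = bsi(make_dataset(rows), "S", "during")
        assert n_genera == 2
        assert value == pytest.approx((50 * 60 + 10 * 40) / 2)  # 1700.0

    def test_min_n_exclusion(self):
        # A: 60 colonies BRI 50; B: 37 colonies (30 C1 + 7 C3), so
        # BRI_B * D_B = (2 * (7/37*100) / 5) * 37 = 280 exactly;
        # C: 3 colonies all C6, BRI 100, excluded by min_n=5 but still in
        # the relative-abundance denominator (total 100 colonies).
        rows = [
            ("S", "S1", "during", "q1", "Acropora", "C1", 30),
            ("S", "S1", "during", "q1", "Acropora", "C6", 30),
            ("S", "S1", "during", "q1", "Galaxea", "C1", 30),
            ("S", "S1", "during", "q1", "Galaxea", "C3", 7),
            ("S", "S1", "during", "q1", "Pavona", "C6", 3),
        ]
        ds = make_dataset(rows)
        value, n_genera = bsi(ds, "S", "during", min_n=5)
        assert n_genera == 2
        assert value == pytest.approx((50 * 60 + 280) / 2)  # 1640.0
        # Without the exclusion the rare all-dead genus joins the sum.
        value0, n0 = bsi(ds, "S", "during", min_n=0)
        assert n0 == 3
        assert value0 == pytest.approx((50 * 60 + 280 + 100 * 3) / 3)

    def test_single_qualifying_genus_all_healthy(self):
        rows = [("S", "S1", "during", "q1", "Acropora", "C1", 10)]
        value, n_genera = bsi(make_dataset(rows), "S", "during")
        assert (value, n_genera) == (0.0, 1)

    def test_single_genus_reduces_to_bri_times_100(self):
        rows = [
            ("S", "S1", "during", "q1", "Acropora", "C1", 6),
            ("S", "S1", "during", "q1", "Acropora", "C6", 6),
        ]
        ds = make_dataset(rows)
        value, _ = bsi(ds, "S", "during", min_n=0)
        assert value == pytest.approx(site_bri(ds, "S", "during") * 100.0)

    def test_no_qualifying_genus_errors(self):
        rows = [("S", "S1", "during", "q1", "Acropora", "C1", 2)]
        with pytest.raises(UndefinedIndexError):
            bsi(make_dataset(rows), "S", "during", min_n=5)


class TestMortalityChange:
    def test_hand_computed(self):
        rows = [
            ("S", "S1", "during", "q1", "Acropora", "C1", 95),
            ("S", "S1", "during", "q1", "Acropora", "C6", 5),
            ("S", "S1", "after", "q1", "Acropora", "C1", 183),
            ("S", "S1", "after", "q1", "Acropora", "C6", 17),
        ]
        # during 5.0% dead, after 8.5% dead
        assert mortality_change(make_dataset(rows)) == pytest.approx(3.5)

    def test_identical_breakdowns_give_zero(self):
        rows = [
            ("S", "S1", p, "q1", "Acropora", c, n)
            for p in ("during", "after")
            for c, n in (("C1", 9), ("C6", 1))
        ]
        assert mortality_change(make_dataset(rows)) == 0.0

    def test_antisymmetric_under_period_swap(self, small_dataset):
        forward = mortality_change(small_dataset)
        swapped = small_dataset.records.copy()
        swapped["period"] = swapped["period"].map(
            {"during": "after", "after": "during"}
        )
        backward = mortality_change(make_dataset(swapped, small_dataset.design))
        assert backward == pytest.approx(-forward)

    def test_missing_period_named_in_error(self, toy_dataset):
        with pytest.raises(UndefinedIndexError, match="after"):
            mortality_change(toy_dataset)


class TestSummaryTables:
    def test_genus_table_bookkeeping(self, small_dataset):
        genus_table, _ = summary_tables(small_dataset)
        assert len(genus_table) == len(set(small_dataset.records["genus"])) * 2
        assert int(genus_table["n"].sum()) == small_dataset.total_count
        # Ordered by total abundance over both periods, descending.
        totals = genus_table.groupby("genus", sort=False)["n"].sum()
        assert list(totals) == sorted(totals, reverse=True)

    def test_absent_taxon_period_flagged_not_zero(self):
        rows = [
            ("S", "S1", "during", "q1", "Acropora", "C3", 5),
            ("S", "S1", "after", "q1", "Galaxea", "C1", 5),
        ]
        genus_table, _ = summary_tables(make_dataset(rows))
        row = genus_table[
            (genus_table["genus"] == "Acropora") & (genus_table["period"] == "after")
        ].iloc[0]
        assert row["n"] == 0
        assert np.isnan(row["bri"])

    def test_site_table_shape_and_ranges(self, default_dataset):
        _, site_table = summary_tables(default_dataset)
        assert len(site_table) == 6 * 2  # sites x periods
        assert site_table["prevalence_pct"].between(0, 100).all()
        assert site_table["bri"].between(0, 100).all()
        assert (site_table["density"] >= 0).all()
        assert (site_table["bsi"] >= 0).all()

    def test_hydrocoral_exclusion_flag(self, default_dataset):
        with_h, _ = summary_tables(default_dataset, include_hydrocorals=True)
        without_h, _ = summary_tables(default_dataset, include_hydrocorals=False)
        assert "Millepora" in set(with_h["genus"])
        assert "Millepora" not in set(without_h["genus"])
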