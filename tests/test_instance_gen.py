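"""Synthetic geography, demand spreading, resource usage and the packaged
diagnosis-group table."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hosplan.domain import CareClass, FacilityType, VOCategory, ZipArea
from hosplan.instance_gen import (
    GeneratorConfig,
    build_travel_matrix,
    generate_usage,
    generate_zips,
    load_table2_fixture,
    make_instance,
    make_micro_instance,
    scaled_extent_km,
    select_candidate_sites,
    spread_demand,
)

from conftest import zero_usage


class TestFixture:
    def test_thirty_groups(self):
        groups = load_table2_fixture()
        assert len(groups) == 30
        assert [g.id for g in groups] == list(range(1, 31))

    def test_neoplasms_row(self):
        g = {g.name: g for g in load_table2_fixture()}["Neoplasms"]
        assert g.n_patients == 405124
        assert g.vo_category is VOCategory.HIGH
        assert g.max_travel_min == 120.0

    def test_diabetes_row(self):
        g = {g.name: g for g in load_table2_fixture()}["Diabetes"]
        assert g.n_patients == 17445
        assert g.vo_category is VOCategory.NONE
        assert g.max_travel_min == 45.0

    def test_excluded_row_available_outside_model_set(self):
        all_rows = load_table2_fixture(include_excluded=True)
        assert len(all_rows) == 31
        extra = [g for g in all_rows if g.id == 0]
        assert len(extra) == 1
        assert "ill-defined" in extra[0].name

    def test_colocation_ids_point_at_gynecology_and_obstetrics(self):
        by_id = {g.id: g for g in load_table2_fixture()}
        assert by_id[21].name == "Gynaecology"
        assert "pregnancy" in by_id[23].name.lower()


class TestZips:
    def test_count_and_positivity(self):
        zips = generate_zips(GeneratorConfig(n_zips=10, n_sites=5,
                                             n_sites_from_population_centers=2,
                                             seed=3))
        assert len(zips) == 10
        assert all(z.population > 0 for z in zips)

    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(n_zips=25, n_sites=10,
                              n_sites_from_population_centers=5, seed=9)
        assert generate_zips(cfg) == generate_zips(cfg)

    def test_total_population_normalized(self):
        cfg = GeneratorConfig(seed=4)
        total = sum(z.population for z in generate_zips(cfg))
        assert total == pytest.approx(cfg.total_population, rel=1e-9)


class TestSiteSelection:
    def test_saturation_gives_zero_travel(self):
        cfg = GeneratorConfig(n_zips=12, n_sites=12,
                              n_sites_from_population_centers=3,
                              coverage_minutes=0.0, seed=1)
        zips = generate_zips(cfg)
        sites = select_candidate_sites(zips, cfg)
        assert len(sites) == 12
        site_coords = {s.coords for s in sites}
        assert all(z.coords in site_coords for z in zips)

    def test_three_collinear_zips_median(self):
        zips = [ZipArea("a", 1.0, (0.0, 0.0)), ZipArea("b", 1.0, (10.0, 0.0)),
                ZipArea("c", 1.0, (20.0, 0.0))]
        cfg = GeneratorConfig(n_zips=3, n_sites=1,
                              n_sites_from_population_centers=0,
                              coverage_minutes=0.0, seed=0)
        sites = select_candidate_sites(zips, cfg)
        assert len(sites) == 1
        assert sites[0].coords == (10.0, 0.0)  # middle beats either end

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_k1_matches_exhaustive_median(self, seed):
        cfg = GeneratorConfig(n_zips=11, n_sites=1,
                              n_sites_from_population_centers=0,
                              coverage_minutes=0.0, seed=seed)
        zips = generate_zips(cfg)
        zx = np.array([z.coords for z in zips])
        w = np.array([z.population for z in zips])
        costs = [
            (w * np.linalg.norm(zx - zx[i], axis=1)).sum() for i in range(len(zips))
        ]
        best = zx[int(np.argmin(costs))]
        sites = select_candidate_sites(zips, cfg)
        assert sites[0].coords == tuple(best)

    def test_deterministic_and_coverage_guaranteed(self):
        cfg = GeneratorConfig(n_zips=60, n_sites=12,
                              n_sites_from_population_centers=7,
                              region_extent_km=scaled_extent_km(12), seed=5)
        zips = generate_zips(cfg)
        s1 = select_candidate_sites(zips, cfg)
        s2 = select_candidate_sites(zips, cfg)
        assert s1 == s2
        tt = build_travel_matrix(zips, s1, cfg)
        assert tt.minutes.min(axis=1).max() <= cfg.coverage_minutes


class TestTravelMatrix:
    def test_distance_speed_arithmetic(self):
        cfg = GeneratorConfig(n_zips=2, n_sites=2,
                              n_sites_from_population_centers=0,
                              road_factor=1.0, speed_kmh=60.0,
                              travel_noise_sd_min=0.0, seed=0)
        zips = [ZipArea("a", 1.0, (0.0, 0.0)), ZipArea("b", 1.0, (60.0, 0.0))]
        from hosplan.domain import CandidateSite
        sites = [CandidateSite("s0", (0.0, 0.0)), CandidateSite("s1", (60.0, 0.0))]
        tt = build_travel_matrix(zips, sites, cfg)
        assert tt.minutes[0, 1] == pytest.approx(60.0)
        assert tt.minutes[0, 0] == 0.0  # co-located

    def test_entries_finite_nonnegative(self):
        cfg = GeneratorConfig(n_zips=30, n_sites=8,
                              n_sites_from_population_centers=4,
                              region_extent_km=scaled_extent_km(8), seed=7)
        zips = generate_zips(cfg)
        sites = select_candidate_sites(zips, cfg)
        tt = build_travel_matrix(zips, sites, cfg).minutes
        assert np.all(np.isfinite(tt)) and np.all(tt >= 0)


class TestDemand:
    def test_proportional_split(self):
        from hosplan.domain import DiagnosisGroup
        g = DiagnosisGroup(id=1, name="g", care_class=CareClass.ACUTE,
                           vo_category=VOCategory.NONE, n_patients=100,
                           n_visits=2.0, max_travel_min=45.0, usage=zero_usage())
        zips = [ZipArea("a", 75.0, (0, 0)), ZipArea("b", 25.0, (1, 0))]
        demand = spread_demand([g], zips)
        assert demand[:, 0].tolist() == [75.0, 25.0]

    def test_single_zip_identity(self):
        from hosplan.domain import DiagnosisGroup
        g = DiagnosisGroup(id=1, name="g", care_class=CareClass.ACUTE,
                           vo_category=VOCategory.NONE, n_patients=977,
                           n_visits=2.0, max_travel_min=45.0, usage=zero_usage())
        demand = spread_demand([g], [ZipArea("a", 5.0, (0, 0))])
        assert demand[0, 0] == 977

    @given(pops=st.lists(st.floats(0.1, 1e6), min_size=1, max_size=12),
           n_patients=st.integers(1, 10**6))
    @settings(max_examples=60, deadline=None)
    def test_exact_conservation(self, pops, n_patients):
        from hosplan.domain import DiagnosisGroup
        g = DiagnosisGroup(id=1, name="g", care_class=CareClass.ACUTE,
                           vo_category=VOCategory.NONE, n_patients=n_patients,
                           n_visits=2.0, max_travel_min=45.0, usage=zero_usage())
        zips = [ZipArea(f"z{i}", p, (float(i), 0.0)) for i, p in enumerate(pops)]
        demand = spread_demand([g], zips)
        assert demand[:, 0].sum() == n_patients
        assert np.all(demand >= 0)


class TestUsage:
    def test_chronic_groups_have_no_or_or_icu(self):
        groups = load_table2_fixture()
        usage = generate_usage(groups, seed=2)
        for g in groups:
            if g.care_class is CareClass.CHRONIC:
                assert usage[(FacilityType.OR, g.id)] == 0.0
                assert usage[(FacilityType.ICU, g.id)] == 0.0

    def test_nonnegative_and_deterministic(self):
        groups = load_table2_fixture()
        u1 = generate_usage(groups, seed=5)
        u2 = generate_usage(groups, seed=5)
        assert u1 == u2
        assert all(v >= 0 for v in u1.values())


class TestFullPipeline:
    def test_generated_instance_satisfies_invariants(self):
        cfg = GeneratorConfig(n_zips=20, n_sites=8,
                              n_sites_from_population_centers=5,
                              region_extent_km=scaled_extent_km(8), seed=6)
        inst = make_instance(cfg)
        # Instance.__post_init__ validates; spot-check the key facts
        assert inst.n_zips == 20 and inst.n_sites == 8 and inst.n_groups == 30
        assert inst.colocate_pairs == [(21, 23)]
        np.testing.assert_allclose(
            inst.demand.sum(axis=0), [g.n_patients for g in inst.groups])

    def test_micro_instance_deterministic(self):
        a = make_micro_instance(seed=3, with_minima=True)
        b = make_micro_instance(seed=3, with_minima=True)
        assert a.equals(b)
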