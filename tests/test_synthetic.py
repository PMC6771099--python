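"""Gravity-model generator: geometry, destination choice, sampling."""

import math

import numpy as np
import pandas as pd
import pytest

import flowregions as fr
from flowregions.io import ValidationError


def _units_from_rows(rows):
    frame = pd.DataFrame(
        rows,
        columns=[
            "unit_id", "name", "lat", "lon", "population", "beds",
            "designated_region", "micro_region",
        ],
    )
    return fr.UnitTable(frame)


class TestGenerateUnits:
    def test_counts_and_memberships(self):
        sc = fr.SyntheticScenario(n_units=60, n_designated=26, seed=1)
        units = fr.generate_units(sc)
        assert len(units) == 60
        assert len(units.designated_units) == 26
        assert sc.hub_unit in units.designated_units
        micro = units.micro_region_members()
        assert set().union(*micro.values()) == units.designated_units

    def test_hub_holds_stated_bed_and_population_shares(self):
        sc = fr.drs13_like(seed=7)
        units = fr.generate_units(sc)
        f = units.frame
        desig = list(units.designated_units)
        bed_share = f.at[sc.hub_unit, "beds"] / f.loc[desig, "beds"].sum()
        pop_share = f.at[sc.hub_unit, "population"] / f.loc[desig, "population"].sum()
        assert bed_share == pytest.approx(sc.hub_bed_share, abs=0.01)
        assert pop_share == pytest.approx(sc.hub_population_share, abs=0.01)

    def test_full_hub_bed_share_leaves_no_other_hospitals(self):
        sc = fr.SyntheticScenario(n_units=10, n_designated=5, hub_bed_share=1.0, seed=2)
        units = fr.generate_units(sc)
        assert units.hospital_units == {sc.hub_unit}

    def test_deterministic_under_seed(self):
        sc = fr.SyntheticScenario(seed=5)
        a = fr.generate_units(sc).frame
        b = fr.generate_units(sc).frame
        pd.testing.assert_frame_equal(a, b)

    def test_more_designated_than_units_rejected(self):
        with pytest.raises(ValidationError):
            fr.SyntheticScenario(n_units=10, n_designated=11)


class TestGravityProbabilities:
    def test_two_equidistant_equal_bed_destinations_split_evenly(self):
        units = _units_from_rows(
            [
                ("O", "Origin", 0.0, 0.0, 1000, 0, "", ""),
                ("L", "Left", 0.0, -0.5, 1000, 50, "", ""),
                ("R", "Right", 0.0, 0.5, 1000, 50, "", ""),
            ]
        )
        sc = fr.SyntheticScenario(
            n_units=3, n_designated=3, hub_unit="U001",
            local_preference=1.0, hub_preference=1.0,
        )
        p = fr.gravity_probabilities(sc, units)
        assert p.loc["O", "L"] == pytest.approx(0.5)
        assert p.loc["O", "R"] == pytest.approx(0.5)

    def test_decay_free_limit_proportional_to_beds(self):
        units = _units_from_rows(
            [
                ("O", "Origin", 0.0, 0.0, 1000, 0, "", ""),
                ("L", "Left", 1.0, -1.0, 1000, 30, "", ""),
                ("R", "Right", -1.0, 1.5, 1000, 90, "", ""),
            ]
        )
        sc = fr.SyntheticScenario(
            n_units=3, n_designated=3, decay_scale_km=1e9,
            attraction_exponent=1.0, local_preference=1.0, hub_preference=1.0,
        )
        p = fr.gravity_probabilities(sc, units)
        assert p.loc["O", "L"] == pytest.approx(0.25, abs=1e-6)
        assert p.loc["O", "R"] == pytest.approx(0.75, abs=1e-6)

    def test_exponential_decay_at_known_distances(self):
        # hospitals 10 km and 20 km due north; decay scale 10 km
        km_per_deg = 2 * math.pi * 6371.0088 / 360
        units = _units_from_rows(
            [
                ("O", "Origin", 0.0, 0.0, 1000, 0, "", ""),
                ("N1", "Near", 10 / km_per_deg, 0.0, 1000, 40, "", ""),
                ("N2", "Far", 20 / km_per_deg, 0.0, 1000, 40, "", ""),
            ]
        )
        sc = fr.SyntheticScenario(
            n_units=3, n_designated=3, decay_scale_km=10.0,
            attraction_exponent=1.0, local_preference=1.0, hub_preference=1.0,
        )
        p = fr.gravity_probabilities(sc, units)
        expected = math.exp(-1) / (math.exp(-1) + math.exp(-2))
        assert p.loc["O", "N1"] == pytest.approx(expected, abs=1e-4)  # 0.7311
        assert p.loc["O", "N2"] == pytest.approx(1 - expected, abs=1e-4)  # 0.2689

    def test_rows_sum_to_one(self):
        sc = fr.drs13_like(seed=3)
        units = fr.generate_units(sc)
        p = fr.gravity_probabilities(sc, units)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_no_beds_anywhere_is_an_error(self):
        units = _units_from_rows([("O", "Origin", 0.0, 0.0, 1000, 0, "", "")])
        with pytest.raises(ValidationError, match="beds"):
            fr.gravity_probabilities(fr.SyntheticScenario(n_units=1, n_designated=1), units)


class TestGenerateAdmissions:
    def test_case_count_arithmetic(self):
        units = _units_from_rows(
            [
                ("O", "Origin", 0.0, 0.0, 10_000, 0, "", ""),
                ("H", "Hosp", 0.1, 0.1, 100, 50, "", ""),
            ]
        )
        sc = fr.SyntheticScenario(
            n_units=2, n_designated=2, birth_rate=0.015, episodes_per_birth=1.0, seed=1
        )
        records = [r for r in fr.generate_admissions(sc, units) if r.residence_unit == "O"]
        assert len(records) == 150

    def test_total_records_match_expected_counts(self):
        sc = fr.SyntheticScenario(n_units=12, n_designated=6, seed=4)
        units = fr.generate_units(sc)
        records = fr.generate_admissions(sc, units)
        expected = sum(
            int(round(p * sc.birth_rate * sc.episodes_per_birth))
            for p in units.frame["population"]
        )
        assert len(records) == expected

    def test_deterministic_under_seed(self):
        sc = fr.SyntheticScenario(n_units=8, n_designated=4, seed=9)
        units = fr.generate_units(sc)
        assert fr.generate_admissions(sc, units) == fr.generate_admissions(sc, units)

    def test_single_destination_universe(self):
        units = _units_from_rows(
            [
                ("O", "Origin", 0.0, 0.0, 2_000, 0, "", ""),
                ("H", "Hosp", 0.1, 0.1, 100, 50, "", ""),
            ]
        )
        sc = fr.SyntheticScenario(n_units=2, n_designated=2, seed=1)
        records = fr.generate_admissions(sc, units)
        assert records and all(r.hospital_unit == "H" for r in records)

    def test_adding_bedless_unit_preserves_existing_draws(self):
        base_rows = [
            ("O", "Origin", 0.0, 0.0, 5_000, 0, "", ""),
            ("H1", "HospA", 0.2, 0.0, 100, 40, "", ""),
            ("H2", "HospB", 0.0, 0.2, 100, 40, "", ""),
        ]
        sc = fr.SyntheticScenario(n_units=3, n_designated=3, seed=6)
        before = fr.generate_admissions(sc, _units_from_rows(base_rows))
        extended = base_rows + [("Z", "NoBeds", 1.0, 1.0, 0, 0, "", "")]
        after = fr.generate_admissions(sc, _units_from_rows(extended))
        assert [r for r in after if r.residence_unit == "O"] == [
            r for r in before if r.residence_unit == "O"
        ]

    def test_empirical_shares_converge_to_gravity_probabilities(self):
        units = _units_from_rows(
            [
                ("O", "Origin", 0.0, 0.0, 1_000_000, 0, "", ""),
                ("H1", "HospA", 0.2, 0.0, 100, 40, "", ""),
                ("H2", "HospB", 0.0, 0.3, 100, 80, "", ""),
                ("H3", "HospC", -0.3, 0.1, 100, 20, "", ""),
            ]
        )
        sc = fr.SyntheticScenario(
            n_units=4, n_designated=4, birth_rate=0.015, episodes_per_birth=1.0, seed=11
        )
        p = fr.gravity_probabilities(sc, units).loc["O"]
        records = [r for r in fr.generate_admissions(sc, units) if r.residence_unit == "O"]
        assert len(records) >= 10_000
        emp = pd.Series([r.hospital_unit for r in records]).value_counts(normalize=True)
        emp = emp.reindex(p.index, fill_value=0.0)
        assert (emp - p).abs().max() < 0.02

    def test_hub_preference_monotonically_raises_hub_inflow(self):
        shares = []
        for eta in (1.0, 2.0, 4.0):
            sc = fr.SyntheticScenario(
                n_units=15, n_designated=8, hub_preference=eta, seed=21
            )
            units = fr.generate_units(sc)
            p = fr.gravity_probabilities(sc, units)
            pop = units.frame["population"]
            expected_hub = (p[sc.hub_unit] * pop).sum() / pop.sum()
            shares.append(expected_hub)
        assert shares[0] < shares[1] < shares[2]
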