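"""Internal-standard/protein normalization, compositions, FAME path."""

import numpy as np
import pandas as pd
import pytest

from spherolipid.quantify import (
    DegenerateSample,
    InternalStandardMap,
    InvalidProtein,
    MissingStandard,
    PeakTable,
    class_composition,
    default_internal_standards,
    fame_composition,
    is_normalize,
    lipidome_to_fa_profile,
    protein_normalize,
    species_composition,
)


def _small_table(intensities: dict, classes: dict, standards: set):
    samples = list(next(iter(intensities.values())).keys())
    idx = pd.Index(list(intensities), name="feature")
    return PeakTable(
        intensities=pd.DataFrame(
            {s: [intensities[f][s] for f in idx] for s in samples}, index=idx
        ),
        features=pd.DataFrame(
            {
                "species": list(idx),
                "lipid_class": [classes[f] for f in idx],
                "is_standard": [f in standards for f in idx],
            },
            index=idx,
        ),
        samples=pd.DataFrame(
            {"group": ["Adherent", "Sphere"], "protein_ug": [1.0, 1.0]},
            index=pd.Index(samples, name="sample"),
        ),
    )


@pytest.fixture
def pc_tg_table():
    return _small_table(
        intensities={
            "PC(34:1)": {"s1": 500.0, "s2": 100.0},
            "TG(52:2)": {"s1": 250.0, "s2": 400.0},
            "PC(17:0/17:0)": {"s1": 500.0, "s2": 200.0},
            "TG(17:0/17:0/17:0)": {"s1": 500.0, "s2": 800.0},
        },
        classes={
            "PC(34:1)": "PC",
            "TG(52:2)": "TG",
            "PC(17:0/17:0)": "PC",
            "TG(17:0/17:0/17:0)": "TG",
        },
        standards={"PC(17:0/17:0)", "TG(17:0/17:0/17:0)"},
    )


class TestIsNormalize:
    def test_ratio_identity_and_spike_amounts(self, pc_tg_table):
        amounts = is_normalize(pc_tg_table, default_internal_standards())
        # PC feature at standard intensity -> the 400 ng spike amount
        assert amounts.loc["PC(34:1)", "s1"] == pytest.approx(400.0)
        # TG at half its 2,000 ng standard -> 1,000 ng
        assert amounts.loc["TG(52:2)", "s1"] == pytest.approx(1000.0)
        assert "TG(17:0/17:0/17:0)" not in amounts.index

    def test_per_sample_scaling_invariance(self, pc_tg_table):
        before = is_normalize(pc_tg_table, default_internal_standards())
        scaled = pc_tg_table.intensities.copy()
        scaled["s2"] *= 10.0
        table = PeakTable(
            intensities=scaled, features=pc_tg_table.features, samples=pc_tg_table.samples
        )
        after = is_normalize(table, default_internal_standards())
        pd.testing.assert_frame_equal(before, after)

    def test_feature_order_invariance(self, pc_tg_table):
        base = is_normalize(pc_tg_table, default_internal_standards())
        perm = pc_tg_table.intensities.index[::-1]
        table = PeakTable(
            intensities=pc_tg_table.intensities.loc[perm],
            features=pc_tg_table.features.loc[perm],
            samples=pc_tg_table.samples,
        )
        shuffled = is_normalize(table, default_internal_standards())
        pd.testing.assert_frame_equal(base.sort_index(), shuffled.sort_index())

    def test_missing_standard_names_class_and_sample(self, pc_tg_table):
        broken = pc_tg_table.intensities.copy()
        broken.loc["PC(17:0/17:0)", "s2"] = 0.0
        table = PeakTable(
            intensities=broken, features=pc_tg_table.features, samples=pc_tg_table.samples
        )
        with pytest.raises(MissingStandard, match="PC.*s2"):
            is_normalize(table, default_internal_standards())

    def test_unmapped_class_raises(self, pc_tg_table):
        with pytest.raises(MissingStandard):
            is_normalize(pc_tg_table, InternalStandardMap({"PC": ("PC(17:0/17:0)", 400.0)}))


class TestProteinNormalize:
    def test_identity_and_halving(self):
        amounts = pd.DataFrame({"s1": [10.0], "s2": [10.0]}, index=["PC(34:1)"])
        ident = protein_normalize(amounts, pd.Series({"s1": 1.0, "s2": 1.0}))
        pd.testing.assert_frame_equal(ident, amounts)
        halved = protein_normalize(amounts, pd.Series({"s1": 0.5, "s2": 2.0}))
        assert halved.loc["PC(34:1)", "s1"] == pytest.approx(20.0)
        assert halved.loc["PC(34:1)", "s2"] == pytest.approx(5.0)

    def test_zero_protein_rejected(self):
        amounts = pd.DataFrame({"s1": [10.0]}, index=["PC(34:1)"])
        with pytest.raises(InvalidProtein):
            protein_normalize(amounts, pd.Series({"s1": 0.0}))


class TestComposition:
    def test_single_class_is_100(self):
        amounts = pd.DataFrame({"s1": [3.0, 7.0]}, index=["a", "b"])
        classes = pd.Series({"a": "PC", "b": "PC"})
        out = class_composition(amounts, classes)
        assert out.loc["PC", "s1"] == pytest.approx(100.0)

    def test_equal_eight_classes(self):
        classes = ["LPC", "PC", "PC O-", "PE", "PE O-", "TG", "SM", "Cer"]
        amounts = pd.DataFrame({"s1": [5.0] * 8}, index=classes)
        out = class_composition(amounts, pd.Series(dict(zip(classes, classes))))
        assert np.allclose(out["s1"], 12.5)

    def test_degenerate_sample(self):
        amounts = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(DegenerateSample):
            class_composition(amounts, pd.Series({"a": "PC", "b": "PC"}))

    def test_within_class_sums_to_100_per_class(self):
        amounts = pd.DataFrame({"s1": [1.0, 3.0, 2.0, 2.0]}, index=list("abcd"))
        classes = pd.Series({"a": "PC", "b": "PC", "c": "TG", "d": "TG"})
        out = species_composition(amounts, classes, scope="within-class")
        assert out.loc[["a", "b"], "s1"].sum() == pytest.approx(100.0)
        assert out.loc[["c", "d"], "s1"].sum() == pytest.approx(100.0)

    def test_total_scope_aggregates_to_class_composition(self):
        amounts = pd.DataFrame({"s1": [1.0, 3.0, 6.0]}, index=list("abc"))
        classes = pd.Series({"a": "PC", "b": "PC", "c": "TG"})
        species_pct = species_composition(amounts, scope="total")
        class_pct = class_composition(amounts, classes)
        assert species_pct.loc[["a", "b"], "s1"].sum() == pytest.approx(
            class_pct.loc["PC", "s1"]
        )


class TestFame:
    def test_unit_rrf_recovers_spike_and_closure(self):
        areas = pd.DataFrame(
            {"s1": [100.0, 300.0, 100.0]}, index=["16:0", "18:1", "23:0"]
        )
        profile = fame_composition(areas, {"16:0": 1.0, "18:1": 1.0}, "23:0", 5.0)
        # 16:0 at the IS area with rrf 1 corresponds to 5 ug before closure
        assert profile.composition.loc["16:0", "s1"] == pytest.approx(25.0)
        assert profile.composition["s1"].sum() == pytest.approx(100.0)

    def test_global_area_scaling_invariance(self):
        areas = pd.DataFrame({"s1": [100.0, 300.0, 80.0]}, index=["16:0", "18:1", "23:0"])
        rrf = {"16:0": 0.9, "18:1": 1.1}
        a = fame_composition(areas, rrf, "23:0", 5.0).composition
        b = fame_composition(areas * 2.0, rrf, "23:0", 5.0).composition
        pd.testing.assert_frame_equal(a, b)

    def test_missing_rrf_warns_then_defaults(self):
        areas = pd.DataFrame({"s1": [100.0, 100.0]}, index=["16:0", "23:0"])
        with pytest.warns(UserWarning, match="no response factor"):
            profile = fame_composition(areas, {}, "23:0", 5.0)
        assert profile.composition.loc["16:0", "s1"] == pytest.approx(100.0)

    def test_missing_standard(self):
        areas = pd.DataFrame({"s1": [100.0]}, index=["16:0"])
        with pytest.raises(MissingStandard):
            fame_composition(areas, {}, "23:0", 5.0)


class TestLipidomeDecomposition:
    def test_tg_counting(self):
        amounts = pd.DataFrame({"s1": [9.0]}, index=["TG(16:0/16:0/18:1)"])
        profile = lipidome_to_fa_profile(amounts)
        assert profile.composition.loc["16:0", "s1"] == pytest.approx(200.0 / 3.0)
        assert profile.composition.loc["18:1", "s1"] == pytest.approx(100.0 / 3.0)

    def test_sum_only_species_excluded_with_warning(self):
        amounts = pd.DataFrame(
            {"s1": [5.0, 5.0]}, index=["PC(34:1)", "TG(16:0/16:0/18:1)"]
        )
        with pytest.warns(UserWarning, match="excluded"):
            profile = lipidome_to_fa_profile(amounts)
        assert profile.composition["s1"].sum() == pytest.approx(100.0)

    def test_sphingoid_base_and_ether_chains_not_counted(self):
        amounts = pd.DataFrame(
            {"s1": [1.0, 1.0]}, index=["Cer(d18:1/16:0)", "PC(O-16:0/18:1)"]
        )
        profile = lipidome_to_fa_profile(amounts)
        assert set(profile.composition.index) == {"16:0", "18:1"}

    def test_duplicate_sample_preserves_profile(self):
        amounts = pd.DataFrame(
            {"s1": [2.0, 3.0], "s2": [2.0, 3.0]},
            index=["TG(16:0/16:0/18:1)", "PE(16:0/18:1)"],
        )
        profile = lipidome_to_fa_profile(amounts)
        pd.testing.assert_series_equal(
            profile.composition["s1"], profile.composition["s2"], check_names=False
        )
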