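"""Dilution-curve efficiency, geNorm M stability, relative expression."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirshift.qpcr import (
    compare_groups,
    fit_dilution_series,
    read_plate,
    reference_stability,
    relative_expression,
    stars,
)


def _wells(gene, dil_ct_pairs):
    return pd.DataFrame(
        [{"sample": "std", "condition": "standard", "gene": gene,
          "dilution": d, "replicate": 1, "Ct": c} for d, c in dil_ct_pairs]
    )


class TestDilutionSeries:
    def test_perfect_doubling_gives_unit_efficiency(self):
        spacing = math.log2(10)
        wells = _wells("g", [(1e-2, 20.0), (1e-3, 20.0 + spacing), (1e-4, 20.0 + 2 * spacing)])
        fit = fit_dilution_series(wells)
        assert fit.efficiency == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.valid

    def test_shallow_slope_efficiency(self):
        wells = _wells("g", [(1e-2, 20.0), (1e-3, 23.6), (1e-4, 27.2)])
        fit = fit_dilution_series(wells)
        assert fit.efficiency == pytest.approx(10 ** (1 / 3.6) - 1, abs=1e-9)
        assert fit.efficiency == pytest.approx(0.8957, abs=1e-4)

    def test_two_dilutions_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_dilution_series(_wells("g", [(1e-2, 20.0), (1e-3, 23.3)]))

    def test_positive_slope_flagged_invalid(self):
        wells = _wells("g", [(1e-2, 24.0), (1e-3, 22.0), (1e-4, 20.0)])
        fit = fit_dilution_series(wells)
        assert not fit.valid
        assert math.isnan(fit.efficiency)


def _tidy(ct_wide: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sample, row in ct_wide.iterrows():
        for gene, ct in row.items():
            rows.append({"sample": sample, "condition": "control", "gene": gene, "Ct": ct})
    return pd.DataFrame(rows)


class TestReferenceStability:
    def test_covarying_pair_has_minimal_m(self, rng):
        base = rng.normal(25, 2, 8)
        wide = pd.DataFrame(
            {
                "stable1": base,
                "stable2": base + 1.3,            # perfectly covarying
                "wild": rng.normal(25, 2, 8),     # independent
            },
            index=[f"s{i}" for i in range(8)],
        )
        m = reference_stability(_tidy(wide))
        assert list(m.index[:2]) == sorted(["stable1", "stable2"], key=lambda g: m.loc[g, "M"])
        assert m.loc["stable1", "M"] < m.loc["wild", "M"]
        assert m.loc["stable1", "M"] == pytest.approx(m.loc["stable2", "M"])

    def test_matches_brute_force_on_random_table(self, rng):
        wide = pd.DataFrame(
            rng.normal(25, 3, (8, 4)), columns=list("abcd"),
            index=[f"s{i}" for i in range(8)],
        )
        m = reference_stability(_tidy(wide))
        # independent recomputation: sd over samples of every pairwise
        # log2-ratio; expression = -Ct at E = 1
        expr = -wide
        for j in "abcd":
            sds = [np.std(expr[j] - expr[k], ddof=1) for k in "abcd" if k != j]
            assert m.loc[j, "M"] == pytest.approx(np.mean(sds), abs=1e-12)

    def test_invariant_under_per_gene_additive_offsets(self, rng):
        wide = pd.DataFrame(rng.normal(25, 3, (6, 4)), columns=list("abcd"))
        wide.index = [f"s{i}" for i in range(6)]
        shifted = wide + pd.Series({"a": 3.0, "b": -2.0, "c": 0.5, "d": 10.0})
        m1 = reference_stability(_tidy(wide))
        m2 = reference_stability(_tidy(shifted))
        assert np.allclose(m1["M"].sort_index(), m2["M"].sort_index())

    def test_two_genes_degenerate_warns(self, rng):
        wide = pd.DataFrame(rng.normal(25, 1, (5, 2)), columns=["a", "b"])
        wide.index = [f"s{i}" for i in range(5)]
        with pytest.warns(UserWarning, match="degenerate"):
            m = reference_stability(_tidy(wide))
        assert m.loc["a", "M"] == pytest.approx(m.loc["b", "M"])

    def test_missing_ct_rejected(self):
        wide = pd.DataFrame(
            {"a": [25.0, np.nan], "b": [24.0, 26.0], "c": [22.0, 23.0]},
            index=["s0", "s1"],
        )
        with pytest.raises(ValueError, match="missing"):
            reference_stability(wide)


def _plate(ct: dict, conditions=("control", "treated"), n=3):
    """Plate with per-gene per-condition Ct values, constant across replicates."""
    rows = []
    for cond in conditions:
        for rep in range(n):
            for gene, vals in ct.items():
                rows.append(
                    {"sample": f"{cond}{rep}", "condition": cond, "gene": gene,
                     "dilution": 1.0, "replicate": rep, "Ct": vals[cond]}
                )
    return pd.DataFrame(rows)


class TestRelativeExpression:
    def test_no_shift_gives_unit_ratio(self):
        plate = _plate({"t": {"control": 25.0, "treated": 25.0},
                        "r": {"control": 20.0, "treated": 20.0}})
        out = relative_expression(plate, ["t"], references=["r"])
        assert out.loc["t", "ratio"] == pytest.approx(1.0)

    def test_one_cycle_drop_doubles_expression(self):
        plate = _plate({"t": {"control": 25.0, "treated": 24.0},
                        "r": {"control": 20.0, "treated": 20.0}})
        out = relative_expression(plate, ["t"], references=["r"])
        assert out.loc["t", "ratio"] == pytest.approx(2.0)

    def test_two_identically_shifted_references_equal_one(self):
        plate2 = _plate({"t": {"control": 25.0, "treated": 23.5},
                         "r1": {"control": 20.0, "treated": 19.0},
                         "r2": {"control": 18.0, "treated": 17.0}})
        plate1 = _plate({"t": {"control": 25.0, "treated": 23.5},
                         "r1": {"control": 20.0, "treated": 19.0}})
        two = relative_expression(plate2, ["t"], references=["r1", "r2"])
        one = relative_expression(plate1, ["t"], references=["r1"])
        assert two.loc["t", "ratio"] == pytest.approx(one.loc["t", "ratio"])

    def test_unit_efficiency_reduces_to_ddct(self, rng):
        genes = ["t1", "t2", "ref"]
        ct = {
            g: {"control": float(rng.uniform(20, 30)), "treated": float(rng.uniform(20, 30))}
            for g in genes
        }
        plate = _plate(ct)
        out = relative_expression(plate, ["t1", "t2"], references=["ref"])
        for g in ("t1", "t2"):
            ddct = (ct[g]["treated"] - ct["ref"]["treated"]) - (
                ct[g]["control"] - ct["ref"]["control"]
            )
            assert out.loc[g, "ratio"] == pytest.approx(2.0 ** (-ddct), rel=1e-12)

    def test_serum_volume_normalization(self):
        plate = _plate({"t": {"control": 25.0, "treated": 25.0}})
        vols = {s: (1.0 if s.startswith("control") else 2.0)
                for s in plate["sample"].unique()}
        out = relative_expression(plate, ["t"], volumes=vols)
        # same Ct from twice the volume means half the concentration
        assert out.loc["t", "ratio"] == pytest.approx(0.5)

    def test_missing_reference_rejected(self):
        plate = _plate({"t": {"control": 25.0, "treated": 24.0}})
        with pytest.raises(ValueError, match="reference"):
            relative_expression(plate, ["t"], references=["nope"])


class TestGroupComparison:
    def test_identical_groups_give_p_one(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_pooled_t(self):
        a = np.array([1.1, 1.9, 1.5])
        b = np.array([2.8, 3.4, 2.9])
        t, p = compare_groups(a, b)
        sp = math.sqrt(((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4)
        t_manual = (b.mean() - a.mean()) / (sp * math.sqrt(1 / 3 + 1 / 3))
        assert t == pytest.approx(t_manual, rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_manual), df=4), rel=1e-12)

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, "ns"), (0.049, "*"), (0.008, "**"), (0.0009, "***"), (0.05, "ns")],
    )
    def test_star_mapping(self, p, expected):
        assert stars(p) == expected


def test_read_plate_requires_core_columns(tmp_path):
    path = tmp_path / "plate.csv"
    pd.DataFrame({"sample": ["a"], "gene": ["g"]}).to_csv(path, index=False)
    with pytest.raises(ValueError, match="columns"):
        read_plate(path)
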