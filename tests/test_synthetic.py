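"""Synthetic experiment generator: structure, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest

from mirshift import datasets
from mirshift.differential import differential_table
from mirshift.quantify import compute_rpkm
from mirshift.synthetic import (
    MirnaCatalog,
    QpcrSimConfig,
    SimulationConfig,
    generate_catalog,
    simulate_counts,
    simulate_experiment,
    simulate_qpcr,
)


class TestCatalog:
    def test_detectable_totals_match_defaults(self):
        cat = generate_catalog(SimulationConfig(seed=1))
        assert cat.n_tumour_detectable == 615
        assert cat.n_serum_detectable == 617

    def test_all_effects_zero_gives_neutral_catalog(self):
        cat = generate_catalog(SimulationConfig(seed=1).null())
        assert (cat.entries["annotation"] == "neutral").all()
        assert (cat.entries["tumour_effect"] == 1.0).all()
        assert (cat.entries["serum_effect"] == 1.0).all()

    def test_affected_partition_counts(self):
        cat = generate_catalog(SimulationConfig(seed=2))
        t_aff = set(cat.affected("tumour"))
        s_aff = set(cat.affected("serum"))
        assert len(t_aff) == 116 + 7
        assert len(s_aff) == 137 + 2
        assert len(t_aff & s_aff) == 81
        assert len(t_aff - s_aff) == 42
        assert len(s_aff - t_aff) == 58

    def test_direction_split(self):
        cat = generate_catalog(SimulationConfig(seed=3))
        t_eff = cat.entries["tumour_effect"]
        s_eff = cat.entries["serum_effect"]
        assert int((t_eff > 1).sum()) == 116
        assert int((t_eff < 1).sum()) == 7
        assert int((s_eff < 1).sum()) == 137
        assert int((s_eff > 1).sum()) == 2

    def test_effect_counts_exceeding_detectable_rejected(self):
        cfg = SimulationConfig(n_tumour_up=700, n_tumour_detectable=615)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_catalog_tsv_round_trip(self, tmp_path):
        cat = generate_catalog(SimulationConfig(seed=4, n_features=60,
                                                n_tumour_detectable=50,
                                                n_serum_detectable=50,
                                                n_tumour_up=4, n_tumour_down=1,
                                                n_serum_down=4, n_serum_up=0,
                                                n_common_affected=2,
                                                affected_min_abundance=0.0))
        cat.to_tsv(tmp_path / "cat.tsv")
        back = MirnaCatalog.from_tsv(tmp_path / "cat.tsv")
        pd.testing.assert_frame_equal(back.entries, cat.entries)


class TestCounts:
    def test_bit_identical_for_same_seed(self):
        cfg = SimulationConfig(seed=42)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.compositions, b.compositions)
        pd.testing.assert_frame_equal(a.catalog.entries, b.catalog.entries)

    def test_undetectable_serum_features_have_zero_serum_counts(self):
        exp = simulate_experiment(SimulationConfig(seed=5))
        not_serum = ~exp.catalog.entries["serum_detectable"]
        assert (exp.counts.counts.loc[not_serum, ["L3", "L4"]] == 0).all().all()

    def test_realized_rpkm_tracks_base_abundance_at_depth(self):
        # near-Poisson, no effects: abundant features within 5% of base RPKM
        cfg = SimulationConfig(seed=6, dispersion=0.0,
                               library_depths=(10**7,) * 4).null()
        exp = simulate_experiment(cfg)
        rpkm = compute_rpkm(exp.counts)
        ent = exp.catalog.entries
        abundant = (ent["base_abundance"] > 100) & ent["tumour_detectable"]
        rel = rpkm.loc[abundant, "L1"] / ent.loc[abundant, "base_abundance"]
        assert ((rel - 1).abs() < 0.05).mean() > 0.95

    def test_composition_fractions_within_multinomial_noise(self):
        exp = simulate_experiment(SimulationConfig(seed=7))
        frac_cfg = datasets.composition_fractions()
        for lib in datasets.LIBRARIES:
            total = exp.compositions.loc[lib, "total"]
            for cls in ("miRNA", "mRNA", "rRNA", "filter"):
                f = frac_cfg.loc[lib, cls]
                sd = np.sqrt(total * f * (1 - f))
                assert abs(exp.compositions.loc[lib, cls] - total * f) < 3 * sd

    def test_mapped_equals_class_sum(self):
        exp = simulate_experiment(SimulationConfig(seed=8))
        parts = exp.compositions[["miRNA", "mRNA", "rRNA", "filter"]].sum(axis=1)
        assert (exp.compositions["mapped"] == parts).all()

    def test_nonzero_counts_only_for_detectable_features(self):
        exp = simulate_experiment(SimulationConfig(seed=9))
        ent = exp.catalog.entries
        for lib, comp in (("L1", "tumour"), ("L2", "tumour"), ("L3", "serum"), ("L4", "serum")):
            nonzero = exp.counts.counts[lib] > 0
            assert ent.loc[nonzero, f"{comp}_detectable"].all()

    def test_non_positive_depth_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(library_depths=(0, 1, 1, 1)).validate()

    def test_fold_change_parameter_recovery(self):
        # counting-noise-limited regime: median abs log2 error < 0.3
        cfg = SimulationConfig(seed=10, dispersion=0.01, library_depths=(10**7,) * 4)
        exp = simulate_experiment(cfg)
        cat = exp.catalog.entries
        dt = differential_table(exp.counts, "L1", "L2", "tumour")
        ds = differential_table(exp.counts, "L3", "L4", "serum")
        errs = []
        for table, col in ((dt, "tumour_effect"), (ds, "serum_effect")):
            aff = cat.index[cat[col] != 1.0]
            errs.append(np.abs(np.log2(table.loc[aff, "ratio"]) - np.log2(cat.loc[aff, col])))
        assert float(np.median(np.concatenate(errs))) < 0.3


class TestQpcrSimulation:
    def test_twofold_difference_is_one_cycle_noiseless(self):
        cfg = QpcrSimConfig(seed=0, ct_sd=0.0, loading_sd=0.0, n_replicates=2)
        plate = simulate_qpcr({"miR-x": 2.0}, cfg)
        target = plate[(plate["gene"] == "miR-x") & (plate["condition"] != "standard")]
        ct = target.groupby("condition")["Ct"].mean()
        assert ct["treated"] - ct["control"] == pytest.approx(-1.0, abs=1e-12)

    def test_dilution_series_spacing_is_log2_ten(self):
        cfg = QpcrSimConfig(seed=0, ct_sd=0.0, loading_sd=0.0, n_replicates=2)
        plate = simulate_qpcr({"miR-x": 2.0}, cfg)
        std = plate[(plate["gene"] == "miR-x") & (plate["condition"] == "standard")]
        ct = std.sort_values("dilution", ascending=False)["Ct"].to_numpy()
        spacing = np.diff(ct)
        # factors 1, 1e-2, 1e-3, 1e-4: 2 decades then 1 and 1
        assert spacing[0] == pytest.approx(2 * np.log2(10), abs=1e-9)
        assert spacing[1] == pytest.approx(np.log2(10), abs=1e-9)
        assert spacing[2] == pytest.approx(np.log2(10), abs=1e-9)

    def test_efficiency_outside_range_rejected(self):
        cfg = QpcrSimConfig(efficiencies={"miR-x": 1.5})
        with pytest.raises(ValueError, match="efficiency"):
            simulate_qpcr({"miR-x": 2.0}, cfg)

    def test_stable_pair_recovered_by_stability_ranking(self):
        from mirshift.qpcr import best_reference_pair, reference_stability

        cfg = QpcrSimConfig(seed=13)
        plate = simulate_qpcr({"miR-x": 2.0}, cfg)
        ref = plate[
            plate["gene"].isin(cfg.reference_genes)
            & plate["condition"].isin(["control", "treated"])
        ]
        stability = reference_stability(ref)
        assert set(best_reference_pair(stability)) == set(cfg.stable_pair)
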