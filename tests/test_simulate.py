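import warnings

import numpy as np
import pandas as pd
import pytest

from gliascreen.design import ScreenDesign
from gliascreen.hits import score_genes
from gliascreen.pipeline import QuantifyParams, quantify_wells
from gliascreen.simulate import SimulationConfig, evaluate_recovery, simulate_screen


def _analyse(cfg: SimulationConfig):
    wells, truth = simulate_screen(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = quantify_wells(wells, QuantifyParams.from_simulation(cfg))
        stats = score_genes(values)
    return wells, truth, values, stats


class TestSimulateScreen:
    def test_same_seed_is_bit_identical(self, small_sim):
        w1, t1 = simulate_screen(small_sim)
        w2, t2 = simulate_screen(small_sim)
        assert w1.equals(w2) and t1.equals(t2)

    def test_different_seed_differs(self, small_design):
        w1, _ = simulate_screen(SimulationConfig(design=small_design, seed=1))
        w2, _ = simulate_screen(SimulationConfig(design=small_design, seed=2))
        assert not w1["readout"].equals(w2["readout"])

    def test_zero_hit_fraction_spikes_nothing(self, small_design):
        _, truth = simulate_screen(
            SimulationConfig(design=small_design, seed=3, hit_fraction=0.0)
        )
        assert (truth["true_log2_effect"] == 0).all()

    def test_default_design_covers_623_genes_on_seven_master_plates(self):
        cfg = SimulationConfig(seed=1, assays=("no",))
        wells, truth = simulate_screen(cfg)
        lib = wells[wells.role == "library"]
        one_set = lib[lib.plate_id.str.startswith("S1_LPS_R1_")]
        assert one_set.plate_id.nunique() == 7
        assert one_set.groupby("plate_id").size().eq(89).all()
        assert one_set.gene_id.nunique() == 623
        assert truth.gene_id.nunique() == 623

    def test_spike_fraction_is_binomially_plausible(self, small_design):
        cfg = SimulationConfig(design=small_design, seed=9, hit_fraction=0.2)
        _, truth = simulate_screen(cfg)
        frac = (truth["true_log2_effect"] != 0).groupby(truth["assay"]).mean()
        # 60 genes, p = 0.2 -> 4 sigma band ~ +-0.21
        assert ((frac - 0.2).abs() < 0.21).all()

    def test_truth_magnitudes_stay_in_configured_range(self, small_sim):
        _, truth = simulate_screen(small_sim)
        nz = truth.loc[truth["true_log2_effect"] != 0, "true_log2_effect"].abs()
        lo, hi = small_sim.effect_range
        assert nz.between(lo, hi).all()


class TestRecovery:
    def test_noise_free_limit_recovers_truth_exactly(self, small_design):
        cfg = SimulationConfig(
            design=small_design, seed=7, noise_sd=0.0, plate_sd=0.0, hit_fraction=0.2
        )
        _, truth, _, stats = _analyse(cfg)
        m = stats[stats.condition == "LPS"].merge(truth, on=["gene_id", "assay"])
        assert (m.mean_log2fc - m.true_log2_effect).abs().max() < 1e-9
        rec = evaluate_recovery(stats, truth)
        assert rec["sensitivity"] == 1.0 and rec["fpr"] == 0.0

    def test_plate_effects_cancel_through_in_plate_normalization(self, small_design):
        """Plate factors hit controls and samples alike, so huge plate-to-plate
        variation must not move the recovered fold changes at all.  Censoring
        limits are widened so no readout saturates (full wound closure or
        100% cytotoxicity would break the cancellation for other reasons)."""
        cfg = SimulationConfig(
            design=small_design, seed=7, noise_sd=0.0, plate_sd=1.5, hit_fraction=0.2,
            wound_initial_width=1e6, ldh_max=1e4,
        )
        _, truth, _, stats = _analyse(cfg)
        m = stats[stats.condition == "LPS"].merge(truth, on=["gene_id", "assay"])
        assert (m.mean_log2fc - m.true_log2_effect).abs().max() < 1e-9

    def test_fold_change_estimator_bias_is_small(self):
        """Mean bias of recovered log2 FC across seeded replicate screens.

        The log of the finite control-well mean adds a small Jensen bias
        (~ -0.014 log2 units at noise SD 0.25, 3 control wells/plate);
        the band asserts it stays within +-0.02."""
        design = ScreenDesign(n_genes=30, n_master_plates=1, pad_to_daughters=None)
        biases = []
        for seed in range(200):
            cfg = SimulationConfig(
                design=design, seed=seed, assays=("no",), hit_fraction=0.2
            )
            _, truth, _, stats = _analyse(cfg)
            m = stats[stats.condition == "LPS"].merge(truth, on=["gene_id", "assay"])
            biases.append((m.mean_log2fc - m.true_log2_effect).mean())
        assert abs(np.mean(biases)) < 0.02

    def test_lps_dependent_genes_are_classified_dependent(self):
        design = ScreenDesign(n_genes=120, n_master_plates=2, pad_to_daughters=None)
        cfg = SimulationConfig(
            design=design,
            seed=13,
            assays=("no",),
            hit_fraction=0.5,
            effect_range=(1.0, 1.0),
            lps_dependent_fraction=1.0,
        )
        _, truth, _, stats = _analyse(cfg)
        called = stats[(stats.condition == "LPS") & (stats.category != "none")]
        spiked = set(truth.loc[truth["true_log2_effect"] != 0, "gene_id"])
        called = called[called.gene_id.isin(spiked)]
        assert len(called) >= 30
        assert called["lps_dependent"].mean() >= 0.9

    def test_mismatched_gene_sets_are_rejected(self, small_sim):
        _, truth, _, stats = _analyse(small_sim)
        with pytest.raises(ValueError, match="different genes"):
            evaluate_recovery(stats[stats.gene_id != "KIN0001"], truth)


def test_untreated_control_wells_read_at_pbs_baseline(small_design):
    """The in-plate LPS-untreated wells must sit at the PBS baseline even on
    LPS-stimulated plates - that contrast is what plate QC gates on."""
    cfg = SimulationConfig(design=small_design, seed=4, noise_sd=0.0, plate_sd=0.0,
                           assays=("no",))
    wells, _ = simulate_screen(cfg)
    lps_plates = wells[wells.plate_id.str.contains("_LPS_")]
    unt = lps_plates[lps_plates.role == "untreated_control"]["readout"].unique()
    neg = lps_plates[lps_plates.role == "neg_control_siRNA"]["readout"].unique()
    slope, intercept = cfg.griess_slope, cfg.griess_intercept
    assert unt == pytest.approx(slope * cfg.baselines["no"]["PBS"] + intercept)
    assert neg == pytest.approx(slope * cfg.baselines["no"]["LPS"] + intercept)
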