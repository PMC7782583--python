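import dataclasses

import numpy as np
import pytest

import thymotrace as tt
from thymotrace.coreceptor import call_states
from thymotrace.io import read_gene_set
from thymotrace.simulate import (
    DEFAULT_PROGRAM_SIZES,
    Kinetics,
    coreceptor_windows,
    mhcii_ko_config,
)


def test_dataset_bookkeeping(wt_dataset):
    cm, ann, truth = wt_dataset
    assert cm.counts.shape == (300, 500)
    assert len(ann) == 300
    assert ann.aligned_with(cm)
    assert truth.true_time.shape == (300,)
    assert set(truth.true_state) <= {"DP_state", "CD4_state", "CD8_state", "DN_state"}
    assert (truth.true_time >= 0).all() and (truth.true_time <= 1).all()


def test_fixed_seed_is_bit_identical():
    cfg = tt.SimulationConfig(seed=42, n_cells_per_subset=10)
    cm1, _, _ = tt.generate_dataset(cfg)
    cm2, _, _ = tt.generate_dataset(tt.SimulationConfig(seed=42, n_cells_per_subset=10))
    assert np.array_equal(cm1.counts, cm2.counts)
    assert cm1.cell_ids == cm2.cell_ids


def test_config_validation_errors():
    bad = tt.SimulationConfig(program_sizes={"coreceptor": 3, "housekeeping": 10})
    with pytest.raises(ValueError, match="partition"):
        bad.validate()
    with pytest.raises(ValueError, match="dropout"):
        tt.SimulationConfig(dropout_rate=1.0).validate()
    with pytest.raises(ValueError, match="nb_dispersion"):
        tt.SimulationConfig(nb_dispersion=0.0).validate()


def test_program_mean_kinetic_endpoints():
    kin = Kinetics()
    b = 3.0
    up = tt.program_mean(np.array([0.0, 1.0]), "maturation_up", kin, baseline=b)
    assert up[0] == pytest.approx(b)
    assert up[1] == pytest.approx(b * kin.maturation_fold)
    t = np.linspace(0, 1, 101)
    down = tt.program_mean(t, "maturation_down", kin, baseline=b)
    assert (np.diff(down) <= 1e-12).all()  # monotone non-increasing
    pulse = tt.program_mean(np.array([0.0, 1.0]), "activation_pulse", kin, baseline=b)
    assert pulse[0] == pytest.approx(pulse[1])  # symmetric pulse ends
    center = tt.program_mean(
        np.array([kin.activation_center]), "activation_pulse", kin, baseline=b
    )
    assert center[0] == pytest.approx(b * kin.activation_amplitude)


def test_activation_scale_scales_pulse_amplitude():
    kin = Kinetics()
    half = tt.program_mean(
        np.array([kin.activation_center]), "activation_pulse", kin,
        baseline=1.0, activation_scale=0.5,
    )
    assert half[0] == pytest.approx(1.0 + (kin.activation_amplitude - 1.0) * 0.5)


def test_no_dropout_high_mean_gives_full_dp_detection():
    cfg = tt.SimulationConfig(
        n_cells_per_subset={p: (100 if p == "CD69neg_DP" else 0) for p in tt.PHENOTYPES},
        dropout_rate=0.0,
        nb_dispersion=1e12,  # near-Poisson
        seed=1,
    )
    cm, ann, truth = tt.generate_dataset(cfg)
    assert (truth.true_state == "DP_state").all()
    assert (cm.gene_counts("Cd4") >= 1).all()
    assert (cm.gene_counts("Cd8a") >= 1).all()


def test_dp_call_rate_matches_independent_dropout_product():
    d = 0.05
    n = 4000
    cfg = tt.SimulationConfig(
        n_cells_per_subset={p: (n if p == "CD69neg_DP" else 0) for p in tt.PHENOTYPES},
        dropout_rate={"coreceptor": d},
        seed=2,
    )
    cm, _, truth = tt.generate_dataset(cfg)
    rate = (call_states(cm)["state"] == "DP_state").mean()
    expected = (1 - d) ** 2
    half_width = 2.576 * np.sqrt(expected * (1 - expected) / n)
    assert abs(rate - expected) < half_width


def test_sequential_timing_orders_state_mean_times():
    cm, ann, truth = tt.generate_dataset(tt.SimulationConfig(seed=3))
    t4 = truth.true_time[truth.true_state == "CD4_state"]
    t8 = truth.true_time[truth.true_state == "CD8_state"]
    assert t4.mean() < t8.mean()


def test_simultaneous_timing_equalises_state_mean_times():
    cfg = tt.SimulationConfig(
        n_cells_per_subset=170, coreceptor_timing="simultaneous", seed=4
    )
    cm, ann, truth = tt.generate_dataset(cfg)
    t4 = truth.true_time[truth.true_state == "CD4_state"]
    t8 = truth.true_time[truth.true_state == "CD8_state"]
    se = np.sqrt(t4.var(ddof=1) / t4.size + t8.var(ddof=1) / t8.size)
    assert abs(t4.mean() - t8.mean()) < 2 * se


def test_counts_are_overdispersed(wt_dataset):
    cm, ann, truth = wt_dataset
    hk = [g for g in cm.gene_ids if truth.program_of_gene[g] == "housekeeping"]
    idx = [cm.gene_index(g) for g in hk]
    sub = cm.counts[:, idx].astype(float)
    mean = sub.mean(axis=0)
    var = sub.var(axis=0, ddof=1)
    assert (var >= mean).mean() > 0.95  # NB: variance exceeds the mean


def test_coreceptor_window_logic_sequential():
    kin = Kinetics()
    # CD8-branch cell passes DP -> CD4_state -> CD8_state
    w_cd4 = coreceptor_windows("Cd4", "CD8", "sequential", kin)
    w_cd8a = coreceptor_windows("Cd8a", "CD8", "sequential", kin)
    t_dp, t_mid, t_late = 0.1, 0.45, 0.9
    on = lambda t, w: any(lo <= t < hi for lo, hi in w)
    assert on(t_dp, w_cd4) and on(t_dp, w_cd8a)
    assert on(t_mid, w_cd4) and not on(t_mid, w_cd8a)
    assert not on(t_late, w_cd4) and on(t_late, w_cd8a)


def test_export_truth_genesets_roundtrip(tmp_path, wt_dataset):
    cm, ann, truth = wt_dataset
    paths = tt.export_truth_genesets(truth, tmp_path)
    sizes = DEFAULT_PROGRAM_SIZES
    assert len(read_gene_set(paths["activation"])) == sizes["activation_pulse"]
    assert len(read_gene_set(paths["maturation"])) == (
        sizes["maturation_up"] + sizes["maturation_down"]
    )
    for name, path in paths.items():
        assert read_gene_set(path).genes == truth.truth_genesets[name].genes
    # membership must match the per-gene program labels exactly
    act = {g for g in cm.gene_ids if truth.program_of_gene[g] == "activation_pulse"}
    assert act == set(truth.truth_genesets["activation"].genes)


def test_export_refuses_overlapping_sets(tmp_path, wt_dataset):
    _, _, truth = wt_dataset
    corrupted = dataclasses.replace(
        truth,
        truth_genesets={
            "a": tt.GeneSetRef("a", {"X", "Y"}),
            "b": tt.GeneSetRef("b", {"Y", "Z"}),
        },
    )
    with pytest.raises(ValueError, match="overlap"):
        tt.export_truth_genesets(corrupted, tmp_path)


def test_ko_config_models_class_ii_loss():
    base = tt.SimulationConfig(seed=5)
    ko = mhcii_ko_config(base)
    assert ko.coreceptor_timing == "simultaneous"
    assert ko.activation_scale < 1
    assert ko.cd4_lineage_silenced
    assert ko.condition == "MHCII_KO"
    # silenced CD4 program stays at baseline even on the CD4 branch
    m = tt.program_mean(
        np.array([0.95]), "cd4_lineage", base.kinetics,
        baseline=2.0, branch=np.array(["CD4"]), cd4_lineage_silenced=True,
    )
    assert m[0] == pytest.approx(2.0)
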