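"""Relative quantification: livak/pfaffl ratios, strategies, bias direction."""

import numpy as np
import pandas as pd
import pytest

from refstab.cq_data import EfficiencyMap
from refstab.relquant import (
    NormalizationStrategy,
    compare_strategies,
    peak_timepoint,
    relative_expression,
)
from refstab.synthetic import generate_experiment, short_preset

from conftest import make_table


def two_timepoint_table(cq_target, cq_ref, extra=None):
    genes = {"T": cq_target, "R": cq_ref}
    genes.update(extra or {})
    return make_table(genes, timepoints=[0, 1])


def test_livak_three_cycle_drop_is_eightfold():
    t = two_timepoint_table([25.0, 22.0], [20.0, 20.0])
    prof = relative_expression(t, "T", NormalizationStrategy.single("R"))
    assert prof.mean[0.0] == pytest.approx(1.0)
    assert prof.mean[1.0] == pytest.approx(8.0)


def test_flat_ddcq_gives_unity_profile():
    t = make_table({"T": [25.0, 25.5, 24.8], "R": [20.0, 20.5, 19.8]},
                   timepoints=[0, 1, 2])
    prof = relative_expression(t, "T", NormalizationStrategy.single("R"))
    np.testing.assert_allclose(prof.mean.to_numpy(), 1.0)


def test_pfaffl_closed_form():
    # dCq_target = 2 (control - treated), dCq_ref = 1, F_t=1.9, F_r=2.1
    t = two_timepoint_table([25.0, 23.0], [20.0, 19.0])
    eff = EfficiencyMap({"T": 1.9, "R": 2.1})
    prof = relative_expression(t, "T", NormalizationStrategy.single("R"),
                               eff, method="pfaffl")
    assert prof.mean[1.0] == pytest.approx(1.9**2 / 2.1)
    assert prof.mean[1.0] == pytest.approx(1.719, abs=5e-4)


def test_multi_rg_pseudo_reference_is_average_cq():
    t = make_table({"T": [25.0, 22.0], "R1": [20.0, 20.0], "R2": [22.0, 22.0]},
                   timepoints=[0, 1])
    prof = relative_expression(t, "T", NormalizationStrategy.multi(["R1", "R2"]))
    # pseudo-reference Cq 21 at both timepoints -> pure target effect
    assert prof.mean[1.0] == pytest.approx(8.0)


def test_pfaffl_equals_livak_at_factor_two(rng):
    table, _ = generate_experiment(short_preset(seed=3, include_targets=True))
    strat = NormalizationStrategy.multi(["UBC", "PP2A"])
    livak = relative_expression(table, "HK3", strat, method="livak")
    pfaffl = relative_expression(table, "HK3", strat,
                                 EfficiencyMap(), method="pfaffl")
    pd.testing.assert_frame_equal(livak.fold_change, pfaffl.fold_change)


def test_multi_geomean_equals_avg_cq_at_equal_efficiency():
    t = make_table({"T": [25.0, 22.0], "R1": [20.0, 20.3], "R2": [22.0, 21.8]},
                   timepoints=[0, 1])
    eff = EfficiencyMap({"T": 1.9, "R1": 1.9, "R2": 1.9})
    avg = relative_expression(t, "T", NormalizationStrategy.multi(["R1", "R2"]),
                              eff, method="pfaffl")
    geo = relative_expression(
        t, "T", NormalizationStrategy.multi(["R1", "R2"], rule="geomean"),
        eff, method="pfaffl")
    assert geo.mean[1.0] == pytest.approx(avg.mean[1.0], abs=1e-12)


def test_loading_shift_cancels():
    t = make_table({"T": [25.0, 23.0], "R": [20.0, 19.5]}, timepoints=[0, 1])
    shifted = make_table({"T": [25.0, 23.0 + 1.3], "R": [20.0, 19.5 + 1.3]},
                         timepoints=[0, 1])
    a = relative_expression(t, "T", NormalizationStrategy.single("R"))
    b = relative_expression(shifted, "T", NormalizationStrategy.single("R"))
    assert b.mean[1.0] == pytest.approx(a.mean[1.0], abs=1e-12)


def test_replicate_pairing_and_missing_control():
    t = make_table(
        {"T": [25.0, 25.0, 22.0, 21.0], "R": [20.0, 20.0, 20.0, 20.0]},
        timepoints=[0, 0, 1, 1], replicates=[1, 2, 1, 2],
    )
    prof = relative_expression(t, "T", NormalizationStrategy.single("R"))
    assert prof.per_replicate.loc[1.0, 1] == pytest.approx(8.0)
    assert prof.per_replicate.loc[1.0, 2] == pytest.approx(16.0)
    assert prof.fold_change.loc[1.0, "n_replicates"] == 2
    # drop replicate 2's control: its treated samples are dropped with warning
    t2 = make_table(
        {"T": [25.0, 22.0, 21.0], "R": [20.0, 20.0, 20.0]},
        timepoints=[0, 1, 1], replicates=[1, 1, 2],
    )
    prof2 = relative_expression(t2, "T", NormalizationStrategy.single("R"))
    assert prof2.fold_change.loc[1.0, "n_replicates"] == 1
    assert any("no control" in w for w in prof2.warnings_)


def test_peak_timepoint_and_ties():
    t = make_table({"T": [25.0, 23.7, 22.4, 23.4, 24.5, 24.9],
                    "R": [20.0] * 6},
                   timepoints=[0, 0.5, 1, 2, 4, 8])
    prof = relative_expression(t, "T", NormalizationStrategy.single("R"))
    tp, tied = peak_timepoint(prof)
    assert tp == 1.0 and not tied
    flat = make_table({"T": [25.0, 25.0, 25.0], "R": [20.0, 20.0, 20.0]},
                      timepoints=[0, 1, 2])
    tp, tied = peak_timepoint(
        relative_expression(flat, "T", NormalizationStrategy.single("R")))
    assert tp == 1.0 and tied


def test_drifting_reference_overestimates_null_target():
    """A reference gene whose Cq rises under treatment inflates the
    fold-change of a target that did not change at all."""
    t = make_table(
        {"NULL": [25.0, 25.0, 25.0], "DRIFT": [20.0, 20.8, 21.6],
         "S1": [19.0, 19.0, 19.0], "S2": [21.0, 21.0, 21.0]},
        timepoints=[0, 1, 2],
    )
    single_drift = relative_expression(
        t, "NULL", NormalizationStrategy.single("DRIFT"))
    multi = relative_expression(
        t, "NULL", NormalizationStrategy.multi(["S1", "S2"]))
    assert single_drift.mean[2.0] == pytest.approx(2 ** 1.6)   # > 1, forced
    np.testing.assert_allclose(multi.mean.to_numpy(), 1.0)


def test_compare_strategies_divergence():
    t = make_table(
        {"NULL": [25.0, 25.0], "DRIFT": [20.0, 21.0],
         "S1": [19.0, 19.0], "S2": [21.0, 21.0], "T": [25.0, 22.0]},
        timepoints=[0, 1],
    )
    strategies = [
        NormalizationStrategy.single("DRIFT"),
        NormalizationStrategy.single("S1"),
        NormalizationStrategy.multi(["S1", "S2"]),
    ]
    profiles, div = compare_strategies(t, "T", strategies)
    assert div.attrs["baseline"] == "multi_rg_avg_cq(S1,S2)"
    assert div["multi_rg_avg_cq(S1,S2)"].loc[1.0] == pytest.approx(1.0)
    assert div["single_rg(DRIFT)"].loc[1.0] == pytest.approx(2.0)  # inflated
    assert div["single_rg(S1)"].loc[1.0] == pytest.approx(1.0)


def test_identical_references_identical_profiles():
    t = make_table({"T": [25.0, 23.0], "R": [20.0, 19.5], "X": [18.0, 18.0]},
                   timepoints=[0, 1])
    strategies = [NormalizationStrategy.single("R"),
                  NormalizationStrategy.multi(["R", "R"])]
    # multi over the same gene twice == single over it
    with pytest.raises(Exception):
        # duplicate genes in one strategy are nonsense; use two real ones
        NormalizationStrategy("single_rg", ("R", "X"))
    profiles, div = compare_strategies(t, "T", strategies)
    assert np.allclose(div.iloc[:, 0], div.iloc[:, 1])


def test_validation_errors():
    t = make_table({"T": [25.0, 23.0], "R": [20.0, 19.5]}, timepoints=[0, 1])
    with pytest.raises(KeyError, match="MISSING"):
        relative_expression(t, "MISSING", NormalizationStrategy.single("R"))
    no_ctrl = make_table({"T": [25.0, 23.0], "R": [20.0, 19.5]},
                         timepoints=[1, 2])
    with pytest.raises(ValueError, match="control"):
        relative_expression(no_ctrl, "T", NormalizationStrategy.single("R"))
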