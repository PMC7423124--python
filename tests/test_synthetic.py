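"""Synthetic Cq generator: determinism, noise-free limits, calibration."""

import numpy as np
import pandas as pd
import pytest

from refstab.bestkeeper import BestKeeper
from refstab.cq_data import collapse_replicates, cq_to_quantity
from refstab.efficiency import fit_dilution_table
from refstab.genorm import m_values
from refstab.synthetic import (
    CQ_ENVELOPE,
    GeneSpec,
    SyntheticSpec,
    generate_dilution_series,
    generate_experiment,
    long_preset,
    short_preset,
    write_experiment,
)


def noise_free_spec(**kwargs):
    genes = [GeneSpec(f"g{i}", sigma=0.0, baseline_cq=20.0 + i) for i in range(4)]
    return SyntheticSpec(genes=genes, loading_sd=0.0, seed=1, **kwargs)


def test_noise_free_limit_everything_flat():
    table, truth = generate_experiment(noise_free_spec())
    assert (table.cq.nunique(axis=1) == 1).all()
    q = cq_to_quantity(table)
    assert (m_values(q).abs() < 1e-12).all()
    bk = BestKeeper(table, dispersion="sd").fit()
    assert (bk.per_gene["sd"].abs() < 1e-12).all()


def test_same_seed_reproduces_byte_identical(tmp_path):
    spec = short_preset(seed=42, include_targets=True)
    t1, _ = generate_experiment(spec)
    t2, _ = generate_experiment(short_preset(seed=42, include_targets=True))
    assert t1 == t2
    p1 = write_experiment(*generate_experiment(spec), tmp_path / "a")[0]
    p2 = write_experiment(*generate_experiment(spec), tmp_path / "b")[0]
    assert p1.read_bytes() == p2.read_bytes()
    t3, _ = generate_experiment(short_preset(seed=43, include_targets=True))
    assert not (t1 == t3)


def test_presets_match_study_design():
    t_short, truth = generate_experiment(short_preset(seed=0))
    assert t_short.timepoints() == [0, 0.5, 1, 2, 4, 8]
    assert t_short.meta["timepoint_unit"].unique().tolist() == ["hours"]
    assert len(t_short.samples) == 6 * 3
    assert len(truth.reference_candidates()) == 12
    assert truth.drifting_genes() == ["PGK"]
    t_long, _ = generate_experiment(long_preset(seed=0))
    assert t_long.timepoints() == [0, 1, 2, 4, 8]
    assert t_long.meta["timepoint_unit"].unique().tolist() == ["days"]


def test_cq_envelope_at_defaults():
    """Nearly all generated Cq values stay inside the published range."""
    lo, hi = CQ_ENVELOPE
    vals = []
    for seed in range(50):
        t, _ = generate_experiment(short_preset(seed=seed))
        vals.append(t.cq.to_numpy().ravel())
    vals = np.concatenate(vals)
    inside = ((vals >= lo) & (vals <= hi)).mean()
    assert inside >= 0.99


def test_loading_invariance_exact_when_sigma_zero():
    genes = [GeneSpec(f"g{i}", sigma=0.0, baseline_cq=20.0 + 0.5 * i)
             for i in range(5)]
    big = SyntheticSpec(genes=genes, loading_sd=2.0, seed=9)
    none = SyntheticSpec(genes=genes, loading_sd=0.0, seed=9)
    q_big = cq_to_quantity(collapse_replicates(generate_experiment(big)[0]))
    q_none = cq_to_quantity(collapse_replicates(generate_experiment(none)[0]))
    pd.testing.assert_series_equal(m_values(q_big), m_values(q_none),
                                   atol=1e-10, rtol=0)


def test_sigma_monotonicity_paired_seeds():
    """Raising a gene's sigma raises its expected M and BestKeeper SD."""
    grid = [0.05, 0.2, 0.6]
    mean_m, mean_sd = [], []
    for sigma in grid:
        ms, sds = [], []
        for seed in range(30):
            genes = [GeneSpec("probe", sigma=sigma, baseline_cq=22.0)] + [
                GeneSpec(f"g{i}", sigma=0.1, baseline_cq=20.0 + i) for i in range(5)
            ]
            t, _ = generate_experiment(SyntheticSpec(genes=genes, seed=seed))
            c = collapse_replicates(t)
            ms.append(m_values(cq_to_quantity(c))["probe"])
            sds.append(BestKeeper(t, dispersion="sd").fit().per_gene.loc["probe", "sd"])
        mean_m.append(np.mean(ms))
        mean_sd.append(np.mean(sds))
    assert mean_m[0] < mean_m[1] < mean_m[2]
    assert mean_sd[0] < mean_sd[1] < mean_sd[2]


def test_fold_change_recovered_in_noise_free_limit():
    """Designed fold-changes survive the Cq round-trip exactly (pfaffl
    self-consistency of the generator)."""
    from refstab.cq_data import EfficiencyMap
    from refstab.relquant import NormalizationStrategy, relative_expression

    curve = {0.0: 1.0, 1.0: 4.0, 2.0: 2.0}
    genes = [
        GeneSpec("T", role="target", sigma=0.0, baseline_cq=25.0,
                 fold_curve=curve, efficiency_factor=1.9),
        GeneSpec("R1", sigma=0.0, baseline_cq=20.0),
        GeneSpec("R2", sigma=0.0, baseline_cq=21.0),
    ]
    spec = SyntheticSpec(genes=genes, timepoints=(0.0, 1.0, 2.0),
                         loading_sd=0.0, seed=4)
    table, truth = generate_experiment(spec)
    eff = EfficiencyMap({"T": 1.9})
    prof = relative_expression(table, "T",
                               NormalizationStrategy.multi(["R1", "R2"]),
                               eff, method="pfaffl")
    for tp, fold in curve.items():
        assert prof.mean[tp] == pytest.approx(fold, abs=1e-9)


def test_dilution_series_exact_and_noisy_recovery():
    rows = generate_dilution_series("G", factor=2.0, noise_sd=0.0)
    curve = fit_dilution_table(rows)["G"]
    assert curve.efficiency_percent == pytest.approx(100.0, abs=1e-9)
    rows = generate_dilution_series("CYP", factor=1.955, noise_sd=0.0)
    assert fit_dilution_table(rows)["CYP"].efficiency_percent == pytest.approx(
        95.5, abs=1e-9
    )
    effs = [
        fit_dilution_table(
            generate_dilution_series("G", 1.955, noise_sd=0.1, seed=s)
        )["G"].efficiency_percent
        for s in range(100)
    ]
    assert abs(np.mean(effs) - 95.5) < 2.0


def test_invalid_spec_fields_named():
    with pytest.raises(ValueError, match="replicates"):
        SyntheticSpec(genes=[GeneSpec("g")], replicates=0)
    with pytest.raises(ValueError, match="loading_sd"):
        SyntheticSpec(genes=[GeneSpec("g")], loading_sd=-1)
    with pytest.raises(ValueError, match="sigma"):
        SyntheticSpec(genes=[GeneSpec("g", sigma=-0.1)])
    with pytest.raises(ValueError, match="fold_curve"):
        SyntheticSpec(genes=[GeneSpec("g", role="target")])
    with pytest.raises(ValueError, match="factor"):
        generate_dilution_series("g", factor=1.0)


def test_ground_truth_sidecar_round_trip(tmp_path):
    import json

    table, truth = generate_experiment(short_preset(seed=7, include_targets=True))
    csv_path, truth_path = write_experiment(table, truth, tmp_path)
    loaded = json.loads(truth_path.read_text())
    assert loaded["roles"]["PGK"] == "drifting"
    assert loaded["roles"]["HK3"] == "target"
    assert loaded["seed"] == 7
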