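"""Synthetic melt/amplification generator: Tm model, determinism, weak runs."""

import numpy as np
import pytest

from meltid.amplicon import AmpliconRecord
from meltid.curves import negative_derivative
from meltid.fixtures import make_panel
from meltid.meltsim import (
    AmplificationParams,
    MeltModelParams,
    TemperatureGrid,
    domain_decompose,
    helicity,
    make_labeled_dataset,
    predict_domain_tm,
    read_runs_csv,
    simulate_amplification,
    simulate_melt,
    write_runs_csv,
)


class TestTemperatureGrid:
    def test_default_grid_has_301_points(self, grid):
        assert len(grid) == 301
        t = grid.temperatures
        assert t[0] == 60.0 and t[-1] == pytest.approx(90.0)
        assert np.allclose(np.diff(t), 0.1)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            TemperatureGrid(start=90, stop=60)


class TestDomainDecompose:
    def test_single_domain_all_gc(self):
        rec = AmpliconRecord(id="x", sequence="GGCC")
        [(seq, gc, w)] = domain_decompose(rec, 1)
        assert (seq, gc, w) == ("GGCC", 1.0, 1.0)

    def test_two_equal_at_domains(self):
        rec = AmpliconRecord(id="x", sequence="ATATATAT")
        doms = domain_decompose(rec, 2)
        assert [len(s) for s, _, _ in doms] == [4, 4]
        assert [gc for _, gc, _ in doms] == [0.0, 0.0]

    def test_remainder_distributed_left_to_right(self, panel10):
        doms = domain_decompose(panel10[0], 3)
        assert [len(s) for s, _, _ in doms] == [75, 74, 74]
        assert sum(w for _, _, w in doms) == pytest.approx(1.0)

    def test_too_many_domains(self):
        rec = AmpliconRecord(id="x", sequence="ACGT")
        with pytest.raises(ValueError):
            domain_decompose(rec, 5)


class TestTmModel:
    def test_hand_evaluated_value(self):
        # 81.5 + 16.6*log10(0.05) + 0.41*50 - 675/74
        tm = predict_domain_tm(0.5, 74, MeltModelParams())
        assert tm == pytest.approx(71.28, abs=0.01)

    def test_gc_zero_long_limit(self):
        p = MeltModelParams()
        tm = predict_domain_tm(0.0, 1e12, p)
        assert tm == pytest.approx(81.5 + 16.6 * np.log10(0.05), abs=1e-6)

    def test_monotone_in_gc(self):
        p = MeltModelParams()
        tms = [predict_domain_tm(g, 74, p) for g in np.linspace(0, 1, 11)]
        assert np.all(np.diff(tms) > 0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            predict_domain_tm(1.5, 74, MeltModelParams())
        with pytest.raises(ValueError):
            predict_domain_tm(float("nan"), 74, MeltModelParams())


class TestSimulateMelt:
    def test_midpoint_at_tm(self, gc_half_record):
        p = MeltModelParams(n_domains=1, noise_sd=0, amplitude_jitter_sd=0,
                            tm_jitter_sd=0, ds_baseline=(1000.0, 0.0),
                            ss_baseline=(100.0, 0.0))
        tm = predict_domain_tm(0.5, len(gc_half_record), p)
        run = simulate_melt(gc_half_record, p, TemperatureGrid())
        f_at_tm = np.interp(tm, run.x, run.fluorescence)
        assert f_at_tm == pytest.approx(550.0, abs=2.0)

    def test_determinism_byte_identical(self, panel10):
        p = MeltModelParams(seed=5)
        a = simulate_melt(panel10[0], p, replicate_seed=9)
        b = simulate_melt(panel10[0], p, replicate_seed=9)
        assert a.fluorescence.tobytes() == b.fluorescence.tobytes()
        c = simulate_melt(panel10[0], p, replicate_seed=10)
        assert a.fluorescence.tobytes() != c.fluorescence.tobytes()

    def test_helicity_bounded(self, panel10, grid):
        p = MeltModelParams()
        theta = helicity(panel10[2], p, grid.temperatures)
        assert np.all(theta >= 0) and np.all(theta <= 1)

    def test_noiseless_monotone_nonincreasing(self, noiseless_run):
        assert np.all(np.diff(noiseless_run.fluorescence) <= 1e-9)

    def test_derivative_peak_at_domain_tm(self, panel10, noiseless_params, grid):
        run = simulate_melt(panel10[0], noiseless_params, grid)
        tm = predict_domain_tm(panel10[0].gc_fraction(), len(panel10[0]),
                               noiseless_params)
        peak = run.x[np.argmax(negative_derivative(run))]
        assert abs(peak - tm) <= 0.1

    def test_single_nucleotide_shifts_peak(self, noiseless_params, grid):
        panel = make_panel(10, seed=7)
        a, b = panel[1], panel[4]     # 1-nt pair, GC-changing substitution
        run_a = simulate_melt(a, noiseless_params, grid)
        run_b = simulate_melt(b, noiseless_params, grid)
        diff = np.abs(run_a.fluorescence - run_b.fluorescence).max()
        assert diff > 0.5   # small but nonzero signature shift


class TestAmplification:
    def test_no_template_is_flat(self):
        p = AmplificationParams(initial_copies=0, noise_sd=0)
        run = simulate_amplification(p)
        assert np.allclose(run.fluorescence, p.baseline_rfu)

    def test_doubling_every_cycle(self):
        p = AmplificationParams(initial_copies=1, efficiency=1.0, noise_sd=0,
                                plateau_cap=1e12)
        copies_10 = 1 * 2.0 ** 10
        assert copies_10 == 1024

    def test_cycles_default_40(self):
        run = simulate_amplification(AmplificationParams())
        assert run.x.size == 40

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            AmplificationParams(efficiency=0.0)
        with pytest.raises(ValueError):
            AmplificationParams(initial_copies=10, plateau_cap=5)


class TestLabeledDataset:
    def test_counts_per_species(self, panel10):
        runs, manifest = make_labeled_dataset(panel10[:3], 5, master_seed=0)
        assert len(manifest) == 15
        assert manifest["species"].value_counts().eq(5).all()
        # each run has a melt and an amplification series
        assert len(runs) == 30

    def test_same_seed_identical(self, panel10):
        runs_a, man_a = make_labeled_dataset(panel10[:3], 4, master_seed=3)
        runs_b, man_b = make_labeled_dataset(panel10[:3], 4, master_seed=3)
        assert man_a.equals(man_b)
        for ra, rb in zip(runs_a, runs_b):
            assert ra.fluorescence.tobytes() == rb.fluorescence.tobytes()

    def test_weak_fraction_exact_count(self, panel10):
        _, manifest = make_labeled_dataset(panel10, 10, master_seed=1,
                                           weak_fraction=0.2)
        assert len(manifest) == 100
        assert int(manifest["weak"].sum()) == 20

    def test_conflicting_duplicate_labels_rejected(self, panel10):
        dup = AmpliconRecord(id="dup", sequence="ACGT" * 56,
                             species_label=panel10[0].species_label)
        with pytest.raises(ValueError, match="conflicting"):
            make_labeled_dataset([panel10[0], dup, panel10[1]], 3)

    def test_csv_roundtrip(self, panel10, tmp_path):
        runs, _ = make_labeled_dataset(panel10[:2], 2, master_seed=2)
        path = tmp_path / "runs.csv"
        write_runs_csv(runs, path)
        back = read_runs_csv(path)
        assert {r.run_id for r in back} == {r.run_id for r in runs}
        orig = {(r.run_id, r.stage): r for r in runs}
        for r in back:
            np.testing.assert_allclose(
                r.fluorescence, orig[(r.run_id, r.stage)].fluorescence, atol=1e-5)

    def test_column_mapping_adapter(self, panel10, tmp_path):
        runs, _ = make_labeled_dataset(panel10[:2], 2, master_seed=2)
        path = tmp_path / "runs.csv"
        write_runs_csv(runs, path)
        import pandas as pd
        df = pd.read_csv(path).rename(columns={"x": "Temperature",
                                               "fluorescence": "RFU"})
        path2 = tmp_path / "instrument.csv"
        df.to_csv(path2, index=False)
        back = read_runs_csv(path2, column_map={"x": "Temperature",
                                                "fluorescence": "RFU"})
        assert len(back) == len(runs)
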