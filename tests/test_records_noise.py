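import numpy as np
import pytest

from mwdetect.noise import NoiseSpec, add_vna_noise, sigma_from_noise_floor
from mwdetect.records import (BLEEDING, HEALTHY, TransmissionRecord,
                              antenna_pairs, default_frequency_grid,
                              load_records, save_records)


def _record(n_freq=10, n_pairs=3, label=HEALTHY, seed=0):
    rng = np.random.default_rng(seed)
    s = rng.standard_normal((n_freq, n_pairs)) \
        + 1j * rng.standard_normal((n_freq, n_pairs))
    return TransmissionRecord(
        frequencies=default_frequency_grid(n_freq),
        pairs=antenna_pairs(3)[:n_pairs], s=s, label=label,
        metadata={"seed": seed})


def test_antenna_pairs_are_unordered_and_unique():
    pairs = antenna_pairs(8)
    assert len(pairs) == 28
    assert all(i < j for i, j in pairs)
    assert len(set(pairs)) == len(pairs)


def test_default_grid_band():
    f = default_frequency_grid()
    assert f[0] == 0.4e9 and f[-1] == 1.2e9 and f.size == 267


def test_record_validation():
    with pytest.raises(ValueError):
        TransmissionRecord(frequencies=[1e9, 0.5e9], pairs=[(0, 1)],
                           s=np.zeros((2, 1)), label=HEALTHY)
    with pytest.raises(ValueError):
        TransmissionRecord(frequencies=[0.5e9, 1e9], pairs=[(0, 1)],
                           s=np.zeros((3, 1)), label=HEALTHY)
    with pytest.raises(ValueError):
        TransmissionRecord(frequencies=[0.5e9, 1e9], pairs=[(0, 1)],
                           s=np.zeros((2, 1)), label="sick")


def test_hdf5_round_trip(tmp_path):
    records = [_record(seed=k, label=BLEEDING if k % 2 else HEALTHY)
               for k in range(4)]
    path = tmp_path / "records.h5"
    save_records(path, records)
    loaded = load_records(path)
    assert len(loaded) == 4
    for a, b in zip(records, loaded):
        assert np.array_equal(a.s, b.s)
        assert np.array_equal(a.frequencies, b.frequencies)
        assert a.pairs == b.pairs and a.label == b.label
        assert a.metadata == b.metadata


def test_touchstone_export_parses_back(tmp_path):
    rec = _record()
    path = tmp_path / "pair.s2p"
    rec.write_touchstone(path, pair_index=1)
    rows = np.loadtxt(path, comments=("!", "#"))
    assert rows.shape == (rec.n_freq, 9)
    assert np.allclose(rows[:, 0], rec.frequencies)
    s21 = rows[:, 3] + 1j * rows[:, 4]
    assert np.allclose(s21, rec.s[:, 1], atol=1e-8)


def test_sigma_from_noise_floor():
    assert sigma_from_noise_floor(-100.0) == pytest.approx(1e-5)
    assert sigma_from_noise_floor(-70.0) == pytest.approx(10 ** -3.5)
    assert sigma_from_noise_floor(-70.0) > sigma_from_noise_floor(-100.0)


def test_noise_statistics_match_model(rng):
    # large record: amplitude perturbation sd ~ sigma, phase ~ arctan form
    n = 400
    s = np.full((n, n // 4), 2.0 + 0.0j)
    rec = TransmissionRecord(frequencies=default_frequency_grid(n),
                             pairs=[(0, i + 1) for i in range(n // 4)],
                             s=s, label=HEALTHY)
    spec = NoiseSpec(nf_db=-40.0)
    noisy = add_vna_noise(rec, spec, rng)
    d_amp = np.abs(noisy.s) - 2.0
    assert np.std(d_amp) == pytest.approx(spec.sigma, rel=0.05)
    d_phase = np.angle(noisy.s)
    assert np.std(d_phase) == pytest.approx(
        np.std(np.arctan(spec.sigma * np.random.default_rng(1)
                         .standard_normal(10000) / 2.0)), rel=0.1)


def test_noise_independent_draws_differ_from_shared(rng):
    rec = _record(n_freq=50, n_pairs=3)
    shared = add_vna_noise(rec, NoiseSpec(nf_db=-30.0, shared_draw=True),
                           np.random.default_rng(3))
    indep = add_vna_noise(rec, NoiseSpec(nf_db=-30.0, shared_draw=False),
                          np.random.default_rng(3))
    assert not np.allclose(shared.s, indep.s)


def test_noise_clamps_amplitude_nonnegative(rng):
    rec = _record(n_freq=100, n_pairs=2)
    rec.s *= 1e-8  # amplitudes far below the noise floor
    noisy = add_vna_noise(rec, NoiseSpec(nf_db=-40.0), rng)
    assert (np.abs(noisy.s) >= 0.0).all()


def test_noise_zero_amplitude_uniform_phase_fallback(rng):
    s = np.zeros((5, 1), dtype=complex)
    rec = TransmissionRecord(frequencies=default_frequency_grid(5),
                             pairs=[(0, 1)], s=s, label=HEALTHY)
    with pytest.warns(UserWarning, match="zero-amplitude"):
        noisy = add_vna_noise(rec, NoiseSpec(nf_db=-20.0), rng)
    assert np.all(np.isfinite(noisy.s))


def test_noise_metadata_and_original_untouched(rng):
    rec = _record()
    before = rec.s.copy()
    noisy = add_vna_noise(rec, NoiseSpec(nf_db=-60.0), rng)
    assert np.array_equal(rec.s, before)
    assert noisy.metadata["noise_floor_db"] == -60.0
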