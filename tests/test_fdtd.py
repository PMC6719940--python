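import numpy as np
import pytest

from mwdetect.dielectric import DebyeModel, TissueLibrary
from mwdetect.fdtd import (C0, VACUUM, AntennaArrayLayout, FDTDSolver,
                           FieldBlowUpError, _cpml_1d, build_layout,
                           extract_spectrum, first_arrival,
                           gaussian_derivative_pulse, plane_wave_alpha,
                           scene_from_phantom, windowed_sine_pulse)


@pytest.fixture(scope="module")
def vacuum_run():
    """One small two-dipole vacuum run shared by several tests."""
    mat = np.zeros((60, 30, 30), dtype=np.int16)
    solver = FDTDSolver(mat, [VACUUM], dx=0.003, pml_cells=10)
    solver.add_dipole((18, 15, 15), "z", 5)
    solver.add_dipole((42, 15, 15), "z", 5)
    wf = gaussian_derivative_pulse()
    volts = solver.run(0, wf, max_steps=6000)
    return solver, wf, volts


def test_time_step_within_cfl_bound():
    mat = np.zeros((10, 10, 10), dtype=np.int16)
    s = FDTDSolver(mat, [VACUUM], dx=0.002)
    assert s.dt <= 0.002 / (C0 * np.sqrt(3.0))


def test_material_index_must_resolve():
    mat = np.full((8, 8, 8), 3, dtype=np.int16)
    with pytest.raises(ValueError):
        FDTDSolver(mat, [VACUUM], dx=0.003)


def test_run_requires_a_port():
    s = FDTDSolver(np.zeros((8, 8, 8), dtype=np.int16), [VACUUM], dx=0.003)
    with pytest.raises(ValueError):
        s.run(0, gaussian_derivative_pulse())


def test_dipole_geometry_validation():
    s = FDTDSolver(np.zeros((12, 12, 12), dtype=np.int16), [VACUUM],
                   dx=0.003)
    with pytest.raises(ValueError):
        s.add_dipole((6, 6, 6), "z", 4)  # even length
    with pytest.raises(ValueError):
        s.add_dipole((6, 6, 11), "z", 7)  # runs off the grid


def test_cpml_profile_vanishes_outside_layers():
    b, a, ik = _cpml_1d(50, 10, 0.003, 5e-12, 1.0, half=False)
    interior = slice(11, 39)
    assert np.all(b[interior] == 0.0)
    assert np.all(a[interior] == 0.0)
    assert np.all(ik[interior] == 1.0)
    assert np.all(b[:10] > 0.0) and np.all(b[-10:] > 0.0)


def test_instability_raises_named_error():
    mat = np.zeros((20, 20, 20), dtype=np.int16)
    s = FDTDSolver(mat, [VACUUM], dx=0.003, courant=3.0)
    s.add_dipole((10, 10, 10), "z", 3)
    with pytest.raises(FieldBlowUpError, match="step"):
        s.run(0, gaussian_derivative_pulse(), n_steps=2000)


def test_run_stops_on_decay(vacuum_run):
    solver, wf, volts = vacuum_run
    assert volts.shape[0] == 2
    assert volts.shape[1] < 6000  # residual-energy stop triggered
    assert np.abs(volts[1]).max() > 0.0  # energy reached the receiver


def test_delayed_impulse_spectrum_shift_theorem():
    dt = 5e-12
    series = np.zeros(256)
    n_d = 40
    series[n_d] = 1.0
    freqs = np.linspace(0.4e9, 1.2e9, 11)
    spec = extract_spectrum(series, dt, freqs)
    assert np.allclose(np.abs(spec), dt)
    expected_phase = -2 * np.pi * freqs * n_d * dt
    assert np.allclose(np.angle(spec), np.angle(np.exp(1j * expected_phase)))


def test_windowed_sine_has_compact_support():
    wf = windowed_sine_pulse(0.8e9, 3.0)
    t = np.array([-1e-9, 0.0, wf.duration, wf.duration + 1e-12, 1e-6])
    v = wf(t)
    assert v[0] == 0.0 and v[3] == 0.0 and v[4] == 0.0
    inside = wf(np.linspace(0, wf.duration, 200))
    assert np.abs(inside).max() > 0.5


def test_first_arrival_linear_interpolation():
    dt = 1.0
    trace = np.array([0.0, 0.0, 0.5, 1.5, 3.0])
    # crosses 1.0 between samples 2 and 3 -> t = 2.5
    assert first_arrival(trace, dt, threshold=1.0) == pytest.approx(2.5)
    with pytest.raises(ValueError):
        first_arrival(trace, dt, threshold=10.0)


def test_plane_wave_alpha_lossless_medium_is_zero():
    lossless = DebyeModel(eps_static=40.0, eps_inf=40.0, sigma=0.0,
                          tau=1e-11)
    assert plane_wave_alpha(lossless, np.array([1e9]))[0] == \
        pytest.approx(0.0, abs=1e-9)
    lossy = DebyeModel(eps_static=40.0, eps_inf=40.0, sigma=1.0, tau=1e-11)
    assert plane_wave_alpha(lossy, np.array([1e9]))[0] > 0.0


def test_nondispersive_media_carry_no_polarization_current():
    med = DebyeModel(eps_static=20.0, eps_inf=20.0, sigma=0.2, tau=1e-11)
    mat = np.zeros((24, 24, 24), dtype=np.int16)
    s = FDTDSolver(mat, [med], dx=0.003)
    s.add_dipole((12, 12, 12), "z", 3)
    peak_j = []
    s.run(0, gaussian_derivative_pulse(), n_steps=150,
          on_step=lambda n, f: peak_j.append(
              max(np.abs(f["Jx"]).max(), np.abs(f["Jy"]).max(),
                  np.abs(f["Jz"]).max())))
    assert max(peak_j) == 0.0


def test_layout_has_sixteen_antennas_and_120_pairs():
    layout = build_layout()
    assert layout.n_antennas == 16
    assert len(layout.pairs) == 120
    assert isinstance(layout, AntennaArrayLayout)


def test_scene_maps_every_cell(reference_phantom):
    layout = build_layout()
    mat, models, mat_of_label = scene_from_phantom(
        reference_phantom, layout, dx=0.006)
    assert mat.min() >= 0 and mat.max() < len(models)
    water_id = len(models) - 1
    assert (mat == water_id).any()  # boluses painted
    present = set(np.unique(reference_phantom.labels))
    assert set(mat_of_label) >= present
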