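"""Simulator checks against closed-form magnetization results and FFT identities."""

from dataclasses import replace

import numpy as np
import pytest

from mrseqopt import examples
from mrseqopt.dsl import parse_sequence, expand_defaults
from mrseqopt.phantom import make_circular_phantom
from mrseqopt.sequence_engine import compile
from mrseqopt.simulator import (
    KSpace,
    _rf_rotation,
    _SpinState,
    add_noise,
    noise_sigma_for,
    reconstruct,
    simulate,
)

GM_T1, GM_T2, GM_PD = 1350.0, 110.0, 0.8


def _single_tissue_phantom(**kwargs):
    return make_circular_phantom(fov=(16.0, 16.0), spin_density=1.0, radius=1.5,
                                 tissue="GM", **kwargs)


# --------------------------------------------------------------------------
# closed-form magnetization limits
# --------------------------------------------------------------------------


def test_free_decay_after_90_pulse():
    """|m_xy(t)| = PD * exp(-t/T2) after a single excitation."""
    state = _SpinState(_single_tissue_phantom(), off_resonance=False)
    state.pulse(90.0, 0.0)
    for t in (1.0, 30.0, 200.0):
        state_t = _SpinState(_single_tissue_phantom(), off_resonance=False)
        state_t.pulse(90.0, 0.0)
        state_t.advance_to(t)
        expected = GM_PD * np.exp(-t / GM_T2)
        assert np.abs(np.abs(state_t.mxy) - expected).max() < 1e-6


def test_spin_echo_amplitude_independent_of_off_resonance():
    """90-180 refocusing cancels uniform off-resonance exactly at TE."""
    te = 30.0
    amplitudes = []
    for df in (0.0, 37.0, 150.0):
        phantom = _single_tissue_phantom(off_resonance=df != 0, off_resonance_hz=df)
        state = _SpinState(phantom, off_resonance=True)
        state.pulse(90.0, 0.0)
        state.advance_to(te / 2)
        state.pulse(180.0, 90.0)
        state.advance_to(te)
        amplitudes.append(np.abs(state.mxy).max())
    expected = GM_PD * np.exp(-te / GM_T2)
    assert np.abs(np.asarray(amplitudes) - expected).max() < 1e-6


def test_180_pulse_conjugates_and_inverts():
    mxy, mz = _rf_rotation(np.array([0.3 + 0.4j]), np.array([0.5]), 180.0, 0.0)
    assert mxy[0] == pytest.approx(0.3 - 0.4j)
    assert mz[0] == pytest.approx(-0.5)


def _bssfp_recursion_oracle(alpha, tr, te, t1, t2, m0, n_pulses=4000):
    """Iterate the alternating-phase two-pulse recursion to steady state."""
    mxy, mz = np.array([0.0 + 0.0j]), np.array([m0])
    for i in range(n_pulses):
        mxy, mz = _rf_rotation(mxy, mz, alpha, 180.0 * (i % 2))
        if i == n_pulses - 1:
            return float(np.abs(mxy * np.exp(-te / t2))[0])
        mxy = mxy * np.exp(-tr / t2)
        mz = m0 + (mz - m0) * np.exp(-tr / t1)


def test_bssfp_steady_state_matches_recursion_oracle():
    """On-resonant bSSFP signal after >= 200 TRs agrees with the iterated
    two-pulse recursion within 1%."""
    spec = expand_defaults(parse_sequence(examples.SEQUENCE_BSSFP_DEFAULT))
    spec = replace(spec, n_rows=16, n_columns=16, measurements=16)  # 264 pulses
    plan = compile(spec)
    phantom = _single_tissue_phantom()
    n_signal_spins = int((phantom.spin_arrays()[0] > 0).sum())
    k = simulate(plan, phantom)
    per_spin = abs(k.data[8, 8]) / n_signal_spins  # DC sample, coherent sum
    oracle = _bssfp_recursion_oracle(90.0, spec.tr, spec.te, GM_T1, GM_T2, GM_PD)
    assert per_spin == pytest.approx(oracle, rel=0.01)


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------


def test_add_noise_properties():
    k = KSpace(data=np.zeros((64, 64), complex), polarity=np.ones(64, int),
               dwell=0.01, pe_fov=100.0, ro_fov=100.0)
    assert np.array_equal(add_noise(k, 0.0, seed=1).data, k.data)
    noisy = add_noise(k, 1.0, seed=2)
    assert noisy.data.real.std() == pytest.approx(1.0, rel=0.05)
    assert noisy.data.imag.std() == pytest.approx(1.0, rel=0.05)
    again = add_noise(k, 1.0, seed=2)
    assert np.array_equal(noisy.data, again.data)
    assert not np.array_equal(add_noise(k, 1.0, seed=3).data, noisy.data)
    with pytest.raises(ValueError):
        add_noise(k, -0.5, seed=1)


def test_noise_sigma_scales_with_bandwidth_and_matrix():
    base = KSpace(data=np.zeros((64, 64), complex), polarity=np.ones(64, int),
                  dwell=2.0 / 64, pe_fov=100.0, ro_fov=100.0,
                  provenance={"spin_density": 4.0})
    fast = replace_dwell(base, dwell=0.5 / 64)
    assert noise_sigma_for(fast) == pytest.approx(2.0 * noise_sigma_for(base))


def replace_dwell(k: KSpace, dwell: float) -> KSpace:
    return KSpace(data=k.data, polarity=k.polarity, dwell=dwell, pe_fov=k.pe_fov,
                  ro_fov=k.ro_fov, provenance=k.provenance)


# --------------------------------------------------------------------------
# reconstruction identities
# --------------------------------------------------------------------------


def _point_source_kspace(y0, x0, n=32, fov=100.0):
    ky = (np.arange(n) - n // 2) / fov
    kx = (np.arange(n) - n // 2) / fov
    data = np.exp(-2j * np.pi * (np.add.outer(ky * y0, kx * x0)))
    return KSpace(data=data, polarity=np.ones(n, int), dwell=0.01,
                  pe_fov=fov, ro_fov=fov)


def test_point_source_reconstructs_at_its_position():
    img = reconstruct(_point_source_kspace(5.0, -7.0))
    r, c = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
    assert (r - 50, c - 50) == (5, -7)


def test_linear_pe_phase_shifts_image():
    """Multiplying k-space by exp(-2i pi ky d) circularly shifts the image."""
    k = _point_source_kspace(0.0, 0.0)
    shifted = _point_source_kspace(0.0, 0.0)
    delta = 9.0
    ky = (np.arange(32) - 16) / 100.0
    shifted.data = shifted.data * np.exp(-2j * np.pi * ky * delta)[:, None]
    base = reconstruct(k).pixels
    moved = reconstruct(shifted).pixels
    assert np.allclose(np.roll(base, int(delta), axis=0), moved, atol=1e-9)


def test_interpolation_to_fov_grid():
    img = reconstruct(_point_source_kspace(0.0, 0.0, n=32, fov=100.0))
    assert img.pixels.shape == (100, 100)
    assert img.pixel_size == 1.0


def test_parseval_energy_conserved():
    rng = np.random.default_rng(0)
    data = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
    k = KSpace(data=data, polarity=np.ones(32, int), dwell=0.01,
               pe_fov=100.0, ro_fov=100.0)
    img = reconstruct(k, return_complex=True)
    k_energy = np.sum(np.abs(data) ** 2)
    img_energy = np.sum(np.abs(img.pixels) ** 2)
    assert abs(img_energy - k_energy) / k_energy < 1e-8


def test_negative_polarity_lines_are_reversed():
    k = _point_source_kspace(3.0, 4.0)
    flipped = KSpace(data=k.data.copy(), polarity=k.polarity.copy(), dwell=k.dwell,
                     pe_fov=k.pe_fov, ro_fov=k.ro_fov)
    flipped.data[1::2] = flipped.data[1::2, ::-1]
    flipped.polarity[1::2] = -1
    assert np.allclose(reconstruct(flipped).pixels, reconstruct(k).pixels, atol=1e-9)


# --------------------------------------------------------------------------
# sequence-level artifact physics
# --------------------------------------------------------------------------


def _epi_spec(**changes):
    spec = expand_defaults(parse_sequence(examples.SEQUENCE_EPI_DEFAULT))
    return replace(spec, n_rows=32, n_columns=32, epi_factor=32, te=20.0,
                   tr=100.0, measurements=1, **changes)


def test_epi_off_resonance_shift_matches_shift_theorem():
    """Uniform off-resonance shifts an EPI image in PE by
    delta_f * echo_spacing * FOV (the shift-theorem prediction)."""
    plan = compile(_epi_spec())
    df = 50.0
    plain = reconstruct(simulate(plan, make_circular_phantom(radius=10.0)))
    shifted = reconstruct(
        simulate(plan, make_circular_phantom(off_resonance=True, off_resonance_hz=df,
                                             radius=10.0))
    )
    predicted = df * (plan.echo_spacing / 1000.0) * 100.0  # mm on the 1-mm grid
    pcc = [
        np.corrcoef(np.roll(shifted.pixels, d, axis=0).ravel(), plain.pixels.ravel())[0, 1]
        for d in range(100)
    ]
    best = int(np.argmax(pcc))
    circular = min(best, 100 - best)
    assert circular == pytest.approx(predicted, abs=1.0)


def test_spin_echo_epi_center_line_immune_to_off_resonance():
    spec = expand_defaults(parse_sequence(examples.SEQUENCE_SE_EPI_DEFAULT))
    spec = replace(spec, n_rows=16, n_columns=16, epi_factor=16, te=40.0,
                   tr=200.0, measurements=1)
    plan = compile(spec)
    center = plan.n_rows // 2
    mags = []
    for df in (0.0, 60.0):
        phantom = make_circular_phantom(off_resonance=df != 0, off_resonance_hz=df,
                                        radius=10.0)
        k = simulate(plan, phantom)
        mags.append(np.abs(k.data[center, 8]))
    assert mags[0] == pytest.approx(mags[1], rel=1e-6)


def test_epi_odd_even_phase_error_creates_growing_n2_ghost():
    """Alternating-line phase errors produce an N/2 ghost whose level grows
    monotonically with the perturbation amplitude."""
    plan = compile(_epi_spec())
    phantom = make_circular_phantom(radius=10.0)
    k = simulate(plan, phantom)
    support = np.hypot(*np.meshgrid(np.arange(100) - 50, np.arange(100) - 50,
                                    indexing="ij")) <= 12
    ghost_region = np.roll(support, 50, axis=0)
    levels = []
    for phase_err in (0.0, 0.2, 0.5, 1.0):
        data = k.data.copy()
        data[1::2] *= np.exp(1j * phase_err)
        perturbed = KSpace(data=data, polarity=k.polarity, dwell=k.dwell,
                           pe_fov=k.pe_fov, ro_fov=k.ro_fov)
        img = reconstruct(perturbed).pixels
        levels.append(img[ghost_region].mean() / img[support].mean())
    assert all(b > a for a, b in zip(levels, levels[1:]))


def test_motion_during_multishot_acquisition_corrupts_image():
    spec = expand_defaults(parse_sequence(examples.SEQUENCE_BSSFP_DEFAULT))
    spec = replace(spec, n_rows=32, n_columns=32)
    plan = compile(spec)
    still = reconstruct(simulate(plan, make_circular_phantom(radius=10.0)))
    moving = reconstruct(
        simulate(plan, make_circular_phantom(radius=10.0, motion=True,
                                             motion_amplitude=8.0))
    )
    assert not np.allclose(still.pixels, moving.pixels, rtol=0.01)


def test_simulation_deterministic():
    plan = compile(_epi_spec())
    phantom = make_circular_phantom(radius=10.0)
    assert np.array_equal(simulate(plan, phantom).data, simulate(plan, phantom).data)
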