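"""Stimulation protocol and CEM forward-solver physics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oeseit import (
    Electrode,
    ElectrodeSet,
    MeasurementFrame,
    NoiseModel,
    PhantomSpec,
    adjacent_protocol,
    apply_noise,
    assemble_cem,
    assign_conductivity,
    build_phantom,
    difference_frame,
    refine_phantom,
    solve_forward,
)
from oeseit.phantom import ConductivityField


def brute_force_adjacent_count(n):
    """Independent enumeration: adjacent pairs avoiding each drive pair."""
    total = 0
    for l in range(n):
        drive = {l, (l + 1) % n}
        for m in range(n):
            pair = {m, (m + 1) % n}
            if not (pair & drive):
                total += 1
    return total


@pytest.mark.parametrize("n_el,expected", [(4, 4), (8, 40), (16, 208)])
def test_adjacent_protocol_measurement_count(n_el, expected):
    proto = adjacent_protocol(n_el)
    assert proto.n_measurements == expected
    assert expected == brute_force_adjacent_count(n_el)
    assert expected == n_el * (n_el - 3)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(min_value=4, max_value=24))
def test_adjacent_protocol_invariants(n_el):
    proto = adjacent_protocol(n_el)
    assert proto.n_measurements == n_el * (n_el - 3)
    for i, (a, b) in enumerate(proto.injections):
        assert b == (a + 1) % n_el  # adjacent drive
    for inj, mp, mm in proto.measurements:
        a, b = proto.injections[inj]
        assert mm == (mp + 1) % n_el  # adjacent measure
        assert not ({mp, mm} & {a, b})  # never on a drive electrode


def test_adjacent_protocol_rejects_tiny_arrays():
    with pytest.raises(ValueError):
        adjacent_protocol(3)


def test_gauge_power_and_reciprocity(small_homogeneous, protocol16):
    _, mesh, electrodes, sigma = small_homogeneous
    system = assemble_cem(mesh, sigma, electrodes)
    sol, frame = solve_forward(system, protocol16)
    # gauge: electrode voltages sum to zero
    assert np.abs(sol.voltages.sum(axis=1)).max() <= 1e-10 * np.abs(sol.voltages).max()
    # passivity: dissipated power positive for every injection
    I = np.zeros((16, 16))
    rows = np.arange(16)
    I[rows, protocol16.injections[:, 0]] = protocol16.amplitude
    I[rows, protocol16.injections[:, 1]] = -protocol16.amplitude
    assert np.einsum("ij,ij->i", sol.voltages, I).min() > 0
    # reciprocity: swap drive and measurement adjacent pairs
    t = (
        sol.voltages[:, protocol16.injections[:, 0]]
        - sol.voltages[:, protocol16.injections[:, 1]]
    ) / protocol16.amplitude
    assert np.abs(t - t.T).max() <= 1e-8 * np.abs(t).max()


def test_u_shaped_injection_pattern(small_homogeneous, protocol16):
    """Voltages fall moving away from the drive pair and rise coming back."""
    _, mesh, electrodes, sigma = small_homogeneous
    _, frame = solve_forward(assemble_cem(mesh, sigma, electrodes), protocol16)
    per_injection = np.abs(frame.values.reshape(16, 13))
    for block in per_injection:
        assert 0 < np.argmin(block) < 12  # minimum strictly interior
        assert np.argmax(block) in (0, 12)  # maxima at the endpoints


def test_conductivity_scaling_invariance(small_homogeneous, protocol16):
    """sigma -> a*sigma with z_c -> z_c/a scales every voltage by 1/a."""
    _, mesh, electrodes, sigma = small_homogeneous
    _, f1 = solve_forward(assemble_cem(mesh, sigma, electrodes), protocol16)
    a = 2.0
    sig2 = ConductivityField(a * sigma.sigma, mesh)
    els2 = ElectrodeSet(
        [Electrode(e.number, e.facets, e.center, e.z_contact / a) for e in electrodes]
    )
    _, f2 = solve_forward(assemble_cem(mesh, sig2, els2), protocol16)
    assert np.abs(a * f2.values - f1.values).max() <= 1e-10 * np.abs(f1.values).max()


def test_contact_impedance_monotonicity(small_homogeneous, protocol16):
    _, mesh, electrodes, sigma = small_homogeneous
    frames, drive_u = {}, {}
    for zc in (1e-4, 1e-3):
        els = ElectrodeSet(
            [Electrode(e.number, e.facets, e.center, zc) for e in electrodes]
        )
        sol, fr = solve_forward(assemble_cem(mesh, sigma, els), protocol16)
        frames[zc] = fr.values
        drive_u[zc] = np.abs(sol.voltages[0, 0])  # drive electrode of injection 1
    assert drive_u[1e-3] > drive_u[1e-4]
    rel = np.abs((frames[1e-3] - frames[1e-4]) / frames[1e-4])
    assert rel.max() < 0.05  # far-field barely perturbed by a 10x z_c change


def test_gauge_choice_does_not_change_difference_frames(small_external, protocol16):
    spec, mesh, electrodes = small_external
    frames = {}
    for gauge in ("sum", "node"):
        vals = {}
        for with_target in (False, True):
            sigma = assign_conductivity(mesh, spec, include_target=with_target)
            _, fr = solve_forward(
                assemble_cem(mesh, sigma, electrodes, gauge=gauge), protocol16
            )
            vals[with_target] = fr
        frames[gauge] = difference_frame(vals[True], vals[False]).values
    scale = np.abs(frames["sum"]).max()
    assert np.abs(frames["sum"] - frames["node"]).max() <= 1e-9 * scale


def test_ungauged_system_fails_loudly(small_homogeneous, protocol16):
    _, mesh, electrodes, sigma = small_homogeneous
    system = assemble_cem(mesh, sigma, electrodes, gauge="none")
    with pytest.raises(RuntimeError):
        solve_forward(system, protocol16)


def test_zero_area_electrode_rejected(small_homogeneous):
    _, mesh, electrodes, sigma = small_homogeneous
    empty = ElectrodeSet(
        [
            Electrode(e.number, e.facets[:0], e.center, e.z_contact)
            if e.number == 3
            else e
            for e in electrodes
        ]
    )
    with pytest.raises(ValueError):
        assemble_cem(mesh, sigma, empty)


def test_frame_converges_under_nested_refinement(small_homogeneous, protocol16):
    _, mesh, electrodes, sigma0 = small_homogeneous
    spec = PhantomSpec(arrangement="external", target_diameter=0.0, include_lungs=False)
    levels = [(mesh, electrodes)]
    levels.append(refine_phantom(*levels[0]))
    levels.append(refine_phantom(*levels[1]))
    vals = []
    for m, e in levels:
        sig = assign_conductivity(m, spec)
        _, fr = solve_forward(assemble_cem(m, sig, e), protocol16)
        vals.append(fr.values)
    d1 = np.linalg.norm(vals[1] - vals[0]) / np.linalg.norm(vals[1])
    d2 = np.linalg.norm(vals[2] - vals[1]) / np.linalg.norm(vals[2])
    assert d2 < d1  # Cauchy-like decrease


def test_once_refined_evaluation_frame_changes_under_2pct(protocol16):
    spec = PhantomSpec(arrangement="external", target_diameter=0.0)
    mesh, electrodes = build_phantom(spec, "forward", seed=0)
    sigma = assign_conductivity(mesh, spec)
    _, coarse = solve_forward(assemble_cem(mesh, sigma, electrodes), protocol16)
    fine_mesh, fine_els = refine_phantom(mesh, electrodes)
    fine_sigma = assign_conductivity(fine_mesh, spec)
    _, fine = solve_forward(assemble_cem(fine_mesh, fine_sigma, fine_els), protocol16)
    rel = np.linalg.norm(fine.values - coarse.values) / np.linalg.norm(fine.values)
    assert rel < 0.02


def test_noise_statistics_and_determinism(small_homogeneous, protocol16):
    _, mesh, electrodes, sigma = small_homogeneous
    _, frame = solve_forward(assemble_cem(mesh, sigma, electrodes), protocol16)
    # zero level is the identity
    same = apply_noise(frame, NoiseModel(0.0, seed=1))
    assert np.array_equal(same.values, frame.values)
    # a long synthetic frame recovers the nominal standard deviation
    long_proto = adjacent_protocol(100, 1e-3)
    big = MeasurementFrame(np.full(long_proto.n_measurements, 1.0), long_proto)
    noisy = apply_noise(big, NoiseModel(5e-4, seed=3))
    sample_std = (noisy.values - big.values).std()
    assert sample_std == pytest.approx(5e-4 * 1.0, rel=0.03)
    # same seed, same draw; different seed, different draw
    a = apply_noise(frame, NoiseModel(5e-4, seed=5))
    b = apply_noise(frame, NoiseModel(5e-4, seed=5))
    c = apply_noise(frame, NoiseModel(5e-4, seed=6))
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)
    with pytest.raises(ValueError):
        NoiseModel(-1e-4, seed=0)


def test_difference_frame_semantics(small_external, protocol16):
    spec, mesh, electrodes = small_external
    ref = assign_conductivity(mesh, spec, include_target=False)
    tgt = assign_conductivity(mesh, spec, include_target=True)
    _, f_ref = solve_forward(assemble_cem(mesh, ref, electrodes), protocol16)
    _, f_tgt = solve_forward(assemble_cem(mesh, tgt, electrodes), protocol16)
    zero = difference_frame(f_ref, f_ref)
    assert np.all(zero.values == 0)
    dv = difference_frame(f_tgt, f_ref)
    assert np.any(dv.values != 0)
    other = adjacent_protocol(8)
    with pytest.raises(ValueError):
        difference_frame(f_tgt, MeasurementFrame(np.zeros(40), other))


def test_difference_response_is_locally_linear(small_external, protocol16):
    """Halving the target contrast roughly halves the voltage difference."""
    spec, mesh, electrodes = small_external
    ref = assign_conductivity(mesh, spec, include_target=False)
    _, f_ref = solve_forward(assemble_cem(mesh, ref, electrodes), protocol16)
    diffs = {}
    for scale in (1.0, 0.5):
        sig = ref.sigma.copy()
        inside = assign_conductivity(mesh, spec, include_target=True).sigma == 0.7
        sig[inside] = 0.48 + scale * 0.05  # small contrast for linearity
        _, f = solve_forward(
            assemble_cem(mesh, ConductivityField(sig, mesh), electrodes), protocol16
        )
        diffs[scale] = difference_frame(f, f_ref).values
    ratio = np.linalg.norm(diffs[0.5]) / np.linalg.norm(diffs[1.0])
    assert ratio == pytest.approx(0.5, rel=0.10)
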