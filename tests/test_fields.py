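"""Coulomb field engine, H-bond classification, trajectory summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnprobe.fields import (
    COULOMB_MV_PER_CM,
    DonorCandidate,
    HBondCriteria,
    ProbeGeometry,
    SingularityError,
    analyze_trajectory,
    classify_hbond,
    donor_candidates_from_charges,
    field_at_point,
    projected_field,
)
from cnprobe.simulate import TRAJECTORY_PRESETS, generate_trajectory, trajectory_preset

PROBE = ProbeGeometry(0, 1)
R_C = np.zeros(3)
R_N = np.array([1.16, 0.0, 0.0])


def brute_force_field(positions, charges, point, exclude=()):
    """Independent naive Coulomb loop (kept deliberately dumb)."""
    e = [0.0, 0.0, 0.0]
    for i in range(len(positions)):
        if i in exclude:
            continue
        dx = [point[k] - positions[i][k] for k in range(3)]
        r = (dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2) ** 0.5
        for k in range(3):
            e[k] += 14.3996 * 100.0 * charges[i] * dx[k] / r ** 3
    return np.array(e)


def brute_force_projected(positions, charges, exclude=(0, 1)):
    axis = (positions[1] - positions[0])
    axis = axis / np.linalg.norm(axis)
    ec = brute_force_field(positions, charges, positions[0], exclude)
    en = brute_force_field(positions, charges, positions[1], exclude)
    return float(0.5 * (ec + en) @ axis)


# --- closed forms ---------------------------------------------------------

def test_unit_charge_at_one_angstrom():
    e = field_at_point(np.array([[1.0, 0.0, 0.0]]), np.array([1.0]), np.zeros(3))
    assert np.linalg.norm(e) == pytest.approx(1439.96)
    assert e[0] < 0  # field points away from the positive charge


def test_symmetric_charges_cancel():
    pos = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
    e = field_at_point(pos, np.array([0.7, 0.7]), np.zeros(3))
    assert np.linalg.norm(e) < 1e-12


def test_dipole_far_field_closed_form():
    """On-axis field of a +/-0.5 e dipole (0.5 A) at 20 A: 2 k q d / r^3."""
    pos = np.array([[20.25, 0, 0], [19.75, 0, 0]])
    q = np.array([0.5, -0.5])
    e = field_at_point(pos, q, np.zeros(3))
    expected = 2.0 * COULOMB_MV_PER_CM * 0.5 * 0.5 / 20.0 ** 3
    assert abs(np.linalg.norm(e) - expected) / expected < 0.01


def test_projected_field_on_axis_charge():
    """+0.5 e at 3.0 A beyond N: -80.0 at N and -41.6 at C, average -60.8."""
    pos = np.vstack([R_C, R_N, R_N + [3.0, 0, 0]])
    q = np.array([0.28, -0.56, 0.5])
    at_n = field_at_point(pos, q, R_N, exclude=[0, 1])[0]
    at_c = field_at_point(pos, q, R_C, exclude=[0, 1])[0]
    assert at_n == pytest.approx(-80.0, abs=0.01)
    assert at_c == pytest.approx(-41.6, abs=0.05)
    f = projected_field(pos, q, PROBE)
    assert f == pytest.approx(-60.8, abs=0.03)


def test_projected_field_no_environment_is_zero():
    pos = np.vstack([R_C, R_N])
    assert projected_field(pos, np.array([0.28, -0.56]), PROBE) == 0.0


def test_singularity_raises():
    pos = np.vstack([R_C, R_N, R_N])
    with pytest.raises(SingularityError, match="atom 2"):
        projected_field(pos, np.array([0.0, 0.0, 1.0]), PROBE)


def test_probe_bond_length_sanity_band():
    pos = np.vstack([R_C, [3.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="sanity band"):
        projected_field(pos, np.array([0.0, 0.0]), PROBE)


# --- properties -----------------------------------------------------------

@given(seed=st.integers(0, 2**16), n=st.integers(1, 8))
def test_superposition(seed, n):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(2.0, 8.0, (n, 3))
    q = rng.uniform(-1.0, 1.0, n)
    total = field_at_point(pos, q, np.zeros(3))
    parts = sum(field_at_point(pos[i:i + 1], q[i:i + 1], np.zeros(3))
                for i in range(n))
    assert np.max(np.abs(total - parts)) < 1e-9


@given(seed=st.integers(0, 2**16), s=st.floats(0.5, 4.0))
def test_inverse_square_scaling(s, seed):
    """Scaling all positions (and the evaluation point) by s scales E by s^-2."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(2.5, 8.0, (5, 3))
    q = rng.uniform(-0.8, 0.8, 5)
    point = rng.uniform(-1.0, 1.0, 3)
    e1 = field_at_point(pos, q, point)
    e2 = field_at_point(pos * s, q, point * s)
    assert np.allclose(e2, e1 / s**2, rtol=1e-12, atol=1e-12)


def test_engine_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(100):
        n_env = rng.integers(3, 12)
        pos = np.vstack([R_C, R_N, rng.uniform(-8, 8, (n_env, 3))])
        keep = np.linalg.norm(pos[2:] - R_N, axis=1) > 1.5
        pos = np.vstack([pos[:2], pos[2:][keep]])
        q = np.concatenate([[0.28, -0.56], rng.uniform(-1, 1, pos.shape[0] - 2)])
        fast = projected_field(pos, q, PROBE)
        slow = brute_force_projected(pos, q)
        worst = max(worst, abs(fast - slow))
    assert worst < 1e-8


# --- hydrogen-bond classification -----------------------------------------

def _donor_frame(distance, angle_deg):
    """Probe along x, donor at `distance` from N on the x axis, hydrogen 1 A
    from the donor at `angle_deg` from the D->N direction."""
    d_pos = R_N + np.array([distance, 0.0, 0.0])
    beta = np.radians(angle_deg)
    h_pos = d_pos + np.array([-np.cos(beta), 0.0, np.sin(beta)])
    return np.vstack([R_C, R_N, d_pos, h_pos])


DONORS = [DonorCandidate(2, 3, "O", "D0")]


def brute_force_hbond(frame, distance_cutoff, angle_cutoff):
    import math
    d = [frame[2][k] - frame[1][k] for k in range(3)]
    dist = math.sqrt(sum(x * x for x in d))
    v1 = [frame[3][k] - frame[2][k] for k in range(3)]
    v2 = [frame[1][k] - frame[2][k] for k in range(3)]
    dot = sum(a * b for a, b in zip(v1, v2))
    n1 = math.sqrt(sum(a * a for a in v1))
    n2 = math.sqrt(sum(a * a for a in v2))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2)))))
    # same contract as the engine: inclusive cutoffs, 1e-9 rounding guard
    return dist <= distance_cutoff + 1e-9 and ang <= angle_cutoff + 1e-9


def test_hbond_short_distance_small_angle_is_bonded():
    res = classify_hbond(_donor_frame(2.9, 10.0), PROBE, DONORS)
    assert res.bonded
    assert res.donor.label == "D0"
    assert res.distance_A == pytest.approx(2.9)
    assert res.angle_deg == pytest.approx(10.0, abs=1e-9)


def test_hbond_boundary_exclusive_beyond_cutoff():
    assert not classify_hbond(_donor_frame(4.01, 0.0), PROBE, DONORS).bonded
    # cutoffs themselves are inclusive
    assert classify_hbond(_donor_frame(4.0, 30.0), PROBE, DONORS).bonded


def test_hbond_grid_matches_brute_force_oracle():
    crit = HBondCriteria()
    for distance in np.linspace(2.5, 5.0, 11):
        for angle in np.linspace(0.0, 60.0, 13):
            frame = _donor_frame(distance, angle)
            fast = classify_hbond(frame, PROBE, DONORS, crit).bonded
            slow = brute_force_hbond(frame, 4.0, 30.0)
            assert fast == slow, (distance, angle)


@given(distance=st.floats(2.2, 6.0), angle=st.floats(0.0, 80.0),
       extra_d=st.floats(0.1, 2.0), extra_a=st.floats(0.1, 30.0))
def test_hbond_monotone_in_cutoffs(distance, angle, extra_d, extra_a):
    """Enlarging either cutoff never unlabels a bonded frame."""
    frame = _donor_frame(distance, angle)
    base = HBondCriteria()
    wider = HBondCriteria(base.distance_cutoff_A + extra_d,
                          base.angle_cutoff_deg + extra_a)
    if classify_hbond(frame, PROBE, DONORS, base).bonded:
        assert classify_hbond(frame, PROBE, DONORS, wider).bonded


def test_hbond_donor_without_hydrogen_rejected():
    with pytest.raises(ValueError, match="no hydrogen"):
        classify_hbond(_donor_frame(2.9, 0.0), PROBE,
                       [DonorCandidate(2, None, "O")])


def test_hbond_nearest_qualifying_donor_reported():
    frame = np.vstack([_donor_frame(3.5, 5.0), _donor_frame(2.8, 5.0)[2:]])
    donors = [DonorCandidate(2, 3, "O", "far"), DonorCandidate(4, 5, "O", "near")]
    res = classify_hbond(frame, PROBE, donors)
    assert res.bonded and res.donor.label == "near"


def test_hbond_carbon_not_a_donor():
    res = classify_hbond(_donor_frame(2.9, 0.0), PROBE,
                         [DonorCandidate(2, 3, "C")])
    assert not res.bonded


# --- trajectory analysis --------------------------------------------------

def test_single_frame_summary_equals_record():
    traj = generate_trajectory(trajectory_preset("apo_F92", 1), seed=0)
    table, summary = analyze_trajectory(traj.coords, traj.charges, PROBE)
    assert summary.n_frames == 1
    assert summary.overall_mean_MVcm == table["field_MVcm"].iloc[0]
    assert summary.replicate_means_MVcm == [table["field_MVcm"].iloc[0]]


def test_two_state_recovery_across_occupancies():
    """Classifier + field engine recover construction occupancy and state
    means for p in {0.1, 0.5, 0.9}."""
    from cnprobe.simulate import TrajectoryModel
    for p in (0.1, 0.5, 0.9):
        model = TrajectoryModel(n_frames=10_000, hbond_occupancy=p,
                                bonded_field_MVcm=-70.0, free_field_MVcm=-20.0)
        traj = generate_trajectory(model, seed=int(p * 10))
        table, summary = analyze_trajectory(traj.coords, traj.charges, PROBE)
        assert abs(summary.populations["bonded"] - traj.labels.mean()) <= 0.01
        assert abs(summary.populations["bonded"] - p) <= 0.02
        assert abs(summary.bonded_mean_MVcm - (-70.0)) < 1.0
        assert abs(summary.free_mean_MVcm - (-20.0)) < 1.0


def test_zero_occupancy_classifier_finds_no_bonded_frames():
    from cnprobe.simulate import TrajectoryModel
    model = TrajectoryModel(n_frames=500, hbond_occupancy=0.0,
                            bonded_field_MVcm=-70.0, free_field_MVcm=-20.0)
    traj = generate_trajectory(model, seed=2)
    table, summary = analyze_trajectory(traj.coords, traj.charges, PROBE)
    assert summary.populations["bonded"] == 0.0


def test_overall_mean_is_population_weighted_state_mean():
    traj = generate_trajectory(trajectory_preset("holo_F92", 2000), seed=1)
    _, s = analyze_trajectory(traj.coords, traj.charges, PROBE)
    weighted = (s.populations["bonded"] * s.bonded_mean_MVcm
                + s.populations["free"] * s.free_mean_MVcm)
    assert abs(weighted - s.overall_mean_MVcm) < 1e-9
    assert abs(sum(s.populations.values()) - 1.0) < 1e-12


def test_apo_less_hydrogen_bonded_than_holo():
    occ = {}
    for name in ("apo_F92", "holo_F92"):
        traj = generate_trajectory(trajectory_preset(name, 2000), seed=8)
        _, s = analyze_trajectory(traj.coords, traj.charges, PROBE)
        occ[name] = s.populations["bonded"]
    assert occ["apo_F92"] < occ["holo_F92"]


def test_replicate_boundaries_validated():
    traj = generate_trajectory(trajectory_preset("apo_F96", 100), seed=0)
    with pytest.raises(ValueError):
        analyze_trajectory(traj.coords, traj.charges, PROBE,
                           replicates=[0, 50, 120])
    table, s = analyze_trajectory(traj.coords, traj.charges, PROBE,
                                  replicates=4)
    assert len(s.replicate_means_MVcm) == 4
    assert s.aggregate_mean_MVcm == pytest.approx(np.mean(s.replicate_means_MVcm))


def test_probe_charges_excluded_from_sum():
    traj = generate_trajectory(trajectory_preset("apo_F96", 5), seed=0)
    charges = traj.charges.copy()
    charges.loc[charges["role"] == "probe_C", "charge_e"] = 5.0  # should not matter
    base, _ = analyze_trajectory(traj.coords, traj.charges, PROBE)
    mod, _ = analyze_trajectory(traj.coords, charges, PROBE)
    assert np.allclose(base["field_MVcm"], mod["field_MVcm"])


def test_donor_candidates_paired_from_roles():
    traj = generate_trajectory(trajectory_preset("apo_F96", 1), seed=0)
    cands = donor_candidates_from_charges(traj.charges)
    assert len(cands) == 1
    assert (cands[0].donor_index, cands[0].hydrogen_index) == (2, 3)
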