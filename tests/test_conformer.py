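"""Kabsch RMSD, redundant-conformer elimination, Boltzmann weights, XYZ I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from stereoshift.conformer import (
    R_GAS,
    Ensemble,
    boltzmann_weights,
    eliminate_redundant,
    kabsch_rmsd,
    read_xyz,
    write_xyz,
)
from stereoshift.synthetic import generate_toy_conformers

# ------------------------------------------------------------------ RMSD


def brute_force_min_rmsd(pa, pb):
    """Independent oracle: coarse Euler-angle grid + local refinement.

    Never calls the Kabsch solver; searches rotation space directly.
    """
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)

    def rmsd_at(angles):
        rot = Rotation.from_euler("zyx", angles).as_matrix()
        return float(np.sqrt(np.mean(np.sum((pb @ rot.T - pa) ** 2, axis=1))))

    grid = np.linspace(0, 2 * math.pi, 25)[:-1]
    best_angles, best = None, np.inf
    for a in grid:
        for b in grid:
            for c in grid:
                v = rmsd_at((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)
    res = minimize(rmsd_at, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return min(best, float(res.fun))


def test_rmsd_identity(make_conf):
    a = make_conf([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
    assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)


def test_rmsd_invariant_under_proper_rotation_and_translation(make_conf, rng):
    coords = rng.normal(size=(7, 3))
    a = make_conf(coords)
    rot = Rotation.random(random_state=7).as_matrix()
    b = make_conf(coords @ rot.T + np.array([3.0, -2.0, 5.0]))
    assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_matches_rotation_grid_oracle(make_conf):
    # 3-atom toy frames, one atom displaced by d
    base = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0]])
    for d in (0.3, 0.8, 2.0):
        moved = base.copy()
        moved[2, 2] += d
        got = kabsch_rmsd(make_conf(base), make_conf(moved))
        expected = brute_force_min_rmsd(base, moved)
        assert got == pytest.approx(expected, abs=1e-6)


def test_rmsd_matches_oracle_on_random_frames(make_conf, rng):
    for _ in range(3):
        pa = rng.normal(size=(5, 3))
        pb = rng.normal(size=(5, 3))
        assert kabsch_rmsd(make_conf(pa), make_conf(pb)) == pytest.approx(
            brute_force_min_rmsd(pa, pb), abs=1e-6
        )


def test_rmsd_excludes_reflections(make_conf):
    # a chiral 4-point set and its mirror image: RMSD must stay positive
    coords = np.array(
        [[0.0, 0, 0], [1.8, 0, 0], [0, 1.4, 0], [0.3, 0.4, 2.2]]
    )
    mirror = coords * np.array([1.0, 1.0, -1.0])
    assert kabsch_rmsd(make_conf(coords), make_conf(mirror)) > 0.1


def test_rmsd_metric_properties(make_conf, rng):
    frames = [make_conf(rng.normal(size=(6, 3))) for _ in range(4)]
    for a in frames:
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-6)
        for b in frames:
            ab = kabsch_rmsd(a, b)
            assert ab >= 0
            assert ab == pytest.approx(kabsch_rmsd(b, a), abs=1e-6)


def test_rmsd_heavy_atom_default_ignores_hydrogens(make_conf):
    els = ("C", "C", "C", "H")
    a = make_conf([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], elements=els)
    shifted_h = make_conf(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 9]], elements=els
    )
    assert kabsch_rmsd(a, shifted_h) == pytest.approx(0.0, abs=1e-9)
    assert kabsch_rmsd(a, shifted_h, heavy_only=False) > 1.0


def test_rmsd_rejects_mismatched_atoms(make_conf):
    a = make_conf([[0, 0, 0], [1, 0, 0]])
    b = make_conf([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    with pytest.raises(ValueError):
        kabsch_rmsd(a, b)
    with pytest.raises(IndexError):
        kabsch_rmsd(a, a, subset=[0, 5])


# ------------------------------------------------------------- elimination


def brute_force_greedy(ensemble, cutoff, window):
    """Literal restatement of the pruning rule, list-by-list."""
    e_min = min(c.energy for c in ensemble.conformers)
    pool = sorted(
        (c for c in ensemble.conformers if c.energy <= e_min + window),
        key=lambda c: c.energy,
    )
    kept = []
    for cand in pool:
        ok = True
        for ref in kept:
            if kabsch_rmsd(cand, ref) < cutoff:
                ok = False
        if ok:
            kept.append(cand)
    return [c.id for c in kept]


def test_identical_geometries_collapse_to_lowest_energy(make_conf):
    coords = [[0, 0, 0], [1, 0, 0], [0, 1, 0]]
    ens = Ensemble(
        "dup",
        tuple(make_conf(coords, cid=f"c{i}", energy=float(i)) for i in range(5)),
    )
    pruned = eliminate_redundant(ens)
    assert len(pruned) == 1
    assert pruned.conformers[0].id == "c0"


def test_energy_window_removes_high_energy_conformers(rng, make_conf):
    # conformer at min + 14 kJ/mol is beyond the 13 kJ/mol window
    coords = rng.normal(size=(5, 3))
    far = rng.normal(size=(5, 3)) * 5
    ens = Ensemble(
        "w",
        (
            make_conf(coords, cid="low", energy=0.0),
            make_conf(far, cid="high", energy=14.0),
        ),
    )
    pruned = eliminate_redundant(ens)
    assert [c.id for c in pruned.conformers] == ["low"]
    # at exactly the window edge the conformer survives
    ens2 = Ensemble(
        "w2",
        (
            make_conf(coords, cid="low", energy=0.0),
            make_conf(far, cid="edge", energy=13.0),
        ),
    )
    assert len(eliminate_redundant(ens2)) == 2


def test_pruning_matches_brute_force_oracle():
    for seed in range(5):
        ens = generate_toy_conformers(6, 5, displacement_sd=1.0, seed=seed)
        pruned = eliminate_redundant(ens)
        assert [c.id for c in pruned.conformers] == brute_force_greedy(
            ens, 1.0, 13.0
        )


def test_pruning_is_idempotent_and_keeps_global_minimum():
    ens = generate_toy_conformers(8, 6, displacement_sd=1.2, seed=42)
    once = eliminate_redundant(ens)
    twice = eliminate_redundant(once)
    assert [c.id for c in once.conformers] == [c.id for c in twice.conformers]
    e_min_id = min(ens.conformers, key=lambda c: c.energy).id
    assert once.conformers[0].id == e_min_id


def test_all_kept_pairs_separated_by_cutoff():
    ens = generate_toy_conformers(10, 5, displacement_sd=1.5, seed=3)
    pruned = eliminate_redundant(ens)
    kept = pruned.conformers
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            assert kabsch_rmsd(kept[i], kept[j]) >= 1.0


def test_empty_ensemble_rejected():
    with pytest.raises(ValueError):
        eliminate_redundant(Ensemble("empty", ()))


# --------------------------------------------------------------- Boltzmann


def test_boltzmann_equal_energies_uniform():
    w = boltzmann_weights([5.0, 5.0, 5.0, 5.0])
    assert np.allclose(w, 0.25, atol=1e-12)


def test_boltzmann_rt_ln2_gives_two_thirds():
    T = 298.15
    rt = R_GAS * T / 1000.0
    w = boltzmann_weights([0.0, rt * math.log(2.0)], T)
    assert w == pytest.approx([2 / 3, 1 / 3], abs=1e-12)


def test_boltzmann_hand_evaluation():
    T = 298.15
    rt = R_GAS * T / 1000.0
    raw = [math.exp(-e / rt) for e in [0.0, 2.0, 5.0]]
    expected = [r / sum(raw) for r in raw]
    assert boltzmann_weights([0.0, 2.0, 5.0], T) == pytest.approx(
        expected, abs=1e-9
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=50), min_size=1, max_size=8),
    st.floats(min_value=-100, max_value=100),
)
def test_boltzmann_shift_invariance_and_normalisation(energies, shift):
    w1 = boltzmann_weights(energies)
    w2 = boltzmann_weights([e + shift for e in energies])
    assert np.allclose(w1, w2, atol=1e-9)
    assert abs(w1.sum() - 1.0) < 1e-12


def test_boltzmann_temperature_limits():
    energies = [0.0, 3.0, 7.0]
    hot = boltzmann_weights(energies, T=1e9)
    assert np.allclose(hot, 1 / 3, atol=1e-6)
    cold = boltzmann_weights(energies, T=1e-2)
    assert cold[0] == pytest.approx(1.0, abs=1e-12)
    # strictly decreasing in energy at finite T
    w = boltzmann_weights(energies)
    assert w[0] > w[1] > w[2]


# --------------------------------------------------------------------- I/O


def test_xyz_roundtrip(tmp_path):
    ens = generate_toy_conformers(3, 4, displacement_sd=0.7, seed=9)
    path = tmp_path / "frames.xyz"
    write_xyz(path, ens.conformers)
    frames = read_xyz(path)
    assert len(frames) == 3
    for orig, back in zip(ens.conformers, frames):
        assert back.elements == orig.elements
        assert np.allclose(back.coords, orig.coords, atol=1e-6)
        assert back.energy == pytest.approx(orig.energy, abs=1e-6)


def test_xyz_energy_units_converted(tmp_path):
    path = tmp_path / "kcal.xyz"
    path.write_text("2\nE=1.0 kcal/mol\nC 0 0 0\nC 1 0 0\n")
    (frame,) = read_xyz(path)
    assert frame.energy == pytest.approx(4.184)
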