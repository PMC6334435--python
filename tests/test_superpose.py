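"""Rigid superposition: Kabsch optimality, pruning, ligand transplantation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tklscan.msa_metrics import build_alignment_map
from tklscan.structure_io import Alignment
from tklscan.superpose import (
    LigandSelection,
    RigidTransform,
    iterative_prune_fit,
    kabsch,
    kabsch_fit,
    matched_calpha_pairs,
    transplant_ligand,
)


def grid_search_rmsd(P, Q, n_grid=4000, seed=0):
    """Independent superposition oracle: random-rotation grid search with
    local refinement over the rotation vector; never uses the SVD path."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = Pc @ R.T - Qc
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_grid, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    Rs = Rotation.from_quat(quats).as_matrix()
    moved = np.einsum("nij,kj->nki", Rs, Pc)
    rmsds = np.sqrt(np.mean(np.sum((moved - Qc) ** 2, axis=2), axis=1))
    best = Rotation.from_quat(quats[int(np.argmin(rmsds))]).as_rotvec()
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
    return float(res.fun)


def random_points(rng, n):
    return rng.normal(scale=3.0, size=(n, 3))


def test_self_fit_is_identity():
    rng = np.random.default_rng(0)
    P = random_points(rng, 10)
    res = kabsch_fit((P, P))
    assert res.rmsd_all < 1e-9
    assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(res.transform.translation, 0.0, atol=1e-9)


def test_planted_transform_recovered_exactly():
    rng = np.random.default_rng(1)
    P = random_points(rng, 12)
    R = Rotation.from_euler("xyz", [33, -70, 15], degrees=True).as_matrix()
    t = np.array([1.0, -2.0, 3.0])
    Q = P @ R.T + t
    res = kabsch_fit((P, Q))
    assert res.rmsd_all < 1e-6
    assert np.abs(res.transform.rotation - R).max() < 1e-6
    assert np.abs(res.transform.translation - t).max() < 1e-6
    # rotation-angle error below 1e-4 rad
    err = RigidTransform(res.transform.rotation @ R.T, np.zeros(3)).angle()
    assert err < 1e-4


@pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (8, 2), (8, 3)])
def test_kabsch_matches_grid_search_oracle(n, seed):
    """On small noisy point sets the closed-form fit equals an independent
    quaternion grid-search + refinement oracle."""
    rng = np.random.default_rng(seed)
    P = random_points(rng, n)
    R = Rotation.random(random_state=seed).as_matrix()
    Q = P @ R.T + rng.normal(scale=0.5, size=(n, 3))
    res = kabsch_fit((P, Q))
    oracle = grid_search_rmsd(P, Q, seed=seed)
    # the oracle can never beat the closed-form optimum, and must reach it
    assert res.rmsd_all <= oracle + 1e-9
    assert oracle - res.rmsd_all < 1e-5


def test_degenerate_point_sets_rejected():
    line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="degenerate|collinear"):
        kabsch(line, line)
    with pytest.raises(ValueError):
        kabsch_fit((np.zeros((4, 3)), np.zeros((4, 3))))


@settings(derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10**6))
def test_rmsd_invariant_under_rigid_pretransform(seed):
    rng = np.random.default_rng(seed)
    P = random_points(rng, 9)
    Q = random_points(rng, 9)
    base = kabsch_fit((P, Q)).rmsd_all
    R = Rotation.random(random_state=seed).as_matrix()
    moved = kabsch_fit((P @ R.T + np.array([4.0, 5.0, -6.0]), Q)).rmsd_all
    assert moved == pytest.approx(base, abs=1e-8)


def test_forward_and_reverse_fits_are_inverse():
    rng = np.random.default_rng(4)
    P = random_points(rng, 15)
    Q = random_points(rng, 15) * 0.1 + P  # nearly rigid pair
    fwd = kabsch_fit((P, Q)).transform
    rev = kabsch_fit((Q, P)).transform
    comp = fwd.compose(rev)
    assert comp.angle() < 1e-6
    assert np.abs(comp.translation).max() < 1e-6


def test_noise_rmsd_scale():
    """Isotropic noise sigma per coordinate gives RMSD near sigma*sqrt(3),
    slightly reduced by the fitted degrees of freedom."""
    rng = np.random.default_rng(5)
    P = random_points(rng, 400)
    sigma = 0.2
    Q = P + rng.normal(scale=sigma, size=P.shape)
    r = kabsch_fit((P, Q)).rmsd_all
    expected = sigma * np.sqrt(3.0)
    assert 0.85 * expected < r <= expected * 1.05


def test_pruning_removes_planted_outliers():
    rng = np.random.default_rng(6)
    P = random_points(rng, 50)
    R = Rotation.from_euler("z", 25, degrees=True).as_matrix()
    Q = P @ R.T + np.array([1.0, 2.0, 3.0])
    outliers = rng.choice(50, size=5, replace=False)
    Q[outliers] += rng.normal(scale=8.0, size=(5, 3)) + 8.0
    res = iterative_prune_fit((P, Q), cutoff=2.0)
    assert res.n_pairs_retained == 45
    assert set(np.nonzero(~res.retained_mask)[0]) == set(outliers)
    clean = np.setdiff1d(np.arange(50), outliers)
    ref = kabsch_fit((P[clean], Q[clean]))
    assert res.rmsd_pruned == pytest.approx(ref.rmsd_all, abs=1e-9)
    assert res.rmsd_pruned <= res.rmsd_all


def test_pruning_noop_on_clean_data():
    rng = np.random.default_rng(7)
    P = random_points(rng, 30)
    Q = P + rng.normal(scale=0.05, size=P.shape)
    plain = kabsch_fit((P, Q))
    pruned = iterative_prune_fit((P, Q), cutoff=2.0)
    assert pruned.n_pairs_retained == 30
    assert pruned.rmsd_pruned == pytest.approx(plain.rmsd_all, abs=1e-12)


def test_all_pairs_pruned_raises():
    rng = np.random.default_rng(8)
    P = random_points(rng, 10)
    Q = P + rng.normal(scale=9.0, size=P.shape)
    with pytest.raises(ValueError, match="cutoff"):
        iterative_prune_fit((P, Q), cutoff=0.01)


# ---------------------------------------------------------------------------
# matched pairs through the alignment map

def test_matched_pairs_and_deletion_columns(toy_pair):
    template, query, truth = toy_pair
    amap = build_alignment_map(
        truth["alignment"],
        [("template", template, "A"), ("query", query, "A")],
    )
    P, Q, cols = matched_calpha_pairs(
        amap, (template, "A"), (query, "A"),
        ref_id="template", query_id="query",
    )
    n_res = len(template.chain("A"))
    n_del = truth["deletion"]["length"]
    assert len(P) == n_res - n_del
    # deletion columns contribute no pairs
    deleted_cols = {
        i for i, ptr in enumerate(amap.pointers["query"]) if ptr is None
    }
    assert deleted_cols.isdisjoint(cols)


def test_structure_against_itself_pairs_all_residues(toy_complex):
    template, _, truth = toy_complex
    aln = Alignment(names=["s1", "s2"], rows=[truth["sequence"]] * 2)
    amap = build_alignment_map(
        aln, [("s1", template, "A"), ("s2", template, "A")]
    )
    P, Q, _ = matched_calpha_pairs(
        amap, (template, "A"), (template, "A"), ref_id="s1", query_id="s2"
    )
    assert len(P) == len(template.chain("A"))
    assert np.array_equal(P, Q)


# ---------------------------------------------------------------------------
# ligand transplantation

def test_identity_transplant_preserves_coordinates(toy_complex):
    template, query, _ = toy_complex
    out = transplant_ligand(
        RigidTransform.identity(), template, LigandSelection(["TLX"]), query
    )
    src = np.array([a.coords for r in template.ligands for a in r.atoms])
    dst = np.array([a.coords for r in out.ligands for a in r.atoms])
    assert np.array_equal(src, dst)


def test_transplant_preserves_distance_matrix(toy_complex, planted_transform):
    template, query, _ = toy_complex
    out = transplant_ligand(
        planted_transform, template, LigandSelection(["TLX"]), query
    )
    src = np.array([a.coords for r in template.ligands for a in r.atoms])
    dst = np.array([a.coords for r in out.ligands for a in r.atoms])
    d_src = np.linalg.norm(src[:, None] - src[None], axis=-1)
    d_dst = np.linalg.norm(dst[:, None] - dst[None], axis=-1)
    assert np.abs(d_src - d_dst).max() < 1e-6


def test_empty_selection_raises(toy_complex):
    template, query, _ = toy_complex
    with pytest.raises(ValueError, match="matched no hetero"):
        transplant_ligand(
            RigidTransform.identity(), template, LigandSelection(["ZZZ"]), query
        )


def test_transplanted_ligand_sits_in_the_interchain_cleft(toy_pair):
    """After fitting the query on the template, the transplanted ligand
    lands between the two query chains (the pseudo-ligand is sparse, so the
    contact radius is wider than for a real cofactor)."""
    from tklscan.interactions import cleft_check

    template, query, truth = toy_pair
    amap = build_alignment_map(
        truth["alignment"],
        [("template", template, "A"), ("query", query, "A")],
    )
    pairs = matched_calpha_pairs(
        amap, (template, "A"), (query, "A"),
        ref_id="template", query_id="query",
    )
    sup = iterative_prune_fit(pairs)
    out = transplant_ligand(sup.transform, template, LigandSelection(["TLX"]), query)
    cleft = cleft_check(out, radius=7.5)
    assert cleft["inter_subunit_cleft"] is True


def test_reflection_is_rejected():
    with pytest.raises(ValueError, match="reflection|improper"):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
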