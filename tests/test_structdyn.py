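"""Superposition, displacement fields, rotation angles: exact round trips
and independent brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dynstalk import structdyn
from dynstalk.structdyn import (
    ca_distance,
    displacement_field,
    interface_gap,
    kabsch,
    load_structure,
    load_subdomain_scheme,
    principal_axis,
    rotation_angle,
    split_subdomains,
    superpose,
    write_structure,
)
from dynstalk.synth import (
    generate_structure_pair,
    rotation_about,
    translation_only,
)


def cloud_rmsd(P, Q):
    return np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1)))


# ---------------------------------------------------------------------------
# I/O

MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       2.000   3.000   1.000  1.00  0.00           C
ATOM      4  CA  SER A   3      -1.000   2.500   0.750  1.00  0.00           C
END
"""


def test_minimal_pdb_parses_exact_coordinates(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    sm = load_structure(path)
    res, letters, xyz = sm.ca_table()
    assert list(res) == [1, 2, 3]
    assert list(letters) == ["A", "G", "S"]
    assert np.allclose(xyz[1], [2.0, 3.0, 1.0])


def test_multi_model_selection(tmp_path):
    two = ("MODEL        1\n" + MINI_PDB.replace("END\n", "ENDMDL\n")
           + "MODEL        2\n"
           + MINI_PDB.replace("1.458", "9.999").replace("END\n", "ENDMDL\nEND\n"))
    path = tmp_path / "two.pdb"
    path.write_text(two)
    sm2 = load_structure(path, model_index=2)
    assert np.isclose(sm2.ca_table()[2][0][0], 9.999)


def test_pdb_and_mmcif_renderings_agree(tmp_path, identity_pair):
    write_structure(identity_pair.state_a, tmp_path / "a.pdb")
    write_structure(identity_pair.state_a, tmp_path / "a.cif")
    a = load_structure(tmp_path / "a.pdb")
    b = load_structure(tmp_path / "a.cif")
    assert np.array_equal(a.resseq, b.resseq)
    assert np.allclose(a.xyz, b.xyz, atol=1e-3)    # PDB format precision
    assert np.allclose(a.xyz, identity_pair.state_a.xyz, atol=1e-3)


def test_structure_with_no_ca_rejected(tmp_path):
    path = tmp_path / "noca.pdb"
    path.write_text(MINI_PDB.replace(" CA ", " CB "))
    with pytest.raises(ValueError, match="no C"):
        load_structure(path)


# ---------------------------------------------------------------------------
# Subdomain split

def test_synthetic_pair_splits_into_13_with_none_unassigned(identity_pair):
    model = split_subdomains(identity_pair.state_a, identity_pair.subdomain_defs)
    assert len(model.members) == 13
    assert model.unassigned.size == 0
    assert model.absent == ()


def test_shifted_definitions_are_all_absent(identity_pair):
    shifted = {k: [[s + 10000, e + 10000] for s, e in v]
               for k, v in identity_pair.subdomain_defs.items()}
    model = split_subdomains(identity_pair.state_a, shifted)
    assert len(model.absent) == 13


def test_overlapping_definitions_rejected(identity_pair):
    bad = {k: [list(seg) for seg in v]
           for k, v in identity_pair.subdomain_defs.items()}
    bad["AAA1s"][0][0] = bad["AAA1L"][0][1]   # overlap on one residue
    with pytest.raises(ValueError, match=str(bad["AAA1L"][0][1])):
        split_subdomains(identity_pair.state_a, bad)


def test_shipped_schemes_load_and_are_disjoint():
    for name in ("yeast_dyn1", "human_dynein2"):
        scheme = load_subdomain_scheme(name)
        assert set(scheme["subdomains"]) == set(structdyn.SUBDOMAIN_NAMES)


# ---------------------------------------------------------------------------
# Kabsch

def test_identical_clouds_give_identity(rng):
    P = rng.normal(size=(10, 3))
    R, t, rmsd = kabsch(P, P)
    assert np.allclose(R, np.eye(3), atol=1e-12)
    assert np.allclose(t, 0, atol=1e-12)
    assert rmsd < 1e-12


def test_known_rotation_translation_recovered_exactly(rng):
    P = rng.normal(size=(10, 3)) * 5
    R_true = Rotation.from_euler("zyx", [30, 0, 0], degrees=True).as_matrix()
    t_true = np.array([5.0, -2.0, 1.0])
    Q = P @ R_true.T + t_true
    R, t, rmsd = kabsch(P, Q)
    assert np.abs(R - R_true).max() < 1e-9
    assert np.abs(t - t_true).max() < 1e-9
    assert rmsd < 1e-9


def test_rmsd_matches_single_axis_grid_oracle(rng):
    # Exactly planar clouds with in-plane noise: the optimal rigid rotation
    # is provably about z, so an exhaustive 0.05-degree single-axis search
    # must match Kabsch to within the grid resolution.
    P = rng.normal(size=(4, 3))
    P[:, 2] = 0.0
    theta = np.radians(37.3)
    Rz = Rotation.from_rotvec([0, 0, theta]).as_matrix()
    noise = rng.normal(scale=0.05, size=P.shape)
    noise[:, 2] = 0.0
    Q = P @ Rz.T + noise
    P[:, 2] = 1e-6 * rng.normal(size=4)   # break exact collinearity in z
    Q[:, 2] = 1e-6 * rng.normal(size=4)
    _, _, rmsd_kabsch = kabsch(P, Q)

    Pc, Qc = P - P.mean(0), Q - Q.mean(0)
    angles = np.radians(np.arange(0.0, 360.0, 0.05))
    best = np.inf
    for a in angles:
        Ra = Rotation.from_rotvec([0, 0, a]).as_matrix()
        best = min(best, cloud_rmsd(Pc @ Ra.T, Qc))
    assert rmsd_kabsch <= best + 1e-12
    # grid-limited oracle gets within its resolution of the optimum
    assert best - rmsd_kabsch < 5e-3


def test_kabsch_optimal_on_coarse_so3_grid(rng):
    # Independent brute force over orientation space: no rotation on a
    # ~4-degree SO(3) Euler grid may do better than the closed-form result.
    P = rng.normal(size=(6, 3))
    Q = rng.normal(size=(6, 3))
    _, _, rmsd_kabsch = kabsch(P, Q)
    Pc, Qc = P - P.mean(0), Q - Q.mean(0)
    grid = np.radians(np.arange(0, 360, 4.0))
    half = np.radians(np.arange(0, 181, 4.0))
    best = np.inf
    for a in grid:
        Ra = Rotation.from_euler("z", a).as_matrix()
        for b in half:
            Rb = Rotation.from_euler("y", b).as_matrix()
            Rab = Ra @ Rb
            for c in grid:
                R = Rab @ Rotation.from_euler("z", c).as_matrix()
                d = cloud_rmsd(Pc @ R.T, Qc)
                if d < best:
                    best = d
    assert rmsd_kabsch <= best + 1e-12
    # the coarse grid comes close: max orientation error ~4 deg
    radius = np.linalg.norm(Pc, axis=1).max()
    assert best - rmsd_kabsch < 2 * radius * np.sin(np.radians(4.0))


def test_kabsch_cross_checked_against_scipy(rng):
    P = rng.normal(size=(8, 3))
    Q = rng.normal(size=(8, 3))
    R, t, rmsd = kabsch(P, Q)
    est, ssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    assert np.abs(R - est.as_matrix()).max() < 1e-8


def test_collinear_cloud_rejected():
    line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="collinear"):
        kabsch(line, line + 1.0)


def test_rmsd_invariant_under_rigid_pretransform(rng, identity_pair):
    pair = generate_structure_pair(
        atoms_per_subdomain=8,
        transforms={"AAA2L": translation_only([3.0, 0, 0])}, seed=5)
    sup1 = superpose(pair.state_b, pair.state_a, selection="AAA1L",
                     definitions=pair.subdomain_defs)
    R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
    moved = pair.state_b.transformed(R, np.array([100.0, -50.0, 7.0]))
    sup2 = superpose(moved, pair.state_a, selection="AAA1L",
                     definitions=pair.subdomain_defs)
    assert sup1.rmsd == pytest.approx(sup2.rmsd, abs=1e-9)


def test_fewer_than_three_pairs_rejected(identity_pair):
    with pytest.raises(ValueError, match=">= 3|at least 3"):
        superpose(identity_pair.state_a, identity_pair.state_b,
                  selection=[1, 2])


# ---------------------------------------------------------------------------
# Displacement fields

def test_same_structure_gives_zero_field(identity_pair):
    fld = displacement_field(identity_pair.state_a, identity_pair.state_b,
                             align_on="AAA1L",
                             definitions=identity_pair.subdomain_defs)
    assert fld.magnitudes.max() < 1e-9


def test_translated_subdomain_reads_exact_magnitude():
    pair = generate_structure_pair(
        atoms_per_subdomain=8,
        transforms={"AAA5s": translation_only([0, 0, 5.0])}, seed=1)
    fld = displacement_field(pair.state_a, pair.state_b, align_on="AAA1L",
                             definitions=pair.subdomain_defs)
    mean, mx = fld.subdomain_summary["AAA5s"]
    assert mean == pytest.approx(5.0, abs=1e-9)
    assert mx == pytest.approx(5.0, abs=1e-9)
    for name, (m, _) in fld.subdomain_summary.items():
        if name != "AAA5s":
            assert m < 1e-9


def test_field_against_transform_composition_oracle():
    # Two moved subdomains, aligned on one of them: the aligned one reads 0
    # and the other reads the composed relative motion T_align^-1 . T_other.
    T1 = rotation_about([0, 1, 0], 12.0, [20.0, 0, 0])
    T2 = translation_only([0, 6.0, 0])
    pair = generate_structure_pair(
        atoms_per_subdomain=8, transforms={"AAA3L": T1, "AAA4s": T2}, seed=4)
    fld = displacement_field(pair.state_a, pair.state_b, align_on="AAA3L",
                             definitions=pair.subdomain_defs)
    assert fld.subdomain_summary["AAA3L"][1] < 1e-9

    R1, t1 = pair.true_transforms["AAA3L"]
    R2, t2 = pair.true_transforms["AAA4s"]
    lo, hi = pair.subdomain_defs["AAA4s"][0]
    res, _, xyz = pair.state_a.ca_table()
    pts = xyz[(res >= lo) & (res <= hi)]
    # position in b, then undo the alignment transform (inverse of T1)
    b = pts @ R2.T + t2
    rel = (b - t1) @ R1
    expected = np.linalg.norm(rel - pts, axis=1)
    got = np.sort(fld.magnitudes[(fld.residues >= lo) & (fld.residues <= hi)])
    assert np.allclose(np.sort(expected), got, atol=1e-6)


def test_field_invariant_under_global_translation(identity_pair):
    pair = generate_structure_pair(
        atoms_per_subdomain=8,
        transforms={"AAA6L": translation_only([2.0, 1.0, 0.0])}, seed=6)
    fld1 = displacement_field(pair.state_a, pair.state_b, align_on="AAA1L",
                              definitions=pair.subdomain_defs)
    shift = np.array([1000.0, -500.0, 250.0])
    a2 = pair.state_a.transformed(np.eye(3), shift)
    b2 = pair.state_b.transformed(np.eye(3), shift)
    fld2 = displacement_field(a2, b2, align_on="AAA1L",
                              definitions=pair.subdomain_defs)
    assert np.allclose(fld1.magnitudes, fld2.magnitudes, atol=1e-9)


# ---------------------------------------------------------------------------
# Rotation angles

def triple_of(pair, name):
    lo, hi = pair.subdomain_defs[name][0]
    return (lo, (lo + hi) // 2, hi)


def test_identical_structures_zero_angle(identity_pair):
    t = triple_of(identity_pair, "AAA2L")
    rot = rotation_angle(identity_pair.state_a, identity_pair.state_b, t, t,
                         align_on="AAA1L",
                         definitions=identity_pair.subdomain_defs)
    assert rot.angle_deg < 1e-9


@pytest.mark.parametrize("angle", [5.0, 20.0, 25.0, 60.0, 89.0])
def test_constructed_rotation_recovered_to_microdegree(angle):
    base = generate_structure_pair(atoms_per_subdomain=8, seed=3)
    t = triple_of(base, "AAA2L")
    pts = np.array([base.state_a.ca_coord(r) for r in t])
    _, u = principal_axis(pts)
    w = np.cross(u, [0.0, 0.0, 1.0])
    w /= np.linalg.norm(w)
    lo, hi = base.subdomain_defs["AAA2L"][0]
    res, _, xyz = base.state_a.ca_table()
    centroid = xyz[(res >= lo) & (res <= hi)].mean(axis=0)
    pair = generate_structure_pair(
        atoms_per_subdomain=8, seed=3,
        transforms={"AAA2L": rotation_about(w, angle, centroid)})
    rot = rotation_angle(pair.state_a, pair.state_b, t, t, align_on="AAA1L",
                         definitions=pair.subdomain_defs)
    assert rot.angle_deg == pytest.approx(angle, abs=1e-6)


def test_angle_symmetric_in_argument_order():
    base = generate_structure_pair(atoms_per_subdomain=8, seed=3)
    t = triple_of(base, "AAA2L")
    pair = generate_structure_pair(
        atoms_per_subdomain=8, seed=3,
        transforms={"AAA2L": rotation_about([0, 1, 0], 20.0, [0, 0, 0])})
    r_ab = rotation_angle(pair.state_a, pair.state_b, t, t, align_on="AAA1L",
                          definitions=pair.subdomain_defs)
    r_ba = rotation_angle(pair.state_b, pair.state_a, t, t, align_on="AAA1L",
                          definitions=pair.subdomain_defs)
    assert r_ab.angle_deg == pytest.approx(r_ba.angle_deg, abs=1e-9)


def test_coincident_triple_rejected(identity_pair):
    t = triple_of(identity_pair, "AAA2L")
    with pytest.raises(ValueError, match="coincident"):
        rotation_angle(identity_pair.state_a, identity_pair.state_b,
                       (t[0], t[0], t[0]), (t[0], t[0], t[0]),
                       align_on="AAA1L",
                       definitions=identity_pair.subdomain_defs)


# ---------------------------------------------------------------------------
# Distances and gaps

def test_ca_distance_same_residue_zero(identity_pair):
    assert ca_distance(identity_pair.state_a, 1, 1) == 0.0


def test_ca_distance_missing_residue_named(identity_pair):
    with pytest.raises(KeyError, match="99999"):
        ca_distance(identity_pair.state_a, 1, 99999)


def test_interface_gap_translation_oracle():
    # AAA5s translated 8 A along +x: the centroid separation vector changes
    # by exactly (8, 0, 0).
    pair = generate_structure_pair(
        atoms_per_subdomain=8,
        transforms={"AAA5s": translation_only([8.0, 0, 0])}, seed=10)
    res, _, xyz_a = pair.state_a.ca_table()
    lo5L = pair.subdomain_defs["AAA5L"][0]
    lo5s = pair.subdomain_defs["AAA5s"][0]
    in_5L = (res >= lo5L[0]) & (res <= lo5L[1])
    in_5s = (res >= lo5s[0]) & (res <= lo5s[1])
    sep_a = xyz_a[in_5s].mean(0) - xyz_a[in_5L].mean(0)
    _, _, xyz_b = pair.state_b.ca_table()
    sep_b = xyz_b[in_5s].mean(0) - xyz_b[in_5L].mean(0)
    assert np.allclose(sep_b - sep_a, [8.0, 0, 0], atol=1e-9)

    gap_a = interface_gap(pair.state_a, pair.subdomain_defs, "AAA5L", "AAA5s")
    gap_b = interface_gap(pair.state_b, pair.subdomain_defs, "AAA5L", "AAA5s")
    assert gap_b["centroid_distance"] == pytest.approx(
        np.linalg.norm(sep_a + [8.0, 0, 0]), abs=1e-9)
    assert gap_a["centroid_distance"] == pytest.approx(
        np.linalg.norm(sep_a), abs=1e-9)


def test_interface_gap_unit_separated_clouds_and_self():
    from dynstalk.structdyn import StructureModel

    n = 4
    xyz = np.array([[0.0, 0, 0], [0, 1, 0], [0, 0, 1],
                    [1.0, 0, 0], [1, 1, 0], [1, 0, 1]])
    sm = StructureModel(
        chain=np.array(["A"] * 6), resseq=np.arange(1, 7),
        icode=np.array([""] * 6), resname=np.array(["GLY"] * 6),
        atname=np.array(["CA"] * 6), xyz=xyz)
    defs = {"left": [[1, 3]], "right": [[4, 6]]}
    gap = interface_gap(sm, defs, "left", "right")
    assert gap["min_ca_distance"] == pytest.approx(1.0)
    self_gap = interface_gap(sm, defs, "left", "left")
    assert self_gap["min_ca_distance"] == 0.0


# ---------------------------------------------------------------------------
# Cross-species correspondence

def test_cross_numbering_superposition_via_sequence_alignment(tmp_path):
    # Same fold, numbering offset by 500: identical-number pairing finds no
    # overlap, the alignment route recovers the rigid fit exactly.
    pair = generate_structure_pair(atoms_per_subdomain=10, seed=8)
    a = pair.state_a
    from dynstalk.structdyn import StructureModel

    # distinctive sequence so the alignment is unambiguous
    seq3 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
            "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
            "TYR", "VAL"]
    resname = np.array([seq3[i % 20] for i in range(len(a.resseq))])
    a = StructureModel(chain=a.chain, resseq=a.resseq, icode=a.icode,
                       resname=resname, atname=a.atname, xyz=a.xyz)
    R = Rotation.from_euler("xyz", [5, -3, 11], degrees=True).as_matrix()
    b = StructureModel(chain=a.chain, resseq=a.resseq + 500, icode=a.icode,
                       resname=resname, atname=a.atname,
                       xyz=a.xyz @ R.T + np.array([4.0, 4.0, -1.0]))
    sup = superpose(b, a, correspondence="align")
    assert sup.n_pairs == len(a.resseq)
    assert sup.rmsd < 1e-9
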