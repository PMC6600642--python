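"""Synthetic two-state structure pairs with known rigid-body motions.

Builds a 13-body Cα point-cloud model mimicking the AAA-ring partition
(large/small subdomain per AAA domain plus the linker) and a second state
obtained by applying a known rigid transform to each body. The generating
transforms are the ground truth for superposition, displacement-field and
rotation-angle recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ..structdyn import SUBDOMAIN_NAMES, StructureModel

__all__ = [
    "SyntheticStructurePair",
    "rotation_about",
    "translation_only",
    "generate_structure_pair",
]


@dataclass
class SyntheticStructurePair:
    state_a: StructureModel
    state_b: StructureModel
    true_transforms: dict   # name -> (3x3 rotation, translation)
    subdomain_defs: dict    # name -> [[start, end]] residue segments
    seed: int


def rotation_about(axis, angle_deg, center):
    """Rigid transform rotating by ``angle_deg`` about ``axis`` through ``center``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    center = np.asarray(center, dtype=float)
    t = center - R @ center
    return R, t


def translation_only(shift):
    return np.eye(3), np.asarray(shift, dtype=float)


def _blob(rng, center, n, spread):
    """Non-degenerate Gaussian point cloud around ``center``."""
    while True:
        pts = center + rng.normal(0.0, spread, size=(n, 3))
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[1] > 1e-3 * max(s[0], 1.0) and s[2] > 1e-6:
            return pts


def generate_structure_pair(atoms_per_subdomain=25, transforms=None, seed=0,
                            names=SUBDOMAIN_NAMES, ring_radius=60.0,
                            spread=8.0):
    """Generate a two-state 13-body pair with recorded ground truth.

    Each named body is a Gaussian Cα cloud (``spread`` Å sd) centred on a
    ring of ``ring_radius`` Å, with contiguous residue numbering so that the
    returned ``subdomain_defs`` partition it exactly. ``transforms`` maps
    body names to (rotation, translation) pairs (identity when omitted; see
    :func:`rotation_about` and :func:`translation_only`). State b applies
    each body's transform to state a's coordinates exactly.
    """
    if atoms_per_subdomain < 3:
        raise ValueError("at least 3 atoms per subdomain required "
                         "(superposition undefined below that)")
    names = tuple(names)
    transforms = dict(transforms or {})
    unknown = set(transforms) - set(names)
    if unknown:
        raise ValueError(f"transforms reference unknown subdomains: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n_dom = len(names)
    angles = 2.0 * np.pi * np.arange(n_dom) / n_dom
    centers = ring_radius * np.column_stack(
        [np.cos(angles), np.sin(angles), 0.15 * rng.standard_normal(n_dom)]
    )

    defs, true_transforms = {}, {}
    resseq, xyz_a, xyz_b = [], [], []
    next_res = 1
    for k, name in enumerate(names):
        pts = _blob(rng, centers[k], atoms_per_subdomain, spread)
        R, t = transforms.get(name, (np.eye(3), np.zeros(3)))
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
            raise ValueError(f"transform for {name} is not a proper rotation")
        moved = pts @ R.T + t
        start = next_res
        end = next_res + atoms_per_subdomain - 1
        next_res = end + 1
        defs[name] = [[start, end]]
        true_transforms[name] = (R, t)
        resseq.extend(range(start, end + 1))
        xyz_a.append(pts)
        xyz_b.append(moved)

    n_atoms = len(resseq)
    common = dict(
        chain=np.array(["A"] * n_atoms),
        resseq=np.array(resseq, dtype=int),
        icode=np.array([""] * n_atoms),
        resname=np.array(["ALA"] * n_atoms),
        atname=np.array(["CA"] * n_atoms),
    )
    state_a = StructureModel(xyz=np.vstack(xyz_a), label="synthetic_state_a", **common)
    state_b = StructureModel(xyz=np.vstack(xyz_b), label="synthetic_state_b", **common)
    return SyntheticStructurePair(
        state_a=state_a, state_b=state_b,
        true_transforms=true_transforms, subdomain_defs=defs, seed=int(seed),
    )
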