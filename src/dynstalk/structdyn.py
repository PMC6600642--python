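"""Rigid-body analysis of AAA-ring conformational changes.

The dynein motor domain is treated as 13 rigid bodies — a large (L) and a
small (s) subdomain for each of the six AAA domains, plus the N-terminal
linker. This module loads atomic models, partitions them into those bodies,
and quantifies motion between two nucleotide states:

* least-squares rigid superposition (Kabsch) on a named subdomain,
* per-residue Cα displacement fields after that superposition,
* rotation angles between axes fit through residue triples (e.g. the
  Walker-A/Walker-B/Q motif axis of AAA1L versus the arginine-finger/
  Sensor-II/insert-loop axis of AAA2L),
* Cα–Cα motif distances (arginine finger to Walker-A lysine as a proxy for
  nucleotide-pocket closure), and
* interface gaps between subdomains (e.g. the AAA5L/AAA5s opening).

Structures from different species are matched residue-by-residue either via
identical numbering or via a global (Needleman–Wunsch, BLOSUM62, affine-gap)
alignment of the selected Cα sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "SUBDOMAIN_NAMES",
    "StructureModel",
    "SubdomainModel",
    "Superposition",
    "DisplacementField",
    "DomainRotation",
    "load_structure",
    "write_structure",
    "load_subdomain_scheme",
    "split_subdomains",
    "kabsch",
    "superpose",
    "apply_transform",
    "displacement_field",
    "principal_axis",
    "rotation_angle",
    "ca_distance",
    "interface_gap",
]

SUBDOMAIN_NAMES = (
    "AAA1L", "AAA1s", "AAA2L", "AAA2s", "AAA3L", "AAA3s",
    "AAA4L", "AAA4s", "AAA5L", "AAA5s", "AAA6L", "AAA6s", "linker",
)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class StructureModel:
    """Flat atom table of one model: parallel arrays plus a source label."""

    chain: np.ndarray     # str per atom
    resseq: np.ndarray    # int residue number
    icode: np.ndarray     # insertion code, "" when none
    resname: np.ndarray   # 3-letter residue name
    atname: np.ndarray    # atom name, e.g. "CA"
    xyz: np.ndarray       # (n_atoms, 3) Å
    label: str = ""
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates in structure")

    @property
    def ca_mask(self):
        return self.atname == "CA"

    def ca_table(self):
        """Residue numbers, one-letter codes, and Cα coordinates (CA atoms only)."""
        m = self.ca_mask
        res = self.resseq[m]
        letters = np.array([_THREE_TO_ONE.get(r, "X") for r in self.resname[m]])
        return res, letters, self.xyz[m]

    def ca_coord(self, resnum):
        m = self.ca_mask & (self.resseq == int(resnum))
        if not m.any():
            raise KeyError(f"no Cα for residue {resnum} in {self.label or 'structure'}")
        return self.xyz[m][0]

    def transformed(self, rotation, translation):
        new_xyz = self.xyz @ np.asarray(rotation).T + np.asarray(translation)
        return StructureModel(
            chain=self.chain, resseq=self.resseq, icode=self.icode,
            resname=self.resname, atname=self.atname, xyz=new_xyz,
            label=self.label,
        )


@dataclass
class SubdomainModel:
    """A structure partitioned into named rigid bodies."""

    structure: StructureModel
    members: dict            # name -> sorted array of residue numbers present
    unassigned: np.ndarray   # residue numbers outside every definition
    absent: tuple            # names with no residues found


@dataclass
class Superposition:
    rotation: np.ndarray   # 3x3, det +1
    translation: np.ndarray
    rmsd: float
    n_pairs: int


@dataclass
class DisplacementField:
    residues: np.ndarray    # matched reference residue numbers
    vectors: np.ndarray     # (n, 3) Å, b - a after superposition
    magnitudes: np.ndarray  # Å
    align_on: tuple
    superposition: Superposition
    subdomain_summary: dict = field(default_factory=dict)  # name -> (mean, max)


@dataclass
class DomainRotation:
    angle_deg: float
    axis_a: tuple   # (centroid, unit direction)
    axis_b: tuple
    align_on: tuple


# ---------------------------------------------------------------------------
# I/O (gemmi behind the module surface)

def load_structure(path, model_index=1, altloc_policy="occupancy",
                   include_hetero=False):
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Keeps the highest-occupancy alternate location per atom, drops hetero
    atoms/waters by default, and takes the first model unless ``model_index``
    (1-based) says otherwise.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if altloc_policy == "occupancy":
        st.remove_alternative_conformations()
    st.remove_empty_chains()
    if not 1 <= model_index <= len(st):
        raise ValueError(f"model_index {model_index} out of range (1..{len(st)})")
    model = st[model_index - 1]

    warnings = []
    rows = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            if het and not include_hetero:
                continue
            if res.name not in _THREE_TO_ONE and not het:
                warnings.append(f"unknown residue name {res.name} {res.seqid.num}")
            for atom in res:
                rows.append((
                    chain.name, res.seqid.num, res.seqid.icode.strip(),
                    res.name, atom.name,
                    atom.pos.x, atom.pos.y, atom.pos.z,
                ))
    if not rows:
        raise ValueError(f"no atoms read from {path}")
    chain_a, resseq, icode, resname, atname, x, y, z = zip(*rows)
    sm = StructureModel(
        chain=np.array(chain_a), resseq=np.array(resseq, dtype=int),
        icode=np.array(icode), resname=np.array(resname),
        atname=np.array(atname), xyz=np.column_stack([x, y, z]),
        label=str(path), warnings=warnings,
    )
    if not sm.ca_mask.any():
        raise ValueError(f"structure {path} contains no Cα atoms")
    return sm


def write_structure(structure, path, name="synthetic"):
    """Write a :class:`StructureModel` to PDB (or mmCIF by extension)."""
    import gemmi

    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    chains = {}
    for i in range(len(structure.resseq)):
        cname = str(structure.chain[i])
        chain = chains.get(cname)
        if chain is None:
            chain = gemmi.Chain(cname)
            chains[cname] = chain
            model.add_chain(chain)
            chain = model[-1]
            chains[cname] = chain
        resnum = int(structure.resseq[i])
        if len(chain) == 0 or chain[-1].seqid.num != resnum:
            res = gemmi.Residue()
            res.name = str(structure.resname[i])
            res.seqid = gemmi.SeqId(resnum, " ")
            chain.add_residue(res)
        res = chain[-1]
        atom = gemmi.Atom()
        atom.name = str(structure.atname[i])
        atom.element = gemmi.Element(str(structure.atname[i])[:1])
        atom.pos = gemmi.Position(*structure.xyz[i])
        atom.occ = 1.0
        res.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    path = str(path)
    if path.endswith(".cif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


# ---------------------------------------------------------------------------
# Subdomain schemes

def load_subdomain_scheme(scheme="yeast_dyn1"):
    """Load a named residue-range table (or a JSON file path).

    Returns a dict with keys ``subdomains`` (name -> list of [start, end]
    segments), ``motifs`` and ``triples`` (named residue numbers), and
    ``anchors`` for the stalk helices. The shipped yeast Dyn1 and human
    dynein-2 tables are package-defined approximations consistent with the
    catalytic motif positions; override with your own JSON for other models.
    """
    import pathlib

    p = pathlib.Path(str(scheme))
    if p.suffix == ".json" and p.exists():
        data = json.loads(p.read_text())
    else:
        ref = resources.files("dynstalk").joinpath(f"data/{scheme}.json")
        data = json.loads(ref.read_text())
    _check_disjoint(data["subdomains"])
    return data


def _check_disjoint(subdomains):
    seen = {}
    for name, segments in subdomains.items():
        for start, end in segments:
            if start > end:
                raise ValueError(f"{name}: segment {start}..{end} reversed")
            for r in range(int(start), int(end) + 1):
                if r in seen and seen[r] != name:
                    raise ValueError(
                        f"residue {r} assigned to both {seen[r]} and {name}"
                    )
                seen[r] = name


def split_subdomains(structure, definitions):
    """Partition a structure's residues among named subdomain definitions.

    ``definitions`` maps names to lists of 1-based inclusive [start, end]
    segments (a ``load_subdomain_scheme`` result or its ``subdomains`` entry).
    Residues matching no definition (stalk, buttress, MTBD...) are listed as
    unassigned; empty subdomains are reported absent with a warning.
    """
    if "subdomains" in definitions and isinstance(definitions["subdomains"], dict):
        definitions = definitions["subdomains"]
    _check_disjoint(definitions)
    res_present = np.unique(structure.resseq[structure.ca_mask])
    members, absent = {}, []
    claimed = np.zeros(res_present.shape, dtype=bool)
    for name, segments in definitions.items():
        mask = np.zeros(res_present.shape, dtype=bool)
        for start, end in segments:
            mask |= (res_present >= int(start)) & (res_present <= int(end))
        if not mask.any():
            absent.append(name)
            continue
        members[name] = res_present[mask]
        claimed |= mask
    model = SubdomainModel(
        structure=structure,
        members=members,
        unassigned=res_present[~claimed],
        absent=tuple(absent),
    )
    if absent:
        structure.warnings.append(f"subdomains absent: {', '.join(absent)}")
    return model


# ---------------------------------------------------------------------------
# Superposition

def _check_not_collinear(points, tol=1e-8):
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s.size < 2 or s[1] <= tol * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set: superposition "
                         "orientation is not unique")


def kabsch(mobile, reference):
    """Least-squares rigid transform mapping ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd); reflections are excluded by the
    usual determinant sign correction.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("at least 3 point pairs required")
    _check_not_collinear(P)
    _check_not_collinear(Q)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(points, rotation, translation):
    return np.asarray(points, dtype=float) @ np.asarray(rotation).T + np.asarray(translation)


def _selection_residues(structure, selection, definitions=None):
    """Resolve a selection (subdomain name(s) or explicit residue numbers)."""
    if selection is None:
        return np.unique(structure.resseq[structure.ca_mask])
    if isinstance(selection, str):
        selection = (selection,)
    selection = tuple(selection)
    if definitions is not None and all(isinstance(s, str) for s in selection):
        if "subdomains" in definitions and isinstance(definitions["subdomains"], dict):
            definitions = definitions["subdomains"]
        model = split_subdomains(structure, {k: definitions[k] for k in selection})
        missing = [s for s in selection if s in model.absent]
        if missing:
            raise ValueError(f"selection subdomain(s) empty: {missing}")
        return np.sort(np.concatenate([model.members[s] for s in selection]))
    return np.asarray(sorted(int(s) for s in selection), dtype=int)


def _match_residues(mobile, reference, sel_mobile, sel_reference, correspondence):
    """Return paired Cα coordinate arrays and the reference residue numbers."""
    res_m, let_m, xyz_m = mobile.ca_table()
    res_r, let_r, xyz_r = reference.ca_table()
    im = np.isin(res_m, sel_mobile)
    ir = np.isin(res_r, sel_reference)
    res_m, let_m, xyz_m = res_m[im], let_m[im], xyz_m[im]
    res_r, let_r, xyz_r = res_r[ir], let_r[ir], xyz_r[ir]

    if correspondence == "numbering":
        common, idx_m, idx_r = np.intersect1d(res_m, res_r, return_indices=True)
        return xyz_m[idx_m], xyz_r[idx_r], common
    if correspondence == "align":
        idx_m, idx_r = _global_align_indices("".join(let_m), "".join(let_r))
        return xyz_m[idx_m], xyz_r[idx_r], res_r[idx_r]
    raise ValueError(f"correspondence must be numbering|align, got {correspondence!r}")


def _global_align_indices(seq_a, seq_b):
    """Needleman–Wunsch global alignment (BLOSUM62, affine gaps) index pairs."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    ia, ib = [], []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        ia.extend(range(a0, a1))
        ib.extend(range(b0, b1))
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int)


def superpose(mobile, reference, selection=None, definitions=None,
              correspondence="numbering", selection_reference=None):
    """Kabsch superposition of ``mobile`` onto ``reference`` over a selection.

    ``selection`` names subdomains (resolved through ``definitions``) or lists
    residue numbers; ``selection_reference`` overrides it for the reference
    when the two structures use different numbering (cross-species).
    """
    sel_m = _selection_residues(mobile, selection, definitions)
    sel_r = (
        _selection_residues(reference, selection_reference, definitions)
        if selection_reference is not None else
        _selection_residues(reference, selection, definitions)
    )
    P, Q, _ = _match_residues(mobile, reference, sel_m, sel_r, correspondence)
    if P.shape[0] < 3:
        raise ValueError(f"only {P.shape[0]} matched Cα pairs; need >= 3")
    R, t, rmsd = kabsch(P, Q)
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=P.shape[0])


def displacement_field(struct_a, struct_b, align_on, definitions=None,
                       correspondence="numbering", align_on_b=None):
    """Per-Cα displacement vectors of state b relative to state a.

    State b is superposed onto state a over the ``align_on`` subdomain(s);
    every matched Cα then contributes the vector from its position in a to
    its (superposed) position in b. When ``definitions`` are given, a
    per-subdomain summary of mean and maximum magnitude is included.
    """
    sup = superpose(struct_b, struct_a, selection=align_on_b or align_on,
                    definitions=definitions, correspondence=correspondence,
                    selection_reference=align_on)
    moved_b = struct_b.transformed(sup.rotation, sup.translation)
    all_m = _selection_residues(moved_b, None)
    all_r = _selection_residues(struct_a, None)
    P, Q, residues = _match_residues(moved_b, struct_a, all_m, all_r, correspondence)
    vectors = P - Q          # b (superposed) minus a, in a's frame
    magnitudes = np.linalg.norm(vectors, axis=1)

    summary = {}
    if definitions is not None:
        if "subdomains" in definitions and isinstance(definitions["subdomains"], dict):
            definitions = definitions["subdomains"]
        for name, segments in definitions.items():
            mask = np.zeros(residues.shape, dtype=bool)
            for start, end in segments:
                mask |= (residues >= int(start)) & (residues <= int(end))
            if mask.any():
                summary[name] = (float(magnitudes[mask].mean()),
                                 float(magnitudes[mask].max()))
    return DisplacementField(
        residues=residues, vectors=vectors, magnitudes=magnitudes,
        align_on=tuple(np.atleast_1d(align_on).tolist()),
        superposition=sup, subdomain_summary=summary,
    )


# ---------------------------------------------------------------------------
# Axes, angles, distances

def principal_axis(points):
    """Total-least-squares line through points: (centroid, unit direction)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0, atol=1e-12):
        raise ValueError("coincident points: axis undefined")
    _, _, Vt = np.linalg.svd(centered)
    direction = Vt[0]
    direction = direction / np.linalg.norm(direction)
    return centroid, direction


def rotation_angle(struct_a, struct_b, triple_a, triple_b, align_on,
                   definitions=None, correspondence="numbering",
                   align_on_b=None):
    """Angle between residue-triple axes after superposition on ``align_on``.

    Each axis is the first principal direction through the three Cα of a
    triple; the angle is arccos of the absolute dot product of the two unit
    directions (sign-free, 0–90°). ``triple_a`` is resolved in ``struct_a``,
    ``triple_b`` in ``struct_b`` before it is superposed onto a.
    """
    sup = superpose(struct_b, struct_a, selection=align_on_b or align_on,
                    definitions=definitions, correspondence=correspondence,
                    selection_reference=align_on)
    pts_a = np.array([struct_a.ca_coord(r) for r in triple_a])
    pts_b = np.array([struct_b.ca_coord(r) for r in triple_b])
    pts_b = apply_transform(pts_b, sup.rotation, sup.translation)
    axis_a = principal_axis(pts_a)
    axis_b = principal_axis(pts_b)
    cosang = np.clip(abs(float(np.dot(axis_a[1], axis_b[1]))), 0.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    return DomainRotation(
        angle_deg=angle, axis_a=axis_a, axis_b=axis_b,
        align_on=tuple(np.atleast_1d(align_on).tolist()),
    )


def ca_distance(structure, res_a, res_b):
    """Euclidean Cα–Cα distance (Å) between two residues."""
    return float(np.linalg.norm(structure.ca_coord(res_a) - structure.ca_coord(res_b)))


def interface_gap(structure, definitions, subdomain_a, subdomain_b):
    """Gap metrics between two subdomains of one structure.

    Returns a dict with ``min_ca_distance`` (smallest Cα–Cα distance across
    the pair) and ``centroid_distance`` (between Cα centroids), both in Å.
    """
    if "subdomains" in definitions and isinstance(definitions["subdomains"], dict):
        definitions = definitions["subdomains"]
    model = split_subdomains(
        structure, {k: definitions[k] for k in (subdomain_a, subdomain_b)}
    )
    for name in (subdomain_a, subdomain_b):
        if name in model.absent:
            raise ValueError(f"subdomain {name} has no residues in this structure")
    res, _, xyz = structure.ca_table()
    pa = xyz[np.isin(res, model.members[subdomain_a])]
    pb = xyz[np.isin(res, model.members[subdomain_b])]
    from scipy.spatial.distance import cdist

    dists = cdist(pa, pb)
    return {
        "min_ca_distance": float(dists.min()),
        "centroid_distance": float(np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0))),
        "n_a": int(pa.shape[0]),
        "n_b": int(pb.shape[0]),
    }
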