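"""Synthetic zinc-site structures for tests, demos, and benchmarks.

Builds structures whose binding atoms sit at exact coordination-geometry
vertices around a known ion position, with full Cα/Cβ scaffolds so the
whole pipeline (curation, indexing, search, placement, scoring) runs on
them.  Also provides perturbed copies, misoriented-histidine variants,
decoys, and a seeded fixture library.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ContractViolationError
from .geometry import initial_zinc_estimate, rotate_his_chi2
from .scoring import IDEAL_DISTANCE, IDEAL_DISTANCE_CYS_S
from .structure_model import Atom, HetIon, ProteinStructure, Residue
from .template_library import TemplateLibrary, curate_templates, extract_observed_sites


@dataclass
class SiteSpec:
    combination: tuple[str, ...]
    geometry: str = "tetrahedral"  # tetrahedral | trigonal_apex | octahedral_partial
    bond_lengths: tuple[float, ...] | None = None
    his_twist: float | tuple[float, ...] = 0.0
    noise_sigma: float = 0.0
    seed: int = 0


#: specs used for the default fixture library; covers all four score cases
DEFAULT_FIXTURE_SPECS: tuple[SiteSpec, ...] = (
    SiteSpec(("HIS", "HIS", "GLU", "CYS"), "tetrahedral"),
    SiteSpec(("HIS", "HIS", "HIS"), "trigonal_apex"),
    SiteSpec(("CYS", "CYS", "CYS", "CYS"), "tetrahedral"),
    SiteSpec(("ASP", "GLU", "SER"), "trigonal_apex"),
    SiteSpec(("HIS", "ASP", "THR", "TYR", "ASN"), "octahedral_partial"),
)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors perpendicular to u."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    w = _unit(np.cross(u, ref))
    v = np.cross(u, w)
    return w, v


def _atom(name: str, coord: np.ndarray) -> Atom:
    return Atom(name=name, element=name[0], coord=np.asarray(coord, float))


_RING_RADIUS = 1.17  # imidazole circumradius, Å (side ~1.37)


def _build_his(zinc, u, d, chain, seq) -> Residue:
    """His whose NE2 sits at zinc + d*u with ideal ring orientation
    (ring plane contains the bond; m->N extension points at the ion)."""
    w, v = _frame(u)
    center = zinc + (d + _RING_RADIUS) * u
    def vertex(theta_deg):
        t = np.radians(theta_deg)
        return center + _RING_RADIUS * (np.cos(t) * (-u) + np.sin(t) * w)
    ne2, ce1, nd1, cg, cd2 = (vertex(t) for t in (0, 72, 144, 216, 288))
    e = _unit(cg - center)
    cb = cg + 1.53 * e
    ca = cb + 1.53 * _unit(e + 0.6 * u + 0.3 * v)
    atoms = [_atom(n, c) for n, c in
             [("CA", ca), ("CB", cb), ("CG", cg), ("ND1", nd1),
              ("CD2", cd2), ("CE1", ce1), ("NE2", ne2)]]
    return Residue(chain, seq, "HIS", atoms)


def _build_cys(zinc, u, d, chain, seq) -> Residue:
    w, _ = _frame(u)
    sg = zinc + d * u
    cb = sg + 1.82 * _unit(u + 0.3 * w)
    ca = cb + 1.53 * _unit(u - 0.5 * w)
    return Residue(chain, seq, "CYS",
                   [_atom("CA", ca), _atom("CB", cb), _atom("SG", sg)])


def _build_asp(zinc, u, d, chain, seq) -> Residue:
    w, v = _frame(u)
    od1 = zinc + d * u
    cg = od1 + 1.25 * _unit(u + 0.4 * w)
    od2 = cg + 1.25 * _unit(0.1 * u + w)
    cb = cg + 1.53 * _unit(u - 0.8 * w)
    ca = cb + 1.53 * _unit(u + 0.2 * w + 0.5 * v)
    return Residue(chain, seq, "ASP",
                   [_atom("CA", ca), _atom("CB", cb), _atom("CG", cg),
                    _atom("OD1", od1), _atom("OD2", od2)])


def _build_glu(zinc, u, d, chain, seq) -> Residue:
    w, v = _frame(u)
    oe1 = zinc + d * u
    cd = oe1 + 1.25 * _unit(u + 0.4 * w)
    oe2 = cd + 1.25 * _unit(0.1 * u + w)
    cg = cd + 1.52 * _unit(u - 0.8 * w)
    cb = cg + 1.53 * _unit(u + 0.3 * v)
    ca = cb + 1.53 * _unit(u - 0.3 * v + 0.2 * w)
    return Residue(chain, seq, "GLU",
                   [_atom("CA", ca), _atom("CB", cb), _atom("CG", cg),
                    _atom("CD", cd), _atom("OE1", oe1), _atom("OE2", oe2)])


def _build_asn(zinc, u, d, chain, seq) -> Residue:
    w, v = _frame(u)
    od1 = zinc + d * u
    cg = od1 + 1.23 * _unit(u + 0.4 * w)
    nd2 = cg + 1.32 * _unit(0.1 * u + w)
    cb = cg + 1.53 * _unit(u - 0.8 * w)
    ca = cb + 1.53 * _unit(u + 0.5 * v)
    return Residue(chain, seq, "ASN",
                   [_atom("CA", ca), _atom("CB", cb), _atom("CG", cg),
                    _atom("OD1", od1), _atom("ND2", nd2)])


def _build_ser(zinc, u, d, chain, seq) -> Residue:
    w, _ = _frame(u)
    og = zinc + d * u
    cb = og + 1.42 * _unit(u + 0.3 * w)
    ca = cb + 1.53 * _unit(u - 0.5 * w)
    return Residue(chain, seq, "SER",
                   [_atom("CA", ca), _atom("CB", cb), _atom("OG", og)])


def _build_thr(zinc, u, d, chain, seq) -> Residue:
    w, v = _frame(u)
    og1 = zinc + d * u
    cb = og1 + 1.43 * _unit(u + 0.3 * w)
    cg2 = cb + 1.52 * _unit(0.3 * u - w)
    ca = cb + 1.53 * _unit(u - 0.3 * w + 0.4 * v)
    return Residue(chain, seq, "THR",
                   [_atom("CA", ca), _atom("CB", cb), _atom("OG1", og1),
                    _atom("CG2", cg2)])


def _build_tyr(zinc, u, d, chain, seq) -> Residue:
    w, _ = _frame(u)
    oh = zinc + d * u
    cz = oh + 1.38 * _unit(u + 0.2 * w)
    cb = cz + 2.9 * _unit(u + 0.15 * w)
    ca = cb + 1.53 * _unit(u - 0.4 * w)
    return Residue(chain, seq, "TYR",
                   [_atom("CA", ca), _atom("CB", cb), _atom("CZ", cz),
                    _atom("OH", oh)])


_BUILDERS = {
    "HIS": _build_his, "CYS": _build_cys, "ASP": _build_asp,
    "GLU": _build_glu, "ASN": _build_asn, "SER": _build_ser,
    "THR": _build_thr, "TYR": _build_tyr,
}

def build_residue(
    res_type: str,
    zinc: Sequence[float],
    direction: Sequence[float],
    bond_length: float | None = None,
    chain: str = "A",
    seq_id: int = 1,
) -> Residue:
    """One idealized binding residue with its binding atom at
    zinc + bond_length * direction (direction is normalized)."""
    if res_type not in _BUILDERS:
        raise ContractViolationError(f"unsupported residue type {res_type}")
    u = _unit(np.asarray(direction, dtype=float))
    d = default_bond_length(res_type) if bond_length is None else bond_length
    return _BUILDERS[res_type](np.asarray(zinc, dtype=float), u, d, chain, seq_id)


_GEOMETRY_DIRECTIONS = {
    ("tetrahedral", 4): np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
    ) / np.sqrt(3.0),
    ("octahedral_partial", 4): np.array(
        [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, 0, 1]], float
    ),
    ("octahedral_partial", 5): np.array(
        [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, 0, 1], [0, -1, 0]], float
    ),
}


def _directions(geometry: str, n: int) -> np.ndarray:
    if geometry == "trigonal_apex":
        if n != 3:
            raise ContractViolationError("trigonal_apex needs exactly 3 residues")
        theta = np.radians(62.0)
        phis = np.radians([90.0, 210.0, 330.0])
        return np.array(
            [[np.sin(theta) * np.cos(p), np.sin(theta) * np.sin(p), -np.cos(theta)]
             for p in phis]
        )
    try:
        return _GEOMETRY_DIRECTIONS[(geometry, n)]
    except KeyError:
        raise ContractViolationError(
            f"unsupported geometry {geometry!r} for {n} residues"
        ) from None


def default_bond_length(res_type: str) -> float:
    return IDEAL_DISTANCE_CYS_S if res_type == "CYS" else IDEAL_DISTANCE


def make_ideal_site(
    spec: SiteSpec | str,
    zinc_coord: Sequence[float] = (0.0, 0.0, 0.0),
    structure_id: str = "ideal",
    chain: str = "A",
    start_seq: int = 10,
    zinc_occupancy: float = 1.0,
) -> ProteinStructure:
    """Structure with one geometrically exact zinc site.

    A spec given as a string ("HIS,HIS,GLU") uses the default geometry for
    its size.  For 3-residue sites the residue numbering is arranged so the
    construction ion lies on side A of the binding-point plane.
    """
    if isinstance(spec, str):
        combo = tuple(t.strip().upper() for t in spec.split(","))
        spec = SiteSpec(combo, "trigonal_apex" if len(combo) == 3 else "tetrahedral")
    combo = tuple(spec.combination)
    for t in combo:
        if t not in _BUILDERS:
            raise ContractViolationError(f"unsupported residue type {t}")
    zinc = np.asarray(zinc_coord, dtype=float)
    dirs = _directions(spec.geometry, len(combo))
    bonds = spec.bond_lengths or tuple(default_bond_length(t) for t in combo)
    if len(bonds) != len(combo):
        raise ContractViolationError("bond_lengths must match combination length")

    twists = spec.his_twist
    n_his = combo.count("HIS")
    if np.isscalar(twists):
        twists = tuple(float(twists) for _ in range(n_his))
    if len(twists) != n_his:
        raise ContractViolationError("his_twist must match the number of His")

    residues = []
    his_seen = 0
    for i, (res_type, u, d) in enumerate(zip(combo, dirs, bonds)):
        res = _BUILDERS[res_type](zinc, np.asarray(u, float), d, chain, start_seq + 10 * i)
        if res_type == "HIS":
            twist = twists[his_seen]
            his_seen += 1
            if twist:
                res = rotate_his_chi2(res, twist)
        residues.append(res)

    if len(residues) == 3:
        # ensure the construction ion sits on side A of the plane normal
        starts = initial_zinc_estimate(residues)
        if np.linalg.norm(starts[1] - zinc) < np.linalg.norm(starts[0] - zinc):
            a, b = residues[0], residues[1]
            a_seq, b_seq = a.seq_id, b.seq_id
            residues[0] = Residue(a.chain, b_seq, a.res_type, a.atoms, a.insertion_code)
            residues[1] = Residue(b.chain, a_seq, b.res_type, b.atoms, b.insertion_code)
            residues.sort(key=lambda r: (r.chain, r.seq_id))

    structure = ProteinStructure(
        structure_id=structure_id,
        residues=residues,
        het_ions=[HetIon("ZN", zinc.copy(), zinc_occupancy)],
    )
    if spec.noise_sigma > 0:
        structure = perturb_site(structure, spec.noise_sigma, spec.seed)
    return structure


def copy_structure(structure: ProteinStructure) -> ProteinStructure:
    residues = [
        Residue(
            r.chain, r.seq_id, r.res_type,
            [replace(a, coord=a.coord.copy()) for a in r.atoms],
            r.insertion_code,
        )
        for r in structure.residues
    ]
    ions = [HetIon(i.element, i.coord.copy(), i.occupancy) for i in structure.het_ions]
    return ProteinStructure(structure.structure_id, residues, ions)


def perturb_site(structure: ProteinStructure, noise_sigma: float, seed: int = 0) -> ProteinStructure:
    """Gaussian-displace every residue atom (the ion ground truth is kept)."""
    if noise_sigma < 0:
        raise ContractViolationError("noise_sigma must be >= 0")
    out = copy_structure(structure)
    if noise_sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for res in out.residues:
        for atom in res.atoms:
            atom.coord = atom.coord + rng.normal(0.0, noise_sigma, size=3)
    return out


def transform_structure(
    structure: ProteinStructure, rotation: np.ndarray, translation: np.ndarray
) -> ProteinStructure:
    """Apply a proper rigid transform to every atom and ion."""
    out = copy_structure(structure)
    for res in out.residues:
        for atom in res.atoms:
            atom.coord = rotation @ atom.coord + translation
    for ion in out.het_ions:
        ion.coord = rotation @ ion.coord + translation
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    quat = rng.normal(size=4)
    return Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()


def make_decoy_site(kind: str, seed: int = 0) -> ProteinStructure:
    """Negative controls: two_residue | stretched | wrong_types."""
    rng = np.random.default_rng(seed)
    zinc = np.zeros(3)
    if kind == "two_residue":
        dirs = _GEOMETRY_DIRECTIONS[("tetrahedral", 4)]
        residues = [
            _build_his(zinc, dirs[0], IDEAL_DISTANCE, "A", 10),
            _build_cys(zinc, dirs[1], IDEAL_DISTANCE_CYS_S, "A", 20),
        ]
        return ProteinStructure(f"decoy_two_residue_{seed}", residues, [])
    if kind == "stretched":
        u = np.array([0.0, 0.0, 1.0])
        anchors = [np.zeros(3), np.array([8.5, 0, 0]), np.array([4.0, 8.0, 0])]
        residues = [
            _build_his(p - IDEAL_DISTANCE * u, u, IDEAL_DISTANCE, "A", 10 + 10 * i)
            for i, p in enumerate(anchors)
        ]
        return ProteinStructure(f"decoy_stretched_{seed}", residues, [])
    if kind == "wrong_types":
        dirs = _GEOMETRY_DIRECTIONS[("tetrahedral", 4)]
        residues = []
        for i, u in enumerate(dirs):
            w, v = _frame(u)
            ca = zinc + 2.15 * u + rng.normal(0, 0.05, 3)
            atoms = [
                _atom("N", ca + 1.45 * v), _atom("CA", ca),
                _atom("CB", ca + 1.53 * w), _atom("C", ca - 1.5 * w),
                _atom("O", ca - 1.5 * w + 1.23 * u),
            ]
            residues.append(Residue("A", 10 + 10 * i, "ALA", atoms))
        return ProteinStructure(f"decoy_wrong_types_{seed}", residues, [])
    raise ContractViolationError(f"unknown decoy kind {kind!r}")


def make_fixture_library(
    specs: Sequence[SiteSpec] = DEFAULT_FIXTURE_SPECS, seed: int = 0
) -> tuple[list[ProteinStructure], TemplateLibrary]:
    """Three rigidly transformed copies of each spec's ideal site (so each
    combination passes the multiplicity filters), curated into a library."""
    if not specs:
        raise ContractViolationError("need at least one spec")
    rng = np.random.default_rng(seed)
    structures = []
    observed = []
    for i, spec in enumerate(specs):
        for j in range(3):
            s = make_ideal_site(spec, structure_id=f"FIX{i}_{j}")
            s = transform_structure(
                s, _random_rotation(rng), rng.uniform(-20, 20, size=3)
            )
            structures.append(s)
            observed.extend(extract_observed_sites(s))
    library = curate_templates(observed, seed=seed)
    return structures, library


def make_scaling_structure(n_residues: int, seed: int = 0) -> ProteinStructure:
    """Structure of given length for runtime-scaling checks: filler residues
    along a loose helix, sparse His, and one embedded ideal site per ~500
    residues placed far from the helix."""
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    ions: list[HetIon] = []
    n_sites = max(1, n_residues // 500)
    site_spec = SiteSpec(("HIS", "HIS", "GLU", "CYS"), "tetrahedral")
    for k in range(n_sites):
        zinc = np.array([80.0 + 40.0 * k, 0.0, 0.0])
        site = make_ideal_site(site_spec, zinc, chain="S", start_seq=1000 * (k + 1))
        residues.extend(site.residues)
        ions.extend(site.het_ions)
    n_filler = n_residues - len(residues)
    u = np.array([0.0, 0.0, 1.0])
    for i in range(n_filler):
        center = np.array(
            [10 * np.cos(0.6 * i), 10 * np.sin(0.6 * i), 1.5 * i], float
        ) + rng.normal(0, 0.1, 3)
        if i % 20 == 10:
            residues.append(_build_his(center - 2.15 * u, u, 2.15, "A", i + 1))
        else:
            w, v = _frame(u)
            atoms = [
                _atom("N", center + 1.45 * v), _atom("CA", center),
                _atom("CB", center + 1.53 * w), _atom("C", center - 1.5 * w),
                _atom("O", center - 1.5 * w + 1.23 * u),
            ]
            residues.append(Residue("A", i + 1, "ALA", atoms))
    return ProteinStructure(f"scale_{n_residues}", residues, ions)


def write_truth_csv(structures: Sequence[ProteinStructure], path) -> None:
    """Ground-truth ion CSV (structure_id, metal, x, y, z)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["structure_id", "metal", "x", "y", "z"])
        for s in structures:
            for ion in s.het_ions:
                writer.writerow(
                    [s.structure_id, ion.element]
                    + [f"{c:.4f}" for c in ion.coord]
                )
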