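"""Ion placement and orientation geometry.

Covers the placement pipeline for a candidate site (initial estimate, atom
selection, least-squares refinement), imidazole orientation angles,
rigid-body superposition RMSD against templates, and histidine chi2 rotamer
sampling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ContractViolationError, DegenerateGeometryError, MissingAtomError
from .scoring import his_angles_score, ideal_distance
from .structure_model import BINDING_ATOMS, Atom, Residue, binding_point

#: offset of the two trial starts from the 3-ligand plane, Å
PLANE_OFFSET = 1.5

_RING_ATOMS = ("CG", "ND1", "CD2", "CE1", "NE2")


@dataclass
class ChosenAtom:
    residue: Residue
    atom_name: str
    coord: np.ndarray
    d_ideal: float


@dataclass
class PlacementResult:
    zinc_coord: np.ndarray
    chosen_atoms: list[ChosenAtom]
    distances: np.ndarray
    ideals: np.ndarray
    drmsd: float
    side_label: str = "n/a"
    converged: bool = True

    @property
    def n_ligands(self) -> int:
        return len(self.chosen_atoms)


def _sorted_residues(residues: Sequence[Residue]) -> list[Residue]:
    return sorted(residues, key=lambda r: (r.chain, r.seq_id, r.insertion_code))


# ---------------------------------------------------------------------------
# initial estimate
# ---------------------------------------------------------------------------

def initial_zinc_estimate(
    residues: Sequence[Residue], delta: float = PLANE_OFFSET
) -> list[np.ndarray]:
    """Starting point(s) for refinement.

    4+ residues: the centroid of the binding points (one start).  3 residues:
    two starts at centroid +/- delta along the plane normal; index 0 is
    "side A" (normal from residues in (chain, seq_id) order).
    """
    residues = _sorted_residues(residues)
    if len(residues) < 3:
        raise ContractViolationError("need at least 3 residues")
    points = np.array([binding_point(r) for r in residues])
    centroid = points.mean(axis=0)
    if len(residues) >= 4:
        return [centroid]
    v1 = points[1] - points[0]
    v2 = points[2] - points[1]
    normal = np.cross(v1, v2)
    norm = np.linalg.norm(normal)
    if norm < 1e-6 * np.linalg.norm(v1) * np.linalg.norm(v2) or norm < 1e-9:
        raise DegenerateGeometryError("collinear binding points; no plane normal")
    normal /= norm
    return [centroid + delta * normal, centroid - delta * normal]


# ---------------------------------------------------------------------------
# atom selection
# ---------------------------------------------------------------------------

def select_binding_atoms(
    residues: Sequence[Residue], zinc_estimate: np.ndarray
) -> list[ChosenAtom]:
    """Per residue, pick the listed side-chain atom nearest the estimate.

    Ties break to the lexicographically smaller atom name.
    """
    chosen = []
    for res in _sorted_residues(residues):
        names = BINDING_ATOMS[res.res_type]
        candidates = [(n, res.atom(n)) for n in names if res.atom(n) is not None]
        if not candidates:
            raise MissingAtomError(f"{res.label}: no binding atom present")
        best = min(
            candidates,
            key=lambda na: (round(float(np.linalg.norm(na[1].coord - zinc_estimate)), 9), na[0]),
        )
        name, atom = best
        chosen.append(ChosenAtom(res, name, atom.coord.copy(), ideal_distance(name)))
    return chosen


# ---------------------------------------------------------------------------
# least-squares refinement
# ---------------------------------------------------------------------------

def refine_zinc_position(
    chosen_atoms: Sequence[ChosenAtom],
    start: np.ndarray,
    side_label: str = "n/a",
    max_iter: int = 200,
    tol: float = 1e-8,
) -> PlacementResult:
    """Levenberg-Marquardt minimization of sum (d_i - d_ideal_i)^2."""
    from scipy.optimize import least_squares

    if len(chosen_atoms) < 3:
        raise ContractViolationError("need at least 3 chosen atoms")
    start = np.asarray(start, dtype=float)
    coords = np.array([c.coord for c in chosen_atoms])
    ideals = np.array([c.d_ideal for c in chosen_atoms])

    def residuals(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(coords - x, axis=1) - ideals

    result = least_squares(
        residuals,
        x0=start,
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 4,
    )
    zinc = result.x
    distances = np.linalg.norm(coords - zinc, axis=1)
    dr = float(np.sqrt(np.mean((distances - ideals) ** 2)))
    return PlacementResult(
        zinc_coord=zinc,
        chosen_atoms=list(chosen_atoms),
        distances=distances,
        ideals=ideals,
        drmsd=dr,
        side_label=side_label,
        converged=bool(result.status > 0),
    )


# ---------------------------------------------------------------------------
# imidazole orientation
# ---------------------------------------------------------------------------

@dataclass
class ImidazoleAngles:
    alpha: float  # out-of-plane elevation of the Zn-N bond, degrees in [0, 90]
    beta: float   # in-plane deviation from the m->N extension, degrees in [0, 180]
    nitrogen_used: str


def _ring_plane_normal(ring_coords: np.ndarray) -> np.ndarray:
    centered = ring_coords - ring_coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def imidazole_angles(his: Residue, zinc: np.ndarray, nitrogen: str) -> ImidazoleAngles:
    """Orientation of the Zn-N coordination bond relative to the imidazole.

    alpha is 90 degrees minus the angle between the ring-plane normal and
    the bond vector (folded into [0, 90]); beta is the angle between the
    bond's in-plane projection and the extension of the midpoint(C1,C2)->N
    axis, where (C1, C2) = (CD2, CE1) for NE2 and (CE1, CG) for ND1.
    """
    if nitrogen not in ("ND1", "NE2"):
        raise ContractViolationError(f"nitrogen must be ND1 or NE2, got {nitrogen}")
    ring = np.array([his.require_atom(n).coord for n in _RING_ATOMS])
    normal = _ring_plane_normal(ring)
    n_coord = his.require_atom(nitrogen).coord
    if nitrogen == "NE2":
        c1, c2 = his.require_atom("CD2").coord, his.require_atom("CE1").coord
    else:
        c1, c2 = his.require_atom("CE1").coord, his.require_atom("CG").coord

    bond = np.asarray(zinc, dtype=float) - n_coord
    bond_norm = np.linalg.norm(bond)
    if bond_norm < 1e-9:
        raise DegenerateGeometryError("zinc coincides with the nitrogen")
    bond_u = bond / bond_norm

    cos_to_normal = np.clip(np.dot(bond_u, normal), -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_to_normal))
    alpha = abs(90.0 - theta)

    m = 0.5 * (c1 + c2)
    mn = n_coord - m
    mn_u = mn / np.linalg.norm(mn)
    proj = bond - np.dot(bond, normal) * normal
    proj_norm = np.linalg.norm(proj)
    if proj_norm < 1e-12:
        beta = 0.0  # bond perpendicular to the ring: in-plane direction undefined
    else:
        cos_b = np.clip(np.dot(proj / proj_norm, mn_u), -1.0, 1.0)
        beta = float(np.degrees(np.arccos(cos_b)))
    return ImidazoleAngles(alpha=float(alpha), beta=beta, nitrogen_used=nitrogen)


def site_his_angles(
    chosen_atoms: Sequence[ChosenAtom], zinc: np.ndarray
) -> list[ImidazoleAngles]:
    """Imidazole angles for every His ligand, using each His's chosen N."""
    out = []
    for c in chosen_atoms:
        if c.residue.res_type == "HIS":
            out.append(imidazole_angles(c.residue, zinc, c.atom_name))
    return out


def site_his_angles_score(
    chosen_atoms: Sequence[ChosenAtom], zinc: np.ndarray
) -> float | None:
    angles = site_his_angles(chosen_atoms, zinc)
    if not angles:
        return None
    return his_angles_score([a.alpha for a in angles], [a.beta for a in angles])


# ---------------------------------------------------------------------------
# side selection for 3-residue sites
# ---------------------------------------------------------------------------

def choose_three_residue_side(
    results: Sequence[PlacementResult],
    his_scores: Sequence[float | None],
    both_sides: bool = False,
) -> list[PlacementResult]:
    """Pick the refined placement among the two mirror-symmetric candidates.

    His-containing sites: lower imidazole-angles score wins; no-His sites:
    side A; ties: side A.  With both_sides=True both placements are kept.
    """
    if len(results) == 1:
        return [results[0]]
    if both_sides:
        return list(results)
    a, b = results
    sa, sb = his_scores
    if sa is not None and sb is not None and sb < sa:
        return [b]
    return [a]


# ---------------------------------------------------------------------------
# superposition RMSD
# ---------------------------------------------------------------------------

def _kabsch_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    from Bio.SVDSuperimposer import SVDSuperimposer

    sup = SVDSuperimposer()
    sup.set(fixed, moving)
    sup.run()
    return float(sup.get_rms())


def superimpose_rmsd(
    site_atoms: Sequence[tuple[str, np.ndarray]],
    template_atoms: Sequence[tuple[str, np.ndarray]],
) -> float:
    """Minimum RMSD between the site's and the template's binding atoms over
    rigid superposition, enumerating correspondences within each residue-type
    group.  Inputs are (res_type, coord) lists.
    """
    site_types = sorted(t for t, _ in site_atoms)
    tmpl_types = sorted(t for t, _ in template_atoms)
    if site_types != tmpl_types:
        raise ContractViolationError(
            f"residue-type multisets differ: {site_types} vs {tmpl_types}"
        )
    # canonical grouping by type
    groups: dict[str, tuple[list[np.ndarray], list[np.ndarray]]] = {}
    for t, c in site_atoms:
        groups.setdefault(t, ([], []))[0].append(np.asarray(c, dtype=float))
    for t, c in template_atoms:
        groups[t][1].append(np.asarray(c, dtype=float))

    types = sorted(groups)
    fixed = np.vstack([g for t in types for g in groups[t][0]])
    perm_spaces = [list(itertools.permutations(range(len(groups[t][1])))) for t in types]
    best = np.inf
    for combo in itertools.product(*perm_spaces):
        moving_rows = []
        for t, perm in zip(types, combo):
            tmpl_coords = groups[t][1]
            moving_rows.extend(tmpl_coords[i] for i in perm)
        rms = _kabsch_rmsd(np.vstack(moving_rows), fixed)
        best = min(best, rms)
    return best


# ---------------------------------------------------------------------------
# histidine rotamer sampling
# ---------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def rotate_his_chi2(his: Residue, angle_deg: float) -> Residue:
    """Return a copy of the His with its ring atoms rotated about the CB-CG
    axis by the given angle (CG stays on the axis)."""
    cb = his.require_atom("CB").coord
    cg = his.require_atom("CG").coord
    rot = _rotation_matrix(cg - cb, angle_deg)
    new_atoms = []
    ring_movers = {"ND1", "CD2", "CE1", "NE2"}
    for atom in his.atoms:
        if atom.name in ring_movers:
            new_coord = cb + rot @ (atom.coord - cb)
            new_atoms.append(replace(atom, coord=new_coord))
        else:
            new_atoms.append(replace(atom, coord=atom.coord.copy()))
    return Residue(his.chain, his.seq_id, his.res_type, new_atoms, his.insertion_code)


@dataclass
class RotamerResult:
    residues: list[Residue]            # site residues with adjusted His rings
    placement: PlacementResult
    his_angles: list[ImidazoleAngles]
    angles_score: float
    rotations: tuple[float, ...]       # cumulative chi2 rotation per sampled His
    n_evaluations: int = 0
    visited: set = field(default_factory=set)


def sample_his_rotamers(
    residues: Sequence[Residue],
    start: np.ndarray,
    step: float = 15.0,
    span: float = 180.0,
    max_his: int = 4,
) -> RotamerResult:
    """Greedy chi2 sampling of the His rings of a site.

    Each round proposes every {-step, 0, +step} combination over the sampled
    His residues, skipping configurations already visited, and keeps the one
    with the lowest imidazole-angles score after re-selecting binding
    nitrogens and re-refining the ion position.  Stops when the cumulative
    rotation bound (span) is reached, no new configuration remains, or no
    proposal improves the score.
    """
    residues = _sorted_residues(residues)
    his_idx = [i for i, r in enumerate(residues) if r.res_type == "HIS"]
    if len(his_idx) > max_his:
        his_idx = sorted(
            his_idx,
            key=lambda i: float(np.linalg.norm(binding_point(residues[i]) - start)),
        )[:max_his]
        his_idx.sort()

    def evaluate(rotations: tuple[float, ...]):
        current = list(residues)
        for i, ang in zip(his_idx, rotations):
            if ang != 0.0:
                current[i] = rotate_his_chi2(residues[i], ang)
        chosen = select_binding_atoms(current, start)
        placement = refine_zinc_position(chosen, start)
        angles = site_his_angles(chosen, placement.zinc_coord)
        if angles:
            score = his_angles_score(
                [a.alpha for a in angles], [a.beta for a in angles]
            )
        else:
            score = 0.0
        return current, placement, angles, score

    base = tuple(0.0 for _ in his_idx)
    visited: set[tuple[float, ...]] = {base}
    cur_res, cur_place, cur_angles, cur_score = evaluate(base)
    n_eval = 1
    best = RotamerResult(cur_res, cur_place, cur_angles, cur_score, base, n_eval, visited)

    if not his_idx:
        return best

    current_rot = base
    deltas = list(itertools.product((-step, 0.0, step), repeat=len(his_idx)))
    while True:
        proposals = []
        for d in deltas:
            cand = tuple(r + dd for r, dd in zip(current_rot, d))
            if cand in visited:
                continue
            if any(abs(r) > span + 1e-9 for r in cand):
                continue
            proposals.append(cand)
        if not proposals:
            break
        round_best = None
        for cand in proposals:
            visited.add(cand)
            res, place, angles, score = evaluate(cand)
            n_eval += 1
            if round_best is None or score < round_best[3]:
                round_best = (res, place, angles, score, cand)
        res, place, angles, score, cand = round_best
        if score < best.angles_score - 1e-12:
            best = RotamerResult(res, place, angles, score, cand, n_eval, visited)
            current_rot = cand
        else:
            break
    best.n_evaluations = n_eval
    best.visited = visited
    return best
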