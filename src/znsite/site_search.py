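"""Candidate-site enumeration: pair collection, index lookup, assembly.

Candidate residue pairs (binding points strictly closer than the 7 Å
cutoff) are matched against the inverted index on residue types and binned
Cα/Cβ distances, then completed into full residue combinations by
backtracking over the pair-compatibility structure of each template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import ProteinStructure, Residue, binding_point, extract_binding_residues
from .template_library import InvertedIndex, TemplateLibrary

logger = logging.getLogger(__name__)

PAIR_CUTOFF = 7.0
ASSEMBLY_CAP = 10_000


@dataclass
class CandidatePair:
    residue_a: Residue
    residue_b: Residue
    binding_distance: float
    ca_distance: float | None
    cb_distance: float | None

    @property
    def key(self) -> frozenset:
        return frozenset((self.residue_a.key, self.residue_b.key))


@dataclass
class CandidateSite:
    residues: list[Residue]
    template_id: str
    combination: tuple[str, ...]

    @property
    def residue_keys(self) -> frozenset:
        return frozenset(r.key for r in self.residues)


def _pair_atom_distance(a: Residue, b: Residue, name: str) -> float | None:
    atom_a, atom_b = a.atom(name), b.atom(name)
    if atom_a is None or atom_b is None:
        return None
    return float(np.linalg.norm(atom_a.coord - atom_b.coord))


def collect_candidate_pairs(
    structure: ProteinStructure, cutoff: float = PAIR_CUTOFF
) -> list[CandidatePair]:
    """All unordered binding-residue pairs with binding points strictly
    closer than the cutoff (KD-tree, near-linear for spread-out chains)."""
    residues = sorted(
        extract_binding_residues(structure),
        key=lambda r: (r.chain, r.seq_id, r.insertion_code),
    )
    if len(residues) < 2:
        return []
    points = np.array([binding_point(r) for r in residues])
    tree = cKDTree(points)
    pairs = []
    for i, j in sorted(tree.query_pairs(r=cutoff)):
        d = float(np.linalg.norm(points[i] - points[j]))
        if d >= cutoff:
            continue
        pairs.append(
            CandidatePair(
                residue_a=residues[i],
                residue_b=residues[j],
                binding_distance=d,
                ca_distance=_pair_atom_distance(residues[i], residues[j], "CA"),
                cb_distance=_pair_atom_distance(residues[i], residues[j], "CB"),
            )
        )
    return pairs


def query_index(
    pairs: Sequence[CandidatePair], index: InvertedIndex
) -> list[tuple[CandidatePair, str, tuple[int, int]]]:
    """Hits (pair, template_id, slot) where residue types match and both the
    Cα and Cβ distances fall within the index tolerance of the template's."""
    hits = []
    for pair in pairs:
        if pair.ca_distance is None or pair.cb_distance is None:
            continue
        types = (pair.residue_a.res_type, pair.residue_b.res_type)
        ca_hits = index.lookup(types, "CA", pair.ca_distance)
        cb_hits = index.lookup(types, "CB", pair.cb_distance)
        for value in ca_hits & cb_hits:
            template_id, slot = value
            hits.append((pair, template_id, slot))
    return hits


def assemble_candidate_sites(
    hits: Sequence[tuple[CandidatePair, str, tuple[int, int]]],
    structure: ProteinStructure,
    library: TemplateLibrary,
    cap: int = ASSEMBLY_CAP,
) -> list[CandidateSite]:
    """Complete pairwise hits into full candidate sites by backtracking.

    A site assigns distinct query residues to all template positions such
    that every internal residue pair was an index hit for its slot.
    Duplicate sites (same residue set, same template) are emitted once; a
    template whose raw assembly count exceeds the cap is skipped.
    """
    # organize hits per template: slot -> set of admissible ordered residue pairs
    per_template: dict[str, dict[tuple[int, int], set]] = {}
    residues_by_key: dict = {}
    for pair, template_id, slot in hits:
        a, b = pair.residue_a, pair.residue_b
        residues_by_key[a.key] = a
        residues_by_key[b.key] = b
        per_template.setdefault(template_id, {}).setdefault(slot, set()).add(
            frozenset((a.key, b.key))
        )

    sites: list[CandidateSite] = []
    seen: set[tuple[str, frozenset]] = set()
    for template_id in sorted(per_template):
        template = library.get(template_id)
        slots = per_template[template_id]
        k = len(template.residues)
        all_slots = [(i, j) for i in range(k) for j in range(i + 1, k)]
        if any(slot not in slots for slot in all_slots):
            continue  # some template pair has no admissible query pair at all
        # candidates per template position, by residue type
        position_candidates: list[list[Residue]] = []
        for pos in range(k):
            wanted = template.residues[pos].res_type
            cands = sorted(
                (r for r in residues_by_key.values() if r.res_type == wanted),
                key=lambda r: (r.chain, r.seq_id, r.insertion_code),
            )
            position_candidates.append(cands)

        assemblies: list[tuple] = []
        overflow = False

        def backtrack(pos: int, assignment: list[Residue]) -> None:
            nonlocal overflow
            if overflow:
                return
            if pos == k:
                assemblies.append(tuple(assignment))
                if len(assemblies) > cap:
                    overflow = True
                return
            for cand in position_candidates[pos]:
                if any(cand.key == prev.key for prev in assignment):
                    continue
                ok = True
                for prev_pos in range(pos):
                    slot = (prev_pos, pos)
                    admissible = slots.get(slot, set())
                    if frozenset((assignment[prev_pos].key, cand.key)) not in admissible:
                        ok = False
                        break
                if ok:
                    assignment.append(cand)
                    backtrack(pos + 1, assignment)
                    assignment.pop()

        backtrack(0, [])
        if overflow:
            logger.warning(
                "structure %s: template %s exceeded the assembly cap (%d); skipped",
                structure.structure_id, template_id, cap,
            )
            continue
        for assembly in assemblies:
            key = (template_id, frozenset(r.key for r in assembly))
            if key in seen:
                continue
            seen.add(key)
            ordered = sorted(assembly, key=lambda r: (r.chain, r.seq_id, r.insertion_code))
            sites.append(
                CandidateSite(
                    residues=ordered,
                    template_id=template_id,
                    combination=template.combination,
                )
            )
    return sites


def find_candidate_sites(
    structure: ProteinStructure,
    library: TemplateLibrary,
    index: InvertedIndex,
    cutoff: float = PAIR_CUTOFF,
    cap: int = ASSEMBLY_CAP,
) -> list[CandidateSite]:
    pairs = collect_candidate_pairs(structure, cutoff)
    hits = query_index(pairs, index)
    return assemble_candidate_sites(hits, structure, library, cap)


def verify_candidate_site(
    site: CandidateSite,
    library: TemplateLibrary,
    index: InvertedIndex,
    cutoff: float = PAIR_CUTOFF,
) -> bool:
    """Independent re-check of a candidate site: type multiset equality and
    all pairwise distance constraints recomputed from scratch."""
    template = library.get(site.template_id)
    if tuple(sorted(r.res_type for r in site.residues)) != template.combination:
        return False
    for i in range(len(site.residues)):
        for j in range(i + 1, len(site.residues)):
            a, b = site.residues[i], site.residues[j]
            d = float(np.linalg.norm(binding_point(a) - binding_point(b)))
            if d >= cutoff:
                return False
    # each residue pair must satisfy the index tolerance for some slot
    slots = index.template_pairs[site.template_id]
    for i in range(len(site.residues)):
        for j in range(i + 1, len(site.residues)):
            a, b = site.residues[i], site.residues[j]
            ca_d = _pair_atom_distance(a, b, "CA")
            cb_d = _pair_atom_distance(a, b, "CB")
            if ca_d is None or cb_d is None:
                return False
            ok = False
            for info in slots.values():
                if tuple(sorted(info["types"])) != tuple(sorted((a.res_type, b.res_type))):
                    continue
                if (
                    abs(index._bin(ca_d) - index._bin(info["ca"])) <= index.tolerance_bins
                    and abs(index._bin(cb_d) - index._bin(info["cb"])) <= index.tolerance_bins
                ):
                    ok = True
                    break
            if not ok:
                return False
    return True
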