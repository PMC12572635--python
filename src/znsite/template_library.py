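"""Template curation, serialization, and the inverted pair index.

A template is one observed zinc-binding site kept as a search pattern: the
residue-type combination, the coordinating atom coordinates, and the ion
position.  Curation applies three filters — at least three coordinating
residues, the combination seen in at least three sites across at least
three distinct structures, and ion occupancy above 0.5 — then keeps one
seeded-random representative per accepted combination.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ContractViolationError, LibraryVersionError, ParseError
from .scoring import CalibrationModel, DEFAULT_CALIBRATION
from .structure_model import (
    BINDING_ATOMS,
    ProteinStructure,
    Residue,
)

LIBRARY_FORMAT_VERSION = 1

#: default distance (Å) within which an atom counts as coordinating an ion
DEFAULT_COORDINATION_CUTOFF = 2.8


# ---------------------------------------------------------------------------
# observed sites
# ---------------------------------------------------------------------------

@dataclass
class ObservedZincSite:
    zinc_coord: np.ndarray
    zinc_occupancy: float
    coordinating: list[tuple[Residue, str, np.ndarray]]  # (residue, atom, coord)
    source_id: str

    @property
    def combination(self) -> tuple[str, ...]:
        return tuple(sorted(r.res_type for r, _, _ in self.coordinating))

    @property
    def n_residues(self) -> int:
        return len(self.coordinating)


def extract_observed_sites(
    structure: ProteinStructure,
    coordination_cutoff: float = DEFAULT_COORDINATION_CUTOFF,
    metals: tuple[str, ...] = ("ZN",),
) -> list[ObservedZincSite]:
    """One site per bound metal ion; coordinating residues are dictionary
    residues with a binding atom within the cutoff (each residue contributes
    its single nearest binding atom)."""
    if coordination_cutoff <= 0:
        raise ContractViolationError("cutoff must be positive")
    sites = []
    for ion in structure.het_ions:
        if ion.element not in metals:
            continue
        coordinating = []
        for res in structure.residues:
            names = BINDING_ATOMS.get(res.res_type)
            if not names:
                continue
            best: tuple[float, str, np.ndarray] | None = None
            for name in names:
                atom = res.atom(name)
                if atom is None:
                    continue
                d = float(np.linalg.norm(atom.coord - ion.coord))
                if d <= coordination_cutoff and (best is None or d < best[0]):
                    best = (d, name, atom.coord)
            if best is not None:
                coordinating.append((res, best[1], best[2]))
        sites.append(
            ObservedZincSite(
                zinc_coord=ion.coord.copy(),
                zinc_occupancy=ion.occupancy,
                coordinating=coordinating,
                source_id=structure.structure_id,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

@dataclass
class TemplateResidue:
    res_type: str
    atom_name: str
    binding_coord: np.ndarray
    ca_coord: np.ndarray | None
    cb_coord: np.ndarray | None

    def __post_init__(self) -> None:
        self.binding_coord = np.asarray(self.binding_coord, dtype=float)
        if self.ca_coord is not None:
            self.ca_coord = np.asarray(self.ca_coord, dtype=float)
        if self.cb_coord is not None:
            self.cb_coord = np.asarray(self.cb_coord, dtype=float)


@dataclass
class Template:
    template_id: str
    residues: list[TemplateResidue]
    zinc_coord: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        self.zinc_coord = np.asarray(self.zinc_coord, dtype=float)
        # canonical residue order: sorted by type, then by distance to ion
        self.residues = sorted(
            self.residues,
            key=lambda r: (r.res_type, float(np.linalg.norm(r.binding_coord - self.zinc_coord))),
        )

    @property
    def combination(self) -> tuple[str, ...]:
        return tuple(sorted(r.res_type for r in self.residues))

    @property
    def binding_atoms(self) -> list[tuple[str, str, np.ndarray]]:
        return [(r.res_type, r.atom_name, r.binding_coord) for r in self.residues]

    @classmethod
    def from_site(cls, site: ObservedZincSite, template_id: str) -> "Template":
        residues = []
        for res, atom_name, coord in site.coordinating:
            ca = res.atom("CA")
            cb = res.atom("CB")
            residues.append(
                TemplateResidue(
                    res_type=res.res_type,
                    atom_name=atom_name,
                    binding_coord=np.asarray(coord, dtype=float),
                    ca_coord=None if ca is None else ca.coord,
                    cb_coord=None if cb is None else cb.coord,
                )
            )
        return cls(template_id, residues, site.zinc_coord, site.source_id)


@dataclass
class TemplateLibrary:
    templates: list[Template] = field(default_factory=list)
    curation_log: dict = field(default_factory=dict)
    calibration: CalibrationModel = DEFAULT_CALIBRATION

    def __len__(self) -> int:
        return len(self.templates)

    def get(self, template_id: str) -> Template:
        for t in self.templates:
            if t.template_id == template_id:
                return t
        raise KeyError(template_id)


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def curate_templates(
    sites: Sequence[ObservedZincSite],
    min_residues: int = 3,
    min_sites: int = 3,
    min_structures: int = 3,
    min_occupancy: float = 0.5,
    seed: int = 0,
) -> TemplateLibrary:
    """Apply the three curation filters and pick one seeded-random
    representative per accepted residue-type combination."""
    log: dict = {"seed": seed, "combinations": {}, "dropped_sites": {}}
    surviving: dict[tuple[str, ...], list[ObservedZincSite]] = {}
    n_few, n_occ = 0, 0
    for site in sites:
        if site.n_residues < min_residues:
            n_few += 1
            continue
        if site.zinc_occupancy <= min_occupancy:
            n_occ += 1
            continue
        surviving.setdefault(site.combination, []).append(site)
    log["dropped_sites"] = {
        "too_few_residues": n_few,
        "low_occupancy": n_occ,
    }

    rng = random.Random(seed)
    library = TemplateLibrary(curation_log=log)
    idx = 1
    for combination in sorted(surviving):
        group = surviving[combination]
        n_structures = len({s.source_id for s in group})
        entry = {"n_sites": len(group), "n_structures": n_structures}
        if len(group) < min_sites:
            entry.update(accepted=False, reason=f"fewer than {min_sites} sites")
        elif n_structures < min_structures:
            entry.update(
                accepted=False, reason=f"fewer than {min_structures} distinct structures"
            )
        else:
            ordered = sorted(
                group, key=lambda s: (s.source_id, tuple(np.round(s.zinc_coord, 6)))
            )
            chosen = rng.choice(ordered)
            template = Template.from_site(chosen, f"T{idx:03d}")
            idx += 1
            library.templates.append(template)
            entry.update(
                accepted=True,
                reason="accepted",
                template_id=template.template_id,
                source_id=chosen.source_id,
            )
        log["combinations"][",".join(combination)] = entry
    return library


def add_user_template(
    library: TemplateLibrary,
    structure: ProteinStructure,
    zinc_selector: int | Sequence[float] = 0,
    coordination_cutoff: float = DEFAULT_COORDINATION_CUTOFF,
    min_residues: int = 3,
) -> TemplateLibrary:
    """Append an explicit user template (multiplicity filters not applied).

    zinc_selector is the het-ion index or an approximate ion coordinate.
    """
    sites = extract_observed_sites(structure, coordination_cutoff)
    if not sites:
        raise ContractViolationError(f"{structure.structure_id} has no zinc ion")
    if isinstance(zinc_selector, int):
        site = sites[zinc_selector]
    else:
        target = np.asarray(zinc_selector, dtype=float)
        site = min(sites, key=lambda s: float(np.linalg.norm(s.zinc_coord - target)))
    if site.n_residues < min_residues:
        raise ContractViolationError(
            f"selected site has {site.n_residues} coordinating residues; "
            f"need at least {min_residues}"
        )
    n_user = sum(1 for t in library.templates if t.template_id.startswith("U"))
    template = Template.from_site(site, f"U{n_user + 1:03d}")
    library.templates.append(template)
    return library


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _template_to_dict(t: Template) -> dict:
    return {
        "template_id": t.template_id,
        "source_id": t.source_id,
        "zinc_coord": t.zinc_coord.tolist(),
        "residues": [
            {
                "res_type": r.res_type,
                "atom_name": r.atom_name,
                "binding_coord": r.binding_coord.tolist(),
                "ca_coord": None if r.ca_coord is None else r.ca_coord.tolist(),
                "cb_coord": None if r.cb_coord is None else r.cb_coord.tolist(),
            }
            for r in t.residues
        ],
    }


def save_library(library: TemplateLibrary, path) -> None:
    payload = {
        "format_version": LIBRARY_FORMAT_VERSION,
        "calibration": {"A": library.calibration.A, "B": library.calibration.B},
        "curation_log": library.curation_log,
        "templates": [_template_to_dict(t) for t in library.templates],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_library(path) -> TemplateLibrary:
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ParseError(f"cannot read library {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ParseError(f"{path} is not a template library file")
    version = payload["format_version"]
    if version != LIBRARY_FORMAT_VERSION:
        raise LibraryVersionError(
            f"library format {version} unsupported (expected {LIBRARY_FORMAT_VERSION})"
        )
    templates = []
    for td in payload["templates"]:
        templates.append(
            Template(
                template_id=td["template_id"],
                source_id=td["source_id"],
                zinc_coord=np.array(td["zinc_coord"], dtype=float),
                residues=[
                    TemplateResidue(
                        res_type=rd["res_type"],
                        atom_name=rd["atom_name"],
                        binding_coord=np.array(rd["binding_coord"], dtype=float),
                        ca_coord=None if rd["ca_coord"] is None else np.array(rd["ca_coord"]),
                        cb_coord=None if rd["cb_coord"] is None else np.array(rd["cb_coord"]),
                    )
                    for rd in td["residues"]
                ],
            )
        )
    cal = payload.get("calibration")
    calibration = (
        CalibrationModel(A=cal["A"], B=cal["B"]) if cal else DEFAULT_CALIBRATION
    )
    return TemplateLibrary(
        templates=templates,
        curation_log=payload.get("curation_log", {}),
        calibration=calibration,
    )


# ---------------------------------------------------------------------------
# inverted index
# ---------------------------------------------------------------------------

@dataclass
class InvertedIndex:
    """Postings from (sorted residue-type pair, atom kind, distance bin) to
    (template_id, residue-pair slot)."""

    bin_width: float = 1.0
    tolerance_bins: int = 1
    postings: dict = field(default_factory=dict)
    template_pairs: dict = field(default_factory=dict)  # template_id -> slot info

    def _bin(self, distance: float) -> int:
        return int(math.floor(distance / self.bin_width))

    def insert(self, res_types: tuple[str, str], kind: str, distance: float, value) -> None:
        key = (tuple(sorted(res_types)), kind, self._bin(distance))
        self.postings.setdefault(key, set()).add(value)

    def lookup(self, res_types: tuple[str, str], kind: str, distance: float) -> set:
        """Query with +/- tolerance_bins expansion."""
        pair = tuple(sorted(res_types))
        center = self._bin(distance)
        out: set = set()
        for b in range(center - self.tolerance_bins, center + self.tolerance_bins + 1):
            out |= self.postings.get((pair, kind, b), set())
        return out


def build_inverted_index(
    library: TemplateLibrary, bin_width: float = 1.0, tolerance_bins: int = 1
) -> InvertedIndex:
    """Index every unordered residue pair of every template under its
    Cα-Cα and Cβ-Cβ distances."""
    index = InvertedIndex(bin_width=bin_width, tolerance_bins=tolerance_bins)
    for template in library.templates:
        slots = {}
        for i in range(len(template.residues)):
            for j in range(i + 1, len(template.residues)):
                ri, rj = template.residues[i], template.residues[j]
                if ri.ca_coord is None or ri.cb_coord is None:
                    raise ContractViolationError(
                        f"template {template.template_id}: residue {i} lacks CA/CB"
                    )
                if rj.ca_coord is None or rj.cb_coord is None:
                    raise ContractViolationError(
                        f"template {template.template_id}: residue {j} lacks CA/CB"
                    )
                ca_d = float(np.linalg.norm(ri.ca_coord - rj.ca_coord))
                cb_d = float(np.linalg.norm(ri.cb_coord - rj.cb_coord))
                slot = (i, j)
                types = (ri.res_type, rj.res_type)
                index.insert(types, "CA", ca_d, (template.template_id, slot))
                index.insert(types, "CB", cb_d, (template.template_id, slot))
                slots[slot] = {"types": types, "ca": ca_d, "cb": cb_d}
        index.template_pairs[template.template_id] = slots
    return index
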