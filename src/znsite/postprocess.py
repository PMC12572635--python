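"""Pipeline orchestration, prediction compression, and output writers."""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import geometry, site_search
from .errors import DegenerateGeometryError, ZnSiteError
from .scoring import (
    ScoreBreakdown,
    composite_score,
    dispatch_case,
    platt_probability,
)
from .site_search import CandidateSite
from .structure_model import ProteinStructure, parse_structure
from .template_library import TemplateLibrary, build_inverted_index

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    library: TemplateLibrary
    include_rotamers: bool = True
    min_probability: float = 0.15
    compression_radius: float = 2.6
    pair_cutoff: float = 7.0
    both_sides: bool = False
    seed: int = 0
    bin_width: float = 1.0
    tolerance_bins: int = 1
    assembly_cap: int = site_search.ASSEMBLY_CAP


@dataclass
class Prediction:
    structure_id: str
    site: CandidateSite
    placement: geometry.PlacementResult
    score: ScoreBreakdown
    rank: int = 0

    @property
    def zinc_coord(self) -> np.ndarray:
        return self.placement.zinc_coord

    @property
    def tie_break(self) -> tuple:
        first = self.site.residues[0]
        return (first.chain, first.seq_id, first.insertion_code, self.site.template_id)


# ---------------------------------------------------------------------------
# scoring one candidate site
# ---------------------------------------------------------------------------

def score_candidate_site(
    site: CandidateSite, structure: ProteinStructure, config: PipelineConfig
) -> list[Prediction]:
    """Run placement, optional rotamer sampling, and scoring for one site.

    Returns one prediction, or two when both_sides is set for a 3-residue
    site, or zero on degenerate geometry.
    """
    library = config.library
    template = library.get(site.template_id)
    try:
        starts = geometry.initial_zinc_estimate(site.residues)
    except DegenerateGeometryError as exc:
        logger.warning("%s: %s; site skipped", structure.structure_id, exc)
        return []

    sides = []
    labels = ["A", "B"] if len(starts) == 2 else ["n/a"]
    for start, label in zip(starts, labels):
        chosen = geometry.select_binding_atoms(site.residues, start)
        placement = geometry.refine_zinc_position(chosen, start, side_label=label)
        his_score = geometry.site_his_angles_score(chosen, placement.zinc_coord)
        sides.append((start, placement, his_score))

    picked = geometry.choose_three_residue_side(
        [p for _, p, _ in sides],
        [h for _, _, h in sides],
        both_sides=config.both_sides,
    )

    predictions = []
    for placement in picked:
        start = next(s for s, p, _ in sides if p is placement)
        residues = site.residues
        if config.include_rotamers and any(r.res_type == "HIS" for r in residues):
            rot = geometry.sample_his_rotamers(residues, start)
            residues = rot.residues
            placement_final = geometry.PlacementResult(
                zinc_coord=rot.placement.zinc_coord,
                chosen_atoms=rot.placement.chosen_atoms,
                distances=rot.placement.distances,
                ideals=rot.placement.ideals,
                drmsd=rot.placement.drmsd,
                side_label=placement.side_label,
                converged=rot.placement.converged,
            )
        else:
            placement_final = placement

        angles = geometry.site_his_angles(
            placement_final.chosen_atoms, placement_final.zinc_coord
        )
        if angles:
            alpha_rms = float(np.sqrt(np.mean([a.alpha**2 for a in angles])))
            beta_rms = float(np.sqrt(np.mean([a.beta**2 for a in angles])))
            his_score = alpha_rms + beta_rms
        else:
            alpha_rms = beta_rms = None
            his_score = None

        site_atoms = [
            (c.residue.res_type, c.coord) for c in placement_final.chosen_atoms
        ]
        template_atoms = [(t, c) for t, _, c in template.binding_atoms]
        trmsd = geometry.superimpose_rmsd(site_atoms, template_atoms)

        params = dispatch_case(
            has_his=any(r.res_type == "HIS" for r in site.residues),
            n_residues=len(site.residues),
        )
        s = composite_score(placement_final.drmsd, trmsd, his_score, params)
        p = platt_probability(s, library.calibration)
        predictions.append(
            Prediction(
                structure_id=structure.structure_id,
                site=site,
                placement=placement_final,
                score=ScoreBreakdown(
                    drmsd=placement_final.drmsd,
                    trmsd=trmsd,
                    alpha_rms=alpha_rms,
                    beta_rms=beta_rms,
                    his_angles_score=his_score,
                    s=s,
                    p=p,
                    template_id=site.template_id,
                    case=params.case,
                ),
            )
        )
    return predictions


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------

def compress_predictions(
    predictions: Sequence[Prediction], radius: float = 2.6
) -> list[Prediction]:
    """Greedy best-first suppression: repeatedly keep the lowest-s
    prediction and discard all others within the radius (per structure).
    Ties break on the first site residue's (chain, seq_id)."""
    by_structure: dict[str, list[Prediction]] = {}
    for p in predictions:
        by_structure.setdefault(p.structure_id, []).append(p)
    kept_all = []
    for sid in sorted(by_structure):
        pool = sorted(by_structure[sid], key=lambda p: (p.score.s, p.tie_break))
        kept: list[Prediction] = []
        for pred in pool:
            if all(
                np.linalg.norm(pred.zinc_coord - k.zinc_coord) > radius for k in kept
            ):
                kept.append(pred)
        kept_all.extend(kept)
    return kept_all


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    structures: Sequence, config: PipelineConfig
) -> tuple[list[Prediction], dict]:
    """Parse -> search -> place -> score -> compress -> threshold, per
    structure; failures are isolated and logged."""
    index = build_inverted_index(
        config.library, bin_width=config.bin_width, tolerance_bins=config.tolerance_bins
    )
    all_predictions: list[Prediction] = []
    summary: dict = {"structures": [], "n_failed": 0}
    for item in structures:
        t0 = time.perf_counter()
        try:
            structure = (
                item if isinstance(item, ProteinStructure) else parse_structure(item)
            )
            sites = site_search.find_candidate_sites(
                structure, config.library, index,
                cutoff=config.pair_cutoff, cap=config.assembly_cap,
            )
            predictions: list[Prediction] = []
            for site in sites:
                predictions.extend(score_candidate_site(site, structure, config))
            predictions = compress_predictions(predictions, config.compression_radius)
            predictions = [
                p for p in predictions if p.score.p >= config.min_probability
            ]
            predictions.sort(key=lambda p: (p.score.s, p.tie_break))
            for rank, p in enumerate(predictions, start=1):
                p.rank = rank
            all_predictions.extend(predictions)
            elapsed = time.perf_counter() - t0
            entry = {
                "structure_id": structure.structure_id,
                "status": "ok",
                "n_candidate_sites": len(sites),
                "n_predictions": len(predictions),
                "seconds": round(elapsed, 4),
            }
            logger.info(
                "%s: %d candidate sites -> %d predictions (%.3f s)",
                structure.structure_id, len(sites), len(predictions), elapsed,
            )
        except ZnSiteError as exc:
            summary["n_failed"] += 1
            entry = {"structure_id": str(item), "status": "failed", "error": str(exc)}
            logger.warning("failed on %s: %s", item, exc)
        summary["structures"].append(entry)
    return all_predictions, summary


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "structure_id", "site_rank", "zinc_x", "zinc_y", "zinc_z", "residues",
    "chosen_atoms", "template_id", "template_source", "dRMSD", "TRMSD",
    "his_angles_score", "s", "p",
]


def write_csv(predictions: Sequence[Prediction], path, library: TemplateLibrary | None = None) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for pred in predictions:
            template_source = ""
            if library is not None:
                template_source = library.get(pred.score.template_id).source_id
            residues = ";".join(
                f"{r.chain}:{r.res_type}:{r.seq_id}" for r in pred.site.residues
            )
            chosen = ";".join(
                f"{c.residue.chain}:{c.residue.seq_id}:{c.atom_name}"
                for c in pred.placement.chosen_atoms
            )
            his = pred.score.his_angles_score
            writer.writerow([
                pred.structure_id,
                pred.rank,
                f"{pred.zinc_coord[0]:.4f}",
                f"{pred.zinc_coord[1]:.4f}",
                f"{pred.zinc_coord[2]:.4f}",
                residues,
                chosen,
                pred.score.template_id,
                template_source,
                f"{pred.score.drmsd:.3f}",
                f"{pred.score.trmsd:.3f}",
                "" if his is None else f"{his:.3f}",
                f"{pred.score.s:.3f}",
                f"{pred.score.p:.3f}",
            ])


def probability_color(p: float) -> tuple[float, float, float]:
    """Linear red->yellow->green ramp: red at p<=0.15, yellow at 0.5,
    green at p>=0.85."""
    lo, mid, hi = 0.15, 0.5, 0.85
    if p <= lo:
        return (1.0, 0.0, 0.0)
    if p >= hi:
        return (0.0, 1.0, 0.0)
    if p <= mid:
        frac = (p - lo) / (mid - lo)
        return (1.0, frac, 0.0)
    frac = (p - mid) / (hi - mid)
    return (1.0 - frac, 1.0, 0.0)


def write_pymol_script(structure_path, predictions: Sequence[Prediction], path) -> None:
    """Text command script: load structure, one colored pseudoatom per
    predicted ion, selections for the binding residues."""
    lines = [f"load {structure_path}"]
    for i, pred in enumerate(predictions, start=1):
        name = f"pred_zn_{i}"
        x, y, z = pred.zinc_coord
        r, g, b = probability_color(pred.score.p)
        lines.append(
            f"pseudoatom {name}, pos=[{x:.4f}, {y:.4f}, {z:.4f}], vdw=1.2"
        )
        lines.append(f"set_color col_{name}, [{r:.3f}, {g:.3f}, {b:.3f}]")
        lines.append(f"color col_{name}, {name}")
        lines.append(f"show spheres, {name}")
        sel = " or ".join(
            f"(chain {res.chain} and resi {res.seq_id})" for res in pred.site.residues
        )
        lines.append(f"select site_{i}, {sel}")
        lines.append(f"show sticks, site_{i}")
    lines.append("deselect")
    Path(path).write_text("\n".join(lines) + "\n")
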