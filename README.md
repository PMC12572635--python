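# znsite

Interpretable, template-based prediction of zinc / transition-metal ion
binding sites — and the ion coordinates themselves — in protein structures
(PDB or mmCIF, experimental or predicted models).

The method is purely stereochemical. Candidate sites are found by matching
residue-pair geometry (residue types plus binned Cα–Cα / Cβ–Cβ distances)
against a curated library of observed zinc-site templates through an inverted
index. For each candidate the ion is placed by Levenberg–Marquardt
least-squares refinement against ideal coordination distances (2.15 Å; 2.32 Å
for the cysteine sulfur), histidine imidazole orientation is optionally
optimized by χ2 rotamer sampling in 15° steps, and each prediction gets a
linear composite score `s` (distance RMSD, template-superposition RMSD,
imidazole-angle score) mapped to a calibrated probability `p` by a logistic
(Platt) model. Overlapping predictions are compressed within a 2.6 Å radius.

## Layout

| module | role |
|---|---|
| `znsite.structure_model` | PDB/mmCIF parsing, binding-atom dictionary, PDB writing |
| `znsite.template_library` | observed-site extraction, curation filters, JSON library, inverted index |
| `znsite.site_search` | candidate pair collection (<7 Å), index lookup, site assembly |
| `znsite.geometry` | ion placement, imidazole angles, superposition RMSD, rotamer sampling |
| `znsite.scoring` | feature scores, per-case weights, Platt calibration, Brier/log-loss, F1/Fβ |
| `znsite.postprocess` | pipeline orchestration, 2.6 Å compression, CSV + PyMOL script output |
| `znsite.evaluation` | TP/FP/FN matching with radius clustering, PR curves + AUC, MAD stats |
| `znsite.fixtures` | synthetic ideal/perturbed/decoy zinc sites and fixture libraries |
| `znsite.cli` | `znsite` command-line front end |

## CLI

```sh
# emit synthetic structures, ground truth CSV, and a fixture library
znsite fixtures --out fx --seed 1

# curate a template library from zinc-bound structures
znsite curate --in fx --out library.json --seed 1

# predict sites (CSV + per-structure .pml scripts + manifest.json)
znsite predict --library fx/fixture_library.json --in fx --out pred \
    [--no-rotamers] [--min-p 0.15] [--both-sides] [--seed 0] [--strict]

# benchmark predictions against ground truth
znsite evaluate --pred pred/predictions.csv --truth fx/truth.csv \
    --radius 2.0 --out report.json

# refit the probability calibration from labeled raw scores (CSV: s,label)
znsite calibrate --scores scores.csv --library library.json --out recal.json
```

Truth CSV schema: `structure_id, metal, x, y, z`. The template library is a
versioned JSON file; users can append their own templates with
`znsite.template_library.add_user_template` (multiplicity filters are not
applied to explicit user templates).

## Library API sketch

```python
from znsite import fixtures, PipelineConfig, run_pipeline

structures, library = fixtures.make_fixture_library(seed=1)
config = PipelineConfig(library=library)
predictions, summary = run_pipeline(["my_model.pdb"], config)
for p in predictions:
    print(p.structure_id, p.zinc_coord, p.score.s, p.score.p)
```

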