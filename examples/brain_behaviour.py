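"""Brain-behaviour dominance analysis on a full synthetic study.

Generates two synthetic datasets (a multi-condition anaesthesia protocol
and a thalamic-stimulation protocol), computes the per-run marker table,
and runs the dominance analysis of the behavioural arousal score on the
three markers, with a permutation test of the full-model fit and the
dichotomised classification variant.
"""

import tempfile
from pathlib import Path

from eigenmarkers import (
    classification_dominance,
    dichotomize_arousal,
    generate_study,
    load_presets,
    normalize_markers,
    run_brain_behaviour,
    run_markers,
)
from eigenmarkers.io import read_arousal_csv
from eigenmarkers.pipeline import PipelineConfig
from eigenmarkers.stats import MARKER_COLUMNS

presets = load_presets()
with tempfile.TemporaryDirectory() as tmp:
    anaesthesia = generate_study(
        Path(tmp) / "anaesthesia",
        presets={k: presets[k] for k in ("awake", "light_anaesthesia", "deep_anaesthesia")},
        runs_per_condition=4,
        seed=1,
        dataset="anaesthesia",
    )
    dbs = generate_study(
        Path(tmp) / "dbs",
        presets={k: presets[k] for k in ("awake", "dbs_off", "ct_low", "ct_high", "vt_low", "vt_high")},
        runs_per_condition=4,
        seed=2,
        dataset="dbs",
    )
    config = PipelineConfig(datasets=(str(anaesthesia), str(dbs)), n_perm=1000, seed=0)
    table = run_markers(config)
    arousal_map = read_arousal_csv(anaesthesia) | read_arousal_csv(dbs)
    result, report = run_brain_behaviour(table, arousal_map, config)
    print(report)

    # classification variant: high arousal (score >= 9) vs the rest
    norm = normalize_markers(table, columns=MARKER_COLUMNS, by="dataset")
    scores = norm["condition"].map(arousal_map).to_numpy()
    labels = dichotomize_arousal(scores, cutoff=9)
    cls = classification_dominance(
        norm[list(MARKER_COLUMNS)].to_numpy(), labels, predictor_names=MARKER_COLUMNS
    )
    print("\nclassification variant (cutoff 9, McFadden pseudo-R^2):")
    for name in MARKER_COLUMNS:
        print(f"    {name:28s} {cls.relative_importance[name]:6.2f} %")

print(
    "\nAll three markers carry independent information about arousal;\n"
    "the permutation p-value is the fraction of score reshuffles that\n"
    "match the observed fit."
)
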