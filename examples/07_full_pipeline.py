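"""End-to-end pipeline: simulate a two-group cohort and analyse it.

Generates dexterity-like and strength-like groups (beta-band common drive
strongest at low vs high force respectively), writes trial bundles to
disk, then runs steadiness, firing, coherence, clustering and bootstrap
stages, leaving delimited tables plus a run log in the report directory.
"""

import tempfile
from pathlib import Path

import pandas as pd

from neuropinch import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    report = run_pipeline({
        "seed": 1,
        "out": str(Path(tmp) / "report"),
        "cohort": {"n_per_group": 2, "n_units": 12},
        "bootstrap_n": 2000,
    })
    print("report files:", sorted(p.name for p in report.iterdir()
                                  if p.is_file()))
    bands = pd.read_csv(report / "coherence_bands.csv", comment="#")
    print("\nmean pooled coherence per band:")
    print(bands.pivot_table(index=["group", "level"], columns="band",
                            values="mean_r2").round(3))
# Each table carries the seed and config hash that produced it; rerunning
# with the same seed reproduces every number exactly.
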