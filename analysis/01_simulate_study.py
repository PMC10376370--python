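#!/usr/bin/env python
"""Generate the synthetic two-diet MSI study and write it to disk.

Emits one continuous-mode imzML file pair (+ JSON metadata sidecar) per
sample under scratch/data/ (binary, not part of the text deliverable), plus
the ground-truth manifest and the epithelium reference mask under results/.

The study simulated here: two feeding time points (3 d and 16 w), positive
mode, 3 mice per diet group, 20x20 spot sections — the earliest and latest
time points bracket the progression the downstream scripts quantify.
"""

from pathlib import Path

import pandas as pd

from ovimsi.io import StudyDesign, write_imzml
from ovimsi.synth import SyntheticConfig, generate_study

SEED = 1
DESIGN = StudyDesign(timepoints=("3d", "16w"), modes=("positive",))

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    config = SyntheticConfig(design=DESIGN)
    datasets, manifest = generate_study(config, SEED)
    for ds in datasets:
        write_imzml(ds, DATA / f"{ds.sample_id}.imzML")
    manifest.to_json(RESULTS / "ground_truth.json")
    pd.DataFrame(
        {
            "x": manifest.coords[:, 0],
            "y": manifest.coords[:, 1],
            "roi": manifest.epithelium_mask().astype(int),
        }
    ).to_csv(RESULTS / "reference_mask.tsv", sep="\t", index=False)

    drls = manifest.planted_drls["positive"]
    print(f"wrote {len(datasets)} samples to {DATA}")
    print(f"planted {len(drls)} DRLs:")
    for d in drls:
        print(f"  m/z {d.mz:9.4f}  {d.direction:<12}  fold {d.fold_change:.1f}  {d.species_name}")


if __name__ == "__main__":
    main()
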