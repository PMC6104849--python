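#!/usr/bin/env python
"""Photo-content validation: percent agreement and Cohen's kappa.

Reads the pipeline outputs produced by 02_viewsheds_and_intensity.py
and writes the per-class agreement table (photo labels vs viewshed-
visible land cover) plus the relevance split to results/.
"""

import json
from pathlib import Path

import pandas as pd

OUT = Path("scratch/pipeline")
RESULTS = Path("results")


def main() -> None:
    validation = json.loads((OUT / "validation.json").read_text())
    RESULTS.mkdir(exist_ok=True)
    rel = validation["relevance"]
    print(f"relevant photos: {rel['n_relevant']}/{rel['n_total']} "
          f"({rel['pct_relevant']}%); non-relevant {rel['pct_nonrelevant']}%")
    rows = []
    for a in validation["agreement"]:
        rows.append({
            "class": a["class"],
            "percent_agreement": round(a["percent_agreement"], 1),
            "kappa": round(a["kappa"], 3),
            "n": sum(a["table"]),
        })
        print(f"  {a['class']:12s} C={rows[-1]['percent_agreement']:5.1f}% "
              f"K={rows[-1]['kappa']:.3f}")
    pd.DataFrame(rows).to_csv(RESULTS / "content_agreement.csv", index=False)
    (RESULTS / "relevance.json").write_text(json.dumps(rel, indent=2))


if __name__ == "__main__":
    main()
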