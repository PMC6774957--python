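#!/usr/bin/env python
"""Inter-colour similarity from the colour decoder's confusions.

Applies the biased-choice moment estimator to the cross-validated colour
confusion matrix produced by analysis step 02: colours whose emotion
associations are similar are confused more often, and the model turns those
confusions into a symmetric similarity matrix with unit diagonal.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from colouremotion import ConfusionMatrix, estimate_similarity, similarity_report

OUT = Path(__file__).resolve().parent.parent / "results"

def main() -> None:
    frame = pd.read_csv(OUT / "colour_confusion.csv", index_col=0)
    cm = ConfusionMatrix(
        classes=tuple(frame.index), counts=frame.to_numpy(dtype=np.int64)
    )
    sm = estimate_similarity(cm, smoothing=0.5)
    sm.to_frame(upper_only=True).to_csv(OUT / "colour_similarity.csv")

    pairs = similarity_report(sm, top_n=5)
    (OUT / "colour_similarity_top.json").write_text(json.dumps(
        [{"pair": [a, b], "similarity": v} for a, b, v in pairs], indent=2
    ) + "\n")

    print("top colour pairs by emotion-association similarity:")
    for a, b, v in pairs:
        print(f"  {a}-{b}: {v:.3f}")
    if sm.n_clipped:
        print(f"  ({sm.n_clipped} estimates clipped at 1.0)")

if __name__ == "__main__":
    main()
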