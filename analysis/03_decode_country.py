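#!/usr/bin/env python
"""Decode a participant's country of origin from all 240 ratings.

Participant-grouped 10-fold cross-validation with a uniform class prior
(inverse-frequency weighting), so unequal country samples would not tilt
the decoder. Above-chance accuracy means colour-emotion associations carry
a country signature.
"""

import json
from pathlib import Path

from colouremotion import (
    HyperParams, chance_level, country_feature_table, cross_validate,
    load_dataset,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"
PARAMS = [HyperParams(C=10.0, kernel_width=0.001)]

def main() -> None:
    dataset = load_dataset(SCRATCH / "cohort_ratings.csv")
    table = country_feature_table(dataset)
    n_countries = len(dataset.countries_present())
    result = cross_validate(table, k=10, grid=PARAMS, seed=2)

    result.confusion.to_frame().to_csv(OUT / "country_confusion.csv")
    payload = {
        "n_participants": table.n_rows,
        "accuracy": result.accuracy,
        "chance_level": chance_level(n_countries),
        "auc_weighted": result.auc_weighted,
        "auc_macro": result.auc_macro,
        "recall": {c: result.confusion.recall(c) for c in result.classes},
    }
    (OUT / "country_decoding.json").write_text(json.dumps(payload, indent=2) + "\n")

    print(f"country decoding on {table.n_rows} participants:")
    print(f"  accuracy {result.accuracy:.3f} vs chance "
          f"{chance_level(n_countries):.3f}; AUC (weighted) {result.auc_weighted:.3f}")
    for c in result.classes:
        print(f"  recall {c}: {result.confusion.recall(c):.3f}")

if __name__ == "__main__":
    main()
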