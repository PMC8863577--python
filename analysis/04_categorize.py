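#!/usr/bin/env python
"""Stage categorization of deconfounded features, scored against the
planted ground truth.

Combines the comparison tables and deconfounding verdicts into
DMF/IHDF/ESCF/DSCF assignments (``results/categories.tsv`` and
``results/summary.json``) and reports per-archetype recovery.
"""

import json
from pathlib import Path

import pandas as pd

from cardstage import build_profiles, categorize_all
from cardstage.containers import COMPARISONS
from cardstage.io import comparison_slug, write_results_table

BASE = Path(__file__).resolve().parent.parent / "results"

ARCHETYPE_TO_CATEGORY = {
    "null": "UNCLASSIFIED",
    "dmf": "DMF",
    "ihdf": "IHDF",
    "escf": "ESCF",
    "dscf": "DSCF",
}


def main() -> None:
    results = {
        comp: pd.read_csv(
            BASE / "tests" / f"results_{comparison_slug(comp)}.tsv",
            sep="\t",
            comment="#",
            index_col=0,
        )
        for comp in COMPARISONS
    }
    verdicts = pd.read_csv(BASE / "verdicts.tsv", sep="\t", comment="#")
    verdicts["confounders"] = verdicts["confounders"].fillna("")
    table, summary = categorize_all(build_profiles(results, verdicts))
    write_results_table(table, BASE / "categories.tsv", [])
    with open(BASE / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print("category counts:", summary["counts"])

    truth = pd.read_csv(BASE / "cohort" / "truth.tsv", sep="\t", index_col=0)
    print("\nrecovery of planted archetypes:")
    for arch, cat in ARCHETYPE_TO_CATEGORY.items():
        planted = truth.index[truth["archetype"] == arch]
        if not len(planted):
            continue
        acc = float((table.loc[planted, "category"] == cat).mean())
        print(f"  {arch:>5} -> {cat:<12} {acc:.2f}  (n={len(planted)})")
    drugged = truth.index[truth["archetype"] == "drug_driven"]
    if len(drugged):
        screened = float((table.loc[drugged, "category"] == "UNCLASSIFIED").mean())
        print(f"  drug_driven screened out: {screened:.2f}  (n={len(drugged)})")


if __name__ == "__main__":
    main()
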