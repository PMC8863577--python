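#!/usr/bin/env python
"""Differential abundance across the disease spectrum.

Runs the two-sided Mann-Whitney test with Cliff's delta effect sizes
and per-kind BH adjustment for the five comparisons spanning the two
disease stages, writing one results table per comparison under
``results/tests/``.
"""

from pathlib import Path

from cardstage import compare_groups, read_matrix, read_metadata
from cardstage.containers import COMPARISONS
from cardstage.io import comparison_slug, write_results_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix = read_matrix(BASE / "cohort" / "abundance.tsv")
    metadata = read_metadata(BASE / "cohort" / "metadata.tsv")
    out = BASE / "tests"
    out.mkdir(parents=True, exist_ok=True)
    for comp in COMPARISONS:
        a, b = comp.split(":")
        res = compare_groups(matrix, metadata, a, b)
        write_results_table(
            res, out / f"results_{comparison_slug(comp)}.tsv", [f"comparison: {comp}"]
        )
        n_sig = int(res["significant"].sum())
        print(f"{comp}: {n_sig}/{len(res)} features significant at FDR <= 0.1")


if __name__ == "__main__":
    main()
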