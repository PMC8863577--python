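#!/usr/bin/env python
"""Drug/host-covariate deconfounding of the differential features.

Screens every feature x comparison against the cohort's covariates
(five drugs, age, BMI, smoking) with the nested-model LRT procedure and
writes the verdict table to ``results/verdicts.tsv``.
"""

from pathlib import Path

from cardstage import read_matrix, read_metadata, run_deconfounding
from cardstage.containers import COMPARISONS
from cardstage.io import write_results_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix = read_matrix(BASE / "cohort" / "abundance.tsv")
    metadata = read_metadata(BASE / "cohort" / "metadata.tsv")
    verdicts = run_deconfounding(matrix, metadata, COMPARISONS)
    write_results_table(verdicts.set_index("feature_id"), BASE / "verdicts.tsv", [])
    counts = verdicts["status"].value_counts().to_dict()
    print("verdict counts across all comparisons:", counts)
    confounded = verdicts[verdicts["status"] == "CONFOUNDED"]
    if len(confounded):
        top = confounded["confounders"].value_counts().head(5).to_dict()
        print("most frequent confounders:", top)


if __name__ == "__main__":
    main()
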