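#!/usr/bin/env python
"""Test the individual signature hypothesis and rank feature importance.

Repeated random-forest cross-validation holding out one bout per caller
(callers need >= 2 bouts of >= 3 whoops), scored against WE chance, plus
test-set permutation importance. Also reruns the test on the A/S-only
subset used for the final analyses.
"""

import json
from pathlib import Path

from whoopsig.classify import (
    SplitSpec,
    drop_failed,
    feature_importance,
    filter_adults,
    prepare_individual_dataset,
    run_repeats,
    subset_types,
)
from whoopsig.pipeline import read_table, write_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    feats = filter_adults(drop_failed(read_table(RESULTS / "features.csv")))
    indiv = prepare_individual_dataset(feats)
    spec = SplitSpec(scheme="individual", n_repeats=200, n_trees=500, seed=41)
    summary = run_repeats(indiv, spec, target="caller_id")
    print(f"individual scheme over {spec.n_repeats} repeats on {len(indiv)} whoops "
          f"from {indiv['caller_id'].nunique()} callers:")
    print(f"  accuracy {summary.mean_accuracy:.3f} (s.d. {summary.sd_accuracy:.3f})"
          f" vs chance WE {summary.mean_we:.3f}")

    final = prepare_individual_dataset(subset_types(indiv, {"A", "S"}),
                                       min_whoops_per_bout=1)
    s_as = run_repeats(final, SplitSpec(scheme="individual", n_repeats=200,
                                        n_trees=500, seed=42), target="caller_id")
    print(f"  A/S-only subset ({len(final)} whoops): accuracy "
          f"{s_as.mean_accuracy:.3f} vs WE {s_as.mean_we:.3f}")

    imp = feature_importance(indiv, SplitSpec(scheme="individual", n_repeats=50,
                                              n_trees=500, seed=43))
    write_table(imp, RESULTS / "importance.csv", f"seed=43")
    print("  top features by mean decrease in accuracy:")
    for _, row in imp.head(5).iterrows():
        print(f"    {row['rank']:2d}. {row['feature']:22s} {row['importance']:+.4f}")

    with open(RESULTS / "individual_summary.json", "w") as fh:
        json.dump({"all_types": summary.to_dict(), "a_s_only": s_as.to_dict()},
                  fh, indent=2)
    write_table(summary.pooled_confusion.reset_index(names="true_class"),
                RESULTS / "individual_confusion.csv", f"seed={spec.seed}")


if __name__ == "__main__":
    main()
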