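#!/usr/bin/env python
"""Test the clan (group) signature hypothesis.

Repeated random-forest cross-validation holding out one caller per clan,
scored against the weighted-expectation (WE) chance level. In this world
the generator injects no clan-level effect, so accuracy should sit at
chance — mirroring the empirical finding for real whoops.
"""

import json
from pathlib import Path

from whoopsig.classify import SplitSpec, drop_failed, filter_adults, run_repeats
from whoopsig.pipeline import read_table, write_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    feats = filter_adults(drop_failed(read_table(RESULTS / "features.csv")))
    spec = SplitSpec(scheme="clan", n_repeats=200, n_trees=500, seed=31)
    summary = run_repeats(feats, spec, target="clan_id")
    out = summary.to_dict()
    with open(RESULTS / "clan_summary.json", "w") as fh:
        json.dump(out, fh, indent=2)
    write_table(summary.pooled_confusion.reset_index(names="true_class"),
                RESULTS / "clan_confusion.csv", f"seed={spec.seed}")
    print(f"clan scheme over {spec.n_repeats} repeats on {len(feats)} whoops:")
    print(f"  accuracy {summary.mean_accuracy:.3f} (s.d. {summary.sd_accuracy:.3f})"
          f" vs chance WE {summary.mean_we:.3f}")
    gap = abs(summary.mean_accuracy - summary.mean_we) / summary.sd_accuracy
    print(f"  |accuracy - WE| = {gap:.2f} s.d. -> "
          + ("no clan signature detected" if gap < 2 else "clan signature detected"))


if __name__ == "__main__":
    main()
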