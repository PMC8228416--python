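"""Contrast the two treatments: shared response and riluzole-specific sites.

Reads the pooled LDOPA-vs-UNT and LDOPA_R-vs-UNT comparison tables and
computes (i) nested Pearson correlations of per-CpG methylation changes
on all shared CpGs, on DMS in either comparison, and on DMS in both —
expected to increase across the nesting when most true effects are
shared; (ii) the per-1-Mb-bin DMS count difference between the two
comparisons; (iii) the screen for CpGs that are DMS in either
comparison and differ by >= 20 points between treatments. Writes
results/contrast_summary.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rrbsdiff.spatial import (
    bin_difference,
    delta_screen,
    nested_correlations,
    shared_comparison_table,
)

ROOT = Path(__file__).resolve().parent.parent


def load(pipeline: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(pipeline / f"{name}.dms.tsv", sep="\t", comment="#")
    df["pos"] = df["pos"] - 1
    return df


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--pipeline", type=Path, default=ROOT / "results" / "pipeline")
    parser.add_argument("--comparison-1", default="LDOPA_vs_UNT")
    parser.add_argument("--comparison-2", default="LDOPA_R_vs_UNT")
    parser.add_argument("--threshold", type=float, default=20.0)
    parser.add_argument(
        "--out", type=Path, default=ROOT / "results" / "contrast_summary.json"
    )
    args = parser.parse_args()

    rec1 = load(args.pipeline, args.comparison_1)
    rec2 = load(args.pipeline, args.comparison_2)
    shared = shared_comparison_table(rec1, rec2)
    corr = nested_correlations(shared)
    screen = delta_screen(shared, threshold=args.threshold)
    track = bin_difference(
        rec1.loc[rec1["is_dms"]], rec2.loc[rec2["is_dms"]]
    )

    summary = {
        "comparisons": [args.comparison_1, args.comparison_2],
        "nested_correlations": corr,
        "n_screen": int(len(screen)),
        "top_bins_by_abs_difference": track.nsmallest(5, "abs_rank")[
            ["chrom", "bin_start", "count_1", "count_2", "difference"]
        ].to_dict("records"),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)

    print(f"shared CpGs: {corr['n_all']}")
    print(
        f"nested correlations: r_all={corr['r_all']:.3f} "
        f"({corr['n_all']}) < r_any={corr['r_any_dms']:.3f} "
        f"({corr['n_any_dms']}) < r_both={corr['r_both_dms']:.3f} "
        f"({corr['n_both_dms']})"
    )
    print(f"delta screen (>= {args.threshold:.0f} points, DMS in either): "
          f"{len(screen)} CpGs")


if __name__ == "__main__":
    main()
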