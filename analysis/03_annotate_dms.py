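"""Genomic-context distributions: DMS vs the background CpG set.

For the pooled LDOPA-vs-UNT comparison, compares the distribution of
called DMS over promoter/exon/intron/intergenic and CpG island/shore/
open-sea contexts against the background of all tested CpGs, reporting
per-class enrichment ratios. With open-sea-biased injected effects the
open-sea enrichment exceeds 1 while promoters and CGIs are depleted.
Writes results/annotation_summary.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rrbsdiff.annotation import assign_contexts, distribution_summary
from rrbsdiff.io import read_annotation

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--pipeline", type=Path, default=ROOT / "results" / "pipeline")
    parser.add_argument("--comparison", default="LDOPA_vs_UNT")
    parser.add_argument(
        "--out", type=Path, default=ROOT / "results" / "annotation_summary.json"
    )
    args = parser.parse_args()

    records = pd.read_csv(
        args.pipeline / f"{args.comparison}.dms.tsv", sep="\t", comment="#"
    )
    records["pos"] = records["pos"] - 1  # reports are 1-based
    ann = read_annotation(
        args.cohort / "genes.bed", args.cohort / "cgi.bed", args.cohort / "exons.bed"
    )
    background = assign_contexts(records, ann)
    dms_labels = background.loc[records["is_dms"]]
    summary = distribution_summary(dms_labels, background)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)

    print(f"{args.comparison}: {int(records['is_dms'].sum())} DMS "
          f"of {len(records)} tested CpGs")
    for axis in ("gene_context", "cpg_context"):
        enr = summary[axis]["enrichment"]
        pretty = ", ".join(f"{k}={v:.2f}" for k, v in enr.items())
        print(f"  {axis} enrichment (DMS/background): {pretty}")


if __name__ == "__main__":
    main()
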