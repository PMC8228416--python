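"""Readers/writers for the formats the pipeline touches.

Formats handled:

* Bismark coverage files: one per-cytosine record per line —
  ``chrom  start(1-based)  end  %methylation  count_methylated
  count_unmethylated``. Internally positions are 0-based half-open; all
  emitted reports convert back to 1-based.
* BED6 for gene models and CpG islands, with an optional companion exon
  BED (when absent, the full gene body counts as one exon).
* A headered TSV design sheet mapping sample -> (group, hemisphere,
  animal).

Missingness in the assembled matrix is explicit (NaN), not
zero-coverage, so that per-site present-sample accounting (e.g. the
4-of-6 inclusion rule) is well defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rrbsdiff.intervals import merge_intervals
from rrbsdiff.annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

HEMISPHERES = ("control", "lesioned")


class CoverageParseError(ValueError):
    """A coverage file line could not be parsed; message carries line numbers."""


class DesignError(ValueError):
    """Design sheet inconsistent with the data it is supposed to describe."""


@dataclass
class SampleDesign:
    """Sample sheet: one row per sample with group, hemisphere and animal id."""

    table: pd.DataFrame  # columns: sample, group, hemisphere, animal

    def __post_init__(self) -> None:
        required = {"sample", "group", "hemisphere", "animal"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"design sheet missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            dups = self.table.loc[self.table["sample"].duplicated(), "sample"]
            raise DesignError(f"duplicate sample ids in design: {list(dups)}")
        bad = set(self.table["hemisphere"]) - set(HEMISPHERES)
        if bad:
            raise DesignError(
                f"hemisphere labels must be in {HEMISPHERES}, got {sorted(bad)}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def samples_of(self, group: str, hemisphere: str | None = None) -> list[str]:
        t = self.table
        mask = t["group"] == group
        if hemisphere is not None:
            mask &= t["hemisphere"] == hemisphere
        return list(t.loc[mask, "sample"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))


@dataclass
class MethylationMatrix:
    """Per-CpG (methylated, coverage) counts across samples.

    ``sites`` is sorted by (chrom, pos) with no duplicate
    (chrom, pos, strand); ``meth``/``cov`` are float arrays of shape
    (n_sites, n_samples) with NaN marking a site not observed in a sample.
    """

    sites: pd.DataFrame  # columns: chrom, pos (0-based), strand
    samples: list[str]
    meth: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        n, k = self.meth.shape
        if self.cov.shape != (n, k) or len(self.sites) != n or len(self.samples) != k:
            raise ValueError("matrix dimensions inconsistent")
        with np.errstate(invalid="ignore"):
            if np.any(self.meth > self.cov):
                raise ValueError("methylated count exceeds coverage")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def present_counts(self) -> np.ndarray:
        """Number of samples with an observation at each site."""
        return (~np.isnan(self.cov)).sum(axis=1)

    def select_samples(self, samples: list[str]) -> "MethylationMatrix":
        idx = [self.samples.index(s) for s in samples]
        return MethylationMatrix(
            sites=self.sites.copy(),
            samples=list(samples),
            meth=self.meth[:, idx].copy(),
            cov=self.cov[:, idx].copy(),
        )

    def select_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        return MethylationMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            meth=self.meth[mask],
            cov=self.cov[mask],
        )


def read_coverage_file(path: str | Path) -> pd.DataFrame:
    """Parse one Bismark coverage file into a per-site record frame.

    Returns a DataFrame with columns chrom, pos (0-based), strand,
    meth, cov. The % methylation column is cross-checked against the
    counts; a discrepancy above 0.5 points triggers a warning and the
    counts win. Malformed lines raise :class:`CoverageParseError` with
    their 1-based line numbers.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "pct", "meth", "unmeth"],
            dtype={"chrom": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=["chrom", "start", "end", "pct", "meth", "unmeth"])
    if len(raw) == 0:
        warnings.warn(f"coverage file {path} is empty", stacklevel=2)
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "meth": pd.Series(dtype=np.int64),
                "cov": pd.Series(dtype=np.int64),
            }
        )

    bad_lines: list[int] = []
    for col in ("start", "end", "pct", "meth", "unmeth"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad_lines.extend(raw.index[coerced.isna()] + 1)
        raw[col] = coerced
    if bad_lines:
        raise CoverageParseError(
            f"{path}: non-numeric fields at lines {sorted(set(bad_lines))}"
        )
    neg = (raw["meth"] < 0) | (raw["unmeth"] < 0) | (raw["start"] < 1)
    if neg.any():
        raise CoverageParseError(
            f"{path}: negative counts or positions at lines {list(raw.index[neg] + 1)}"
        )

    meth = raw["meth"].astype(np.int64)
    unmeth = raw["unmeth"].astype(np.int64)
    cov = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        expect_pct = np.where(cov > 0, 100.0 * meth / np.maximum(cov, 1), 0.0)
    off = np.abs(raw["pct"].to_numpy() - expect_pct) > 0.5
    if off.any():
        warnings.warn(
            f"{path}: % methylation column disagrees with counts at "
            f"{int(off.sum())} lines (first: line {int(np.flatnonzero(off)[0]) + 1}); "
            "counts take precedence",
            stacklevel=2,
        )

    out = pd.DataFrame(
        {
            "chrom": raw["chrom"].astype(str),
            "pos": raw["start"].astype(np.int64) - 1,  # 1-based -> 0-based
            "strand": "+",
            "meth": meth,
            "cov": cov,
        }
    )
    dup = out.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        first = out.loc[dup].iloc[0]
        raise CoverageParseError(
            f"{path}: duplicate site {first['chrom']}:{first['pos'] + 1}"
        )
    return out


def write_coverage_file(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-site records (chrom, pos 0-based, meth, cov) as Bismark coverage."""
    records = records.loc[records["cov"] > 0]
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": records["pos"].astype(np.int64) + 1,
            "end": records["pos"].astype(np.int64) + 1,
            "pct": np.round(100.0 * records["meth"] / records["cov"], 6),
            "meth": records["meth"].astype(np.int64),
            "unmeth": (records["cov"] - records["meth"]).astype(np.int64),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def assemble_matrix(
    per_sample: dict[str, pd.DataFrame], design: SampleDesign
) -> MethylationMatrix:
    """Union per-sample records into a cross-sample matrix with explicit NaN.

    Sample order follows the design sheet; site order is (chrom, pos)
    regardless of input file order. A sample present in the data but
    absent from the design raises :class:`DesignError`.
    """
    if not per_sample:
        raise ValueError("need at least one sample")
    unknown = set(per_sample) - set(design.samples)
    if unknown:
        raise DesignError(f"samples missing from design sheet: {sorted(unknown)}")
    samples = [s for s in design.samples if s in per_sample]

    frames = []
    for s in samples:
        df = per_sample[s]
        frames.append(df[["chrom", "pos", "strand"]])
    sites = (
        pd.concat(frames, ignore_index=True)
        .drop_duplicates()
        .sort_values(["chrom", "pos", "strand"], kind="stable")
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(sites)
    n, k = len(sites), len(samples)
    meth = np.full((n, k), np.nan)
    cov = np.full((n, k), np.nan)
    for j, s in enumerate(samples):
        df = per_sample[s]
        idx = key.get_indexer(pd.MultiIndex.from_frame(df[["chrom", "pos", "strand"]]))
        meth[idx, j] = df["meth"].to_numpy(dtype=float)
        cov[idx, j] = df["cov"].to_numpy(dtype=float)
    logger.info("assembled matrix: %d sites x %d samples", n, k)
    return MethylationMatrix(sites=sites, samples=samples, meth=meth, cov=cov)


def read_design(path: str | Path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleDesign(table=table)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def _read_bed6(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"]].iloc[0]
        raise ValueError(
            f"{what} {path}: interval end <= start at {bad['chrom']}:{bad['start']}"
        )
    return df


def read_annotation(
    genes_bed: str | Path,
    cgi_bed: str | Path,
    exons_bed: str | Path | None = None,
    promoter_upstream: int = 1000,
    promoter_downstream: int = 1000,
) -> GenomeAnnotation:
    """Load gene models and CpG islands from BED6 files.

    TSS is the 5' end of the gene interval: ``start`` on '+', ``end - 1``
    on '-'. Overlapping CGIs are merged per chromosome. When no exon BED
    is supplied, each gene body is treated as a single exon.
    """
    g = _read_bed6(genes_bed, "gene BED")
    genes = pd.DataFrame(
        {
            "gene_id": g["name"],
            "chrom": g["chrom"],
            "start": g["start"].astype(np.int64),
            "end": g["end"].astype(np.int64),
            "strand": g["strand"],
        }
    )
    genes["tss"] = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])

    if exons_bed is not None:
        e = _read_bed6(exons_bed, "exon BED")
        exons = pd.DataFrame(
            {
                "gene_id": e["name"],
                "chrom": e["chrom"],
                "start": e["start"].astype(np.int64),
                "end": e["end"].astype(np.int64),
            }
        )
    else:
        exons = genes[["gene_id", "chrom", "start", "end"]].copy()

    c = _read_bed6(cgi_bed, "CGI BED") if cgi_bed is not None else None
    if c is None or len(c) == 0:
        cgis = pd.DataFrame(
            {"chrom": pd.Series(dtype=str),
             "start": pd.Series(dtype=np.int64),
             "end": pd.Series(dtype=np.int64)}
        )
    else:
        merged = []
        for chrom, sub in c.groupby("chrom", sort=True):
            s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            merged.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
        cgis = pd.concat(merged, ignore_index=True)

    return GenomeAnnotation(
        genes=genes.reset_index(drop=True),
        exons=exons.reset_index(drop=True),
        cgis=cgis,
        promoter_upstream=promoter_upstream,
        promoter_downstream=promoter_downstream,
    )


def write_annotation_beds(
    ann: GenomeAnnotation, genes_bed: str | Path, cgi_bed: str | Path,
    exons_bed: str | Path | None = None,
) -> None:
    g = ann.genes
    pd.DataFrame(
        {
            "chrom": g["chrom"], "start": g["start"], "end": g["end"],
            "name": g["gene_id"], "score": 0, "strand": g["strand"],
        }
    ).to_csv(genes_bed, sep="\t", header=False, index=False)
    c = ann.cgis
    pd.DataFrame(
        {
            "chrom": c["chrom"], "start": c["start"], "end": c["end"],
            "name": [f"cgi_{i}" for i in range(len(c))], "score": 0, "strand": ".",
        }
    ).to_csv(cgi_bed, sep="\t", header=False, index=False)
    if exons_bed is not None:
        e = ann.exons
        pd.DataFrame(
            {
                "chrom": e["chrom"], "start": e["start"], "end": e["end"],
                "name": e["gene_id"], "score": 0, "strand": ".",
            }
        ).to_csv(exons_bed, sep="\t", header=False, index=False)
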