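"""Genomic-context assignment for CpG sites.

Each site gets exactly one label on each of two axes:

* gene axis: promoter > exon > intron > intergenic (precedence across
  all genes; a site in gene A's promoter window and gene B's exon is a
  promoter site),
* CpG-density axis: cpg_island > cpg_shore > other, where a shore is
  within 2 kb of a CGI edge but outside every CGI and "other" is the
  CpG-poor open sea.

The promoter window defaults to 1 kb on either side of the TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rrbsdiff.intervals import merge_intervals, points_in_intervals

GENE_CONTEXTS = ("promoter", "exon", "intron", "intergenic")
CPG_CONTEXTS = ("cpg_island", "cpg_shore", "other")

SHORE_WIDTH = 2000  # bp flanking a CGI edge; fixed by the shore definition


@dataclass
class GenomeAnnotation:
    """Gene models (with TSS and exons) plus merged CpG-island intervals."""

    genes: pd.DataFrame   # gene_id, chrom, start, end, strand, tss
    exons: pd.DataFrame   # gene_id, chrom, start, end
    cgis: pd.DataFrame    # chrom, start, end (merged, disjoint)
    promoter_upstream: int = 1000
    promoter_downstream: int = 1000
    chrom_sizes: dict = field(default_factory=dict)

    @property
    def shore_width(self) -> int:
        return SHORE_WIDTH


def _merged_per_chrom(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[chrom] = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
    return out


def assign_contexts(sites: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Label every site on both context axes.

    ``sites`` needs chrom and pos columns; the result aligns row-for-row
    with columns gene_context and cpg_context.
    """
    genes = ann.genes
    prom = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            # window is inclusive of both ends: |pos - tss| within the margins
            "start": np.maximum(genes["tss"] - ann.promoter_upstream, 0),
            "end": genes["tss"] + ann.promoter_downstream + 1,
        }
    )
    prom_iv = _merged_per_chrom(prom) if len(prom) else {}
    exon_iv = _merged_per_chrom(ann.exons) if len(ann.exons) else {}
    body_iv = _merged_per_chrom(genes) if len(genes) else {}
    cgi_iv = _merged_per_chrom(ann.cgis) if len(ann.cgis) else {}

    gene_ctx = np.full(len(sites), "intergenic", dtype=object)
    cpg_ctx = np.full(len(sites), "other", dtype=object)

    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        loc = sub.index.to_numpy()

        in_prom = (
            points_in_intervals(pos, *prom_iv[chrom])
            if chrom in prom_iv else np.zeros(len(pos), bool)
        )
        in_exon = (
            points_in_intervals(pos, *exon_iv[chrom])
            if chrom in exon_iv else np.zeros(len(pos), bool)
        )
        in_body = (
            points_in_intervals(pos, *body_iv[chrom])
            if chrom in body_iv else np.zeros(len(pos), bool)
        )
        gene_ctx[loc[in_prom]] = "promoter"
        gene_ctx[loc[~in_prom & in_exon]] = "exon"
        gene_ctx[loc[~in_prom & ~in_exon & in_body]] = "intron"

        if chrom in cgi_iv:
            s, e = cgi_iv[chrom]
            in_cgi = points_in_intervals(pos, s, e)
            shore_s, shore_e = merge_intervals(
                np.maximum(s - SHORE_WIDTH, 0), e + SHORE_WIDTH
            )
            in_shorezone = points_in_intervals(pos, shore_s, shore_e)
            cpg_ctx[loc[in_cgi]] = "cpg_island"
            cpg_ctx[loc[~in_cgi & in_shorezone]] = "cpg_shore"

    return pd.DataFrame(
        {"gene_context": gene_ctx, "cpg_context": cpg_ctx}, index=sites.index
    )


def nearest_gene(sites: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Nearest gene id and distance per site.

    Distance is 0 inside a gene body, otherwise base pairs to the closest
    gene boundary. Ties (equidistant genes, or a site inside overlapping
    genes) resolve to the lexicographically smaller gene id. Sites on a
    chromosome with no genes get gene_id None and NaN distance.
    """
    gene_id = np.full(len(sites), None, dtype=object)
    distance = np.full(len(sites), np.nan)

    genes_by_chrom = dict(tuple(ann.genes.groupby("chrom", sort=False)))
    for chrom, sub in sites.groupby("chrom", sort=False):
        if chrom not in genes_by_chrom:
            continue
        g = genes_by_chrom[chrom].sort_values("gene_id", kind="stable")
        gs = g["start"].to_numpy()[None, :]
        ge = g["end"].to_numpy()[None, :]
        ids = g["gene_id"].to_numpy()
        pos = sub["pos"].to_numpy(dtype=np.int64)[:, None]
        # distance to each gene: 0 inside, else gap to the nearer boundary
        d = np.where(
            (pos >= gs) & (pos < ge),
            0,
            np.where(pos < gs, gs - pos, pos - (ge - 1)),
        )
        best = np.argmin(d, axis=1)  # argmin takes the first = smallest id on ties
        loc = sub.index.to_numpy()
        gene_id[loc] = ids[best]
        distance[loc] = d[np.arange(len(pos)), best]

    return pd.DataFrame({"gene_id": gene_id, "distance": distance}, index=sites.index)


def distribution_summary(
    labels: pd.DataFrame, background_labels: pd.DataFrame
) -> dict:
    """Per-class fractions for a DMS set vs the background, with enrichment.

    Returns, per axis, fractions over each label set (summing to 1) and
    the DMS/background enrichment ratio per class. An empty DMS set
    yields background fractions only, with a warning.
    """
    if len(background_labels) == 0:
        raise ValueError("background label set is empty")
    out: dict = {}
    empty_dms = len(labels) == 0
    if empty_dms:
        warnings.warn("empty DMS label set; reporting background only", stacklevel=2)
    for axis, classes in (("gene_context", GENE_CONTEXTS), ("cpg_context", CPG_CONTEXTS)):
        bg = background_labels[axis].value_counts(normalize=True)
        bg_frac = {c: float(bg.get(c, 0.0)) for c in classes}
        axis_out = {"background": bg_frac}
        if not empty_dms:
            fg = labels[axis].value_counts(normalize=True)
            fg_frac = {c: float(fg.get(c, 0.0)) for c in classes}
            axis_out["dms"] = fg_frac
            axis_out["enrichment"] = {
                c: (fg_frac[c] / bg_frac[c]) if bg_frac[c] > 0 else np.nan
                for c in classes
            }
        out[axis] = axis_out
    return out
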