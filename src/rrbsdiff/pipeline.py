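"""End-to-end orchestration: counts -> DMS -> annotation -> spatial reports.

A run is declared by a :class:`RunConfig` (YAML-loadable): input paths,
a list of two-group comparisons resolved against the design sheet, the
filtering/calling thresholds, and the contrast pairs for the
cross-treatment analyses (1-Mb bin differencing, nested correlations,
delta screen). Every artifact carries the config hash in a header
comment; runs are deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import rrbsdiff
from rrbsdiff.io import (
    SampleDesign,
    read_coverage_file,
    assemble_matrix,
    read_design,
    read_annotation,
)
from rrbsdiff.annotation import assign_contexts, nearest_gene, distribution_summary
from rrbsdiff.dms import ComparisonSpec, call_dms
from rrbsdiff.spatial import (
    neighbor_distances,
    resample_null,
    same_direction_fraction,
    bin_difference,
    nested_correlations,
    delta_screen,
    shared_comparison_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    counts_dir: str
    design: str
    genes_bed: str
    cgi_bed: str
    outdir: str
    exons_bed: str | None = None
    # each comparison: {"name", "group_a", "group_b", "hemisphere_a",
    # "hemisphere_b"}; hemisphere None pools both sides of the group
    comparisons: list[dict] = field(default_factory=list)
    contrast_pairs: list[list[str]] = field(default_factory=list)
    min_coverage: int = 10
    min_samples_per_group: int | None = None
    q_threshold: float = 0.01
    delta_threshold: float = 20.0
    codirection_radius: int = 100
    bin_size: int = 1_000_000
    n_resamples: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def preset_comparisons(
    groups: tuple[str, str, str] = ("UNT", "LDOPA", "LDOPA_R"),
) -> tuple[list[dict], list[list[str]]]:
    """The study's comparison plan as a declarative preset.

    Within-group lesioned-vs-control side comparisons for each group,
    plus the pooled six-vs-six between-group comparisons of each treated
    group against the untreated reference and of the two treatments
    against each other. Contrast pairs feed the cross-treatment
    analyses.
    """
    unt, ldopa, ldopa_r = groups
    comparisons = [
        {
            "name": f"{g}_lesioned_vs_control",
            "group_a": g, "group_b": g,
            "hemisphere_a": "control", "hemisphere_b": "lesioned",
        }
        for g in groups
    ]
    comparisons += [
        {"name": f"{ldopa}_vs_{unt}", "group_a": unt, "group_b": ldopa,
         "hemisphere_a": None, "hemisphere_b": None},
        {"name": f"{ldopa_r}_vs_{unt}", "group_a": unt, "group_b": ldopa_r,
         "hemisphere_a": None, "hemisphere_b": None},
        {"name": f"{ldopa_r}_vs_{ldopa}", "group_a": ldopa, "group_b": ldopa_r,
         "hemisphere_a": None, "hemisphere_b": None},
    ]
    contrast_pairs = [[f"{ldopa}_vs_{unt}", f"{ldopa_r}_vs_{unt}"]]
    return comparisons, contrast_pairs


def _resolve_spec(comp: dict, design: SampleDesign, config: RunConfig) -> ComparisonSpec:
    group_a = design.samples_of(comp["group_a"], comp.get("hemisphere_a"))
    group_b = design.samples_of(comp["group_b"], comp.get("hemisphere_b"))
    if not group_a or not group_b:
        raise ValueError(
            f"comparison {comp['name']}: no samples resolved for "
            f"{comp['group_a']} / {comp['group_b']}"
        )
    return ComparisonSpec(
        name=comp["name"],
        group_a=group_a,
        group_b=group_b,
        min_coverage=config.min_coverage,
        min_samples_per_group=config.min_samples_per_group,
        q_threshold=config.q_threshold,
    )


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rrbsdiff {rrbsdiff.__version__} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute filter -> test -> call -> annotate -> spatial for every comparison.

    Writes per-comparison DMS tables (1-based positions), context
    annotations, spatial summaries, per contrast pair a 1-Mb bin
    difference bedgraph and the delta-screen table, and a machine-
    readable ``report.json``. Returns the report dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    design = read_design(config.design)
    counts_dir = Path(config.counts_dir)
    per_sample = {}
    for path in sorted(counts_dir.glob("*.cov")):
        per_sample[path.stem] = read_coverage_file(path)
    if not per_sample:
        raise FileNotFoundError(f"no .cov files under {counts_dir}")
    matrix = assemble_matrix(per_sample, design)
    ann = read_annotation(config.genes_bed, config.cgi_bed, config.exons_bed)

    background_contexts = assign_contexts(matrix.sites, ann)

    report: dict = {
        "version": rrbsdiff.__version__,
        "config": asdict(config),
        "config_hash": chash,
        "seed": config.seed,
        "n_sites_assembled": int(matrix.n_sites),
        "comparisons": {},
        "contrasts": {},
    }
    results: dict[str, pd.DataFrame] = {}
    for comp in config.comparisons:
        spec = _resolve_spec(comp, design, config)
        records = call_dms(matrix, spec)
        results[spec.name] = records
        dms = records.loc[records["is_dms"]].reset_index(drop=True)

        ctx = assign_contexts(records, ann)
        near = nearest_gene(records, ann)
        annotated = pd.concat([records, ctx, near], axis=1)
        out = annotated.copy()
        out["pos"] = out["pos"] + 1  # reports are 1-based
        _write_tsv(out, outdir / f"{spec.name}.dms.tsv", chash)

        stage: dict = {
            "n_sites_tested": int(len(records)),
            "n_dms": int(len(dms)),
            "n_hyper": int((dms["direction"] == "hyper").sum()),
            "n_hypo": int((dms["direction"] == "hypo").sum()),
        }
        if len(dms) > 0:
            summary = distribution_summary(
                ctx.loc[records["is_dms"]], background_contexts
            )
            stage["context_distribution"] = summary
            codir = same_direction_fraction(dms, radius=config.codirection_radius)
            stage["same_direction"] = codir
            obs = neighbor_distances(dms)
            null = resample_null(
                len(dms),
                matrix.sites,
                n_resamples=config.n_resamples,
                seed=config.seed,
            )
            dist_df = pd.DataFrame(
                {
                    "bin_lo": obs.bin_edges[:-1],
                    "bin_hi": obs.bin_edges[1:],
                    "observed": obs.observed_counts,
                    "null_mean": null.null_mean,
                    "null_sd": null.null_sd,
                }
            )
            _write_tsv(dist_df, outdir / f"{spec.name}.distances.tsv", chash)
        report["comparisons"][spec.name] = stage

    for pair in config.contrast_pairs:
        name_1, name_2 = pair
        shared = shared_comparison_table(results[name_1], results[name_2])
        corr = nested_correlations(shared)
        screen = delta_screen(shared, threshold=config.delta_threshold)
        if len(screen):
            sctx = assign_contexts(screen, ann)
            snear = nearest_gene(screen, ann)
            screen = pd.concat([screen, sctx, snear], axis=1)
        sout = screen.copy()
        if len(sout):
            sout["pos"] = sout["pos"] + 1
        _write_tsv(sout, outdir / f"{name_1}__{name_2}.screen.tsv", chash)

        dms_1 = results[name_1].loc[results[name_1]["is_dms"]]
        dms_2 = results[name_2].loc[results[name_2]["is_dms"]]
        track = bin_difference(dms_1, dms_2, bin_size=config.bin_size)
        bedgraph = track[["chrom", "bin_start", "bin_end", "difference"]]
        bedgraph.to_csv(
            outdir / f"{name_1}__{name_2}.bindiff.bedgraph",
            sep="\t", header=False, index=False,
        )
        report["contrasts"][f"{name_1}__{name_2}"] = {
            "nested_correlations": corr,
            "n_screen": int(len(screen)),
            "top_bins": track.nsmallest(5, "abs_rank")[
                ["chrom", "bin_start", "difference"]
            ].to_dict("records"),
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    logger.info("pipeline complete: %s", outdir / "report.json")
    return report


def make_demo(outdir: str | Path, seed: int = 7) -> dict:
    """Generate a small seeded dataset, run the full pipeline, store digests.

    The demo emulates the study design at reduced scale (2 chromosomes x
    1 Mb) with effects shared between the two treated groups, runs every
    preset comparison, and records sha256 digests of all artifacts so a
    re-run can be verified byte-for-byte.
    """
    from rrbsdiff.simulate import (
        SimulationConfig, simulate_dataset, emit_dataset, lid_like_effects,
    )

    outdir = Path(outdir)
    data_dir = outdir / "data"
    sim = SimulationConfig(
        seed=seed,
        effect_table=lid_like_effects(n_shared=40, n_private=15),
    )
    dataset = simulate_dataset(sim)
    emit_dataset(dataset, data_dir)

    comparisons, contrast_pairs = preset_comparisons()
    config = RunConfig(
        counts_dir=str(data_dir / "counts"),
        design=str(data_dir / "design.tsv"),
        genes_bed=str(data_dir / "genes.bed"),
        cgi_bed=str(data_dir / "cgi.bed"),
        exons_bed=str(data_dir / "exons.bed"),
        outdir=str(outdir / "results"),
        comparisons=comparisons,
        contrast_pairs=contrast_pairs,
        min_samples_per_group=4,
        seed=seed,
    )
    report = run_pipeline(config)

    digests = {}
    for path in sorted(Path(config.outdir).iterdir()):
        digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(outdir / "digests.json", "w") as fh:
        json.dump(digests, fh, indent=2, sort_keys=True)
    report["digests"] = digests
    return report
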