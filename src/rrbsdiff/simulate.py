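"""Synthetic RRBS datasets with known injected group effects.

The generator emulates the statistical structure of an RRBS study of rat
striatum with three treatment groups (untreated, levodopa, levodopa +
riluzole), three animals per group and both hemispheres sequenced:

* a miniature genome with genes (TSS, exons, strand) and CpG islands,
  CpG sites placed genome-wide with elevated density inside CGIs;
* MspI-style restriction sites (CCGG) whose inter-site fragments undergo
  size selection — only CpGs on fragments inside the detectable window
  receive coverage;
* latent regional methylation levels shared by CpGs within a
  co-methylation radius (~100 bp), low in CGIs/promoters and high in the
  CpG-poor open sea, with beta-binomial counts on top;
* treatment effects injected at region granularity into configured
  groups, biased toward methylation loss outside promoters and CGIs,
  recorded in a ground-truth table;
* both hemispheres of an animal share the animal's latent levels, so the
  two sides are near-identical replicates by construction.

Randomness is fully determined by ``SimulationConfig.seed``; the same
config yields byte-identical emitted datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from rrbsdiff.annotation import GenomeAnnotation, assign_contexts
from rrbsdiff.io import (
    MethylationMatrix,
    SampleDesign,
    write_coverage_file,
    write_design,
    write_annotation_beds,
)

# placement densities (mean gap in bp); genome-scale knobs that are not
# part of the study design and therefore not SimulationConfig fields
CPG_GAP_OPEN = 100
CPG_GAP_CGI = 12
CCGG_GAP_OPEN = 400
CCGG_GAP_CGI = 150
REGION_BETA_CONCENTRATION = 30.0
BASELINE_MEANS = {"cgi_promoter": 0.10, "shore": 0.50, "open_sea": 0.80}

DEFAULT_GROUPS = ("UNT", "LDOPA", "LDOPA_R")
HEMISPHERES = ("control", "lesioned")

REGION_PREFERENCES = ("open_sea", "gene_body", "promoter", "any")


class SizingError(ValueError):
    """Requested features do not fit on the configured chromosomes."""


class CapacityError(ValueError):
    """An effect table requests more sites than the preferred region holds."""


@dataclass(frozen=True)
class EffectSpec:
    """One injected treatment effect.

    ``target_group`` may be a single group label or a tuple of labels; a
    tuple injects the same sites and delta into every listed group
    (shared effects across the two drug-treated groups). ``delta`` is a
    signed methylation shift in percentage points applied to the latent
    level of the affected sites in the target group(s) only.
    """

    target_group: str | tuple[str, ...]
    delta: float
    region_preference: str = "any"
    n_sites: int = 1

    def groups(self) -> tuple[str, ...]:
        if isinstance(self.target_group, str):
            return (self.target_group,)
        return tuple(self.target_group)

    def validate(self, known_groups: tuple[str, ...]) -> None:
        if abs(self.delta) > 100:
            raise ValueError(f"|delta| must be <= 100, got {self.delta}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.region_preference not in REGION_PREFERENCES:
            raise ValueError(
                f"region_preference must be one of {REGION_PREFERENCES}"
            )
        unknown = set(self.groups()) - set(known_groups)
        if unknown:
            raise ValueError(f"effect targets unknown groups {sorted(unknown)}")


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world: study design, genome sizing and noise levels.

    Defaults mirror the study: 3 animals per group x 2 hemispheres x 3
    groups, detectable MspI fragments of 50-1200 bp, ~30x depth at
    covered CpGs, co-methylation within 100 bp, and a 3:1 bias of
    methylation loss among injected effects.
    """

    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 20
    n_cgis: int = 30
    fragment_size_window: tuple[int, int] = (50, 1200)
    mean_depth: float = 30.0
    dispersion: float = 0.01
    n_animals_per_group: int = 3
    groups: tuple[str, ...] = DEFAULT_GROUPS
    effect_table: tuple[EffectSpec, ...] = ()
    hypo_fraction: float = 0.75
    comethylation_radius: int = 100
    side_effect: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.fragment_size_window
        if lo < 50 or hi > 1200 or lo > hi:
            raise ValueError(
                "fragment_size_window must lie within the detectable 50-1200 bp range"
            )
        if not 0.0 <= self.hypo_fraction <= 1.0:
            raise ValueError("hypo_fraction must be in [0, 1]")
        if not 0.0 <= self.dispersion < 1.0:
            raise ValueError("dispersion must be in [0, 1)")
        if self.mean_depth < 10:
            raise ValueError("mean_depth must be >= 10 so filtering retains data")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        for eff in self.effect_table:
            eff.validate(self.groups)


@dataclass
class SimulatedGenome:
    annotation: GenomeAnnotation
    cpgs: pd.DataFrame            # chrom, pos, strand; sorted by (chrom, pos)
    ccgg: dict[str, np.ndarray]   # restriction-site positions per chromosome
    chrom_sizes: dict[str, int]


@dataclass
class SimulatedDataset:
    genome: SimulatedGenome
    design: SampleDesign
    matrix: MethylationMatrix
    truth: pd.DataFrame
    config: SimulationConfig


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _poisson_positions(
    rng: np.random.Generator, length: int, mean_gap: float, offset: int = 0
) -> np.ndarray:
    """Positions of a homogeneous Poisson process on [offset, offset+length)."""
    n_exp = int(length / mean_gap * 1.5 + 20)
    gaps = rng.exponential(mean_gap, size=n_exp)
    pos = np.cumsum(gaps)
    while pos.size and pos[-1] < length:
        extra = np.cumsum(rng.exponential(mean_gap, size=n_exp)) + pos[-1]
        pos = np.concatenate([pos, extra])
    pos = pos[pos < length]
    return (pos.astype(np.int64) + offset)


def build_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate the miniature genome: genes, exons, CGIs, CCGG and CpG maps.

    Gene placement partitions each chromosome into equal slots; a slot
    narrower than ~8 kb cannot host a gene with flanks and raises
    :class:`SizingError`. Half the CGIs sit on randomly chosen TSSs (the
    promoter-CGI association of real genomes), the rest are uniform. CpG
    density is elevated ~8-fold inside CGIs.
    """
    rng = _rng(config, 0)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sizes = {c: config.chrom_length for c in chroms}

    # genes, round-robin across chromosomes
    per_chrom = {c: 0 for c in chroms}
    for i in range(config.n_genes):
        per_chrom[chroms[i % len(chroms)]] += 1
    gene_rows, exon_rows = [], []
    gi = 0
    for chrom in chroms:
        g = per_chrom[chrom]
        if g == 0:
            continue
        slot = sizes[chrom] // g
        if slot < 8000:
            raise SizingError(
                f"{chrom} ({sizes[chrom]} bp) too short for {g} genes: "
                f"slot {slot} bp < 8000 bp minimum"
            )
        for j in range(g):
            max_len = min(30_000, slot - 3000)
            length = int(rng.integers(2000, max_len + 1))
            start = j * slot + int(rng.integers(500, slot - length - 500 + 1))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gi:04d}"
            gene_rows.append((gid, chrom, start, end, strand))
            n_ex = int(rng.integers(1, 5))
            seg = length // n_ex
            for k in range(n_ex):
                ex_len = int(rng.integers(100, min(1500, seg - 50) + 1))
                ex_start = start + k * seg
                exon_rows.append((gid, chrom, ex_start, ex_start + ex_len))
            gi += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    genes["start"] = genes["start"].astype(np.int64) if len(genes) else genes.get("start")
    if len(genes):
        genes["tss"] = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
    else:
        genes = pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
        )
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])

    # CpG islands: half anchored at TSSs, half uniform
    total_len = sum(sizes.values())
    if config.n_cgis * 2000 > total_len:
        raise SizingError(
            f"{config.n_cgis} CGIs cannot fit in a {total_len} bp genome"
        )
    cgi_rows = []
    n_at_tss = min(len(genes), config.n_cgis // 2)
    if n_at_tss > 0:
        picked = rng.choice(len(genes), size=n_at_tss, replace=False)
        for idx in picked:
            length = int(rng.integers(300, 1501))
            tss = int(genes["tss"].iloc[idx])
            chrom = genes["chrom"].iloc[idx]
            start = max(0, tss - length // 2)
            cgi_rows.append((chrom, start, min(start + length, sizes[chrom])))
    for _ in range(config.n_cgis - n_at_tss):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(300, 1501))
        start = int(rng.integers(0, max(1, sizes[chrom] - length)))
        cgi_rows.append((chrom, start, start + length))
    from rrbsdiff.intervals import merge_intervals

    cgi_frames = []
    raw = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    for chrom in chroms:
        sub = raw.loc[raw["chrom"] == chrom]
        if len(sub) == 0:
            continue
        s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        cgi_frames.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    cgis = (
        pd.concat(cgi_frames, ignore_index=True)
        if cgi_frames
        else pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64)})
    )

    # CCGG restriction sites and CpG sites: base Poisson process plus an
    # extra, denser process inside CGIs
    ccgg: dict[str, np.ndarray] = {}
    cpg_frames = []
    for chrom in chroms:
        L = sizes[chrom]
        islands = cgis.loc[cgis["chrom"] == chrom]
        cc = [_poisson_positions(rng, L, CCGG_GAP_OPEN)]
        cp = [_poisson_positions(rng, L, CPG_GAP_OPEN)]
        for _, isl in islands.iterrows():
            ilen = int(isl["end"] - isl["start"])
            cc.append(_poisson_positions(rng, ilen, CCGG_GAP_CGI, int(isl["start"])))
            cp.append(_poisson_positions(rng, ilen, CPG_GAP_CGI, int(isl["start"])))
        ccgg[chrom] = np.unique(np.concatenate(cc))
        cpg_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": np.unique(np.concatenate(cp))})
        )
    cpgs = pd.concat(cpg_frames, ignore_index=True)
    cpgs["strand"] = "+"
    cpgs = cpgs.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    annotation = GenomeAnnotation(
        genes=genes.reset_index(drop=True),
        exons=exons.reset_index(drop=True),
        cgis=cgis,
        chrom_sizes=dict(sizes),
    )
    return SimulatedGenome(
        annotation=annotation, cpgs=cpgs, ccgg=ccgg, chrom_sizes=dict(sizes)
    )


def build_design(config: SimulationConfig) -> SampleDesign:
    """Sample sheet for the configured groups x animals x hemispheres."""
    rows = []
    for group in config.groups:
        for a in range(1, config.n_animals_per_group + 1):
            for side in HEMISPHERES:
                rows.append(
                    {
                        "sample": f"{group}_{a}_{side}",
                        "group": group,
                        "hemisphere": side,
                        "animal": f"{group}_{a}",
                    }
                )
    return SampleDesign(table=pd.DataFrame(rows))


def fragment_covered_mask(genome: SimulatedGenome, config: SimulationConfig) -> np.ndarray:
    """True for CpGs on an inter-CCGG fragment inside the size window."""
    lo, hi = config.fragment_size_window
    mask = np.zeros(len(genome.cpgs), dtype=bool)
    for chrom, sub in genome.cpgs.groupby("chrom", sort=False):
        cc = genome.ccgg[chrom]
        pos = sub["pos"].to_numpy()
        if cc.size < 2:
            continue
        idx = np.searchsorted(cc, pos, side="right") - 1
        ok = (idx >= 0) & (idx < cc.size - 1)
        frag_len = np.zeros(len(pos), dtype=np.int64)
        frag_len[ok] = cc[idx[ok] + 1] - cc[idx[ok]]
        mask[sub.index.to_numpy()] = ok & (frag_len >= lo) & (frag_len <= hi)
    return mask


def simulate_rrbs_coverage(
    genome: SimulatedGenome, config: SimulationConfig, n_samples: int | None = None
) -> np.ndarray:
    """Per-sample read depth per CpG; NaN for CpGs off selected fragments.

    Depth at covered CpGs is 1 + Poisson(mean_depth - 1), so selected
    fragments always yield at least one read and the mean equals the
    configured depth.
    """
    if n_samples is None:
        n_samples = len(config.groups) * config.n_animals_per_group * 2
    rng = _rng(config, 1)
    covered = fragment_covered_mask(genome, config)
    cov = np.full((len(genome.cpgs), n_samples), np.nan)
    n_cov = int(covered.sum())
    if n_cov:
        cov[covered] = 1.0 + rng.poisson(config.mean_depth - 1.0, size=(n_cov, n_samples))
    return cov


def _region_ids(cpgs: pd.DataFrame, radius: int) -> np.ndarray:
    """Cluster consecutive CpGs within `radius` bp (same chromosome) together."""
    pos = cpgs["pos"].to_numpy()
    chrom = cpgs["chrom"].to_numpy()
    new = np.ones(len(cpgs), dtype=bool)
    if len(cpgs) > 1:
        same = chrom[1:] == chrom[:-1]
        close = (pos[1:] - pos[:-1]) <= radius
        new[1:] = ~(same & close)
    return np.cumsum(new) - 1


def _select_effect_sites(
    spec: EffectSpec,
    contexts: pd.DataFrame,
    covered: np.ndarray,
    region_ids: np.ndarray,
    site_baseline: np.ndarray,
    taken: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    if spec.region_preference == "open_sea":
        pref = (contexts["cpg_context"] == "other").to_numpy()
    elif spec.region_preference == "promoter":
        pref = (contexts["gene_context"] == "promoter").to_numpy()
    elif spec.region_preference == "gene_body":
        pref = contexts["gene_context"].isin(["exon", "intron"]).to_numpy()
    else:
        pref = np.ones(len(contexts), dtype=bool)
    # feasibility: the shifted latent level must stay inside (0, 1), else
    # clipping would silently shrink the effect and falsify the truth table
    shifted = site_baseline + spec.delta / 100.0
    feasible = (shifted >= 0.02) & (shifted <= 0.98)
    candidates = pref & covered & ~taken & feasible
    n_avail = int(candidates.sum())
    if n_avail < spec.n_sites:
        raise CapacityError(
            f"effect requests {spec.n_sites} sites in '{spec.region_preference}' "
            f"compatible with a {spec.delta:+.0f}-point shift, but only "
            f"{n_avail} eligible CpGs exist"
        )
    # whole co-methylation regions at a time, so neighbours share the effect
    cand_regions = np.unique(region_ids[candidates])
    order = rng.permutation(cand_regions)
    chosen: list[np.ndarray] = []
    count = 0
    for reg in order:
        sites = np.flatnonzero(candidates & (region_ids == reg))
        if count + len(sites) > spec.n_sites:
            sites = sites[: spec.n_sites - count]
        chosen.append(sites)
        count += len(sites)
        if count >= spec.n_sites:
            break
    return np.concatenate(chosen)


def simulate_methylation(
    genome: SimulatedGenome,
    coverage: np.ndarray,
    config: SimulationConfig,
    design: SampleDesign | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Draw methylated counts from latent regional levels plus effects.

    Baseline latent levels are Beta-distributed per co-methylation region
    with context-dependent means (CGI/promoter 0.1, shore 0.5, open sea
    0.8). Each animal draws a region-level deviation with intra-class
    correlation ``dispersion``; both hemisphere samples of an animal
    share that draw, making the two sides near-identical. Injected
    effects shift the latent mean by delta/100 in the target group(s)
    only. Returns the count matrix and the ground-truth effect table.
    """
    if design is None:
        design = build_design(config)
    if coverage.shape != (len(genome.cpgs), len(design.samples)):
        raise ValueError("coverage array does not match genome x design")
    rng = _rng(config, 2)
    contexts = assign_contexts(genome.cpgs, genome.annotation)
    region_ids = _region_ids(genome.cpgs, config.comethylation_radius)
    n_regions = int(region_ids[-1]) + 1 if len(region_ids) else 0

    # context class per region: any island/promoter CpG -> low baseline
    rank = np.full(len(contexts), 2)
    rank[(contexts["cpg_context"] == "cpg_shore").to_numpy()] = 1
    rank[
        (contexts["cpg_context"] == "cpg_island").to_numpy()
        | (contexts["gene_context"] == "promoter").to_numpy()
    ] = 0
    region_rank = np.full(n_regions, 2)
    np.minimum.at(region_rank, region_ids, rank)
    means = np.array(
        [BASELINE_MEANS["cgi_promoter"], BASELINE_MEANS["shore"],
         BASELINE_MEANS["open_sea"]]
    )[region_rank]
    k0 = REGION_BETA_CONCENTRATION
    region_p = np.clip(rng.beta(means * k0, (1 - means) * k0), 0.02, 0.98)

    covered = ~np.all(np.isnan(coverage), axis=1)
    group_index = {g: i for i, g in enumerate(config.groups)}
    delta = np.zeros((len(genome.cpgs), len(config.groups)))
    taken = np.zeros((len(genome.cpgs), len(config.groups)), dtype=bool)
    truth_rows = []
    site_baseline = region_p[region_ids] if len(region_ids) else np.array([])
    for spec in config.effect_table:
        taken_any = taken[:, [group_index[g] for g in spec.groups()]].any(axis=1)
        sites = _select_effect_sites(
            spec, contexts, covered, region_ids, site_baseline, taken_any, rng
        )
        for g in spec.groups():
            delta[sites, group_index[g]] += spec.delta / 100.0
            taken[sites, group_index[g]] = True
        for s in sites:
            for g in spec.groups():
                truth_rows.append(
                    {
                        "chrom": genome.cpgs["chrom"].iloc[s],
                        "pos": int(genome.cpgs["pos"].iloc[s]),
                        "target_group": g,
                        "delta": spec.delta,
                        "gene_context": contexts["gene_context"].iloc[s],
                        "cpg_context": contexts["cpg_context"].iloc[s],
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "target_group", "delta",
                 "gene_context", "cpg_context"],
    )

    sample_pos = {s: j for j, s in enumerate(design.samples)}
    meth = np.full_like(coverage, np.nan)
    rho = config.dispersion
    for group in design.groups:
        gidx = group_index[group]
        animals = sorted(set(design.table.loc[design.table["group"] == group, "animal"]))
        for animal in animals:
            if rho > 0:
                a = region_p * (1 - rho) / rho
                b = (1 - region_p) * (1 - rho) / rho
                animal_region = rng.beta(a, b)
            else:
                animal_region = region_p.copy()
            base_mu = animal_region[region_ids] + delta[:, gidx]
            rows = design.table.loc[design.table["animal"] == animal]
            for _, row in rows.iterrows():
                mu = base_mu
                if config.side_effect != 0.0 and row["hemisphere"] == "lesioned":
                    mu = mu + config.side_effect
                mu = np.clip(mu, 1e-3, 1 - 1e-3)
                j = sample_pos[row["sample"]]
                c = coverage[:, j]
                obs = ~np.isnan(c)
                meth[obs, j] = rng.binomial(c[obs].astype(np.int64), mu[obs])

    matrix = MethylationMatrix(
        sites=genome.cpgs[["chrom", "pos", "strand"]].copy(),
        samples=list(design.samples),
        meth=meth,
        cov=coverage,
    )
    return matrix, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full generator chain: genome -> coverage -> counts + truth."""
    genome = build_genome(config)
    design = build_design(config)
    coverage = simulate_rrbs_coverage(genome, config, len(design.samples))
    matrix, truth = simulate_methylation(genome, coverage, config, design)
    return SimulatedDataset(
        genome=genome, design=design, matrix=matrix, truth=truth, config=config
    )


def lid_like_effects(
    treated_groups: tuple[str, ...] = ("LDOPA", "LDOPA_R"),
    n_shared: int = 60,
    n_private: int = 20,
    delta: float = 40.0,
    hypo_fraction: float = 0.75,
    region_preference: str = "open_sea",
) -> tuple[EffectSpec, ...]:
    """Effect table shaped like the study's findings.

    Most effects are shared between the two drug-treated groups with a
    smaller private component per group; the hypo:hyper ratio follows
    ``hypo_fraction`` (default 3:1 loss bias). Methylation losses
    concentrate in the CpG-poor open sea (where baseline methylation is
    high); gains are unconstrained in location since they require a
    low-baseline region to be feasible.
    """
    effects: list[EffectSpec] = []

    def split(n: int) -> tuple[int, int]:
        h = round(n * hypo_fraction)
        return h, n - h

    h, up = split(n_shared)
    if h:
        effects.append(EffectSpec(tuple(treated_groups), -delta, region_preference, h))
    if up:
        effects.append(EffectSpec(tuple(treated_groups), +delta, "any", up))
    for g in treated_groups:
        h, up = split(n_private)
        if h:
            effects.append(EffectSpec(g, -delta, region_preference, h))
        if up:
            effects.append(EffectSpec(g, +delta, "any", up))
    return tuple(effects)


def emit_dataset(
    dataset: SimulatedDataset, outdir: str | Path
) -> dict[str, Path]:
    """Write coverage files, design sheet, truth table and annotation BEDs.

    One Bismark-coverage file per sample (cells with no observation are
    simply absent); reading the files back through the io module
    reproduces the count matrix exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    matrix = dataset.matrix
    paths: dict[str, Path] = {}
    for j, sample in enumerate(matrix.samples):
        obs = ~np.isnan(matrix.cov[:, j])
        rec = pd.DataFrame(
            {
                "chrom": matrix.sites["chrom"].to_numpy()[obs],
                "pos": matrix.sites["pos"].to_numpy()[obs],
                "meth": matrix.meth[obs, j].astype(np.int64),
                "cov": matrix.cov[obs, j].astype(np.int64),
            }
        )
        p = counts_dir / f"{sample}.cov"
        write_coverage_file(rec, p)
        paths[sample] = p
    write_design(dataset.design, outdir / "design.tsv")
    paths["design"] = outdir / "design.tsv"
    dataset.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = outdir / "truth.tsv"
    write_annotation_beds(
        dataset.genome.annotation,
        outdir / "genes.bed",
        outdir / "cgi.bed",
        outdir / "exons.bed",
    )
    paths["genes"] = outdir / "genes.bed"
    paths["cgi"] = outdir / "cgi.bed"
    paths["exons"] = outdir / "exons.bed"
    return paths
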