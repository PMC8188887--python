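"""End-to-end synthetic pipeline: simulate -> hapmap -> linkage -> de.

Everything is driven by a :class:`PipelineConfig` (YAML round-trippable) and
a single seed, producing a machine-readable report of segment counts, the
class-count length table, significant loci, DE category counts and cis
fractions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import expression as de
from . import fileio, hapmap, linkage, synthetic
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class CrossSpec:
    """One experimental cross entering the meta-analysis."""

    cross_type: str = linkage.F2
    n_individuals: int = 200
    qtls: list[dict] = field(default_factory=list)  # chrom/pos_cM/var_frac
    polygenic_sd: float = 0.0
    missing_rate: float = 0.0


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run, with paper defaults."""

    seed: int = 0
    # genome / founders
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 40_000_000, "2": 30_000_000}
    )
    n_founders: int = 4
    n_strains: int = 6
    variant_density: float = 50.0  # variants per Mb
    alt_freq: float = 0.5
    mean_block_cM: float = 10.0
    cM_per_Mb: float = 1.0
    # segmentation
    min_run: int = 20
    max_gap: int = 100
    # linkage
    crosses: list[CrossSpec] = field(default_factory=lambda: [CrossSpec()])
    marker_spacing_cM: float = 10.0
    error_rate: float = 0.01
    grid_step: float = 0.5
    z_threshold: float = linkage.Z_THRESHOLD
    # expression
    n_probes: int = 200
    n_cis_probes: int = 20
    cis_effect: float = 2.0
    expression_noise_sd: float = 0.2
    n_replicates: int = 5
    call_rate: float = 0.5
    shared_p: float = 1e-4
    nonshared_p: float = 1e-8
    other_p: float = 0.05
    fdr: float = 0.05

    def __post_init__(self) -> None:
        self.crosses = [
            c if isinstance(c, CrossSpec) else CrossSpec(**c) for c in self.crosses
        ]
        for thr in (self.shared_p, self.nonshared_p, self.other_p, self.fdr, self.call_rate):
            if not 0.0 < thr <= 1.0:
                raise InvalidArgumentError(f"threshold {thr} outside (0, 1]")
        if self.z_threshold <= 0:
            raise InvalidArgumentError("z_threshold must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _marker_map(config: PipelineConfig) -> dict[str, list[float]]:
    out = {}
    for c, length in config.chrom_lengths.items():
        genetic_len = length / 1e6 * config.cM_per_Mb
        out[c] = list(np.arange(0.0, genetic_len + 1e-9, config.marker_spacing_cM))
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run simulate -> hapmap -> linkage -> de and return the report dict.

    When ``outdir`` is given, intermediate files (VCF, BED, TSVs) and
    ``report.json`` are written there.  Fully reproducible per seed.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"seed": config.seed}

    # --- simulate strains -------------------------------------------------
    logger.info("stage simulate: founders and inbred strains")
    pool = synthetic.simulate_founder_pool(
        config.n_founders,
        config.chrom_lengths,
        config.variant_density,
        config.alt_freq,
        seed=int(rng.integers(2**31)),
    )
    geno, truth = synthetic.simulate_inbred_strains(
        pool,
        config.n_strains,
        config.mean_block_cM,
        config.cM_per_Mb,
        seed=int(rng.integers(2**31)),
    )
    if out is not None:
        fileio.write_genotypes_vcf(geno, out / "strains.vcf")
        geno = fileio.read_genotypes_vcf(out / "strains.vcf")
    report["n_variants"] = geno.n_variants
    report["n_strains"] = geno.n_strains

    # --- haplotype map ----------------------------------------------------
    logger.info("stage hapmap: SDP enumeration and segment detection")
    catalog, assignment = hapmap.enumerate_sdps(geno)
    params = hapmap.SegmentationParams(min_run=config.min_run, max_gap=config.max_gap)
    segments = hapmap.detect_segments(geno, assignment, params)
    region_map, class_table = hapmap.build_region_map(
        segments, config.chrom_lengths, catalog
    )
    a, b = geno.strains[0], geno.strains[1]
    diversity = hapmap.pairwise_diversity(
        segments, catalog, geno.strains, a, b, config.chrom_lengths
    )
    report["n_sdps"] = len(catalog)
    report["n_segments"] = len(segments)
    report["n_regions"] = sum(len(r) for r in region_map.regions.values())
    report["class_length_table"] = {str(k): v for k, v in class_table.items()}
    report["diversity_first_pair"] = diversity
    if out is not None:
        fileio.write_segments_bed(segments, out / "segments.bed")

    # --- linkage ----------------------------------------------------------
    logger.info("stage linkage: per-cross scans and meta-analysis")
    marker_map = _marker_map(config)
    hmm = linkage.HmmParams(error_rate=config.error_rate, grid_step=config.grid_step)
    scans = []
    for i, spec in enumerate(config.crosses):
        cross = synthetic.simulate_cross(
            spec.cross_type,
            spec.n_individuals,
            marker_map,
            qtls=[synthetic.QtlSpec(**q) for q in spec.qtls],
            polygenic_sd=spec.polygenic_sd,
            missing_rate=spec.missing_rate,
            seed=int(rng.integers(2**31)),
        )
        if out is not None:
            fileio.write_cross_tsv(
                cross, out / f"cross{i+1}.map.tsv", out / f"cross{i+1}.data.tsv"
            )
        y = linkage.inverse_normal_transform(cross.phenotypes["trait"])
        grid = linkage.genotype_posteriors(cross, hmm)
        scans.append(linkage.score_test(grid, y))
    meta = linkage.meta_scan(scans, z_threshold=config.z_threshold)
    report["n_loci"] = len(meta)
    report["n_significant_loci"] = int(meta["significant"].sum())
    report["max_abs_z"] = float(meta["z"].abs().max())
    if out is not None:
        meta.to_csv(out / "meta_scan.tsv", sep="\t", index=False)

    # --- expression -------------------------------------------------------
    logger.info("stage de: differential expression and cis annotation")
    probes = _make_probes(config, segments, catalog, geno, rng)
    mat = synthetic.simulate_expression(
        geno,
        segments,
        catalog,
        probes,
        n_replicates=config.n_replicates,
        noise_sd=config.expression_noise_sd,
        seed=int(rng.integers(2**31)),
    )
    mat = de.filter_probes(mat, config.call_rate)
    mat = de.quantile_normalize(mat)
    ref = geno.strains[2] if geno.n_strains > 2 else geno.strains[1]
    res_a = de.differential_expression(mat, a, ref)
    res_b = de.differential_expression(mat, b, ref)
    res_a["q"] = de.bh_fdr(res_a["p"].to_numpy())
    res_b["q"] = de.bh_fdr(res_b["p"].to_numpy())
    cats = de.classify_shared_nonshared(
        res_a, res_b, config.shared_p, config.nonshared_p, config.other_p
    )
    annotated = de.annotate_cis(
        cats, mat.probes, segments, catalog, geno.strains, a, ref
    )
    counts = annotated["category"].value_counts().to_dict()
    report["de_categories"] = {k: int(v) for k, v in sorted(counts.items())}
    report["de_q_significant"] = {
        "A_vs_ref": int((res_a["q"] < config.fdr).sum()),
        "B_vs_ref": int((res_b["q"] < config.fdr).sum()),
    }
    report["cis_summary"] = annotated.attrs["cis_summary"]
    if out is not None:
        annotated.to_csv(out / "de_categories.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _make_probes(config, segments, catalog, geno, rng) -> list[tuple[str, str, int, float]]:
    """Place cis probes inside segments divergent for the compared strain
    pairs (falling back to any segment), background probes anywhere."""
    probes: list[tuple[str, str, int, float]] = []
    chroms = list(config.chrom_lengths)
    n_cis = min(config.n_cis_probes, config.n_probes)
    if geno.n_strains > 2:
        a, b, ref = geno.strains[0], geno.strains[1], geno.strains[2]
        ia, ib, ir = 0, 1, 2
        seg_pool = [
            s for s in segments
            if catalog[s.sdp_id].splits(ia, ir) and catalog[s.sdp_id].splits(ib, ir)
        ] or list(segments)
    else:
        seg_pool = list(segments)
    for i in range(n_cis):
        if seg_pool:
            seg = seg_pool[int(rng.integers(len(seg_pool)))]
            pos = int(rng.integers(seg.start, seg.end + 1))
            probes.append((f"cis{i+1}", seg.chrom, pos, config.cis_effect))
        else:
            c = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, config.chrom_lengths[c] + 1))
            probes.append((f"cis{i+1}", c, pos, config.cis_effect))
    for i in range(config.n_probes - n_cis):
        c = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, config.chrom_lengths[c] + 1))
        probes.append((f"bg{i+1}", c, pos, 0.0))
    return probes
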