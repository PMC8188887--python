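"""Readers and writers for the plain-text interchange formats.

VCF for strain genotype tables (cyvcf2-backed reader with the homozygosity /
depth / quality filters), BED6 for haplotype segments, and tab-separated
tables for crosses and expression matrices.  TSV dialect: tab-separated,
'#'-prefixed header comments, "NA" for missing.  Internal coordinates are
1-based inclusive; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import InvalidInputError
from .expression import ExpressionMatrix
from .hapmap import GenotypeTable, HaplotypeSegment
from .linkage import AA, AB, BB, MISSING, CrossDataset

logger = logging.getLogger(__name__)

_GENO_TOKENS = {AA: "AA", AB: "AB", BB: "BB", MISSING: "NA"}
_GENO_CODES = {v: k for k, v in _GENO_TOKENS.items()}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_genotypes_vcf(geno: GenotypeTable, path: str | Path) -> None:
    """Write a genotype table as a minimal VCF with 0/0 and 1/1 GT calls."""
    path = Path(path)
    ref = np.asarray(geno.ref, dtype=object)
    alt = np.asarray(geno.alt, dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in geno.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.strains)
            + "\n"
        )
        for j in range(geno.n_variants):
            gts = "\t".join("1/1" if g else "0/0" for g in geno.calls[:, j])
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _format_field(variant, key: str):
    """Per-sample FORMAT values, or None when absent (cyvcf2 raises)."""
    try:
        return variant.format(key)
    except KeyError:
        return None


def read_genotypes_vcf(
    path: str | Path, min_depth: int = 4, min_gq: int = 10
) -> GenotypeTable:
    """Read homozygous biallelic calls from a VCF.

    Records are dropped (with per-reason counts logged) when multi-allelic,
    when any strain is heterozygous or missing, or — if the FORMAT fields are
    present — when any strain falls below ``min_depth`` read depth or
    ``min_gq`` genotype quality.
    """
    path = Path(path)
    vcf = VCF(str(path))
    strains = list(vcf.samples)
    dropped = {"multiallelic": 0, "het_or_missing": 0, "low_depth": 0, "low_gq": 0}
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    calls: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        gt = v.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        if np.isin(gt, (1, 2)).any():
            dropped["het_or_missing"] += 1
            continue
        depth = _format_field(v, "DP")
        if depth is not None and np.nanmin(depth) < min_depth:
            dropped["low_depth"] += 1
            continue
        gq = _format_field(v, "GQ")
        if gq is not None and np.nanmin(gq) < min_gq:
            dropped["low_gq"] += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        calls.append((gt == 3).astype(np.uint8))
    vcf.close()
    logger.info("read_genotypes_vcf: kept %d records, dropped %s", len(pos), dropped)
    return GenotypeTable(
        strains=strains,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        calls=(
            np.column_stack(calls)
            if calls
            else np.zeros((len(strains), 0), dtype=np.uint8)
        ),
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_segments_bed(segments: list[HaplotypeSegment], path: str | Path) -> None:
    """Write segments as BED6 (name = sdp id, score = n_support)."""
    path = Path(path)
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start, s.end, s.sdp_id))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for s in ordered:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\tsdp{s.sdp_id}\t{s.n_support}\t.\n")


def read_segments_bed(path: str | Path) -> list[HaplotypeSegment]:
    """Read segments written by :func:`write_segments_bed`."""
    segments: list[HaplotypeSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5 or not fields[3].startswith("sdp"):
                raise InvalidInputError(f"{path}:{lineno}: malformed BED line")
            segments.append(
                HaplotypeSegment(
                    chrom=fields[0],
                    start=int(fields[1]) + 1,
                    end=int(fields[2]),
                    sdp_id=int(fields[3][3:]),
                    n_support=int(fields[4]),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# cross TSVs
# ---------------------------------------------------------------------------

def write_cross_tsv(cross: CrossDataset, map_path: str | Path, data_path: str | Path) -> None:
    """Write a cross as two TSVs: genetic map, and genotypes + phenotypes."""
    with open(map_path, "w") as fh:
        fh.write("# genetic map: marker, chromosome, position (cM)\n")
        cross.markers.to_csv(fh, sep="\t", index=False)
    tokens = pd.DataFrame(
        np.vectorize(_GENO_TOKENS.get)(cross.geno),
        columns=cross.markers["marker"],
    )
    data = pd.DataFrame({"individual": [f"ind{i+1}" for i in range(cross.n_individuals)]})
    data["sex"] = cross.sex if cross.sex is not None else "NA"
    data = pd.concat([data, tokens], axis=1)
    for name, values in cross.phenotypes.items():
        data[name] = values
    with open(data_path, "w") as fh:
        fh.write(f"# cross_type={cross.cross_type}\n")
        data.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_cross_tsv(map_path: str | Path, data_path: str | Path) -> CrossDataset:
    """Read a cross written by :func:`write_cross_tsv`."""
    markers = pd.read_csv(map_path, sep="\t", comment="#")
    cross_type = None
    with open(data_path) as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "cross_type=" in first:
            cross_type = first.split("cross_type=")[1].strip()
    if cross_type is None:
        raise InvalidInputError(f"{data_path}: missing '# cross_type=' header")
    data = pd.read_csv(data_path, sep="\t", comment="#", na_values=["NA"])
    marker_cols = markers["marker"].tolist()
    missing_cols = [m for m in marker_cols if m not in data.columns]
    if missing_cols:
        raise InvalidInputError(f"{data_path}: missing marker columns {missing_cols[:3]}")
    geno = np.full((len(data), len(marker_cols)), MISSING, dtype=np.int8)
    for j, m in enumerate(marker_cols):
        col = data[m]
        for i, tok in enumerate(col):
            if isinstance(tok, str):
                if tok not in _GENO_CODES:
                    raise InvalidInputError(f"{data_path}: bad genotype token {tok!r}")
                geno[i, j] = _GENO_CODES[tok]
    pheno_cols = [c for c in data.columns if c not in ("individual", "sex", *marker_cols)]
    phenotypes = {c: data[c].to_numpy(dtype=float) for c in pheno_cols}
    sex = data["sex"].astype(str).to_numpy() if "sex" in data.columns else None
    return CrossDataset(
        cross_type=cross_type, markers=markers, geno=geno, phenotypes=phenotypes, sex=sex
    )


# ---------------------------------------------------------------------------
# expression TSVs
# ---------------------------------------------------------------------------

def write_expression_tsv(
    mat: ExpressionMatrix, matrix_path: str | Path, probes_path: str | Path
) -> None:
    """Write intensities plus a probe-annotation sidecar (probe, chrom, pos)."""
    df = pd.DataFrame(mat.values, columns=mat.samples["sample"])
    df.insert(0, "probe", mat.probes["probe"].to_numpy())
    with open(matrix_path, "w") as fh:
        fh.write("# log2 intensities; groups: ")
        fh.write(",".join(f"{s}={g}" for s, g in
                          zip(mat.samples["sample"], mat.samples["group"])))
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
    with open(probes_path, "w") as fh:
        fh.write("# probe annotation\n")
        mat.probes.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_expression_tsv(matrix_path: str | Path, probes_path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix written by :func:`write_expression_tsv`."""
    groups: dict[str, str] = {}
    with open(matrix_path) as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "groups:" in first:
            spec = first.split("groups:")[1].strip()
            for pair in spec.split(","):
                s, g = pair.split("=")
                groups[s] = g
    df = pd.read_csv(matrix_path, sep="\t", comment="#", na_values=["NA"])
    probes = pd.read_csv(probes_path, sep="\t", comment="#")
    sample_ids = [c for c in df.columns if c != "probe"]
    samples = pd.DataFrame(
        {"sample": sample_ids, "group": [groups.get(s, "NA") for s in sample_ids]}
    )
    probes = probes.set_index("probe").loc[df["probe"]].reset_index()
    return ExpressionMatrix(
        probes=probes, samples=samples, values=df[sample_ids].to_numpy(dtype=float)
    )
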