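"""Synthetic data with known ground truth for every pipeline stage.

Generates a small founder pool, inbred strains as homozygous founder
mosaics (with the true segment map retained), experimental crosses with
planted additive QTLs, and expression matrices with cis effects tied to the
haplotype state at the probe position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .expression import ExpressionMatrix
from .hapmap import SDP, GenotypeTable, HaplotypeSegment
from .linkage import AA, AB, BB, F2, BACKCROSS, MISSING, CrossDataset, haldane

_BASES = np.array(list("ACGT"))


@dataclass
class FounderPool:
    """Ancestral haplotypes of the outbred colony: founder x variant alleles."""

    chrom_lengths: dict[str, int]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    alleles: np.ndarray  # uint8 (n_founders, n_variants), 0=ref-hom 1=alt-hom

    def __post_init__(self) -> None:
        if self.alleles.shape[0] < 2:
            raise InvalidArgumentError("founder pool needs >= 2 founders")

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def polymorphic(self) -> np.ndarray:
        """Boolean mask of variants segregating among the founders."""
        return self.alleles.min(axis=0) != self.alleles.max(axis=0)


@dataclass
class TrueSegmentMap:
    """Ground-truth founder of origin for every base of every strain.

    ``segments[strain][chrom]`` is an ordered list of (start, end, founder)
    tiling the chromosome, 1-based inclusive.
    """

    chrom_lengths: dict[str, int]
    segments: dict[str, dict[str, list[tuple[int, int, int]]]] = field(default_factory=dict)

    def founder_at(self, strain: str, chrom: str, pos: int) -> int:
        for start, end, f in self.segments[strain][chrom]:
            if start <= pos <= end:
                return f
        raise InvalidArgumentError(f"position {chrom}:{pos} outside chromosome")

    def divergent_intervals(self, strains: list[str] | None = None) -> dict[str, list[tuple[int, int]]]:
        """Per chromosome, merged intervals where >=2 strains carry
        different founders (the truth the segment detector should recover)."""
        names = strains if strains is not None else list(self.segments)
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, length in self.chrom_lengths.items():
            cuts = {1, length + 1}
            for s in names:
                for start, end, _ in self.segments[s][chrom]:
                    cuts.add(start)
                    cuts.add(end + 1)
            bounds = sorted(cuts)
            ivals: list[tuple[int, int]] = []
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                founders = {self.founder_at(s, chrom, lo) for s in names}
                if len(founders) > 1:
                    if ivals and ivals[-1][1] == lo - 1:
                        ivals[-1] = (ivals[-1][0], hi - 1)
                    else:
                        ivals.append((lo, hi - 1))
            out[chrom] = ivals
        return out


@dataclass
class QtlSpec:
    """A planted additive QTL.

    ``var_frac`` is the fraction of total phenotypic variance explained
    (total variance is standardized to 1); ``effect_size`` in phenotype SD
    units per allele is derived from it at simulation time if not given.
    """

    chrom: str
    pos_cM: float
    var_frac: float
    effect_size: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.var_frac < 1.0:
            raise InvalidArgumentError("var_frac must be in [0, 1)")


# ---------------------------------------------------------------------------
# founders and strains
# ---------------------------------------------------------------------------

def simulate_founder_pool(
    n_founders: int,
    chrom_lengths: dict[str, int],
    variant_density: float,
    alt_freq: float = 0.5,
    seed: int = 0,
) -> FounderPool:
    """Draw a founder pool with Poisson variant counts and i.i.d. alleles.

    Variant count per chromosome ~ Poisson(length_Mb * density); positions
    uniform; founder alleles i.i.d. Bernoulli(alt_freq).  Deterministic for
    a fixed seed.
    """
    if n_founders < 2:
        raise InvalidArgumentError("n_founders must be >= 2")
    if not chrom_lengths or any(l <= 0 for l in chrom_lengths.values()):
        raise InvalidArgumentError("chromosome lengths must be positive")
    if variant_density <= 0:
        raise InvalidArgumentError("variant_density must be positive")
    if not 0.0 < alt_freq < 1.0:
        raise InvalidArgumentError("alt_freq must be in (0, 1)")
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for c, length in chrom_lengths.items():
        n = rng.poisson(length / 1e6 * variant_density)
        pos = np.unique(rng.integers(1, length + 1, size=n))
        while len(pos) < n:  # top up collisions; rare at realistic densities
            extra = rng.integers(1, length + 1, size=n - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.append(np.full(len(pos), c, dtype=object))
        positions.append(pos)
    chrom = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    pos = np.concatenate(positions) if positions else np.array([], dtype=np.int64)
    n_var = len(pos)
    ref_idx = rng.integers(0, 4, size=n_var)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_var)) % 4
    alleles = (rng.random((n_founders, n_var)) < alt_freq).astype(np.uint8)
    return FounderPool(
        chrom_lengths=dict(chrom_lengths),
        chrom=chrom,
        pos=pos,
        ref=_BASES[ref_idx].astype(object),
        alt=_BASES[alt_idx].astype(object),
        alleles=alleles,
    )


def simulate_inbred_strains(
    pool: FounderPool,
    n_strains: int,
    mean_block_cM: float,
    cM_per_Mb: float = 1.0,
    fixed_founders: list[int] | None = None,
    seed: int = 0,
) -> tuple[GenotypeTable, TrueSegmentMap]:
    """Build inbred strains as homozygous founder mosaics.

    Breakpoints follow a Poisson process with rate 1/mean_block_cM along the
    genetic length (fixed cM/Mb conversion); the founder of each strain's
    first block is drawn once per strain (so the zero-recombination limit
    reproduces a single founder genome-wide) and subsequent blocks draw
    founders uniformly and independently.  ``fixed_founders`` pins every
    block of strain i to ``fixed_founders[i]``.  Returns the genotype table
    and the true per-base founder map.
    """
    if pool.n_variants == 0:
        raise InvalidArgumentError("founder pool has no variants")
    if n_strains < 2:
        raise InvalidArgumentError("n_strains must be >= 2")
    if mean_block_cM <= 0 or cM_per_Mb <= 0:
        raise InvalidArgumentError("mean_block_cM and cM_per_Mb must be positive")
    if fixed_founders is not None and len(fixed_founders) != n_strains:
        raise InvalidArgumentError("fixed_founders must list one founder per strain")
    rng = np.random.default_rng(seed)
    strains = [f"S{i+1:02d}" for i in range(n_strains)]
    truth = TrueSegmentMap(chrom_lengths=dict(pool.chrom_lengths))
    calls = np.empty((n_strains, pool.n_variants), dtype=np.uint8)
    for i, name in enumerate(strains):
        truth.segments[name] = {}
        base_founder = int(rng.integers(0, pool.n_founders))
        for c, length in pool.chrom_lengths.items():
            genetic_len = length / 1e6 * cM_per_Mb
            n_bp = rng.poisson(genetic_len / mean_block_cM)
            bp_cm = np.sort(rng.uniform(0, genetic_len, size=n_bp))
            bp_bp = np.unique(np.floor(bp_cm / cM_per_Mb * 1e6).astype(np.int64))
            bp_bp = bp_bp[(bp_bp >= 1) & (bp_bp < length)]
            starts = np.concatenate(([1], bp_bp + 1))
            ends = np.concatenate((bp_bp, [length]))
            founders = np.concatenate(
                ([base_founder], rng.integers(0, pool.n_founders, size=len(starts) - 1))
            )
            if fixed_founders is not None:
                founders = np.full(len(starts), fixed_founders[i])
            truth.segments[name][c] = [
                (int(s), int(e), int(f)) for s, e, f in zip(starts, ends, founders)
            ]
            vmask = pool.chrom == c
            vpos = pool.pos[vmask]
            # founder of origin per variant: locate the containing block
            block = np.searchsorted(ends, vpos, side="left")
            calls[i, vmask] = pool.alleles[founders[block], np.flatnonzero(vmask)]
    geno = GenotypeTable(
        strains=strains,
        chrom=pool.chrom.copy(),
        pos=pool.pos.copy(),
        ref=pool.ref.copy(),
        alt=pool.alt.copy(),
        calls=calls,
    )
    return geno, truth


# ---------------------------------------------------------------------------
# crosses
# ---------------------------------------------------------------------------

def _simulate_gametes(
    rng: np.random.Generator, n: int, cm: np.ndarray, n_gametes: int
) -> np.ndarray:
    """Markov chain of parental-origin alleles along one chromosome.

    Returns uint8 (n, n_loci, n_gametes); allele 1 = second-parent origin.
    Switch probability between adjacent loci is the Haldane recombination
    fraction.
    """
    n_loci = len(cm)
    r = haldane(np.diff(cm))
    g = np.empty((n, n_loci, n_gametes), dtype=np.uint8)
    g[:, 0, :] = rng.random((n, n_gametes)) < 0.5
    for t in range(1, n_loci):
        switch = rng.random((n, n_gametes)) < r[t - 1]
        g[:, t, :] = g[:, t - 1, :] ^ switch
    return g


def simulate_cross(
    cross_type: str,
    n_individuals: int,
    marker_map: dict[str, list[float]],
    qtls: list[QtlSpec] | None = None,
    polygenic_sd: float = 0.0,
    residual_sd: float | None = None,
    missing_rate: float = 0.0,
    phenotype_name: str = "trait",
    seed: int = 0,
) -> CrossDataset:
    """Simulate an F2 or backcross with planted additive QTLs.

    Genotypes arise from a Markov walk along each chromosome with Haldane
    recombination fractions; QTLs are simulated as hidden loci and dropped
    from the marker set.  Phenotype = sum of additive QTL effects (dosage
    coded -1/0/+1 for F2, -1/2/+1/2 for backcross) + N(0, polygenic_sd) +
    N(0, residual_sd); when ``residual_sd`` is None it is chosen so total
    variance is 1 and each QTL's ``var_frac`` holds.
    """
    qtls = list(qtls or [])
    if cross_type not in (F2, BACKCROSS):
        raise InvalidArgumentError(f"unknown cross type {cross_type!r}")
    if n_individuals < 1:
        raise InvalidArgumentError("n_individuals must be >= 1")
    if polygenic_sd < 0 or not 0.0 <= missing_rate < 1.0:
        raise InvalidArgumentError("bad polygenic_sd or missing_rate")
    for c, cms in marker_map.items():
        if any(b < a for a, b in zip(cms, cms[1:])):
            raise InvalidArgumentError(f"markers not sorted on chromosome {c}")
    for q in qtls:
        if q.chrom not in marker_map:
            raise InvalidArgumentError(f"QTL chromosome {q.chrom!r} has no markers")
        lo, hi = marker_map[q.chrom][0], marker_map[q.chrom][-1]
        if not lo <= q.pos_cM <= hi:
            raise InvalidArgumentError("QTL position outside the marker map range")

    # additive dosage coding variance: F2 -1/0/+1 (1:2:1) -> 0.5; BC -> 0.25
    var_x = 0.5 if cross_type == F2 else 0.25
    total_frac = sum(q.var_frac for q in qtls)
    if total_frac + polygenic_sd**2 >= 1.0 and residual_sd is None:
        raise InvalidArgumentError(
            "QTL variance fractions plus polygenic variance must sum to < 1"
        )
    effects = [
        q.effect_size if q.effect_size is not None else float(np.sqrt(q.var_frac / var_x))
        for q in qtls
    ]
    if residual_sd is None:
        resid_var = 1.0 - sum(e**2 * var_x for e in effects) - polygenic_sd**2
        residual_sd = float(np.sqrt(max(resid_var, 0.0)))

    rng = np.random.default_rng(seed)
    n_gametes = 2 if cross_type == F2 else 1
    marker_ids: list[str] = []
    marker_chrom: list[str] = []
    marker_cm: list[float] = []
    geno_cols: list[np.ndarray] = []
    genetic = np.zeros(n_individuals)
    for c, cms in marker_map.items():
        qtl_here = [(q, e) for q, e in zip(qtls, effects) if q.chrom == c]
        loci = sorted(set(cms) | {q.pos_cM for q, _ in qtl_here})
        loci_arr = np.array(loci, dtype=float)
        g = _simulate_gametes(rng, n_individuals, loci_arr, n_gametes)
        dosage = g.sum(axis=2)  # copies of second-parent allele
        for q, e in qtl_here:
            k = loci.index(q.pos_cM)
            x = dosage[:, k] - (1.0 if cross_type == F2 else 0.5)
            genetic += e * x
        for j, cm in enumerate(cms):
            k = loci.index(cm)
            marker_ids.append(f"c{c}m{j+1}")
            marker_chrom.append(c)
            marker_cm.append(cm)
            geno_cols.append(dosage[:, k].astype(np.int8))

    geno = (
        np.column_stack(geno_cols) if geno_cols else np.zeros((n_individuals, 0), np.int8)
    )
    if missing_rate > 0 and geno.size:
        geno[rng.random(geno.shape) < missing_rate] = MISSING

    y = genetic
    if polygenic_sd > 0:
        y = y + rng.normal(0.0, polygenic_sd, size=n_individuals)
    y = y + rng.normal(0.0, residual_sd, size=n_individuals)
    sex = np.where(rng.random(n_individuals) < 0.5, "M", "F")
    markers = pd.DataFrame({"marker": marker_ids, "chrom": marker_chrom, "cM": marker_cm})
    return CrossDataset(
        cross_type=cross_type,
        markers=markers,
        geno=geno,
        phenotypes={phenotype_name: y},
        sex=sex,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    geno: GenotypeTable,
    segments: list[HaplotypeSegment],
    catalog: list[SDP],
    probes: list[tuple[str, str, int, float]],
    n_replicates: int,
    noise_sd: float,
    baseline: float = 8.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression with cis effects tied to the haplotype state at the probe.

    ``probes`` holds (probe id, chrom, pos, effect log2FC).  For a probe
    inside haplotype segments, each strain's intensity is shifted by
    effect x (the strain's summed SDP allele over all containing segments —
    its haplotype state at the position); probes outside every segment get
    no genetic effect.  Every strain contributes ``n_replicates`` arrays
    with N(0, noise_sd) noise.
    """
    if n_replicates < 2:
        raise InvalidArgumentError("n_replicates must be >= 2 (tests need variance)")
    chrom_set = set(geno.chromosomes)
    for pid, chrom, _, _ in probes:
        if chrom not in chrom_set:
            raise InvalidArgumentError(f"probe {pid!r} on unknown chromosome {chrom!r}")
    rng = np.random.default_rng(seed)
    n_strains = geno.n_strains
    sample_ids = [
        f"{s}_r{r+1}" for s in geno.strains for r in range(n_replicates)
    ]
    groups = [s for s in geno.strains for _ in range(n_replicates)]
    values = np.empty((len(probes), len(sample_ids)))
    rows = []
    for i, (pid, chrom, pos, effect) in enumerate(probes):
        state = np.zeros(n_strains)
        for seg in segments:
            if seg.contains(chrom, pos):
                state += np.asarray(catalog[seg.sdp_id].pattern, dtype=float)
        shift = effect * state
        mean = baseline + np.repeat(shift, n_replicates)
        values[i] = mean + rng.normal(0.0, noise_sd, size=len(sample_ids))
        rows.append((pid, chrom, pos))
    probes_df = pd.DataFrame(rows, columns=["probe", "chrom", "pos"])
    samples_df = pd.DataFrame({"sample": sample_ids, "group": groups})
    return ExpressionMatrix(probes=probes_df, samples=samples_df, values=values)
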