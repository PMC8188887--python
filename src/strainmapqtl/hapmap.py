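"""Ancestral haplotype map reconstruction from inbred-strain genotypes.

An inbred strain panel descended from a single outbred colony is a mosaic of
a small number of ancestral haplotypes.  Within a conserved tract every
bi-allelic variant splits the panel the same way, so tracts are detectable as
dense runs of variants sharing one strain distribution pattern (SDP).  This
module enumerates canonical SDPs, detects haplotype segments as gapped runs
of same-SDP variants, tiles the genome into regions by haplotype-class count,
and derives pairwise inter-strain diversity and cis-candidacy from the
segment set.

Coordinates are 1-based inclusive throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, InvalidInputError

MONOMORPHIC = -1  # assignment value for variants identical in all strains


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Strains x variants matrix of homozygous biallelic calls.

    ``calls[i, j]`` is 0 (reference homozygote) or 1 (alternate homozygote)
    for strain ``strains[i]`` at variant ``j``.  Variants must be sorted by
    chromosome with strictly increasing positions within each chromosome;
    heterozygous or missing calls are not representable and must be filtered
    upstream.
    """

    strains: list[str]
    chrom: np.ndarray  # str, per variant
    pos: np.ndarray    # int bp, 1-based
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray  # uint8 (n_strains, n_variants), values in {0, 1}

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.shape != (len(self.strains), len(self.pos)):
            raise InvalidInputError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.strains)} strains x {len(self.pos)} variants"
            )
        if self.calls.size and not np.isin(self.calls, (0, 1)).all():
            raise InvalidInputError(
                "calls must be 0 (ref-hom) or 1 (alt-hom); heterozygous or "
                "missing genotypes must be filtered before building the table"
            )
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise InvalidInputError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def strain_index(self, name: str) -> int:
        try:
            return self.strains.index(name)
        except ValueError:
            raise InvalidArgumentError(f"unknown strain id: {name!r}") from None

    def subset_strains(self, names: list[str]) -> "GenotypeTable":
        """Restrict the table to ``names`` (SDPs must be re-enumerated)."""
        idx = [self.strain_index(n) for n in names]
        return GenotypeTable(
            strains=list(names),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=np.asarray(self.ref, dtype=object).copy(),
            alt=np.asarray(self.alt, dtype=object).copy(),
            calls=self.calls[idx],
        )


@dataclass(frozen=True)
class SDP:
    """A canonical strain distribution pattern (bipartition of the panel).

    ``pattern[k]`` gives the allele class of strain k; the pattern is
    canonicalized so the first strain carries 0, merging each bipartition
    with its ref/alt complement.
    """

    id: int
    pattern: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pattern[0] != 0:
            raise InvalidInputError("canonical SDP must assign 0 to the first strain")
        if not (0 < sum(self.pattern) < len(self.pattern)):
            raise InvalidInputError("SDP must be non-trivial (both classes present)")

    def splits(self, i: int, j: int) -> bool:
        """True iff strains i and j fall on opposite sides of the bipartition."""
        return self.pattern[i] != self.pattern[j]


@dataclass(frozen=True)
class SegmentationParams:
    """Run/gap thresholds for segment detection.

    A segment needs at least ``min_run`` supporting variants, and two
    consecutive supporting variants may be separated by strictly fewer than
    ``max_gap`` non-SDP polymorphic variants.
    """

    min_run: int = 20
    max_gap: int = 100

    def __post_init__(self) -> None:
        if self.min_run < 2:
            raise InvalidArgumentError("min_run must be >= 2")
        if self.max_gap < 1:
            raise InvalidArgumentError("max_gap must be >= 1")


@dataclass(frozen=True)
class HaplotypeSegment:
    """A detected run of same-SDP variants: one ancestral haplotype tract."""

    chrom: str
    start: int  # bp of first supporting variant, 1-based inclusive
    end: int    # bp of last supporting variant, 1-based inclusive
    sdp_id: int
    n_support: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidInputError("segment start must be <= end")

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    segment_ids: tuple[int, ...]      # indices into the segment list
    class_count_joint: int            # distinct joint strain patterns
    class_count_paper: int            # overlapping segments + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionMap:
    """Tiling of each chromosome into regions of constant segment overlap."""

    regions: dict[str, list[Region]] = field(default_factory=dict)

    def summary(self) -> dict[int, int]:
        """Cumulative bp per ``class_count_paper``."""
        out: dict[int, int] = {}
        for regs in self.regions.values():
            for r in regs:
                out[r.class_count_paper] = out.get(r.class_count_paper, 0) + r.length
        return dict(sorted(out.items()))

    def total_length(self) -> int:
        return sum(r.length for regs in self.regions.values() for r in regs)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def enumerate_sdps(geno: GenotypeTable) -> tuple[list[SDP], np.ndarray]:
    """Enumerate canonical SDPs and assign each variant to one.

    Returns the SDP catalog (first-appearance order) and a per-variant
    assignment array holding the SDP id, or ``MONOMORPHIC`` for variants at
    which all strains agree.  Patterns are canonicalized by flipping alleles
    so the first strain carries 0, which merges ref/alt complements.
    """
    calls = geno.calls
    if calls.shape[0] < 2:
        raise InvalidArgumentError("need at least two strains to define SDPs")
    # flip columns where the first strain carries the alternate allele
    canon = calls ^ calls[0]
    assignment = np.full(geno.n_variants, MONOMORPHIC, dtype=np.int64)
    catalog: list[SDP] = []
    index: dict[bytes, int] = {}
    poly = canon.any(axis=0)  # canonical all-zero column <=> monomorphic
    for j in np.flatnonzero(poly):
        key = canon[:, j].tobytes()
        sdp_id = index.get(key)
        if sdp_id is None:
            sdp_id = len(catalog)
            index[key] = sdp_id
            catalog.append(SDP(id=sdp_id, pattern=tuple(int(x) for x in canon[:, j])))
        assignment[j] = sdp_id
    return catalog, assignment


def detect_segments(
    geno: GenotypeTable,
    assignment: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> list[HaplotypeSegment]:
    """Detect haplotype segments as gapped runs of same-SDP variants.

    For each SDP independently and per chromosome, maximal runs of its
    variants in which every pair of consecutive supporting variants is
    separated by fewer than ``params.max_gap`` non-SDP polymorphic variants,
    with run length >= ``params.min_run``, become segments.  Monomorphic
    variants never count toward gaps (they were never retained as SDP
    material); segments of different SDPs may overlap.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != geno.n_variants:
        raise InvalidInputError("assignment length does not match variant count")
    segments: list[HaplotypeSegment] = []
    for c in geno.chromosomes:
        mask = geno.chrom == c
        assign_c = assignment[mask]
        pos_c = geno.pos[mask]
        # prefix[k] = number of polymorphic variants among the first k
        prefix = np.concatenate(([0], np.cumsum(assign_c != MONOMORPHIC)))
        for sdp_id in np.unique(assign_c):
            if sdp_id == MONOMORPHIC:
                continue
            support = np.flatnonzero(assign_c == sdp_id)
            # polymorphic variants strictly between consecutive supports
            gaps = prefix[support[1:]] - prefix[support[:-1] + 1]
            breaks = np.flatnonzero(gaps >= params.max_gap)
            run_starts = np.concatenate(([0], breaks + 1))
            run_ends = np.concatenate((breaks, [len(support) - 1]))
            for a, b in zip(run_starts, run_ends):
                n = b - a + 1
                if n >= params.min_run:
                    segments.append(
                        HaplotypeSegment(
                            chrom=c,
                            start=int(pos_c[support[a]]),
                            end=int(pos_c[support[b]]),
                            sdp_id=int(sdp_id),
                            n_support=int(n),
                        )
                    )
    segments.sort(key=lambda s: (geno.chromosomes.index(s.chrom), s.start, s.end, s.sdp_id))
    return segments


def build_region_map(
    segments: list[HaplotypeSegment],
    chrom_lengths: dict[str, int],
    catalog: list[SDP],
) -> tuple[RegionMap, dict[int, int]]:
    """Tile each chromosome into regions of constant segment overlap.

    Chromosomes are split at every segment start and at end+1; per region two
    class counts are reported: ``class_count_paper`` = (#overlapping
    segments)+1 and ``class_count_joint`` = number of distinct joint strain
    patterns over the overlapping SDPs (1 when none overlap).  Also returns
    the cumulative-length table keyed by ``class_count_paper``.
    """
    by_chrom: dict[str, list[tuple[int, HaplotypeSegment]]] = {c: [] for c in chrom_lengths}
    for i, s in enumerate(segments):
        if s.chrom not in chrom_lengths:
            raise InvalidInputError(f"segment on unknown chromosome {s.chrom!r}")
        if s.end > chrom_lengths[s.chrom]:
            raise InvalidInputError(
                f"segment end {s.end} beyond chromosome {s.chrom} length "
                f"{chrom_lengths[s.chrom]}"
            )
        by_chrom[s.chrom].append((i, s))

    rmap = RegionMap()
    for c, length in chrom_lengths.items():
        if length <= 0:
            raise InvalidArgumentError(f"non-positive length for chromosome {c!r}")
        cuts = {1, length + 1}
        for _, s in by_chrom[c]:
            cuts.add(s.start)
            cuts.add(s.end + 1)
        bounds = sorted(b for b in cuts if 1 <= b <= length + 1)
        regions: list[Region] = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            start, end = lo, hi - 1
            overlapping = [
                (i, s) for i, s in by_chrom[c] if s.start <= start and s.end >= start
            ]
            ids = tuple(i for i, _ in overlapping)
            if overlapping:
                pats = np.array([catalog[s.sdp_id].pattern for _, s in overlapping])
                joint = len({tuple(col) for col in pats.T})
            else:
                joint = 1
            regions.append(
                Region(
                    chrom=c,
                    start=start,
                    end=end,
                    segment_ids=ids,
                    class_count_joint=joint,
                    class_count_paper=len(ids) + 1,
                )
            )
        rmap.regions[c] = regions
    return rmap, rmap.summary()


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals; input need not be sorted."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def divergent_segments(
    segments: list[HaplotypeSegment],
    catalog: list[SDP],
    strains: list[str],
    strain_a: str,
    strain_b: str,
) -> list[HaplotypeSegment]:
    """Segments whose SDP assigns different alleles to the two strains."""
    try:
        ia, ib = strains.index(strain_a), strains.index(strain_b)
    except ValueError as exc:
        raise InvalidArgumentError(f"unknown strain id: {exc}") from None
    return [s for s in segments if catalog[s.sdp_id].splits(ia, ib)]


def pairwise_diversity(
    segments: list[HaplotypeSegment],
    catalog: list[SDP],
    strains: list[str],
    strain_a: str,
    strain_b: str,
    chrom_lengths: dict[str, int],
    normalize: str = "genome",
) -> float:
    """Fraction of the genome covered by segments separating two strains.

    Overlapping divergent segments are merged before summing.  With
    ``normalize="genome"`` (default) the union length is divided by total
    genome length; ``normalize="covered"`` divides by the union length of all
    segments instead.
    """
    if normalize not in ("genome", "covered"):
        raise InvalidArgumentError("normalize must be 'genome' or 'covered'")
    div = divergent_segments(segments, catalog, strains, strain_a, strain_b)

    def union_length(segs: list[HaplotypeSegment]) -> int:
        total = 0
        for c in chrom_lengths:
            merged = _merge_intervals(
                [(s.start, s.end) for s in segs if s.chrom == c]
            )
            total += sum(e - s + 1 for s, e in merged)
        return total

    if normalize == "genome":
        denom = sum(chrom_lengths.values())
    else:
        denom = union_length(list(segments))
    if denom == 0:
        return 0.0
    return union_length(div) / denom


def classify_cis(
    position: tuple[str, int],
    segments: list[HaplotypeSegment],
    catalog: list[SDP],
    strains: list[str],
    strain_a: str,
    strain_b: str,
) -> bool:
    """True iff the position lies in >=1 segment whose SDP splits the pair."""
    chrom, bp = position
    return any(
        s.contains(chrom, bp)
        for s in divergent_segments(segments, catalog, strains, strain_a, strain_b)
    )
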