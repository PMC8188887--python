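"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately naive (explicit loops, base-resolution
scans) and shares no code with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np


def brute_sdp_catalog(calls: np.ndarray) -> tuple[list[tuple[int, ...]], list[int]]:
    """Distinct canonical bipartitions in first-appearance order.

    Returns (patterns, per-variant assignment with -1 for monomorphic).
    """
    patterns: list[tuple[int, ...]] = []
    assignment: list[int] = []
    for j in range(calls.shape[1]):
        col = [int(x) for x in calls[:, j]]
        if col[0] == 1:
            col = [1 - x for x in col]
        if all(x == 0 for x in col):
            assignment.append(-1)
            continue
        pat = tuple(col)
        if pat not in patterns:
            patterns.append(pat)
        assignment.append(patterns.index(pat))
    return patterns, assignment


def brute_segments(
    chrom: np.ndarray,
    pos: np.ndarray,
    assignment: np.ndarray,
    min_run: int,
    max_gap: int,
) -> set[tuple[str, int, int, int, int]]:
    """Direct scan for gapped same-SDP runs.

    Returns a set of (chrom, start, end, sdp_id, n_support).
    """
    out: set[tuple[str, int, int, int, int]] = set()
    for c in dict.fromkeys(chrom):
        idx = [i for i in range(len(pos)) if chrom[i] == c]
        for sdp in sorted({int(a) for a in assignment if a >= 0}):
            support = [i for i in idx if assignment[i] == sdp]
            runs: list[list[int]] = []
            for i in support:
                if runs:
                    prev = runs[-1][-1]
                    gap = sum(
                        1 for k in idx if prev < k < i and assignment[k] >= 0
                    )
                    if gap < max_gap:
                        runs[-1].append(i)
                        continue
                runs.append([i])
            for run in runs:
                if len(run) >= min_run:
                    out.add((c, int(pos[run[0]]), int(pos[run[-1]]), sdp, len(run)))
    return out


def positional_class_count(
    segments, catalog, n_strains: int, chrom: str, bp: int
) -> int:
    """Distinct strain haplotype vectors at one base (joint-class oracle)."""
    vectors = set()
    for s_idx in range(n_strains):
        vec = tuple(
            catalog[seg.sdp_id].pattern[s_idx]
            for seg in segments
            if seg.chrom == chrom and seg.start <= bp <= seg.end
        )
        vectors.add(vec)
    return len(vectors)


def base_resolution_diversity(
    segments, catalog, strains, a: str, b: str, chrom_lengths
) -> float:
    """Per-base scan of divergent coverage (only usable on tiny genomes)."""
    ia, ib = strains.index(a), strains.index(b)
    covered = 0
    for c, length in chrom_lengths.items():
        for bp in range(1, length + 1):
            for seg in segments:
                if (
                    seg.chrom == c
                    and seg.start <= bp <= seg.end
                    and catalog[seg.sdp_id].pattern[ia] != catalog[seg.sdp_id].pattern[ib]
                ):
                    covered += 1
                    break
    return covered / sum(chrom_lengths.values())


def stab_intervals(position, segments, catalog, strains, a: str, b: str) -> bool:
    """Interval-stabbing cis oracle."""
    chrom, bp = position
    ia, ib = strains.index(a), strains.index(b)
    for seg in segments:
        if (
            seg.chrom == chrom
            and seg.start <= bp <= seg.end
            and catalog[seg.sdp_id].pattern[ia] != catalog[seg.sdp_id].pattern[ib]
        ):
            return True
    return False


def f2_midpoint_posterior(d_left_cM: float, d_right_cM: float, g_left: int, g_right: int) -> np.ndarray:
    """Exact 3-state conditional P(mid | flanking genotypes), error-free.

    Enumerates the two-step chain with the F2 (two-meiosis) transition
    matrix built from Haldane recombination fractions.
    """

    def trans(d):
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        return np.array(
            [
                [(1 - r) ** 2, 2 * r * (1 - r), r * r],
                [r * (1 - r), (1 - r) ** 2 + r * r, r * (1 - r)],
                [r * r, 2 * r * (1 - r), (1 - r) ** 2],
            ]
        )

    tl, tr = trans(d_left_cM), trans(d_right_cM)
    probs = np.array([tl[g_left, m] * tr[m, g_right] for m in range(3)])
    return probs / probs.sum()


def interval_jaccard(set_a: list[tuple[int, int]], set_b: list[tuple[int, int]], length: int) -> float:
    """Jaccard overlap of two 1-based inclusive interval sets, per-base."""
    mask_a = np.zeros(length + 1, dtype=bool)
    mask_b = np.zeros(length + 1, dtype=bool)
    for s, e in set_a:
        mask_a[s : e + 1] = True
    for s, e in set_b:
        mask_b[s : e + 1] = True
    union = (mask_a | mask_b).sum()
    if union == 0:
        return 1.0
    return (mask_a & mask_b).sum() / union
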