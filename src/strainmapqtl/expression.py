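"""Microarray differential expression and cis annotation.

Probe filtering by call rate, across-array quantile normalization, two-group
linear-model testing on log2 intensities (with optional variance
moderation), Benjamini-Hochberg FDR, the two-comparison shared/non-shared
classification, and cis flagging of probes via the haplotype segment map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, InvalidInputError, InvalidStateError
from .hapmap import SDP, HaplotypeSegment, classify_cis

logger = logging.getLogger(__name__)

SHARED = "shared"
NONSHARED_A = "non-shared-A"
NONSHARED_B = "non-shared-B"
NONE = "none"


@dataclass
class ExpressionMatrix:
    """Probe x sample log2 intensity matrix with probe coordinates.

    ``probes`` columns: probe, chrom, pos (and optional bool ``flagged`` for
    platform-level low-quality calls); ``samples`` columns: sample, group.
    Missing intensities are NaN; flagged cells count as missing for call
    rates.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    values: np.ndarray  # float (n_probes, n_samples), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), len(self.samples)):
            raise InvalidInputError("intensity matrix does not match probe/sample tables")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def group_columns(self, group: str) -> np.ndarray:
        cols = np.flatnonzero((self.samples["group"] == group).to_numpy())
        if len(cols) == 0:
            raise InvalidArgumentError(f"no samples in group {group!r}")
        return cols


def filter_probes(mat: ExpressionMatrix, min_call_rate: float = 0.5) -> ExpressionMatrix:
    """Drop probes whose call fraction is below ``min_call_rate``.

    A call is a non-missing intensity; probes called in exactly
    ``min_call_rate`` of samples are retained (strict '<' removal).
    """
    called = ~np.isnan(mat.values)
    rate = called.mean(axis=1)
    keep = rate >= min_call_rate
    n_removed = int((~keep).sum())
    logger.info("filter_probes: removed %d of %d probes", n_removed, mat.n_probes)
    if not keep.any():
        raise InvalidStateError("call-rate filter removed every probe")
    return ExpressionMatrix(
        probes=mat.probes.loc[keep].reset_index(drop=True),
        samples=mat.samples.copy(),
        values=mat.values[keep],
    )


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean distribution.

    Each sample's order statistics are replaced by the mean of order
    statistics across samples; ties receive the mean of their would-be
    quantiles; missing values stay missing and are excluded from the
    reference.  Rank order within each sample is preserved.
    """
    if len(mat.samples) < 2:
        raise InvalidArgumentError("quantile normalization needs >= 2 samples")
    V = mat.values
    n_probes, n_samples = V.shape
    # reference quantile function on a common grid, averaging the per-sample
    # empirical quantile functions (handles unequal missingness)
    grid = (np.arange(n_probes) + 0.5) / n_probes
    ref = np.zeros(n_probes)
    for j in range(n_samples):
        col = np.sort(V[~np.isnan(V[:, j]), j])
        if len(col) == 0:
            raise InvalidInputError(f"sample {mat.samples['sample'].iat[j]!r} is all-missing")
        q = (np.arange(len(col)) + 0.5) / len(col)
        ref += np.interp(grid, q, col)
    ref /= n_samples

    out = np.full_like(V, np.nan)
    for j in range(n_samples):
        ok = ~np.isnan(V[:, j])
        n = int(ok.sum())
        ranks = stats.rankdata(V[ok, j], method="average")  # ties -> mean quantile
        out[ok, j] = np.interp((ranks - 0.5) / n, grid, ref)
    return ExpressionMatrix(probes=mat.probes.copy(), samples=mat.samples.copy(), values=out)


def differential_expression(
    mat: ExpressionMatrix,
    group_a: str,
    group_b: str,
    moderation: bool = False,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-probe two-group linear model on log2 intensities.

    Returns a table with log2FC (mean A - mean B), t, p (two-sided) per
    probe.  With ``moderation`` the per-probe variance is shrunk toward the
    across-probe trimmed-mean variance with ``prior_df`` prior degrees of
    freedom before computing t.  Probes with zero pooled within-group
    variance fall back to the across-probe pooled variance and are flagged.
    """
    ca = mat.group_columns(group_a)
    cb = mat.group_columns(group_b)
    if len(ca) < 2 or len(cb) < 2:
        raise InvalidArgumentError("need >= 2 samples per group")
    A, B = mat.values[:, ca], mat.values[:, cb]
    na = (~np.isnan(A)).sum(axis=1)
    nb = (~np.isnan(B)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(A, axis=1)
        mb = np.nanmean(B, axis=1)
        va = np.nanvar(A, axis=1, ddof=1)
        vb = np.nanvar(B, axis=1, ddof=1)
    lfc = ma - mb
    df = na + nb - 2
    pooled = ((na - 1) * np.nan_to_num(va) + (nb - 1) * np.nan_to_num(vb)) / np.maximum(df, 1)

    fallback = pooled <= 0
    if fallback.any():
        good = pooled[~fallback]
        global_var = float(np.mean(good)) if len(good) else 1e-12
        pooled = np.where(fallback, max(global_var, 1e-12), pooled)

    if moderation:
        good = pooled[pooled > 0]
        s0 = float(stats.trim_mean(good, 0.1)) if len(good) else 1e-12
        pooled = (prior_df * s0 + df * pooled) / (prior_df + df)
        df = df + prior_df

    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "probe": mat.probes["probe"].to_numpy(),
            "log2fc": lfc,
            "t": t,
            "p": p,
            "var_fallback": fallback,
        }
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise InvalidInputError("p-values must lie in (0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_shared_nonshared(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    shared_p: float = 1e-4,
    nonshared_p: float = 1e-8,
    other_p: float = 0.05,
) -> pd.DataFrame:
    """Two-comparison shared / non-shared classification per probe.

    shared: p < ``shared_p`` in both comparisons with concordant direction.
    non-shared-A: p_A < ``nonshared_p`` while B is not differential
    (p_B >= ``other_p`` with concordant direction, or any p_B with opposite
    direction); non-shared-B symmetric.  Everything else: none.  Direction is
    the sign of log2FC; a zero log2FC under a sub-threshold p is invalid.
    """
    a = res_a.set_index("probe")
    b = res_b.set_index("probe")
    if set(a.index) != set(b.index):
        raise InvalidInputError("the two comparisons must cover the same probes")
    b = b.loc[a.index]
    pa, pb = a["p"].to_numpy(), b["p"].to_numpy()
    da, db = np.sign(a["log2fc"].to_numpy()), np.sign(b["log2fc"].to_numpy())
    needs_dir = (pa < max(shared_p, nonshared_p)) | (pb < max(shared_p, nonshared_p))
    if ((da == 0) & needs_dir & (pa < shared_p)).any() or (
        (db == 0) & needs_dir & (pb < shared_p)
    ).any():
        raise InvalidInputError("zero log2FC with p below threshold: direction undefined")
    concordant = da * db > 0
    opposite = da * db < 0
    shared = (pa < shared_p) & (pb < shared_p) & concordant
    ns_a = (pa < nonshared_p) & (((pb >= other_p) & concordant) | opposite)
    ns_b = (pb < nonshared_p) & (((pa >= other_p) & concordant) | opposite)
    category = np.where(
        shared, SHARED,
        np.where(ns_a & ~ns_b, NONSHARED_A,
                 np.where(ns_b & ~ns_a, NONSHARED_B, NONE)),
    )
    return pd.DataFrame({"probe": a.index.to_numpy(), "category": category})


def annotate_cis(
    de: pd.DataFrame,
    probes: pd.DataFrame,
    segments: list[HaplotypeSegment],
    catalog: list[SDP],
    strains: list[str],
    strain_a: str,
    strain_b: str,
) -> pd.DataFrame:
    """Flag probes lying in haplotype segments that split the strain pair.

    ``de`` must carry a ``probe`` column; ``probes`` maps probe -> (chrom,
    pos).  Probes without coordinates are marked unannotated (cis = NA) and
    excluded from the per-category cis fractions, which are attached to the
    returned frame as ``.attrs["cis_summary"]``.
    """
    coords = probes.set_index("probe")
    out = de.copy()
    cis: list[object] = []
    for probe in out["probe"]:
        if probe not in coords.index or pd.isna(coords.at[probe, "chrom"]):
            cis.append(pd.NA)
            continue
        pos = (str(coords.at[probe, "chrom"]), int(coords.at[probe, "pos"]))
        cis.append(classify_cis(pos, segments, catalog, strains, strain_a, strain_b))
    out["cis"] = pd.array(cis, dtype="boolean")
    summary = {}
    if "category" in out.columns:
        for cat, grp in out.dropna(subset=["cis"]).groupby("category"):
            n = len(grp)
            k = int(grp["cis"].sum())
            summary[cat] = {"n": n, "cis": k, "fraction": k / n if n else float("nan")}
    out.attrs["cis_summary"] = summary
    return out
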