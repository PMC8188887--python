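"""Genome scans in experimental crosses and fixed-effect meta-analysis.

Per cross: genotype posteriors on a cM grid from a forward-backward HMM
(Haldane map function, genotyping-error emission), then an additive-model
score test realized as OLS of the (quantile-normalized) phenotype on the
posterior-expected allele dosage.  Across crosses: inverse-variance
fixed-effect combination with Cochran's Q heterogeneity, which also powers
the background-stratified epistasis screen.

Genotype codes are integers: 0=AA, 1=AB, 2=BB, -1=missing.  AA means
homozygous for the first (recurrent / hypertensive by convention) parental
strain; dosage counts the second parent's alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, InvalidInputError

F2 = "F2"
BACKCROSS = "backcross"

AA, AB, BB, MISSING = 0, 1, 2, -1

#: genome-wide significance threshold on |Z|, equivalent to P < 1e-4
Z_THRESHOLD = 3.89


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CrossDataset:
    """Marker genotypes, genetic map and phenotypes for one cross.

    ``geno[i, m]`` holds the integer genotype code of individual ``i`` at
    marker ``m``; ``markers`` has columns (marker, chrom, cM) sorted by
    chromosome with non-decreasing cM.
    """

    cross_type: str
    markers: pd.DataFrame            # columns: marker, chrom, cM
    geno: np.ndarray                 # int8 (n_ind, n_markers)
    phenotypes: dict[str, np.ndarray]
    sex: np.ndarray | None = None    # str per individual, optional

    def __post_init__(self) -> None:
        if self.cross_type not in (F2, BACKCROSS):
            raise InvalidArgumentError(f"unknown cross type {self.cross_type!r}")
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2 or self.geno.shape[1] != len(self.markers):
            raise InvalidInputError("genotype matrix does not match marker table")
        legal = {AA, AB, BB, MISSING} if self.cross_type == F2 else {AA, AB, MISSING}
        observed = set(np.unique(self.geno).tolist())
        if not observed <= legal:
            raise InvalidInputError(
                f"illegal genotype codes {observed - legal} for {self.cross_type}"
            )
        for _, grp in self.markers.groupby("chrom", sort=False):
            d = np.diff(grp["cM"].to_numpy())
            if len(d) and (d < 0).any():
                raise InvalidInputError("cM positions must be non-decreasing per chromosome")

    @property
    def n_individuals(self) -> int:
        return self.geno.shape[0]

    @property
    def n_states(self) -> int:
        return 3 if self.cross_type == F2 else 2


@dataclass(frozen=True)
class HmmParams:
    """Genotyping-error rate and pseudomarker grid step for the HMM."""

    error_rate: float = 0.01
    grid_step: float = 0.5  # cM

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise InvalidArgumentError("error_rate must be in [0, 0.5)")
        if self.grid_step <= 0:
            raise InvalidArgumentError("grid_step must be positive")


@dataclass
class GenotypeProbGrid:
    """Posterior genotype probabilities on a cM grid, one cross."""

    cross_type: str
    loci: pd.DataFrame               # columns: chrom, cM, is_marker
    posteriors: np.ndarray           # (n_ind, n_loci, n_states)
    dosage: np.ndarray = field(init=False)  # expected count of 2nd-parent alleles

    def __post_init__(self) -> None:
        state_dosage = (
            np.array([0.0, 1.0, 2.0]) if self.cross_type == F2 else np.array([0.0, 1.0])
        )
        self.dosage = self.posteriors @ state_dosage


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance fixed-effect combination of one locus across strata."""

    beta: float
    se: float
    z: float
    p: float
    significant: bool
    Q: float
    p_het: float
    k: int


# ---------------------------------------------------------------------------
# phenotype transforms
# ---------------------------------------------------------------------------

def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform; NaN propagates.

    Ranks (ties averaged) are mapped through the standard-normal quantile at
    (rank - 0.375) / (n + 0.25).
    """
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    ok = ~np.isnan(values)
    n = int(ok.sum())
    if n < 2:
        raise InvalidInputError("need >= 2 non-missing values")
    v = values[ok]
    if np.all(v == v[0]):
        raise InvalidInputError("all-constant input: ranks are degenerate")
    ranks = stats.rankdata(v, method="average")
    out[ok] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def adjust_phenotype(y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residuals of OLS of y on intercept + covariate; NaN propagates."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise InvalidArgumentError("y and covariate must have equal length")
    ok = ~(np.isnan(y) | np.isnan(x))
    if ok.sum() < 3:
        raise InvalidArgumentError("need >= 3 complete pairs")
    out = np.full_like(y, np.nan)
    xo, yo = x[ok], y[ok]
    if np.ptp(xo) == 0:
        warnings.warn("constant covariate: returning centered phenotype", stacklevel=2)
        out[ok] = yo - yo.mean()
        return out
    X = np.column_stack([np.ones_like(xo), xo])
    coef, *_ = np.linalg.lstsq(X, yo, rcond=None)
    out[ok] = yo - X @ coef
    return out


# ---------------------------------------------------------------------------
# HMM genotype posteriors
# ---------------------------------------------------------------------------

def haldane(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction from genetic distance, no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def _transition(r: float, cross_type: str) -> np.ndarray:
    if cross_type == BACKCROSS:
        return np.array([[1 - r, r], [r, 1 - r]])
    # F2: two independent meioses
    return np.array(
        [
            [(1 - r) ** 2, 2 * r * (1 - r), r**2],
            [r * (1 - r), (1 - r) ** 2 + r**2, r * (1 - r)],
            [r**2, 2 * r * (1 - r), (1 - r) ** 2],
        ]
    )


def _emission(n_states: int, error_rate: float) -> np.ndarray:
    """Rows: observed code (0..n_states-1); columns: true state."""
    e = np.full((n_states, n_states), error_rate / (n_states - 1))
    np.fill_diagonal(e, 1.0 - error_rate)
    return e


def _grid_positions(marker_cM: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Pseudomarker grid: every ``step`` cM plus all marker positions.

    Returns (grid cM sorted, marker index into grid).
    """
    lo, hi = float(marker_cM[0]), float(marker_cM[-1])
    pseudo = np.arange(lo, hi + step / 2, step)
    grid = np.unique(np.concatenate([pseudo, marker_cM]))
    marker_idx = np.searchsorted(grid, marker_cM)
    return grid, marker_idx


def genotype_posteriors(cross: CrossDataset, params: HmmParams = HmmParams()) -> GenotypeProbGrid:
    """Forward-backward posteriors of the true genotype on a cM grid.

    The grid holds pseudomarkers every ``params.grid_step`` cM plus all
    marker positions.  Transitions come from the Haldane map function
    (F2: two-meiosis transition matrix); emissions are observed = true with
    probability 1 - error_rate, each wrong state error_rate/(#states-1);
    missing genotypes are uninformative.
    """
    n_states = cross.n_states
    emit = _emission(n_states, params.error_rate)
    prior = np.array([0.25, 0.5, 0.25]) if cross.cross_type == F2 else np.array([0.5, 0.5])
    n_ind = cross.n_individuals

    loci_frames: list[pd.DataFrame] = []
    post_blocks: list[np.ndarray] = []
    for chrom, grp in cross.markers.groupby("chrom", sort=False):
        cm = grp["cM"].to_numpy(dtype=float)
        if (np.diff(cm) < 0).any():
            raise InvalidInputError("negative inter-marker distance")
        midx = grp.index.to_numpy()
        grid, marker_at = _grid_positions(cm, params.grid_step)
        n_loci = len(grid)

        # per-locus emission likelihood, vectorized over individuals
        lik = np.ones((n_ind, n_loci, n_states))
        obs = cross.geno[:, midx]  # (n_ind, n_markers_chrom)
        for k, g in enumerate(marker_at):
            o = obs[:, k]
            observed = o != MISSING
            lik[observed, g, :] *= emit[o[observed]]

        trans = [ _transition(float(haldane(d)), cross.cross_type)
                  for d in np.diff(grid) ]

        alpha = np.empty((n_ind, n_loci, n_states))
        scale = np.empty((n_ind, n_loci))
        a = prior[None, :] * lik[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, 0, None]
        for t in range(1, n_loci):
            a = (alpha[:, t - 1, :] @ trans[t - 1]) * lik[:, t, :]
            scale[:, t] = a.sum(axis=1)
            alpha[:, t, :] = a / scale[:, t, None]

        beta = np.empty((n_ind, n_loci, n_states))
        beta[:, -1, :] = 1.0
        for t in range(n_loci - 2, -1, -1):
            b = (beta[:, t + 1, :] * lik[:, t + 1, :]) @ trans[t].T
            beta[:, t, :] = b / scale[:, t + 1, None]

        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        post_blocks.append(post)
        is_marker = np.zeros(n_loci, dtype=bool)
        is_marker[marker_at] = True
        loci_frames.append(
            pd.DataFrame({"chrom": chrom, "cM": grid, "is_marker": is_marker})
        )

    loci = pd.concat(loci_frames, ignore_index=True)
    posteriors = np.concatenate(post_blocks, axis=1)
    return GenotypeProbGrid(cross_type=cross.cross_type, loci=loci, posteriors=posteriors)


# ---------------------------------------------------------------------------
# association and meta-analysis
# ---------------------------------------------------------------------------

def score_test(grid: GenotypeProbGrid, phenotype: np.ndarray) -> pd.DataFrame:
    """Additive-model association at every grid locus.

    OLS of the phenotype on the posterior-expected dosage (Haley-Knott
    substitution), intercept included; z = beta/se with a two-sided normal
    p-value.  Loci with zero dosage variance are flagged non-informative and
    reported with z=0, p=1.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != grid.dosage.shape[0]:
        raise InvalidArgumentError("phenotype length does not match individuals")
    ok = ~np.isnan(y)
    n = int(ok.sum())
    if n < 10:
        raise InvalidArgumentError("need >= 10 complete individuals")
    yc = y[ok] - y[ok].mean()
    X = grid.dosage[ok]                    # (n, n_loci)
    Xc = X - X.mean(axis=0)
    sxx = (Xc**2).sum(axis=0)
    sxy = Xc.T @ yc
    syy = float((yc**2).sum())
    informative = sxx > 1e-12
    beta = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[informative] = sxy[informative] / sxx[informative]
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / max(n - 2, 1)
        se[informative] = np.sqrt(sigma2[informative] / sxx[informative])
    z = np.where(informative & (se > 0), beta / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(informative, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    out = grid.loci.copy()
    out["beta"] = beta
    out["se"] = se
    out["z"] = z
    out["p"] = p
    out["informative"] = informative
    return out


def meta_fixed(betas: np.ndarray, ses: np.ndarray, z_threshold: float = Z_THRESHOLD) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis of one locus.

    weights w_i = 1/se_i^2; beta = sum(w b)/sum(w); se = sum(w)^-1/2;
    Q = sum w (b - beta)^2 with p_het from chi-square on k-1 df (p_het = 1
    for a single stratum).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    finite = np.isfinite(ses) & (ses > 0) & np.isfinite(betas)
    betas, ses = betas[finite], ses[finite]
    k = len(betas)
    if k == 0:
        raise InvalidArgumentError("meta_fixed needs >= 1 stratum with finite se")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))
    Q = float((w * (betas - beta) ** 2).sum())
    p_het = float(stats.chi2.sf(Q, k - 1)) if k > 1 else 1.0
    return MetaResult(
        beta=beta, se=se, z=float(z), p=p,
        significant=bool(abs(z) > z_threshold),
        Q=Q, p_het=p_het, k=k,
    )


def meta_scan(
    results: list[pd.DataFrame], z_threshold: float = Z_THRESHOLD
) -> pd.DataFrame:
    """Combine per-stratum scan tables locus by locus via :func:`meta_fixed`.

    All tables must share the same (chrom, cM) loci in the same order.
    """
    if not results:
        raise InvalidArgumentError("no strata to combine")
    base = results[0][["chrom", "cM"]]
    for r in results[1:]:
        if len(r) != len(base) or not (
            (r["chrom"].to_numpy() == base["chrom"].to_numpy()).all()
            and np.allclose(r["cM"].to_numpy(), base["cM"].to_numpy())
        ):
            raise InvalidInputError("strata scans are not on a common locus grid")
    rows = []
    for i in range(len(base)):
        betas = np.array([r["beta"].iat[i] for r in results])
        ses = np.array([r["se"].iat[i] for r in results])
        m = meta_fixed(betas, ses, z_threshold=z_threshold)
        rows.append((m.beta, m.se, m.z, m.p, m.significant, m.Q, m.p_het, m.k))
    out = base.copy()
    out[["beta", "se", "z", "p", "significant", "Q", "p_het", "k"]] = pd.DataFrame(
        rows, index=base.index
    )
    return out


def epistasis_screen(
    results_by_background: list[pd.DataFrame], p_het_threshold: float = 0.05
) -> pd.DataFrame:
    """Heterogeneity screen of effects across fixed genetic backgrounds.

    Strata are scans from crosses fixed for alternative alleles at a
    conditioning locus; loci where the effect differs between backgrounds
    (Cochran p_het < threshold) are flagged as candidate interactions.
    """
    if len(results_by_background) < 2:
        raise InvalidArgumentError("epistasis screen needs >= 2 backgrounds")
    out = meta_scan(results_by_background)
    out["interaction"] = out["p_het"] < p_het_threshold
    return out[["chrom", "cM", "Q", "p_het", "interaction"]]
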