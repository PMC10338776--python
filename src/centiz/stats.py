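"""Agreement and inference statistics for paired quantification methods.

Covers the comparison battery used when two pipelines (e.g. CT-guided
vs MRI-guided normalization, or two normative databases) are run on the
same subjects: Pearson and Spearman correlation, Bland-Altman agreement
(bias, limits of agreement, CI of the bias, and a Spearman test of
difference-vs-load association), and a voxel-wise paired t-test with
family-wise-error control by sign-flipping maxT permutation plus a
cluster extent threshold (default 300 voxels).

The permutation FWE replaces random-field-theory correction: under the
exchangeability of paired-difference signs it is exact, needs no
smoothness estimation, and is feasible at these problem sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from centiz.volume_io import Volume3D, VOIMask
from centiz.zscore import Cluster, cluster_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "BlandAltmanReport",
    "VoxelTTestResult",
    "pearson",
    "spearman",
    "bland_altman",
    "paired_t_map",
]


@dataclass
class BlandAltmanReport:
    """Bland-Altman agreement of paired measurements (d = b - a)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean_low: float
    ci_mean_high: float
    p_bias: float
    n: int
    spearman_rho_diff_vs_mean: float
    spearman_p: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class VoxelTTestResult:
    """Voxel-wise paired t map with permutation-FWE cluster inference."""

    tmap: Volume3D
    df: int
    fwe_threshold: float
    significant_clusters: list
    alpha: float
    extent_threshold: int
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "df": self.df,
            "fwe_threshold": self.fwe_threshold,
            "alpha": self.alpha,
            "extent_threshold": self.extent_threshold,
            "n_permutations": self.n_permutations,
            "significant_clusters": [
                {**c.to_dict(), "direction": d} for c, d in self.significant_clusters
            ],
        }


def _check_pair(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return x, y


def pearson(x, y):
    """Product-moment correlation; returns (r, r^2, p) with the p-value
    from the t distribution on n-2 degrees of freedom."""
    x, y = _check_pair(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r) ** 2, float(p)


def spearman(x, y):
    """Rank correlation (mean ranks for ties); returns (rho, p)."""
    x, y = _check_pair(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bland_altman(a, b, orientation: str = "b_minus_a", alpha: float = 0.05) -> BlandAltmanReport:
    """Bland-Altman agreement of two paired measurement series.

    Differences are ``d = b - a`` (the ``orientation`` string documents
    this and is validated); means ``m = (a + b)/2``.  Reports the bias
    (mean difference), the sample SD of differences, the conventional
    limits of agreement bias +/- 1.96 SD, the t-based 95% CI of the
    bias, a paired t-test of zero bias, and the Spearman correlation of
    difference against mean (difference-vs-load association).
    """
    if orientation != "b_minus_a":
        raise ValueError("orientation must be 'b_minus_a' (swap inputs for the other sign)")
    a, b = _check_pair(a, b, min_n=2)
    d = b - a
    m = (a + b) / 2.0
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = 1.96 * sd
    if sd > 0:
        tcrit = float(sps.t.ppf(1 - alpha / 2, n - 1))
        half = tcrit * sd / np.sqrt(n)
        tstat = bias / (sd / np.sqrt(n))
        p_bias = float(2 * sps.t.sf(abs(tstat), n - 1))
    else:
        half = 0.0
        p_bias = 1.0 if bias == 0 else 0.0
    if np.std(d) > 0 and np.std(m) > 0 and n >= 3:
        rho, rho_p = sps.spearmanr(d, m)
    else:
        rho, rho_p = float("nan"), float("nan")
    return BlandAltmanReport(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa,
        loa_high=bias + loa,
        ci_mean_low=bias - half,
        ci_mean_high=bias + half,
        p_bias=p_bias,
        n=n,
        spearman_rho_diff_vs_mean=float(rho),
        spearman_p=float(rho_p),
    )


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Voxel-wise one-sample t of difference images, shape (n, V) -> (V,).
    Zero-variance voxels get t = 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    return t


def _sign_patterns(n: int, n_perm: int, rng: np.random.Generator):
    """Sign-flip matrix (P, n); full enumeration when 2^n <= n_perm,
    otherwise n_perm random flips with the identity included first."""
    if 2**n <= n_perm:
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        return np.where(bits & 1, -1.0, 1.0), True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0
    return signs, False


def paired_t_map(
    group_a: list,
    group_b: list,
    mask: VOIMask,
    alpha: float = 0.05,
    extent: int = 300,
    n_perm: int = 1024,
    seed: int = 0,
) -> VoxelTTestResult:
    """Voxel-wise paired t-test (B vs A) with maxT permutation FWE.

    Differences ``B - A`` inside the mask are sign-flipped over all
    ``2^n`` patterns when feasible (else ``n_perm`` random patterns
    including the identity); the FWE critical value is the (1-alpha)
    quantile of the permutation distribution of max |t|.  Supra-critical
    voxels are clustered (18-connectivity) and filtered by the extent
    threshold, reported separately for B > A and A > B.  Two-sided.
    """
    if len(group_a) != len(group_b):
        raise ValueError("paired groups must have equal length")
    n = len(group_a)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    grid = group_a[0]
    for v in list(group_a) + list(group_b):
        if not v.same_grid(grid):
            raise ValueError("all volumes must share the grid")
    if not mask.same_grid(grid, tol=1e-3):
        raise ValueError("mask not on the data grid")

    m = mask.data
    diffs = np.stack([(b.data - a.data)[m] for a, b in zip(group_a, group_b)])
    t_obs = _paired_t(diffs)

    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_patterns(n, n_perm, rng)
    max_t = np.empty(signs.shape[0])
    for i, s in enumerate(signs):
        max_t[i] = np.abs(_paired_t(diffs * s[:, None])).max()
    # conservative permutation quantile: smallest c with P(maxT > c) <= alpha
    k = int(np.ceil((1 - alpha) * len(max_t)))
    fwe_threshold = float(np.sort(max_t)[min(k, len(max_t) - 1)])

    tvol_data = np.zeros(grid.shape)
    tvol_data[m] = t_obs
    tmap = Volume3D(tvol_data, grid.affine, space_label=grid.space_label)

    significant = []
    strict = float(np.nextafter(fwe_threshold, np.inf))  # supra-critical is strict
    for direction, signed in (("b_gt_a", tvol_data), ("a_gt_b", -tvol_data)):
        svol = Volume3D(signed, grid.affine)
        for c in cluster_threshold(svol, strict, min_voxels=max(extent, 1), connectivity=18):
            significant.append((c, direction))
    significant.sort(key=lambda cd: -cd[0].size_voxels)

    logger.info(
        "paired_t_map: n=%d, %s %d permutations, FWE t-crit %.3f, %d significant clusters",
        n, "exhaustive" if exhaustive else "random", len(max_t), fwe_threshold, len(significant),
    )
    return VoxelTTestResult(
        tmap=tmap,
        df=n - 1,
        fwe_threshold=fwe_threshold,
        significant_clusters=significant,
        alpha=alpha,
        extent_threshold=extent,
        n_permutations=len(max_t),
    )


def permutation_p_values(diffs: np.ndarray, n_perm: int = 1024, seed: int = 0):
    """Voxel-wise two-sided permutation p-values for paired differences
    (n, V): fraction of sign patterns with |t| >= |t_observed|.  Used for
    small-n exactness checks; full enumeration when 2^n <= n_perm."""
    diffs = np.asarray(diffs, float)
    if diffs.ndim == 1:
        diffs = diffs[:, None]
    t_obs = np.abs(_paired_t(diffs))
    rng = np.random.default_rng(seed)
    signs, _ = _sign_patterns(diffs.shape[0], n_perm, rng)
    count = np.zeros(diffs.shape[1])
    for s in signs:
        count += np.abs(_paired_t(diffs * s[:, None])) >= t_obs - 1e-12
    return count / signs.shape[0]
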