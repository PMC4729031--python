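"""Beta-diversity partitioning (BD / LCBD / SCBD) with permutation inference.

The community matrix (units x taxa counts; unit = site or site-month
sampling event) is Hellinger-transformed row-wise, and the total variance of
the transformed matrix is taken as the beta diversity:

    y'_ij = sqrt(y_ij / y_i.),   s_ij = y'_ij - mean_i(y'_ij)
    SS_total = sum s_ij^2,       BD = SS_total / (n - 1)

Under the Hellinger route BD lies in [0, 1]: 0 when every unit hosts the
same assemblage, 1 at complete turnover.  The partition follows directly
from the sums of squares: LCBD_i = SS_i / SS_total (the share of community
variance due to unit i) and SCBD_j = SS_j / SS_total (the share due to taxon
j).  Both vectors sum to one.

LCBD significance is assessed by permuting each taxon's raw abundances
independently across units (which breaks unit-taxon association while
preserving each taxon's abundance distribution), re-transforming and
re-partitioning per permutation; p-values use the add-one convention
p = (1 + #{LCBD* >= LCBD}) / (1 + nperm), so they are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .survey_io import AbundanceMatrix


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, AbundanceMatrix):
        return matrix.frame
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"u{i}" for i in range(arr.shape[0])],
        columns=[f"t{j}" for j in range(arr.shape[1])],
    )


@dataclass
class BetaDiversityResult:
    """BD partition: total beta diversity plus unit and taxon contributions."""

    bd_total: float
    lcbd: pd.Series
    scbd: pd.Series
    ss_total: float
    undefined: bool = False  # identical communities everywhere: SS_total = 0
    lcbd_pvalues: pd.Series | None = None
    nperm: int | None = None
    seed: int | None = None


@dataclass
class VariancePartition:
    """Adjusted-R^2 decomposition of LCBD onto climate vs sampling geography."""

    r2adj_climate: float
    r2adj_sites: float
    r2adj_joint: float
    n_units: int
    n_params: dict[str, int]


# ---------------------------------------------------------------------------


def hellinger_transform(matrix, allow_zero_rows: bool = False):
    """Row-wise square-root of relative abundances.

    An all-zero row has no defined composition; it raises unless
    ``allow_zero_rows`` (used internally by the permutation test, where a
    permuted matrix may create empty units) in which case it maps to a zero
    row.
    """
    frame = _as_frame(matrix)
    values = frame.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundances")
    rowsum = values.sum(axis=1)
    zero = rowsum == 0
    if zero.any() and not allow_zero_rows:
        units = list(frame.index[zero])
        raise ValueError(f"all-zero unit(s) {units}: Hellinger transform undefined")
    safe = np.where(zero, 1.0, rowsum)
    out = np.sqrt(values / safe[:, None])
    result = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    return result


def _partition_array(values: np.ndarray):
    """Numpy core of the partition: returns (ss_total, lcbd, scbd).

    All-zero rows map to zero Hellinger rows (callers decide whether those
    are legal); lcbd/scbd are None when SS_total vanishes.
    """
    rowsum = values.sum(axis=1)
    safe = np.where(rowsum == 0, 1.0, rowsum)
    hel = np.sqrt(values / safe[:, None])
    s = hel - hel.mean(axis=0, keepdims=True)
    sq = s * s
    ss_total = float(sq.sum())
    if ss_total < 1e-12:
        return ss_total, None, None
    return ss_total, sq.sum(axis=1) / ss_total, sq.sum(axis=0) / ss_total


def beta_diversity_partition(matrix, allow_zero_rows: bool = False) -> BetaDiversityResult:
    """Partition total community variance into BD, LCBD and SCBD."""
    frame = _as_frame(matrix)
    n, p = frame.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 units and 2 taxa")
    hel = hellinger_transform(frame, allow_zero_rows=allow_zero_rows)
    s = hel.to_numpy() - hel.to_numpy().mean(axis=0, keepdims=True)
    sq = s**2
    ss_total = float(sq.sum())
    if ss_total < 1e-12:
        nan = float("nan")
        return BetaDiversityResult(
            bd_total=0.0,
            lcbd=pd.Series(nan, index=frame.index, name="lcbd"),
            scbd=pd.Series(nan, index=frame.columns, name="scbd"),
            ss_total=0.0,
            undefined=True,
        )
    bd = ss_total / (n - 1)
    lcbd = pd.Series(sq.sum(axis=1) / ss_total, index=frame.index, name="lcbd")
    scbd = pd.Series(sq.sum(axis=0) / ss_total, index=frame.columns, name="scbd")
    return BetaDiversityResult(bd_total=bd, lcbd=lcbd, scbd=scbd, ss_total=ss_total)


def lcbd_permutation_test(
    matrix, nperm: int = 999, seed: int | None = None
) -> pd.Series:
    """Permutation p-values for LCBD: independent within-column shuffles.

    Each taxon's raw abundances are permuted independently across units
    before re-applying the Hellinger transform (row sums, hence the
    transform, change under permutation — intentionally so).  Swapping whole
    columns instead would leave LCBD nearly invariant and is not a test of
    unit-taxon association.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    frame = _as_frame(matrix)
    observed = beta_diversity_partition(frame)
    if observed.undefined:
        raise ValueError("LCBD undefined (identical communities everywhere)")
    rng = np.random.default_rng(seed)
    values = frame.to_numpy(dtype=float)
    n, p = values.shape
    obs = observed.lcbd.to_numpy()
    exceed = np.zeros(n, dtype=int)
    perm = np.empty_like(values)
    for _ in range(nperm):
        for j in range(p):
            perm[:, j] = values[rng.permutation(n), j]
        _, lcbd_perm, _ = _partition_array(perm)
        if lcbd_perm is None:
            continue  # degenerate permutation exceeds nothing
        exceed += lcbd_perm >= obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + nperm)
    return pd.Series(pvals, index=frame.index, name="lcbd_pvalue")


def richness_lcbd_correlation(matrix, result: BetaDiversityResult) -> tuple[float, float]:
    """Pearson correlation between unit species richness and LCBD.

    A negative correlation signals that high-LCBD units are species-poor
    sampling events.  Returns (nan, nan) when either side is constant.
    """
    frame = _as_frame(matrix)
    if len(frame) < 3:
        raise ValueError("need at least 3 units")
    richness = (frame.to_numpy() > 0).sum(axis=1).astype(float)
    lcbd = result.lcbd.reindex(frame.index).to_numpy()
    if np.ptp(richness) == 0 or np.ptp(lcbd) == 0 or np.isnan(lcbd).any():
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(richness, lcbd)
    return (float(r), float(p))


def partition_lcbd_variance(
    lcbd: pd.Series,
    climate: pd.DataFrame,
    sites: pd.Series,
) -> VariancePartition:
    """Adjusted R^2 of LCBD on climate, on site identity, and on both.

    ``climate`` must carry ``rainfall_mm`` and ``temperature_c`` aligned with
    ``lcbd``; ``sites`` is the categorical sampling-site factor.  Ordinary
    least squares throughout; R^2_adj = 1 - (1 - R^2)(n - 1)/(n - m - 1)
    with m non-intercept parameters (the statsmodels convention).
    """
    y = np.asarray(lcbd, dtype=float)
    n = len(y)
    rain = np.asarray(climate["rainfall_mm"], dtype=float)
    temp = np.asarray(climate["temperature_c"], dtype=float)
    if len(rain) != n or len(sites) != n:
        raise ValueError("inputs not aligned")
    site_dummies = pd.get_dummies(pd.Series(sites).astype(str), drop_first=True, dtype=float)

    designs = {
        "climate": pd.DataFrame({"rainfall_mm": rain, "temperature_c": temp}),
        "sites": site_dummies,
    }
    designs["joint"] = pd.concat(
        [designs["climate"].reset_index(drop=True), site_dummies.reset_index(drop=True)],
        axis=1,
    )

    out = {}
    n_params = {}
    for name, X in designs.items():
        Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            aliased = _aliased_columns(Xc, ["const"] + list(X.columns))
            raise ValueError(f"rank-deficient design {name!r}: aliased columns {aliased}")
        m = X.shape[1]
        if n <= m + 1:
            raise ValueError(f"design {name!r} has too few units ({n}) for {m} parameters")
        fit = sm.OLS(y, Xc).fit()
        out[name] = float(fit.rsquared_adj)
        n_params[name] = m
    return VariancePartition(
        r2adj_climate=out["climate"],
        r2adj_sites=out["sites"],
        r2adj_joint=out["joint"],
        n_units=n,
        n_params=n_params,
    )


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased = []
    rank = 0
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            rank = r
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased
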