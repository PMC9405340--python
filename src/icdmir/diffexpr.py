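"""Expression filtering, normalization, and negative-binomial contrast testing.

The contrast test is a deliberately simple NB Wald test: median-of-ratios
size factors, per-feature method-of-moments dispersion pooled across the two
groups, and a delta-method standard error on the log2 fold change.  It does
not attempt to replicate a full DESeq2 fit (no shrinkage, no Cook's
filtering, no dispersion trend); for published contrast tables the signature
stage reads those tables directly rather than re-deriving them.

Fold changes are reported both as log2 ratios and in the signed-ratio
convention used by the contrast tables: a ratio r >= 1 is printed as r, a
ratio r < 1 as -1/r, so |signed fc| >= 1 always.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContrastError, NormalizationError, ParameterError
from .io import CONDITIONS, SampleInfo

#: Expression floors: a feature counts as expressed when seen at this many
#: reads (mRNA: 10, miRNA: 3).
EXPRESSION_FLOORS = {"mRNA": 10, "miRNA": 3}


def filter_expressed(
    counts: pd.DataFrame,
    floor: int | None = None,
    feature_kind: str = "mRNA",
    mode: str = "max",
) -> pd.DataFrame:
    """Drop features never detected at ``floor`` reads.

    A feature is retained when its maximum count over samples reaches the
    floor (``mode="max"``, the default deterministic reading of "detected by
    at least N reads"); ``mode="sum"`` applies the floor to the summed counts
    instead.  Row order is preserved.
    """
    if floor is None:
        try:
            floor = EXPRESSION_FLOORS[feature_kind]
        except KeyError:
            raise ParameterError(
                f"feature_kind must be one of {sorted(EXPRESSION_FLOORS)}"
            ) from None
    if floor < 0:
        raise ParameterError(f"floor must be >= 0, got {floor}")
    if mode not in ("max", "sum"):
        raise ParameterError(f"mode must be 'max' or 'sum', got {mode!r}")
    stat = counts.max(axis=1) if mode == "max" else counts.sum(axis=1)
    return counts.loc[stat >= floor]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, rescaled to geometric mean 1.

    For each feature with all-positive counts, the ratio of each sample's
    count to the feature's geometric mean is formed; a sample's factor is the
    median of those ratios.  Requires at least one all-positive feature.
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no feature has positive counts in every sample; add a "
            "pseudo-count or filter samples"
        )
    pos = values[positive]
    log_geomean = np.mean(np.log(pos), axis=1, keepdims=True)
    ratios = np.exp(np.log(pos) - log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def signed_fc(log2_fc: float) -> float:
    """Convert a log2 ratio to the signed-ratio convention (|value| >= 1)."""
    x = float(log2_fc)
    return 2.0 ** x if x >= 0 else -(2.0 ** (-x))


def signed_fc_to_log2(value: float) -> float:
    """Inverse of :func:`signed_fc`."""
    v = float(value)
    if abs(v) < 1.0:
        raise ParameterError(
            f"signed fold change must satisfy |value| >= 1, got {v}"
        )
    return np.log2(v) if v >= 1 else -np.log2(-v)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with missing passthrough.

    Missing entries (NaN/None) are excluded from the number of tests m and
    returned as NaN; output order matches input order and monotonicity is
    enforced.
    """
    arr = np.asarray(
        [np.nan if p is None else float(p) for p in np.ravel(p_values)],
        dtype=float,
    )
    present = ~np.isnan(arr)
    vals = arr[present]
    if ((vals < 0) | (vals > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    m = vals.size
    if m:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
        restored = np.empty(m)
        restored[order] = np.minimum(adjusted, 1.0)
        out[present] = restored
    return out


def nb_contrast_test(
    counts: pd.DataFrame,
    samples: list[SampleInfo],
    cell_line: str,
    treatment: str,
    dispersion_floor: float = 1e-8,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Negative-binomial Wald test of ``treatment`` vs ``untreated``.

    Counts are normalized by median-of-ratios size factors computed over the
    two groups; each feature gets a method-of-moments NB dispersion pooled
    across the two groups (floored at ``dispersion_floor``) and then
    moderated toward the cross-feature median with ``prior_df`` prior
    degrees of freedom — per-feature moment estimates are far too noisy at
    the 2-4 replicates this design uses, inflating the Wald statistic for
    features whose dispersion is underestimated and destroying power where
    it is overestimated.  The log2 fold change gets a delta-method standard
    error, a two-sided p-value from a Student t reference with
    (n_t - 1) + (n_c - 1) + prior_df degrees of freedom (the moderated-t
    convention), and a BH adjusted p over all tested features.  Set
    ``prior_df=0`` for the raw per-feature estimator.  Features with zero counts in both
    groups report log2_fc 0 and missing p; a single zero-mean group receives
    a 0.5 pseudo-count on the normalized mean (flagged in ``pseudo``).

    Returns a DataFrame indexed by feature_id with columns base_mean,
    log2_fc, signed_fc, p, p_adj, pseudo.
    """
    if treatment not in CONDITIONS or treatment == "untreated":
        raise ContrastError(f"unknown treatment {treatment!r}")
    by_id = {s.sample_id: s for s in samples}
    grp_t = [
        s.sample_id for s in samples
        if s.cell_line == cell_line and s.condition == treatment
    ]
    grp_c = [
        s.sample_id for s in samples
        if s.cell_line == cell_line and s.condition == "untreated"
    ]
    if not grp_t or not grp_c:
        missing = treatment if not grp_t else "untreated"
        raise ContrastError(
            f"no samples for group ({cell_line!r}, {missing!r})"
        )
    del by_id

    sub = counts[grp_t + grp_c]
    sf = size_factors(sub)
    norm = sub / sf
    yt = norm[grp_t].to_numpy(dtype=float)
    yc = norm[grp_c].to_numpy(dtype=float)
    nt, nc = yt.shape[1], yc.shape[1]

    mu_t = yt.mean(axis=1)
    mu_c = yc.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # Pooled method-of-moments dispersion: within-group variance in excess of
    # the Poisson term, relative to the squared mean.
    var_t = yt.var(axis=1, ddof=1) if nt > 1 else np.zeros_like(mu_t)
    var_c = yc.var(axis=1, ddof=1) if nc > 1 else np.zeros_like(mu_c)
    wt = max(nt - 1, 0)
    wc = max(nc - 1, 0)
    if wt + wc == 0:
        raise ContrastError(
            "dispersion estimation needs at least two samples in one group"
        )
    pooled_var = (wt * var_t + wc * var_c) / (wt + wc)
    pooled_mu = (nt * mu_t + nc * mu_c) / (nt + nc)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mu) / np.square(pooled_mu)
    alpha = np.where(np.isfinite(alpha), alpha, dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)
    if prior_df < 0:
        raise ParameterError(f"prior_df must be >= 0, got {prior_df}")
    if prior_df > 0 and alpha.size:
        alpha_prior = float(np.median(alpha))
        alpha = (prior_df * alpha_prior + (wt + wc) * alpha) / (
            prior_df + wt + wc
        )

    both_zero = (mu_t == 0) & (mu_c == 0)
    pseudo = ((mu_t == 0) ^ (mu_c == 0)) & ~both_zero
    mt = np.where(pseudo & (mu_t == 0), 0.5, mu_t)
    mc = np.where(pseudo & (mu_c == 0), 0.5, mu_c)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.where(both_zero, 0.0, np.log2(mt) - np.log2(mc))
        # Var(mean of normalized counts) per group under NB(mu, alpha):
        # each normalized count has variance ~ mu/s_j + alpha mu^2.
        inv_s_t = (1.0 / sf[grp_t].to_numpy()).sum() / nt**2
        inv_s_c = (1.0 / sf[grp_c].to_numpy()).sum() / nc**2
        var_mean_t = mt * inv_s_t + alpha * np.square(mt) / nt
        var_mean_c = mc * inv_s_c + alpha * np.square(mc) / nc
        se_log2 = np.sqrt(
            var_mean_t / np.square(mt) + var_mean_c / np.square(mc)
        ) / np.log(2.0)
        z = log2_fc / se_log2
    p = 2.0 * stats.t.sf(np.abs(z), df=wt + wc + prior_df)
    p = np.where(both_zero, np.nan, p)
    p = np.where(log2_fc == 0.0, np.where(both_zero, np.nan, 1.0), p)

    result = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "signed_fc": [signed_fc(x) for x in log2_fc],
            "p": p,
            "p_adj": bh_adjust(p),
            "pseudo": pseudo,
        },
        index=counts.index,
    )
    result.index.name = "feature_id"
    return result


def ddct_relative_quantity(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative quantity 2^-ddCt from four qPCR cycle thresholds.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control).
    """
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return 2.0 ** (-ddct)
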