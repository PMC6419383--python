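"""Differential methylation and differential variability statistics.

Two-group comparisons at CpG or region level. The machinery is:

* a moderated two-sample t-test with empirical-Bayes variance shrinkage:
  per-unit sample variances are shrunk toward a common prior variance
  ``s0^2`` with ``d0`` prior degrees of freedom,

      s_post^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

  where ``(d0, s0^2)`` are estimated by moment-matching a scaled-F model
  on the log sample variances (digamma/trigamma matching); the t statistic
  uses ``s_post^2`` and ``d0 + d_g`` degrees of freedom. With the prior
  disabled (``d0 = 0``) this reduces exactly to the classical Student t.

* differential variability via the same machinery applied to absolute
  deviations from the group median (the diffVar approach), or via the
  Bartlett heteroscedasticity test with t-test regularisation (the iEVORA
  approach).

* worst-rank scoring: units are ranked separately by (i) adjusted p-value,
  (ii) effect size (mean difference, or variance difference), and (iii)
  log-ratio of group summaries; the combined rank is the worst (maximum)
  of the three, so a unit scores well only if all criteria agree.

* an automatic rank cutoff: the number of units passing Benjamini-
  Hochberg FDR control determines how many top worst-rank units are
  "selected".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DataError

EPS_QUOTIENT = 0.01  # pseudo-count inside log2 quotients

#: criterion triplets for the two table flavours
DM_CRITERIA = ("p_adj", "diff", "log_quotient")
DV_CRITERIA = ("p_adj", "var_diff", "var_log_ratio")


@dataclass
class GroupComparison:
    """A two-group contrast over sample columns."""

    labels: tuple[str, str]
    idx0: np.ndarray  # column indices of group 0 (the first label)
    idx1: np.ndarray
    level: str = "cpg"

    def __post_init__(self):
        self.idx0 = np.asarray(self.idx0, dtype=int)
        self.idx1 = np.asarray(self.idx1, dtype=int)
        if len(self.idx0) < 2 or len(self.idx1) < 2:
            raise DataError("each comparison group needs at least 2 samples")
        if set(self.idx0) & set(self.idx1):
            raise DataError("comparison groups overlap")

    @classmethod
    def from_sheet(
        cls, samples: pd.DataFrame, column: str, groups: tuple[str, str] | None = None,
        level: str = "cpg",
    ) -> "GroupComparison":
        if column not in samples.columns:
            raise DataError(f"no column {column!r} in the sample sheet")
        vals = samples[column].astype(str)
        if groups is None:
            levels = [g for g in pd.unique(vals) if g not in ("nan", "None")]
            if len(levels) != 2:
                raise DataError(
                    f"column {column!r} has {len(levels)} levels; give groups= explicitly"
                )
            groups = (levels[0], levels[1])
        idx0 = np.nonzero((vals == groups[0]).to_numpy())[0]
        idx1 = np.nonzero((vals == groups[1]).to_numpy())[0]
        return cls(labels=groups, idx0=idx0, idx1=idx1, level=level)


# ---------------------------------------------------------------------------
# Empirical-Bayes machinery
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # good starting point: trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(50):
        tri = special.polygamma(1, x)
        # damped Newton step on f(x) = trigamma(x) - y (psi'' < 0)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = np.maximum(x + step, 1e-8)
        if np.all(np.abs(step) < 1e-12 * np.maximum(x, 1.0)):
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled-F variance prior by moment
    matching on log sample variances.

    Under the model s_g^2 ~ s0^2 * F(d_g, d0), the statistic
    e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2) has
    mean log(s0^2) + digamma(d0/2) - log(d0/2) and variance
    trigamma(d_g/2) + trigamma(d0/2). Matching the empirical mean and
    variance of e yields the estimates; a non-positive excess variance
    means no between-unit variance dispersion, i.e. d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(evar))
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return d0, s0


def moderated_t_table(
    values: np.ndarray,
    comparison: GroupComparison,
    prior: bool = True,
    missing: str = "drop",
) -> pd.DataFrame:
    """Per-unit moderated two-sample t-test (group 1 minus group 0).

    ``values`` is units x samples. With ``prior=False`` no shrinkage is
    applied (d0 = 0) and the statistic equals the classical pooled
    Student t. Units containing missing values are excluded from testing
    (``missing='drop'``; their rows are returned with NaN statistics and
    counted in ``result.attrs['n_dropped']``) or are an error
    (``missing='error'``).

    Returns columns: mean0, mean1, diff, statistic, p, df, s2_post.
    The fitted prior is in ``result.attrs['d0']`` / ``attrs['s0_sq']``.
    """
    V = np.asarray(values, dtype=float)
    if V.ndim != 2:
        raise DataError("values must be a units x samples matrix")
    g0, g1 = comparison.idx0, comparison.idx1
    n0, n1 = len(g0), len(g1)
    used = V[:, np.concatenate([g0, g1])]
    complete = ~np.isnan(used).any(axis=1)
    if missing == "error" and not complete.all():
        raise DataError("missing values present; impute first or use missing='drop'")
    n_units = V.shape[0]

    mean0 = np.full(n_units, np.nan)
    mean1 = np.full(n_units, np.nan)
    tstat = np.full(n_units, np.nan)
    pval = np.full(n_units, np.nan)
    s2_post_out = np.full(n_units, np.nan)
    dof_out = np.full(n_units, np.nan)
    d0_used, s0_used = 0.0, np.nan

    if complete.any():
        X0 = V[np.ix_(complete, g0)]
        X1 = V[np.ix_(complete, g1)]
        m0 = X0.mean(axis=1)
        m1 = X1.mean(axis=1)
        v0 = X0.var(axis=1, ddof=1)
        v1 = X1.var(axis=1, ddof=1)
        df_res = float(n0 + n1 - 2)
        s2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / df_res

        if prior:
            d0, s0 = fit_variance_prior(s2, df_res)
            if np.isinf(d0):
                s2_post = np.full_like(s2, s0)
                dof = np.full_like(s2, np.inf)
            else:
                s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)
                dof = np.full_like(s2, d0 + df_res)
            d0_used, s0_used = d0, s0
        else:
            s2_post = s2
            dof = np.full_like(s2, df_res)
            zero = s2_post == 0
            if zero.any():
                warnings.warn(
                    f"{int(zero.sum())} unit(s) with zero pooled variance and no prior; "
                    "p set to the smallest representable value",
                    stacklevel=2,
                )

        se = np.sqrt(s2_post * (1.0 / n0 + 1.0 / n1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1 - m0) / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        inf_t = np.isinf(t)
        p[inf_t] = np.finfo(float).tiny
        t[np.isnan(t) & (se == 0)] = 0.0  # 0/0: no difference, no evidence
        p[np.isnan(p)] = 1.0
        p = np.maximum(p, np.finfo(float).tiny)  # keep p in (0, 1]

        mean0[complete] = m0
        mean1[complete] = m1
        tstat[complete] = t
        pval[complete] = p
        s2_post_out[complete] = s2_post
        dof_out[complete] = dof

    out = pd.DataFrame(
        {
            "mean0": mean0,
            "mean1": mean1,
            "diff": mean1 - mean0,
            "statistic": tstat,
            "p": pval,
            "df": dof_out,
            "s2_post": s2_post_out,
        }
    )
    if isinstance(values, pd.DataFrame):
        out.index = values.index
    out.attrs["d0"] = d0_used
    out.attrs["s0_sq"] = s0_used
    out.attrs["n_dropped"] = int((~complete).sum())
    return out


# ---------------------------------------------------------------------------
# Differential variability
# ---------------------------------------------------------------------------

def _group_variance_stats(V, g0, g1, eps=EPS_QUOTIENT):
    v0 = np.nanvar(V[:, g0], axis=1, ddof=1)
    v1 = np.nanvar(V[:, g1], axis=1, ddof=1)
    return v0, v1, v1 - v0, np.log2((v1 + eps) / (v0 + eps))


def diffvar_table(
    values: np.ndarray,
    comparison: GroupComparison,
    prior: bool = True,
    missing: str = "drop",
) -> pd.DataFrame:
    """Differential variability by moderated t on absolute deviations.

    Each observation is transformed to z = |v - median of its group|, and
    the moderated t machinery is applied to z (group 1 minus group 0). The
    group variances of the untransformed values, their difference and
    log2 ratio are reported alongside.
    """
    V = np.asarray(values, dtype=float)
    g0, g1 = comparison.idx0, comparison.idx1
    Z = np.full_like(V, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med0 = np.nanmedian(V[:, g0], axis=1)
        med1 = np.nanmedian(V[:, g1], axis=1)
    Z[:, g0] = np.abs(V[:, g0] - med0[:, None])
    Z[:, g1] = np.abs(V[:, g1] - med1[:, None])
    out = moderated_t_table(Z, comparison, prior=prior, missing=missing)
    out = out.rename(columns={"mean0": "meandev0", "mean1": "meandev1", "diff": "dev_diff"})
    v0, v1, vdiff, vlr = _group_variance_stats(V, g0, g1)
    out["var0"], out["var1"], out["var_diff"], out["var_log_ratio"] = v0, v1, vdiff, vlr
    if isinstance(values, pd.DataFrame):
        out.index = values.index
    return out


def bartlett_two_group(v0, v1, n0: int, n1: int):
    """Closed-form Bartlett statistic and p for k = 2 groups.

    T = ((N-k) ln(sp^2) - sum (n_i - 1) ln(s_i^2)) / C with the usual
    correction C = 1 + (sum 1/(n_i-1) - 1/(N-k)) / (3(k-1)); p from
    chi-square with k-1 = 1 df. Zero group variances yield NaN.
    """
    v0 = np.asarray(v0, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    N = n0 + n1
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (N - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (N - 2) * np.log(sp2) - (n0 - 1) * np.log(v0) - (n1 - 1) * np.log(v1)
    C = 1.0 + (1.0 / (n0 - 1) + 1.0 / (n1 - 1) - 1.0 / (N - 2)) / 3.0
    T = num / C
    bad = ~np.isfinite(T)
    T = np.where(bad, np.nan, T)
    p = stats.chi2.sf(T, df=1)
    p = np.where(bad, np.nan, np.maximum(p, np.finfo(float).tiny))
    return T, p


def ievora_table(
    values: np.ndarray,
    comparison: GroupComparison,
    q_threshold: float = 0.001,
    t_threshold: float = 0.05,
    missing: str = "drop",
) -> pd.DataFrame:
    """Differential variability by the Bartlett test with t regularisation.

    A unit is *selected* iff its BH-adjusted Bartlett q-value is below
    ``q_threshold`` and its plain two-sample t-test p-value is below
    ``t_threshold`` (the t filter discards units whose variance difference
    is driven by a mean shift of a few outliers); selected units are
    ordered by the t-test p-value.
    """
    V = np.asarray(values, dtype=float)
    g0, g1 = comparison.idx0, comparison.idx1
    n0, n1 = len(g0), len(g1)
    used = V[:, np.concatenate([g0, g1])]
    complete = ~np.isnan(used).any(axis=1)
    if missing == "error" and not complete.all():
        raise DataError("missing values present; impute first or use missing='drop'")

    n_units = V.shape[0]
    cols = ["bartlett_stat", "bartlett_p", "bartlett_q", "t_p", "var0", "var1",
            "var_diff", "var_log_ratio"]
    out = pd.DataFrame(np.nan, index=range(n_units), columns=cols)
    out["selected"] = False
    if complete.any():
        X0 = V[np.ix_(complete, g0)]
        X1 = V[np.ix_(complete, g1)]
        v0 = X0.var(axis=1, ddof=1)
        v1 = X1.var(axis=1, ddof=1)
        T, p = bartlett_two_group(v0, v1, n0, n1)
        finite = ~np.isnan(p)
        q = np.full_like(p, np.nan)
        if finite.any():
            q[finite] = adjust_bh(p[finite])
        t_res = stats.ttest_ind(X1, X0, axis=1)
        t_p = np.asarray(t_res.pvalue, dtype=float)
        sel = (q < q_threshold) & (t_p < t_threshold)
        sel = np.where(np.isnan(q) | np.isnan(t_p), False, sel)
        idx = np.nonzero(complete)[0]
        out.loc[idx, "bartlett_stat"] = T
        out.loc[idx, "bartlett_p"] = p
        out.loc[idx, "bartlett_q"] = q
        out.loc[idx, "t_p"] = t_p
        out.loc[idx, "var0"] = v0
        out.loc[idx, "var1"] = v1
        out.loc[idx, "var_diff"] = v1 - v0
        out.loc[idx, "var_log_ratio"] = np.log2((v1 + EPS_QUOTIENT) / (v0 + EPS_QUOTIENT))
        out.loc[idx, "selected"] = sel
    if isinstance(values, pd.DataFrame):
        out.index = values.index
    out.attrs["n_dropped"] = int((~complete).sum())
    # selected units ordered by t-test p
    sel_idx = out.index[out["selected"]]
    out.attrs["selected_order"] = list(out.loc[sel_idx].sort_values("t_p").index)
    return out


# ---------------------------------------------------------------------------
# Ranking and FDR
# ---------------------------------------------------------------------------

def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} m * p_(j) / j over the ascending order
    statistics, capped at 1; monotone and idempotent.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def combine_ranks(
    table: pd.DataFrame,
    p_col: str = "p_adj",
    effect_col: str = "diff",
    quotient_col: str = "log_quotient",
) -> pd.DataFrame:
    """Worst-rank combination of three criteria.

    Each criterion is ranked 1-based with ties sharing the minimal rank:
    smaller adjusted p is better; larger |effect| and larger |quotient|
    are better. ``combined_rank`` is the maximum of the three. Units with
    any missing criterion are ranked last (rank = number of units) and
    counted in ``attrs['n_unranked']``. The returned table is ordered by
    combined_rank ascending, ties broken by adjusted p, then input order.
    """
    for col in (p_col, effect_col, quotient_col):
        if col not in table.columns:
            raise DataError(f"criterion column {col!r} missing")
    n = len(table)
    p = table[p_col].to_numpy(float)
    eff = np.abs(table[effect_col].to_numpy(float))
    quo = np.abs(table[quotient_col].to_numpy(float))
    bad = np.isnan(p) | np.isnan(eff) | np.isnan(quo)

    def _rank(values, ascending):
        v = values if ascending else -values
        r = np.full(n, n, dtype=float)
        ok = ~np.isnan(v)
        if ok.any():
            r[ok] = stats.rankdata(v[ok], method="min")
        return r

    rank_p = _rank(p, ascending=True)
    rank_effect = _rank(eff, ascending=False)
    rank_quotient = _rank(quo, ascending=False)
    combined = np.maximum.reduce([rank_p, rank_effect, rank_quotient])
    combined[bad] = n

    out = table.copy()
    out["rank_p"] = rank_p.astype(int)
    out["rank_effect"] = rank_effect.astype(int)
    out["rank_quotient"] = rank_quotient.astype(int)
    out["combined_rank"] = combined.astype(int)
    out["_input_order"] = np.arange(n)
    out = out.sort_values(
        ["combined_rank", p_col, "_input_order"], kind="stable", na_position="last"
    ).drop(columns="_input_order")
    out.attrs.update(table.attrs)
    out.attrs["n_unranked"] = int(bad.sum())
    return out


def auto_rank_cutoff(table: pd.DataFrame, fdr: float = 0.05, p_col: str = "p_adj") -> int:
    """Automatic rank cutoff: the number of units with adjusted p below
    the FDR level. The selected set is the cutoff-many best units by
    combined rank."""
    if not (0.0 < fdr < 1.0):
        raise DataError("fdr must be in (0, 1)")
    if len(table) == 0:
        raise DataError("empty differential table")
    p = table[p_col].to_numpy(float)
    return int(np.nansum(p < fdr))


def select_units(table: pd.DataFrame, fdr: float = 0.05, p_col: str = "p_adj") -> pd.Index:
    """Indices of the auto-cutoff-many best units by combined rank."""
    cutoff = auto_rank_cutoff(table, fdr=fdr, p_col=p_col)
    if "combined_rank" not in table.columns:
        raise DataError("run combine_ranks first")
    ordered = table.sort_values(["combined_rank", p_col], kind="stable")
    return ordered.index[:cutoff]


# ---------------------------------------------------------------------------
# High-level tables (shared worst-rank code path for DM and DV)
# ---------------------------------------------------------------------------

def differential_methylation(
    values,
    comparison: GroupComparison,
    prior: bool = True,
    eps: float = EPS_QUOTIENT,
    missing: str = "drop",
) -> pd.DataFrame:
    """Full differential-methylation table with worst-rank scoring.

    Criteria: BH-adjusted moderated-t p, |mean difference|, and
    |log2 quotient of group means| (with pseudo-count eps).
    """
    base = moderated_t_table(values, comparison, prior=prior, missing=missing)
    base["log_quotient"] = np.log2((base["mean1"] + eps) / (base["mean0"] + eps))
    base["p_adj"] = _adjust_with_nans(base["p"].to_numpy())
    out = combine_ranks(base, p_col="p_adj", effect_col="diff", quotient_col="log_quotient")
    return out


def differential_variability(
    values,
    comparison: GroupComparison,
    method: str = "diffvar",
    prior: bool = True,
    missing: str = "drop",
    q_threshold: float = 0.001,
    t_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full differential-variability table with worst-rank scoring.

    The test p-value comes from diffVar (moderated t on absolute
    deviations) or iEVORA (Bartlett + t regularisation); the worst-rank
    criteria are the BH-adjusted p, the between-group variance difference,
    and the log2 ratio of group variances.
    """
    if method == "diffvar":
        base = diffvar_table(values, comparison, prior=prior, missing=missing)
        base["p_adj"] = _adjust_with_nans(base["p"].to_numpy())
    elif method == "ievora":
        base = ievora_table(
            values, comparison, q_threshold=q_threshold, t_threshold=t_threshold,
            missing=missing,
        )
        base = base.rename(columns={"bartlett_stat": "statistic", "bartlett_p": "p"})
        base["p_adj"] = base["bartlett_q"]
    else:
        raise DataError(f"unknown differential-variability method {method!r}")
    out = combine_ranks(base, p_col="p_adj", effect_col="var_diff", quotient_col="var_log_ratio")
    return out


def _adjust_with_nans(p: np.ndarray) -> np.ndarray:
    out = np.full_like(np.asarray(p, float), np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = adjust_bh(np.asarray(p, float)[ok])
    return out
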