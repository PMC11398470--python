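"""Negative-binomial differential analysis of barcode and construct counts.

The count model is NB with mean mu and variance mu + alpha * mu^2.  The
workflow mirrors the standard RNA-seq recipe: median-of-ratios size
factors, per-feature method-of-moments dispersions shrunk toward a fitted
mean-dispersion trend, and per-feature NB log-link regressions with Wald
tests on a single contrast coefficient, followed by Benjamini-Hochberg
adjustment and two-threshold hit calling (padj < alpha and |log2FC| above
a fold-change cutoff).

Three contrasts cover the screen designs:

* ``condition_effect`` — one channel's libraries, test condition vs
  reference (e.g. CRISPRi induced vs uninduced, or TNF-stimulated vs not);
* ``channel_ratio`` — red (pathway reporter) vs ir (constitutive control)
  within a condition (or across all samples), with sample-level factors
  absorbing the pairing;
* ``interaction`` — change of the red:ir ratio between two conditions.

A control screen in which both reporters share the same promoter measures
each feature's sequence-intrinsic red:ir baseline; supplying that
:func:`estimate_baseline` table to :func:`nb_wald` enters it as a fixed
offset on the red-channel columns, so later screens test departures from
the measured baseline rather than from zero.

All fitting is vectorized across features (shared design matrix, batched
IRLS), which keeps genome-scale matrices fast on one core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

LN2 = float(np.log(2.0))

CONTRAST_KINDS = ("condition_effect", "channel_ratio", "interaction")


@dataclass
class DesignSpec:
    """Which columns enter the model and which coefficient is tested.

    ``condition_test`` vs ``condition_ref`` orient the reported log2FC as
    test over reference; ``channel`` restricts ``condition_effect`` to one
    reporter channel; ``condition`` restricts ``channel_ratio`` to one
    condition (None pools all samples, appropriate for a control screen).
    """

    kind: str
    condition_test: str | None = None
    condition_ref: str | None = None
    channel: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in CONTRAST_KINDS:
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.kind in ("condition_effect", "interaction"):
            if self.condition_test is None or self.condition_ref is None:
                raise ValueError(f"{self.kind} needs condition_test and condition_ref")
        if self.kind == "condition_effect" and self.channel is None:
            raise ValueError("condition_effect needs a channel")

    @property
    def involves_channel(self) -> bool:
        return self.kind in ("channel_ratio", "interaction")

    def column_mask(self, meta: pd.DataFrame) -> np.ndarray:
        """Boolean mask over matrix columns used by this contrast."""
        mask = np.ones(len(meta), dtype=bool)
        if self.kind == "condition_effect":
            mask &= (meta["channel"] == self.channel).to_numpy()
            mask &= meta["condition"].isin([self.condition_test, self.condition_ref]).to_numpy()
        elif self.kind == "channel_ratio":
            if self.condition is not None:
                mask &= (meta["condition"] == self.condition).to_numpy()
        else:  # interaction
            mask &= meta["condition"].isin([self.condition_test, self.condition_ref]).to_numpy()
        return mask

    def model_matrix(self, meta: pd.DataFrame) -> tuple[np.ndarray, int]:
        """Model matrix for the masked columns and the contrast column index.

        Levels referenced by the contrast must exist in the metadata.
        """
        for attr in ("condition_test", "condition_ref", "condition"):
            level = getattr(self, attr)
            if level is not None and level not in set(meta["condition"]):
                raise ValueError(f"condition level {level!r} absent from the design")
        if self.channel is not None and self.channel not in set(meta["channel"]):
            raise ValueError(f"channel {self.channel!r} absent from the design")

        n = len(meta)
        cols = [np.ones(n)]
        if self.kind == "condition_effect":
            cols.append((meta["condition"] == self.condition_test).to_numpy(float))
            contrast = 1
        else:
            samples = sorted(meta["sample_id"].unique())
            for s in samples[1:]:
                cols.append((meta["sample_id"] == s).to_numpy(float))
            red = (meta["channel"] == "red").to_numpy(float)
            cols.append(red)
            if self.kind == "channel_ratio":
                contrast = len(cols) - 1
            else:
                test = (meta["condition"] == self.condition_test).to_numpy(float)
                cols.append(red * test)
                contrast = len(cols) - 1
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design is not estimable (model matrix is rank-deficient)")
        return X, contrast


@dataclass
class NBModelParams:
    """Fitted normalization and dispersion parameters.

    ``dispersion`` is the per-feature NB overdispersion alpha used for
    testing; ``trend`` holds the (intercept, slope) of the log-log
    mean-dispersion fit.
    """

    size_factors: pd.Series
    dispersion: pd.Series
    trend: tuple[float, float]
    raw_dispersion: pd.Series | None = None


def size_factors(matrix: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Each column's factor is the median, over features with all-positive
    counts, of the count divided by the feature's geometric mean across
    columns.  When no feature is positive everywhere, ``pseudo_reference``
    computes geometric means over the positive entries of each feature
    instead; without the flag that situation raises.
    """
    counts = matrix.to_numpy(dtype=float)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any():
        sub = counts[all_pos]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / ref[:, None]
    elif pseudo_reference:
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(np.where(counts > 0, counts, 1.0)), np.nan)
        log_ref = np.nanmean(logc, axis=1)
        usable = np.isfinite(log_ref)
        if not usable.any():
            raise ValueError("no feature with a positive count")
        ratios = np.exp(logc[usable] - log_ref[usable, None])
    else:
        raise ValueError(
            "no feature has positive counts in every column; rerun with "
            "pseudo_reference=True to use a positive-entry pseudo-reference")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        sf = np.nanmedian(ratios, axis=0)
    if not (np.isfinite(sf).all() and (sf > 0).all()):
        raise ValueError("could not compute a positive size factor for every column")
    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    return pd.Series(sf, index=matrix.columns, name="size_factor")


def estimate_dispersions(matrix: pd.DataFrame, sf: pd.Series,
                         cells: Sequence | None = None,
                         trend_weight: float = 0.5,
                         alpha_floor: float = 1e-8,
                         floor_at_trend: bool = True) -> NBModelParams:
    """Method-of-moments dispersions shrunk toward a mean-dispersion trend.

    Counts are normalized by the size factors; for each feature the
    within-cell sample variances (cells = groups of replicate columns,
    e.g. condition x channel) are pooled and converted to a raw dispersion
    ``alpha_hat = max(0, (s2 - mean) / mean^2)``.  A log-log least-squares
    trend of alpha_hat on the mean is fitted over features with positive
    raw dispersion, and the final dispersion takes a weighted geometric
    mean of trend and raw values.

    With ``floor_at_trend`` (default) raw dispersions below the trend are
    raised to the trend before averaging, so a feature is never assigned
    less dispersion than the trend predicts for its expression level.
    Per-feature moment estimates at a handful of replicates are noisy, and
    shrinking below the trend would understate the variance of quiet
    features and inflate their Wald statistics; the one-sided floor keeps
    the false-positive rate of a null screen at its nominal level.  Setting
    ``floor_at_trend=False`` restores the symmetric two-sided shrink with
    ``alpha_floor`` as the absolute lower bound.

    When fewer than 10 features have a positive raw dispersion the trend
    is replaced by the global median dispersion (with a warning).
    """
    counts = matrix.to_numpy(dtype=float)
    norm = counts / sf.to_numpy()[None, :]
    n_cols = norm.shape[1]
    if cells is None:
        cells = ["all"] * n_cols
    cells = np.asarray([str(c) for c in cells])
    if cells.shape != (n_cols,):
        raise ValueError("cells must label every column")

    mean_all = norm.mean(axis=1)
    ss = np.zeros(norm.shape[0])
    df = 0
    for cell in np.unique(cells):
        sub = norm[:, cells == cell]
        if sub.shape[1] < 2:
            continue
        ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
        df += sub.shape[1] - 1
    if df < 1:
        raise ValueError("need at least 2 replicate columns in some design cell")
    s2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(mean_all > 0, (s2 - mean_all) / mean_all ** 2, np.nan)
    raw = np.maximum(np.nan_to_num(mom, nan=0.0), 0.0)

    # Trend fit on quantile-binned *untruncated* moment estimates: the
    # per-feature moment estimator is roughly unbiased on the alpha scale
    # but strongly skewed, so averaging within mean-expression bins before
    # taking logs avoids the downward bias a log-scale per-feature fit
    # would have.  Bins whose average dispersion is not positive carry no
    # information about a log-linear trend and are dropped.
    positive = (raw > 0) & (mean_all > 0)
    a0 = a1 = None
    ok = np.isfinite(mom)
    if positive.sum() >= 10 and ok.sum() >= 40:
        logmu = np.log(mean_all[ok])
        vals = mom[ok]
        n_bins = min(20, max(2, ok.sum() // 50))
        edges = np.quantile(logmu, np.linspace(0, 1, n_bins + 1))
        which = np.clip(np.searchsorted(edges, logmu, side="right") - 1,
                        0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.sum() >= 10:
                m_alpha = float(vals[sel].mean())
                if m_alpha > 0:
                    xs.append(float(logmu[sel].mean()))
                    ys.append(np.log(m_alpha))
        if len(xs) >= 2:
            a1, a0 = np.polyfit(xs, ys, 1)
        elif len(xs) == 1:
            a0, a1 = ys[0], 0.0
    if a0 is None:
        med = float(np.median(raw[mean_all > 0])) if (mean_all > 0).any() else 0.0
        med = max(med, alpha_floor)
        warnings.warn(
            "too few informative features for a mean-dispersion trend; "
            "falling back to the global median dispersion", RuntimeWarning)
        a0, a1 = np.log(med), 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        log_trend = a0 + a1 * np.log(np.where(mean_all > 0, mean_all, 1.0))
    trend_alpha = np.exp(log_trend)
    if floor_at_trend:
        log_raw = np.log(np.maximum(raw, np.maximum(trend_alpha, alpha_floor)))
    else:
        log_raw = np.log(np.maximum(raw, alpha_floor))
    final = np.exp(trend_weight * log_trend + (1.0 - trend_weight) * log_raw)
    final = np.where(mean_all > 0, final, 0.0)

    return NBModelParams(
        size_factors=sf,
        dispersion=pd.Series(final, index=matrix.index, name="dispersion"),
        trend=(float(a0), float(a1)),
        raw_dispersion=pd.Series(raw, index=matrix.index, name="raw_dispersion"),
    )


def _batched_irls(Y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                  alpha: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Fit NB log-link regressions for all features at once.

    Y: (F, n) counts; X: (n, p) shared design; offset: (F, n) log offsets;
    alpha: (F,) dispersions.  Returns (beta (F, p), cov (F, p, p),
    converged (F,)).
    """
    F, n = Y.shape
    p = X.shape[1]
    # start from a least-squares fit on shifted log counts
    z0 = np.log(Y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (F, p)
    converged = np.zeros(F, dtype=bool)
    active = np.arange(F)
    cov = np.zeros((F, p, p))
    for _ in range(max_iter):
        if active.size == 0:
            break
        b = beta[active]
        eta = np.clip(offset[active] + b @ X.T, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[active][:, None] * mu)
        W = np.maximum(W, 1e-12)
        z = (eta - offset[active]) + (Y[active] - mu) / mu
        # normal equations per feature
        XW = X[None, :, :] * W[:, :, None]           # (f, n, p)
        A = np.einsum("np,fnq->fpq", X, XW)          # (f, p, p)
        rhs = np.einsum("fnp,fn->fp", XW, z)
        try:
            new_b = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.eye(p)[None, :, :]
            new_b = np.linalg.solve(A, rhs[..., None])[..., 0]
        delta = np.abs(new_b - b).max(axis=1)
        beta[active] = new_b
        done = delta < tol
        if done.any():
            # Fisher information at the converged estimate
            cov_a = np.linalg.pinv(A[done])
            cov[active[done]] = cov_a
            converged[active[done]] = True
            active = active[~done]
    if active.size:
        # non-converged: still report curvature at the last iterate
        b = beta[active]
        eta = np.clip(offset[active] + b @ X.T, -30.0, 30.0)
        mu = np.exp(eta)
        W = np.maximum(mu / (1.0 + alpha[active][:, None] * mu), 1e-12)
        XW = X[None, :, :] * W[:, :, None]
        A = np.einsum("np,fnq->fpq", X, XW)
        cov[active] = np.linalg.pinv(A)
    return beta, cov, converged


def nb_wald(matrix: pd.DataFrame, params: NBModelParams, design: DesignSpec,
            baseline: pd.DataFrame | None = None,
            max_iter: int = 50) -> pd.DataFrame:
    """Per-feature NB Wald test of the design's contrast coefficient.

    Log size factors enter as fixed offsets; when a ``baseline`` table
    (columns ``beta0``, ``se``) is supplied and the contrast involves the
    channel ratio, each feature's baseline log2 ratio adds ``beta0 * ln 2``
    to the offset of its red-channel columns, so the test measures the
    departure from the control-screen baseline.  The baseline is treated
    as known: its uncertainty is reported upstream but not propagated.

    Returns a DataFrame with baseMean, log2FC, SE, stat, pvalue and a
    convergence flag; all-zero features get NA statistics, and features
    whose fit did not converge are flagged with NA p-values.  For features
    with an all-zero contrast group the reported log2FC is recomputed from
    0.5-pseudo-counted normalized means (reporting only — the test
    statistic keeps the model fit).
    """
    meta = matrix.columns.to_frame(index=False)
    mask = design.column_mask(meta)
    if mask.sum() < 2:
        raise ValueError("contrast selects fewer than 2 columns")
    sub = matrix.loc[:, mask]
    meta = meta.loc[mask].reset_index(drop=True)
    X, contrast = design.model_matrix(meta)
    sf = params.size_factors.loc[sub.columns]
    alpha = params.dispersion.reindex(matrix.index).to_numpy(dtype=float)

    Y = sub.to_numpy(dtype=float)
    F, n = Y.shape
    offset = np.broadcast_to(np.log(sf.to_numpy())[None, :], (F, n)).copy()
    if baseline is not None and design.involves_channel:
        beta0 = baseline["beta0"].reindex(matrix.index).fillna(0.0).to_numpy()
        red_cols = (meta["channel"] == "red").to_numpy()
        offset[:, red_cols] += (beta0 * LN2)[:, None]

    nonzero = Y.sum(axis=1) > 0
    beta = np.full((F, X.shape[1]), np.nan)
    se = np.full(F, np.nan)
    converged = np.zeros(F, dtype=bool)
    if nonzero.any():
        b, cov, conv = _batched_irls(Y[nonzero], X, offset[nonzero],
                                     alpha[nonzero], max_iter=max_iter)
        beta[nonzero] = b
        var = cov[:, contrast, contrast]
        se[nonzero] = np.sqrt(np.maximum(var, 0.0))
        converged[nonzero] = conv

    log2fc = beta[:, contrast] / LN2
    se2 = se / LN2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = log2fc / se2
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    pvalue = np.where(np.isfinite(stat) & converged, pvalue, np.nan)

    base_mean = (Y / sf.to_numpy()[None, :]).mean(axis=1)

    # reporting-only fold change for features with an all-zero contrast group
    contrast_col = X[:, contrast]
    in_test = contrast_col > 0
    norm = Y / sf.to_numpy()[None, :]
    zero_group = (Y[:, in_test].sum(axis=1) == 0) | (Y[:, ~in_test].sum(axis=1) == 0)
    zero_group &= nonzero
    if zero_group.any():
        m1 = norm[zero_group][:, in_test].mean(axis=1) + 0.5
        m0 = norm[zero_group][:, ~in_test].mean(axis=1) + 0.5
        log2fc[zero_group] = np.log2(m1 / m0)

    out = pd.DataFrame({
        "baseMean": base_mean,
        "log2FC": log2fc,
        "SE": se2,
        "stat": stat,
        "pvalue": pvalue,
        "converged": converged,
    }, index=matrix.index)
    out.loc[~nonzero, ["log2FC", "SE", "stat", "pvalue"]] = np.nan
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    NA entries are excluded from the multiplicity count and stay NA.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return out
    order = np.argsort(p[ok], kind="stable")
    ranked = p[ok][order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    vals = np.empty(m)
    vals[order] = adj
    out[ok] = vals
    return out


def call_hits(results: pd.DataFrame, alpha: float = 0.01,
              lfc_threshold: float = 1.5) -> pd.DataFrame:
    """Add significance and hit flags to a results table with ``padj``.

    ``significant`` means padj < alpha; ``hit`` additionally requires
    |log2FC| > lfc_threshold; ``direction`` records the sign of the change
    for hits ("up"/"down", empty otherwise).
    """
    if "padj" not in results.columns:
        raise ValueError("results must carry a padj column (run bh_adjust first)")
    out = results.copy()
    padj = out["padj"].to_numpy(dtype=float)
    lfc = out["log2FC"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        significant = np.where(np.isfinite(padj), padj < alpha, False)
        hit = significant & np.where(np.isfinite(lfc), np.abs(lfc) > lfc_threshold, False)
    out["significant"] = significant
    out["hit"] = hit
    out["direction"] = np.where(hit, np.where(lfc > 0, "up", "down"), "")
    return out


def estimate_baseline(control_matrix: pd.DataFrame,
                      pseudo_reference: bool = True):
    """Per-feature baseline log2 red:ir ratio from a control screen.

    ``control_matrix`` must be channel-paired (rows = features, columns =
    (sample, channel) libraries, e.g. the output of
    :func:`ciberseq.tabulate.paired_matrix` or :func:`~ciberseq.tabulate.pair_counts`).
    Features observed in only one channel cannot contribute a ratio; they
    are excluded and returned separately.

    Returns (BaselineTable, excluded_ids): the table has columns ``beta0``
    (log2 red:ir) and ``se``.
    """
    if control_matrix.shape[0] == 0 or control_matrix.shape[1] == 0:
        raise ValueError("empty control screen")
    meta = control_matrix.columns.to_frame(index=False)
    if set(meta["channel"]) != {"red", "ir"}:
        raise ValueError("control screen must contain both channels")
    red_cols = (meta["channel"] == "red").to_numpy()
    vals = control_matrix.to_numpy(dtype=float)
    has_red = vals[:, red_cols].sum(axis=1) > 0
    has_ir = vals[:, ~red_cols].sum(axis=1) > 0
    both = has_red & has_ir
    excluded = control_matrix.index[~both]
    usable = control_matrix.loc[both]
    if usable.shape[0] == 0:
        raise ValueError("no feature observed in both channels of the control screen")

    sf = size_factors(usable, pseudo_reference=pseudo_reference)
    cells = [f"{c}:{ch}" for c, ch in zip(meta["condition"], meta["channel"])]
    params = estimate_dispersions(usable, sf, cells=cells)
    design = DesignSpec(kind="channel_ratio", condition=None)
    res = nb_wald(usable, params, design)
    table = pd.DataFrame({"beta0": res["log2FC"], "se": res["SE"]},
                         index=usable.index)
    return table, list(excluded)
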