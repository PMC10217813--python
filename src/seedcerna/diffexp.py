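"""Count normalization and negative-binomial differential expression.

The two-group test follows the classic DESeq recipe: median-of-ratios size
factors, method-of-moments gene-wise dispersion pooled across the two
groups, and an exact conditional test on the two group sums under the
fitted negative-binomial null. Screening gates reproduce the thresholds
used for lncRNA discovery (|log2FC| >= 1, FDR < 0.05), ceRNA candidates
(FDR < 0.01, strict) and small RNAs (FDR <= 0.01, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SCREEN_MODES = {
    # mode: (min |log2FC|, FDR threshold, FDR inclusive?)
    "lnc_fdr05": (1.0, 0.05, False),
    "cerna_fdr01": (1.0, 0.01, False),
    "mirna": (1.0, 0.01, True),
}


def fpkm(counts: pd.DataFrame, lengths: pd.Series, lib_sizes: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (length * lib_size)."""
    lengths = lengths.reindex(counts.index)
    lib_sizes = lib_sizes.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    if lib_sizes.isna().any() or (lib_sizes <= 0).any():
        raise ValueError("every sample needs a positive library size")
    return counts.mul(1e9).div(lengths, axis=0).div(lib_sizes, axis=1)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors; features with any zero are excluded."""
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature with all-positive counts; add a pseudocount before "
            "computing size factors"
        )
    logs = np.log(mat[allpos])
    log_geomean = logs.mean(axis=1)
    log_factors = np.median(logs - log_geomean[:, None], axis=0)
    # unit geometric mean, so re-estimating on the normalized matrix gives 1
    factors = np.exp(log_factors - log_factors.mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    if var <= mean * (1 + 1e-12):
        return stats.poisson.logpmf(k, mean)
    n = mean * mean / (var - mean)
    p = n / (n + mean)
    return stats.nbinom.logpmf(k, n, p)


def _exact_cond_p(ka: int, kb: int, mu_a: float, mu_b: float, var_a: float, var_b: float) -> float:
    """Two-sided exact test: probability, conditional on the total, of a
    split at most as likely as the observed one under the null."""
    total = ka + kb
    if total == 0:
        return 1.0
    a = np.arange(total + 1)
    logp = _nb_logpmf(a, mu_a, var_a) + _nb_logpmf(total - a, mu_b, var_b)
    logp -= logp.max()
    probs = np.exp(logp)
    obs = probs[ka]
    denom = probs.sum()
    if denom <= 0 or not np.isfinite(denom):
        return 1.0
    return float(min(1.0, probs[probs <= obs * (1 + 1e-10)].sum() / denom))


@dataclass
class NBTestOptions:
    dispersion_floor: float = 1e-8
    # "pooled" shares the median method-of-moments dispersion across all
    # features (well calibrated at small n); "per-feature" keeps gene-wise
    # estimates (anti-conservative at n = 3); "pooled-max" takes the maximum
    # of the two (conservative).
    dispersion_mode: str = "pooled"
    pseudocount: float = 0.5  # for log2FC only


def _mom_dispersions(
    norm: np.ndarray, raw: np.ndarray, sf: np.ndarray, ia: np.ndarray, ib: np.ndarray
) -> np.ndarray:
    """Gene-wise method-of-moments dispersion pooled across both groups.

    For normalized counts x = k/s, E[var(x)] ~= q * mean(1/s) + alpha * q^2,
    so alpha = (pooled within-group variance - shot noise) / q^2.
    """
    na, nb = ia.sum(), ib.sum()
    var_a = norm[:, ia].var(axis=1, ddof=1)
    var_b = norm[:, ib].var(axis=1, ddof=1)
    w = (var_a * (na - 1) + var_b * (nb - 1)) / (na + nb - 2)
    q = norm.mean(axis=1)
    z = q * np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(q > 0, (w - z) / np.maximum(q, 1e-300) ** 2, 0.0)
    return alpha


def nb_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    options: NBTestOptions | None = None,
) -> pd.DataFrame:
    """Two-group negative-binomial test of equal means, per feature.

    Returns a DataFrame with normalized group means, log2FC (B over A,
    pseudocount 0.5), dispersion, two-sided p-value and BH FDR.
    """
    opt = options or NBTestOptions()
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group for dispersion estimation")
    cols = list(group_a) + list(group_b)
    missing = set(cols) - set(counts.columns)
    if missing:
        raise KeyError(f"samples not in counts: {sorted(missing)}")
    sub = counts[cols]
    raw = sub.to_numpy(dtype=float)
    if np.any(raw < 0):
        raise ValueError("negative counts")
    sf = size_factors(sub).to_numpy()
    norm = raw / sf
    ia = np.zeros(len(cols), dtype=bool)
    ia[: len(group_a)] = True
    ib = ~ia

    alpha = _mom_dispersions(norm, raw, sf, ia, ib)
    alpha = np.maximum(alpha, opt.dispersion_floor)
    if opt.dispersion_mode in ("pooled-max", "pooled"):
        informative = alpha > opt.dispersion_floor
        pooled = float(np.median(alpha[informative])) if informative.any() else opt.dispersion_floor
        if opt.dispersion_mode == "pooled":
            alpha = np.full_like(alpha, pooled)
        else:  # conservative sharing: max(gene-wise, pooled)
            alpha = np.maximum(alpha, pooled)
    elif opt.dispersion_mode != "per-feature":
        raise ValueError(f"unknown dispersion_mode {opt.dispersion_mode!r}")

    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    log2fc = np.log2((mean_b + opt.pseudocount) / (mean_a + opt.pseudocount))

    s_a, s_b = sf[ia], sf[ib]
    q0 = norm.mean(axis=1)  # pooled mean under the null
    ka = raw[:, ia].sum(axis=1).astype(int)
    kb = raw[:, ib].sum(axis=1).astype(int)
    pvals = np.ones(len(sub))
    for i in range(len(sub)):
        mu_a = q0[i] * s_a.sum()
        mu_b = q0[i] * s_b.sum()
        var_a = mu_a + alpha[i] * q0[i] ** 2 * (s_a**2).sum()
        var_b = mu_b + alpha[i] * q0[i] ** 2 * (s_b**2).sum()
        pvals[i] = _exact_cond_p(ka[i], kb[i], mu_a, mu_b, var_a, var_b)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "dispersion": alpha,
            "pvalue": pvals,
            "fdr": bh_fdr(pvals),
        },
        index=sub.index,
    )


def de_screen(results: pd.DataFrame, mode: str) -> pd.Series:
    """Call features up / down / ns under the chosen gate set."""
    if mode not in SCREEN_MODES:
        raise ValueError(f"unknown screen mode {mode!r}; known: {sorted(SCREEN_MODES)}")
    min_lfc, fdr_thr, inclusive = SCREEN_MODES[mode]
    lfc = results["log2fc"]
    fdr = results["fdr"]
    passed = (lfc.abs() >= min_lfc) & ((fdr <= fdr_thr) if inclusive else (fdr < fdr_thr))
    call = pd.Series("ns", index=results.index, name="call")
    call[passed & (lfc > 0)] = "up"
    call[passed & (lfc < 0)] = "down"
    return call


def ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddc = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddc))


def fold_increase(a: float, b: float) -> float:
    """Relative increase (b - a) / a, rounded to 2 decimals."""
    if a <= 0:
        raise ValueError("baseline count must be positive")
    return round((b - a) / a, 2)
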