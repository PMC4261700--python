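"""Count-based differential expression between two host libraries.

The two-library test is the MA-plot random-sampling statistic: conditional
on a gene's total count t = k1 + k2, the null distribution of k1 is
binomial(t, n1/(n1+n2)) with n1, n2 the effective library sizes, and the
reported z / p are the (continuity-corrected) normal approximation to that
exact conditional test. M and A are the usual log2 fold change and mean
log2 intensity, with zero counts offset by 0.5 in M/A only — never in the
test itself.

Orientation convention: contrasts are (original host, derived host) and
"up" means higher expression in the ORIGINAL library (M > 0).

Between-library normalization is the trimmed mean of M-values re-implemented
from its published definition; multiple testing uses Storey q-values (with a
Benjamini-Hochberg fallback/alternative).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import CountMatrix

# ------------------------------------------------------------ normalization


def tmm_normalization(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values factors, one per sample.

    The reference column is the sample whose upper quartile (of library-size
    scaled counts) is closest to the mean upper quartile. For each sample,
    gene-wise M (log2 ratio vs reference, library-size adjusted) and A are
    computed on genes nonzero in both columns; the top and bottom ``trim_m``
    fraction by M and ``trim_a`` by A are trimmed; the factor is the
    precision-weighted mean M, exponentiated. Factors are rescaled to have
    geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lib = counts.sum(axis=0).astype(float) if lib_sizes is None else lib_sizes.astype(float)
    scaled = counts.divide(lib, axis=1)
    if ref_sample is None:
        uq = scaled.quantile(0.75, axis=0)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(dtype=float)
    n_ref = float(lib[ref_sample])

    log_factors = {}
    for sample in counts.columns:
        if sample == ref_sample:
            log_factors[sample] = 0.0
            continue
        obs = counts[sample].to_numpy(dtype=float)
        n_obs = float(lib[sample])
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0:
            warnings.warn(f"no shared nonzero genes for {sample!r}; factor set to 1")
            log_factors[sample] = 0.0
            continue
        o, r = obs[keep], ref[keep]
        M = np.log2((o / n_obs) / (r / n_ref))
        A = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))

        n = len(M)
        rank_m = stats.rankdata(M, method="ordinal")
        rank_a = stats.rankdata(A, method="ordinal")
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any():
            warnings.warn(f"all genes trimmed for {sample!r}; factor set to 1")
            log_factors[sample] = 0.0
            continue
        log_factors[sample] = float(np.sum(w[sel] * M[sel]) / np.sum(w[sel]))

    f = pd.Series({s: 2.0 ** v for s, v in log_factors.items()})[counts.columns]
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    return f


# ---------------------------------------------------------------- the test


@dataclass
class MarsResult:
    M: float
    A: float
    z: float
    p: float
    tested: bool = True


def mars_statistic(k1: int, k2: int, n1: float, n2: float) -> MarsResult:
    """MA statistic and conditional-binomial p-value for one gene.

    k1/n1 is the original-host library, k2/n2 the derived one. Both counts
    zero yields no test.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("effective library sizes must be positive")
    if k1 == 0 and k2 == 0:
        return MarsResult(M=0.0, A=float("-inf"), z=0.0, p=float("nan"), tested=False)
    k1m = k1 if k1 > 0 else 0.5
    k2m = k2 if k2 > 0 else 0.5
    x, y = math.log2(k1m / n1), math.log2(k2m / n2)
    M, A = x - y, 0.5 * (x + y)

    t = k1 + k2
    # dev = k1 - t*q and sd = sqrt(t*q*(1-q)) written in exactly
    # swap-antisymmetric form so exchanging the libraries negates z
    # and preserves p bit-for-bit
    dev = (k1 * n2 - k2 * n1) / (n1 + n2)
    sd = math.sqrt(t * (n1 * n2)) / (n1 + n2)
    z = (abs(dev) - 0.5) / sd if abs(dev) > 0.5 else 0.0
    z = math.copysign(z, dev) if dev else 0.0
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return MarsResult(M=M, A=A, z=z, p=p)


def mars_table(
    counts: pd.DataFrame,
    sample_original: str,
    sample_derived: str,
    lib_sizes: pd.Series | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Vectorized two-library MA test over all genes.

    Effective library size = library size x normalization factor. Returns a
    gene-indexed frame with M, A, z, p (p is NaN for untested genes).
    """
    lib = counts.sum(axis=0).astype(float) if lib_sizes is None else lib_sizes.astype(float)
    if factors is not None:
        lib = lib * factors
    k1 = counts[sample_original].to_numpy(dtype=float)
    k2 = counts[sample_derived].to_numpy(dtype=float)
    n1, n2 = float(lib[sample_original]), float(lib[sample_derived])

    k1m = np.where(k1 > 0, k1, 0.5)
    k2m = np.where(k2 > 0, k2, 0.5)
    x, y = np.log2(k1m / n1), np.log2(k2m / n2)
    M, A = x - y, 0.5 * (x + y)

    t = k1 + k2
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (k1 * n2 - k2 * n1) / (n1 + n2)
        sd = np.sqrt(t * (n1 * n2)) / (n1 + n2)
        z = np.where(np.abs(dev) > 0.5, np.sign(dev) * (np.abs(dev) - 0.5) / sd, 0.0)
    p = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    tested = t > 0
    p = np.where(tested, p, np.nan)
    return pd.DataFrame(
        {"M": M, "A": A, "z": np.where(tested, z, 0.0), "p": p, "tested": tested},
        index=counts.index,
    )


# ----------------------------------------------------------- q-values


def qvalues(pvals: np.ndarray | list[float], method: str = "storey") -> np.ndarray:
    """FDR q-values; ``storey`` (pi0-estimated) or ``bh`` step-up.

    Storey's pi0 is estimated on a lambda grid 0.05..0.95 with cubic-spline
    smoothing evaluated at the largest lambda. Fewer than 10 p-values fall
    back to BH with a warning. Results are invariant to input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError(f"unknown method {method!r}")
    mask = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return q
    if method == "storey" and m < 10:
        warnings.warn("fewer than 10 p-values; falling back to BH")
        method = "bh"
    pi0 = 1.0
    if method == "storey":
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(pv > l).sum() / (m * (1.0 - l)) for l in lam])
        from scipy.interpolate import UnivariateSpline

        spline = UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(np.clip(spline(lam[-1]), 1.0 / m, 1.0))

    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order]
    qv = pi0 * m * ranked / np.arange(1, m + 1)
    qv = np.minimum.accumulate(qv[::-1])[::-1]
    qv = np.clip(qv, 0.0, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[mask] = out
    return q


# ----------------------------------------------------------- calling


def call_dets(
    results: pd.DataFrame, q_max: float = 0.05, min_abs_log2fc: float = 1.0, stat_col: str = "q"
) -> pd.DataFrame:
    """Add an up/down/ns call per gene.

    up: significant and M > min_abs_log2fc (higher in the original host);
    down: significant and M < -min_abs_log2fc.
    """
    if stat_col not in results.columns:
        raise ValueError(f"results lack the {stat_col!r} column")
    sig = results[stat_col] < q_max
    call = np.where(
        sig & (results["M"] > min_abs_log2fc),
        "up",
        np.where(sig & (results["M"] < -min_abs_log2fc), "down", "ns"),
    )
    out = results.copy()
    out["call"] = call
    return out


def det_tallies(called: pd.DataFrame) -> dict[str, int]:
    vc = called["call"].value_counts()
    up, down = int(vc.get("up", 0)), int(vc.get("down", 0))
    return {"up": up, "down": down, "total_de": up + down}


def intersect_up_sets(
    up_sets: dict[str, set[str]], sex_of: dict[str, str]
) -> dict[str, set[str]]:
    """Per-sex consistent up-sets and the cross-sex intersection.

    ``up_sets`` is keyed by contrast name; ``sex_of`` maps contrast -> sex.
    The per-sex set is the intersection over that sex's contrasts; the final
    set intersects the per-sex sets.
    """
    by_sex: dict[str, list[set[str]]] = {}
    for contrast, genes in up_sets.items():
        by_sex.setdefault(sex_of[contrast], []).append(set(genes))
    out: dict[str, set[str]] = {}
    per_sex = []
    for sex, sets in sorted(by_sex.items()):
        consistent = set.intersection(*sets)
        out[f"consistent_{sex}"] = consistent
        per_sex.append(consistent)
    out["consistent_all"] = set.intersection(*per_sex) if per_sex else set()
    return out


# ----------------------------------------------------------- extras


def sample_correlations(
    counts: pd.DataFrame, lib_sizes: pd.Series | None = None, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Spearman correlation matrix of normalized counts (ties mid-ranked).

    Zero-variance samples get NaN rows/columns (undefined correlation).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lib = counts.sum(axis=0).astype(float) if lib_sizes is None else lib_sizes.astype(float)
    if factors is not None:
        lib = lib * factors
    norm = counts.divide(lib, axis=1)
    rho = norm.corr(method="spearman").to_numpy()
    var0 = norm.std(axis=0).to_numpy() == 0.0
    rho[var0, :] = np.nan
    rho[:, var0] = np.nan
    np.fill_diagonal(rho, np.where(var0, np.nan, 1.0))
    return pd.DataFrame(rho, index=counts.columns, columns=counts.columns)


def delta_ct(
    ct_target: float | list[float], ct_ref: float | list[float]
) -> float | tuple[float, float]:
    """Relative expression 2^-(Ct_target - Ct_ref).

    Scalars return a scalar; replicate lists are paired and return
    (mean, sd) of the per-replicate relative expressions.
    """
    scalar = np.isscalar(ct_target) and np.isscalar(ct_ref)
    t = np.atleast_1d(np.asarray(ct_target, dtype=float))
    r = np.atleast_1d(np.asarray(ct_ref, dtype=float))
    if r.size == 0:
        raise ValueError("reference Ct values are missing")
    if (t <= 0).any() or (r <= 0).any():
        raise ValueError("Ct values must be positive")
    if t.size != r.size:
        raise ValueError("target and reference replicate counts differ")
    rel = 2.0 ** -(t - r)
    if scalar:
        return float(rel[0])
    return float(rel.mean()), float(rel.std(ddof=0))
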