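"""Per-GATC differential occupancy statistics.

The contrast between a Dam-fusion condition and the Dam-only control is
scored fragment by fragment on log2 CPM with an empirical-Bayes moderated
t-statistic: per-fragment sample variances are shrunk towards a prior
variance s0^2 with prior degrees of freedom d0, both estimated from the
ensemble of fragments by matching moments of log sample variances (the
scaled-F model of moderated t-statistics).  Fragments passing the stringent
per-site threshold p < 1e-5 feed the peak-merging step.

The model: for fragment g with pooled residual variance s_g^2 on d degrees
of freedom,

    s_g^2 | sigma_g^2 ~ sigma_g^2 * chi^2_d / d,     1/sigma_g^2 ~ chi^2_d0 / (d0 s0^2)

gives the posterior variance  s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)  and

    t~_g = logFC_g / (s~_g * sqrt(1/n1 + 1/n2))  ~  t_{d + d0}   under the null.

d0 = 0 recovers the classical pooled two-sample t; d0 = +inf gives a normal
z-statistic with fixed standard deviation s0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

P_SITE_THRESHOLD = 1e-5  # per-GATC significance gate before peak merging


@dataclass
class EBHyperparams:
    """Prior degrees of freedom (may be math.inf) and prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError("prior df d0 must be >= 0 (0 is the no-shrinkage limit)")
        if not self.s0_sq > 0:
            raise ValueError("prior variance must be > 0")


def log_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(x + pseudocount); inputs must be non-negative."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative values in count/CPM matrix")
    return np.log2(matrix + pseudocount)


def estimate_eb_hyperparams(variances: np.ndarray, df: int) -> EBHyperparams:
    """Method-of-moments fit of (d0, s0^2) from log sample variances.

    With z_g = ln s_g^2, the scaled-F model implies
        var(z) = trigamma(d/2) + trigamma(d0/2)
        mean(z) = ln s0^2 + digamma(d/2) - ln(d/2) - digamma(d0/2) + ln(d0/2).
    Solve trigamma(d0/2) = max(0, var(z) - trigamma(d/2)); a non-positive
    right-hand side means the variances are no more spread than chi^2 sampling
    alone allows, so d0 = +inf and s0^2 is the common value.
    """
    v = np.asarray(variances, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError("need >= 10 finite fragment variances")
    if df < 1:
        raise ValueError("residual df must be >= 1")
    if np.all(v <= 0):
        raise ValueError("all variances are zero: degenerate data")
    z = np.log(np.maximum(v, 1e-300))
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    if float(np.var(z)) < 1e-14:
        # degenerate zero spread: the common value is known exactly
        return EBHyperparams(d0=math.inf, s0_sq=float(np.exp(np.mean(z))))
    excess = float(np.var(z, ddof=1) - special.polygamma(1, df / 2.0))
    if excess <= 0:
        return EBHyperparams(d0=math.inf, s0_sq=float(np.exp(np.mean(e))))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(
        np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return EBHyperparams(d0=d0, s0_sq=s0_sq)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        tetra = float(special.polygamma(2, x))
        delta = tri * (1.0 - tri / y) / tetra
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    return x


def moderated_t_test(
    log_matrix: pd.DataFrame,
    fusion_samples: list[str],
    dam_samples: list[str],
    hyper: EBHyperparams | None = None,
    p_threshold: float = P_SITE_THRESHOLD,
) -> pd.DataFrame:
    """Moderated two-sample t per fragment: fusion condition vs. Dam-only.

    Returns a table with logFC (mean fusion - mean Dam on the log2 scale),
    the ordinary pooled variance and residual df, the posterior variance,
    the moderated t, a two-sided p from t_{d + d0} (normal when d0 = inf),
    and the per-site significance flag at ``p_threshold``.

    ``hyper`` with d0 = 0 is accepted as the no-shrinkage limit (classical
    pooled t).  When ``hyper`` is None the prior is estimated from the data.
    """
    if set(fusion_samples) & set(dam_samples):
        raise ValueError("fusion and Dam sample sets overlap")
    n1, n2 = len(fusion_samples), len(dam_samples)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups need at least one sample")
    x1 = log_matrix[fusion_samples].to_numpy(float)
    x2 = log_matrix[dam_samples].to_numpy(float)
    logfc = x1.mean(axis=1) - x2.mean(axis=1)
    d = n1 + n2 - 2
    ss = np.zeros(len(log_matrix))
    if n1 > 1:
        ss += x1.var(axis=1, ddof=1) * (n1 - 1)
    if n2 > 1:
        ss += x2.var(axis=1, ddof=1) * (n2 - 1)
    s_sq = ss / d if d > 0 else np.full(len(log_matrix), np.nan)

    if hyper is None:
        if d < 1:
            raise ValueError("cannot estimate the prior with zero residual df")
        hyper = estimate_eb_hyperparams(s_sq, d)
    d0, s0_sq = hyper.d0, hyper.s0_sq

    if d0 == 0:
        post_var = s_sq.copy()
        df_total = float(d)
    elif math.isinf(d0):
        post_var = np.full(len(log_matrix), s0_sq)
        df_total = math.inf
    else:
        post_var = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "fragment_id": log_matrix.index,
            "logFC": logfc,
            "s_sq": s_sq,
            "df": d,
            "post_var": post_var,
            "t": t,
            "p": p,
            "significant": p < p_threshold,
        }
    ).set_index("fragment_id", drop=False)


def differential_gatc(
    counts: pd.DataFrame,
    fusion_samples: list[str],
    dam_samples: list[str],
    pseudocount: float = 1.0,
    p_threshold: float = P_SITE_THRESHOLD,
) -> pd.DataFrame:
    """CPM -> log2 -> moderated t, dropping all-zero fragments.

    All-zero rows carry no information and would produce degenerate
    variances; they are removed before fitting (the returned table simply
    omits them).
    """
    from .counts import normalize_cpm

    keep = counts.sum(axis=1) > 0
    filtered = counts.loc[keep]
    logm = log_transform(normalize_cpm(filtered), pseudocount)
    return moderated_t_test(logm, fusion_samples, dam_samples, p_threshold=p_threshold)
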