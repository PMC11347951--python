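"""Expression statistics: QC, replicate summaries, differential expression.

The differential-expression engine is a desk-scale stand-in for the exact
negative-binomial testing used by mainstream RNA-seq packages: counts are
normalized with median-of-ratios size factors, a common dispersion is
estimated by pooled method-of-moments (var = mu + phi*mu^2, floored at
1e-4), and each gene is tested with an exact conditional NB test on the
normalized group sums.  A CDS is called modulated when |log2FC| > 1 and
BH-FDR < 0.05 (both boundaries strict).

Mapping-rate QC excludes libraries that fall far below the consensus of the
others (leave-one-out median minus k robust SDs) — the rule that flags a
single failed library among otherwise consistent ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cds_extraction import CountsMatrix

__all__ = [
    "SampleQc",
    "DeResult",
    "LfqTable",
    "qc_mapping_rates",
    "summarize_replicates",
    "estimate_common_dispersion",
    "size_factors",
    "de_test",
    "bh_fdr",
    "call_modulated",
    "filter_proteins",
]


@dataclass(frozen=True)
class SampleQc:
    library_id: str
    mapping_rate: float
    excluded: bool
    reason: str = ""


@dataclass(frozen=True)
class DeResult:
    cds_id: str
    log2_fold_change: float
    p_value: float
    fdr: float
    modulated: str  # 'up' | 'down' | 'none'


@dataclass
class LfqTable:
    """Protein x replicate log2 LFQ intensities; NaN marks not-detected."""

    intensities: pd.DataFrame
    contaminant: pd.Series
    host: pd.Series

    def __post_init__(self) -> None:
        idx = self.intensities.index
        self.contaminant = self.contaminant.reindex(idx, fill_value=False).astype(bool)
        self.host = self.host.reindex(idx, fill_value=False).astype(bool)


# ---------------------------------------------------------------------------
# QC and summaries
# ---------------------------------------------------------------------------

def qc_mapping_rates(rates: dict[str, float], k: float = 5.0) -> list[SampleQc]:
    """Flag libraries with an outlying low mapping rate.

    For each library the median and MAD-based SD (1.4826 * MAD) of the
    *other* libraries are computed; the library is excluded when its rate
    falls below median - k * SD.  With k = 5 a single failed library among
    otherwise tight replicates (e.g. 8.9% against a 29.2% +/- 1.1%
    consensus) is excluded while ordinary scatter is not.
    """
    if len(rates) < 3:
        raise ValueError("mapping-rate QC needs at least 3 libraries")
    for lib, r in rates.items():
        if not 0 <= r <= 1:
            raise ValueError(f"mapping rate of {lib} outside [0, 1]: {r}")
    results = []
    libs = list(rates)
    values = np.array([rates[lib] for lib in libs])
    for i, lib in enumerate(libs):
        others = np.delete(values, i)
        med = float(np.median(others))
        sd = 1.4826 * float(np.median(np.abs(others - med)))
        low = values[i] < med - k * sd
        results.append(
            SampleQc(
                library_id=lib,
                mapping_rate=float(values[i]),
                excluded=bool(low),
                reason=(
                    f"mapping rate {values[i]:.4f} < {med:.4f} - {k:g}*{sd:.4f}"
                    if low
                    else ""
                ),
            )
        )
    if all(r.excluded for r in results):
        raise ValueError("every library flagged as an outlier; QC rule degenerate")
    return results


def summarize_replicates(values, ndigits: int | None = None) -> tuple[float, float | None]:
    """Mean and sample SD (n-1 denominator) of replicate measurements.

    ``ndigits`` applies report rounding (2 decimals in the standard
    summary tables).  With a single replicate the SD is None.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    if ndigits is not None:
        mean = round(mean, ndigits)
        sd = round(sd, ndigits) if sd is not None else None
    return mean, sd


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)
    usable = log_ref.notna()
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    sf = sf / np.exp(np.log(sf).mean())  # normalize to geometric mean 1
    return sf.fillna(1.0)


def estimate_common_dispersion(
    normalized: pd.DataFrame, groups: list[list[str]], floor: float = 1e-4
) -> float:
    """Pooled method-of-moments common dispersion.

    For var = mu + phi * mu^2, each gene/group contributes (s^2 - m) and
    m^2.  Ratios are pooled within expression deciles and the median decile
    estimate is returned: pooling keeps the estimator nearly unbiased at
    n = 3 per group, while the median stops a handful of very abundant
    genes from dominating it.
    """
    means: list[np.ndarray] = []
    excess: list[np.ndarray] = []
    for libs in groups:
        sub = normalized[libs]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1).to_numpy()
        v = sub.var(axis=1, ddof=1).to_numpy()
        keep = m > 0
        means.append(m[keep])
        excess.append(v[keep] - m[keep])
    if not means:
        return floor
    m_all = np.concatenate(means)
    e_all = np.concatenate(excess)
    if m_all.size == 0:
        return floor
    order = np.argsort(m_all)
    n_bins = min(10, max(1, m_all.size // 50))
    estimates = []
    for chunk in np.array_split(order, n_bins):
        den = float(np.sum(m_all[chunk] ** 2))
        if den > 0:
            estimates.append(float(np.sum(e_all[chunk])) / den)
    if not estimates:
        return floor
    return max(float(np.median(estimates)), floor)


def _nb_logpmf(x: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if phi <= 0:
        return stats.poisson.logpmf(x, mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return stats.nbinom.logpmf(x, r, p)


def _exact_nb_p(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional NB p-value for group sums.

    Sums of n i.i.d. NB(mu, phi) counts are NB(n*mu, phi/n); conditioning
    on the total, the p-value sums the probabilities of all splits no more
    likely than the observed one (doubling-by-enumeration, the standard
    exact-test convention).
    """
    total = s_a + s_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    a = np.arange(total + 1)
    log_p = _nb_logpmf(a, n_a * mu, phi / n_a) + _nb_logpmf(total - a, n_b * mu, phi / n_b)
    log_p -= log_p.max()
    prob = np.exp(log_p)
    prob /= prob.sum()
    observed = prob[s_a]
    return float(min(1.0, prob[prob <= observed * (1 + 1e-10)].sum()))


def de_test(
    counts: CountsMatrix,
    group_a: str,
    group_b: str,
    lfc_cut: float = 1.0,
    fdr_cut: float = 0.05,
    dispersion: float | None = None,
) -> list[DeResult]:
    """Exact-style NB differential expression of condition B versus A.

    log2 fold changes are computed from normalized group means with a 0.5
    pseudo-count (positive = higher in ``group_b``); p-values come from the
    exact conditional NB test under a pooled common dispersion; FDR is
    Benjamini-Hochberg.  Genes with zero counts in both groups get
    p = 1 and logFC = 0.
    """
    libs_a = counts.libraries_for(group_a)
    libs_b = counts.libraries_for(group_b)
    if len(libs_a) < 2 or len(libs_b) < 2:
        raise ValueError("differential expression needs >= 2 replicates per group")
    sub = counts.counts[libs_a + libs_b]
    sf = size_factors(sub)
    normalized = sub.div(sf, axis=1)
    if dispersion is None:
        dispersion = estimate_common_dispersion(normalized, [libs_a, libs_b])

    mean_a = normalized[libs_a].mean(axis=1)
    mean_b = normalized[libs_b].mean(axis=1)
    logfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))

    # integer pseudo-counts at the common scale for the exact test
    pseudo = normalized.round().astype(int)
    s_a = pseudo[libs_a].sum(axis=1)
    s_b = pseudo[libs_b].sum(axis=1)

    p_values = np.ones(len(sub))
    for i, gene in enumerate(sub.index):
        sa, sb_ = int(s_a.loc[gene]), int(s_b.loc[gene])
        if sa + sb_ > 0:
            p_values[i] = _exact_nb_p(sa, sb_, len(libs_a), len(libs_b), dispersion)
    fdr = bh_fdr(p_values)

    results = []
    for i, gene in enumerate(sub.index):
        lfc = 0.0 if (s_a.loc[gene] + s_b.loc[gene]) == 0 else float(logfc.loc[gene])
        results.append(
            DeResult(
                cds_id=str(gene),
                log2_fold_change=lfc,
                p_value=float(p_values[i]),
                fdr=float(fdr[i]),
                modulated=call_modulated(lfc, float(fdr[i]), lfc_cut, fdr_cut),
            )
        )
    return results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(ranked, 1.0)
    return fdr


def call_modulated(
    log2_fold_change: float, fdr: float, lfc_cut: float = 1.0, fdr_cut: float = 0.05
) -> str:
    """Modulation call: strict |log2FC| > cut and FDR < cut boundaries."""
    if fdr < fdr_cut:
        if log2_fold_change > lfc_cut:
            return "up"
        if log2_fold_change < -lfc_cut:
            return "down"
    return "none"


def filter_proteins(lfq: LfqTable, min_replicates: int = 2) -> list[str]:
    """Proteomics presence filter.

    Drops contaminant- and host-flagged proteins and those detected
    (non-NaN intensity) in fewer than ``min_replicates`` replicates.
    """
    if lfq.intensities.shape[1] < 2:
        raise ValueError("replicate presence filter needs >= 2 replicate columns")
    detected = lfq.intensities.notna().sum(axis=1)
    keep = (detected >= min_replicates) & ~lfq.contaminant & ~lfq.host
    return [str(i) for i in lfq.intensities.index[keep]]
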