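"""Detection thresholding, expression filtering, size-factor normalization and
a negative-binomial exact-style test for consecutive-stage differential
expression, plus the qRT-PCR 2^-ddCt calculator.

The NB test conditions on the observed total of the (normalized) group sums
and enumerates all splits of that total between the two groups, summing the
probabilities of splits no more probable than the observed one.  Per-gene
dispersion is the maximum of a pooled method-of-moments estimate and a robust
log-log mean-dispersion trend — conservative by construction.  No numerical
equivalence to any particular DESeq release is claimed.

All thresholds are strict: detection means mean FPKM strictly above 0.1, the
pre-filter keeps genes whose expression sum is strictly above the 25th
percentile, and significance means p strictly below alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .iohub import ExpressionMatrix, StageDesign

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


def detected_genes(
    fpkm: ExpressionMatrix,
    design: StageDesign,
    stage: str,
    threshold: float = 0.1,
) -> set[str]:
    """Genes whose mean FPKM across the stage's samples is strictly > threshold."""
    if fpkm.kind != "fpkm":
        raise ValueError("detection thresholding requires an FPKM matrix")
    samples = design.samples_for(stage)  # raises on unknown stage
    means = fpkm.values[samples].mean(axis=1)
    return set(means.index[means > threshold])


def percentile_filter(
    counts: ExpressionMatrix,
    samples: list[str],
    percentile: float = 25.0,
) -> set[str]:
    """Genes whose expression sum over the compared samples is strictly greater
    than the given percentile (linear interpolation) of those sums."""
    if counts.n_genes == 0:
        raise ValueError("empty expression matrix")
    if len(samples) < 2:
        raise ValueError("need at least two samples to filter")
    sums = counts.values[samples].sum(axis=1)
    cutoff = np.percentile(sums.to_numpy(), percentile, method="linear")
    kept = set(sums.index[sums > cutoff])
    if not kept:
        logger.warning("percentile filter kept no genes (all sums equal?)")
    return kept


def estimate_size_factors(counts: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    s_j = median over genes with all-positive counts of count_gj / gm_g, where
    gm_g is the gene's geometric mean across samples.
    """
    df = counts.values if isinstance(counts, ExpressionMatrix) else counts
    arr = df.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with nonzero counts in every sample")
    sub = arr[positive]
    log_gm = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_gm[:, None]
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=df.columns, name="size_factor")


@dataclass
class DEResult:
    """Per-gene differential-expression results between two sample groups."""

    group_a: list[str]
    group_b: list[str]
    table: pd.DataFrame  # columns: mean_a, mean_b, log2fc, pvalue, direction
    label: str = ""

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["pvalue"] < alpha]

    def n_up(self, alpha: float = 0.05) -> int:
        sig = self.significant(alpha)
        return int((sig["direction"] == "up").sum())

    def n_down(self, alpha: float = 0.05) -> int:
        sig = self.significant(alpha)
        return int((sig["direction"] == "down").sum())


def _pooled_dispersion_mom(
    norm: np.ndarray, groups: list[np.ndarray], xi: float
) -> np.ndarray:
    """Pooled method-of-moments dispersion per gene.

    Within-group variances of normalized counts are pooled across both groups;
    the Poisson (shot-noise) part ``xi * q`` is subtracted and the excess is
    divided by q^2.  ``xi`` is the mean reciprocal size factor, the expected
    shot-noise scale on the normalized-count scale.
    """
    q = norm.mean(axis=1)
    num = np.zeros(norm.shape[0])
    dof = 0
    for idx in groups:
        if len(idx) >= 2:
            sub = norm[:, idx]
            num += sub.var(axis=1, ddof=1) * (len(idx) - 1)
            dof += len(idx) - 1
    if dof == 0:
        return np.full(norm.shape[0], DISPERSION_FLOOR)
    w = num / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (w - xi * q) / q**2
    disp[~np.isfinite(disp)] = 0.0
    return np.maximum(disp, DISPERSION_FLOOR)


def _dispersion_trend(q: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Robust linear fit of log(dispersion) on log(mean); returns fitted
    dispersion per gene (floored)."""
    ok = (q > 0) & (disp > DISPERSION_FLOOR * 10)
    if ok.sum() < 10:
        return np.full_like(q, DISPERSION_FLOOR)
    x = np.log(q[ok])
    y = np.log(disp[ok])
    try:
        fit = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT()).fit()
        coef = fit.params
    except Exception:  # singular design etc.
        coef = np.array([np.mean(y), 0.0])
    with np.errstate(over="ignore"):
        fitted = np.exp(coef[0] + coef[1] * np.log(np.maximum(q, 1e-12)))
    fitted[q <= 0] = DISPERSION_FLOOR
    return np.maximum(fitted, DISPERSION_FLOOR)


def _nb_pmf(k: np.ndarray, mu: float, disp: float) -> np.ndarray:
    """NB pmf with Var = mu + disp * mu^2; Poisson limit for tiny dispersion."""
    if mu <= 0:
        return np.where(k == 0, 1.0, 0.0)
    if disp < 1e-10:
        return stats.poisson.pmf(k, mu)
    r = 1.0 / disp
    return stats.nbinom.pmf(k, r, r / (r + mu))


def _exact_split_pvalue(
    ka: int, kb: int, na: int, nb_: int, disp: float
) -> float:
    """Two-sided conditional NB p-value for the split (ka, kb) of ka+kb.

    Group sums are modeled NB with per-group mean n_g * q and dispersion
    disp / n_g (sum of n_g independent NB genes); all splits of the observed
    total are enumerated and those no more probable than the observed split
    are summed.
    """
    total = ka + kb
    if total == 0:
        return 1.0
    q = total / (na + nb_)
    a = np.arange(total + 1)
    pa = _nb_pmf(a, na * q, disp / na)
    pb = _nb_pmf(total - a, nb_ * q, disp / nb_)
    probs = pa * pb
    denom = probs.sum()
    if denom <= 0:
        return 1.0
    obs = probs[ka]
    return float(probs[probs <= obs * (1.0 + 1e-7)].sum() / denom)


def nb_test(
    counts: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    size_factors: pd.Series | None = None,
    alpha: float = 0.05,
    label: str = "",
) -> DEResult:
    """Exact-style NB test per gene between two disjoint sample groups."""
    if set(group_a) & set(group_b):
        raise ValueError("sample groups overlap")
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    samples = list(group_a) + list(group_b)
    sub = counts.values[samples]
    if size_factors is None:
        size_factors = estimate_size_factors(sub)
    sf = size_factors.loc[samples].to_numpy(dtype=float)
    norm = sub.to_numpy(dtype=float) / sf[None, :]

    na, nb_ = len(group_a), len(group_b)
    ia = np.arange(na)
    ib = np.arange(na, na + nb_)
    xi = float(np.mean(1.0 / sf))
    disp_gene = _pooled_dispersion_mom(norm, [ia, ib], xi)
    q = norm.mean(axis=1)
    disp_fit = _dispersion_trend(q, disp_gene)
    disp = np.maximum(disp_gene, disp_fit)

    ka = np.rint(norm[:, ia].sum(axis=1)).astype(np.int64)
    kb = np.rint(norm[:, ib].sum(axis=1)).astype(np.int64)
    pvals = np.array(
        [
            _exact_split_pvalue(int(a_), int(b_), na, nb_, float(d_))
            for a_, b_, d_ in zip(ka, kb, disp)
        ]
    )
    pvals = np.minimum(pvals, 1.0)

    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    direction = np.where(
        pvals < alpha, np.where(log2fc > 0, "up", "down"), "none"
    )
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "dispersion": disp,
            "direction": direction,
        },
        index=counts.values.index,
    )
    return DEResult(group_a=list(group_a), group_b=list(group_b), table=table,
                    label=label)


def consecutive_stage_de(
    counts: ExpressionMatrix,
    design: StageDesign,
    alpha: float = 0.05,
    percentile: float = 25.0,
) -> dict[tuple[str, str], DEResult]:
    """Percentile-filter then NB-test every adjacent stage pair in stage order."""
    if len(design.stages) < 2:
        raise ValueError("need at least two stages for consecutive comparisons")
    size_factors = estimate_size_factors(counts)
    results: dict[tuple[str, str], DEResult] = {}
    for stage_a, stage_b in design.consecutive_pairs():
        ga = design.samples_for(stage_a)
        gb = design.samples_for(stage_b)
        kept = percentile_filter(counts, ga + gb, percentile=percentile)
        kept_ordered = [g for g in counts.gene_ids if g in kept]
        sub = counts.subset_genes(kept_ordered)
        res = nb_test(
            sub, ga, gb, size_factors=size_factors, alpha=alpha,
            label=f"{stage_a}->{stage_b}",
        )
        results[(stage_a, stage_b)] = res
        logger.info(
            "%s -> %s: %d tested, %d up, %d down",
            stage_a, stage_b, len(kept_ordered), res.n_up(alpha), res.n_down(alpha),
        )
    return results


def union_de_genes(
    results: dict[tuple[str, str], DEResult], alpha: float = 0.05
) -> set[str]:
    """Unique genes differentially expressed in any consecutive-stage pair."""
    out: set[str] = set()
    for res in results.values():
        out |= set(res.significant(alpha).index)
    return out


# ---------------------------------------------------------------------------
# qRT-PCR relative quantification
# ---------------------------------------------------------------------------


@dataclass
class CtTable:
    """Raw qPCR Ct values (genes x samples) with the internal-control gene and
    the calibrator sample."""

    ct: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        if self.reference_gene not in self.ct.index:
            raise ValueError(f"reference gene {self.reference_gene!r} missing")
        if self.calibrator_sample not in self.ct.columns:
            raise ValueError(f"calibrator sample {self.calibrator_sample!r} missing")
        if self.ct.loc[self.reference_gene].isna().any():
            raise ValueError("reference gene Ct missing for some sample")


def relative_expression_ddct(ct: CtTable, gene: str, sample: str) -> float:
    """2^-ddCt relative expression of ``gene`` in ``sample``.

    dCt = Ct_gene - Ct_reference within each sample; ddCt subtracts the
    calibrator sample's dCt.
    """
    for g, s in ((gene, sample), (gene, ct.calibrator_sample)):
        if g not in ct.ct.index:
            raise ValueError(f"gene {g!r} missing from Ct table")
        if pd.isna(ct.ct.loc[g, s]):
            raise ValueError(f"missing Ct for gene {g!r}, sample {s!r}")
    dct_sample = ct.ct.loc[gene, sample] - ct.ct.loc[ct.reference_gene, sample]
    dct_cal = (
        ct.ct.loc[gene, ct.calibrator_sample]
        - ct.ct.loc[ct.reference_gene, ct.calibrator_sample]
    )
    ddct = dct_sample - dct_cal
    return float(2.0 ** (-ddct))
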