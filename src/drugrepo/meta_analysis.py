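"""Fisher-z meta-analysis of per-batch drug enrichment scores.

A drug's Connectivity-Map enrichment score rho lies in [-1, 1] and is
treated as a sample correlation coefficient.  Each batch contributes one
observation, variance-stabilized to the Fisher-z scale

    Y = z(rho) = 1/2 ln((1 + rho) / (1 - rho)),     V = 1 / (N - 3),

where N is the number of Connectivity-Map instances behind the score.
Batches are combined with inverse-variance weights under a fixed-effect
model; the Q statistic and I^2 quantify between-batch heterogeneity, and
when the heterogeneity test rejects (p < 0.1) the DerSimonian-Laird
random-effects model is used instead, its between-batch variance tau^2
added to each weight's denominator.  Summary effects and confidence limits
are transformed back to the enrichment-score scale.  The one-tailed p-value
tests for a NEGATIVE combined effect: the pipeline seeks drugs whose induced
signature reverses (anti-correlates with) the disease signature.

The Fisher combined-probability test (-2 sum ln p, chi-square with 2N df)
is provided as the alternative p-value-based route.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSize",
    "MetaResult",
    "fisher_z",
    "inverse_fisher_z",
    "variance_of_z",
    "fixed_effect_combine",
    "q_statistic",
    "i_squared",
    "tau_squared_dl",
    "random_effect_combine",
    "select_model",
    "fisher_combined_test",
    "meta_analyze_drug",
    "effects_from_table",
    "meta_table",
]

#: literal 95% CI multiplier of the summary-effect formula
CI_MULTIPLIER = 1.96


def fisher_z(rho: float) -> float:
    """Fisher's variance-stabilizing transform z = 1/2 ln((1+rho)/(1-rho))."""
    if not abs(rho) < 1:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    return float(np.arctanh(rho))


def inverse_fisher_z(z: float) -> float:
    """Back-transform a Fisher-z value to the correlation scale."""
    return float(np.tanh(z))


def variance_of_z(n: int) -> float:
    """Sampling variance of a Fisher-z value: 1/(N-3)."""
    if n <= 3:
        raise ValueError("N must be >= 4: variance 1/(N-3) undefined otherwise")
    return 1.0 / (n - 3)


@dataclass
class EffectSize:
    """One drug-in-one-batch observation on the Fisher-z scale."""

    label: str
    rho: float
    N: int
    p_batch: float = np.nan
    batch: str = ""
    Y: float = None  # type: ignore[assignment]
    V: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.Y is None:
            self.Y = fisher_z(self.rho)
        if self.V is None:
            self.V = variance_of_z(self.N)


@dataclass
class MetaResult:
    """Combined summary effect for one drug across batches."""

    label: str
    k_studies: int
    model: str  # fixed | random | unweighted
    M: float
    V_M: float
    SE_M: float
    Z: float
    p_one_tailed: float
    LL_M: float
    UL_M: float
    rho_combined: float
    rho_LL: float
    rho_UL: float
    Q: float = np.nan
    df: int = 0
    p_het: float = np.nan
    I2: float = np.nan
    tau2: float = np.nan
    single_study: bool = False


def _combine(
    effects: list[EffectSize],
    weights: np.ndarray,
    model: str,
    alternative: str,
) -> MetaResult:
    y = np.array([e.Y for e in effects])
    w = np.asarray(weights, dtype=float)
    sw = w.sum()
    M = float((w * y).sum() / sw)
    V_M = float(1.0 / sw)
    SE_M = math.sqrt(V_M)
    # the weighted Z-score sum(W Y)/sqrt(sum(W)) equals M/SE_M identically
    Z = M / SE_M
    if alternative == "less":
        p = float(stats.norm.cdf(Z))
    elif alternative == "greater":
        p = float(stats.norm.sf(Z))
    else:
        p = float(2.0 * stats.norm.sf(abs(Z)))
    LL = M - CI_MULTIPLIER * SE_M
    UL = M + CI_MULTIPLIER * SE_M
    return MetaResult(
        label=effects[0].label,
        k_studies=len(effects),
        model=model,
        M=M,
        V_M=V_M,
        SE_M=SE_M,
        Z=Z,
        p_one_tailed=p,
        LL_M=LL,
        UL_M=UL,
        rho_combined=inverse_fisher_z(M),
        rho_LL=inverse_fisher_z(LL),
        rho_UL=inverse_fisher_z(UL),
    )


def fixed_effect_combine(
    effects: list[EffectSize],
    weighted: bool = True,
    alternative: str = "less",
) -> MetaResult:
    """Fixed-effect (or unweighted) combination of Fisher-z effects.

    Weights are W_i = 1/V_i (inverse variance) or all 1 when
    ``weighted=False``.  The summary is M = sum(W Y)/sum(W) with variance
    V_M = 1/sum(W), Z = M/SE_M, and a 95% CI of M +/- 1.96 SE_M.  The
    default one-tailed p-value is the lower normal tail (negative effect).
    """
    if not effects:
        raise ValueError("need at least one effect size")
    if weighted:
        w = np.array([1.0 / e.V for e in effects])
        model = "fixed"
    else:
        w = np.ones(len(effects))
        model = "unweighted"
    return _combine(effects, w, model, alternative)


def q_statistic(effects: list[EffectSize], m_fixed: float | None = None):
    """Cochran's Q heterogeneity statistic with fixed-effect weights.

    Returns (Q, df, p_het) where p_het is the chi-square upper tail with
    df = k - 1.
    """
    if len(effects) < 2:
        raise ValueError("heterogeneity needs k >= 2 studies")
    w = np.array([1.0 / e.V for e in effects])
    y = np.array([e.Y for e in effects])
    if m_fixed is None:
        m_fixed = float((w * y).sum() / w.sum())
    q = float((w * (y - m_fixed) ** 2).sum())
    df = len(effects) - 1
    p_het = float(stats.chi2.sf(q, df))
    return q, df, p_het


def i_squared(q: float, df: int) -> float:
    """I^2 heterogeneity percentage: max(0, (Q - df)/Q) * 100.

    Below ~25% is read as no heterogeneity, above ~75% as extreme.
    """
    if q < 0 or df < 1:
        raise ValueError("need Q >= 0 and df >= 1")
    if q == 0:
        return 0.0
    return float(max(0.0, (q - df) / q) * 100.0)


def tau_squared_dl(effects: list[EffectSize], q: float, df: int) -> float:
    """DerSimonian-Laird between-study variance tau^2 = max(0, (Q-df)/C)."""
    if len(effects) < 2:
        raise ValueError("tau^2 needs k >= 2 studies")
    w = np.array([1.0 / e.V for e in effects])
    c = float(w.sum() - (w**2).sum() / w.sum())
    if c == 0:
        raise ValueError("degenerate weights: C = 0")
    return float(max(0.0, (q - df) / c))


def random_effect_combine(
    effects: list[EffectSize],
    tau2: float | None = None,
    alternative: str = "less",
) -> MetaResult:
    """DerSimonian-Laird random-effects combination.

    Weights are W*_i = 1/(V_i + tau^2); with tau^2 = 0 this reduces exactly
    to the fixed-effect result.
    """
    if len(effects) < 2:
        raise ValueError("random-effects model needs k >= 2 studies")
    q, df, p_het = q_statistic(effects)
    if tau2 is None:
        tau2 = tau_squared_dl(effects, q, df)
    w = np.array([1.0 / (e.V + tau2) for e in effects])
    res = _combine(effects, w, "random", alternative)
    res.Q, res.df, res.p_het = q, df, p_het
    res.I2 = i_squared(q, df)
    res.tau2 = tau2
    return res


def select_model(p_het: float, threshold: float = 0.1) -> str:
    """Heterogeneity-driven model choice.

    p_het >= threshold (default 0.1) means little between-batch variation and
    selects the fixed-effect model; otherwise the random-effects model.
    """
    if not 0 <= p_het <= 1:
        raise ValueError("p_het must be in [0, 1]")
    return "fixed" if p_het >= threshold else "random"


def fisher_combined_test(pvalues, zero_floor: float = 1e-16):
    """Fisher's combined probability test F = -2 sum ln p.

    Returns (F, df, p) with df = 2 * len(pvalues) and p the chi-square upper
    tail.  Zero p-values (which some score resources emit) would make F
    infinite; they are floored to ``zero_floor`` with a warning.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn(
            f"zero p-value(s) floored to {zero_floor} before combining",
            stacklevel=2,
        )
        p = np.maximum(p, zero_floor)
    f = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return f, df, float(stats.chi2.sf(f, df))


def meta_analyze_drug(
    effects: list[EffectSize],
    het_threshold: float = 0.1,
    weighted: bool = True,
    alternative: str = "less",
) -> MetaResult:
    """Full per-drug meta-analysis with heterogeneity-driven model choice.

    With a single batch the study is returned as-is (model fixed, flagged
    ``single_study``).  With k >= 2, Q/I^2/p_het are computed, the model is
    selected by ``select_model``, and the chosen combination is returned
    with heterogeneity statistics attached.
    """
    if not effects:
        raise ValueError("no effect sizes for drug")
    if len(effects) == 1:
        res = fixed_effect_combine(effects, weighted=weighted, alternative=alternative)
        res.single_study = True
        return res
    q, df, p_het = q_statistic(effects)
    tau2 = tau_squared_dl(effects, q, df)
    model = select_model(p_het, het_threshold)
    if model == "random":
        res = random_effect_combine(effects, tau2=tau2, alternative=alternative)
    else:
        res = fixed_effect_combine(effects, weighted=weighted, alternative=alternative)
        res.Q, res.df, res.p_het, res.tau2 = q, df, p_het, tau2
        res.I2 = i_squared(q, df)
    return res


# ---------------------------------------------------------------------------
# table interfaces
# ---------------------------------------------------------------------------

def effects_from_table(
    table: pd.DataFrame, default_n: int | None = None
) -> dict[str, list[EffectSize]]:
    """Group a per-batch score table (drug, es, p, n, batch) by drug.

    Rows without a usable instance count N are skipped with a warning unless
    ``default_n`` supplies a global fallback.
    """
    out: dict[str, list[EffectSize]] = {}
    for row in table.itertuples(index=False):
        n = getattr(row, "n", None)
        if n is None or (isinstance(n, float) and np.isnan(n)):
            if default_n is None:
                warnings.warn(
                    f"drug {row.drug!r} in batch {getattr(row, 'batch', '?')!r} "
                    "has no instance count N; record skipped",
                    stacklevel=2,
                )
                continue
            n = default_n
        eff = EffectSize(
            label=str(row.drug),
            rho=float(row.es),
            N=int(n),
            p_batch=float(getattr(row, "p", np.nan)),
            batch=str(getattr(row, "batch", "")),
        )
        out.setdefault(eff.label, []).append(eff)
    return out


def meta_table(results: list[MetaResult]) -> pd.DataFrame:
    """Tabulate meta-analysis results for TSV export."""
    cols = [
        "label", "k_studies", "model", "M", "V_M", "SE_M", "Z",
        "p_one_tailed", "LL_M", "UL_M", "rho_combined", "rho_LL", "rho_UL",
        "Q", "df", "p_het", "I2", "tau2", "single_study",
    ]
    return pd.DataFrame({c: [getattr(r, c) for r in results] for c in cols})
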