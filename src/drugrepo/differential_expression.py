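"""Paired moderated-t differential expression.

Each batch supplies per-gene tumor-minus-normal log2 differences from a
paired design (both tissues from the same patient).  Differential expression
is tested with an empirical-Bayes moderated t-statistic: per-gene sample
variances are shrunk toward a pooled prior whose hyperparameters (d0, s0^2)
are estimated by method of moments on log s^2 across genes, and the
resulting t-statistic gains d0 extra degrees of freedom.  Significant genes
are split into up- and downregulated signatures by the sign of the mean
log2 fold change, intersected across batches, and their fold changes floored
in magnitude at log2(50) before export as a query signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedExpression",
    "DEGRecord",
    "FC_FLOOR",
    "paired_log2fc",
    "moderated_t_paired",
    "adjust_pvalues",
    "select_degs",
    "clamp_fold_change",
    "common_degs",
    "read_expression_tsv",
    "deg_table",
]

#: default fold-change floor on the log2 scale (log2 of 50-fold)
FC_FLOOR: float = float(np.log2(50.0))


@dataclass
class PairedExpression:
    """Per-gene paired log2 differences (tumor minus normal) for one batch."""

    genes: list[str]
    diffs: np.ndarray  # shape (n_genes, n_pairs)
    batch: str = "batch1"
    stage: str = "early"

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=float)
        if self.diffs.ndim != 2:
            raise ValueError("diffs must be a 2-D (genes x pairs) array")
        if len(self.genes) != self.diffs.shape[0]:
            raise ValueError("gene list and diffs row count disagree")
        if any(not g for g in self.genes):
            raise ValueError("missing gene symbol")

    @property
    def n_pairs(self) -> int:
        return self.diffs.shape[1]


@dataclass
class DEGRecord:
    """Result of the moderated paired t-test for one gene."""

    gene: str
    log2fc: float
    t_mod: float
    df_total: float
    p_raw: float
    p_adj: float = np.nan
    direction: str = "none"


def paired_log2fc(expr: PairedExpression) -> np.ndarray:
    """Mean per-pair log2 difference for every gene."""
    if expr.diffs.size == 0:
        raise ValueError("empty expression matrix")
    return expr.diffs.mean(axis=1)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    # Smyth's starting value: trigamma(x) ~ 1/x for large x, ~ 1/x^2 near 0
    x = 0.5 + 1.0 / y if y > 1e-6 else 1.0 / np.sqrt(y)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on gene-wise variances.

    Given sample variances s2 with df degrees of freedom each, matches the
    first two moments of log s^2 (whose distribution under the hierarchical
    model is a shifted log-F) to estimate the prior degrees of freedom d0 and
    prior variance s0^2.  Returns (d0, s0^2); d0 may be ``inf`` when the
    observed spread of log s^2 is no larger than pure sampling noise.
    """
    positive = s2 > 0
    if not positive.any():
        raise ValueError(
            "cannot estimate variance prior: every gene has zero sample "
            "variance (all-constant expression matrix)"
        )
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) if n > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(
            np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    return d0, s0_sq


def moderated_t_paired(
    expr: PairedExpression, prior_df: float | None = None
) -> list[DEGRecord]:
    """Empirical-Bayes moderated paired t-test, one record per gene.

    Per-gene variances s_g^2 (d_g = n_pairs - 1 df) are shrunk toward the
    estimated prior s0^2 with weight d0:

        s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

    and t_mod = log2fc / (s_tilde / sqrt(n_pairs)) is referred to a t
    distribution with d0 + d_g degrees of freedom (normal when d0 is
    infinite).  ``prior_df`` overrides the estimated d0 (0 recovers the
    ordinary paired t-test).
    """
    n = expr.n_pairs
    if n < 2:
        raise ValueError("need >= 2 pairs to estimate per-gene variance")
    fc = paired_log2fc(expr)
    s2 = expr.diffs.var(axis=1, ddof=1)
    d_g = n - 1

    if prior_df is None:
        d0, s0_sq = _fit_f_dist(s2, d_g)
    else:
        d0 = float(prior_df)
        s0_sq = _fit_f_dist(s2, d_g)[1] if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fc / np.sqrt(s2_post / n)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    return [
        DEGRecord(
            gene=g,
            log2fc=float(fc[i]),
            t_mod=float(t_mod[i]),
            df_total=float(df_total),
            p_raw=float(p[i]),
        )
        for i, g in enumerate(expr.genes)
    ]


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(
    records: list[DEGRecord], alpha: float = 0.005
) -> tuple[set[str], set[str]]:
    """Split significant genes into up/down sets by sign of log2 fold change.

    A gene qualifies when p_adj < alpha; genes with exactly zero fold change
    are excluded from both sets.  Records are updated in place with their
    direction label.
    """
    up, down = set(), set()
    for rec in records:
        if np.isnan(rec.p_adj):
            raise ValueError("records must carry adjusted p-values; run adjust first")
        if rec.p_adj < alpha and rec.log2fc > 0:
            rec.direction = "up"
            up.add(rec.gene)
        elif rec.p_adj < alpha and rec.log2fc < 0:
            rec.direction = "down"
            down.add(rec.gene)
        else:
            rec.direction = "none"
    return up, down


def clamp_fold_change(log2fc: float, floor: float = FC_FLOOR) -> float:
    """Floor the magnitude of a log2 fold change, preserving its sign.

    Query signatures fed to a Connectivity-Map style search need large fold
    changes; values below the floor (default log2(50) ~ 5.64) are reset to
    +/- the floor.
    """
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if log2fc == 0.0:
        return 0.0
    if abs(log2fc) < floor:
        return float(np.sign(log2fc) * floor)
    return float(log2fc)


def common_degs(
    per_batch: list[tuple[set[str], set[str]]]
) -> tuple[set[str], set[str]]:
    """Intersect per-batch (up, down) DEG sets across all batches."""
    if not per_batch:
        raise ValueError("need at least one batch")
    up = set.intersection(*(set(u) for u, _ in per_batch))
    down = set.intersection(*(set(d) for _, d in per_batch))
    return up, down


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_expression_tsv(path, batch: str = "batch1", stage: str = "early") -> PairedExpression:
    """Read a paired expression TSV (gene, <patient>_T / <patient>_N columns)."""
    df = pd.read_csv(path, sep="\t")
    gene_col = df.columns[0]
    tumor_cols = [c for c in df.columns if c.endswith("_T")]
    pairs = []
    for tc in tumor_cols:
        nc = tc[:-2] + "_N"
        if nc not in df.columns:
            raise ValueError(f"tumor column {tc} has no matching normal column")
        pairs.append(df[tc].to_numpy(float) - df[nc].to_numpy(float))
    if not pairs:
        raise ValueError("no <patient>_T / <patient>_N column pairs found")
    return PairedExpression(
        genes=df[gene_col].astype(str).tolist(),
        diffs=np.column_stack(pairs),
        batch=batch,
        stage=stage,
    )


def deg_table(records: list[DEGRecord]) -> pd.DataFrame:
    """Tabulate DEG records for TSV export."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "log2fc": [r.log2fc for r in records],
            "t_mod": [r.t_mod for r in records],
            "df_total": [r.df_total for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
            "direction": [r.direction for r in records],
        }
    )
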