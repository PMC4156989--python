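"""Synthetic generators for every input the pipeline consumes.

The analysis combines three kinds of external data: paired tumor/normal
log2 expression matrices from several microarray batches, a protein-protein
interaction (PPI) edge list, and per-batch drug enrichment-score tables of
the kind a Connectivity-Map query returns.  None of those can be shipped
with the package, so this module generates stand-ins that have exactly the
statistical structure the downstream stages assume:

* paired expression with a planted set of up/down differentially expressed
  genes whose mean tumor-minus-normal shift is shared across batches;
* a PPI graph in which chosen gene sets are wired as chains of overlapping
  k-cliques, so that clique percolation at that k is guaranteed to recover
  each set as one community, on top of Erdos-Renyi background edges;
* drug score tables whose Fisher-z values are Normal around a drug-specific
  true effect with configurable between-batch variance tau^2, matching the
  random-effects model the meta-analysis stage fits.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential_expression import PairedExpression

__all__ = [
    "SimulationConfig",
    "DrugSimConfig",
    "simulate_paired_expression",
    "simulate_ppi",
    "simulate_drug_scores",
    "write_expression_tsv",
    "write_truth_tsv",
    "write_edge_list_tsv",
    "write_drug_scores_tsv",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the paired tumor/normal expression simulation.

    Parameters
    ----------
    n_genes : total number of genes on the synthetic platform.
    n_pairs_per_batch : number of patient pairs in each batch; its length
        fixes ``n_batches`` unless the latter is given explicitly.
    frac_up, frac_down : fractions of genes planted as up-/downregulated.
    effect_mean, effect_sd : the magnitude of a planted gene's log2
        fold change is drawn once, globally, from N(effect_mean, effect_sd^2)
        and reused in every batch (the common-DEG structure of a multi-batch
        paired design); the sign follows the up/down assignment.
    batch_effect_sd : optional per-batch jitter added to the planted shift;
        0 keeps effects identical across batches.
    noise_sd : within-pair residual standard deviation on the log2 scale.
    """

    n_genes: int = 1000
    n_pairs_per_batch: list[int] = field(default_factory=lambda: [15, 15, 15, 15])
    n_batches: int | None = None
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_mean: float = 3.0
    effect_sd: float = 0.0
    batch_effect_sd: float = 0.0
    noise_sd: float = 0.5
    stage: str = "early"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches is None:
            self.n_batches = len(self.n_pairs_per_batch)
        elif self.n_batches != len(self.n_pairs_per_batch):
            if len(self.n_pairs_per_batch) == 1:
                self.n_pairs_per_batch = self.n_pairs_per_batch * self.n_batches
            else:
                raise ConfigurationError(
                    "n_batches does not match len(n_pairs_per_batch)"
                )
        if self.n_genes < 1 or self.n_batches < 1:
            raise ConfigurationError("counts must be >= 1")
        if any(n < 1 for n in self.n_pairs_per_batch):
            raise ConfigurationError("each batch needs >= 1 pair")
        if not (0 <= self.frac_up and 0 <= self.frac_down):
            raise ConfigurationError("fractions must be non-negative")
        if self.frac_up + self.frac_down > 1:
            raise ConfigurationError("frac_up + frac_down must be <= 1")
        if self.noise_sd < 0 or self.effect_sd < 0 or self.batch_effect_sd < 0:
            raise ConfigurationError("scale parameters must be non-negative")


@dataclass
class DrugSimConfig:
    """Parameters of the per-batch drug enrichment-score simulation.

    ``true_rho`` maps each drug name to its true enrichment score in (-1, 1);
    a negative value means the drug's induced signature reverses the disease
    signature.  ``n_instances`` is the per-drug Connectivity-Map instance
    count N, which sets the within-batch sampling variance 1/(N-3) of the
    Fisher-z value; ``tau2`` is the between-batch variance of the true
    Fisher-z effect.
    """

    true_rho: dict[str, float] = field(
        default_factory=lambda: {f"drug_{i:02d}": 0.0 for i in range(10)}
    )
    n_instances: int = 50
    tau2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_rho:
            raise ConfigurationError("at least one drug is required")
        for name, rho in self.true_rho.items():
            if not abs(rho) < 1:
                raise ConfigurationError(f"|true_rho| must be < 1 (drug {name!r})")
        if self.n_instances < 4:
            raise ConfigurationError(
                "n_instances must be >= 4: the Fisher-z variance 1/(N-3) "
                "is undefined for N <= 3"
            )
        if self.tau2 < 0:
            raise ConfigurationError("tau2 must be >= 0")

    @property
    def n_drugs(self) -> int:
        return len(self.true_rho)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_paired_expression(
    cfg: SimulationConfig,
) -> tuple[list[PairedExpression], pd.DataFrame]:
    """Simulate per-batch paired tumor-minus-normal log2 differences.

    Returns one :class:`PairedExpression` per batch plus a truth table with
    columns ``gene``, ``direction`` (up|down) and ``log2fc`` for the planted
    genes.  Planted shifts are drawn once and shared across batches; per-pair
    noise is i.i.d. Normal(0, noise_sd^2).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)

    n_up = int(round(cfg.frac_up * cfg.n_genes))
    n_down = int(round(cfg.frac_down * cfg.n_genes))
    planted_idx = rng.choice(cfg.n_genes, size=n_up + n_down, replace=False)
    up_idx, down_idx = planted_idx[:n_up], planted_idx[n_up:]

    # global per-gene shift, sign by direction
    shift = np.zeros(cfg.n_genes)
    shift[up_idx] = rng.normal(cfg.effect_mean, cfg.effect_sd, n_up)
    shift[down_idx] = -rng.normal(cfg.effect_mean, cfg.effect_sd, n_down)

    batches = []
    for b, n_pairs in enumerate(cfg.n_pairs_per_batch):
        batch_shift = shift.copy()
        if cfg.batch_effect_sd > 0:
            jitter = rng.normal(0.0, cfg.batch_effect_sd, cfg.n_genes)
            batch_shift[planted_idx] += jitter[planted_idx]
        diffs = batch_shift[:, None] + rng.normal(
            0.0, cfg.noise_sd, size=(cfg.n_genes, n_pairs)
        )
        batches.append(
            PairedExpression(
                genes=genes, diffs=diffs, batch=f"batch{b + 1}", stage=cfg.stage
            )
        )

    truth = pd.DataFrame(
        {
            "gene": [genes[i] for i in planted_idx],
            "direction": ["up"] * n_up + ["down"] * n_down,
            "log2fc": shift[planted_idx],
        }
    ).sort_values("gene", ignore_index=True)
    return batches, truth


def simulate_ppi(
    genes: list[str],
    planted: list[set[str]] | list[list[str]],
    k: int = 3,
    background_p: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Simulate an undirected PPI edge list with planted k-clique communities.

    Each planted gene set is wired as a chain of k-cliques over consecutive
    windows of its (sorted) members, adjacent windows sharing k-1 nodes, so
    clique percolation at this k recovers the set as a single community.
    Every remaining unordered gene pair becomes a background edge
    independently with probability ``background_p``.
    """
    if not 0 <= background_p < 1:
        raise ConfigurationError("background_p must be in [0, 1)")
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    gene_set = set(genes)
    edges: set[tuple[str, str]] = set()

    for members in planted:
        members = sorted(members)
        if len(members) < k:
            raise ConfigurationError(
                f"planted set {members} smaller than clique size k={k}"
            )
        if not set(members) <= gene_set:
            raise ConfigurationError("planted set contains genes outside the universe")
        for start in range(len(members) - k + 1):
            window = members[start : start + k]
            for a, b in itertools.combinations(window, 2):
                edges.add((a, b) if a < b else (b, a))

    if background_p > 0:
        rng = np.random.default_rng(seed)
        ordered = sorted(gene_set)
        for a, b in itertools.combinations(ordered, 2):
            if (a, b) not in edges and rng.random() < background_p:
                edges.add((a, b))

    return sorted(edges)


def simulate_drug_scores(
    cfg: DrugSimConfig, n_batches: int, stage: str = "early"
) -> list[pd.DataFrame]:
    """Simulate per-batch drug enrichment-score tables.

    For drug d in batch b the observed Fisher-z value is drawn from
    Normal(arctanh(true_rho_d), 1/(N-3) + tau2) and back-transformed to an
    enrichment score rho in (-1, 1).  The reported p-value is the two-sided
    normal tail of z_obs / sqrt(1/(N-3)), i.e. the single-batch test that a
    Connectivity-Map style resource attaches to each score.
    """
    from scipy import stats

    if n_batches < 1:
        raise ConfigurationError("n_batches must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    drugs = sorted(cfg.true_rho)
    true_z = np.arctanh([cfg.true_rho[d] for d in drugs])
    v_within = 1.0 / (cfg.n_instances - 3)
    sd_total = np.sqrt(v_within + cfg.tau2)

    tables = []
    for b in range(n_batches):
        z_obs = rng.normal(true_z, sd_total)
        rho_obs = np.tanh(z_obs)
        p = 2.0 * stats.norm.sf(np.abs(z_obs) / np.sqrt(v_within))
        tables.append(
            pd.DataFrame(
                {
                    "drug": drugs,
                    "es": rho_obs,
                    "p": p,
                    "n": cfg.n_instances,
                    "batch": f"batch{b + 1}",
                    "stage": stage,
                }
            )
        )
    return tables


# ---------------------------------------------------------------------------
# TSV export of the simulated inputs (the on-disk formats the CLI consumes)
# ---------------------------------------------------------------------------

def write_expression_tsv(expr: PairedExpression, path) -> None:
    """Write a batch as TSV: gene column plus <patient>_T / <patient>_N pairs.

    Tumor and normal log2 intensities are reconstructed from the differences
    by placing the normal channel at a constant baseline; the downstream
    reader only uses their difference.
    """
    n_pairs = expr.diffs.shape[1]
    baseline = 8.0
    cols = {"gene": expr.genes}
    for j in range(n_pairs):
        cols[f"p{j + 1}_T"] = baseline + expr.diffs[:, j]
        cols[f"p{j + 1}_N"] = np.full(len(expr.genes), baseline)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth[["gene", "direction"]].to_csv(path, sep="\t", index=False)


def write_edge_list_tsv(edges: list[tuple[str, str]], path) -> None:
    pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def write_drug_scores_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
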