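"""Candidate drug filtering, ranking, list comparison, and target mapping.

Candidate drugs must reverse the disease signature: only records with a
negative enrichment score survive, optionally tightened by a per-batch
p-value cutoff.  Surviving drugs are ranked by the one-tailed meta-analysis
p-value; lists built under different effect-size choices or disease stages
are compared with the Jaccard index; and ranked drugs are mapped to their
known target genes within the up- and downregulated community networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .meta_analysis import MetaResult

logger = logging.getLogger(__name__)

__all__ = [
    "DrugList",
    "DrugTargetTable",
    "filter_candidates",
    "rank_by_meta",
    "jaccard_index",
    "pairwise_jaccard_matrix",
    "map_targets",
    "aggregate_target_directions",
    "export_neighbor_network",
    "read_drug_target_tsv",
]


def normalize_drug(name: str) -> str:
    """Case-insensitive, trimmed drug-name key (score resources vary in case)."""
    return str(name).strip().lower()


@dataclass
class DrugList:
    """An ordered candidate drug list with its provenance."""

    members: list[str]
    stage: str = ""
    effect_basis: str = "ES"  # ES | cMapP
    threshold: float | None = None

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for m in self.members:
            key = normalize_drug(m)
            if key not in seen:
                seen.add(key)
                deduped.append(m)
        self.members = deduped

    def as_set(self) -> set[str]:
        return {normalize_drug(m) for m in self.members}


@dataclass
class DrugTargetTable:
    """Drug -> target gene symbols (uppercase-normalized)."""

    targets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.targets = {
            normalize_drug(d): {str(g).strip().upper() for g in genes}
            for d, genes in self.targets.items()
        }

    def get(self, drug: str) -> set[str]:
        return self.targets.get(normalize_drug(drug), set())


def filter_candidates(
    scores: pd.DataFrame, es_max: float = 0.0, cmap_p_max: float | None = None
) -> pd.DataFrame:
    """Keep per-batch records with es < es_max (strict) and p < cmap_p_max.

    The default es_max = 0 retains only signature-reversing (negative)
    scores; a record with es exactly 0 is excluded.
    """
    keep = scores["es"] < es_max
    if cmap_p_max is not None:
        keep &= scores["p"] < cmap_p_max
    return scores.loc[keep].reset_index(drop=True)


def rank_by_meta(
    results: list[MetaResult],
    ma_p_max: float = 0.05,
    stage: str = "",
    effect_basis: str = "ES",
) -> DrugList:
    """Drugs with one-tailed meta-analysis p below the cutoff, ranked.

    Order is ascending p, ties broken lexicographically by drug name — the
    output is deterministic.
    """
    hits = [r for r in results if r.p_one_tailed < ma_p_max]
    hits.sort(key=lambda r: (r.p_one_tailed, normalize_drug(r.label)))
    return DrugList(
        members=[r.label for r in hits],
        stage=stage,
        effect_basis=effect_basis,
        threshold=ma_p_max,
    )


def jaccard_index(a, b) -> float:
    """Intersection over union of two sets; 0 when both are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def pairwise_jaccard_matrix(lists: dict[str, DrugList] | dict[str, set]) -> pd.DataFrame:
    """All-pairs comparison: intersection counts below the diagonal, Jaccard
    indices above, list sizes on the diagonal."""
    if len(lists) < 2:
        raise ValueError("need at least two drug lists to compare")
    names = list(lists)
    sets = {
        n: (v.as_set() if isinstance(v, DrugList) else set(v))
        for n, v in lists.items()
    }
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                mat.loc[a, b] = len(sets[a])
            elif i > j:
                mat.loc[a, b] = len(sets[a] & sets[b])
            else:
                mat.loc[a, b] = round(jaccard_index(sets[a], sets[b]), 3)
    return mat


def map_targets(
    drug_list: DrugList,
    targets: DrugTargetTable,
    up_genes,
    down_genes,
) -> dict[str, tuple[set[str], set[str]]]:
    """Per-drug (up targets, down targets): target genes within the up- and
    downregulated community gene sets.  Drugs without a table entry map to
    empty sets with a warning."""
    up_genes = {str(g).upper() for g in up_genes}
    down_genes = {str(g).upper() for g in down_genes}
    out = {}
    for drug in drug_list.members:
        t = targets.get(drug)
        if not t and normalize_drug(drug) not in targets.targets:
            logger.warning("drug %r absent from the target table", drug)
        out[drug] = (t & up_genes, t & down_genes)
    return out


def aggregate_target_directions(
    mapped: dict[str, tuple[set[str], set[str]]]
) -> tuple[set[str], set[str]]:
    """Union of up and down target genes across drugs (each counted once)."""
    up, down = set(), set()
    for u, d in mapped.values():
        up |= u
        down |= d
    return up, down


def export_neighbor_network(target_genes, ppi: nx.Graph) -> pd.DataFrame:
    """Edges incident to target genes plus first-degree partners.

    Returns a TSV-ready table with columns gene_a, gene_b, role_a, role_b
    (target | partner); targets with no interaction appear as isolated rows
    with an empty partner.
    """
    targets = {str(g).upper() for g in target_genes}
    nodes = {str(n).upper(): n for n in ppi.nodes}
    rows = []
    for t in sorted(targets):
        node = nodes.get(t)
        neighbors = sorted(ppi.neighbors(node)) if node is not None else []
        if not neighbors:
            rows.append({"gene_a": t, "gene_b": "", "role_a": "target", "role_b": ""})
            continue
        for nb in neighbors:
            rows.append(
                {
                    "gene_a": t,
                    "gene_b": str(nb),
                    "role_a": "target",
                    "role_b": "target" if str(nb).upper() in targets else "partner",
                }
            )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "role_a", "role_b"])


def read_drug_target_tsv(path) -> DrugTargetTable:
    """Read a two-column TSV (drug, target gene symbol), one row per link."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("drug-target table needs two columns")
    targets: dict[str, set[str]] = {}
    for drug, gene in df.iloc[:, :2].itertuples(index=False, name=None):
        targets.setdefault(str(drug), set()).add(str(gene))
    return DrugTargetTable(targets=targets)
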