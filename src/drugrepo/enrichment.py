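"""Over-representation analysis of community gene sets against GMT pathways.

Community genes are tested for enrichment in each pathway of a gene-set
collection with the one-sided hypergeometric (Fisher-exact) test: the
p-value is the probability of drawing at least the observed overlap when
|query| genes are sampled without replacement from the background universe.
The background defaults to all genes present on the platform, the standard
convention for microarray-derived queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .differential_expression import adjust_pvalues

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "ORAResult", "read_gmt", "ora", "ora_table"]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe.

    Sets are intersected with the background on construction; sets that end
    up empty are dropped.
    """

    sets: dict[str, set[str]]
    background: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.background = set(self.background)
        restricted = {}
        for name, members in self.sets.items():
            kept = set(members) & self.background
            if kept:
                restricted[name] = kept
        self.sets = restricted


@dataclass
class ORAResult:
    pathway: str
    count: int
    percent: float  # overlap / |query| * 100
    effective_size: int  # pathway size within the background
    p_raw: float
    p_adj: float


def read_gmt(path, background: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, members...) into a collection.

    When ``background`` is None the union of all set members is used.
    """
    sets, descriptions = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
            descriptions[parts[0]] = parts[1]
    if background is None:
        background = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, background=background, descriptions=descriptions)


def ora(
    query: set[str], collection: GeneSetCollection, alpha: float = 0.05
) -> list[ORAResult]:
    """One-sided hypergeometric over-representation test per pathway.

    Query genes outside the background are dropped with a warning.  Results
    are BH-adjusted across all tested pathways, ranked by ascending raw
    p-value, and filtered to p_raw < alpha.
    """
    query = set(query)
    outside = query - collection.background
    if outside:
        logger.warning(
            "%d query gene(s) outside the background dropped: %s",
            len(outside),
            ", ".join(sorted(outside)[:5]),
        )
        query -= outside
    if not query:
        raise ValueError("query is empty after restriction to the background")

    m = len(collection.background)
    n_query = len(query)
    names, counts, sizes, pvals = [], [], [], []
    for name, members in collection.sets.items():
        overlap = len(query & members)
        # P(X >= overlap), X ~ Hypergeom(M=m, K=|pathway|, n=|query|)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(members), n_query))
        names.append(name)
        counts.append(overlap)
        sizes.append(len(members))
        pvals.append(min(p, 1.0))

    padj = adjust_pvalues(pvals) if pvals else []
    results = [
        ORAResult(
            pathway=names[i],
            count=counts[i],
            percent=100.0 * counts[i] / n_query,
            effective_size=sizes[i],
            p_raw=pvals[i],
            p_adj=float(padj[i]),
        )
        for i in range(len(names))
    ]
    results.sort(key=lambda r: (r.p_raw, r.pathway))
    return [r for r in results if r.p_raw < alpha]


def ora_table(results: list[ORAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "count": [r.count for r in results],
            "percent": [r.percent for r in results],
            "effective_size": [r.effective_size for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
        }
    )
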