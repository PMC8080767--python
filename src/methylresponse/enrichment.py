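"""Gene-set over-representation with hypergeometric tests and BH q-values."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "enrich", "compare_target_classes"]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional category labels (e.g. immune/oncogenic)."""

    sets: dict[str, frozenset]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not s for s in self.sets.values()):
            raise ValueError("gene sets must be non-empty")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name<TAB>description<TAB>gene...).

    The description field is kept as the set's category label.
    """
    sets: dict[str, frozenset] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"duplicate gene-set name: {name}")
            sets[name] = frozenset(genes)
            categories[name] = desc
    return GeneSetCollection(sets=sets, categories=categories)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.categories.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def enrich(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    Genes outside the universe are dropped from both query and sets (the
    dropped-query count is reported in ``attrs['query_dropped']``).  The
    upper-tail p is ``P[X >= k]`` for X ~ Hypergeom(N, K, n) with N the
    universe size, K the in-universe set size, n the in-universe query
    size and k the overlap; q is BH across all sets in the collection.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    raw_query = frozenset(query)
    query = raw_query & universe
    n, N = len(query), len(universe)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name] & universe
        K = len(genes)
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set": name,
                "category": collection.categories.get(name, ""),
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] if len(out) else []
    out = out.sort_values("q", kind="stable")
    out.attrs["query_dropped"] = len(raw_query) - n
    return out


def compare_target_classes(
    pdmr_results: pd.DataFrame,
    edmr_results: pd.DataFrame,
    q_threshold: float = 0.01,
) -> dict:
    """Significant sets per target class, their intersection and differences."""
    if not pdmr_results.index.sort_values().equals(
        edmr_results.index.sort_values()
    ):
        raise ValueError("result lists must come from the same collection")
    p_sig = set(pdmr_results.index[pdmr_results["q"] < q_threshold])
    e_sig = set(edmr_results.index[edmr_results["q"] < q_threshold])
    return {
        "pdmr_significant": sorted(p_sig),
        "edmr_significant": sorted(e_sig),
        "shared": sorted(p_sig & e_sig),
        "pdmr_only": sorted(p_sig - e_sig),
        "edmr_only": sorted(e_sig - p_sig),
    }
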