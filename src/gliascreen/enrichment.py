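"""Cross-assay integration of hit sets and hypergeometric over-representation.

After per-assay hit calling, the same kinase can surface in several
phenotype assays; the overlap table enumerates every exclusive Venn region
across the labelled hit sets.  Over-representation of a hit list within
predefined gene sets is scored with the hypergeometric upper tail against
the screened library as the universe, with Benjamini-Hochberg adjustment
across sets.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .design import GeneSetCollection
from .errors import IntegrityError


def phenotype_overlap(
    hit_sets: Mapping[str, Iterable[str]], universe: Iterable[str]
) -> dict:
    """All intersection cardinalities across labelled hit sets.

    ``hit_sets`` maps a label (conventionally "assay:category") to a gene
    set.  Returns a dict with:

    - ``exclusive``: for every nonempty combination of labels, the number of
      genes belonging to exactly those sets (the Venn regions; keys are
      '&'-joined sorted labels);
    - ``intersection``: pairwise and full intersection counts;
    - ``unique``: per-label count of genes in no other set;
    - ``union``: size of the union (equals the sum of exclusive regions).
    """
    uni = set(universe)
    sets = {k: set(v) for k, v in hit_sets.items()}
    for name, s in sets.items():
        stray = s - uni
        if stray:
            raise IntegrityError(f"genes outside universe in {name!r}: {sorted(stray)[:5]}")

    labels = sorted(sets)
    exclusive: dict[str, int] = {}
    union = set().union(*sets.values()) if sets else set()
    for gene in union:
        members = tuple(l for l in labels if gene in sets[l])
        key = "&".join(members)
        exclusive[key] = exclusive.get(key, 0) + 1

    intersections: dict[str, int] = {}
    for r in range(2, len(labels) + 1):
        for combo in combinations(labels, r):
            common = set.intersection(*(sets[l] for l in combo))
            intersections["&".join(combo)] = len(common)

    unique = {l: exclusive.get(l, 0) for l in labels}
    assert sum(exclusive.values()) == len(union)
    return {
        "exclusive": exclusive,
        "intersection": intersections,
        "unique": unique,
        "union": len(union),
        "set_sizes": {l: len(sets[l]) for l in labels},
    }


def hit_sets_from_stats(stats: pd.DataFrame, condition: str = "LPS") -> dict[str, set[str]]:
    """Group a per-gene stats table into '(assay:category)' hit sets."""
    hit = stats[(stats["condition"] == condition) & (stats["category"] != "none")]
    out: dict[str, set[str]] = {}
    for (assay, cat), sub in hit.groupby(["assay", "category"]):
        out[f"{assay}:{cat}"] = set(sub["gene_id"])
    return out


def enrichment_ora(hits: Iterable[str], gene_sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list in each gene set.

    For a universe of size N, a set of size K and n hits with k overlapping
    genes, the p-value is P(X >= k) for X ~ Hypergeom(N, K, n).  Rows are
    BH-adjusted across sets and sorted by raw p.
    """
    hits = set(hits)
    if not hits:
        raise ValueError("empty hit list")
    uni = set(gene_sets.universe)
    stray = hits - uni
    if stray:
        raise IntegrityError(f"hits outside universe: {sorted(stray)[:5]}")
    if not gene_sets.sets:
        raise ValueError("no gene sets to test")

    n_uni = len(uni)
    n_hits = len(hits)
    rows = []
    for name, members in gene_sets.sets.items():
        k = len(hits & set(members))
        p = float(hypergeom.sf(k - 1, n_uni, len(members), n_hits))
        rows.append(
            dict(
                set_name=name,
                overlap=k,
                set_size=len(members),
                hits_size=n_hits,
                universe_size=n_uni,
                p_value=min(p, 1.0),
            )
        )
    df = pd.DataFrame(rows)
    df["bh_adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
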