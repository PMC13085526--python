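"""Cross-species and cross-study gene-set comparison.

Species-specific gene lists are mapped into a common reference namespace by
best-hit reduction of a scored homolog table (the search producing the table
is upstream of this package). Overlap significance uses the hypergeometric
upper tail: drawing |B| genes from a universe containing |A| successes,
``p = P(X >= |A intersect B|)``; an optional seeded Monte-Carlo z-score of
the observed overlap against random draws is provided for parity with
permutation-based platforms. Flat term enrichment applies the same tail test
per annotation term with BH control across terms (no ontology-graph
propagation — supply pre-propagated annotations if that is wanted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .shoot import benjamini_hochberg


class SetComparisonError(ValueError):
    pass


@dataclass
class OverlapResult:
    size_a: int
    size_b: int
    overlap: int
    universe: int
    p_upper: float
    fold_enrichment: float
    mc_z: float | None = None


def best_hit_reduce(homolog_map: pd.DataFrame) -> dict[str, str]:
    """One target per source gene: the maximal score, ties to the
    lexicographically smallest target gene."""
    if homolog_map.empty:
        return {}
    df = homolog_map.sort_values(
        ["source_gene", "score", "target_gene"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    best = df.drop_duplicates("source_gene", keep="first")
    return dict(zip(best["source_gene"], best["target_gene"]))


def map_gene_set(genes, mapping: dict[str, str]) -> set[str]:
    """Translate a gene set through a best-hit mapping, dropping unmapped ids."""
    return {mapping[g] for g in genes if g in mapping}


def overlap_significance(
    set_a,
    set_b,
    universe: int,
    mc_draws: int = 0,
    seed: int = 0,
) -> OverlapResult:
    """Hypergeometric significance of a two-set overlap within a universe.

    ``p_upper`` is P(X >= overlap) for X hypergeometric(universe, |A|, |B|);
    ``fold_enrichment`` is observed / expected overlap with expected
    |A||B|/universe. With ``mc_draws > 0`` a Monte-Carlo z-score of the
    observed overlap against random draws of |B| genes is added.
    """
    a, b = set(set_a), set(set_b)
    if len(a | b) > universe:
        raise SetComparisonError(
            f"universe {universe} smaller than the union ({len(a | b)})"
        )
    k = len(a & b)
    p_upper = float(stats.hypergeom.sf(k - 1, universe, len(a), len(b)))
    expected = len(a) * len(b) / universe if universe else np.nan
    fold = k / expected if expected > 0 else np.inf
    mc_z = None
    if mc_draws > 0:
        rng = np.random.default_rng(seed)
        marks = np.zeros(universe, dtype=bool)
        marks[: len(a)] = True  # labels are exchangeable under the null
        draws = np.array(
            [marks[rng.choice(universe, len(b), replace=False)].sum() for _ in range(mc_draws)]
        )
        sd = draws.std()
        mc_z = float((k - draws.mean()) / sd) if sd > 0 else np.inf
    return OverlapResult(
        size_a=len(a),
        size_b=len(b),
        overlap=k,
        universe=universe,
        p_upper=p_upper,
        fold_enrichment=fold,
        mc_z=mc_z,
    )


def three_way_overlap(sets: dict[str, set[str]]) -> dict[str, int]:
    """Counts of the 7 Venn regions of three gene sets (common namespace).

    Region keys join the member set names with ``&``; the all-three region
    is always present (it is empty in the cross-species systemic-N
    comparison this reproduces, but is reported explicitly either way).
    """
    if len(sets) != 3:
        raise SetComparisonError("exactly three sets are required")
    names = list(sets)
    import itertools

    counts = {}
    for k in range(1, 4):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            )
            counts["&".join(combo)] = len(inside - outside)
    return counts


def flat_enrichment(
    gene_set,
    universe_set,
    annotation: dict[str, set[str]],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a gene set within a universe.

    Terms are tested against the annotation restricted to the universe;
    terms with no annotated universe genes are skipped with a warning.
    Returns the terms passing BH FDR <= cutoff, sorted by p, with columns
    ``term_id, n_term, n_overlap, p, fdr``.
    """
    import warnings

    genes = set(gene_set) & set(universe_set)
    universe = set(universe_set)
    rows = []
    for term, members in annotation.items():
        members_u = members & universe
        if not members_u:
            warnings.warn(f"term {term!r} has no genes in the universe; skipped")
            continue
        k = len(genes & members_u)
        p = float(
            stats.hypergeom.sf(k - 1, len(universe), len(members_u), len(genes))
        )
        rows.append((term, len(members_u), k, p))
    if not rows:
        return pd.DataFrame(columns=["term_id", "n_term", "n_overlap", "p", "fdr"])
    df = pd.DataFrame(rows, columns=["term_id", "n_term", "n_overlap", "p"])
    df["fdr"] = benjamini_hochberg(df["p"].to_numpy())
    df = df[df["fdr"] <= fdr_cutoff].sort_values(
        ["p", "term_id"], kind="mergesort"
    )
    return df.reset_index(drop=True)
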