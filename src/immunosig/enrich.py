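"""Over-representation analysis (OVA) of gene lists against gene sets.

For a hit list of n genes drawn from a universe of N tested genes, the
overlap k with a K-gene set is referred to the hypergeometric upper tail
P(X >= k); p-values are adjusted by Benjamini-Hochberg across sets.  The
gene ratio k/K (hits in set over set size) is reported for plotting.  The
universe is the set of genes actually tested in the cohort's DE table, not
a whole-genome annotation.  Cross-cohort consensus pathways are those
significant in every cohort; Venn-style overlap counts are emitted
alongside.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GeneSetCollection
from .de import bh_adjust
from .exceptions import DataValidationError

logger = logging.getLogger(__name__)


def hypergeom_enrich(
    hit_genes: Iterable[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided over-representation test per gene set.

    Returns a frame indexed by set name with columns k, K, n, N, p_value,
    fdr, gene_ratio, sorted by p then name.  Sets with no member in the
    universe are dropped with a warning.
    """
    universe_list = list(dict.fromkeys(universe))
    if not universe_list:
        raise DataValidationError("empty universe")
    uni = set(universe_list)
    hits = set(hit_genes)
    outside = hits - uni
    if outside:
        raise DataValidationError(
            f"{len(outside)} hit gene(s) not in universe, e.g. {sorted(outside)[:5]}"
        )
    N, n = len(uni), len(hits)
    rows = []
    skipped = 0
    for gs in sets.sets:
        members = set(gs.genes) & uni
        K = len(members)
        if K == 0:
            skipped += 1
            continue
        k = len(hits & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": gs.name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": min(p, 1.0),
                "gene_ratio": k / K,
            }
        )
    if skipped:
        logger.warning("%d gene set(s) had no member in the universe", skipped)
    if not rows:
        raise DataValidationError("no gene set overlaps the universe")
    out = pd.DataFrame(rows).set_index("set_name")
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(["p_value", "set_name"], kind="mergesort")
    return out[["k", "K", "n", "N", "p_value", "fdr", "gene_ratio"]]


def intersect_pathways(
    results: Mapping[str, pd.DataFrame], fdr_threshold: float = 0.05
) -> tuple[list[str], dict[tuple[str, ...], int]]:
    """Pathways significant in every cohort, plus Venn-style overlap counts.

    ``results`` maps cohort id to an enrichment frame indexed by set name
    with an ``fdr`` column.  Returns the sorted consensus list and a dict
    mapping each exact cohort combination (sorted tuple) to the number of
    pathways significant in exactly those cohorts; the counts partition the
    distinct significant pathways.
    """
    if len(results) < 2:
        raise DataValidationError("pathway intersection needs >= 2 cohorts")
    sig_by_cohort = {
        cid: set(tab.index[tab["fdr"] < fdr_threshold]) for cid, tab in results.items()
    }
    union = set().union(*sig_by_cohort.values())
    combos: Counter[tuple[str, ...]] = Counter()
    for name in union:
        key = tuple(sorted(c for c, s in sig_by_cohort.items() if name in s))
        combos[key] += 1
    consensus = sorted(set.intersection(*sig_by_cohort.values()))
    logger.info(
        "pathway consensus: %d significant in all %d cohorts (%d distinct overall)",
        len(consensus), len(results), len(union),
    )
    return consensus, dict(combos)
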