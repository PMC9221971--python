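"""Fisher's-exact functional enrichment of protein sets.

Given a foreground set (e.g. succinylated or differentially succinylated
proteins), a universe, and term → member annotation maps (KEGG pathways, GO
terms, protein domains, subcellular labels), each term is tested with the
one-sided (enrichment) Fisher's exact test, i.e. the hypergeometric upper
tail of the 2×2 table

    a = |foreground ∩ term|      b = |foreground \\ term|
    c = |term \\ foreground|     d = |universe \\ (foreground ∪ term)|

Benjamini–Hochberg adjustment is available on top.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationTable


def hypergeom_enrichment_p(a: int, n_universe: int, n_term: int, n_fg: int) -> float:
    """One-sided Fisher's exact p for enrichment: the upper hypergeometric
    tail P(X >= a) when drawing ``n_fg`` proteins from a universe of
    ``n_universe`` of which ``n_term`` carry the term."""
    return float(min(stats.hypergeom.sf(a - 1, n_universe, n_term, n_fg), 1.0))


def fisher_enrichment(
    foreground: Iterable[str],
    universe: Iterable[str],
    annotations: AnnotationTable,
    alternative: str = "greater",
    bh: bool = False,
) -> pd.DataFrame:
    """One row per term with at least one foreground member, sorted by p.

    Term members outside the universe are dropped with a warning;
    ``alternative`` may be "greater" (enrichment, default) or "two-sided".
    """
    fg = set(foreground)
    uni = set(universe)
    if not fg or not uni:
        raise ValueError("foreground and universe must be nonempty")
    if not fg <= uni:
        raise ValueError(f"foreground not contained in universe: {sorted(fg - uni)[:5]}")
    rows = []
    n_universe = len(uni)
    n_fg = len(fg)
    dropped = 0
    for term_id, (name, category, members) in annotations.terms.items():
        outside = members - uni
        dropped += len(outside)
        members = members & uni
        a = len(fg & members)
        if a == 0:
            continue
        b = n_fg - a
        c = len(members) - a
        d = n_universe - n_fg - c
        if alternative == "greater":
            p = hypergeom_enrichment_p(a, n_universe, len(members), n_fg)
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "category": category,
                "fg_in_term": a,
                "fg_not_in_term": b,
                "bg_in_term": c,
                "bg_not_in_term": d,
                "odds_ratio": odds,
                "p_value": min(p, 1.0),
            }
        )
    if dropped:
        warnings.warn(
            f"dropped {dropped} term memberships outside the universe", stacklevel=2
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "category", "fg_in_term", "fg_not_in_term",
            "bg_in_term", "bg_not_in_term", "odds_ratio", "p_value",
        ],
    )
    result = result.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    if bh and len(result):
        result["p_adjusted"] = adjust_bh(result["p_value"].to_numpy())
    return result


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
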