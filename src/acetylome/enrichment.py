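"""Generic term enrichment and set tallies.

One hypergeometric engine serves every over-representation panel: GO/KEGG-
style term enrichment of the acetylated proteins, subcellular-compartment
tallies, ortholog-kingdom distributions, and dual-modification domain
enrichment.  p is the upper hypergeometric tail P(X >= k) of drawing k
term-annotated proteins in a foreground of size n from a universe of N
containing K annotated proteins (identical to a one-sided Fisher exact
test); q is the Benjamini-Hochberg step-up adjustment across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import AnnotationTable


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def term_enrichment(foreground: Set[str], annotation: AnnotationTable,
                    universe: Set[str]) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of every term hit by the
    foreground; terms with zero foreground hits are omitted.

    Returns columns term, k, n, K, N, p, q sorted by (q, p, term).
    """
    if not universe:
        raise ValueError("empty universe")
    extra = foreground - universe
    if extra:
        raise ValueError(f"foreground not contained in universe "
                         f"({len(extra)} ids outside)")
    N = len(universe)
    n = len(foreground)
    term_universe: Dict[str, int] = {}
    term_fg: Dict[str, int] = {}
    for pid in universe:
        for term in annotation.mapping.get(pid, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if pid in foreground:
                term_fg[term] = term_fg.get(term, 0) + 1
    rows = []
    for term, k in term_fg.items():
        K = term_universe[term]
        rows.append((term, k, n, K, N,
                     hypergeom_upper_tail(k, N, K, n)))
    frame = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if frame.empty:
        frame["q"] = []
        return frame
    frame["q"] = bh_qvalues(frame["p"].to_numpy())
    return frame.sort_values(["q", "p", "term"]).reset_index(drop=True)


def set_tally(protein_set: Set[str],
              annotation: AnnotationTable) -> pd.DataFrame:
    """Term counts over a protein set; multi-term proteins count once per
    term.  Percentages are relative to the set size."""
    counts: Dict[str, int] = {}
    for pid in protein_set:
        for term in annotation.mapping.get(pid, ()):
            counts[term] = counts.get(term, 0) + 1
    n = len(protein_set)
    rows = [(term, c, 100.0 * c / n if n else 0.0)
            for term, c in sorted(counts.items(),
                                  key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["term", "count", "percent_of_set"])
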