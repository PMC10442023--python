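"""Descriptive structure of the acetylome catalog.

Covers the sites-per-protein distribution, reproducibility of replicate
detection (overlap ratios), the organ Venn partition with organ-specific
fractions, within-replicate spectral-area normalization, and deterministic
hierarchical ordering for abundance heatmaps.

The replicate "overlap ratio" convention is ambiguous in the literature; we
compute both the Jaccard ratio |A∩B|/|A∪B| and the min-denominator ratio
|A∩B|/min(|A|,|B|), with ``method`` selecting the headline number (default
"min", the most common reading of reproducibility claims).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_tables import SiteCatalog, SiteKey


@dataclass
class OverlapResult:
    set_a_size: int
    set_b_size: int
    intersection: int
    union: int
    ratio_jaccard: Optional[float]
    ratio_min: Optional[float]
    method_used: str = "min"

    @property
    def ratio(self) -> Optional[float]:
        return self.ratio_min if self.method_used == "min" \
            else self.ratio_jaccard


@dataclass
class VennPartition:
    """Counts over the organ power set plus organ-specific summaries."""

    level: str                                   # "site" or "protein"
    regions: Dict[FrozenSet[str], int]
    organ_totals: Dict[str, int]                 # elements present in organ
    organ_specific: Dict[str, int]               # elements only in organ
    organ_specific_fraction: Dict[str, float]
    n_elements: int
    n_excluded: int = 0                          # rows lacking an organ label

    def all_organ_count(self, organs) -> int:
        return self.regions.get(frozenset(organs), 0)


@dataclass
class AbundanceMatrix:
    """Per-replicate within-replicate proportions and per-organ means."""

    per_replicate: pd.DataFrame   # rows SiteKey, cols organ|replicate
    per_organ: pd.DataFrame       # rows SiteKey, cols organ
    normalization: str = "within-replicate proportion, organ mean"


def sites_per_protein(catalog: SiteCatalog
                      ) -> Tuple[Dict[int, int], Optional[float]]:
    """Histogram {k -> number of proteins carrying k distinct acetyl sites}
    and the mean sites/protein; (empty, None) for an empty catalog."""
    f = catalog.frame
    f = f[f.ptm_type == "acetyl"]
    if f.empty:
        return {}, None
    per_protein = f.drop_duplicates(["protein_id", "position"]) \
                   .groupby("protein_id").size()
    hist = per_protein.value_counts().sort_index()
    mean = float(per_protein.sum() / len(per_protein))
    return {int(k): int(v) for k, v in hist.items()}, mean


def replicate_overlap(sites_a: Set[SiteKey], sites_b: Set[SiteKey],
                      method: str = "min") -> OverlapResult:
    """Overlap of two replicate site-key sets; both ratio conventions are
    always computed.  Two empty sets give undefined (None) ratios, never 0."""
    if method not in ("min", "jaccard"):
        raise ValueError(f"unknown overlap method {method!r}")
    inter = len(sites_a & sites_b)
    union = len(sites_a | sites_b)
    jac = inter / union if union else None
    m = min(len(sites_a), len(sites_b))
    rmin = inter / m if m else None
    return OverlapResult(len(sites_a), len(sites_b), inter, union,
                         jac, rmin, method_used=method)


def pairwise_replicate_overlaps(catalog: SiteCatalog,
                                method: str = "min") -> pd.DataFrame:
    """All within-organ replicate pairs of the acetyl catalog."""
    f = catalog.frame
    f = f[(f.ptm_type == "acetyl") & f.organ.notna() & f.replicate.notna()]
    rows = []
    for organ, grp in f.groupby("organ", sort=True):
        reps = sorted(set(grp.replicate))
        keys = {rep: {SiteKey(p, int(q)) for p, q in
                      zip(grp[grp.replicate == rep].protein_id,
                          grp[grp.replicate == rep].position)}
                for rep in reps}
        for ra, rb in combinations(reps, 2):
            ov = replicate_overlap(keys[ra], keys[rb], method=method)
            rows.append((organ, ra, rb, ov.set_a_size, ov.set_b_size,
                         ov.intersection, ov.union, ov.ratio_jaccard,
                         ov.ratio_min))
    return pd.DataFrame(rows, columns=[
        "organ", "replicate_a", "replicate_b", "size_a", "size_b",
        "intersection", "union", "ratio_jaccard", "ratio_min"])


def organ_venn(catalog: SiteCatalog, level: str = "site") -> VennPartition:
    """Partition distinct sites (or proteins) by the exact set of organs in
    which they were observed; an element present in organ X by any replicate
    counts as present in X."""
    if level not in ("site", "protein"):
        raise ValueError("level must be 'site' or 'protein'")
    f = catalog.frame
    f = f[f.ptm_type == "acetyl"]
    n_excluded_rows = int(f.organ.isna().sum())
    f = f[f.organ.notna()]
    if level == "site":
        grouping = f.groupby([f.protein_id, f.position])["organ"]
    else:
        grouping = f.groupby("protein_id")["organ"]
    membership: Dict[object, FrozenSet[str]] = {
        key: frozenset(organs) for key, organs in grouping.unique().items()}
    regions: Dict[FrozenSet[str], int] = {}
    organ_totals: Dict[str, int] = {}
    organ_specific: Dict[str, int] = {}
    for organs in membership.values():
        regions[organs] = regions.get(organs, 0) + 1
        for o in organs:
            organ_totals[o] = organ_totals.get(o, 0) + 1
        if len(organs) == 1:
            (o,) = organs
            organ_specific[o] = organ_specific.get(o, 0) + 1
    frac = {o: organ_specific.get(o, 0) / organ_totals[o]
            for o in organ_totals}
    return VennPartition(level=level, regions=regions,
                         organ_totals=organ_totals,
                         organ_specific={o: organ_specific.get(o, 0)
                                         for o in organ_totals},
                         organ_specific_fraction=frac,
                         n_elements=len(membership),
                         n_excluded=n_excluded_rows)


def normalize_abundance(catalog: SiteCatalog) -> AbundanceMatrix:
    """Within each (organ, replicate) the site abundances are divided by the
    replicate total (proportions of total spectral area); per-organ value is
    the mean of the replicate proportions.  Missing abundances stay missing."""
    f = catalog.frame
    f = f[(f.ptm_type == "acetyl") & f.organ.notna() & f.replicate.notna()]
    if f.empty or f.abundance.isna().all():
        raise ValueError("no abundances present")
    f = f.assign(site=[SiteKey(p, int(q))
                       for p, q in zip(f.protein_id, f.position)])
    wide = f.pivot_table(index="site", columns=["organ", "replicate"],
                         values="abundance", aggfunc="mean")
    totals = wide.sum(axis=0, skipna=True)
    per_rep = wide / totals
    per_organ = per_rep.T.groupby(level="organ").mean().T
    per_rep.columns = [f"{o}|{r}" for o, r in per_rep.columns]
    return AbundanceMatrix(per_replicate=per_rep, per_organ=per_organ)


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        _warnings.warn(f"{int(constant.sum())} constant rows z-scored to 0")
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def heatmap_order(matrix: pd.DataFrame) -> Tuple[List, List]:
    """Leaf orders from average-linkage Euclidean clustering of the row-wise
    z-scored matrix (missing values treated as 0 for ordering only).
    scipy's linkage on a fixed input order is deterministic, which makes the
    ordering reproducible."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix")
    values = matrix.to_numpy(dtype=float)
    values = np.nan_to_num(values, nan=0.0)
    z = _zscore_rows(values)
    row_link = hierarchy.linkage(pdist(z), method="average")
    col_link = hierarchy.linkage(pdist(z.T), method="average")
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    return ([matrix.index[i] for i in row_order],
            [matrix.columns[j] for j in col_order])
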