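"""Crosstalk between lysine acetylation and other PTMs.

Three questions, three statistics:

* do the same *proteins* carry several PTMs?  Pairwise hypergeometric
  overlap tests against a common universe, plus overlap percentages and
  power-set region counts;
* do the same *residues*?  Exact site-key intersections between the acetyl
  catalog and K-targeted catalogs (ubiquitin, SUMO);
* is phosphorylation spatially clustered around acetylated lysines?  An
  anchor-centric positional profile: for each anchor lysine (acetylated vs
  the non-acetylated lysines of the same acetylated proteins — lysines of
  comparable detectability) and each S/T/Y at unsigned sequence distance d,
  the fraction phosphorylated, with percentile-bootstrap CIs over proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .enrichment import hypergeom_upper_tail, term_enrichment
from .io_tables import AnnotationTable, Proteome, SiteCatalog, SiteKey

_RES_CLASSES = ("S", "T", "Y")
ANCHOR_ACK = "acK"
ANCHOR_NON = "non-acK"


@dataclass
class OverlapTest:
    ptm_a: str
    ptm_b: str
    universe: int
    size_a: int
    size_b: int
    intersection: int
    p_value: float
    percent_of_a: float
    percent_of_b: float


def protein_overlap(ptm_sets: Dict[str, Set[str]], universe_size: int
                    ) -> Tuple[List[OverlapTest], Dict[FrozenSet[str], int]]:
    """Pairwise hypergeometric overlap tests P(X >= k) over a universe of
    ``universe_size`` proteins, plus counts per power-set region."""
    for name, s in ptm_sets.items():
        if len(s) > universe_size:
            raise ValueError(f"{name}: set exceeds universe")
    tests = []
    for a, b in combinations(sorted(ptm_sets), 2):
        sa, sb = ptm_sets[a], ptm_sets[b]
        k = len(sa & sb)
        p = hypergeom_upper_tail(k, universe_size, len(sa), len(sb))
        tests.append(OverlapTest(
            ptm_a=a, ptm_b=b, universe=universe_size,
            size_a=len(sa), size_b=len(sb), intersection=k, p_value=p,
            percent_of_a=100.0 * k / len(sa) if sa else 0.0,
            percent_of_b=100.0 * k / len(sb) if sb else 0.0))
    regions: Dict[FrozenSet[str], int] = {}
    union = set().union(*ptm_sets.values()) if ptm_sets else set()
    for pid in union:
        member = frozenset(n for n, s in ptm_sets.items() if pid in s)
        regions[member] = regions.get(member, 0) + 1
    return tests, regions


def site_overlap(kac_catalog: SiteCatalog, other_catalog: SiteCatalog,
                 ) -> Dict[str, Tuple[int, List[SiteKey]]]:
    """Exact shared site keys between acetyl sites and each K-targeted PTM
    in ``other_catalog`` (non-K rows of the other PTM are ignored)."""
    kac = kac_catalog.site_keys(ptm_type="acetyl")
    out: Dict[str, Tuple[int, List[SiteKey]]] = {}
    f = other_catalog.frame
    for ptm in sorted(set(f.ptm_type) - {"acetyl"}):
        g = f[(f.ptm_type == ptm) & (f.residue == "K")]
        keys = {SiteKey(p, int(q)) for p, q in zip(g.protein_id, g.position)}
        shared = sorted(kac & keys)
        out[ptm] = (len(shared), shared)
    return out


def _protein_counts(sequence: str, anchors_ack: np.ndarray,
                    anchors_non: np.ndarray, phospho: Set[int],
                    d_max: int) -> np.ndarray:
    """num/den counts, shape (2, 2 classes, 3 residues, d_max)."""
    seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
    L = seq.size
    counts = np.zeros((2, 2, 3, d_max), dtype=np.int64)
    res_pos = {r: np.flatnonzero(seq == ord(r)) + 1 for r in _RES_CLASSES}
    phos = np.zeros(L + 1, dtype=bool)
    for pos in phospho:
        phos[pos] = True
    is_res = {r: np.zeros(L + 2 * d_max + 2, dtype=bool)
              for r in _RES_CLASSES}
    for r, pos in res_pos.items():
        is_res[r][pos] = True
    for ci, anchors in enumerate((anchors_ack, anchors_non)):
        if anchors.size == 0:
            continue
        for d in range(1, d_max + 1):
            for side in (-d, d):
                j = anchors + side
                valid = (j >= 1) & (j <= L)
                jv = j[valid]
                for ri, r in enumerate(_RES_CLASSES):
                    hit = is_res[r][jv]
                    den = int(hit.sum())
                    if den:
                        counts[1, ci, ri, d - 1] += den
                        counts[0, ci, ri, d - 1] += int(phos[jv[hit]].sum())
    return counts


def positional_profile(proteome: Proteome, kac_keys: Set[SiteKey],
                       phospho_keys: Set[SiteKey], d_max: int = 15,
                       n_boot: int = 1000, seed: int = 0,
                       anchor_scope: str = "kac_proteins",
                       ci_level: float = 0.95) -> pd.DataFrame:
    """Phosphorylated fraction of S/T/Y at distance d from acK vs non-acK
    anchor lysines, with percentile-bootstrap CIs (resampling proteins).

    ``anchor_scope``: "kac_proteins" restricts non-acK anchors to lysines of
    proteins carrying at least one acetylation; "all" uses every protein.
    """
    if anchor_scope not in ("kac_proteins", "all"):
        raise ValueError(f"unknown anchor scope {anchor_scope!r}")
    ack_by_prot: Dict[str, List[int]] = {}
    for key in kac_keys:
        ack_by_prot.setdefault(key.protein_id, []).append(key.position)
    phos_by_prot: Dict[str, Set[int]] = {}
    for key in phospho_keys:
        phos_by_prot.setdefault(key.protein_id, set()).add(key.position)

    if anchor_scope == "kac_proteins":
        pids = sorted(ack_by_prot)
    else:
        pids = sorted(proteome)
    per_protein = []
    for pid in pids:
        seq = proteome[pid].sequence
        kpos = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("K")
        kpos = np.flatnonzero(kpos) + 1
        ack = np.asarray(sorted(ack_by_prot.get(pid, ())), dtype=int)
        non = kpos[~np.isin(kpos, ack)]
        per_protein.append(_protein_counts(
            seq, ack, non, phos_by_prot.get(pid, set()), d_max))
    if not per_protein:
        raise ValueError("no anchor proteins")
    stack = np.stack(per_protein)               # (P, 2, 2, 3, d)
    P = stack.shape[0]
    flat = stack.reshape(P, -1)
    total = stack.sum(axis=0)                   # (2, 2, 3, d)

    rng = np.random.default_rng(seed)
    weights = rng.multinomial(P, np.full(P, 1.0 / P), size=n_boot)
    boot = (weights @ flat).reshape(n_boot, 2, 2, 3, d_max).astype(float)

    def _fractions(arr):
        num, den = arr[..., 0, :, :, :], arr[..., 1, :, :, :]
        num_c = num.sum(axis=-2, keepdims=True)
        den_c = den.sum(axis=-2, keepdims=True)
        num = np.concatenate([num, num_c], axis=-2)
        den = np.concatenate([den, den_c], axis=-2)
        with np.errstate(invalid="ignore", divide="ignore"):
            return num / den, num, den

    frac, num, den = _fractions(total[None])    # (1, 2, 4, d)
    bfrac, _, _ = _fractions(boot)              # (B, 2, 4, d)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        ci_lo = np.nanquantile(bfrac, lo_q, axis=0)
        ci_hi = np.nanquantile(bfrac, hi_q, axis=0)

    classes = (ANCHOR_ACK, ANCHOR_NON)
    residues = _RES_CLASSES + ("combined",)
    rows = []
    for ci, cls in enumerate(classes):
        for ri, res in enumerate(residues):
            for d in range(d_max):
                rows.append((cls, res, d + 1,
                             int(num[0, ci, ri, d]), int(den[0, ci, ri, d]),
                             float(frac[0, ci, ri, d]),
                             float(ci_lo[ci, ri, d]),
                             float(ci_hi[ci, ri, d])))
    return pd.DataFrame(rows, columns=["anchor_class", "residue", "d",
                                       "numerator", "denominator",
                                       "fraction", "ci_lo", "ci_hi"])


def dual_modification_enrichment(annotation: AnnotationTable,
                                 acetyl_proteins: Set[str],
                                 phospho_proteins: Set[str],
                                 universe: Set[str]) -> pd.DataFrame:
    """Term enrichment (one-sided Fisher / hypergeometric upper tail, BH) of
    the proteins carrying both acetylation and phosphorylation."""
    foreground = (acetyl_proteins & phospho_proteins) & universe
    if not foreground:
        frame = pd.DataFrame(columns=["term", "k", "n", "K", "N", "p", "q"])
        frame.attrs["empty_foreground"] = True
        return frame
    return term_enrichment(foreground, annotation, universe)
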