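"""Conservation of acetylated vs non-acetylated lysines on ortholog
alignments, the 2x2 contrast test, and the substitution spectrum.

A reference lysine is called conserved when its alignment column shows K in
every aligned species ("all_species" rule; a fractional rule is available
since the threshold convention varies between studies).  A gap counts as
not-K and removes that species from the aligned count; columns covered by
fewer than ``min_aligned_frac`` of the species are excluded from the
contrast rather than called unconserved.

K->Q substitutions mimic the acetylated state (charge neutralized), K->R the
constitutively non-acetylated state (charge retained); the substitution
spectrum tallies both.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import ceil
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy import stats

from .io_tables import ValidationError


@dataclass
class OrthologAlignmentSet:
    """Aligned ortholog rows for one reference protein.

    ``reference_row`` may contain gaps; it must degap to the proteome
    sequence.  ``rows`` are the species rows, equal in length to the
    reference row.
    """

    reference_id: str
    reference_row: str
    species: List[str]
    rows: List[str]

    def __post_init__(self):
        L = len(self.reference_row)
        if L == 0:
            raise ValidationError(
                f"{self.reference_id}: empty reference row")
        bad = [s for s, r in zip(self.species, self.rows) if len(r) != L]
        if bad:
            raise ValidationError(
                f"{self.reference_id}: rows differ in length", bad)
        if len(self.species) != len(self.rows):
            raise ValidationError(
                f"{self.reference_id}: species/rows count mismatch")

    @property
    def n_species(self) -> int:
        return len(self.rows)

    def degapped_reference(self) -> str:
        return self.reference_row.replace("-", "")


@dataclass
class ConservationRecord:
    reference_position: int  # 1-based position of a K in the reference
    is_ack: bool
    n_species_aligned: int
    n_species_with_k: int
    conserved: bool
    substitutions: Counter = field(default_factory=Counter)
    excluded: bool = False  # aligned coverage below the threshold
    protein_id: str = ""


@dataclass
class ContrastResult:
    table: np.ndarray  # 2x2: rows acK/non-acK, cols conserved/not
    frac_ack_conserved: float
    frac_non_conserved: float
    chi2: float
    p_value: float
    degenerate: bool = False  # a zero margin: p undefined


def map_columns(alignment: OrthologAlignmentSet,
                proteome_sequence: Optional[str] = None) -> Dict[int, int]:
    """Map alignment columns (1-based) to 1-based reference positions over
    the non-gap reference columns."""
    degapped = alignment.degapped_reference()
    if not degapped:
        raise ValidationError(
            f"{alignment.reference_id}: all-gap reference row")
    if proteome_sequence is not None and degapped != proteome_sequence:
        raise ValidationError(
            f"{alignment.reference_id}: degapped reference row does not "
            "match the proteome sequence")
    out: Dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(alignment.reference_row, start=1):
        if ch != "-":
            pos += 1
            out[col] = pos
    return out


def classify_lysines(alignment: OrthologAlignmentSet,
                     ack_positions: Iterable[int],
                     conservation_rule: str = "all_species",
                     min_conserved_frac: float = 0.8,
                     min_aligned_frac: float = 0.8,
                     ) -> List[ConservationRecord]:
    """One :class:`ConservationRecord` per reference lysine.

    ``conservation_rule``: "all_species" (K in every aligned species) or
    "fraction" (K in >= ceil(min_conserved_frac * aligned) species).
    """
    if conservation_rule not in ("all_species", "fraction"):
        raise ValueError(f"unknown rule {conservation_rule!r}")
    colmap = map_columns(alignment)
    pos_to_col = {p: c for c, p in colmap.items()}
    ack = set(int(p) for p in ack_positions)
    ref = alignment.reference_row
    for p in ack:
        col = pos_to_col.get(p)
        if col is None or ref[col - 1] != "K":
            raise ValidationError(
                f"{alignment.reference_id}: acK position {p} is not a "
                "reference lysine")
    n_total = alignment.n_species
    rows = alignment.rows
    records: List[ConservationRecord] = []
    for col, pos in colmap.items():
        if ref[col - 1] != "K":
            continue
        column = [r[col - 1] for r in rows]
        aligned = [c for c in column if c != "-"]
        n_aligned = len(aligned)
        n_k = sum(1 for c in aligned if c == "K")
        subs = Counter(c for c in aligned if c != "K")
        excluded = n_aligned < min_aligned_frac * n_total
        if conservation_rule == "all_species":
            conserved = n_aligned > 0 and n_k == n_aligned
        else:
            conserved = n_aligned > 0 and \
                n_k >= ceil(min_conserved_frac * n_aligned)
        records.append(ConservationRecord(
            reference_position=pos, is_ack=pos in ack,
            n_species_aligned=n_aligned, n_species_with_k=n_k,
            conserved=conserved, substitutions=subs, excluded=excluded,
            protein_id=alignment.reference_id))
    return records


def classify_all(alignments: Dict[str, OrthologAlignmentSet],
                 ack_truth: Dict[str, Sequence[int]],
                 **kwargs) -> List[ConservationRecord]:
    """classify_lysines over a whole alignment set."""
    records: List[ConservationRecord] = []
    for pid, aln in alignments.items():
        records.extend(classify_lysines(
            aln, ack_truth.get(pid, ()), **kwargs))
    return records


def pearson_chi2_2x2(table: np.ndarray) -> tuple:
    """Pearson chi-square without continuity correction, 1 df."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("2x2 table required")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, np.nan
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def conservation_contrast(records: Sequence[ConservationRecord]
                          ) -> ContrastResult:
    """2x2 acK/non-acK x conserved/not contrast; excluded records dropped."""
    kept = [r for r in records if not r.excluded]
    ack = [r for r in kept if r.is_ack]
    non = [r for r in kept if not r.is_ack]
    if not ack or not non:
        raise ValueError("both lysine classes must be non-empty")
    a_c = sum(r.conserved for r in ack)
    n_c = sum(r.conserved for r in non)
    table = np.array([[a_c, len(ack) - a_c],
                      [n_c, len(non) - n_c]], dtype=float)
    chi2, p = pearson_chi2_2x2(table)
    return ContrastResult(
        table=table,
        frac_ack_conserved=a_c / len(ack),
        frac_non_conserved=n_c / len(non),
        chi2=chi2, p_value=p,
        degenerate=not np.isfinite(chi2))


def substitution_spectrum(records: Sequence[ConservationRecord],
                          ack_only: bool = True) -> Counter:
    """Counts of non-K residues aligned at (by default) acK columns."""
    spectrum: Counter = Counter()
    for r in records:
        if ack_only and not r.is_ack:
            continue
        spectrum.update(r.substitutions)
    return spectrum
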