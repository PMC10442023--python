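"""Readers, writers and validation for the on-disk formats, plus the shared
data model.

Everything downstream operates on a :class:`SiteCatalog` — the central table
of PTM sites (acetylation and co-occurring modifications) with organ,
replicate and abundance context — validated against the proteome FASTA it
refers to.  Coordinates are 1-based inclusive residue positions throughout
(the field writes K56, H4K5; never 0-based).

TSV dialect: tab-separated, UTF-8, ``#`` comment lines ignored, header
mandatory.  Missing optional columns are permitted; an absent abundance is
missing, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: residues permitted in a proteome sequence; X is an unknown residue and
#: never matches a modified residue.
VALID_RESIDUES = frozenset(AA20) | {"X"}
PTM_TYPES = ("acetyl", "phospho", "ubiquitin", "sumo")
#: PTM types that target lysine.
K_PTMS = frozenset({"acetyl", "ubiquitin", "sumo"})
PHOSPHO_RESIDUES = frozenset({"S", "T", "Y"})

SITE_COLUMNS = ("protein_id", "position", "residue", "ptm_type",
                "organ", "replicate", "abundance")


class FormatError(ValueError):
    """Malformed on-disk input (bad FASTA/TSV syntax)."""


class ValidationError(ValueError):
    """Content violates a data-model invariant.

    ``problems`` lists *every* offending row/record, not just the first.
    """

    def __init__(self, message: str, problems: Optional[Sequence[str]] = None):
        self.problems = list(problems or [])
        if self.problems:
            message = "%s:\n  %s" % (message, "\n  ".join(self.problems))
        super().__init__(message)


class SiteKey(NamedTuple):
    """Identity of a modified residue: the unit of all set/overlap work."""

    protein_id: str
    position: int


@dataclass(frozen=True)
class Protein:
    id: str
    sequence: str
    gene_id: Optional[str] = None
    description: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


class Proteome(dict):
    """id -> Protein mapping with uniqueness enforced on construction."""

    def __init__(self, proteins: Iterable[Protein]):
        super().__init__()
        dups = []
        for p in proteins:
            if p.id in self:
                dups.append(p.id)
            self[p.id] = p
        if dups:
            raise ValidationError("duplicate protein ids", sorted(set(dups)))

    def gene_of(self, protein_id: str) -> str:
        p = self[protein_id]
        return p.gene_id if p.gene_id else p.id


@dataclass(frozen=True)
class PtmSite:
    protein_id: str
    position: int  # 1-based, inclusive
    residue: str
    ptm_type: str
    organ: Optional[str] = None
    replicate: Optional[str] = None
    abundance: Optional[float] = None

    @property
    def key(self) -> SiteKey:
        return SiteKey(self.protein_id, self.position)


def _validate_site_frame(frame: pd.DataFrame, proteome: Proteome) -> None:
    problems = []
    for i, row in enumerate(frame.itertuples(index=False)):
        tag = f"row {i}: ({row.protein_id}, {row.position}, {row.residue}, {row.ptm_type})"
        if row.ptm_type not in PTM_TYPES:
            problems.append(f"{tag}: unknown ptm_type")
            continue
        prot = proteome.get(row.protein_id)
        if prot is None:
            problems.append(f"{tag}: protein not in proteome")
            continue
        pos = row.position
        if not (isinstance(pos, (int, np.integer)) and 1 <= pos <= len(prot)):
            problems.append(
                f"{tag}: position out of range 1..{len(prot)}")
            continue
        actual = prot.sequence[pos - 1]
        if row.residue != actual or row.residue == "X":
            problems.append(
                f"{tag}: residue mismatch (sequence has {actual!r})")
            continue
        if row.ptm_type in K_PTMS and row.residue != "K":
            problems.append(f"{tag}: {row.ptm_type} site must be K")
        elif row.ptm_type == "phospho" and row.residue not in PHOSPHO_RESIDUES:
            problems.append(f"{tag}: phospho site must be S/T/Y")
        if row.abundance is not None and not np.isnan(row.abundance) \
                and row.abundance < 0:
            problems.append(f"{tag}: negative abundance")
    dup_cols = ["protein_id", "position", "ptm_type", "organ", "replicate"]
    dup = frame.duplicated(subset=dup_cols, keep=False)
    if dup.any():
        for i in frame.index[dup]:
            problems.append(f"row {i}: duplicate (site, ptm, organ, replicate)")
    if problems:
        raise ValidationError("invalid site table", problems)


@dataclass
class SiteCatalog:
    """Validated table of PTM sites with organ/replicate/abundance context.

    ``frame`` columns: protein_id, position, residue, ptm_type, organ,
    replicate, abundance.  organ/replicate are object dtype with None for
    absent; abundance is float with NaN for missing.
    """

    frame: pd.DataFrame
    proteome_ref: str = ""

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, proteome: Proteome,
                   proteome_ref: str = "") -> "SiteCatalog":
        frame = frame.copy()
        for col in SITE_COLUMNS:
            if col not in frame.columns:
                frame[col] = None if col != "abundance" else np.nan
        frame = frame[list(SITE_COLUMNS)].reset_index(drop=True)
        frame["position"] = frame["position"].astype(int)
        frame["abundance"] = pd.to_numeric(frame["abundance"], errors="raise")
        frame["organ"] = frame["organ"].astype(object).where(
            frame["organ"].notna(), None)
        frame["replicate"] = frame["replicate"].astype(object).where(
            frame["replicate"].notna(), None)
        _validate_site_frame(frame, proteome)
        return cls(frame=frame, proteome_ref=proteome_ref)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, ptm_type: Optional[str] = None,
               organ: Optional[str] = None,
               replicate: Optional[str] = None) -> "SiteCatalog":
        f = self.frame
        if ptm_type is not None:
            f = f[f.ptm_type == ptm_type]
        if organ is not None:
            f = f[f.organ == organ]
        if replicate is not None:
            f = f[f.replicate == replicate]
        return SiteCatalog(f.reset_index(drop=True), self.proteome_ref)

    def site_keys(self, ptm_type: Optional[str] = None,
                  organ: Optional[str] = None,
                  replicate: Optional[str] = None) -> set:
        f = self.subset(ptm_type, organ, replicate).frame
        return {SiteKey(p, int(q)) for p, q in zip(f.protein_id, f.position)}

    def protein_ids(self, ptm_type: Optional[str] = None) -> set:
        f = self.frame
        if ptm_type is not None:
            f = f[f.ptm_type == ptm_type]
        return set(f.protein_id)

    def sites(self) -> Iterable[PtmSite]:
        for row in self.frame.itertuples(index=False):
            ab = row.abundance
            yield PtmSite(row.protein_id, int(row.position), row.residue,
                          row.ptm_type, row.organ, row.replicate,
                          None if pd.isna(ab) else float(ab))


@dataclass
class AnnotationTable:
    """protein_id -> set of term ids, with a namespace label."""

    mapping: Mapping[str, set] = field(default_factory=dict)
    namespace: str = "go-like"

    def terms_of(self, protein_id: str) -> set:
        return set(self.mapping.get(protein_id, set()))

    def all_terms(self) -> set:
        out = set()
        for terms in self.mapping.values():
            out |= terms
        return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> Proteome:
    """Parse a proteome FASTA into a Proteome (sequences uppercased)."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if s:
                if not s.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header '>'")
                break
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        desc = rec.description[len(rec.id):].strip() or None
        proteins.append(Protein(id=rec.id, sequence=seq, description=desc))
    return Proteome(proteins)


def write_fasta(proteome: Proteome, path) -> None:
    records = [SeqRecord(Seq(p.sequence), id=p.id,
                         description=p.description or "")
               for p in proteome.values()]
    SeqIO.write(records, str(path), "fasta")


def write_alignment_fasta(reference_id: str, reference_row: str,
                          species: Sequence[str], rows: Sequence[str],
                          path) -> None:
    """Aligned FASTA with the reference row first, one species per record."""
    with open(path, "w") as fh:
        fh.write(f">{reference_id}\n{reference_row}\n")
        for name, row in zip(species, rows):
            fh.write(f">{name}\n{row}\n")


def read_alignment_fasta(path) -> list:
    """Aligned FASTA: returns [(id, row), ...] preserving order; rows must be
    equal length (gaps '-')."""
    rows = [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise FormatError(f"{path}: empty alignment")
    lens = {len(r) for _, r in rows}
    if len(lens) != 1:
        raise ValidationError(f"{path}: aligned rows differ in length")
    return rows


# ---------------------------------------------------------------------------
# TSV

def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_site_table(path, proteome: Proteome,
                    proteome_ref: str = "") -> SiteCatalog:
    """Read a PTM site TSV and validate every row against the proteome.

    Required columns: protein_id, position, residue, ptm_type.  Optional:
    organ, replicate, abundance.
    """
    frame = _read_tsv(path, dtype={"protein_id": str, "residue": str,
                                   "ptm_type": str})
    required = {"protein_id", "position", "residue", "ptm_type"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return SiteCatalog.from_frame(frame, proteome, proteome_ref)


def write_site_table(catalog: SiteCatalog, path) -> None:
    catalog.frame.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x samples matrix; first column is the gene id. Rejects ragged
    rows and negative values."""
    frame = _read_tsv(path, index_col=0)
    if frame.isna().any().any():
        raise ValidationError(f"{path}: ragged rows / missing values")
    values = frame.to_numpy(dtype=float)
    if (values < 0).any():
        bad = frame.index[(values < 0).any(axis=1)]
        raise ValidationError("negative expression values",
                              [str(g) for g in bad])
    frame.index = frame.index.astype(str)
    return frame


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path, namespace: str = "go-like") -> AnnotationTable:
    """Two-column (protein_id, term) TSV -> AnnotationTable."""
    frame = _read_tsv(path, dtype=str)
    if not {"protein_id", "term"} <= set(frame.columns):
        raise FormatError(f"{path}: need columns protein_id, term")
    problems = [f"row {i}: empty term"
                for i, t in enumerate(frame["term"])
                if not isinstance(t, str) or not t.strip()]
    if problems:
        raise ValidationError("invalid annotation table", problems)
    mapping: dict = {}
    for pid, term in zip(frame.protein_id, frame.term):
        mapping.setdefault(pid, set()).add(term)
    return AnnotationTable(mapping=mapping, namespace=namespace)


def write_annotation(table: AnnotationTable, path) -> None:
    rows = [(pid, term) for pid in sorted(table.mapping)
            for term in sorted(table.mapping[pid])]
    pd.DataFrame(rows, columns=["protein_id", "term"]).to_csv(
        path, sep="\t", index=False)


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return _read_tsv(path)
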