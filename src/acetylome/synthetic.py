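"""Seeded synthetic data with the statistical structure the analyses assume.

The generator emulates a five-organ plant lysine acetylome at desk scale:

* sites per acetylated protein follow ``Geometric(pi)`` (support 1, 2, ...),
  so protein counts decay exponentially with site number;
* each true site lives in all organs (probability ``core_site_fraction``) or
  exactly one, and is *observed* in each biological replicate independently
  with detection probability ``q`` — which fixes the replicate overlap ratio
  (min-denominator overlap ~ q, Jaccard ~ q/(2-q));
* flanks of chosen sites are re-drawn with position-specific multipliers
  (default: +1 R/K/N/H excess, Cys depletion) and written back into the
  proteome copy, so catalog and sequences stay consistent;
* gene expression profiles are symmetric-Dirichlet draws whose concentration
  differs between acetylated and non-acetylated genes (high concentration =
  uniform = high Shannon entropy);
* serine/threonine/tyrosine residues are phosphorylated with probability
  ``p0 + a*exp(-d/lam)`` where d is the distance to the nearest acetylated
  lysine; ubiquitin/SUMO hit lysines at low per-residue rates with an
  exclusion factor at acetylated lysines;
* ortholog alignments toggle whole lysine columns conserved-in-all-species
  with probability ``rho_ac`` (acetylated K) or ``rho_non`` (other K), the
  substitution alphabet defaulting to {Q, R}.

Identical config + seed gives byte-identical outputs.  One global seed
drives fixed-offset substreams per table, so regenerating one table does not
shift the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .conservation import OrthologAlignmentSet
from .io_tables import AA20, Protein, Proteome, SiteCatalog

# typical proteome amino-acid frequencies (Swiss-Prot averages), normalized
DEFAULT_AA_FREQUENCIES: Dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

DEFAULT_ORGANS = ("root", "stem", "leaf", "flower", "seed")

#: flanking-residue bias applied to chosen acetylation sites; integer keys
#: are offsets from the central K, "any" applies at every redrawn offset.
DEFAULT_MOTIF_BOOST: Dict[object, Dict[str, float]] = {
    1: {"R": 3.0, "K": 2.0, "N": 2.0, "H": 2.0},
    "any": {"C": 0.3},
}

# fixed substream offsets: regenerating one table never shifts another
_STREAM_PROTEOME = 0
_STREAM_ACETYLOME = 1
_STREAM_EXPRESSION = 2
_STREAM_PTM = 3
_STREAM_ALIGNMENTS = 4
_STREAM_ANNOTATION = 5


@dataclass
class SyntheticConfig:
    """All knobs of the generator, with the study-scale defaults."""

    seed: int = 0
    # proteome
    n_proteins: int = 800
    length_mean: float = 300.0
    length_dispersion: float = 4.0  # gamma shape; larger = narrower lengths
    min_length: int = 31
    aa_frequencies: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES))
    # acetylome
    frac_acetylated: float = 0.5
    site_count_pi: float = 0.5          # Geometric success prob; mean 1/pi
    motif_boost: Dict[object, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_MOTIF_BOOST.items()})
    flank_redraw_width: int = 5
    organs: Tuple[str, ...] = DEFAULT_ORGANS
    core_site_fraction: float = 0.2
    replicate_count: int = 3
    detection_prob: float = 0.75        # q: per-replicate observation prob
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    # expression
    entropy_alpha_kac: float = 5.0
    entropy_alpha_non: float = 0.5
    n_samples: int = 158
    library_size_mu: float = 9.2        # log of ~1e4 counts
    library_size_sigma: float = 0.3
    # co-occurring PTMs
    phospho_base: float = 0.05          # p0
    phospho_boost: float = 0.3          # a
    phospho_decay: float = 3.0          # lam, residues
    ub_rate: float = 0.02
    sumo_rate: float = 0.01
    ack_exclusion: float = 0.1          # multiplier on Ub/SUMO rate at acK
    # ortholog alignments
    n_species: int = 10
    rho_ac: float = 0.22
    rho_non: float = 0.11
    background_identity: float = 0.7
    gap_rate: float = 0.05
    nonconserved_k_prob: float = 0.5
    k_subst_alphabet: Tuple[str, ...] = ("Q", "R")

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        probs = {
            "frac_acetylated": self.frac_acetylated,
            "site_count_pi": self.site_count_pi,
            "core_site_fraction": self.core_site_fraction,
            "detection_prob": self.detection_prob,
            "phospho_base": self.phospho_base,
            "ub_rate": self.ub_rate,
            "sumo_rate": self.sumo_rate,
            "ack_exclusion": self.ack_exclusion,
            "rho_ac": self.rho_ac,
            "rho_non": self.rho_non,
            "background_identity": self.background_identity,
            "gap_rate": self.gap_rate,
            "nonconserved_k_prob": self.nonconserved_k_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not 0.0 < self.site_count_pi <= 1.0:
            raise ValueError("site_count_pi must be in (0, 1]")
        if self.length_mean < 10:
            raise ValueError("degenerate length law: mean < 10")
        if self.entropy_alpha_kac <= 0 or self.entropy_alpha_non <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.n_species < 2:
            raise ValueError("need at least 2 ortholog species")
        freq = np.array([self.aa_frequencies[a] for a in AA20], dtype=float)
        if (freq < 0).any() or freq.sum() <= 0:
            raise ValueError("aa_frequencies must be non-negative, sum > 0")
        for pos, mult in self.motif_boost.items():
            if pos != "any" and not isinstance(pos, int):
                raise ValueError("motif_boost keys are offsets or 'any'")
            for res, m in mult.items():
                if res not in AA20 or m <= 0:
                    raise ValueError(f"bad motif_boost entry {pos}:{res}={m}")

    def aa_vector(self) -> np.ndarray:
        v = np.array([self.aa_frequencies[a] for a in AA20], dtype=float)
        return v / v.sum()

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motif_boost"] = {str(k): v for k, v in self.motif_boost.items()}
        d["organs"] = list(self.organs)
        d["k_subst_alphabet"] = list(self.k_subst_alphabet)
        return d


@dataclass
class AcetylomeResult:
    """Observed catalog + ground truth + the flank-edited proteome."""

    proteome: Proteome
    catalog: SiteCatalog
    truth: pd.DataFrame  # columns: protein_id, position, organ
    warnings: Dict[str, int]

    def truth_keys_by_protein(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for pid, grp in self.truth.groupby("protein_id", sort=False):
            out[pid] = np.unique(grp["position"].to_numpy())
        return out


_AA_BYTES = np.frombuffer(AA20.encode(), dtype=np.uint8)
_CODE_OF = np.full(256, -1, dtype=np.int16)
for _i, _a in enumerate(AA20):
    _CODE_OF[ord(_a)] = _i


def generate_proteome(config: SyntheticConfig) -> Proteome:
    """i.i.d. sequences from ``aa_frequencies``; gamma-distributed lengths."""
    rng = config.rng(_STREAM_PROTEOME)
    n = config.n_proteins
    if n == 0:
        return Proteome([])
    shape = config.length_dispersion
    lengths = rng.gamma(shape, config.length_mean / shape, size=n)
    lengths = np.maximum(config.min_length, np.round(lengths)).astype(int)
    total = int(lengths.sum())
    codes = rng.choice(20, size=total, p=config.aa_vector())
    seq_bytes = _AA_BYTES[codes]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    width = len(str(n))
    proteins = []
    for i in range(n):
        seq = bytes(seq_bytes[offsets[i]:offsets[i + 1]]).decode()
        pid = f"P{i + 1:0{width}d}"
        proteins.append(Protein(id=pid, sequence=seq, gene_id=f"G{i + 1:0{width}d}"))
    return Proteome(proteins)


def _boost_weights(config: SyntheticConfig, offset: int,
                   base: np.ndarray) -> np.ndarray:
    w = base.copy()
    any_mult = config.motif_boost.get("any", {})
    for res, m in any_mult.items():
        w[_CODE_OF[ord(res)]] *= m
    pos_mult = config.motif_boost.get(offset, {})
    for res, m in pos_mult.items():
        w[_CODE_OF[ord(res)]] *= m
    return w / w.sum()


def generate_acetylome(proteome: Proteome,
                       config: SyntheticConfig) -> AcetylomeResult:
    """Draw true acetylation sites, edit their flanks per ``motif_boost``,
    distribute sites over organs, and emit per-replicate observations with
    detection probability ``q``."""
    if not proteome:
        raise ValueError("empty proteome")
    rng = config.rng(_STREAM_ACETYLOME)
    base = config.aa_vector()
    offsets = sorted(
        set(k for k in config.motif_boost if isinstance(k, int))
        | set(range(-config.flank_redraw_width,
                    config.flank_redraw_width + 1)) - {0})
    weights = {off: _boost_weights(config, off, base) for off in offsets}

    pids = list(proteome)
    edited: Dict[str, bytearray] = {}
    n_no_k = 0
    truth_rows: List[Tuple[str, int, str]] = []
    obs_rows: List[tuple] = []
    organs = list(config.organs)
    reps = [f"rep{j + 1}" for j in range(config.replicate_count)]

    acet_flags = rng.random(len(pids)) < config.frac_acetylated
    n_sites_draw = rng.geometric(config.site_count_pi, size=len(pids))

    for idx, pid in enumerate(pids):
        if not acet_flags[idx]:
            continue
        seq = proteome[pid].sequence
        k_pos = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("K")
        k_idx = np.flatnonzero(k_pos) + 1  # 1-based
        if k_idx.size == 0:
            n_no_k += 1  # acetylated label impossible: resample as unmodified
            continue
        n_sites = min(int(n_sites_draw[idx]), k_idx.size)
        chosen = np.sort(rng.choice(k_idx, size=n_sites, replace=False))
        chosen_set = set(int(c) for c in chosen)
        buf = bytearray(seq.encode())
        L = len(seq)
        for pos in chosen:
            for off in offsets:
                j = int(pos) + off  # 1-based flank position
                if j < 1 or j > L or j in chosen_set:
                    continue
                code = rng.choice(20, p=weights[off])
                buf[j - 1] = _AA_BYTES[code]
        edited[pid] = buf

        for pos in chosen:
            if rng.random() < config.core_site_fraction:
                site_organs = organs
            else:
                site_organs = [organs[rng.integers(len(organs))]]
            for organ in site_organs:
                truth_rows.append((pid, int(pos), organ))
                detected = rng.random(len(reps)) < config.detection_prob
                abund = rng.lognormal(config.abundance_mu,
                                      config.abundance_sigma, size=len(reps))
                for rep, det, ab in zip(reps, detected, abund):
                    if det:
                        obs_rows.append((pid, int(pos), "K", "acetyl",
                                         organ, rep, float(ab)))

    new_proteins = []
    for pid in pids:
        p = proteome[pid]
        if pid in edited:
            p = Protein(id=p.id, sequence=edited[pid].decode(),
                        gene_id=p.gene_id, description=p.description)
        new_proteins.append(p)
    out_proteome = Proteome(new_proteins)

    truth = pd.DataFrame(truth_rows,
                         columns=["protein_id", "position", "organ"])
    obs = pd.DataFrame(obs_rows, columns=["protein_id", "position", "residue",
                                          "ptm_type", "organ", "replicate",
                                          "abundance"])
    catalog = SiteCatalog.from_frame(obs, out_proteome,
                                     proteome_ref="synthetic")
    return AcetylomeResult(proteome=out_proteome, catalog=catalog,
                           truth=truth,
                           warnings={"proteins_without_lysine": n_no_k})


def generate_expression(gene_ids: Sequence[str], kac_flags: Sequence[bool],
                        config: SyntheticConfig) -> pd.DataFrame:
    """Dirichlet expression profiles: concentration ``entropy_alpha_kac`` for
    flagged genes, ``entropy_alpha_non`` otherwise, scaled by a lognormal
    library size."""
    if len(gene_ids) != len(kac_flags):
        raise ValueError("one kac flag per gene required")
    config.validate()
    rng = config.rng(_STREAM_EXPRESSION)
    flags = np.asarray(kac_flags, dtype=bool)
    alphas = np.where(flags, config.entropy_alpha_kac,
                      config.entropy_alpha_non)
    # gamma trick: row-normalized Gamma(alpha) draws are Dirichlet(alpha)
    g = rng.gamma(alphas[:, None],
                  size=(len(gene_ids), config.n_samples))
    g = g / g.sum(axis=1, keepdims=True)
    lib = rng.lognormal(config.library_size_mu, config.library_size_sigma,
                        size=len(gene_ids))
    values = g * lib[:, None]
    samples = [f"S{j + 1:03d}" for j in range(config.n_samples)]
    return pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=samples)


def generate_ptm_sites(proteome: Proteome,
                       ack_truth: Mapping[str, np.ndarray],
                       config: SyntheticConfig) -> SiteCatalog:
    """Phospho/ubiquitin/SUMO catalog.  Phospho probability at an S/T/Y is
    ``p0 + a*exp(-d/lam)`` with d the distance to the nearest acetylated K
    (p0 alone if the protein has none); Ub/SUMO hit each K at their base
    rates, times ``ack_exclusion`` at acetylated lysines."""
    rng = config.rng(_STREAM_PTM)
    rows: List[tuple] = []
    for pid, protein in proteome.items():
        seq = np.frombuffer(protein.sequence.encode(), dtype=np.uint8)
        ack = np.asarray(ack_truth.get(pid, ()), dtype=int)
        sty = np.flatnonzero((seq == ord("S")) | (seq == ord("T"))
                             | (seq == ord("Y"))) + 1
        if sty.size:
            if ack.size:
                d = np.abs(sty[:, None] - ack[None, :]).min(axis=1)
                p = config.phospho_base + config.phospho_boost * np.exp(
                    -d / config.phospho_decay)
            else:
                p = np.full(sty.size, config.phospho_base)
            hit = rng.random(sty.size) < p
            for pos in sty[hit]:
                rows.append((pid, int(pos), protein.sequence[pos - 1],
                             "phospho"))
        kpos = np.flatnonzero(seq == ord("K")) + 1
        if kpos.size:
            is_ack = np.isin(kpos, ack)
            factor = np.where(is_ack, config.ack_exclusion, 1.0)
            ub = rng.random(kpos.size) < config.ub_rate * factor
            su = rng.random(kpos.size) < config.sumo_rate * factor
            for pos in kpos[ub]:
                rows.append((pid, int(pos), "K", "ubiquitin"))
            for pos in kpos[su]:
                rows.append((pid, int(pos), "K", "sumo"))
    frame = pd.DataFrame(rows, columns=["protein_id", "position", "residue",
                                        "ptm_type"])
    return SiteCatalog.from_frame(frame, proteome, proteome_ref="synthetic")


DEFAULT_COMPARTMENTS = ("nucleus", "cytosol", "plastid", "mitochondrion",
                        "peroxisome", "vacuole", "golgi", "er",
                        "plasma membrane", "extracellular")


def generate_annotation(proteome: Proteome, config: SyntheticConfig,
                        terms: Sequence[str] = DEFAULT_COMPARTMENTS,
                        mean_terms: float = 1.5,
                        namespace: str = "compartment") -> "AnnotationTable":
    """Random protein -> term annotation with Zipf-weighted term usage.

    Plumbing for the enrichment/tally stages when running on synthetic data;
    real annotation tables (SUBA/InterPro/GO-style) are consumed as inputs.
    """
    from .io_tables import AnnotationTable

    rng = config.rng(_STREAM_ANNOTATION)
    weights = 1.0 / np.arange(1, len(terms) + 1)
    weights = weights / weights.sum()
    mapping: Dict[str, set] = {}
    for pid in proteome:
        k = min(len(terms), 1 + rng.poisson(max(mean_terms - 1, 0.0)))
        chosen = rng.choice(len(terms), size=k, replace=False, p=weights)
        mapping[pid] = {terms[int(i)] for i in chosen}
    return AnnotationTable(mapping=mapping, namespace=namespace)


def generate_alignments(proteome: Proteome,
                        ack_truth: Mapping[str, np.ndarray],
                        config: SyntheticConfig,
                        protein_ids: Optional[Iterable[str]] = None,
                        ) -> Dict[str, OrthologAlignmentSet]:
    """Ortholog alignment per protein: lysine columns stay K in all species
    with probability rho_ac (acetylated) / rho_non (other), otherwise each
    species shows K or a ``k_subst_alphabet`` residue; non-K columns match
    the reference with probability ``background_identity``."""
    rng = config.rng(_STREAM_ALIGNMENTS)
    ns = config.n_species
    species = [f"species{j + 1:02d}" for j in range(ns)]
    subst = np.frombuffer("".join(config.k_subst_alphabet).encode(),
                          dtype=np.uint8)
    gap = ord("-")
    out: Dict[str, OrthologAlignmentSet] = {}
    ids = list(protein_ids) if protein_ids is not None else list(proteome)
    for pid in ids:
        seq = proteome[pid].sequence
        ref = np.frombuffer(seq.encode(), dtype=np.uint8)
        L = ref.size
        mat = np.tile(ref, (ns, 1))

        kcol = ref == ord("K")
        ack = np.asarray(ack_truth.get(pid, ()), dtype=int)
        is_ack_col = np.zeros(L, dtype=bool)
        if ack.size:
            is_ack_col[ack - 1] = True
        rho = np.where(is_ack_col, config.rho_ac, config.rho_non)
        conserved = (rng.random(L) < rho) & kcol
        free_k = kcol & ~conserved
        if free_k.any():
            cols = np.flatnonzero(free_k)
            keep = rng.random((ns, cols.size)) < config.nonconserved_k_prob
            sub_idx = rng.integers(0, subst.size, size=(ns, cols.size))
            block = np.where(keep, ord("K"), subst[sub_idx])
            mat[:, cols] = block

        noncol = ~kcol
        if noncol.any():
            cols = np.flatnonzero(noncol)
            match = rng.random((ns, cols.size)) < config.background_identity
            # mismatches drawn uniformly from the 19 non-reference residues
            r = rng.integers(0, 19, size=(ns, cols.size))
            refcode = _CODE_OF[ref[cols]]
            mis = r + (r >= refcode[None, :])
            block = np.where(match, ref[cols][None, :], _AA_BYTES[mis])
            mat[:, cols] = block

        if config.gap_rate > 0:
            gmask = rng.random((ns, L)) < config.gap_rate
            mat[gmask] = gap

        rows = [bytes(mat[j]).decode() for j in range(ns)]
        out[pid] = OrthologAlignmentSet(reference_id=pid, reference_row=seq,
                                        species=list(species), rows=rows)
    return out
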