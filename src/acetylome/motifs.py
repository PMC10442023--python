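"""Flanking-window extraction and position-specific residue enrichment
around acetylated lysines.

Windows are ``2w+1``-mers centered on the modified K (default w = 15, i.e.
15 residues on each side), padded with ``-`` beyond protein termini; padding
carries no residue information and is excluded from all counts.

Position scores follow the pLogo convention: for residue r at flank position
j with foreground count k out of n informative windows and background
frequency p, the score is the signed -log10 binomial tail probability —
positive ``-log10 P(X >= k)`` when over-represented (k/n >= p), negative
``-(-log10 P(X <= k))`` when depleted.  Significance is Bonferroni-corrected
over the 20 x 2w score cells.

Motif extraction is motif-x style: greedily fix the most significant
(position, residue) cell, keep only matching foreground/background windows,
recurse; emit the motif when no cell passes the probability and count
thresholds, remove its foreground matches, and continue on the remainder.

Two backgrounds are provided: windows centered on every proteome lysine
(``all_K_windows``, the standard conditional background for centered PTM
logos) and the plain proteome-wide residue frequency (``proteome_global``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .io_tables import AA20, Proteome, SiteCatalog, SiteKey

_CODE = np.full(256, -1, dtype=np.int16)
for _i, _a in enumerate(AA20):
    _CODE[ord(_a)] = _i

PAD = "-"


@dataclass(frozen=True)
class FlankWindow:
    center: SiteKey
    sequence: str  # length 2w+1, '-' padded, center residue K

    @property
    def w(self) -> int:
        return (len(self.sequence) - 1) // 2


@dataclass
class PositionResidueScore:
    position: int      # in [-w, w], never 0
    residue: str
    k: int             # foreground count
    n: int             # informative foreground windows at this position
    p: float           # background frequency
    score: float       # signed -log10 tail
    p_over: float
    p_under: float
    significant: bool
    degenerate: bool = False  # p=0 with k>0, or p=1 with k<n


@dataclass
class Motif:
    constraints: Dict[int, str]   # position -> residue (central K implicit)
    text: str                     # e.g. "K(ac)R"
    fg_matches: int
    fg_total: int
    bg_matches: int
    bg_total: int
    p_value: float


@dataclass
class Background:
    mode: str                                   # all_K_windows | proteome_global
    w: int
    per_position: Optional[np.ndarray] = None   # (2w+1, 20), rows sum to 1
    global_freq: Optional[np.ndarray] = None    # (20,)
    windows: List[str] = field(default_factory=list)

    def freq_at(self, position: int) -> np.ndarray:
        if self.mode == "proteome_global":
            return self.global_freq
        return self.per_position[position + self.w]


def _window_at(sequence: str, position: int, w: int) -> str:
    lo, hi = position - 1 - w, position - 1 + w + 1
    left = max(0, -lo)
    right = max(0, hi - len(sequence))
    return PAD * left + sequence[max(lo, 0):min(hi, len(sequence))] + PAD * right


def extract_windows(catalog: SiteCatalog, proteome: Proteome,
                    w: int = 15) -> List[FlankWindow]:
    """One window per distinct acetyl SiteKey, in sorted key order."""
    keys = sorted(catalog.site_keys(ptm_type="acetyl"))
    out = []
    for key in keys:
        seq = proteome[key.protein_id].sequence
        out.append(FlankWindow(center=key,
                               sequence=_window_at(seq, key.position, w)))
    return out


def _as_strings(windows: Sequence[Union[FlankWindow, str]]) -> List[str]:
    return [w.sequence if isinstance(w, FlankWindow) else w for w in windows]


def _matrix(windows: Sequence[str]) -> np.ndarray:
    """(n_windows, 2w+1) matrix of residue codes; -1 for padding/unknown."""
    joined = "".join(windows)
    codes = _CODE[np.frombuffer(joined.encode(), dtype=np.uint8)]
    return codes.reshape(len(windows), -1)


def _position_counts(mat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Counts (L, 20) of informative residues per column, and n per column."""
    L = mat.shape[1]
    counts = np.zeros((L, 20), dtype=np.int64)
    for j in range(L):
        col = mat[:, j]
        col = col[col >= 0]
        counts[j] = np.bincount(col, minlength=20)
    return counts, counts.sum(axis=1)


def frequencies_from_windows(windows: Sequence[str], w: int) -> np.ndarray:
    """Per-position residue frequencies (2w+1, 20); padding excluded."""
    counts, n = _position_counts(_matrix(list(windows)))
    n = np.where(n == 0, 1, n)
    return counts / n[:, None]


def background_model(proteome: Proteome, mode: str = "all_K_windows",
                     w: int = 15) -> Background:
    """Background residue frequencies: per flank position over windows on
    every proteome lysine, or a single proteome-wide frequency vector."""
    if mode == "proteome_global":
        counts = np.zeros(20, dtype=np.int64)
        for p in proteome.values():
            codes = _CODE[np.frombuffer(p.sequence.encode(), dtype=np.uint8)]
            codes = codes[codes >= 0]
            counts += np.bincount(codes, minlength=20)
        if counts.sum() == 0:
            raise ValueError("empty proteome")
        return Background(mode=mode, w=w, global_freq=counts / counts.sum())
    if mode != "all_K_windows":
        raise ValueError(f"unknown background mode {mode!r}")
    windows = []
    for p in proteome.values():
        seq = p.sequence
        for i, ch in enumerate(seq, start=1):
            if ch == "K":
                windows.append(_window_at(seq, i, w))
    if not windows:
        raise ValueError("proteome contains no lysine: cannot build "
                         "all_K_windows background")
    return Background(mode=mode, w=w,
                      per_position=frequencies_from_windows(windows, w),
                      windows=windows)


def position_scores(foreground: Sequence[Union[FlankWindow, str]],
                    background: Background,
                    alpha: float = 0.05) -> List[PositionResidueScore]:
    """Signed binomial enrichment score for every (flank position, residue)
    cell; Bonferroni threshold alpha / (20 residues x 2w positions)."""
    seqs = _as_strings(foreground)
    if not seqs:
        raise ValueError("no foreground windows")
    w = (len(seqs[0]) - 1) // 2
    counts, n_per_pos = _position_counts(_matrix(seqs))
    n_cells = 20 * 2 * w
    thresh = alpha / n_cells
    out: List[PositionResidueScore] = []
    for pos in range(-w, w + 1):
        if pos == 0:
            continue
        n = int(n_per_pos[pos + w])
        if n < 1:
            continue
        k = counts[pos + w]
        p = np.asarray(background.freq_at(pos), dtype=float)
        p_over = stats.binom.sf(k - 1, n, p)
        p_under = stats.binom.cdf(k, n, p)
        enriched = k / n >= p
        with np.errstate(divide="ignore"):
            score = np.where(enriched, -np.log10(p_over), np.log10(p_under))
        degenerate = ((p == 0) & (k > 0)) | ((p == 1) & (k < n))
        significant = np.minimum(p_over, p_under) < thresh
        for r in range(20):
            out.append(PositionResidueScore(
                position=pos, residue=AA20[r], k=int(k[r]), n=n,
                p=float(p[r]), score=float(score[r]),
                p_over=float(p_over[r]), p_under=float(p_under[r]),
                significant=bool(significant[r]),
                degenerate=bool(degenerate[r])))
    return out


def _motif_text(constraints: Dict[int, str]) -> str:
    lo = min(min(constraints), 0)
    hi = max(max(constraints), 0)
    parts = []
    for off in range(lo, hi + 1):
        if off == 0:
            parts.append("K(ac)")
        else:
            parts.append(constraints.get(off, "."))
    return "".join(parts)


def extract_motifs(foreground: Sequence[Union[FlankWindow, str]],
                   background_windows: Sequence[Union[FlankWindow, str]],
                   p_thresh: float = 1e-6,
                   min_count: int = 20) -> List[Motif]:
    """motif-x style iterative extraction against a window background."""
    fg = _as_strings(foreground)
    bg = _as_strings(background_windows)
    if not fg:
        return []
    w = (len(fg[0]) - 1) // 2
    fg_mat = _matrix(fg)
    bg_mat = _matrix(bg)
    motifs: List[Motif] = []
    while fg_mat.shape[0] > 0 and bg_mat.shape[0] > 0:
        cur_fg, cur_bg = fg_mat, bg_mat
        constraints: Dict[int, str] = {}
        fg_total = cur_fg.shape[0]
        while True:
            fg_counts, fg_n = _position_counts(cur_fg)
            bg_counts, bg_n = _position_counts(cur_bg)
            bg_nn = np.where(bg_n == 0, 1, bg_n)
            pmat = bg_counts / bg_nn[:, None]
            with np.errstate(invalid="ignore"):
                p_over = stats.binom.sf(fg_counts - 1, fg_n[:, None], pmat)
            p_over[:, :] = np.where(fg_counts >= min_count, p_over, np.inf)
            p_over[w, :] = np.inf  # central K is fixed by construction
            for pos in constraints:
                p_over[pos + w, :] = np.inf
            best = np.unravel_index(np.argmin(p_over), p_over.shape)
            best_p = p_over[best]
            if not (best_p < p_thresh):
                break
            pos = int(best[0]) - w
            res_code = int(best[1])
            constraints[pos] = AA20[res_code]
            keep_fg = cur_fg[:, pos + w] == res_code
            keep_bg = cur_bg[:, pos + w] == res_code
            cur_fg = cur_fg[keep_fg]
            cur_bg = cur_bg[keep_bg]
            if cur_bg.shape[0] == 0:
                break
        if not constraints:
            break
        # final motif-level binomial p: fg matches vs bg match frequency
        bg_frac = cur_bg.shape[0] / bg_mat.shape[0] if bg_mat.shape[0] else 0.0
        p_final = float(stats.binom.sf(cur_fg.shape[0] - 1, fg_total,
                                       bg_frac)) if bg_frac > 0 else 0.0
        motifs.append(Motif(constraints=dict(sorted(constraints.items())),
                            text=_motif_text(constraints),
                            fg_matches=int(cur_fg.shape[0]),
                            fg_total=fg_total,
                            bg_matches=int(cur_bg.shape[0]),
                            bg_total=int(bg_mat.shape[0]),
                            p_value=p_final))
        # drop matched foreground windows, keep searching the remainder
        mask = np.ones(fg_mat.shape[0], dtype=bool)
        for pos, res in constraints.items():
            mask &= fg_mat[:, pos + w] == _CODE[ord(res)]
        fg_mat = fg_mat[~mask]
        bmask = np.ones(bg_mat.shape[0], dtype=bool)
        for pos, res in constraints.items():
            bmask &= bg_mat[:, pos + w] == _CODE[ord(res)]
        bg_mat = bg_mat[~bmask]
    return motifs


def scores_frame(scores: Sequence[PositionResidueScore]):
    """PositionResidueScore list -> tidy DataFrame for TSV output."""
    import pandas as pd

    return pd.DataFrame([vars(s) for s in scores])
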