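"""Cross-species hotspot mapping and the shared-hotspot decision.

An amino-acid position in a human oncogene or tumor suppressor is mapped to
the orthologous mouse position; the position counts as a *shared* hotspot when
(i) the focal residue is identical in both species and (ii) the mean
per-column score of a windowed alignment (the focal residue +/- 14 flanking
residues) is positive under a short-evolutionary-distance substitution matrix.

The matrix is a parameter.  The default is PAM10 (loaded from biotite): a
~10-PAM-unit log-odds matrix whose strongly positive diagonal and negative
off-diagonal entries make the mean window score a sharp classifier between
conserved windows (score > 0) and chance matches (score <= 0), the role the
windowed-alignment rule requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

import biotite.sequence as bseq
import biotite.sequence.align as balign


class CdsError(ValueError):
    pass


@lru_cache(maxsize=None)
def default_matrix() -> balign.SubstitutionMatrix:
    alph = bseq.ProteinSequence.alphabet
    return balign.SubstitutionMatrix(alph, alph, "PAM10")


# ----------------------------------------------------------- CDS geometry

@dataclass
class CdsModel:
    """Exon structure plus peptide for one transcript.

    ``exons`` are 0-based half-open genomic intervals in genomic order
    (ascending start).  For minus-strand transcripts, transcription walks the
    exons from the last to the first, each right-to-left.  The total CDS
    length must be 3 * peptide length, optionally + 3 for the stop codon.
    """

    transcript_id: str
    strand: str
    exons: list[tuple[int, int]]
    peptide: str
    principal_rank: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CdsError(f"bad strand {self.strand!r}")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in exons:
            if e <= s:
                raise CdsError("empty exon")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise CdsError("overlapping exons")
        self.exons = exons
        total = sum(e - s for s, e in exons)
        n = len(self.peptide)
        if total not in (3 * n, 3 * (n + 1)):
            raise CdsError(
                f"CDS length {total} inconsistent with peptide length {n}")
        self.includes_stop = total == 3 * (n + 1)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def _walk(self):
        """Exon intervals in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_offset_to_genomic(self, offset: int) -> int:
        if not (0 <= offset < self.cds_length):
            raise CdsError(f"CDS offset {offset} out of range")
        for s, e in self._walk():
            size = e - s
            if offset < size:
                return s + offset if self.strand == "+" else e - 1 - offset
            offset -= size
        raise AssertionError("unreachable")

    def genomic_to_cds_offset(self, pos: int) -> int | None:
        off = 0
        for s, e in self._walk():
            if s <= pos < e:
                return off + (pos - s if self.strand == "+" else e - 1 - pos)
            off += e - s
        return None


def map_cds_coordinates(model: CdsModel, aa_index: int) -> list[int]:
    """Genomic positions of the codon for 1-based amino-acid ``aa_index``,
    in transcript order (descending genomic coordinates on the minus strand).
    """
    n = len(model.peptide)
    if not (1 <= aa_index <= n + (1 if model.includes_stop else 0)):
        raise CdsError(f"aa index {aa_index} outside peptide of length {n}")
    return [model.cds_offset_to_genomic(3 * (aa_index - 1) + k)
            for k in range(3)]


def genomic_to_aa(model: CdsModel, pos: int) -> int | None:
    """1-based amino-acid index containing a genomic position, or None when
    the position does not overlap the CDS."""
    off = model.genomic_to_cds_offset(pos)
    if off is None:
        return None
    return off // 3 + 1


# ------------------------------------------------------- window alignment

@dataclass
class WindowAlignment:
    focal_aligned: bool
    residue_match: bool
    mean_score: float
    aligned_pos_b: int | None   # 1-based index in seq_b aligned to the focal
    n_columns: int


def _window(seq: str, pos: int, flank: int) -> tuple[str, int]:
    lo = max(0, pos - 1 - flank)
    hi = min(len(seq), pos + flank)
    return seq[lo:hi], pos - 1 - lo


def window_alignment_score(seq_a: str, pos_a: int, seq_b: str, pos_b: int,
                           flank: int = 14,
                           matrix: balign.SubstitutionMatrix | None = None,
                           gap_open: float = 10.0, gap_extend: float = 1.0
                           ) -> WindowAlignment:
    """Global alignment of the two focal windows; the mean local alignment
    score is the total score divided by the number of alignment columns
    (gap columns included)."""
    win_a, ia = _window(seq_a, pos_a, flank)
    win_b, ib = _window(seq_b, pos_b, flank)
    if not win_a or not win_b:
        raise CdsError("empty alignment window")
    matrix = matrix or default_matrix()
    al = balign.align_optimal(
        bseq.ProteinSequence(win_a), bseq.ProteinSequence(win_b), matrix,
        gap_penalty=(-abs(gap_open), -abs(gap_extend)),
        terminal_penalty=True, local=False)[0]
    trace = al.trace
    focal_cols = np.flatnonzero(trace[:, 0] == ia)
    focal_aligned = False
    aligned_b = None
    if focal_cols.size:
        j = int(trace[focal_cols[0], 1])
        if j >= 0:
            focal_aligned = j == ib
            aligned_b = j
    residue_match = (seq_a[pos_a - 1] == seq_b[pos_b - 1]) and focal_aligned
    return WindowAlignment(
        focal_aligned=focal_aligned, residue_match=residue_match,
        mean_score=al.score / len(trace),
        aligned_pos_b=None if aligned_b is None else aligned_b + (pos_b - 1 - ib) + 1,
        n_columns=len(trace))


# ------------------------------------------------------------ shared call

@dataclass
class HotspotMapping:
    human_gene: str
    human_pos: int
    human_residue: str
    mouse_transcript: str
    mouse_pos: int | None
    residue_match: bool
    mean_score: float
    shared: bool

    def __post_init__(self) -> None:
        if self.shared and not (self.residue_match and self.mean_score > 0):
            raise CdsError("shared requires residue match and positive score")


# Gap costs for the full-peptide coordinate map.  They are deliberately
# stiffer than the window-scoring penalties: PAM10-scale mismatches run to
# about -27, and cheaper gaps would let the aligner route around single
# substitutions instead of keeping orthologous positions in register.
CANDIDATE_GAP_OPEN = 25.0
CANDIDATE_GAP_EXTEND = 2.0


def _find_candidate_position(human_pep: str, aa_pos: int, mouse_pep: str,
                             flank: int, matrix, gap_open: float,
                             gap_extend: float) -> int | None:
    """Locate the mouse residue the human focal position aligns to, from a
    global alignment of the two full peptides (the ortholog coordinate map)."""
    al = balign.align_optimal(
        bseq.ProteinSequence(human_pep), bseq.ProteinSequence(mouse_pep),
        matrix or default_matrix(),
        gap_penalty=(-CANDIDATE_GAP_OPEN, -CANDIDATE_GAP_EXTEND),
        terminal_penalty=False, local=False)[0]
    trace = al.trace
    col = np.flatnonzero(trace[:, 0] == aa_pos - 1)
    if not col.size:
        return None
    j = int(trace[col[0], 1])
    return j + 1 if j >= 0 else None


def classify_shared_hotspot(human_pep: str, mouse_pep: str, aa_pos: int,
                            human_gene: str = "", mouse_transcript: str = "",
                            mouse_pos: int | None = None, flank: int = 14,
                            matrix: balign.SubstitutionMatrix | None = None,
                            gap_open: float = 10.0,
                            gap_extend: float = 1.0) -> HotspotMapping:
    """Shared-hotspot verdict: residue identity at the aligned focal position
    AND positive mean window alignment score.

    When no candidate mouse position is supplied, one is found by locally
    aligning the human window across the mouse peptide.
    """
    if not (1 <= aa_pos <= len(human_pep)):
        raise CdsError(f"aa position {aa_pos} outside human peptide")
    if mouse_pos is None:
        mouse_pos = _find_candidate_position(
            human_pep, aa_pos, mouse_pep, flank, matrix, gap_open, gap_extend)
    if mouse_pos is None or not (1 <= mouse_pos <= len(mouse_pep)):
        return HotspotMapping(
            human_gene=human_gene, human_pos=aa_pos,
            human_residue=human_pep[aa_pos - 1],
            mouse_transcript=mouse_transcript, mouse_pos=None,
            residue_match=False, mean_score=float("-inf"), shared=False)
    wa = window_alignment_score(human_pep, aa_pos, mouse_pep, mouse_pos,
                                flank=flank, matrix=matrix,
                                gap_open=gap_open, gap_extend=gap_extend)
    shared = wa.residue_match and wa.mean_score > 0
    return HotspotMapping(
        human_gene=human_gene, human_pos=aa_pos,
        human_residue=human_pep[aa_pos - 1],
        mouse_transcript=mouse_transcript,
        mouse_pos=mouse_pos if shared else mouse_pos,
        residue_match=wa.residue_match, mean_score=wa.mean_score,
        shared=shared)


@dataclass
class TranscriptCandidate:
    transcript_id: str
    conserved_count: int
    principal_rank: int  # 1 = principal isoform, larger = lower priority


def choose_mouse_transcript(candidates: list[TranscriptCandidate]
                            ) -> TranscriptCandidate:
    """Rank by conserved-position count, tie-broken by principal-isoform rank."""
    if not candidates:
        raise CdsError("no candidate transcripts")
    return sorted(candidates,
                  key=lambda t: (-t.conserved_count, t.principal_rank))[0]


# -------------------------------------------------------- factor regression

@dataclass
class FactorRegressionResult:
    table: pd.DataFrame          # term, beta, OR, CI bounds (std + raw)
    separation: bool
    log_likelihood: float | None = None
    flags: list[str] = field(default_factory=list)


def conservation_factor_regression(df: pd.DataFrame, outcome: str,
                                   continuous: list[str],
                                   binary: list[str],
                                   ci_alpha: float = 0.05
                                   ) -> FactorRegressionResult:
    """Logistic regression of the shared outcome on conservation determinants.

    Continuous predictors are centered at the median and scaled by two SDs
    before fitting the standardized model, making their odds ratios comparable
    with those of the binary predictors; raw (unscaled) ORs are reported too.
    """
    import statsmodels.api as sm

    y = df[outcome].astype(float).values
    if len(np.unique(y)) < 2:
        return FactorRegressionResult(
            table=pd.DataFrame(), separation=True,
            flags=["degenerate-outcome"])
    terms = list(continuous) + list(binary)
    Xraw = df[terms].astype(float).copy()
    Xstd = Xraw.copy()
    for c in continuous:
        sd = Xstd[c].std(ddof=1)
        Xstd[c] = (Xstd[c] - Xstd[c].median()) / (2.0 * sd)

    def _fit(X):
        model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            return None
        if not np.isfinite(res.bse).all() or (np.abs(res.params) > 25).any():
            return None
        return res

    res_std = _fit(Xstd)
    res_raw = _fit(Xraw)
    if res_std is None:
        return FactorRegressionResult(table=pd.DataFrame(), separation=True,
                                      flags=["separation"])
    ci = res_std.conf_int(alpha=ci_alpha)
    rows = []
    for t in terms:
        row = {
            "term": t,
            "beta_std": res_std.params[t],
            "or_std": float(np.exp(res_std.params[t])),
            "or_std_lo": float(np.exp(ci.loc[t, 0])),
            "or_std_hi": float(np.exp(ci.loc[t, 1])),
        }
        if res_raw is not None:
            ci_raw = res_raw.conf_int(alpha=ci_alpha)
            row.update(or_raw=float(np.exp(res_raw.params[t])),
                       or_raw_lo=float(np.exp(ci_raw.loc[t, 0])),
                       or_raw_hi=float(np.exp(ci_raw.loc[t, 1])))
        rows.append(row)
    return FactorRegressionResult(table=pd.DataFrame(rows), separation=False,
                                  log_likelihood=float(res_std.llf))
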