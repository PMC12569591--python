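"""Copy-number pipeline: counts -> log2 copy-number ratios -> gene calls.

The normalization stages, in order:

1. drop amplicons whose pooled-normal mean (total-normalized) count falls in
   the bottom 5th percentile;
2. divide each sample's counts by its total;
3. per-amplicon ratio against the weighted pooled normal;
4. log2;
5. subtract a loess fit of log2CNR on amplicon GC fraction (per sample);
6. median-center the sample so the diploid background sits at ~0.

Gene-level significance: per-gene z against the pool of normals, two-tailed
normal p, Benjamini-Hochberg q across genes within a sample, and a noise rule
that zeroes calls which are both insignificant (q > q_max) and small
(|log2CNR| < cnr_floor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .calls import GeneCall
from .panel import AmpliconPanel, ReadCountMatrix


class PipelineError(ValueError):
    pass


@dataclass
class QcReport:
    sample: str
    mean_depth: float
    uniformity: float
    mapd: float
    on_target_fraction: float = 1.0
    tumor_content: float | None = None
    mapd_max: float = 0.50
    min_tumor_content: float = 0.30

    @property
    def mapd_pass(self) -> bool:
        return self.mapd <= self.mapd_max

    @property
    def tumor_content_pass(self) -> bool | None:
        if self.tumor_content is None:
            return None
        return self.tumor_content >= self.min_tumor_content

    @property
    def passed(self) -> bool:
        tc = self.tumor_content_pass
        return self.mapd_pass and (tc is None or tc)


@dataclass
class TumorContentEstimate:
    sample: str
    flox_target: str
    cnr: float            # linear CNR at the flox site
    tumor_content: float  # 1 - CNR, clipped to [0, 1]


class CnrNormalizer(BaseEstimator, TransformerMixin):
    """Pooled-normal log2CNR normalizer (sklearn-style transformer).

    Fit on the normal samples of a count matrix; transform any sample's
    counts into GC-corrected, median-centered log2 copy-number ratios.

    Parameters
    ----------
    drop_percentile:
        Amplicons whose pooled-normal mean normalized count is below this
        percentile are dropped before any ratio is formed.
    loess_frac, loess_iterations:
        Span and robustifying iterations of the per-sample GC loess.
    normal_weights:
        Optional per-normal weights for the pooled normal (default equal).
    include_snp_amplicons:
        Keep genotyping-SNP amplicons in the CNR profile (they are never part
        of gene calls either way).
    """

    def __init__(self, drop_percentile: float = 5.0, loess_frac: float = 0.5,
                 loess_iterations: int = 2,
                 normal_weights: dict[str, float] | None = None,
                 include_snp_amplicons: bool = True,
                 pseudocount: float = 0.5):
        self.drop_percentile = drop_percentile
        self.loess_frac = loess_frac
        self.loess_iterations = loess_iterations
        self.normal_weights = normal_weights
        self.include_snp_amplicons = include_snp_amplicons
        self.pseudocount = pseudocount

    def fit(self, counts: ReadCountMatrix, panel: AmpliconPanel,
            normal_ids: list[str]):
        if len(normal_ids) < 2:
            raise PipelineError("need at least 2 normal samples")
        df = counts.counts
        missing = [s for s in normal_ids if s not in df.columns]
        if missing:
            raise PipelineError(f"normals not in count matrix: {missing}")
        pdf = panel.df.set_index("amplicon").loc[df.index]
        keep = pd.Series(True, index=df.index)
        if not self.include_snp_amplicons:
            keep &= pdf["target_class"] != "genotyping-snp"

        normals = df[normal_ids].astype(float)
        totals = normals.sum(axis=0)
        if (totals <= 0).any():
            raise PipelineError("all-zero normal sample")
        norm_frac = normals / totals
        if self.normal_weights:
            w = np.array([self.normal_weights.get(s, 1.0) for s in normal_ids],
                         dtype=float)
        else:
            w = np.ones(len(normal_ids))
        pooled = (norm_frac * (w / w.sum())).sum(axis=1)

        cut = np.percentile(pooled[keep], self.drop_percentile)
        keep &= pooled >= cut
        keep &= pooled > 0
        self.retained_amplicons_ = df.index[keep]
        self.pooled_normal_ = pooled[keep]
        self.gc_ = pdf.loc[keep, "gc"].astype(float)
        self.panel_ = panel
        self.normal_ids_ = list(normal_ids)
        return self

    def transform(self, counts: ReadCountMatrix) -> pd.DataFrame:
        """Per-sample log2CNR over the retained amplicons."""
        df = counts.counts.astype(float)
        out = {}
        for sample in df.columns:
            col = df[sample]
            total = col.sum()
            if total <= 0:
                raise PipelineError(f"all-zero sample {sample!r}")
            col = col.loc[self.retained_amplicons_]
            col = col.where(col > 0, self.pseudocount)
            frac = col / total
            log2cnr = np.log2(frac / self.pooled_normal_)
            log2cnr = self._gc_correct(log2cnr)
            out[sample] = log2cnr - np.median(log2cnr)
        return pd.DataFrame(out, index=self.retained_amplicons_)

    def fit_transform_normals(self, counts: ReadCountMatrix,
                              panel: AmpliconPanel,
                              normal_ids: list[str]) -> pd.DataFrame:
        """Convenience: fit on normals and return their own CNR profiles."""
        self.fit(counts, panel, normal_ids)
        sub = ReadCountMatrix(counts.counts[normal_ids],
                              allow_float=True)
        return self.transform(sub)

    def _gc_correct(self, log2cnr: pd.Series) -> pd.Series:
        gc = self.gc_.values
        if np.ptp(gc) < 1e-9:
            return log2cnr
        fit = lowess(log2cnr.values, gc, frac=self.loess_frac,
                     it=self.loess_iterations, return_sorted=False)
        return log2cnr - fit


def normalize_counts(counts: ReadCountMatrix, panel: AmpliconPanel,
                     normal_ids: list[str], **kwargs) -> pd.DataFrame:
    """Functional wrapper: log2CNR profiles for every sample in the matrix."""
    norm = CnrNormalizer(**kwargs).fit(counts, panel, normal_ids)
    return norm.transform(counts)


# ------------------------------------------------------------- gene calls

def summarize_genes(cnr: pd.Series, panel: AmpliconPanel,
                    summary: str = "mean") -> pd.Series:
    """Per-gene summary of amplicon log2CNR (flox targets are their own genes)."""
    genes = panel.gene_targets(include_flox=True).set_index("amplicon")
    idx = cnr.index.intersection(genes.index)
    grouped = cnr.loc[idx].groupby(genes.loc[idx, "target"])
    if summary == "mean":
        return grouped.mean()
    if summary == "median":
        return grouped.median()
    raise PipelineError(f"unknown gene summary {summary!r}")


def call_genes(cnr: pd.Series, normals_cnr: pd.DataFrame,
               panel: AmpliconPanel, q_max: float = 0.05,
               cnr_floor: float = 0.2, summary: str = "mean",
               zero_rule: str = "and") -> list[GeneCall]:
    """Gene-level calls with z/p/q against the pool of normals.

    ``zero_rule="and"`` zeroes a call when q > q_max AND |log2CNR| < cnr_floor
    (the literal noise rule); ``"or"`` zeroes when either holds, i.e. a call
    must be both significant and large to survive.
    """
    if zero_rule not in ("and", "or"):
        raise PipelineError("zero_rule must be 'and' or 'or'")
    gene_vals = summarize_genes(cnr, panel, summary)
    normal_gene = pd.DataFrame(
        {s: summarize_genes(normals_cnr[s], panel, summary)
         for s in normals_cnr.columns})
    mu = normal_gene.mean(axis=1)
    sd = normal_gene.std(axis=1, ddof=1)
    spans = panel.gene_intervals(include_flox=True).set_index("target")

    genes = gene_vals.index
    z = (gene_vals - mu.loc[genes]) / sd.loc[genes]
    degenerate = ~np.isfinite(z)
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z.fillna(0.0))), index=genes)
    p[degenerate] = 1.0
    q = pd.Series(multipletests(p.values, method="fdr_bh")[1], index=genes)

    calls = []
    for g in genes:
        v = float(gene_vals[g])
        flags = []
        if degenerate[g]:
            state = 0
            flags.append("normals-sd-zero")
            warnings.warn(f"gene {g}: zero normal SD; state forced to 0")
        else:
            state = int(np.sign(v))
            insignificant = q[g] > q_max
            small = abs(v) < cnr_floor
            zero = (insignificant and small) if zero_rule == "and" \
                else (insignificant or small)
            if zero:
                state = 0
        row = spans.loc[g]
        calls.append(GeneCall(
            gene=g, log2cnr=v,
            z=float(z[g]) if not degenerate[g] else float("nan"),
            p=float(p[g]), q=float(q[g]), state=state,
            chrom=str(row["chrom"]), start=int(row["start"]),
            end=int(row["end"]), n_amplicons=int(row["n_amplicons"]),
            flags=flags))
    return calls


def gene_calls_frame(calls: list[GeneCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": c.gene, "chrom": c.chrom, "start": c.start, "end": c.end,
        "n_amplicons": c.n_amplicons, "log2cnr": c.log2cnr, "z": c.z,
        "p": c.p, "q": c.q, "state": c.state} for c in calls])


# -------------------------------------------------------------------- QC

def mapd(cnr: pd.Series, panel: AmpliconPanel) -> float:
    """Median absolute pairwise difference of genomic-order adjacent log2CNR."""
    order = panel.genomic_order()
    ids = [a for a in order["amplicon"] if a in cnr.index]
    vals = cnr.loc[ids].values
    if len(vals) < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(vals))))


def qc_sample(counts: ReadCountMatrix, cnr: pd.Series, panel: AmpliconPanel,
              sample: str, tumor_content: float | None = None,
              mapd_max: float = 0.50,
              min_tumor_content: float = 0.30) -> QcReport:
    col = counts.counts[sample].astype(float)
    mean_depth = float(col.mean())
    uniformity = float((col >= 0.2 * mean_depth).mean()) if mean_depth > 0 else 0.0
    return QcReport(sample=sample, mean_depth=mean_depth,
                    uniformity=uniformity, mapd=mapd(cnr, panel),
                    tumor_content=tumor_content, mapd_max=mapd_max,
                    min_tumor_content=min_tumor_content)


# ---------------------------------------------------- tumor content, scale

def estimate_tumor_content(cnr: pd.Series, panel: AmpliconPanel,
                           flox_target: str, sample: str = "",
                           summary: str = "mean") -> TumorContentEstimate:
    """Tumor content from a flox site with expected biallelic loss: 1 - CNR."""
    flox_rows = panel.df[(panel.df["target"] == flox_target)
                         & (panel.df["target_class"] == "flox")]
    if flox_rows.empty:
        raise PipelineError(f"no flox target {flox_target!r} in panel")
    vals = summarize_genes(cnr, panel, summary)
    if flox_target not in vals.index:
        raise PipelineError(f"flox target {flox_target!r} has no retained amplicons")
    linear = float(2.0 ** vals[flox_target])
    tc = min(max(1.0 - linear, 0.0), 1.0)
    return TumorContentEstimate(sample=sample, flox_target=flox_target,
                                cnr=linear, tumor_content=tc)


def scale_cnr(cnr: pd.Series, purity: float, ploidy: float,
              round_to_int: bool = False) -> pd.Series:
    """Invert the purity/ploidy mixture: estimated tumor copy number.

    CN_hat = (2**log2CNR * (p*psi + 2(1-p)) - 2(1-p)) / p; negative estimates
    are clipped to 0 with a warning, and ``round_to_int`` snaps to integers.
    """
    if not (0.0 < purity <= 1.0):
        raise PipelineError("purity must be in (0, 1]")
    if ploidy <= 0:
        raise PipelineError("ploidy must be positive")
    denom = purity * ploidy + 2.0 * (1.0 - purity)
    cn = (2.0 ** cnr * denom - 2.0 * (1.0 - purity)) / purity
    if (cn < -1e-9).any():
        warnings.warn("negative copy-number estimates clipped to 0")
    cn = cn.clip(lower=0.0)
    if round_to_int:
        cn = cn.round().clip(lower=0)
    return cn


# --------------------------------------------------------- variant filter

@dataclass
class VariantRecord:
    """One candidate variant with flow-corrected evidence."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_forward: int
    alt_reverse: int
    homopolymer_len: int
    allele_fraction: float

    def __post_init__(self) -> None:
        if self.alt_forward + self.alt_reverse > self.depth:
            raise PipelineError("alt reads exceed depth")
        if not (0.0 <= self.allele_fraction <= 1.0):
            raise PipelineError("allele fraction out of [0, 1]")

    @property
    def strand_ratio(self) -> float:
        if self.alt_reverse == 0:
            return float("inf")
        return self.alt_forward / self.alt_reverse


@dataclass
class VariantVerdict:
    record: VariantRecord
    passed: bool
    reasons: list[str] = field(default_factory=list)


def filter_variants(records: list[VariantRecord],
                    strand_ratio_range: tuple[float, float] = (0.2, 5.0),
                    min_depth: int = 100, min_alt_reads: int = 10,
                    max_homopolymer: int = 4,
                    min_allele_fraction: float = 0.1) -> list[VariantVerdict]:
    """Empirical flow-space filters: strand ratio in [0.2, 5.0], depth > 100,
    alt reads > 10, homopolymer run < 4, allele fraction > 0.1."""
    out = []
    for rec in records:
        reasons = []
        sr = rec.strand_ratio
        if not (strand_ratio_range[0] <= sr <= strand_ratio_range[1]):
            reasons.append("strand-ratio")
        if not rec.depth > min_depth:
            reasons.append("depth")
        if not rec.alt_forward + rec.alt_reverse > min_alt_reads:
            reasons.append("alt-reads")
        if not rec.homopolymer_len < max_homopolymer:
            reasons.append("homopolymer")
        if not rec.allele_fraction > min_allele_fraction:
            reasons.append("allele-fraction")
        out.append(VariantVerdict(record=rec, passed=not reasons,
                                  reasons=reasons))
    return out
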