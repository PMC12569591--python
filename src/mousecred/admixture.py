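"""Strain-admixture estimation from a small genotyping-SNP set.

Informative SNPs are selected by entropy filtering and, optionally, reduced
further by multiple correspondence analysis (MCA) of the strain x allele
indicator matrix.  Admixture proportions are estimated supervised: reference
strain allele frequencies are fixed (0/1 for inbred strains) and the sample's
diploid genotypes are modelled per SNP as two independent Bernoulli draws with
frequency f_j = sum_s Q_s f_js; the simplex-constrained maximum-likelihood
proportions Q are found by EM from the barycenter, so the fit is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .simulate import SampleGenotype, simulate_f1, strain_columns


class AdmixtureError(ValueError):
    pass


# --------------------------------------------------------- SNP selection

def filter_informative_snps(panel_df: pd.DataFrame,
                            strains: list[str] | None = None) -> pd.DataFrame:
    """Drop SNPs whose allele pattern is identical across the selected strains
    (zero entropy — no information about strain of origin)."""
    strains = strains or strain_columns(panel_df)
    if len(strains) < 2:
        raise AdmixtureError("need at least 2 strains")
    alleles = panel_df[strains].values
    informative = alleles.min(axis=1) != alleles.max(axis=1)
    out = panel_df[informative].reset_index(drop=True)
    if out.empty:
        import warnings
        warnings.warn("all SNPs are monomorphic across the selected strains")
    return out


@dataclass
class McaResult:
    """MCA of the strain x (SNP-allele indicator) matrix."""

    selected: pd.DataFrame          # reduced panel (top n_target SNPs)
    snp_scores: pd.Series           # contribution-based ranking score per SNP
    row_coords: pd.DataFrame        # strain factor scores (strains x dims)
    inertia: np.ndarray             # principal inertia per dimension


def reduce_snps_mca(panel_df: pd.DataFrame, n_target: int,
                    n_dimensions: int = 4,
                    strains: list[str] | None = None) -> McaResult:
    """Rank SNPs by summed MCA contribution over the top dimensions and keep
    the best ``n_target``.

    Correspondence analysis of the complete disjunctive table: each SNP
    contributes two indicator columns (ref-allele and alt-allele carrier); the
    standardized residual matrix is decomposed by SVD, a SNP's score is the sum
    over its columns of the column contribution to each retained dimension,
    weighted by that dimension's share of the retained inertia.
    """
    strains = strains or strain_columns(panel_df)
    if len(panel_df) < n_target:
        raise AdmixtureError("panel smaller than n_target")
    alleles = panel_df[strains].values.T.astype(float)  # strains x snps
    n_s, n_j = alleles.shape
    # complete disjunctive coding: [is_ref, is_alt] per SNP
    X = np.empty((n_s, 2 * n_j))
    X[:, 0::2] = 1.0 - alleles
    X[:, 1::2] = alleles
    snp_of_col = np.repeat(np.arange(n_j), 2)
    # monomorphic SNPs contribute an empty indicator column; drop it
    nonzero = X.sum(axis=0) > 0
    X, snp_of_col = X[:, nonzero], snp_of_col[nonzero]
    N = X / X.sum()
    r = N.sum(axis=1)
    c = N.sum(axis=0)
    S = (N - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    if not np.isfinite(S).all():
        raise AdmixtureError("degenerate indicator matrix")
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    if sv.size == 0:
        raise AdmixtureError("degenerate indicator matrix (no variation)")
    n_dim = min(n_dimensions, sv.size)
    inertia = sv ** 2
    # principal column coordinates and contributions
    col_coord = (Vt.T / np.sqrt(c)[:, None]) * sv[None, :]
    contrib = c[:, None] * col_coord ** 2 / inertia[None, :]   # cols x dims
    share = inertia[:n_dim] / inertia[:n_dim].sum()
    col_score = contrib[:, :n_dim] @ share
    snp_score = np.zeros(n_j)
    np.add.at(snp_score, snp_of_col, col_score)
    scores = pd.Series(snp_score, index=panel_df["snp"].values, name="score")
    order = np.argsort(-snp_score, kind="mergesort")[:n_target]
    selected = panel_df.iloc[np.sort(order)].reset_index(drop=True)
    row_coord = (U / np.sqrt(r)[:, None]) * sv[None, :]
    row_coords = pd.DataFrame(row_coord[:, :n_dim], index=strains,
                              columns=[f"dim{k + 1}" for k in range(n_dim)])
    return McaResult(selected=selected, snp_scores=scores,
                     row_coords=row_coords, inertia=inertia)


# ------------------------------------------------------------- estimation

@dataclass
class AdmixtureEstimate:
    sample: str
    proportions: pd.Series
    log_likelihood: float
    n_snps_used: int
    n_iterations: int
    converged: bool
    qc_pass: bool = True
    qc_reason: str = ""

    def __post_init__(self) -> None:
        q = self.proportions.values
        if self.qc_pass and ((q < -1e-9).any()
                             or abs(q.sum() - 1.0) > 1e-6):
            raise AdmixtureError("proportions must lie on the simplex")

    def detected_strains(self, min_fraction: float = 0.05) -> list[str]:
        """Strains above the conservative detection threshold (default 5%)."""
        return list(self.proportions[self.proportions > min_fraction].index)


class AdmixtureEstimator(BaseEstimator):
    """Supervised admixture proportions by EM (sklearn-style estimator).

    fit() fixes the reference allele-frequency matrix from an inbred strain
    panel; predict() returns simplex proportions for a genotyped sample.

    Parameters
    ----------
    min_call_rate:
        Samples below this genotyping rate QC-fail (estimate still returned,
        flagged).
    tol, max_iter:
        EM stops when the relative log-likelihood change drops below ``tol``
        (default 1e-8) or after ``max_iter`` iterations.
    freq_clamp:
        Inbred 0/1 frequencies are clamped into [clamp, 1-clamp] so vertex
        likelihoods stay finite.
    """

    def __init__(self, min_call_rate: float = 0.8, tol: float = 1e-8,
                 max_iter: int = 2000, freq_clamp: float = 1e-6):
        self.min_call_rate = min_call_rate
        self.tol = tol
        self.max_iter = max_iter
        self.freq_clamp = freq_clamp

    def fit(self, panel_df: pd.DataFrame,
            strains: list[str] | None = None):
        strains = strains or strain_columns(panel_df)
        if len(strains) < 2:
            raise AdmixtureError("need at least 2 reference strains")
        self.strains_ = list(strains)
        self.snp_ids_ = pd.Index(panel_df["snp"].values)
        F = panel_df[strains].values.astype(float)
        self.freqs_ = np.clip(F, self.freq_clamp, 1.0 - self.freq_clamp)
        return self

    def predict(self, sample: SampleGenotype) -> AdmixtureEstimate:
        g = sample.genotypes.reindex(self.snp_ids_)
        call_rate = float(g.notna().mean())
        dropped_all_missing = int(g.isna().sum())
        use = g.notna().values
        gv = g.values[use].astype(float)
        F = self.freqs_[use]  # snps x strains
        n_strains = len(self.strains_)
        Q = np.full(n_strains, 1.0 / n_strains)

        ll_prev = -np.inf
        it = 0
        converged = False
        for it in range(1, self.max_iter + 1):
            f = F @ Q
            ll = float(np.sum(gv * np.log(f) + (2.0 - gv) * np.log1p(-f)))
            if ll < ll_prev - 1e-9:
                raise AdmixtureError("EM log-likelihood decreased")
            if np.isfinite(ll_prev) and \
                    abs(ll - ll_prev) <= self.tol * (abs(ll_prev) + 1e-12):
                converged = True
                break
            ll_prev = ll
            # expected ancestry counts of alt and ref allele copies
            alt = (gv[:, None] * (F * Q[None, :]) / f[:, None]).sum(axis=0)
            ref = ((2.0 - gv)[:, None] * ((1.0 - F) * Q[None, :])
                   / (1.0 - f)[:, None]).sum(axis=0)
            Q = (alt + ref) / (alt + ref).sum()
        f = F @ Q
        ll = float(np.sum(gv * np.log(f) + (2.0 - gv) * np.log1p(-f)))
        qc_pass = call_rate >= self.min_call_rate
        return AdmixtureEstimate(
            sample=sample.sample,
            proportions=pd.Series(Q, index=self.strains_),
            log_likelihood=ll, n_snps_used=int(use.sum()),
            n_iterations=it, converged=converged, qc_pass=qc_pass,
            qc_reason="" if qc_pass else
            f"call rate {call_rate:.3f} < {self.min_call_rate}")


def estimate_admixture(sample: SampleGenotype, panel_df: pd.DataFrame,
                       strains: list[str] | None = None,
                       min_call_rate: float = 0.8,
                       **kwargs) -> AdmixtureEstimate:
    est = AdmixtureEstimator(min_call_rate=min_call_rate, **kwargs)
    return est.fit(panel_df, strains).predict(sample)


# -------------------------------------------------------------- benchmark

def benchmark_snp_sets(panel_df: pd.DataFrame,
                       set_sizes: list[int],
                       n_replicates: int = 100,
                       seed: int = 0,
                       strains: list[str] | None = None) -> pd.DataFrame:
    """RMSE of estimated vs true proportions for pairwise F1 crosses, per SNP
    set size (random subsets, one per replicate)."""
    strains = strains or strain_columns(panel_df)
    pairs = [(a, b) for i, a in enumerate(strains)
             for b in strains[i + 1:]]
    rows = []
    for size in set_sizes:
        if size > len(panel_df):
            raise AdmixtureError(f"set size {size} exceeds panel")
        sq_errs = []
        for rep in range(n_replicates):
            rng = np.random.default_rng(np.random.SeedSequence([seed, size, rep]))
            idx = rng.choice(len(panel_df), size=size, replace=False)
            sub = panel_df.iloc[np.sort(idx)].reset_index(drop=True)
            a, b = pairs[rep % len(pairs)]
            f1 = simulate_f1(sub, a, b, seed=int(rng.integers(2 ** 31)))
            est = estimate_admixture(f1, sub, strains)
            truth = pd.Series(0.0, index=strains)
            truth[a] = truth[b] = 0.5
            sq_errs.append(((est.proportions - truth) ** 2).mean())
        rows.append({"set_size": size,
                     "rmse": float(np.sqrt(np.mean(sq_errs))),
                     "n_replicates": n_replicates})
    return pd.DataFrame(rows)
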