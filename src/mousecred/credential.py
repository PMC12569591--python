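"""Credentialing statistics.

Genomic-instability summaries (fraction of genes altered, copy-state score),
flox-site ratio analyses of engineered deletions, Fisher exact tests with
conditional-MLE odds ratios, within-sample permutation tests for recurrent
arm-level aneuploidy, arm-specificity tests across cohorts, and the
synteny-aware three-scenario test for cross-species conservation of arm gains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from .genome import GenomeLayout


class CredentialError(ValueError):
    pass


# ------------------------------------------------------------------- FGA

@dataclass
class FgaResult:
    sample: str
    fga: float
    n_altered: int
    n_genes: int
    threshold: float


def fraction_genes_altered(gene_calls: pd.DataFrame, threshold: float = 0.2,
                           gene_set: list[str] | None = None,
                           sample: str = "") -> FgaResult:
    """FGA: genes with |log2CNR| strictly above the threshold, over genes
    measured.  Flox targets must be excluded via ``gene_set``."""
    df = gene_calls
    if gene_set is not None:
        missing = set(gene_set) - set(df["gene"])
        if missing:
            raise CredentialError(f"gene set not covered by calls: {sorted(missing)[:5]}")
        df = df[df["gene"].isin(set(gene_set))]
    if df.empty:
        raise CredentialError("empty gene set")
    altered = (df["log2cnr"].abs() > threshold).sum()
    return FgaResult(sample=sample, fga=altered / len(df),
                     n_altered=int(altered), n_genes=len(df),
                     threshold=threshold)


# ------------------------------------------------------- copy-state score

@dataclass
class CopyStateScore:
    sample: str
    per_arm: dict[str, int]
    total: int
    flagged_arms: list[str] = field(default_factory=list)


def copy_state_score(gene_calls: pd.DataFrame, layout: GenomeLayout,
                     sample: str = "", min_run: int = 2,
                     mode: str = "runs") -> CopyStateScore:
    """Number of copy states per arm, summed over arms.

    ``mode="runs"`` (default) counts maximal runs of identical state with at
    least ``min_run`` adjacent genes, so a quiet genome scores one per arm;
    ``mode="distinct"`` counts distinct state values that appear in a
    qualifying run.  Genes must be orderable by position within arms.
    """
    per_arm: dict[str, int] = {}
    flagged = []
    for arm in layout.arms:
        genes = gene_calls[gene_calls["chrom"] == arm.chrom]
        genes = genes[(genes["start"] >= arm.start) & (genes["start"] < arm.end)]
        genes = genes.sort_values("start", kind="mergesort")
        if len(genes) < min_run:
            per_arm[arm.arm] = 0
            flagged.append(arm.arm)
            continue
        states = genes["state"].values
        runs = []
        run_state, run_len = states[0], 1
        for s in states[1:]:
            if s == run_state:
                run_len += 1
            else:
                runs.append((run_state, run_len))
                run_state, run_len = s, 1
        runs.append((run_state, run_len))
        qualifying = [s for s, ln in runs if ln >= min_run]
        if mode == "runs":
            per_arm[arm.arm] = len(qualifying)
        elif mode == "distinct":
            per_arm[arm.arm] = len(set(qualifying))
        else:
            raise CredentialError("mode must be 'runs' or 'distinct'")
    return CopyStateScore(sample=sample, per_arm=per_arm,
                          total=sum(per_arm.values()), flagged_arms=flagged)


# ------------------------------------------------------------- flox ratio

@dataclass
class FloxRatio:
    sample: str
    numerator_target: str
    denominator_target: str
    ratio: float | None
    genotype: str = ""


def flox_ratio(flox_log2cnr: pd.Series, numerator: str = "Trp53_flox",
               denominator: str = "Apc_flox", sample: str = "",
               genotype: str = "") -> FloxRatio:
    """Ratio of flox-site log2CNR signals (numerator Trp53 over denominator
    Apc): 1 for homozygous loss of both, 0 when the numerator site is intact,
    0.5 in the low-purity limit of a heterozygous numerator deletion."""
    for t in (numerator, denominator):
        if t not in flox_log2cnr.index:
            raise CredentialError(f"flox target {t!r} missing")
    den = float(flox_log2cnr[denominator])
    if den == 0.0:
        warnings.warn(f"sample {sample}: denominator flox log2CNR is 0; "
                      "ratio undefined")
        return FloxRatio(sample=sample, numerator_target=numerator,
                         denominator_target=denominator, ratio=None,
                         genotype=genotype)
    return FloxRatio(sample=sample, numerator_target=numerator,
                     denominator_target=denominator,
                     ratio=float(flox_log2cnr[numerator]) / den,
                     genotype=genotype)


def expected_flox_log2cnr(flox_cn: int, purity: float) -> float:
    """Noise-free expected flox-site log2CNR at a given engineered copy number
    and tumor purity (diploid background, psi = 2)."""
    return float(np.log2((purity * flox_cn + 2.0 * (1.0 - purity)) / 2.0))


def genotype_ratio_regression(samples: pd.DataFrame,
                              ratio_col: str = "ratio",
                              genotype_col: str = "genotype") -> pd.DataFrame:
    """Linear model of flox ratio on genotype category: per-genotype mean
    coefficients with Wald p-values (cell-means coding)."""
    import statsmodels.formula.api as smf

    df = samples.dropna(subset=[ratio_col]).copy()
    if df.empty:
        raise CredentialError("no samples with defined ratio")
    res = smf.ols(f"{ratio_col} ~ C({genotype_col}) - 1", data=df).fit()
    rows = []
    for name, coef, se, p in zip(res.params.index, res.params.values,
                                 res.bse.values, res.pvalues.values):
        genotype = name.split("[")[-1].rstrip("]")
        rows.append({"genotype": genotype, "mean_ratio": float(coef),
                     "se": float(se), "p": float(p)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ Fisher 2x2

@dataclass
class FisherResult:
    odds_ratio: float | None    # conditional MLE; None when a margin is zero
    p: float
    alternative: str


def fisher_exact_2x2(table, alternative: str = "two-sided") -> FisherResult:
    """Fisher exact test with the conditional-MLE odds ratio (not the sample
    cross-product)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise CredentialError("table must be a non-negative 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FisherResult(odds_ratio=None, p=1.0, alternative=alternative)
    p = stats.fisher_exact(t, alternative=alternative)[1]
    or_cmle = float(_odds_ratio(t, kind="conditional").statistic)
    return FisherResult(odds_ratio=or_cmle, p=float(p),
                        alternative=alternative)


# ----------------------------------------- recurrent-aneuploidy permutation

def _two_proportion_z(k: np.ndarray, n1: int, K: np.ndarray, n_other: int
                      ) -> np.ndarray:
    """|z| of each arm's event rate vs the other arms pooled.

    ``k``: events at each arm (last axis); ``K``: total events across arms.
    """
    k = np.asarray(k, dtype=float)
    k_other = K - k
    p1 = k / n1
    p2 = k_other / n_other
    pooled = (k + k_other) / (n1 + n_other)
    denom = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n_other))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(denom > 0, (p1 - p2) / denom, 0.0)
    return np.abs(z)


def _permute_rows(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle arm labels independently within each sample (row)."""
    idx = np.argsort(rng.random(mat.shape), axis=1)
    return np.take_along_axis(mat, idx, axis=1)


def recurrent_aneuploidy_permutation(matrix: pd.DataFrame,
                                     n_perm: int = 10_000,
                                     seed: int = 0) -> pd.DataFrame:
    """Within-sample permutation test for recurrent arm gains and losses.

    The statistic per arm/direction is the absolute two-proportion z of that
    arm's event rate against the other arms pooled (the tested arm's events
    excluded from the comparison pool).  The null shuffles each sample's arm
    labels without replacement; the empirical p uses the +1 correction and is
    therefore never exactly 0.  BH q values span all arms and both directions.
    """
    vals = matrix.values
    if not np.isin(vals, (-1, 0, 1)).all():
        raise CredentialError("matrix entries must be -1/0/+1")
    n, n_arms = vals.shape
    if n_arms < 2:
        raise CredentialError("need at least 2 arms")
    rng = np.random.default_rng(seed)
    if (vals != 0).sum() == 0:
        return pd.DataFrame({
            "arm": list(matrix.columns) * 2,
            "direction": ["gain"] * n_arms + ["loss"] * n_arms,
            "frequency": 0.0, "z": 0.0, "p": 1.0, "q": 1.0})

    n_other = n * (n_arms - 1)

    def stats_for(m: np.ndarray) -> np.ndarray:
        out = []
        for d in (1, -1):
            b = m == d
            k = b.sum(axis=0)
            out.append(_two_proportion_z(k, n, b.sum(), n_other))
        return np.concatenate(out)  # gains then losses

    obs = stats_for(vals)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = _permute_rows(vals, rng)
        exceed += stats_for(perm) >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    q = multipletests(p, method="fdr_bh")[1]
    freq = np.concatenate([(vals == 1).mean(axis=0), (vals == -1).mean(axis=0)])
    return pd.DataFrame({
        "arm": list(matrix.columns) * 2,
        "direction": ["gain"] * n_arms + ["loss"] * n_arms,
        "frequency": freq, "z": obs, "p": p, "q": q})


# --------------------------------------------------------- arm specificity

def arm_specificity_test(target: pd.DataFrame,
                         comparisons: dict[str, pd.DataFrame],
                         direction: int = 1, alpha: float = 0.05
                         ) -> dict:
    """Per-arm Fisher tests of the target cohort against each comparison
    cohort, BH-corrected across all tests; arms altered more frequently in the
    target than in at least half of the comparisons are flagged, and pairwise
    co-occurrence among flagged arms is tested the same way."""
    if not comparisons:
        raise CredentialError("need at least one comparison cohort")
    if target.empty or any(c.empty for c in comparisons.values()):
        raise CredentialError("empty cohort")
    arms = list(target.columns)
    rows = []
    for arm in arms:
        t_alt = int((target[arm] == direction).sum())
        t_n = len(target)
        for name, comp in comparisons.items():
            if arm not in comp.columns:
                continue
            c_alt = int((comp[arm] == direction).sum())
            c_n = len(comp)
            res = fisher_exact_2x2(
                [[t_alt, t_n - t_alt], [c_alt, c_n - c_alt]],
                alternative="two-sided")
            rows.append({"arm": arm, "comparison": name,
                         "target_rate": t_alt / t_n,
                         "comparison_rate": c_alt / c_n,
                         "odds_ratio": res.odds_ratio, "p": res.p})
    per_arm = pd.DataFrame(rows)
    per_arm["q"] = multipletests(per_arm["p"].values, method="fdr_bh")[1]
    flagged = []
    half = len(comparisons) / 2.0
    for arm, grp in per_arm.groupby("arm", sort=False):
        more = ((grp["target_rate"] > grp["comparison_rate"])
                & (grp["q"] < alpha)).sum()
        if more >= half:
            flagged.append(arm)

    cooc_rows = []
    for i, a in enumerate(flagged):
        for b in flagged[i + 1:]:
            t_both = int(((target[a] == direction)
                          & (target[b] == direction)).sum())
            for name, comp in comparisons.items():
                if a not in comp.columns or b not in comp.columns:
                    continue
                c_both = int(((comp[a] == direction)
                              & (comp[b] == direction)).sum())
                res = fisher_exact_2x2(
                    [[t_both, len(target) - t_both],
                     [c_both, len(comp) - c_both]], alternative="two-sided")
                cooc_rows.append({"arm_a": a, "arm_b": b, "comparison": name,
                                  "odds_ratio": res.odds_ratio, "p": res.p})
    cooc = pd.DataFrame(cooc_rows)
    if not cooc.empty:
        cooc["q"] = multipletests(cooc["p"].values, method="fdr_bh")[1]
    return {"per_arm": per_arm, "flagged": flagged, "co_occurrence": cooc}


# ------------------------------------------------------- synteny scenarios

def map_syntenic(human_interval: tuple[str, int, int],
                 synteny_map: pd.DataFrame,
                 peaks: list[tuple[str, int, int]] | None = None) -> dict:
    """Mouse blocks hit by a human interval, percent synteny per mouse
    chromosome (overlap length over the human interval length), and overlaps
    with supplied peak intervals."""
    chrom, start, end = human_interval
    if end <= start:
        raise CredentialError("empty human interval")
    hits = synteny_map[(synteny_map["hchrom"] == chrom)
                       & (synteny_map["hstart"] < end)
                       & (synteny_map["hend"] > start)].copy()
    if hits.empty:
        warnings.warn("no syntenic blocks overlap the interval")
    hits["overlap"] = (np.minimum(hits["hend"], end)
                       - np.maximum(hits["hstart"], start))
    pct = (hits.groupby("mchrom")["overlap"].sum()
           / (end - start)).sort_values(ascending=False)
    peak_hits = []
    for p in peaks or []:
        pc, ps, pe = p
        if pc == chrom and ps < end and pe > start:
            peak_hits.append((pc, max(ps, start), min(pe, end)))
    return {"blocks": hits, "percent_synteny": pct, "peak_overlaps": peak_hits}


def syntenic_mouse_chroms(human_arm_interval: tuple[str, int, int],
                          synteny_map: pd.DataFrame,
                          min_fraction: float = 0.0) -> list[str]:
    pct = map_syntenic(human_arm_interval, synteny_map)["percent_synteny"]
    return list(pct[pct > min_fraction].index.astype(str))


def _scenario_indicator(mouse_gains: np.ndarray, subset_mode: str
                        ) -> dict[int, np.ndarray]:
    """Per-sample indicators of the three scenarios over the syntenic set S.

    mouse_gains: samples x |S| boolean.  Scenario 1: all of S gained;
    scenario 2: a proper nonempty subset ('any' mode) or exactly one ('one');
    scenario 3: none gained.
    """
    total = mouse_gains.sum(axis=1)
    k = mouse_gains.shape[1]
    s1 = total == k
    s3 = total == 0
    if subset_mode == "any":
        s2 = (total > 0) & (total < k)
    elif subset_mode == "one":
        s2 = total == 1 if k > 1 else np.zeros_like(s1)
    else:
        raise CredentialError("subset_mode must be 'any' or 'one'")
    return {1: s1, 2: s2, 3: s3}


def _joint_log_or(k_h: int, n_h: int, k_m: int, n_m: int) -> float:
    """Log odds of the joint human-gain x mouse-scenario event.

    Each frequency gets a Haldane-style continuity correction (+0.5 events)
    so degenerate 0/1 rates stay finite without collapsing the comparison.
    """
    p_h = (k_h + 0.5) / (n_h + 1.0)
    p_m = (k_m + 0.5) / (n_m + 1.0)
    joint = p_h * p_m
    return float(np.log(joint / (1.0 - joint)))


def synteny_scenario_test(human_matrix: pd.DataFrame,
                          human_arms: dict[str, tuple[str, int, int]],
                          mouse_matrix: pd.DataFrame,
                          synteny_map: pd.DataFrame,
                          n_perm: int = 10_000, seed: int = 0,
                          subset_mode: str = "any",
                          alpha: float = 0.05,
                          min_synteny_fraction: float = 0.0) -> pd.DataFrame:
    """Three-scenario synteny test for each human arm of interest.

    For each human arm with syntenic mouse chromosome set S, the observed log
    odds of the joint event (human arm gained x mouse scenario) is computed
    for scenario 1 (all of S gained), 2 (a subset gained) and 3 (none gained),
    and compared with the same quantity on 10,000 within-sample-permuted human
    and mouse matrices.  Reported per arm: the three log ORs, each scenario's
    own enrichment p, the p of scenarios 2 and 3 against scenario 1 (on the
    log-OR difference), and the favored scenario (significant own-p, largest
    log OR; none when nothing is significant).
    """
    rng = np.random.default_rng(seed)
    hvals = human_matrix.values
    mvals = mouse_matrix.values
    n_h, n_m = len(hvals), len(mvals)
    rows = []
    for arm, interval in human_arms.items():
        if arm not in human_matrix.columns:
            raise CredentialError(f"human arm {arm!r} not in matrix")
        S = [c for c in syntenic_mouse_chroms(interval, synteny_map,
                                              min_synteny_fraction)
             if c in mouse_matrix.columns]
        if not S:
            warnings.warn(f"human arm {arm}: no syntenic mouse chromosome; "
                          "skipped")
            continue
        h_col = human_matrix.columns.get_loc(arm)
        m_cols = [mouse_matrix.columns.get_loc(c) for c in S]

        def log_ors(h: np.ndarray, m: np.ndarray) -> np.ndarray:
            k_h = int((h[:, h_col] == 1).sum())
            ind = _scenario_indicator(m[:, m_cols] == 1, subset_mode)
            return np.array([_joint_log_or(k_h, n_h, int(ind[k].sum()), n_m)
                             for k in (1, 2, 3)])

        obs = log_ors(hvals, mvals)
        null = np.empty((n_perm, 3))
        for b in range(n_perm):
            null[b] = log_ors(_permute_rows(hvals, rng),
                              _permute_rows(mvals, rng))
        p_own = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (1.0 + n_perm)

        def p_diff(a: int, b: int) -> float:
            d_obs = obs[a] - obs[b]
            d_null = null[:, a] - null[:, b]
            return float((1.0 + (d_null >= d_obs).sum()) / (1.0 + n_perm))

        p21, p31 = p_diff(1, 0), p_diff(2, 0)
        p23, p32 = p_diff(1, 2), p_diff(2, 1)
        # Scenario 2 or 3 is favored when its log OR significantly exceeds
        # both alternatives (the human-arm enrichment cancels in the log-OR
        # differences); scenario 1 when it is itself enriched and neither
        # alternative beats it.
        favored = None
        if p21 < alpha and p23 < alpha:
            favored = 2
        elif p31 < alpha and p32 < alpha:
            favored = 3
        elif (p_own[0] < alpha and p21 >= alpha and p31 >= alpha
              and obs[0] >= max(obs[1], obs[2]) - 1e-12):
            favored = 1
        rows.append({
            "human_arm": arm, "mouse_chroms": ",".join(S),
            "log_or_s1": obs[0], "log_or_s2": obs[1], "log_or_s3": obs[2],
            "p_s1": p_own[0], "p_s2": p_own[1], "p_s3": p_own[2],
            "p_s2_vs_s1": p21, "p_s3_vs_s1": p31,
            "p_s2_vs_s3": p23, "p_s3_vs_s2": p32,
            "favored": favored})
    return pd.DataFrame(rows)
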