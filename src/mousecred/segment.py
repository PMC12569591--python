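"""CBS-style segmentation of per-amplicon log2CNR profiles.

Per chromosome: light outlier smoothing, then recursive mean-shift splitting —
at each level the candidate changepoint maximizing the two-sample t statistic
is accepted when a within-chromosome permutation test rejects homogeneity
(p < alpha) and both sides keep at least ``min_markers`` markers.

Accepted segments are annotated exactly like genes: a z score of the segment
mean against the distribution of the same markers' mean across the pool of
normals, two-tailed normal p, BH q across segments within the sample, and the
same q/CNR noise-zeroing rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calls import Segment
from .panel import AmpliconPanel


def _best_split(x: np.ndarray, min_markers: int) -> tuple[int | None, float]:
    """Best single changepoint by max |t| of the mean difference; exhaustive."""
    n = len(x)
    if n < 2 * min_markers:
        return None, 0.0
    cs = np.cumsum(x)
    total = cs[-1]
    ks = np.arange(min_markers, n - min_markers + 1)
    m1 = cs[ks - 1] / ks
    m2 = (total - cs[ks - 1]) / (n - ks)
    css = np.cumsum(x ** 2)
    ss1 = css[ks - 1] - ks * m1 ** 2
    ss2 = (css[-1] - css[ks - 1]) - (n - ks) * m2 ** 2
    dof = n - 2
    pooled = np.sqrt(np.maximum((ss1 + ss2) / np.maximum(dof, 1), 1e-300))
    t = np.abs(m1 - m2) / (pooled * np.sqrt(1.0 / ks + 1.0 / (n - ks)))
    i = int(np.argmax(t))
    return int(ks[i]), float(t[i])


def _split_significant(x: np.ndarray, t_obs: float, min_markers: int,
                       alpha: float, n_perm: int,
                       rng: np.random.Generator) -> bool:
    exceed = 0
    for _ in range(n_perm):
        _, t_perm = _best_split(rng.permutation(x), min_markers)
        if t_perm >= t_obs:
            exceed += 1
    return (exceed + 1) / (n_perm + 1) < alpha


def _smooth_outliers(x: np.ndarray, window: int = 2, nsd: float = 3.0) -> np.ndarray:
    """Shrink single-point outliers toward the local median (CBS-style)."""
    if len(x) < 2 * window + 1:
        return x
    out = x.copy()
    sd = 1.4826 * np.median(np.abs(np.diff(x))) / np.sqrt(2.0)
    if sd <= 0:
        return out
    for i in range(len(x)):
        lo, hi = max(0, i - window), min(len(x), i + window + 1)
        med = np.median(np.concatenate([x[lo:i], x[i + 1:hi]]))
        if abs(x[i] - med) > nsd * sd:
            out[i] = med + np.sign(x[i] - med) * nsd * sd
    return out


def _segment_chrom(x: np.ndarray, min_markers: int, alpha: float,
                   n_perm: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Recursive binary splitting; returns marker-index boundaries."""
    def rec(lo: int, hi: int) -> list[int]:
        seg = x[lo:hi]
        k, t_obs = _best_split(seg, min_markers)
        if k is None or t_obs <= 0:
            return []
        if not _split_significant(seg, t_obs, min_markers, alpha, n_perm, rng):
            return []
        return rec(lo, lo + k) + [lo + k] + rec(lo + k, hi)

    cuts = sorted(rec(0, len(x)))
    bounds = [0] + cuts + [len(x)]
    return list(zip(bounds[:-1], bounds[1:]))


def segment_profile(cnr: pd.Series, panel: AmpliconPanel,
                    normals_cnr: pd.DataFrame | None = None,
                    alpha: float = 0.01, n_perm: int = 200,
                    min_markers: int = 3, smooth: bool = True,
                    q_max: float = 0.05, cnr_floor: float = 0.2,
                    zero_rule: str = "and", seed: int = 0) -> list[Segment]:
    """Segment one sample's log2CNR profile into significance-annotated
    constant-copy segments."""
    rng = np.random.default_rng(seed)
    order = panel.genomic_order()
    order = order[order["amplicon"].isin(cnr.index)]
    segments: list[Segment] = []
    seg_marker_ids: list[list[str]] = []
    for chrom, grp in order.groupby("chrom", sort=False):
        ids = grp["amplicon"].tolist()
        x = cnr.loc[ids].values.astype(float)
        starts = grp["start"].values
        ends = grp["end"].values
        if len(x) < 2:
            pieces = [(0, len(x))]
        else:
            xs = _smooth_outliers(x) if smooth else x
            pieces = _segment_chrom(xs, min_markers, alpha, n_perm, rng)
        for lo, hi in pieces:
            if hi <= lo:
                continue
            segments.append(Segment(
                chrom=str(chrom), start=int(starts[lo]), end=int(ends[hi - 1]),
                n_markers=hi - lo, mean_log2cnr=float(np.mean(x[lo:hi]))))
            seg_marker_ids.append(ids[lo:hi])
    if normals_cnr is not None:
        _annotate_segments(segments, seg_marker_ids, normals_cnr,
                           q_max, cnr_floor, zero_rule)
    return segments


def _annotate_segments(segments: list[Segment],
                       seg_marker_ids: list[list[str]],
                       normals_cnr: pd.DataFrame, q_max: float,
                       cnr_floor: float, zero_rule: str) -> None:
    zs = []
    for seg, ids in zip(segments, seg_marker_ids):
        norm_means = normals_cnr.loc[ids].mean(axis=0)
        sd = norm_means.std(ddof=1)
        zs.append((seg.mean_log2cnr - norm_means.mean()) / sd if sd > 0
                  else float("nan"))
    zs = np.asarray(zs, dtype=float)
    ps = 2.0 * stats.norm.sf(np.abs(np.nan_to_num(zs)))
    ps[~np.isfinite(zs)] = 1.0
    qs = multipletests(ps, method="fdr_bh")[1]
    for seg, z, p, q in zip(segments, zs, ps, qs):
        seg.z = float(z)
        seg.q = float(q)
        if not np.isfinite(z):
            seg.state = 0
            continue
        state = int(np.sign(seg.mean_log2cnr))
        insignificant = q > q_max
        small = abs(seg.mean_log2cnr) < cnr_floor
        zero = (insignificant and small) if zero_rule == "and" \
            else (insignificant or small)
        seg.state = 0 if zero else state
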