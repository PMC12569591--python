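"""Arm-level aneuploidy calling under reduced breadth of coverage.

``R_c`` is the fraction of a coverage-restricted arm window (breadth ``c``,
centered at the arm midpoint) covered by same-direction CNA segments.  An arm
direction is called when ``R_c`` meets the threshold and — with the
directionality filter on — when a sufficient fraction of the arm's genes are
altered in that direction.  Reference calls use the full arm (``R_1.0 >= 0.8``)
with no gene filter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calls import ArmCall, Segment
from .genome import ArmWindow, GenomeLayout, build_arm_windows, \
    interval_union_length


class AneuploidyError(ValueError):
    pass


def compute_rc(segments: list[Segment] | list[tuple[int, int]],
               window: ArmWindow) -> float:
    """Fraction of the window covered by the union of the segments."""
    if window.length <= 0:
        raise AneuploidyError(f"zero-length window for arm {window.arm}")
    intervals = [(s.start, s.end) if isinstance(s, Segment) else tuple(s)
                 for s in segments]
    covered = interval_union_length(intervals, clip=(window.start, window.end))
    return covered / window.length


def _direction_fraction(gene_calls: pd.DataFrame, arm_chrom: str,
                        direction: int, segs: list[Segment],
                        genes_on: str, window: ArmWindow) -> float:
    genes = gene_calls[gene_calls["chrom"] == arm_chrom]
    if genes_on == "segments":
        def overlaps(row) -> bool:
            return any(row["start"] < s.end and s.start < row["end"]
                       for s in segs)
        genes = genes[genes.apply(overlaps, axis=1)] if segs else genes.iloc[:0]
    elif genes_on != "arm":
        raise AneuploidyError("genes_on must be 'segments' or 'arm'")
    if genes.empty:
        return 0.0
    return float((genes["state"] == direction).mean())


def call_arm_aneuploidy(segments: list[Segment], gene_calls: pd.DataFrame,
                        layout: GenomeLayout, c: float = 0.6,
                        rc_threshold: float = 0.8,
                        min_direction_fraction: float = 1.0,
                        genes_on: str = "segments") -> list[ArmCall]:
    """Arm calls for one sample.

    ``gene_calls`` needs columns gene, chrom, start, end, state.  Gains and
    losses are evaluated independently; if both pass, the direction with the
    larger ``R_c`` wins (an exact tie yields no call, with a warning).
    """
    if not (0.0 <= min_direction_fraction <= 1.0):
        raise AneuploidyError("min_direction_fraction must be in [0, 1]")
    # 0 disables the directionality filter (pure R_c calling).
    windows = {w.arm: w for w in build_arm_windows(layout, c)}
    calls = []
    for arm in layout.arms:
        w = windows[arm.arm]
        results = {}
        for direction, label in ((1, "gain"), (-1, "loss")):
            segs = [s for s in segments
                    if s.chrom == arm.chrom and s.state == direction]
            rc = compute_rc(segs, w)
            frac = _direction_fraction(gene_calls, arm.chrom, direction,
                                       segs, genes_on, w)
            qualifies = rc >= rc_threshold and (
                min_direction_fraction == 0.0
                or frac >= min_direction_fraction)
            results[label] = (qualifies, rc, frac)
        g_ok, g_rc, g_frac = results["gain"]
        l_ok, l_rc, l_frac = results["loss"]
        flags: list[str] = []
        if g_ok and l_ok:
            if g_rc == l_rc:
                direction, rc, frac = "none", g_rc, g_frac
                flags.append("gain-loss-tie")
                warnings.warn(f"arm {arm.arm}: gain/loss R_c tie; no call")
            elif g_rc > l_rc:
                direction, rc, frac = "gain", g_rc, g_frac
            else:
                direction, rc, frac = "loss", l_rc, l_frac
        elif g_ok:
            direction, rc, frac = "gain", g_rc, g_frac
        elif l_ok:
            direction, rc, frac = "loss", l_rc, l_frac
        else:
            direction = "none"
            rc, frac = max((g_rc, g_frac), (l_rc, l_frac))
        calls.append(ArmCall(arm=arm.arm, direction=direction, rc=rc, c=c,
                             direction_fraction=frac, flags=flags))
    return calls


def arm_calls_to_row(calls: list[ArmCall]) -> pd.Series:
    return pd.Series({c.arm: c.state for c in calls})


def reference_arm_calls(cohort_segments: dict[str, list[Segment]],
                        layout: GenomeLayout,
                        rc_threshold: float = 0.8) -> pd.DataFrame:
    """Reference aneuploidy matrix: per arm/direction, call iff R_1.0 meets the
    threshold; no directionality filter."""
    windows = {w.arm: w for w in build_arm_windows(layout, 1.0)}
    rows = {}
    for sample, segments in cohort_segments.items():
        row = {}
        for arm in layout.arms:
            w = windows[arm.arm]
            rc_gain = compute_rc(
                [s for s in segments if s.chrom == arm.chrom and s.state == 1], w)
            rc_loss = compute_rc(
                [s for s in segments if s.chrom == arm.chrom and s.state == -1], w)
            state = 0
            if rc_gain >= rc_threshold and rc_gain >= rc_loss:
                state = 1
            elif rc_loss >= rc_threshold:
                state = -1
            row[arm.arm] = state
        rows[sample] = row
    return pd.DataFrame.from_dict(rows, orient="index")[
        [a.arm for a in layout.arms]]


def evaluate_concordance(calls: pd.DataFrame,
                         reference: pd.DataFrame) -> dict:
    """PPA over reference-altered cells (direction must match), NPA over
    reference-neutral cells, and the full 3x3 confusion matrix."""
    if calls.shape != reference.shape:
        raise AneuploidyError("calls and reference shapes differ")
    calls = calls.loc[reference.index, reference.columns]
    c = calls.values.ravel()
    r = reference.values.ravel()
    states = (-1, 0, 1)
    confusion = pd.DataFrame(0, index=states, columns=states)
    for rv, cv in zip(r, c):
        confusion.loc[rv, cv] += 1
    altered = r != 0
    ppa = float((c[altered] == r[altered]).mean()) if altered.any() else float("nan")
    neutral = ~altered
    npa = float((c[neutral] == 0).mean()) if neutral.any() else float("nan")
    return {"PPA": ppa, "NPA": npa, "confusion": confusion}


# --------------------------------------------------- marker subsampling

WINDOW_SIZES = (100_000, 250_000, 500_000, 1_000_000, 5_000_000, 10_000_000)


def subsample_markers(targets: pd.DataFrame, window_size: int,
                      mode: str = "single-marker", n_repeats: int = 10,
                      seed: int = 0) -> list[pd.Index]:
    """Marker-density subsampling: per non-overlapping genomic window, keep one
    random marker — or all markers of one random gene when one is present and
    ``mode="whole-gene"``.  Returns one amplicon-id Index per repeat.

    ``targets`` needs columns amplicon, chrom, start, target, target_class
    (gene rows are every class except genotyping-snp), sorted or not.
    """
    if mode not in ("single-marker", "whole-gene"):
        raise AneuploidyError("mode must be 'single-marker' or 'whole-gene'")
    t = targets.sort_values(["chrom", "start"], kind="mergesort")
    t = t.assign(_win=t["start"] // window_size)
    out = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        chosen: list[str] = []
        for (_, _), grp in t.groupby(["chrom", "_win"], sort=False):
            if grp.empty:
                continue
            genic = grp[grp["target_class"] != "genotyping-snp"]
            if mode == "whole-gene" and not genic.empty:
                gene = rng.choice(genic["target"].unique())
                chosen.extend(genic.loc[genic["target"] == gene, "amplicon"])
            else:
                chosen.append(grp["amplicon"].iloc[
                    rng.integers(0, len(grp))])
        out.append(pd.Index(chosen))
    return out


def run_coverage_simulation(cohort_segments: dict[str, list[Segment]],
                            gene_calls: dict[str, pd.DataFrame],
                            layout: GenomeLayout,
                            c_grid=(0.2, 0.4, 0.6, 0.8, 1.0),
                            rc_grid=(0.2, 0.4, 0.6, 0.8, 1.0),
                            direction_fractions=(None,),
                            reference: pd.DataFrame | None = None
                            ) -> pd.DataFrame:
    """Grid evaluation of (c, R_c threshold, directionality fraction) against
    reference calls; returns a tidy PPA/NPA table.

    ``direction_fractions`` entries of None disable the gene filter.
    """
    if reference is None:
        reference = reference_arm_calls(cohort_segments, layout)
    rows = []
    for c in c_grid:
        for thr in rc_grid:
            for frac in direction_fractions:
                mat = {}
                for sample, segs in cohort_segments.items():
                    calls = call_arm_aneuploidy(
                        segs, gene_calls[sample], layout, c=c,
                        rc_threshold=thr,
                        min_direction_fraction=frac if frac else 0.0,
                        genes_on="segments")
                    mat[sample] = arm_calls_to_row(calls)
                mat = pd.DataFrame.from_dict(mat, orient="index")[
                    reference.columns].loc[reference.index]
                perf = evaluate_concordance(mat, reference)
                n_ref_neutral = int((reference.values == 0).sum())
                fp = int(((mat.values != 0) & (reference.values == 0)).sum())
                called = mat.values != 0
                tp = int((called & (mat.values == reference.values)).sum())
                rows.append({
                    "c": c, "rc_threshold": thr,
                    "direction_fraction": frac, "PPA": perf["PPA"],
                    "NPA": perf["NPA"],
                    "PPV": tp / called.sum() if called.any() else float("nan"),
                    "FPR": fp / n_ref_neutral if n_ref_neutral else float("nan"),
                    "n_calls": int(called.sum()),
                })
    return pd.DataFrame(rows)
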