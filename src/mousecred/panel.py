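"""Amplicon panel and read-count containers.

Both are thin wrappers around pandas objects: the panel is a DataFrame with one
row per amplicon, the count matrix a DataFrame of non-negative counts indexed
by amplicon with one column per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TARGET_CLASSES = ("hotspot", "tsg-cds", "cn-tiling", "genotyping-snp", "flox")

PANEL_COLUMNS = ["amplicon", "chrom", "start", "end", "target",
                 "target_class", "gc", "pool", "flox_parent"]


class PanelError(ValueError):
    pass


@dataclass
class AmpliconPanel:
    """Targeted panel definition.

    ``df`` columns: amplicon (unique id), chrom, start, end (0-based
    half-open), target (gene symbol or SNP id; flox amplicons carry a distinct
    flox-target label), target_class, gc (fraction), pool, flox_parent (parent
    gene for flox amplicons, empty otherwise).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.df.columns]
        if missing:
            raise PanelError(f"panel missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if df["amplicon"].duplicated().any():
            dup = df.loc[df["amplicon"].duplicated(), "amplicon"].iloc[0]
            raise PanelError(f"duplicate amplicon id {dup!r}")
        if (df["end"] <= df["start"]).any():
            bad = df.loc[df["end"] <= df["start"], "amplicon"].iloc[0]
            raise PanelError(f"amplicon {bad!r} has end <= start")
        if ((df["gc"] < 0) | (df["gc"] > 1)).any():
            raise PanelError("gc fractions must be in [0, 1]")
        unknown = set(df["target_class"]) - set(TARGET_CLASSES)
        if unknown:
            raise PanelError(f"unknown target classes: {sorted(unknown)}")
        flox = df["target_class"] == "flox"
        if flox.any():
            bad = flox & ((df["flox_parent"] == "") | (df["flox_parent"] == df["target"]))
            if bad.any():
                raise PanelError(
                    "flox amplicons need a parent gene distinct from their "
                    "flox-target label"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def amplicon_ids(self) -> pd.Index:
        return pd.Index(self.df["amplicon"])

    def subset(self, amplicon_ids) -> "AmpliconPanel":
        keep = self.df[self.df["amplicon"].isin(set(amplicon_ids))]
        return AmpliconPanel(keep.copy())

    def genomic_order(self) -> pd.DataFrame:
        """Panel rows sorted by (chrom, start); chromosomes in natural order."""
        df = self.df.copy()
        df["_ck"] = df["chrom"].map(_chrom_key)
        out = df.sort_values(["_ck", "start"], kind="mergesort").drop(columns="_ck")
        return out

    def gene_targets(self, include_flox: bool = True) -> pd.DataFrame:
        """Gene-level targets (everything except genotyping SNPs).

        Flox targets are distinct "genes" here: they were split from their
        parent before any calling.
        """
        classes = {"hotspot", "tsg-cds", "cn-tiling"}
        if include_flox:
            classes.add("flox")
        return self.df[self.df["target_class"].isin(classes)]

    def gene_intervals(self, include_flox: bool = True) -> pd.DataFrame:
        """Per-gene span: chrom, min start, max end, amplicon count."""
        g = self.gene_targets(include_flox)
        out = g.groupby("target").agg(
            chrom=("chrom", "first"), start=("start", "min"),
            end=("end", "max"), n_amplicons=("amplicon", "size"),
        ).reset_index()
        return out


@dataclass
class ReadCountMatrix:
    """Per-amplicon, per-sample counts (rows = amplicons, columns = samples)."""

    counts: pd.DataFrame
    allow_float: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise PanelError("negative read counts")
        if not self.allow_float:
            vals = self.counts.values
            if not np.allclose(vals, np.round(vals)):
                raise PanelError("read counts must be integers")
            self.counts = self.counts.round().astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def amplicon_ids(self) -> pd.Index:
        return self.counts.index

    def matches_panel(self, panel: AmpliconPanel) -> bool:
        return self.counts.index.equals(pd.Index(panel.df["amplicon"]))


def _chrom_key(chrom: str):
    c = str(chrom).removeprefix("chr")
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)
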