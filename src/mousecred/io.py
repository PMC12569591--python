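"""Readers and writers for the on-disk formats.

Formats are all plain text:

* panel — BED6+ (chrom, start, end, name, score, strand) with extra columns
  ``class``, ``gc``, ``pool``, ``floxParent``
* counts — TSV, rows = amplicons, columns = samples
* segments — SEG (sample, chrom, start, end, num.mark, seg.mean) with optional
  ``z``, ``q``, ``state`` columns; SEG start coordinates are 1-based inclusive
  on disk and converted to 0-based half-open in memory
* strain panel — VCF-like TSV (chrom, pos, snp, ref, alt, one 0/1 column per
  strain)
* synteny — TSV (hchrom, hstart, hend, mchrom, mstart, mend, orientation)
* arm layout — TSV (species, chrom, arm, start, end)

Every ``read_*`` / ``write_*`` pair round-trips typed content exactly.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .calls import Segment
from .genome import Arm, GenomeLayout
from .panel import AmpliconPanel, PANEL_COLUMNS, ReadCountMatrix, _chrom_key


class ParseError(ValueError):
    """Malformed input row; message carries the 1-based line number."""


# ---------------------------------------------------------------- panel BED

_BED_HEADER = ["#chrom", "start", "end", "name", "score", "strand",
               "class", "gc", "pool", "floxParent"]


def write_panel_bed(panel: AmpliconPanel, path) -> None:
    df = panel.df
    out = pd.DataFrame({
        "#chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df["amplicon"], "score": 0, "strand": ".",
        "class": df["target_class"], "gc": df["gc"], "pool": df["pool"],
        "floxParent": df["flox_parent"].replace("", "."),
        "target": df["target"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_panel_bed(path, layout: GenomeLayout | None = None) -> AmpliconPanel:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                start, end = int(parts[idx["start"]]), int(parts[idx["end"]])
                gc = float(parts[idx["gc"]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if end <= start:
                raise ParseError(f"{path}: line {lineno}: end <= start")
            chrom = parts[idx["#chrom"]]
            if layout is not None:
                if chrom not in layout.chrom_lengths:
                    raise ParseError(
                        f"{path}: line {lineno}: chromosome {chrom!r} not in layout")
                if end > layout.chrom_lengths[chrom]:
                    raise ParseError(
                        f"{path}: line {lineno}: interval beyond chromosome end")
            flox_parent = parts[idx["floxParent"]]
            rows.append({
                "amplicon": parts[idx["name"]], "chrom": chrom,
                "start": start, "end": end,
                "target": parts[idx["target"]],
                "target_class": parts[idx["class"]], "gc": gc,
                "pool": parts[idx["pool"]],
                "flox_parent": "" if flox_parent == "." else flox_parent,
            })
    return AmpliconPanel(pd.DataFrame(rows, columns=PANEL_COLUMNS))


# ------------------------------------------------------------- counts TSV

def write_counts_tsv(counts: ReadCountMatrix, path) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="amplicon")


def read_counts_tsv(path) -> ReadCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="amplicon")
    return ReadCountMatrix(df)


# -------------------------------------------------------------------- SEG

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num.mark", "seg.mean"]


def write_seg(segments: dict[str, list[Segment]], path) -> None:
    """Write per-sample segments as SEG (1-based inclusive start on disk)."""
    rows = []
    for sample, segs in segments.items():
        for s in segs:
            rows.append({
                "sample": sample, "chrom": s.chrom, "start": s.start + 1,
                "end": s.end, "num.mark": s.n_markers,
                "seg.mean": s.mean_log2cnr, "z": s.z, "q": s.q,
                "state": s.state,
            })
    pd.DataFrame(rows, columns=SEG_COLUMNS + ["z", "q", "state"]).to_csv(
        path, sep="\t", index=False)


def read_seg(path) -> dict[str, list[Segment]]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: SEG missing columns {missing}")
    has_extra = all(c in df.columns for c in ("z", "q", "state"))
    out: dict[str, list[Segment]] = {}
    for sample, grp in df.groupby("sample", sort=False):
        grp = grp.copy()
        grp["_ck"] = grp["chrom"].map(_chrom_key)
        ordered = grp.sort_values(["_ck", "start"], kind="mergesort")
        if not ordered.index.equals(grp.index):
            warnings.warn(f"{path}: sample {sample}: segments out of order; "
                          "normalized to sorted order")
        segs = []
        for _, r in ordered.iterrows():
            segs.append(Segment(
                chrom=str(r["chrom"]), start=int(r["start"]) - 1,
                end=int(r["end"]), n_markers=int(r["num.mark"]),
                mean_log2cnr=float(r["seg.mean"]),
                z=float(r["z"]) if has_extra else float("nan"),
                q=float(r["q"]) if has_extra else float("nan"),
                state=int(r["state"]) if has_extra else 0,
            ))
        out[str(sample)] = segs
    return out


# ----------------------------------------------------------- strain panel

def write_strain_panel_tsv(panel_df: pd.DataFrame, path) -> None:
    """``panel_df``: chrom, pos, snp, ref, alt + one 0/1 column per strain."""
    panel_df.to_csv(path, sep="\t", index=False)


def read_strain_panel_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["chrom", "pos", "snp", "ref", "alt"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: strain panel missing columns {missing}")
    strains = [c for c in df.columns if c not in fixed]
    if not strains:
        raise ParseError(f"{path}: strain panel has no strain columns")
    bad = ~df[strains].isin([0, 1]).all(axis=1)
    if bad.any():
        raise ParseError(
            f"{path}: line {bad.idxmax() + 2}: inbred strain alleles must be 0/1")
    if df["pos"].duplicated().any() and df.groupby("chrom")["pos"].apply(
            lambda s: s.duplicated().any()).any():
        raise ParseError(f"{path}: duplicate SNP positions")
    return df


# ----------------------------------------------------------------- synteny

SYNTENY_COLUMNS = ["hchrom", "hstart", "hend", "mchrom", "mstart", "mend",
                   "orientation"]


def write_synteny_tsv(blocks: pd.DataFrame, path) -> None:
    blocks[SYNTENY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_synteny_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"hchrom": str, "mchrom": str})
    missing = [c for c in SYNTENY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: synteny table missing columns {missing}")
    if ((df["hend"] <= df["hstart"]) | (df["mend"] <= df["mstart"])).any():
        raise ParseError(f"{path}: synteny blocks must have positive length")
    return df


# -------------------------------------------------------------- arm layout

def write_arm_layout_tsv(layout: GenomeLayout, path) -> None:
    rows = [{"species": layout.species, "chrom": a.chrom, "arm": a.arm,
             "start": a.start, "end": a.end} for a in layout.arms]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_arm_layout_tsv(path,
                        chrom_lengths: dict[str, int] | None = None
                        ) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("species", "chrom", "arm", "start", "end")
               if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: arm layout missing columns {missing}")
    species = str(df["species"].iloc[0])
    if chrom_lengths is None:
        chrom_lengths = df.groupby("chrom")["end"].max().to_dict()
        chrom_lengths = {str(k): int(v) for k, v in chrom_lengths.items()}
    arms = [Arm(arm=str(r["arm"]), chrom=str(r["chrom"]),
                start=int(r["start"]), end=int(r["end"]))
            for _, r in df.iterrows()]
    return GenomeLayout(species=species, chrom_lengths=chrom_lengths, arms=arms)
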