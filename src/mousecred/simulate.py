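"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be produced here: amplicon read counts
from tumors with known integer copy-number profiles, purity, ploidy, GC bias
and overdispersed counting noise; inbred-strain reference panels and admixed
offspring; ortholog peptide pairs with controlled conservation; and
sample x arm aneuploidy matrices with planted recurrent events.

The count model: a tumor of purity ``p`` and ploidy ``psi`` mixed with diploid
normal tissue has, at a locus of tumor copy number ``CN``, the expected
copy-number ratio

    CNR = (p * CN + 2 * (1 - p)) / (p * psi + 2 * (1 - p))

Counts are negative-binomial draws with mean proportional to
``CNR * efficiency * gc_bias(gc)``; per-amplicon efficiencies are log-normal
and fixed per panel (their own seed) so tumor and normal share them.
Strain crosses draw alleles independently per SNP — no linkage, which is the
assumption of the simulation this generator emulates (markers ~1.5 Mb apart).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import Segment
from .genome import GenomeLayout
from .panel import AmpliconPanel, ReadCountMatrix

DEFAULT_STRAINS = ("C57BL/6J", "BALB/cJ", "C3H/HeJ", "FVB/NJ", "129S1/SvImJ")


class SimulationError(ValueError):
    pass


# ------------------------------------------------------------ copy number

@dataclass(frozen=True)
class CnEvent:
    chrom: str
    start: int
    end: int
    cn: int

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise SimulationError("copy number must be >= 0")
        if self.end <= self.start:
            raise SimulationError("empty event interval")


@dataclass
class TruthProfile:
    """Ground-truth tumor state: integer CN events over a diploid baseline,
    engineered flox deletions, purity and ploidy."""

    layout: GenomeLayout
    events: list[CnEvent] = field(default_factory=list)
    flox_cn: dict[str, int] = field(default_factory=dict)
    purity: float = 1.0
    ploidy: float = 2.0
    baseline_cn: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise SimulationError(f"purity out of [0, 1]: {self.purity}")
        if self.ploidy <= 0:
            raise SimulationError("ploidy must be positive")
        by_chrom: dict[str, list[CnEvent]] = {}
        for ev in self.events:
            if ev.chrom not in self.layout.chrom_lengths:
                raise SimulationError(f"event on unknown chromosome {ev.chrom!r}")
            if ev.end > self.layout.chrom_lengths[ev.chrom]:
                raise SimulationError("event beyond chromosome end")
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end and a.cn != b.cn:
                    raise SimulationError(
                        f"conflicting overlapping events on {chrom}")

    def copy_number_at(self, chrom: str, pos: int,
                       flox_target: str | None = None) -> int:
        """Tumor integer CN at a position; flox targets override their locus."""
        if flox_target is not None and flox_target in self.flox_cn:
            return self.flox_cn[flox_target]
        for ev in self.events:
            if ev.chrom == chrom and ev.start <= pos < ev.end:
                return ev.cn
        return self.baseline_cn

    def expected_cnr(self, cn: float) -> float:
        """Purity/ploidy mixture: expected linear CNR for tumor CN ``cn``."""
        p, psi = self.purity, self.ploidy
        return (p * cn + 2.0 * (1.0 - p)) / (p * psi + 2.0 * (1.0 - p))

    def expected_cnr_at(self, chrom: str, pos: int,
                        flox_target: str | None = None) -> float:
        return self.expected_cnr(self.copy_number_at(chrom, pos, flox_target))

    def expected_panel_cnr(self, panel: AmpliconPanel) -> pd.Series:
        df = panel.df
        vals = []
        for _, r in df.iterrows():
            flox = r["target"] if r["target_class"] == "flox" else None
            mid = (r["start"] + r["end"]) // 2
            vals.append(self.expected_cnr_at(r["chrom"], mid, flox))
        return pd.Series(vals, index=df["amplicon"].values, name="cnr")


def simulate_cn_profile(layout: GenomeLayout,
                        events: list[dict] | list[CnEvent] | None = None,
                        flox_cn: dict[str, int] | None = None,
                        purity: float = 1.0,
                        ploidy: float = 2.0) -> TruthProfile:
    """Build a validated :class:`TruthProfile` from event specifications."""
    evs = []
    for ev in events or []:
        if isinstance(ev, CnEvent):
            evs.append(ev)
        else:
            evs.append(CnEvent(chrom=str(ev["chrom"]), start=int(ev["start"]),
                               end=int(ev["end"]), cn=int(ev["cn"])))
    return TruthProfile(layout=layout, events=evs, flox_cn=dict(flox_cn or {}),
                        purity=purity, ploidy=ploidy)


def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Gentle quadratic amplification-efficiency curve peaking near 45% GC."""
    return 1.0 - 1.2 * (np.asarray(gc, dtype=float) - 0.45) ** 2


def panel_efficiencies(panel: AmpliconPanel, sigma: float = 0.25,
                       efficiency_seed: int = 0) -> pd.Series:
    """Log-normal per-amplicon efficiencies, fixed given the efficiency seed."""
    rng = np.random.default_rng(efficiency_seed)
    eff = rng.lognormal(mean=0.0, sigma=sigma, size=len(panel))
    return pd.Series(eff, index=panel.df["amplicon"].values, name="efficiency")


def simulate_read_counts(truth: TruthProfile, panel: AmpliconPanel,
                         sample_ids: list[str] | str = "tumor",
                         mean_depth: float = 500.0,
                         dispersion: float = 0.05,
                         gc_bias=None,
                         seed: int = 0,
                         efficiency_seed: int = 0,
                         efficiency_sigma: float = 0.25,
                         noise: bool = True) -> ReadCountMatrix:
    """Draw an amplicon count matrix for one truth profile.

    With ``noise=False`` the exact expected (float) counts are returned, which
    is the hook for the pipeline's zero-noise identity checks.  ``dispersion``
    is the negative-binomial excess: Var = m + dispersion * m**2 (0 = Poisson).
    """
    if mean_depth <= 0:
        raise SimulationError("mean depth must be positive")
    if dispersion < 0:
        raise SimulationError("dispersion must be >= 0")
    if isinstance(sample_ids, str):
        sample_ids = [sample_ids]
    cnr = truth.expected_panel_cnr(panel).values
    eff = panel_efficiencies(panel, efficiency_sigma, efficiency_seed).values
    gcs = panel.df["gc"].values.astype(float)
    gc_mult = np.ones_like(gcs) if gc_bias is None else np.asarray(
        gc_bias(gcs), dtype=float)
    raw = cnr * eff * gc_mult
    m = raw / raw.mean() * mean_depth
    rng = np.random.default_rng(seed)
    cols = {}
    for sid in sample_ids:
        if not noise:
            cols[sid] = m.copy()
        elif dispersion == 0:
            cols[sid] = rng.poisson(m).astype(float)
        else:
            n = 1.0 / dispersion
            lam = rng.gamma(shape=n, scale=m / n)
            cols[sid] = rng.poisson(lam).astype(float)
    df = pd.DataFrame(cols, index=panel.df["amplicon"].values)
    df.index.name = "amplicon"
    return ReadCountMatrix(df, allow_float=not noise)


def simulate_panel(layout: GenomeLayout, genes_per_chrom: int = 3,
                   amplicons_per_gene: int = 8,
                   flox_targets: dict[str, str] | None = None,
                   n_snps: int = 0, seed: int = 0) -> AmpliconPanel:
    """Toy amplicon panel: tiling genes spread along every chromosome, optional
    flox targets placed inside their parent gene's locus, optional genotyping
    SNP amplicons.

    ``flox_targets`` maps flox-target label -> parent gene (the parent must be
    one of the generated gene names, which are ``g{chrom}_{i}``).
    """
    rng = np.random.default_rng(seed)
    rows = []
    gene_spans: dict[str, tuple[str, int, int]] = {}
    for chrom, length in layout.chrom_lengths.items():
        for i in range(genes_per_chrom):
            gene = f"g{chrom}_{i}"
            # genes spread across the whole chromosome so the panel's per-arm
            # breadth of coverage resembles a real tiling design
            gstart = int((i + 0.5) / (genes_per_chrom + 0.5) * length)
            gene_spans[gene] = (chrom, gstart, gstart + 120 * amplicons_per_gene)
            for k in range(amplicons_per_gene):
                s = gstart + 120 * k
                rows.append({
                    "amplicon": f"{gene}_a{k}", "chrom": chrom, "start": s,
                    "end": s + 100, "target": gene,
                    "target_class": "cn-tiling",
                    "gc": float(np.clip(rng.normal(0.45, 0.08), 0.2, 0.8)),
                    "pool": f"pool{k % 2 + 1}", "flox_parent": "",
                })
    for flox, parent in (flox_targets or {}).items():
        chrom, gstart, gend = gene_spans[parent]
        for k in range(2):
            s = gend + 200 + 120 * k
            rows.append({
                "amplicon": f"{flox}_a{k}", "chrom": chrom, "start": s,
                "end": s + 100, "target": flox, "target_class": "flox",
                "gc": float(np.clip(rng.normal(0.45, 0.08), 0.2, 0.8)),
                "pool": "pool1", "flox_parent": parent,
            })
    chroms = list(layout.chrom_lengths)
    for j in range(n_snps):
        chrom = chroms[j % len(chroms)]
        s = int(rng.integers(0, layout.chrom_lengths[chrom] - 200))
        rows.append({
            "amplicon": f"snp{j}_a", "chrom": chrom, "start": s, "end": s + 100,
            "target": f"rs{j:06d}", "target_class": "genotyping-snp",
            "gc": float(np.clip(rng.normal(0.45, 0.08), 0.2, 0.8)),
            "pool": "pool2", "flox_parent": "",
        })
    return AmpliconPanel(pd.DataFrame(rows))


# ------------------------------------------------------------- genotyping

def simulate_strain_panel(n_strains: int = 5, n_snps: int = 500,
                          divergence: float = 1.0, seed: int = 0,
                          strain_names: list[str] | None = None,
                          layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Inbred reference panel: 0/1 alleles per strain per SNP.

    ``divergence`` is the probability that a SNP carries a non-constant allele
    pattern across the strains (informative); the remainder are monomorphic.
    """
    if strain_names is None:
        strain_names = list(DEFAULT_STRAINS[:n_strains]) if n_strains <= len(
            DEFAULT_STRAINS) else [f"strain{i}" for i in range(n_strains)]
    if len(strain_names) != n_strains:
        raise SimulationError("strain_names length mismatch")
    rng = np.random.default_rng(seed)
    alleles = np.zeros((n_snps, n_strains), dtype=int)
    informative = rng.random(n_snps) < divergence
    for j in np.flatnonzero(informative):
        pat = rng.integers(0, 2, size=n_strains)
        while pat.min() == pat.max():
            pat = rng.integers(0, 2, size=n_strains)
        alleles[j] = pat
    chroms = [str(c) for c in range(1, 20)]
    df = pd.DataFrame({
        "chrom": [chroms[j % len(chroms)] for j in range(n_snps)],
        "pos": [1_500_000 * (j // len(chroms) + 1) + j for j in range(n_snps)],
        "snp": [f"rs{j:06d}" for j in range(n_snps)],
        "ref": "A", "alt": "G",
    })
    for s, name in enumerate(strain_names):
        df[name] = alleles[:, s]
    return df


def strain_columns(panel_df: pd.DataFrame) -> list[str]:
    return [c for c in panel_df.columns
            if c not in ("chrom", "pos", "snp", "ref", "alt")]


@dataclass
class SampleGenotype:
    """Diploid genotypes (alt-allele dosage 0/1/2, NaN = missing)."""

    sample: str
    genotypes: pd.Series

    @property
    def call_rate(self) -> float:
        return float(self.genotypes.notna().mean())


def simulate_f1(panel_df: pd.DataFrame, strain_a: str, strain_b: str,
                missing_rate: float = 0.0, seed: int = 0,
                sample: str | None = None) -> SampleGenotype:
    """F1 offspring: one allele per SNP from each inbred parent."""
    rng = np.random.default_rng(seed)
    g = (panel_df[strain_a] + panel_df[strain_b]).astype(float)
    g.index = panel_df["snp"].values
    if missing_rate > 0:
        g[rng.random(len(g)) < missing_rate] = np.nan
    return SampleGenotype(sample=sample or f"F1({strain_a}x{strain_b})",
                          genotypes=g)


def simulate_admixed(panel_df: pd.DataFrame, proportions: dict[str, float],
                     missing_rate: float = 0.0, seed: int = 0,
                     sample: str = "admixed") -> SampleGenotype:
    """Admixed sample: each of two allele copies drawn independently per SNP
    from a strain chosen with the stated proportions (no linkage)."""
    strains = list(proportions)
    q = np.array([proportions[s] for s in strains], dtype=float)
    if (q < 0).any() or abs(q.sum() - 1.0) > 1e-8:
        raise SimulationError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    alleles = panel_df[strains].values  # n_snps x n_strains
    n = len(panel_df)
    g = np.zeros(n, dtype=float)
    for _ in range(2):
        pick = rng.choice(len(strains), size=n, p=q)
        g += alleles[np.arange(n), pick]
    if missing_rate > 0:
        g[rng.random(n) < missing_rate] = np.nan
    return SampleGenotype(sample=sample,
                          genotypes=pd.Series(g, index=panel_df["snp"].values))


# -------------------------------------------------------------- orthologs

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def simulate_ortholog_pair(length: int, conserved_fraction: float = 1.0,
                           seed: int = 0, cds_start_a: int = 1000,
                           cds_start_b: int = 5000):
    """Ortholog peptide pair with known per-position conservation labels.

    Returns ``(pep_a, cds_a, pep_b, cds_b, conserved)`` where ``conserved`` is
    a boolean array (True = identical residue) and the CDS models are
    single-exon forward-strand models consistent with the peptides.
    """
    from .hotspot import CdsModel

    if length < 29:
        raise SimulationError("length must be >= 29 (window of +/-14)")
    rng = np.random.default_rng(seed)
    a = rng.choice(_AA, size=length)
    b = a.copy()
    conserved = np.ones(length, dtype=bool)
    n_sub = int(round((1.0 - conserved_fraction) * length))
    subs = rng.choice(length, size=n_sub, replace=False)
    for i in subs:
        choices = _AA[_AA != a[i]]
        b[i] = rng.choice(choices)
        conserved[i] = False
    pep_a, pep_b = "".join(a), "".join(b)
    cds_a = CdsModel(transcript_id="txA", strand="+",
                     exons=[(cds_start_a, cds_start_a + 3 * length)],
                     peptide=pep_a)
    cds_b = CdsModel(transcript_id="txB", strand="+",
                     exons=[(cds_start_b, cds_start_b + 3 * length)],
                     peptide=pep_b)
    return pep_a, cds_a, pep_b, cds_b, conserved


# ------------------------------------------------------------- aneuploidy

def simulate_aneuploidy_matrix(n_samples: int, arms: list[str],
                               background_rate: float = 0.0,
                               planted: dict[str, tuple[float, int]] | None = None,
                               seed: int = 0,
                               sample_prefix: str = "S") -> pd.DataFrame:
    """Sample x arm matrix in {-1, 0, +1}: independent Bernoulli background
    events (random direction) plus planted arms with their own rate/direction.
    """
    planted = planted or {}
    for arm, (rate, direction) in planted.items():
        if not (0.0 <= rate <= 1.0) or direction not in (-1, 1):
            raise SimulationError(f"bad planted spec for arm {arm}")
    if not (0.0 <= background_rate <= 1.0):
        raise SimulationError("background rate out of [0, 1]")
    rng = np.random.default_rng(seed)
    mat = np.zeros((n_samples, len(arms)), dtype=int)
    for j, arm in enumerate(arms):
        if arm in planted:
            rate, direction = planted[arm]
            hit = rng.random(n_samples) < rate
            mat[hit, j] = direction
        else:
            hit = rng.random(n_samples) < background_rate
            signs = rng.choice([-1, 1], size=n_samples)
            mat[hit, j] = signs[hit]
    return pd.DataFrame(mat, columns=arms,
                        index=[f"{sample_prefix}{i}" for i in range(n_samples)])


def simulate_segment_cohort(layout: GenomeLayout, n_samples: int,
                            p_event: float = 0.2,
                            arm_fraction: tuple[float, float] = (0.85, 1.0),
                            mean_log2cnr: float = 0.58,
                            seed: int = 0) -> dict[str, list[Segment]]:
    """Per-sample segment lists with planted arm-scale events.

    Each arm independently carries an event with probability ``p_event``; the
    event covers a uniform fraction of the arm (anchored at a random end) with
    random direction, emulating a perfect segmentation of the true profile.
    """
    rng = np.random.default_rng(seed)
    cohort: dict[str, list[Segment]] = {}
    for i in range(n_samples):
        segs: list[Segment] = []
        for a in layout.arms:
            if rng.random() >= p_event:
                continue
            frac = rng.uniform(*arm_fraction)
            span = max(1, int(round(frac * a.length)))
            if rng.random() < 0.5:
                s, e = a.start, a.start + span
            else:
                s, e = a.end - span, a.end
            direction = int(rng.choice([-1, 1]))
            segs.append(Segment(chrom=a.chrom, start=s, end=e,
                                n_markers=max(2, span // 10_000_000),
                                mean_log2cnr=direction * mean_log2cnr,
                                z=direction * 10.0, q=0.0, state=direction))
        cohort[f"S{i}"] = segs
    return cohort
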