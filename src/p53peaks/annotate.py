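"""Correlation of peak maxima with genes, TSSs, CpG islands and repeats.

Every association is a pure function of the peak maximum (a single base) and
the annotation, under fixed distance rules: gene proximity spans 20 kb
upstream of the TSS through 5 kb past the TES; CpG-island association extends
island boundaries by 350 nt (half the average chromatin-fragment size);
repeat association requires the maximum strictly inside the element.  The
genic classification bins a peak by its strand-oriented distance to the TSS,
falling back to exon/intron structure only beyond 5 kb downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    CpgIsland,
    FeatureIndex,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    RepeatElement,
    REPEAT_CLASSES,
    OTHER_CLASS,
    ValidationError,
)
from .peaks import Peak, PeakSet

UPSTREAM_BINS = (
    ("20-10 kb to TSS", 10_000, 20_000),
    ("10-5 kb to TSS", 5_000, 10_000),
    ("5-2 kb to TSS", 2_000, 5_000),
    ("2-1 kb to TSS", 1_000, 2_000),
    ("1 kb to TSS", 0, 1_000),
)
DOWNSTREAM_BINS = (
    ("TSS to 1 kb down", 0, 1_000),
    ("1-2 kb down TSS", 1_000, 2_000),
    ("2-5 kb down TSS", 2_000, 5_000),
)
GENIC_BIN_LABELS = (
    [label for label, *_ in UPSTREAM_BINS]
    + [label for label, *_ in DOWNSTREAM_BINS]
    + ["intron 1", "intron >1", "exon", "5 kb down TES", "unassigned"]
)

DEFAULT_UPSTREAM_LIMIT = 20_000
DEFAULT_TES_DOWNSTREAM = 5_000
DEFAULT_CGI_SLOP = 350
DEFAULT_FRAGMENT_SIZE = 700


def _tss_distance(gene: GeneModel, pos: int) -> int:
    """Strand-oriented signed distance from TSS; negative = upstream."""
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def _tes_distance(gene: GeneModel, pos: int) -> int:
    """Strand-oriented signed distance past the TES; positive = downstream."""
    return pos - gene.tes if gene.strand == "+" else gene.tes - pos


def gene_qualifies(gene: GeneModel, pos: int,
                   upstream_limit: int = DEFAULT_UPSTREAM_LIMIT,
                   tes_downstream: int = DEFAULT_TES_DOWNSTREAM) -> bool:
    """Proximity rule: within ``upstream_limit`` bp upstream of the TSS,
    inside the gene, or up to ``tes_downstream`` bp past the TES."""
    if gene.interval.contains(pos):
        return True
    d_tss = _tss_distance(gene, pos)
    if d_tss < 0 and -d_tss <= upstream_limit:
        return True
    d_tes = _tes_distance(gene, pos)
    return 0 < d_tes <= tes_downstream


def gene_proximity(
    maximum: tuple[str, int] | Peak,
    genes: Sequence[GeneModel] | FeatureIndex,
    upstream_limit: int = DEFAULT_UPSTREAM_LIMIT,
    tes_downstream: int = DEFAULT_TES_DOWNSTREAM,
) -> tuple[str, list[GeneModel]]:
    """Classify a maximum as close to {none, single, multiple} genes."""
    chrom, pos = _chrom_pos(maximum)
    near = [
        g
        for g in _candidate_genes(genes, chrom, pos, upstream_limit + tes_downstream)
        if g.interval.chrom == chrom and gene_qualifies(g, pos, upstream_limit, tes_downstream)
    ]
    ids = {g.gene_id for g in near}
    if not ids:
        return "none", []
    return ("single" if len(ids) == 1 else "multiple"), near


def _chrom_pos(maximum) -> tuple[str, int]:
    if isinstance(maximum, Peak):
        return maximum.region.chrom, maximum.maximum
    return maximum


def _candidate_genes(genes, chrom, pos, slop):
    if isinstance(genes, FeatureIndex):
        # index must have been built with at least this slop
        return genes.query(chrom, pos)
    return genes


def build_gene_index(genes: Sequence[GeneModel],
                     upstream_limit: int = DEFAULT_UPSTREAM_LIMIT,
                     tes_downstream: int = DEFAULT_TES_DOWNSTREAM) -> FeatureIndex:
    """Index genes with enough slop that any qualifying gene is retrieved."""
    return FeatureIndex(genes, slop=max(upstream_limit, tes_downstream))


def classify_genic_bin(
    maximum: tuple[str, int] | Peak,
    genes: Sequence[GeneModel] | FeatureIndex,
    upstream_limit: int = DEFAULT_UPSTREAM_LIMIT,
    tes_downstream: int = DEFAULT_TES_DOWNSTREAM,
) -> str:
    """Assign the peak maximum to one genic bin of its nearest-TSS gene.

    Within 5 kb downstream of the TSS the distance bins win regardless of
    exon/intron context; beyond that, containment decides exon / intron 1 /
    intron >1, and positions up to 5 kb past the TES map to the TES bin.
    """
    chrom, pos = _chrom_pos(maximum)
    _, near = gene_proximity((chrom, pos), genes, upstream_limit, tes_downstream)
    if not near:
        return "unassigned"
    gene = min(near, key=lambda g: (abs(_tss_distance(g, pos)), g.gene_id))
    d = _tss_distance(gene, pos)
    if d < 0:
        up = -d
        for label, lo, hi in UPSTREAM_BINS:
            if lo < up <= hi:
                return label
        return "unassigned"
    if d <= 5_000:
        for label, lo, hi in DOWNSTREAM_BINS:
            if lo <= d < hi or (d == 5_000 and label == "2-5 kb down TSS"):
                return label
    if gene.interval.contains(pos):
        if gene.in_exon(pos):
            return "exon"
        intron = gene.intron_number(pos)
        if intron == 1:
            return "intron 1"
        if intron is not None:
            return "intron >1"
        return "unassigned"
    d_tes = _tes_distance(gene, pos)
    if 0 < d_tes <= tes_downstream:
        return "5 kb down TES"
    return "unassigned"


def cgi_association(
    maximum: tuple[str, int] | Peak,
    cgis: Sequence[CpgIsland] | FeatureIndex,
    slop: int = DEFAULT_CGI_SLOP,
) -> bool:
    """True iff the maximum lies within island boundaries extended by
    ``slop`` nt on both sides (half-open after extension)."""
    chrom, pos = _chrom_pos(maximum)
    if isinstance(cgis, FeatureIndex):
        return any(c.interval.chrom == chrom for c in cgis.query(chrom, pos))
    for c in cgis:
        iv = c.interval
        if iv.chrom == chrom and iv.start - slop <= pos < iv.end + slop:
            return True
    return False


def repeat_association(
    maximum: tuple[str, int] | Peak,
    repeats: Sequence[RepeatElement] | FeatureIndex,
) -> RepeatElement | None:
    """The repeat element containing the maximum, or None.  When nested
    elements both contain it, the shortest (most specific) wins."""
    chrom, pos = _chrom_pos(maximum)
    if isinstance(repeats, FeatureIndex):
        hits = [r for r in repeats.query(chrom, pos) if r.interval.contains(pos)]
    else:
        hits = [
            r
            for r in repeats
            if r.interval.chrom == chrom and r.interval.contains(pos)
        ]
    if not hits:
        return None
    return min(hits, key=lambda r: (len(r.interval), r.interval.start))


def tss_distance_profile(
    peaks: Iterable[Peak],
    genes: Sequence[GeneModel],
    window: int = 10_000,
    bin_size: int = 200,
) -> pd.DataFrame:
    """Histogram of signed TSS − maximum distances within ±window/2, pooled
    over peaks; every TSS near a peak is counted."""
    if window % 2:
        raise ValidationError("window must be even")
    half = window // 2
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.interval.chrom, [])
    for g in genes:
        tss_by_chrom[g.interval.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    distances = []
    for p in peaks:
        chrom, pos = _chrom_pos(p)
        tss = tss_by_chrom.get(chrom)
        if tss is None or not len(tss):
            continue
        lo = np.searchsorted(tss, pos - half, side="left")
        hi = np.searchsorted(tss, pos + half, side="right")
        distances.extend((tss[lo:hi] - pos).tolist())
    edges = np.arange(-half, half + bin_size, bin_size)
    counts, _ = np.histogram(distances, bins=edges)
    return pd.DataFrame({"distance_bin": edges[:-1], "count": counts})


@dataclass
class RandomControlSet:
    """A Monte-Carlo control set; shares the PeakSet iteration surface but,
    unlike called peaks, its intervals may overlap each other."""

    label: str
    assembly: GenomeAssembly
    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def random_locations(
    n: int,
    assembly: GenomeAssembly,
    fragment_size: int = DEFAULT_FRAGMENT_SIZE,
    seed: int = 0,
) -> PeakSet:
    """Monte-Carlo control: ``n`` uniform genomic points (chromosome chosen
    proportional to length), each extended to a fragment-sized interval
    centered on the point; points whose fragment would overhang a chromosome
    edge are resampled."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(assembly.chrom_sizes)
    lengths = np.array([assembly.chrom_sizes[c] for c in chroms], dtype=np.float64)
    p = lengths / lengths.sum()
    half = fragment_size // 2
    peaks = []
    while len(peaks) < n:
        ci = int(rng.choice(len(chroms), p=p))
        pos = int(rng.integers(0, int(lengths[ci])))
        start, end = pos - half, pos + (fragment_size - half)
        if start < 0 or end > lengths[ci]:
            continue  # overhanging fragment: resample
        peaks.append(
            Peak(
                GenomicInterval(chroms[ci], start, end),
                pos,
                1.0,
                conf_enrichment=1.0,
                conf_background=1.0,
            )
        )
    peaks.sort(key=lambda q: (q.region.chrom, q.region.start))
    return RandomControlSet("random", assembly, peaks)


def chromosome_density(
    peaks: PeakSet,
    chrom: str,
    bandwidth: float = 2e6,
    grid_step: int = 100_000,
    height_weighted: bool = True,
) -> pd.DataFrame:
    """Gaussian-kernel density of peak maxima along one chromosome.

    Weights are proportional to peak height (normalized to sum 1); values are
    scaled per Mb, so the density integrates to ~1 over the chromosome when
    the kernels' mass lies inside it.
    """
    maxima = np.array(
        [p.maximum for p in peaks if p.region.chrom == chrom], dtype=np.float64
    )
    if not len(maxima):
        return pd.DataFrame({"position": [], "density_per_mb": []})
    if height_weighted:
        w = np.array([p.height for p in peaks if p.region.chrom == chrom])
    else:
        w = np.ones_like(maxima)
    w = w / w.sum()
    length = peaks.assembly.chrom_sizes[chrom]
    grid = np.arange(0, length + grid_step, grid_step, dtype=np.float64)
    z = (grid[:, None] - maxima[None, :]) / bandwidth
    dens = (np.exp(-0.5 * z**2) / (bandwidth * np.sqrt(2 * np.pi))) @ w
    return pd.DataFrame({"position": grid.astype(int), "density_per_mb": dens * 1e6})


def write_bedgraph(profile: pd.DataFrame, chrom: str, grid_step: int,
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in profile.itertuples(index=False):
            fh.write(
                f"{chrom}\t{int(row.position)}\t{int(row.position) + grid_step}\t"
                f"{row.density_per_mb:.6g}\n"
            )


@dataclass
class AnnotationReport:
    """Per-dataset association fractions across the annotation landscape."""

    fractions: pd.DataFrame       # dataset x {single, multiple, no_gene, in_cgi, in_repeats}
    repeat_classes: pd.DataFrame  # dataset x repeat class fractions
    genic_bins: pd.DataFrame      # dataset x genic-bin fractions

    def write_tsv(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        self.fractions.to_csv(out_dir / "fractions.tsv", sep="\t")
        self.repeat_classes.to_csv(out_dir / "repeat_classes.tsv", sep="\t")
        self.genic_bins.to_csv(out_dir / "genic_bins.tsv", sep="\t")

    def to_json_dict(self) -> dict:
        return {
            "fractions": self.fractions.to_dict(orient="index"),
            "repeat_classes": self.repeat_classes.to_dict(orient="index"),
            "genic_bins": self.genic_bins.to_dict(orient="index"),
        }


def annotate_peakset(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    cgis: Sequence[CpgIsland],
    repeats: Sequence[RepeatElement],
    cgi_slop: int = DEFAULT_CGI_SLOP,
    upstream_limit: int = DEFAULT_UPSTREAM_LIMIT,
    tes_downstream: int = DEFAULT_TES_DOWNSTREAM,
) -> pd.DataFrame:
    """Per-peak annotation table: proximity class, genic bin, CGI flag,
    repeat class."""
    gene_index = build_gene_index(genes, upstream_limit, tes_downstream)
    cgi_index = FeatureIndex(cgis, slop=cgi_slop)
    repeat_index = FeatureIndex(repeats)
    rows = []
    for p in peaks:
        prox, _ = gene_proximity(p, gene_index, upstream_limit, tes_downstream)
        rep = repeat_association(p, repeat_index)
        rows.append(
            {
                "chrom": p.region.chrom,
                "maximum": p.maximum,
                "height": p.height,
                "proximity": prox,
                "genic_bin": classify_genic_bin(
                    p, gene_index, upstream_limit, tes_downstream
                ),
                "in_cgi": cgi_association(p, cgi_index, cgi_slop),
                "repeat_class": rep.repeat_class if rep else "none",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "maximum",
            "height",
            "proximity",
            "genic_bin",
            "in_cgi",
            "repeat_class",
        ],
    )


def summarize(
    peaksets: Mapping[str, PeakSet],
    genes: Sequence[GeneModel],
    cgis: Sequence[CpgIsland],
    repeats: Sequence[RepeatElement],
    cgi_slop: int = DEFAULT_CGI_SLOP,
    upstream_limit: int = DEFAULT_UPSTREAM_LIMIT,
    tes_downstream: int = DEFAULT_TES_DOWNSTREAM,
) -> AnnotationReport:
    """Multi-dataset summary: gene proximity / CGI / repeat fractions, the
    repeat-class breakdown, and genic-bin fractions.  Empty sets report NA."""
    classes = list(REPEAT_CLASSES) + [OTHER_CLASS]
    frac_rows, class_rows, bin_rows = {}, {}, {}
    for label, ps in peaksets.items():
        table = annotate_peakset(
            ps, genes, cgis, repeats, cgi_slop, upstream_limit, tes_downstream
        )
        n = len(table)
        if n == 0:
            frac_rows[label] = {
                k: np.nan
                for k in (
                    "close_to_single_gene",
                    "close_to_multiple_genes",
                    "no_gene",
                    "in_cgi",
                    "in_repeats",
                )
            }
            class_rows[label] = {c: np.nan for c in classes}
            bin_rows[label] = {b: np.nan for b in GENIC_BIN_LABELS}
            continue
        frac_rows[label] = {
            "close_to_single_gene": (table["proximity"] == "single").mean(),
            "close_to_multiple_genes": (table["proximity"] == "multiple").mean(),
            "no_gene": (table["proximity"] == "none").mean(),
            "in_cgi": table["in_cgi"].mean(),
            "in_repeats": (table["repeat_class"] != "none").mean(),
        }
        class_rows[label] = {
            c: (table["repeat_class"] == c).mean() for c in classes
        }
        bin_rows[label] = {
            b: (table["genic_bin"] == b).mean() for b in GENIC_BIN_LABELS
        }
    return AnnotationReport(
        pd.DataFrame.from_dict(frac_rows, orient="index"),
        pd.DataFrame.from_dict(class_rows, orient="index"),
        pd.DataFrame.from_dict(bin_rows, orient="index"),
    )
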