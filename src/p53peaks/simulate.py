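"""Synthetic genomes, annotations, and ChIP/Input tag sets with planted truth.

The generator builds a desk-scale genome (default 2 chromosomes x 2.5 Mb)
with non-overlapping genes, promoter CpG islands, and repeat elements placed
to hit per-class bp-fraction targets.  Response-element consensus sequences
are planted at sites chosen by feature context (e.g. inside LINE elements, at
CpG islands, or uniformly), and tags are drawn from a piecewise-constant
intensity: the Input track carries class-specific biases (satellite
over-representation, SINE/LINE/LTR under-representation relative to random),
and the ChIP track multiplies the same intensity by a local enrichment factor
at each planted site.  Everything is a deterministic function of
(config, seed), and every planted site records its feature context, so each
pipeline stage can be tested against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import (
    CpgIsland,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    RepeatElement,
    ValidationError,
    write_bed,
    write_chrom_sizes,
    write_gene_table,
    write_repeat_table,
)
from .peaks import write_tags

CONSENSUS_SITE = "GGGCATGCCC" * 2  # perfect RRRCWWGYYY x2, spacer 0

# typical element lengths (bp) per repeat class
_REPEAT_LENGTHS = {
    "SINE": (250, 350),
    "LINE": (1500, 6000),
    "LTR": (500, 1200),
    "Satellite": (1000, 3000),
    "Simple": (100, 300),
    "Low_complexity": (100, 300),
    "DNA": (200, 800),
    "RNA": (80, 150),
}
_REPEAT_FAMILIES = {
    "SINE": ("Alu", "MIR"),
    "LINE": ("L1", "L2"),
    "LTR": ("ERV1", "ERVL"),
    "Satellite": ("centr",),
    "Simple": ("",),
    "Low_complexity": ("",),
    "DNA": ("hAT-Charlie",),
    "RNA": ("tRNA",),
}


def _default_chrom_sizes() -> dict[str, int]:
    return {"chrS1": 2_500_000, "chrS2": 2_500_000}


def _default_repeat_fractions() -> dict[str, float]:
    return {
        "SINE": 0.10,
        "LINE": 0.20,
        "LTR": 0.08,
        "Satellite": 0.02,
        "Simple": 0.02,
        "Low_complexity": 0.02,
    }


def _default_input_bias() -> dict[str, float]:
    # Input chromatin biases relative to random: satellites over-represented,
    # SINE/LINE/LTR under-represented.
    return {"Satellite": 2.5, "SINE": 0.6, "LINE": 0.6, "LTR": 0.6}


def _default_context_weights() -> dict[str, float]:
    return {"random": 1.0}


@dataclass
class SyntheticConfig:
    """Full description of one synthetic study; (config, seed) determines all
    outputs.  Library sizes default to ~30x mean fragment coverage on the
    5 Mb toy genome."""

    name: str = "default"
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_genes: int = 150
    cgi_at_promoter_prob: float = 0.6
    repeat_fractions: dict[str, float] = field(
        default_factory=_default_repeat_fractions
    )
    n_planted_sites: int = 200
    site_context_weights: dict[str, float] = field(
        default_factory=_default_context_weights
    )
    enrichment: float = 8.0
    chip_library_size: int = 214_000
    input_library_size: int = 214_000
    fragment_size: int = 700
    tag_len: int = 36
    input_bias: dict[str, float] = field(default_factory=_default_input_bias)
    min_site_separation: int = 3_000
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.repeat_fractions.values()) > 1.0:
            raise ValidationError("repeat fractions sum above 1")
        if any(v <= 0 for v in self.input_bias.values()):
            raise ValidationError("bias multipliers must be > 0")
        if self.enrichment <= 0:
            raise ValidationError("enrichment must be > 0")
        if self.chip_library_size <= 0 or self.input_library_size <= 0:
            raise ValidationError("library sizes must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def scenario(name: str) -> SyntheticConfig:
    """Documented presets for the study's qualitative contrasts.

    ``hct116_like`` plants extra sites inside LINE elements and none at CpG
    islands; ``imr90_like`` plants extra sites at CpG islands and
    low-complexity repeats; ``null`` plants nothing.  The context weights are
    chosen so the expected LINE fraction of recovered peaks is about twice as
    large in the hct116-like run as in the imr90-like run.
    """
    if name == "null":
        return SyntheticConfig(name="null", n_planted_sites=0)
    if name == "hct116_like":
        return SyntheticConfig(
            name="hct116_like",
            site_context_weights={"LINE": 0.30, "random": 0.70},
        )
    if name == "imr90_like":
        # expected LINE fraction = 0.06 + (0.52 + 0.30) x 0.20 (random/CGI
        # sites landing in LINE bp) = 0.224, half the hct116-like 0.44
        return SyntheticConfig(
            name="imr90_like",
            site_context_weights={
                "CGI": 0.30,
                "Low_complexity": 0.12,
                "LINE": 0.06,
                "random": 0.52,
            },
        )
    raise ValueError(f"unknown scenario {name!r}")


@dataclass(frozen=True)
class PlantedSite:
    """Truth record for one planted response element."""

    chrom: str
    midpoint: int
    interval: GenomicInterval
    enrichment: float
    context: str


@dataclass
class SyntheticTruth:
    sites: list[PlantedSite]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [
                    {
                        "chrom": s.chrom,
                        "midpoint": s.midpoint,
                        "start": s.interval.start,
                        "end": s.interval.end,
                        "enrichment": s.enrichment,
                        "context": s.context,
                    }
                    for s in self.sites
                ],
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            records = json.load(fh)
        return cls(
            [
                PlantedSite(
                    r["chrom"],
                    r["midpoint"],
                    GenomicInterval(r["chrom"], r["start"], r["end"]),
                    r["enrichment"],
                    r["context"],
                )
                for r in records
            ]
        )


@dataclass
class SyntheticGenome:
    """One generated study: genome, annotations, sequence and planted truth."""

    config: SyntheticConfig
    assembly: GenomeAssembly
    genes: list[GeneModel]
    cgis: list[CpgIsland]
    repeats: list[RepeatElement]
    sequences: dict[str, str]
    truth: SyntheticTruth

    def repeat_bp_fraction(self) -> float:
        """Union bp fraction of repeats (elements are placed disjointly)."""
        total = sum(len(r.interval) for r in self.repeats)
        return total / self.assembly.total_length

    def write_all(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "chrom_sizes": out_dir / "chrom.sizes",
            "genes": out_dir / "genes.tsv",
            "cgis": out_dir / "cgi.bed",
            "repeats": out_dir / "repeats.tsv",
            "fasta": out_dir / "genome.fa",
            "truth": out_dir / "truth.json",
            "config": out_dir / "config.yaml",
        }
        write_chrom_sizes(self.assembly, paths["chrom_sizes"])
        write_gene_table(self.genes, paths["genes"])
        write_bed([c.interval for c in self.cgis], paths["cgis"])
        write_repeat_table(self.repeats, paths["repeats"])
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        self.truth.to_json(paths["truth"])
        self.config.to_yaml(paths["config"])
        return paths


class _Occupancy:
    """Sorted disjoint intervals per chromosome with overlap rejection."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        import bisect

        ivs = self._by_chrom.get(chrom, [])
        i = bisect.bisect_left(ivs, (start, start))
        if i > 0 and ivs[i - 1][1] > start:
            return False
        if i < len(ivs) and ivs[i][0] < end:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        import bisect

        ivs = self._by_chrom.setdefault(chrom, [])
        bisect.insort(ivs, (start, end))


def _pick_chrom(rng: np.random.Generator, assembly: GenomeAssembly) -> str:
    chroms = list(assembly.chrom_sizes)
    lengths = np.array([assembly.chrom_sizes[c] for c in chroms], dtype=float)
    return chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]


def _place_genes(
    cfg: SyntheticConfig, rng: np.random.Generator, assembly: GenomeAssembly
) -> list[GeneModel]:
    occupancy = _Occupancy()
    genes = []
    attempts = 0
    while len(genes) < cfg.n_genes and attempts < cfg.n_genes * 200:
        attempts += 1
        chrom = _pick_chrom(rng, assembly)
        length = assembly.chrom_sizes[chrom]
        n_exons = int(rng.integers(3, 9))
        exon_lens = rng.integers(100, 500, size=n_exons)
        intron_lens = rng.integers(500, 5000, size=n_exons - 1)
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        start = int(rng.integers(1000, length - gene_len - 1000))
        if not occupancy.free(chrom, start - 500, start + gene_len + 500):
            continue
        occupancy.add(chrom, start - 500, start + gene_len + 500)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for i in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        genes.append(
            GeneModel(
                f"gene{len(genes):04d}",
                GenomicInterval(chrom, start, start + gene_len, strand),
                strand,
                tuple(exons),
            )
        )
    return genes


def _place_cgis(
    cfg: SyntheticConfig, rng: np.random.Generator, genes: Sequence[GeneModel]
) -> list[CpgIsland]:
    cgis = []
    for g in genes:
        if rng.random() >= cfg.cgi_at_promoter_prob:
            continue
        width = int(rng.integers(600, 1400))
        # island straddles the promoter region around the TSS
        if g.strand == "+":
            start = g.tss - width // 2
        else:
            start = g.tss - width // 2
        start = max(0, start)
        cgis.append(CpgIsland(GenomicInterval(g.interval.chrom, start, start + width)))
    return cgis


def _place_repeats(
    cfg: SyntheticConfig, rng: np.random.Generator, assembly: GenomeAssembly
) -> list[RepeatElement]:
    occupancy = _Occupancy()
    repeats = []
    genome_len = assembly.total_length
    counter = 0
    for cls, target in cfg.repeat_fractions.items():
        lo, hi = _REPEAT_LENGTHS[cls]
        families = _REPEAT_FAMILIES[cls]
        placed = 0
        target_bp = target * genome_len
        attempts = 0
        while placed < target_bp - 0.002 * genome_len and attempts < 500_000:
            attempts += 1
            chrom = _pick_chrom(rng, assembly)
            length = assembly.chrom_sizes[chrom]
            rep_len = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, length - rep_len))
            if not occupancy.free(chrom, start, start + rep_len):
                continue
            occupancy.add(chrom, start, start + rep_len)
            family = families[int(rng.integers(0, len(families)))]
            name = f"{cls.lower()}{counter}"
            counter += 1
            repeats.append(
                RepeatElement(
                    GenomicInterval(chrom, start, start + rep_len), name, cls, family
                )
            )
            placed += rep_len
    repeats.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return repeats


def _plant_sites(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    assembly: GenomeAssembly,
    cgis: Sequence[CpgIsland],
    repeats: Sequence[RepeatElement],
) -> list[PlantedSite]:
    if cfg.n_planted_sites == 0:
        return []
    contexts = list(cfg.site_context_weights)
    weights = np.array([cfg.site_context_weights[c] for c in contexts], dtype=float)
    weights = weights / weights.sum()
    # deterministic per-context counts: largest-remainder apportionment, so
    # the realized context mix always matches the configured weights
    raw = weights * cfg.n_planted_sites
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in order[: cfg.n_planted_sites - counts.sum()]:
        counts[i] += 1
    hosts_by_class: dict[str, list[RepeatElement]] = {}
    for r in repeats:
        hosts_by_class.setdefault(r.repeat_class, []).append(r)
    placed: list[PlantedSite] = []

    def far_enough(chrom: str, mid: int) -> bool:
        return all(
            s.chrom != chrom or abs(s.midpoint - mid) >= cfg.min_site_separation
            for s in placed
        )

    edge = 1_500
    half = len(CONSENSUS_SITE) // 2
    for context, n_context in zip(contexts, counts):
        for _ in range(int(n_context)):
            mid = None
            for _attempt in range(500):
                if context == "random":
                    chrom = _pick_chrom(rng, assembly)
                    cand = int(rng.integers(edge, assembly.chrom_sizes[chrom] - edge))
                elif context == "CGI":
                    if not cgis:
                        break
                    island = cgis[int(rng.integers(0, len(cgis)))]
                    iv = island.interval
                    chrom = iv.chrom
                    cand = int(rng.integers(iv.start + len(iv) // 4,
                                            iv.end - len(iv) // 4))
                else:  # a repeat class: plant well inside the element
                    hosts = hosts_by_class.get(context, [])
                    if not hosts:
                        break
                    host = hosts[int(rng.integers(0, len(hosts)))]
                    iv = host.interval
                    chrom = iv.chrom
                    margin = min(150, max(20, (len(iv) - 30) // 2))
                    cand = int(rng.integers(iv.start + margin, iv.end - margin))
                if cand < edge or cand > assembly.chrom_sizes[chrom] - edge:
                    continue
                if far_enough(chrom, cand):
                    mid = cand
                    break
            if mid is None:
                raise ValidationError(
                    f"could not place a {context!r} site after 500 attempts"
                )
            placed.append(
                PlantedSite(
                    chrom,
                    mid,
                    GenomicInterval(chrom, mid - half, mid + half),
                    cfg.enrichment,
                    context,
                )
            )
    placed.sort(key=lambda s: (s.chrom, s.midpoint))
    return placed


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[rng.integers(0, 4, size=length)]


def generate_annotation(cfg: SyntheticConfig) -> SyntheticGenome:
    """Generate the genome, annotation tables, sequence and planted truth."""
    assembly = GenomeAssembly(cfg.name, dict(cfg.chrom_sizes))
    rng = np.random.default_rng([cfg.seed, 11])
    genes = _place_genes(cfg, rng, assembly)
    cgis = _place_cgis(cfg, rng, genes)
    repeats = _place_repeats(cfg, rng, assembly)
    sites = _plant_sites(cfg, rng, assembly, cgis, repeats)
    sequences = {}
    site_bytes = np.frombuffer(CONSENSUS_SITE.encode(), dtype=np.uint8)
    for chrom, length in assembly.chrom_sizes.items():
        seq = _random_sequence(rng, length)
        for s in sites:
            if s.chrom == chrom:
                seq[s.interval.start : s.interval.end] = site_bytes
        sequences[chrom] = seq.tobytes().decode()
    return SyntheticGenome(
        cfg, assembly, genes, cgis, repeats, sequences, SyntheticTruth(sites)
    )


def _intensity(
    cfg: SyntheticConfig,
    genome: SyntheticGenome,
    chrom: str,
    enriched: bool,
) -> np.ndarray:
    length = genome.assembly.chrom_sizes[chrom]
    w = np.ones(length, dtype=np.float64)
    for r in genome.repeats:
        if r.interval.chrom != chrom:
            continue
        bias = cfg.input_bias.get(r.repeat_class)
        if bias is not None:
            w[r.interval.start : r.interval.end] *= bias
    if enriched:
        half = cfg.fragment_size // 2
        for s in genome.truth.sites:
            if s.chrom == chrom:
                lo = max(0, s.midpoint - half)
                hi = min(length, s.midpoint + half)
                w[lo:hi] *= s.enrichment
    return w


def _sample_tags(
    cfg: SyntheticConfig,
    genome: SyntheticGenome,
    rng: np.random.Generator,
    library_size: int,
    enriched: bool,
) -> pd.DataFrame:
    """Draw fragment centers from the intensity, then emit tag 5' positions on
    either fragment end so + tags flank sites from the left and − tags from
    the right."""
    chroms = list(genome.assembly.chrom_sizes)
    weights = {c: _intensity(cfg, genome, c, enriched) for c in chroms}
    totals = np.array([weights[c].sum() for c in chroms])
    counts = rng.multinomial(library_size, totals / totals.sum())
    frames = []
    frag, tag_len = cfg.fragment_size, cfg.tag_len
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        cdf = np.cumsum(weights[chrom])
        centers = np.searchsorted(cdf, rng.random(n) * cdf[-1])
        length = genome.assembly.chrom_sizes[chrom]
        starts = np.clip(centers - frag // 2, 0, length - frag)
        plus = rng.random(n) < 0.5
        pos = np.where(plus, starts, starts + frag - tag_len)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "strand": np.where(plus, "+", "-"),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(
        drop=True
    )


def simulate_tags(
    cfg: SyntheticConfig, genome: SyntheticGenome
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ChIP and Input tag frames (chrom, pos, strand), both seeded from the
    config; total emitted tags equal the configured library sizes."""
    rng_chip = np.random.default_rng([cfg.seed, 21])
    rng_input = np.random.default_rng([cfg.seed, 22])
    chip = _sample_tags(cfg, genome, rng_chip, cfg.chip_library_size, enriched=True)
    inp = _sample_tags(cfg, genome, rng_input, cfg.input_library_size, enriched=False)
    return chip, inp


def write_tag_files(
    chip: pd.DataFrame, inp: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chip_tags": out_dir / "chip_tags.tsv",
        "input_tags": out_dir / "input_tags.tsv",
    }
    write_tags(chip, paths["chip_tags"])
    write_tags(inp, paths["input_tags"])
    return paths
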