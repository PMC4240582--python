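"""Cross-dataset comparison: peak–peak overlap, PET-cluster overlap by rank,
CGI stratification, and peak-height correlation at common sites.

Two peak sets are compared by a maximum-in-extended-region rule: a peak of
set A matches a peak of set B when A's maximum lies within B's region
extended by 350 nt (half the average chromatin-fragment size) on both sides,
and pairing is one-to-one by nearest maxima.  The same 350 nt rule, applied
to cluster boundaries, reports which ChIP-PET clusters of each rank are
identified by a peak set.  Common-site heights are normalized to percent of
the highest peak in each set before computing the squared Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import CpgIsland, FeatureIndex, GenomicInterval, ParseError, ValidationError
from .peaks import Peak, PeakSet
from .annotate import cgi_association, DEFAULT_CGI_SLOP

DEFAULT_SLOP = 350


@dataclass(frozen=True)
class PetCluster:
    """A ChIP-PET cluster; rank = number of overlapping PET fragments, so the
    PET(n+1)+ set is nested inside PETn+."""

    interval: GenomicInterval
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError("PET rank must be >= 1")


def read_pet_clusters(path: str | Path) -> list[PetCluster]:
    """BED + rank column: chrom, start, end, rank."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            out.append(
                PetCluster(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                    int(parts[3]),
                )
            )
    return out


@dataclass
class CommonPeakPair:
    """A matched peak pair with heights as percent of each set's maximum."""

    peak_a: Peak
    peak_b: Peak
    height_a_pct: float
    height_b_pct: float


def _candidate_pairs(a_peaks: Sequence[Peak], b_peaks: Sequence[Peak], slop: int):
    """All (i, j, |Δmaximum|) with A_i's maximum in B_j's extended region."""
    by_chrom: dict[str, list[int]] = {}
    for j, pb in enumerate(b_peaks):
        by_chrom.setdefault(pb.region.chrom, []).append(j)
    cands = []
    for i, pa in enumerate(a_peaks):
        for j in by_chrom.get(pa.region.chrom, []):
            pb = b_peaks[j]
            if pb.region.start - slop <= pa.maximum < pb.region.end + slop:
                cands.append((abs(pa.maximum - pb.maximum), i, j))
    return cands


def overlap_peaksets(
    a: PeakSet | Iterable[Peak],
    b: PeakSet | Iterable[Peak],
    slop: int = DEFAULT_SLOP,
) -> list[CommonPeakPair]:
    """One-to-one pairing of A peaks with B peaks.

    A peak of A is pairable with a B peak whose slop-extended region contains
    A's maximum; conflicts resolve greedily by smallest maximum-to-maximum
    distance (then input order), so each peak joins at most one pair.
    """
    a_peaks, b_peaks = list(a), list(b)
    cands = sorted(_candidate_pairs(a_peaks, b_peaks, slop))
    max_a = max((p.height for p in a_peaks), default=0.0)
    max_b = max((p.height for p in b_peaks), default=0.0)
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(
            CommonPeakPair(
                a_peaks[i],
                b_peaks[j],
                100.0 * a_peaks[i].height / max_a if max_a else np.nan,
                100.0 * b_peaks[j].height / max_b if max_b else np.nan,
            )
        )
    pairs.sort(key=lambda pr: (pr.peak_a.region.chrom, pr.peak_a.region.start))
    return pairs


def overlap_fraction(a, b, slop: int = DEFAULT_SLOP) -> float:
    """Fraction of A peaks matched in B."""
    a_peaks = list(a)
    if not a_peaks:
        return float("nan")
    return len(overlap_peaksets(a_peaks, b, slop)) / len(a_peaks)


def overlap_percent_rounded(n_common: int, n_total: int, multiple: int = 5) -> int:
    """Overlap as a percentage rounded to the nearest ``multiple``."""
    return multiple * round(100.0 * n_common / n_total / multiple)


def overlap_with_pet(
    peaks: PeakSet | Iterable[Peak],
    clusters: Sequence[PetCluster],
    slop: int = DEFAULT_SLOP,
    max_rank: int = 7,
) -> pd.DataFrame:
    """For each rank n, the fraction of PETn+ clusters identified by a peak,
    i.e. having >= 1 peak maximum within ``slop`` nt of the cluster
    boundaries.  Identified-cluster sets are nested across ranks."""
    maxima_by_chrom: dict[str, np.ndarray] = {}
    for p in peaks:
        maxima_by_chrom.setdefault(p.region.chrom, []).append(p.maximum)
    maxima_by_chrom = {c: np.sort(np.array(v)) for c, v in maxima_by_chrom.items()}

    def identified(cluster: PetCluster) -> bool:
        m = maxima_by_chrom.get(cluster.interval.chrom)
        if m is None:
            return False
        lo = np.searchsorted(m, cluster.interval.start - slop, side="left")
        hi = np.searchsorted(m, cluster.interval.end + slop, side="left")
        return hi > lo

    hits = np.array([identified(c) for c in clusters])
    ranks = np.array([c.rank for c in clusters])
    rows = []
    for n in range(1, max_rank + 1):
        sel = ranks >= n
        total = int(sel.sum())
        found = int(hits[sel].sum())
        rows.append(
            {
                "rank": n,
                "n_clusters": total,
                "n_identified": found,
                "fraction_identified": found / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def stratify_by_cgi(
    peaks_or_pairs,
    cgis: Sequence[CpgIsland],
    slop: int = DEFAULT_CGI_SLOP,
) -> dict[str, list]:
    """Partition peaks (or the B side of pairs) by CGI association."""
    index = FeatureIndex(cgis, slop=slop)
    strata: dict[str, list] = {"in_CGI": [], "out_CGI": []}
    for item in peaks_or_pairs:
        peak = item.peak_b if isinstance(item, CommonPeakPair) else item
        key = "in_CGI" if cgi_association(peak, index, slop) else "out_CGI"
        strata[key].append(item)
    return strata


def height_correlation(pairs: Sequence[CommonPeakPair]) -> tuple[float, pd.DataFrame]:
    """Squared Pearson correlation of percent-of-max heights at common sites,
    plus the pair table ordered both ways (by side A, then by side B)."""
    if len(pairs) < 3:
        raise ValidationError("need >= 3 pairs for a correlation")
    x = np.array([p.height_a_pct for p in pairs])
    y = np.array([p.height_b_pct for p in pairs])
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValidationError("zero variance in peak heights")
    r = float(np.corrcoef(x, y)[0, 1])
    table = pd.DataFrame({"height_a_pct": x, "height_b_pct": y})
    table["order_by_a"] = table["height_a_pct"].rank(ascending=False, method="first")
    table["order_by_b"] = table["height_b_pct"].rank(ascending=False, method="first")
    return r * r, table


def write_pairs(pairs: Sequence[CommonPeakPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tmax_a\tmax_b\theight_a\theight_b\theight_a_pct\theight_b_pct\n"
        )
        for pr in pairs:
            fh.write(
                f"{pr.peak_a.region.chrom}\t{pr.peak_a.maximum}\t{pr.peak_b.maximum}\t"
                f"{pr.peak_a.height:g}\t{pr.peak_b.height:g}\t"
                f"{pr.height_a_pct:.4f}\t{pr.height_b_pct:.4f}\n"
            )


def read_common_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a common-peak list as written by :func:`write_pairs` (one record
    per common site, with both height columns when available)."""
    return pd.read_csv(path, sep="\t")
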