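"""End-to-end orchestration shared by the CLI, the tests and the acceptance
script: simulate a scenario, call high-confidence peaks, and measure recovery
of the planted truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .peaks import PeakSet, PoissonThreshold, call_high_confidence
from .simulate import SyntheticConfig, SyntheticGenome, scenario, generate_annotation, simulate_tags


@dataclass
class PipelineRun:
    """Everything one scenario run produced."""

    scenario: SyntheticConfig
    config: PipelineConfig
    genome: SyntheticGenome
    chip_track: object
    input_track: object
    candidates: PeakSet
    input_peaks: PeakSet
    high_confidence: PeakSet


def run_scenario(
    name_or_config: str | SyntheticConfig,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> PipelineRun:
    """Simulate one scenario and call peaks with the default pipeline."""
    if isinstance(name_or_config, str):
        scfg = scenario(name_or_config)
    else:
        scfg = name_or_config
    scfg.seed = seed
    pcfg = (config or PipelineConfig()).validate()
    genome = generate_annotation(scfg)
    chip, inp = simulate_tags(scfg, genome)
    result = call_high_confidence(
        chip,
        inp,
        genome.assembly,
        fragment_size=pcfg.fragment_size,
        tag_len=pcfg.tag_len,
        rule=PoissonThreshold(pcfg.poisson_q),
        merge_gap=pcfg.merge_gap,
        n_samples=pcfg.background_samples,
        min_conf=pcfg.hc_confidence,
        max_offset=pcfg.symmetric_max_offset,
        max_height_ratio=pcfg.symmetric_max_height_ratio,
        seed=seed,
        label=scfg.name,
    )
    return PipelineRun(
        scfg,
        pcfg,
        genome,
        result["chip_track"],
        result["input_track"],
        result["candidates"],
        result["input_peaks"],
        result["high_confidence"],
    )


def planted_recall(run: PipelineRun, radius: int = 350) -> float:
    """Fraction of planted sites matched by a high-confidence peak maximum
    within ``radius`` bp of the site midpoint."""
    sites = run.genome.truth.sites
    if not sites:
        return float("nan")
    maxima = {
        chrom: np.sort(run.high_confidence.maxima(chrom))
        for chrom in run.genome.assembly.chrom_sizes
    }
    hit = 0
    for s in sites:
        m = maxima[s.chrom]
        if len(m):
            i = np.searchsorted(m, s.midpoint)
            near = [m[j] for j in (i - 1, i) if 0 <= j < len(m)]
            if near and min(abs(x - s.midpoint) for x in near) <= radius:
                hit += 1
    return hit / len(sites)
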