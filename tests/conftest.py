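"""Shared fixtures: hand-built call-sets and one full simulated pipeline run."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pytest

import anemonepg as apg
from anemonepg.callset import INFO_FIELDS, CallSet

CLONE_EXCLUDE = ["BM1", "HI1"]
PIPELINE_SEED = 1


def make_callset(gt, contig="chr1", start=100, spacing=10, ref="A", alt="G",
                 samples=None, dp=None, gq=None, qual=None, total_depth=None,
                 info=None):
    """Small hand-built CallSet; scalars broadcast over all sites."""
    gt = np.asarray(gt, dtype=np.int8)
    n, s = gt.shape
    samples = samples or [f"S{i + 1}" for i in range(s)]
    sites = pd.DataFrame({
        "contig": contig if not isinstance(contig, (list, tuple))
        else list(contig),
        "pos": np.arange(start, start + n * spacing, spacing)[:n],
        "ref": ref, "alt": alt,
        "qual": qual if qual is not None else 100.0,
        "total_depth": total_depth if total_depth is not None else 100,
    })
    for key in INFO_FIELDS:
        sites[key] = (info or {}).get(key, math.nan)
    return CallSet(
        sites=sites,
        samples=samples,
        gt=gt,
        dp=np.full((n, s), dp if dp is not None else 30, dtype=np.int32),
        gq=np.full((n, s), gq if gq is not None else 60, dtype=np.int32),
    )


@dataclass
class PipelineRun:
    """End-to-end products of one simulated analysis, shared across tests."""

    dataset: apg.simulate.SimulatedDataset = None
    filtered: CallSet = None          # site + genotype filtered
    analysis: CallSet = None          # + call-rate selected
    site_report: apg.FilterReport = None
    contig_lengths: dict = None
    hw: pd.DataFrame = None
    diversity: pd.DataFrame = None
    regions: list = field(default_factory=list)
    coding_counts: pd.DataFrame = None


@pytest.fixture(scope="session")
def pipeline() -> PipelineRun:
    ds = apg.simulate_dataset(seed=PIPELINE_SEED)
    cfg = apg.FilterConfig()
    site_filtered, report = apg.apply_site_filters(ds.callset, cfg)
    filtered = apg.apply_genotype_filters(site_filtered, cfg, report=report)
    analysis = apg.select_by_call_rate(filtered, cfg.min_called_samples,
                                       exclude=CLONE_EXCLUDE)
    lengths = ds.reference.contig_lengths()
    spec = apg.WindowSpec()
    hw = apg.window_heterozygosity(analysis, spec, lengths,
                                   exclude=CLONE_EXCLUDE)
    dv = apg.window_diversity(analysis, spec, lengths)
    regions = []
    for df, stat in ((hw, "h_w"), (dv, "pi_per_bp"), (dv, "tajimas_d")):
        track = apg.zscore_windows(df, stat, step=spec.step)
        regions.extend(apg.call_outlier_regions(track))
    counts = apg.gene_sample_counts(ds.reference.contigs, ds.reference.genes,
                                    filtered)
    return PipelineRun(dataset=ds, filtered=filtered, analysis=analysis,
                       site_report=report, contig_lengths=lengths, hw=hw,
                       diversity=dv, regions=regions, coding_counts=counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
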