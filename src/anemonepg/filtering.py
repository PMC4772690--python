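"""Site- and genotype-level quality filtering of a SNP call-set.

The site filters follow the GATK-style hard-filter recipe: annotation
thresholds (QD, FS, MQ, HaplotypeScore, MQRankSum, ReadPosRankSum), a
variant-quality floor, and overall-coverage bounds of [depth_min,
depth_factor x mean depth].  A missing INFO annotation never fails a site —
only a present, threshold-violating value does (GATK emits rank-sum
annotations only at sites with heterozygous calls, so their absence is
uninformative).

Genotype-level filtering masks individual calls below a depth or GQ floor;
call-rate selection then keeps sites confidently genotyped in a minimum
number of counted (non-clone) samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .callset import HET, HOM_ALT, HOM_REF, MISSING, CallSet

#: First-failing-rule attribution order for the site-filter report.
SITE_RULE_ORDER = (
    "qual",
    "depth_low",
    "depth_high",
    "QD",
    "FS",
    "MQ",
    "HaplotypeScore",
    "MQRankSum",
    "ReadPosRankSum",
)


class FilterConfigError(ValueError):
    pass


@dataclass
class FilterConfig:
    """Thresholds for site and genotype filtering.

    Defaults are the GATK-recommended hard filters plus the coverage,
    genotype-depth and call-rate rules used for joint anemone call-sets:
    sites need QUAL >= 50 and summed depth within [50, 1.5 x mean];
    genotypes need >= 8x depth and GQ >= 24 (a <= 0.4 % call-error bound);
    sites are kept when called in >= 6 counted samples.
    """

    qd_min: float = 2.0
    fs_max: float = 40.0
    mq_min: float = 40.0
    haplotypescore_max: float = 13.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    qual_min: float = 50.0
    depth_min: float = 50.0
    depth_factor: float = 1.5
    gt_depth_min: int = 8
    gt_gq_min: int = 24
    min_called_samples: int = 6

    def __post_init__(self) -> None:
        for f in fields(self):
            if not np.isfinite(getattr(self, f.name)):
                raise FilterConfigError(f"threshold {f.name} must be finite")
        if self.depth_factor <= 1:
            raise FilterConfigError("depth_factor must exceed 1")

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class FilterReport:
    """Per-rule removal counts and the mutation-spectrum summary."""

    n_input_sites: int = 0
    n_retained_sites: int = 0
    sites_removed: dict[str, int] = field(default_factory=dict)
    genotypes_masked: dict[str, int] = field(default_factory=dict)
    spectrum: dict[str, float] = field(default_factory=dict)
    transition_fraction: float | None = None
    coverage_bounds: tuple[float, float] | None = None

    @property
    def n_removed_sites(self) -> int:
        return sum(self.sites_removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input_sites", self.n_input_sites),
                ("retained_sites", self.n_retained_sites)]
        rows += [(f"removed_{k}", v) for k, v in self.sites_removed.items()]
        rows += [(f"masked_{k}", v) for k, v in self.genotypes_masked.items()]
        return pd.DataFrame(rows, columns=["rule", "count"])


def compute_coverage_bounds(callset: CallSet, cfg: FilterConfig) -> tuple[float, float]:
    """Overall-coverage bounds (low, high) for site retention.

    ``low`` is the fixed minimum; ``high`` is ``depth_factor`` times the
    mean total depth over all input sites, reported to the unit place.
    """
    if callset.n_sites == 0:
        raise FilterConfigError("cannot compute coverage bounds on an empty call-set")
    mean_depth = float(callset.sites["total_depth"].mean())
    high = round(cfg.depth_factor * mean_depth)
    return (cfg.depth_min, float(high))


def _site_failures(callset: CallSet, cfg: FilterConfig,
                   bounds: tuple[float, float]) -> dict[str, np.ndarray]:
    """Boolean failure mask per rule; NaN annotations never fail."""
    s = callset.sites
    low, high = bounds

    def present_and(col: str, bad) -> np.ndarray:
        v = s[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            return ~np.isnan(v) & bad(v)

    return {
        "qual": present_and("qual", lambda v: v < cfg.qual_min),
        "depth_low": s["total_depth"].to_numpy(dtype=float) < low,
        "depth_high": s["total_depth"].to_numpy(dtype=float) > high,
        "QD": present_and("QD", lambda v: v < cfg.qd_min),
        "FS": present_and("FS", lambda v: v > cfg.fs_max),
        "MQ": present_and("MQ", lambda v: v < cfg.mq_min),
        "HaplotypeScore": present_and(
            "HaplotypeScore", lambda v: v > cfg.haplotypescore_max),
        "MQRankSum": present_and("MQRankSum", lambda v: v < cfg.mqranksum_min),
        "ReadPosRankSum": present_and(
            "ReadPosRankSum", lambda v: v < cfg.readposranksum_min),
    }


def apply_site_filters(callset: CallSet, cfg: FilterConfig | None = None,
                       bounds: tuple[float, float] | None = None
                       ) -> tuple[CallSet, FilterReport]:
    """Apply the hard site filters; retention requires passing every rule.

    Removal is attributed to the first failing rule in
    :data:`SITE_RULE_ORDER` for reporting.  Coverage bounds default to
    :func:`compute_coverage_bounds` on the input set; pass the bounds from
    an earlier report when re-filtering an already-filtered call-set, so
    the upper bound is anchored to the full ingested data.
    """
    cfg = cfg or FilterConfig()
    if bounds is None:
        bounds = compute_coverage_bounds(callset, cfg)
    failures = _site_failures(callset, cfg, bounds)

    any_fail = np.zeros(callset.n_sites, dtype=bool)
    attributed = np.zeros(callset.n_sites, dtype=bool)
    removed: dict[str, int] = {}
    for rule in SITE_RULE_ORDER:
        fail = failures[rule]
        removed[rule] = int((fail & ~attributed).sum())
        attributed |= fail
        any_fail |= fail

    out = callset.take_sites(
        ~any_fail, note=f"site_filters: removed={int(any_fail.sum())}")
    report = FilterReport(
        n_input_sites=callset.n_sites,
        n_retained_sites=out.n_sites,
        sites_removed=removed,
        coverage_bounds=bounds,
    )
    return out, report


def apply_genotype_filters(callset: CallSet, cfg: FilterConfig | None = None,
                           report: FilterReport | None = None) -> CallSet:
    """Mask genotypes below the per-call depth or GQ floor."""
    cfg = cfg or FilterConfig()
    called = callset.called_mask()
    low_dp = called & (callset.dp < cfg.gt_depth_min)
    low_gq = called & ~low_dp & (callset.gq < cfg.gt_gq_min)
    gt = callset.gt.copy()
    gt[low_dp | low_gq] = MISSING
    if report is not None:
        report.genotypes_masked["depth"] = int(low_dp.sum())
        report.genotypes_masked["gq"] = int(low_gq.sum())
    return callset.with_genotypes(
        gt, note=f"genotype_filters: masked={int((low_dp | low_gq).sum())}")


def select_by_call_rate(callset: CallSet, min_called: int | None = None,
                        exclude: list[str] | None = None) -> CallSet:
    """Keep sites called in at least ``min_called`` counted samples.

    ``exclude`` lists samples (typically clone duplicates) that stay in the
    genotype matrix but do not contribute to the call-rate count.
    """
    if min_called is None:
        min_called = FilterConfig().min_called_samples
    exclude = exclude or []
    unknown = set(exclude) - set(callset.samples)
    if unknown:
        raise KeyError(f"exclude lists unknown samples: {sorted(unknown)}")
    counted = [i for i, s in enumerate(callset.samples) if s not in exclude]
    if min_called > len(counted):
        raise FilterConfigError(
            f"min_called={min_called} exceeds {len(counted)} counted samples")
    n_called = callset.called_mask()[:, counted].sum(axis=1)
    keep = n_called >= min_called
    return callset.take_sites(
        keep, note=f"call_rate>= {min_called}: removed={int((~keep).sum())}")


#: Canonical unordered base-pair change classes (strand-collapsed).
SPECTRUM_CLASSES = ("C/T", "A/G", "C/G", "C/A", "T/G", "A/T")
_CLASS_OF_PAIR = {frozenset(c.split("/")): c for c in SPECTRUM_CLASSES}
TRANSITIONS = ("C/T", "A/G")


def mutation_spectrum(callset: CallSet, report: FilterReport | None = None
                      ) -> dict[str, float]:
    """Fractions of the 6 unordered ref<->alt classes plus transition share.

    Strand is collapsed: a G->A change counts in the A/G class.  Returns a
    dict keyed by class name with an extra ``transition_fraction`` entry.
    """
    pairs = [
        _CLASS_OF_PAIR[frozenset((r, a))]
        for r, a in zip(callset.sites["ref"], callset.sites["alt"])
    ]
    n = len(pairs)
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for p in pairs:
        counts[p] += 1
    fractions = {c: (counts[c] / n if n else 0.0) for c in SPECTRUM_CLASSES}
    ts = sum(fractions[c] for c in TRANSITIONS)
    if report is not None:
        report.spectrum = fractions
        report.transition_fraction = ts
    out = dict(fractions)
    out["transition_fraction"] = ts
    return out


def extract_homozygous_only(callset: CallSet) -> CallSet:
    """Keep only sites with zero heterozygous calls among non-missing genotypes."""
    any_het = (callset.gt == HET).any(axis=1)
    return callset.take_sites(
        ~any_het, note=f"homozygous_only: removed={int(any_het.sum())}")


def clone_discordance(callset: CallSet, a: str, b: str) -> dict[str, float]:
    """Genotype discordance between two (putatively clonal) samples.

    Over sites where both genotypes are non-missing, counts hom-vs-het
    disagreements and opposite-homozygote disagreements, and reports the
    hom-vs-het fraction of compared sites.
    """
    if a == b:
        raise ValueError("clone comparison needs two distinct samples")
    ia, ib = callset.sample_index(a), callset.sample_index(b)
    ga, gb = callset.gt[:, ia], callset.gt[:, ib]
    both = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[both], gb[both]
    hom_vs_het = ((ga == HET) ^ (gb == HET)) & (ga != gb)
    opposite_hom = ((ga == HOM_REF) & (gb == HOM_ALT)) | (
        (ga == HOM_ALT) & (gb == HOM_REF))
    n = int(both.sum())
    return {
        "n_compared": n,
        "n_hom_vs_het": int(hom_vs_het.sum()),
        "n_opposite_homozygote": int(opposite_hom.sum()),
        "fraction_hom_vs_het": (int(hom_vs_het.sum()) / n) if n else float("nan"),
    }
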