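"""Individual and windowed heterozygosity.

Individual heterozygosity of a diploid genome is

    H_I = S_HET / (S_TOT - S_NA)

where ``S_HET`` counts confidently-called heterozygous SNP sites in the
sample, ``S_TOT`` counts positions meeting both per-sample and across-sample
coverage requirements (supplied by the caller, since it depends on per-base
coverage the call-set itself does not carry), and ``S_NA`` counts call-set
variants at callable positions whose genotype in this sample is missing.

Window heterozygosity ``H_W`` is the population-level analogue: within a
sliding window, the number of heterozygous genotype calls divided by all
non-missing genotype calls at SNP positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .callset import HET, MISSING, CallSet
from .windows import WindowSpec, aggregate_in_windows

EXONIC = "exonic"
NON_EXONIC = "non_exonic"

#: GFF3 feature types whose span makes an overlapping SNP exonic.
EXONIC_FEATURES = ("CDS", "five_prime_UTR", "three_prime_UTR")


class AnnotationError(ValueError):
    pass


@dataclass
class HIResult:
    """One sample's individual heterozygosity over one site partition."""

    sample: str
    partition: str
    s_het: int
    s_tot: int
    s_na: int

    @property
    def h_i(self) -> float:
        return self.s_het / (self.s_tot - self.s_na)

    @property
    def h_i_percent(self) -> float:
        return 100.0 * self.h_i


def classify_sites(callset: CallSet, annotation) -> np.ndarray:
    """Label each site ``exonic`` or ``non_exonic`` from GFF3 gene models.

    A site is exonic when it overlaps any CDS or 5'/3' UTR interval of any
    gene model.  ``annotation`` is a :mod:`gffutils` database (or anything
    with ``features_of_type``).

    Raises
    ------
    AnnotationError
        If no call-set contig appears in the annotation (likely a naming
        mismatch between VCF and GFF3).
    """
    trees: dict[str, IntervalTree] = {}
    for ftype in EXONIC_FEATURES:
        for feat in annotation.features_of_type(ftype):
            # interval tree uses half-open [begin, end); GFF is 1-based inclusive
            trees.setdefault(feat.seqid, IntervalTree()).addi(
                feat.start, feat.end + 1)

    vcf_contigs = set(callset.contigs())
    if vcf_contigs and trees and not (vcf_contigs & set(trees)):
        raise AnnotationError(
            "no VCF contig matches the annotation; offending contigs: "
            f"{sorted(vcf_contigs)}")

    labels = np.full(callset.n_sites, NON_EXONIC, dtype=object)
    for i, (contig, pos) in enumerate(
            zip(callset.sites["contig"], callset.sites["pos"])):
        tree = trees.get(contig)
        if tree is not None and tree.overlaps_point(int(pos)):
            labels[i] = EXONIC
    return labels.astype("U10")


def individual_heterozygosity(callset: CallSet, sample: str, callable_total: int,
                              partition: str = "genome",
                              site_classes: np.ndarray | None = None) -> HIResult:
    """Compute H_I for one sample (genotype filters must be applied first).

    Parameters
    ----------
    callable_total
        Number of positions meeting the per-sample (>= 8x) and across-sample
        coverage requirements for this partition; typically from a callable
        mask or the simulator's truth table.
    partition
        ``genome`` (default), ``exonic`` or ``non_exonic``; the latter two
        require ``site_classes`` from :func:`classify_sites`.
    """
    j = callset.sample_index(sample)
    gt = callset.gt[:, j]
    if partition != "genome":
        if site_classes is None:
            raise ValueError("partitioned H_I requires site_classes")
        gt = gt[np.asarray(site_classes) == partition]
    s_het = int((gt == HET).sum())
    s_na = int((gt == MISSING).sum())
    if callable_total < s_het + s_na:
        raise ValueError(
            f"callable_total={callable_total} inconsistent with "
            f"s_het={s_het} + s_na={s_na}")
    return HIResult(sample=sample, partition=partition,
                    s_het=s_het, s_tot=int(callable_total), s_na=s_na)


def hi_table(callset: CallSet, callable_totals: dict[str, int],
             site_classes: np.ndarray | None = None) -> pd.DataFrame:
    """Per-sample H_I table, partitioned when site classes are available."""
    partitions = ["genome"]
    if site_classes is not None:
        partitions += [EXONIC, NON_EXONIC]
    rows = []
    for sample in callset.samples:
        for part in partitions:
            tot = callable_totals[sample]
            if part != "genome":
                # partition callable totals proportionally to SNP classes
                frac = float((np.asarray(site_classes) == part).mean())
                tot = int(round(tot * frac))
            r = individual_heterozygosity(callset, sample, tot, part, site_classes)
            rows.append({
                "sample": r.sample, "partition": r.partition, "s_het": r.s_het,
                "s_tot": r.s_tot, "s_na": r.s_na,
                "h_i_percent": r.h_i_percent,
            })
    return pd.DataFrame(rows)


def window_heterozygosity(callset: CallSet, spec: WindowSpec,
                          contig_lengths: dict[str, int],
                          exclude: list[str] | None = None) -> pd.DataFrame:
    """Sliding-window H_W over all genotype calls at SNP positions.

    Returns one row per window: contig, start, end, n_snps,
    n_genotypes_called, n_het, h_w (NaN when nothing called) and a
    ``flagged`` column marking windows with fewer than ``spec.min_snps``
    SNPs, which downstream means/SDs exclude.
    """
    exclude = set(exclude or [])
    cols = [i for i, s in enumerate(callset.samples) if s not in exclude]
    gt = callset.gt[:, cols]
    per_site = np.column_stack([
        np.ones(callset.n_sites),               # SNP count
        (gt != MISSING).sum(axis=1),            # called genotypes
        (gt == HET).sum(axis=1),                # het calls
    ])

    frames = []
    site_contig = callset.sites["contig"].to_numpy()
    site_pos = callset.sites["pos"].to_numpy()
    for contig, length in contig_lengths.items():
        starts = spec.starts(int(length))
        if starts.size == 0:
            continue
        in_contig = site_contig == contig
        agg = aggregate_in_windows(site_pos[in_contig], per_site[in_contig],
                                   starts, spec.size)
        n_snps, n_called, n_het = agg[:, 0], agg[:, 1], agg[:, 2]
        with np.errstate(invalid="ignore", divide="ignore"):
            h_w = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
        frames.append(pd.DataFrame({
            "contig": contig,
            "start": starts,
            "end": starts + spec.size - 1,
            "n_snps": n_snps.astype(int),
            "n_genotypes_called": n_called.astype(int),
            "n_het": n_het.astype(int),
            "h_w": h_w,
            "flagged": n_snps < spec.min_snps,
        }))
    if not frames:
        return pd.DataFrame(columns=["contig", "start", "end", "n_snps",
                                     "n_genotypes_called", "n_het", "h_w",
                                     "flagged"])
    return pd.concat(frames, ignore_index=True)


def write_hw_bed(df: pd.DataFrame, path) -> None:
    """BED-like TSV export (0-based start column)."""
    out = df.copy()
    out["start0"] = out["start"] - 1
    out[["contig", "start0", "end", "n_snps", "n_genotypes_called", "h_w"]].to_csv(
        path, sep="\t", index=False, header=True)
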