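"""Mitochondrial polymorphism summaries from per-position allele counts.

Works from a per-sample table of read counts per base (A/C/G/T) at each
mitochondrial position.  A position is a fixed SNP when the major allele
differs from the reference with only trace minor support; heteroplasmic
when a minor allele reaches the evidence threshold at adequate depth.
Nuclear-mitochondrial insertions (NUMTs) can mimic heteroplasmy and are not
distinguished here; reported heteroplasmic sites warrant inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

BASES = ("A", "C", "G", "T")

FIXED_SNP = "fixed_snp"
HETEROPLASMIC = "heteroplasmic"
REFERENCE = "reference"


@dataclass
class MtVariant:
    pos: int
    ref: str
    major: str
    minor: str | None
    minor_fraction: float
    depth: int
    variant_class: str


def read_count_table(path) -> pd.DataFrame:
    """Load a per-position allele-count TSV with columns pos, A, C, G, T."""
    df = pd.read_csv(path, sep="\t")
    required = {"pos", *BASES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def call_mt_variants(table: pd.DataFrame, reference: str,
                     min_depth: int = 10,
                     het_fraction: float = 0.2) -> list[MtVariant]:
    """Classify mitochondrial positions from allele-count evidence.

    Positions below ``min_depth`` are skipped.  The minor fraction is the
    second-most-supported allele's share of reads; at or above
    ``het_fraction`` the site is heteroplasmic, otherwise it is a fixed SNP
    when the major allele differs from the reference.
    """
    out = []
    for row in table.itertuples():
        pos = int(row.pos)
        if pos < 1 or pos > len(reference):
            raise ValueError(f"position {pos} outside reference of length "
                             f"{len(reference)}")
        counts = {b: int(getattr(row, b)) for b in BASES}
        depth = sum(counts.values())
        if depth < min_depth:
            continue
        ranked = sorted(BASES, key=lambda b: (-counts[b], b))
        major = ranked[0]
        minor = ranked[1] if counts[ranked[1]] > 0 else None
        minor_fraction = counts[ranked[1]] / depth
        ref_base = reference[pos - 1].upper()
        if minor_fraction >= het_fraction:
            cls = HETEROPLASMIC
        elif major != ref_base:
            cls = FIXED_SNP
        else:
            cls = REFERENCE
        out.append(MtVariant(pos=pos, ref=ref_base, major=major, minor=minor,
                             minor_fraction=minor_fraction, depth=depth,
                             variant_class=cls))
    return out


def variants_to_frame(variants: list[MtVariant],
                      include_reference: bool = False) -> pd.DataFrame:
    rows = [v.__dict__ for v in variants
            if include_reference or v.variant_class != REFERENCE]
    return pd.DataFrame(rows, columns=["pos", "ref", "major", "minor",
                                       "minor_fraction", "depth",
                                       "variant_class"])


def mt_copy_ratio(mt_mean_cov: float, nuclear_mean_cov: float) -> float:
    """mtDNA : nuclear mean per-site coverage ratio (a copy-number proxy)."""
    if nuclear_mean_cov <= 0:
        raise ValueError("nuclear mean coverage must be positive")
    return mt_mean_cov / nuclear_mean_cov


def mt_copy_ratio_report(mt_mean_cov: float, nuclear_mean_cov: float) -> int:
    """The ratio rounded to the unit place, as conventionally reported."""
    return int(round(mt_copy_ratio(mt_mean_cov, nuclear_mean_cov)))
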