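"""VCF ingestion and re-emission.

Reading is delegated to :mod:`cyvcf2` (htslib); only biallelic SNP records
with GT/DP/GQ per genotype are ingested.  Writing emits a plain-text VCF 4.2
with the fixed ``GT:DP:GQ`` layout and the INFO annotations the hard filters
consume, so that a written call-set round-trips through :func:`read_vcf`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .callset import HET, HOM_ALT, HOM_REF, INFO_FIELDS, MISSING, CallSet

_GT_STR = {MISSING: "./.", HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}


class VCFFormatError(ValueError):
    """Raised for VCF files missing required fields or malformed records."""


@dataclass
class IngestStats:
    n_records: int = 0
    n_snps: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0

    def note(self) -> str:
        return (
            f"ingest: records={self.n_records} snps={self.n_snps} "
            f"multiallelic={self.n_multiallelic} non_snp={self.n_non_snp}"
        )


def read_vcf(path, samples: list[str] | None = None) -> CallSet:
    """Read a multi-sample VCF into a :class:`CallSet`.

    Multiallelic records and non-SNP records (indels, MNPs, symbolic
    alleles) are excluded and counted in the provenance log.

    Parameters
    ----------
    path
        VCF v4.x file, plain or bgzip-compressed, with GT, DP and GQ
        genotype fields.
    samples
        Optional subset of sample ids to load (order preserved as given
        in the file header).
    """
    vcf = VCF(str(path), gts012=True)
    try:
        vcf.get_header_type("GT")
    except KeyError:
        raise VCFFormatError(f"{path}: no GT FORMAT field defined") from None
    if samples is not None:
        unknown = set(samples) - set(vcf.samples)
        if unknown:
            raise VCFFormatError(f"{path}: samples not in header: {sorted(unknown)}")
        vcf.set_samples(samples)
    sample_ids = list(vcf.samples)

    stats = IngestStats()
    rows = []
    gts, dps, gqs = [], [], []
    for line_no, v in enumerate(vcf, start=1):
        stats.n_records += 1
        if len(v.ALT) != 1:
            stats.n_multiallelic += 1
            continue
        if not v.is_snp:
            stats.n_non_snp += 1
            continue
        stats.n_snps += 1

        gt = v.gt_types.astype(np.int8)  # 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
        gt[gt == 3] = MISSING
        dp = _format_ints(v, "DP", len(sample_ids))
        gq = _format_ints(v, "GQ", len(sample_ids))
        row = {
            "contig": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": v.ALT[0],
            "qual": float(v.QUAL) if v.QUAL is not None else math.nan,
            "total_depth": _info_depth(v, dp),
        }
        for key in INFO_FIELDS:
            val = v.INFO.get(key)
            row[key] = float(val) if val is not None else math.nan
        rows.append(row)
        gts.append(gt)
        dps.append(dp)
        gqs.append(gq)

    n = len(rows)
    sites = pd.DataFrame(rows) if rows else _empty_sites()
    shape = (n, len(sample_ids))
    cs = CallSet(
        sites=sites,
        samples=sample_ids,
        gt=np.array(gts, dtype=np.int8).reshape(shape),
        dp=np.array(dps, dtype=np.int32).reshape(shape),
        gq=np.array(gqs, dtype=np.int32).reshape(shape),
        provenance=[stats.note()],
    )
    return cs


def _format_ints(v, key: str, n_samples: int) -> np.ndarray:
    arr = v.format(key)
    if arr is None:
        return np.zeros(n_samples, dtype=np.int32)
    out = np.asarray(arr).reshape(n_samples, -1)[:, 0].astype(np.int64)
    out[out < 0] = 0  # htslib missing-value sentinels
    return out.astype(np.int32)


def _info_depth(v, dp: np.ndarray) -> int:
    info_dp = v.INFO.get("DP")
    return int(info_dp) if info_dp is not None else int(dp.sum())


def _empty_sites() -> pd.DataFrame:
    cols = ["contig", "pos", "ref", "alt", "qual", "total_depth", *INFO_FIELDS]
    return pd.DataFrame({c: [] for c in cols})


_HEADER_META = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth across samples">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (Phred)">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Haplotype consistency score">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping-quality rank-sum z">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read-position rank-sum z">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (Phred)">',
]


def write_vcf(callset: CallSet, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a call-set as a plain-text VCF 4.2 file.

    Masked genotypes are emitted as ``./.`` (their DP/GQ are preserved).
    INFO floats are written at 6 significant digits, which round-trips the
    two-decimal annotations the simulator produces.
    """
    sites = callset.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths is None:
            contig_lengths = {
                c: int(sites.loc[sites["contig"] == c, "pos"].max())
                for c in callset.contigs()
            }
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        for line in _HEADER_META:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(callset.samples)
            + "\n"
        )
        for i in range(callset.n_sites):
            row = sites.iloc[i]
            qual = "." if math.isnan(row.qual) else f"{row.qual:.2f}"
            info_parts = [f"DP={int(row.total_depth)}"]
            for key in INFO_FIELDS:
                val = row[key]
                if not math.isnan(val):
                    info_parts.append(f"{key}={val:.6g}")
            fields = [
                row.contig,
                str(int(row.pos)),
                ".",
                row.ref,
                row.alt,
                qual,
                "PASS",
                ";".join(info_parts),
                "GT:DP:GQ",
            ]
            for s in range(callset.n_samples):
                fields.append(
                    f"{_GT_STR[int(callset.gt[i, s])]}:"
                    f"{int(callset.dp[i, s])}:{int(callset.gq[i, s])}"
                )
            fh.write("\t".join(fields) + "\n")
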