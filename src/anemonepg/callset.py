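"""Central genotype-matrix container for a multi-sample SNP call-set.

A :class:`CallSet` holds biallelic SNP sites (rows) by samples (columns).
Genotype states are encoded in a compact ``int8`` matrix:

====== =================
code   state
====== =================
``-1``  missing (``./.``)
``0``   homozygous reference
``1``   heterozygous
``2``   homozygous alternate
====== =================

Per-genotype read depth (DP) and genotype quality (GQ, Phred) are carried in
parallel integer matrices.  Site-level metadata (contig, position, ref/alt,
QUAL, total depth and the INFO annotations used by hard filtering) live in a
pandas DataFrame aligned row-for-row with the genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

#: INFO annotations consumed by the hard site filters, in canonical order.
INFO_FIELDS = ("QD", "FS", "MQ", "HaplotypeScore", "MQRankSum", "ReadPosRankSum")

SITE_COLUMNS = ("contig", "pos", "ref", "alt", "qual", "total_depth") + INFO_FIELDS

_BASES = frozenset("ACGT")


class CallSetError(ValueError):
    """Raised when a call-set violates its structural invariants."""


@dataclass
class CallSet:
    """Sites x samples genotype matrix with QC metadata.

    Parameters
    ----------
    sites
        DataFrame with columns ``contig, pos, ref, alt, qual, total_depth``
        plus the INFO annotations in :data:`INFO_FIELDS` (NaN where absent).
        Must be sorted by (contig, pos) with no duplicate positions.
    samples
        Ordered sample identifiers.
    gt, dp, gq
        ``(n_sites, n_samples)`` matrices of genotype code, depth and GQ.
    provenance
        Log of filters applied so far, oldest first.
    """

    sites: pd.DataFrame
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n_sites, n_samples = len(self.sites), len(self.samples)
        for name in ("gt", "dp", "gq"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_sites, n_samples):
                raise CallSetError(
                    f"{name} matrix shape {arr.shape} does not match "
                    f"{n_sites} sites x {n_samples} samples"
                )
            setattr(self, name, arr)
        self.gt = self.gt.astype(np.int8)
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise CallSetError(f"sites table missing columns: {missing}")
        self._check_sites()

    def _check_sites(self) -> None:
        if self.n_sites == 0:
            return
        key = self.sites[["contig", "pos"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise CallSetError(f"duplicate site {dup.contig}:{dup.pos}")
        ordered = key.sort_values(["contig", "pos"], kind="mergesort")
        if not np.array_equal(ordered.index.to_numpy(), np.arange(len(key))):
            raise CallSetError("sites are not sorted by (contig, pos)")
        if (self.sites["pos"] < 1).any():
            raise CallSetError("positions must be 1-based (>= 1)")
        bad = ~(
            self.sites["ref"].isin(_BASES)
            & self.sites["alt"].isin(_BASES)
            & (self.sites["ref"] != self.sites["alt"])
        )
        if bad.any():
            row = self.sites[bad].iloc[0]
            raise CallSetError(
                f"invalid SNP alleles {row.ref}>{row.alt} at {row.contig}:{row.pos}"
            )

    # -- basic views ------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.sites["contig"]))

    # -- derived per-site summaries --------------------------------------

    def called_mask(self) -> np.ndarray:
        """Boolean matrix: genotype is non-missing."""
        return self.gt != MISSING

    def het_mask(self) -> np.ndarray:
        return self.gt == HET

    def alt_allele_counts(self) -> np.ndarray:
        """Per-site count of alternate alleles over non-missing genotypes."""
        counts = np.where(self.gt == MISSING, 0, self.gt)
        return counts.sum(axis=1)

    def called_chromosomes(self) -> np.ndarray:
        """Per-site count of called chromosomes (2 x called genotypes)."""
        return 2 * self.called_mask().sum(axis=1)

    # -- subsetting -------------------------------------------------------

    def take_sites(self, mask_or_index, note: str | None = None) -> "CallSet":
        """Row-subset the call-set, preserving sample order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        out = CallSet(
            sites=self.sites.iloc[idx],
            samples=list(self.samples),
            gt=self.gt[idx],
            dp=self.dp[idx],
            gq=self.gq[idx],
            provenance=list(self.provenance),
        )
        if note:
            out.provenance.append(note)
        return out

    def with_genotypes(self, gt: np.ndarray, note: str | None = None) -> "CallSet":
        out = replace(self, gt=np.asarray(gt, dtype=np.int8),
                      provenance=list(self.provenance))
        if note:
            out.provenance.append(note)
        return out

    def equals(self, other: "CallSet", qual_tol: float = 1e-4) -> bool:
        """Structural equality up to floating-point QUAL/INFO rounding."""
        if self.samples != other.samples or self.n_sites != other.n_sites:
            return False
        for name in ("gt", "dp", "gq"):
            if not np.array_equal(getattr(self, name), getattr(other, name)):
                return False
        a, b = self.sites, other.sites
        for col in ("contig", "pos", "ref", "alt"):
            if not a[col].equals(b[col]):
                return False
        for col in ("qual", "total_depth") + INFO_FIELDS:
            x = a[col].to_numpy(dtype=float)
            y = b[col].to_numpy(dtype=float)
            ok = np.isclose(x, y, atol=qual_tol, rtol=1e-5) | (
                np.isnan(x) & np.isnan(y)
            )
            if not ok.all():
                return False
        return True
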