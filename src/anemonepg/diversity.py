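"""Per-site and windowed nucleotide diversity (pi) and Tajima's D.

Per-site pi for a biallelic site with ``k`` alternate alleles among ``n``
called chromosomes is the fraction of differing chromosome pairs,
``k (n - k) / C(n, 2)``.  Windowed pi sums per-site values and divides by
the callable base count.  Tajima's D contrasts windowed pi with the
Watterson estimate ``S / a1`` using the standard variance normalisation:

    D = (pi_sum - S / a1) / sqrt(e1 S + e2 S (S - 1))

These are genotype-call-based estimators: per-site ``n`` is twice the
number of non-missing genotypes, and the per-window coefficient ``n`` is
the floor of the mean called-chromosome count over the window's SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .callset import MISSING, CallSet
from .windows import GenomeMask, WindowSpec, aggregate_in_windows


@dataclass(frozen=True)
class TajimaCoefficients:
    """Constants of Tajima's test for a sample of ``n`` chromosomes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@lru_cache(maxsize=None)
def tajima_coefficients(n: int) -> TajimaCoefficients:
    if n < 4:
        raise ValueError("Tajima coefficients require n >= 4 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaCoefficients(n, a1, a2, b1, b2, c1, c2, e1, e2)


def site_pi(alt_count: int, called_chromosomes: int) -> float:
    """Average pairwise difference at one site: ``k(n-k)/C(n,2)``."""
    k, n = alt_count, called_chromosomes
    if n < 2:
        raise ValueError("site pi undefined for fewer than 2 chromosomes")
    if not 0 <= k <= n:
        raise ValueError(f"alt count {k} outside [0, {n}]")
    return k * (n - k) / (n * (n - 1) / 2.0)


def tajimas_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D from segregating-site count, summed pi and chromosome count.

    Returns NaN when ``S`` is zero or the variance term is non-positive.
    """
    if S <= 0 or n < 4:
        return float("nan")
    c = tajima_coefficients(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - S / c.a1) / np.sqrt(var)


def window_diversity(callset: CallSet, spec: WindowSpec,
                     contig_lengths: dict[str, int],
                     callable_mask: GenomeMask | None = None,
                     min_called_samples: int | None = None) -> pd.DataFrame:
    """Sliding-window pi and Tajima's D.

    Sites called in fewer than ``min_called_samples`` samples are dropped
    before windowing.  ``callable_bp`` defaults to the window size; with a
    mask it is the masked base count inside the window.  ``tajimas_d`` is
    NaN for windows with no SNPs or a degenerate variance term.
    """
    cs = callset
    if min_called_samples is not None:
        called = (cs.gt != MISSING).sum(axis=1)
        cs = cs.take_sites(called >= min_called_samples)

    n_chrom = cs.called_chromosomes().astype(float)
    k = cs.alt_allele_counts().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n_chrom >= 2,
                      k * (n_chrom - k) / (n_chrom * (n_chrom - 1) / 2.0), 0.0)
    usable = n_chrom >= 2
    per_site = np.column_stack([usable.astype(float), pi * usable,
                                n_chrom * usable])

    site_contig = cs.sites["contig"].to_numpy()
    site_pos = cs.sites["pos"].to_numpy()
    frames = []
    for contig, length in contig_lengths.items():
        starts = spec.starts(int(length))
        if starts.size == 0:
            continue
        in_contig = site_contig == contig
        agg = aggregate_in_windows(site_pos[in_contig], per_site[in_contig],
                                   starts, spec.size)
        S = agg[:, 0]
        pi_sum = agg[:, 1]
        chrom_sum = agg[:, 2]
        ends = starts + spec.size - 1
        if callable_mask is None:
            callable_bp = np.full(starts.shape, spec.size, dtype=float)
        else:
            callable_bp = np.array([
                callable_mask.window_bp(contig, int(s), int(e))
                for s, e in zip(starts, ends)], dtype=float)

        d_vals = np.full(starts.shape, np.nan)
        theta_w = np.zeros(starts.shape)
        for w in range(starts.size):
            if S[w] > 0:
                n_d = int(np.floor(chrom_sum[w] / S[w]))
                d_vals[w] = tajimas_d(int(S[w]), float(pi_sum[w]), n_d)
                if n_d >= 2 and callable_bp[w] > 0:
                    a1 = float(np.sum(1.0 / np.arange(1, n_d)))
                    theta_w[w] = S[w] / (a1 * callable_bp[w])
        with np.errstate(invalid="ignore", divide="ignore"):
            pi_per_bp = np.where(callable_bp > 0, pi_sum / callable_bp, np.nan)
        frames.append(pd.DataFrame({
            "contig": contig,
            "start": starts,
            "end": ends,
            "n_snps": S.astype(int),
            "callable_bp": callable_bp.astype(int),
            "pi_sum": pi_sum,
            "pi_per_bp": pi_per_bp,
            "theta_w": theta_w,
            "tajimas_d": d_vals,
            "flagged": S < spec.min_snps,
        }))
    if not frames:
        return pd.DataFrame(columns=["contig", "start", "end", "n_snps",
                                     "callable_bp", "pi_sum", "pi_per_bp",
                                     "theta_w", "tajimas_d", "flagged"])
    return pd.concat(frames, ignore_index=True)


def reciprocal_bp(proportion: float) -> int:
    """Report a per-bp proportion as '1 difference per N bp' (N rounded)."""
    if proportion <= 0:
        raise ValueError("proportion must be positive")
    return int(round(1.0 / proportion))


def summarize_windows(records: pd.DataFrame) -> dict[str, float]:
    """Mean/SD of per-window pi (and Tajima's D where present) over
    non-flagged windows, with the reciprocal 'one difference per N bp'."""
    ok = records.loc[~records["flagged"]]
    if ok.empty:
        raise ValueError("no non-flagged windows to summarize")
    out: dict[str, float] = {}
    if "pi_per_bp" in ok:
        mean_pi = float(ok["pi_per_bp"].mean())
        out["mean_pi_per_bp"] = mean_pi
        out["sd_pi_per_bp"] = float(ok["pi_per_bp"].std(ddof=1))
        out["bp_per_pairwise_diff"] = reciprocal_bp(mean_pi)
    if "h_w" in ok:
        out["mean_h_w"] = float(ok["h_w"].mean())
        out["sd_h_w"] = float(ok["h_w"].std(ddof=1))
    if "tajimas_d" in ok:
        d = ok["tajimas_d"].dropna()
        if len(d):
            out["mean_tajimas_d"] = float(d.mean())
            out["sd_tajimas_d"] = float(d.std(ddof=1))
    return out
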