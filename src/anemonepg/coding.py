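"""Within-individual nonsynonymous/synonymous heterozygosity (H_A / H_S).

Each diploid sample carries two alleles of every coding gene; substituting
its SNP genotypes into the reference spliced CDS yields an aligned allele
pair.  Nei-Gojobori (1986) counting partitions codon positions into
fractional synonymous/nonsynonymous sites, classifies allele differences by
equal-weight pathway enumeration, and the per-site proportions are corrected
for multiple substitutions with the Jukes-Cantor transform
``h = -(3/4) ln(1 - 4p/3)``.  H_A / H_S below 1 indicates purifying
selection on the gene; above 1, relaxed or diversifying pressure.

Inference helpers: a seeded gene-concatenation bootstrap for genome-wide
H_A and H_S, a permutation test comparing a gene set's median ratio with
random sets, and an exact (enumeration-based) Wilcoxon signed-rank test for
small paired samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import rankdata

from .callset import HET, HOM_ALT, MISSING, CallSet

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: codon -> amino acid, with '*' for stops (standard nuclear code).
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"

_BASES = "ACGT"


class GeneModelError(ValueError):
    pass


@dataclass
class GeneModel:
    """CDS structure of one gene: ordered, non-overlapping segments.

    ``cds_segments`` are (start, end, phase) in 1-based inclusive genomic
    coordinates, stored in ascending genomic order; coding order follows the
    strand.  ``flagged`` marks genes whose reference frame contains an
    internal stop codon.
    """

    gene_id: str
    contig: str
    strand: str
    cds_segments: list[tuple[int, int, int]]
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be + or -")
        segs = sorted(self.cds_segments)
        for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise GeneModelError(f"{self.gene_id}: overlapping CDS segments")
        self.cds_segments = segs

    @property
    def first_phase(self) -> int:
        segs = self.cds_segments if self.strand == "+" else self.cds_segments[::-1]
        return segs[0][2]

    def coding_positions(self) -> np.ndarray:
        """Genomic positions of the spliced CDS in 5'->3' coding order,
        after trimming the leading phase bases."""
        if self.strand == "+":
            parts = [np.arange(s, e + 1) for s, e, _ in self.cds_segments]
        else:
            parts = [np.arange(e, s - 1, -1) for s, e, _ in self.cds_segments[::-1]]
        pos = np.concatenate(parts)
        return pos[self.first_phase:]

    def spliced_length(self) -> int:
        return len(self.coding_positions())


def load_gene_models(annotation) -> list[GeneModel]:
    """Build :class:`GeneModel` objects from a gffutils database.

    CDS features are gathered per gene (via its transcripts when present);
    the phase column is honoured.  Genes whose spliced length is not a
    multiple of 3 are rejected.
    """
    models = []
    for gene in annotation.features_of_type("gene"):
        cds = list(annotation.children(gene, featuretype="CDS"))
        if not cds:
            continue
        seen = set()
        segments = []
        for c in cds:
            key = (c.start, c.end)
            if key in seen:
                continue  # same segment via multiple transcripts
            seen.add(key)
            phase = int(c.frame) if c.frame not in (None, ".") else 0
            segments.append((c.start, c.end, phase))
        gm = GeneModel(gene_id=gene.id, contig=gene.seqid,
                       strand=gene.strand, cds_segments=segments)
        if gm.spliced_length() % 3 != 0:
            raise GeneModelError(
                f"{gene.id}: spliced CDS length {gm.spliced_length()} "
                "not divisible by 3 after phase trimming")
        models.append(gm)
    return models


def reference_cds(gene: GeneModel, reference) -> str:
    """Reference spliced CDS in coding orientation.

    ``reference`` maps contig name to sequence (a pyfaidx.Fasta works).
    Flags the gene if the reference frame contains an internal stop.
    """
    contig_seq = str(reference[gene.contig][:])
    bases = []
    for s, e, _ in gene.cds_segments:
        bases.append(contig_seq[s - 1:e])
    seq = "".join(bases)
    if gene.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    seq = seq[gene.first_phase:]
    for i in range(0, len(seq) - 3, 3):
        if GENETIC_CODE.get(seq[i:i + 3]) == "*":
            gene.flagged = True
            break
    return seq


@dataclass
class AllelePairCDS:
    """A sample's two alleles over one gene's spliced CDS."""

    gene_id: str
    sample: str
    cds_a: str
    cds_b: str

    def __post_init__(self) -> None:
        if len(self.cds_a) != len(self.cds_b):
            raise ValueError("allele sequences must be equal length")

    @property
    def n_het_cds(self) -> int:
        return sum(a != b for a, b in zip(self.cds_a, self.cds_b))


def _gene_site_index(gene: GeneModel, callset: CallSet):
    """Call-set rows landing in the gene's CDS, mapped to CDS coordinates.

    Returns (site_rows, cds_indices, ref_bases, alt_bases) with bases in
    coding orientation (complemented for minus-strand genes).
    """
    positions = gene.coding_positions()
    pos_to_idx = {int(p): i for i, p in enumerate(positions)}
    sites = callset.sites
    on_contig = sites["contig"].to_numpy() == gene.contig
    pos = sites["pos"].to_numpy()
    lo, hi = positions.min(), positions.max()
    cand = np.flatnonzero(on_contig & (pos >= lo) & (pos <= hi))
    rows, cds_idx = [], []
    for i in cand:
        idx = pos_to_idx.get(int(pos[i]))
        if idx is not None:
            rows.append(int(i))
            cds_idx.append(idx)
    refs = sites["ref"].to_numpy()[rows]
    alts = sites["alt"].to_numpy()[rows]
    if gene.strand == "-":
        refs = np.array([r.translate(_COMPLEMENT) for r in refs])
        alts = np.array([a.translate(_COMPLEMENT) for a in alts])
    return np.array(rows, dtype=int), np.array(cds_idx, dtype=int), refs, alts


def _substitute_alleles(gene: GeneModel, ref_cds: str, site_index,
                        gt_column: np.ndarray, sample: str) -> AllelePairCDS:
    rows, cds_idx, refs, alts = site_index
    a = list(ref_cds)
    b = list(ref_cds)
    for row, idx, ref_base, alt_base in zip(rows, cds_idx, refs, alts):
        gt = int(gt_column[row])
        if gt in (MISSING, 0):
            continue
        if a[idx] != ref_base:
            raise GeneModelError(
                f"{gene.gene_id}: SNP ref {ref_base} at CDS index {idx} "
                f"mismatches reference base {a[idx]}")
        b[idx] = alt_base
        if gt == HOM_ALT:
            a[idx] = alt_base
    return AllelePairCDS(gene_id=gene.gene_id, sample=sample,
                         cds_a="".join(a), cds_b="".join(b))


def build_allele_cds(reference, gene: GeneModel, callset: CallSet,
                     sample: str, ref_cds: str | None = None) -> AllelePairCDS:
    """Substitute a sample's SNP genotypes into the reference spliced CDS.

    hom_alt substitutes both alleles; het substitutes allele B only (phase
    is immaterial for per-codon pathway-averaged counting); missing leaves
    the reference base in both.
    """
    if ref_cds is None:
        ref_cds = reference_cds(gene, reference)
    site_index = _gene_site_index(gene, callset)
    j = callset.sample_index(sample)
    return _substitute_alleles(gene, ref_cds, site_index, callset.gt[:, j],
                               sample)


# ---------------------------------------------------------------------------
# NG86 counting

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one codon.

    Each position contributes f/3 synonymous sites, f being the fraction of
    its 3 possible single-base changes that preserve the amino acid; changes
    creating stop codons count as nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for i in range(3):
        preserved = 0
        for base in _BASES:
            if base == codon[i]:
                continue
            mut = codon[:i] + base + codon[i + 1:]
            if GENETIC_CODE[mut] == aa:
                preserved += 1
        syn += preserved / 3.0
    return syn, 3.0 - syn


_SITE_COUNT_CACHE = {c: _codon_site_counts(c)
                     for c in map("".join, product(_BASES, repeat=3))}


def ng86_site_counts(cds: str) -> tuple[float, float, int]:
    """NG86 fractional site totals over a CDS.

    Returns ``(syn_sites, nonsyn_sites, n_codons_skipped)``.  Codons with
    ambiguity codes or internal stops are skipped and counted; a terminal
    stop codon is excluded from the totals.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and GENETIC_CODE.get(codons[-1]) == "*":
        codons = codons[:-1]
    syn = nonsyn = 0.0
    skipped = 0
    for codon in codons:
        counts = _SITE_COUNT_CACHE.get(codon)
        if counts is None or GENETIC_CODE[codon] == "*":
            skipped += 1
            continue
        syn += counts[0]
        nonsyn += counts[1]
    return syn, nonsyn, skipped


def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) difference counts for one codon pair.

    Codons differing at 2-3 positions average over all substitution
    orderings with equal weight; pathways passing through intermediate stop
    codons are excluded when alternatives exist.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        syn = nonsyn = 0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt != c2 and GENETIC_CODE[nxt] == "*":
                through_stop = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((syn, nonsyn, through_stop))
    usable = [p for p in paths if not p[2]] or paths
    syn = sum(p[0] for p in usable) / len(usable)
    nonsyn = sum(p[1] for p in usable) / len(usable)
    return syn, nonsyn


def count_pairwise_differences(pair: AllelePairCDS) -> tuple[float, float]:
    """Pathway-averaged (syn_diffs, nonsyn_diffs) between the two alleles.

    Codons containing ambiguity codes in either allele are skipped; a
    terminal stop codon (in allele A's frame) is excluded.
    """
    a, b = pair.cds_a, pair.cds_b
    n_codons = len(a) // 3
    if n_codons and GENETIC_CODE.get(a[-3:]) == "*":
        n_codons -= 1
    syn = nonsyn = 0.0
    for c in range(n_codons):
        ca, cb = a[3 * c:3 * c + 3], b[3 * c:3 * c + 3]
        if ca not in _SITE_COUNT_CACHE or cb not in _SITE_COUNT_CACHE:
            continue
        if GENETIC_CODE[ca] == "*":  # reference-frame internal stop
            continue
        s, ns = _codon_path_counts(ca, cb)
        syn += s
        nonsyn += ns
    return syn, nonsyn


def jukes_cantor(p: float) -> float:
    """Multiple-substitution correction; identity to first order at p -> 0."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class HaHsRecord:
    """One sample's corrected H_A and H_S on one gene."""

    gene_id: str
    sample: str
    n_het_cds: int
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    h_s: float
    h_a: float

    @property
    def ratio(self) -> float:
        if not np.isfinite(self.h_s) or self.h_s == 0:
            return float("nan")
        return self.h_a / self.h_s


def ha_hs_gene(pair: AllelePairCDS, min_het: int = 5) -> HaHsRecord | None:
    """Per-gene H_A/H_S for one sample; None when fewer than ``min_het``
    heterozygous CDS sites (too little signal for a ratio)."""
    n_het = pair.n_het_cds
    if n_het < min_het:
        return None
    syn_a, nonsyn_a, _ = ng86_site_counts(pair.cds_a)
    syn_b, nonsyn_b, _ = ng86_site_counts(pair.cds_b)
    syn_sites = (syn_a + syn_b) / 2.0
    nonsyn_sites = (nonsyn_a + nonsyn_b) / 2.0
    syn_diffs, nonsyn_diffs = count_pairwise_differences(pair)
    p_s = syn_diffs / syn_sites if syn_sites > 0 else float("nan")
    p_a = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else float("nan")
    return HaHsRecord(
        gene_id=pair.gene_id, sample=pair.sample, n_het_cds=n_het,
        syn_sites=syn_sites, nonsyn_sites=nonsyn_sites,
        syn_diffs=syn_diffs, nonsyn_diffs=nonsyn_diffs,
        h_s=jukes_cantor(p_s) if np.isfinite(p_s) else float("nan"),
        h_a=jukes_cantor(p_a) if np.isfinite(p_a) else float("nan"),
    )


def gene_sample_counts(reference, genes: list[GeneModel], callset: CallSet,
                       samples: list[str] | None = None) -> pd.DataFrame:
    """Uncorrected NG86 counts for every (gene, sample) pair.

    The workhorse table behind both the per-gene records and the
    concatenation bootstrap: columns gene_id, sample, n_het_cds, syn_sites,
    nonsyn_sites, syn_diffs, nonsyn_diffs.
    """
    samples = samples if samples is not None else list(callset.samples)
    rows = []
    for gene in genes:
        ref_seq = reference_cds(gene, reference)
        if gene.flagged:
            continue
        site_index = _gene_site_index(gene, callset)
        for sample in samples:
            j = callset.sample_index(sample)
            pair = _substitute_alleles(gene, ref_seq, site_index,
                                       callset.gt[:, j], sample)
            syn_a, nonsyn_a, _ = ng86_site_counts(pair.cds_a)
            syn_b, nonsyn_b, _ = ng86_site_counts(pair.cds_b)
            syn_d, nonsyn_d = count_pairwise_differences(pair)
            rows.append({
                "gene_id": gene.gene_id, "sample": sample,
                "n_het_cds": pair.n_het_cds,
                "syn_sites": (syn_a + syn_b) / 2.0,
                "nonsyn_sites": (nonsyn_a + nonsyn_b) / 2.0,
                "syn_diffs": syn_d, "nonsyn_diffs": nonsyn_d,
            })
    return pd.DataFrame(rows)


def ha_hs_table(counts: pd.DataFrame, min_het: int = 5) -> pd.DataFrame:
    """Per-gene-per-sample corrected H_A, H_S and ratio (>= min_het rows)."""
    df = counts[counts["n_het_cds"] >= min_het].copy()
    df["h_s"] = [jukes_cantor(d / s) if s > 0 else np.nan
                 for d, s in zip(df["syn_diffs"], df["syn_sites"])]
    df["h_a"] = [jukes_cantor(d / s) if s > 0 else np.nan
                 for d, s in zip(df["nonsyn_diffs"], df["nonsyn_sites"])]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["ratio"] = np.where(df["h_s"] > 0, df["h_a"] / df["h_s"], np.nan)
    return df.reset_index(drop=True)


def gene_mean_ratios(table: pd.DataFrame) -> pd.Series:
    """Per-gene H_A/H_S averaged over qualifying samples (the permutation
    universe: genes with >= min_het heterozygous sites in >= 1 sample)."""
    return table.dropna(subset=["ratio"]).groupby("gene_id")["ratio"].mean()


def genomewide_ha_hs(counts: pd.DataFrame, n_genes: int = 100,
                     reps: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Genome-wide per-sample H_A and H_S by gene-concatenation bootstrap.

    Each replicate samples ``n_genes`` genes without replacement,
    concatenates each sample's allele pairs (i.e. pools NG86 counts) and
    applies the correction to the pooled proportions; the report is the
    per-sample mean over replicates.
    """
    genes = counts["gene_id"].unique()
    if len(genes) < n_genes:
        raise ValueError(
            f"need >= {n_genes} eligible genes, have {len(genes)}")
    rng = np.random.default_rng(seed)
    samples = list(dict.fromkeys(counts["sample"]))
    # gene x sample x [syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs]
    pivot = (counts.set_index(["gene_id", "sample"])
             [["syn_sites", "nonsyn_sites", "syn_diffs", "nonsyn_diffs"]]
             .unstack("sample")
             .reindex(genes))
    cube = pivot.to_numpy().reshape(len(genes), 4, -1)
    sample_order = list(pivot["syn_sites"].columns)

    acc = np.zeros((len(sample_order), 2))
    for _ in range(reps):
        idx = rng.choice(len(genes), size=n_genes, replace=False)
        pooled = cube[idx].sum(axis=0)  # (4, n_samples)
        p_s = pooled[2] / pooled[0]
        p_a = pooled[3] / pooled[1]
        acc[:, 0] += [-0.75 * math.log1p(-4 * p / 3) for p in p_a]
        acc[:, 1] += [-0.75 * math.log1p(-4 * p / 3) for p in p_s]
    acc /= reps
    out = pd.DataFrame(acc, columns=["h_a", "h_s"], index=sample_order)
    out.index.name = "sample"
    return out.loc[[s for s in samples if s in out.index]]


@dataclass
class PermutationResult:
    gene_set: str
    observed_median: float
    n_perm: int
    p_ge: float
    p_le: float
    seed: int | None


def permutation_median_test(gene_ratios: pd.Series | dict[str, float],
                            gene_set: list[str], n_perm: int = 10_000,
                            seed: int | None = None,
                            name: str = "gene_set") -> PermutationResult:
    """Compare a gene set's median H_A/H_S with random same-size sets.

    ``p_ge`` is the fraction of permutation medians that equal or exceed
    the observed median; ``p_le`` the fraction that equal or fall below it.
    """
    ratios = pd.Series(gene_ratios, dtype=float)
    missing = set(gene_set) - set(ratios.index)
    if missing:
        raise KeyError(f"gene set members absent from universe: "
                       f"{sorted(missing)[:5]}")
    k = len(gene_set)
    if k > len(ratios):
        raise ValueError("gene set larger than universe")
    observed = float(ratios.loc[list(gene_set)].median())
    rng = np.random.default_rng(seed)
    values = ratios.to_numpy()
    order = np.argsort(rng.random((n_perm, len(values))), axis=1)[:, :k]
    perm_medians = np.median(values[order], axis=1)
    return PermutationResult(
        gene_set=name, observed_median=observed, n_perm=n_perm,
        p_ge=float((perm_medians >= observed).sum() / n_perm),
        p_le=float((perm_medians <= observed).sum() / n_perm),
        seed=seed,
    )


def wilcoxon_signed_rank_exact(pairs: list[tuple[float, float]]) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value by sign enumeration.

    Zero differences are dropped; ties in |difference| get average ranks.
    The null distribution of W+ is built by enumerating all 2^n sign
    assignments (n <= 20); the two-sided p is ``2 min(P(W <= w), P(W >= w))``
    capped at 1.
    """
    d = np.array([x - y for x, y in pairs], dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    # integerise (average ranks may be half-integers)
    r2 = np.round(ranks * 2).astype(int)
    total = r2.sum()
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= 2.0 ** n
    w2 = int(round(w_plus * 2))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
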