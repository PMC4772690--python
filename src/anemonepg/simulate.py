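"""Synthetic diploid call-set generator with planted selection signatures.

Generates a reference FASTA, GFF3 gene models, a multi-sample VCF, mtDNA
allele-count tables and a truth table that together emulate the statistical
structure of a small panel of clonally propagating sea-anemone genomes:

* 10 samples containing 2 clone pairs and 3 genetic clusters;
* a site-frequency spectrum skewed toward rare alleles (negative Tajima's
  D baseline) mixed with cluster-private shared alleles;
* heterozygote excess relative to Hardy-Weinberg (clonal reproduction),
  implemented as allele-count-preserving hom/hom -> het/het swaps so the
  allele-frequency spectrum — and hence pi and D — is untouched;
* planted balancing regions (intermediate frequencies, elevated
  heterozygosity) and sweep regions (sparse singletons, depressed
  diversity), each long enough to span >= 4 overlapping 100 kb windows;
* coding genes with controlled nonsynonymous/synonymous heterozygosity
  classes for the H_A/H_S machinery;
* per-genotype depth/GQ, missing data, a small hom<->het genotyping-error
  rate producing realistic clone-pair discordance, and a fraction of sites
  planted to violate each hard filter.

Genotypes are simulated directly from allele counts (no coalescent
machinery); the generator is a controllable test harness, not a
population-genetic simulator of record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .callset import HET, HOM_ALT, HOM_REF, MISSING, CallSet
from .coding import GENETIC_CODE, GeneModel, ng86_site_counts, reference_cds
from .io_vcf import write_vcf
from .outliers import OutlierRegion

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

BALANCING = "balancing"
SWEEP = "sweep"
NEUTRAL = "neutral"

#: minimum planted-region span: 4 window steps + 1 window (default geometry)
MIN_REGION_SPAN = 4 * 10_000 + 100_000


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedRegion:
    contig: str
    start: int  # 1-based inclusive
    end: int
    kind: str   # balancing | sweep | neutral

    def __post_init__(self) -> None:
        if self.kind not in (BALANCING, SWEEP, NEUTRAL):
            raise SimulationConfigError(f"unknown region kind {self.kind!r}")
        if self.end - self.start < MIN_REGION_SPAN - 1:
            raise SimulationConfigError(
                f"region {self.contig}:{self.start}-{self.end} shorter than "
                f"{MIN_REGION_SPAN} bp (must span >= 4 consecutive windows)")

    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "PlantedRegion") -> bool:
        return (self.contig == other.contig and self.start <= other.end
                and other.start <= self.end)


_SAMPLES = ("BM1", "BM2", "HI1", "HI2", "HI3", "FL1", "CC7", "UN1", "UN2", "UN3")

# depth means / mt ratios follow the study panel's per-sample scale
_DEPTH_MEANS = (16.0, 17.0, 13.0, 14.0, 15.0, 19.0, 20.0, 13.0, 15.0, 15.0)
_MT_RATIOS = (10, 11, 21, 19, 12, 14, 10, 24, 42, 21)
_TARGET_HET = (0.0052, 0.0053, 0.0055, 0.0058, 0.0042, 0.0047,
               0.0037, 0.0048, 0.0051, 0.0053)


def _default_regions() -> tuple[PlantedRegion, ...]:
    return (
        PlantedRegion("contig_1", 2_000_001, 2_200_000, BALANCING),
        PlantedRegion("contig_2", 1_000_001, 1_200_000, SWEEP),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the generator (all rates per site or
    per genotype; lengths in bp).  Defaults emulate the 10-anemone panel:
    two clone pairs, three clusters, per-sample heterozygosity targets in
    0.37-0.58 %, ~0.37 heterozygous-call fraction at SNP sites, a negative
    genome-wide Tajima's D, and clone discordance near 1.2 %."""

    contigs: tuple[tuple[str, int], ...] = (
        ("contig_1", 3_000_000), ("contig_2", 3_000_000))
    samples: tuple[str, ...] = _SAMPLES
    # (copy, source): the first sample duplicates the second's genotypes
    clone_pairs: tuple[tuple[str, str], ...] = (("BM1", "BM2"), ("HI1", "HI2"))
    clusters: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("bermuda", ("BM1", "BM2")),
        ("hawaii", ("HI1", "HI2", "HI3", "UN1", "UN3")),
        ("south_atlantic", ("FL1", "CC7", "UN2")),
    )
    target_het: tuple[float, ...] = _TARGET_HET      # per sample, proportion
    snp_density: float = 0.002                       # background SNPs per bp
    sfs_mode: str = "skewed"                         # skewed | neutral
    rare_gamma: float = 2.3                          # SFS weight ~ i^-gamma
    share_prob: float = 0.33                         # cluster-shared site share
    shared_alt_prob: float = 0.85                    # alt prob within cluster
    het_boost: float = 1.0                           # hom/hom -> het/het swap prob
    balancing_density_mult: float = 1.2
    sweep_density_mult: float = 0.15
    missing_rate: float = 0.03
    genotype_error_rate: float = 0.006               # hom<->het flip per call
    depth_means: tuple[float, ...] = _DEPTH_MEANS
    depth_dispersion: float = 8.0                    # NB size parameter
    gq_slope: float = 3.0
    gq_sd: float = 10.0
    bad_site_rate: float = 0.02                      # planted filter violations
    n_genes: int = 140
    gene_codon_range: tuple[int, int] = (160, 320)
    max_exons: int = 3
    coding_snps_mean: float = 16.0
    gene_class_counts: tuple[tuple[str, int], ...] = (
        ("background", 90), ("low", 25), ("high", 25))
    gene_class_ratios: tuple[tuple[str, float], ...] = (
        ("background", 0.22), ("low", 0.07), ("high", 0.64))
    planted_regions: tuple[PlantedRegion, ...] = field(
        default_factory=_default_regions)
    mito_length: int = 3_000
    mito_ratios: tuple[float, ...] = _MT_RATIOS

    def __post_init__(self) -> None:
        n = len(self.samples)
        if len(self.target_het) != n or len(self.depth_means) != n \
                or len(self.mito_ratios) != n:
            raise SimulationConfigError("per-sample parameter length mismatch")
        copies = [a for a, _ in self.clone_pairs]
        if len(set(copies)) != len(copies):
            raise SimulationConfigError("clone pairs must be disjoint")
        for a, b in self.clone_pairs:
            if a not in self.samples or b not in self.samples or a == b:
                raise SimulationConfigError(f"bad clone pair ({a}, {b})")
        lengths = dict(self.contigs)
        regions = list(self.planted_regions)
        for r in regions:
            if r.contig not in lengths or r.end > lengths[r.contig] or r.start < 1:
                raise SimulationConfigError(
                    f"region {r.contig}:{r.start}-{r.end} outside contig bounds")
        for i, r in enumerate(regions):
            for s in regions[i + 1:]:
                if r.overlaps(s):
                    raise SimulationConfigError("planted regions overlap")
        for rate in (self.snp_density, self.share_prob, self.het_boost,
                     self.missing_rate, self.genotype_error_rate,
                     self.bad_site_rate):
            if not 0 <= rate <= 1:
                raise SimulationConfigError("rates must lie in [0, 1]")

    # -- derived views ---------------------------------------------------

    def clone_map(self) -> dict[str, str]:
        return {a: b for a, b in self.clone_pairs}

    def genets(self) -> list[str]:
        copies = set(self.clone_map())
        return [s for s in self.samples if s not in copies]

    def cluster_of(self) -> dict[str, str]:
        out = {}
        for name, members in self.clusters:
            for m in members:
                out[m] = name
        return out


# ---------------------------------------------------------------------------
# reference + gene models


@dataclass
class SimulatedReference:
    contigs: dict[str, str]
    genes: list[GeneModel]
    gene_classes: dict[str, str]

    def contig_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.contigs.items()}


def _random_seq(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = [c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_NON_STOP_CODONS), size=n_codons - 2)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(_NON_STOP_CODONS[i] for i in body) + stop


def simulate_reference(config: SimulationConfig,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None
                       ) -> SimulatedReference:
    """Random-composition contigs with multi-exon genes stamped in.

    Every gene is a valid ORF (ATG start, no internal stops, terminal
    stop), placed outside planted regions, on either strand; identical
    seeds give byte-identical output.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    contigs = {name: _random_seq(rng, length) for name, length in config.contigs}
    lengths = dict(config.contigs)

    class_names = [name for name, count in config.gene_class_counts
                   for _ in range(count)]
    if config.n_genes != len(class_names):
        raise SimulationConfigError(
            "gene_class_counts must sum to n_genes")
    rng.shuffle(class_names)

    genes: list[GeneModel] = []
    gene_classes: dict[str, str] = {}
    contig_names = list(lengths)
    ci = 0
    cursor = 5_000
    lo, hi = config.gene_codon_range
    for g in range(config.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        cds = _random_cds(rng, n_codons)
        n_exons = int(rng.integers(1, config.max_exons + 1))
        cuts = sorted(rng.choice(np.arange(3, len(cds) - 3), size=n_exons - 1,
                                 replace=False).tolist()) if n_exons > 1 else []
        pieces = [cds[a:b] for a, b in
                  zip([0] + cuts, cuts + [len(cds)])]
        introns = [int(rng.integers(60, 301)) for _ in range(n_exons - 1)]
        span = sum(map(len, pieces)) + sum(introns)
        strand = "+" if rng.random() < 0.5 else "-"

        placed = False
        while not placed:
            if cursor + span + 1_000 > lengths[contig_names[ci]]:
                ci += 1
                cursor = 5_000
                if ci >= len(contig_names):
                    raise SimulationConfigError(
                        "gene layout exceeds contig space; reduce n_genes")
                continue
            hit = next((r for r in config.planted_regions
                        if r.contig == contig_names[ci]
                        and cursor <= r.end + 5_000
                        and cursor + span >= r.start - 5_000), None)
            if hit is not None:
                cursor = hit.end + 5_001
                continue
            placed = True
        contig = contig_names[ci]

        # genomic order of coding pieces follows the strand
        coding_pieces = pieces if strand == "+" else pieces[::-1]
        if strand == "-":
            coding_pieces = [p.translate(_COMPLEMENT)[::-1] for p in coding_pieces]
        segments = []
        pos = cursor
        seq = contigs[contig]
        for k, piece in enumerate(coding_pieces):
            seq[pos - 1:pos - 1 + len(piece)] = piece.encode()
            segments.append((pos, pos + len(piece) - 1))
            pos += len(piece)
            if k < len(coding_pieces) - 1:
                intron = introns[k] if strand == "+" else introns[::-1][k]
                pos += intron

        # GFF phase per segment in coding order
        coding_order = segments if strand == "+" else segments[::-1]
        phases, consumed = [], 0
        for s, e in coding_order:
            phases.append((3 - consumed % 3) % 3)
            consumed += e - s + 1
        phase_by_segment = dict(zip(coding_order, phases))
        gene_id = f"gene_{g + 1:04d}"
        gm = GeneModel(
            gene_id=gene_id, contig=contig, strand=strand,
            cds_segments=[(s, e, phase_by_segment[(s, e)]) for s, e in segments])
        genes.append(gm)
        gene_classes[gene_id] = class_names[g]
        cursor = pos + int(rng.integers(8_000, 30_000))

    ref = SimulatedReference(
        contigs={k: v.decode() for k, v in contigs.items()},
        genes=genes, gene_classes=gene_classes)
    for gm in genes:  # sanity: stamped ORFs must be clean
        reference_cds(gm, ref.contigs)
        if gm.flagged:
            raise AssertionError(f"{gm.gene_id}: internal stop after stamping")
    return ref


def write_fasta(contigs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(reference: SimulatedReference, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in reference.contig_lengths().items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for gm in reference.genes:
            start = min(s for s, _, _ in gm.cds_segments)
            end = max(e for _, e, _ in gm.cds_segments)
            base = f"{gm.contig}\tanemonepg_sim"
            fh.write(f"{base}\tgene\t{start}\t{end}\t.\t{gm.strand}\t.\t"
                     f"ID={gm.gene_id}\n")
            mrna = f"{gm.gene_id}.t1"
            fh.write(f"{base}\tmRNA\t{start}\t{end}\t.\t{gm.strand}\t.\t"
                     f"ID={mrna};Parent={gm.gene_id}\n")
            for k, (s, e, ph) in enumerate(gm.cds_segments, 1):
                fh.write(f"{base}\texon\t{s}\t{e}\t.\t{gm.strand}\t.\t"
                         f"ID={mrna}.exon{k};Parent={mrna}\n")
                fh.write(f"{base}\tCDS\t{s}\t{e}\t.\t{gm.strand}\t{ph}\t"
                         f"ID={mrna}.cds{k};Parent={mrna}\n")


# ---------------------------------------------------------------------------
# genotype machinery


def _sfs_weights(config: SimulationConfig, n_chrom: int) -> np.ndarray:
    i = np.arange(1, n_chrom)
    gamma = 1.0 if config.sfs_mode == "neutral" else config.rare_gamma
    w = i.astype(float) ** -gamma
    return w / w.sum()


def _assign_count(rng, counts: np.ndarray, n_genets: int) -> np.ndarray:
    """Place exact alt-allele counts on random chromosomes -> genotype rows."""
    m = len(counts)
    out = np.empty((m, n_genets), dtype=np.int8)
    n_chrom = 2 * n_genets
    for s in range(m):
        perm = rng.permutation(n_chrom)
        alt = np.zeros(n_chrom, dtype=np.int8)
        alt[perm[:counts[s]]] = 1
        out[s] = alt[0::2] + alt[1::2]
    return out


def _het_boost(rng, gt: np.ndarray, prob: float) -> None:
    """Convert hom_alt/hom_ref genet pairs to het/het in place.

    Preserves every site's alt-allele count, so pi and Tajima's D are
    unchanged while the heterozygous-call fraction rises (heterozygote
    excess under clonal reproduction)."""
    if prob <= 0:
        return
    for s in range(gt.shape[0]):
        ha = np.flatnonzero(gt[s] == HOM_ALT)
        hr = np.flatnonzero(gt[s] == HOM_REF)
        k = min(len(ha), len(hr))
        if k == 0:
            continue
        n_swap = rng.binomial(k, prob)
        if n_swap == 0:
            continue
        pick_a = rng.choice(ha, size=n_swap, replace=False)
        pick_r = rng.choice(hr, size=n_swap, replace=False)
        gt[s, pick_a] = HET
        gt[s, pick_r] = HET


def _draw_site_block(rng, config: SimulationConfig, m: int, kind: str,
                     genets: list[str]) -> np.ndarray:
    """Genotypes (m x n_genets) for one site category."""
    n_genets = len(genets)
    n_chrom = 2 * n_genets
    if m == 0:
        return np.empty((0, n_genets), dtype=np.int8)
    if kind == SWEEP:
        counts = np.ones(m, dtype=np.int64)
        gt = _assign_count(rng, counts, n_genets)
        return gt
    if kind == BALANCING:
        counts = 1 + rng.binomial(n_chrom - 2, 0.5, size=m)
        gt = _assign_count(rng, counts, n_genets)
        _het_boost(rng, gt, config.het_boost)
        return gt

    # background / coding / neutral regions: mixture of rare + cluster-shared
    weights = _sfs_weights(config, n_chrom)
    share = 0.0 if config.sfs_mode == "neutral" else config.share_prob
    is_shared = rng.random(m) < share
    counts = 1 + rng.choice(len(weights), size=m, p=weights)
    gt = _assign_count(rng, counts, n_genets)

    if is_shared.any():
        cluster_members = []
        sizes = []
        for _, members in config.clusters:
            idx = [genets.index(s) for s in members if s in genets]
            if idx:
                cluster_members.append(np.array(idx))
                sizes.append(len(idx))
        p_cluster = np.array(sizes, dtype=float) / sum(sizes)
        for s in np.flatnonzero(is_shared):
            c = rng.choice(len(cluster_members), p=p_cluster)
            members = cluster_members[c]
            alleles = rng.binomial(2, config.shared_alt_prob, size=len(members))
            if alleles.sum() == 0:
                alleles[rng.integers(0, len(members))] = 1
            row = np.zeros(n_genets, dtype=np.int8)
            row[members] = alleles.astype(np.int8)
            gt[s] = row
    _het_boost(rng, gt, config.het_boost)
    return gt


def _sample_positions(rng, eligible: np.ndarray, density: float) -> np.ndarray:
    """Bernoulli site placement over eligible positions at the given density."""
    n = rng.binomial(len(eligible), density)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.sort(rng.choice(eligible, size=n, replace=False))


# ---------------------------------------------------------------------------
# population simulation


@dataclass
class SimulationTruth:
    """Planted parameters for recovery tests."""

    samples: list[str]
    genets: list[str]
    clone_map: dict[str, str]
    cluster_of: dict[str, str]
    target_het: dict[str, float]
    genotype_error_rate: float
    regions: pd.DataFrame                   # contig, start, end, kind
    gene_classes: dict[str, str]
    gene_class_ratios: dict[str, float]
    true_gt: np.ndarray                     # pre-error, pre-missing
    site_category: np.ndarray               # background|balancing|sweep|coding
    callable_total: dict[str, int]
    n_bad_sites: int
    mito: dict | None = None

    def to_json(self, path) -> None:
        payload = {
            "samples": self.samples,
            "genets": self.genets,
            "clone_map": self.clone_map,
            "cluster_of": self.cluster_of,
            "target_het": self.target_het,
            "genotype_error_rate": self.genotype_error_rate,
            "regions": self.regions.to_dict(orient="records"),
            "gene_classes": self.gene_classes,
            "gene_class_ratios": self.gene_class_ratios,
            "callable_total": self.callable_total,
            "n_sites": int(self.true_gt.shape[0]),
            "n_bad_sites": self.n_bad_sites,
            "mito": self.mito,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _plan_coding_snps(rng, config: SimulationConfig,
                      reference: SimulatedReference):
    """Choose coding SNP positions/alleles hitting each gene's ratio class.

    Returns a list of (contig, pos, ref, alt, gene_id) in arbitrary order.
    At most one SNP per codon; changes never create stop codons.
    """
    ratio_of = dict(config.gene_class_ratios)
    plan = []
    for gm in reference.genes:
        ref_seq = reference_cds(gm, reference.contigs)
        positions = gm.coding_positions()
        target = ratio_of[reference.gene_classes[gm.gene_id]]

        syn_sites = nonsyn_sites = 0.0
        candidates: dict[int, dict[str, list[tuple[int, str]]]] = {}
        n_codons = len(ref_seq) // 3
        for c in range(1, n_codons - 1):      # skip start and stop codons
            codon = ref_seq[3 * c:3 * c + 3]
            aa = GENETIC_CODE[codon]
            per = {"syn": [], "nonsyn": []}
            for j in range(3):
                for b in "ACGT":
                    if b == codon[j]:
                        continue
                    mut = codon[:j] + b + codon[j + 1:]
                    if GENETIC_CODE[mut] == "*":
                        continue
                    per["syn" if GENETIC_CODE[mut] == aa else "nonsyn"].append(
                        (3 * c + j, b))
            candidates[c] = per
        syn_s, nonsyn_s, _ = ng86_site_counts(ref_seq)
        # synonymous share needed for ratio R: f_s = S / (S + R * A)
        f_syn = syn_s / (syn_s + target * nonsyn_s)

        n_snps = min(int(rng.poisson(config.coding_snps_mean)) + 4,
                     n_codons - 2)
        n_syn = rng.binomial(n_snps, f_syn)
        n_nonsyn = n_snps - n_syn

        codon_ids = list(candidates)
        rng.shuffle(codon_ids)
        chosen = []
        for c in codon_ids:
            if n_syn > 0 and candidates[c]["syn"]:
                opts = candidates[c]["syn"]
                chosen.append(opts[rng.integers(0, len(opts))])
                n_syn -= 1
            elif n_nonsyn > 0 and candidates[c]["nonsyn"]:
                opts = candidates[c]["nonsyn"]
                chosen.append(opts[rng.integers(0, len(opts))])
                n_nonsyn -= 1
            if n_syn == 0 and n_nonsyn == 0:
                break
        for cds_idx, alt in chosen:
            genomic_pos = int(positions[cds_idx])
            ref_base = reference.contigs[gm.contig][genomic_pos - 1]
            alt_base = alt if gm.strand == "+" else alt.translate(_COMPLEMENT)
            plan.append((gm.contig, genomic_pos, ref_base, alt_base,
                         gm.gene_id))
    return plan


def simulate_population(config: SimulationConfig,
                        reference: SimulatedReference,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[CallSet, SimulationTruth]:
    """Simulate the joint call-set over the reference and its gene models."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    genets = config.genets()
    lengths = reference.contig_lengths()
    clone_map = config.clone_map()

    cds_positions = {name: set() for name in lengths}
    for gm in reference.genes:
        for s, e, _ in gm.cds_segments:
            cds_positions[gm.contig].update(range(s, e + 1))

    records = []  # (contig, pos, ref, alt, category, gene_id)
    for contig, length in lengths.items():
        regions = [r for r in config.planted_regions if r.contig == contig]
        blocked = np.zeros(length + 1, dtype=bool)
        for r in regions:
            blocked[r.start:r.end + 1] = True
        if cds_positions[contig]:
            blocked[np.fromiter(cds_positions[contig], dtype=np.int64)] = True
        eligible = np.flatnonzero(~blocked[1:]) + 1
        for pos in _sample_positions(rng, eligible, config.snp_density):
            records.append((contig, int(pos), None, None, "background", None))
        for r in regions:
            mult = {BALANCING: config.balancing_density_mult,
                    SWEEP: config.sweep_density_mult,
                    NEUTRAL: 1.0}[r.kind]
            span = np.arange(r.start, r.end + 1)
            span = span[~np.isin(span, list(cds_positions[contig]))] \
                if cds_positions[contig] else span
            for pos in _sample_positions(rng, span,
                                         config.snp_density * mult):
                records.append((contig, int(pos), None, None, r.kind, None))

    for contig, pos, ref_b, alt_b, gene_id in _plan_coding_snps(
            rng, config, reference):
        records.append((contig, pos, ref_b, alt_b, "coding", gene_id))

    # allele assignment for non-coding sites
    filled = []
    for contig, pos, ref_b, alt_b, cat, gene_id in records:
        if ref_b is None:
            ref_b = reference.contigs[contig][pos - 1]
            others = [b for b in "ACGT" if b != ref_b]
            # transition-rich spectrum: favour the transition partner
            transition = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_b]
            if rng.random() < 0.58:
                alt_b = transition
            else:
                tv = [b for b in others if b != transition]
                alt_b = tv[rng.integers(0, len(tv))]
        filled.append((contig, pos, ref_b, alt_b, cat, gene_id))

    sites = pd.DataFrame(filled, columns=["contig", "pos", "ref", "alt",
                                          "category", "gene_id"])
    sites = sites.drop_duplicates(["contig", "pos"], keep="first")
    sites = sites.sort_values(["contig", "pos"], kind="mergesort",
                              ignore_index=True)
    m = len(sites)

    # genotypes per category (order within category preserved by index)
    gt_genets = np.zeros((m, len(genets)), dtype=np.int8)
    categories = sites["category"].to_numpy()
    for cat in ("background", "coding", NEUTRAL, BALANCING, SWEEP):
        sel = np.flatnonzero(categories == cat)
        kind = cat if cat in (BALANCING, SWEEP) else "background"
        gt_genets[sel] = _draw_site_block(rng, config, len(sel), kind, genets)

    # expand genets -> samples; clones copy their source genet
    sample_source = [clone_map.get(s, s) for s in config.samples]
    col_of = {g: i for i, g in enumerate(genets)}
    true_gt = gt_genets[:, [col_of[src] for src in sample_source]].copy()

    # observed genotypes: error flips then missingness
    gt = true_gt.copy()
    flip = rng.random(gt.shape) < config.genotype_error_rate
    hets = flip & (gt == HET)
    homs = flip & ((gt == HOM_REF) | (gt == HOM_ALT))
    gt[hets] = np.where(rng.random(int(hets.sum())) < 0.5,
                        HOM_REF, HOM_ALT)
    gt[homs] = HET
    post_error_gt = gt.copy()
    gt[rng.random(gt.shape) < config.missing_rate] = MISSING

    # depth / GQ
    mu = np.array(config.depth_means)
    r = config.depth_dispersion
    dp = rng.negative_binomial(r, r / (r + mu), size=(m, len(mu))).astype(np.int32)
    gq = np.rint(config.gq_slope * dp
                 + rng.normal(0.0, config.gq_sd, size=dp.shape))
    gq = np.clip(gq, 0, 99).astype(np.int32)


    # site-level annotations
    info = {
        "QD": np.round(np.clip(rng.normal(22, 4, m), 5, 40), 2),
        "FS": np.round(rng.exponential(3.0, m), 2),
        "MQ": np.round(rng.normal(55, 3, m), 2),
        "HaplotypeScore": np.round(rng.exponential(2.0, m), 2),
        "MQRankSum": np.round(rng.normal(0, 1.5, m), 2),
        "ReadPosRankSum": np.round(rng.normal(0, 1.5, m), 2),
    }
    qual = np.round(np.clip(rng.normal(900, 250, m), 60, None), 2)

    # planted hard-filter violations
    bad = np.flatnonzero(rng.random(m) < config.bad_site_rate)
    rules = rng.integers(0, 9, size=len(bad))
    for idx, rule in zip(bad, rules):
        if rule == 0:
            qual[idx] = round(rng.uniform(10, 49), 2)
        elif rule == 1:
            dp[idx] = np.maximum(dp[idx] // 4, 0)
        elif rule == 2:
            dp[idx] = dp[idx] * 3 + 10
        elif rule == 3:
            info["QD"][idx] = round(rng.uniform(0.2, 1.9), 2)
        elif rule == 4:
            info["FS"][idx] = round(rng.uniform(41, 90), 2)
        elif rule == 5:
            info["MQ"][idx] = round(rng.uniform(20, 39), 2)
        elif rule == 6:
            info["HaplotypeScore"][idx] = round(rng.uniform(13.5, 30), 2)
        elif rule == 7:
            info["MQRankSum"][idx] = round(rng.uniform(-20, -12.6), 2)
        else:
            info["ReadPosRankSum"][idx] = round(rng.uniform(-15, -8.1), 2)

    # Heterozygosity-target bookkeeping.  callable_total plays the role of
    # the external per-sample count of positions meeting coverage/quality
    # requirements; positions are thinned by the same per-sample genotype
    # pass rate that thins the heterozygous calls, so the H_I estimator is
    # unbiased for the planted target.  Sites planted to violate a hard
    # filter are left out (they leave the call-set before H_I is measured);
    # 8x / GQ 24 are the genotype-calling conditions the panel emulates.
    genome_len = sum(lengths.values())
    good = np.ones(m, dtype=bool)
    good[bad] = False
    pass_mask = (gt != MISSING) & (dp >= 8) & (gq >= 24)
    callable_total = {}
    for j, sample in enumerate(config.samples):
        n_het = int((post_error_gt[good, j] == HET).sum())
        pass_rate = float(pass_mask[good, j].mean()) if good.any() else 1.0
        target = config.target_het[j]
        callable_s = int(round(n_het * pass_rate / target
                               + good.sum() * (1.0 - pass_rate)))
        if callable_s > genome_len:
            raise SimulationConfigError(
                f"target_het={target} for {sample} is not achievable at "
                f"snp_density={config.snp_density}: requires "
                f"{callable_s} callable bp > genome of {genome_len} bp")
        callable_total[sample] = callable_s

    # rank-sum annotations exist only where a heterozygous call exists
    has_het = (gt == HET).any(axis=1)
    forced = np.zeros(m, dtype=bool)
    forced[bad[np.isin(rules, (7, 8))]] = True
    for key in ("MQRankSum", "ReadPosRankSum"):
        info[key] = np.where(has_het | forced, info[key], np.nan)

    site_table = pd.DataFrame({
        "contig": sites["contig"], "pos": sites["pos"],
        "ref": sites["ref"], "alt": sites["alt"],
        "qual": qual, "total_depth": dp.sum(axis=1),
        **info,
    })
    callset = CallSet(sites=site_table, samples=list(config.samples),
                      gt=gt, dp=dp, gq=gq,
                      provenance=["simulated"])

    truth = SimulationTruth(
        samples=list(config.samples),
        genets=genets,
        clone_map=clone_map,
        cluster_of=config.cluster_of(),
        target_het=dict(zip(config.samples, config.target_het)),
        genotype_error_rate=config.genotype_error_rate,
        regions=pd.DataFrame(
            [{"contig": rr.contig, "start": rr.start, "end": rr.end,
              "kind": rr.kind} for rr in config.planted_regions]),
        gene_classes=dict(reference.gene_classes),
        gene_class_ratios=dict(config.gene_class_ratios),
        true_gt=true_gt,
        site_category=sites["category"].to_numpy(),
        callable_total=callable_total,
        n_bad_sites=len(bad),
    )
    return callset, truth


# ---------------------------------------------------------------------------
# mtDNA


def simulate_mtdna(config: SimulationConfig,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[str, dict[str, pd.DataFrame], dict]:
    """Mitochondrial reference, per-sample allele-count tables and truth.

    Plants one fixed synonymous-style SNP in one sample, one heteroplasmic
    site shared by a clone pair, and per-sample coverage at the configured
    mtDNA:nuclear ratios.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    mito = _random_seq(rng, config.mito_length).decode()
    L = config.mito_length

    snp_pos = int(rng.integers(100, L // 2))
    het_pos = int(rng.integers(L // 2 + 1, L - 100))
    snp_sample = "CC7" if "CC7" in config.samples else config.samples[0]
    het_samples = [s for s in config.clone_pairs[0]] if config.clone_pairs \
        else [config.samples[-1]]
    alt_of = {"A": "G", "G": "A", "C": "T", "T": "C"}
    snp_alt = alt_of[mito[snp_pos - 1]]
    het_alt = alt_of[mito[het_pos - 1]]

    tables = {}
    for j, sample in enumerate(config.samples):
        mean_cov = config.mito_ratios[j] * config.depth_means[j]
        depth = rng.poisson(mean_cov, size=L)
        counts = {b: np.zeros(L, dtype=np.int64) for b in "ACGT"}
        ref_idx = np.frombuffer(mito.encode(), dtype="S1")
        for b in "ACGT":
            counts[b][ref_idx == b.encode()] = depth[ref_idx == b.encode()]
        if sample == snp_sample:
            d = depth[snp_pos - 1]
            counts[mito[snp_pos - 1]][snp_pos - 1] = int(round(d * 0.03))
            counts[snp_alt][snp_pos - 1] = d - int(round(d * 0.03))
        if sample in het_samples:
            d = depth[het_pos - 1]
            alt_reads = rng.binomial(d, 0.45)
            counts[mito[het_pos - 1]][het_pos - 1] = d - alt_reads
            counts[het_alt][het_pos - 1] = alt_reads
        tables[sample] = pd.DataFrame({
            "pos": np.arange(1, L + 1),
            **{b: counts[b] for b in "ACGT"},
        })

    truth = {
        "fixed_snp": {"sample": snp_sample, "pos": snp_pos,
                      "ref": mito[snp_pos - 1], "alt": snp_alt},
        "heteroplasmy": {"samples": het_samples, "pos": het_pos,
                         "ref": mito[het_pos - 1], "alt": het_alt},
        "ratios": dict(zip(config.samples,
                           [float(x) for x in config.mito_ratios])),
    }
    return mito, tables, truth


# ---------------------------------------------------------------------------
# one-call dataset + recovery scoring


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: SimulatedReference
    callset: CallSet
    truth: SimulationTruth
    mito_reference: str
    mito_tables: dict[str, pd.DataFrame]


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None,
                     out_dir=None) -> SimulatedDataset:
    """Generate reference, call-set and mtDNA tables in one seeded pass.

    With ``out_dir`` set, writes ref.fa, genes.gff3, variants.vcf,
    mito.fa, mito_counts_<sample>.tsv and truth.json there.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    reference = simulate_reference(config, rng=rng)
    callset, truth = simulate_population(config, reference, rng=rng)
    mito, tables, mito_truth = simulate_mtdna(config, rng=rng)
    truth.mito = mito_truth
    ds = SimulatedDataset(config=config, reference=reference, callset=callset,
                          truth=truth, mito_reference=mito, mito_tables=tables)
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(reference.contigs, out / "ref.fa")
        write_gff3(reference, out / "genes.gff3")
        write_vcf(callset, out / "variants.vcf",
                  contig_lengths=reference.contig_lengths())
        write_fasta({"mito": mito}, out / "mito.fa")
        for sample, table in tables.items():
            table.to_csv(out / f"mito_counts_{sample}.tsv", sep="\t",
                         index=False)
        truth.to_json(out / "truth.json")
    return ds


_KIND_DIRECTION = {BALANCING: "high", SWEEP: "low"}


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> bool:
    inter = min(a_end, b_end) - max(a_start, b_start) + 1
    if inter <= 0:
        return False
    return (inter / (a_end - a_start + 1) >= 0.5
            and inter / (b_end - b_start + 1) >= 0.5)


def evaluate_recovery(regions_called: list[OutlierRegion],
                      truth: SimulationTruth) -> pd.DataFrame:
    """Precision/recall of called outlier regions against planted regions.

    A called region matches a planted region when their reciprocal overlap
    is >= 50 % and the call's direction agrees with the planted kind
    (balancing -> high, sweep -> low).  Rows are reported per statistic and
    kind plus an ``overall`` row where a planted region counts as recovered
    when any statistic finds it.  Precision is NaN when nothing was called.
    """
    tr = truth.regions[truth.regions["kind"] != NEUTRAL]
    rows = []
    statistics = sorted({r.statistic for r in regions_called}) or []

    def score(calls, kinds):
        t = tr[tr["kind"].isin(kinds)]
        matched_truth = set()
        matched_calls = 0
        for ci, call in enumerate(calls):
            hit = False
            for ti, trow in t.iterrows():
                if (call.contig == trow.contig
                        and _KIND_DIRECTION[trow.kind] == call.direction
                        and _reciprocal_overlap(call.start, call.end,
                                                trow.start, trow.end)):
                    matched_truth.add(ti)
                    hit = True
            matched_calls += hit
        precision = matched_calls / len(calls) if calls else float("nan")
        recall = len(matched_truth) / len(t) if len(t) else float("nan")
        return len(calls), len(t), precision, recall

    all_kinds = [BALANCING, SWEEP]
    for stat in statistics:
        for kind in all_kinds:
            calls = [c for c in regions_called
                     if c.statistic == stat
                     and c.direction == _KIND_DIRECTION[kind]]
            n_called, n_truth, precision, recall = score(calls, [kind])
            rows.append({"statistic": stat, "kind": kind,
                         "n_called": n_called, "n_truth": n_truth,
                         "precision": precision, "recall": recall})
    n_called, n_truth, precision, recall = score(list(regions_called),
                                                 all_kinds)
    rows.append({"statistic": "overall", "kind": "any",
                 "n_called": n_called, "n_truth": n_truth,
                 "precision": precision, "recall": recall})
    return pd.DataFrame(rows)
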