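"""Outlier-region scanning and gene-set enrichment.

Window statistics are converted to z-scores against genome-wide moments
(sample SD, n-1); outlier regions are maximal runs of at least
``min_consecutive`` same-direction windows beyond ``threshold`` SD, where
consecutiveness requires adjacent starts exactly one step apart on one
contig (a flagged or missing window breaks a run, as does a sign change).
Genes overlapping a region by >= 1 bp are collected, and gene-list
enrichment uses the upper-tail hypergeometric test with Benjamini-Yekutieli
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class DegenerateTrackError(ValueError):
    pass


@dataclass
class ZScoreTrack:
    """Per-window z-scores of one statistic plus the genome-wide moments."""

    statistic: str
    windows: pd.DataFrame  # contig, start, end, value, z, ok
    mean: float
    sd: float
    step: int


@dataclass
class OutlierRegion:
    contig: str
    start: int
    end: int
    statistic: str
    direction: str  # "high" | "low"
    n_windows: int
    peak_z: float


def zscore_windows(records: pd.DataFrame, statistic: str,
                   step: int | None = None) -> ZScoreTrack:
    """Standardise a window statistic against its genome-wide moments.

    ``statistic`` names a column of ``records`` (e.g. ``h_w``, ``pi_per_bp``
    or ``tajimas_d``).  Flagged or missing windows get no z-score and do not
    enter the mean/SD.
    """
    if statistic not in records.columns:
        raise KeyError(f"no column {statistic!r} in window records")
    df = records[["contig", "start", "end"]].copy()
    df["value"] = records[statistic].to_numpy(dtype=float)
    flagged = records["flagged"].to_numpy() if "flagged" in records else \
        np.zeros(len(records), dtype=bool)
    df["ok"] = ~flagged & ~np.isnan(df["value"])
    ok_vals = df.loc[df["ok"], "value"]
    if len(ok_vals) < 2:
        raise DegenerateTrackError("need >= 2 usable windows")
    mean = float(ok_vals.mean())
    sd = float(ok_vals.std(ddof=1))
    if sd == 0:
        raise DegenerateTrackError("constant track: zero variance")
    df["z"] = np.where(df["ok"], (df["value"] - mean) / sd, np.nan)
    if step is None:
        diffs = df.groupby("contig")["start"].diff().dropna()
        step = int(diffs.min()) if len(diffs) else 0
    return ZScoreTrack(statistic=statistic, windows=df, mean=mean, sd=sd,
                       step=step)


def call_outlier_regions(track: ZScoreTrack, threshold: float = 3.0,
                         min_consecutive: int = 4) -> list[OutlierRegion]:
    """Maximal runs of >= ``min_consecutive`` consecutive extreme windows.

    Member windows all satisfy ``|z| > threshold`` with a common sign; a
    region's span is the union of its member windows.
    """
    df = track.windows.sort_values(["contig", "start"], kind="mergesort")
    regions: list[OutlierRegion] = []
    run: list[pd.Series] = []
    run_dir = 0

    def flush() -> None:
        nonlocal run, run_dir
        if len(run) >= min_consecutive:
            zs = [w.z for w in run]
            regions.append(OutlierRegion(
                contig=run[0].contig,
                start=int(run[0].start),
                end=int(run[-1].end),
                statistic=track.statistic,
                direction="high" if run_dir > 0 else "low",
                n_windows=len(run),
                peak_z=float(max(zs, key=abs)),
            ))
        run, run_dir = [], 0

    for w in df.itertuples():
        if not w.ok or np.isnan(w.z) or abs(w.z) <= threshold:
            flush()
            continue
        direction = 1 if w.z > 0 else -1
        contiguous = (
            run
            and w.contig == run[-1].contig
            and w.start - run[-1].start == track.step
            and direction == run_dir
        )
        if not contiguous:
            flush()
            run_dir = direction
        run.append(w)
    flush()
    return regions


def regions_to_frame(regions: list[OutlierRegion]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in regions],
                        columns=["contig", "start", "end", "statistic",
                                 "direction", "n_windows", "peak_z"])


def genes_in_regions(regions: list[OutlierRegion], annotation
                     ) -> tuple[dict[int, list[str]], list[str]]:
    """Genes whose span overlaps each region by >= 1 bp.

    Returns (per-region gene-id lists keyed by region index, deduplicated
    union preserving first-seen order).
    """
    genes = [(g.seqid, g.start, g.end, g.id)
             for g in annotation.features_of_type("gene")]
    per_region: dict[int, list[str]] = {}
    union: list[str] = []
    seen = set()
    for idx, r in enumerate(regions):
        hits = [gid for seqid, s, e, gid in genes
                if seqid == r.contig and s <= r.end and e >= r.start]
        per_region[idx] = hits
        for gid in hits:
            if gid not in seen:
                seen.add(gid)
                union.append(gid)
    return per_region, union


def enrichment(gene_list: list[str], universe: list[str],
               term_map: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric term enrichment of ``gene_list`` within ``universe``.

    ``term_map`` is a two-column frame (gene_id, term_id), one row per
    gene/term pair.  For each term with at least one list hit, the raw
    p-value is the upper tail P(X >= k) with population N = |universe|,
    K universe genes carrying the term, n = |gene_list|; adjusted p-values
    use the Benjamini-Yekutieli step-up procedure over all tested terms.
    """
    universe_set = set(universe)
    missing = set(gene_list) - universe_set
    if missing:
        raise ValueError(f"genes absent from universe: {sorted(missing)[:5]}")
    list_set = set(gene_list)
    tm = term_map.iloc[:, :2].copy()
    tm.columns = ["gene_id", "term_id"]
    tm = tm[tm["gene_id"].isin(universe_set)].drop_duplicates()

    N, n = len(universe_set), len(list_set)
    rows = []
    for term, grp in tm.groupby("term_id", sort=True):
        term_genes = set(grp["gene_id"])
        k = len(term_genes & list_set)
        if k == 0:
            continue
        K = len(term_genes)
        p_raw = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N,
                     "p_raw": p_raw})
    if not rows:
        return pd.DataFrame(columns=["term_id", "k", "K", "n", "N",
                                     "p_raw", "p_adj"])
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_by")[1]
    return out.sort_values("p_raw", ignore_index=True)
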