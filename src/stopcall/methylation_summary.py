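"""WGBS summary statistics: tiles, sample similarity, elements, HMP calls.

Per-CpG methylated/unmethylated counts (bedGraph-style tables) are summarised
into fixed 1-kb tile means (CpGs with coverage >= 3X, tiles with >= 3 usable
CpGs), pairwise sample similarity (1 minus the min-max-normalized Euclidean
distance over shared tiles), per-element means (promoters = TSS +/- 2 kb,
strand-aware), and hypermethylated-element calls (group difference > 30% with
per-element Welch t-test p < 0.05).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .annotation_io import TranscriptModel

logger = logging.getLogger(__name__)

CPG_COLUMNS = ("contig", "pos", "meth", "unmeth")


def read_cpg_table(path, columns: tuple[str, ...] = CPG_COLUMNS) -> pd.DataFrame:
    """Read a per-CpG count table (TSV: contig, position, methylated count,
    unmethylated count). Column order is configurable via ``columns``."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.iloc[:, : len(columns)]
    df.columns = list(columns)
    return validate_cpgs(df[list(CPG_COLUMNS)])


def validate_cpgs(cpgs: pd.DataFrame) -> pd.DataFrame:
    missing = set(CPG_COLUMNS) - set(cpgs.columns)
    if missing:
        raise ValueError(f"CpG table missing columns {sorted(missing)}")
    if (cpgs["meth"] < 0).any() or (cpgs["unmeth"] < 0).any():
        raise ValueError("negative methylation counts")
    return cpgs


def _usable(cpgs: pd.DataFrame, min_cov: int) -> pd.DataFrame:
    cpgs = validate_cpgs(cpgs)
    cov = cpgs["meth"] + cpgs["unmeth"]
    out = cpgs.loc[cov >= min_cov].copy()
    out["level"] = out["meth"] / (out["meth"] + out["unmeth"])
    return out


def tile_methylation(
    cpgs: pd.DataFrame,
    tile_size: int = 1000,
    min_cpg: int = 3,
    min_cov: int = 3,
) -> pd.DataFrame:
    """Mean methylation per fixed-grid tile.

    Tiles lie on the grid [k*tile_size, (k+1)*tile_size). CpGs below the
    coverage threshold are dropped before tiling; tiles with fewer than
    ``min_cpg`` usable CpGs are reported with an undefined (NaN) level. The
    per-tile mean is the unweighted mean of per-CpG levels. Result is
    invariant to input record order.
    """
    usable = _usable(cpgs, min_cov)
    all_tiles = cpgs.assign(tile=cpgs["pos"] // tile_size)
    keys = all_tiles[["contig", "tile"]].drop_duplicates()
    if usable.empty:
        grouped = pd.DataFrame(columns=["contig", "tile", "n_cpg_used", "mean_level"])
    else:
        usable = usable.assign(tile=usable["pos"] // tile_size)
        grouped = (
            usable.groupby(["contig", "tile"], sort=True)["level"]
            .agg(n_cpg_used="size", mean_level="mean")
            .reset_index()
        )
    out = keys.merge(grouped, on=["contig", "tile"], how="left")
    out["n_cpg_used"] = out["n_cpg_used"].fillna(0).astype(int)
    out.loc[out["n_cpg_used"] < min_cpg, "mean_level"] = np.nan
    out["start"] = out["tile"] * tile_size
    out["end"] = out["start"] + tile_size
    out = out.sort_values(["contig", "tile"], kind="mergesort").reset_index(drop=True)
    return out[["contig", "start", "end", "n_cpg_used", "mean_level"]]


def tile_matrix(samples: dict[str, pd.DataFrame], **kwargs) -> pd.DataFrame:
    """Stack tile_methylation outputs for several samples into a samples x
    tiles level matrix (tiles indexed by contig:start)."""
    rows = {}
    for name, cpgs in samples.items():
        tiles = tile_methylation(cpgs, **kwargs)
        key = tiles["contig"].astype(str) + ":" + tiles["start"].astype(str)
        rows[name] = pd.Series(tiles["mean_level"].values, index=key)
    return pd.DataFrame(rows).T


def sample_similarity(levels: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample similarity = 1 - min-max-normalized Euclidean distance.

    ``levels`` is a samples x tiles matrix; tiles undefined (NaN) in any
    sample are dropped listwise. Normalization uses off-diagonal distances
    only; the diagonal is fixed at 1. When all pairwise distances are equal
    the off-diagonal similarities are defined as 1 with a warning.
    """
    if levels.shape[0] < 2:
        raise ValueError("need at least two samples")
    complete = levels.dropna(axis=1, how="any")
    if complete.shape[1] == 0:
        raise ValueError("no tiles defined in every sample")
    d = pdist(complete.values, metric="euclidean")
    d_min, d_max = d.min(), d.max()
    if d_max == d_min:
        warnings.warn("all pairwise distances equal; similarities set to 1")
        sim_flat = np.ones_like(d)
    else:
        sim_flat = 1.0 - (d - d_min) / (d_max - d_min)
    sim = squareform(sim_flat)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=levels.index, columns=levels.index)


def promoters_from_transcripts(
    transcripts: list[TranscriptModel], flank: int = 2000
) -> pd.DataFrame:
    """Promoter elements: TSS - flank .. TSS + flank, honoring strand."""
    rows = []
    for t in transcripts:
        tss = t.tss
        rows.append(
            {
                "element_id": f"promoter:{t.transcript_id}",
                "contig": t.contig,
                "start": max(0, tss - flank),
                "end": tss + flank,
                "class": "promoter",
            }
        )
    return pd.DataFrame(rows)


def element_methylation(
    cpgs: pd.DataFrame,
    elements: pd.DataFrame,
    min_cpg: int = 3,
    min_cov: int = 3,
) -> pd.DataFrame:
    """Unweighted mean CpG level per element.

    ``elements`` has columns element_id, contig, start, end (and optionally
    class). Elements with fewer than ``min_cpg`` usable CpGs get NaN.
    """
    usable = _usable(cpgs, min_cov)
    rows = []
    for el in elements.to_dict("records"):
        sel = usable[
            (usable["contig"] == el["contig"])
            & (usable["pos"] >= el["start"])
            & (usable["pos"] < el["end"])
        ]
        n = len(sel)
        rows.append(
            {
                "element_id": el["element_id"],
                "contig": el["contig"],
                "start": el["start"],
                "end": el["end"],
                "class": el.get("class", "custom"),
                "n_cpg_used": n,
                "mean_level": sel["level"].mean() if n >= min_cpg else np.nan,
            }
        )
    return pd.DataFrame(rows)


def call_hypermethylated(
    group_a: list[pd.DataFrame],
    group_b: list[pd.DataFrame],
    diff_min: float = 0.30,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call elements hypermethylated in group A versus group B.

    Inputs are per-replicate element_methylation tables. Per element a
    two-sided Welch t-test compares replicate means; an element is called
    hypermethylated when mean_A - mean_B > ``diff_min`` (strict) and the raw
    p-value < ``alpha`` (strict). A Benjamini-Hochberg column is reported
    alongside but the raw p is the calling criterion. Elements with fewer
    than 2 defined replicates in either group are skipped with a warning.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")

    def stack(reps: list[pd.DataFrame]) -> pd.DataFrame:
        mat = {}
        for i, rep in enumerate(reps):
            mat[i] = pd.Series(
                rep["mean_level"].values, index=rep["element_id"].values
            )
        return pd.DataFrame(mat)

    a, b = stack(group_a), stack(group_b)
    elements = a.index.union(b.index)
    rows = []
    skipped = 0
    for el in elements:
        va = a.loc[el].dropna().values if el in a.index else np.array([])
        vb = b.loc[el].dropna().values if el in b.index else np.array([])
        if len(va) < 2 or len(vb) < 2:
            skipped += 1
            continue
        mean_a, mean_b = float(va.mean()), float(vb.mean())
        diff = mean_a - mean_b
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            p = 1.0 if mean_a == mean_b else 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p = ttest_ind(va, vb, equal_var=False)
            p = float(p)
            if np.isnan(p):
                p = 1.0
        rows.append(
            {
                "element_id": el,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "difference": diff,
                "p_value": p,
                "is_hyper": bool(diff > diff_min and p < alpha),
            }
        )
    if skipped:
        logger.warning("skipped %d elements with <2 defined replicates", skipped)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
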