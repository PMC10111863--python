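"""Genomic interval algebra and annotation.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1`` and two intervals overlap
iff they share at least one base; half-open adjacency (``end == start``) is
not an overlap. Summits are absolute 0-based single-base positions.

Peak sets are plain :class:`pandas.DataFrame` objects with at least the
columns ``chrom``, ``start``, ``end`` and optionally ``name`` (unique ids),
``score``, ``strand`` and ``summit``. TSS tables carry ``gene_id``,
``symbol``, ``chrom``, ``strand``, ``tss``, ``gene_start``, ``gene_end``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "validate_intervals",
    "interval_centers",
    "intersect_any",
    "merge_overlapping",
    "nearest_tss",
    "annotate_site",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_bedgraph",
    "write_bedgraph",
    "step_track",
    "interval_signal",
]

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def validate_intervals(df: pd.DataFrame, name: str = "intervals") -> None:
    """Check 0 <= start < end for every record; raise ``ValueError`` naming
    the first offending record, and check summits lie inside their interval."""
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{name}: missing required column {col!r}")
    start = np.asarray(df["start"], dtype=np.int64)
    end = np.asarray(df["end"], dtype=np.int64)
    bad = np.flatnonzero((start < 0) | (start >= end))
    if bad.size:
        i = int(bad[0])
        ident = df["name"].iloc[i] if "name" in df.columns else df.index[i]
        raise ValueError(
            f"{name}: malformed interval {ident!r} "
            f"({df['chrom'].iloc[i]}:{start[i]}-{end[i]}): requires 0 <= start < end"
        )
    if "summit" in df.columns:
        summit = pd.to_numeric(df["summit"], errors="coerce").to_numpy(dtype=float)
        have = ~np.isnan(summit)
        bad = np.flatnonzero(have & ((summit < start) | (summit >= end)))
        if bad.size:
            i = int(bad[0])
            ident = df["name"].iloc[i] if "name" in df.columns else df.index[i]
            raise ValueError(f"{name}: summit of {ident!r} outside its interval")


def interval_centers(df: pd.DataFrame) -> np.ndarray:
    """Peak center = floor((start + end) / 2)."""
    start = np.asarray(df["start"], dtype=np.int64)
    end = np.asarray(df["end"], dtype=np.int64)
    return (start + end) // 2


def _merged_arrays(reference: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome sorted, merged (starts, ends) arrays."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in reference.groupby("chrom", sort=False):
        s = np.asarray(grp["start"], dtype=np.int64)
        e = np.asarray(grp["end"], dtype=np.int64)
        order = np.argsort(s, kind="stable")
        s, e = s[order], e[order]
        # collapse to disjoint runs
        if s.size:
            run_end = np.maximum.accumulate(e)
            new_run = np.empty(s.size, dtype=bool)
            new_run[0] = True
            new_run[1:] = s[1:] > run_end[:-1]
            idx = np.flatnonzero(new_run)
            ms = s[idx]
            last = np.append(idx[1:], s.size) - 1
            me = run_end[last]
            out[str(chrom)] = (ms, me)
    return out


def intersect_any(query: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Per-query boolean: does the query interval share >= 1 bp with any
    reference interval on the same chromosome? Query order preserved."""
    validate_intervals(query, "query")
    validate_intervals(reference, "reference")
    merged = _merged_arrays(reference)
    flags = np.zeros(len(query), dtype=bool)
    qs = np.asarray(query["start"], dtype=np.int64)
    qe = np.asarray(query["end"], dtype=np.int64)
    chroms = np.asarray(query["chrom"], dtype=object)
    for chrom in pd.unique(chroms):
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        sel = np.flatnonzero(chroms == chrom)
        # last merged interval starting before the query end; merged runs are
        # disjoint and sorted, so its end bounds all earlier ends too
        pos = np.searchsorted(ms, qe[sel], side="left") - 1
        ok = pos >= 0
        hit = np.zeros(sel.size, dtype=bool)
        hit[ok] = me[pos[ok]] > qs[sel][ok]
        flags[sel] = hit
    return flags


def merge_overlapping(peaks: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping intervals into disjoint runs, sorted by
    (chrom, start). The merged record keeps the summit (and name) of the
    highest-score member; without a score column the first member wins."""
    validate_intervals(peaks, "peaks")
    if len(peaks) == 0:
        return peaks.copy()
    df = peaks.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    start = df["start"].to_numpy(np.int64)
    end = df["end"].to_numpy(np.int64)
    chrom = df["chrom"].to_numpy(object)
    # running max of ends must reset at each chromosome
    run_end = end.copy()
    seg_starts = np.flatnonzero(np.concatenate([[True], chrom[1:] != chrom[:-1]]))
    seg_bounds = np.append(seg_starts, len(df))
    for s, e in zip(seg_bounds[:-1], seg_bounds[1:]):
        run_end[s:e] = np.maximum.accumulate(end[s:e])
    new_run = np.empty(len(df), dtype=bool)
    new_run[0] = True
    new_run[1:] = (chrom[1:] != chrom[:-1]) | (start[1:] > run_end[:-1])
    group = np.cumsum(new_run) - 1
    score = (
        pd.to_numeric(df["score"], errors="coerce").fillna(0.0).to_numpy(float)
        if "score" in df.columns
        else np.zeros(len(df))
    )
    frames = {"group": group, "chrom": chrom, "start": start, "end": end, "score": score}
    g = pd.DataFrame(frames)
    agg = g.groupby("group", sort=True).agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    # representative = highest-score member, first on ties
    best = g.groupby("group", sort=True)["score"].idxmax()
    out = agg.reset_index(drop=True)
    for col in ("name", "summit", "score", "strand"):
        if col in df.columns:
            out[col] = df[col].to_numpy()[best.to_numpy()]
    return out


def nearest_tss(sites: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Nearest selected TSS per site, by distance from the site center.

    Returns a DataFrame aligned to ``sites`` with columns ``gene_id`` and
    ``distance``; ties are broken by the lexicographically smaller gene id.
    Sites on a chromosome with no TSS get gene_id=None, distance=NaN.
    """
    validate_intervals(sites, "sites")
    centers = interval_centers(sites)
    chroms = np.asarray(sites["chrom"], dtype=object)
    gene_out = np.full(len(sites), None, dtype=object)
    dist_out = np.full(len(sites), np.nan)
    # per-position lexicographic-min gene id, positions sorted
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in tss.groupby("chrom", sort=False):
        g = grp.sort_values(["tss", "gene_id"], kind="stable")
        pos = g["tss"].to_numpy(np.int64)
        gid = g["gene_id"].to_numpy(object)
        first = np.ones(pos.size, dtype=bool)
        first[1:] = pos[1:] != pos[:-1]
        by_chrom[str(chrom)] = (pos[first], gid[first])
    for chrom in pd.unique(chroms):
        if chrom not in by_chrom:
            continue
        pos, gid = by_chrom[chrom]
        sel = np.flatnonzero(chroms == chrom)
        c = centers[sel]
        right = np.searchsorted(pos, c, side="left")
        left = right - 1
        d_left = np.where(left >= 0, np.abs(c - pos[np.clip(left, 0, None)]), np.inf)
        d_right = np.where(right < pos.size, np.abs(pos[np.clip(right, None, pos.size - 1)] - c), np.inf)
        use_left = d_left < d_right
        tie = d_left == d_right
        best_gene = np.where(use_left, gid[np.clip(left, 0, None)], gid[np.clip(right, None, pos.size - 1)])
        if tie.any():
            gl = gid[np.clip(left, 0, None)][tie]
            gr = gid[np.clip(right, None, pos.size - 1)][tie]
            best_gene[tie] = np.where(gl.astype(str) <= gr.astype(str), gl, gr)
        gene_out[sel] = best_gene
        dist_out[sel] = np.minimum(d_left, d_right)
    return pd.DataFrame({"gene_id": gene_out, "distance": dist_out}, index=sites.index)


def annotate_site(
    sites: pd.DataFrame, tss: pd.DataFrame, promoter_distance: int = 1000
) -> np.ndarray:
    """Label each site promoter_proximal / genic / intergenic.

    promoter_proximal: center within ``promoter_distance`` bp of a selected
    TSS; genic: center inside any gene body; else intergenic. The three
    labels partition any site set.
    """
    near = nearest_tss(sites, tss)
    labels = np.full(len(sites), "intergenic", dtype=object)
    with np.errstate(invalid="ignore"):
        prox = near["distance"].to_numpy() <= promoter_distance
    prox &= ~near["distance"].isna().to_numpy()
    centers = interval_centers(sites)
    bodies = pd.DataFrame(
        {"chrom": tss["chrom"], "start": tss["gene_start"], "end": tss["gene_end"]}
    )
    points = pd.DataFrame(
        {"chrom": sites["chrom"].to_numpy(), "start": centers, "end": centers + 1}
    )
    genic = intersect_any(points, bodies)
    labels[genic] = "genic"
    labels[prox] = "promoter_proximal"
    return labels


# ---------------------------------------------------------------------------
# file formats


def read_bed(path, summit_column: str | None = None) -> pd.DataFrame:
    """Read BED3/BED6 or 10-column narrowPeak.

    narrowPeak's 10th column (summit offset relative to start, -1 = absent)
    is normalized to an absolute 0-based ``summit``. Alternatively
    ``summit_column`` names a header column holding absolute positions, for
    TSV-with-header inputs.
    """
    if summit_column is not None:
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={summit_column: "summit"})
        validate_intervals(df, str(path))
        return df
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(BED_COLUMNS) + ["summit"])
    ncol = df.shape[1]
    names = list(BED_COLUMNS[: min(ncol, 6)])
    if ncol == 10:
        names = list(BED_COLUMNS) + ["signal", "pvalue", "qvalue", "peak_offset"]
    df.columns = names + [f"extra_{i}" for i in range(ncol - len(names))]
    if "peak_offset" in df.columns:
        off = df["peak_offset"].to_numpy(np.int64)
        df["summit"] = np.where(off >= 0, df["start"].to_numpy(np.int64) + off, -1)
        df.loc[df["summit"] < 0, "summit"] = np.nan
    validate_intervals(df, str(path))
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    """Write BED6, or narrowPeak when a ``summit`` column is present."""
    validate_intervals(df, "bed")
    out = pd.DataFrame({"chrom": df["chrom"], "start": df["start"], "end": df["end"]})
    out["name"] = df["name"] if "name" in df.columns else "."
    out["score"] = df["score"] if "score" in df.columns else 0
    out["strand"] = df["strand"] if "strand" in df.columns else "."
    if "summit" in df.columns:
        out["signal"] = 0.0
        out["pvalue"] = -1
        out["qvalue"] = -1
        summit = pd.to_numeric(df["summit"], errors="coerce")
        off = summit.to_numpy(float) - df["start"].to_numpy(np.int64)
        out["peak_offset"] = np.where(np.isnan(off), -1, off).astype(np.int64)
    out.to_csv(path, sep="\t", header=False, index=False)


GENE_TABLE_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "gene_start", "gene_end"]


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path}: missing columns {missing}")
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph step tracks


def read_bedgraph(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            comment="#", dtype={0: str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    validate_intervals(df, str(path))
    return df


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)


def step_track(bumps: pd.DataFrame) -> pd.DataFrame:
    """Sum possibly-overlapping rectangular bumps (chrom/start/end/value)
    into a piecewise-constant track with sorted, non-overlapping steps;
    zero-valued runs are dropped."""
    validate_intervals(bumps, "bumps")
    pieces = []
    for chrom, grp in bumps.groupby("chrom", sort=True):
        edges = np.unique(np.concatenate([grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)]))
        if edges.size < 2:
            continue
        heights = np.zeros(edges.size - 1)
        left = np.searchsorted(edges, grp["start"].to_numpy(np.int64))
        right = np.searchsorted(edges, grp["end"].to_numpy(np.int64))
        delta = np.zeros(edges.size)
        np.add.at(delta, left, grp["value"].to_numpy(float))
        np.add.at(delta, right, -grp["value"].to_numpy(float))
        heights = np.cumsum(delta)[:-1]
        keep = heights != 0
        pieces.append(
            pd.DataFrame(
                {"chrom": chrom, "start": edges[:-1][keep], "end": edges[1:][keep], "value": heights[keep]}
            )
        )
    if not pieces:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return pd.concat(pieces, ignore_index=True)


def interval_signal(track: pd.DataFrame, intervals: pd.DataFrame, how: str = "sum") -> np.ndarray:
    """Signal mass of a step track over each interval.

    ``how='sum'`` returns sum(value * overlap_bp); ``how='mean'`` divides by
    the interval width.
    """
    validate_intervals(intervals, "intervals")
    out = np.zeros(len(intervals))
    ivs = np.asarray(intervals["start"], dtype=np.int64)
    ive = np.asarray(intervals["end"], dtype=np.int64)
    chroms = np.asarray(intervals["chrom"], dtype=object)
    for chrom, grp in track.groupby("chrom", sort=False):
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        ts = grp["start"].to_numpy(np.int64)
        te = grp["end"].to_numpy(np.int64)
        tv = grp["value"].to_numpy(float)
        # cumulative mass at step edges for O(log n) range queries
        mass = np.concatenate([[0.0], np.cumsum(tv * (te - ts))])

        def mass_below(pos: np.ndarray) -> np.ndarray:
            # steps are disjoint and sorted; i = last step starting at or
            # before pos, partial covers the inside of that step
            i = np.searchsorted(ts, pos, side="right") - 1
            j = np.clip(i, 0, None)
            partial = tv[j] * np.clip(np.minimum(pos, te[j]) - ts[j], 0, None)
            return np.where(i < 0, 0.0, mass[j] + partial)

        out[sel] = mass_below(ive[sel]) - mass_below(ivs[sel])
    if how == "mean":
        width = (ive - ivs).astype(float)
        return out / width
    if how != "sum":
        raise ValueError("how must be 'sum' or 'mean'")
    return out
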