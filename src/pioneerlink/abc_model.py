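"""Activity-by-contact (ABC) enhancer-gene linking.

An element's ABC score for a gene is A * C / sum(A * C) over all candidate
elements within a window of the gene's TSS, where activity A is the
geometric mean of ATAC and H3K27ac signal over the element and contact C is
a powerlaw decay of genomic distance, C(d) = max(d, d_min)^(-gamma). Scores
for a gene sum to one before thresholding; links with score >= threshold
are kept.

Candidate elements are consensus ATAC peaks recentered on their summits
(+/- 275 bp by default), ranked by mean normalized read count with the top
150,000 retained, merged with 500-bp promoter regions around every kept
gene's selected TSS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import RegionCountMatrix, estimate_size_factors
from .intervals import interval_centers, intersect_any, merge_overlapping, validate_intervals

__all__ = [
    "select_tss",
    "filter_genes",
    "build_candidate_elements",
    "compute_activity",
    "powerlaw_contact",
    "compute_abc_links",
    "GAMMA_DEFAULT",
    "D_MIN_DEFAULT",
    "ABC_THRESHOLD_DEFAULT",
    "ABC_WINDOW_DEFAULT",
]

GAMMA_DEFAULT = 1.024
D_MIN_DEFAULT = 5_000
ABC_THRESHOLD_DEFAULT = 0.022
ABC_WINDOW_DEFAULT = 5_000_000
N_TOP_DEFAULT = 150_000
SUMMIT_HALFWIDTH_DEFAULT = 275
PROMOTER_HALFWIDTH = 250


def select_tss(isoforms: pd.DataFrame) -> pd.DataFrame:
    """One TSS per gene from an isoform table.

    Selection rules, applied in order: (1) the TSS of the unique isoform
    with highest mean expression; (2) on expression ties, the TSS used by
    the majority of the gene's isoforms; (3) if still ambiguous, the most 5'
    TSS (smallest coordinate on +, largest on -).

    ``isoforms`` needs gene_id, isoform_id, chrom, strand, tss, tpm_mean
    (and optionally symbol, gene_start, gene_end, carried through).
    """
    rows = []
    carry = [c for c in ("symbol", "gene_start", "gene_end") if c in isoforms.columns]
    for gene_id, grp in isoforms.groupby("gene_id", sort=True):
        if grp["chrom"].nunique() > 1:
            raise ValueError(f"gene {gene_id!r}: isoforms on multiple chromosomes")
        if grp["strand"].nunique() > 1:
            raise ValueError(f"gene {gene_id!r}: inconsistent strand")
        strand = grp["strand"].iloc[0]
        tpm = grp["tpm_mean"].to_numpy(float)
        top = np.flatnonzero(tpm == tpm.max())
        if top.size == 1:
            tss = int(grp["tss"].iloc[top[0]])
        else:
            votes = grp["tss"].value_counts()
            winners = votes[votes == votes.max()].index.to_numpy()
            if winners.size == 1:
                tss = int(winners[0])
            else:
                tss = int(winners.max() if strand == "-" else winners.min())
        row = {"gene_id": gene_id, "chrom": grp["chrom"].iloc[0], "strand": strand, "tss": tss}
        for c in carry:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def filter_genes(genes: pd.DataFrame, min_body_length: int = 300) -> pd.DataFrame:
    """Drop small-RNA genes (symbol containing "MIR" or "RNU",
    case-sensitive) and genes with body length < ``min_body_length`` bp.

    Body length is the ``exon_bp`` column (sum of exon widths) when
    present, else gene_end - gene_start.
    """
    symbol = genes["symbol"].astype(str)
    small_rna = symbol.str.contains("MIR", regex=False) | symbol.str.contains("RNU", regex=False)
    if "exon_bp" in genes.columns:
        body = genes["exon_bp"].to_numpy(float)
    else:
        body = (genes["gene_end"] - genes["gene_start"]).to_numpy(float)
    keep = ~small_rna.to_numpy() & (body >= min_body_length)
    return genes.loc[keep].reset_index(drop=True)


def build_candidate_elements(
    consensus_peaks: pd.DataFrame,
    counts: RegionCountMatrix,
    tss: pd.DataFrame,
    n_top: int = N_TOP_DEFAULT,
    summit_halfwidth: int = SUMMIT_HALFWIDTH_DEFAULT,
    blocklist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Candidate regulatory elements from consensus ATAC peaks.

    Steps: drop peaks overlapping the blocklist by >= 1 bp; recenter each
    peak to [summit - hw, summit + hw + 1); keep the ``n_top`` peaks with
    the highest mean size-factor-normalized count (ties by peak id); add
    500-bp promoter elements around every kept gene's TSS; merge
    overlapping intervals. Merged elements are promoters iff they contain
    any TSS region.
    """
    validate_intervals(consensus_peaks, "consensus_peaks")
    peaks = consensus_peaks.copy()
    if "summit" not in peaks.columns or peaks["summit"].isna().any():
        missing = (
            peaks.loc[peaks["summit"].isna(), "name"].iloc[0]
            if "summit" in peaks.columns
            else peaks["name"].iloc[0] if "name" in peaks.columns else "<first>"
        )
        raise ValueError(f"peak {missing!r} lacks a summit")
    if blocklist is not None and len(blocklist):
        blocked = intersect_any(peaks, blocklist)
        peaks = peaks.loc[~blocked]
    factors = estimate_size_factors(counts)
    norm_mean = (counts.counts / factors).mean(axis=1)
    peaks = peaks.set_index(peaks["name"].rename("peak_id"))
    missing = [p for p in peaks.index if p not in norm_mean.index]
    if missing:
        raise ValueError(f"peak {missing[0]!r} has no count row")
    peaks["rank_key"] = norm_mean.loc[peaks.index].to_numpy()
    peaks = peaks.sort_values(["rank_key", "name"], ascending=[False, True], kind="stable").head(n_top)

    summit = peaks["summit"].to_numpy(float).astype(np.int64)
    recentered = pd.DataFrame(
        {
            "chrom": peaks["chrom"].to_numpy(),
            "start": np.maximum(summit - summit_halfwidth, 0),
            "end": summit + summit_halfwidth + 1,
            "name": peaks["name"].to_numpy(),
            "score": peaks["rank_key"].to_numpy(),
            "summit": summit,
        }
    )
    promoters = pd.DataFrame(
        {
            "chrom": tss["chrom"].to_numpy(),
            "start": np.maximum(tss["tss"].to_numpy(np.int64) - PROMOTER_HALFWIDTH, 0),
            "end": tss["tss"].to_numpy(np.int64) + PROMOTER_HALFWIDTH,
            "name": "promoter_" + tss["gene_id"].astype(str),
            "score": 0.0,
            "summit": tss["tss"].to_numpy(np.int64),
        }
    )
    merged = merge_overlapping(pd.concat([recentered, promoters], ignore_index=True))
    merged["is_promoter"] = intersect_any(merged, promoters)
    merged["element_id"] = (
        merged["chrom"].astype(str)
        + ":"
        + merged["start"].astype(str)
        + "-"
        + merged["end"].astype(str)
    )
    cols = ["element_id", "chrom", "start", "end", "is_promoter"]
    return merged[cols].reset_index(drop=True)


def compute_activity(atac_rpm, h3k27ac_rpm) -> np.ndarray:
    """Element activity = sqrt(ATAC RPM x H3K27ac RPM); zero if either
    assay is zero."""
    atac = np.asarray(atac_rpm, dtype=float)
    h3k = np.asarray(h3k27ac_rpm, dtype=float)
    if (atac < 0).any() or (h3k < 0).any():
        raise ValueError("RPM inputs must be nonnegative")
    return np.sqrt(atac * h3k)


def powerlaw_contact(distance, gamma: float = GAMMA_DEFAULT, d_min: int = D_MIN_DEFAULT) -> np.ndarray:
    """Powerlaw contact C(d) = max(d, d_min)^(-gamma)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d = np.maximum(np.asarray(distance, dtype=float), d_min)
    return d ** (-gamma)


def compute_abc_links(
    elements: pd.DataFrame,
    tss: pd.DataFrame,
    expressed_genes,
    window: int = ABC_WINDOW_DEFAULT,
    threshold: float = ABC_THRESHOLD_DEFAULT,
    gamma: float = GAMMA_DEFAULT,
    d_min: int = D_MIN_DEFAULT,
) -> pd.DataFrame:
    """Normalized ABC scores for every expressed gene.

    ``elements`` needs element_id, chrom, start, end, activity (and
    optionally is_promoter). For each expressed gene, candidate elements
    are those with center within ``window`` bp of the gene's TSS on the
    same chromosome; scores are activity x contact normalized to sum to one
    over the candidates. Genes with a zero denominator produce no links.
    """
    if "activity" not in elements.columns:
        raise ValueError("elements need an 'activity' column; run compute_activity")
    expressed = set(expressed_genes)
    centers = interval_centers(elements)
    out_frames = []
    tss_expr = tss.loc[tss["gene_id"].isin(expressed)]
    for chrom, genes in tss_expr.groupby("chrom", sort=True):
        mask = (elements["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        el = elements.loc[mask]
        ctr = centers[mask]
        order = np.argsort(ctr, kind="stable")
        el = el.iloc[order]
        ctr = ctr[order]
        act = el["activity"].to_numpy(float)
        for _, gene in genes.sort_values("gene_id").iterrows():
            t = int(gene["tss"])
            lo = np.searchsorted(ctr, t - window, side="left")
            hi = np.searchsorted(ctr, t + window, side="right")
            if hi <= lo:
                continue
            dist = np.abs(ctr[lo:hi] - t)
            a = act[lo:hi]
            contact = powerlaw_contact(dist, gamma=gamma, d_min=d_min)
            weight = a * contact
            denom = weight.sum()
            if denom <= 0:
                continue
            score = weight / denom
            sub = el.iloc[lo:hi]
            frame = pd.DataFrame(
                {
                    "element_id": sub["element_id"].to_numpy(),
                    "chrom": chrom,
                    "start": sub["start"].to_numpy(),
                    "end": sub["end"].to_numpy(),
                    "is_promoter": sub["is_promoter"].to_numpy()
                    if "is_promoter" in sub.columns
                    else False,
                    "gene_id": gene["gene_id"],
                    "distance": dist,
                    "activity": a,
                    "contact": contact,
                    "abc_score": score,
                    "kept": score >= threshold,
                }
            )
            out_frames.append(frame)
    if not out_frames:
        return pd.DataFrame(
            columns=[
                "element_id", "chrom", "start", "end", "is_promoter", "gene_id",
                "distance", "activity", "contact", "abc_score", "kept",
            ]
        )
    return pd.concat(out_frames, ignore_index=True)
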