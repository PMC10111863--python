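"""Synthetic regulatory-genomics study with planted ground truth.

Generates a complete toy study mirroring a knockout/inhibitor design for a
pioneer transcription factor: a small genome, genes with isoform TSSs and
expression, TF / remodeler / H3K27ac peak sets, ATAC consensus peaks and
count matrices in four conditions (wild-type late, wild-type early,
TF-knockout, ATPase-inhibitor-treated), ChIP count matrices, RNA counts,
and idealized coverage tracks — together with a per-site truth table of
planted classes so every downstream stage is testable without external
data.

Planted classes per TF site: chromatin state (open/closed), dependency
(opens/represses/static), mode (classical_pioneer/permissive), remodeler
cobinding, KO/inhibitor codependency, and a linked gene whose RNA shifts
concordantly for a configured fraction of genes. Counts are
negative-binomial draws around the planted per-condition means; per-site
random streams are derived by stable hashing of the site id, so adding
sites does not reshuffle existing ones.

Condition naming: ``wt_late`` (peak TF expression), ``wt_early`` (TF-naive
prebound state), ``ko`` (TF knockout), ``inhibitor`` (remodeler-ATPase
inhibited).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .differential import RegionCountMatrix
from .intervals import (
    read_bed,
    read_bedgraph,
    read_gene_table,
    step_track,
    write_bed,
    write_bedgraph,
    write_gene_table,
)

__all__ = ["StudyConfig", "Bundle", "simulate_study", "write_bundle", "read_bundle"]

ATAC_CONDITIONS = ("wt_late", "wt_early", "ko", "inhibitor")


@dataclass
class StudyConfig:
    """Study design and planted effect sizes.

    The class-proportion defaults are the observed fractions of the
    knockout study being emulated; effect sizes are simulator parameters
    chosen for high but unsaturated power at the default replicate number.
    """

    seed: int = 0
    genome: list = field(default_factory=lambda: [["chr1", 10_000_000], ["chr2", 10_000_000]])
    n_genes: int = 200
    n_tf_sites: int = 2_000
    n_background_peaks: int = 800
    replicates: int = 3

    # planted class proportions
    frac_open: float = 0.683
    frac_dependent_of_open: float = 0.239
    frac_decreasing_of_dependent: float = 0.468
    frac_pioneer_of_decreasing: float = 0.503
    frac_cobound_open: float = 0.549
    frac_cobound_closed: float = 0.058
    frac_codependent_of_cobound_dependent: float = 0.531
    frac_prebound_consistent: float = 0.747
    frac_partner_affected: float = 0.927
    frac_partner_absent_of_affected: float = 0.3

    # effect sizes and noise
    mu_open: float = 200.0
    mu_bg: float = 8.0
    attenuation: float = 3.5
    nb_dispersion: float = 0.02
    chip_mu_bound: float = 150.0
    chip_mu_bg: float = 5.0
    partner_drop: float = 3.0
    rna_fold: float = 2.0
    concordance_fraction: float = 0.8

    # geometry
    site_width: int = 200
    atac_peak_pad: int = 150
    promoter_atac_mu: float = 100.0

    def validate(self) -> None:
        fracs = {
            k: v
            for k, v in asdict(self).items()
            if k.startswith("frac_") or k == "concordance_fraction"
        }
        for k, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k}={v} outside [0, 1]")
        if not self.mu_open > self.mu_bg > 0:
            raise ValueError("requires mu_open > mu_bg > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.attenuation <= 1 or self.partner_drop <= 1 or self.rna_fold <= 1:
            raise ValueError("attenuation, partner_drop and rna_fold must exceed 1")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        for name, length in self.genome:
            if length <= 200_000:
                raise ValueError(f"chromosome {name} too short ({length} bp)")

    @property
    def prob_developmental_closed(self) -> float:
        """Probability that a static open site is closed in the early
        condition, derived so the planted prebound-consistency fraction
        comes out at ``frac_prebound_consistent``."""
        p_opens = self.frac_dependent_of_open * self.frac_decreasing_of_dependent
        p_static = 1.0 - self.frac_dependent_of_open
        f = self.frac_prebound_consistent
        if f <= 0 or p_static == 0:
            return 0.0
        return min(1.0, p_opens * (1.0 - f) / f / p_static)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class Bundle:
    """In-memory study: gene tables, peak sets, count matrices, coverage
    tracks and the planted truth."""

    config: StudyConfig
    genes: pd.DataFrame
    isoforms: pd.DataFrame
    peaks: dict  # name -> DataFrame
    counts: dict  # name -> RegionCountMatrix
    tracks: dict  # name -> bedGraph DataFrame
    truth_sites: pd.DataFrame
    truth_genes: pd.DataFrame


def _stream(seed: int, *tokens) -> np.random.Generator:
    """Deterministic per-entity stream keyed by stable string hashes."""
    keys = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))


def _nb(rng: np.random.Generator, mean, alpha: float, size) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if alpha < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / alpha, mean * alpha)
    return rng.poisson(lam)


def _make_genes(cfg: StudyConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene bodies, isoform TSSs and expression. Includes a few small-RNA
    and short decoy genes that the ABC gene filter must remove."""
    chrom_names = [c[0] for c in cfg.genome]
    chrom_len = {c[0]: int(c[1]) for c in cfg.genome}
    n = cfg.n_genes
    records = []
    iso_records = []
    # even spacing with jitter keeps genes well separated and sorted
    per_chrom = np.array_split(np.arange(n), len(chrom_names))
    for chrom, idx in zip(chrom_names, per_chrom):
        if idx.size == 0:
            continue
        usable = chrom_len[chrom] - 200_000
        anchors = 100_000 + (np.arange(idx.size) + 0.5) * usable / idx.size
        anchors = anchors.astype(np.int64)
        for k, gi in enumerate(idx):
            gid = f"gene_{gi:04d}"
            g = _stream(cfg.seed, gid, "gene")
            jitter = int(g.integers(-usable // (4 * idx.size), usable // (4 * idx.size) + 1))
            tss_anchor = int(anchors[k] + jitter)
            strand = "+" if g.random() < 0.5 else "-"
            body_len = int(g.integers(5_000, 100_000))
            if strand == "+":
                gene_start, gene_end = tss_anchor, tss_anchor + body_len
            else:
                gene_start, gene_end = tss_anchor - body_len, tss_anchor
            tpm = float(np.exp(g.normal(2.0, 1.2)))
            if g.random() < 0.05:
                tpm = float(g.random() * 0.5)  # below the expression floor
            n_iso = int(g.integers(1, 5))
            tss_list = [tss_anchor]
            for j in range(1, n_iso):
                off = int(g.integers(0, 2_000))
                tss_list.append(tss_anchor + off if strand == "+" else tss_anchor - off)
            tpm_shares = np.sort(g.dirichlet(np.ones(n_iso)))[::-1]
            for j, (tss_j, share) in enumerate(zip(tss_list, tpm_shares)):
                iso_records.append(
                    {
                        "gene_id": gid,
                        "isoform_id": f"{gid}.{j + 1}",
                        "symbol": f"GENE{gi:04d}",
                        "chrom": chrom,
                        "strand": strand,
                        "tss": int(tss_j),
                        "tpm_mean": round(tpm * float(share), 6),
                        "gene_start": gene_start,
                        "gene_end": gene_end,
                    }
                )
            records.append(
                {
                    "gene_id": gid,
                    "symbol": f"GENE{gi:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "gene_start": gene_start,
                    "gene_end": gene_end,
                    "tss": tss_anchor,
                    "tpm": tpm,
                }
            )
    # decoys exercising the gene filters (never linked to planted sites)
    decoys = []
    if n > 0:
        for j, (sym, short) in enumerate(
            [("MIR9001", False), ("MIR9002", False), ("RNU9001", False), ("RNU9002", False),
             ("GENES01", True), ("GENES02", True)]
        ):
            chrom = chrom_names[j % len(chrom_names)]
            pos = 50_000 + 7_000 * j
            length = 150 if short else 2_000
            gid = f"decoy_{j:02d}"
            decoys.append(
                {"gene_id": gid, "symbol": sym, "chrom": chrom, "strand": "+",
                 "gene_start": pos, "gene_end": pos + length, "tss": pos, "tpm": 5.0}
            )
            iso_records.append(
                {"gene_id": gid, "isoform_id": f"{gid}.1", "symbol": sym, "chrom": chrom,
                 "strand": "+", "tss": pos, "tpm_mean": 5.0, "gene_start": pos,
                 "gene_end": pos + length}
            )
    gene_cols = ["gene_id", "symbol", "chrom", "strand", "gene_start", "gene_end", "tss", "tpm"]
    iso_cols = [
        "gene_id", "isoform_id", "symbol", "chrom", "strand", "tss", "tpm_mean",
        "gene_start", "gene_end",
    ]
    genes = pd.DataFrame(records + decoys, columns=gene_cols)
    isoforms = pd.DataFrame(iso_records, columns=iso_cols)
    return genes, isoforms


def simulate_study(config: StudyConfig) -> Bundle:
    """Generate the full study bundle with planted truth.

    Deterministic: the same config (including seed) yields byte-identical
    tables.
    """
    cfg = config
    cfg.validate()
    layout_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), 0xA11CE]))
    chrom_names = [c[0] for c in cfg.genome]
    chrom_len = {c[0]: int(c[1]) for c in cfg.genome}

    genes, isoforms = _make_genes(cfg, layout_rng)
    real_genes = genes.loc[~genes["gene_id"].str.startswith("decoy")].reset_index(drop=True)

    # --- planted site classes (per-site streams) -------------------------
    n_sites = cfg.n_tf_sites
    site_ids = [f"site_{i:05d}" for i in range(n_sites)]
    cls = {
        "open": np.zeros(n_sites, bool),
        "dependent": np.zeros(n_sites, bool),
        "decreasing": np.zeros(n_sites, bool),
        "pioneer": np.zeros(n_sites, bool),
        "cobound": np.zeros(n_sites, bool),
        "codependent": np.zeros(n_sites, bool),
        "dev_closed": np.zeros(n_sites, bool),
        "partner_affected": np.zeros(n_sites, bool),
        "partner_absent": np.zeros(n_sites, bool),
    }
    p_dev = cfg.prob_developmental_closed
    for i, sid in enumerate(site_ids):
        r = _stream(cfg.seed, sid, "class")
        u = r.random(9)
        is_open = u[0] < cfg.frac_open
        dependent = is_open and u[1] < cfg.frac_dependent_of_open
        decreasing = dependent and u[2] < cfg.frac_decreasing_of_dependent
        pioneer = decreasing and u[3] < cfg.frac_pioneer_of_decreasing
        cobound = (is_open and u[4] < cfg.frac_cobound_open) or (
            not is_open and u[4] < cfg.frac_cobound_closed
        )
        codependent = cobound and dependent and u[5] < cfg.frac_codependent_of_cobound_dependent
        dev_closed = is_open and not dependent and u[6] < p_dev
        partner_affected = codependent and u[7] < cfg.frac_partner_affected
        partner_absent = partner_affected and u[8] < cfg.frac_partner_absent_of_affected
        for key, val in (
            ("open", is_open), ("dependent", dependent), ("decreasing", decreasing),
            ("pioneer", pioneer), ("cobound", cobound), ("codependent", codependent),
            ("dev_closed", dev_closed), ("partner_affected", partner_affected),
            ("partner_absent", partner_absent),
        ):
            cls[key][i] = val

    dependency = np.where(
        cls["dependent"] & cls["decreasing"], "opens",
        np.where(cls["dependent"], "represses", np.where(cls["open"], "static", "not_assessed")),
    ).astype(object)
    mode = np.where(
        cls["dependent"] & cls["decreasing"] & cls["pioneer"], "classical_pioneer",
        np.where(cls["dependent"], "permissive", "not_applicable"),
    ).astype(object)

    # --- link dependent sites to genes (direction-consistent per gene) ---
    linked_gene = np.full(n_sites, "", dtype=object)
    if len(real_genes):
        shuffled = real_genes["gene_id"].to_numpy(object).copy()
        layout_rng.shuffle(shuffled)
        half = max(1, len(shuffled) // 2)
        pool_down, pool_up = shuffled[:half], shuffled[half:]
        if pool_up.size == 0:
            pool_up = pool_down
        down_sites = np.flatnonzero(dependency == "opens")
        up_sites = np.flatnonzero(dependency == "represses")
        for k, si in enumerate(down_sites):
            linked_gene[si] = pool_down[k % pool_down.size]
        for k, si in enumerate(up_sites):
            linked_gene[si] = pool_up[k % pool_up.size]

    gene_info = genes.set_index("gene_id")

    # --- site geometry ----------------------------------------------------
    # linked dependent sites sit 5-25 kb from their gene's TSS: distal
    # (> 1 kb) yet close enough that the powerlaw contact keeps their ABC
    # link above threshold at this genome scale; unlinked sites stay clear
    # of every TSS so closed sites never sit in promoter-open chromatin
    w = cfg.site_width
    tss_sorted = {
        c: np.sort(genes.loc[genes["chrom"] == c, "tss"].to_numpy(np.int64))
        for c in chrom_names
    }

    def near_tss(chrom: str, center: int, min_d: int = 2_500) -> bool:
        arr = tss_sorted.get(chrom)
        if arr is None or arr.size == 0:
            return False
        i = int(np.searchsorted(arr, center))
        return any(
            0 <= j < arr.size and abs(center - int(arr[j])) < min_d for j in (i - 1, i)
        )

    import bisect

    placed: dict[str, list[int]] = {c: [] for c in chrom_names}

    def too_close(chrom: str, center: int, min_d: int = 800) -> bool:
        arr = placed[chrom]
        i = bisect.bisect_left(arr, center)
        return any(
            0 <= j < len(arr) and abs(center - arr[j]) < min_d for j in (i - 1, i)
        )

    starts = np.zeros(n_sites, np.int64)
    chroms = np.empty(n_sites, object)
    for i, sid in enumerate(site_ids):
        r = _stream(cfg.seed, sid, "pos")
        if linked_gene[i]:
            g = gene_info.loc[linked_gene[i]]
            chroms[i] = g["chrom"]
            center = int(g["tss"]) + int(r.integers(5_000, 25_000)) * (
                1 if r.random() < 0.5 else -1
            )
            for _ in range(200):
                if not too_close(chroms[i], center):
                    break
                center = int(g["tss"]) + int(r.integers(5_000, 25_000)) * (
                    1 if r.random() < 0.5 else -1
                )
        else:
            chroms[i] = chrom_names[int(r.integers(0, len(chrom_names)))]
            center = int(r.integers(100_000, chrom_len[chroms[i]] - 100_000))
            for _ in range(200):
                if not (near_tss(chroms[i], center) or too_close(chroms[i], center)):
                    break
                center = int(r.integers(100_000, chrom_len[chroms[i]] - 100_000))
        center = int(np.clip(center, 100_000, chrom_len[chroms[i]] - 100_000))
        bisect.insort(placed[chroms[i]], center)
        starts[i] = center - w // 2
    tf_sites = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + w,
            "name": site_ids,
            "score": 0,
            "strand": ".",
            "summit": starts + w // 2,
        }
    )

    # --- planted per-condition ATAC means at the site regions -------------
    mu = np.zeros((n_sites, len(ATAC_CONDITIONS)))
    for i in range(n_sites):
        if not cls["open"][i]:
            mu[i] = cfg.mu_bg
            continue
        wt = cfg.mu_open
        if dependency[i] == "opens":
            ko = cfg.mu_bg if mode[i] == "classical_pioneer" else cfg.mu_open / cfg.attenuation
        elif dependency[i] == "represses":
            ko = cfg.mu_open * cfg.attenuation
        else:
            ko = wt
        early = ko if dependency[i] in ("opens", "represses") else (
            cfg.mu_bg if cls["dev_closed"][i] else wt
        )
        inhib = ko if cls["codependent"][i] else wt
        mu[i] = [wt, early, ko, inhib]
    mu_by_cond = {cond: mu[:, j] for j, cond in enumerate(ATAC_CONDITIONS)}

    # --- sample sheet and library factors ---------------------------------
    def sample_ids(assay: str, cond: str) -> list[str]:
        return [f"{assay}_{cond}_r{r + 1}" for r in range(cfg.replicates)]

    lib_factor: dict[str, float] = {}

    def lib(sample: str) -> float:
        if sample not in lib_factor:
            lib_factor[sample] = float(_stream(cfg.seed, sample, "lib").uniform(0.75, 1.25))
        return lib_factor[sample]

    # --- ATAC counts on site regions --------------------------------------
    atac_samples = [s for cond in ATAC_CONDITIONS for s in sample_ids("atac", cond)]
    atac_libs = np.array([lib(s) for s in atac_samples])
    atac_counts = np.zeros((n_sites, len(atac_samples)), np.int64)
    for i, sid in enumerate(site_ids):
        r = _stream(cfg.seed, sid, "atac")
        means = np.repeat(mu[i], cfg.replicates) * atac_libs
        atac_counts[i] = _nb(r, means, cfg.nb_dispersion, means.shape)
    atac_sites = RegionCountMatrix(
        pd.DataFrame(atac_counts, index=pd.Index(site_ids, name="region_id"), columns=atac_samples),
        _sample_sheet("atac", list(ATAC_CONDITIONS), cfg.replicates),
    )

    # --- background ATAC peaks and promoters (consensus peak universe) ----
    # background peaks represent TF-unrelated open chromatin: they must not
    # overlap TF sites, or planted closed/classical sites would acquire
    # spurious peaks
    site_sorted = {
        c: np.sort(starts[np.asarray(chroms == c)]) for c in chrom_names
    }

    def near_site(chrom: str, center: int, min_d: int = 1_200) -> bool:
        arr = site_sorted.get(chrom)
        if arr is None or arr.size == 0:
            return False
        i = int(np.searchsorted(arr, center))
        return any(
            0 <= j < arr.size and abs(center - int(arr[j])) < min_d for j in (i - 1, i)
        )

    bg_ids = [f"bgpeak_{i:05d}" for i in range(cfg.n_background_peaks)]
    bg_rows = []
    for i, bid in enumerate(bg_ids):
        r = _stream(cfg.seed, bid, "bg")
        chrom = chrom_names[int(r.integers(0, len(chrom_names)))]
        center = int(r.integers(100_000, chrom_len[chrom] - 100_000))
        for _ in range(200):
            if not near_site(chrom, center):
                break
            center = int(r.integers(100_000, chrom_len[chrom] - 100_000))
        half = int(r.integers(150, 400))
        bg_rows.append(
            {
                "chrom": chrom, "start": center - half, "end": center + half,
                "name": bid, "score": 0, "strand": ".", "summit": center,
                "mu": float(r.uniform(20, 300)),
                "h3k27ac": bool(r.random() < 0.7),
            }
        )
    background = pd.DataFrame(
        bg_rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "summit", "mu", "h3k27ac"],
    )

    expressed = real_genes.loc[real_genes["tpm"] >= 1.0]
    promoters = pd.DataFrame(
        {
            "chrom": expressed["chrom"].to_numpy(),
            "start": expressed["tss"].to_numpy(np.int64) - 250,
            "end": expressed["tss"].to_numpy(np.int64) + 250,
            "name": "prom_" + expressed["gene_id"].astype(str),
            "score": 0,
            "strand": ".",
            "summit": expressed["tss"].to_numpy(np.int64),
        }
    )

    pad = cfg.atac_peak_pad
    site_peaks = tf_sites.assign(
        start=tf_sites["start"] - pad, end=tf_sites["end"] + pad,
        name="atac_" + tf_sites["name"].astype(str),
    )

    def atac_peakset(cond: str) -> pd.DataFrame:
        if cond == "wt_late":
            keep = cls["open"]
        elif cond == "ko":
            keep = cls["open"] & ~((dependency == "opens") & (mode == "classical_pioneer"))
        elif cond == "wt_early":
            keep = (
                cls["open"]
                & ~((dependency == "opens") & (mode == "classical_pioneer"))
                & ~cls["dev_closed"]
            )
        else:  # inhibitor: signal attenuation does not delete called peaks
            keep = cls["open"]
        parts = [site_peaks.loc[keep], background.drop(columns=["mu", "h3k27ac"]), promoters]
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    peaks = {f"atac_{cond}": atac_peakset(cond) for cond in ATAC_CONDITIONS}

    # counts over the WT-late consensus peaks, for candidate-element ranking
    wt_samples = sample_ids("atac", "wt_late")
    peak_index = []
    peak_mu = []
    for keep_i in np.flatnonzero(cls["open"]):
        peak_index.append(f"atac_{site_ids[keep_i]}")
        peak_mu.append(mu_by_cond["wt_late"][keep_i])
    peak_index += list(background["name"])
    peak_mu += list(background["mu"])
    peak_index += list(promoters["name"])
    peak_mu += [cfg.promoter_atac_mu] * len(promoters)
    wt_libs = np.array([lib(s) for s in wt_samples])
    pk_counts = np.zeros((len(peak_index), len(wt_samples)), np.int64)
    for i, (pid, m) in enumerate(zip(peak_index, peak_mu)):
        r = _stream(cfg.seed, pid, "peakcount")
        pk_counts[i] = _nb(r, m * wt_libs, cfg.nb_dispersion, wt_libs.shape)
    atac_peak_counts = RegionCountMatrix(
        pd.DataFrame(pk_counts, index=pd.Index(peak_index, name="region_id"), columns=wt_samples),
        _sample_sheet("atac", ["wt_late"], cfg.replicates),
    )

    # --- ChIP peak sets ----------------------------------------------------
    peaks["tf"] = tf_sites.copy()
    h3_parts = [
        site_peaks.loc[cls["open"]].assign(name="h3k_" + tf_sites.loc[cls["open"], "name"].astype(str)),
        background.loc[background["h3k27ac"]].drop(columns=["mu", "h3k27ac"]).assign(
            name="h3k_" + background.loc[background["h3k27ac"], "name"].astype(str)
        ),
        promoters.assign(name="h3k_" + promoters["name"].astype(str)),
    ]
    peaks["h3k27ac"] = (
        pd.concat(h3_parts, ignore_index=True)
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
    rem = tf_sites.assign(name="rem_" + tf_sites["name"].astype(str))
    peaks["remodeler_control"] = rem.loc[cls["cobound"]].reset_index(drop=True)
    peaks["remodeler_ko"] = rem.loc[cls["cobound"] & ~cls["partner_absent"]].reset_index(drop=True)

    # --- ChIP count matrices on site regions -------------------------------
    def chip_matrix(name: str, cond_means: dict[str, np.ndarray]) -> RegionCountMatrix:
        samples = [s for cond in cond_means for s in sample_ids(name, cond)]
        libs = np.array([lib(s) for s in samples])
        site_means = np.column_stack(
            [np.repeat(means[:, None], cfg.replicates, axis=1) for means in cond_means.values()]
        ) if n_sites else np.zeros((0, len(samples)))
        arr = np.zeros((n_sites, len(samples)), np.int64)
        for i, sid in enumerate(site_ids):
            r = _stream(cfg.seed, sid, name)
            arr[i] = _nb(r, site_means[i] * libs, cfg.nb_dispersion, libs.shape)
        return RegionCountMatrix(
            pd.DataFrame(arr, index=pd.Index(site_ids, name="region_id"), columns=samples),
            _sample_sheet(name, list(cond_means), cfg.replicates),
        )

    tf_control = np.full(n_sites, cfg.chip_mu_bound)
    tf_inhib = np.where(
        cls["codependent"], cfg.chip_mu_bound / cfg.partner_drop, cfg.chip_mu_bound
    )
    counts = {
        "atac_sites": atac_sites,
        "atac_peaks": atac_peak_counts,
        "chip_tf": chip_matrix("chip_tf", {"control": tf_control, "inhibitor": tf_inhib}),
    }
    rem_control = np.where(cls["cobound"], cfg.chip_mu_bound, cfg.chip_mu_bg)
    rem_ko = np.where(
        cls["partner_absent"], cfg.chip_mu_bg,
        np.where(cls["partner_affected"], cfg.chip_mu_bound / cfg.partner_drop, rem_control),
    )
    counts["chip_remodeler"] = chip_matrix(
        "chip_remodeler", {"control": rem_control, "ko": rem_ko}
    )

    # --- RNA counts ---------------------------------------------------------
    truth_gene_rows = []
    owners: dict[str, str] = {}
    for i in np.flatnonzero(linked_gene != ""):
        owners.setdefault(linked_gene[i], dependency[i])
    rna_samples = sample_ids("rna", "wt") + sample_ids("rna", "ko")
    rna_libs = np.array([lib(s) for s in rna_samples])
    rna = np.zeros((len(real_genes), len(rna_samples)), np.int64)
    for gi, row in real_genes.iterrows():
        gid = row["gene_id"]
        r = _stream(cfg.seed, gid, "rna")
        base = 50.0 + 20.0 * min(row["tpm"], 40.0)
        direction = ""
        concordant = False
        ko_mean = base
        if gid in owners:
            direction = "down" if owners[gid] == "opens" else "up"
            concordant = bool(r.random() < cfg.concordance_fraction)
            shift = cfg.rna_fold if (direction == "up") == concordant else 1.0 / cfg.rna_fold
            ko_mean = base * shift
        means = np.repeat([base, ko_mean], cfg.replicates) * rna_libs
        rna[gi] = _nb(r, means, cfg.nb_dispersion, means.shape)
        truth_gene_rows.append(
            {
                "gene_id": gid,
                "linked_direction": direction or ".",
                "concordant": concordant if direction else False,
                "base_mean": base,
                "ko_mean": ko_mean,
            }
        )
    counts["rna"] = RegionCountMatrix(
        pd.DataFrame(
            rna, index=pd.Index(real_genes["gene_id"], name="region_id"), columns=rna_samples
        ),
        _sample_sheet("rna", ["wt", "ko"], cfg.replicates),
    )

    # --- idealized coverage tracks -----------------------------------------
    def atac_track(cond: str) -> pd.DataFrame:
        bumps = [
            pd.DataFrame(
                {
                    "chrom": site_peaks["chrom"],
                    "start": site_peaks["start"],
                    "end": site_peaks["end"],
                    "value": mu_by_cond[cond],
                }
            ),
            pd.DataFrame(
                {
                    "chrom": background["chrom"], "start": background["start"],
                    "end": background["end"], "value": background["mu"],
                }
            ),
            pd.DataFrame(
                {
                    "chrom": promoters["chrom"], "start": promoters["start"],
                    "end": promoters["end"], "value": cfg.promoter_atac_mu,
                }
            ),
        ]
        return step_track(pd.concat(bumps, ignore_index=True))

    h3_bumps = [
        pd.DataFrame(
            {
                "chrom": site_peaks.loc[cls["open"], "chrom"],
                "start": site_peaks.loc[cls["open"], "start"],
                "end": site_peaks.loc[cls["open"], "end"],
                "value": 100.0,
            }
        ),
        pd.DataFrame(
            {
                "chrom": background.loc[background["h3k27ac"], "chrom"],
                "start": background.loc[background["h3k27ac"], "start"],
                "end": background.loc[background["h3k27ac"], "end"],
                "value": 100.0,
            }
        ),
        pd.DataFrame(
            {
                "chrom": promoters["chrom"], "start": promoters["start"],
                "end": promoters["end"], "value": 100.0,
            }
        ),
    ]
    tracks = {f"atac_{cond}": atac_track(cond) for cond in ATAC_CONDITIONS}
    tracks["h3k27ac"] = step_track(pd.concat(h3_bumps, ignore_index=True))

    # --- truth tables -------------------------------------------------------
    truth_sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "chrom": tf_sites["chrom"],
            "start": tf_sites["start"],
            "end": tf_sites["end"],
            "chromatin_state": np.where(cls["open"], "open", "closed"),
            "dependency": dependency,
            "mode": mode,
            "cobound": cls["cobound"],
            "codependent": cls["codependent"],
            "dev_closed_early": cls["dev_closed"],
            "partner_affected": cls["partner_affected"],
            "partner_absent": cls["partner_absent"],
            "linked_gene": np.where(linked_gene == "", ".", linked_gene),
            **{f"mu_{cond}": mu_by_cond[cond] for cond in ATAC_CONDITIONS},
        }
    )
    truth_genes = pd.DataFrame(
        truth_gene_rows,
        columns=["gene_id", "linked_direction", "concordant", "base_mean", "ko_mean"],
    )

    return Bundle(
        config=cfg,
        genes=genes,
        isoforms=isoforms,
        peaks=peaks,
        counts=counts,
        tracks=tracks,
        truth_sites=truth_sites,
        truth_genes=truth_genes,
    )


def _sample_sheet(assay: str, conditions: list[str], replicates: int) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{assay}_{cond}_r{r + 1}",
            "assay": assay,
            "condition": cond,
            "replicate": r + 1,
        }
        for cond in conditions
        for r in range(replicates)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# persistence


def write_bundle(bundle: Bundle, directory) -> pd.DataFrame:
    """Write the bundle as BED/narrowPeak, bedGraph and TSV files; returns
    a manifest DataFrame (also written as manifest.tsv)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = []

    def note(fname: str, rows: int) -> None:
        manifest.append({"file": fname, "rows": rows})

    bundle.config.to_yaml(d / "config.yaml")
    note("config.yaml", 1)
    write_gene_table(bundle.genes, d / "genes.tsv")
    note("genes.tsv", len(bundle.genes))
    bundle.isoforms.to_csv(d / "isoforms.tsv", sep="\t", index=False)
    note("isoforms.tsv", len(bundle.isoforms))
    for name, df in sorted(bundle.peaks.items()):
        fname = f"peaks_{name}.bed"
        write_bed(df, d / fname)
        note(fname, len(df))
    all_samples = []
    for name, rcm in sorted(bundle.counts.items()):
        fname = f"counts_{name}.tsv"
        rcm.to_tsv(d / fname)
        note(fname, len(rcm.counts))
        all_samples.append(rcm.samples)
    sheet = pd.concat(all_samples)
    sheet = sheet[~sheet.index.duplicated()]
    sheet.index.name = "sample_id"
    sheet.to_csv(d / "samples.tsv", sep="\t")
    note("samples.tsv", len(sheet))
    for name, track in sorted(bundle.tracks.items()):
        fname = f"track_{name}.bedGraph"
        write_bedgraph(track, d / fname)
        note(fname, len(track))
    bundle.truth_sites.to_csv(d / "truth_sites.tsv", sep="\t", index=False)
    note("truth_sites.tsv", len(bundle.truth_sites))
    bundle.truth_genes.to_csv(d / "truth_genes.tsv", sep="\t", index=False)
    note("truth_genes.tsv", len(bundle.truth_genes))
    mdf = pd.DataFrame(manifest, columns=["file", "rows"])
    mdf.to_csv(d / "manifest.tsv", sep="\t", index=False)
    return mdf


def read_bundle(directory) -> Bundle:
    """Load a bundle directory written by :func:`write_bundle`."""
    d = Path(directory)
    cfg = StudyConfig.from_yaml(d / "config.yaml")
    genes = read_gene_table(d / "genes.tsv")
    isoforms = pd.read_csv(d / "isoforms.tsv", sep="\t", dtype={"chrom": str})
    sheet = pd.read_csv(d / "samples.tsv", sep="\t", index_col=0)
    peaks = {}
    for f in sorted(d.glob("peaks_*.bed")):
        peaks[f.stem.removeprefix("peaks_")] = read_bed(f)
    counts = {}
    for f in sorted(d.glob("counts_*.tsv")):
        cdf = pd.read_csv(f, sep="\t", index_col=0)
        counts[f.stem.removeprefix("counts_")] = RegionCountMatrix(
            cdf, sheet.loc[[s for s in cdf.columns]]
        )
    tracks = {}
    for f in sorted(d.glob("track_*.bedGraph")):
        tracks[f.stem.removeprefix("track_")] = read_bedgraph(f)
    truth_sites = pd.read_csv(d / "truth_sites.tsv", sep="\t", dtype={"chrom": str})
    truth_genes = pd.read_csv(d / "truth_genes.tsv", sep="\t")
    return Bundle(
        config=cfg, genes=genes, isoforms=isoforms, peaks=peaks, counts=counts,
        tracks=tracks, truth_sites=truth_sites, truth_genes=truth_genes,
    )
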