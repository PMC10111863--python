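"""End-to-end orchestration: simulate -> differential -> ABC -> classify ->
gene linking -> concordance -> report.

The report directory is fully derivable and deterministic: ``inputs/``
holds the study bundle, ``tables/`` the per-stage TSVs, ``summary.tsv``
the category counts/fractions, and ``run.log`` the config echo, seed and
SHA-256 checksum of every written table. Identical config + seed yields a
byte-identical directory.
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc_model, classify as cls_mod
from .classify import ClassificationThresholds
from .differential import RegionCountMatrix, bh_adjust, call_differential, estimate_size_factors, nb_wald_test
from .intervals import interval_signal, intersect_any
from .simulate import Bundle, StudyConfig, read_bundle, simulate_study, write_bundle

__all__ = [
    "PipelineConfig",
    "link_sites_to_genes",
    "expression_concordance",
    "run_pipeline",
    "summarize_tables",
]


@dataclass
class PipelineConfig:
    """Everything a run needs; ``preset='paper'`` pins the study's printed
    thresholds (1.5 / 0.05 / 0.5 / 0.022 / 5 Mb / 150,000 / 275)."""

    study: StudyConfig = field(default_factory=StudyConfig)
    simulate: bool = True
    bundle_dir: str | None = None
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    abc_window: int = abc_model.ABC_WINDOW_DEFAULT
    abc_threshold: float = abc_model.ABC_THRESHOLD_DEFAULT
    abc_n_top: int = abc_model.N_TOP_DEFAULT
    abc_summit_halfwidth: int = abc_model.SUMMIT_HALFWIDTH_DEFAULT
    abc_gamma: float = abc_model.GAMMA_DEFAULT
    abc_d_min: int = abc_model.D_MIN_DEFAULT
    tpm_floor: float = 1.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        study = StudyConfig.from_dict(d.pop("study", {}) or {})
        thr = ClassificationThresholds(**(d.pop("thresholds", {}) or {}))
        abc = d.pop("abc", {}) or {}
        kwargs = {f"abc_{k}": v for k, v in abc.items() if f"abc_{k}" in cls.__dataclass_fields__}
        if "tpm_floor" in abc:
            kwargs["tpm_floor"] = abc["tpm_floor"]
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(study=study, thresholds=thr, **kwargs, **known)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def echo(self) -> dict:
        return {
            "seed": self.study.seed,
            "simulate": self.simulate,
            "bundle_dir": self.bundle_dir,
            "fc_min": self.thresholds.fc_min,
            "q_max_dependency": self.thresholds.q_max_dependency,
            "q_max_codependency": self.thresholds.q_max_codependency,
            "ko_signal_quantile": self.thresholds.ko_signal_quantile,
            "require_no_ko_peak": self.thresholds.require_no_ko_peak,
            "abc_window": self.abc_window,
            "abc_threshold": self.abc_threshold,
            "abc_n_top": self.abc_n_top,
            "abc_summit_halfwidth": self.abc_summit_halfwidth,
            "abc_gamma": self.abc_gamma,
            "abc_d_min": self.abc_d_min,
            "tpm_floor": self.tpm_floor,
        }


# ---------------------------------------------------------------------------
# stages


def _samples(rcm: RegionCountMatrix, condition: str) -> list[str]:
    sel = rcm.samples.index[rcm.samples["condition"] == condition]
    return list(sel)


def differential_stage(bundle: Bundle) -> dict[str, pd.DataFrame]:
    """All two-group comparisons of the study design (B vs A; positive
    log2fc = higher in B)."""
    atac = bundle.counts["atac_sites"]
    rna = bundle.counts["rna"]
    rem = bundle.counts["chip_remodeler"]
    tf = bundle.counts["chip_tf"]
    pairs = {
        "atac_ko_vs_wt": (atac, "wt_late", "ko"),
        "atac_early_vs_wt": (atac, "wt_late", "wt_early"),
        "atac_inhibitor_vs_wt": (atac, "wt_late", "inhibitor"),
        "rna_ko_vs_wt": (rna, "wt", "ko"),
        "chip_remodeler_ko_vs_control": (rem, "control", "ko"),
        "chip_tf_inhibitor_vs_control": (tf, "control", "inhibitor"),
    }
    out = {}
    for name, (rcm, cond_a, cond_b) in pairs.items():
        res = nb_wald_test(rcm, _samples(rcm, cond_a), _samples(rcm, cond_b))
        res["q"] = bh_adjust(res["p"].to_numpy())
        out[name] = res
    return out


def abc_stage(bundle: Bundle, cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TSS selection, candidate elements, activity and ABC links."""
    tss = abc_model.select_tss(bundle.isoforms)
    missing = [c for c in ("symbol", "gene_start", "gene_end") if c not in tss.columns]
    if missing:
        tss = tss.merge(
            bundle.genes[["gene_id", *missing]].drop_duplicates("gene_id"),
            on="gene_id", how="left",
        )
    tss = abc_model.filter_genes(tss)
    elements = abc_model.build_candidate_elements(
        bundle.peaks["atac_wt_late"],
        bundle.counts["atac_peaks"],
        tss,
        n_top=cfg.abc_n_top,
        summit_halfwidth=cfg.abc_summit_halfwidth,
    )
    atac_mass = interval_signal(bundle.tracks["atac_wt_late"], elements, how="sum")
    h3k_mass = interval_signal(bundle.tracks["h3k27ac"], elements, how="sum")
    atac_rpm = atac_mass / max(atac_mass.sum(), 1.0) * 1e6
    h3k_rpm = h3k_mass / max(h3k_mass.sum(), 1.0) * 1e6
    elements = elements.assign(
        atac_rpm=atac_rpm,
        h3k27ac_rpm=h3k_rpm,
        activity=abc_model.compute_activity(atac_rpm, h3k_rpm),
    )
    expressed = (
        bundle.isoforms.groupby("gene_id")["tpm_mean"].sum().pipe(lambda s: s[s >= cfg.tpm_floor]).index
    )
    links = abc_model.compute_abc_links(
        elements,
        tss,
        expressed,
        window=cfg.abc_window,
        threshold=cfg.abc_threshold,
        gamma=cfg.abc_gamma,
        d_min=cfg.abc_d_min,
    )
    return tss, elements, links


def classification_stage(
    bundle: Bundle, diffs: dict[str, pd.DataFrame], thresholds: ClassificationThresholds
) -> tuple[pd.DataFrame, dict]:
    """Per-site taxonomy plus the scalar summaries attached to it."""
    sites = bundle.peaks["tf"]
    site_ids = sites["name"].to_numpy(object)
    state = cls_mod.classify_chromatin_state(sites, bundle.peaks["atac_wt_late"])
    open_ids = site_ids[state == "open"]

    diff_ko = diffs["atac_ko_vs_wt"]
    dependency_open = cls_mod.classify_dependency(open_ids, diff_ko, thresholds)
    dependency = pd.Series("not_assessed", index=pd.Index(site_ids, name="site_id"), dtype=object)
    dependency.loc[dependency_open.index] = dependency_open

    atac = bundle.counts["atac_sites"]
    factors = estimate_size_factors(atac)
    norm = atac.counts / factors
    meta = atac.samples
    ko_signal = norm[meta.index[meta["condition"] == "ko"]].mean(axis=1)
    wt_signal = norm[meta.index[meta["condition"] == "wt_late"]].mean(axis=1)

    ko_peak = pd.Series(
        intersect_any(sites, bundle.peaks["atac_ko"]), index=pd.Index(site_ids, name="site_id")
    )
    wt_peak = pd.Series(
        intersect_any(sites, bundle.peaks["atac_wt_late"]), index=pd.Index(site_ids, name="site_id")
    )
    dependent = dependency[dependency.isin(["opens", "represses"])]
    wt_open_ref = wt_signal.loc[open_ids].to_numpy()
    ko_open_ids = site_ids[ko_peak.to_numpy()]
    ko_open_ref = ko_signal.loc[ko_open_ids].to_numpy() if len(ko_open_ids) else wt_open_ref
    modes_dep = cls_mod.classify_pioneer_mode(
        dependent,
        ko_peak=ko_peak,
        ko_signal=ko_signal,
        wt_open_reference=wt_open_ref,
        thresholds=thresholds,
        wt_peak=wt_peak,
        wt_signal=wt_signal,
        ko_open_reference=ko_open_ref,
    )
    mode = pd.Series("not_applicable", index=pd.Index(site_ids, name="site_id"), dtype=object)
    mode.loc[modes_dep.index] = modes_dep

    prebound_fraction, prebound_flags = cls_mod.prebound_consistency(
        diffs["atac_early_vs_wt"], dependency, thresholds
    )
    early_called = call_differential(
        diffs["atac_early_vs_wt"], fc_min=thresholds.fc_min, q_max=thresholds.q_max_dependency
    )
    prebound_closed = pd.Series(pd.NA, index=pd.Index(site_ids, name="site_id"), dtype=object)
    prebound_closed.loc[open_ids] = (
        early_called.loc[open_ids, "called"] & (early_called.loc[open_ids, "direction"] < 0)
    ).to_numpy()

    cobound = pd.Series(
        cls_mod.flag_cobound(sites, bundle.peaks["remodeler_control"]),
        index=pd.Index(site_ids, name="site_id"),
    )
    codependent = cls_mod.codependent_sites(
        cobound, diff_ko, diffs["atac_inhibitor_vs_wt"], thresholds
    )
    rem = bundle.counts["chip_remodeler"]
    partner = cls_mod.partner_binding_change(
        rem, _samples(rem, "control"), _samples(rem, "ko"),
        bundle.peaks["remodeler_ko"], sites, thresholds,
    )
    dep_ids = dependent.index
    r = (
        cls_mod.accessibility_fc_correlation(diff_ko, diffs["atac_inhibitor_vs_wt"], dep_ids)
        if len(dep_ids) >= 3
        else float("nan")
    )

    classification = pd.DataFrame(
        {
            "site_id": site_ids,
            "chrom": sites["chrom"].to_numpy(),
            "start": sites["start"].to_numpy(),
            "end": sites["end"].to_numpy(),
            "chromatin_state": state,
            "dependency": dependency.to_numpy(),
            "mode": mode.to_numpy(),
            "cobound": cobound.to_numpy(),
            "codependent": codependent.to_numpy(),
            "prebound_closed": prebound_closed.to_numpy(),
            "partner_binding": partner.to_numpy(),
        }
    )
    extras = {
        "prebound_consistency": prebound_fraction,
        "fc_correlation_r": r,
        "n_prebound_closed": int(len(prebound_flags)),
    }
    return classification, extras


def link_sites_to_genes(
    classification: pd.DataFrame, links: pd.DataFrame, tf_sites: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Assign each site to every kept element it overlaps (>= 1 bp) and
    thereby to that element's genes.

    Returns (gene_results, site-element-gene pair table, unassigned site
    ids). ``gene_results`` aggregates per gene the linked element ids, site
    ids and the sites' dependency directions.
    """
    kept = links.loc[links["kept"]]
    elements = kept[["element_id", "chrom", "start", "end"]].drop_duplicates("element_id")
    pairs = []
    for chrom, el in elements.groupby("chrom", sort=True):
        el = el.sort_values("start", kind="stable")
        es = el["start"].to_numpy(np.int64)
        ee = el["end"].to_numpy(np.int64)
        eid = el["element_id"].to_numpy(object)
        sel = tf_sites.loc[tf_sites["chrom"] == chrom]
        ss = sel["start"].to_numpy(np.int64)
        se = sel["end"].to_numpy(np.int64)
        sid = sel["name"].to_numpy(object)
        # elements are disjoint and sorted: overlaps form a contiguous run
        lo = np.searchsorted(ee, ss, side="right")
        hi = np.searchsorted(es, se, side="left")
        for k in range(len(sel)):
            for j in range(lo[k], hi[k]):
                if ee[j] > ss[k] and es[j] < se[k]:
                    pairs.append((sid[k], eid[j]))
    pair_df = pd.DataFrame(pairs, columns=["site_id", "element_id"])
    triple = pair_df.merge(kept[["element_id", "gene_id"]], on="element_id")
    triple = triple.merge(
        classification[["site_id", "dependency", "mode", "cobound", "codependent"]],
        on="site_id", how="left",
    )
    assigned = set(pair_df["site_id"])
    unassigned = [s for s in classification["site_id"] if s not in assigned]

    rows = []
    for gene_id, grp in triple.groupby("gene_id", sort=True):
        dep = grp.drop_duplicates("site_id")
        n_down = int((dep["dependency"] == "opens").sum())
        n_up = int((dep["dependency"] == "represses").sum())
        if n_down > n_up:
            consensus = "decrease"
        elif n_up > n_down:
            consensus = "increase"
        elif n_up == n_down and n_up > 0:
            consensus = "tied"
        else:
            consensus = "none"
        rows.append(
            {
                "gene_id": gene_id,
                "element_ids": ";".join(sorted(set(grp["element_id"]))),
                "site_ids": ";".join(sorted(set(grp["site_id"]))),
                "n_sites": int(grp["site_id"].nunique()),
                "n_dependent_down": n_down,
                "n_dependent_up": n_up,
                "accessibility_consensus": consensus,
            }
        )
    gene_results = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "element_ids", "site_ids", "n_sites", "n_dependent_down",
            "n_dependent_up", "accessibility_consensus",
        ],
    )
    return gene_results, triple, unassigned


def expression_concordance(
    gene_results: pd.DataFrame,
    de_genes: pd.DataFrame,
    fc_min: float = 1.5,
    q_max: float = 0.05,
) -> dict:
    """Accessibility <-> expression concordance per direction.

    Among genes with a decrease consensus and a differential-expression
    call, the fraction down-regulated; symmetrically for increase/up.
    Tied-consensus genes are excluded and counted.
    """
    called = call_differential(de_genes, fc_min=fc_min, q_max=q_max)
    out = {"n_tied": int((gene_results["accessibility_consensus"] == "tied").sum())}
    for consensus, expr_dir, key in (("decrease", -1, "down"), ("increase", 1, "up")):
        sub = gene_results.loc[gene_results["accessibility_consensus"] == consensus]
        sub = sub.loc[sub["gene_id"].isin(called.index)]
        calls = called.loc[sub["gene_id"]]
        with_call = calls.loc[calls["called"]]
        n = int(len(with_call))
        frac = float((with_call["direction"] == expr_dir).mean()) if n else float("nan")
        out[f"concordance_{key}"] = frac
        out[f"n_{key}"] = n
    return out


# ---------------------------------------------------------------------------
# orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(outdir, config: PipelineConfig | None = None, seed: int | None = None) -> Path:
    """Execute the full pipeline into ``outdir`` and return its path."""
    cfg = config or PipelineConfig()
    if seed is not None:
        cfg.study.seed = int(seed)
    out = Path(outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        print(msg, file=sys.stderr)

    log(f"config\t{yaml.safe_dump(cfg.echo(), sort_keys=True).strip()}")

    stage = "simulate"
    try:
        if cfg.simulate:
            bundle = simulate_study(cfg.study)
            write_bundle(bundle, out / "inputs")
        else:
            if not cfg.bundle_dir:
                raise ValueError("bundle_dir required when simulate is false")
            bundle = read_bundle(cfg.bundle_dir)
        log(f"stage\t{stage}\tsites={len(bundle.truth_sites)}\tgenes={len(bundle.genes)}")

        stage = "differential"
        diffs = differential_stage(bundle)
        for name, df in diffs.items():
            p = out / "tables" / f"diff_{name}.tsv"
            _write_table(df, p, index=True)
            log(f"stage\t{stage}\t{p.name}\trows={len(df)}\tsha256={_sha256(p)}")

        stage = "abc"
        tss, elements, links = abc_stage(bundle, cfg)
        for name, df in (("tss", tss), ("elements", elements), ("links", links)):
            p = out / "tables" / f"abc_{name}.tsv"
            _write_table(df, p)
            log(f"stage\t{stage}\t{p.name}\trows={len(df)}\tsha256={_sha256(p)}")

        stage = "classify"
        classification, extras = classification_stage(bundle, diffs, cfg.thresholds)
        p = out / "tables" / "classification.tsv"
        _write_table(classification, p)
        log(f"stage\t{stage}\t{p.name}\trows={len(classification)}\tsha256={_sha256(p)}")

        stage = "link"
        gene_results, triple, unassigned = link_sites_to_genes(
            classification, links, bundle.peaks["tf"]
        )
        conc = expression_concordance(
            gene_results, diffs["rna_ko_vs_wt"],
            fc_min=cfg.thresholds.fc_min, q_max=cfg.thresholds.q_max_dependency,
        )
        _write_table(gene_results, out / "tables" / "gene_results.tsv")
        _write_table(triple, out / "tables" / "site_element_gene.tsv")
        pd.DataFrame({"site_id": unassigned}).to_csv(
            out / "tables" / "unassigned_sites.tsv", sep="\t", index=False
        )
        log(f"stage\t{stage}\tgene_results.tsv\trows={len(gene_results)}")

        stage = "summary"
        summary = _summarize(classification, extras, conc, cfg, len(unassigned))
        _write_table(summary, out / "summary.tsv")
        log(f"stage\t{stage}\tsummary.tsv\trows={len(summary)}\tsha256={_sha256(out / 'summary.tsv')}")
    except Exception as err:
        (out / "run.log").write_text("\n".join(log_lines + [f"FAILED\t{stage}\t{err}"]) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def _summarize(
    classification: pd.DataFrame, extras: dict, conc: dict, cfg: PipelineConfig, n_unassigned: int
) -> pd.DataFrame:
    c = classification
    n_sites = len(c)
    n_open = int((c["chromatin_state"] == "open").sum())
    dep = c.loc[c["dependency"].isin(["opens", "represses"])]
    n_dep = len(dep)
    n_opens = int((c["dependency"] == "opens").sum())
    n_classical = int(((c["mode"] == "classical_pioneer") & (c["dependency"] == "opens")).sum())
    open_c = c.loc[c["chromatin_state"] == "open"]
    rows = [
        ("n_sites", n_sites),
        ("n_open", n_open),
        ("frac_open", n_open / n_sites if n_sites else float("nan")),
        ("n_dependent", n_dep),
        ("frac_dependent_of_open", n_dep / n_open if n_open else float("nan")),
        ("n_decreasing", n_opens),
        ("frac_decreasing_of_dependent", n_opens / n_dep if n_dep else float("nan")),
        ("n_classical_pioneer", n_classical),
        ("frac_classical_of_decreasing", n_classical / n_opens if n_opens else float("nan")),
        ("frac_cobound_open", float(open_c["cobound"].mean()) if len(open_c) else float("nan")),
        ("n_codependent", int(c["codependent"].sum())),
        ("prebound_consistency", extras["prebound_consistency"]),
        ("n_prebound_closed", extras["n_prebound_closed"]),
        ("fc_correlation_r", extras["fc_correlation_r"]),
        ("n_unassigned_sites", n_unassigned),
        ("concordance_down", conc["concordance_down"]),
        ("n_concordance_down", conc["n_down"]),
        ("concordance_up", conc["concordance_up"]),
        ("n_concordance_up", conc["n_up"]),
        ("n_consensus_tied", conc["n_tied"]),
        ("threshold_fc_min", cfg.thresholds.fc_min),
        ("threshold_q_max", cfg.thresholds.q_max_dependency),
        ("threshold_q_max_codependency", cfg.thresholds.q_max_codependency),
        ("abc_threshold", cfg.abc_threshold),
        ("abc_window", cfg.abc_window),
        ("abc_n_top", cfg.abc_n_top),
        ("abc_summit_halfwidth", cfg.abc_summit_halfwidth),
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])


def summarize_tables(report_dir) -> pd.DataFrame:
    """Recompute the headline fractions from a report's per-record tables
    (the summary is derivable; no hidden state)."""
    d = Path(report_dir)
    c = pd.read_csv(d / "tables" / "classification.tsv", sep="\t")
    n_open = int((c["chromatin_state"] == "open").sum())
    dep = c["dependency"].isin(["opens", "represses"])
    out = {
        "n_sites": len(c),
        "frac_open": n_open / len(c) if len(c) else float("nan"),
        "frac_dependent_of_open": float(dep.sum() / n_open) if n_open else float("nan"),
        "n_codependent": int(c["codependent"].sum()),
    }
    return pd.DataFrame(sorted(out.items()), columns=["metric", "value"])
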