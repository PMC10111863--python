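"""Classification of TF-bound sites by chromatin state and remodeling mode.

The taxonomy follows the knockout/inhibitor study design: a TF site is
*open* or *closed* by overlap with wild-type ATAC consensus peaks;
dependency (*opens* / *represses* / *static*) is assessed only on open
sites from the KO-versus-WT accessibility comparison; dependent sites are
split into *classical_pioneer* (no residual accessibility in the TF-naive
state: no KO ATAC peak and KO signal below a low quantile of the wild-type
open-site signal distribution) versus *permissive* (accessibility
attenuated but present without the TF). Cobinding with a remodeler subunit
is peak overlap; codependency additionally requires a called KO change at
a relaxed q and a sign-concordant (threshold-free) inhibitor response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import (
    FC_MIN_DEFAULT,
    Q_MAX_CODEPENDENCY,
    Q_MAX_DEFAULT,
    RegionCountMatrix,
    bh_adjust,
    call_differential,
    nb_wald_test,
)
from .intervals import intersect_any

__all__ = [
    "ClassificationThresholds",
    "classify_chromatin_state",
    "classify_dependency",
    "classify_pioneer_mode",
    "prebound_consistency",
    "flag_cobound",
    "codependent_sites",
    "partner_binding_change",
    "accessibility_fc_correlation",
]

OPEN, CLOSED = "open", "closed"
OPENS, REPRESSES, STATIC, NOT_ASSESSED = "opens", "represses", "static", "not_assessed"
CLASSICAL, PERMISSIVE, NOT_APPLICABLE = "classical_pioneer", "permissive", "not_applicable"


@dataclass(frozen=True)
class ClassificationThresholds:
    """Thresholds of the site taxonomy.

    fc_min / q_max_dependency gate the dependency call (study preset
    1.5 / 0.05); q_max_codependency is the relaxed bound of the inhibitor
    codependency step (study preset 0.5); ko_signal_quantile is the
    wild-type open-site signal quantile below which a TF-naive site counts
    as devoid of signal; require_no_ko_peak additionally demands that no
    ATAC peak was called in the TF-naive condition.
    """

    fc_min: float = FC_MIN_DEFAULT
    q_max_dependency: float = Q_MAX_DEFAULT
    q_max_codependency: float = Q_MAX_CODEPENDENCY
    ko_signal_quantile: float = 0.10
    require_no_ko_peak: bool = True

    def __post_init__(self) -> None:
        if min(self.fc_min, self.q_max_dependency, self.q_max_codependency) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.ko_signal_quantile < 1:
            raise ValueError("ko_signal_quantile must lie in (0, 1)")


def classify_chromatin_state(tf_sites: pd.DataFrame, atac_peaks_wt: pd.DataFrame) -> np.ndarray:
    """'open' iff the site shares >= 1 bp with a WT ATAC consensus peak."""
    flags = intersect_any(tf_sites, atac_peaks_wt)
    return np.where(flags, OPEN, CLOSED).astype(object)


def _called(diff: pd.DataFrame, thresholds: ClassificationThresholds, q_max: float) -> pd.DataFrame:
    return call_differential(diff, fc_min=thresholds.fc_min, q_max=q_max)


def classify_dependency(
    open_site_ids,
    diff_ko_vs_wt: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.Series:
    """Dependency labels for open sites from the KO-vs-WT differential
    (log2fc positive = more accessible in KO).

    opens = called decrease in KO (the TF was needed to open the site);
    represses = called increase; else static.
    """
    open_site_ids = list(open_site_ids)
    missing = [s for s in open_site_ids if s not in diff_ko_vs_wt.index]
    if missing:
        raise ValueError(f"open site {missing[0]!r} missing from differential table")
    called = _called(diff_ko_vs_wt, thresholds, thresholds.q_max_dependency).loc[open_site_ids]
    labels = np.full(len(open_site_ids), STATIC, dtype=object)
    labels[(called["called"] & (called["direction"] < 0)).to_numpy()] = OPENS
    labels[(called["called"] & (called["direction"] > 0)).to_numpy()] = REPRESSES
    return pd.Series(labels, index=pd.Index(open_site_ids, name="site_id"), name="dependency")


def classify_pioneer_mode(
    dependency: pd.Series,
    ko_peak: pd.Series,
    ko_signal: pd.Series,
    wt_open_reference,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    wt_peak: pd.Series | None = None,
    wt_signal: pd.Series | None = None,
    ko_open_reference=None,
) -> pd.Series:
    """classical_pioneer vs permissive for dependent sites.

    For *opens* sites: classical iff (no KO ATAC peak overlaps the site,
    when required) and the KO signal lies below the ``ko_signal_quantile``
    quantile of the wild-type open-site signal distribution; else
    permissive. For *represses* sites the same rule with WT and KO roles
    swapped (a classical repressive site is closed in WT and open in KO);
    when the swapped-side inputs are not supplied, represses sites are
    permissive (they carry a WT peak by construction of the taxonomy).

    Raises on static / not_assessed input: mode is defined only for
    dependent sites.
    """
    bad = dependency[~dependency.isin([OPENS, REPRESSES])]
    if len(bad):
        raise ValueError(f"mode undefined for site {bad.index[0]!r} with dependency {bad.iloc[0]!r}")
    modes = pd.Series(PERMISSIVE, index=dependency.index, name="mode", dtype=object)

    is_opens = dependency == OPENS
    ref = np.asarray(wt_open_reference, dtype=float)
    cut = np.quantile(ref, thresholds.ko_signal_quantile) if ref.size else np.inf
    low = ko_signal.loc[dependency.index].to_numpy(float) < cut
    nopeak = ~ko_peak.loc[dependency.index].to_numpy(bool) if thresholds.require_no_ko_peak else True
    modes[is_opens & low & nopeak] = CLASSICAL

    is_repr = dependency == REPRESSES
    if is_repr.any() and wt_peak is not None and wt_signal is not None and ko_open_reference is not None:
        ref2 = np.asarray(ko_open_reference, dtype=float)
        cut2 = np.quantile(ref2, thresholds.ko_signal_quantile) if ref2.size else np.inf
        low2 = wt_signal.loc[dependency.index].to_numpy(float) < cut2
        nopeak2 = ~wt_peak.loc[dependency.index].to_numpy(bool) if thresholds.require_no_ko_peak else True
        modes[is_repr & low2 & nopeak2] = CLASSICAL
    return modes


def prebound_consistency(
    diff_early_vs_late: pd.DataFrame,
    dependency: pd.Series,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> tuple[float, pd.Series]:
    """Among sites differentially closed in the early (TF-naive) condition,
    the fraction that are also TF-dependent (*opens*) in the KO.

    Returns (fraction, per-site flags over the early-closed sites);
    fraction is NaN when no site is early-closed.
    """
    called = _called(diff_early_vs_late, thresholds, thresholds.q_max_dependency)
    early_closed = called.index[(called["called"] & (called["direction"] < 0)).to_numpy()]
    early_closed = [s for s in early_closed if s in dependency.index]
    flags = pd.Series(
        dependency.loc[early_closed].eq(OPENS).to_numpy(),
        index=pd.Index(early_closed, name="site_id"),
        name="prebound_consistent",
    )
    fraction = float(flags.mean()) if len(flags) else float("nan")
    return fraction, flags


def flag_cobound(tf_sites: pd.DataFrame, remodeler_peaks: pd.DataFrame) -> np.ndarray:
    """True iff the site shares >= 1 bp with a remodeler peak."""
    return intersect_any(tf_sites, remodeler_peaks)


def codependent_sites(
    cobound: pd.Series,
    diff_ko: pd.DataFrame,
    diff_inhibitor: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.Series:
    """Sites whose accessibility responds concordantly to TF knockout and
    remodeler-ATPase inhibition.

    codependent iff cobound AND the KO change is called at the relaxed
    q_max_codependency with |fold| >= fc_min AND the inhibitor log2fc has
    the same sign (threshold-free on the inhibitor side; an exactly zero
    inhibitor fold change counts as discordant).
    """
    ids = list(cobound.index)
    for table, label in ((diff_ko, "KO"), (diff_inhibitor, "inhibitor")):
        missing = [s for s in ids if s not in table.index]
        if missing:
            raise ValueError(f"site {missing[0]!r} missing from {label} differential table")
    ko = _called(diff_ko, thresholds, thresholds.q_max_codependency).loc[ids]
    inh_sign = np.sign(diff_inhibitor.loc[ids, "log2fc"].to_numpy(float))
    concordant = ko["called"].to_numpy() & (inh_sign == ko["direction"].to_numpy()) & (inh_sign != 0)
    flags = cobound.loc[ids].to_numpy(bool) & concordant
    return pd.Series(flags, index=pd.Index(ids, name="site_id"), name="codependent")


def partner_binding_change(
    partner_counts: RegionCountMatrix,
    control_samples,
    perturbed_samples,
    partner_peaks_perturbed: pd.DataFrame,
    sites: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.Series:
    """Label partner (remodeler or TF) binding at each site after
    perturbing the other factor: absent / decreased / unchanged.

    absent iff no partner peak overlaps the site in the perturbed
    condition; else decreased iff a called decrease in partner ChIP counts
    (q <= q_max_dependency, |fold| >= fc_min); else unchanged.
    """
    diff = nb_wald_test(partner_counts, control_samples, perturbed_samples)
    diff["q"] = bh_adjust(diff["p"].to_numpy())
    called = _called(diff, thresholds, thresholds.q_max_dependency)
    site_ids = sites["name"].to_numpy(object)
    has_peak = intersect_any(sites, partner_peaks_perturbed)
    labels = np.full(len(sites), "unchanged", dtype=object)
    dec = (called.loc[site_ids, "called"] & (called.loc[site_ids, "direction"] < 0)).to_numpy()
    labels[dec] = "decreased"
    labels[~has_peak] = "absent"
    return pd.Series(labels, index=pd.Index(site_ids, name="site_id"), name="partner_binding")


def accessibility_fc_correlation(diff_a: pd.DataFrame, diff_b: pd.DataFrame, site_ids) -> float:
    """Pearson correlation of log2 fold changes between two comparisons
    over a site set; NaN when either vector has zero variance."""
    ids = list(site_ids)
    if len(ids) < 3:
        raise ValueError("need >= 3 sites for a correlation")
    a = diff_a.loc[ids, "log2fc"].to_numpy(float)
    b = diff_b.loc[ids, "log2fc"].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
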