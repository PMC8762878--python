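"""Posterior summaries: variance partitions, PIPs and probe groups.

Because phenotype and markers are standardized, the variance explained by
a marker set in one retained draw is the sum of its squared effects; the
partition reports the mean over draws with the 2.5/97.5 percentiles as
the 95% credible interval.  The EWAS summary groups CpGs that are within
2.5 kb of, and correlated |r| > 0.5 with, a lead CpG, and reports the
group posterior inclusion probability: the fraction of draws in which at
least one member is in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MarkerMatrix, PosteriorDraws

GROUP_WINDOW_BP = 2_500
GROUP_R_MIN = 0.5
LEAD_PIP_MIN = 0.2


@dataclass
class VariancePartition:
    """Per-set share of phenotypic variance with credible interval."""

    set_label: str
    mean: float
    ci_low: float
    ci_high: float
    mixture_means: tuple  # per non-null component, sums to `mean`
    kind: str = "marginal"  # or "conditional"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean + 1e-12 and self.mean <= self.ci_high + 1e-12):
            raise ValueError("credible interval must bracket the mean")


@dataclass
class ProbeGroup:
    lead: str
    members: list
    group_pip: float
    group_variance: float
    lead_pip: float

    def __post_init__(self) -> None:
        if self.lead not in self.members:
            raise ValueError("lead must be a group member")
        if self.group_pip + 1e-12 < self.lead_pip:
            raise ValueError("group PIP cannot be below the lead PIP")


def variance_partition(draws: PosteriorDraws, kind: str = "marginal") -> dict:
    """Per-set variance explained and per-mixture contributions.

    Per draw t and set s, V_s(t) = sum_j beta_j(t)^2; the per-mixture
    contribution restricts the sum to markers currently assigned to that
    component, so the mixture contributions sum to the set total draw by
    draw.  Returns ``{set_label: VariancePartition}``.
    """
    if draws.n_draws == 0:
        raise ValueError("no retained draws")
    if not draws.standardized_input:
        raise ValueError("variance partition requires standardized inputs")
    out = {}
    b2 = draws.beta**2
    for s, label in enumerate(draws.set_labels):
        cols = np.flatnonzero(draws.set_index == s)
        v = b2[:, cols].sum(axis=1)
        mix = []
        k_max = int(draws.components.max(initial=0))
        for k in range(1, max(k_max, 3) + 1):
            mask = draws.components[:, cols] == k
            mix.append(float((b2[:, cols] * mask).sum(axis=1).mean()))
        out[label] = VariancePartition(
            set_label=label,
            mean=float(v.mean()),
            ci_low=float(np.percentile(v, 2.5)),
            ci_high=float(np.percentile(v, 97.5)),
            mixture_means=tuple(mix),
            kind=kind,
        )
    return out


def attenuation_report(marginal: VariancePartition, conditional: VariancePartition) -> dict:
    """Absolute and relative attenuation of a set's variance share.

    ``absolute`` is marginal minus conditional in percentage points;
    ``relative`` is the absolute attenuation as a percentage of the
    marginal estimate.
    """
    if marginal.set_label != conditional.set_label:
        raise ValueError("partitions describe different marker sets")
    if marginal.mean == 0:
        if conditional.mean != 0:
            raise ValueError("zero marginal share with nonzero conditional share")
        return {"absolute": 0.0, "relative": 0.0}
    m, c = 100.0 * marginal.mean, 100.0 * conditional.mean  # percentage points
    absolute = m - c
    return {"absolute": absolute, "relative": 100.0 * absolute / m}


def attenuation_from_percent(marginal_pct: float, conditional_pct: float) -> dict:
    """Attenuation arithmetic directly from percentage estimates."""
    if marginal_pct == 0:
        raise ValueError("zero marginal estimate")
    absolute = marginal_pct - conditional_pct
    return {"absolute": absolute, "relative": 100.0 * absolute / marginal_pct}


def marker_pips(draws: PosteriorDraws) -> pd.Series:
    """Per-marker posterior inclusion probability."""
    if draws.n_draws == 0:
        raise ValueError("no retained draws")
    pip = (draws.components != 0).mean(axis=0)
    return pd.Series(pip, index=pd.Index(draws.marker_ids, name="id"), name="pip")


def group_probes(
    draws: PosteriorDraws,
    markers: MarkerMatrix,
    lead_pip_min: float = LEAD_PIP_MIN,
    window: int = GROUP_WINDOW_BP,
    r_min: float = GROUP_R_MIN,
    set_label: str = "methylation",
) -> list[ProbeGroup]:
    """Group correlated, physically close probes around lead markers.

    Leads are taken in descending PIP among markers of the set with
    PIP > ``lead_pip_min`` (ties broken by genomic position).  A lead's
    group collects the still-unassigned markers on the same chromosome
    within ``window`` bp (closed interval, lead-to-member) whose absolute
    Pearson correlation with the lead on the analyzed matrix exceeds
    ``r_min``.  The group PIP is the fraction of draws in which at least
    one member is non-null.
    """
    man = markers.manifest.set_index("id")
    if man["pos"].isna().any():
        raise ValueError("manifest positions required for grouping")
    pips = marker_pips(draws)
    set_ids = [
        mid
        for mid in draws.marker_ids
        if mid in man.index and man.loc[mid, "set"] == set_label
    ]
    col_of = {mid: i for i, mid in enumerate(draws.marker_ids)}
    incl = draws.components != 0

    candidates = [m for m in set_ids if pips[m] > lead_pip_min]
    candidates.sort(key=lambda m: (-pips[m], str(man.loc[m, "chr"]), int(man.loc[m, "pos"])))

    x = markers.values
    assigned: set = set()
    groups: list[ProbeGroup] = []
    for lead in candidates:
        if lead in assigned:
            continue
        chrom, pos = man.loc[lead, "chr"], int(man.loc[lead, "pos"])
        lead_vals = x[lead].to_numpy(float)
        members = [lead]
        for other in set_ids:
            if other == lead or other in assigned:
                continue
            if man.loc[other, "chr"] != chrom:
                continue
            if abs(int(man.loc[other, "pos"]) - pos) > window:
                continue
            r = np.corrcoef(lead_vals, x[other].to_numpy(float))[0, 1]
            if np.abs(r) > r_min:
                members.append(other)
        cols = [col_of[m] for m in members]
        group_pip = float(incl[:, cols].any(axis=1).mean())
        group_var = float((draws.beta[:, cols] ** 2).sum(axis=1).mean())
        groups.append(
            ProbeGroup(
                lead=lead,
                members=members,
                group_pip=group_pip,
                group_variance=group_var,
                lead_pip=float(pips[lead]),
            )
        )
        assigned.update(members)
    return groups


def report_leads(
    groups: list[ProbeGroup],
    group_pip_min: float = 0.95,
    lead_pip_min: float = 0.80,
) -> pd.DataFrame:
    """Lead markers whose group and lead PIPs pass the reporting thresholds."""
    rows = [
        {
            "lead": g.lead,
            "lead_pip": g.lead_pip,
            "group_pip": g.group_pip,
            "group_variance": g.group_variance,
            "n_members": len(g.members),
        }
        for g in groups
        if g.group_pip > group_pip_min and g.lead_pip > lead_pip_min
    ]
    df = pd.DataFrame(
        rows, columns=["lead", "lead_pip", "group_pip", "group_variance", "n_members"]
    )
    return df.sort_values("group_pip", ascending=False).reset_index(drop=True)
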