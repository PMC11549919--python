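"""Virus-to-host abundance ratios and ecological model classification.

The virus-to-host abundance ratio (VHR) divides the normalized
coverage of a virus by that of its linked host within one sample;
VHR > 1 reads as lytic-leaning (free virions outnumber host copies),
VHR < 1 as lysogenic-leaning.  Community-level patterns of VHR against
host dominance separate the Piggyback-the-Winner regime (a dominant
"winner" host carrying lysogenic viruses while rare hosts are lysed)
from the Piggyback-the-Persistent / Piggyback-the-Loser regime (no
dominant host; prevalent low-abundance hosts with VHR at or below 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .host_linking import HostLink

BALANCED_BAND = 0.05  # |VHR - 1| tolerance for the "balanced" tendency


@dataclass(frozen=True)
class VhrRecord:
    sample_id: str
    virus_id: str
    host_id: str
    vhr: float
    tendency: str  # lytic_leaning | lysogenic_leaning | balanced


@dataclass(frozen=True)
class ModelCall:
    group_id: str
    model: str  # PtW | PtP_or_PtL | indeterminate
    winner_taxon: str
    winner_abundance: float
    winner_vhr: float
    rare_host_median_vhr: float
    dominance_cut: float
    prevalence_cut: float


def compute_vhr(
    virus_cov: float, host_cov: float, sample_id: str = "", virus_id: str = "",
    host_id: str = "",
) -> VhrRecord:
    """VHR for one (virus, host) pair in one sample.

    Undefined when the host is absent: a ratio to zero coverage is
    uninterpretable, so callers should skip those records rather than
    pseudocount them.
    """
    if host_cov <= 0:
        raise ValueError("VHR undefined for host coverage 0")
    if virus_cov < 0:
        raise ValueError("virus coverage must be >= 0")
    vhr = virus_cov / host_cov
    if abs(vhr - 1.0) <= BALANCED_BAND:
        tendency = "balanced"
    elif vhr > 1.0:
        tendency = "lytic_leaning"
    else:
        tendency = "lysogenic_leaning"
    return VhrRecord(sample_id, virus_id, host_id, vhr, tendency)


def vhr_table(
    coverage: pd.DataFrame,
    links: Sequence[HostLink],
) -> list[VhrRecord]:
    """Per-sample VHR records for every link; zero-host samples skipped."""
    records: list[VhrRecord] = []
    for link in links:
        if link.virus_id not in coverage.columns or link.host_id not in coverage.columns:
            continue
        for sample_id in coverage.index:
            h = float(coverage.at[sample_id, link.host_id])
            if h <= 0:
                continue  # undefined; skipped by design
            v = float(coverage.at[sample_id, link.virus_id])
            records.append(
                compute_vhr(v, h, sample_id, link.virus_id, link.host_id)
            )
    return records


_LYTIC_MARKERS = {"endolysin", "lysin", "holin", "peptidoglycan hydrolase"}


def lifestyle_from_markers(gene_annotations: Iterable[str]) -> str:
    """Marker-based lifestyle call.

    Integrase marks a lysogenic (temperate) phage even when lysis genes
    are also present — temperate phages carry lysis machinery for the
    induced cycle.  Lytic markers alone mark a lytic phage.
    """
    labels = {a.strip().lower() for a in gene_annotations}
    if "integrase" in labels:
        return "lysogenic"
    if labels & _LYTIC_MARKERS:
        return "lytic"
    return "unassigned"


def host_summary_table(
    relative_abundance: pd.DataFrame,
    vhr_records: Sequence[VhrRecord],
    hosts: Sequence[str],
) -> pd.DataFrame:
    """Per-host (mean relative abundance, prevalence, mean VHR) table.

    Prevalence is the fraction of samples where the host is detected;
    mean VHR averages per-sample VHRs over samples where defined, then
    over the host's virus partners.
    """
    rows = []
    vhr_by_host: dict[str, dict[str, list[float]]] = {}
    for rec in vhr_records:
        vhr_by_host.setdefault(rec.host_id, {}).setdefault(rec.virus_id, []).append(
            rec.vhr
        )
    for h in hosts:
        col = relative_abundance[h] if h in relative_abundance.columns else None
        mean_ab = float(col.mean()) if col is not None else 0.0
        prev = float((col > 0).mean()) if col is not None else 0.0
        per_virus = [np.mean(v) for v in vhr_by_host.get(h, {}).values()]
        mean_vhr = float(np.mean(per_virus)) if per_virus else np.nan
        rows.append((h, mean_ab, prev, mean_vhr))
    return pd.DataFrame(
        rows, columns=["host_id", "mean_abundance", "prevalence", "mean_vhr"]
    ).set_index("host_id")


def classify_model(
    host_table: pd.DataFrame,
    group_id: str = "",
    dominance_cut: float = 0.25,
    prevalence_cut: float = 0.5,
) -> ModelCall:
    """Classify a community as PtW, PtP_or_PtL, or indeterminate.

    PtW: a dominant winner (mean relative abundance >= dominance_cut)
    with mean VHR <= 1 while the remaining hosts' median VHR exceeds 1
    (lysogeny on the winner, lysis on the rare).  PtP_or_PtL: no host
    reaches dominance and the prevalent hosts' median VHR is <= 1
    (lysogeny on persistent low-abundance hosts).  The cutoffs are
    reported alongside the call; the rule is this package's
    operationalization of narrative models.
    """
    if len(host_table) < 3:
        raise ValueError("need at least 3 hosts to classify")
    tab = host_table.dropna(subset=["mean_vhr"])
    if len(tab) < 3:
        raise ValueError("need at least 3 hosts with defined VHR")
    winner = tab["mean_abundance"].idxmax()
    winner_ab = float(tab.at[winner, "mean_abundance"])
    winner_vhr = float(tab.at[winner, "mean_vhr"])
    others = tab.drop(index=winner)
    rare_median = float(others["mean_vhr"].median()) if len(others) else np.nan
    prevalent = tab[tab["prevalence"] >= prevalence_cut]
    prevalent_median = (
        float(prevalent["mean_vhr"].median()) if len(prevalent) else np.nan
    )
    if winner_ab >= dominance_cut and winner_vhr <= 1.0 and rare_median > 1.0:
        model = "PtW"
    elif winner_ab < dominance_cut and prevalent_median <= 1.0:
        model = "PtP_or_PtL"
    else:
        model = "indeterminate"
    return ModelCall(
        group_id,
        model,
        winner,
        winner_ab,
        winner_vhr,
        rare_median,
        dominance_cut,
        prevalence_cut,
    )


def classify_groups(
    coverage: pd.DataFrame,
    links: Sequence[HostLink],
    group_of_sample: Mapping[str, int],
    host_ids: Sequence[str],
    dominance_cut: float = 0.25,
    prevalence_cut: float = 0.5,
) -> dict[int, ModelCall]:
    """Per-group ecological model calls from a normalized coverage table.

    For each group, host relative abundances are renormalized over the
    host features, VHRs are computed for every link in every sample
    where the host is detected, and the host summary is classified.
    """
    totals = coverage.sum(axis=1).replace(0, 1.0)
    rel = coverage.div(totals, axis=0)
    out: dict[int, ModelCall] = {}
    for g in sorted(set(group_of_sample.values())):
        samples = [s for s, gg in group_of_sample.items() if gg == g]
        cov_g = coverage.loc[samples]
        host_rel = rel.loc[samples, list(host_ids)]
        host_rel = host_rel.div(host_rel.sum(axis=1).replace(0, 1.0), axis=0)
        records = vhr_table(cov_g, links)
        table = host_summary_table(host_rel, records, host_ids)
        out[g] = classify_model(
            table, group_id=str(g), dominance_cut=dominance_cut,
            prevalence_cut=prevalence_cut,
        )
    return out


def correlate_vhr_covariate(
    vhr_by_sample: Sequence[float], covariate: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between per-sample VHRs and a covariate."""
    x = np.asarray(vhr_by_sample, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def links_per_group(
    links: Sequence[HostLink], enriched_hosts: Mapping[str, set[str]]
) -> dict[str, float]:
    """Links whose host is group-enriched, normalized per enriched host."""
    out: dict[str, float] = {}
    for group, hosts in enriched_hosts.items():
        if not hosts:
            raise ValueError(f"empty enriched set for group {group!r}")
        n = sum(1 for link in links if link.host_id in hosts)
        out[group] = n / len(hosts)
    return out
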