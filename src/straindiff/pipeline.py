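"""End-to-end orchestration: counts -> filters -> TMM -> moderated DE
per region -> consensus sets.

Mirrors the study workflow: gene filters applied once on the full
matrix, then each brain region fitted separately with strain (cell
means) + sex + batch, all pairwise strain contrasts as one global-FDR
family per region and the two Low_Average contrasts as their own
two-contrast family per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .consensus import (
    ConsensusResult,
    DirectionalGeneSet,
    high_preference_overlap,
    intersect_across_regions,
    low_average_degs,
    signature_genes,
    unique_degs,
)
from .de import ModeratedDE, low_average_contrasts, pairwise_contrasts
from .preprocess import filter_genes, tmm_normalize


@dataclass
class StudyResult:
    """Per-region DEG tables plus consensus sets for one full run."""

    pairwise: dict[str, pd.DataFrame]       # region -> DEG table (28 contrasts)
    low_average: dict[str, pd.DataFrame]    # region -> DEG table (2 contrasts)
    consensus: ConsensusResult
    filter_report: object = None
    models: dict[str, ModeratedDE] = field(default_factory=dict)

    def pairwise_long(self) -> pd.DataFrame:
        return pd.concat(self.pairwise.values(), ignore_index=True)


def run_region_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    region: str,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    high_preference: tuple[str, str] = ("B6", "PWK"),
    with_low_average: bool = True,
    treat: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None, ModeratedDE]:
    """Fit one region and return (pairwise DEG table, Low_Average DEG
    table, fitted model).  Each table is its own global-FDR family."""
    mask = samples["region"] == region
    sub_samples = samples.loc[mask]
    sub_counts = counts[sub_samples.index]
    model = ModeratedDE(fdr_threshold=fdr_threshold, lfc_threshold=lfc_threshold)
    model.fit(sub_counts, sub_samples, norm=tmm_normalize(sub_counts))

    strains = list(dict.fromkeys(sub_samples["strain"]))
    pw = model.deg_table(pairwise_contrasts(strains), region=region, treat=treat)
    la = None
    if with_low_average and all(h in strains for h in high_preference):
        la = model.deg_table(
            low_average_contrasts(strains, high_preference), region=region,
            treat=treat,
        )
    return pw, la, model


def run_study(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    high_preference: tuple[str, str] = ("B6", "PWK"),
    apply_filters: bool = True,
    treat: bool = True,
    keep_models: bool = False,
) -> StudyResult:
    """Run the full multi-region pipeline and assemble consensus sets."""
    report = None
    if apply_filters:
        counts, report = filter_genes(counts, genes)

    regions = list(dict.fromkeys(samples["region"]))
    strains = list(dict.fromkeys(samples["strain"]))
    hp_a, hp_b = high_preference
    have_hp = (
        all(h in strains for h in high_preference)
        and any(s not in high_preference for s in strains)
    )

    pairwise: dict[str, pd.DataFrame] = {}
    low_avg: dict[str, pd.DataFrame] = {}
    models: dict[str, ModeratedDE] = {}
    for region in regions:
        pw, la, model = run_region_de(
            counts, samples, region,
            fdr_threshold=fdr_threshold, lfc_threshold=lfc_threshold,
            high_preference=high_preference, with_low_average=have_hp,
        )
        pairwise[region] = pw
        if la is not None:
            low_avg[region] = la
        if keep_models:
            models[region] = model

    cons = ConsensusResult()
    for region in regions:
        for strain in strains:
            cons.unique[(strain, region)] = unique_degs(
                pairwise[region], strain, region, strains=strains
            )
        if have_hp:
            cons.signature[(hp_a, region)] = signature_genes(
                pairwise[region], hp_a, hp_b, region, strains=strains
            )
            cons.signature[(hp_b, region)] = signature_genes(
                pairwise[region], hp_b, hp_a, region, strains=strains
            )
            if region in low_avg:
                for hp in high_preference:
                    cons.low_average[(hp, region)] = low_average_degs(
                        low_avg[region], hp, region
                    )

    if have_hp and len(regions) >= 2:
        for hp in high_preference:
            sig_sets = {r: cons.signature[(hp, r)] for r in regions}
            common, venn = intersect_across_regions(sig_sets)
            cons.cross_region[f"signature_{hp}"] = common
            cons.venn[f"signature_{hp}"] = venn
            if low_avg:
                la_sets = {r: cons.low_average[(hp, r)] for r in regions}
                common_la, venn_la = intersect_across_regions(la_sets)
                cons.cross_region[f"low_average_{hp}"] = common_la
                cons.venn[f"low_average_{hp}"] = venn_la

        # strict: both strains' signature genes, same direction, all regions
        per_region_sig_a = {r: cons.signature[(hp_a, r)] for r in regions}
        per_region_sig_b = {r: cons.signature[(hp_b, r)] for r in regions}
        _, strict_common = high_preference_overlap(per_region_sig_a, per_region_sig_b)
        strict_common.label = "strict_common"
        cons.cross_region["strict_common"] = strict_common

        if low_avg:
            la_a = {r: cons.low_average[(hp_a, r)] for r in regions}
            la_b = {r: cons.low_average[(hp_b, r)] for r in regions}
            _, relaxed_common = high_preference_overlap(la_a, la_b)
            relaxed_common.label = "relaxed_common"
            cons.cross_region["relaxed_common"] = relaxed_common

    return StudyResult(
        pairwise=pairwise, low_average=low_avg, consensus=cons,
        filter_report=report, models=models,
    )


def strict_in_relaxed_percentage(result: StudyResult) -> float:
    """Percentage of the strict cross-region common genes (signature
    criterion, both high-preference strains, all regions) that are also
    in the relaxed Low_Average cross-region common set."""
    strict = result.consensus.cross_region.get("strict_common")
    relaxed = result.consensus.cross_region.get("relaxed_common")
    if strict is None or relaxed is None:
        raise ValueError("run_study must produce both strict and relaxed sets")
    if len(strict) == 0:
        return float("nan")
    hit = sum(
        1 for g, d in strict.members.items()
        if g in relaxed.members and relaxed.members[g] == d
    )
    return 100.0 * hit / len(strict)
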