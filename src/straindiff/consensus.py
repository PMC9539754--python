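"""Consensus gene-set logic over families of pairwise strain contrasts.

Definitions (all direction-aware; direction is the sign of log2FC in the
contrast oriented strain-minus-comparator):

* **unique DEGs** of strain S in a region: genes DE (global FDR below
  threshold) between S and *each* of the other 7 strains, with the same
  direction in all 7 comparisons.
* **signature genes** of a high-preference strain (B6 or PWK): as unique
  DEGs, but the other high-preference strain's contrast is ignored
  entirely — so a gene shared by both high drinkers can still qualify.
* **Low_Average DEGs** (relaxed criterion): genes DE in the single
  contrast of the strain against the mean of the six low-preference
  strains, with no fold-change floor.
* **cross-region common sets**: genes present in every region's set with
  the same direction everywhere; Venn cells are reported per direction.

All operations are pure functions of DEG tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd


@dataclass
class DirectionalGeneSet:
    """A labelled gene -> direction ('up'/'down') mapping."""

    label: str
    members: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def genes(self, direction: str | None = None) -> set[str]:
        if direction is None:
            return set(self.members)
        return {g for g, d in self.members.items() if d == direction}

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.members.items()), columns=["gene", "direction"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, label: str | None = None) -> "DirectionalGeneSet":
        df = pd.read_csv(path, sep="\t")
        return cls(label or Path(path).stem,
                   dict(zip(df["gene"], df["direction"])))


def _oriented_calls(
    deg_table: pd.DataFrame, strain: str, others: list[str], region: str | None,
) -> pd.DataFrame:
    """Wide per-gene frame of (is_deg, oriented sign) vs each comparator.

    The stored contrast may be named either ``S_vs_O`` or ``O_vs_S``;
    orientation is normalised to strain-minus-other by flipping the sign
    of log2FC when needed.
    """
    tab = deg_table
    if region is not None and "region" in tab.columns:
        tab = tab[tab["region"] == region]
    pieces = {}
    for other in others:
        fwd = tab[tab["contrast"] == f"{strain}_vs_{other}"]
        if len(fwd):
            sub = fwd.set_index("gene")
            sign = sub["log2FC"]
        else:
            rev = tab[tab["contrast"] == f"{other}_vs_{strain}"]
            if not len(rev):
                raise KeyError(
                    f"missing contrast between {strain!r} and {other!r}"
                    + (f" in region {region!r}" if region else "")
                )
            sub = rev.set_index("gene")
            sign = -sub["log2FC"]
        pieces[other] = pd.DataFrame({"is_deg": sub["is_deg"], "sign": sign})
    return pd.concat(pieces, axis=1)


def _consistent_members(wide: pd.DataFrame) -> dict[str, str]:
    """Genes DE vs every comparator with a single, nonzero direction."""
    is_deg = wide.xs("is_deg", axis=1, level=1)
    sign = wide.xs("sign", axis=1, level=1)
    all_deg = is_deg.fillna(False).all(axis=1)
    all_up = (sign > 0).all(axis=1)
    all_down = (sign < 0).all(axis=1)
    members = {}
    for gene in wide.index[all_deg & (all_up | all_down)]:
        members[gene] = "up" if all_up.loc[gene] else "down"
    return members


def unique_degs(
    deg_table: pd.DataFrame, strain: str, region: str | None = None,
    strains: list[str] | None = None,
) -> DirectionalGeneSet:
    """Genes DE in the same direction between ``strain`` and every other
    strain in the region (all 7 contrasts for an 8-strain panel)."""
    if strains is None:
        strains = _strains_from_contrasts(deg_table)
    others = [s for s in strains if s != strain]
    wide = _oriented_calls(deg_table, strain, others, region)
    return DirectionalGeneSet(
        f"unique|{strain}|{region or 'all'}", _consistent_members(wide)
    )


def signature_genes(
    deg_table: pd.DataFrame, strain: str, excluded: str,
    region: str | None = None, strains: list[str] | None = None,
) -> DirectionalGeneSet:
    """Unique-DEG logic with the partner high-preference strain's
    contrast ignored entirely (6 contrasts for an 8-strain panel)."""
    if excluded == strain:
        raise ValueError("excluded strain must differ from the target strain")
    if strains is None:
        strains = _strains_from_contrasts(deg_table)
    others = [s for s in strains if s not in (strain, excluded)]
    wide = _oriented_calls(deg_table, strain, others, region)
    return DirectionalGeneSet(
        f"signature|{strain}|excl-{excluded}|{region or 'all'}",
        _consistent_members(wide),
    )


def low_average_degs(
    deg_table: pd.DataFrame, strain: str, region: str | None = None,
    contrast_suffix: str = "LowAverage",
) -> DirectionalGeneSet:
    """DE calls for the strain-vs-Low_Average contrast (FDR only, no
    fold-change floor — the relaxed criterion)."""
    tab = deg_table
    if region is not None and "region" in tab.columns:
        tab = tab[tab["region"] == region]
    name = f"{strain}_vs_{contrast_suffix}"
    sub = tab[tab["contrast"] == name]
    if not len(sub):
        raise KeyError(f"missing contrast {name!r}" +
                       (f" in region {region!r}" if region else ""))
    hits = sub[sub["is_deg"] & (sub["log2FC"] != 0)]
    members = {
        g: ("up" if fc > 0 else "down")
        for g, fc in zip(hits["gene"], hits["log2FC"])
    }
    return DirectionalGeneSet(f"low_average|{strain}|{region or 'all'}", members)


def _strains_from_contrasts(deg_table: pd.DataFrame) -> list[str]:
    seen: list[str] = []
    for name in deg_table["contrast"].unique():
        if "_vs_" not in name:
            continue
        a, b = name.split("_vs_", 1)
        for s in (a, b):
            if s not in seen and s != "LowAverage":
                seen.append(s)
    return seen


# ---------------------------------------------------------------------------
# intersections
# ---------------------------------------------------------------------------

def venn_counts(
    sets: dict[str, DirectionalGeneSet], by_direction: bool = True,
) -> dict[str, dict[str, int] | int]:
    """Exclusive Venn cell counts over k labelled sets (all 2^k - 1 cells).

    With ``by_direction`` (the default for directional sets), the up and
    down sub-vennns are computed independently: a gene up in two regions
    and down in the third lands in the two-region cell of the up-venn
    and the singleton cell of the down-venn.  Cell keys are
    '&'-joined sorted labels.
    """
    labels = sorted(sets)
    out: dict[str, dict[str, int] | int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            key = "&".join(combo)
            if by_direction:
                cell = {}
                for d in ("up", "down"):
                    inside = set.intersection(*[sets[l].genes(d) for l in combo])
                    outside = set.union(
                        *[sets[l].genes(d) for l in labels if l not in combo],
                        set(),
                    )
                    cell[d] = len(inside - outside)
                out[key] = cell
            else:
                inside = set.intersection(*[sets[l].genes() for l in combo])
                outside = set.union(
                    *[sets[l].genes() for l in labels if l not in combo], set()
                )
                out[key] = len(inside - outside)
    return out


def intersect_across_regions(
    region_sets: dict[str, DirectionalGeneSet],
    require_direction: bool = True,
) -> tuple[DirectionalGeneSet, dict]:
    """Common set across regions plus full Venn cell counts.

    The common set holds genes present in *every* region's set; with
    ``require_direction`` the direction must agree in all regions
    (the default, matching the split up/down common counts reported for
    cross-region signatures).
    """
    if len(region_sets) < 2:
        raise ValueError("need at least two region sets to intersect")
    labels = list(region_sets)
    common_genes = set.intersection(*[region_sets[l].genes() for l in labels])
    members = {}
    for g in common_genes:
        dirs = {region_sets[l].members[g] for l in labels}
        if require_direction and len(dirs) != 1:
            continue
        members[g] = dirs.pop() if len(dirs) == 1 else "mixed"
    label = "common|" + "&".join(sorted(labels))
    return DirectionalGeneSet(label, members), venn_counts(region_sets)


def high_preference_overlap(
    first_sets: dict[str, DirectionalGeneSet],
    second_sets: dict[str, DirectionalGeneSet],
) -> tuple[dict[str, DirectionalGeneSet], DirectionalGeneSet]:
    """Same-direction overlap of two strains' per-region sets.

    Returns the per-region overlap sets and the all-region common set
    (genes shared by both strains in every region, same direction
    throughout).
    """
    regions = sorted(set(first_sets) & set(second_sets))
    if not regions:
        raise ValueError("no shared regions between the two strains' sets")
    per_region: dict[str, DirectionalGeneSet] = {}
    for r in regions:
        a, b = first_sets[r], second_sets[r]
        members = {
            g: a.members[g]
            for g in a.genes() & b.genes()
            if a.members[g] == b.members[g]
        }
        per_region[r] = DirectionalGeneSet(f"overlap|{r}", members)
    if len(per_region) >= 2:
        common, _ = intersect_across_regions(per_region)
    else:
        only = next(iter(per_region.values()))
        common = DirectionalGeneSet("common|" + regions[0], dict(only.members))
    return per_region, common


@dataclass
class ConsensusResult:
    """Bundle of consensus sets for one analysis run."""

    unique: dict[tuple[str, str], DirectionalGeneSet] = field(default_factory=dict)
    signature: dict[tuple[str, str], DirectionalGeneSet] = field(default_factory=dict)
    low_average: dict[tuple[str, str], DirectionalGeneSet] = field(default_factory=dict)
    cross_region: dict[str, DirectionalGeneSet] = field(default_factory=dict)
    venn: dict[str, dict] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for coll, prefix in [(self.unique, "unique"), (self.signature, "signature"),
                             (self.low_average, "low_average")]:
            for (strain, region), s in coll.items():
                s.write(out / f"{prefix}_{strain}_{region}.tsv")
        for name, s in self.cross_region.items():
            s.write(out / f"common_{name}.tsv")
        (out / "venn_counts.json").write_text(json.dumps(self.venn, indent=1))
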