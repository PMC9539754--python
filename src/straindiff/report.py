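"""Summary encodings and export: pairwise DEG circle grids, Venn counts,
over-representation analysis, and manifest-stamped table export.

The circle-grid figure encodes, for every ordered strain pair in a
region: circle size ∝ total DEGs (normalized to the grid maximum),
red/blue split = up/down DEG ratio (oriented row-strain minus
column-strain), and opacity = quartile bin of the hDEG count across the
grid (upper quartile brightest).

The enrichment routine is plain over-representation: a one-sided
hypergeometric (Fisher) test of each category's overlap with a query
set inside a declared universe, BH-adjusted across categories, with
GMT-style category files supported.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from scipy import stats

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .de import global_fdr  # noqa: E402


# ---------------------------------------------------------------------------
# pairwise summary + circle grid
# ---------------------------------------------------------------------------

def build_pairwise_summary(
    deg_table: pd.DataFrame, region: str | None = None,
    strains: list[str] | None = None,
) -> pd.DataFrame:
    """Per ordered strain pair: total/up/down DEG and hDEG counts.

    The (i, j) and (j, i) rows have equal totals with up and down
    swapped, since direction is defined by the oriented contrast.
    """
    tab = deg_table
    if region is not None and "region" in tab.columns:
        tab = tab[tab["region"] == region]
    if strains is None:
        from .consensus import _strains_from_contrasts
        strains = _strains_from_contrasts(tab)
    hdeg_col = "is_hdeg" if "is_hdeg" in tab.columns else "is_hdeg_simple"
    rows = []
    for a in strains:
        for b in strains:
            if a == b:
                continue
            sub = tab[tab["contrast"] == f"{a}_vs_{b}"]
            flip = False
            if not len(sub):
                sub = tab[tab["contrast"] == f"{b}_vs_{a}"]
                flip = True
            if not len(sub):
                raise KeyError(f"missing contrast between {a!r} and {b!r}")
            deg = sub[sub["is_deg"]]
            n_up = int((deg["log2FC"] > 0).sum())
            n_down = int((deg["log2FC"] < 0).sum())
            if flip:
                n_up, n_down = n_down, n_up
            rows.append({
                "strain_a": a, "strain_b": b, "region": region or "all",
                "n_deg_total": len(deg), "n_deg_up": n_up, "n_deg_down": n_down,
                "n_hdeg": int(sub[hdeg_col].sum()),
            })
    return pd.DataFrame(rows)


def _quartile_bins(values: np.ndarray) -> np.ndarray:
    """Quartile bin 1..4 per value, inclusive upper boundaries so ties
    share the higher bin."""
    qs = np.quantile(values, [0.25, 0.5, 0.75])
    return np.searchsorted(qs, values, side="left") + 1


@dataclass
class CircleGridSpec:
    cells: pd.DataFrame  # strain_a, strain_b, radius, up_fraction, opacity_bin
    strains: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "strains": self.strains,
            "cells": self.cells.to_dict("records"),
        }, indent=1))


_OPACITY = {1: 0.25, 2: 0.5, 3: 0.75, 4: 1.0}


def circle_grid_encoding(
    summary: pd.DataFrame,
    out_path: str | Path | None = None,
    up_color: str = "#d62728",
    down_color: str = "#1f77b4",
) -> CircleGridSpec:
    """Derive the circle-grid spec (and optionally render it).

    Radius = n_deg_total / grid max (cells with the maximum get 1.0);
    color split = up:down ratio; opacity = hDEG-count quartile over all
    grid cells, top quartile brightest.
    """
    if not len(summary):
        raise ValueError("empty summary")
    cells = summary.copy()
    max_total = cells["n_deg_total"].max()
    cells["radius"] = (
        cells["n_deg_total"] / max_total if max_total > 0
        else 0.05  # all-zero grid: sentinel minimal circles
    )
    with np.errstate(invalid="ignore"):
        cells["up_fraction"] = np.where(
            cells["n_deg_total"] > 0,
            cells["n_deg_up"] / cells["n_deg_total"].clip(lower=1), 0.5,
        )
    cells["opacity_bin"] = _quartile_bins(cells["n_hdeg"].to_numpy())
    strains = list(dict.fromkeys(summary["strain_a"]))
    spec = CircleGridSpec(cells=cells, strains=strains)
    if out_path is not None:
        _render_circle_grid(spec, out_path, up_color, down_color)
    return spec


def _render_circle_grid(spec: CircleGridSpec, out_path: str | Path,
                        up_color: str, down_color: str) -> None:
    strains = spec.strains
    n = len(strains)
    fig, ax = plt.subplots(figsize=(1.1 * n, 1.1 * n))
    pos = {s: i for i, s in enumerate(strains)}
    for _, cell in spec.cells.iterrows():
        i, j = pos[cell["strain_a"]], pos[cell["strain_b"]]
        x, y = j, n - 1 - i
        r = 0.45 * max(cell["radius"], 0.05)
        alpha = _OPACITY[int(cell["opacity_bin"])]
        frac_up = cell["up_fraction"]
        theta_split = 360.0 * frac_up
        ax.add_patch(matplotlib.patches.Wedge(
            (x, y), r, 90 - theta_split, 90, color=up_color, alpha=alpha))
        ax.add_patch(matplotlib.patches.Wedge(
            (x, y), r, 90, 90 - theta_split + 360, color=down_color, alpha=alpha))
    ax.set_xticks(range(n), strains, rotation=45)
    ax.set_yticks(range(n), strains[::-1])
    ax.set_xlim(-0.6, n - 0.4)
    ax.set_ylim(-0.6, n - 0.4)
    ax.set_aspect("equal")
    ax.set_title("Pairwise DEGs: size=total, color=up/down, opacity=hDEG quartile")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path)
    if out_path.suffix != ".svg":
        fig.savefig(out_path.with_suffix(".svg"))
    plt.close(fig)


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora_enrichment(
    query: set[str],
    universe: set[str],
    categories: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per category.

    p = P(overlap >= observed) for drawing |query| genes from a universe
    containing the category; BH FDR across categories.  Categories are
    clipped to the universe; the query must be contained in it.
    """
    if not query <= universe:
        raise ValueError("query gene set must be contained in the universe")
    m = len(universe)
    n_query = len(query)
    rows = []
    for name, genes in categories.items():
        cat = genes & universe
        k = len(query & cat)
        p = float(stats.hypergeom.sf(k - 1, m, len(cat), n_query)) if cat else 1.0
        rows.append({
            "category": name, "overlap": k, "category_size": len(cat),
            "universe_size": m, "query_size": n_query, "p": min(p, 1.0),
        })
    out = pd.DataFrame(rows)
    out["fdr"] = global_fdr(out["p"]) if len(out) else []
    return out.sort_values("p").reset_index(drop=True)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    cats = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, _desc, *genes = line.rstrip("\n").split("\t")
        cats[name] = set(genes)
    return cats


def write_gmt(categories: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in categories.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_run(
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame],
    manifest: dict | None = None,
    input_files: list[str | Path] | None = None,
) -> Path:
    """Write tab-delimited tables plus a JSON manifest.

    The manifest records the caller's parameters, package version and
    sha256 digests of declared input files, so a rerun can be checked
    for byte-identity on deterministic stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = p.name
    from . import __version__
    payload = {
        "package_version": __version__,
        "tables": written,
        "inputs": {
            str(p): _digest(Path(p)) for p in (input_files or [])
        },
        **(manifest or {}),
    }
    (out / "manifest.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return out
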