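"""Synthetic bulk RNA-seq count generator for multi-strain brain designs.

Emulates a Collaborative Cross founder-strain study: 8 inbred strains
(three of them wild-derived), 3 brain regions, both sexes, 3 replicates
per cell, samples multiplexed in batches balanced for strain, sex and
region.  Counts are negative-binomial with a mean–dispersion
parameterisation (variance = mu + phi * mu^2).  Ground truth about every
planted effect is returned alongside the counts so downstream recovery
can be scored exactly.

Planted architecture
--------------------
* *strain-unique* genes: a log2 effect applied to a single strain,
  across all regions and both sexes (region-restricted planting is a
  config option).
* *shared signature* genes: the same-direction log2 effect applied to
  the two designated high-preference strains (B6 and PWK by default).
* *background divergence*: optional per-strain random log2 offsets on a
  fraction of genes, inflated for wild-derived strains, so that the
  wild strains dominate pairwise fold-change distances the way they do
  in real founder panels.

Everything else (region, sex, batch offsets) is gene-specific Gaussian
noise on the log2 scale and carries no strain information.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_STRAINS = ("AJ", "S129", "B6", "CAST", "NOD", "NZO", "PWK", "WSB")
DEFAULT_REGIONS = ("CeA", "NAcc", "PrL")
DEFAULT_SEXES = ("F", "M")
WILD_DERIVED = frozenset({"CAST", "PWK", "WSB"})
HIGH_PREFERENCE = ("B6", "PWK")

#: sentinel used in the gene table for features without a chromosome
NON_CHROMOSOMAL = "NA"


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce a desk-scale version of the study design:
    8 strains x 3 regions x 2 sexes x 3 replicates = 144 samples in
    3 balanced batches, ~5,000 expressed genes and ~500k counts per
    sample (the full-depth profile simply widens ``library_size_range``).
    """

    n_genes: int = 5000
    strains: tuple[str, ...] = DEFAULT_STRAINS
    regions: tuple[str, ...] = DEFAULT_REGIONS
    sexes: tuple[str, ...] = DEFAULT_SEXES
    replicates_per_cell: int = 3
    n_batches: int = 3
    #: mean and sd of the per-gene baseline log2 relative expression
    baseline_log2_mean: tuple[float, float] = (3.0, 2.0)
    #: central NB dispersion phi and the sd of log(phi) across genes
    dispersion: float = 0.1
    dispersion_log_sd: float = 0.3
    #: expected total counts per sample, sampled log-uniformly
    library_size_range: tuple[float, float] = (4e5, 6e5)
    frac_unique_per_strain: float = 0.005
    frac_shared_signature: float = 0.01
    effect_size_log2: float = 2.0
    high_preference_strains: tuple[str, ...] = HIGH_PREFERENCE
    #: background strain divergence (not recorded as planted memberships)
    frac_strain_background: float = 0.0
    strain_background_sd: float = 0.5
    wild_background_multiplier: float = 2.0
    batch_effect_sd: float = 0.1
    sex_effect_sd: float = 0.05
    region_effect_sd: float = 0.5
    #: restrict planted effects to these regions (None = all regions)
    planted_regions: tuple[str, ...] | None = None
    frac_non_chromosomal: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.replicates_per_cell <= 0 or self.n_batches <= 0:
            raise ValueError("replicates_per_cell and n_batches must be positive")
        fracs = [
            self.frac_unique_per_strain,
            self.frac_shared_signature,
            self.frac_strain_background,
            self.frac_non_chromosomal,
        ]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("planted fractions must lie in [0, 1]")
        planted = self.frac_unique_per_strain * len(self.strains) + self.frac_shared_signature
        if planted > 1:
            raise ValueError(
                f"planted fractions sum to {planted:.3f} > 1 "
                "(frac_unique_per_strain x n_strains + frac_shared_signature)"
            )
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain labels must be unique")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")

    @property
    def n_samples(self) -> int:
        return (
            self.replicates_per_cell * len(self.strains) * len(self.regions) * len(self.sexes)
        )

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth of the planted structure.

    ``effect_matrix`` holds the planted log2 effect per gene for every
    (strain, region) combination; ``unique_membership`` maps each strain
    to its planted gene -> direction dict, ``signature_membership`` is
    the shared same-direction set for the high-preference pair, and
    ``null_genes`` are genes with zero strain effect everywhere
    (background-divergent genes are in none of the sets).
    """

    effect_matrix: pd.DataFrame
    unique_membership: dict[str, dict[str, str]]
    signature_membership: dict[str, str]
    null_genes: list[str]
    background_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "unique_membership": self.unique_membership,
            "signature_membership": self.signature_membership,
            "null_genes": self.null_genes,
            "background_genes": self.background_genes,
            "effect_matrix": {
                "index_name": self.effect_matrix.index.name,
                "genes": list(self.effect_matrix.index),
                "columns": [list(c) for c in self.effect_matrix.columns],
                "values": self.effect_matrix.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        em = payload["effect_matrix"]
        effect = pd.DataFrame(
            np.asarray(em["values"], dtype=float),
            index=em["genes"],
            columns=pd.MultiIndex.from_tuples(
                [tuple(c) for c in em["columns"]], names=["strain", "region"]
            ),
        )
        effect.index.name = em.get("index_name")
        return cls(
            effect_matrix=effect,
            unique_membership=payload["unique_membership"],
            signature_membership=payload["signature_membership"],
            null_genes=payload["null_genes"],
            background_genes=payload.get("background_genes", []),
        )


def _sample_table(config: SimConfig) -> pd.DataFrame:
    """Enumerate the design and assign batches.

    Batches are assigned round-robin over replicate index within each
    strain x region x sex cell, so each batch is exactly balanced for
    strain, sex and region whenever ``replicates_per_cell`` is a
    multiple of ``n_batches`` (3 replicates over 3 batches in the study
    design: one replicate of every cell per batch).
    """
    rows = []
    i = 0
    for strain in config.strains:
        for region in config.regions:
            for sex in config.sexes:
                for rep in range(config.replicates_per_cell):
                    rows.append(
                        {
                            "sample_id": f"s{i:03d}_{strain}_{region}_{sex}{rep + 1}",
                            "strain": strain,
                            "region": region,
                            "sex": sex,
                            "batch": f"b{rep % config.n_batches + 1}",
                        }
                    )
                    i += 1
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def _gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    biotypes = rng.choice(
        ["protein_coding", "lincRNA", "processed_pseudogene"],
        size=n,
        p=[0.9, 0.06, 0.04],
    )
    chrom_pool = [str(c) for c in range(1, 20)] + ["X"]
    chroms = rng.choice(chrom_pool, size=n).astype(object)
    n_nc = int(round(config.frac_non_chromosomal * n))
    if n_nc:
        nc_idx = rng.choice(n, size=n_nc, replace=False)
        chroms[nc_idx] = NON_CHROMOSOMAL
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [f"Sym{i:05d}" for i in range(n)],
            "biotype": biotypes,
            "chromosome": chroms,
        }
    ).set_index("gene_id", drop=False)


def _plant_effects(
    config: SimConfig,
    genes: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, dict[str, str]], dict[str, str], list[str]]:
    """Draw planted memberships and build the (strain, region) effect matrix."""
    strains, regions = list(config.strains), list(config.regions)
    cols = pd.MultiIndex.from_product([strains, regions], names=["strain", "region"])
    effect = pd.DataFrame(0.0, index=genes.index, columns=cols)

    plant_regions = list(config.planted_regions or regions)
    # non-chromosomal genes never carry planted effects: the preprocessing
    # filter removes them, which would make recovery metrics undefined
    eligible = genes.index[genes["chromosome"] != NON_CHROMOSOMAL].to_numpy()
    eligible = rng.permutation(eligible)

    n_unique = int(round(config.frac_unique_per_strain * config.n_genes))
    n_shared = int(round(config.frac_shared_signature * config.n_genes))
    hp = [s for s in config.high_preference_strains if s in strains]

    pos = 0
    unique_membership: dict[str, dict[str, str]] = {}
    for strain in strains:
        block = eligible[pos : pos + n_unique]
        pos += n_unique
        members: dict[str, str] = {}
        for g in block:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            members[g] = "up" if sign > 0 else "down"
            for r in plant_regions:
                effect.loc[g, (strain, r)] = sign * config.effect_size_log2
        unique_membership[strain] = members

    signature_membership: dict[str, str] = {}
    if len(hp) == 2 and n_shared:
        block = eligible[pos : pos + n_shared]
        pos += n_shared
        for g in block:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            signature_membership[g] = "up" if sign > 0 else "down"
            for strain in hp:
                for r in plant_regions:
                    effect.loc[g, (strain, r)] = sign * config.effect_size_log2

    background_genes: list[str] = []
    n_bg = int(round(config.frac_strain_background * config.n_genes))
    if n_bg:
        block = eligible[pos : pos + n_bg]
        background_genes = list(block)
        idx = effect.index.get_indexer(block)
        for strain in strains:
            sd = config.strain_background_sd
            if strain in WILD_DERIVED:
                sd *= config.wild_background_multiplier
            offs = rng.normal(0.0, sd, size=len(block))
            for r in regions:
                effect.iloc[idx, effect.columns.get_loc((strain, r))] += offs

    return effect, unique_membership, signature_membership, background_genes


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a count matrix under the configured design.

    Returns ``(counts, samples, genes, truth)`` where ``counts`` is a
    genes x samples integer DataFrame, ``samples``/``genes`` are the
    aligned metadata tables and ``truth`` records all planted structure.

    Expected log2 means are baseline + planted strain effect + gene-
    specific region/sex/batch offsets; relative expression is renormalised
    per sample and scaled to a log-uniformly drawn library size, then NB
    counts are drawn with variance mu + phi * mu^2.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_offsets, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    samples = _sample_table(config)
    genes = _gene_table(config, rng_struct)
    effect, uniq, sig, background = _plant_effects(config, genes, rng_struct)

    n_g, n_s = config.n_genes, config.n_samples
    mu0, sd0 = config.baseline_log2_mean
    baseline = rng_offsets.normal(mu0, sd0, size=n_g)
    phi = config.dispersion * np.exp(
        rng_offsets.normal(0.0, config.dispersion_log_sd, size=n_g)
        - config.dispersion_log_sd**2 / 2.0
    )

    def _level_offsets(levels: list[str], sd: float) -> dict[str, np.ndarray]:
        return {
            lv: (rng_offsets.normal(0.0, sd, size=n_g) if sd > 0 else np.zeros(n_g))
            for lv in levels
        }

    region_off = _level_offsets(list(config.regions), config.region_effect_sd)
    sex_off = _level_offsets(list(config.sexes), config.sex_effect_sd)
    batch_off = _level_offsets(
        sorted(samples["batch"].unique()), config.batch_effect_sd
    )

    lo, hi = config.library_size_range
    lib_sizes = np.exp(rng_offsets.uniform(np.log(lo), np.log(hi), size=n_s))

    counts = np.empty((n_g, n_s), dtype=np.int64)
    effect_np = effect.to_numpy()
    col_index = {c: i for i, c in enumerate(effect.columns)}
    r_shape = 1.0 / phi
    for j, (_, row) in enumerate(samples.iterrows()):
        log2_mu = (
            baseline
            + effect_np[:, col_index[(row["strain"], row["region"])]]
            + region_off[row["region"]]
            + sex_off[row["sex"]]
            + batch_off[row["batch"]]
        )
        rel = np.exp2(log2_mu)
        mu = rel / rel.sum() * lib_sizes[j]
        p = r_shape / (r_shape + mu)
        counts[:, j] = rng_counts.negative_binomial(r_shape, p)

    counts_df = pd.DataFrame(counts, index=genes.index, columns=samples.index)
    truth = SimTruth(
        effect_matrix=effect,
        unique_membership=uniq,
        signature_membership=sig,
        null_genes=list(genes.index[(effect_np == 0).all(axis=1)]),
        background_genes=background,
    )
    return counts_df, samples, genes, truth


def simulate_null(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate counts with zero strain effect for every gene.

    Identical to :func:`simulate_counts` with all planted fractions set
    to zero and the same seed; batch, sex and region offsets remain.
    """
    null_cfg = config.replace(
        frac_unique_per_strain=0.0,
        frac_shared_signature=0.0,
        frac_strain_background=0.0,
    )
    counts, samples, genes, _ = simulate_counts(null_cfg)
    return counts, samples, genes


def write_simulation(
    out_dir: str | Path,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genes: pd.DataFrame,
    truth: SimTruth | None = None,
) -> None:
    """Write counts and metadata as tab-delimited files (+ truth JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_json(out / "truth.json")
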