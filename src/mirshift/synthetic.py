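"""Seeded synthetic experiments with the structure the analysis assumes.

The generator emulates the four-pooled-library design: a miRNA catalog with
compartment detectability (615 tumour / 617 serum by default), treatment
effects partitioned into common / tumour-only / serum-only affected sets
(81/42/58), negative-binomial feature counts at configurable miRNA-read
depths, multinomial read-class compositions on the published fractions,
and stem-loop qPCR plates (targets, six candidate reference genes of which
two are built stable, and serial-dilution wells).

Randomness: one master seed; ``numpy.random.SeedSequence(seed).spawn``
children are consumed in the documented order catalog -> counts ->
compositions -> qPCR, so each stage is reproducible independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .quantify import CountMatrix

_STREAM_CATALOG, _STREAM_COUNTS, _STREAM_COMPOSITION, _STREAM_QPCR = range(4)

COMPARTMENT_OF_LIBRARY = {"L1": "tumour", "L2": "tumour", "L3": "serum", "L4": "serum"}
TREATED_LIBRARIES = ("L2", "L4")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic experiment.

    ``library_depths`` are expected miRNA-mapped reads per library (L1..L4);
    the published libraries carried 0.56-1.4 million such reads. Effects are
    fold multipliers applied to the treated library of the compartment:
    tumour boosts drawn from ``tumour_up_range``, serum drops from
    ``serum_down_range`` (stored as multiplier 1/drop).
    """

    seed: int = 0
    n_features: int = 720
    n_tumour_detectable: int = 615
    n_serum_detectable: int = 617
    n_tumour_up: int = 116
    n_tumour_down: int = 7
    n_serum_down: int = 137
    n_serum_up: int = 2
    n_common_affected: int = 81
    tumour_up_range: tuple[float, float] = (2.0, 10.0)
    tumour_down_range: tuple[float, float] = (2.0, 10.0)
    serum_down_range: tuple[float, float] = (2.0, 6.0)
    serum_up_range: tuple[float, float] = (2.0, 6.0)
    abundance_meanlog: float = 3.0
    abundance_sdlog: float = 2.0
    affected_min_abundance: float = 50.0
    length_range: tuple[int, int] = (19, 24)
    library_depths: tuple[int, int, int, int] = (965_017, 1_399_612, 835_664, 560_568)
    dispersion: float = 0.005
    composition_fractions: pd.DataFrame | None = None
    replicates: int = 1

    def resolved_fractions(self) -> pd.DataFrame:
        frac = (
            datasets.composition_fractions()
            if self.composition_fractions is None
            else self.composition_fractions
        )
        if not np.allclose(frac.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("composition fractions must sum to 1 per library")
        return frac

    def validate(self) -> None:
        if self.n_features < max(self.n_tumour_detectable, self.n_serum_detectable):
            raise ValueError("fewer features than detectable totals")
        n_tumour_aff = self.n_tumour_up + self.n_tumour_down
        n_serum_aff = self.n_serum_down + self.n_serum_up
        if n_tumour_aff > self.n_tumour_detectable:
            raise ValueError("tumour effect counts exceed tumour-detectable total")
        if n_serum_aff > self.n_serum_detectable:
            raise ValueError("serum effect counts exceed serum-detectable total")
        if self.n_common_affected > min(n_tumour_aff, n_serum_aff):
            raise ValueError("common affected count exceeds a compartment total")
        if any(d <= 0 for d in self.library_depths):
            raise ValueError("library depths must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for lo, hi in (
            self.tumour_up_range,
            self.tumour_down_range,
            self.serum_down_range,
            self.serum_up_range,
        ):
            if not (0 < lo <= hi):
                raise ValueError("effect ranges must be positive and ordered")
        self.resolved_fractions()

    def null(self) -> "SimulationConfig":
        """The matching no-effect configuration (all features neutral)."""
        return replace(
            self, n_tumour_up=0, n_tumour_down=0, n_serum_down=0, n_serum_up=0,
            n_common_affected=0,
        )


@dataclass
class MirnaCatalog:
    """Simulation ground truth: one row per feature.

    Columns: length_nt, base_abundance (expected RPKM in the control tumour
    library; serum control reuses the same scale), tumour_detectable,
    serum_detectable, tumour_effect, serum_effect, annotation.
    """

    entries: pd.DataFrame

    def validate(self) -> None:
        df = self.entries
        if df.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if not df["length_nt"].between(15, 30).all():
            raise ValueError("mature lengths outside 15-30 nt")
        if (df["base_abundance"] <= 0).any():
            raise ValueError("non-positive base abundance")
        if (df[["tumour_effect", "serum_effect"]] <= 0).to_numpy().any():
            raise ValueError("non-positive effect multiplier")
        neutral = df["annotation"] == "neutral"
        if not np.allclose(df.loc[neutral, ["tumour_effect", "serum_effect"]], 1.0):
            raise ValueError("neutral features must have unit effects")

    @property
    def n_tumour_detectable(self) -> int:
        return int(self.entries["tumour_detectable"].sum())

    @property
    def n_serum_detectable(self) -> int:
        return int(self.entries["serum_detectable"].sum())

    def affected(self, compartment: str) -> pd.Index:
        eff = self.entries[f"{compartment}_effect"]
        return self.entries.index[eff != 1.0]

    def to_tsv(self, path: str | Path) -> None:
        out = self.entries.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MirnaCatalog":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        df["tumour_detectable"] = df["tumour_detectable"].astype(bool)
        df["serum_detectable"] = df["serum_detectable"].astype(bool)
        return cls(df)


def generate_catalog(config: SimulationConfig) -> MirnaCatalog:
    """Draw a catalog satisfying the configured detectability and effect
    structure.

    Base abundances are log-normal on the RPKM scale. Affected features are
    drawn (without replacement) from features detectable in the relevant
    compartment(s) with base abundance >= ``affected_min_abundance``, since
    observed affected lists are conditioned on quantifiable abundance. The
    common/tumour-only/serum-only partition matches
    ``n_common_affected`` / remainder exactly.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(4)[_STREAM_CATALOG]
    )
    n = config.n_features
    ids = pd.Index([f"mmu-miR-s{i:04d}" for i in range(1, n + 1)], name="feature_id")
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, n)
    base = np.exp(rng.normal(config.abundance_meanlog, config.abundance_sdlog, n))

    tumour_det = np.zeros(n, dtype=bool)
    tumour_det[rng.choice(n, config.n_tumour_detectable, replace=False)] = True
    serum_det = np.zeros(n, dtype=bool)
    serum_det[rng.choice(n, config.n_serum_detectable, replace=False)] = True

    floor = base >= config.affected_min_abundance
    n_tumour_aff = config.n_tumour_up + config.n_tumour_down
    n_serum_aff = config.n_serum_down + config.n_serum_up
    n_common = config.n_common_affected
    pool_both = np.flatnonzero(tumour_det & serum_det & floor)
    if len(pool_both) < n_common:
        raise ValueError(
            "not enough abundant both-compartment features for the common affected set; "
            "increase n_features or lower affected_min_abundance"
        )
    common = rng.choice(pool_both, n_common, replace=False) if n_common else np.array([], int)
    used = set(common.tolist())
    pool_t = np.array(
        [i for i in np.flatnonzero(tumour_det & floor) if i not in used]
    )
    n_t_only = n_tumour_aff - n_common
    if len(pool_t) < n_t_only:
        raise ValueError("not enough abundant tumour-detectable features")
    t_only = rng.choice(pool_t, n_t_only, replace=False) if n_t_only else np.array([], int)
    used |= set(t_only.tolist())
    pool_s = np.array(
        [i for i in np.flatnonzero(serum_det & floor) if i not in used]
    )
    n_s_only = n_serum_aff - n_common
    if len(pool_s) < n_s_only:
        raise ValueError("not enough abundant serum-detectable features")
    s_only = rng.choice(pool_s, n_s_only, replace=False) if n_s_only else np.array([], int)

    tumour_aff = np.concatenate([common, t_only]).astype(int)
    serum_aff = np.concatenate([common, s_only]).astype(int)

    tumour_eff = np.ones(n)
    if n_tumour_aff:
        down_idx = rng.choice(tumour_aff, config.n_tumour_down, replace=False)
        down_mask = np.isin(tumour_aff, down_idx)
        eff = rng.uniform(*config.tumour_up_range, n_tumour_aff)
        eff[down_mask] = 1.0 / rng.uniform(*config.tumour_down_range, int(down_mask.sum()))
        tumour_eff[tumour_aff] = eff
    serum_eff = np.ones(n)
    if n_serum_aff:
        up_idx = rng.choice(serum_aff, config.n_serum_up, replace=False)
        up_mask = np.isin(serum_aff, up_idx)
        eff = 1.0 / rng.uniform(*config.serum_down_range, n_serum_aff)
        eff[up_mask] = rng.uniform(*config.serum_up_range, int(up_mask.sum()))
        serum_eff[serum_aff] = eff

    annotation = np.full(n, "neutral", dtype=object)
    any_aff = np.union1d(tumour_aff, serum_aff)
    if len(any_aff):
        annotation[any_aff] = rng.choice(["oncomir", "suppressor"], len(any_aff))

    cat = MirnaCatalog(
        pd.DataFrame(
            {
                "length_nt": lengths,
                "base_abundance": base,
                "tumour_detectable": tumour_det,
                "serum_detectable": serum_det,
                "tumour_effect": tumour_eff,
                "serum_effect": serum_eff,
                "annotation": annotation,
            },
            index=ids,
        )
    )
    cat.validate()
    return cat


@dataclass
class SyntheticExperiment:
    """A complete simulated four-library experiment plus its ground truth."""

    catalog: MirnaCatalog
    counts: CountMatrix
    compositions: pd.DataFrame
    truth: pd.DataFrame  # true_fold_tumour, true_fold_serum per feature

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.catalog.to_tsv(outdir / "catalog.tsv")
        self.counts.to_tsv(outdir / "counts.tsv")
        comp = self.compositions.copy()
        comp.index.name = "library"
        comp.to_csv(outdir / "compositions.tsv", sep="\t")
        truth = self.truth.copy()
        truth.index.name = "feature_id"
        truth.to_csv(outdir / "truth.tsv", sep="\t")


def simulate_counts(catalog: MirnaCatalog, config: SimulationConfig) -> SyntheticExperiment:
    """Draw feature counts and read-class compositions for L1..L4.

    ``library_depths`` are expected miRNA-mapped reads: within a
    compartment, count means are ``base x effect x length_kb x T / 1e6``
    with the normalization total ``T = 1e6 x depth / sum(base x length_kb
    over detectable features)``, so the control library's expected
    feature-read sum equals the configured depth and the expected RPKM of
    every feature (computed against T) equals base x effect exactly.
    Counts are negative-binomial with the configured overdispersion
    (Poisson at dispersion 0); features undetectable in a compartment get
    exactly zero counts there.
    """
    config.validate()
    catalog.validate()
    seqs = np.random.SeedSequence(config.seed).spawn(4)
    rng = np.random.default_rng(seqs[_STREAM_COUNTS])
    df = catalog.entries
    length_kb = df["length_nt"].to_numpy(float) / 1000.0
    base = df["base_abundance"].to_numpy(float)

    counts = {}
    totals = {}
    for lib, depth in zip(datasets.LIBRARIES, config.library_depths):
        comp = COMPARTMENT_OF_LIBRARY[lib]
        detectable = df[f"{comp}_detectable"].to_numpy(bool)
        effect = (
            df[f"{comp}_effect"].to_numpy(float)
            if lib in TREATED_LIBRARIES
            else np.ones(len(df))
        )
        rpkm_mass = float((base * length_kb)[detectable].sum())  # sum RPKM x kb
        norm_total = 1e6 * depth / rpkm_mass
        mu = base * effect * length_kb * norm_total / 1e6
        mu = np.where(detectable, mu, 0.0)
        if config.dispersion > 0:
            r = 1.0 / config.dispersion
            lam = np.where(mu > 0, rng.gamma(r, mu / r), 0.0)
            c = rng.poisson(lam)
        else:
            c = rng.poisson(mu)
        counts[lib] = c
        totals[lib] = norm_total

    count_df = pd.DataFrame(counts, index=df.index)
    totals = pd.Series(totals).round().astype(np.int64)
    cm = CountMatrix(count_df, df["length_nt"].copy(), totals)

    rng_comp = np.random.default_rng(seqs[_STREAM_COMPOSITION])
    frac = config.resolved_fractions()
    rows = {}
    for lib, depth in zip(datasets.LIBRARIES, config.library_depths):
        f = frac.loc[lib]
        total_reads = int(round(depth / f["miRNA"]))
        draw = rng_comp.multinomial(total_reads, f.to_numpy(float))
        row = dict(zip(f.index, draw))
        row["mapped"] = row["miRNA"] + row["mRNA"] + row["rRNA"] + row["filter"]
        row["total"] = total_reads
        del row["unmapped"]
        rows[lib] = row
    compositions = pd.DataFrame.from_dict(rows, orient="index")[
        ["miRNA", "mRNA", "rRNA", "filter", "mapped", "total"]
    ]

    truth = pd.DataFrame(
        {
            "true_fold_tumour": df["tumour_effect"],
            "true_fold_serum": df["serum_effect"],
        },
        index=df.index,
    )
    return SyntheticExperiment(catalog, cm, compositions, truth)


def simulate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Catalog + counts + compositions in one call."""
    return simulate_counts(generate_catalog(config), config)


# ---------------------------------------------------------------------------
# qPCR simulation


@dataclass
class QpcrSimConfig:
    """Noise specification for simulated stem-loop RT-qPCR plates.

    The Ct model is ``Ct = intercept - log(quantity) / log(1 + E) + noise``.
    Reference candidates: two built stable (per-sample wobble
    ``stable_sd`` log2 units) and the rest unstable (``unstable_sd``).
    Dilution wells cover factors 1, 1e-2, 1e-3, 1e-4.
    """

    seed: int = 0
    n_replicates: int = 6
    ct_sd: float = 0.2
    loading_sd: float = 0.5
    stable_sd: float = 0.05
    unstable_sd: float = 0.8
    intercept: float = 32.0
    reference_base: float = 200.0
    efficiencies: dict[str, float] = field(default_factory=dict)
    dilution_factors: tuple[float, ...] = (1.0, 1e-2, 1e-3, 1e-4)
    reference_genes: tuple[str, ...] = datasets.REFERENCE_GENE_CANDIDATES
    stable_pair: tuple[str, str] = datasets.STABLE_REFERENCE_PAIR

    def efficiency(self, gene: str) -> float:
        e = self.efficiencies.get(gene, 1.0)
        if not (0 < e <= 1.2):
            raise ValueError(f"amplification efficiency for {gene!r} outside (0, 1.2]")
        return e


def simulate_qpcr(
    truth: pd.Series | dict[str, float],
    config: QpcrSimConfig,
    base_abundance: pd.Series | dict[str, float] | None = None,
    compartment: str = "cells",
) -> pd.DataFrame:
    """Simulate a qPCR plate for target genes with known fold changes.

    ``truth`` maps target gene -> treated/control fold. Returns a tidy
    table (sample, condition, gene, dilution, replicate, Ct, compartment)
    including standard-curve wells for every gene at the configured
    dilution factors.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(4)[_STREAM_QPCR]
    )
    truth = pd.Series(truth, dtype=float)
    if base_abundance is None:
        base_abundance = pd.Series(100.0, index=truth.index)
    else:
        base_abundance = pd.Series(base_abundance, dtype=float).reindex(truth.index)

    def ct_of(quantity: float, gene: str) -> float:
        e = config.efficiency(gene)
        return config.intercept - math.log(quantity) / math.log(1.0 + e)

    records = []
    genes = list(truth.index) + list(config.reference_genes)
    for cond in ("control", "treated"):
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}-{rep}"
            loading = 2.0 ** rng.normal(0.0, config.loading_sd)
            for gene in genes:
                if gene in truth.index:
                    q = float(base_abundance[gene]) * (truth[gene] if cond == "treated" else 1.0)
                else:
                    sd = (
                        config.stable_sd
                        if gene in config.stable_pair
                        else config.unstable_sd
                    )
                    q = config.reference_base * 2.0 ** rng.normal(0.0, sd)
                q *= loading
                ct = ct_of(q, gene) + rng.normal(0.0, config.ct_sd)
                records.append(
                    {
                        "sample": sample,
                        "condition": cond,
                        "gene": gene,
                        "dilution": 1.0,
                        "replicate": rep,
                        "Ct": ct,
                        "compartment": compartment,
                    }
                )
    # standard curves on a pooled control sample
    for gene in genes:
        q0 = float(base_abundance.get(gene, config.reference_base))
        for dil in config.dilution_factors:
            ct = ct_of(q0 * dil, gene) + rng.normal(0.0, config.ct_sd)
            records.append(
                {
                    "sample": "standard",
                    "condition": "standard",
                    "gene": gene,
                    "dilution": dil,
                    "replicate": 1,
                    "Ct": ct,
                    "compartment": compartment,
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# A seeded scenario with the nine validated candidates


def validation_scenario(
    seed: int = 0,
    n_background: int = 191,
    depth: int = 100_000_000,
) -> tuple[SyntheticExperiment, SimulationConfig]:
    """Experiment in which the nine qPCR-validated miRNAs are abundant and
    strongly affected (tumour boost 8-10x, serum drop 3-6x, base 50-90
    RPKM), against a neutral-to-moderately-affected background.

    Built directly (not via :func:`generate_catalog`) so the nine carry
    their literature names and controlled effect sizes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    nine = list(datasets.VALIDATED_MIRNAS)
    ids = nine + [f"mmu-miR-b{i:04d}" for i in range(1, n_background + 1)]
    n = len(ids)
    base = np.empty(n)
    base[: len(nine)] = rng.uniform(50.0, 90.0, len(nine))
    base[len(nine):] = np.exp(rng.normal(3.0, 2.0, n_background))
    tumour_eff = np.ones(n)
    serum_eff = np.ones(n)
    tumour_eff[: len(nine)] = rng.uniform(8.0, 10.0, len(nine))
    serum_eff[: len(nine)] = 1.0 / rng.uniform(4.0, 6.0, len(nine))
    # a moderately affected, unannotated background slice
    bg_aff = len(nine) + rng.choice(n_background, 30, replace=False)
    tumour_eff[bg_aff] = rng.uniform(2.0, 10.0, len(bg_aff))
    serum_eff[bg_aff] = 1.0 / rng.uniform(2.0, 6.0, len(bg_aff))
    annotation = np.full(n, "neutral", dtype=object)
    affected = np.flatnonzero((tumour_eff != 1) | (serum_eff != 1))
    annotation[affected] = "suppressor"
    annotation[: len(nine)] = "oncomir"  # ground-truth labels are cosmetic here

    catalog = MirnaCatalog(
        pd.DataFrame(
            {
                "length_nt": rng.integers(20, 24, n),
                "base_abundance": base,
                "tumour_detectable": True,
                "serum_detectable": True,
                "tumour_effect": tumour_eff,
                "serum_effect": serum_eff,
                "annotation": annotation,
            },
            index=pd.Index(ids, name="feature_id"),
        )
    )
    config = SimulationConfig(
        seed=seed,
        n_features=n,
        n_tumour_detectable=n,
        n_serum_detectable=n,
        library_depths=(depth,) * 4,
        dispersion=0.005,
    )
    return simulate_counts(catalog, config), config
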