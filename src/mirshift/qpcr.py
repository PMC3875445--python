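"""Stem-loop RT-qPCR analysis: dilution-series efficiency, geNorm-style
reference stability, efficiency-corrected relative expression, and group
comparison by Student's t-test.

Quantities are handled on the log2 scale throughout and back-transformed
only for reporting. With all amplification efficiencies equal to 1 the
relative-expression machinery reduces exactly to 2^(-ddCt).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PERFECT_SLOPE = -math.log2(10.0)  # Ct per log10 dilution at efficiency 1


def stars(p_value: float) -> str:
    """Significance stars: *, **, *** at p < 0.05 / 0.01 / 0.001."""
    if not (0 <= p_value <= 1 or np.isnan(p_value)):
        raise ValueError("p-value outside [0, 1]")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def read_plate(path) -> pd.DataFrame:
    """Read a plate CSV (sample, condition, gene, dilution, replicate, Ct)."""
    df = pd.read_csv(path)
    required = {"sample", "condition", "gene", "Ct"}
    if not required <= set(df.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    if "dilution" not in df.columns:
        df["dilution"] = 1.0
    return df


@dataclass(frozen=True)
class DilutionFit:
    gene_id: str
    slope: float
    efficiency: float
    r_squared: float
    valid: bool


def fit_dilution_series(wells: pd.DataFrame, gene_id: str | None = None) -> DilutionFit:
    """Least-squares Ct vs log10(dilution); efficiency E = 10^(-1/slope) - 1.

    Needs at least 3 distinct dilution factors. A non-negative slope (more
    template giving later Ct) or an efficiency outside (0, 1.2] flags the
    fit invalid.
    """
    if gene_id is not None:
        wells = wells[wells["gene"] == gene_id]
    elif wells["gene"].nunique() == 1:
        gene_id = wells["gene"].iloc[0]
    else:
        raise ValueError("multiple genes in wells; pass gene_id")
    dil = wells["dilution"].to_numpy(dtype=float)
    if (dil <= 0).any() or (dil > 1).any():
        raise ValueError("dilution factors must be in (0, 1]")
    if len(np.unique(dil)) < 3:
        raise ValueError("need at least 3 distinct dilutions for a standard curve")
    fit = stats.linregress(np.log10(dil), wells["Ct"].to_numpy(dtype=float))
    slope = float(fit.slope)
    if slope >= 0:
        return DilutionFit(gene_id, slope, float("nan"), float(fit.rvalue) ** 2, False)
    eff = 10.0 ** (-1.0 / slope) - 1.0
    valid = 0.0 < eff <= 1.2
    return DilutionFit(gene_id, slope, eff, float(fit.rvalue) ** 2, valid)


def _log2_expression(ct: pd.Series, efficiency: float) -> pd.Series:
    """Relative log2 quantity from Ct: -Ct * log2(1 + E)."""
    if not (0 < efficiency <= 1.2):
        raise ValueError("amplification efficiency outside (0, 1.2]")
    return -ct * math.log2(1.0 + efficiency)


def reference_stability(
    ct_table: pd.DataFrame,
    efficiencies: dict[str, float] | None = None,
    iterative: bool = False,
) -> pd.DataFrame:
    """geNorm gene-stability measure M per candidate reference gene.

    ``ct_table`` is tidy (sample, gene, Ct) or wide (samples x genes). For
    gene j, M_j is the arithmetic mean over all other candidates k of the
    standard deviation across samples of the pairwise log2 expression
    ratio x_j - x_k. Returns genes ranked ascending in M; with
    ``iterative=True`` the classic stepwise exclusion is run and the rank
    reflects elimination order (last survivors first).
    """
    wide = _to_wide(ct_table)
    if wide.isna().any().any():
        raise ValueError("missing Ct values; impute or drop samples first")
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 candidate genes")
    if wide.shape[1] == 2:
        warnings.warn("only 2 candidate genes: M is pairwise-degenerate")
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    efficiencies = efficiencies or {}
    expr = pd.DataFrame(
        {
            g: _log2_expression(wide[g], efficiencies.get(g, 1.0))
            for g in wide.columns
        }
    )

    def m_values(cols: list[str]) -> pd.Series:
        out = {}
        for j in cols:
            sds = [
                float(np.std(expr[j] - expr[k], ddof=1)) for k in cols if k != j
            ]
            out[j] = float(np.mean(sds))
        return pd.Series(out, name="M")

    if not iterative:
        m = m_values(list(wide.columns)).sort_values(kind="stable")
        return pd.DataFrame({"M": m, "rank": np.arange(1, len(m) + 1)})

    remaining = list(wide.columns)
    eliminated: list[tuple[str, float]] = []
    while len(remaining) > 2:
        m = m_values(remaining)
        worst = m.idxmax()
        eliminated.append((worst, float(m[worst])))
        remaining.remove(worst)
    m_final = m_values(remaining)
    ordered = list(m_final.sort_values(kind="stable").items()) + eliminated[::-1]
    return pd.DataFrame(
        {"M": [v for _, v in ordered], "rank": np.arange(1, len(ordered) + 1)},
        index=[g for g, _ in ordered],
    )


def best_reference_pair(stability: pd.DataFrame) -> tuple[str, str]:
    """The two minimal-M candidates."""
    top = stability.sort_values(["rank"]).index[:2]
    return tuple(top)


def _to_wide(ct_table: pd.DataFrame) -> pd.DataFrame:
    if {"sample", "gene", "Ct"} <= set(ct_table.columns):
        df = ct_table
        if "dilution" in df.columns:
            df = df[df["dilution"] == 1.0]
        return df.pivot_table(index="sample", columns="gene", values="Ct", aggfunc="mean")
    return ct_table


def relative_expression(
    ct_table: pd.DataFrame,
    targets: list[str],
    references: list[str] | None = None,
    volumes: pd.Series | dict[str, float] | None = None,
    efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Treated/control expression ratio per target gene.

    Cell mode (``references``): each sample's target log2 quantity is
    normalized by the arithmetic mean of the reference genes' log2
    quantities (the geometric mean on the linear scale), with per-gene
    efficiency correction (1+E)^(-Ct). Serum mode (``volumes``): the
    linearized quantity is divided by the sample's serum volume instead.
    The group ratio is 2^(treated mean - control mean) of the normalized
    log2 values, with a two-tailed unpaired Student's t-test.
    """
    if (references is None) == (volumes is None):
        raise ValueError("pass exactly one of references or volumes")
    efficiencies = efficiencies or {}
    df = ct_table[ct_table["condition"].isin(["control", "treated"])].copy()
    if "dilution" in df.columns:
        df = df[df["dilution"] == 1.0]

    wide = df.pivot_table(index=["sample", "condition"], columns="gene",
                          values="Ct", aggfunc="mean")
    if references is not None:
        missing = [r for r in references if r not in wide.columns or wide[r].isna().any()]
        if missing:
            raise ValueError(f"reference gene(s) missing in some samples: {missing}")
        ref_log2 = pd.concat(
            [_log2_expression(wide[r], efficiencies.get(r, 1.0)) for r in references],
            axis=1,
        ).mean(axis=1)
    else:
        vols = pd.Series(volumes, dtype=float)
        samples = wide.index.get_level_values("sample")
        missing = [s for s in samples if s not in vols.index]
        if missing:
            raise ValueError(f"serum volume missing for sample(s): {missing}")
        if (vols <= 0).any():
            raise ValueError("serum volumes must be positive")
        ref_log2 = pd.Series(
            np.log2(vols.reindex(samples).to_numpy()), index=wide.index
        )

    records = []
    for gene in targets:
        if gene not in wide.columns:
            raise KeyError(f"target gene {gene!r} not in table")
        norm = _log2_expression(wide[gene], efficiencies.get(gene, 1.0)) - ref_log2
        ctrl = norm.xs("control", level="condition").dropna()
        trt = norm.xs("treated", level="condition").dropna()
        t, p = compare_groups(ctrl.to_numpy(), trt.to_numpy())
        log2_ratio = float(trt.mean() - ctrl.mean())
        records.append(
            {
                "gene": gene,
                "ratio": 2.0 ** log2_ratio,
                "log2_ratio": log2_ratio,
                "normalizer": "references" if references is not None else "serum volume",
                "t_statistic": t,
                "p_value": p,
                "stars": stars(p),
                "n_control": len(ctrl),
                "n_treated": len(trt),
            }
        )
    return pd.DataFrame.from_records(records).set_index("gene")


def compare_groups(control, treated, equal_var: bool = True) -> tuple[float, float]:
    """Two-tailed unpaired Student's t-test on log-scale expression.

    Returns (t statistic, p-value); Welch via ``equal_var=False``.
    Identical groups give t = 0, p = 1.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need at least 2 samples per group")
    t, p = stats.ttest_ind(treated, control, equal_var=equal_var)
    if np.isnan(t):  # zero variance in both groups, equal means
        return 0.0, 1.0
    return float(t), float(p)


def analyse_plate(
    ct_table: pd.DataFrame,
    targets: list[str],
    reference_candidates: list[str],
    volumes=None,
    n_references: int = 2,
) -> dict:
    """End-to-end plate analysis.

    Fits standard curves per gene, ranks reference candidates by M, picks
    the minimal-M pair (cell mode) or uses serum volumes, and reports
    per-target relative expression with significance. Returns a JSON-able
    summary dict.
    """
    curves = {}
    std = ct_table[ct_table["condition"] == "standard"]
    for gene in ct_table["gene"].unique():
        wells = std[std["gene"] == gene]
        if wells["dilution"].nunique() >= 3:
            fit = fit_dilution_series(wells)
            curves[gene] = fit
    efficiencies = {g: f.efficiency for g, f in curves.items() if f.valid}

    ref_table = ct_table[
        ct_table["gene"].isin(reference_candidates)
        & ct_table["condition"].isin(["control", "treated"])
    ]
    stability = reference_stability(ref_table, efficiencies)
    if volumes is None:
        refs = list(stability.index[:n_references])
        expr = relative_expression(ct_table, targets, references=refs,
                                   efficiencies=efficiencies)
    else:
        refs = []
        expr = relative_expression(ct_table, targets, volumes=volumes,
                                   efficiencies=efficiencies)
    return {
        "efficiencies": {
            g: {"efficiency": f.efficiency, "slope": f.slope, "r2": f.r_squared}
            for g, f in curves.items()
        },
        "stability": stability["M"].to_dict(),
        "references_used": refs,
        "expression": expr.reset_index().to_dict(orient="records"),
    }
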