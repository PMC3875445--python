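"""Treated-vs-control differential abundance between two pooled libraries.

The study design has one pooled library per condition and compartment, so
significance is assessed per feature from the pair (count, library depth)
under the test's multinomial sampling model:

* ``exact`` (default): central conditional exact test — given the feature's total
  reads, the control count is hypergeometric across the two depths
  (Fisher's framework); the two-sided p is twice the smaller tail,
  capped at 1.
* ``midp``: the exact test with the mid-p correction.
* ``lrt``: likelihood-ratio G-test on the same 2x2 table, chi-square
  with 1 df.

All variants are close to nominal size at informative per-feature counts
and conservative (never anti-conservative) at shallow ones.
Benjamini-Hochberg q-values are computed across features within a
compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix, compute_rpkm

LOW_EVIDENCE_MAX_COUNT = 10  # both-library counts below this -> flagged


def fold_changes(
    counts: CountMatrix,
    control_lib: str,
    treated_lib: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature RPKM fold change between two libraries.

    Fold change is reported as a ratio >= 1 with an explicit direction
    (up/down/unchanged as treated vs control). Features with a zero count
    on either side get ``pseudocount`` added to both raw counts before the
    RPKM ratio, so folds stay finite.
    """
    for lib in (control_lib, treated_lib):
        if lib not in counts.counts.columns:
            raise KeyError(f"library {lib!r} not in count matrix")
    rpkm = compute_rpkm(counts)
    c_ctrl = counts.counts[control_lib].to_numpy(dtype=float)
    c_trt = counts.counts[treated_lib].to_numpy(dtype=float)
    zero_side = (c_ctrl == 0) | (c_trt == 0)
    adj_ctrl = np.where(zero_side, c_ctrl + pseudocount, c_ctrl)
    adj_trt = np.where(zero_side, c_trt + pseudocount, c_trt)

    length_kb = counts.lengths_nt.to_numpy(dtype=float) / 1000.0
    tot = counts.library_total_reads
    r_ctrl = adj_ctrl / (length_kb * float(tot[control_lib]) / 1e6)
    r_trt = adj_trt / (length_kb * float(tot[treated_lib]) / 1e6)

    ratio = r_trt / r_ctrl
    direction = np.where(ratio > 1, "up", np.where(ratio < 1, "down", "unchanged"))
    fold = np.maximum(ratio, 1.0 / ratio)
    return pd.DataFrame(
        {
            "rpkm_control": rpkm[control_lib],
            "rpkm_treated": rpkm[treated_lib],
            "ratio": ratio,
            "fold_change": fold,
            "direction": direction,
            "low_evidence": (c_ctrl < LOW_EVIDENCE_MAX_COUNT)
            & (c_trt < LOW_EVIDENCE_MAX_COUNT),
        },
        index=counts.counts.index,
    )


def _g_test(c1, c2, d1, d2) -> np.ndarray:
    """Two-sided LRT p-values for equal relative abundance, vectorized."""
    c1 = c1.astype(float)
    c2 = c2.astype(float)
    n = c1 + c2
    with np.errstate(divide="ignore", invalid="ignore"):
        # expected counts under the pooled rate, per library
        e1 = n * d1 / (d1 + d2)
        e2 = n * d2 / (d1 + d2)
        g = 2.0 * (
            np.where(c1 > 0, c1 * np.log(c1 / e1), 0.0)
            + np.where(c2 > 0, c2 * np.log(c2 / e2), 0.0)
        )
        # remainder cells of the 2x2 table; negligible for depth >> count but
        # kept for exactness of the statistic
        r1, r2 = d1 - c1, d2 - c2
        er1 = (r1 + r2) * d1 / (d1 + d2)
        er2 = (r1 + r2) * d2 / (d1 + d2)
        g += 2.0 * (
            np.where(r1 > 0, r1 * np.log(r1 / er1), 0.0)
            + np.where(r2 > 0, r2 * np.log(r2 / er2), 0.0)
        )
    p = stats.chi2.sf(g, df=1)
    return np.where(n > 0, p, 1.0)


def _conditional_exact_p(c1: int, n: int, d1: float, d2: float, midp: bool) -> float:
    """Central two-sided exact p for one feature: twice the smaller tail.

    Conditional on the feature's total reads n, the control count follows
    Hypergeometric(M=d1+d2, K=d1, N=n); mid-p halves the point mass of
    the observed count in each tail.
    """
    if n == 0:
        return 1.0
    if n <= 1e-3 * (d1 + d2):
        # depths dwarf the feature total: the conditional hypergeometric is
        # binomial to O(n / (d1 + d2)) relative accuracy, and binom has an
        # O(1) cdf
        h = stats.binom(n, d1 / (d1 + d2))
    else:
        h = stats.hypergeom(int(d1 + d2), int(d1), n)
    point = h.pmf(c1)
    lower = h.cdf(c1)
    upper = h.sf(c1 - 1)
    if midp:
        lower -= 0.5 * point
        upper -= 0.5 * point
    return float(min(1.0, 2.0 * min(lower, upper)))


def significance_test(
    counts: CountMatrix,
    control_lib: str,
    treated_lib: str,
    alpha: float = 0.05,
    method: str = "exact",
) -> pd.DataFrame:
    """Per-feature p/q-values for equal relative abundance in two libraries.

    Returns columns ``p_value``, ``q_value`` (Benjamini-Hochberg) and
    ``significant`` (q <= alpha).
    """
    for lib in (control_lib, treated_lib):
        if lib not in counts.counts.columns:
            raise KeyError(f"library {lib!r} not in count matrix")
    d1 = float(counts.library_total_reads[control_lib])
    d2 = float(counts.library_total_reads[treated_lib])
    if d1 <= 0 or d2 <= 0:
        raise ValueError("zero-depth library")
    c1 = counts.counts[control_lib].to_numpy()
    c2 = counts.counts[treated_lib].to_numpy()

    if method == "lrt":
        p = _g_test(c1, c2, d1, d2)
    elif method in ("exact", "midp"):
        p = np.array(
            [
                _conditional_exact_p(int(a), int(a + b), d1, d2, method == "midp")
                for a, b in zip(c1, c2)
            ]
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.clip(p, 0.0, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"p_value": p, "q_value": q, "significant": q <= alpha},
        index=counts.counts.index,
    )


def differential_table(
    counts: CountMatrix,
    control_lib: str,
    treated_lib: str,
    compartment: str,
    alpha: float = 0.05,
    min_fold: float = 1.5,
    method: str = "exact",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Joined fold-change and significance table for one compartment.

    ``affected`` marks features that are significant at q <= alpha AND show
    a fold change of at least ``min_fold`` — the "reliable change" rule.
    """
    fc = fold_changes(counts, control_lib, treated_lib, pseudocount)
    sig = significance_test(counts, control_lib, treated_lib, alpha, method)
    out = fc.join(sig)
    out.insert(0, "compartment", compartment)
    out["affected"] = out["significant"] & (out["fold_change"] >= min_fold)
    return out


@dataclass(frozen=True)
class OverlapPartition:
    """Disjoint partition of affected features across the two compartments."""

    common: frozenset
    tumour_only: frozenset
    serum_only: frozenset

    @property
    def counts(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "tumour_only": len(self.tumour_only),
            "serum_only": len(self.serum_only),
        }

    def validate(self, n_tumour: int, n_serum: int) -> None:
        assert not (self.common & self.tumour_only)
        assert not (self.common & self.serum_only)
        assert not (self.tumour_only & self.serum_only)
        if len(self.common) + len(self.tumour_only) != n_tumour:
            raise ValueError("tumour partition does not sum to the tumour total")
        if len(self.common) + len(self.serum_only) != n_serum:
            raise ValueError("serum partition does not sum to the serum total")


def overlap_partition(tumour_significant, serum_significant) -> OverlapPartition:
    """Split affected features into common / tumour-only / serum-only sets."""
    t = frozenset(tumour_significant)
    s = frozenset(serum_significant)
    return OverlapPartition(common=t & s, tumour_only=t - s, serum_only=s - t)
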