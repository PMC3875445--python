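"""TS/TF prioritization of qPCR validation candidates.

The ranking statistic takes the most abundant and most affected species:
TS (total score) is the summed control-library abundance (RPKM in L1 plus
RPKM in L3), TF (total fold) is the summed compartment fold change
(L2/L1 boost plus L3/L4 drop), and candidates are ranked by TS/TF
ascending. Features with high TF and TS/TF in (0, 20] are selection
targets; the final cut keeps those with a literature oncomir /
tumour-suppressor annotation.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_TOP_N = 100
DEFAULT_TS_TF_MAX = 20.0
DEFAULT_MIN_TF = 4.0


def load_annotations(path: str | Path | None = None) -> pd.DataFrame:
    """Curated oncomir/suppressor list (feature_id, class, citation).

    Without a path, the packaged default list is used (the nine validated
    candidates plus the let-7 family).
    """
    if path is None:
        src = resources.files("mirshift.data").joinpath("oncomir_annotations.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "class"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    return df


def prioritize(
    rpkm: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    top_n: int = DEFAULT_TOP_N,
    ts_tf_max: float = DEFAULT_TS_TF_MAX,
    min_tf: float = DEFAULT_MIN_TF,
    top_pool: str = "L1",
    libraries: tuple[str, str, str, str] = ("L1", "L2", "L3", "L4"),
) -> pd.DataFrame:
    """Rank validation candidates by TS/TF, mirroring the published steps.

    1-2. Sort by control abundance (L1, then L3) descending, superposing
         the treated libraries.
    3.   Compute the tumour boost L2/L1 and the serum drop L3/L4.
    4.   Keep the ``top_n`` features by L1 abundance (``top_pool="union"``
         instead pools the top_n of L1 with the top_n of L2) and sort by
         tumour boost descending.
    5.   Reject features not present (zero abundance) in any of the four
         libraries.
    6-7. Compute TS, TF and TS/TF; sort TS/TF ascending (ties: TF
         descending, then feature id).
    8.   ``selected``  <=>  0 < TS/TF <= ts_tf_max  and  TF >= min_tf.
    9.   Annotate from the curated list.

    Returns the surviving features only, in final rank order.
    """
    l1, l2, l3, l4 = libraries
    for lib in libraries:
        if lib not in rpkm.columns:
            raise KeyError(f"library {lib!r} not in RPKM matrix")
    if annotations is None:
        annotations = load_annotations()

    tumour_view = rpkm[[l1, l2]].sort_values(l1, ascending=False)  # step 1
    rpkm.loc[tumour_view.index, [l3, l4]].sort_values(l3, ascending=False)  # step 2 view

    with np.errstate(divide="ignore", invalid="ignore"):
        fold_tumour = rpkm[l2] / rpkm[l1]
        fold_serum = rpkm[l3] / rpkm[l4]

    if top_pool == "L1":
        top = tumour_view.head(top_n).index
    elif top_pool == "union":
        top = tumour_view.head(top_n).index.union(
            rpkm[l2].sort_values(ascending=False).head(top_n).index
        )
    else:
        raise ValueError("top_pool must be 'L1' or 'union'")

    cand = rpkm.loc[top, list(libraries)].copy()
    cand["fold_tumour"] = fold_tumour[top]
    cand = cand.sort_values("fold_tumour", ascending=False)  # step 4
    present = (cand[list(libraries)] > 0).all(axis=1)  # step 5
    cand = cand[present]
    if cand.empty:
        warnings.warn("no features present in all four libraries after the top-N cut")

    cand["fold_serum"] = fold_serum[cand.index]
    cand = cand.rename(columns={l1: "score_L1", l3: "score_L3"})
    cand["TS"] = cand["score_L1"] + cand["score_L3"]
    cand["TF"] = cand["fold_tumour"] + cand["fold_serum"]
    cand["ts_over_tf"] = cand["TS"] / cand["TF"]

    cand = cand.reset_index().rename(columns={cand.index.name or "index": "feature_id"})
    cand = cand.sort_values(
        ["ts_over_tf", "TF", "feature_id"], ascending=[True, False, True]
    ).set_index("feature_id")

    cand["selected"] = (
        (cand["ts_over_tf"] > 0)
        & (cand["ts_over_tf"] <= ts_tf_max)
        & (cand["TF"] >= min_tf)
    )
    ann = annotations.set_index("feature_id")["class"]
    cand["annotation"] = ann.reindex(cand.index).fillna("unknown")
    cand["rank"] = np.arange(1, len(cand) + 1)
    cols = [
        "rank", "score_L1", "score_L3", "fold_tumour", "fold_serum",
        "TS", "TF", "ts_over_tf", "selected", "annotation", l2, l4,
    ]
    return cand[cols]


def annotated_selection(candidates: pd.DataFrame) -> pd.DataFrame:
    """Candidates that are selected and carry a literature annotation."""
    return candidates[
        candidates["selected"] & candidates["annotation"].isin(["oncomir", "suppressor"])
    ]
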