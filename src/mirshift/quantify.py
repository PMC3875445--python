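"""RPKM quantification and library-composition summaries.

Abundance unit is RPKM: reads of a miRNA divided by (mature length in kb
times library total reads in millions). Composition percentages follow the
published table convention — percent of total library reads, rounded
half-up to one decimal.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_MATURE_LENGTH_NT = 22

COMPOSITION_CLASSES = ("miRNA", "mRNA", "rRNA", "filter", "mapped")


def round_half_up(values, decimals: int = 1):
    """Round half away from zero-free, half-up (2.65 -> 2.7), elementwise.

    numpy's default is banker's rounding; percentage cells in sequencing
    summary tables are conventionally rounded half-up.
    """
    q = decimal.Decimal(1).scaleb(-decimals)

    def _one(x: float) -> float:
        return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))

    if np.isscalar(values):
        return _one(values)
    arr = np.asarray(values, dtype=float)
    return np.vectorize(_one)(arr)


@dataclass
class CountMatrix:
    """Integer read counts for features (rows) across libraries (columns).

    ``library_total_reads`` is the per-library denominator of the RPKM
    formula — the total number of reads in the library.
    """

    counts: pd.DataFrame
    lengths_nt: pd.Series
    library_total_reads: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.lengths_nt = self.lengths_nt.reindex(self.counts.index)
        self.library_total_reads = self.library_total_reads.reindex(self.counts.columns)
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.lengths_nt.isna().any():
            missing = list(self.lengths_nt.index[self.lengths_nt.isna()])
            raise ValueError(f"missing lengths for features: {missing[:5]}")
        if (self.lengths_nt <= 0).any():
            bad = list(self.lengths_nt.index[self.lengths_nt <= 0])
            raise ValueError(f"non-positive length for feature(s) {bad[:5]}")
        if self.library_total_reads.isna().any() or (self.library_total_reads <= 0).any():
            bad = list(self.library_total_reads.index[~(self.library_total_reads > 0)])
            raise ValueError(f"non-positive total reads for library(ies) {bad}")
        too_big = self.counts.sum(axis=0) > self.library_total_reads
        if too_big.any():
            bad = list(too_big.index[too_big])
            raise ValueError(f"feature counts exceed library total for {bad}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    # -- round-trip TSV dialect: feature_id, length_nt, one column per library;
    #    totals stored in a leading comment line.
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        totals = "\t".join(f"{lib}={int(t)}" for lib, t in self.library_total_reads.items())
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# library_total_reads\t{totals}\n")
            out = self.counts.copy()
            out.insert(0, "length_nt", self.lengths_nt)
            out.index.name = "feature_id"
            out.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if not first.startswith("# library_total_reads"):
                raise ValueError(f"{path}: missing library_total_reads header line")
            totals = {}
            for tok in first.strip().split("\t")[1:]:
                lib, _, val = tok.partition("=")
                totals[lib] = int(val)
            df = pd.read_csv(fh, sep="\t", index_col="feature_id")
        lengths = df.pop("length_nt")
        return cls(df, lengths, pd.Series(totals))


def compute_rpkm(counts: CountMatrix) -> pd.DataFrame:
    """RPKM matrix: count / (length_kb x total_reads_millions).

    Zero counts map to exactly zero; the result keeps the count matrix's
    feature and library ordering.
    """
    counts.validate()
    length_kb = counts.lengths_nt.to_numpy(dtype=float) / 1000.0
    total_mln = counts.library_total_reads.to_numpy(dtype=float) / 1e6
    values = counts.counts.to_numpy(dtype=float) / (length_kb[:, None] * total_mln[None, :])
    return pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns)


@dataclass
class CompositionSummary:
    """Per-library read-class counts and percentages of total reads."""

    counts: pd.DataFrame        # libraries x classes, plus "total" column
    percentages: pd.DataFrame   # libraries x classes, one decimal, half-up
    decimals: int = 1

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        for cls_ in self.percentages.columns:
            out[f"{cls_}_pct"] = self.percentages[cls_]
        out.index.name = "library"
        out.to_csv(path, sep="\t")


def summarize_composition(
    class_counts: pd.DataFrame,
    totals: pd.Series | None = None,
    decimals: int = 1,
) -> CompositionSummary:
    """Percentages of total library reads per read class.

    ``class_counts`` holds one row per library with columns from
    ``COMPOSITION_CLASSES`` (a ``total`` column may be included instead of
    passing ``totals``). The mapped class must contain the four specific
    classes and be contained in the total.
    """
    df = class_counts.copy()
    if totals is None:
        if "total" not in df.columns:
            raise ValueError("totals not given and no 'total' column present")
        totals = df["total"]
    df = df[[c for c in df.columns if c != "total"]]
    totals = totals.reindex(df.index)
    if (totals <= 0).any():
        raise ValueError("library total must be positive")
    if (df.gt(totals, axis=0)).any().any():
        raise ValueError("class count exceeds library total")
    if "mapped" in df.columns:
        parts = [c for c in ("miRNA", "mRNA", "rRNA", "filter") if c in df.columns]
        if (df[parts].sum(axis=1) > df["mapped"] + 0.5).any():
            raise ValueError("specific classes exceed mapped reads")
    pct = df.div(totals, axis=0) * 100.0
    pct = pct.apply(lambda col: round_half_up(col, decimals))
    counts_out = df.copy()
    counts_out["total"] = totals
    return CompositionSummary(counts_out, pct, decimals)


def lengths_from_gff3(path: str | Path, id_attr: str = "Name") -> pd.Series:
    """Mature miRNA lengths from a miRBase-style GFF3.

    Reads ``miRNA`` feature lines; the length is end - start + 1 and the id
    comes from the ``Name`` (fallback ``ID``) attribute.
    """
    records: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "miRNA":
                continue
            start, end = int(parts[3]), int(parts[4])
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get(id_attr) or attrs.get("ID")
            if name:
                records[name] = end - start + 1
    if not records:
        raise ValueError(f"{path}: no miRNA features found")
    return pd.Series(records, name="length_nt")
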