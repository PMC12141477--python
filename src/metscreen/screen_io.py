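"""Reading, writing and normalization of pooled-screen count data.

On-disk dialect
---------------
Count tables are tab-separated with a header ``sgRNA<TAB>gene<TAB><sample...>``
and one non-negative integer column per sample.  The sgRNA library is a
two/three column TSV (``sgrna``, ``gene``, optional ``sequence``).  Sample
metadata lives in a separate YAML file mapping each sample id to its cell
line, mouse and tissue; metadata never travels inside the count file.

Normalization is median-of-ratios against the geometric-mean reference
profile (the convention used for sequencing count data), with a total-count
fallback when no sgRNA is detected in every sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TISSUES = ("primary", "lung_met", "liver_met", "plasmid")

#: Column order of a gene report, 1-based ranks, rank 1 = most significant.
REPORT_COLUMNS = (
    "id", "num",
    "neg|score", "neg|p-value", "neg|fdr", "neg|rank",
    "pos|score", "pos|p-value", "pos|fdr", "pos|rank",
)

_REPORT_TO_INTERNAL = {
    "id": "gene", "num": "num",
    "neg|score": "neg_score", "neg|p-value": "neg_p",
    "neg|fdr": "neg_fdr", "neg|rank": "neg_rank",
    "pos|score": "pos_score", "pos|p-value": "pos_p",
    "pos|fdr": "pos_fdr", "pos|rank": "pos_rank",
}


class ScreenFormatError(ValueError):
    """A screen input file violates the expected dialect or an invariant."""


@dataclass(frozen=True)
class SgRNALibrary:
    """sgRNA-to-gene map of a pooled knockout library.

    ``table`` is indexed by unique sgRNA id and carries a ``gene`` column
    (optionally ``sequence``).  Every sgRNA maps to exactly one gene.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "gene" not in self.table.columns:
            raise ScreenFormatError("library table needs a 'gene' column")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ScreenFormatError(f"duplicate sgRNA id in library: {dup!r}")
        if self.table["gene"].isna().any():
            raise ScreenFormatError("library contains sgRNAs without a gene")

    @classmethod
    def from_mapping(cls, sgrna_to_gene: Mapping[str, str]) -> "SgRNALibrary":
        tab = pd.DataFrame({"gene": pd.Series(dict(sgrna_to_gene))})
        tab.index.name = "sgrna"
        return cls(tab)

    @property
    def sgrna_ids(self) -> pd.Index:
        return self.table.index

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    @property
    def gene_of(self) -> pd.Series:
        return self.table["gene"]

    def sgrnas_per_gene(self) -> pd.Series:
        return self.table.groupby("gene").size()

    def __len__(self) -> int:
        return len(self.table)


def read_library(path) -> SgRNALibrary:
    """Read a library TSV with columns sgrna, gene[, sequence]."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in tab.columns]
    tab.columns = cols
    if cols[:2] != ["sgrna", "gene"]:
        raise ScreenFormatError(
            f"library header must start with 'sgrna<TAB>gene', got {cols[:2]}"
        )
    return SgRNALibrary(tab.set_index("sgrna"))


def write_library(library: SgRNALibrary, path) -> None:
    library.table.to_csv(path, sep="\t", index_label="sgrna")


def read_sample_meta(path) -> tuple[pd.DataFrame, dict]:
    """Read sample metadata YAML.

    Returns ``(meta, mouse_info)`` where ``meta`` is a DataFrame indexed by
    sample id with columns cell_line, mouse_id, tissue, and ``mouse_info``
    maps cell line -> mouse id -> attribute dict (e.g. ``lung_preference``).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "samples" not in doc:
        raise ScreenFormatError("metadata YAML needs a top-level 'samples' mapping")
    rows = {}
    for sample_id, rec in doc["samples"].items():
        missing = {"cell_line", "mouse_id", "tissue"} - set(rec)
        if missing:
            raise ScreenFormatError(
                f"sample {sample_id!r} missing metadata fields {sorted(missing)}"
            )
        if rec["tissue"] not in TISSUES:
            raise ScreenFormatError(
                f"sample {sample_id!r} has unknown tissue {rec['tissue']!r}; "
                f"expected one of {TISSUES}"
            )
        rows[sample_id] = rec
    meta = pd.DataFrame.from_dict(rows, orient="index")
    meta.index.name = "sample_id"
    mouse_info = doc.get("mice", {}) or {}
    return meta, mouse_info


def write_sample_meta(meta: pd.DataFrame, path, mouse_info: dict | None = None) -> None:
    doc: dict = {"samples": {
        s: {"cell_line": str(r.cell_line), "mouse_id": str(r.mouse_id),
            "tissue": str(r.tissue)}
        for s, r in meta.iterrows()
    }}
    if mouse_info:
        doc["mice"] = mouse_info
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_count_table(path, library: SgRNALibrary,
                     meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a count TSV against a library (and optional metadata).

    Returns an sgRNA x sample DataFrame of non-negative int64 counts indexed
    by sgRNA id.  The ``gene`` column of the file must agree with the library
    mapping; sample columns must be known to ``meta`` when it is given.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 3 or header[0] != "sgRNA" or header[1] != "gene":
        raise ScreenFormatError(
            "count table header must be 'sgRNA<TAB>gene<TAB><samples...>', "
            f"got {header[:3]}"
        )
    samples = header[2:]
    if len(set(samples)) != len(samples):
        raise ScreenFormatError("duplicate sample columns in count table")
    raw = pd.read_csv(path, sep="\t", dtype={"sgRNA": str, "gene": str})
    if raw["sgRNA"].duplicated().any():
        dup = raw.loc[raw["sgRNA"].duplicated(), "sgRNA"].iloc[0]
        raise ScreenFormatError(f"duplicate sgRNA row {dup!r} in count table")

    for col in samples:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ScreenFormatError(
                f"non-integer or negative count {raw[col][bad].iloc[0]!r} "
                f"in column {col!r} at line {line}"
            )

    unknown = ~raw["sgRNA"].isin(library.sgrna_ids)
    if unknown.any():
        raise ScreenFormatError(
            f"count table row {raw['sgRNA'][unknown].iloc[0]!r} not in library"
        )
    lib_gene = library.gene_of.reindex(raw["sgRNA"]).to_numpy()
    mismatch = raw["gene"].to_numpy() != lib_gene
    if mismatch.any():
        sg = raw["sgRNA"][mismatch].iloc[0]
        raise ScreenFormatError(
            f"gene column contradicts library mapping for sgRNA {sg!r}"
        )
    if meta is not None:
        absent = [s for s in samples if s not in meta.index]
        if absent:
            raise ScreenFormatError(f"sample columns not in metadata: {absent}")

    counts = raw.set_index("sgRNA")[samples].astype(np.int64)
    counts.index.name = "sgRNA"
    return counts


def write_count_table(counts: pd.DataFrame, library: SgRNALibrary, path) -> None:
    out = counts.copy()
    out.insert(0, "gene", library.gene_of.reindex(out.index))
    out.to_csv(path, sep="\t", index_label="sgRNA")


@dataclass(frozen=True)
class NormalizedCounts:
    """Sample-depth normalized counts: ``values = raw / size_factor``."""

    values: pd.DataFrame
    size_factors: pd.Series

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


def median_ratio_normalize(counts: pd.DataFrame,
                           pseudocount: float = 0.0) -> NormalizedCounts:
    """Median-of-ratios size factors over sgRNAs detected in every sample.

    Each sample's size factor is the median, over sgRNAs with all-positive
    (pseudocounted) counts, of its count divided by the across-sample
    geometric mean of that sgRNA.  When no sgRNA is positive in every sample
    the function falls back to total-count normalization and logs a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("normalization needs at least two samples")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    x = counts.to_numpy(dtype=float) + pseudocount
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        logx = np.log(x[all_pos])
        geo = np.exp(logx.mean(axis=1, keepdims=True))
        sf = np.median(x[all_pos] / geo, axis=0)
    else:
        logger.warning(
            "no sgRNA with positive counts in every sample; "
            "falling back to total-count normalization"
        )
        totals = counts.to_numpy(dtype=float).sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot normalize a sample with zero total count")
        sf = totals / np.exp(np.mean(np.log(totals)))
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    return NormalizedCounts(values=counts / size_factors, size_factors=size_factors)


def write_gene_report(results: pd.DataFrame, path) -> None:
    """Write a per-comparison gene report TSV, sorted by neg|rank ascending.

    ``results`` is a GeneResult table indexed by gene id with columns
    num, neg_score, neg_p, neg_fdr, neg_rank, pos_score, pos_p, pos_fdr,
    pos_rank (extra columns are ignored).
    """
    needed = [v for v in _REPORT_TO_INTERNAL.values() if v != "gene"]
    missing = [c for c in needed if c not in results.columns]
    if missing:
        raise ScreenFormatError(f"gene result table missing fields: {missing}")
    out = pd.DataFrame({"id": results.index})
    for rep_col in REPORT_COLUMNS[1:]:
        out[rep_col] = results[_REPORT_TO_INTERNAL[rep_col]].to_numpy()
    out = out.sort_values("neg|rank", kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_gene_report(path) -> pd.DataFrame:
    rep = pd.read_csv(path, sep="\t")
    missing = [c for c in REPORT_COLUMNS if c not in rep.columns]
    if missing:
        raise ScreenFormatError(f"gene report missing columns: {missing}")
    rep = rep.rename(columns=_REPORT_TO_INTERNAL).set_index("gene")
    for col in ("num", "neg_rank", "pos_rank"):
        rep[col] = rep[col].astype(np.int64)
    return rep


def write_table(table: pd.DataFrame, path, index_label: str = "gene") -> None:
    """Generic TSV writer for essentiality / concordance / filter tables."""
    table.to_csv(path, sep="\t", index_label=index_label)
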