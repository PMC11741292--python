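"""Tab-separated readers and writers for count tables, metadata and results.

Count matrices are UTF-8 TSV with a header row of sample identifiers, a
first column named ``asv_id`` and integer cells (ASVs in rows, samples in
columns). Metadata tables carry the canonical column set of
:data:`igaseq.profiles.METADATA_COLUMNS`. All result tables are written with
a header and ``NA`` for missing values; reading then writing a valid table
reproduces it exactly.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .profiles import AsvCountTable, validate_sample_metadata

NA_REP = "NA"


def read_count_table(path) -> AsvCountTable:
    """Read and validate an ASV count TSV; errors cite the offending line."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dups = [name for i, name in enumerate(header[1:]) if name in header[1 : i + 1]]
    if dups:
        raise ValueError(f"{path}, line 1: duplicated sample_id(s): {sorted(set(dups))}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "asv_id":
        raise ValueError(
            f"{path}: first column must be named 'asv_id', got {raw.columns[0]!r}"
        )
    body = raw.set_index("asv_id")
    try:  # fast path: every cell parses as an integer
        return AsvCountTable(body.astype("int64"))
    except (ValueError, TypeError):
        pass
    for row_pos, (asv, row) in enumerate(body.iterrows()):
        for sample, cell in row.items():
            try:
                value = int(cell)
            except ValueError:
                raise ValueError(
                    f"{path}, line {row_pos + 2}: non-integer count {cell!r} "
                    f"for ASV {asv!r}, sample {sample!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"{path}, line {row_pos + 2}: negative count for ASV {asv!r}"
                )
    return AsvCountTable(body.astype("int64"))


def write_count_table(table: AsvCountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="asv_id")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV, validate categories, index by sample_id."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_sample_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    cols = [c for c in meta.columns if c != "steroid"]
    meta[cols].to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def read_flow(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str})


def write_results(frame: pd.DataFrame, path, index: bool = False,
                  float_format: str = "%.10g") -> None:
    """Write any result table as TSV with NA for missing values."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, na_rep=NA_REP,
                 float_format=float_format)
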