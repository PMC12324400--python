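"""Readers and writers for the pipeline's file surface.

Expression matrices are delimited text with gene ids in the first
column and sample ids in the header; the GEO series-matrix dialect
(leading ``!``-prefixed metadata lines, table delimited by the
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers)
is detected automatically.  Signatures come in GMT (one cluster per
line: name, description, genes, with an optional ``|Down`` direction
suffix per gene) or long TSV (gene, cluster[, direction]).  Group
labels are a two-column TSV (sample, group).

Gene identifiers are matched case-sensitively by exact string; no
symbol-alias resolution is attempted (a case-folding option exists for
convenience but is off by default, since e.g. human SMaRT symbols do
not line up with mouse symbols by case alone).  All writers emit a
deterministic column order and a ``#``-prefixed provenance header.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .signature import GeneSignature, SignatureGene

logger = logging.getLogger(__name__)


def _sniff_sep(line: str) -> str:
    return "," if ("," in line and "\t" not in line) else "\t"


def read_matrix(path, sep: str | None = None, casefold: bool = False) -> pd.DataFrame:
    """Read a gene-by-sample expression matrix from delimited text.

    Handles plain TSV/CSV and the GEO series-matrix dialect.  Duplicate
    gene ids are resolved by keeping the row with the highest mean
    (logged).  Blank cells become missing values.

    Raises
    ------
    ValueError
        On an empty matrix or an unparseable cell (with coordinates).
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    data_lines = []
    in_table = None  # None: plain file; True/False inside/outside markers
    for ln in lines:
        low = ln.strip().lower()
        if low.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if low.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if ln.startswith(("!", "#")):
            continue
        if in_table is False:
            continue
        if ln.strip():
            data_lines.append(ln)
    if not data_lines:
        raise ValueError(f"{path}: no data rows found")
    if sep is None:
        sep = _sniff_sep(data_lines[0])
    df = pd.read_csv(
        _io.StringIO("\n".join(data_lines)), sep=sep, index_col=0, dtype=str
    )
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    if casefold:
        df.index = df.index.str.upper()

    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col].str.strip('"'), errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            i = int(np.where(bad.to_numpy())[0][0])
            raise ValueError(
                f"{path}: unparseable value {df[col].iloc[i]!r} at "
                f"row {df.index[i]!r}, column {col!r} (data row {i + 1}, col {j + 2})"
            )
        values[col] = converted

    if values.index.has_duplicates:
        dupes = sorted(set(values.index[values.index.duplicated()]))
        logger.warning(
            "duplicate gene ids %s: keeping the row with highest mean", dupes
        )
        values = (
            values.assign(_mean=values.mean(axis=1))
            .sort_values("_mean", ascending=False, kind="stable")
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
        )
        values = values.loc[sorted(values.index)]
    values.index.name = "gene"
    return values


def read_groups(path) -> pd.Series:
    """Read a two-column (sample, group) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    first = df.iloc[0]
    if first.iloc[0].lower() in ("sample", "sample_id") or first.iloc[1].lower() in (
        "group",
        "label",
    ):
        df = df.iloc[1:]
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    if s.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    return s


def align_groups(X: pd.DataFrame, groups: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict a matrix and group map to their shared samples.

    Matrix samples without a group label are dropped with a warning;
    group entries naming samples absent from the matrix are an error.
    """
    unknown = [s for s in groups.index if s not in X.columns]
    if unknown:
        raise ValueError(f"groups reference unknown samples: {sorted(unknown)}")
    missing = [s for s in X.columns if s not in groups.index]
    if missing:
        logger.warning("samples without group labels excluded: %s", sorted(missing))
    keep = [s for s in X.columns if s in groups.index]
    return X[keep], groups.loc[keep]


def _parse_sig_gene(token: str) -> SignatureGene:
    if "|" in token:
        gene, direction = token.rsplit("|", 1)
        return SignatureGene(gene=gene, direction=direction)
    return SignatureGene(gene=token, direction="Up")


def read_signature(path) -> GeneSignature:
    """Read a signature from GMT or long TSV (by extension).

    GMT lines are ``name<TAB>description<TAB>gene[|direction]...``;
    the TSV form has columns gene, cluster and optionally direction.
    """
    path = Path(path)
    clusters: dict[str, list[SignatureGene]] = {}
    if path.suffix.lower() == ".gmt":
        for ln in path.read_text().splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line needs name, description, genes")
            clusters[parts[0]] = [_parse_sig_gene(t) for t in parts[2:] if t]
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        cols = [c.lower() for c in df.columns]
        if "gene" not in cols or "cluster" not in cols:
            # headerless two/three-column form
            df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
            df.columns = ["gene", "cluster", "direction"][: df.shape[1]]
        else:
            df.columns = cols
        if "direction" not in df.columns:
            df["direction"] = "Up"
        df["direction"] = df["direction"].fillna("Up")
        for _, row in df.iterrows():
            clusters.setdefault(str(row["cluster"]), []).append(
                SignatureGene(gene=str(row["gene"]), direction=str(row["direction"]))
            )
    return GeneSignature(clusters=clusters)


def _provenance_header(**params) -> str:
    parts = [f"# colam v{__version__}"]
    for key in sorted(params):
        parts.append(f"# {key}={params[key]}")
    return "\n".join(parts) + "\n"


def write_matrix(X: pd.DataFrame, path, **params) -> None:
    with open(path, "w") as fh:
        if params:
            fh.write(_provenance_header(**params))
        X.to_csv(fh, sep="\t")


def write_table(table: pd.DataFrame, path, **params) -> None:
    """Write a report table as TSV with a provenance header."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(**params))
        table.to_csv(fh, sep="\t")


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_signature(sig: GeneSignature, path, description: str = "colam") -> None:
    """Write a signature as GMT with ``|Down`` suffixes where needed."""
    with open(path, "w") as fh:
        for name in sorted(sig.clusters):
            tokens = [
                sg.gene if sg.direction == "Up" else f"{sg.gene}|{sg.direction}"
                for sg in sig.clusters[name]
            ]
            fh.write("\t".join([name, description] + tokens) + "\n")


def write_groups(groups: pd.Series, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, label in groups.items():
            fh.write(f"{sample}\t{label}\n")
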