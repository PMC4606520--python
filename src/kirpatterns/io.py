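"""Reading and writing genotype tables (CSV/TSV) and ARFF export.

Input tables have one row per donor, one column per gene, one class
column, optionally a sample-id column.  Cells may be coded ``0/1``,
``blank/✓`` (typing-report style) or ``absent/present``; the three
dialects can be mixed cell by cell.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

from .cohort import Cohort, GenotypeRecord
from .exceptions import ParseError, SchemaError
from .genes import KIR_GENES, normalize_gene

_TRUE_CELLS = {"1", "✓", "present", "yes", "true", "x"}
_FALSE_CELLS = {"0", "", "absent", "no", "false", "nan"}
_ID_COLUMNS = {"id", "sample_id", "sample", "#"}


def _parse_cell(raw: object, row: int, column: str) -> int:
    text = str(raw).strip().lower()
    if text in _TRUE_CELLS:
        return 1
    if text in _FALSE_CELLS:
        return 0
    raise ParseError(
        f"cell {raw!r} at row {row}, column {column!r} is not a recognised "
        "presence/absence encoding (expected 0/1, ✓/blank or present/absent)",
        row=row,
        column=column,
    )


def read_genotype_table(
    source: str | Path | IO[str],
    genes: Iterable[str] | None = None,
    class_column: str | None = None,
    sep: str | None = None,
    provenance: str = "",
) -> Cohort:
    """Read a genotype table into a :class:`Cohort`.

    Gene-column matching is case-insensitive and tolerates an optional
    ``KIR`` prefix.  The class column is matched by ``class_column`` if
    given; otherwise the single non-gene, non-id column is used.  Row
    order is preserved.
    """
    expected = tuple(normalize_gene(g) for g in genes) if genes is not None else KIR_GENES
    if sep is None and isinstance(source, (str, Path)):
        sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(
        source, sep=sep if sep is not None else ",",
        dtype=str, keep_default_na=False, engine="python",
    )
    if df.empty:
        raise SchemaError("table has a header but no data rows")

    by_norm: dict[str, str] = {}
    for col in df.columns:
        by_norm.setdefault(normalize_gene(col), col)
    missing = [g for g in expected if g not in by_norm]
    if missing:
        raise SchemaError(f"missing gene column(s): {', '.join(missing)}")

    gene_cols = {g: by_norm[g] for g in expected}
    used = set(gene_cols.values())
    id_col = next(
        (c for c in df.columns if c not in used and c.strip().lower() in _ID_COLUMNS),
        None,
    )
    if class_column is not None:
        matches = [c for c in df.columns if c.strip().lower() == class_column.strip().lower()]
        if not matches:
            raise SchemaError(f"missing class column: {class_column}")
        cls_col = matches[0]
    else:
        rest = [c for c in df.columns if c not in used and c != id_col]
        if len(rest) != 1:
            raise SchemaError(
                "cannot identify the class column; candidates: "
                f"{rest!r} — pass class_column explicitly"
            )
        cls_col = rest[0]

    records = []
    for pos in range(len(df)):
        row = df.iloc[pos]
        sid = str(row[id_col]).strip() if id_col else str(pos + 1)
        presence = {
            g: _parse_cell(row[col], pos + 1, col) for g, col in gene_cols.items()
        }
        label = _parse_cell(row[cls_col], pos + 1, cls_col)
        records.append(GenotypeRecord(sid, presence, label))
    return Cohort(
        records,
        genes=expected,
        class_attribute=cls_col.strip(),
        provenance=provenance or (str(source) if isinstance(source, (str, Path)) else ""),
    )


def write_genotype_table(
    cohort: Cohort, sink: str | Path | IO[str], sep: str = ","
) -> None:
    """Write the cohort as a 0/1 CSV/TSV with sample ids and class last."""
    cohort.to_dataframe().to_csv(sink, sep=sep, index=False)


def write_arff(
    cohort: Cohort, sink: str | Path | IO[str], relation: str = "kir_cohort"
) -> None:
    """Write the cohort in ARFF with nominal {0,1} attributes, class last."""
    buf = _io.StringIO()
    buf.write(f"@RELATION {relation}\n\n")
    for g in cohort.genes:
        buf.write(f"@ATTRIBUTE {g} {{0,1}}\n")
    buf.write(f"@ATTRIBUTE {cohort.class_attribute} {{0,1}}\n\n@DATA\n")
    mat = cohort.gene_matrix()
    labels = cohort.class_labels()
    for i in range(len(cohort)):
        buf.write(",".join(str(int(v)) for v in mat[i]) + f",{labels[i]}\n")
    text = buf.getvalue()
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)
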