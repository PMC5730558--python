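"""File formats consumed and produced by the pipeline.

All formats are plain text:

* event tables — CSV with header ``event_id,<channel>,...`` plus a sidecar
  JSON of panel metadata (``<path>.meta.json``);
* expression matrices — TSV, genes in rows (first column ``gene``), samples
  in columns, log2 scale;
* sample groups — two-column TSV ``sample<TAB>group`` (control|tumor);
* gene sets / signatures — GMT (term, description, genes...);
* ortholog maps — two-column TSV ``rat_symbol<TAB>human_symbol``;
* ground truth, thresholds and reports — JSON.

Writers and readers round-trip exactly for strings/integers and to float
repr precision (well below 1e-12 relative) for reals.  Malformed rows raise
:class:`~gliomaprofiler.datatypes.ValidationError` with the line number;
duplicate identifiers are reported by name.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CONTROL, TUMOR, EventTable, ExpressionStudy, ValidationError


def _meta_path(path) -> Path:
    return Path(str(path) + ".meta.json")


# -- event tables -----------------------------------------------------------

def write_event_table(table: EventTable, path) -> None:
    path = Path(path)
    table.data.to_csv(path, index=True, index_label="event_id")
    meta = {
        "panel": table.panel,
        "condition": table.condition,
        "compartment": table.compartment,
        "day": table.day,
        "stain": table.stain,
        "channels": table.channels,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_event_table(path) -> EventTable:
    path = Path(path)
    data = pd.read_csv(path, index_col="event_id")
    meta_file = _meta_path(path)
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    return EventTable(
        data,
        panel=meta.get("panel", "unknown"),
        condition=meta.get("condition", "naive"),
        compartment=meta.get("compartment", "brain"),
        day=meta.get("day"),
        stain=meta.get("stain", "antibody"),
    )


# -- expression studies -----------------------------------------------------

def write_expression_study(study: ExpressionStudy, matrix_path, groups_path) -> None:
    study.matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    study.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")


def read_expression_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValidationError(
            f"duplicate gene row(s) in {path}: {dupes[:5]}"
        )
    return matrix


def read_groups(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (sample, group)")
    sample_col, group_col = table.columns[:2]
    if table[sample_col].duplicated().any():
        dupe = table[sample_col][table[sample_col].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample {dupe!r}")
    groups = pd.Series(table[group_col].values, index=table[sample_col].values)
    bad = sorted(set(groups.unique()) - {CONTROL, TUMOR})
    if bad:
        raise ValidationError(
            f"{path}: group labels must be '{CONTROL}'/'{TUMOR}', got {bad}"
        )
    return groups


def read_expression_study(matrix_path, groups_path, name="study") -> ExpressionStudy:
    return ExpressionStudy(
        read_expression_matrix(matrix_path), read_groups(groups_path), name=name
    )


# -- gene sets (GMT) --------------------------------------------------------

def read_gmt(path) -> dict[str, list]:
    """GMT: one line per set — ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs name, description and "
                "at least one gene"
            )
        name, genes = fields[0], fields[2:]
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = genes
    if not sets:
        raise ValidationError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *map(str, genes)])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- ortholog maps ----------------------------------------------------------

def read_ortholog_pairs(path) -> list[tuple]:
    """Two-column TSV ``rat_symbol<TAB>human_symbol`` with a header line."""
    pairs = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValidationError(
                f"{path}:{lineno}: expected exactly two tab-separated columns"
            )
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValidationError(f"{path}: no ortholog pairs")
    return pairs


def write_ortholog_pairs(pairs, path) -> None:
    lines = ["rat_symbol\thuman_symbol"] + [f"{r}\t{h}" for r, h in pairs]
    Path(path).write_text("\n".join(lines) + "\n")


# -- JSON with numpy-friendly encoding -------------------------------------

class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())


# -- tidy fraction tables ---------------------------------------------------

def fractions_tidy_row(fractions, population: str, meta: dict) -> dict:
    return {
        "population": population,
        "count": fractions.counts[population],
        "fraction": fractions.fraction(population),
        "percent": fractions.percent(population),
        **meta,
    }
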