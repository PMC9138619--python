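"""Readers and writers for the package's plain-text formats.

Counts travel as TSV (gene_id, length_bp, one column per sample), the
cell-type reference as TSV with ``cell_type@region`` columns, gene sets as
standard GMT (name, description, tab-separated members), qPCR plates as
tidy TSV, and run summaries as JSON. Every writer's output is re-readable
by the matching reader.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .simulate import BulkExperiment

logger = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(r"^(?P<cytokine>[A-Za-z0-9]+)_(?P<timepoint>\d+)h$")


def sample_meta_from_names(samples: Iterable[str]) -> pd.DataFrame:
    """Infer (cytokine, timepoint) from sample names like ``TNFA_4h``.

    The control is any name with time point 0 (cytokine recorded as NONE);
    non-conforming names get cytokine NONE, timepoint -1.
    """
    rows = []
    for s in samples:
        m = _SAMPLE_RE.match(s)
        if m:
            tp = int(m.group("timepoint"))
            cyt = "NONE" if tp == 0 else m.group("cytokine")
            rows.append((cyt, tp))
        else:
            rows.append(("NONE", -1))
    return pd.DataFrame(rows, columns=["cytokine", "timepoint"], index=pd.Index(samples, name="sample"))


def read_counts(path: str | Path) -> BulkExperiment:
    """Read a count matrix TSV (gene_id, length_bp, sample columns)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id" or "length_bp" not in df.columns:
        raise ValueError(f"{path}: header must start with gene_id and include length_bp")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    df = df.set_index("gene_id")
    lengths = df.pop("length_bp")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"{path}: non-positive length for gene {bad!r}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number) or not np.all(np.mod(vals, 1) == 0):
            bad = vals.index[np.mod(pd.to_numeric(vals, errors="coerce"), 1) != 0]
            raise ValueError(f"{path}: non-integer count in sample {col!r} (gene {bad[0]!r})")
        if (vals < 0).any():
            bad = vals.index[vals < 0][0]
            raise ValueError(f"{path}: negative count for gene {bad!r} in sample {col!r}")
    counts = df.astype(np.int64)
    return BulkExperiment(counts=counts, lengths=lengths.astype(np.int64), sample_meta=sample_meta_from_names(counts.columns))


def write_counts(bulk: BulkExperiment, path: str | Path) -> None:
    out = bulk.counts.copy()
    out.insert(0, "length_bp", bulk.lengths)
    out.to_csv(path, sep="\t")


def read_reference(path: str | Path) -> pd.DataFrame:
    ref = pd.read_csv(path, sep="\t", index_col=0)
    if ref.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids in reference")
    bad = [c for c in ref.columns if "@" not in c]
    if bad:
        raise ValueError(f"{path}: reference columns must be 'cell_type@region'; got {bad[:3]}")
    return ref


def write_reference(reference: pd.DataFrame, path: str | Path) -> None:
    reference.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Standard GMT: name TAB description TAB member...

    Empty sets are dropped with a warning; duplicate names and lines with
    fewer than two fields are errors (reported with their line number).
    The universe defaults to the union of all members.
    """
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (need name and description)")
            name, _desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = [m for m in members if m]
            if not members:
                logger.warning("%s:%d: empty gene set %r dropped", path, lineno, name)
                continue
            sets[name] = frozenset(members)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_plate(path: str | Path) -> pd.DataFrame:
    plate = pd.read_csv(path, sep="\t")
    required = {"sample", "condition", "primer", "ct"}
    if not required <= set(plate.columns):
        raise ValueError(f"{path}: plate TSV must have columns {sorted(required)}")
    if (plate["ct"] <= 0).any():
        raise ValueError(f"{path}: ct values must be positive")
    return plate


def write_plate(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
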