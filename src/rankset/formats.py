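"""Readers and writers for the formats the pipeline touches.

Supported formats: GMT gene-set collections (MSigDB's distribution
format), tab-separated count/design tables, differential-expression
tables, ranked profiles, result tables, and a flat key=value
configuration file. All readers validate and reject malformed input
rather than silently coercing; all writers round-trip through the
matching reader.

Gene identifiers are upper-cased on ingestion everywhere, so that
symbol-cased expression tables and gene-set files join correctly.
"""

from __future__ import annotations

import hashlib
import logging
from collections.abc import Iterable, Iterator, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, FormatError, ValidationError, validate_de_table

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_counts",
    "write_counts",
    "read_de_table",
    "write_de_table",
    "read_ranked",
    "write_ranked",
    "write_table",
    "read_config",
]


class GeneSetCollection:
    """Ordered mapping of set name -> (description, member genes).

    Member gene identifiers are upper-cased and de-duplicated preserving
    first occurrence. Set names must be unique and every set non-empty.
    """

    def __init__(self) -> None:
        self._sets: dict[str, tuple[str, tuple[str, ...]]] = {}

    @classmethod
    def from_dict(cls, sets: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        coll = cls()
        for name, genes in sets.items():
            coll.add(name, "", genes)
        return coll

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self._sets:
            raise ValidationError(f"duplicate gene-set name {name!r}")
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(str(g).upper(), None)
        members = tuple(seen)
        if not members:
            raise ValidationError(f"gene set {name!r} is empty")
        self._sets[name] = (description, members)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __contains__(self, name: object) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self._sets[name][1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets

    def description(self, name: str) -> str:
        return self._sets[name][0]

    def items(self) -> Iterator[tuple[str, tuple[str, ...]]]:
        for name, (_, genes) in self._sets.items():
            yield name, genes

    def sizes(self) -> pd.Series:
        return pd.Series({name: len(genes) for name, genes in self.items()})

    def restrict(
        self,
        universe: Iterable[str] | None = None,
        min_size: int = 1,
        max_size: int | None = None,
    ) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and filter by size.

        Sets falling outside [min_size, max_size] after intersection are
        dropped (logged). Order is preserved.
        """
        uni = None if universe is None else frozenset(str(g).upper() for g in universe)
        out = GeneSetCollection()
        for name, (desc, genes) in self._sets.items():
            members = genes if uni is None else tuple(g for g in genes if g in uni)
            k = len(members)
            if k < min_size or (max_size is not None and k > max_size):
                logger.debug("set %s dropped by size filter (k=%d)", name, k)
                continue
            out._sets[name] = (desc, members)
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are collapsed; line order is preserved.
    Raises :class:`FormatError` with the line number on malformed lines
    and on duplicate set names.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with path.open() as fh:
        digest = hashlib.sha256()
        for lineno, raw in enumerate(fh, start=1):
            digest.update(raw.encode())
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            try:
                coll.add(name, description, genes)
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    logger.info(
        "read_gmt: %d sets from %s (sha256=%s)", len(coll), path, digest.hexdigest()[:16]
    )
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in coll.items():
            fh.write("\t".join([name, coll.description(name), *genes]) + "\n")


def read_counts(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a genes x samples count table plus a two-column design TSV.

    The count table has gene identifiers in the first column and a header
    row of sample identifiers. The design file has columns ``sample`` and
    ``group``. Samples are reordered as listed in the design; mismatches
    between the two files raise listing the offending samples.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str).str.upper()
    counts.index.name = "gene_id"
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in design.columns:
            raise FormatError(f"{design_path}: missing required column {col!r}")
    if design["sample"].duplicated().any():
        raise FormatError(f"{design_path}: duplicate sample identifiers")
    design_series = pd.Series(
        design["group"].to_numpy(), index=pd.Index(design["sample"], name="sample"), name="group"
    )
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric count entries")
    if not np.allclose(values, np.round(values)):
        raise ValidationError(f"{path}: counts must be integers")
    counts = counts.astype(np.int64)
    return CountMatrix(counts, design_series)


def write_counts(cm: CountMatrix, counts_path: str | Path, design_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    design = pd.DataFrame({"sample": cm.design.index, "group": cm.design.to_numpy()})
    design.to_csv(design_path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table (TSV with header).

    Required columns: ``gene_id``, ``log2fc``, ``p``. A missing ``fdr``
    column is recomputed from the p column with Benjamini-Hochberg.
    Gene identifiers are upper-cased; duplicates raise.
    """
    de = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc", "p"):
        if col not in de.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    de["gene_id"] = de["gene_id"].astype(str).str.upper()
    if "fdr" not in de.columns:
        from .diffexpr import bh_adjust

        de["fdr"] = bh_adjust(de["p"].to_numpy(dtype=float))
    try:
        return validate_de_table(de)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    validate_de_table(de)
    de.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ranked(path: str | Path) -> pd.DataFrame:
    ranked = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "score", "rank", "scaled_rank"):
        if col not in ranked.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    ranked["gene_id"] = ranked["gene_id"].astype(str).str.upper()
    return ranked


def write_ranked(ranked: pd.DataFrame, path: str | Path) -> None:
    """Serialize a ranked profile, ordering ties lexicographically by gene."""
    out = ranked.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic result-table writer (TSV, full float precision)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    return value


def read_config(path: str | Path) -> dict:
    """Parse a flat ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored. Values are coerced to
    int/float/bool where possible. Every CLI flag has a config twin; the
    CLI wins on conflict (enforced by the CLI layer).
    """
    path = Path(path)
    config: dict = {}
    for lineno, raw in enumerate(path.open(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise FormatError(f"{path}:{lineno}: empty key")
        config[key] = _coerce(value)
    return config
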