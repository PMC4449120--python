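"""Lexical data model: long-format lexicon tables, binary cognate coding,
inter-variant distances, and NEXUS character I/O.

A lexicon is a list of records ``(variant, meaning, form, cognate_class)``.
Cognate-class labels live in a per-meaning namespace: the label ``"A"`` under
meaning ``hand`` and the label ``"A"`` under meaning ``foot`` are distinct
characters.  Binarization produces one presence/absence column per
``(meaning, cognate_class)`` pair; a variant with no record at all for a
meaning is coded *missing* for every column of that meaning, not absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

log = logging.getLogger(__name__)

MISSING = -1  # cell code for "no record for this meaning at all"

#: default header names; read_lexicon accepts a mapping to override them
DEFAULT_COLUMNS = {
    "variant": "variant",
    "meaning": "meaning",
    "form": "form",
    "cognate_class": "cognate_class",
}


@dataclass
class LexiconTable:
    """Long-format lexical records with deterministic variant/meaning order.

    ``variants`` and ``meanings`` are ordered by first appearance in
    ``records``.  A (variant, meaning) pair may carry zero, one, or several
    records (synonyms).
    """

    records: list[tuple[str, str, str, str]]
    variants: list[str] = field(default_factory=list)
    meanings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError("lexicon table is empty")
        for rec in self.records:
            variant, meaning, _form, cls = rec
            if not variant or not meaning or not cls:
                raise FormatError(f"record with empty id field: {rec!r}")
        if not self.variants:
            self.variants = list(dict.fromkeys(r[0] for r in self.records))
        if not self.meanings:
            self.meanings = list(dict.fromkeys(r[1] for r in self.records))

    def classes_for(self, meaning: str) -> list[str]:
        """Sorted cognate-class labels attested for one meaning."""
        return sorted({r[3] for r in self.records if r[1] == meaning})


@dataclass
class BinaryCharacterMatrix:
    """Taxa x characters presence/absence matrix with meaning partition.

    ``cells`` holds 0, 1, or :data:`MISSING` (int8).  ``characters`` is the
    ordered list of ``(meaning, cognate_class)`` pairs; ``meaning_partition``
    maps each meaning to its column indices.
    """

    taxa: list[str]
    characters: list[tuple[str, str]]
    cells: np.ndarray
    meaning_partition: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise DataError(
                f"cell block {self.cells.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        if not self.meaning_partition:
            part: dict[str, list[int]] = {}
            for j, (meaning, _cls) in enumerate(self.characters):
                part.setdefault(meaning, []).append(j)
            self.meaning_partition = part

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) cells."""
        return self.cells != MISSING

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryCharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and np.array_equal(self.cells, other.cells)
        )


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise DataError(f"distance block {self.d.shape} does not match {n} taxa")
        if not np.allclose(self.d, self.d.T):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DataError("distance matrix has nonzero diagonal")
        if np.any(self.d < 0):
            raise DataError("negative distances")

    def submatrix(self, taxa: list[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.d[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# I/O


def read_lexicon(
    path: str | Path,
    columns: dict[str, str] | None = None,
    sep: str | None = None,
) -> LexiconTable:
    """Read a lexicon from CSV/TSV or XLSX.

    Parameters
    ----------
    path:
        Table file.  ``.xlsx`` is read with pandas/openpyxl (first sheet);
        anything else as delimited text with the delimiter sniffed unless
        ``sep`` is given.
    columns:
        Optional mapping from the canonical names
        ``variant/meaning/form/cognate_class`` to the file's header names.

    Duplicate identical records are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    for canon, name in colmap.items():
        if canon == "form":
            continue  # form is optional
        if name not in df.columns:
            raise FormatError(f"required column {name!r} ({canon}) not found in {path.name}")
    if colmap["form"] not in df.columns:
        df[colmap["form"]] = ""
    sub = df[[colmap["variant"], colmap["meaning"], colmap["form"], colmap["cognate_class"]]]
    sub = sub.dropna(subset=[colmap["variant"], colmap["meaning"], colmap["cognate_class"]])
    records = [
        (str(v).strip(), str(m).strip(), "" if pd.isna(f) else str(f).strip(), str(c).strip())
        for v, m, f, c in sub.itertuples(index=False)
    ]
    if not records:
        raise DataError(f"no usable records in {path.name}")
    deduped = list(dict.fromkeys(records))
    n_dup = len(records) - len(deduped)
    if n_dup:
        log.info("dropped %d duplicate records from %s", n_dup, path.name)
    return LexiconTable(deduped)


def write_lexicon(lex: LexiconTable, path: str | Path) -> None:
    df = pd.DataFrame(lex.records, columns=["variant", "meaning", "form", "cognate_class"])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Binary coding


def binarize(lex: LexiconTable) -> BinaryCharacterMatrix:
    """Code a lexicon as a taxa x cognate-class presence/absence matrix.

    One column per (meaning, class) pair, in meaning order then sorted class
    label order.  A cell is 1 if the variant has a record in that class, 0 if
    it has records for the meaning but none in that class, and missing if the
    variant has no record for the meaning at all.
    """
    characters: list[tuple[str, str]] = []
    for meaning in lex.meanings:
        characters.extend((meaning, cls) for cls in lex.classes_for(meaning))
    col_of = {mc: j for j, mc in enumerate(characters)}
    row_of = {t: i for i, t in enumerate(lex.variants)}
    meaning_cols: dict[str, list[int]] = {}
    for j, (meaning, _cls) in enumerate(characters):
        meaning_cols.setdefault(meaning, []).append(j)

    cells = np.full((len(lex.variants), len(characters)), MISSING, dtype=np.int8)
    # first pass: any variant with >=1 record for a meaning gets 0 across it
    has_meaning: set[tuple[str, str]] = {(r[0], r[1]) for r in lex.records}
    for variant, meaning in has_meaning:
        cells[row_of[variant], meaning_cols[meaning]] = 0
    for variant, meaning, _form, cls in lex.records:
        cells[row_of[variant], col_of[(meaning, cls)]] = 1
    return BinaryCharacterMatrix(list(lex.variants), characters, cells,
                                 {m: list(c) for m, c in meaning_cols.items()})


# ---------------------------------------------------------------------------
# Distances


def hamming_distance(m: BinaryCharacterMatrix) -> DistanceMatrix:
    """Normalized Hamming distance with pairwise deletion of missing cells."""
    if len(m.taxa) < 2:
        raise DataError("need at least 2 taxa")
    x = m.cells
    obs = m.observed()
    n = len(m.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            n_both = int(both.sum())
            if n_both == 0:
                raise DataError(
                    f"taxa {m.taxa[i]!r} and {m.taxa[j]!r} share no observed characters"
                )
            diff = int(np.sum(x[i, both] != x[j, both]))
            d[i, j] = d[j, i] = diff / n_both
    return DistanceMatrix(list(m.taxa), d)


def jaccard_distance(m: BinaryCharacterMatrix) -> DistanceMatrix:
    """Jaccard distance 1 - |A&B| / |A|B| over jointly observed columns.

    A pair whose jointly observed presence sets are both empty gets
    distance 0 with a warning (no shared signal to compare).
    """
    if len(m.taxa) < 2:
        raise DataError("need at least 2 taxa")
    x = m.cells
    obs = m.observed()
    n = len(m.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            a = x[i, both] == 1
            b = x[j, both] == 1
            union = int(np.sum(a | b))
            if union == 0:
                log.warning(
                    "taxa %r and %r have empty presence union; Jaccard set to 0",
                    m.taxa[i], m.taxa[j],
                )
                continue
            inter = int(np.sum(a & b))
            d[i, j] = d[j, i] = 1.0 - inter / union
    return DistanceMatrix(list(m.taxa), d)


# ---------------------------------------------------------------------------
# NEXUS characters block
#
# The writer emits a standard DATA block (symbols "01", missing "?") plus a
# CHARSTATELABELS list encoding the (meaning, class) identity of each column,
# which generic NEXUS readers do not model; the reader restores it so a
# write -> read round trip is the identity.

_SYMBOL = {0: "0", 1: "1", MISSING: "?"}
_VALUE = {"0": 0, "1": 1, "?": MISSING}


def write_nexus_characters(m: BinaryCharacterMatrix, path: str | Path) -> None:
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(m.taxa)} NCHAR={len(m.characters)};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "    CHARSTATELABELS",
    ]
    labels = [
        f"        {j + 1} '{meaning}::{cls}'" for j, (meaning, cls) in enumerate(m.characters)
    ]
    lines.append(",\n".join(labels) + ";")
    lines.append("    MATRIX")
    width = max(len(t) for t in m.taxa) + 2
    for i, taxon in enumerate(m.taxa):
        row = "".join(_SYMBOL[int(v)] for v in m.cells[i])
        lines.append(f"        '{taxon}'".ljust(width + 10) + row)
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_nexus_characters(path: str | Path) -> BinaryCharacterMatrix:
    text = Path(path).read_text()
    lines = text.splitlines()
    ntax = nchar = None
    characters: list[tuple[str, str]] = []
    taxa: list[str] = []
    rows: list[list[int]] = []
    mode = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        upper = line.upper()
        if upper.startswith("DIMENSIONS"):
            import re

            mt = re.search(r"NTAX\s*=\s*(\d+)", upper)
            mc = re.search(r"NCHAR\s*=\s*(\d+)", upper)
            if not mt or not mc:
                raise FormatError(f"line {lineno}: DIMENSIONS missing NTAX/NCHAR")
            ntax, nchar = int(mt.group(1)), int(mc.group(1))
        elif upper.startswith("CHARSTATELABELS"):
            mode = "labels"
        elif upper.startswith("MATRIX"):
            mode = "matrix"
        elif mode == "labels" and line:
            for item in line.rstrip(";").split(","):
                item = item.strip()
                if not item:
                    continue
                _idx, _, label = item.partition(" ")
                label = label.strip().strip("'")
                if "::" not in label:
                    raise FormatError(f"line {lineno}: character label {label!r} lacks '::'")
                meaning, _, cls = label.partition("::")
                characters.append((meaning, cls))
            if line.endswith(";"):
                mode = None
        elif mode == "matrix":
            if line == ";" or upper.startswith("END"):
                mode = None
                continue
            if not line:
                continue
            if line.startswith("'"):
                name, _, rest = line[1:].partition("'")
            else:
                name, _, rest = line.partition(" ")
            symbols = rest.strip().replace(" ", "")
            try:
                rows.append([_VALUE[ch] for ch in symbols])
            except KeyError as exc:
                raise FormatError(f"line {lineno}: bad state symbol {exc}") from exc
            taxa.append(name)
    if ntax is None:
        raise FormatError("no DIMENSIONS line found")
    if len(taxa) != ntax:
        raise FormatError(f"taxon count mismatch: DIMENSIONS NTAX={ntax}, found {len(taxa)}")
    for i, row in enumerate(rows):
        if len(row) != nchar:
            raise FormatError(f"taxon {taxa[i]!r}: {len(row)} states, expected NCHAR={nchar}")
    if characters and len(characters) != nchar:
        raise FormatError(f"{len(characters)} CHARSTATELABELS for NCHAR={nchar}")
    if not characters:  # fall back to anonymous single-partition characters
        characters = [("char", str(j + 1)) for j in range(nchar)]
    return BinaryCharacterMatrix(taxa, characters, np.array(rows, dtype=np.int8))
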