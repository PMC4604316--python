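"""Readers and writers for the external text formats.

Formats handled here:

* ortholog groups text (``cluster_id: genomeA|gene1 genomeB|gene2 ...``)
* TSV presence matrices (strains x features, cells 0/1 or configurable tokens)
* strain -> compartment label tables (two-column TSV)
* compound -> class maps (two-column TSV)
* aligned FASTA (via Biopython)

All writers emit plain text only and accept an optional ``#`` comment
header so that reports carry their provenance (tool version, seed,
thresholds).
"""

from __future__ import annotations

import os
from collections.abc import Mapping
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from ..consensus import Alignment
from ..errors import ParseError
from .types import (
    COMPARTMENTS,
    Cluster,
    ClusterSet,
    CompartmentLabels,
    MATRIX_KINDS,
    PresenceMatrix,
)

# Matrix kinds for which an all-zero feature column is meaningful
# (a compound no strain oxidizes, a reaction no model carries) rather
# than a loading error.
_EMPTY_FEATURES_OK = {"utilization", "prediction"}

DEFAULT_TRUE_TOKENS = ("1",)
DEFAULT_FALSE_TOKENS = ("0",)


# ---------------------------------------------------------------------------
# ortholog groups
# ---------------------------------------------------------------------------

def read_ortholog_groups(path) -> ClusterSet:
    """Parse an OrthoMCL-style groups file into a :class:`ClusterSet`.

    One cluster per line: ``cluster_id: genome|gene genome|gene ...``.
    The genome id is the token before the *first* ``|``; any further
    ``|`` characters belong to the gene id. File order is preserved.
    """
    clusters: list[Cluster] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError(
                    "expected 'cluster_id: members...' (no colon found)",
                    path=path, line=lineno,
                )
            cid, _, rest = line.partition(":")
            cid = cid.strip()
            if not cid:
                raise ParseError("empty cluster id", path=path, line=lineno)
            if cid in seen:
                raise ParseError(
                    f"duplicate cluster id {cid!r}", path=path, line=lineno
                )
            seen.add(cid)
            members = []
            for token in rest.split():
                if "|" not in token:
                    raise ParseError(
                        f"member {token!r} lacks the genome|gene separator",
                        path=path, line=lineno,
                    )
                genome, _, gene = token.partition("|")
                if not genome or not gene:
                    raise ParseError(
                        f"member {token!r} has an empty genome or gene id",
                        path=path, line=lineno,
                    )
                members.append((genome, gene))
            if not members:
                raise ParseError(
                    f"cluster {cid!r} has no members", path=path, line=lineno
                )
            try:
                clusters.append(Cluster(cid, frozenset(members)))
            except ValueError as exc:  # pragma: no cover - guarded above
                raise ParseError(str(exc), path=path, line=lineno) from exc
    try:
        return ClusterSet(tuple(clusters))
    except ValueError as exc:
        raise ParseError(str(exc), path=path) from exc


def write_ortholog_groups(clusters: ClusterSet, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for cl in clusters:
            members = " ".join(
                f"{g}|{gene}" for g, gene in sorted(cl.members)
            )
            fh.write(f"{cl.id}: {members}\n")


# ---------------------------------------------------------------------------
# presence matrices
# ---------------------------------------------------------------------------

def read_matrix(
    path,
    kind: str = "presence",
    true_tokens: Iterable[str] = DEFAULT_TRUE_TOKENS,
    false_tokens: Iterable[str] = DEFAULT_FALSE_TOKENS,
    allow_empty_features: bool | None = None,
) -> PresenceMatrix:
    """Read a strains x features TSV into a :class:`PresenceMatrix`.

    The first row holds feature ids (first cell is an ignored corner
    label), the first column strain ids. Cells must be one of the
    configured truthy/falsy tokens (default strict ``{0,1}``; pass e.g.
    ``true_tokens=("+",), false_tokens=("-",)`` for Biolog-style exports).

    ``allow_empty_features`` controls whether an all-zero feature column
    is accepted; by default it is for utilization/prediction matrices
    (a compound used by nobody is data) and rejected for trait/presence
    matrices (a feature absent everywhere is a loading mistake).
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    if allow_empty_features is None:
        allow_empty_features = kind in _EMPTY_FEATURES_OK
    tmap = {t: 1 for t in true_tokens}
    tmap.update({t: 0 for t in false_tokens})

    with open(path, "rt", encoding="utf-8") as fh:
        lines = [
            (i, ln.rstrip("\n"))
            for i, ln in enumerate(fh, start=1)
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines:
        raise ParseError("empty matrix file", path=path)

    header_lineno, header = lines[0]
    features = header.split("\t")[1:]
    if not features:
        raise ParseError("header row has no feature ids", path=path,
                         line=header_lineno)

    strains: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(features) + 1:
            raise ParseError(
                f"ragged row: expected {len(features) + 1} columns, "
                f"got {len(cells)}",
                path=path, line=lineno,
            )
        strain, *vals = cells
        row = []
        for col_idx, token in enumerate(vals):
            token = token.strip()
            if token not in tmap:
                raise ParseError(
                    f"non-binary cell {token!r} at strain {strain!r}, "
                    f"feature {features[col_idx]!r}",
                    path=path, line=lineno,
                )
            row.append(tmap[token])
        strains.append(strain)
        rows.append(row)
    if not rows:
        raise ParseError("matrix has a header but no strain rows", path=path)

    matrix = PresenceMatrix.from_arrays(strains, features, np.array(rows),
                                        kind=kind)
    if not allow_empty_features:
        empty = matrix.data.columns[matrix.data.sum(axis=0) == 0].tolist()
        if empty:
            raise ParseError(
                f"feature(s) absent from every strain: {empty}", path=path
            )
    return matrix


def write_matrix(matrix: PresenceMatrix, path, header: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("strain\t" + "\t".join(matrix.features) + "\n")
        for strain, row in zip(matrix.strains, matrix.values):
            fh.write(strain + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# labels / compound classes
# ---------------------------------------------------------------------------

def _read_two_columns(path, what: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise ParseError(
                    f"expected two tab-separated columns, got {len(cells)}",
                    path=path, line=lineno,
                )
            key, value = cells[0].strip(), cells[1].strip()
            if lineno == 1 and what == "compartment" and value not in COMPARTMENTS:
                continue  # tolerate a header row
            if key in out:
                raise ParseError(f"duplicate id {key!r}", path=path, line=lineno)
            out[key] = value
    if not out:
        raise ParseError(f"no {what} entries found", path=path)
    return out


def read_labels(path) -> CompartmentLabels:
    """Read a two-column TSV of ``strain<TAB>compartment``.

    A single header row is tolerated if its second column is not a valid
    compartment name.
    """
    mapping = _read_two_columns(path, "compartment")
    try:
        return CompartmentLabels(mapping)
    except ValueError as exc:
        raise ParseError(str(exc), path=path) from exc


def write_labels(labels: CompartmentLabels, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("strain\tcompartment\n")
        for strain, comp in labels.mapping.items():
            fh.write(f"{strain}\t{comp}\n")


def read_compound_classes(path) -> dict[str, str]:
    """Read a two-column TSV of ``compound<TAB>class_name``."""
    mapping = _read_two_columns(path, "compound class")
    # tolerate a header row such as "compound\tclass"
    first = next(iter(mapping))
    if first.lower() in {"compound", "compound_id"} and len(mapping) > 1:
        mapping.pop(first)
    return mapping


def write_compound_classes(classes: Mapping[str, str], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("compound\tclass\n")
        for compound, cls in classes.items():
            fh.write(f"{compound}\t{cls}\n")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_alignment(path) -> Alignment:
    """Read a pre-aligned FASTA file."""
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(os.fspath(path), "fasta")]
    if not records:
        raise ParseError("no FASTA records found", path=path)
    try:
        return Alignment.from_records(records)
    except ValueError as exc:
        raise ParseError(str(exc), path=path) from exc


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, header: str | None = None,
                float_format: str = "%.6g") -> None:
    """Write a report DataFrame as TSV with an optional ``#`` header line."""
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format,
                  lineterminator="\n")
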