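"""Readers and writers for the pipeline's plain-text file shapes.

Dialects:

* pairs — 2-column TSV ``(lncRNA, partner)`` (ontology files are
  ``(parent, child)``), optional header;
* matrix — square labelled TSV (first column = row labels, header =
  column labels), or 3-column long form ``(A, B, value)``;
* GMT — ``set_name<TAB>description<TAB>member...`` per line;
* list — one symbol per line, ``#`` comments and blank lines ignored;
* embedding — TSV with a label column plus ``d`` numeric columns.

Everything the pipeline writes is sorted deterministically and reads
back to an identical in-memory object.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .dag_semantics import DiseaseOntology, DSSMatrix, load_ontology
from .lnc_similarity import AssociationTable, ExpressionMatrix, SimilarityMatrix
from .sdne import EmbeddingMatrix
from .fusion_rwr import AssocNetwork, ExpansionResult
from .enrichment import EnrichmentRow, GeneSetLibrary, rows_to_frame


class FormatError(ValueError):
    pass


def _open_lines(path: str) -> list[str]:
    with open(path, encoding="utf-8", newline=None) as fh:  # universal newlines
        return [line.rstrip("\r\n") for line in fh]


# -- pair / list files --------------------------------------------------------

def read_pairs(path: str, header: bool | None = None) -> list[tuple[str, str]]:
    """2-column TSV of pairs; header auto-detected unless forced."""
    rows = []
    for i, line in enumerate(_open_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{i}: expected 2 tab-separated columns, "
                              f"got {len(parts)}")
        rows.append((parts[0].strip(), parts[1].strip()))
    if rows and (header or (header is None and rows[0][0].lower() in
                            ("parent", "lncrna", "source", "from"))):
        rows = rows[1:]
    return rows


def write_pairs(path: str, pairs: Iterable[tuple[str, str]],
                header: tuple[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def read_list(path: str) -> list[str]:
    """One symbol per line; '#' comments and blanks skipped; order kept, deduped."""
    seen, out = set(), []
    for line in _open_lines(path):
        symbol = line.split("#")[0].strip()
        if symbol and symbol not in seen:
            seen.add(symbol)
            out.append(symbol)
    return out


def write_list(path: str, symbols: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in symbols:
            fh.write(f"{s}\n")


# -- matrices -----------------------------------------------------------------

def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_matrix_frame(path: str) -> pd.DataFrame:
    """Square labelled TSV; also accepts 3-column long form (A, B, value).

    Long form is recognised when every data line has exactly 3 fields
    whose third field is numeric and whose first two are not; the square
    form requires row labels to equal column labels.
    """
    lines = [l for l in _open_lines(path) if l.strip()]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    widths = {len(l.split("\t")) for l in lines}
    if len(widths) > 1 and not (len(widths) == 2 and
                                len(lines[0].split("\t")) == min(widths)):
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")

    data_lines = lines
    body = [l.split("\t") for l in data_lines]
    looks_long = (widths == {3}
                  and all(_is_float(r[2]) for r in body[1:])
                  and not any(_is_float(r[0]) or _is_float(r[1]) for r in body[1:]))
    if looks_long and not _is_float(body[0][2]):
        body = body[1:]  # header row on a long-form file
    if looks_long:
        labels = sorted({r[0] for r in body} | {r[1] for r in body})
        wide = pd.DataFrame(np.zeros((len(labels), len(labels))),
                            index=labels, columns=labels)
        for a, b, v in body:
            wide.loc[a, b] = float(v)
            wide.loc[b, a] = float(v)
        np.fill_diagonal(wide.values, 1.0)
        return wide

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate row or column labels")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ (not a square "
                          "labelled matrix)")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values) | np.isnan(values)):
        raise FormatError(f"{path}: non-numeric or infinite cells")
    return df


def read_similarity(path: str, value_range: tuple[float, float] = (0.0, 1.0)
                    ) -> SimilarityMatrix:
    df = read_matrix_frame(path)
    return SimilarityMatrix(labels=list(df.index), values=df.to_numpy(dtype=float),
                            range=value_range)


def write_matrix(path: str, labels: list[str], values: np.ndarray) -> None:
    order = np.argsort(np.asarray(labels, dtype=object))
    sorted_labels = [labels[i] for i in order]
    df = pd.DataFrame(np.asarray(values, dtype=float)[np.ix_(order, order)],
                      index=sorted_labels, columns=sorted_labels)
    df.to_csv(path, sep="\t", float_format="%.12g")


def write_matrix_long(path: str, labels: list[str], values: np.ndarray,
                      header: tuple[str, str, str] = ("a", "b", "value")) -> None:
    """Upper-triangle long form (A, B, value), sorted by label pair."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(np.asarray(labels, dtype=object))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for ii, i in enumerate(order):
            for j in order[ii + 1:]:
                fh.write(f"{labels[i]}\t{labels[j]}\t{values[i, j]:.12g}\n")


def read_network(path: str) -> AssocNetwork:
    df = read_matrix_frame(path)
    w = df.to_numpy(dtype=float)
    np.fill_diagonal(w, 0.0)
    return AssocNetwork(nodes=list(df.index), edge_weights=w)


def read_expression(path: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).all(axis=1).any():
        raise FormatError(f"{path}: all-missing expression rows")
    return ExpressionMatrix(lncrnas=list(df.index), tissues=[str(c) for c in df.columns],
                            values=values)


def write_expression(path: str, expr: ExpressionMatrix) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format="%.12g")


# -- embeddings ---------------------------------------------------------------

def read_embedding(path: str) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate embedding labels")
    return EmbeddingMatrix(labels=list(df.index), vectors=df.to_numpy(dtype=float))


def write_embedding(path: str, emb: EmbeddingMatrix) -> None:
    df = pd.DataFrame(emb.vectors, index=emb.labels,
                      columns=[f"dim{i + 1}" for i in range(emb.dim)])
    df.sort_index().to_csv(path, sep="\t", float_format="%.12g")


# -- GMT ----------------------------------------------------------------------

def read_gmt(path: str, universe: Iterable[str] | None = None) -> GeneSetLibrary:
    sets: dict[str, frozenset[str]] = {}
    for i, line in enumerate(_open_lines(path), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: GMT line needs name, description and "
                              "at least one member")
        name = parts[0].strip()
        if name in sets:
            raise FormatError(f"{path}:{i}: duplicate set name {name!r}")
        members = frozenset(p.strip() for p in parts[2:] if p.strip())
        if not members:
            raise FormatError(f"{path}:{i}: set {name!r} has no members")
        sets[name] = members
    return GeneSetLibrary(sets=sets,
                          universe=frozenset(universe) if universe else frozenset())


def write_gmt(path: str, library: GeneSetLibrary,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(library.sets):
            desc = descriptions.get(name, "")
            members = "\t".join(sorted(library.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# -- reports ------------------------------------------------------------------

def write_report(path: str, rows: Iterable[EnrichmentRow]) -> None:
    df = rows_to_frame(list(rows))
    if len(df):
        df = df.sort_values(["p_value", "set_name"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_expansion(path: str, result: ExpansionResult) -> None:
    nodes = sorted(set(result.probabilities) | set(result.seeds_used))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lncRNA\tprobability\tis_seed\n")
        for node in nodes:
            p = result.probabilities.get(node, 0.0)
            fh.write(f"{node}\t{p:.12g}\t{int(node in set(result.seeds_used))}\n")


def read_ontology(path: str) -> DiseaseOntology:
    return load_ontology(read_pairs(path))


def read_associations(path: str) -> AssociationTable:
    return AssociationTable.from_pairs(read_pairs(path))
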