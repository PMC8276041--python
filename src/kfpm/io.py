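"""Typed input/output layer.

Reads the six plain-text tables the pipeline consumes (PPI edge list,
protein-domain annotation, gene-expression matrix, orthology counts,
subcellular localisation, essential reference list) and writes rankings.
All downstream modules operate only on the typed containers defined here.

Conventions: UTF-8 TSV/whitespace-separated files, lines starting with '#'
are comments, protein and domain order is first-appearance order in the
source file. Proteins that occur only in auxiliary tables are retained at
read time; restriction to the PPI node set happens downstream.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .config import InputFormatError

logger = logging.getLogger("kfpm")

#: Decimal places used when writing scores to ranking files.
SCORE_DECIMALS = 6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PPIGraph:
    """Undirected protein-protein interaction network.

    ``proteins`` is the node order used by every matrix in the pipeline;
    ``edges`` holds unordered pairs stored as index tuples (i, j) with i < j.
    No self-loops, no duplicates.
    """

    proteins: list[str]
    edges: set[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("duplicate protein IDs in node list")
        n = len(self.proteins)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references unknown node")
            if i > j:
                raise ValueError("edges must be stored with i < j")

    @property
    def n(self) -> int:
        return len(self.proteins)

    @property
    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.proteins)}

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency matrix (zero diagonal)."""
        if not self.edges:
            return sp.csr_matrix((self.n, self.n))
        rows, cols = zip(*self.edges)
        rows, cols = np.array(rows), np.array(cols)
        data = np.ones(len(rows))
        a = sp.coo_matrix((data, (rows, cols)), shape=(self.n, self.n))
        return (a + a.T).tocsr()

    def neighbor_sets(self) -> list[set[int]]:
        out: list[set[int]] = [set() for _ in range(self.n)]
        for i, j in self.edges:
            out[i].add(j)
            out[j].add(i)
        return out

    def edge_ids(self) -> set[frozenset[str]]:
        return {frozenset((self.proteins[i], self.proteins[j]))
                for i, j in self.edges}


@dataclasses.dataclass
class DomainAnnotation:
    """Protein-to-domain membership (Pfam-style)."""

    domains: list[str]
    membership: set[tuple[str, str]]  # (protein ID, domain ID)

    def __post_init__(self) -> None:
        if len(set(self.domains)) != len(self.domains):
            raise ValueError("duplicate domain IDs")
        known = set(self.domains)
        for _, d in self.membership:
            if d not in known:
                raise ValueError(f"membership references unlisted domain {d!r}")

    @property
    def m(self) -> int:
        return len(self.domains)


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene-expression profiles keyed by protein ID; equal-length rows."""

    profiles: dict[str, np.ndarray]
    length: int

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("expression profiles need length >= 2")
        for p, v in self.profiles.items():
            if v.shape != (self.length,):
                raise ValueError(f"profile for {p!r} has wrong length")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite expression value for {p!r}")


@dataclasses.dataclass
class OrthologyTable:
    """Per-protein orthology counts (number of reference organisms in which
    an ortholog was found, InParanoid-style); non-negative."""

    counts: dict[str, float]

    def __post_init__(self) -> None:
        for p, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative orthology count for {p!r}")


@dataclasses.dataclass
class SubcellTable:
    """Subcellular localisation labels per protein plus the label universe."""

    localizations: dict[str, set[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("label universe must be non-empty")
        known = set(self.universe)
        for p, labels in self.localizations.items():
            if not labels <= known:
                raise ValueError(f"unknown localisation label for {p!r}")

    @property
    def n_sub(self) -> int:
        return len(self.universe)


@dataclasses.dataclass
class EssentialSet:
    """Reference set of essential protein IDs (evaluation only)."""

    proteins: set[str]

    def __contains__(self, p: str) -> bool:
        return p in self.proteins

    def __len__(self) -> int:
        return len(self.proteins)


@dataclasses.dataclass
class RankedList:
    """Proteins in final ranking order (score descending, ID ascending on
    ties) with their scores and, optionally, essentiality labels."""

    proteins: list[str]
    scores: np.ndarray
    essential: np.ndarray | None = None  # boolean, aligned with proteins

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.proteins) != len(self.scores):
            raise ValueError("proteins and scores length mismatch")
        if self.essential is not None:
            self.essential = np.asarray(self.essential, dtype=bool)
            if len(self.essential) != len(self.proteins):
                raise ValueError("labels must cover every entry")
        for k in range(len(self.proteins) - 1):
            a, b = self.scores[k], self.scores[k + 1]
            if a < b or (a == b and self.proteins[k] >= self.proteins[k + 1]):
                raise ValueError("entries not ordered by (score desc, ID asc)")

    def __len__(self) -> int:
        return len(self.proteins)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, whitespace-split fields), skipping blank
    lines and '#' comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def _two_columns(path: str | Path, what: str) -> Iterable[tuple[int, str, str]]:
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise InputFormatError(
                f"{path}: line {lineno}: expected two {what} fields, "
                f"got {len(fields)}")
        yield lineno, fields[0], fields[1]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_ppi(path: str | Path, directed_input: bool = False) -> PPIGraph:
    """Read a two-column interaction file into a :class:`PPIGraph`.

    Each line names one interaction; pairs are treated as unordered, so a
    reciprocal listing (``a b`` and ``b a``) collapses to one edge.
    Self-loops are dropped (with a logged count). Node order is
    first-appearance order. ``directed_input`` only affects logging: when
    True, reciprocal duplicates are expected and not reported.
    """
    proteins: list[str] = []
    index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    n_self = 0
    n_dup = 0

    def _get(p: str) -> int:
        if p not in index:
            index[p] = len(proteins)
            proteins.append(p)
        return index[p]

    saw_line = False
    for lineno, a, b in _two_columns(path, "protein"):
        saw_line = True
        ia, ib = _get(a), _get(b)
        if ia == ib:
            n_self += 1
            continue
        e = (ia, ib) if ia < ib else (ib, ia)
        if e in edges:
            n_dup += 1
        edges.add(e)
    if not saw_line:
        raise InputFormatError(f"{path}: no interaction lines found")
    if n_self:
        logger.info("read_ppi: dropped %d self-loop line(s)", n_self)
    if n_dup and not directed_input:
        logger.info("read_ppi: merged %d duplicate interaction line(s)", n_dup)
    return PPIGraph(proteins=proteins, edges=edges)


def read_domains(path: str | Path) -> DomainAnnotation:
    """Read a two-column (protein, domain) annotation file."""
    domains: list[str] = []
    seen: set[str] = set()
    membership: set[tuple[str, str]] = set()
    for _, p, d in _two_columns(path, "annotation"):
        if d not in seen:
            seen.add(d)
            domains.append(d)
        membership.add((p, d))
    return DomainAnnotation(domains=domains, membership=membership)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene-expression matrix: protein ID followed by a fixed-length
    numeric profile. Ragged rows are an error."""
    profiles: dict[str, np.ndarray] = {}
    length: int | None = None
    n_dup = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise InputFormatError(
                f"{path}: line {lineno}: expression rows need an ID plus at "
                f"least 2 values")
        pid = fields[0]
        try:
            vec = np.array([float(x) for x in fields[1:]], dtype=float)
        except ValueError as exc:
            raise InputFormatError(
                f"{path}: line {lineno}: non-numeric expression value "
                f"({exc})") from None
        if length is None:
            length = len(vec)
        elif len(vec) != length:
            raise InputFormatError(
                f"{path}: line {lineno}: profile length {len(vec)} differs "
                f"from {length}")
        if pid in profiles:
            n_dup += 1
            continue  # keep first occurrence
        profiles[pid] = vec
    if length is None:
        raise InputFormatError(f"{path}: no expression rows found")
    if n_dup:
        logger.info("read_expression: ignored %d duplicate row(s)", n_dup)
    return ExpressionMatrix(profiles=profiles, length=length)


def read_orthology(path: str | Path) -> OrthologyTable:
    """Read (protein, count) orthology scores; counts must be >= 0."""
    counts: dict[str, float] = {}
    for lineno, p, v in _two_columns(path, "orthology"):
        try:
            val = float(v)
        except ValueError:
            raise InputFormatError(
                f"{path}: line {lineno}: non-numeric orthology value "
                f"{v!r}") from None
        if val < 0:
            raise InputFormatError(
                f"{path}: line {lineno}: negative orthology value {val}")
        counts[p] = val
    return OrthologyTable(counts=counts)


def read_subcellular(path: str | Path,
                     universe: Sequence[str] | None = None) -> SubcellTable:
    """Read (protein, localisation label) pairs. The label universe is the
    set of labels seen, in first-appearance order, unless supplied."""
    localizations: dict[str, set[str]] = {}
    seen_order: list[str] = []
    seen: set[str] = set()
    for _, p, lab in _two_columns(path, "localisation"):
        localizations.setdefault(p, set()).add(lab)
        if lab not in seen:
            seen.add(lab)
            seen_order.append(lab)
    uni = list(universe) if universe is not None else seen_order
    if not uni:
        raise InputFormatError(f"{path}: no localisation lines found")
    return SubcellTable(localizations=localizations, universe=uni)


def read_essential(path: str | Path) -> EssentialSet:
    """Read one essential-protein ID per line (duplicates collapse)."""
    ids: set[str] = set()
    for _, fields in _data_lines(path):
        ids.add(fields[0])
    return EssentialSet(proteins=ids)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_ppi(g: PPIGraph, path: str | Path) -> None:
    """Write the edge list back out (one unordered pair per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in sorted(g.edges):
            fh.write(f"{g.proteins[i]}\t{g.proteins[j]}\n")


def write_ranking(ranked: RankedList, path: str | Path) -> None:
    """Write a ranking as TSV: rank (1-based), protein, score, and an
    ``essential`` 0/1 column when labels are attached. Scores are printed
    with :data:`SCORE_DECIMALS` decimals."""
    if len(ranked) == 0:
        raise ValueError("refusing to write an empty ranking")
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["rank", "protein", "score"]
        if ranked.essential is not None:
            cols.append("essential")
        fh.write("#" + "\t".join(cols) + "\n")
        for k, (p, s) in enumerate(zip(ranked.proteins, ranked.scores), 1):
            row = [str(k), p, f"{s:.{SCORE_DECIMALS}f}"]
            if ranked.essential is not None:
                row.append(str(int(ranked.essential[k - 1])))
            fh.write("\t".join(row) + "\n")


def read_ranking(path: str | Path) -> RankedList:
    """Read a ranking file written by :func:`write_ranking` (or any TSV with
    columns rank, protein, score[, essential]).

    Scores that became equal at the printed precision are re-ordered by the
    canonical tie rule (protein ID ascending); all other entries keep their
    file order.
    """
    proteins: list[str] = []
    scores: list[float] = []
    flags: list[bool] = []
    has_flags = False
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise InputFormatError(
                f"{path}: line {lineno}: ranking rows need rank, protein, "
                f"score")
        proteins.append(fields[1])
        scores.append(float(fields[2]))
        if len(fields) >= 4:
            has_flags = True
            flags.append(bool(int(fields[3])))
    if not proteins:
        raise InputFormatError(f"{path}: empty ranking file")
    arr = np.array(scores)
    order = sorted(range(len(proteins)),
                   key=lambda i: (-arr[i], proteins[i]))
    return RankedList(
        proteins=[proteins[i] for i in order], scores=arr[order],
        essential=np.array([flags[i] for i in order]) if has_flags else None)
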