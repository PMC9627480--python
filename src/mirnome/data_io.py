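"""Readers and writers for the four tabular input formats and the result artifacts.

The pipeline consumes four local tables:

* a miRNA → target table (miRDB-style) with a 0–100 prediction score,
* a gene–gene interaction table (STRING-style) with a combined confidence,
* a term → gene annotation table (flat two-column TSV or GAF 2.x),
* a gene → knockout-phenotype table (IMPC-style).

Filtering thresholds are applied at read time with the conventions used
throughout the package: the target score is filtered with a *strict* ``>``
(pairs scoring exactly the cutoff are dropped), the interaction confidence
with ``>=`` by default. Interaction confidences are dialect-normalized: the
interaction-database ecosystem exports both 0–1 reals and 0–1000 integers,
and any value above 1 in the column switches the whole column to the
0–1000 reading.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields, is_dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("mirnome")

PHENOTYPE_CATEGORIES = frozenset({"reproductive_system", "embryo", "other"})


class FormatError(ValueError):
    """Raised when an input table violates the expected format."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetRecord:
    """One miRNA → gene prediction with its target score (0–100)."""

    mirna_id: str
    gene_id: str
    score: float


@dataclass(frozen=True)
class InteractionRecord:
    """One gene–gene functional association with a combined confidence in [0, 1]."""

    gene_a: str
    gene_b: str
    confidence: float


@dataclass
class AnnotationSet:
    """Flat term → gene-set map (no ontology-graph propagation).

    ``terms`` maps a term id to the set of annotated gene ids; ``names``
    optionally carries human-readable term names.
    """

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"annotation term {term!r} has an empty gene set")

    def genes(self) -> frozenset[str]:
        """Union of all annotated genes."""
        out: set[str] = set()
        for g in self.terms.values():
            out |= g
        return frozenset(out)


@dataclass(frozen=True)
class PhenotypeRecord:
    """One knockout-phenotype observation for a gene.

    ``category`` is drawn from the closed set {reproductive_system, embryo,
    other}; free-text disease/notes columns are carried opaquely.
    """

    gene_id: str
    phenotype_term: str
    category: str = "other"
    accession: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if self.category not in PHENOTYPE_CATEGORIES:
            raise ValueError(f"unknown phenotype category {self.category!r}")
        if not self.gene_id:
            raise ValueError("empty gene_id in phenotype record")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention)."""
    if x != x or math.isinf(x):  # NaN / inf pass through
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file with no header") from None
    return df


def _resolve_columns(
    df: pd.DataFrame, columns: Sequence[str] | None, n_required: int, path: Path | str
) -> list[str]:
    """Pick column names: explicit ``columns`` if given, else positional."""
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: line 1: missing column(s) {missing}; found {list(df.columns)}"
            )
        return list(columns)
    if len(df.columns) < n_required:
        raise FormatError(
            f"{path}: line 1: expected at least {n_required} columns, "
            f"found {len(df.columns)}"
        )
    return list(df.columns[:n_required])


def _numeric_column(df: pd.DataFrame, col: str, path: str | Path) -> pd.Series:
    values = pd.to_numeric(df[col].str.strip(), errors="coerce")
    bad = values.index[values.isna() & df[col].notna()]
    if len(bad):
        # +2: one for the header line, one for 0-based index
        raise FormatError(f"{path}: line {bad[0] + 2}: unparseable number {df[col][bad[0]]!r}")
    if values.isna().any():
        i = int(values.index[values.isna()][0])
        raise FormatError(f"{path}: line {i + 2}: missing numeric value")
    return values


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_target_table(
    path: str | Path,
    min_score: float = 90.0,
    columns: Sequence[str] | None = None,
) -> list[TargetRecord]:
    """Read a miRNA→target table, keeping pairs with score strictly > ``min_score``.

    Input order is preserved and duplicate (miRNA, gene) pairs are kept —
    deduplication is a network-build concern.
    """
    df = _read_tsv(path)
    mirna_c, gene_c, score_c = _resolve_columns(df, columns, 3, path)
    if df.empty:
        logger.warning("%s: empty target table (header only)", path)
        return []
    scores = _numeric_column(df, score_c, path)
    records: list[TargetRecord] = []
    for i in df.index:
        score = float(scores[i])
        if not 0.0 <= score <= 100.0:
            raise FormatError(f"{path}: line {i + 2}: target score {score} outside [0, 100]")
        if score > min_score:
            mirna = str(df[mirna_c][i]).strip()
            gene = str(df[gene_c][i]).strip()
            if not mirna or not gene:
                raise FormatError(f"{path}: line {i + 2}: empty identifier")
            records.append(TargetRecord(mirna, gene, score))
    return records


def normalize_confidences(values: Sequence[float]) -> list[float]:
    """Normalize a confidence column to [0, 1], auto-detecting the dialect.

    Any value > 1 switches the whole column to the 0–1000 integer reading
    (divide by 1000). Idempotent on an already-[0, 1] column.
    """
    vals = [float(v) for v in values]
    if any(v < 0 for v in vals):
        raise FormatError("negative confidence score")
    if any(v > 1 for v in vals):
        vals = [v / 1000.0 for v in vals]
    if any(not 0.0 <= v <= 1.0 for v in vals):
        raise FormatError("confidence column mixes 0–1 and 0–1000 dialects")
    return vals


def read_interaction_table(
    path: str | Path,
    min_confidence: float = 0.700,
    columns: Sequence[str] | None = None,
    strict: bool = False,
) -> list[InteractionRecord]:
    """Read a gene–gene interaction table filtered at ``min_confidence``.

    Confidences are dialect-normalized to [0, 1] first. Duplicate unordered
    pairs (case-insensitive) are collapsed keeping the maximum confidence
    *before* the threshold is applied. The cutoff is inclusive (``>=``) by
    default; ``strict=True`` switches to ``>``.
    """
    df = _read_tsv(path)
    a_c, b_c, conf_c = _resolve_columns(df, columns, 3, path)
    if df.empty:
        return []
    raw = _numeric_column(df, conf_c, path)
    confs = normalize_confidences(list(raw))
    best: dict[tuple[str, str], InteractionRecord] = {}
    order: list[tuple[str, str]] = []
    for i, conf in zip(df.index, confs):
        a = str(df[a_c][i]).strip()
        b = str(df[b_c][i]).strip()
        if not a or not b:
            raise FormatError(f"{path}: line {i + 2}: empty identifier")
        key = tuple(sorted((a.casefold(), b.casefold())))
        prev = best.get(key)
        if prev is None:
            best[key] = InteractionRecord(a, b, conf)
            order.append(key)
        elif conf > prev.confidence:
            best[key] = InteractionRecord(prev.gene_a, prev.gene_b, conf)
    keep = (lambda c: c > min_confidence) if strict else (lambda c: c >= min_confidence)
    return [best[k] for k in order if keep(best[k].confidence)]


def read_annotation_table(
    path: str | Path, columns: Sequence[str] | None = None
) -> AnnotationSet:
    """Read term→gene annotations from a two-column TSV or a GAF 2.x file.

    GAF detection: comment lines starting with ``!`` or data lines with 15+
    tab-separated fields; the gene symbol is taken from GAF column 3 and the
    term id from column 5.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation table not found: {path}")
    text_lines = path.read_text().splitlines()
    data_lines = [ln for ln in text_lines if ln.strip() and not ln.startswith("!")]
    is_gaf = any(ln.startswith("!") for ln in text_lines) or (
        data_lines and len(data_lines[0].split("\t")) >= 15
    )
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    if is_gaf:
        for ln in data_lines:
            parts = ln.split("\t")
            if len(parts) < 5:
                continue
            gene, term = parts[2].strip(), parts[4].strip()
            if gene and term:
                terms.setdefault(term, set()).add(gene)
    else:
        df = _read_tsv(path)
        term_c, gene_c = _resolve_columns(df, columns, 2, path)
        name_c = df.columns[2] if columns is None and len(df.columns) > 2 else None
        for i in df.index:
            term = str(df[term_c][i]).strip()
            gene = str(df[gene_c][i]).strip()
            if not term or not gene:
                continue
            terms.setdefault(term, set()).add(gene)
            if name_c is not None and pd.notna(df[name_c][i]):
                names.setdefault(term, str(df[name_c][i]).strip())
    if not terms:
        raise FormatError(f"{path}: no parseable annotation rows")
    return AnnotationSet({t: frozenset(g) for t, g in terms.items()}, names)


_PHENO_GENE_NAMES = ("gene", "gene_id", "gene_symbol", "symbol", "marker_symbol")
_PHENO_TERM_NAMES = ("phenotype", "phenotype_term", "term", "mp_term", "phenotype_name")


def read_phenotype_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[PhenotypeRecord]:
    """Read an IMPC-style gene→phenotype table.

    Columns are located by name (case-insensitive); ``category``, ``accession``
    and ``notes`` are optional. Records without a category default to
    ``other`` (a keyword classifier fills categories downstream).
    """
    df = _read_tsv(path)
    lower = {c.lower(): c for c in df.columns}

    def find(key: str, candidates: Iterable[str]) -> str | None:
        if columns and key in columns:
            if columns[key] not in df.columns:
                raise FormatError(f"{path}: line 1: missing column {columns[key]!r}")
            return columns[key]
        for cand in candidates:
            if cand in lower:
                return lower[cand]
        return None

    gene_c = find("gene", _PHENO_GENE_NAMES)
    if gene_c is None:
        raise FormatError(f"{path}: line 1: no gene column among {list(df.columns)}")
    term_c = find("phenotype", _PHENO_TERM_NAMES)
    if term_c is None:
        raise FormatError(f"{path}: line 1: no phenotype column among {list(df.columns)}")
    cat_c = find("category", ("category",))
    acc_c = find("accession", ("accession", "mgi", "mgi_accession"))
    notes_c = find("notes", ("notes", "disease", "human_disease"))

    records: list[PhenotypeRecord] = []
    for i in df.index:
        gene = str(df[gene_c][i]).strip()
        if not gene:
            raise FormatError(f"{path}: line {i + 2}: empty gene id")
        category = "other"
        if cat_c is not None and pd.notna(df[cat_c][i]):
            category = str(df[cat_c][i]).strip().lower().replace(" ", "_")
            if category not in PHENOTYPE_CATEGORIES:
                raise FormatError(
                    f"{path}: line {i + 2}: unknown phenotype category {category!r}"
                )
        records.append(
            PhenotypeRecord(
                gene_id=gene,
                phenotype_term=str(df[term_c][i]).strip() if pd.notna(df[term_c][i]) else "",
                category=category,
                accession=str(df[acc_c][i]).strip() if acc_c and pd.notna(df[acc_c][i]) else "",
                notes=str(df[notes_c][i]).strip() if notes_c and pd.notna(df[notes_c][i]) else "",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Network writers / readers
# ---------------------------------------------------------------------------


def write_network(network, path: str | Path, format: str = "edge_list") -> None:
    """Write a gene network as an edge-list TSV or GraphML.

    The edge-list dialect carries a ``#node`` section so isolated nodes
    survive the round trip; GraphML preserves them natively.
    """
    path = Path(path)
    g = network.graph
    if format == "edge_list":
        with path.open("w") as fh:
            fh.write(f"#label\t{network.label}\n")
            for node in sorted(g.nodes):
                fh.write(f"#node\t{node}\n")
            fh.write("gene_a\tgene_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in g.edges):
                fh.write(f"{a}\t{b}\n")
    elif format == "graphml":
        out = nx.Graph()
        out.add_nodes_from(g.nodes)
        out.add_edges_from(g.edges)
        for node in out.nodes:
            mirnas = network.provenance.get(node, frozenset())
            if mirnas:
                out.nodes[node]["mirnas"] = ";".join(sorted(mirnas))
        out.graph["label"] = network.label
        nx.write_graphml(out, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "edge_list"):
    """Read a network written by :func:`write_network` (round-trip safe)."""
    from .network_build import GeneNetwork  # local import avoids a cycle

    path = Path(path)
    if format == "edge_list":
        g = nx.Graph()
        label = "network"
        with path.open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#label\t"):
                    label = line.split("\t", 1)[1]
                elif line.startswith("#node\t"):
                    g.add_node(line.split("\t", 1)[1])
                elif line and line != "gene_a\tgene_b":
                    a, b = line.split("\t")[:2]
                    g.add_edge(a, b)
        return GeneNetwork(graph=g, provenance={}, label=label)
    if format == "graphml":
        raw = nx.read_graphml(path)
        g = nx.Graph()
        provenance: dict[str, frozenset[str]] = {}
        for node, attrs in raw.nodes(data=True):
            g.add_node(str(node))
            if attrs.get("mirnas"):
                provenance[str(node)] = frozenset(attrs["mirnas"].split(";"))
        g.add_edges_from((str(a), str(b)) for a, b in raw.edges)
        return GeneNetwork(
            graph=g, provenance=provenance, label=raw.graph.get("label", "network")
        )
    raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def _report_to_dict(report) -> dict:
    if is_dataclass(report) and not isinstance(report, type):
        d = asdict(report)
    elif isinstance(report, Mapping):
        d = dict(report)
    else:
        raise TypeError(f"cannot serialize report of type {type(report)!r}")
    display = {
        k: f"{round_half_up(v, 3):.3f}"
        for k, v in d.items()
        if isinstance(v, float) and v == v and not math.isinf(v)
    }
    d["display"] = display
    return d


def write_report(
    report, path: str | Path, format: str = "json", columns: Sequence[str] | None = None
) -> None:
    """Serialize a report (dataclass or list of row dataclasses) to JSON or TSV.

    Float fields are written at full precision; JSON additionally carries a
    ``display`` block rounded half-up at 3 decimals, the rendering used in
    the topology tables.
    """
    path = Path(path)

    def default(o):
        if isinstance(o, (frozenset, set)):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)!r}")

    if format == "json":
        if isinstance(report, (list, tuple)):
            payload = [_report_to_dict(r) for r in report]
        else:
            payload = _report_to_dict(report)
        path.write_text(json.dumps(payload, indent=2, default=default) + "\n")
    elif format == "tsv":
        rows = list(report) if isinstance(report, (list, tuple)) else [report]
        if columns is not None:
            cols = list(columns)
        elif rows:
            cols = [f.name for f in fields(rows[0])]
        else:
            raise ValueError("columns required to write an empty TSV report")
        with path.open("w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                vals = []
                for c in cols:
                    v = getattr(row, c)
                    if isinstance(v, (frozenset, set, list, tuple)):
                        v = ";".join(str(x) for x in sorted(v))
                    vals.append(str(v))
                fh.write("\t".join(vals) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
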