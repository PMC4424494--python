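"""Curated interaction records and node descriptors.

The curated model is a table of directed, typed interactions between named
molecular species.  Node names carry a compartment suffix (``_kerat`` for
keratinocyte, ``_melan`` for melanocyte); protein complexes list their
members separated by colons (e.g. ``RAC1:PARD6A:CDC42_melan``); the
environmental triggers (UV, UVA, UVB) and the phenotypic end processes
(melanogenesis, dendrite formation, melanosome phagocytosis, ...) are
ordinary nodes of the same graph.
"""

from __future__ import annotations

import csv
import io as _io
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

__all__ = [
    "INTERACTION_VOCABULARY",
    "InteractionRecord",
    "NodeDescriptor",
    "ParserOptions",
    "SchemaError",
    "canonical_interaction_type",
    "classify_node",
    "normalise_name",
    "parse_interaction_table",
]

#: Controlled vocabulary of interaction types, canonical lower-case form.
INTERACTION_VOCABULARY: frozenset[str] = frozenset(
    {
        "activates",
        "inhibits",
        "induces",
        "increases level",
        "increases expression",
        "decreases level",
        "decreases expression",
        "third molecule regulation",
    }
)

#: Environmental trigger names (no compartment suffix).
ENVIRONMENTAL_FACTORS: frozenset[str] = frozenset({"UV", "UVA", "UVB"})

#: Base names (compartment suffix stripped) recognised as biological end
#: processes, i.e. phenotypic destinations where signal flow terminates.
PROCESS_BASE_NAMES: frozenset[str] = frozenset(
    {
        "Eumelanin",
        "Pheomelanin",
        "Dendrite_formation",
        "Melanosome_phagocytosis",
        "Apoptosis",
        "Cell_proliferation",
        "Melanosome_biogenesis",
        "Cell_survival",
        "Cell_cycle_arrest",
        "melanogenesis",
        "Melanogensis",  # spelling as printed in the curated tables
    }
)

#: Name suffixes that mark a node as a biological process.
PROCESS_SUFFIXES: tuple[str, ...] = ("_formation", "_phagocytosis", "_biogenesis")

MANDATORY_COLUMNS = ("Node A", "Node B", "Interaction type A->B")

_WS_RUN = re.compile(r"\s+")
# tolerate the typographic variants "A->B", "A- > B", "A - > B" in headers
_ARROW_NORM = re.compile(r"\s*-\s*>\s*")


class SchemaError(ValueError):
    """The input table does not conform to the interaction-table schema."""


def normalise_name(raw: str) -> str:
    """Canonicalise a node name: trim, collapse whitespace runs to ``_``.

    Case is preserved — node identity is case-significant (``MC1R_kerat``
    and ``MC1R_melan`` name the same receptor in different cells, and
    ``TYR_melan`` / ``Tyr_melan`` would be distinct curation artefacts).
    """
    return _WS_RUN.sub("_", raw.strip())


def canonical_interaction_type(raw: str) -> tuple[str, bool]:
    """Map an interaction-type string onto the controlled vocabulary.

    Returns ``(canonical, known)``.  Matching is case-insensitive with
    whitespace collapsed; strings outside the vocabulary are preserved
    (trimmed, lower-cased) but flagged ``known=False``.
    """
    cleaned = _WS_RUN.sub(" ", raw.strip()).lower()
    return cleaned, cleaned in INTERACTION_VOCABULARY


@dataclass(frozen=True)
class InteractionRecord:
    """One curated directed typed edge (one row of the interaction table)."""

    node_a: str
    node_b: str
    interaction_type: str
    provenance: str | None = None
    type_known: bool = True


@dataclass(frozen=True)
class NodeDescriptor:
    """A network node with parsed compartment, category and complex members.

    ``id`` is the canonical name; ``base_name`` has the compartment suffix
    removed; ``members`` is non-empty only for complexes.
    """

    id: str
    base_name: str
    compartment: str  # "keratinocyte" | "melanocyte" | "none"
    category: str  # protein | small_molecule | complex | biological_process
    #              | environmental_factor | unknown
    members: tuple[str, ...] = ()


def classify_node(
    name: str,
    *,
    annotations: dict[str, str] | None = None,
    default_category: str = "unknown",
) -> NodeDescriptor:
    """Parse a raw node name into a :class:`NodeDescriptor`.

    The terminal ``_kerat`` / ``_melan`` suffix determines the compartment;
    a colon in the base name marks a complex whose members are listed in
    order; UV/UVA/UVB are environmental factors; names on the packaged
    process list (or ending in a process suffix) are biological processes.
    An optional ``annotations`` mapping (node id -> category) overrides the
    heuristics, which otherwise fall back to ``default_category``.
    """
    node_id = normalise_name(name)
    if not node_id:
        raise ValueError("node name is empty after trimming")

    if node_id.endswith("_kerat"):
        compartment, base = "keratinocyte", node_id[: -len("_kerat")]
    elif node_id.endswith("_melan"):
        compartment, base = "melanocyte", node_id[: -len("_melan")]
    else:
        compartment, base = "none", node_id

    members: tuple[str, ...] = ()
    if ":" in base and len([m for m in base.split(":") if m]) >= 2:
        members = tuple(m for m in base.split(":") if m)
        category = "complex"
    elif base in ENVIRONMENTAL_FACTORS:
        category = "environmental_factor"
    elif base in PROCESS_BASE_NAMES or base.endswith(PROCESS_SUFFIXES):
        category = "biological_process"
    else:
        category = default_category

    if annotations and node_id in annotations:
        category = annotations[node_id]

    return NodeDescriptor(
        id=node_id,
        base_name=base,
        compartment=compartment,
        category=category,
        members=members,
    )


@dataclass
class ParserOptions:
    """Options for :func:`parse_interaction_table`."""

    delimiter: str | None = None  # auto-detect tab vs comma when None
    strict: bool = False  # error on bad rows instead of warning
    annotations: dict[str, str] = field(default_factory=dict)
    default_category: str = "unknown"


def _normalise_header(cell: str) -> str:
    return _ARROW_NORM.sub("->", _WS_RUN.sub(" ", cell.strip()))


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def parse_interaction_table(
    source: IO[str] | str | Iterable[str],
    options: ParserOptions | None = None,
) -> tuple[list[InteractionRecord], list[NodeDescriptor], list[str]]:
    """Parse a delimiter-separated interaction table.

    Returns ``(records, descriptors, warnings)``: one record per data row,
    descriptors deduplicated over the union of both name columns in stable
    first-appearance order.  Rows with a missing endpoint or type are
    skipped with a warning (raised instead under ``strict``).  Extra
    columns beyond the optional fourth (provenance) pass through unread.
    """
    opts = options or ParserOptions()
    if isinstance(source, str):
        source = _io.StringIO(source)
    lines = iter(source)

    try:
        header_line = next(lines)
    except StopIteration:
        raise SchemaError("empty stream: no header row") from None
    while not header_line.strip():
        try:
            header_line = next(lines)
        except StopIteration:
            raise SchemaError("empty stream: no header row") from None

    delim = opts.delimiter or _detect_delimiter(header_line)
    reader = csv.reader([header_line], delimiter=delim)
    header = [_normalise_header(c) for c in next(reader)]
    try:
        col_idx = {col: header.index(col) for col in MANDATORY_COLUMNS}
    except ValueError:
        missing = [c for c in MANDATORY_COLUMNS if c not in header]
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}") from None
    prov_idx = len(MANDATORY_COLUMNS) if len(header) > len(MANDATORY_COLUMNS) else None

    records: list[InteractionRecord] = []
    descriptors: list[NodeDescriptor] = []
    seen: set[str] = set()
    warnings: list[str] = []

    def _add_node(name: str) -> str:
        desc = classify_node(
            name,
            annotations=opts.annotations,
            default_category=opts.default_category,
        )
        if desc.id not in seen:
            seen.add(desc.id)
            descriptors.append(desc)
        return desc.id

    for lineno, row in enumerate(csv.reader(lines, delimiter=delim), start=2):
        if not row or not any(cell.strip() for cell in row):
            continue
        try:
            raw_a = row[col_idx["Node A"]]
            raw_b = row[col_idx["Node B"]]
            raw_t = row[col_idx["Interaction type A->B"]]
        except IndexError:
            raw_a = raw_b = raw_t = ""
        if not (raw_a.strip() and raw_b.strip() and raw_t.strip()):
            msg = f"row {lineno}: missing mandatory field(s); row skipped"
            if opts.strict:
                raise SchemaError(msg)
            warnings.append(msg)
            continue
        itype, known = canonical_interaction_type(raw_t)
        if not known:
            warnings.append(
                f"row {lineno}: interaction type {itype!r} outside controlled vocabulary"
            )
        prov = None
        if prov_idx is not None and len(row) > prov_idx and row[prov_idx].strip():
            prov = row[prov_idx].strip()
        records.append(
            InteractionRecord(
                node_a=_add_node(raw_a),
                node_b=_add_node(raw_b),
                interaction_type=itype,
                provenance=prov,
                type_known=known,
            )
        )

    return records, descriptors, warnings


def read_annotations(source: IO[str] | str) -> dict[str, str]:
    """Read a node-annotation table (columns ``node``, ``category``)."""
    if isinstance(source, str):
        source = _io.StringIO(source)
    reader = csv.reader(source, delimiter="\t")
    try:
        header = [c.strip().lower() for c in next(reader)]
    except StopIteration:
        return {}
    try:
        n_i, c_i = header.index("node"), header.index("category")
    except ValueError:
        raise SchemaError("annotation table needs 'node' and 'category' columns") from None
    out: dict[str, str] = {}
    for row in reader:
        if len(row) > max(n_i, c_i) and row[n_i].strip():
            out[normalise_name(row[n_i])] = row[c_i].strip()
    return out


def redescribe(desc: NodeDescriptor, category: str) -> NodeDescriptor:
    """Return a copy of ``desc`` with a different category."""
    return replace(desc, category=category)


def descriptor_ids(descriptors: Sequence[NodeDescriptor]) -> list[str]:
    return [d.id for d in descriptors]
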