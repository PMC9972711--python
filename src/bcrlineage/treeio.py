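"""Reading and writing lineage trees.

Three text formats are supported, all carrying the same information
(topology, integer edge weights, abundances):

newick
    ``(a@3:2)root@0;`` — every label carries an ``@abundance`` suffix,
    branch lengths are the integer edge weights, internal node labels are
    written.  Unobserved nodes are recognised by a ``U<k>`` label with
    abundance 0.
edgelist
    one ``parent TAB child TAB weight TAB child_abundance`` row per edge,
    preceded by a ``#root TAB label TAB abundance`` comment that pins down
    the root's abundance (the root never appears as a child).
dot
    Graphviz output for quick visual inspection; also re-readable.

Sequences are never serialized with the tree; :func:`read_tree` attaches
them from a label→sequence mapping when the caller needs sequence-aware
metrics.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Mapping, Optional

from Bio import Phylo

from .errors import ParseError, ValidationError
from .tree import LineageTree, is_unobserved_label

FORMATS = ("newick", "edgelist", "dot")


# ---------------------------------------------------------------------------
# writing

def _newick_node(tree: LineageTree, label: str) -> str:
    children = sorted(tree.children(label))
    inner = ""
    if children:
        inner = "(" + ",".join(_newick_node(tree, c) for c in children) + ")"
    token = f"{label}@{tree.abundance(label)}"
    if label != tree.root:
        token += f":{tree.weight(tree.parent(label), label)}"
    return inner + token


def write_tree(tree: LineageTree, format: str = "newick") -> str:
    """Serialize ``tree`` to text in one of :data:`FORMATS`."""
    tree.validate()
    if format == "newick":
        return _newick_node(tree, tree.root) + ";\n"
    if format == "edgelist":
        lines = [f"#root\t{tree.root}\t{tree.abundance(tree.root)}"]
        for parent in tree.preorder():
            for child in sorted(tree.children(parent)):
                lines.append(
                    f"{parent}\t{child}\t{tree.weight(parent, child)}"
                    f"\t{tree.abundance(child)}"
                )
        return "\n".join(lines) + "\n"
    if format == "dot":
        lines = ["digraph lineage {"]
        for n in tree.preorder():
            shape = "ellipse" if tree.is_observed(n) else "diamond"
            lines.append(
                f'  "{n}" [label="{n}@{tree.abundance(n)}", shape={shape}, '
                f"width={0.5 + 0.1 * tree.abundance(n):.2f}];"
            )
        for parent in tree.preorder():
            for child in sorted(tree.children(parent)):
                lines.append(
                    f'  "{parent}" -> "{child}" '
                    f'[label="{tree.weight(parent, child)}"];'
                )
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValidationError(f"unknown tree format {format!r}; use one of {FORMATS}")


def write_tree_file(tree: LineageTree, path: str | Path, format: str = "newick") -> None:
    Path(path).write_text(write_tree(tree, format))


# ---------------------------------------------------------------------------
# reading

def _split_label(token: str, where: str) -> tuple[str, int]:
    if "@" not in token:
        raise ParseError(f"{where}: label {token!r} lacks an '@abundance' suffix")
    label, count = token.rsplit("@", 1)
    try:
        ab = int(count)
    except ValueError as exc:
        raise ParseError(f"{where}: abundance {count!r} is not an integer") from exc
    if ab < 0:
        raise ParseError(f"{where}: negative abundance on {label!r}")
    return label, ab


def _from_newick(text: str, where: str) -> LineageTree:
    try:
        clade_tree = Phylo.read(_io.StringIO(text), "newick")
    except Exception as exc:
        raise ParseError(f"{where}: malformed newick: {exc}") from exc
    root_clade = clade_tree.root
    if root_clade.name is None:
        raise ParseError(f"{where}: root clade has no label")
    label, ab = _split_label(root_clade.name, where)
    tree = LineageTree(label, abundance=ab,
                       observed=not is_unobserved_label(label, ab))

    def visit(clade, parent_label: str) -> None:
        for child in clade.clades:
            if child.name is None:
                raise ParseError(f"{where}: unlabeled internal node")
            clabel, cab = _split_label(child.name, where)
            if clabel in tree:
                raise ValidationError(f"{where}: duplicate label {clabel!r}")
            if child.branch_length is None:
                raise ParseError(f"{where}: edge to {clabel!r} lacks a branch length")
            tree.add_node(clabel, abundance=cab,
                          observed=not is_unobserved_label(clabel, cab))
            tree.add_edge(parent_label, clabel, int(round(child.branch_length)))
            visit(child, clabel)

    visit(root_clade, label)
    return tree


def _from_edgelist(text: str, where: str) -> LineageTree:
    root_label: Optional[str] = None
    root_ab = 0
    rows: list[tuple[str, str, int, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].split("\t")
            if parts and parts[0] == "root" and len(parts) == 3:
                root_label, root_ab = parts[1], int(parts[2])
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(f"{where}:{lineno}: expected 4 tab-separated columns")
        p, c, w, ab = parts
        try:
            rows.append((p, c, int(w), int(ab)))
        except ValueError as exc:
            raise ParseError(f"{where}:{lineno}: non-integer weight/abundance") from exc
    if not rows and root_label is None:
        raise ParseError(f"{where}: empty edgelist")

    children = [c for _, c, _, _ in rows]
    dupes = {c for c in children if children.count(c) > 1}
    if dupes:
        raise ValidationError(
            f"{where}: node(s) with multiple parents: {sorted(dupes)}"
        )
    parents = {p for p, _, _, _ in rows}
    roots = parents - set(children)
    if root_label is None:
        if len(roots) != 1:
            raise ValidationError(f"{where}: cannot identify a unique root ({sorted(roots)})")
        root_label = next(iter(roots))
    elif rows and roots != {root_label}:
        raise ValidationError(
            f"{where}: declared root {root_label!r} does not match topology "
            f"(apparent roots: {sorted(roots)})"
        )
    tree = LineageTree(root_label, abundance=root_ab,
                       observed=not is_unobserved_label(root_label, root_ab))
    pending = list(rows)
    while pending:
        progressed = False
        remaining = []
        for p, c, w, ab in pending:
            if p in tree:
                tree.add_node(c, abundance=ab,
                              observed=not is_unobserved_label(c, ab))
                tree.add_edge(p, c, w)
                progressed = True
            else:
                remaining.append((p, c, w, ab))
        if not progressed:
            raise ValidationError(
                f"{where}: rows unreachable from the root (cycle?): "
                f"{[(p, c) for p, c, _, _ in remaining]}"
            )
        pending = remaining
    return tree


_DOT_EDGE_RE = re.compile(r'"(?P<p>[^"]+)"\s*->\s*"(?P<c>[^"]+)"\s*\[label="(?P<w>\d+)"\]')
_DOT_NODE_RE = re.compile(r'"(?P<n>[^"]+)"\s*\[label="(?P<lab>[^"]+)", shape=')


def _from_dot(text: str, where: str) -> LineageTree:
    abundances: dict[str, int] = {}
    for m in _DOT_NODE_RE.finditer(text):
        label, ab = _split_label(m.group("lab"), where)
        abundances[m.group("n")] = ab
    rows = [
        f"{m.group('p')}\t{m.group('c')}\t{m.group('w')}\t"
        f"{abundances.get(m.group('c'), 0)}"
        for m in _DOT_EDGE_RE.finditer(text)
    ]
    if not rows:
        raise ParseError(f"{where}: no edges found in DOT input")
    parents = {r.split("\t")[0] for r in rows}
    children = {r.split("\t")[1] for r in rows}
    roots = sorted(parents - children)
    header = []
    if len(roots) == 1:
        header = [f"#root\t{roots[0]}\t{abundances.get(roots[0], 0)}"]
    return _from_edgelist("\n".join(header + rows), where)


def read_tree(
    path: str | Path,
    sequence_map: Optional[Mapping[str, str]] = None,
    format: Optional[str] = None,
) -> LineageTree:
    """Read a lineage tree written by :func:`write_tree`.

    The format is sniffed from the file suffix or content unless given
    explicitly.  When ``sequence_map`` is supplied, every node label must
    resolve to a sequence — except unobserved ``U<k>`` nodes, whose
    sequences only exist after editing and are left unset.
    """
    text = Path(path).read_text()
    where = str(path)
    if format is None:
        suffix = Path(path).suffix.lower()
        if suffix in (".nwk", ".newick", ".tree"):
            format = "newick"
        elif suffix == ".dot":
            format = "dot"
        elif suffix in (".tsv", ".edgelist", ".txt"):
            format = "edgelist"
        else:
            stripped = text.lstrip()
            if stripped.startswith("digraph"):
                format = "dot"
            elif stripped.startswith("("):
                format = "newick"
            else:
                format = "edgelist"
    if format == "newick":
        tree = _from_newick(text, where)
    elif format == "edgelist":
        tree = _from_edgelist(text, where)
    elif format == "dot":
        tree = _from_dot(text, where)
    else:
        raise ValidationError(f"unknown tree format {format!r}; use one of {FORMATS}")
    tree.validate()
    if sequence_map is not None:
        missing = [
            n for n in tree.nodes
            if n not in sequence_map and tree.is_observed(n)
        ]
        if missing:
            raise ValidationError(
                f"{where}: no sequence supplied for labels: {sorted(missing)}"
            )
        for n in tree.nodes:
            if n in sequence_map:
                tree.set_seq(n, sequence_map[n].upper())
    return tree
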