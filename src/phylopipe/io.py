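"""Reading and writing Newick and NEXUS tree files.

The Newick dialect parsed here is the Felsenstein grammar plus the
annotation conventions of Bayesian phylogenetics output:

* square-bracket comments of the form ``[&key=value,...]`` attached to a
  node become attributes (numeric when the value parses as a number,
  text otherwise); ``{...}`` range values such as BEAST's
  ``height_95%_HDI={x,y}`` are kept verbatim as text;
* other comments are ignored;
* single-quoted labels may contain special characters, with a doubled
  quote escaping a quote;
* a bare internal-node label that parses as a number is stored as the
  ``Support`` attribute, otherwise as ``Name`` (configurable);
* underscores in unquoted labels are preserved verbatim by default
  (``underscore_to_space=True`` enables the classic dialect).

NEXUS support covers the TREES block with an optional TRANSLATE table.
A serialized pipeline document can be embedded in NEXUS output inside a
``[!phylopipe-pipeline ...]`` comment, which standard NEXUS readers
skip and :func:`read_nexus_pipeline` recovers byte-exactly.

All parse errors carry the character offset at which they occurred.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple

from .tree import Tree, TreeCollection, TreeNode

__all__ = [
    "FormatDescriptor",
    "ParseError",
    "sniff_format",
    "parse_newick",
    "parse_newick_tree",
    "write_newick",
    "parse_nexus",
    "iter_nexus_trees",
    "write_nexus",
    "read_nexus_pipeline",
    "read_tree_file",
    "PIPELINE_BLOCK_TAG",
]

PIPELINE_BLOCK_TAG = "!phylopipe-pipeline"

_SPECIALS = set("()[]:;,' \t\n\r")
_NUMBER_RE = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?")


class ParseError(ValueError):
    """Tree-file syntax error, with the offending character offset."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class FormatDescriptor:
    format: str  # "newick" | "nexus"
    tree_count: int
    has_translate: bool


# ---------------------------------------------------------------------------
# Newick


class _NewickParser:
    def __init__(self, text: str, base_offset: int = 0,
                 support_labels: str = "auto",
                 underscore_to_space: bool = False) -> None:
        self.text = text
        self.pos = 0
        self.base = base_offset
        self.support_labels = support_labels
        self.underscore_to_space = underscore_to_space

    def error(self, message: str) -> ParseError:
        return ParseError(message, self.base + self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in " \t\r\n":
            self.pos += 1

    def parse_tree(self) -> TreeNode:
        self.skip_ws()
        root = self.parse_clade()
        self.skip_ws()
        if self.peek() != ";":
            raise self.error("expected ';' at end of tree statement")
        self.pos += 1
        return root

    def parse_clade(self) -> TreeNode:
        self.skip_ws()
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.add_child(self.parse_clade())
                self.skip_ws()
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                if ch in ("", ";"):
                    raise self.error("unbalanced parentheses")
                raise self.error(f"unexpected character {ch!r} in clade list")
            self._parse_annotations(node, leaf=False)
        else:
            self._parse_annotations(node, leaf=True)
            if "Name" not in node.attributes:
                raise self.error("expected a leaf label")
        return node

    def _parse_annotations(self, node: TreeNode, leaf: bool) -> None:
        """Optional label, comments, ``:length``, more comments."""
        self.skip_ws()
        label = self._maybe_label()
        if label is not None:
            if leaf:
                node.attributes["Name"] = label
            else:
                as_number = _as_number(label)
                if self.support_labels == "name" or as_number is None:
                    node.attributes["Name"] = label
                else:
                    node.attributes["Support"] = as_number
        self._consume_comments(node)
        self.skip_ws()
        if self.peek() == ":":
            self.pos += 1
            self._consume_comments(node)
            self.skip_ws()
            match = _NUMBER_RE.match(self.text, self.pos)
            if not match:
                raise self.error("dangling ':' without a branch length")
            self.pos = match.end()
            length = float(match.group())
            if length < 0:
                raise self.error(f"negative branch length {length}")
            node.attributes["Length"] = length
            self._consume_comments(node)

    def _maybe_label(self) -> Optional[str]:
        ch = self.peek()
        if ch == "'":
            return self._quoted_label()
        if ch and ch not in _SPECIALS:
            start = self.pos
            while self.pos < len(self.text) and self.text[self.pos] not in _SPECIALS:
                self.pos += 1
            label = self.text[start:self.pos]
            if self.underscore_to_space:
                label = label.replace("_", " ")
            return label
        return None

    def _quoted_label(self) -> str:
        start = self.pos
        self.pos += 1
        out: List[str] = []
        while True:
            if self.pos >= len(self.text):
                self.pos = start
                raise self.error("unterminated quoted label")
            ch = self.text[self.pos]
            if ch == "'":
                if self.pos + 1 < len(self.text) and self.text[self.pos + 1] == "'":
                    out.append("'")
                    self.pos += 2
                    continue
                self.pos += 1
                return "".join(out)
            out.append(ch)
            self.pos += 1

    def _consume_comments(self, node: TreeNode) -> None:
        self.skip_ws()
        while self.peek() == "[":
            start = self.pos
            body = self._comment_body()
            if body.startswith("&"):
                _apply_attribute_comment(node, body[1:])
            # other comments ignored
            self.skip_ws()
            del start

    def _comment_body(self) -> str:
        # '[' already peeked; comments may nest
        start = self.pos
        depth = 0
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch == "[":
                depth += 1
            elif ch == "]":
                depth -= 1
                if depth == 0:
                    body = self.text[start + 1:self.pos]
                    self.pos += 1
                    return body
            self.pos += 1
        self.pos = start
        raise self.error("unterminated '[' comment")


def _as_number(text: str) -> Optional[float]:
    match = _NUMBER_RE.fullmatch(text.strip())
    return float(text) if match else None


def _apply_attribute_comment(node: TreeNode, body: str) -> None:
    """Split ``key=value,key=value`` honouring ``{...}`` and quotes."""
    for key, value in _split_kv(body):
        if value.startswith("{"):
            node.attributes[key] = value  # range values kept verbatim
        else:
            if value.startswith('"') and value.endswith('"') and len(value) >= 2:
                node.attributes[key] = value[1:-1]
                continue
            number = _as_number(value)
            node.attributes[key] = number if number is not None else value


def _split_kv(body: str) -> List[Tuple[str, str]]:
    pairs: List[Tuple[str, str]] = []
    i, n = 0, len(body)
    while i < n:
        eq = body.find("=", i)
        if eq < 0:
            break
        key = body[i:eq].strip().lstrip(",").strip()
        j = eq + 1
        depth = 0
        in_quote = False
        while j < n:
            ch = body[j]
            if ch == '"':
                in_quote = not in_quote
            elif not in_quote:
                if ch == "{":
                    depth += 1
                elif ch == "}":
                    depth -= 1
                elif ch == "," and depth == 0:
                    break
            j += 1
        value = body[eq + 1:j].strip()
        if key:
            pairs.append((key, value))
        i = j + 1
    return pairs


def parse_newick_tree(text: str, *, support_labels: str = "auto",
                      underscore_to_space: bool = False,
                      base_offset: int = 0) -> Tree:
    """Parse a single semicolon-terminated Newick statement."""
    parser = _NewickParser(text, base_offset, support_labels,
                           underscore_to_space)
    root = parser.parse_tree()
    parser.skip_ws()
    if parser.pos < len(text):
        raise parser.error("trailing characters after tree statement")
    return Tree(root)


def _split_statements(text: str) -> List[Tuple[int, str]]:
    """Split on top-level ';', respecting quotes and bracket comments."""
    statements: List[Tuple[int, str]] = []
    start = 0
    depth = 0
    in_quote = False
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if in_quote:
            if ch == "'":
                if i + 1 < n and text[i + 1] == "'":
                    i += 1
                else:
                    in_quote = False
        elif ch == "'":
            in_quote = True
        elif ch == "[":
            depth += 1
        elif ch == "]":
            depth = max(0, depth - 1)
        elif ch == ";" and depth == 0:
            statements.append((start, text[start:i + 1]))
            start = i + 1
        i += 1
    tail = text[start:].strip()
    if tail:
        statements.append((start, text[start:]))
    return statements


def parse_newick(text: str, **options) -> TreeCollection:
    """Parse one or more Newick statements into a :class:`TreeCollection`."""
    trees: List[Tree] = []
    for offset, statement in _split_statements(text):
        if not statement.strip():
            continue
        lead = len(statement) - len(statement.lstrip())
        trees.append(parse_newick_tree(statement.strip(),
                                       base_offset=offset + lead, **options))
    if not trees:
        raise ParseError("no tree statements found", 0)
    return TreeCollection(trees)


def _needs_quoting(name: str) -> bool:
    return any(ch in "()[]:;, '" for ch in name)


def _quote(name: str) -> str:
    if _needs_quoting(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _format_length(value: float, digits: int) -> str:
    return format(value, f".{digits}g")


def _format_attr_value(value) -> str:
    if isinstance(value, float):
        return format(value, ".12g")
    text = str(value)
    if text.startswith("{"):
        return text
    if any(ch in text for ch in ",=[] "):
        return '"' + text + '"'
    return text


def write_newick(tree: Tree, *, attributes: bool = False,
                 digits: int = 12, name_map: Optional[Dict[str, str]] = None) -> str:
    """Serialize a tree to a Newick string (semicolon-terminated).

    With ``attributes=True`` every attribute other than Name/Length is
    emitted in a ``[&key=value,...]`` comment; otherwise only a numeric
    ``Support`` survives, as a bare internal label. ``name_map``
    replaces leaf names on output (used for NEXUS translate tables).
    """

    def emit(node: TreeNode) -> str:
        parts: List[str] = []
        if node.children:
            inner = ",".join(emit(child) for child in node.children)
            parts.append(f"({inner})")
            if node.name is not None:
                parts.append(_quote(node.name))
            elif not attributes and "Support" in node.attributes:
                parts.append(_format_length(float(node.attributes["Support"]), digits))
        else:
            name = node.name or ""
            if name_map:
                name = name_map.get(name, name)
            parts.append(_quote(name))
        if attributes:
            extra = {k: v for k, v in sorted(node.attributes.items())
                     if k not in ("Name", "Length")}
            if extra:
                body = ",".join(f"{k}={_format_attr_value(v)}"
                                for k, v in extra.items())
                parts.append(f"[&{body}]")
        if node.length is not None:
            parts.append(":" + _format_length(node.length, digits))
        return "".join(parts)

    return emit(tree.root) + ";"


# ---------------------------------------------------------------------------
# NEXUS


def sniff_format(text: str) -> FormatDescriptor:
    """Detect the file format from content.

    NEXUS iff the first non-whitespace token is ``#NEXUS``
    (case-insensitive); anything else is treated as Newick.
    """
    stripped = text.lstrip()
    if not stripped:
        raise ParseError("empty input", 0)
    if stripped[:6].upper() == "#NEXUS":
        statements = _nexus_tree_statements(text)
        return FormatDescriptor("nexus", len(statements[1]),
                                statements[0] is not None)
    count = sum(1 for _, s in _split_statements(text) if s.strip())
    return FormatDescriptor("newick", count, False)


def _strip_outer_comments(text: str) -> str:
    """Remove bracket comments (used outside tree statements)."""
    out: List[str] = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth = max(0, depth - 1)
        elif depth == 0:
            out.append(ch)
    return "".join(out)


def _nexus_tree_statements(text: str):
    """Locate the TREES block; return (translate or None, [(offset, newick)])."""
    match = re.search(r"begin\s+trees\s*;", text, re.IGNORECASE)
    if not match:
        raise ParseError("no TREES block found", 0)
    block_start = match.end()
    end_match = re.search(r"\bend\s*;", text[block_start:], re.IGNORECASE)
    block_end = block_start + (end_match.start() if end_match else
                               len(text) - block_start)
    translate: Optional[Dict[str, str]] = None
    statements: List[Tuple[int, str]] = []
    for offset, statement in _split_statements(text[block_start:block_end]):
        stripped = statement.strip().rstrip(";").strip()
        if not stripped:
            continue
        keyword = stripped.split(None, 1)[0].lower()
        if keyword == "translate":
            translate = _parse_translate(stripped[len("translate"):])
        elif keyword == "tree":
            rest = stripped[len("tree"):].lstrip()
            eq = rest.find("=")
            if eq < 0:
                raise ParseError("TREE statement without '='",
                                 block_start + offset)
            newick = rest[eq + 1:].strip()
            # strip a leading rooting comment such as [&R] / [&U]
            newick = re.sub(r"^\[\s*&[RU]\s*\]\s*", "", newick)
            inner = statement.find("=")
            statements.append((block_start + offset + inner + 1,
                               newick + ";"))
    if not statements:
        raise ParseError("TREES block contains no TREE statements",
                         block_start)
    return translate, statements


def _parse_translate(body: str) -> Dict[str, str]:
    table: Dict[str, str] = {}
    body = _strip_outer_comments(body)
    for entry in body.split(","):
        entry = entry.strip()
        if not entry:
            continue
        if entry.startswith("'"):
            m = re.match(r"'((?:[^']|'')*)'\s+(.*)", entry, re.DOTALL)
            token, name = m.group(1).replace("''", "'"), m.group(2).strip()
        else:
            parts = entry.split(None, 1)
            if len(parts) != 2:
                raise ParseError(f"malformed translate entry {entry!r}", 0)
            token, name = parts
        name = name.strip()
        if name.startswith("'") and name.endswith("'"):
            name = name[1:-1].replace("''", "'")
        table[token] = name
    return table


def _apply_translate(tree: Tree, translate: Dict[str, str],
                     offset: int) -> None:
    for leaf in tree.leaves():
        token = leaf.name
        if token not in translate:
            raise ParseError(
                f"translate token {token!r} not found in TRANSLATE table",
                offset)
        leaf.name = translate[token]


def iter_nexus_trees(text: str, **options) -> Iterator[Tree]:
    """Yield the trees of a NEXUS file one at a time (streaming contract)."""
    translate, statements = _nexus_tree_statements(text)
    for offset, newick in statements:
        tree = parse_newick_tree(newick, base_offset=offset, **options)
        if translate is not None:
            _apply_translate(tree, translate, offset)
        yield tree


def parse_nexus(text: str, **options) -> TreeCollection:
    """Parse the TREES block of a NEXUS file into a collection."""
    translate, _ = _nexus_tree_statements(text)
    trees = list(iter_nexus_trees(text, **options))
    return TreeCollection(trees, translate=translate)


def write_nexus(collection: TreeCollection, pipeline_json: Optional[str] = None,
                *, attributes: bool = False) -> str:
    """Serialize a collection (and optionally a pipeline document) to NEXUS.

    ``pipeline_json`` is embedded verbatim inside a
    ``[!phylopipe-pipeline ...]`` comment after the TREES block; because
    its brackets are balanced, NEXUS comment nesting keeps standard
    readers happy while :func:`read_nexus_pipeline` recovers it exactly.
    """
    taxa = collection.trees[0].leaf_names()
    lines = ["#NEXUS", "", "BEGIN TAXA;",
             f"\tDIMENSIONS NTAX={len(taxa)};",
             "\tTAXLABELS " + " ".join(_quote(t) for t in taxa) + ";",
             "END;", "", "BEGIN TREES;"]
    name_map: Optional[Dict[str, str]] = None
    if collection.translate:
        name_map = {name: token for token, name in collection.translate.items()}
        entries = ",\n".join(f"\t\t{token} {_quote(name)}"
                             for token, name in collection.translate.items())
        lines.append("\tTRANSLATE")
        lines.append(entries + ";")
    for index, tree in enumerate(collection.trees, start=1):
        newick = write_newick(tree, attributes=attributes, name_map=name_map)
        lines.append(f"\tTREE tree{index} = [&R] {newick}")
    lines.append("END;")
    if pipeline_json is not None:
        lines.append("")
        lines.append(f"[{PIPELINE_BLOCK_TAG}\n{pipeline_json}\n]")
    return "\n".join(lines) + "\n"


def read_nexus_pipeline(text: str) -> Optional[str]:
    """Recover an embedded pipeline document from NEXUS text, or None."""
    tag = "[" + PIPELINE_BLOCK_TAG
    start = text.find(tag)
    if start < 0:
        return None
    depth = 0
    for i in range(start, len(text)):
        if text[i] == "[":
            depth += 1
        elif text[i] == "]":
            depth -= 1
            if depth == 0:
                body = text[start + len(tag):i]
                return body.strip("\n")
    raise ParseError("unterminated pipeline comment block", start)


def read_tree_file(path: str, **options) -> TreeCollection:
    """Read a tree file, auto-detecting Newick vs NEXUS."""
    with open(path, "r", encoding="utf-8") as handle:
        text = handle.read()
    descriptor = sniff_format(text)
    if descriptor.format == "nexus":
        return parse_nexus(text, **options)
    return parse_newick(text, **options)
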