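"""Readers and writers for common graph interchange formats.

Supported dialects: whitespace edge list, GraphML, GML, Pajek (.net),
UCINET DL (FULLMATRIX and EDGELIST1 sub-dialects), GEXF (1.2draft,
static), GraphViz DOT, and a portable native JSON serialization
``{"directed": ..., "nodes": [{"id", "attrs"}], "edges": [{"u", "v",
"weight", "attrs"}]}``.

All readers accept a file path or an open text stream.  Node labels are
read as text by default; pass ``label_type="auto"`` (or ``"int"``) in the
dialect options to coerce integer-looking labels back to integers, which
is what the round-trip guarantees in the test suite rely on.  Writers
emit a canonical ordering (nodes and edges sorted by label text), so
write-read-write is byte stable.
"""

from __future__ import annotations

import io as _io
import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

from .exceptions import (CapabilityError, ConfigurationError,
                         GraphFormatError)
from .graph import Graph

__all__ = ["FormatDialect", "read", "write", "detect_format", "FORMATS"]

FORMATS = ("edgelist", "graphml", "gml", "pajek", "ucinet_dl", "gexf",
           "dot", "native_json")

_EXTENSIONS = {
    ".edgelist": "edgelist", ".edges": "edgelist", ".txt": "edgelist",
    ".graphml": "graphml", ".gml": "gml", ".net": "pajek",
    ".pajek": "pajek", ".dl": "ucinet_dl", ".gexf": "gexf",
    ".dot": "dot", ".gv": "dot", ".json": "native_json",
}


@dataclass
class FormatDialect:
    """A format name plus per-format options.

    Options understood (all optional): ``label_type`` in {"str", "auto",
    "int"}; ``delimiter`` and ``comment`` for edge lists; ``directed``
    override for formats that cannot express orientation; ``sub`` in
    {"fullmatrix", "edgelist1"} for UCINET DL writing.
    """

    name: str
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in FORMATS:
            raise ConfigurationError(
                f"unknown dialect {self.name!r}; expected one of {FORMATS}")
        known = {"label_type", "delimiter", "comment", "directed", "sub"}
        bad = set(self.options) - known
        if bad:
            raise ConfigurationError(f"unknown options {sorted(bad)} "
                                     f"for dialect {self.name!r}")

    def opt(self, key: str, default: Any = None) -> Any:
        return self.options.get(key, default)


def _as_dialect(dialect: Union[str, FormatDialect, None], **opts) -> FormatDialect:
    if isinstance(dialect, FormatDialect):
        return dialect
    if isinstance(dialect, str):
        return FormatDialect(dialect, dict(opts))
    raise ConfigurationError(f"not a dialect: {dialect!r}")


def _coerce(label: str, label_type: str):
    if label_type == "str":
        return label
    if label_type in ("auto", "int"):
        try:
            return int(label)
        except (TypeError, ValueError):
            if label_type == "int":
                raise GraphFormatError(
                    f"label {label!r} is not an integer")
            return label
    raise ConfigurationError(f"unknown label_type {label_type!r}")


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text()


def _write_text(target, text: str) -> None:
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)



def _nodes_sorted(g: Graph) -> list:
    """Canonical node order for writers: sorted by label text."""
    return sorted(g.nodes, key=str)


def _edges_sorted(g: Graph) -> list:
    """Canonical edge order for writers: sorted by endpoint label text.

    Undirected edges are also re-oriented (smaller label first) so the
    serialization does not depend on the storage orientation.
    """
    edges = []
    for u, v, data in g.edges():
        if not g.directed and str(v) < str(u):
            u, v = v, u
        edges.append((u, v, data))
    return sorted(edges, key=lambda e: (str(e[0]), str(e[1])))


# ---------------------------------------------------------------------------
# public entry points

def read(source, dialect: Union[str, FormatDialect, None] = None,
         **options) -> Graph:
    """Parse *source* (path or text stream) into a :class:`Graph`.

    When *dialect* is omitted the format is detected from the file
    extension and content (:func:`detect_format`).
    """
    if dialect is None:
        dialect = detect_format(source)
        dialect.options.update(options)
    else:
        dialect = _as_dialect(dialect, **options)
    text = _read_text(source)
    reader = _READERS[dialect.name]
    return reader(text, dialect)


def write(g: Graph, target, dialect: Union[str, FormatDialect, None] = None,
          **options) -> None:
    """Serialize *g* to *target* (path or text stream) in *dialect*."""
    if dialect is None and not hasattr(target, "write"):
        ext = Path(target).suffix.lower()
        if ext in _EXTENSIONS:
            dialect = _EXTENSIONS[ext]
    if dialect is None:
        raise ConfigurationError("write() needs an explicit dialect "
                                 "when the target has no known extension")
    dialect = _as_dialect(dialect, **options)
    writer = _WRITERS[dialect.name]
    _write_text(target, writer(g, dialect))


def detect_format(source) -> FormatDialect:
    """Choose a dialect by extension first, then by content sniffing."""
    name = None
    if not hasattr(source, "read"):
        ext = Path(source).suffix.lower()
        name = _EXTENSIONS.get(ext)
        if name not in (None, "edgelist"):  # .txt still needs sniffing? no
            return FormatDialect(name)
        text = Path(source).read_text()
    else:
        text = source.read()
        source.seek(0)
    head = text.lstrip()[:4096]
    low = head.lower()
    if low.startswith("<?xml") or low.startswith("<"):
        root = re.search(r"<\s*([a-zA-Z_][\w.-]*)", re.sub(r"<\?.*?\?>", "",
                                                           head, flags=re.S))
        tag = root.group(1).lower() if root else ""
        if tag == "graphml":
            return FormatDialect("graphml")
        if tag == "gexf":
            return FormatDialect("gexf")
        raise ConfigurationError(
            f"XML input with unrecognized root {tag!r}: "
            "candidates are graphml, gexf")
    if low.startswith("dl"):
        return FormatDialect("ucinet_dl")
    if low.startswith("*vertices"):
        return FormatDialect("pajek")
    if re.match(r"(strict\s+)?(di)?graph\b[^[]*\{", head):
        return FormatDialect("dot")
    if re.match(r"graph\s*\[", head):
        return FormatDialect("gml")
    if low.startswith("{"):
        return FormatDialect("native_json")
    if name == "edgelist":
        return FormatDialect("edgelist")
    # fallback: edge list
    return FormatDialect("edgelist")


# ---------------------------------------------------------------------------
# native JSON

def _graph_from_native(doc: dict) -> Graph:
    g = Graph(directed=bool(doc.get("directed", False)))
    for nd in doc.get("nodes", []):
        g.add_node(nd["id"], **nd.get("attrs", {}))
    for ed in doc.get("edges", []):
        g.add_edge(ed["u"], ed["v"], weight=ed.get("weight", 1.0),
                   **ed.get("attrs", {}))
    return g


def _graph_to_native(g: Graph) -> dict:
    nodes = [{"id": v, "attrs": dict(g.nodes[v])} for v in _nodes_sorted(g)]
    edges = []
    for u, v, data in _edges_sorted(g):
        attrs = {k: w for k, w in data.items() if k != "weight"}
        edges.append({"u": u, "v": v, "weight": data["weight"],
                      "attrs": attrs})
    return {"directed": g.directed, "nodes": nodes, "edges": edges}


def _read_native(text: str, dialect: FormatDialect) -> Graph:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise GraphFormatError(f"invalid JSON: {e.msg}", line=e.lineno)
    return _graph_from_native(doc)


def _write_native(g: Graph, dialect: FormatDialect) -> str:
    return json.dumps(_graph_to_native(g), indent=1, default=str) + "\n"


# ---------------------------------------------------------------------------
# edge list

def _read_edgelist(text: str, dialect: FormatDialect) -> Graph:
    comment = dialect.opt("comment", "#")
    delim = dialect.opt("delimiter")
    label_type = dialect.opt("label_type", "str")
    directed = dialect.opt("directed")
    lines = text.splitlines()
    # a leading "# directed=true/false" comment records orientation
    for ln in lines[:5]:
        m = re.match(rf"\s*{re.escape(comment)}\s*directed\s*=\s*(\w+)", ln)
        if m and directed is None:
            directed = m.group(1).lower() in ("true", "yes", "1")
    g = Graph(directed=bool(directed))
    for i, raw in enumerate(lines, 1):
        line = raw.split(comment, 1)[0].strip() if comment else raw.strip()
        if not line:
            continue
        parts = line.split(delim)
        if len(parts) < 2:
            raise GraphFormatError("edge line needs at least two fields",
                                   line=i)
        u = _coerce(parts[0], label_type)
        v = _coerce(parts[1], label_type)
        if len(parts) >= 3:
            try:
                w = float(parts[2])
            except ValueError:
                raise GraphFormatError(
                    f"third column {parts[2]!r} is not a weight", line=i)
            g.add_edge(u, v, weight=w)
        else:
            g.add_edge(u, v)
    return g


def _write_edgelist(g: Graph, dialect: FormatDialect) -> str:
    delim = dialect.opt("delimiter") or " "
    out = [f"# directed={'true' if g.directed else 'false'}"]
    for v in _nodes_sorted(g):
        if g.degree(v) == 0:
            out.append(str(v))  # isolated nodes kept as single-field lines
    for u, v, data in _edges_sorted(g):
        w = data["weight"]
        if w == 1.0:
            out.append(f"{u}{delim}{v}")
        else:
            out.append(f"{u}{delim}{v}{delim}{w!r}")
    return "\n".join(out) + "\n"


# isolated-node single-field lines need a tolerant re-read
_read_edgelist_strict = _read_edgelist


def _read_edgelist_tolerant(text: str, dialect: FormatDialect) -> Graph:
    comment = dialect.opt("comment", "#")
    label_type = dialect.opt("label_type", "str")
    g = _read_edgelist(
        "\n".join(ln for ln in text.splitlines()
                  if len(ln.split(comment, 1)[0].split()) != 1),
        dialect)
    for i, raw in enumerate(text.splitlines(), 1):
        line = raw.split(comment, 1)[0].strip()
        if line and len(line.split()) == 1:
            g.add_node(_coerce(line, label_type))
    return g


# ---------------------------------------------------------------------------
# attribute typing shared by GraphML / GEXF

_XSD_TYPES = {bool: "boolean", int: "int", float: "double", str: "string"}


def _attr_type(value: Any) -> str:
    for t, name in _XSD_TYPES.items():
        if isinstance(value, t) and not (t is int and isinstance(value, bool)):
            return name
    return "string"


def _parse_typed(text: Optional[str], typ: str) -> Any:
    if text is None:
        text = ""
    if typ == "boolean":
        return text.strip().lower() == "true"
    if typ in ("int", "long", "integer"):
        return int(text)
    if typ in ("double", "float"):
        return float(text)
    return text


def _fmt(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


# ---------------------------------------------------------------------------
# GraphML

_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_graphml(text: str, dialect: FormatDialect) -> Graph:
    label_type = dialect.opt("label_type", "str")
    try:
        root = ET.fromstring(text)
    except ET.ParseError as e:
        raise GraphFormatError(f"invalid XML: {e}", element="graphml")
    if _localname(root.tag) != "graphml":
        raise GraphFormatError("root element is not <graphml>",
                               element=_localname(root.tag))
    keys = {}
    for el in root.iter():
        if _localname(el.tag) == "key":
            keys[el.get("id")] = (el.get("attr.name", el.get("id")),
                                  el.get("attr.type", "string"))
    graph_el = next((el for el in root.iter()
                     if _localname(el.tag) == "graph"), None)
    if graph_el is None:
        raise GraphFormatError("no <graph> element", element="graph")
    directed = graph_el.get("edgedefault", "undirected") == "directed"
    g = Graph(directed=directed)

    def collect(el) -> dict:
        attrs = {}
        for d in el:
            if _localname(d.tag) != "data":
                continue
            name, typ = keys.get(d.get("key"), (d.get("key"), "string"))
            attrs[name] = _parse_typed(d.text, typ)
        return attrs

    for el in graph_el:
        ln = _localname(el.tag)
        if ln == "node":
            g.add_node(_coerce(el.get("id"), label_type), **collect(el))
        elif ln == "edge":
            attrs = collect(el)
            w = attrs.pop("weight", 1.0)
            g.add_edge(_coerce(el.get("source"), label_type),
                       _coerce(el.get("target"), label_type),
                       weight=float(w), **attrs)
    return g


def _write_graphml(g: Graph, dialect: FormatDialect) -> str:
    # declare one <key> per (scope, attribute name) with an inferred type
    node_keys: dict[str, str] = {}
    edge_keys: dict[str, str] = {"weight": "double"}
    for _, a in g.nodes.items():
        for k, val in a.items():
            node_keys.setdefault(k, _attr_type(val))
    for _, _, data in g.edges():
        for k, val in data.items():
            if k != "weight":
                edge_keys.setdefault(k, _attr_type(val))
    out = ['<?xml version="1.0" encoding="utf-8"?>',
           f'<graphml xmlns="{_GRAPHML_NS}">']
    key_ids = {}
    i = 0
    for scope, keys in (("node", node_keys), ("edge", edge_keys)):
        for name, typ in keys.items():
            kid = f"d{i}"
            i += 1
            key_ids[(scope, name)] = kid
            out.append(f'  <key id="{kid}" for="{scope}" '
                       f'attr.name="{_xml_escape(name)}" attr.type="{typ}"/>')
    default = "directed" if g.directed else "undirected"
    out.append(f'  <graph edgedefault="{default}">')
    for v, a in ((v, g.nodes[v]) for v in _nodes_sorted(g)):
        if a:
            out.append(f'    <node id="{_xml_escape(str(v))}">')
            for k, val in a.items():
                out.append(f'      <data key="{key_ids[("node", k)]}">'
                           f'{_xml_escape(_fmt(val))}</data>')
            out.append('    </node>')
        else:
            out.append(f'    <node id="{_xml_escape(str(v))}"/>')
    for u, v, data in _edges_sorted(g):
        out.append(f'    <edge source="{_xml_escape(str(u))}" '
                   f'target="{_xml_escape(str(v))}">')
        for k, val in data.items():
            out.append(f'      <data key="{key_ids[("edge", k)]}">'
                       f'{_xml_escape(_fmt(val))}</data>')
        out.append('    </edge>')
    out.append('  </graph>')
    out.append('</graphml>')
    return "\n".join(out) + "\n"


def _xml_escape(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;").replace('"', "&quot;"))


# ---------------------------------------------------------------------------
# GEXF (1.2draft, static)

_GEXF_NS = "http://www.gexf.net/1.2draft"
_GEXF_TYPES = {"boolean": "boolean", "int": "integer", "double": "double",
               "string": "string"}


def _read_gexf(text: str, dialect: FormatDialect) -> Graph:
    label_type = dialect.opt("label_type", "str")
    try:
        root = ET.fromstring(text)
    except ET.ParseError as e:
        raise GraphFormatError(f"invalid XML: {e}", element="gexf")
    if _localname(root.tag) != "gexf":
        raise GraphFormatError("root element is not <gexf>",
                               element=_localname(root.tag))
    graph_el = next((el for el in root.iter()
                     if _localname(el.tag) == "graph"), None)
    if graph_el is None:
        raise GraphFormatError("no <graph> element", element="graph")
    directed = graph_el.get("defaultedgetype", "undirected") == "directed"
    g = Graph(directed=directed)
    attr_defs: dict[tuple, tuple] = {}
    for el in graph_el:
        if _localname(el.tag) == "attributes":
            scope = el.get("class", "node")
            for at in el:
                attr_defs[(scope, at.get("id"))] = (
                    at.get("title", at.get("id")), at.get("type", "string"))

    def collect(el, scope) -> dict:
        attrs = {}
        for sub in el:
            if _localname(sub.tag) != "attvalues":
                continue
            for av in sub:
                name, typ = attr_defs.get((scope, av.get("for")),
                                          (av.get("for"), "string"))
                inv = {"integer": "int", "long": "int", "float": "double"}
                attrs[name] = _parse_typed(av.get("value"),
                                           inv.get(typ, typ))
        return attrs

    for el in graph_el:
        ln = _localname(el.tag)
        if ln == "nodes":
            for nd in el:
                g.add_node(_coerce(nd.get("id"), label_type),
                           **collect(nd, "node"))
        elif ln == "edges":
            for ed in el:
                w = float(ed.get("weight", 1.0))
                g.add_edge(_coerce(ed.get("source"), label_type),
                           _coerce(ed.get("target"), label_type),
                           weight=w, **collect(ed, "edge"))
    return g


def _write_gexf(g: Graph, dialect: FormatDialect) -> str:
    node_keys: dict[str, str] = {}
    edge_keys: dict[str, str] = {}
    for _, a in g.nodes.items():
        for k, val in a.items():
            node_keys.setdefault(k, _attr_type(val))
    for _, _, data in g.edges():
        for k, val in data.items():
            if k != "weight":
                edge_keys.setdefault(k, _attr_type(val))
    out = ['<?xml version="1.0" encoding="utf-8"?>',
           f'<gexf xmlns="{_GEXF_NS}" version="1.2">']
    kind = "directed" if g.directed else "undirected"
    out.append(f'  <graph mode="static" defaultedgetype="{kind}">')
    ids = {}
    for scope, keys in (("node", node_keys), ("edge", edge_keys)):
        if not keys:
            continue
        out.append(f'    <attributes class="{scope}">')
        for i, (name, typ) in enumerate(keys.items()):
            ids[(scope, name)] = f"a{scope[0]}{i}"
            out.append(f'      <attribute id="{ids[(scope, name)]}" '
                       f'title="{_xml_escape(name)}" '
                       f'type="{_GEXF_TYPES[typ]}"/>')
        out.append('    </attributes>')

    def attvalues(scope, items, indent):
        rows = []
        pad = " " * indent
        real = {k: v for k, v in items.items() if k != "weight"}
        if real:
            rows.append(f"{pad}<attvalues>")
            for k, val in real.items():
                rows.append(f'{pad}  <attvalue for="{ids[(scope, k)]}" '
                            f'value="{_xml_escape(_fmt(val))}"/>')
            rows.append(f"{pad}</attvalues>")
        return rows

    out.append('    <nodes>')
    for v, a in ((v, g.nodes[v]) for v in _nodes_sorted(g)):
        body = attvalues("node", a, 8)
        vid = _xml_escape(str(v))
        if body:
            out.append(f'      <node id="{vid}" label="{vid}">')
            out.extend(body)
            out.append('      </node>')
        else:
            out.append(f'      <node id="{vid}" label="{vid}"/>')
    out.append('    </nodes>')
    out.append('    <edges>')
    for i, (u, v, data) in enumerate(_edges_sorted(g)):
        su, sv = _xml_escape(str(u)), _xml_escape(str(v))
        body = attvalues("edge", data, 8)
        head = (f'      <edge id="{i}" source="{su}" target="{sv}" '
                f'weight="{data["weight"]!r}"')
        if body:
            out.append(head + ">")
            out.extend(body)
            out.append('      </edge>')
        else:
            out.append(head + "/>")
    out.append('    </edges>')
    out.append('  </graph>')
    out.append('</gexf>')
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# GML

_GML_TOKEN = re.compile(r'"(?:[^"\\]|\\.)*"|\[|\]|[^\s\[\]]+')


def _gml_tokens(text: str):
    for m in _GML_TOKEN.finditer(text):
        yield m.group(0)


def _gml_parse_value(tok: str):
    if tok.startswith('"'):
        return tok[1:-1].replace('\\"', '"').replace("\\\\", "\\")
    try:
        return int(tok)
    except ValueError:
        pass
    try:
        return float(tok)
    except ValueError:
        return tok


def _gml_parse_list(tokens) -> list[tuple]:
    """Parse a bracketed GML key/value list into (key, value) pairs."""
    items = []
    while True:
        try:
            key = next(tokens)
        except StopIteration:
            return items
        if key == "]":
            return items
        try:
            val = next(tokens)
        except StopIteration:
            raise GraphFormatError(f"GML key {key!r} has no value")
        if val == "[":
            items.append((key, _gml_parse_list(tokens)))
        else:
            items.append((key, _gml_parse_value(val)))


def _read_gml(text: str, dialect: FormatDialect) -> Graph:
    label_type = dialect.opt("label_type", "str")
    tokens = _gml_tokens(text)
    top = _gml_parse_list(tokens)
    graph_list = next((v for k, v in top if k == "graph"), None)
    if graph_list is None:
        raise GraphFormatError("no 'graph [' block found", element="graph")
    directed = any(k == "directed" and v == 1 for k, v in graph_list)
    g = Graph(directed=directed)
    id_to_label = {}
    for key, val in graph_list:
        if key == "node":
            d = dict(val)
            nid = d.pop("id", None)
            label = d.pop("label", None)
            if label is not None:
                label = _coerce(str(label), label_type)
            elif nid is not None:
                label = nid
            else:
                raise GraphFormatError("node without id or label",
                                       element="node")
            id_to_label[nid] = label
            g.add_node(label, **d)
    for key, val in graph_list:
        if key == "edge":
            d = dict(val)
            try:
                s, t = d.pop("source"), d.pop("target")
            except KeyError:
                raise GraphFormatError("edge without source/target",
                                       element="edge")
            w = float(d.pop("weight", d.pop("value", 1.0)))
            g.add_edge(id_to_label.get(s, s), id_to_label.get(t, t),
                       weight=w, **d)
    return g


def _gml_fmt_value(val: Any) -> str:
    if isinstance(val, bool):
        return f'"{val}"'
    if isinstance(val, int):
        return str(val)
    if isinstance(val, float):
        return repr(val)
    s = str(val).replace("\\", "\\\\").replace('"', '\\"')
    return f'"{s}"'


def _write_gml(g: Graph, dialect: FormatDialect) -> str:
    out = ["graph ["]
    if g.directed:
        out.append("  directed 1")
    ids = {v: i for i, v in enumerate(_nodes_sorted(g))}
    for v, a in ((v, g.nodes[v]) for v in _nodes_sorted(g)):
        out.append("  node [")
        out.append(f"    id {ids[v]}")
        out.append(f'    label "{_gml_escape(str(v))}"')
        for k, val in a.items():
            out.append(f"    {k} {_gml_fmt_value(val)}")
        out.append("  ]")
    for u, v, data in _edges_sorted(g):
        out.append("  edge [")
        out.append(f"    source {ids[u]}")
        out.append(f"    target {ids[v]}")
        out.append(f"    weight {data['weight']!r}")
        for k, val in data.items():
            if k != "weight":
                out.append(f"    {k} {_gml_fmt_value(val)}")
        out.append("  ]")
    out.append("]")
    return "\n".join(out) + "\n"


def _gml_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


# ---------------------------------------------------------------------------
# Pajek

_PAJEK_VERTEX = re.compile(r'\s*(\d+)(?:\s+"((?:[^"\\]|\\.)*)"|\s+(\S+))?')


def _read_pajek(text: str, dialect: FormatDialect) -> Graph:
    label_type = dialect.opt("label_type", "str")
    lines = text.splitlines()
    idx_to_label: dict[int, Any] = {}
    mode = None
    n_declared = 0
    g: Optional[Graph] = None
    edges: list[tuple] = []
    directed = False
    for i, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            parts = line.split()
            if len(parts) < 2 or not parts[1].isdigit():
                raise GraphFormatError("*Vertices needs a count", line=i)
            n_declared = int(parts[1])
            mode = "vertices"
            continue
        if low.startswith("*edges"):
            mode, directed = "edges", directed or False
            continue
        if low.startswith("*arcs"):
            mode, directed = "edges", True
            continue
        if line.startswith("*"):
            raise GraphFormatError(f"unsupported section {line!r}", line=i)
        if mode == "vertices":
            m = _PAJEK_VERTEX.match(line)
            if not m:
                raise GraphFormatError("bad vertex line", line=i)
            idx = int(m.group(1))
            label = m.group(2) if m.group(2) is not None else m.group(3)
            if label is None:
                label = str(idx)
            idx_to_label[idx] = _coerce(label, label_type)
        elif mode == "edges":
            parts = line.split()
            if len(parts) < 2:
                raise GraphFormatError("edge line needs two endpoints",
                                       line=i)
            u, v = int(parts[0]), int(parts[1])
            w = float(parts[2]) if len(parts) > 2 else 1.0
            edges.append((u, v, w))
        else:
            raise GraphFormatError("data before any *Vertices section",
                                   line=i)
    g = Graph(directed=directed)
    for idx in range(1, n_declared + 1):
        g.add_node(idx_to_label.get(idx, _coerce(str(idx), label_type)))
    for u, v, w in edges:
        ul = idx_to_label.get(u, _coerce(str(u), label_type))
        vl = idx_to_label.get(v, _coerce(str(v), label_type))
        g.add_edge(ul, vl, weight=w)
    return g


def _write_pajek(g: Graph, dialect: FormatDialect) -> str:
    ids = {v: i + 1 for i, v in enumerate(_nodes_sorted(g))}
    out = [f"*Vertices {g.n_nodes}"]
    for v, i in ids.items():
        s = str(v).replace("\\", "\\\\").replace('"', '\\"')
        out.append(f'{i} "{s}"')
    out.append("*Arcs" if g.directed else "*Edges")
    for u, v, data in _edges_sorted(g):
        out.append(f"{ids[u]} {ids[v]} {data['weight']!r}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# UCINET DL (FULLMATRIX and EDGELIST1)

def _read_ucinet_dl(text: str, dialect: FormatDialect) -> Graph:
    label_type = dialect.opt("label_type", "str")
    directed_opt = dialect.opt("directed")
    body = text.strip()
    if not body.lower().startswith("dl"):
        raise GraphFormatError("missing DL header", line=1)
    m = re.search(r"\bn\s*[=:]\s*(\d+)", body, re.I)
    if not m:
        raise GraphFormatError("missing N= declaration", line=1)
    n = int(m.group(1))
    fm = re.search(r"format\s*[=:]\s*([a-z0-9_]+)", body, re.I)
    sub = (fm.group(1).lower() if fm else "fullmatrix")
    if sub not in ("fullmatrix", "edgelist1"):
        raise CapabilityError(f"unsupported DL sub-format {sub!r}; "
                              "only FULLMATRIX and EDGELIST1 are handled")
    labels: Optional[list] = None
    lm = re.search(r"labels\s*:\s*(.*?)(?=\n\s*(?:data|labels)\s*:|\Z)",
                   body, re.I | re.S)
    if lm:
        raw = lm.group(1).replace("\n", ",")
        labels = [_coerce(tok.strip().strip('"'), label_type)
                  for tok in raw.split(",") if tok.strip()]
        if len(labels) != n:
            raise GraphFormatError(
                f"LABELS lists {len(labels)} names for N={n}")
    dm = re.search(r"data\s*:\s*(.*)\Z", body, re.I | re.S)
    if not dm:
        raise GraphFormatError("missing DATA: section")
    data = dm.group(1).strip()
    if labels is None:
        labels = [_coerce(str(i), label_type) for i in range(n)]
    if sub == "fullmatrix":
        rows = [r.split() for r in data.splitlines() if r.strip()]
        flat = [x for r in rows for x in r]
        if len(flat) != n * n:
            raise GraphFormatError(
                f"FULLMATRIX expects {n * n} entries, got {len(flat)}")
        mat = [[float(flat[i * n + j]) for j in range(n)] for i in range(n)]
        symmetric = all(mat[i][j] == mat[j][i]
                        for i in range(n) for j in range(i + 1, n))
        directed = (not symmetric) if directed_opt is None else directed_opt
        g = Graph(directed=directed)
        for lab in labels:
            g.add_node(lab)
        for i in range(n):
            rng = range(n) if directed else range(i, n)
            for j in rng:
                if i == j:
                    continue
                if mat[i][j] != 0:
                    g.add_edge(labels[i], labels[j], weight=mat[i][j])
        return g
    # EDGELIST1: "u v [w]" rows, 1-based indices or labels
    dd = re.search(r"directed\s*[=:]\s*(yes|no|true|false)", body, re.I)
    if directed_opt is None and dd:
        directed_opt = dd.group(1).lower() in ("yes", "true")
    directed = False if directed_opt is None else directed_opt
    g = Graph(directed=directed)
    for lab in labels:
        g.add_node(lab)
    for i, row in enumerate(data.splitlines(), 1):
        parts = row.split()
        if not parts:
            continue
        if len(parts) < 2:
            raise GraphFormatError("EDGELIST1 row needs two fields", line=i)

        def resolve(tok):
            if tok.isdigit() and 1 <= int(tok) <= n and lm is None:
                return labels[int(tok) - 1]
            return _coerce(tok.strip('"'), label_type)

        u, v = resolve(parts[0]), resolve(parts[1])
        w = float(parts[2]) if len(parts) > 2 else 1.0
        g.add_edge(u, v, weight=w)
    return g


def _write_ucinet_dl(g: Graph, dialect: FormatDialect) -> str:
    sub = dialect.opt("sub", "edgelist1")
    n = g.n_nodes
    if sub == "fullmatrix":
        if set(g.nodes) != set(range(n)):
            raise CapabilityError(
                "DL FULLMATRIX without labels can only express graphs "
                "whose node labels are exactly 0..n-1; use the edgelist1 "
                "sub-dialect instead")
        out = [f"DL N={n}", "FORMAT=FULLMATRIX", "DATA:"]
        for i in range(n):
            row = [repr(g.weight(i, j)) if g.has_edge(i, j) else "0"
                   for j in range(n)]
            out.append(" ".join(row))
        return "\n".join(out) + "\n"
    if sub != "edgelist1":
        raise ConfigurationError(f"unknown DL sub-dialect {sub!r}")
    out = [f"DL N={n}", "FORMAT=EDGELIST1",
           f"DIRECTED={'YES' if g.directed else 'NO'}"]
    labels = _nodes_sorted(g)
    out.append("LABELS:")
    out.append(",".join(str(v) for v in labels))
    out.append("DATA:")
    for u, v, data in _edges_sorted(g):
        out.append(f"{u} {v} {data['weight']!r}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# GraphViz DOT

_DOT_ID = r'(?:"(?:[^"\\]|\\.)*"|[A-Za-z_][A-Za-z_0-9]*|-?\d+(?:\.\d+)?)'
_DOT_EDGE = re.compile(rf"^({_DOT_ID})\s*(--|->)\s*({_DOT_ID})"
                       rf"\s*(\[[^\]]*\])?\s*;?\s*$")
_DOT_NODE = re.compile(rf"^({_DOT_ID})\s*(\[[^\]]*\])?\s*;?\s*$")
_DOT_ATTR = re.compile(rf"({_DOT_ID})\s*=\s*({_DOT_ID})")


def _dot_unquote(tok: str) -> str:
    if tok.startswith('"'):
        return tok[1:-1].replace('\\"', '"').replace("\\\\", "\\")
    return tok


def _dot_attrs(block: Optional[str]) -> dict:
    if not block:
        return {}
    attrs = {}
    for m in _DOT_ATTR.finditer(block[1:-1]):
        key = _dot_unquote(m.group(1))
        val = _dot_unquote(m.group(2))
        attrs[key] = _gml_parse_value(f'"{val}"') if m.group(2).startswith('"') \
            else _gml_parse_value(m.group(2))
    return attrs


def _read_dot(text: str, dialect: FormatDialect) -> Graph:
    label_type = dialect.opt("label_type", "str")
    stripped = re.sub(r"//[^\n]*|/\*.*?\*/", "", text, flags=re.S)
    m = re.match(r"\s*(strict\s+)?(graph|digraph)\s*" + f"({_DOT_ID})?" +
                 r"\s*\{(.*)\}\s*$", stripped, re.S)
    if not m:
        raise GraphFormatError("not a DOT graph/digraph block", line=1)
    directed = m.group(2) == "digraph"
    body = m.group(4)
    if re.search(r"\bsubgraph\b|\{", body):
        raise CapabilityError(
            "DOT subgraph/cluster syntax is not supported; "
            "flatten the graph to plain node and edge statements")
    g = Graph(directed=directed)
    # split on ; and newlines, keeping [...] blocks intact
    stmts = [s.strip() for s in re.split(r";|\n", body) if s.strip()]
    for i, stmt in enumerate(stmts, 1):
        em = _DOT_EDGE.match(stmt)
        if em:
            op = em.group(2)
            if directed and op == "--" or (not directed and op == "->"):
                raise GraphFormatError(
                    f"edge operator {op!r} conflicts with graph kind",
                    line=i)
            attrs = _dot_attrs(em.group(4))
            w = float(attrs.pop("weight", 1.0))
            g.add_edge(_coerce(_dot_unquote(em.group(1)), label_type),
                       _coerce(_dot_unquote(em.group(3)), label_type),
                       weight=w, **attrs)
            continue
        nm = _DOT_NODE.match(stmt)
        if nm:
            name = _dot_unquote(nm.group(1))
            if name in ("node", "edge", "graph"):  # default-attr statements
                continue
            g.add_node(_coerce(name, label_type), **_dot_attrs(nm.group(2)))
            continue
        raise GraphFormatError(f"unparseable DOT statement {stmt!r}", line=i)
    return g


def _dot_quote(s: str) -> str:
    if re.fullmatch(r"[A-Za-z_][A-Za-z_0-9]*|-?\d+(\.\d+)?", s):
        return s
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _write_dot(g: Graph, dialect: FormatDialect) -> str:
    kind = "digraph" if g.directed else "graph"
    op = "->" if g.directed else "--"
    out = [f"{kind} G {{"]
    for v, a in ((v, g.nodes[v]) for v in _nodes_sorted(g)):
        if a or g.degree(v) == 0:
            attrs = ", ".join(f"{k}={_dot_quote(_fmt(val))}"
                              for k, val in a.items())
            out.append(f"  {_dot_quote(str(v))}"
                       + (f" [{attrs}]" if attrs else "") + ";")
    for u, v, data in _edges_sorted(g):
        attrs = ", ".join(f"{k}={_dot_quote(_fmt(val))}"
                          for k, val in data.items())
        out.append(f"  {_dot_quote(str(u))} {op} {_dot_quote(str(v))} "
                   f"[{attrs}];")
    out.append("}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------

_READERS = {
    "edgelist": _read_edgelist_tolerant,
    "graphml": _read_graphml,
    "gml": _read_gml,
    "pajek": _read_pajek,
    "ucinet_dl": _read_ucinet_dl,
    "gexf": _read_gexf,
    "dot": _read_dot,
    "native_json": _read_native,
}

_WRITERS = {
    "edgelist": _write_edgelist,
    "graphml": _write_graphml,
    "gml": _write_gml,
    "pajek": _write_pajek,
    "ucinet_dl": _write_ucinet_dl,
    "gexf": _write_gexf,
    "dot": _write_dot,
    "native_json": _write_native,
}


def dumps(g: Graph, dialect: Union[str, FormatDialect], **options) -> str:
    """Serialize to a string (convenience wrapper over :func:`write`)."""
    buf = _io.StringIO()
    write(g, buf, dialect, **options)
    return buf.getvalue()


def loads(text: str, dialect: Union[str, FormatDialect], **options) -> Graph:
    """Parse from a string (convenience wrapper over :func:`read`)."""
    return read(_io.StringIO(text), dialect, **options)
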