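"""Minimal RDF triple reader: N-Triples plus a restricted Turtle subset.

Only what tabular ingestion needs: subjects, predicate IRIs and object values
(IRIs or plain literals).  Supported Turtle constructs: ``@prefix`` /
``PREFIX`` declarations, prefixed names, the ``a`` keyword, ``;``
predicate-object lists, ``,`` object lists, string literals with optional
language tag or datatype (both stripped), and ``#`` comments.  Blank-node
property lists, collections, multi-line literals and numeric shorthand are
not supported; vocabularies are treated as opaque IRIs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"

_TOKEN_RE = re.compile(
    r"""
    (?P<iri><[^<>"{}|^`\\\s]*>)
  | (?P<literal>"(?:[^"\\]|\\.)*"(?:@[A-Za-z][A-Za-z0-9-]*|\^\^<[^>\s]+>|\^\^[A-Za-z_][\w.-]*:[\w.-]*)?)
  | (?P<punct>[;,.])
  | (?P<keyword>@prefix|@base|\ba\b(?=[\s<]))
  | (?P<pname>[A-Za-z_][\w.-]*?:[\w.-]*|:[\w.-]*)
  | (?P<bnode>_:[\w.-]+)
    """,
    re.VERBOSE,
)

_ESCAPES = {"n": "\n", "t": "\t", "r": "\r", '"': '"', "\\": "\\"}


@dataclass(frozen=True)
class Triple:
    subject: str
    predicate: str
    obj: str
    obj_is_literal: bool


class RDFParseError(ValueError):
    pass


def _unquote(lit: str) -> str:
    # strip language tag / datatype
    body = lit
    if body.endswith(">") and "^^<" in body:
        body = body[: body.rindex("^^<")]
    elif "^^" in body and body.rsplit('"', 1)[-1].startswith("^^"):
        body = body[: body.rindex("^^")]
    elif body.rsplit('"', 1)[-1].startswith("@"):
        body = body[: body.rindex("@")]
    body = body[1:-1]
    out, i = [], 0
    while i < len(body):
        c = body[i]
        if c == "\\" and i + 1 < len(body):
            nxt = body[i + 1]
            if nxt == "u" and i + 5 < len(body):
                out.append(chr(int(body[i + 2 : i + 6], 16)))
                i += 6
                continue
            out.append(_ESCAPES.get(nxt, nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _strip_comments(text: str) -> str:
    out_lines = []
    for line in text.splitlines():
        buf, in_str, i = [], False, 0
        while i < len(line):
            c = line[i]
            if c == '"' and (i == 0 or line[i - 1] != "\\"):
                in_str = not in_str
            if c == "#" and not in_str:
                break
            buf.append(c)
            i += 1
        out_lines.append("".join(buf))
    return "\n".join(out_lines)


def parse_triples(text: str) -> list[Triple]:
    """Parse N-Triples or restricted-Turtle text into a list of triples."""
    text = _strip_comments(text)
    tokens: list[tuple[str, str]] = []
    pos = 0
    # allow SPARQL-style PREFIX (case-insensitive, no leading @)
    text = re.sub(r"(?im)^\s*(PREFIX)\b", "@prefix", text)
    text = re.sub(r"(?im)^\s*(BASE)\b", "@base", text)
    for m in _TOKEN_RE.finditer(text):
        between = text[pos : m.start()]
        if between.strip():
            raise RDFParseError(f"unparseable RDF content near: {between.strip()[:40]!r}")
        tokens.append((m.lastgroup, m.group()))
        pos = m.end()
    if text[pos:].strip():
        raise RDFParseError(f"unparseable RDF content near: {text[pos:].strip()[:40]!r}")

    prefixes: dict[str, str] = {}
    base = ""

    def expand(kind: str, tok: str) -> tuple[str, bool]:
        if kind == "iri":
            iri = tok[1:-1]
            if base and not re.match(r"^[A-Za-z][A-Za-z0-9+.-]*:", iri):
                iri = base + iri
            return iri, False
        if kind == "literal":
            return _unquote(tok), True
        if kind == "pname":
            pre, _, local = tok.partition(":")
            if pre not in prefixes:
                raise RDFParseError(f"undeclared prefix {pre!r} in {tok!r}")
            return prefixes[pre] + local, False
        if kind == "bnode":
            return tok, False
        if kind == "keyword" and tok == "a":
            return RDF_TYPE, False
        raise RDFParseError(f"unexpected token {tok!r}")

    triples: list[Triple] = []
    i = 0
    n = len(tokens)
    while i < n:
        kind, tok = tokens[i]
        if kind == "keyword" and tok in ("@prefix", "@base"):
            if tok == "@prefix":
                if i + 2 >= n or tokens[i + 1][0] != "pname" or tokens[i + 2][0] != "iri":
                    raise RDFParseError("malformed @prefix declaration")
                pre = tokens[i + 1][1].rstrip(":").split(":")[0]
                prefixes[pre] = tokens[i + 2][1][1:-1]
                i += 3
            else:
                if i + 1 >= n or tokens[i + 1][0] != "iri":
                    raise RDFParseError("malformed @base declaration")
                base = tokens[i + 1][1][1:-1]
                i += 2
            if i < n and tokens[i] == ("punct", "."):
                i += 1
            continue
        # subject
        subj, subj_lit = expand(kind, tok)
        if subj_lit:
            raise RDFParseError(f"literal cannot be a subject: {tok!r}")
        i += 1
        while True:  # predicate-object list
            if i >= n:
                raise RDFParseError("unexpected end of input (expected predicate)")
            pkind, ptok = tokens[i]
            pred, pred_lit = expand(pkind, ptok)
            if pred_lit:
                raise RDFParseError(f"literal cannot be a predicate: {ptok!r}")
            i += 1
            while True:  # object list
                if i >= n:
                    raise RDFParseError("unexpected end of input (expected object)")
                okind, otok = tokens[i]
                obj, is_lit = expand(okind, otok)
                triples.append(Triple(subj, pred, obj, is_lit))
                i += 1
                if i < n and tokens[i] == ("punct", ","):
                    i += 1
                    continue
                break
            if i < n and tokens[i] == ("punct", ";"):
                i += 1
                # tolerate trailing ; before .
                if i < n and tokens[i] == ("punct", "."):
                    i += 1
                    break
                continue
            if i < n and tokens[i] == ("punct", "."):
                i += 1
                break
            raise RDFParseError("expected '.', ';' or ',' in triple block")
        # end subject block
    return triples


def emit_ntriples(triples: list[Triple]) -> str:
    """Serialize triples as N-Triples (used for round-trip fixtures)."""
    lines = []
    for t in triples:
        if t.obj_is_literal:
            escaped = t.obj.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")
            obj = f'"{escaped}"'
        elif t.obj.startswith("_:"):
            obj = t.obj
        else:
            obj = f"<{t.obj}>"
        subj = t.subject if t.subject.startswith("_:") else f"<{t.subject}>"
        lines.append(f"{subj} <{t.predicate}> {obj} .")
    return "\n".join(lines) + "\n"
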