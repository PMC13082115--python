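"""Line-oriented parser for the modeling language.

One statement per line (``;`` also separates statements, except inside a
reaction clause where it introduces the rate law).  Statement kinds:

=====================  =============================================
reaction               ``J0: 2 A + n B -> C; k1*A``
event                  ``E0: at time > 3, priority = uniform(0,1): k4 = 10``
algebraic rule         ``A1: 0 = S1 + S2``
assignment rule        ``x := k*y``
rate rule              ``x' = k*y``
initialization         ``S1 = 10`` / ``ka = lognormal(0.1, 0.25)``
inequality             ``10 < J2 < 50`` / ``0 <= R1 <= 1000``
objective              ``maximize 2 R1 - 0.5 R2``
dot property           ``x.mean = 10`` / ``x.position = {50, 40}``
annotation / notes     ``S1 is "http://..."`` / ``model notes "..."``
declaration            ``const species $X in C1``
substanceOnly          ``substanceOnly S1, S2``
model header           ``model foo`` ... ``end``
=====================  =============================================

Identifiers are declared implicitly from the role they appear in; a bare
math reference defaults to parameter.  Parsing never aborts: every problem
becomes a :class:`Diagnostic` with a 1-based line number and parsing
continues with the next statement.  ``//`` and ``/* */`` comments are
stripped (and dropped on round trips).
"""

from __future__ import annotations

import math as _math
import re

from .mathexpr import (
    ExpressionError, MathNode, Neg, Num, free_symbols, parse_expression,
)
from .model import (
    AnnotationEntry, Constraint, Diagnostic, Event, FluxBoundSet, Model,
    NotesEntry, Objective, QUALIFIERS, Reaction, Rule, SpeciesReference,
    SymbolConflictError, SymbolKind, UNCERTAINTY_STATS, UncertaintyStat,
    declare,
)

__all__ = [
    "parse_document", "parse_reaction_clause", "parse_event_clause",
    "parse_rule_or_init_clause", "parse_inequality_clause",
    "parse_objective_clause", "parse_dot_clause", "parse_annotation_clause",
    "ClauseError",
]

_IDENT = r"[A-Za-z_][A-Za-z0-9_]*"
_NUM = r"(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"

_LAYOUT_PROPS = ("position", "size", "centroid", "curvePoints", "styleTemplate")


class ClauseError(ValueError):
    """Malformed statement; converted to a Diagnostic by parse_document."""


# ---------------------------------------------------------------------------
# Lexical helpers (string- and bracket-aware)
# ---------------------------------------------------------------------------

def _strip_comments(text: str) -> str:
    """Blank out // and /* */ comments, preserving newlines and strings."""
    out: list[str] = []
    i, n = 0, len(text)
    state = "code"
    while i < n:
        ch = text[i]
        if state == "code":
            if ch == '"':
                state = "string"
                out.append(ch)
            elif ch == "/" and i + 1 < n and text[i + 1] == "/":
                while i < n and text[i] != "\n":
                    i += 1
                continue
            elif ch == "/" and i + 1 < n and text[i + 1] == "*":
                i += 2
                while i + 1 < n and not (text[i] == "*" and text[i + 1] == "/"):
                    if text[i] == "\n":
                        out.append("\n")
                    i += 1
                i += 2
                continue
            else:
                out.append(ch)
        elif state == "string":
            out.append(ch)
            if ch == "\\" and i + 1 < n:
                out.append(text[i + 1])
                i += 2
                continue
            if ch == '"' or ch == "\n":
                state = "code"
        i += 1
    return "".join(out)


def _scan_top(text: str):
    """Yield (index, char) for characters at bracket depth 0 outside strings."""
    depth = 0
    in_string = False
    i = 0
    while i < len(text):
        ch = text[i]
        if in_string:
            if ch == "\\":
                i += 2
                continue
            if ch == '"':
                in_string = False
        elif ch == '"':
            in_string = True
        elif ch in "({":
            depth += 1
        elif ch in ")}":
            depth = max(depth - 1, 0)
        elif depth == 0:
            yield i, ch
        i += 1


def _split_top(text: str, sep: str) -> list[str]:
    parts: list[str] = []
    last = 0
    for i, ch in _scan_top(text):
        if ch == sep:
            parts.append(text[last:i])
            last = i + 1
    parts.append(text[last:])
    return parts


def _find_top(text: str, sep: str, start: int = 0) -> int:
    for i, ch in _scan_top(text):
        if i >= start and ch == sep:
            return i
    return -1


def _contains_arrow(text: str) -> bool:
    prev = ""
    for _, ch in _scan_top(text):
        if prev == "-" and ch == ">":
            return True
        prev = ch if ch != " " else prev if False else ch
    return False


def _has_comparison(text: str) -> bool:
    chars = dict(_scan_top(text))
    for i, ch in chars.items():
        if ch in "<>":
            return True
    return False


def _find_top_assign(text: str) -> int:
    """Index of the first top-level single '=' (not ==, <=, >=, !=, :=)."""
    chars = dict(_scan_top(text))
    for i, ch in sorted(chars.items()):
        if ch != "=":
            continue
        before = text[i - 1] if i > 0 else ""
        after = text[i + 1] if i + 1 < len(text) else ""
        if before in "<>!=:" or after == "=":
            continue
        return i
    return -1


def _unescape(raw: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(raw):
        ch = raw[i]
        if ch == "\\" and i + 1 < len(raw):
            nxt = raw[i + 1]
            out.append({"n": "\n", '"': '"', "\\": "\\"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _parse_number(text: str) -> float | None:
    text = text.strip()
    if re.fullmatch(r"[+-]?" + _NUM, text):
        return float(text)
    return None


def _parse_brace_list(text: str) -> list[float] | None:
    text = text.strip()
    if not (text.startswith("{") and text.endswith("}")):
        return None
    values: list[float] = []
    inner = text[1:-1].strip()
    if not inner:
        return []
    for part in inner.split(","):
        v = _parse_number(part)
        if v is None:
            raise ClauseError(f"expected a number inside {{...}}, found {part.strip()!r}")
        values.append(v)
    return values


# ---------------------------------------------------------------------------
# Document parser
# ---------------------------------------------------------------------------

class _DocumentParser:
    def __init__(self) -> None:
        self.model = Model()
        self.diags: list[Diagnostic] = []
        self.saw_header = False
        self.saw_end = False
        self._auto = {"reaction": 0, "event": 0, "rule": 0}

    # -- diagnostics -------------------------------------------------------

    def error(self, line: int, msg: str) -> None:
        self.diags.append(Diagnostic("error", line, msg))

    def warning(self, line: int, msg: str) -> None:
        self.diags.append(Diagnostic("warning", line, msg))

    # -- symbol helpers ----------------------------------------------------

    def declare(self, sid: str, kind: SymbolKind, explicit: bool = False):
        return declare(self.model, sid, kind, explicit)

    def declare_math_symbols(self, node: MathNode) -> None:
        for sid in sorted(free_symbols(node)):
            self.declare(sid, SymbolKind.PARAMETER, explicit=False)

    def auto_id(self, prefix: str, counter: str) -> str:
        while True:
            candidate = f"{prefix}{self._auto[counter]}"
            self._auto[counter] += 1
            if candidate not in self.model.symbols:
                return candidate

    # -- driver ------------------------------------------------------------

    def parse(self, text: str) -> tuple[Model, list[Diagnostic]]:
        text = text.replace("\r\n", "\n").replace("−", "-")
        text = _strip_comments(text)
        for lineno, line in enumerate(text.split("\n"), start=1):
            line = line.strip()
            if not line:
                continue
            if _contains_arrow(line):
                statements = [line]
            else:
                statements = [s.strip() for s in _split_top(line, ";")]
            for stmt in statements:
                if not stmt:
                    continue
                try:
                    self.dispatch(stmt, lineno)
                except (ClauseError, ExpressionError, SymbolConflictError) as exc:
                    self.error(lineno, str(exc))
                except Exception as exc:  # crash-freedom over precision
                    self.error(lineno, f"cannot parse statement: {exc}")
        self.finalize()
        return self.model, self.diags

    # -- statement classification -----------------------------------------

    def dispatch(self, stmt: str, line: int) -> None:
        if stmt == "end":
            if not self.saw_header:
                self.warning(line, "'end' without a model header")
            self.saw_end = True
            return
        m = re.fullmatch(rf"model\s+({_IDENT})", stmt)
        if m:
            if self.saw_header:
                self.error(line, "only one model block is supported")
            else:
                self.model.id = m.group(1)
                self.saw_header = True
            return
        if self.saw_end:
            self.warning(line, "statement after 'end' is ignored")
            return
        if _contains_arrow(stmt):
            self.reaction_clause(stmt, line)
            return
        if re.match(r"substanceOnly\b", stmt):
            self.substance_only_clause(stmt, line)
            return
        if re.match(r"(maximize|minimize)\b", stmt):
            self.objective_clause(stmt, line)
            return
        if re.match(rf"(?:{_IDENT}\s*:\s*)?at\b", stmt):
            self.event_clause(stmt, line)
            return
        if re.match(r"(?:const\s+)?(species|compartment|parameter|stoichiometry)\b", stmt):
            self.declaration_clause(stmt, line)
            return
        if re.match(rf"(model|{_IDENT})\s*\.\s*{_IDENT}\s*=", stmt):
            self.dot_clause(stmt, line)
            return
        if re.match(rf"(model|{_IDENT})\s+{_IDENT}\s+\"", stmt):
            self.annotation_clause(stmt, line)
            return
        if re.match(r"0\s*:=", stmt):
            raise ClauseError("cannot assign to the literal 0")
        if re.match(rf"(?:{_IDENT}\s*:\s*)?0\s*=(?!=)", stmt):
            self.algebraic_clause(stmt, line)
            return
        if re.match(rf"{_IDENT}\s*:=", stmt):
            self.assignment_rule_clause(stmt, line)
            return
        if re.match(rf"{_IDENT}\s*'\s*=(?!=)", stmt):
            self.rate_rule_clause(stmt, line)
            return
        if re.match(r"const\s+", stmt):
            self.const_clause(stmt, line)
            return
        if _find_top_assign(stmt) >= 0 and re.match(rf"\$?{_IDENT}\s*=", stmt):
            self.initialization_clause(stmt, line)
            return
        if _has_comparison(stmt):
            self.inequality_clause(stmt, line)
            return
        if re.fullmatch(rf"\$?{_IDENT}\s+in\s+{_IDENT}", stmt):
            self.placement_clause(stmt, line)
            return
        raise ClauseError(f"unrecognized statement: {stmt!r}")

    # -- clause parsers ----------------------------------------------------

    def reaction_clause(self, stmt: str, line: int) -> Reaction:
        semi = _find_top(stmt, ";")
        rate_text = None
        if semi >= 0:
            rate_text = stmt[semi + 1:].strip()
            stmt = stmt[:semi].strip()
            if not rate_text:
                rate_text = None
        label = None
        m = re.match(rf"({_IDENT})\s*:\s*", stmt)
        if m:
            label = m.group(1)
            stmt = stmt[m.end():]
        arrow = stmt.find("->")
        lhs, rhs = stmt[:arrow].strip(), stmt[arrow + 2:].strip()
        reactants = self._parse_side(lhs, line)
        products = self._parse_side(rhs, line)
        if not reactants and not products:
            raise ClauseError("reaction has neither reactants nor products")
        rid = label if label is not None else self.auto_id("_J", "reaction")
        self.declare(rid, SymbolKind.REACTION, explicit=True)
        math = None
        if rate_text:
            math = parse_expression(rate_text)
            self.declare_math_symbols(math)
        rxn = Reaction(id=rid, reactants=reactants, products=products,
                       kinetic_math=math, reversible=True, line=line)
        self.model.reactions.append(rxn)
        return rxn

    def _parse_side(self, text: str, line: int) -> list[SpeciesReference]:
        text = text.strip()
        if not text:
            return []
        refs: list[SpeciesReference] = []
        for term in _split_top(text, "+"):
            term = term.strip()
            if not term:
                raise ClauseError("empty term in reaction side")
            tokens = term.split()
            if len(tokens) > 2:
                if all(re.fullmatch(_NUM, t) for t in tokens[:2]):
                    raise ClauseError(
                        f"two coefficients in a row in term {term!r}")
                raise ClauseError(f"malformed reaction term {term!r}")
            coeff_num: float | None = None
            coeff_id: str | None = None
            if len(tokens) == 2:
                first = tokens[0]
                if re.fullmatch(_NUM, first):
                    coeff_num = float(first)
                    if not coeff_num > 0:
                        raise ClauseError("stoichiometry must be positive")
                elif re.fullmatch(_IDENT, first):
                    coeff_id = first
                else:
                    raise ClauseError(f"bad stoichiometry {first!r}")
                species_tok = tokens[1]
                if re.fullmatch(_NUM, species_tok):
                    raise ClauseError(
                        f"two coefficients in a row in term {term!r}")
            else:
                species_tok = tokens[0]
            boundary = species_tok.startswith("$")
            if boundary:
                species_tok = species_tok[1:]
            if not re.fullmatch(_IDENT, species_tok):
                raise ClauseError(f"bad species name {species_tok!r}")
            entry = self.declare(species_tok, SymbolKind.SPECIES, explicit=boundary)
            if boundary:
                entry.is_boundary = True
            if coeff_id is not None:
                self.declare(coeff_id, SymbolKind.STOICHIOMETRY, explicit=False)
                refs.append(SpeciesReference(species_tok, stoichiometry_id=coeff_id))
            else:
                refs.append(SpeciesReference(species_tok, stoichiometry=coeff_num))
        return refs

    def event_clause(self, stmt: str, line: int) -> Event:
        label = None
        m = re.match(rf"({_IDENT})\s*:\s*", stmt)
        if m and m.group(1) != "at":
            label = m.group(1)
            stmt = stmt[m.end():]
        if not re.match(r"at\b", stmt):
            raise ClauseError("event clause must start with 'at'")
        stmt = stmt[2:].strip()
        colon = _find_top(stmt, ":")
        if colon < 0:
            raise ClauseError("missing ':' after event trigger")
        head, tail = stmt[:colon].strip(), stmt[colon + 1:].strip()
        priority = None
        for i, ch in _scan_top(head):
            if ch == "," and re.match(r"\s*priority\s*=", head[i + 1:]):
                prio_text = head[i + 1:]
                prio_text = prio_text[_find_top_assign(prio_text) + 1:].strip()
                priority = parse_expression(prio_text)
                self.declare_math_symbols(priority)
                head = head[:i].strip()
                break
        if not head:
            raise ClauseError("event has an empty trigger")
        trigger = parse_expression(head)
        self.declare_math_symbols(trigger)
        assignments: list[tuple[str, MathNode]] = []
        if tail:
            for part in _split_top(tail, ","):
                part = part.strip()
                am = re.fullmatch(rf"({_IDENT})\s*=(?!=)\s*(.+)", part, re.DOTALL)
                if not am:
                    raise ClauseError(f"bad event assignment {part!r}")
                target, expr_text = am.group(1), am.group(2)
                expr = parse_expression(expr_text)
                self.declare(target, SymbolKind.PARAMETER, explicit=False)
                self.declare_math_symbols(expr)
                assignments.append((target, expr))
        if not assignments:
            raise ClauseError("event has an empty assignment list")
        eid = label if label is not None else self.auto_id("_E", "event")
        self.declare(eid, SymbolKind.EVENT, explicit=True)
        ev = Event(id=eid, trigger=trigger, priority=priority,
                   assignments=assignments, line=line)
        self.model.events.append(ev)
        return ev

    def algebraic_clause(self, stmt: str, line: int) -> Rule:
        label = None
        m = re.match(rf"({_IDENT})\s*:\s*", stmt)
        if m:
            label = m.group(1)
            stmt = stmt[m.end():]
        m = re.match(r"0\s*=\s*(.+)", stmt, re.DOTALL)
        if not m:
            raise ClauseError("malformed algebraic rule")
        math = parse_expression(m.group(1))
        self.declare_math_symbols(math)
        rid = label if label is not None else self.auto_id("_A", "rule")
        self.declare(rid, SymbolKind.RULE, explicit=True)
        rule = Rule("algebraic", math=math, id=rid, line=line)
        self.model.rules.append(rule)
        return rule

    def assignment_rule_clause(self, stmt: str, line: int) -> Rule:
        m = re.fullmatch(rf"({_IDENT})\s*:=\s*(.+)", stmt, re.DOTALL)
        if not m:
            raise ClauseError("malformed assignment rule")
        target, math = m.group(1), parse_expression(m.group(2))
        self.declare(target, SymbolKind.PARAMETER, explicit=False)
        self.declare_math_symbols(math)
        rule = Rule("assignment", math=math, target_id=target, line=line)
        self.model.rules.append(rule)
        return rule

    def rate_rule_clause(self, stmt: str, line: int) -> Rule:
        m = re.fullmatch(rf"({_IDENT})\s*'\s*=\s*(.+)", stmt, re.DOTALL)
        if not m:
            raise ClauseError("malformed rate rule")
        target, math = m.group(1), parse_expression(m.group(2))
        self.declare(target, SymbolKind.PARAMETER, explicit=False)
        self.declare_math_symbols(math)
        rule = Rule("rate", math=math, target_id=target, line=line)
        self.model.rules.append(rule)
        return rule

    def initialization_clause(self, stmt: str, line: int,
                              is_const: bool = False) -> None:
        m = re.fullmatch(r"(\$?)(%s)\s*=\s*(.+)" % _IDENT, stmt, re.DOTALL)
        if not m:
            raise ClauseError("malformed initialization")
        boundary, target, expr_text = m.group(1) == "$", m.group(2), m.group(3)
        entry = self.declare(
            target,
            SymbolKind.SPECIES if boundary else SymbolKind.PARAMETER,
            explicit=boundary)
        if boundary:
            entry.is_boundary = True
        if is_const:
            entry.is_const = True
        expr = parse_expression(expr_text)
        if isinstance(expr, Num):
            entry.initial_value = expr.value
        elif isinstance(expr, Neg) and isinstance(expr.child, Num):
            entry.initial_value = -expr.child.value
        else:
            self.declare_math_symbols(expr)
            self.model.initial_assignments = [
                (t, e) for t, e in self.model.initial_assignments if t != target]
            self.model.initial_assignments.append((target, expr))

    def const_clause(self, stmt: str, line: int) -> None:
        rest = re.sub(r"^const\s+", "", stmt)
        if _find_top_assign(rest) >= 0:
            self.initialization_clause(rest, line, is_const=True)
            return
        for item in _split_top(rest, ","):
            item = item.strip()
            if not re.fullmatch(_IDENT, item):
                raise ClauseError(f"bad const declaration {item!r}")
            entry = self.declare(item, SymbolKind.PARAMETER, explicit=False)
            entry.is_const = True

    def declaration_clause(self, stmt: str, line: int) -> None:
        m = re.match(r"(const\s+)?(species|compartment|parameter|stoichiometry)\s+(.+)",
                     stmt, re.DOTALL)
        if not m:
            raise ClauseError("malformed declaration")
        is_const = bool(m.group(1))
        kind = SymbolKind(m.group(2))
        for item in _split_top(m.group(3), ","):
            item = item.strip()
            im = re.fullmatch(
                rf"(\$?)({_IDENT})(?:\s+in\s+({_IDENT}))?(?:\s*=\s*(.+))?",
                item, re.DOTALL)
            if not im:
                raise ClauseError(f"malformed declaration item {item!r}")
            boundary, sid, comp, init = (im.group(1) == "$", im.group(2),
                                         im.group(3), im.group(4))
            if boundary and kind is not SymbolKind.SPECIES:
                raise ClauseError("'$' boundary prefix applies only to species")
            entry = self.declare(sid, kind, explicit=True)
            entry.is_const = entry.is_const or is_const
            if boundary:
                entry.is_boundary = True
            if comp:
                if kind is not SymbolKind.SPECIES:
                    raise ClauseError("'in <compartment>' applies only to species")
                self.declare(comp, SymbolKind.COMPARTMENT, explicit=False)
                entry.compartment = comp
            if init is not None:
                expr = parse_expression(init)
                if isinstance(expr, Num):
                    entry.initial_value = expr.value
                elif isinstance(expr, Neg) and isinstance(expr.child, Num):
                    entry.initial_value = -expr.child.value
                else:
                    self.declare_math_symbols(expr)
                    self.model.initial_assignments = [
                        (t, e) for t, e in self.model.initial_assignments if t != sid]
                    self.model.initial_assignments.append((sid, expr))

    def placement_clause(self, stmt: str, line: int) -> None:
        m = re.fullmatch(rf"(\$?)({_IDENT})\s+in\s+({_IDENT})", stmt)
        boundary, sid, comp = m.group(1) == "$", m.group(2), m.group(3)
        entry = self.declare(sid, SymbolKind.SPECIES, explicit=boundary)
        if boundary:
            entry.is_boundary = True
        self.declare(comp, SymbolKind.COMPARTMENT, explicit=False)
        entry.compartment = comp

    def substance_only_clause(self, stmt: str, line: int) -> None:
        rest = re.sub(r"^substanceOnly\s*", "", stmt)
        if not rest:
            raise ClauseError("substanceOnly needs at least one species id")
        for item in rest.split(","):
            item = item.strip()
            if not re.fullmatch(_IDENT, item):
                raise ClauseError(f"bad species id {item!r} in substanceOnly")
            entry = self.declare(item, SymbolKind.SPECIES, explicit=False)
            entry.substance_only = True

    def objective_clause(self, stmt: str, line: int) -> Objective:
        m = re.match(r"(maximize|minimize)\s+(.+)", stmt, re.DOTALL)
        if not m:
            raise ClauseError("objective needs at least one reaction term")
        sense, rest = m.group(1), m.group(2)
        if re.search(r"[*/^()]", rest):
            raise ClauseError(
                "objective must be a linear combination of reaction ids")
        terms: list[tuple[float, str]] = []
        # split into signed terms
        pattern = re.compile(rf"\s*([+-])?\s*(?:({_NUM})\s+)?({_IDENT})\s*")
        pos = 0
        first = True
        while pos < len(rest):
            tm = pattern.match(rest, pos)
            if not tm:
                raise ClauseError(f"malformed objective term near {rest[pos:].strip()!r}")
            if not first and not tm.group(1):
                raise ClauseError(
                    "objective terms must be separated by '+' or '-'")
            sign = -1.0 if tm.group(1) == "-" else 1.0
            coeff = float(tm.group(2)) if tm.group(2) else 1.0
            rid = tm.group(3)
            if re.fullmatch(_NUM, rid):
                raise ClauseError("objective term must end with a reaction id")
            self.declare(rid, SymbolKind.PARAMETER, explicit=False)
            terms.append((sign * coeff, rid))
            pos = tm.end()
            first = False
        if not terms:
            raise ClauseError("objective has no terms")
        obj = Objective(sense=sense, terms=terms, line=line)
        self.model.objectives.append(obj)
        return obj

    def inequality_clause(self, stmt: str, line: int):
        ops: list[str] = []
        segments: list[str] = []
        last = 0
        chars = sorted(dict(_scan_top(stmt)).items())
        i = 0
        while i < len(chars):
            idx, ch = chars[i]
            if ch in "<>":
                nxt = stmt[idx + 1] if idx + 1 < len(stmt) else ""
                op = ch + ("=" if nxt == "=" else "")
                segments.append(stmt[last:idx])
                ops.append(op)
                last = idx + len(op)
            i += 1
        segments.append(stmt[last:])
        segments = [s.strip() for s in segments]
        if len(ops) == 0 or len(ops) > 2:
            raise ClauseError("expected a single or chained inequality")
        directions = {op[0] for op in ops}
        if len(directions) > 1:
            raise ClauseError("mixed '<' and '>' in a chained inequality")
        if ">" in directions:  # normalize to ascending order
            segments = segments[::-1]
            ops = [("<" + op[1:]) for op in ops[::-1]]

        def as_bound(text: str):
            if not text:
                raise ClauseError("missing bound in inequality")
            expr = parse_expression(text)
            if isinstance(expr, Num):
                return expr.value
            if isinstance(expr, Neg) and isinstance(expr.child, Num):
                return -expr.child.value
            self.declare_math_symbols(expr)
            return expr

        if len(ops) == 2:
            subject = segments[1]
            if not re.fullmatch(_IDENT, subject):
                raise ClauseError(
                    "the middle term of a chained inequality must be an identifier")
            lower, upper = as_bound(segments[0]), as_bound(segments[2])
            strict_lower, strict_upper = ops[0] == "<", ops[1] == "<"
        else:
            left, right = segments
            left_is_id = bool(re.fullmatch(_IDENT, left)) and _parse_number(left) is None
            right_is_id = bool(re.fullmatch(_IDENT, right)) and _parse_number(right) is None
            if left_is_id == right_is_id:
                raise ClauseError(
                    "a single inequality needs an identifier on exactly one side")
            if left_is_id:  # id < upper
                subject = left
                lower, upper = None, as_bound(right)
                strict_lower, strict_upper = False, ops[0] == "<"
            else:  # lower < id
                subject = right
                lower, upper = as_bound(left), None
                strict_lower, strict_upper = ops[0] == "<", False

        if self.model.kind_of(subject) is SymbolKind.REACTION:
            return self._make_flux_bound(subject, lower, upper,
                                         strict_lower, strict_upper, line)
        self.declare(subject, SymbolKind.PARAMETER, explicit=False)
        con = Constraint(symbol_id=subject, lower=lower, upper=upper,
                         strict_lower=strict_lower, strict_upper=strict_upper,
                         line=line)
        self.model.constraints.append(con)
        return con

    def _make_flux_bound(self, rid: str, lower, upper,
                         strict_lower: bool, strict_upper: bool,
                         line: int) -> FluxBoundSet:
        if isinstance(lower, MathNode) or isinstance(upper, MathNode):
            raise ClauseError(f"flux bounds on '{rid}' must be numeric")
        if (strict_lower and lower is not None) or (strict_upper and upper is not None):
            self.warning(line, f"strict flux-bound inequality on '{rid}' "
                               "treated as non-strict")
        fb = FluxBoundSet(
            reaction_id=rid,
            lower=-_math.inf if lower is None else lower,
            upper=_math.inf if upper is None else upper,
            line=line)
        self.model.flux_bounds.append(fb)
        return fb

    def dot_clause(self, stmt: str, line: int) -> None:
        m = re.match(rf"(model|{_IDENT})\s*\.\s*({_IDENT})\s*=\s*(.+)",
                     stmt, re.DOTALL)
        target, prop, value = m.group(1), m.group(2), m.group(3).strip()
        lay = self.model.layout
        if target == "model":
            if prop == "layout":
                if value not in ("on", "off"):
                    raise ClauseError("model.layout must be 'on' or 'off'")
                lay.enabled = value == "on"
                return
            if prop == "styleTemplate":
                sm = re.fullmatch(r'"((?:[^"\\]|\\.)*)"', value)
                if not sm:
                    raise ClauseError("styleTemplate needs a quoted name")
                lay.style_template = _unescape(sm.group(1))
                return
            raise ClauseError(f"unknown model property '{prop}'")
        if prop in UNCERTAINTY_STATS:
            self.declare(target, SymbolKind.PARAMETER, explicit=False)
            if prop == "confidenceInterval":
                pair = _parse_brace_list(value)
                if pair is None or len(pair) != 2:
                    raise ClauseError("confidenceInterval needs '{lo, hi}'")
                val: object = (pair[0], pair[1])
            else:
                num = _parse_number(value)
                if num is None:
                    raise ClauseError(f"{prop} needs a single number")
                val = num
            self.model.uncertainty.append(
                UncertaintyStat(element_id=target, stat=prop, value=val, line=line))
            return
        if prop in ("position", "centroid", "size", "curvePoints"):
            values = _parse_brace_list(value)
            if values is None:
                raise ClauseError(f"{prop} needs a brace list of numbers")
            self.declare(target, SymbolKind.PARAMETER, explicit=False)
            if prop in ("position", "centroid", "size"):
                if len(values) != 2:
                    raise ClauseError(f"{prop} needs exactly two numbers")
                if prop == "size":
                    lay.sizes[target] = (values[0], values[1])
                else:
                    lay.positions[target] = (values[0], values[1])
            else:
                if len(values) < 4 or len(values) % 2:
                    raise ClauseError(
                        "curvePoints needs an even number (>= 4) of coordinates")
                points = tuple((values[i], values[i + 1])
                               for i in range(0, len(values), 2))
                lay.reaction_curves[target] = points
            return
        raise ClauseError(f"unknown dot property '{prop}'")

    def annotation_clause(self, stmt: str, line: int) -> None:
        m = re.fullmatch(
            rf"(model|{_IDENT})\s+({_IDENT})\s+\"((?:[^\"\\]|\\.)*)\"\s*",
            stmt, re.DOTALL)
        if not m:
            raise ClauseError("malformed annotation (missing quotes?)")
        target, qualifier, raw = m.group(1), m.group(2), m.group(3)
        text = _unescape(raw)
        if target != "model":
            self.declare(target, SymbolKind.PARAMETER, explicit=False)
        if qualifier == "notes":
            existing = [n for n in self.model.notes if n.element_id == target]
            if existing:
                self.warning(line, f"notes for '{target}' replace an earlier entry")
                self.model.notes = [n for n in self.model.notes
                                    if n.element_id != target]
            self.model.notes.append(NotesEntry(element_id=target, markdown=text,
                                               line=line))
            return
        if qualifier not in QUALIFIERS:
            raise ClauseError(f"unknown annotation qualifier '{qualifier}'")
        self.model.annotations.append(
            AnnotationEntry(element_id=target, qualifier=qualifier, uri=text,
                            line=line))

    # -- finalization ------------------------------------------------------

    def finalize(self) -> None:
        """Reclassify constraints whose subject turned out to be a reaction.

        ``0 <= R1 <= 1000`` may precede the definition of R1; statement
        order must not matter, so the decision is revisited once the whole
        document is known.
        """
        kept: list[Constraint] = []
        for con in self.model.constraints:
            if self.model.kind_of(con.symbol_id) is SymbolKind.REACTION:
                try:
                    self._make_flux_bound(con.symbol_id, con.lower, con.upper,
                                          con.strict_lower, con.strict_upper,
                                          con.line)
                except ClauseError as exc:
                    self.error(con.line, str(exc))
            else:
                kept.append(con)
        self.model.constraints = kept
        if self.saw_header and not self.saw_end:
            self.warning(1, "model block not closed with 'end'")


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def parse_document(text: str) -> tuple[Model, list[Diagnostic]]:
    """Parse a complete model script into a Model plus diagnostics.

    Never raises on malformed input; empty input yields an empty valid
    model.  Both the ASCII ``->`` arrow and the typographic minus-arrow
    are accepted.
    """
    return _DocumentParser().parse(text)


def _clause_parser(model: Model | None) -> _DocumentParser:
    p = _DocumentParser()
    if model is not None:
        p.model = model
    return p


def parse_reaction_clause(text: str, model: Model | None = None) -> Reaction:
    """Parse a single reaction statement (raises ClauseError on problems)."""
    return _clause_parser(model).reaction_clause(text.replace("−", "-").strip(), 1)


def parse_event_clause(text: str, model: Model | None = None) -> Event:
    return _clause_parser(model).event_clause(text.strip(), 1)


def parse_rule_or_init_clause(text: str, model: Model | None = None):
    """Parse an algebraic/assignment/rate rule or an initialization.

    Returns the Rule for rule statements and None for initializations
    (which mutate the model's symbol table / initial-assignment list).
    """
    p = _clause_parser(model)
    stmt = text.strip()
    if re.match(r"0\s*:=", stmt):
        raise ClauseError("cannot assign to the literal 0")
    if re.match(rf"(?:{_IDENT}\s*:\s*)?0\s*=(?!=)", stmt):
        return p.algebraic_clause(stmt, 1)
    if re.match(rf"{_IDENT}\s*:=", stmt):
        return p.assignment_rule_clause(stmt, 1)
    if re.match(rf"{_IDENT}\s*'\s*=(?!=)", stmt):
        return p.rate_rule_clause(stmt, 1)
    if re.match(rf"\$?{_IDENT}\s*=(?!=)", stmt):
        return p.initialization_clause(stmt, 1)
    raise ClauseError("not a rule or initialization statement")


def parse_inequality_clause(text: str, model: Model | None = None):
    """Parse a chained or single inequality into a Constraint or FluxBoundSet.

    The subject becomes a flux bound iff the model already knows it as a
    reaction; otherwise it is declared a parameter and a Constraint results
    (parse_document revisits the decision after the full read).
    """
    return _clause_parser(model).inequality_clause(text.strip(), 1)


def parse_objective_clause(text: str, model: Model | None = None) -> Objective:
    return _clause_parser(model).objective_clause(text.strip(), 1)


def parse_dot_clause(text: str, model: Model | None = None) -> Model:
    p = _clause_parser(model)
    p.dot_clause(text.strip(), 1)
    return p.model


def parse_annotation_clause(text: str, model: Model | None = None) -> Model:
    p = _clause_parser(model)
    p.annotation_clause(text.strip(), 1)
    return p.model
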