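"""Radiology keyword rule-sets and ICD code-sets for case-finding enrichment.

Keyword rules are Boolean expressions over case-insensitive substring
patterns (word stems work: ``opacit`` hits "opacity" and "opacities"),
written in a small infix grammar::

    expr  := or
    or    := and ("OR" and)*
    and   := unary ("AND" unary)*
    unary := "NOT" unary | "(" expr ")" | TERM

Terms are bare words or double-quoted phrases. A rule must contain at least
one positive (non-negated) term. Negation masking is applied at match time:
a term occurrence preceded by a negation cue (default ``"no "``,
``"without "``, ``"resolved"``) within the same sentence (sentences split on
``. ; :``) does not count as a positive mention.

The six shipped rule-sets ``T1``–``T6`` are *illustrative* nested defaults of
strictly increasing breadth, not a published list; real analyses should
supply their own rule file (YAML mapping of id → expression). Likewise the
default ICD code-set (``J80``, ``51882``, ``5185``, prefix ``J9600*``) is an
illustrative stand-in for a site-specific ARDS/respiratory-failure code list.

Enrichment is applied within two report windows relative to screening onset:
``H0_48`` (0–48 h after onset) and ``ANY`` (any time during the admission).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DEFAULT_NEGATION_CUES = ("no ", "without ", "resolved")
_SENTENCE_SPLIT = re.compile(r"[.;:]")


class RuleParseError(ValueError):
    """Rule text is malformed; message carries the token position."""


# ---------------------------------------------------------------------------
# expression tree

@dataclass(frozen=True)
class Term:
    pattern: str

    def serialize(self) -> str:
        if re.search(r"[\s()\"]", self.pattern):
            return f'"{self.pattern}"'
        return self.pattern


@dataclass(frozen=True)
class Not:
    child: "Expr"

    def serialize(self) -> str:
        return f"NOT {self.child.serialize()}"


@dataclass(frozen=True)
class And:
    children: tuple["Expr", ...]

    def serialize(self) -> str:
        return "(" + " AND ".join(c.serialize() for c in self.children) + ")"


@dataclass(frozen=True)
class Or:
    children: tuple["Expr", ...]

    def serialize(self) -> str:
        return "(" + " OR ".join(c.serialize() for c in self.children) + ")"


Expr = Union[Term, Not, And, Or]


@dataclass(frozen=True)
class RuleSet:
    """A named Boolean keyword rule with its negation cues."""

    id: str
    expr: Expr
    negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES

    def serialize(self) -> str:
        return self.expr.serialize()

    def terms(self) -> list[str]:
        out: list[str] = []

        def walk(e: Expr) -> None:
            if isinstance(e, Term):
                out.append(e.pattern)
            elif isinstance(e, Not):
                walk(e.child)
            else:
                for c in e.children:
                    walk(c)

        walk(self.expr)
        return out


# ---------------------------------------------------------------------------
# parsing

_TOKEN = re.compile(r'\s*(\(|\)|"[^"]*"|[^\s()]+)')


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def _positive_terms(expr: Expr, negated: bool = False) -> int:
    if isinstance(expr, Term):
        return 0 if negated else 1
    if isinstance(expr, Not):
        return _positive_terms(expr.child, not negated)
    return sum(_positive_terms(c, negated) for c in expr.children)


def _flatten(cls, children: Iterable[Expr]) -> Expr:
    flat: list[Expr] = []
    for c in children:
        if isinstance(c, cls):
            flat.extend(c.children)
        else:
            flat.append(c)
    return flat[0] if len(flat) == 1 else cls(tuple(flat))


def compile_ruleset(
    rule_id: str,
    text: str,
    negation_cues: Sequence[str] = DEFAULT_NEGATION_CUES,
) -> RuleSet:
    """Parse a rule expression into a :class:`RuleSet`.

    The tree is put in a stable normal form (nested same-operator nodes
    flattened into n-ary nodes) so that
    ``compile(serialize(compile(s))) == compile(s)``.

    Raises :class:`RuleParseError` on malformed input, empty terms, or rules
    with no positive term.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos][0] if pos < len(tokens) else None

    def err(msg: str) -> RuleParseError:
        at = tokens[pos][1] if pos < len(tokens) else len(text)
        return RuleParseError(f"rule {rule_id!r}: {msg} at position {at}")

    def parse_or() -> Expr:
        nonlocal pos
        parts = [parse_and()]
        while peek() is not None and peek().upper() == "OR":
            pos += 1
            parts.append(parse_and())
        return _flatten(Or, parts)

    def parse_and() -> Expr:
        nonlocal pos
        parts = [parse_unary()]
        while peek() is not None and peek().upper() == "AND":
            pos += 1
            parts.append(parse_unary())
        return _flatten(And, parts)

    def parse_unary() -> Expr:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise err("unexpected end of rule")
        if tok.upper() == "NOT":
            pos += 1
            return Not(parse_unary())
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise err("unbalanced parentheses: expected ')'")
            pos += 1
            return inner
        if tok == ")":
            raise err("unbalanced parentheses: unexpected ')'")
        if tok.upper() in ("AND", "OR"):
            raise err(f"unexpected operator {tok!r}")
        pos += 1
        pattern = tok[1:-1] if tok.startswith('"') else tok
        pattern = pattern.strip().lower()
        if not pattern:
            raise err("empty term")
        return Term(pattern)

    if not tokens:
        raise RuleParseError(f"rule {rule_id!r}: empty rule")
    expr = parse_or()
    if pos != len(tokens):
        raise err(f"unexpected trailing token {tokens[pos][0]!r}")
    if _positive_terms(expr) == 0:
        raise RuleParseError(f"rule {rule_id!r}: no positive term")
    return RuleSet(id=rule_id, expr=expr, negation_cues=tuple(negation_cues))


# ---------------------------------------------------------------------------
# matching

def _term_in_text(pattern: str, sentences: list[str], cues: tuple[str, ...],
                  mask_negation: bool) -> bool:
    """True when ``pattern`` has a non-negated occurrence in some sentence."""
    for sent in sentences:
        start = 0
        while True:
            idx = sent.find(pattern, start)
            if idx < 0:
                break
            if not mask_negation:
                return True
            cue_before = any((c_at := sent.find(cue)) >= 0 and c_at < idx for cue in cues)
            if not cue_before:
                return True
            start = idx + 1
    return False


def _eval(expr: Expr, sentences: list[str], cues: tuple[str, ...],
          mask_negation: bool) -> bool:
    if isinstance(expr, Term):
        return _term_in_text(expr.pattern, sentences, cues, mask_negation)
    if isinstance(expr, Not):
        return not _eval(expr.child, sentences, cues, mask_negation)
    if isinstance(expr, And):
        return all(_eval(c, sentences, cues, mask_negation) for c in expr.children)
    return any(_eval(c, sentences, cues, mask_negation) for c in expr.children)


def report_matches(rule: RuleSet, text: str, *, mask_negation: bool = True) -> bool:
    """Evaluate one report's text against a rule."""
    sentences = _SENTENCE_SPLIT.split(str(text).lower())
    return _eval(rule.expr, sentences, rule.negation_cues, mask_negation)


def apply_ruleset(
    rule: RuleSet,
    reports: pd.DataFrame,
    onset: Optional[pd.Timestamp],
    window: str = "H0_48",
    *,
    mask_negation: bool = True,
) -> bool:
    """True iff any in-window report of a stay satisfies the rule.

    ``window`` is ``"H0_48"`` (reports with onset ≤ t < onset + 48 h) or
    ``"ANY"`` (all reports of the admission). With ``window="H0_48"`` and no
    onset, no report is in-window.
    """
    if len(reports) == 0:
        return False
    if window.upper() in ("ANY", "ANYTIME"):
        sel = reports
    elif window.upper() == "H0_48":
        if onset is None or pd.isna(onset):
            return False
        t = reports["time"]
        sel = reports[(t >= onset) & (t < onset + pd.Timedelta(hours=48))]
    else:
        raise ValueError(f"unknown report window {window!r}")
    return any(report_matches(rule, txt, mask_negation=mask_negation) for txt in sel["text"])


# ---------------------------------------------------------------------------
# ICD code-sets

@dataclass(frozen=True)
class CodeSet:
    """Canonical ICD codes, exact plus declared prefixes (trailing ``*``)."""

    exact: frozenset[str]
    prefixes: tuple[str, ...] = ()

    @classmethod
    def from_list(cls, entries: Iterable[str]) -> "CodeSet":
        from .ehr_model import canonical_icd
        exact, prefixes = set(), []
        for e in entries:
            e = canonical_icd(e)
            if e.endswith("*"):
                prefixes.append(e[:-1])
            else:
                exact.add(e)
        return cls(exact=frozenset(exact), prefixes=tuple(prefixes))

    def matches(self, code: str) -> bool:
        return code in self.exact or any(code.startswith(p) for p in self.prefixes)


#: Illustrative ARDS-related code-set (ICD-10 J80 = ARDS; ICD-9 518.82 /
#: 518.5 and ICD-10 J96.00* = acute respiratory failure). Not a published list.
DEFAULT_CODESET = CodeSet.from_list(["J80", "51882", "5185", "J9600*"])


def match_icd(records: pd.DataFrame, codeset: CodeSet = DEFAULT_CODESET) -> bool:
    """True iff any of a stay's ICD records matches the code-set."""
    if len(records) == 0:
        return False
    return bool(records["code"].map(codeset.matches).any())


# ---------------------------------------------------------------------------
# shipped rule-sets and cohort driver

#: Illustrative nested rule family, T1 narrowest … T6 broadest. Each level
#: adds OR-terms, so the positive sets widen monotonically.
DEFAULT_RULE_TEXTS: dict[str, str] = {
    "T1": "ards",
    "T2": "ards OR (diffuse AND alveolar)",
    "T3": "ards OR (diffuse AND alveolar) OR (bilateral AND infiltrat)",
    "T4": "ards OR (diffuse AND alveolar) OR (bilateral AND infiltrat) OR (bilateral AND opacit)",
    "T5": ("ards OR (diffuse AND alveolar) OR (bilateral AND infiltrat) "
           "OR (bilateral AND opacit) OR consolidat"),
    "T6": ("ards OR (diffuse AND alveolar) OR (bilateral AND infiltrat) "
           "OR (bilateral AND opacit) OR consolidat OR effusion OR atelecta"),
}


def default_rulesets() -> dict[str, RuleSet]:
    return {rid: compile_ruleset(rid, txt) for rid, txt in DEFAULT_RULE_TEXTS.items()}


def load_rulesets(path: str | Path) -> dict[str, RuleSet]:
    """Load rule-sets from a YAML mapping of id → expression string."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise RuleParseError(f"{path}: expected a mapping of rule id -> expression")
    return {str(rid): compile_ruleset(str(rid), str(txt)) for rid, txt in raw.items()}


def load_codeset(path: str | Path) -> CodeSet:
    """Load a code-set from a YAML list of codes (trailing ``*`` = prefix)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: expected a list of ICD codes")
    return CodeSet.from_list([str(c) for c in raw])


ENRICH_COLUMNS = ["stay_id", "keyword_hit_48h", "keyword_hit_any", "icd_hit"]


def enrich_cohort(
    bundle,
    screen_results: pd.DataFrame,
    rule: RuleSet,
    codeset: CodeSet = DEFAULT_CODESET,
    *,
    mask_negation: bool = True,
) -> pd.DataFrame:
    """Apply one keyword rule (both windows) and the code-set per screened stay.

    Returns a table with columns ``stay_id, keyword_hit_48h, keyword_hit_any,
    icd_hit``, one row per screen-result row.
    """
    rep_by_stay = dict(iter(bundle.reports.groupby("stay_id", sort=False))) if len(bundle.reports) else {}
    icd_by_stay = dict(iter(bundle.icd.groupby("stay_id", sort=False))) if len(bundle.icd) else {}
    empty_rep = bundle.reports.iloc[0:0]
    empty_icd = bundle.icd.iloc[0:0]
    rows = []
    for r in screen_results.itertuples(index=False):
        reps = rep_by_stay.get(r.stay_id, empty_rep)
        hit48 = apply_ruleset(rule, reps, r.onset, "H0_48", mask_negation=mask_negation)
        hit_any = hit48 or apply_ruleset(rule, reps, r.onset, "ANY", mask_negation=mask_negation)
        rows.append({
            "stay_id": r.stay_id,
            "keyword_hit_48h": hit48,
            "keyword_hit_any": hit_any,
            "icd_hit": match_icd(icd_by_stay.get(r.stay_id, empty_icd), codeset),
        })
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    logger.info("enrich[%s]: %d stays, %d keyword hits (0-48h), %d (any), %d ICD hits",
                rule.id, len(out), int(out["keyword_hit_48h"].sum()) if len(out) else 0,
                int(out["keyword_hit_any"].sum()) if len(out) else 0,
                int(out["icd_hit"].sum()) if len(out) else 0)
    return out
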