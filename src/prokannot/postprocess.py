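"""Post-processing of functional annotations: name hygiene, embedded
assertion extraction and keyword-based role backfilling.

Automated suffixing can produce stuttered names ("kinase protein domain
protein"); transferred names can carry EC numbers or gene symbols inline.
This stage repairs names with an ordered, editable rule table, moves
embedded assertions to their proper fields (EC tokens are never altered;
partial EC numbers remain valid), and assigns a coarse functional role
from name keywords when no role has been assigned.  The whole stage is
idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence, TextIO

from .core import (
    FunctionalAnnotation,
    ROLE_HYPOTHETICAL,
    ROLE_UNKNOWN_FUNCTION,
)

__all__ = [
    "NameRewriteRule",
    "DEFAULT_NAME_RULES",
    "fix_name",
    "extract_embedded",
    "keyword_role",
    "load_keyword_table",
    "load_name_rules",
    "post_process_annotation",
]


@dataclass
class NameRewriteRule:
    pattern: str  # word-boundary regex
    replacement: str
    rule_id: str

    def apply(self, name: str) -> str:
        return re.sub(self.pattern, self.replacement, name)


#: Ordered suffix-repair rules.  Doubled-suffix rules run before the
#: plain stutter rules so "x family protein family protein" collapses to
#: "x family protein" rather than "x family family protein".
DEFAULT_NAME_RULES = (
    NameRewriteRule(
        r"\bdomain protein domain protein\b",
        "domain protein",
        "double-domain",
    ),
    NameRewriteRule(
        r"\bfamily protein family protein\b",
        "family protein",
        "double-family",
    ),
    NameRewriteRule(
        r"\bprotein domain protein\b", "domain protein", "stutter-domain"
    ),
    NameRewriteRule(
        r"\bprotein family protein\b", "family protein", "stutter-family"
    ),
    NameRewriteRule(r"\bprotein protein\b", "protein", "double-protein"),
)

_MAX_PASSES = 3


def fix_name(
    name: str, rules: Sequence[NameRewriteRule] = DEFAULT_NAME_RULES
) -> str:
    """Collapse stuttered suffixes and squeeze whitespace (fixed point)."""
    if not name:
        raise ValueError("name must be non-empty")
    for _ in range(_MAX_PASSES):
        new = name
        for rule in rules:
            new = rule.apply(new)
        new = re.sub(r"\s+", " ", new).strip()
        if new == name:
            break
        name = new
    return name


_EC_TOKEN = r"\d+\.(?:\d+|-)\.(?:\d+|-)\.(?:n?\d+|-)"
_EC_CONTEXT_RE = re.compile(
    rf"\(\s*(?:EC[:\s]\s*)?({_EC_TOKEN})\s*\)|(?:\bEC[:\s]\s*)({_EC_TOKEN})"
)
_SYMBOL_RE = re.compile(r"\(\s*([a-z][A-Za-z0-9]{1,5})\s*\)\s*$")


def extract_embedded(name: str) -> tuple[str, Optional[str], list[str]]:
    """Move embedded EC numbers and a trailing gene symbol out of a name.

    Returns (clean name, gene symbol or None, EC numbers).  EC tokens
    (including partial ones like ``3.4.-.-``) are moved verbatim, never
    rewritten.  A trailing parenthesized short letter-initial token is
    taken as the gene symbol.  The cleaned name is never left empty.
    """
    ecs: list[str] = []

    def _take_ec(m: re.Match) -> str:
        ecs.append(m.group(1) or m.group(2))
        return " "

    clean = _EC_CONTEXT_RE.sub(_take_ec, name)
    symbol: Optional[str] = None
    clean = re.sub(r"\s+", " ", clean).strip(" ,;")
    while True:  # strip stacked trailing symbol tokens in one pass
        m = _SYMBOL_RE.search(clean)
        if not m:
            break
        if symbol is None:
            symbol = m.group(1)
        clean = clean[: m.start()].strip(" ,;")
    if not clean:
        clean = name.strip()
    return clean, symbol, ecs


#: Illustrative default keyword -> role-category table; site-specific
#: vocabularies should be supplied via ``load_keyword_table``.
DEFAULT_KEYWORD_ROLES = {
    "transporter": 143,
    "permease": 143,
    "transport": 143,
    "ribosomal": 158,
    "kinase": 130,
    "protease": 138,
    "transcription": 118,
}


def load_keyword_table(stream: TextIO) -> dict[str, int]:
    """Read a two-column (keyword, role_id) TSV, '#' comments skipped."""
    table: dict[str, int] = {}
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        keyword, role = line.split("\t")
        table[keyword] = int(role)
    return table


def load_name_rules(stream: TextIO) -> list[NameRewriteRule]:
    """Read an ordered (pattern, replacement) TSV of name-repair rules."""
    rules = []
    for idx, raw in enumerate(stream):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        pattern, replacement = line.split("\t")
        rules.append(NameRewriteRule(pattern, replacement, f"rule-{idx}"))
    return rules


def default_keyword_table() -> dict[str, int]:
    ref = resources.files("prokannot.data").joinpath("keyword_roles.tsv")
    with ref.open("r") as fh:
        return load_keyword_table(fh)


_NO_ROLE = {ROLE_UNKNOWN_FUNCTION, ROLE_HYPOTHETICAL}


def keyword_role(
    name: str,
    current_roles: Sequence[int],
    keyword_table: Optional[Mapping[str, int]] = None,
) -> list[int]:
    """Assign a coarse role from name keywords when none is assigned.

    Applies only when the role list is empty or holds only placeholder
    roles (unknown function / hypothetical).  Keywords are tried longest
    first; the first word-boundary match wins.
    """
    if keyword_table is None:
        keyword_table = DEFAULT_KEYWORD_ROLES
    roles = list(current_roles)
    if roles and not set(roles) <= _NO_ROLE:
        return roles
    for keyword in sorted(keyword_table, key=lambda k: (-len(k), k)):
        if re.search(rf"\b{re.escape(keyword)}\b", name, re.IGNORECASE):
            return [keyword_table[keyword]]
    return roles


def post_process_annotation(
    ann: FunctionalAnnotation,
    rules: Sequence[NameRewriteRule] = DEFAULT_NAME_RULES,
    keyword_table: Optional[Mapping[str, int]] = None,
) -> FunctionalAnnotation:
    """Apply the whole post-processing stage to one annotation."""
    clean, symbol, ecs = extract_embedded(ann.common_name)
    clean = fix_name(clean, rules)
    merged_ecs = list(ann.ec_numbers)
    for ec in ecs:
        if ec not in merged_ecs:
            merged_ecs.append(ec)
    roles = keyword_role(clean, ann.tigr_roles, keyword_table)
    return ann.replace(
        common_name=clean,
        gene_symbol=ann.gene_symbol or symbol,
        ec_numbers=merged_ecs,
        tigr_roles=roles,
    )
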