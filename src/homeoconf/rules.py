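"""The rule base: "if ... then ..." statements mapping fuzzy inputs to confidence.

Antecedents are boolean expressions over atoms of the form
``<variable> is <label>`` (e.g. ``synteny is high``) combined with ``and``,
``or``, ``not`` and parentheses.  Under the Mamdani algebra these evaluate
on membership degrees with AND = min, OR = max, NOT = complement.

The default five-rule base encodes the scoring rationale: a pair with high
local synteny, low evolutionary distance and a one-to-one-like copy number
is almost certainly a real homoeolog (very high confidence); a pair with no
synteny, high distance and a high copy number looks like a fast-evolving
repeat family (very low confidence); the three middle rules grade everything
in between, leaning heavily on the synteny score.  Rules live in a YAML file
so the base can be swapped without touching code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

INPUT_VARIABLES = ("synteny", "distance", "copynr")
INPUT_LABELS = ("low", "med", "high")
OUTPUT_LABELS = ("very low", "low", "med", "high", "very high")

# accepted spellings for the input variables in rule files
_VARIABLE_ALIASES = {
    "synteny": "synteny",
    "synteny_score": "synteny",
    "distance": "distance",
    "copynr": "copynr",
    "copy_nr": "copynr",
    "total_copy_nr": "copynr",
    "totalcopynr": "copynr",
}

Degrees = Mapping[tuple[str, str], float]


class RuleError(ValueError):
    """A rule references an unknown variable/label or cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    variable: str
    label: str

    def evaluate(self, degrees: Degrees) -> float:
        try:
            return degrees[(self.variable, self.label)]
        except KeyError:
            raise RuleError(
                f"no membership degree for '{self.variable} is {self.label}'"
            ) from None

    def __str__(self) -> str:
        return f"{self.variable} is {self.label}"


@dataclass(frozen=True)
class Not:
    child: "Node"

    def evaluate(self, degrees: Degrees) -> float:
        return 1.0 - self.child.evaluate(degrees)

    def __str__(self) -> str:
        return f"not ({self.child})"


@dataclass(frozen=True)
class And:
    left: "Node"
    right: "Node"

    def evaluate(self, degrees: Degrees) -> float:
        return min(self.left.evaluate(degrees), self.right.evaluate(degrees))

    def __str__(self) -> str:
        return f"({self.left}) and ({self.right})"


@dataclass(frozen=True)
class Or:
    left: "Node"
    right: "Node"

    def evaluate(self, degrees: Degrees) -> float:
        return max(self.left.evaluate(degrees), self.right.evaluate(degrees))

    def __str__(self) -> str:
        return f"({self.left}) or ({self.right})"


Node = Atom | Not | And | Or

_TOKEN_RE = re.compile(r"\(|\)|[A-Za-z_]+")


def _tokenize(text: str) -> list[str]:
    tokens = _TOKEN_RE.findall(text)
    if "".join(tokens).replace("(", "").replace(")", "") != re.sub(r"\s|\(|\)", "", text):
        raise RuleError(f"unrecognized characters in antecedent: {text!r}")
    return tokens


def parse_antecedent(text: str) -> Node:
    """Parse an antecedent expression string into an evaluable tree.

    Grammar (lowest to highest precedence)::

        expr   := term ("or" term)*
        term   := factor ("and" factor)*
        factor := "not" factor | "(" expr ")" | VAR "is" LABEL
    """
    tokens = _tokenize(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise RuleError(f"unexpected end of antecedent: {text!r}")
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> Node:
        node = parse_term()
        while peek() == "or":
            take()
            node = Or(node, parse_term())
        return node

    def parse_term() -> Node:
        node = parse_factor()
        while peek() == "and":
            take()
            node = And(node, parse_factor())
        return node

    def parse_factor() -> Node:
        tok = take()
        if tok == "not":
            return Not(parse_factor())
        if tok == "(":
            node = parse_expr()
            if take() != ")":
                raise RuleError(f"missing ')' in antecedent: {text!r}")
            return node
        var = _VARIABLE_ALIASES.get(tok.lower())
        if var is None:
            raise RuleError(f"unknown variable {tok!r} in antecedent: {text!r}")
        if take() != "is":
            raise RuleError(f"expected 'is' after {tok!r} in antecedent: {text!r}")
        label = take().lower()
        if label not in INPUT_LABELS:
            raise RuleError(
                f"unknown class {label!r} for {var}; expected one of {INPUT_LABELS}"
            )
        return Atom(var, label)

    node = parse_expr()
    if pos != len(tokens):
        raise RuleError(f"trailing tokens in antecedent: {text!r}")
    return node


@dataclass(frozen=True)
class Rule:
    """One fuzzy rule: an antecedent tree and one output class label."""

    antecedent: Node
    consequent: str
    text: str = ""

    def firing_strength(self, degrees: Degrees) -> float:
        return self.antecedent.evaluate(degrees)


def _normalize_output_label(label: str) -> str:
    norm = label.strip().lower().replace("_", " ")
    if norm not in OUTPUT_LABELS:
        raise RuleError(
            f"unknown confidence class {label!r}; expected one of {OUTPUT_LABELS}"
        )
    return norm


@dataclass
class RuleSet:
    """An ordered, non-empty collection of rules."""

    rules: list[Rule]

    def __post_init__(self) -> None:
        if not self.rules:
            raise RuleError("a ruleset must contain at least one rule")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RuleSet":
        entries = data.get("rules")
        if not isinstance(entries, list):
            raise RuleError("rule file must contain a top-level 'rules' list")
        rules = []
        for entry in entries:
            try:
                cond, cons = entry["if"], entry["then"]
            except (TypeError, KeyError):
                raise RuleError(f"rule entry needs 'if' and 'then': {entry!r}") from None
            rules.append(
                Rule(
                    antecedent=parse_antecedent(cond),
                    consequent=_normalize_output_label(cons),
                    text=cond,
                )
            )
        return cls(rules)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleSet":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "RuleSet":
        text = resources.files("homeoconf.data").joinpath("default_rules.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    def to_yaml_text(self) -> str:
        return yaml.safe_dump(
            {"rules": [{"if": r.text or str(r.antecedent), "then": r.consequent} for r in self.rules]},
            sort_keys=False,
        )
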