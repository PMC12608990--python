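"""Heuristic IF-THEN rules and rule blocks, loadable from YAML.

Rule bases are data, not code: the default base ships as a YAML file with
one document per block. Each rule has an antecedent (a list of
``(variable, label)`` terms joined by AND = minimum or OR = maximum), a
consequent ``(output variable, output label)``, and an optional weight in
(0, 1] that scales the firing degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml


@dataclass(frozen=True)
class Rule:
    antecedent: tuple[tuple[str, str], ...]  # ((variable, label), ...)
    consequent: tuple[str, str]  # (output variable, output label)
    connective: str = "and"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.antecedent) <= 8:
            raise ValueError(f"antecedent must have 1-8 terms, got {len(self.antecedent)}")
        if self.connective not in ("and", "or"):
            raise ValueError(f"connective must be 'and' or 'or', got {self.connective!r}")
        if not 0 < self.weight <= 1:
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")

    def firing_degree(self, memberships: dict[str, dict[str, float]]) -> float:
        """Weighted antecedent degree given fuzzified inputs.

        ``memberships`` maps variable name -> {label: degree}. A missing
        variable is a configuration error.
        """
        degrees = []
        for var, label in self.antecedent:
            if var not in memberships:
                raise KeyError(f"rule references variable {var!r} absent from memberships")
            degrees.append(memberships[var].get(label, 0.0))
        combined = min(degrees) if self.connective == "and" else max(degrees)
        return self.weight * combined


@dataclass(frozen=True)
class RuleBlock:
    block_id: str
    rules: tuple[Rule, ...]

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def output_variables(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.consequent[0], None)
        return tuple(seen)

    def rules_for_output(self, output_variable: str) -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.consequent[0] == output_variable)


def _parse_rule(raw: dict) -> Rule:
    terms = tuple((t["var"], t["is"]) for t in raw["if"])
    then = (raw["then"]["var"], raw["then"]["is"])
    return Rule(
        antecedent=terms,
        consequent=then,
        connective=raw.get("connective", "and"),
        weight=float(raw.get("weight", 1.0)),
    )


def load_rule_blocks(path: str | Path) -> dict[str, RuleBlock]:
    """Load all rule blocks from a YAML file (one document per block).

    Each document is ``{block: <id>, rules: [{if: [{var, is}...],
    connective, then: {var, is}, weight}, ...]}``.
    """
    blocks: dict[str, RuleBlock] = {}
    with open(path) as fh:
        for doc in yaml.safe_load_all(fh):
            if doc is None:
                continue
            block_id = doc["block"]
            rules = tuple(_parse_rule(r) for r in doc["rules"])
            blocks[block_id] = RuleBlock(block_id=block_id, rules=rules)
    return blocks


def validate_blocks(
    blocks: dict[str, RuleBlock],
    variables: dict[str, Iterable[str]],
) -> None:
    """Check that every referenced variable/label exists.

    ``variables`` maps variable name -> iterable of valid labels (covers both
    input and output variables).
    """
    vocab = {name: set(labels) for name, labels in variables.items()}
    for block in blocks.values():
        for rule in block.rules:
            for var, label in (*rule.antecedent, rule.consequent):
                if var not in vocab:
                    raise ValueError(f"block {block.block_id!r}: unknown variable {var!r}")
                if label not in vocab[var]:
                    raise ValueError(f"block {block.block_id!r}: variable {var!r} has no label {label!r}")
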