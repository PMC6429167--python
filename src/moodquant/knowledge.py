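"""Decision-tree knowledge export: Jena-style rules and feature annotations.

Every root-to-leaf path of every tree in a trained model becomes one
textual inference rule.  The dialect follows the flat clause grammar of
Jena forward rules: a typed subject binding, a ``hasValue`` binding per
feature, a comparator clause (``greaterThan`` for right branches,
``lessThanOrEqual`` for left branches, ties going left), an
``onElectrode`` clause naming the recording site, and a terminal
``AssignOne`` that assigns the leaf's mood-status value::

    rule1: (?subject rdf:type base:Subject)
           (?v1 rdf:type base:denoised_min_CD6) (?v1 base:hasValue ?value1)
           greaterThan(?value1, -0.2539)
           (?v1 base:onElectrode ?point1) (?point1 rdfs:label "FP1") ...
           (?out rdf:type base:MoodStatus) (?out base:hasMoodStatusValue ?valueOut)
           -> AssignOne(?valueOut, 0.41)

Rules reuse the tree's stored thresholds and leaf values verbatim (full
``repr`` precision), so applying the rules reproduces ``predict`` exactly.
Feature annotations translate catalog names into clinician-readable
descriptions (e.g. which wavelet layer and which subband a coefficient
statistic refers to).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CatalogError, InferenceIntegrityError, MoodQuantError, SchemaError
from .features import ALIASES, CATALOG, resolve_feature_name
from .model import QuantModel, TreeStruct

COMPARATORS = ("greaterThan", "lessThanOrEqual")


@dataclass(frozen=True)
class Condition:
    feature_name: str
    electrode: str
    comparator: str  # greaterThan | lessThanOrEqual
    threshold: float

    def holds(self, value: float) -> bool:
        if self.comparator == "greaterThan":
            return value > self.threshold
        return value <= self.threshold


@dataclass
class Rule:
    """One root-to-leaf path rendered as a Jena-style rule."""

    rule_id: str
    tree_index: int
    conditions: tuple[Condition, ...]
    leaf_value: float

    def render(self) -> str:
        parts = [f"{self.rule_id}:", "(?subject rdf:type base:Subject)"]
        for i, c in enumerate(self.conditions, start=1):
            parts.append(f"(?v{i} rdf:type base:{c.feature_name})")
            parts.append(f"(?v{i} base:hasValue ?value{i})")
            parts.append(f"{c.comparator}(?value{i}, {c.threshold!r})")
            parts.append(f"(?v{i} base:onElectrode ?point{i})")
            parts.append(f'(?point{i} rdfs:label "{c.electrode}")')
        parts.append("(?out rdf:type base:MoodStatus)")
        parts.append("(?out base:hasMoodStatusValue ?valueOut)")
        parts.append(f"-> AssignOne(?valueOut, {self.leaf_value!r})")
        return " ".join(parts)

    @property
    def rendered_text(self) -> str:
        return self.render()


_COND_RE = re.compile(
    r"\(\?v(\d+) rdf:type base:([A-Za-z0-9_]+)\)\s*"
    r"\(\?v\1 base:hasValue \?value\1\)\s*"
    r"(greaterThan|lessThanOrEqual)\(\?value\1, ([-+0-9.eE]+)\)\s*"
    r"\(\?v\1 base:onElectrode \?point\1\)\s*"
    r'\(\?point\1 rdfs:label "([^"]+)"\)'
)
_HEAD_RE = re.compile(r"^\s*([A-Za-z0-9_]+):")
_ASSIGN_RE = re.compile(r"->\s*AssignOne\(\?valueOut, ([-+0-9.eE]+)\)")


def parse_rule(text: str, tree_index: int = 0) -> Rule:
    """Parse a rendered rule back into its structured form."""
    head = _HEAD_RE.match(text)
    if not head:
        raise SchemaError("rule text missing 'ruleN:' header")
    assign = _ASSIGN_RE.search(text)
    if not assign:
        raise SchemaError("rule text missing AssignOne consequent")
    conditions = tuple(
        Condition(
            feature_name=m.group(2),
            electrode=m.group(5),
            comparator=m.group(3),
            threshold=float(m.group(4)),
        )
        for m in _COND_RE.finditer(text)
    )
    return Rule(
        rule_id=head.group(1),
        tree_index=tree_index,
        conditions=conditions,
        leaf_value=float(assign.group(1)),
    )


def _split_electrode(column: str, channel_mode: str) -> tuple[str, str]:
    """Resolve a model column to (base feature name, electrode label)."""
    for prefix, elec in (("fp1__", "FP1"), ("fp2__", "FP2")):
        if column.startswith(prefix):
            return column[len(prefix) :], elec
    if channel_mode == "fp1":
        return column, "FP1"
    if channel_mode == "fp2":
        return column, "FP2"
    if channel_mode == "mean":
        return column, "FP1&FP2"
    return column, "FP1"


def _tree_rules(
    tree: TreeStruct, tree_index: int, feature_names: tuple[str, ...],
    channel_mode: str, start_id: int,
) -> list[Rule]:
    rules: list[Rule] = []

    def walk(node: int, path: tuple[Condition, ...]) -> None:
        if tree.feature[node] < 0:
            rules.append(
                Rule(
                    rule_id=f"rule{start_id + len(rules)}",
                    tree_index=tree_index,
                    conditions=path,
                    leaf_value=float(tree.value[node]),
                )
            )
            return
        name, elec = _split_electrode(
            feature_names[int(tree.feature[node])], channel_mode
        )
        thr = float(tree.threshold[node])
        walk(
            int(tree.left[node]),
            path + (Condition(name, elec, "lessThanOrEqual", thr),),
        )
        walk(
            int(tree.right[node]),
            path + (Condition(name, elec, "greaterThan", thr),),
        )

    walk(0, ())
    return rules


def tree_to_rules(model: QuantModel) -> list[Rule]:
    """One rule per root-to-leaf path per tree of a fitted model."""
    if not model.trees:
        raise MoodQuantError("model has no fitted trees")
    rules: list[Rule] = []
    for ti, tree in enumerate(model.trees):
        rules.extend(
            _tree_rules(
                tree, ti, model.feature_names, model.channel_mode,
                start_id=len(rules) + 1,
            )
        )
    return rules


def _condition_value(values: dict[str, float], cond: Condition) -> float:
    """Look a condition's feature up in a (standardized) feature mapping."""
    candidates = []
    if cond.electrode in ("FP1", "FP2"):
        candidates.append(f"{cond.electrode.lower()}__{cond.feature_name}")
        if cond.feature_name in ALIASES:
            candidates.append(f"{cond.electrode.lower()}__{ALIASES[cond.feature_name]}")
    candidates.append(cond.feature_name)
    candidates.append(ALIASES.get(cond.feature_name, cond.feature_name))
    for key in candidates:
        if key in values:
            return float(values[key])
    raise SchemaError(f"feature {cond.feature_name!r} ({cond.electrode}) not in vector")


def apply_rules(
    rules: list[Rule], feature_vector: dict[str, float] | pd.Series
) -> float:
    """Fire the rule set on one standardized feature vector.

    Within each tree's rule group exactly one rule must fire (the paths
    partition the feature space); the forest output is the mean of the
    fired leaf values, identical to ``QuantModel.predict``.
    """
    if isinstance(feature_vector, pd.Series):
        feature_vector = feature_vector.to_dict()
    by_tree: dict[int, list[Rule]] = {}
    for r in rules:
        by_tree.setdefault(r.tree_index, []).append(r)
    assigned: list[float] = []
    for ti in sorted(by_tree):
        fired = [
            r
            for r in by_tree[ti]
            if all(c.holds(_condition_value(feature_vector, c)) for c in r.conditions)
        ]
        if len(fired) != 1:
            raise InferenceIntegrityError(
                f"tree {ti}: {len(fired)} rules fired (expected exactly 1)"
            )
        assigned.append(fired[0].leaf_value)
    return float(np.mean(assigned))


def write_rules(rules: list[Rule], path: str | Path) -> None:
    """UTF-8 rule file, one rule block per path, grouped per tree.

    The header documents the forest contract: the fired leaf values of the
    per-tree rule groups are averaged to give the model output.
    """
    lines = [
        "# Jena-style rule export",
        "# One rule per root-to-leaf path; rule groups are per tree.",
        "# Forest output = mean over trees of the fired rule's assigned value.",
    ]
    current = None
    for r in rules:
        if r.tree_index != current:
            current = r.tree_index
            lines.append(f"# tree {current}")
        lines.append(r.render())
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rules(path: str | Path) -> list[Rule]:
    rules = []
    tree_index = 0
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line.startswith("# tree "):
            tree_index = int(line.split()[-1])
            continue
        if not line or line.startswith("#"):
            continue
        rules.append(parse_rule(line, tree_index=tree_index))
    return rules


# ---------------------------------------------------------------------------
# feature annotations


@dataclass(frozen=True)
class FeatureAnnotation:
    feature_name: str
    description: str
    source: str
    electrode: str = "FP1|FP2"


def annotate_feature(feature_name: str) -> FeatureAnnotation:
    """Human-readable annotation of a catalog feature (aliases resolved)."""
    name = feature_name
    electrode = "FP1|FP2"
    for prefix, elec in (("fp1__", "FP1"), ("fp2__", "FP2")):
        if name.startswith(prefix):
            name, electrode = name[len(prefix) :], elec
    try:
        canonical = resolve_feature_name(name)
    except CatalogError:
        raise CatalogError(f"unknown feature name {feature_name!r}") from None
    entry = CATALOG[canonical]
    return FeatureAnnotation(
        feature_name=canonical,
        description=entry.description,
        source=entry.source,
        electrode=electrode,
    )


def annotations_frame() -> pd.DataFrame:
    """All 176 annotations as a DataFrame."""
    rows = [vars(annotate_feature(name)) for name in CATALOG]
    return pd.DataFrame(rows)


def export_annotations(
    path_csv: str | Path | None = None,
    path_triples: str | Path | None = None,
    rules: list[Rule] | None = None,
) -> str:
    """Flat annotation report: a CSV table and a triple-style text document.

    The triple document carries subject-property-object lines for every
    catalog feature, followed by any rules; it re-parses to the same set.
    """
    df = annotations_frame()
    if path_csv is not None:
        df.to_csv(path_csv, index=False)
    lines = []
    for row in df.itertuples(index=False):
        lines.append(f'base:{row.feature_name} base:source "{row.source}" .')
        lines.append(f'base:{row.feature_name} base:onElectrode "{row.electrode}" .')
        lines.append(
            f'base:{row.feature_name} base:hasDescription "{row.description}" .'
        )
    if rules:
        lines.append("")
        for r in rules:
            lines.append(r.render())
    doc = "\n".join(lines) + "\n"
    if path_triples is not None:
        Path(path_triples).write_text(doc, encoding="utf-8")
    return doc


_TRIPLE_RE = re.compile(r'^base:([A-Za-z0-9_]+) base:([A-Za-z]+) "([^"]*)" \.$')


def parse_annotations(doc: str) -> dict[str, dict[str, str]]:
    """Parse the triple-style document back into {feature: {property: value}}."""
    out: dict[str, dict[str, str]] = {}
    for line in doc.splitlines():
        m = _TRIPLE_RE.match(line.strip())
        if m:
            out.setdefault(m.group(1), {})[m.group(2)] = m.group(3)
    return out
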