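"""Read and write Bayesian-network model files.

The native dialect is YAML (JSON is accepted too, being a YAML subset) with
three top-level keys:

``nodes``
    list of ``{name, states, group}`` entries (``group`` optional);
``edges``
    list of ``{parent, child}`` pairs;
``cpt_rules``
    list of ``{child, pattern, distribution}`` entries, where ``pattern``
    maps a subset of the child's parents to state labels (unlisted parents
    are wildcards) and ``distribution`` maps every child state to a
    probability in ``[0, 1]``.

Unknown keys are rejected so that typos cannot silently drop information.
Loading compiles the rules into full CPTs; saving writes the compact rules
back out, and a save/load cycle reproduces the in-memory model exactly.

An experimental write-only export to the GeNIe XDSL format is provided for
interoperability with graphical BN editors; the YAML dialect remains the
source of truth.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from pathlib import Path

import yaml

from .network import (
    BayesianNetworkModel,
    CPTRule,
    EdgeSpec,
    ModelError,
    NodeSpec,
    compile_cpt,
)

__all__ = ["load_model", "loads_model", "save_model", "dumps_model", "to_xdsl"]

_TOP_KEYS = {"nodes", "edges", "cpt_rules"}
_NODE_KEYS = {"name", "states", "group"}
_EDGE_KEYS = {"parent", "child"}
_RULE_KEYS = {"child", "pattern", "distribution"}


def _check_keys(mapping: dict, allowed: set[str], what: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ModelError(f"{what} contains unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


def loads_model(text: str) -> BayesianNetworkModel:
    """Parse a model from YAML/JSON text and compile its CPTs."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ModelError("model file must contain a mapping at the top level")
    _check_keys(doc, _TOP_KEYS, "model file")

    nodes: list[NodeSpec] = []
    for raw in doc.get("nodes", []):
        _check_keys(raw, _NODE_KEYS, f"node entry {raw.get('name', '?')!r}")
        nodes.append(
            NodeSpec(
                name=str(raw["name"]),
                states=tuple(str(s) for s in raw["states"]),
                group=str(raw.get("group", "")),
            )
        )

    edges: list[EdgeSpec] = []
    for raw in doc.get("edges", []):
        _check_keys(raw, _EDGE_KEYS, "edge entry")
        edges.append(EdgeSpec(parent=str(raw["parent"]), child=str(raw["child"])))

    rules: list[CPTRule] = []
    for raw in doc.get("cpt_rules", []):
        _check_keys(raw, _RULE_KEYS, f"cpt_rule for {raw.get('child', '?')!r}")
        rules.append(
            CPTRule.make(
                child=str(raw["child"]),
                pattern={str(k): str(v) for k, v in (raw.get("pattern") or {}).items()},
                distribution={str(k): float(v) for k, v in raw["distribution"].items()},
            )
        )

    model = BayesianNetworkModel(nodes=nodes, edges=edges, cpt_rules=rules)
    by_name = {n.name: n for n in nodes}
    for node in nodes:
        parent_names = model.parents_of(node.name)
        missing = [p for p in parent_names if p not in by_name]
        if missing:
            raise ModelError(f"edges for {node.name!r} reference unknown node(s) {missing}")
        node_rules = [r for r in rules if r.child == node.name]
        model.cpts[node.name] = compile_cpt(node_rules, node, [by_name[p] for p in parent_names])
    return model


def load_model(path: str | Path) -> BayesianNetworkModel:
    return loads_model(Path(path).read_text())


def dumps_model(model: BayesianNetworkModel) -> str:
    """Serialize the model (nodes, edges, and compact CPT rules) to YAML."""
    doc = {
        "nodes": [
            {"name": n.name, "states": list(n.states), "group": n.group} for n in model.nodes
        ],
        "edges": [{"parent": e.parent, "child": e.child} for e in model.edges],
        "cpt_rules": [
            {
                "child": r.child,
                "pattern": dict(r.pattern),
                "distribution": dict(r.distribution),
            }
            for r in model.cpt_rules
        ],
    }
    buf = io.StringIO()
    yaml.safe_dump(doc, buf, sort_keys=False, default_flow_style=None, width=120)
    return buf.getvalue()


def save_model(model: BayesianNetworkModel, path: str | Path) -> None:
    Path(path).write_text(dumps_model(model))


def to_xdsl(model: BayesianNetworkModel) -> str:
    """Write-only, best-effort export to GeNIe's XDSL (XML) format.

    Mapping: node names become node ids, state labels become state ids
    (non-alphanumeric characters replaced by underscores), and CPT rows are
    flattened in this package's mixed-radix row order (first parent most
    significant), which matches GeNIe's probability-vector layout.
    """

    def ident(s: str) -> str:
        out = "".join(c if c.isalnum() or c == "_" else "_" for c in s)
        return out if out and not out[0].isdigit() else f"s_{out}"

    root = ET.Element("smile", version="1.0", id="cscc_bn_export", numsamples="10000")
    nodes_el = ET.SubElement(root, "nodes")
    for n in model.nodes:
        cpt = model.cpts[n.name]
        cpt_el = ET.SubElement(nodes_el, "cpt", id=ident(n.name))
        for s in n.states:
            ET.SubElement(cpt_el, "state", id=ident(s))
        if cpt.parents:
            ET.SubElement(cpt_el, "parents").text = " ".join(ident(p) for p in cpt.parents)
        probs = " ".join(repr(float(v)) for v in cpt.rows.reshape(-1))
        ET.SubElement(cpt_el, "probabilities").text = probs

    ext = ET.SubElement(root, "extensions")
    genie = ET.SubElement(ext, "genie", version="1.0", name="cscc_bn export")
    for n in model.nodes:
        node_el = ET.SubElement(genie, "node", id=ident(n.name))
        ET.SubElement(node_el, "name").text = n.name

    return ET.tostring(root, encoding="unicode", xml_declaration=True)
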