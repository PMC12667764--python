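"""Provenance graphs: who/what used and generated which artifacts.

Each run is recorded as a typed directed acyclic graph in the W3C PROV
spirit: Entities (model, connectome, coupling, integrator, initial
conditions, stimuli, every time series and derivative), Activities (the
simulation and each observation step) and Agents (software, optionally a
human author), connected by ``used``, ``wasGeneratedBy``,
``wasDerivedFrom`` and ``wasAttributedTo`` relations.  Usages may carry a
role string (qualified usage) to distinguish, say, the coupling function
from the integrator within the same activity.

Graphs are append-only across re-runs of derived steps: re-derivation adds
new Entities rather than mutating recorded ones.  Export is linked-data
JSON with a context mapping the relation names to PROV vocabulary IRIs;
re-import reproduces the graph isomorphically.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .errors import NeuromassError

ENTITY, ACTIVITY, AGENT = "Entity", "Activity", "Agent"
NODE_TYPES = (ENTITY, ACTIVITY, AGENT)
RELATIONS = ("used", "wasGeneratedBy", "wasDerivedFrom", "wasAttributedTo")

#: fixed role vocabulary for qualified usages
ROLES = (
    "dynamics model", "connectome", "coupling function", "integrator",
    "initial conditions", "stimulus", "input time series", "kernel",
)

PROV_CONTEXT = {
    "prov": "http://www.w3.org/ns/prov#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "label": "rdfs:label",
    "Entity": "prov:Entity",
    "Activity": "prov:Activity",
    "Agent": "prov:Agent",
    "used": {"@id": "prov:used", "@type": "@id"},
    "wasGeneratedBy": {"@id": "prov:wasGeneratedBy", "@type": "@id"},
    "wasDerivedFrom": {"@id": "prov:wasDerivedFrom", "@type": "@id"},
    "wasAttributedTo": {"@id": "prov:wasAttributedTo", "@type": "@id"},
    "qualifiedUsage": "prov:qualifiedUsage",
    "entity": {"@id": "prov:entity", "@type": "@id"},
    "hadRole": "prov:hadRole",
}


class ProvenanceError(NeuromassError):
    pass


@dataclass
class ProvenanceGraph:
    """Typed PROV graph backed by a networkx DiGraph."""

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    # -- construction -------------------------------------------------------
    def _add_node(self, ntype: str, label: str, node_id: Optional[str] = None,
                  **attrs) -> str:
        if node_id is None:
            node_id = f"urn:uuid:{uuid.uuid4()}"
        self.graph.add_node(node_id, type=ntype, label=label, **attrs)
        return node_id

    def add_entity(self, label, node_id=None, **attrs):
        return self._add_node(ENTITY, label, node_id, **attrs)

    def add_activity(self, label, node_id=None, **attrs):
        return self._add_node(ACTIVITY, label, node_id, **attrs)

    def add_agent(self, label, node_id=None, **attrs):
        return self._add_node(AGENT, label, node_id, **attrs)

    def node_type(self, node_id):
        return self.graph.nodes[node_id]["type"]

    def relate(self, src: str, relation: str, dst: str,
               role: Optional[str] = None) -> None:
        if relation not in RELATIONS:
            raise ProvenanceError(f"unknown relation {relation!r}")
        if relation == "used":
            if self.node_type(src) != ACTIVITY or self.node_type(dst) != ENTITY:
                raise ProvenanceError("'used' must link Activity -> Entity")
            if role is not None and not role:
                raise ProvenanceError("qualified usage requires a nonempty role")
        if relation == "wasGeneratedBy" and self.node_type(dst) != ACTIVITY:
            raise ProvenanceError("'wasGeneratedBy' target must be an Activity")
        self.graph.add_edge(src, dst, key=relation, relation=relation, role=role)

    # -- queries ------------------------------------------------------------
    def nodes(self, ntype: Optional[str] = None):
        if ntype is None:
            return list(self.graph.nodes)
        return [n for n, d in self.graph.nodes(data=True) if d["type"] == ntype]

    def labels(self):
        return {n: d["label"] for n, d in self.graph.nodes(data=True)}

    def find(self, label: str):
        hits = [n for n, d in self.graph.nodes(data=True) if d["label"] == label]
        if not hits:
            raise KeyError(label)
        return hits[0]

    def relations(self, relation: Optional[str] = None):
        out = []
        for u, v, d in self.graph.edges(data=True):
            if relation is None or d["relation"] == relation:
                out.append((u, d["relation"], v, d.get("role")))
        return out

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)

    def topological_order(self):
        return list(nx.topological_sort(self.graph))

    def derivation_chain(self, start_label: str):
        """Labels reachable from ``start_label`` along wasDerivedFrom edges."""
        sub = nx.MultiDiGraph(
            (u, v) for u, v, d in self.graph.edges(data=True)
            if d["relation"] == "wasDerivedFrom")
        start = self.find(start_label)
        if start not in sub:
            return [start_label]
        order = nx.descendants(sub, start) | {start}
        lab = self.labels()
        return sorted(lab[n] for n in order)


# ---------------------------------------------------------------------------
# recording a run
# ---------------------------------------------------------------------------

def record_run(exp, outputs, observation_trace=None,
               observation_inputs=None, agents=None,
               graph: Optional[ProvenanceGraph] = None) -> ProvenanceGraph:
    """Record a completed simulation (and optional observation DAG run).

    ``outputs`` is the monitor-name -> TimeSeries mapping returned by the
    engine; ``observation_trace`` the trace collected by
    :func:`neuromass.observation.execute` and ``observation_inputs`` the
    mapping of source-node names to the monitor outputs fed in (so derived
    entities link back to the time series they came from).  An existing
    graph may be passed to append re-derivations.
    """
    g = graph or ProvenanceGraph()
    import neuromass

    sw = g.add_agent(f"neuromass {neuromass.__version__}",
                     version=neuromass.__version__)
    for extra in (agents or []):
        g.add_agent(str(extra))

    sim = g.add_activity(f"simulation of {exp.dynamics.name}")
    g.relate(sim, "wasAttributedTo", sw)
    roles = {
        f"model:{exp.dynamics.name}": "dynamics model",
        "connectome": "connectome",
        f"coupling:{exp.coupling.name}": "coupling function",
        f"integrator:{exp.integrator.method}": "integrator",
        "initial conditions": "initial conditions",
    }
    for label, role in roles.items():
        e = g.add_entity(label)
        g.relate(sim, "used", e, role=role)
    for i, _ in enumerate(exp.stimuli):
        e = g.add_entity(f"stimulus[{i}]")
        g.relate(sim, "used", e, role="stimulus")

    ts_entities = {}
    for name in outputs:
        e = g.add_entity(f"timeseries:{name}")
        g.relate(e, "wasGeneratedBy", sim)
        g.relate(e, "wasAttributedTo", sw)
        ts_entities[name] = e

    if observation_trace:
        node_entities = {}
        src_map = dict(observation_inputs or {})
        for node, input_names in observation_trace:
            act = g.add_activity(f"observe:{node.name}")
            g.relate(act, "wasAttributedTo", sw)
            out_e = g.add_entity(f"derived:{node.name}")
            g.relate(out_e, "wasGeneratedBy", act)
            upstream = input_names or [
                nm for nm in ([src_map.get(node.name)] if node.name in src_map else [])]
            for nm in input_names:
                up = node_entities.get(nm)
                if up is None and nm in src_map:
                    up = ts_entities.get(src_map[nm])
                if up is None and nm in ts_entities:
                    up = ts_entities[nm]
                if up is not None:
                    g.relate(act, "used", up, role="input time series")
                    g.relate(out_e, "wasDerivedFrom", up)
            if not input_names and node.name in src_map:
                up = ts_entities.get(src_map[node.name])
                if up is not None:
                    g.relate(act, "used", up, role="input time series")
                    g.relate(out_e, "wasDerivedFrom", up)
            node_entities[node.name] = out_e

    if not g.is_acyclic():  # defensive; construction above cannot cycle
        raise ProvenanceError("recorded graph is not acyclic")
    return g


# ---------------------------------------------------------------------------
# JSON-LD export / import
# ---------------------------------------------------------------------------

def export_jsonld(g: ProvenanceGraph) -> dict:
    """Linked-data document; import reproduces the graph isomorphically."""
    nodes = []
    for n in sorted(g.graph.nodes):
        d = g.graph.nodes[n]
        rec = {"@id": n, "@type": d["type"], "label": d["label"]}
        for k, v in d.items():
            if k not in ("type", "label"):
                rec[k] = v
        for _, dst, ed in g.graph.out_edges(n, data=True):
            rel = ed["relation"]
            if ed.get("role") and rel == "used":
                rec.setdefault("qualifiedUsage", []).append(
                    {"entity": dst, "hadRole": ed["role"]})
                rec.setdefault(rel, []).append(dst)
            else:
                rec.setdefault(rel, []).append(dst)
        nodes.append(rec)
    return {"@context": dict(PROV_CONTEXT), "@graph": nodes}


def import_jsonld(doc: dict) -> ProvenanceGraph:
    g = ProvenanceGraph()
    roles = {}
    for rec in doc.get("@graph", []):
        attrs = {k: v for k, v in rec.items()
                 if k not in ("@id", "@type", "label", "qualifiedUsage", *RELATIONS)}
        g._add_node(rec["@type"], rec.get("label", ""), node_id=rec["@id"], **attrs)
        for qu in rec.get("qualifiedUsage", []):
            roles[(rec["@id"], qu["entity"])] = qu["hadRole"]
    for rec in doc.get("@graph", []):
        for rel in RELATIONS:
            for dst in rec.get(rel, []):
                g.relate(rec["@id"], rel, dst,
                         role=roles.get((rec["@id"], dst)) if rel == "used" else None)
    return g


def isomorphic(a: ProvenanceGraph, b: ProvenanceGraph) -> bool:
    nm = nx.algorithms.isomorphism.categorical_node_match(["type", "label"], [None, None])
    em = nx.algorithms.isomorphism.categorical_multiedge_match(
        ["relation", "role"], [None, None])
    return nx.is_isomorphic(a.graph, b.graph, node_match=nm, edge_match=em)
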