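"""Serializable dataflow-graph pipeline runtime.

A pipeline is a typed directed acyclic graph of processing nodes.  Each
node's operation comes from a registry mapping names to library functions,
with declared input/output port kinds drawn from a small closed algebra
(``recording``, ``epochs``, ``scores``, ``features``, ``covs``, ``labels``,
``report``) so that wiring mistakes are detected structurally, before
execution.  Graphs serialize to JSON and round-trip losslessly.

Two execution modes share the same graph:

* offline (batch) — whole datasets flow along the edges in topological
  order; used for channel selection, artifact-model and classifier fitting;
* online (streaming) — single epochs are pulled one at a time from a stream
  source and pushed through the chain; stateful nodes (ICA model, CSP,
  RMDM, regression coefficients) must be fit offline and loaded frozen.

For chains of stateless per-epoch nodes the two modes produce identical
per-epoch results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import chansel, features, preprocess, riemann, signal_model
from .signal_model import EpochSet, Recording

__all__ = [
    "Node", "FlowGraph", "NODE_REGISTRY", "register_node",
    "validate", "execute", "save", "load",
    "StreamAdapter", "FileReplayAdapter", "stream_epochs", "iter_epochs",
    "SCHEMA_VERSION", "KINDS",
]

SCHEMA_VERSION = 1
KINDS = ("recording", "epochs", "scores", "features", "covs", "labels",
         "report")


@dataclass
class NodeSpec:
    inputs: dict[str, str]      # port -> kind
    outputs: dict[str, str]
    fn: object                  # fn(params, state, **inputs) -> {port: value}
    stateful: bool = False
    streamable: bool = True


NODE_REGISTRY: dict[str, NodeSpec] = {}


def register_node(name: str, spec: NodeSpec) -> None:
    if name in NODE_REGISTRY:
        raise ValueError(f"node op {name!r} already registered")
    for kind in list(spec.inputs.values()) + list(spec.outputs.values()):
        if kind not in KINDS:
            raise ValueError(f"unknown port kind {kind!r}")
    NODE_REGISTRY[name] = spec


@dataclass
class Node:
    id: str
    op_name: str
    params: dict = field(default_factory=dict)

    @property
    def spec(self) -> NodeSpec:
        if self.op_name not in NODE_REGISTRY:
            raise KeyError(f"unknown op {self.op_name!r}; registry: "
                           f"{sorted(NODE_REGISTRY)}")
        return NODE_REGISTRY[self.op_name]


@dataclass
class FlowGraph:
    nodes: list[Node]
    edges: list[tuple[tuple[str, str], tuple[str, str]]]  # (from, to), each (node, port)
    mode: str = "offline"

    def node(self, node_id: str) -> Node:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(f"no node {node_id!r}")


# ------------------------------------------------------------------ built-ins

def _out(**kw):
    return kw


def _register_builtins() -> None:
    register_node("source", NodeSpec(
        inputs={}, outputs={"out": "epochs"}, fn=None))
    register_node("source_recording", NodeSpec(
        inputs={}, outputs={"out": "recording"}, fn=None))

    register_node("segment_epochs", NodeSpec(
        inputs={"rec": "recording", "events": "labels"},
        outputs={"out": "epochs"},
        fn=lambda p, s, rec, events: _out(out=signal_model.segment_epochs(
            rec, events, tuple(p["window"]), p.get("offset", 0.0))),
        streamable=False))

    register_node("select_channels", NodeSpec(
        inputs={"in": "epochs"}, outputs={"out": "epochs"},
        fn=lambda p, s, **kw: _out(out=signal_model.channel_subset(
            kw["in"], p["names"]))))

    register_node("filter", NodeSpec(
        inputs={"in": "epochs"}, outputs={"out": "epochs"},
        fn=lambda p, s, **kw: _out(out=preprocess.apply_filter(
            kw["in"], preprocess.FilterSpec(
                p["kind"], p["order"], tuple(np.atleast_1d(p["cutoffs_hz"])),
                kw["in"].fs, p.get("mode", "zero_phase"))))))

    register_node("kaiser_window", NodeSpec(
        inputs={"in": "epochs"}, outputs={"out": "epochs"},
        fn=lambda p, s, **kw: _out(out=preprocess.apply_window(
            kw["in"], "kaiser", p.get("length"), p.get("beta", 8.6)))))

    register_node("car", NodeSpec(
        inputs={"in": "epochs"}, outputs={"out": "epochs"},
        fn=lambda p, s, **kw: _out(out=preprocess.rereference_car(kw["in"]))))

    def _reject(p, s, **kw):
        kept, _, report = preprocess.reject_amplitude(kw["in"],
                                                      p["threshold_uv"])
        return _out(out=kept, report=report)

    register_node("reject_amplitude", NodeSpec(
        inputs={"in": "epochs"}, outputs={"out": "epochs", "report": "report"},
        fn=_reject))

    def _ica_clean(p, s, **kw):
        # frozen ICA model applied per epoch: zero artifact activations
        model: preprocess.ICAModel = s["model"]
        drop = s.get("drop", [])
        keep = [i for i in range(model.unmixing.shape[0]) if i not in drop]
        ep = kw["in"]
        out = np.empty_like(ep.data)
        src_mean = model.unmixing @ model.mean
        for i, x in enumerate(ep.data):
            src = model.unmixing @ (x - model.mean[:, None])
            out[i] = model.mixing[:, keep] @ (src[keep]
                                              + src_mean[keep, None])
        return _out(out=EpochSet(out, list(ep.labels), ep.fs, ep.window,
                                 list(ep.channel_names)))

    register_node("ica_clean", NodeSpec(
        inputs={"in": "epochs"}, outputs={"out": "epochs"},
        fn=_ica_clean, stateful=True))

    register_node("channel_scores", NodeSpec(
        inputs={"in": "epochs"}, outputs={"out": "scores"},
        fn=lambda p, s, **kw: _out(out=chansel.score_channels(
            kw["in"], p["method"], **p.get("kwargs", {}))),
        streamable=False))

    register_node("extract_features", NodeSpec(
        inputs={"in": "epochs"}, outputs={"out": "features"},
        fn=lambda p, s, **kw: _out(out=features.extract(kw["in"], p["spec"]))))

    register_node("covariance", NodeSpec(
        inputs={"in": "epochs"}, outputs={"out": "covs"},
        fn=lambda p, s, **kw: _out(out=riemann.epoch_covariance(
            kw["in"], p.get("shrinkage", 0.05)))))

    register_node("csp_transform", NodeSpec(
        inputs={"in": "epochs"}, outputs={"out": "features"},
        fn=lambda p, s, **kw: _out(out=features.csp_transform(
            s["model"], kw["in"])), stateful=True))

    register_node("rmdm_predict", NodeSpec(
        inputs={"in": "covs"}, outputs={"out": "labels"},
        fn=lambda p, s, **kw: _out(out=riemann.rmdm_predict(
            s["model"], kw["in"])), stateful=True))


_register_builtins()


# ------------------------------------------------------------------ structure

def _digraph(graph: FlowGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(n.id for n in graph.nodes)
    g.add_edges_from((src[0], dst[0]) for src, dst in graph.edges)
    return g


def validate(graph: FlowGraph) -> list[str]:
    """Structural validation; returns a list of violations (empty = ok)."""
    issues: list[str] = []
    ids = [n.id for n in graph.nodes]
    if len(set(ids)) != len(ids):
        issues.append("duplicate node ids")
    specs = {}
    for n in graph.nodes:
        if n.op_name not in NODE_REGISTRY:
            issues.append(f"node {n.id!r}: unknown op {n.op_name!r}")
        else:
            specs[n.id] = n.spec
    inbound: dict[tuple[str, str], int] = {}
    for (src, sp), (dst, dp) in graph.edges:
        if src not in ids or dst not in ids:
            issues.append(f"edge {src}.{sp} -> {dst}.{dp}: unknown node")
            continue
        if src in specs and sp not in specs[src].outputs:
            issues.append(f"edge from unknown output port {src}.{sp}")
            continue
        if dst in specs and dp not in specs[dst].inputs:
            issues.append(f"edge into unknown input port {dst}.{dp}")
            continue
        if src in specs and dst in specs:
            k_out = specs[src].outputs[sp]
            k_in = specs[dst].inputs[dp]
            if k_out != k_in:
                issues.append(
                    f"kind mismatch {src}.{sp} ({k_out}) -> {dst}.{dp} "
                    f"({k_in})")
        inbound[(dst, dp)] = inbound.get((dst, dp), 0) + 1
    for n in graph.nodes:
        if n.id not in specs:
            continue
        for port in specs[n.id].inputs:
            c = inbound.get((n.id, port), 0)
            if c == 0:
                issues.append(f"dangling input port {n.id}.{port}")
            elif c > 1:
                issues.append(f"input port {n.id}.{port} has {c} inbound edges")
    dg = _digraph(graph)
    try:
        cycles = list(nx.find_cycle(dg))
        issues.append("cycle: " + " -> ".join(f"{a}->{b}" for a, b in cycles))
    except nx.NetworkXNoCycle:
        pass
    return issues


# ------------------------------------------------------------------ execution

class GraphExecutionError(RuntimeError):
    def __init__(self, node_id: str, upstream: list[str], cause: Exception):
        self.node_id = node_id
        self.upstream = upstream
        super().__init__(
            f"node {node_id!r} failed ({cause}); upstream: {upstream}")


def _run_batch(graph: FlowGraph, inputs: dict, state: dict,
               run_log: list[str] | None = None) -> dict:
    order = list(nx.topological_sort(_digraph(graph)))
    values: dict[tuple[str, str], object] = {}
    in_edges: dict[str, list] = {n.id: [] for n in graph.nodes}
    for src, dst in graph.edges:
        in_edges[dst[0]].append((src, dst))
    consumed = {src for src, _ in graph.edges}
    for nid in order:
        node = graph.node(nid)
        spec = node.spec
        if run_log is not None:
            run_log.append(nid)
        if not spec.inputs:  # source node
            if nid not in inputs:
                raise KeyError(f"no input payload for source node {nid!r}")
            values[(nid, "out")] = inputs[nid]
            continue
        kwargs = {dp: values[(src_n, src_p)]
                  for (src_n, src_p), (_, dp) in in_edges[nid]}
        try:
            outs = spec.fn(node.params, state.get(nid, {}), **kwargs)
        except Exception as exc:
            upstream = [f"{s[0]}.{s[1]}" for s, _ in in_edges[nid]]
            raise GraphExecutionError(nid, upstream, exc) from exc
        for port, val in outs.items():
            values[(nid, port)] = val
    return {f"{n}.{p}": v for (n, p), v in values.items()
            if (n, p) not in consumed}


def _concat_payloads(chunks: list):
    first = chunks[0]
    if isinstance(first, EpochSet):
        return EpochSet(np.concatenate([c.data for c in chunks]),
                        [l for c in chunks for l in c.labels],
                        first.fs, first.window, list(first.channel_names))
    if isinstance(first, np.ndarray):
        return np.concatenate(chunks)
    if isinstance(first, list):
        return [x for c in chunks for x in c]
    import pandas as pd
    if isinstance(first, pd.DataFrame):
        return pd.concat(chunks, ignore_index=True)
    return chunks


def execute(graph: FlowGraph, inputs: dict, state: dict | None = None,
            run_log: list[str] | None = None) -> dict:
    """Run the graph; returns payloads at sink ports keyed ``"node.port"``.

    ``inputs`` maps source-node ids to payloads.  In offline mode payloads
    are whole datasets.  In online mode the single epoch-kind source payload
    must be an iterable of one-epoch ``EpochSet`` items (e.g. from
    ``stream_epochs``); per-epoch results are concatenated at the sinks.
    ``state`` maps stateful node ids to their frozen fitted objects.
    """
    state = state or {}
    issues = validate(graph)
    if issues:
        raise ValueError("invalid graph: " + "; ".join(issues))
    for n in graph.nodes:
        if n.spec.stateful and n.id not in state:
            raise KeyError(f"stateful node {n.id!r} needs a fitted state "
                           "(fit offline, load frozen)")
    if graph.mode == "offline":
        return _run_batch(graph, inputs, state, run_log)

    # online: identify the streaming source
    sources = [n for n in graph.nodes if not n.spec.inputs]
    stream_srcs = [n for n in sources if n.spec.outputs.get("out") == "epochs"]
    if len(stream_srcs) != 1:
        raise ValueError("online mode needs exactly one epochs source node")
    for n in graph.nodes:
        if not n.spec.streamable:
            raise ValueError(f"node {n.id!r} ({n.op_name}) cannot stream")
    sid = stream_srcs[0].id
    collected: dict[str, list] = {}
    for item in inputs[sid]:
        step_inputs = dict(inputs)
        step_inputs[sid] = item
        outs = _run_batch(graph, step_inputs, state, run_log)
        for k, v in outs.items():
            collected.setdefault(k, []).append(v)
    return {k: _concat_payloads(v) for k, v in collected.items()}


# ------------------------------------------------------------- serialization

def save(graph: FlowGraph, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "mode": graph.mode,
        "nodes": [{"id": n.id, "op": n.op_name, "params": n.params}
                  for n in graph.nodes],
        "edges": [{"from": list(src), "to": list(dst)}
                  for src, dst in graph.edges],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load(path: str | Path) -> FlowGraph:
    doc = json.loads(Path(path).read_text())
    for key, ptr in (("schema_version", "/schema_version"),
                     ("nodes", "/nodes"), ("edges", "/edges")):
        if key not in doc:
            raise ValueError(f"invalid graph file: missing {ptr}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {doc['schema_version']} "
                         f"at /schema_version (expected {SCHEMA_VERSION})")
    nodes = []
    for i, nd in enumerate(doc["nodes"]):
        if nd["op"] not in NODE_REGISTRY:
            raise ValueError(f"unknown op {nd['op']!r} at /nodes/{i}/op")
        nodes.append(Node(nd["id"], nd["op"], nd.get("params", {})))
    edges = [(tuple(e["from"]), tuple(e["to"])) for e in doc["edges"]]
    return FlowGraph(nodes, edges, doc.get("mode", "offline"))


# ----------------------------------------------------------------- streaming

class StreamAdapter:
    """Stream-source contract: ``next_chunk() -> (samples, timestamps) | None``.

    ``samples`` is a (channels × n) array, ``timestamps`` the per-sample
    times in seconds; ``None`` signals end of stream.  Implement this to
    connect live hardware; ``FileReplayAdapter`` replays a recording file as
    a pseudo live-stream for development and testing.
    """

    def next_chunk(self):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def fs(self) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def channel_names(self) -> list[str]:  # pragma: no cover - interface
        raise NotImplementedError


class FileReplayAdapter(StreamAdapter):
    """Replay a CSV recording (or in-memory Recording) chunk by chunk."""

    def __init__(self, source: str | Path | Recording,
                 chunk_samples: int = 256):
        if isinstance(source, Recording):
            self._rec = source
        else:
            from .io import read_recording_csv
            self._rec = read_recording_csv(source)
        self._chunk = chunk_samples
        self._pos = 0

    @property
    def fs(self) -> float:
        return self._rec.fs

    @property
    def channel_names(self) -> list[str]:
        return list(self._rec.channel_names)

    def next_chunk(self):
        if self._pos >= self._rec.n_samples:
            return None
        stop = min(self._pos + self._chunk, self._rec.n_samples)
        t = self._rec.t0 + np.arange(self._pos, stop) / self._rec.fs
        chunk = self._rec.data[:, self._pos:stop]
        self._pos = stop
        return chunk, t


def stream_epochs(adapter: StreamAdapter, events, window: tuple[float, float],
                  offset: float = 0.0):
    """Generate one-epoch EpochSets from a stream as data becomes available.

    Buffers incoming chunks and emits each event's epoch as soon as the
    recording covers its window (timestamps honored; wall-clock ignored).
    """
    import math

    buf = []
    t0 = None
    n_have = 0
    fs = adapter.fs
    n_win = round((window[1] - window[0]) * fs)
    pending = list(zip(events.onsets, events.labels))
    while True:
        chunk = adapter.next_chunk()
        if chunk is None:
            break
        data, ts = chunk
        if t0 is None:
            t0 = ts[0]
        buf.append(data)
        n_have += data.shape[1]
        # emit every pending epoch now fully buffered
        while pending:
            onset, label = pending[0]
            start = math.floor((onset + offset + window[0] - t0) * fs)
            stop = start + n_win
            if stop > n_have:
                break
            pending.pop(0)
            if start < 0:
                continue
            full = np.concatenate(buf, axis=1)
            yield EpochSet(full[None, :, start:stop], [label], fs, window,
                           adapter.channel_names)


def iter_epochs(epochs: EpochSet):
    """View a batch EpochSet as a stream of single-epoch sets."""
    for i in range(epochs.n_epochs):
        yield EpochSet(epochs.data[i:i + 1], [epochs.labels[i]], epochs.fs,
                       epochs.window, list(epochs.channel_names))
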