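"""Flow-cytometry event reduction: gating hierarchy, subset proportions, MFI.

Events arrive as a plain table (one row per event, one column per scatter or
fluorescence channel).  Gates are declarative data, not code: each gate is a
named predicate over columns — a ratio band (doublet exclusion on
FSC-H/FSC-A), a 2-D polygon (lymphocytes on FSC-A/SSC-A), or a 1-D threshold
(viability dye, CD3, CD4) — attached to a parent gate, and an event is in a
gate iff it satisfies the predicate and is in the parent.  The standard
T-cell hierarchy is singlets -> lymphocytes -> live -> CD3+ -> CD4+.

Endpoints are subset proportions (100 x child / parent counts) and the median
fluorescence intensity (MFI) of a marker within a gate.  Cervical (CMC)
samples with fewer than 100 CD3+ events are excluded as a quality rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon as _Polygon

__all__ = [
    "FlowEvents",
    "Gate",
    "GateTree",
    "GateResult",
    "apply_gates",
    "subset_proportion",
    "mfi",
    "cmc_inclusion",
    "default_gate_tree",
    "summarize_sample",
]

#: columns the default panel carries (CD161 is in the panel but drives no endpoint)
PANEL_COLUMNS = (
    "FSC-A",
    "FSC-H",
    "SSC-A",
    "viability",
    "CD3",
    "CD4",
    "CCR5",
    "CD69",
    "CD95",
    "HLA-DR",
    "CD161",
)


@dataclass
class FlowEvents:
    """Per-event intensity table for one sample.

    compartment is ``"blood"`` (PBMC) or ``"cervical"`` (CMC); the CD3-count
    inclusion rule applies to cervical samples.
    """

    data: pd.DataFrame
    sample_id: str = ""
    compartment: str = "blood"

    def __post_init__(self) -> None:
        if self.compartment not in ("blood", "cervical"):
            raise ValueError("compartment must be 'blood' or 'cervical'")
        vals = self.data.select_dtypes(include=[np.number]).to_numpy()
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("event intensities must be finite")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class Gate:
    """One node of the gating hierarchy.

    kind ``"ratio_band"``: |num/den - center| <= tol.
    kind ``"polygon"``: point (x, y) inside the vertex polygon.
    kind ``"threshold"``: column `op` value with op in {">", "<", ">=", "<="}.
    """

    name: str
    parent: str | None
    kind: str
    params: dict = field(default_factory=dict)

    def columns(self) -> list[str]:
        p = self.params
        if self.kind == "ratio_band":
            return [p["num"], p["den"]]
        if self.kind == "polygon":
            return [p["x"], p["y"]]
        if self.kind == "threshold":
            return [p["col"]]
        raise ValueError(f"unknown gate kind {self.kind!r}")

    def evaluate(self, data: pd.DataFrame) -> np.ndarray:
        for col in self.columns():
            if col not in data.columns:
                raise KeyError(f"gate {self.name!r} references missing column {col!r}")
        p = self.params
        if self.kind == "ratio_band":
            den = data[p["den"]].to_numpy(dtype=float)
            num = data[p["num"]].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(den != 0, num / den, np.inf)
            return np.abs(ratio - float(p["center"])) <= float(p["tol"])
        if self.kind == "polygon":
            verts = np.asarray(p["vertices"], dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ValueError(f"gate {self.name!r}: malformed polygon")
            poly = _Polygon(verts)
            if not poly.is_valid:
                raise ValueError(f"gate {self.name!r}: malformed polygon")
            return shapely.contains_xy(
                poly,
                data[p["x"]].to_numpy(dtype=float),
                data[p["y"]].to_numpy(dtype=float),
            )
        if self.kind == "threshold":
            x = data[p["col"]].to_numpy(dtype=float)
            v = float(p["value"])
            op = p.get("op", ">")
            try:
                return {
                    ">": x > v,
                    "<": x < v,
                    ">=": x >= v,
                    "<=": x <= v,
                }[op]
            except KeyError:
                raise ValueError(f"gate {self.name!r}: unknown operator {op!r}") from None
        raise ValueError(f"unknown gate kind {self.kind!r}")


@dataclass
class GateTree:
    """Ordered gate list forming a single-rooted hierarchy."""

    gates: list[Gate]

    def __post_init__(self) -> None:
        names = [g.name for g in self.gates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gate names")
        roots = [g for g in self.gates if g.parent is None]
        if len(roots) != 1:
            raise ValueError("GateTree must have exactly one root gate")
        seen: set[str] = set()
        for g in self.gates:
            if g.parent is not None and g.parent not in seen:
                raise ValueError(f"gate {g.name!r} appears before its parent {g.parent!r}")
            seen.add(g.name)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "gates": [
                    {"name": g.name, "parent": g.parent, "kind": g.kind, **g.params}
                    for g in self.gates
                ]
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "GateTree":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        gates = []
        for g in doc["gates"]:
            g = dict(g)
            gates.append(
                Gate(
                    name=g.pop("name"),
                    parent=g.pop("parent"),
                    kind=g.pop("kind"),
                    params=g,
                )
            )
        return cls(gates=gates)


@dataclass
class GateResult:
    """Boolean membership per gate plus event counts (child always ⊆ parent)."""

    membership: dict[str, np.ndarray]
    counts: dict[str, int]

    def index(self, gate: str) -> np.ndarray:
        return np.flatnonzero(self.membership[gate])


def default_gate_tree() -> GateTree:
    """Hierarchy used for synthetic events: singlet -> lymphocyte -> live -> CD3 -> CD4.

    Positions are tuned to the synthetic generator only; real experiments must
    supply their own gate JSON.
    """
    return GateTree(
        gates=[
            Gate("singlet", None, "ratio_band",
                 {"num": "FSC-H", "den": "FSC-A", "center": 1.0, "tol": 0.1}),
            Gate("lymphocyte", "singlet", "polygon",
                 {"x": "FSC-A", "y": "SSC-A",
                  "vertices": [[15000, 1000], [95000, 1000],
                               [95000, 50000], [15000, 50000]]}),
            # dead-cell dye positive = dead, so live = viability below threshold
            Gate("live", "lymphocyte", "threshold",
                 {"col": "viability", "op": "<", "value": 1000}),
            Gate("cd3", "live", "threshold", {"col": "CD3", "op": ">", "value": 300}),
            Gate("cd4", "cd3", "threshold", {"col": "CD4", "op": ">", "value": 300}),
        ]
    )


def apply_gates(events: FlowEvents, tree: GateTree) -> GateResult:
    """Evaluate the hierarchy; each gate's membership is ANDed with its parent's."""
    membership: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for gate in tree.gates:
        own = np.asarray(gate.evaluate(events.data), dtype=bool)
        if gate.parent is not None:
            own = own & membership[gate.parent]
        membership[gate.name] = own
        counts[gate.name] = int(own.sum())
    return GateResult(membership=membership, counts=counts)


def subset_proportion(parent_count: int, child_count: int) -> float:
    """Percentage of parent-gate events falling in the child gate."""
    if parent_count <= 0:
        raise ValueError("parent gate is empty")
    if child_count > parent_count:
        raise ValueError("child count exceeds parent count")
    return 100.0 * child_count / parent_count

def mfi(values: Sequence[float]) -> float:
    """Median fluorescence intensity (even n: mean of the central pair)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty gate")
    return float(np.median(arr))


def cmc_inclusion(events: FlowEvents, tree: GateTree, min_cd3: int = 100,
                  cd3_gate: str = "cd3") -> bool:
    """Quality rule: keep a sample iff its CD3+ event count reaches min_cd3."""
    if not any(g.name == cd3_gate for g in tree.gates):
        raise ValueError(f"gate {cd3_gate!r} not in tree")
    if len(events) == 0:
        return False
    res = apply_gates(events, tree)
    return res.counts[cd3_gate] >= min_cd3


def summarize_sample(
    events: FlowEvents,
    tree: GateTree,
    mfi_markers: Sequence[str] = ("CCR5", "CD69", "CD95", "HLA-DR"),
    mfi_gate: str = "cd4",
    proportions: Mapping[str, tuple[str, str]] | None = None,
) -> dict:
    """Per-sample endpoint row: gate counts, subset %, and per-marker MFI.

    proportions maps endpoint name -> (parent gate, child gate); default is
    the CD4-of-CD3 frequency.  MFIs are NaN when the gate is empty.
    """
    res = apply_gates(events, tree)
    proportions = proportions or {"pct_cd4_of_cd3": ("cd3", "cd4")}
    row: dict = {
        "sample_id": events.sample_id,
        "compartment": events.compartment,
        **{f"count_{k}": v for k, v in res.counts.items()},
    }
    for name, (parent, child) in proportions.items():
        row[name] = (
            subset_proportion(res.counts[parent], res.counts[child])
            if res.counts[parent] > 0
            else float("nan")
        )
    in_gate = res.membership[mfi_gate]
    for marker in mfi_markers:
        vals = events.data.loc[in_gate, marker]
        row[f"mfi_{marker}"] = mfi(vals) if len(vals) else float("nan")
    return row
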