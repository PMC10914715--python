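"""Serialization of discrete Bayesian networks.

Two formats are supported:

* a JSON dialect (read + write) with top-level fields ``variables``,
  ``edges`` and ``cpts``; CPT rows are listed in row-major order of the
  parents' declared level orders, and key ordering on write is
  deterministic so identical networks serialize byte-identically;
* BIF (Bayesian Interchange Format) export for interoperability with
  other Bayesian-network software.  BIF import is not provided.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .network import CategoricalVariable, Cpt, Dag, DiscreteBayesNet

__all__ = ["network_to_dict", "network_from_dict", "save_network", "load_network", "to_bif"]


def network_to_dict(net: DiscreteBayesNet) -> dict[str, Any]:
    """JSON-ready dict; variable order, edge order and row order are fixed."""
    return {
        "variables": [
            {"name": v.name, "levels": list(v.levels)} for v in net.variables
        ],
        "edges": sorted([p, c] for p, c in net.dag.edges),
        "cpts": [
            {
                "child": name,
                "parents": list(net.cpts[name].parents),
                "rows": [
                    {
                        "given": list(combo),
                        "p": [float(x) for x in net.cpts[name].row(combo)],
                    }
                    for combo in net.parent_combinations(name)
                ],
            }
            for name in net.names
        ],
    }


def network_from_dict(payload: dict[str, Any]) -> DiscreteBayesNet:
    variables = [
        CategoricalVariable(v["name"], tuple(v["levels"])) for v in payload["variables"]
    ]
    dag = Dag([v.name for v in variables], [tuple(e) for e in payload["edges"]])
    cpts = {}
    for entry in payload["cpts"]:
        table = {tuple(row["given"]): row["p"] for row in entry["rows"]}
        cpts[entry["child"]] = Cpt(entry["child"], entry["parents"], table)
    return DiscreteBayesNet(variables=variables, dag=dag, cpts=cpts)


def save_network(net: DiscreteBayesNet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(network_to_dict(net), indent=1, sort_keys=False) + "\n"
    )


def load_network(path: str | Path) -> DiscreteBayesNet:
    return network_from_dict(json.loads(Path(path).read_text()))


def _bif_name(name: str) -> str:
    # BIF identifiers: no spaces or punctuation
    return "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in name)


def to_bif(net: DiscreteBayesNet, name: str = "network") -> str:
    """Render the network in the classic BIF text format."""
    lines = [f"network {_bif_name(name)} {{", "}"]
    for var in net.variables:
        levels = ", ".join(_bif_name(lv) for lv in var.levels)
        lines += [
            f"variable {_bif_name(var.name)} {{",
            f"  type discrete [ {var.cardinality} ] {{ {levels} }};",
            "}",
        ]
    for node in net.names:
        cpt = net.cpts[node]
        if not cpt.parents:
            probs = ", ".join(f"{p:.10g}" for p in cpt.row(()))
            lines += [
                f"probability ( {_bif_name(node)} ) {{",
                f"  table {probs};",
                "}",
            ]
        else:
            parents = ", ".join(_bif_name(p) for p in cpt.parents)
            lines.append(f"probability ( {_bif_name(node)} | {parents} ) {{")
            for combo in net.parent_combinations(node):
                key = ", ".join(_bif_name(v) for v in combo)
                probs = ", ".join(f"{p:.10g}" for p in cpt.row(combo))
                lines.append(f"  ({key}) {probs};")
            lines.append("}")
    return "\n".join(lines) + "\n"
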