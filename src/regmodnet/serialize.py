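"""ModuleNetwork serialization: JSON round-trip, DOT trees, heatmap TSV."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix
from .network import (
    LeafModel,
    Module,
    ModuleNetwork,
    RegulatoryTree,
    SplitQuery,
    TreeNode,
)


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {
            "leaf": {
                "conditions": list(node.leaf.condition_ids),
                "mu": node.leaf.mu,
                "sigma": node.leaf.sigma,
            }
        }
    return {
        "query": {"tf": node.query.tf_id, "state": node.query.query_state},
        "yes": _node_to_dict(node.yes),
        "no": _node_to_dict(node.no),
    }


def _node_from_dict(d: dict) -> TreeNode:
    if "leaf" in d:
        leaf = d["leaf"]
        return TreeNode(
            leaf=LeafModel(tuple(leaf["conditions"]), leaf["mu"], leaf["sigma"])
        )
    return TreeNode(
        query=SplitQuery(d["query"]["tf"], d["query"]["state"]),
        yes=_node_from_dict(d["yes"]),
        no=_node_from_dict(d["no"]),
    )


def network_to_dict(network: ModuleNetwork) -> dict:
    return {
        "iterations_run": network.iterations_run,
        "total_log_likelihood_trace": list(network.total_log_likelihood_trace),
        "modules": [
            {
                "genes": list(mod.genes),
                "tree": {
                    "conditions": list(mod.tree.condition_ids),
                    "root": _node_to_dict(mod.tree.root),
                },
            }
            for mod in network.modules
        ],
    }


def network_from_dict(d: dict) -> ModuleNetwork:
    modules = []
    assignment: dict[str, int] = {}
    for i, md in enumerate(d["modules"]):
        tree = RegulatoryTree(
            _node_from_dict(md["tree"]["root"]), tuple(md["tree"]["conditions"])
        )
        modules.append(Module(tuple(md["genes"]), tree))
        for g in md["genes"]:
            assignment[g] = i
    return ModuleNetwork(
        modules, assignment, d.get("iterations_run", 0),
        list(d.get("total_log_likelihood_trace", [])),
    )


def save_network(network: ModuleNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(network), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_network(path: str | Path) -> ModuleNetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh))


def tree_to_dot(tree: RegulatoryTree, name: str = "tree") -> str:
    """Graphviz DOT rendering: query nodes as boxes, leaves as condition
    lists with their Gaussian parameters."""
    lines = [f"digraph {name} {{", "  node [fontsize=10];"]
    counter = [0]

    def walk(node: TreeNode) -> str:
        nid = f"n{counter[0]}"
        counter[0] += 1
        if node.is_leaf:
            conds = ",".join(node.leaf.condition_ids)
            lines.append(
                f'  {nid} [shape=ellipse label="{conds}\\n'
                f'mu={node.leaf.mu:.3g} sigma={node.leaf.sigma:.3g}"];'
            )
        else:
            lines.append(
                f'  {nid} [shape=box label="{node.query.tf_id} {node.query.query_state}?"];'
            )
            yid = walk(node.yes)
            nid2 = walk(node.no)
            lines.append(f'  {nid} -> {yid} [label="yes"];')
            lines.append(f'  {nid} -> {nid2} [label="no"];')
        return nid

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)


def module_heatmap_tsv(module: Module, m: ExpressionMatrix, path: str | Path) -> None:
    """Genes × conditions expression of a module, columns ordered by the
    tree's leaf partition (heatmap-ready layout)."""
    order = [c for leaf in module.tree.leaves() for c in leaf.condition_ids]
    m.data.loc[list(module.genes), order].to_csv(path, sep="\t", index_label="gene_id")
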