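"""Plain-text I/O for networks, patterns and node-set files.

Formats:

* connectivity matrix: whitespace- or comma-delimited square matrix with a
  header row of ROI labels;
* edge list: three columns (roi_a, roi_b, weight);
* seizure pattern: tidy table with columns (roi, activation_step) plus a
  separate sampled-ROI list; sampled ROIs absent from the table are the
  inactive set;
* node-set file: one ROI label per line.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import BrainNetwork
from .patterns import SeizurePattern


def write_matrix(net: BrainNetwork, path) -> None:
    df = pd.DataFrame(net.weights, columns=net.node_labels)
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> BrainNetwork:
    df = pd.read_csv(path, sep=None, engine="python")
    labels = [str(c) for c in df.columns]
    w = df.to_numpy(float)
    return BrainNetwork(w, node_labels=labels)


def write_edge_list(net: BrainNetwork, path) -> None:
    ii, jj = np.nonzero(np.triu(net.weights, 1))
    df = pd.DataFrame({
        "roi_a": [net.node_labels[i] for i in ii],
        "roi_b": [net.node_labels[j] for j in jj],
        "weight": net.weights[ii, jj],
    })
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path, node_labels: Sequence[str] = None) -> BrainNetwork:
    df = pd.read_csv(path, sep=None, engine="python")
    if node_labels is None:
        node_labels = sorted(set(df["roi_a"].astype(str))
                             | set(df["roi_b"].astype(str)))
    lut = {l: i for i, l in enumerate(node_labels)}
    n = len(node_labels)
    w = np.zeros((n, n))
    for _, row in df.iterrows():
        i, j = lut[str(row["roi_a"])], lut[str(row["roi_b"])]
        w[i, j] = w[j, i] = float(row["weight"])
    return BrainNetwork(w, node_labels=list(node_labels))


def write_node_set(labels: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(str(l) for l in labels) + "\n")


def read_node_set(path) -> List[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def write_pattern(pattern: SeizurePattern, net: BrainNetwork,
                  pattern_path, sampled_path) -> None:
    rows = [{"roi": net.node_labels[r], "activation_step": s}
            for r, s in sorted(pattern.steps.items())]
    pd.DataFrame(rows).to_csv(pattern_path, sep="\t", index=False)
    write_node_set([net.node_labels[r] for r in pattern.sampled], sampled_path)


def read_pattern(pattern_path, sampled_path, net: BrainNetwork) -> SeizurePattern:
    df = pd.read_csv(pattern_path, sep=None, engine="python")
    sampled_labels = read_node_set(sampled_path)
    sampled = net.label_indices(sampled_labels)
    active = net.label_indices([str(r) for r in df["roi"]])
    steps = {int(r): int(s) for r, s in zip(active, df["activation_step"])}
    return SeizurePattern(sampled=sampled, steps=steps)
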