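"""Differential network analysis: added, removed, and switched edges.

Disease and control interaction matrices are first thresholded to their
strongest connections (|E| above the median plus two standard deviations
of all entries) and scaled to (-1, 1).  An edge difference
dE = E_disease - E_control is called only when it exceeds the edge
threshold E_th = max(2 sd(E_control), 2 sd(E_disease)); edge presence in
exactly one thresholded network makes an added/removed call, opposite
signs in both make a switched call.  Class-specific |dE| cutoffs
(defaults 0.15 / 0.15 / 0.2) prune the smallest differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hmfnet.containers import node_label

DEFAULT_CUTOFFS = {"added": 0.15, "removed": 0.15, "switched": 0.2}


def threshold_and_scale(K: np.ndarray) -> np.ndarray:
    """Keep only the strongest connections and scale them to (-1, 1).

    Entries with |E_ij| <= med(E) + 2 sd(E) (statistics over all entries,
    zeros included) are set to zero; survivors are divided by the largest
    absolute entry of the original matrix.
    """
    K = np.asarray(K, dtype=float)
    if K.size == 0:
        raise ValueError("empty coefficient matrix")
    thr = float(np.median(K) + 2.0 * K.std(ddof=1))
    out = np.where(np.abs(K) > thr, K, 0.0)
    peak = float(np.max(np.abs(K)))
    if peak > 0.0:
        out = out / peak
    return out


def differential_edges(
    K_disease: np.ndarray,
    K_control: np.ndarray,
    node_labels: list[tuple[str, str]] | None = None,
    cutoffs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Call edges added to, removed from, or sign-switched in disease.

    Presence is judged on the thresholded scaled matrices; magnitude
    criteria use the unscaled difference dE = E_disease - E_control,
    which must exceed both the edge threshold
    max(2 sd(E_control), 2 sd(E_disease)) and the class-specific cutoff.
    Returns a tidy edge list (source, target, class, E_disease,
    E_control, delta); K[i, j] is the influence of source j on target i.
    """
    K_d = np.asarray(K_disease, dtype=float)
    K_c = np.asarray(K_control, dtype=float)
    if K_d.shape != K_c.shape:
        raise ValueError("matrices must share the node set")
    cut = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)

    S_d = threshold_and_scale(K_d)
    S_c = threshold_and_scale(K_c)
    e_th = max(2.0 * K_c.std(ddof=1), 2.0 * K_d.std(ddof=1))
    delta = K_d - K_c

    present_d = np.abs(S_d) > 0.0
    present_c = np.abs(S_c) > 0.0
    big = np.abs(delta) > e_th

    added = present_d & ~present_c & big & (np.abs(delta) > cut["added"])
    removed = ~present_d & present_c & big & (np.abs(delta) > cut["removed"])
    switched = (
        present_d
        & present_c
        & (np.sign(S_d) != np.sign(S_c))
        & big
        & (np.abs(delta) > cut["switched"])
    )

    rows = []
    for cls, mask in (("added", added), ("removed", removed), ("switched", switched)):
        for i, j in zip(*np.nonzero(mask)):
            rows.append(
                {
                    "source": _label(node_labels, j),
                    "target": _label(node_labels, i),
                    "class": cls,
                    "E_disease": K_d[i, j],
                    "E_control": K_c[i, j],
                    "delta": delta[i, j],
                    "source_idx": int(j),
                    "target_idx": int(i),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "source",
            "target",
            "class",
            "E_disease",
            "E_control",
            "delta",
            "source_idx",
            "target_idx",
        ],
    )
    return df.sort_values(["class", "target_idx", "source_idx"]).reset_index(drop=True)


def _label(node_labels, idx: int) -> str:
    if node_labels is None:
        return f"n{idx}"
    organ, gene = node_labels[idx]
    return node_label(organ, gene)


def write_sif(edges: pd.DataFrame, path, relation_col: str = "class") -> None:
    """Write an edge list in SIF format for network visualization tools."""
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['source']}\t{row[relation_col]}\t{row['target']}\n")


def network_to_sif(K: np.ndarray, node_labels, path) -> None:
    """Dump the nonzero off-diagonal entries of K as signed SIF edges."""
    K = np.asarray(K, dtype=float)
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(K)):
            if i == j:
                continue
            rel = "up" if K[i, j] > 0 else "down"
            fh.write(f"{_label(node_labels, j)}\t{rel}\t{_label(node_labels, i)}\n")
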