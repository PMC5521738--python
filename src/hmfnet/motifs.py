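"""Feed-forward-loop enumeration and adaptation classification.

A feed-forward loop (FFL) is an ordered node triple (input a,
intermediate b, output c) with the three edges a->b, b->c and a->c all
present.  The loop is *incoherent* when the direct edge sign differs
from the product of the two indirect edge signs; among three-node
feed-forward topologies, the incoherent configuration is the one capable
of adaptation to a sustained input — the output responds and then
returns toward baseline as the delayed indirect branch catches up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hmfnet.containers import node_label


@dataclass
class MotifInstance:
    """One signed feed-forward loop."""

    input: str
    intermediate: str
    output: str
    s_in: int  # sign of input -> intermediate
    s_out: int  # sign of intermediate -> output
    s_direct: int  # sign of input -> output
    cls: str  # coherent | incoherent
    adaptation_capable: bool


def classify_adaptation(s_in: int, s_out: int, s_direct: int) -> tuple[str, bool]:
    """Coherence class and adaptation capability from the three edge signs.

    The loop is incoherent — and counted adaptation-capable — exactly
    when sign(direct) != sign(indirect product).
    """
    if 0 in (s_in, s_out, s_direct):
        raise ValueError("motif edges must carry nonzero signs")
    incoherent = s_direct != s_in * s_out
    return ("incoherent" if incoherent else "coherent"), incoherent


def enumerate_ffl(
    K: np.ndarray,
    node_labels: list[tuple[str, str]] | None = None,
    restrict_to: list[int] | None = None,
) -> list[MotifInstance]:
    """All signed feed-forward loops of the network defined by K.

    K[i, j] nonzero means an edge from source j to target i; self-loops
    are ignored.  ``restrict_to`` limits the search to a node subset
    (e.g. one organ's subnetwork).  Enumeration walks edge pairs
    (a->b, b->c) and checks the closing edge a->c, which is exhaustive.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    nodes = list(range(n)) if restrict_to is None else list(restrict_to)
    node_set = set(nodes)

    # successors[a] = nodes b with edge a -> b (K[b, a] != 0)
    successors: dict[int, list[int]] = {a: [] for a in nodes}
    for a in nodes:
        for b in np.nonzero(K[:, a])[0]:
            if b != a and b in node_set:
                successors[a].append(int(b))

    def name(idx: int) -> str:
        if node_labels is None:
            return f"n{idx}"
        return node_label(*node_labels[idx])

    out = []
    for a in nodes:
        for b in successors[a]:
            for c in successors[b]:
                if c == a or c == b:
                    continue
                if K[c, a] == 0.0:
                    continue
                s_in = int(np.sign(K[b, a]))
                s_out = int(np.sign(K[c, b]))
                s_direct = int(np.sign(K[c, a]))
                cls, capable = classify_adaptation(s_in, s_out, s_direct)
                out.append(
                    MotifInstance(
                        input=name(a),
                        intermediate=name(b),
                        output=name(c),
                        s_in=s_in,
                        s_out=s_out,
                        s_direct=s_direct,
                        cls=cls,
                        adaptation_capable=capable,
                    )
                )
    return out


def motifs_frame(motifs: list[MotifInstance]):
    import pandas as pd

    return pd.DataFrame(
        {
            "input": [m.input for m in motifs],
            "intermediate": [m.intermediate for m in motifs],
            "output": [m.output for m in motifs],
            "s_in": [m.s_in for m in motifs],
            "s_out": [m.s_out for m in motifs],
            "s_direct": [m.s_direct for m in motifs],
            "class": [m.cls for m in motifs],
            "adaptation_capable": [m.adaptation_capable for m in motifs],
        }
    )
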