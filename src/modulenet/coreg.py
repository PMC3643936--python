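"""Co-regulation layer construction.

Starting from a binary gene x treatment significance-call matrix (gene g was
significantly regulated in treatment t), two genes are connected when they
are co-called in at least one treatment, weighted by the frequency of
co-regulation across treatments:

    w(a, b) = c_both / (c_both + c_a_only + c_b_only)

where c_both counts treatments calling both genes and c_a_only / c_b_only
count treatments calling exactly one of them. For graph partitioning, which
consumes integer edge weights, each weight is also stored scaled-and-rounded
(round-half-up of scale * w, default scale 10); edges that round to zero are
kept in the continuous network but excluded from the partitioning view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from modulenet.netio import Network


@dataclass
class CoregCounts:
    """Per-pair co-regulation counts over all treatments."""

    c_both: int
    c_a_only: int
    c_b_only: int

    def __post_init__(self):
        if min(self.c_both, self.c_a_only, self.c_b_only) < 0:
            raise ValueError("co-regulation counts must be non-negative")


@dataclass
class TreatmentCalls:
    """Binary significance calls: rows are genes, columns are treatments."""

    genes: list
    treatments: list
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.genes), len(self.treatments)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.genes)} genes x {len(self.treatments)} treatments"
            )
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be 0/1")
        self.calls = self.calls.astype(np.uint8)

    @classmethod
    def read_tsv(cls, path) -> "TreatmentCalls":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.calls, index=self.genes, columns=self.treatments)
        df.to_csv(path, sep="\t")

    @classmethod
    def from_pvalues(cls, pvalues: pd.DataFrame, threshold: float = 0.01) -> "TreatmentCalls":
        """Threshold a gene x treatment p-value matrix into binary calls."""
        calls = (pvalues.to_numpy() < threshold).astype(np.uint8)
        return cls(list(pvalues.index), list(pvalues.columns), calls)


def coregulation_weight(counts: CoregCounts) -> float:
    """Frequency with which two genes are co-regulated across treatments."""
    if counts.c_both < 1:
        raise ValueError("pairs never co-called carry no edge (c_both >= 1 required)")
    total = counts.c_both + counts.c_a_only + counts.c_b_only
    return counts.c_both / total


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_coregulation_network(calls: TreatmentCalls, scale: int = 10,
                               layer_name: str = "coreg") -> Network:
    """Build the weighted co-regulation network from binary calls.

    Every gene pair co-called in >= 1 treatment receives an edge whose
    ``weight`` is the continuous co-regulation frequency and whose
    ``iweight`` is the scaled-rounded integer used for partitioning.
    """
    if len(calls.treatments) < 1:
        raise ValueError("need at least one treatment")
    m = calls.calls.astype(np.int32)
    both = m @ m.T                      # c_both for every pair
    totals = m.sum(axis=1)              # per-gene call counts
    iu, ju = np.triu_indices(len(calls.genes), k=1)
    cb = both[iu, ju]
    hit = cb >= 1
    iu, ju, cb = iu[hit], ju[hit], cb[hit]
    union = totals[iu] + totals[ju] - cb   # c_both + c_a_only + c_b_only
    weights = cb / union

    net = Network(layer_name, weighted=True)
    genes = calls.genes
    net.graph.add_nodes_from(genes)
    for a, b, w in zip(iu, ju, weights):
        net.graph.add_edge(genes[a], genes[b], weight=float(w),
                           iweight=round_half_up(scale * float(w)))
    return net
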