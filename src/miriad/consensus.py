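"""Consensus miRNA-target calling by multi-tool support voting.

Target-prediction tools disagree wildly; a standard remedy is to keep only
genes predicted by at least ``threshold`` of the tools (default 4 of 11).
Predictions arrive as a pre-computed boolean gene x tool matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PredictionMatrix", "ConsensusSet", "consensus_targets", "support_histogram"]

#: Eleven commonly used miRNA target-prediction tools.
DEFAULT_TOOLS = (
    "DIANA-microT", "MicroInspector", "miRanda", "MirTarget2", "miTarget",
    "NBmiRTar", "PicTar", "PITA", "RNA22", "RNAhybrid", "TargetScan",
)


@dataclass(frozen=True)
class PredictionMatrix:
    """Boolean support grid: which tools predict which genes."""

    genes: tuple[str, ...]
    tools: tuple[str, ...]
    support: np.ndarray  # bool, shape (len(genes), len(tools))

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in prediction matrix")
        if len(set(self.tools)) != len(self.tools):
            raise ValueError("duplicate tool names in prediction matrix")
        if self.support.shape != (len(self.genes), len(self.tools)):
            raise ValueError(
                f"support grid shape {self.support.shape} does not match "
                f"{len(self.genes)} genes x {len(self.tools)} tools"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PredictionMatrix":
        """Build from a DataFrame indexed by gene with one 0/1 column per tool."""
        return cls(
            genes=tuple(str(g) for g in frame.index),
            tools=tuple(str(t) for t in frame.columns),
            support=frame.to_numpy().astype(bool),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.support.astype(int), index=list(self.genes),
                            columns=list(self.tools))

    @property
    def support_counts(self) -> np.ndarray:
        """Per-gene number of supporting tools (row sums)."""
        return self.support.sum(axis=1)


@dataclass(frozen=True)
class ConsensusSet:
    """Genes whose support count reached the voting threshold."""

    threshold: int
    members: dict[str, int] = field(default_factory=dict)  # gene -> support count

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def consensus_targets(matrix: PredictionMatrix, threshold: int = 4) -> ConsensusSet:
    """Genes predicted by at least ``threshold`` tools.

    ``threshold=1`` is the union of all tools' calls and
    ``threshold=len(tools)`` the intersection.
    """
    if not (1 <= threshold <= len(matrix.tools)):
        raise ValueError(
            f"threshold must be in [1, {len(matrix.tools)}], got {threshold}"
        )
    counts = matrix.support_counts
    members = {g: int(c) for g, c in zip(matrix.genes, counts) if c >= threshold}
    return ConsensusSet(threshold=threshold, members=members)


def support_histogram(matrix: PredictionMatrix) -> np.ndarray:
    """Number of genes at each support level 0..n_tools; sums to the gene count."""
    return np.bincount(matrix.support_counts, minlength=len(matrix.tools) + 1)
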