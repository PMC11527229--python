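"""Principal projection: low-rank operators from task-head weights.

Concatenating the weight matrices of a group of task heads and keeping the
leading left-singular directions that account for a fraction lambda of the
squared singular values yields a projection operator that isolates the
information those tasks use.  Alignment between two operators is the
spectral norm of U1^T U2, which is 0 for orthogonal spans and 1 when the
spans coincide up to a unitary rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import HeadSpec

__all__ = [
    "ProjectionOperator",
    "low_rank_operator",
    "project_embeddings",
    "alignment_score",
    "attribute_contributions",
]


@dataclass
class ProjectionOperator:
    attribute: str
    U: np.ndarray                # (D, D_tilde), orthonormal columns
    retained_energy: float       # fraction of squared singular values kept
    source_tasks: tuple[str, ...] = ()
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def rank(self) -> int:
        return int(self.U.shape[1])

    def validate(self) -> None:
        gram = self.U.T @ self.U
        if not np.allclose(gram, np.eye(self.rank), atol=1e-8):
            raise ValueError("operator columns are not orthonormal")


def low_rank_operator(
    task_heads: Sequence[HeadSpec] | Sequence[np.ndarray] | np.ndarray,
    retain: float = 0.95,
    attribute: str = "",
) -> ProjectionOperator:
    """Build the low-rank operator from concatenated head weight matrices.

    Keeps the smallest leading set of singular values whose squared sum
    first reaches ``retain`` of the total (singular values in decreasing
    order); the operator is the corresponding left-singular columns.
    """
    if not (0 < retain <= 1):
        raise ValueError("retain must be in (0, 1]")
    if isinstance(task_heads, np.ndarray):
        W = task_heads
        names: tuple[str, ...] = ()
    else:
        heads = list(task_heads)
        if len(heads) == 0:
            raise ValueError("task head list is empty")
        mats = [h.W if isinstance(h, HeadSpec) else np.asarray(h) for h in heads]
        dims = {m.shape[0] for m in mats}
        if len(dims) != 1:
            raise ValueError(f"heads disagree on embedding dimension: {dims}")
        W = np.concatenate(mats, axis=1)
        names = tuple(h.task_name for h in heads if isinstance(h, HeadSpec))

    U, s, _ = np.linalg.svd(W, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("concatenated weight matrix is zero")
    cum = np.cumsum(s**2) / total
    rank = int(np.searchsorted(cum, retain - 1e-12) + 1)
    rank = min(rank, s.size)
    op = ProjectionOperator(
        attribute=attribute,
        U=U[:, :rank],
        retained_energy=float(cum[rank - 1]),
        source_tasks=names,
        singular_values=s.copy(),
    )
    op.validate()
    return op


def project_embeddings(embeddings: np.ndarray, op: ProjectionOperator) -> np.ndarray:
    """z_tilde = U^T z, applied row-wise to an (N, D) embedding matrix."""
    Z = np.asarray(embeddings)
    if Z.shape[-1] != op.U.shape[0]:
        raise ValueError(
            f"embedding dim {Z.shape[-1]} != operator dim {op.U.shape[0]}"
        )
    return Z @ op.U


def alignment_score(op1: ProjectionOperator, op2: ProjectionOperator) -> float:
    """phi = ||U1^T U2||_2, the spectral norm of the cross-Gram matrix."""
    if op1.U.shape[0] != op2.U.shape[0]:
        raise ValueError("operators live in different embedding dimensions")
    phi = float(np.linalg.norm(op1.U.T @ op2.U, ord=2))
    return float(np.clip(phi, 0.0, 1.0))


def attribute_contributions(
    classifier_head: HeadSpec,
    attribute_ops: Sequence[ProjectionOperator],
    retain: float = 0.95,
) -> dict:
    """Alignment of a fine-tuned head with each attribute operator.

    Returns the raw per-attribute phi values and, normalized to sum 1, the
    fractional contributions.  A head orthogonal to every attribute yields
    uniform fractions with a warning.
    """
    head_op = low_rank_operator([classifier_head], retain=retain,
                                attribute=classifier_head.task_name)
    phis = {op.attribute: alignment_score(head_op, op) for op in attribute_ops}
    total = sum(phis.values())
    if total <= 0:
        warnings.warn(
            "classifier head is orthogonal to all attribute operators; "
            "reporting uniform fractions"
        )
        n = len(phis)
        fractions = {a: 1.0 / n for a in phis}
    else:
        fractions = {a: v / total for a, v in phis.items()}
    return {"phi": phis, "fractions": fractions}
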