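"""Flat cluster assignments."""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = ["Partition"]


class Partition:
    """A total assignment of observations to cluster labels.

    Labels are arbitrary hashable symbols (ints after dendrogram cutting,
    strings when read from a file); observation ids default to 0..n-1.
    """

    def __init__(self, labels: Sequence, ids: Sequence | None = None):
        self.labels = np.asarray(labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if ids is None:
            ids = np.arange(len(self.labels))
        self.ids = np.asarray(ids)
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels must have equal length")
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("observation ids must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()))

    def clusters(self) -> dict:
        """Map each cluster label to the array of member ids."""
        out: dict = {}
        for i, lab in zip(self.ids, self.labels):
            out.setdefault(lab, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "cluster": self.labels})

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.ids == other.ids))
            and bool(np.all(self.labels == other.labels))
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Partition(n={len(self)}, k={self.n_clusters()})"
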