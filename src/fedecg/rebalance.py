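"""SMOTE minority-class oversampling on fiducial-feature tables.

Synthetic minority records are convex combinations ``x + u * (x_nn - x)``
(``u ~ Uniform(0, 1)``) of an original minority record and one of its k
nearest same-class neighbours under the Euclidean metric on the 9 features.
Original rows are always preserved verbatim and come first in the output;
``synthetic_mask`` on the result marks the appended rows.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .features import CLASS_NAMES, N_CLASSES, FeatureMatrix


class SMOTEOverSampler:
    """Minority oversampler with the classic interpolation rule.

    Parameters
    ----------
    k_neighbors:
        Neighbourhood size for interpolation partners; internally capped at
        (class size - 1). Default 5, the reference default.
    target:
        ``"balance"`` (every class raised to the majority count) or a mapping
        of class code/name to target counts.
    random_state:
        Seed for parent/neighbour/offset draws.
    """

    def __init__(self, k_neighbors: int = 5, target="balance", random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.target = target
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"k_neighbors": self.k_neighbors, "target": self.target,
                "random_state": self.random_state}

    def set_params(self, **kw) -> "SMOTEOverSampler":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def _targets(self, counts: np.ndarray) -> np.ndarray:
        if isinstance(self.target, str) and self.target == "balance":
            return np.where(counts > 0, counts.max(), 0)
        if isinstance(self.target, Mapping):
            out = counts.copy()
            for key, v in self.target.items():
                code = CLASS_NAMES.index(key) if isinstance(key, str) else int(key)
                out[code] = int(v)
            return out
        raise ValueError(f"unrecognised target {self.target!r}")

    def fit_resample(self, data: FeatureMatrix) -> FeatureMatrix:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        rng = np.random.default_rng(self.random_state)
        counts = data.class_counts()
        targets = self._targets(counts)
        if np.any(targets < counts):
            raise ValueError("SMOTE never removes records; target below current count")

        new_rows, new_labels = [], []
        for code in range(N_CLASSES):
            deficit = int(targets[code] - counts[code])
            if deficit == 0:
                continue
            if counts[code] < 2:
                raise ValueError(
                    f"class {CLASS_NAMES[code]!r} has {counts[code]} sample(s); "
                    "need >= 2 to oversample"
                )
            idx = np.flatnonzero(data.labels == code)
            X = data.values[idx]
            k = min(self.k_neighbors, len(idx) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
            # drop self-neighbour in column 0
            neighbours = nn.kneighbors(X, return_distance=False)[:, 1:]
            parents = rng.integers(0, len(idx), size=deficit)
            partner_col = rng.integers(0, k, size=deficit)
            u = rng.uniform(0.0, 1.0, size=deficit)
            partners = neighbours[parents, partner_col]
            synth = X[parents] + u[:, None] * (X[partners] - X[parents])
            new_rows.append(synth)
            new_labels.append(np.full(deficit, code, dtype=int))

        if not new_rows:
            out = data.take(np.arange(data.n))
            out.synthetic_mask = np.zeros(data.n, dtype=bool)
            return out

        values = np.concatenate([data.values] + new_rows)
        labels = np.concatenate([data.labels] + new_labels)
        sids = None
        if data.subject_ids is not None:
            n_new = sum(len(r) for r in new_rows)
            sids = np.concatenate(
                [data.subject_ids, np.array(["synthetic"] * n_new)]
            )
        out = FeatureMatrix(values, labels, sids)
        out.synthetic_mask = np.concatenate(
            [np.zeros(data.n, dtype=bool),
             np.ones(len(values) - data.n, dtype=bool)]
        )
        return out


def smote_oversample(
    data: FeatureMatrix,
    k_neighbors: int = 5,
    target="balance",
    seed: int = 0,
) -> FeatureMatrix:
    """Functional wrapper around :class:`SMOTEOverSampler`."""
    return SMOTEOverSampler(k_neighbors, target, seed).fit_resample(data)
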