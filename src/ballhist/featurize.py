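"""Propositionalization: ball histograms -> fixed-length attribute vectors.

Each attribute is a (template, count vector, sampling radius) triple observed
with non-zero weight in at least one training histogram; a protein's value
for it is the height of that bin in the protein's own histogram (0 when
absent). Bins first seen at prediction time are silently dropped — the
attribute space is frozen on the training set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .ball_histogram import BallHistogram, CountVector, Template
from .exceptions import DataError

AttributeId = tuple[Template, CountVector, float]


@dataclass(frozen=True)
class AttributeSpace:
    """Ordered, immutable list of attribute ids fixed at training time."""

    attributes: tuple[AttributeId, ...]

    def __post_init__(self) -> None:
        if len(set(self.attributes)) != len(self.attributes):
            raise DataError("attribute ids must be distinct")

    def __len__(self) -> int:
        return len(self.attributes)

    def labels(self) -> list[str]:
        return [
            f"{'|'.join(t.properties)}@R{radius:g}:{','.join(map(str, vec))}"
            for (t, vec, radius) in self.attributes
        ]


@dataclass
class FeatureVector:
    """Values aligned with an AttributeSpace, optionally labeled."""

    values: np.ndarray
    label: int | None = None


def collect_attributes(
    training_histograms: Sequence[Sequence[BallHistogram]],
) -> AttributeSpace:
    """Union of non-zero bins over all training proteins.

    ``training_histograms`` holds one histogram list per protein; every
    protein must present the same (template, radius) sequence in the same
    order. Attribute order: template order, then lexicographic count vector.
    """
    if not training_histograms:
        raise DataError("cannot collect attributes from an empty training set")
    signature = [
        (h.template, h.sampling_radius) for h in training_histograms[0]
    ]
    attributes: list[AttributeId] = []
    for pos, (template, radius) in enumerate(signature):
        support: set[CountVector] = set()
        for hist_set in training_histograms:
            h = hist_set[pos]
            if (h.template, h.sampling_radius) != (template, radius):
                raise DataError("all proteins must share one (template, radius) sequence")
            support.update(h.bins)
        attributes.extend((template, vec, radius) for vec in sorted(support))
    return AttributeSpace(tuple(attributes))


def vectorize(
    histograms: Sequence[BallHistogram], space: AttributeSpace
) -> np.ndarray:
    """One protein's feature values; bins outside the space are dropped."""
    lookup: dict[tuple[Template, float], BallHistogram] = {
        (h.template, h.sampling_radius): h for h in histograms
    }
    values = np.zeros(len(space), dtype=float)
    for i, (template, vec, radius) in enumerate(space.attributes):
        try:
            h = lookup[(template, radius)]
        except KeyError:
            raise DataError(
                f"no histogram supplied for template {template!r} at R={radius}"
            ) from None
        values[i] = h.bins.get(vec, 0.0)
    return values


def feature_matrix(
    histogram_sets: Sequence[Sequence[BallHistogram]], space: AttributeSpace
) -> np.ndarray:
    return np.stack([vectorize(hs, space) for hs in histogram_sets])


def rank_features(
    X: np.ndarray, y: Sequence[int], space: AttributeSpace, n_bins: int = 10
) -> list[tuple[AttributeId, float]]:
    """χ² ranking of individual attributes, descending.

    Each feature (a bin fraction in [0, 1]) is discretized into ``n_bins``
    equal-width bins; empty bins are dropped before the χ² statistic of the
    bin-by-class contingency table is computed (no continuity correction).
    Ties keep attribute order.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DataError("chi-square ranking requires both classes")
    if X.shape != (len(y), len(space)):
        raise DataError(f"feature matrix shape {X.shape} does not match inputs")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    scores = np.zeros(len(space))
    for j in range(X.shape[1]):
        binned = np.clip(np.digitize(X[:, j], edges[1:-1], right=False), 0, n_bins - 1)
        table = np.zeros((n_bins, 2))
        for b, cls in zip(binned, y):
            table[b, cls] += 1
        table = table[table.sum(axis=1) > 0]
        if table.shape[0] < 2:
            scores[j] = 0.0
        else:
            scores[j] = float(chi2_contingency(table, correction=False)[0])
    order = sorted(range(len(space)), key=lambda j: (-scores[j], j))
    return [(space.attributes[j], scores[j]) for j in order]


def write_features(
    path: str,
    X: np.ndarray,
    y: Sequence[int],
    space: AttributeSpace,
    ids: Sequence[str],
) -> None:
    """TSV: one row per protein, attribute columns, final label column."""
    with open(path, "w") as fh:
        fh.write("\t".join(["id", *space.labels(), "label"]) + "\n")
        for pid, row, label in zip(ids, X, y):
            fh.write(
                "\t".join([str(pid), *(repr(float(v)) for v in row), str(int(label))])
                + "\n"
            )


def read_features(path: str) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    """Inverse of :func:`write_features`: (ids, X, y, attribute labels)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = header[1:-1]
        ids, rows, y = [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:-1]])
            y.append(int(parts[-1]))
    return ids, np.array(rows), np.array(y), labels
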