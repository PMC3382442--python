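"""Ball histograms: Monte-Carlo spatial distributions of amino-acid properties.

A ball histogram for a template τ = (f1, ..., fk) estimates the joint
probability that a sampling ball of radius R, placed uniformly at random
inside the protein's bounding sphere and containing at least one residue,
contains exactly t_i residues complying with property f_i. Empty balls are
discarded before normalization, which removes any dependence on the amount
of empty space inside the bounding sphere; the resulting descriptor is
invariant to rotation and translation of the structure and insensitive to
inflating the bounding sphere.

Ball membership is crisp: a residue falls within a ball iff its alpha-carbon
lies at Euclidean distance <= R from the ball's center.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import DataError, DegenerateSamplingError
from .structures import PropertyTable, ProteinStructure, geometric_center

CountVector = tuple[int, ...]


@dataclass(frozen=True)
class Template:
    """Ordered list of distinct Boolean amino-acid property names."""

    properties: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "properties", tuple(self.properties))
        if len(set(self.properties)) != len(self.properties):
            raise DataError(f"template properties must be distinct: {self.properties}")

    def __len__(self) -> int:
        return len(self.properties)

    def __iter__(self):
        return iter(self.properties)

    def __repr__(self) -> str:
        return f"Template({', '.join(self.properties)})"

    def is_subset_of(self, other: "Template") -> bool:
        return set(self.properties) <= set(other.properties)


@dataclass(frozen=True)
class BoundingSphere:
    """Sampling domain: centered at the geometric center, radius R_S."""

    center: tuple[float, float, float]
    radius: float


class BallHistogram:
    """Normalized sparse map from count vectors to probabilities.

    Histograms produced by Monte-Carlo sampling additionally retain integer
    draw counts per bin (``counts``), which lets :func:`marginalize` reproduce
    a directly-built sub-template histogram bit for bit.
    """

    def __init__(
        self,
        template: Template,
        sampling_radius: float,
        bins: Mapping[CountVector, float],
        n_samples: int = 0,
        counts: Mapping[CountVector, int] | None = None,
        n_used: int | None = None,
    ):
        self.template = template
        self.sampling_radius = float(sampling_radius)
        self.bins: dict[CountVector, float] = {
            tuple(int(t) for t in k): float(w) for k, w in bins.items() if w != 0.0
        }
        self.n_samples = int(n_samples)
        self.counts = (
            {tuple(int(t) for t in k): int(c) for k, c in counts.items() if c}
            if counts is not None
            else None
        )
        self.n_used = n_used  # non-empty draws actually normalized over
        k = len(template)
        for vec, w in self.bins.items():
            if len(vec) != k:
                raise DataError(f"count vector {vec} does not match template length {k}")
            if w < 0 or any(t < 0 for t in vec):
                raise DataError("negative weight or count in histogram")
        total = math.fsum(self.bins.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"histogram weights sum to {total!r}, expected 1")

    def total(self) -> float:
        return math.fsum(self.bins.values())

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BallHistogram)
            and self.template == other.template
            and self.sampling_radius == other.sampling_radius
            and self.bins == other.bins
        )

    def __repr__(self) -> str:
        return (
            f"BallHistogram({self.template!r}, R={self.sampling_radius}, "
            f"{len(self.bins)} bins)"
        )

    def l1_distance(self, other: "BallHistogram") -> float:
        keys = set(self.bins) | set(other.bins)
        return math.fsum(abs(self.bins.get(k, 0.0) - other.bins.get(k, 0.0)) for k in keys)


def bounding_sphere(structure: ProteinStructure, R: float) -> BoundingSphere:
    """Sphere at the geometric center with radius max_res distance(res, C) + R."""
    if R <= 0:
        raise DataError(f"sampling-ball radius must be positive, got {R}")
    center = geometric_center(structure)
    max_dist = float(np.linalg.norm(structure.coords - center, axis=1).max())
    return BoundingSphere(center=tuple(center), radius=max_dist + float(R))


def count_in_ball(
    structure: ProteinStructure,
    template: Template,
    center: Sequence[float],
    R: float,
    table: PropertyTable | None = None,
) -> CountVector | None:
    """Property-count vector of the residues in one sampling ball.

    Returns ``None`` (the EMPTY marker) when the ball contains no residue at
    all — distinct from the all-zero vector, which means the ball contains
    residues but none complying with any template property.
    """
    if R <= 0:
        raise DataError(f"sampling-ball radius must be positive, got {R}")
    table = table if table is not None else PropertyTable.default()
    d = np.linalg.norm(structure.coords - np.asarray(center, dtype=float), axis=1)
    inside = d <= R
    if not inside.any():
        return None
    types_inside = [t for t, keep in zip(structure.res_types, inside) if keep]
    return tuple(
        sum(1 for t in types_inside if t in table.members(p)) for p in template
    )


def protein_seed(global_seed: int, structure_id: str) -> int:
    """Stable per-protein seed (< 2**31) derived from a global seed and the id."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(structure_id.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _uniform_ball_points(rng: np.random.Generator, n: int) -> np.ndarray:
    """n points uniform in the unit ball: Gaussian direction x cube-root radius."""
    directions = rng.standard_normal((n, 3))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    radii = np.cbrt(rng.random(n))[:, None]
    return directions / norms * radii


def _sample_count_matrix(
    structure: ProteinStructure,
    properties: Sequence[str],
    R: float,
    n_samples: int,
    seed: int,
    table: PropertyTable,
    extra_bounding_radius: float = 0.0,
) -> np.ndarray:
    """(m, k) integer matrix of property counts for the m non-empty draws.

    The random stream depends only on (structure, R, n_samples, seed, extra
    bounding radius) — never on the property list — so every template built
    from the same call parameters shares one sample set exactly.
    """
    if n_samples <= 0:
        raise DataError(f"n_samples must be positive, got {n_samples}")
    sphere = bounding_sphere(structure, R)
    rng = np.random.default_rng(seed)
    points = (
        _uniform_ball_points(rng, n_samples) * (sphere.radius + extra_bounding_radius)
        + np.asarray(sphere.center)
    )
    tree = cKDTree(structure.coords)
    neighbours = tree.query_ball_point(points, R)
    lens = np.fromiter((len(ix) for ix in neighbours), dtype=np.int64, count=n_samples)
    nonempty = lens > 0
    if not nonempty.any():
        raise DegenerateSamplingError(
            f"all {n_samples} sampling balls were empty for structure {structure.id!r}"
        )
    flat = np.concatenate([neighbours[i] for i in np.nonzero(nonempty)[0]]).astype(np.int64)
    sample_id = np.repeat(np.arange(int(nonempty.sum())), lens[nonempty])
    membership = table.membership_matrix(structure.res_types, properties)
    m = int(nonempty.sum())
    counts = np.empty((m, len(properties)), dtype=np.int64)
    for j in range(len(properties)):
        counts[:, j] = np.bincount(
            sample_id, weights=membership[flat, j], minlength=m
        ).astype(np.int64)
    return counts


def _histogram_from_counts(
    counts: np.ndarray, template: Template, R: float, n_samples: int
) -> BallHistogram:
    vectors, freq = np.unique(counts, axis=0, return_counts=True)
    m = int(freq.sum())
    raw = {tuple(int(t) for t in v): int(c) for v, c in zip(vectors, freq)}
    bins = {k: c / m for k, c in raw.items()}
    return BallHistogram(
        template=template,
        sampling_radius=R,
        bins=bins,
        n_samples=n_samples,
        counts=raw,
        n_used=m,
    )


def build_histogram(
    structure: ProteinStructure,
    template: Template,
    R: float,
    n_samples: int = 10_000,
    seed: int = 0,
    table: PropertyTable | None = None,
    extra_bounding_radius: float = 0.0,
) -> BallHistogram:
    """Monte-Carlo ball histogram for one template.

    Draws ``n_samples`` ball centers uniformly from the bounding sphere,
    discards empty balls, counts residues complying with each template
    property in the rest, and normalizes by the number of non-empty draws.
    Deterministic given the seed.
    """
    table = table if table is not None else PropertyTable.default()
    counts = _sample_count_matrix(
        structure, template.properties, R, n_samples, seed, table, extra_bounding_radius
    )
    return _histogram_from_counts(counts, template, R, n_samples)


def master_count_vectors(
    structure: ProteinStructure,
    pool: Sequence[str],
    R: float,
    n_samples: int = 10_000,
    seed: int = 0,
    table: PropertyTable | None = None,
) -> BallHistogram:
    """Full-pool histogram: counts over every property in the pool at once.

    Built once per (structure, radius, seed), it can be marginalized to any
    sub-template, reproducing :func:`build_histogram` exactly for the same
    seed and sample count.
    """
    table = table if table is not None else PropertyTable.default()
    template = Template(tuple(pool))
    counts = _sample_count_matrix(structure, template.properties, R, n_samples, seed, table)
    return _histogram_from_counts(counts, template, R, n_samples)


def marginalize(hist: BallHistogram, sub: Template) -> BallHistogram:
    """Project a histogram onto a sub-template, summing colliding bins.

    Projection preserves total mass, so the result is normalized. When the
    source retains integer draw counts the aggregation is exact.
    """
    positions = []
    parent = list(hist.template.properties)
    for p in sub.properties:
        try:
            positions.append(parent.index(p))
        except ValueError:
            raise DataError(
                f"property {p!r} of sub-template not in histogram template {parent}"
            ) from None
    if hist.counts is not None and hist.n_used:
        agg_counts: dict[CountVector, int] = {}
        for vec, c in hist.counts.items():
            key = tuple(vec[i] for i in positions)
            agg_counts[key] = agg_counts.get(key, 0) + c
        bins = {k: c / hist.n_used for k, c in agg_counts.items()}
        return BallHistogram(
            template=sub,
            sampling_radius=hist.sampling_radius,
            bins=bins,
            n_samples=hist.n_samples,
            counts=agg_counts,
            n_used=hist.n_used,
        )
    agg: dict[CountVector, float] = {}
    for vec, w in hist.bins.items():
        key = tuple(vec[i] for i in positions)
        agg[key] = agg.get(key, 0.0) + w
    return BallHistogram(
        template=sub, sampling_radius=hist.sampling_radius, bins=agg,
        n_samples=hist.n_samples,
    )


def write_histogram(hist: BallHistogram, path: str) -> None:
    """Serialize as TSV with a JSON header line; round-trips exactly."""
    header = {
        "template": list(hist.template.properties),
        "sampling_radius": hist.sampling_radius,
        "n_samples": hist.n_samples,
        "n_used": hist.n_used,
        "has_counts": hist.counts is not None,
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        for vec in sorted(hist.bins):
            w = hist.bins[vec]
            c = hist.counts.get(vec, 0) if hist.counts is not None else ""
            fh.write("\t".join([",".join(map(str, vec)), repr(w), str(c)]) + "\n")


def read_histogram(path: str) -> BallHistogram:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise DataError(f"{path}: missing histogram header line")
        header = json.loads(first[1:])
        bins: dict[CountVector, float] = {}
        counts: dict[CountVector, int] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            vec_s, w_s, c_s = line.split("\t")
            vec = tuple(int(t) for t in vec_s.split(",")) if vec_s else ()
            bins[vec] = float(w_s)
            if header["has_counts"]:
                counts[vec] = int(c_s)
    return BallHistogram(
        template=Template(tuple(header["template"])),
        sampling_radius=header["sampling_radius"],
        bins=bins,
        n_samples=header["n_samples"],
        counts=counts if header["has_counts"] else None,
        n_used=header["n_used"],
    )
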