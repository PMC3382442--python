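"""Automatic template discovery by best-first search on Bhattacharyya distance.

A good template is one whose ball histograms differ as much as possible, on
average, between DNA-binding and non-DNA-binding proteins. The search scores
a candidate template by the Bhattacharyya distance between the two classes'
average full-pool histograms marginalized onto that template, explores the
template lattice up to a maximum length with best-first expansion, penalizes
candidates that are subsets of already-discovered templates (diversity), and
seeds each later search round with pairwise intersections of the discovered
templates (shared "cores" of informative templates).

Greedy expansion is insufficient here: two properties can be individually
uninformative (identical class marginals) yet jointly perfectly
discriminative, which is why the lattice is explored exhaustively up to the
length bound. A greedy variant is provided as a diagnostic only.
"""

from __future__ import annotations

import heapq
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ball_histogram import BallHistogram, Template, marginalize
from .exceptions import DataError

logger = logging.getLogger(__name__)

#: Finite surrogate for an infinite Bhattacharyya distance during scoring.
DEFAULT_DISTANCE_CAP = -math.log(1e-12)


@dataclass(frozen=True)
class SearchConfig:
    """Hyperparameters of the template search.

    pool : ordered property names the search may combine.
    max_length : L, the largest template length explored (attribute count is
        exponential in L, so keep it small).
    lambda_penalty : λ in [0, 1]; scores of candidates that are subsets of an
        already-discovered template are multiplied by λ, steering the search
        away from redundant templates.
    n_templates : how many templates to discover.
    distance_cap : finite stand-in for an infinite distance while scoring.
    """

    pool: tuple[str, ...]
    max_length: int = 3
    lambda_penalty: float = 0.5
    n_templates: int = 3
    distance_cap: float = DEFAULT_DISTANCE_CAP

    def __post_init__(self) -> None:
        if not self.pool:
            raise DataError("search pool must be non-empty")
        if len(set(self.pool)) != len(self.pool):
            raise DataError("search pool properties must be distinct")
        if not (0.0 <= self.lambda_penalty <= 1.0):
            raise DataError(f"lambda_penalty must be in [0, 1], got {self.lambda_penalty}")
        if self.max_length < 1 or self.n_templates < 1 or self.distance_cap <= 0:
            raise DataError("max_length, n_templates >= 1 and distance_cap > 0 required")


def class_average(histograms: Sequence[BallHistogram]) -> BallHistogram:
    """Unweighted mean of per-protein histograms (proteins weighted equally)."""
    if not histograms:
        raise DataError("cannot average an empty histogram collection")
    first = histograms[0]
    agg: dict[tuple[int, ...], float] = {}
    for h in histograms:
        if h.template != first.template or h.sampling_radius != first.sampling_radius:
            raise DataError("class_average requires identical templates and radii")
        for vec, w in h.bins.items():
            agg[vec] = agg.get(vec, 0.0) + w
    n = len(histograms)
    return BallHistogram(
        template=first.template,
        sampling_radius=first.sampling_radius,
        bins={k: v / n for k, v in agg.items()},
    )


def bhattacharyya(ha: BallHistogram, hb: BallHistogram) -> float:
    """D_B = -ln Σ_x sqrt(ha(x)·hb(x)); +inf for disjoint supports, 0 for equal."""
    if ha.template != hb.template:
        raise DataError("Bhattacharyya distance requires identical templates")
    if ha.sampling_radius != hb.sampling_radius:
        raise DataError("Bhattacharyya distance requires identical sampling radii")
    bc = math.fsum(
        math.sqrt(w * hb.bins[vec]) for vec, w in ha.bins.items() if vec in hb.bins
    )
    if bc <= 0.0:
        return math.inf
    return max(0.0, -math.log(min(bc, 1.0)))


class ClassAverages:
    """Class-average histograms plus a fast marginal-distance evaluator.

    Built either from two full-pool average histograms (the normal path —
    marginal distances are computed by projecting the joint support, using a
    packed-key bincount for speed) or from precomputed per-template marginals
    via :meth:`from_marginals` (used when only marginal tables are available,
    e.g. for worked examples and unit fixtures).
    """

    def __init__(self, positive_avg: BallHistogram, negative_avg: BallHistogram):
        if positive_avg.template != negative_avg.template:
            raise DataError("class averages must share a template")
        self.positive_avg = positive_avg
        self.negative_avg = negative_avg
        self.pool: tuple[str, ...] = positive_avg.template.properties
        self._marginals: dict[tuple[str, ...], tuple[BallHistogram, BallHistogram]] | None = None
        self._distance_cache: dict[tuple[str, ...], float] = {}
        self._arrays: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @classmethod
    def from_marginals(
        cls,
        pool: Sequence[str],
        positive: Mapping[Template, BallHistogram],
        negative: Mapping[Template, BallHistogram],
    ) -> "ClassAverages":
        """Construct from explicit per-template marginal histograms."""
        obj = cls.__new__(cls)
        obj.positive_avg = None
        obj.negative_avg = None
        obj.pool = tuple(pool)
        obj._marginals = {}
        for t in positive:
            if t not in negative:
                raise DataError(f"template {t!r} missing from the negative marginals")
            obj._marginals[t.properties] = (positive[t], negative[t])
        obj._distance_cache = {}
        obj._arrays = None
        return obj

    def _build_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._arrays is None:
            keys = sorted(set(self.positive_avg.bins) | set(self.negative_avg.bins))
            V = np.array(keys, dtype=np.int64).reshape(len(keys), len(self.pool))
            wp = np.array([self.positive_avg.bins.get(k, 0.0) for k in keys])
            wn = np.array([self.negative_avg.bins.get(k, 0.0) for k in keys])
            self._arrays = (V, wp, wn)
        return self._arrays

    def marginal_pair(self, template: Template) -> tuple[BallHistogram, BallHistogram]:
        if self._marginals is not None:
            try:
                return self._marginals[template.properties]
            except KeyError:
                raise DataError(
                    f"no precomputed marginal for template {template!r}"
                ) from None
        return (
            marginalize(self.positive_avg, template),
            marginalize(self.negative_avg, template),
        )

    def distance(self, template: Template) -> float:
        """Bhattacharyya distance of the two class averages on this template."""
        key = template.properties
        if key in self._distance_cache:
            return self._distance_cache[key]
        if len(template) == 0:
            d = 0.0  # both marginals collapse to the point mass {(): 1}
        elif self._marginals is not None:
            ha, hb = self.marginal_pair(template)
            d = bhattacharyya(ha, hb)
        else:
            d = self._fast_distance(template)
        self._distance_cache[key] = d
        return d

    def _fast_distance(self, template: Template) -> float:
        V, wp, wn = self._build_arrays()
        cols = [self.pool.index(p) for p in template.properties]
        sub = V[:, cols]
        sizes = sub.max(axis=0) + 1
        keyspace = int(np.prod(sizes))
        if keyspace <= 4_000_000:
            key = sub[:, 0].copy()
            for j in range(1, sub.shape[1]):
                key *= sizes[j]
                key += sub[:, j]
            bp = np.bincount(key, weights=wp, minlength=keyspace)
            bn = np.bincount(key, weights=wn, minlength=keyspace)
        else:  # huge count range: group via sort instead of dense bincount
            _, inverse = np.unique(sub, axis=0, return_inverse=True)
            bp = np.bincount(inverse, weights=wp)
            bn = np.bincount(inverse, weights=wn)
        bc = float(np.sqrt(bp * bn).sum())
        if bc <= 0.0:
            return math.inf
        return max(0.0, -math.log(min(bc, 1.0)))


def _canonical(properties: Iterable[str], pool: Sequence[str]) -> Template:
    order = {p: i for i, p in enumerate(pool)}
    return Template(tuple(sorted(set(properties), key=order.__getitem__)))


def heuristic_score(
    template: Template,
    averages: ClassAverages,
    discovered: Iterable[Template],
    config: SearchConfig,
) -> float:
    """Capped class-average distance, multiplied by λ for redundant candidates."""
    base = min(averages.distance(template), config.distance_cap)
    if any(template.is_subset_of(d) for d in discovered):
        base *= config.lambda_penalty
    return base


def _pop_key(score: float, template: Template) -> tuple:
    # heapq is a min-heap: negate score; then shorter templates, then
    # lexicographic property order.
    return (-score, len(template), template.properties)


def best_first_search(
    averages: ClassAverages,
    discovered: Iterable[Template],
    config: SearchConfig,
) -> Template | None:
    """One round of template search; returns the best non-discovered template.

    Open starts with the empty template plus all non-empty pairwise
    intersections of already-discovered templates. Nodes are popped in score
    order (ties: shorter template, then property order), expanded by one
    property at a time up to the length bound, and the incumbent best is
    replaced whenever a popped template's actual (uncapped-rule) distance
    exceeds the incumbent's and the template is not already discovered.
    Returns ``None`` only when every template in the lattice is discovered.
    """
    discovered = list(discovered)
    discovered_keys = {d.properties for d in discovered}
    heap: list[tuple] = []
    closed: set[tuple[str, ...]] = set()

    def push(t: Template) -> None:
        if t.properties in closed:
            return
        closed.add(t.properties)
        heapq.heappush(heap, _pop_key(heuristic_score(t, averages, discovered, config), t))

    push(Template(()))
    for i, ti in enumerate(discovered):
        for tj in discovered[:i]:
            inter = set(ti.properties) & set(tj.properties)
            if inter:
                push(_canonical(inter, config.pool))

    best: Template | None = None
    best_distance = -math.inf
    fallback: Template | None = None
    fallback_score = -math.inf
    while heap:
        neg_score, _, props = heapq.heappop(heap)
        template = Template(props)
        if len(template) > 0 and template.properties not in discovered_keys:
            d = averages.distance(template)
            if d > best_distance:
                best, best_distance = template, d
            if -neg_score > fallback_score:
                fallback, fallback_score = template, -neg_score
        if len(template) < config.max_length:
            present = set(template.properties)
            for p in config.pool:
                if p not in present:
                    push(_canonical(present | {p}, config.pool))
    return best if best is not None else fallback


def greedy_search(
    averages: ClassAverages,
    discovered: Iterable[Template],
    config: SearchConfig,
) -> Template | None:
    """Greedy variant (expand only the best child, no backtracking).

    Diagnostic only: it demonstrates why best-first exploration is needed —
    jointly informative property pairs whose members are individually
    uninformative are invisible to it.
    """
    discovered = list(discovered)
    current = Template(())
    best: Template | None = None
    best_distance = -math.inf
    while len(current) < config.max_length:
        children = []
        present = set(current.properties)
        for p in config.pool:
            if p not in present:
                child = _canonical(present | {p}, config.pool)
                children.append(
                    (_pop_key(heuristic_score(child, averages, discovered, config), child), child)
                )
        if not children:
            break
        children.sort(key=lambda item: item[0])
        current = children[0][1]
        d = averages.distance(current)
        if current not in discovered and d > best_distance:
            best, best_distance = current, d
    return best


def discover_templates(
    positives: Sequence[BallHistogram],
    negatives: Sequence[BallHistogram],
    config: SearchConfig,
) -> list[Template]:
    """Run best-first search ``n_templates`` times, accumulating templates."""
    if not positives or not negatives:
        raise DataError("both classes must be non-empty for template discovery")
    averages = ClassAverages(class_average(list(positives)), class_average(list(negatives)))
    return discover_from_averages(averages, config)


def discover_from_averages(averages: ClassAverages, config: SearchConfig) -> list[Template]:
    templates: list[Template] = []
    for _ in range(config.n_templates):
        t = best_first_search(averages, templates, config)
        if t is None:
            warnings.warn(
                f"template lattice exhausted after {len(templates)} templates "
                f"(requested {config.n_templates})",
                stacklevel=2,
            )
            break
        templates.append(t)
    return templates


def template_report(
    averages: ClassAverages, templates: Sequence[Template], config: SearchConfig
) -> list[dict]:
    """JSON-ready report: each template with capped and uncapped distances."""
    rows = []
    for t in templates:
        d = averages.distance(t)
        rows.append(
            {
                "template": list(t.properties),
                "distance": None if math.isinf(d) else d,
                "capped_distance": min(d, config.distance_cap),
                "infinite": math.isinf(d),
            }
        )
    return rows
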