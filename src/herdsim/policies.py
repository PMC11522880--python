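"""Target-selection policy catalogue.

Twenty heuristic policies are formed from a timing mode (initial,
successive, dynamic), a ranking criterion (linear distance from the herder,
angular distance from the herder subtended at the containment-zone centre,
or linear distance from the zone), a direction (closest/furthest) and an
optional collinear-clustering rule.  The headline policy is the *successive
collinear angle* (SCA): pick the target angularly closest to the herder,
re-decide at each engagement, and when targets are near-collinear with the
zone (pairwise subtended angle below a ~18.9 deg threshold) treat them as a
cluster and take the cluster member furthest from the zone first.

``predict_order`` replays a trajectory log's decision instants to produce
the full selection order a policy implies; ``select_next``/``sca_select``
are the corresponding single-decision functions the simulator drives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

from .geometry import subtended_angle

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import TrajectoryLog

__all__ = [
    "PolicySpec",
    "POLICY_CATALOGUE",
    "policy_from_name",
    "angular_distance_ha_ta",
    "collinear_clusters",
    "select_next",
    "sca_select",
    "predict_order",
    "predict_order_from_initial",
    "IncompleteTrialError",
]

TIMINGS = ("initial", "successive", "dynamic")
CRITERIA = ("distance_from_herder", "angle_from_herder", "distance_from_zone")
DEFAULT_COLLINEAR_THRESHOLD = 18.9


class IncompleteTrialError(ValueError):
    """A log lacks the events (influence/containment) a policy needs."""


@dataclass(frozen=True)
class PolicySpec:
    timing: str = "successive"
    criterion: str = "angle_from_herder"
    direction: str = "closest"
    collinear: bool = False
    collinear_threshold: float = DEFAULT_COLLINEAR_THRESHOLD

    def __post_init__(self) -> None:
        if self.timing not in TIMINGS:
            raise ValueError(f"unknown timing {self.timing!r}")
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.direction not in ("closest", "furthest"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.criterion == "distance_from_zone" and (
                self.timing != "initial" or self.collinear):
            raise ValueError(
                "distance_from_zone is only defined as an initial, "
                "non-collinear policy")
        if self.collinear_threshold < 0:
            raise ValueError("collinear threshold must be >= 0")

    @property
    def name(self) -> str:
        if self.collinear:
            kind = "angle" if self.criterion == "angle_from_herder" else "distance"
            return f"{self.timing}_collinear_{kind}"
        if self.criterion == "distance_from_zone":
            return f"{self.direction}_from_containment_zone"
        kind = "angle" if self.criterion == "angle_from_herder" else "distance"
        prefix = "" if self.timing == "initial" else f"{self.timing}_"
        return f"{prefix}{self.direction}_{kind}_from_herder"

    def with_threshold(self, threshold: float) -> "PolicySpec":
        return replace(self, collinear_threshold=threshold)


def _build_catalogue() -> dict[str, PolicySpec]:
    # Insertion order follows the published score table; exclusive-rank ties
    # are broken by this order.
    specs = [
        PolicySpec("successive", "angle_from_herder", "closest", collinear=True),
        PolicySpec("initial", "distance_from_zone", "furthest"),
        PolicySpec("successive", "angle_from_herder", "closest"),
        PolicySpec("successive", "distance_from_herder", "furthest"),
        PolicySpec("dynamic", "angle_from_herder", "closest", collinear=True),
        PolicySpec("initial", "distance_from_herder", "furthest"),
        PolicySpec("initial", "distance_from_herder", "closest"),
        PolicySpec("initial", "distance_from_zone", "closest"),
        PolicySpec("dynamic", "distance_from_herder", "closest", collinear=True),
        PolicySpec("successive", "distance_from_herder", "closest"),
        PolicySpec("successive", "angle_from_herder", "furthest"),
        PolicySpec("dynamic", "distance_from_herder", "furthest"),
        PolicySpec("dynamic", "angle_from_herder", "closest"),
        PolicySpec("dynamic", "angle_from_herder", "furthest"),
        PolicySpec("initial", "angle_from_herder", "furthest"),
        PolicySpec("initial", "angle_from_herder", "closest"),
        PolicySpec("initial", "angle_from_herder", "closest", collinear=True),
        PolicySpec("initial", "distance_from_herder", "closest", collinear=True),
        PolicySpec("successive", "distance_from_herder", "closest", collinear=True),
        PolicySpec("dynamic", "distance_from_herder", "closest"),
    ]
    return {s.name: s for s in specs}


POLICY_CATALOGUE: dict[str, PolicySpec] = _build_catalogue()
SCA = POLICY_CATALOGUE["successive_collinear_angle"]


def policy_from_name(name: str) -> PolicySpec:
    try:
        return POLICY_CATALOGUE[name]
    except KeyError:
        raise ValueError(
            f"unknown policy {name!r}; valid names: "
            + ", ".join(sorted(POLICY_CATALOGUE))) from None


def angular_distance_ha_ta(ha: tuple[float, float], ta: tuple[float, float]) -> float:
    """Herder-target angular distance (deg) subtended at the zone centre."""
    return subtended_angle(ha, ta)


def collinear_clusters(
    tas: Sequence[tuple[float, float]],
    threshold: float = DEFAULT_COLLINEAR_THRESHOLD,
    ids: Sequence[int] | None = None,
) -> list[list[int]]:
    """Single-linkage partition of targets by pairwise subtended angle.

    Targets i, j share a cluster iff connected by a chain of pairs whose
    angle at the zone centre is strictly below ``threshold``.  Returned as a
    list of id lists, each sorted, in order of first appearance.
    """
    if ids is None:
        ids = list(range(len(tas)))
    n = len(tas)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if subtended_angle(tas[i], tas[j]) < threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    return [sorted(g) for g in groups.values()]


def _criterion_value(spec: PolicySpec, ha: tuple[float, float],
                     ta: tuple[float, float]) -> float:
    if spec.criterion == "distance_from_herder":
        return math.hypot(ta[0] - ha[0], ta[1] - ha[1])
    if spec.criterion == "angle_from_herder":
        return subtended_angle(ha, ta)
    return math.hypot(ta[0], ta[1])  # distance_from_zone


def _best(spec: PolicySpec, values: dict[int, float]) -> int:
    # ties broken by the lower target id
    if spec.direction == "closest":
        return min(values, key=lambda i: (values[i], i))
    return min(values, key=lambda i: (-values[i], i))


def select_next(
    spec: PolicySpec,
    ha: tuple[float, float],
    ta_positions: Sequence[tuple[float, float]],
    remaining: Sequence[int],
) -> int:
    """One selection decision among ``remaining`` target ids.

    For collinear policies the remaining targets are first partitioned into
    clusters at the current positions; the winning cluster is the one whose
    best member wins under the base criterion, and within it the member
    furthest from the zone centre takes precedence.
    """
    if not remaining:
        raise ValueError("no remaining target to select")
    values = {i: _criterion_value(spec, ha, ta_positions[i]) for i in remaining}
    if not spec.collinear or spec.collinear_threshold <= 0:
        return _best(spec, values)
    clusters = collinear_clusters(
        [ta_positions[i] for i in remaining],
        spec.collinear_threshold, ids=list(remaining))
    cluster_scores = {
        ci: values[_best(spec, {i: values[i] for i in cl})]
        for ci, cl in enumerate(clusters)
    }
    best_cluster = clusters[_best(replace(spec, collinear=False),
                                  cluster_scores)]
    return max(best_cluster,
               key=lambda i: (math.hypot(*ta_positions[i]), -i))


def sca_select(
    ha: tuple[float, float],
    ta_positions: Sequence[tuple[float, float]],
    remaining: Sequence[int],
    threshold: float = DEFAULT_COLLINEAR_THRESHOLD,
) -> int:
    """The SCA decision: closest-angle cluster, furthest-from-zone member."""
    return select_next(SCA.with_threshold(threshold), ha, ta_positions, remaining)


def predict_order_from_initial(
    spec: PolicySpec,
    ha: tuple[float, float],
    ta_positions: Sequence[tuple[float, float]],
) -> list[int]:
    """Full selection order of an initial-timing policy from the start state."""
    if spec.timing != "initial":
        raise ValueError("only initial-timing policies are defined by the "
                         "start state alone; pass a trajectory log instead")
    ids = list(range(len(ta_positions)))
    values = {i: _criterion_value(spec, ha, ta_positions[i]) for i in ids}
    if not spec.collinear or spec.collinear_threshold <= 0:
        sign = 1.0 if spec.direction == "closest" else -1.0
        return sorted(ids, key=lambda i: (sign * values[i], i))
    clusters = collinear_clusters(ta_positions, spec.collinear_threshold)
    if spec.direction == "closest":
        clusters.sort(key=lambda cl: (min(values[i] for i in cl), min(cl)))
    else:
        clusters.sort(key=lambda cl: (-max(values[i] for i in cl), min(cl)))
    order: list[int] = []
    for cl in clusters:
        order.extend(sorted(cl, key=lambda i: (-math.hypot(*ta_positions[i]), i)))
    return order


def predict_order(spec: PolicySpec, log: "TrajectoryLog") -> list[int]:
    """Selection order the policy implies for a recorded trial.

    The first pick uses the initial state.  Each later pick is evaluated at
    the policy's decision instant for the *predicted* current target — its
    first-influence sample (successive) or first-containment sample
    (dynamic) — using the herder position and remaining-target positions
    recorded at that sample.  Collinear clusters are recomputed at every
    decision instant.
    """
    n = log.n_tas
    ha0 = tuple(log.ha[0])
    tas0 = [tuple(p) for p in log.ta[0]]
    if spec.timing == "initial":
        return predict_order_from_initial(spec, ha0, tas0)

    if spec.timing == "successive":
        event_idx = log.first_influence_indices()
        what = "influenced"
    else:
        event_idx = log.containment_indices()
        what = "contained"

    remaining = list(range(n))
    order = [select_next(spec, ha0, tas0, remaining)]
    remaining.remove(order[0])
    while remaining:
        cur = order[-1]
        k = event_idx[cur]
        if k < 0:
            raise IncompleteTrialError(
                f"target {cur} never {what}; cannot evaluate "
                f"{spec.timing}-timing decisions")
        ha_k = tuple(log.ha[k])
        tas_k = [tuple(p) for p in log.ta[k]]
        nxt = select_next(spec, ha_k, tas_k, remaining)
        order.append(nxt)
        remaining.remove(nxt)
    return order
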