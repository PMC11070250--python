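"""Dendritic river networks with hydraulic geometry.

A river network is a rooted tree of *reaches* (elementary segments, a few
hundred metres long).  Every reach points to the reach immediately
downstream; exactly one reach (the outlet) has no downstream neighbour.
Each reach carries hydraulic geometry (length, wetted width, discharge,
velocity), catchment areas (local/incremental and cumulative drainage
area) and arbitrary named covariates used by the production model.

The two queries the transport model needs are provided here:

* :func:`upstream_set` — all reaches draining through a focal reach
  (the set over which eDNA production is accumulated), and
* :func:`travel_time` — the advective water travel time between an
  upstream reach and a downstream one.

Networks are built either from an edge-list table (:func:`build_network`)
or synthesised (:func:`generate_synthetic_network`) with downstream
hydraulic-geometry power laws Q = c·A^e, v ∝ A^0.2, w ∝ A^0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Reach",
    "RiverNetwork",
    "NetworkScaling",
    "NetworkValidationError",
    "build_network",
    "generate_synthetic_network",
    "upstream_set",
    "travel_time",
]


class NetworkValidationError(ValueError):
    """A network table violates a structural or positivity invariant."""


@dataclass(frozen=True)
class Reach:
    """A single river segment and its attributes.

    ``source_area`` (m²) is the streambed area over which the reach sheds
    eDNA locally; ``local_area`` (km²) is the incremental subcatchment and
    ``drainage_area`` (km²) the cumulative upstream catchment including
    the local one.
    """

    id: str
    downstream_id: str | None
    length: float  # m
    width: float  # m
    source_area: float  # m², local eDNA-contributing area
    local_area: float  # km²
    drainage_area: float  # km²
    discharge: float  # m³/s
    velocity: float  # m/s
    covariates: Mapping[str, float] = field(default_factory=dict)
    habitat_class: int | None = None


@dataclass(frozen=True)
class NetworkScaling:
    """Hydraulic-geometry power laws and synthetic-topology knobs.

    Discharge, velocity and width scale with drainage area A (km²) as
    ``coef * A**exp``; defaults give ~0.01 m³/s and ~0.4 m/s per km².
    Reach lengths are drawn uniformly from ``reach_length_m``.
    """

    discharge_coef: float = 0.01
    discharge_exp: float = 1.0
    velocity_coef: float = 0.4
    velocity_exp: float = 0.2
    width_coef: float = 2.0
    width_exp: float = 0.4
    mean_local_area_km2: float = 1.0
    local_area_sigma: float = 0.5
    reach_length_m: tuple[float, float] = (200.0, 500.0)
    chain: bool = False  # single unbranched chain instead of a random tree

    def validate(self) -> None:
        vals = [
            self.discharge_coef, self.discharge_exp,
            self.velocity_coef, self.velocity_exp,
            self.width_coef, self.width_exp,
            self.mean_local_area_km2, self.local_area_sigma,
            *self.reach_length_m,
        ]
        if not np.all(np.isfinite(vals)):
            raise NetworkValidationError("non-finite scaling parameter")
        if min(self.discharge_coef, self.velocity_coef, self.width_coef,
               self.mean_local_area_km2) <= 0:
            raise NetworkValidationError("scaling coefficients must be positive")


class RiverNetwork:
    """Rooted-tree river network backed by flat numpy arrays.

    Reaches are stored in a fixed order (``ids``); ``downstream`` holds
    the positional index of each reach's downstream neighbour (-1 for the
    outlet).  Covariates live in a DataFrame indexed by reach id.
    """

    def __init__(
        self,
        ids: Iterable[str],
        downstream_ids: Iterable[str | None],
        length: np.ndarray,
        width: np.ndarray,
        local_area: np.ndarray,
        discharge: np.ndarray,
        velocity: np.ndarray,
        covariates: pd.DataFrame | None = None,
        habitat_class: np.ndarray | None = None,
        validate: bool = True,
    ):
        self.ids = np.asarray(list(ids), dtype=object)
        n = len(self.ids)
        self.index = {rid: k for k, rid in enumerate(self.ids)}
        if len(self.index) != n:
            dup = pd.Series(self.ids).value_counts()
            raise NetworkValidationError(
                f"duplicate reach id(s): {list(dup[dup > 1].index)}")
        self.downstream = np.full(n, -1, dtype=np.int64)
        for k, did in enumerate(downstream_ids):
            if did is None or (isinstance(did, float) and np.isnan(did)) or did == "":
                continue
            if did not in self.index:
                raise NetworkValidationError(
                    f"reach {self.ids[k]!r}: unknown downstream id {did!r}")
            self.downstream[k] = self.index[did]

        self.length = np.asarray(length, dtype=float)
        self.width = np.asarray(width, dtype=float)
        self.local_area = np.asarray(local_area, dtype=float)
        self.discharge = np.asarray(discharge, dtype=float)
        self.velocity = np.asarray(velocity, dtype=float)
        self.source_area = self.length * self.width
        if covariates is None:
            covariates = pd.DataFrame(index=pd.Index(self.ids, name="id"))
        self.covariates = covariates.loc[list(self.ids)]
        self.habitat_class = (
            None if habitat_class is None else np.asarray(habitat_class))

        self._children: list[list[int]] | None = None
        self._topo: np.ndarray | None = None
        self._cum_time: np.ndarray | None = None
        self.drainage_area = self._accumulate(self.local_area)
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    # structure
    @property
    def n_reaches(self) -> int:
        return len(self.ids)

    @property
    def outlet_index(self) -> int:
        outs = np.flatnonzero(self.downstream < 0)
        if len(outs) != 1:
            raise NetworkValidationError(
                f"multiple outlets: {[self.ids[i] for i in outs]}"
                if len(outs) > 1 else "no outlet (cycle through every reach)")
        return int(outs[0])

    @property
    def outlet_id(self) -> str:
        return str(self.ids[self.outlet_index])

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_reaches)]
            for k, d in enumerate(self.downstream):
                if d >= 0:
                    ch[d].append(k)
            self._children = ch
        return self._children

    @property
    def topo_order(self) -> np.ndarray:
        """Reach indices ordered root-first (downstream before upstream)."""
        if self._topo is None:
            order = []
            stack = [self.outlet_index]
            ch = self.children
            while stack:
                k = stack.pop()
                order.append(k)
                stack.extend(ch[k])
            if len(order) != self.n_reaches:
                missing = set(range(self.n_reaches)) - set(order)
                raise NetworkValidationError(
                    "cycle or disconnected reach(es): "
                    f"{[self.ids[i] for i in sorted(missing)][:5]}")
            self._topo = np.asarray(order, dtype=np.int64)
        return self._topo

    def _accumulate(self, local: np.ndarray) -> np.ndarray:
        """Sum a per-reach quantity over every reach's upstream set."""
        out = np.array(local, dtype=float)
        for k in self.topo_order[::-1]:  # leaves first
            d = self.downstream[k]
            if d >= 0:
                out[d] += out[k]
        return out

    @property
    def cum_time_to_outlet(self) -> np.ndarray:
        """Per reach: Σ length/velocity from the reach (inclusive) to the outlet."""
        if self._cum_time is None:
            t = self.length / self.velocity
            c = np.zeros(self.n_reaches)
            for k in self.topo_order:  # root first
                d = self.downstream[k]
                c[k] = t[k] + (c[d] if d >= 0 else 0.0)
            self._cum_time = c
        return self._cum_time

    # ------------------------------------------------------------------
    # validation
    def _validate(self) -> None:
        for name, arr in [("length", self.length), ("width", self.width),
                          ("local_area", self.local_area),
                          ("discharge", self.discharge),
                          ("velocity", self.velocity)]:
            bad = np.flatnonzero(~(arr > 0) | ~np.isfinite(arr))
            if len(bad):
                raise NetworkValidationError(
                    f"non-positive {name} at reach {self.ids[bad[0]]!r}")
        self.outlet_index  # single outlet
        self.topo_order    # acyclic, connected
        # drainage accumulation identity
        acc = self._accumulate(self.local_area)
        rel = np.abs(acc - self.drainage_area) / np.abs(acc)
        if rel.max() > 1e-9:
            k = int(rel.argmax())
            raise NetworkValidationError(
                f"drainage_area inconsistent at reach {self.ids[k]!r}")
        # monotone drainage area and discharge downstream
        for name, arr in [("drainage_area", self.drainage_area),
                          ("discharge", self.discharge)]:
            d = self.downstream
            up = d >= 0
            if np.any(arr[up] > arr[d[up]] * (1 + 1e-9)):
                k = int(np.flatnonzero(up & (arr > arr[np.maximum(d, 0)] * (1 + 1e-9)))[0])
                raise NetworkValidationError(
                    f"{name} decreases downstream of reach {self.ids[k]!r}")

    # ------------------------------------------------------------------
    # access
    def _pos(self, reach_id: str) -> int:
        try:
            return self.index[reach_id]
        except KeyError:
            raise KeyError(f"unknown reach id {reach_id!r}") from None

    def positions(self, reach_ids: Iterable[str]) -> np.ndarray:
        return np.asarray([self._pos(r) for r in reach_ids], dtype=np.int64)

    def reach(self, reach_id: str) -> Reach:
        k = self._pos(reach_id)
        d = self.downstream[k]
        hab = None if self.habitat_class is None else self.habitat_class[k]
        return Reach(
            id=str(self.ids[k]),
            downstream_id=None if d < 0 else str(self.ids[d]),
            length=float(self.length[k]),
            width=float(self.width[k]),
            source_area=float(self.source_area[k]),
            local_area=float(self.local_area[k]),
            drainage_area=float(self.drainage_area[k]),
            discharge=float(self.discharge[k]),
            velocity=float(self.velocity[k]),
            covariates=dict(self.covariates.iloc[k]),
            habitat_class=None if hab is None else int(hab),
        )

    @property
    def covariate_matrix(self) -> np.ndarray:
        return self.covariates.to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Edge-list table (the CSV interchange format, see io module)."""
        down = np.where(self.downstream >= 0,
                        self.ids[np.maximum(self.downstream, 0)], "")
        df = pd.DataFrame({
            "id": self.ids,
            "downstream_id": down,
            "length_m": self.length,
            "width_m": self.width,
            "local_area_km2": self.local_area,
            "discharge_m3s": self.discharge,
            "velocity_ms": self.velocity,
        })
        for c in self.covariates.columns:
            df[f"cov_{c}"] = self.covariates[c].to_numpy()
        if self.habitat_class is not None:
            df["habitat_class"] = self.habitat_class
        return df

    def upstream_sets_flat(self, targets: np.ndarray | None = None
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (target_slot, upstream_reach, travel_time) triples.

        For each target reach j (all reaches by default) emit one entry per
        i in upstream_set(j), with the advective travel time from i to j.
        Entries are grouped by target slot; used to vectorise transport.
        """
        if targets is None:
            targets = np.arange(self.n_reaches)
        c = self.cum_time_to_outlet
        # travel_time(i, j) = c[down(i)] - c[down(j)], with c[down(outlet)]=0
        c_down = np.where(self.downstream >= 0, c[np.maximum(self.downstream, 0)], 0.0)
        slot_l, reach_l, time_l = [], [], []
        ch = self.children
        for slot, j in enumerate(targets):
            stack = [int(j)]
            while stack:
                i = stack.pop()
                slot_l.append(slot)
                reach_l.append(i)
                time_l.append(c_down[i] - c_down[j])
                stack.extend(ch[i])
        return (np.asarray(slot_l, dtype=np.int64),
                np.asarray(reach_l, dtype=np.int64),
                np.asarray(time_l, dtype=float))


# ----------------------------------------------------------------------
# construction

_REQUIRED_ATTRS = ("length_m", "width_m", "local_area_km2",
                   "discharge_m3s", "velocity_ms")


def build_network(edges: pd.DataFrame, attributes: pd.DataFrame | None = None
                  ) -> RiverNetwork:
    """Build and validate a network from an edge list plus attributes.

    ``edges`` needs columns ``id`` and ``downstream_id`` (empty/NaN marks
    the outlet); ``attributes`` (or the same frame) must supply
    ``length_m, width_m, local_area_km2, discharge_m3s, velocity_ms``,
    optional covariate columns prefixed ``cov_`` and an optional
    ``habitat_class`` column.
    """
    edges = edges.copy()
    if attributes is not None:
        missing = set(edges["id"]) - set(attributes["id"])
        if missing:
            raise NetworkValidationError(
                f"missing attributes for reach(es) {sorted(missing)[:5]}")
        edges = edges.merge(attributes, on="id", how="left",
                            suffixes=("", "_attr"))
    for col in _REQUIRED_ATTRS:
        if col not in edges.columns:
            raise NetworkValidationError(f"missing attribute column {col!r}")
        if edges[col].isna().any():
            rid = edges.loc[edges[col].isna(), "id"].iloc[0]
            raise NetworkValidationError(f"missing {col} for reach {rid!r}")
    cov_cols = [c for c in edges.columns if c.startswith("cov_")]
    cov = edges[["id", *cov_cols]].set_index("id")
    cov.columns = [c[4:] for c in cov_cols]
    hab = None
    if "habitat_class" in edges.columns and edges["habitat_class"].notna().any():
        hab = edges["habitat_class"].to_numpy()
    down = edges["downstream_id"]
    down = [None if pd.isna(v) or v == "" else str(v) for v in down]
    return RiverNetwork(
        ids=edges["id"].astype(str),
        downstream_ids=down,
        length=edges["length_m"].to_numpy(),
        width=edges["width_m"].to_numpy(),
        local_area=edges["local_area_km2"].to_numpy(),
        discharge=edges["discharge_m3s"].to_numpy(),
        velocity=edges["velocity_ms"].to_numpy(),
        covariates=cov,
        habitat_class=hab,
    )


def generate_synthetic_network(n_reaches: int, seed: int,
                               scaling: NetworkScaling | None = None
                               ) -> RiverNetwork:
    """Synthesise a random dendritic network of ``n_reaches`` reaches.

    Topology is a uniform random-attachment rooted tree (Horton-like
    branching); incremental areas are lognormal; discharge, velocity and
    width follow the power laws in ``scaling``.  A standardised
    log10-drainage-area covariate ``logA`` is attached (longitudinal
    position proxy).  Identical seeds give bit-identical networks.
    """
    if n_reaches < 1:
        raise ValueError("n_reaches must be >= 1")
    scaling = scaling or NetworkScaling()
    scaling.validate()
    rng = np.random.default_rng(seed)

    ids = [f"r{k:04d}" for k in range(n_reaches)]
    down: list[str | None] = [None]
    for k in range(1, n_reaches):
        parent = 0 if scaling.chain and k == 1 else (
            k - 1 if scaling.chain else int(rng.integers(0, k)))
        down.append(ids[parent])

    mu = np.log(scaling.mean_local_area_km2) - 0.5 * scaling.local_area_sigma ** 2
    local = rng.lognormal(mu, scaling.local_area_sigma, n_reaches)
    length = rng.uniform(*scaling.reach_length_m, n_reaches)

    # drainage accumulation before hydraulic geometry
    tmp = RiverNetwork(ids, down, length, np.ones(n_reaches), local,
                       np.ones(n_reaches), np.ones(n_reaches), validate=False)
    A = tmp.drainage_area
    Q = scaling.discharge_coef * A ** scaling.discharge_exp
    v = scaling.velocity_coef * A ** scaling.velocity_exp
    w = scaling.width_coef * A ** scaling.width_exp
    logA = np.log10(A)
    sd = logA.std()
    cov = pd.DataFrame(
        {"logA": (logA - logA.mean()) / (sd if sd > 0 else 1.0)},
        index=pd.Index(ids, name="id"))
    return RiverNetwork(ids, down, length, w, local, Q, v, covariates=cov)


# ----------------------------------------------------------------------
# queries

def upstream_set(net: RiverNetwork, reach_id: str) -> set[str]:
    """All reach ids draining through ``reach_id`` (itself included)."""
    out: set[str] = set()
    stack = [net._pos(reach_id)]
    ch = net.children
    while stack:
        k = stack.pop()
        out.add(str(net.ids[k]))
        stack.extend(ch[k])
    return out


def travel_time(net: RiverNetwork, i: str, j: str) -> float:
    """Advective travel time (s) from reach ``i`` down to reach ``j``.

    Sums length/velocity over the path from i (exclusive) to j
    (inclusive); ``travel_time(j, j) == 0`` by convention (production of
    a reach is evaluated at its own downstream node with no decay).
    """
    ki, kj = net._pos(i), net._pos(j)
    if i not in upstream_set(net, j):
        raise ValueError(f"reach {i!r} is not upstream of {j!r}")
    c = net.cum_time_to_outlet
    c_down = lambda k: c[net.downstream[k]] if net.downstream[k] >= 0 else 0.0
    return float(c_down(ki) - c_down(kj))
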