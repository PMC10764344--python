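"""Structural causal models over the site covariates.

A directed acyclic graph (DAG) encodes the assumed causal relationships among
the landscape covariates and arthropod occupancy.  From it we derive

* d-separation queries and the full list of implied conditional
  independencies,
* data-consistency tests of those independencies by partial correlation,
* minimal backdoor adjustment sets for each exposure of interest, and
* the catalog of single-exposure occupancy model specifications (one model
  per group x exposure, sharing one joint fit for the two "luxury effect"
  covariates), which for the six default groups yields 37 entries.

Covariates are named by what they measure: ``t_mean`` (mean annual air
temperature, BIO1), ``diurnal_range`` (mean diurnal range, BIO2), ``rh_mean``
(mean relative humidity), ``elevation``, ``d_ocean`` (slope-cost distance to
the ocean), ``d_natural`` (distance to natural areas), ``impervious``
(neighbourhood impervious surface %), ``land_value`` (neighbourhood land
value); the outcome node is ``occupancy``.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

OUTCOME = "occupancy"

GROUPS = (
    "Phoridae",
    "Syrphidae",
    "Tipuloidea",
    "Drosophilidae",
    "Mycetophilidae",
    "Araneae",
)

#: Buffer radius (km) used for the neighbourhood covariates, by group.
#: Small-bodied poor dispersers get the tighter buffer.
GROUP_BUFFER_KM = {
    "Phoridae": 0.25,
    "Araneae": 0.25,
    "Syrphidae": 0.5,
    "Tipuloidea": 0.5,
    "Drosophilidae": 0.5,
    "Mycetophilidae": 0.5,
}

#: Predictors entering the all-covariate prediction model.
ALL_MODEL_TERMS = (
    "t_mean",
    "diurnal_range",
    "elevation",
    "d_ocean",
    "d_natural",
    "impervious",
    "land_value",
)


class CausalDAG:
    """A named DAG over covariates (and optionally the occupancy outcome)."""

    def __init__(self, edges, nodes=None):
        g = nx.DiGraph()
        if nodes:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph has a directed cycle")
        if OUTCOME in g and g.out_degree(OUTCOME) > 0:
            raise ValueError("occupancy must have no outgoing edges")
        self.graph = g

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def covariate_nodes(self) -> list[str]:
        return [n for n in self.nodes if n != OUTCOME]

    def without_outcome(self) -> "CausalDAG":
        g = [(a, b) for a, b in self.graph.edges if OUTCOME not in (a, b)]
        nodes = [n for n in self.graph.nodes if n != OUTCOME]
        return CausalDAG(g, nodes=nodes)

    # -- serialization --------------------------------------------------
    def to_dot(self) -> str:
        lines = ["digraph {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for a, b in self.edges:
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_dot(cls, text: str) -> "CausalDAG":
        edges = re.findall(r'"?([\w.]+)"?\s*->\s*"?([\w.]+)"?', text)
        nodes = re.findall(r'^\s*"?([\w.]+)"?\s*;', text, flags=re.M)
        return cls(edges, nodes=nodes)

    def to_edgelist_csv(self, path) -> None:
        pd.DataFrame(self.edges, columns=["from", "to"]).to_csv(path, index=False)

    @classmethod
    def from_edgelist_csv(cls, path) -> "CausalDAG":
        df = pd.read_csv(path)
        return cls(list(df.itertuples(index=False, name=None)))


def default_dag(group: str = "Phoridae") -> CausalDAG:
    """Canonical per-group DAG over covariates and occupancy.

    The structure reflects the Los Angeles setting: elevation and ocean
    proximity drive living desirability (land value) and development
    (impervious surface); natural areas sit in the higher surrounding
    terrain; inland cells see larger diurnal swings; humidity responds to
    temperature, marine influence, terrain and development.  Relative
    humidity is carried only for Phoridae, the one group it is modelled for.
    """
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}")
    edges = [
        ("elevation", "d_natural"),
        ("elevation", "land_value"),
        ("elevation", "impervious"),
        ("d_ocean", "diurnal_range"),
        ("d_ocean", "land_value"),
        ("d_ocean", "impervious"),
        ("d_natural", "land_value"),
        ("d_natural", "impervious"),
    ]
    covariates = list(ALL_MODEL_TERMS)
    if group == "Phoridae":
        covariates.append("rh_mean")
        edges += [
            ("elevation", "rh_mean"),
            ("d_ocean", "rh_mean"),
            ("t_mean", "rh_mean"),
            ("impervious", "rh_mean"),
        ]
    edges += [(c, OUTCOME) for c in covariates]
    return CausalDAG(edges, nodes=covariates + [OUTCOME])


# ---------------------------------------------------------------------------
# d-separation and implied independencies
# ---------------------------------------------------------------------------

def d_separated(dag: CausalDAG, x: str, y: str, given=()) -> bool:
    """Whether x and y are d-separated given the conditioning set."""
    if x == y:
        raise ValueError("x and y must differ")
    for n in (x, y, *given):
        if n not in dag.graph:
            raise KeyError(f"unknown node {n!r}")
    return nx.is_d_separator(dag.graph, {x}, {y}, set(given))


def implied_independencies(dag: CausalDAG) -> list[tuple[str, str, frozenset]]:
    """All pairwise conditional independencies implied by the DAG.

    For every non-adjacent pair (x, y) this returns each minimal conditioning
    set Z (no proper subset of Z also separates the pair).  Intended for the
    small covariate DAGs used here; the search is exponential in node count.
    """
    out: list[tuple[str, str, frozenset]] = []
    nodes = dag.nodes
    for x, y in itertools.combinations(nodes, 2):
        if dag.graph.has_edge(x, y) or dag.graph.has_edge(y, x):
            continue
        others = [n for n in nodes if n not in (x, y)]
        minimal: list[frozenset] = []
        for size in range(len(others) + 1):
            for z in itertools.combinations(others, size):
                zs = frozenset(z)
                if any(m <= zs for m in minimal):
                    continue
                if d_separated(dag, x, y, zs):
                    minimal.append(zs)
        out.extend((x, y, z) for z in minimal)
    return out


def test_consistency(
    dag: CausalDAG, data: pd.DataFrame, alpha: float = 0.05
) -> list[tuple[str, str, frozenset, float]]:
    """Partial-correlation tests of every implied independency against data.

    Returns the violated independencies as (x, y, Z, p) with p < alpha.
    Linear-Gaussian partial correlation is used throughout.
    """
    import pingouin as pg

    missing = [n for n in dag.nodes if n not in data.columns]
    if missing:
        raise KeyError(f"data lacks DAG covariates: {missing}")
    violations = []
    for x, y, z in implied_independencies(dag):
        if len(data) - len(z) - 3 <= 0:
            raise ValueError("too few rows for conditioning set size")
        res = pg.partial_corr(data=data, x=x, y=y, covar=sorted(z) or None)
        p = float(res["p_val"].iloc[0])
        if p < alpha:
            violations.append((x, y, z, p))
    return violations


def simulate_linear_sem(dag: CausalDAG, n: int, coefs: dict | None = None,
                        default_coef: float = 0.6, seed: int = 0) -> pd.DataFrame:
    """IID draws from a linear-Gaussian structural equation model on the DAG.

    Each node is its parents' weighted sum plus unit Gaussian noise; edge
    weights come from ``coefs`` (default ``default_coef``).  Useful for
    calibration checks of :func:`test_consistency`, whose partial-correlation
    p-values assume exchangeable rows.
    """
    rng = np.random.default_rng(seed)
    coefs = coefs or {}
    data: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(dag.graph):
        x = rng.standard_normal(n)
        for par in dag.graph.predecessors(node):
            x = x + coefs.get((par, node), default_coef) * data[par]
        data[node] = x
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Backdoor adjustment
# ---------------------------------------------------------------------------

def backdoor_sets(dag: CausalDAG, exposure: str, outcome: str = OUTCOME):
    """All minimal backdoor adjustment sets for exposure -> outcome.

    A set Z is valid when it contains no descendant of the exposure and
    d-separates exposure from outcome in the graph with the exposure's
    outgoing edges removed.  Returns minimal sets sorted by size then name;
    an empty list means no valid set exists.
    """
    g = dag.graph
    if exposure not in g or outcome not in g:
        raise KeyError("exposure/outcome not in DAG")
    desc = nx.descendants(g, exposure)
    candidates = [n for n in dag.nodes if n not in desc and n not in (exposure, outcome)]
    g_bar = g.copy()
    g_bar.remove_edges_from(list(g.out_edges(exposure)))
    minimal: list[frozenset] = []
    for size in range(len(candidates) + 1):
        for z in itertools.combinations(candidates, size):
            zs = frozenset(z)
            if any(m <= zs for m in minimal):
                continue
            if nx.is_d_separator(g_bar, {exposure}, {outcome}, set(zs)):
                minimal.append(zs)
    return sorted(minimal, key=lambda s: (len(s), sorted(s)))


def open_backdoor_paths(dag: CausalDAG, exposure: str, outcome: str = OUTCOME):
    """Diagnostic: backdoor paths left open with the empty adjustment set."""
    g = dag.graph
    ug = g.to_undirected()
    open_paths = []
    for path in nx.all_simple_paths(ug, exposure, outcome):
        if len(path) < 2 or not g.has_edge(path[1], path[0]):
            continue  # not a backdoor path (does not start with an edge into exposure)
        if _path_open(g, path, set()):
            open_paths.append(tuple(path))
    return open_paths


def _path_open(g: nx.DiGraph, path, given: set) -> bool:
    """d-connection status of one undirected path given a conditioning set."""
    for i in range(1, len(path) - 1):
        prev, node, nxt = path[i - 1], path[i], path[i + 1]
        collider = g.has_edge(prev, node) and g.has_edge(nxt, node)
        if collider:
            desc = nx.descendants(g, node) | {node}
            if not (desc & given):
                return False
        elif node in given:
            return False
    return True


# ---------------------------------------------------------------------------
# Model catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One occupancy model specification.

    ``terms`` is the full covariate list entering the occupancy linear
    predictor; ``exposures`` are the effect(s) of interest it estimates and
    ``adjustment`` the backdoor covariates.  Catalog entries that share a
    joint fit (impervious surface and land value) carry the same ``fit_key``.
    """

    group: str
    name: str
    exposures: tuple[str, ...]
    adjustment: tuple[str, ...]
    buffer_km: float
    terms: tuple[str, ...] = field(default=())
    fit_key: str = ""

    def __post_init__(self):
        if set(self.exposures) & set(self.adjustment):
            raise ValueError("exposure cannot appear in its own adjustment set")
        if not self.terms:
            object.__setattr__(self, "terms", self.exposures + self.adjustment)
        if not self.fit_key:
            object.__setattr__(self, "fit_key", f"{self.group}:{self.name}")

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "name": self.name,
            "exposures": list(self.exposures),
            "adjustment": list(self.adjustment),
            "buffer_km": self.buffer_km,
            "terms": list(self.terms),
            "fit_key": self.fit_key,
        }


def _single_exposure_specs(group: str, dag: CausalDAG, buffer_km: float):
    """The per-group catalog rows, with adjustment sets from the DAG."""
    specs = []

    def minimal_set(exposure):
        sets = backdoor_sets(dag, exposure)
        if not sets:
            raise ValueError(f"no backdoor set for {exposure} in {group}")
        return tuple(sorted(sets[0]))

    specs.append(
        ModelSpec(group, "d_ocean", ("d_ocean",), minimal_set("d_ocean"), buffer_km)
    )
    specs.append(
        ModelSpec(group, "d_natural", ("d_natural",), minimal_set("d_natural"), buffer_km)
    )
    specs.append(ModelSpec(group, "t_mean", ("t_mean",), minimal_set("t_mean"), buffer_km))
    specs.append(
        ModelSpec(
            group,
            "diurnal_range",
            ("diurnal_range",),
            minimal_set("diurnal_range"),
            buffer_km,
        )
    )
    # Impervious surface and land value share one joint fit; the minimal
    # backdoor set is identical for both exposures, and each is reported as
    # its own catalog entry.
    joint_adj = minimal_set("impervious")
    assert joint_adj == minimal_set("land_value")
    fit_key = f"{group}:impervious+land_value"
    joint_terms = ("impervious", "land_value") + joint_adj
    for exposure in ("impervious", "land_value"):
        specs.append(
            ModelSpec(
                group,
                exposure,
                (exposure,),
                joint_adj,
                buffer_km,
                terms=joint_terms,
                fit_key=fit_key,
            )
        )
    if "rh_mean" in dag.graph:
        specs.append(
            ModelSpec(group, "rh_mean", ("rh_mean",), minimal_set("rh_mean"), buffer_km)
        )
    return specs


def build_catalog(dags=None, buffers=None) -> list[ModelSpec]:
    """Catalog of single-exposure occupancy models for the six groups.

    With the default DAGs this yields 37 entries: six exposures per group
    plus the relative-humidity model for Phoridae only.
    """
    dags = dags or {g: default_dag(g) for g in GROUPS}
    buffers = buffers or GROUP_BUFFER_KM
    unknown = set(dags) - set(GROUPS)
    if unknown:
        raise KeyError(f"unknown groups: {sorted(unknown)}")
    catalog = []
    for group in GROUPS:
        if group not in dags:
            continue
        catalog.extend(_single_exposure_specs(group, dags[group], buffers[group]))
    return catalog


def all_model_spec(group: str, buffer_km: float | None = None) -> ModelSpec:
    """The all-covariate prediction model ("Model All") for one group."""
    return ModelSpec(
        group,
        "all",
        ALL_MODEL_TERMS,
        (),
        buffer_km if buffer_km is not None else GROUP_BUFFER_KM[group],
    )


def catalog_to_json(catalog: list[ModelSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in catalog], fh, indent=1)


def catalog_from_json(path) -> list[ModelSpec]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        ModelSpec(
            d["group"],
            d["name"],
            tuple(d["exposures"]),
            tuple(d["adjustment"]),
            d["buffer_km"],
            terms=tuple(d["terms"]),
            fit_key=d["fit_key"],
        )
        for d in raw
    ]
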