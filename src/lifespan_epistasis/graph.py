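"""Intervention networks: strains as nodes, single added interventions as edges.

The graph over one organism's strains is the observed part of the Boolean
lattice of gene subsets: an edge joins a k-mutant to a (k+1)-mutant whose
gene set adds exactly one gene.  On a fully assayed n-mutant family the
number of WT -> n-mutant paths is n!.  Exports target Cytoscape.js JSON
and GraphML.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import networkx as nx

from .epistasis import (
    INSUFFICIENT,
    NOT_ASSESSABLE,
    delta_percent,
    full_synergy,
    monotony,
    simple_synergy,
)
from .records import ExperimentGroup, MutantModel


@dataclass(frozen=True)
class EffectInterval:
    """[min, max] percent lifespan change for a combination across experiments."""

    combination: MutantModel
    min_percent: float
    max_percent: float
    n_experiments: int

    def __post_init__(self):
        if self.min_percent > self.max_percent:
            raise ValueError("interval bounds out of order")


def _models_by_name(groups, organism) -> dict[str, MutantModel]:
    out: dict[str, MutantModel] = {}
    for g in groups:
        for m in g.models():
            if m.organism == organism:
                out.setdefault(m.canonical_name, m)
    return out


def build_graph(groups, organism: str) -> nx.DiGraph:
    """Build the wild-type -> n-mutant intervention DAG for one organism.

    One node per distinct strain (canonical name); a directed edge A -> B
    whenever B's gene set is A's plus exactly one gene and both strains
    are observed anywhere in the dataset (the site-wide network
    aggregates studies; per-experiment subgraphs are used for monotony).
    Nodes carry observation count, mean percent effect and the effect
    interval; edges carry the added gene.
    """
    models = _models_by_name(groups, organism)
    graph = nx.DiGraph(organism=organism)
    for name, model in models.items():
        attrs = {"label": name, "n": model.n, "n_records": _record_count(groups, model)}
        try:
            interval = effect_interval(groups, model)
        except ValueError:
            interval = None
        if interval is not None and not model.is_wt:
            attrs["mean_delta_percent"] = (interval.min_percent + interval.max_percent) / 2.0
            attrs["min_delta_percent"] = interval.min_percent
            attrs["max_delta_percent"] = interval.max_percent
        graph.add_node(name, **attrs)
    names = list(models)
    sets = {name: models[name].gene_set for name in names}
    for a, b in itertools.permutations(names, 2):
        if len(sets[b]) == len(sets[a]) + 1 and sets[a] < sets[b]:
            (added,) = sets[b] - sets[a]
            graph.add_edge(a, b, added_gene=added)
    return graph


def _record_count(groups, model: MutantModel) -> int:
    key = model.key()
    return sum(1 for g in groups for o in g.observations if o.model.key() == key)


def effect_interval(
    groups,
    combination: MutantModel,
    *,
    stratify_temperature: bool = True,
) -> EffectInterval:
    """Display interval of percent effects for one combination.

    Each experiment with an in-group WT contributes the delta against
    that WT.  An experiment without one contributes two bracketing deltas
    against the species-wide minimum and maximum WT lifespan — restricted
    to the same temperature stratum when the observation's temperature is
    recorded and WT data exist there (``stratify_temperature``).
    Wild type itself has the degenerate interval [0, 0].
    """
    org = combination.organism
    wt_pool: list[tuple[float | None, float]] = [
        (o.temperature_c, o.lifespan_days)
        for g in groups
        for o in g.observations
        if o.model.organism == org and o.model.is_wt
    ]
    deltas: list[float] = []
    experiments = set()
    key = combination.key()
    for g in groups:
        obs = [o for o in g.observations if o.model.key() == key]
        if not obs:
            continue
        experiments.add(g.experiment_key)
        wt = g.wt_lifespan_days
        mean_ls = sum(o.lifespan_days for o in obs) / len(obs)
        if wt is not None:
            deltas.append(delta_percent(mean_ls, wt))
            continue
        temp = obs[0].temperature_c
        pool = wt_pool
        if stratify_temperature and temp is not None:
            stratum = [p for p in wt_pool if p[0] == temp]
            if stratum:
                pool = stratum
        if not pool:
            continue
        values = [ls for _, ls in pool]
        deltas.append(delta_percent(mean_ls, max(values)))
        deltas.append(delta_percent(mean_ls, min(values)))
    if not experiments:
        raise ValueError(f"no observations for {combination.canonical_name}")
    if not deltas:
        raise ValueError(
            f"no comparable wild-type lifespan for {combination.canonical_name}"
        )
    return EffectInterval(combination, min(deltas), max(deltas), len(experiments))


def enumerate_paths(graph: nx.DiGraph, source, target) -> list[list[str]]:
    """All directed paths source -> target, in deterministic order.

    Nodes may be given as strain names or MutantModels.  Paths are
    explored choosing the lexicographically smallest added gene first.
    source == target yields the single zero-step path; an unreachable
    target yields an empty list.
    """
    src = source.canonical_name if isinstance(source, MutantModel) else source
    dst = target.canonical_name if isinstance(target, MutantModel) else target
    if src not in graph or dst not in graph:
        return []
    paths: list[list[str]] = []

    def walk(node, acc):
        if node == dst:
            paths.append(acc + [node])
            return
        nxt = sorted(
            graph.successors(node),
            key=lambda s: graph.edges[node, s].get("added_gene", s),
        )
        for s in nxt:
            walk(s, acc + [node])

    walk(src, [])
    return paths


def export_network(graph: nx.DiGraph, path, fmt: str = "cytoscape-json") -> None:
    """Write the intervention network as Cytoscape.js JSON or GraphML.

    Nodes carry a ``color_hint`` (green for long-lived, red for
    short-lived, neutral otherwise), a color ``intensity`` proportional
    to |mean percent effect| scaled to the largest effect in the graph,
    and a ``size`` proportional to the number of records.
    """
    if fmt not in ("cytoscape-json", "graphml"):
        raise ValueError(f"unknown format {fmt!r}")
    styled = graph.copy()
    effects = [
        abs(d["mean_delta_percent"])
        for _, d in styled.nodes(data=True)
        if "mean_delta_percent" in d
    ]
    max_effect = max(effects) if effects else 1.0
    max_records = max((d.get("n_records", 0) for _, d in styled.nodes(data=True)), default=1)
    for _, data in styled.nodes(data=True):
        delta = data.get("mean_delta_percent")
        if delta is None or delta == 0:
            data["color_hint"] = "neutral"
            data["intensity"] = 0.0
        else:
            data["color_hint"] = "green" if delta > 0 else "red"
            data["intensity"] = abs(delta) / max_effect if max_effect else 0.0
        data["size"] = data.get("n_records", 0) / max_records if max_records else 0.0

    if fmt == "graphml":
        clean = styled.copy()
        for _, data in clean.nodes(data=True):  # GraphML has no null type
            for k, v in list(data.items()):
                if v is None:
                    del data[k]
        nx.write_graphml(clean, path)
        return
    elements = {
        "nodes": [
            {"data": {"id": name, **{k: v for k, v in data.items() if v is not None}}}
            for name, data in styled.nodes(data=True)
        ],
        "edges": [
            {"data": {"source": a, "target": b, **data}}
            for a, b, data in styled.edges(data=True)
        ],
    }
    with open(path, "w") as fh:
        json.dump({"elements": elements}, fh, indent=1)
        fh.write("\n")


def _pair_calls(groups):
    """One full-synergy call per (2-gene combination, experiment)."""
    calls = []
    for g in groups:
        for model in g.models():
            if model.n == 2:
                calls.append((g, model, full_synergy(g, model)))
    return calls


def summarize_database(groups) -> dict:
    """Database-level summary tables.

    * ``table1`` — per organism (plus totals): lifespan values
      (observation count), gene combinations (distinct n>=2 strains),
      distinct genes in those combinations, and articles (distinct study
      ids).
    * ``table2`` — full-synergy calls for 2-gene combinations
      cross-tabulated by phenotype direction and category; each
      (combination, experiment) call counts once, so one combination may
      contribute to several categories across experiments.
    * ``opposite_direction`` — doubles whose singles disagree in sign,
      among experiments where full synergism is computable, split by the
      double mutant's own direction.
    * ``higher_order`` — evaluability: how many n>=3 mutants support
      full, simple and monotony evaluation, and the same for 2-mutants.
    """
    organisms = sorted({o.model.organism for g in groups for o in g.observations})

    table1: dict[str, dict[str, int]] = {}
    for org in organisms + ["Total"]:
        def keep(obs):
            return org == "Total" or obs.model.organism == org

        obs_all = [o for g in groups for o in g.observations if keep(o)]
        combos = {o.model.key() for o in obs_all if o.model.n >= 2}
        genes = {
            (o.model.organism, gene)
            for o in obs_all
            if o.model.n >= 2
            for gene in o.model.gene_set
        }
        table1[org] = {
            "lifespan_values": len(obs_all),
            "gene_combinations": len(combos),
            "genes": len(genes),
            "articles": len({o.study_id for o in obs_all}),
        }

    table2: dict[str, dict[str, dict[str, int]]] = {}
    opposite = {"long-lived": 0, "short-lived": 0}
    pair_computable = 0
    for g, model, call in _pair_calls(groups):
        if call.category == INSUFFICIENT:
            continue
        pair_computable += 1
        if call.category == NOT_ASSESSABLE:
            d12 = _combo_delta(g, model)
            if d12 is not None and d12 != 0:
                opposite["long-lived" if d12 > 0 else "short-lived"] += 1
            continue
        if call.phenotype_direction == "opposite":
            d12 = _combo_delta(g, model)
            bucket = "long-lived phenotype" if d12 > 0 else "short-lived phenotype"
        else:
            bucket = f"{call.phenotype_direction} phenotype"
        org_tab = table2.setdefault(bucket, {})
        cat_tab = org_tab.setdefault(call.category, {})
        cat_tab[model.organism] = cat_tab.get(model.organism, 0) + 1
        cat_tab["Total"] = sum(v for k, v in cat_tab.items() if k != "Total")

    opp_total = opposite["long-lived"] + opposite["short-lived"]
    opposite_summary = {
        **opposite,
        "total": opp_total,
        "percent_of_computable": 100.0 * opp_total / pair_computable if pair_computable else 0.0,
    }

    counts = {"n2": _evaluability(groups, lambda m: m.n == 2),
              "n3plus": _evaluability(groups, lambda m: m.n >= 3)}
    degree: dict[int, int] = {}
    for key_n in sorted({m.n for g in groups for m in g.models() if m.n >= 2}):
        degree[key_n] = len({m.key() for g in groups for m in g.models() if m.n == key_n})

    return {
        "table1": table1,
        "table2": table2,
        "opposite_direction": opposite_summary,
        "higher_order": counts,
        "mutants_by_degree": degree,
    }


def _combo_delta(group: ExperimentGroup, model: MutantModel) -> float | None:
    wt = group.wt_lifespan_days
    ls = group.lifespan_of(model)
    if wt is None or ls is None:
        return None
    return delta_percent(ls, wt)


def _evaluability(groups, predicate) -> dict[str, int]:
    """Distinct combinations with at least one experiment supporting each mode."""
    full_ok, simple_ok, mono_ok, universe = set(), set(), set(), set()
    for g in groups:
        for model in g.models():
            if model.is_wt or not predicate(model):
                continue
            universe.add(model.key())
            if full_synergy(g, model).category != INSUFFICIENT:
                full_ok.add(model.key())
            if simple_synergy(g, model).category != INSUFFICIENT:
                simple_ok.add(model.key())
            if monotony(g, model).verdict != "no_known_path":
                mono_ok.add(model.key())
    return {
        "combinations": len(universe),
        "full": len(full_ok),
        "simple": len(simple_ok),
        "monotony": len(mono_ok),
    }
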