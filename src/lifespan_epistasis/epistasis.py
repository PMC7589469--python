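"""Lifespan epistasis mathematics.

All effects are percent lifespan changes relative to the same-experiment
wild type,

    delta(M) = (LS(M) - LS(WT)) * 100 / LS(WT),

and every comparison below is stated in these deltas (not raw lifespans).
For a double mutant with single effects d1, d2 and combined effect d12,
where d1 and d2 share a sign, the interaction is classified on absolute
values as

    synergistic       |d12| >  |d1| + |d2|
    additive          |d12| == |d1| + |d2|          (within tolerance)
    almost additive   max(|d1|,|d2|) < |d12| < |d1|+|d2|
    dependent         min(|d1|,|d2|) <= |d12| <= max(|d1|,|d2|)
    antagonistic      |d12| <  min(|d1|,|d2|)

A double mutant shifted in the *opposite* direction from both singles is
also antagonistic.  Singles with opposite (or zero) effects are not
directly assessable for epistasis.

For n-mutants, "full" synergism requires the combination's delta to beat
the summed deltas of every disjoint bipartition into a k-mutant and an
(n-k)-mutant, with every proper subset assayed in the same experiment;
"simple" synergism compares only against the summed single effects; and
partially-known monotony checks that lifespan strictly increases (or
strictly decreases) along every experimentally assayed intervention path
from wild type to the n-mutant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .records import ExperimentGroup, MutantModel, canonical_name

CATEGORIES = (
    "synergistic",
    "additive",
    "almost_additive",
    "dependent",
    "antagonistic",
)
NOT_SYNERGISTIC = "not_synergistic"
NOT_ASSESSABLE = "not_assessable_mixed_directions"
INSUFFICIENT = "insufficient_data"

#: relative tolerance for the (mostly theoretical) exact-additivity band
ADDITIVE_EPSILON = 1e-9


def delta_percent(ls_mutant: float, ls_wt: float) -> float:
    """Percent lifespan change of a mutant relative to wild type."""
    if not (ls_mutant > 0 and ls_wt > 0):
        raise ValueError("lifespans must be positive")
    return (ls_mutant - ls_wt) * 100.0 / ls_wt


@dataclass(frozen=True)
class LifespanDelta:
    """A percent effect attributed to one strain in one experiment."""

    value_percent: float
    source_model: MutantModel | None = None
    experiment_key: str = ""

    def __post_init__(self):
        if not self.value_percent > -100.0:
            raise ValueError("a percent lifespan change must exceed -100")


@dataclass(frozen=True)
class EpistasisCall:
    """Outcome of one epistasis evaluation for one gene combination."""

    combination: MutantModel | None
    category: str
    phenotype_direction: str | None = None  # long-lived | short-lived | opposite
    mode: str = "full"  # full | simple | monotony
    experiment_key: str = ""
    evidence: tuple[LifespanDelta, ...] = ()
    #: for non-synergistic full calls with n>2: the bipartition with the
    #: largest summed effect, its summed value, and its n=2-style category
    violated_bipartition: tuple[tuple[str, ...], tuple[str, ...]] | None = None
    detail: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class MonotonyResult:
    """Partially-known monotony verdict along assayed intervention paths."""

    combination: MutantModel
    paths_known: int
    paths_total: int  # n! for an n-mutant
    verdict: str  # monotonic_positive | monotonic_negative | contains_dependency | no_known_path


def _sign(x: float, tol: float = 0.0) -> int:
    if x > tol:
        return 1
    if x < -tol:
        return -1
    return 0


def classify_pair(
    d1: float,
    d2: float,
    d12: float,
    *,
    additive_epsilon: float = ADDITIVE_EPSILON,
    direction_tol: float = 0.0,
) -> EpistasisCall:
    """Five-way classification of a two-gene interaction from percent deltas.

    Returns an EpistasisCall whose ``category`` is one of the five
    interaction classes, or ``not_assessable_mixed_directions`` when the
    single effects disagree in sign (or either is zero within
    ``direction_tol``).  ``phenotype_direction`` is ``long-lived`` or
    ``short-lived`` per the shared sign of the singles, or ``opposite``
    when the double mutant flips direction (always antagonistic).
    Symmetric in (d1, d2).
    """
    s1, s2 = _sign(d1, direction_tol), _sign(d2, direction_tol)
    if s1 == 0 or s2 == 0 or s1 != s2:
        return EpistasisCall(None, NOT_ASSESSABLE, None, mode="full")
    shared = s1
    direction = "long-lived" if shared > 0 else "short-lived"
    s12 = _sign(d12, direction_tol)
    if s12 != 0 and s12 != shared:
        return EpistasisCall(None, "antagonistic", "opposite", mode="full")

    a1, a2, a12 = abs(d1), abs(d2), abs(d12)
    total = a1 + a2
    if math.isclose(a12, total, rel_tol=additive_epsilon, abs_tol=0.0):
        category = "additive"
    elif a12 > total:
        category = "synergistic"
    elif a12 > max(a1, a2):
        category = "almost_additive"
    elif a12 >= min(a1, a2):
        category = "dependent"
    else:
        category = "antagonistic"
    return EpistasisCall(None, category, direction, mode="full")


def _group_deltas(group: ExperimentGroup, organism: str) -> dict[str, LifespanDelta] | None:
    """Percent deltas for every non-WT model in the group, or None without WT."""
    wt = group.wt_lifespan_days
    if wt is None:
        return None
    out = {}
    for model in group.models():
        if model.is_wt or model.organism != organism:
            continue
        ls = group.lifespan_of(model)
        out[model.canonical_name] = LifespanDelta(
            value_percent=delta_percent(ls, wt),
            source_model=model,
            experiment_key=group.experiment_key,
        )
    return out


def _bipartitions(genes: frozenset[str]):
    """All unordered splits of a gene set into two non-empty disjoint parts."""
    items = sorted(genes)
    n = len(items)
    for r in range(1, n // 2 + 1):
        for left in itertools.combinations(items, r):
            right = tuple(g for g in items if g not in left)
            if r == n - r and left > right:
                continue  # unordered: emit each split once
            yield frozenset(left), frozenset(right)


def full_synergy(
    group: ExperimentGroup,
    combination: MutantModel,
    *,
    strict: bool = False,
    additive_epsilon: float = ADDITIVE_EPSILON,
    direction_tol: float = 0.0,
) -> EpistasisCall:
    """Evaluate "full" synergism of an n-mutant within one experiment.

    Requires a same-experiment lifespan for the wild type, the
    combination, and *every* proper non-empty gene subset; otherwise
    ``insufficient_data``.  For n = 2 this reduces exactly to
    :func:`classify_pair`.  For n > 2 the combination is synergistic iff
    for every bipartition (S, S~) of its genes, |d(combination)| >
    |d(S)| + |d(S~)|; a non-synergistic call is labelled
    ``not_synergistic`` and reports the violated bipartition with the
    largest summed effect, plus that bipartition's pair-style category as
    auxiliary detail.  With ``strict=True``, every subset of size >= 2
    must itself be fully synergistic (the stricter, recursive reading).
    """
    genes = combination.gene_set
    n = len(genes)
    if n < 2:
        raise ValueError("full synergism is defined for combinations of >= 2 genes")
    deltas = _group_deltas(group, combination.organism)
    if deltas is None:
        return EpistasisCall(combination, INSUFFICIENT, mode="full",
                             experiment_key=group.experiment_key)

    required = [frozenset(c) for r in range(1, n) for c in itertools.combinations(sorted(genes), r)]
    names = {s: canonical_name(s) for s in required}
    names[genes] = canonical_name(genes)
    if names[genes] not in deltas or any(names[s] not in deltas for s in required):
        return EpistasisCall(combination, INSUFFICIENT, mode="full",
                             experiment_key=group.experiment_key)

    evidence = tuple(deltas[names[s]] for s in required + [genes])
    d = {s: deltas[names[s]].value_percent for s in required + [genes]}

    signs = {_sign(v, direction_tol) for v in d.values()}
    if 0 in signs or len(signs) > 1:
        # n=2 keeps the printed rules' nuances (opposite-direction doubles
        # are antagonistic, only the *singles* must agree in sign)
        if n == 2:
            g1, g2 = (frozenset({g}) for g in sorted(genes))
            call = classify_pair(d[g1], d[g2], d[genes],
                                 additive_epsilon=additive_epsilon,
                                 direction_tol=direction_tol)
            return EpistasisCall(combination, call.category, call.phenotype_direction,
                                 mode="full", experiment_key=group.experiment_key,
                                 evidence=evidence)
        return EpistasisCall(combination, NOT_ASSESSABLE, mode="full",
                             experiment_key=group.experiment_key, evidence=evidence)

    if n == 2:
        g1, g2 = (frozenset({g}) for g in sorted(genes))
        call = classify_pair(d[g1], d[g2], d[genes],
                             additive_epsilon=additive_epsilon,
                             direction_tol=direction_tol)
        return EpistasisCall(combination, call.category, call.phenotype_direction,
                             mode="full", experiment_key=group.experiment_key,
                             evidence=evidence)

    direction = "long-lived" if signs == {1} else "short-lived"
    a_comb = abs(d[genes])
    splits = [(abs(d[left]) + abs(d[right]), left, right) for left, right in _bipartitions(genes)]
    worst = max(splits, key=lambda t: t[0])
    synergistic = all(a_comb > total for total, _, _ in splits)

    if synergistic and strict:
        synergistic = all(
            full_synergy(group, MutantModel(combination.organism,
                                            _sub_interventions(combination, s)),
                         strict=True, additive_epsilon=additive_epsilon,
                         direction_tol=direction_tol).category == "synergistic"
            for s in required if len(s) >= 2
        )

    if synergistic:
        return EpistasisCall(combination, "synergistic", direction, mode="full",
                             experiment_key=group.experiment_key, evidence=evidence)
    total, left, right = worst
    pair_style = classify_pair(d[left], d[right], d[genes],
                               additive_epsilon=additive_epsilon,
                               direction_tol=direction_tol)
    return EpistasisCall(
        combination, NOT_SYNERGISTIC, direction, mode="full",
        experiment_key=group.experiment_key, evidence=evidence,
        violated_bipartition=(tuple(sorted(left)), tuple(sorted(right))),
        detail={"worst_bipartition_sum": total,
                "worst_bipartition_category": pair_style.category},
    )


def _sub_interventions(model: MutantModel, genes: frozenset[str]):
    return frozenset(iv for iv in model.interventions if iv.gene_symbol in genes)


def simple_synergy(
    group: ExperimentGroup,
    combination: MutantModel,
    *,
    direction_tol: float = 0.0,
) -> EpistasisCall:
    """Approximate synergism from single-mutant and combination deltas only.

    Synergistic iff |d(combination)| > sum of |d(single_i)| with all
    effects sharing one sign; no intermediary mutants are required, which
    is what makes this approximation falsifiable by later full data.
    """
    genes = combination.gene_set
    if len(genes) < 2:
        raise ValueError("simple synergism is defined for combinations of >= 2 genes")
    deltas = _group_deltas(group, combination.organism)
    if deltas is None:
        return EpistasisCall(combination, INSUFFICIENT, mode="simple",
                             experiment_key=group.experiment_key)
    singles = {g: frozenset({g}) for g in sorted(genes)}
    needed = [canonical_name(s) for s in singles.values()] + [canonical_name(genes)]
    if any(name not in deltas for name in needed):
        return EpistasisCall(combination, INSUFFICIENT, mode="simple",
                             experiment_key=group.experiment_key)
    evidence = tuple(deltas[name] for name in needed)
    vals = [deltas[name].value_percent for name in needed]
    signs = {_sign(v, direction_tol) for v in vals}
    if 0 in signs or len(signs) > 1:
        return EpistasisCall(combination, NOT_ASSESSABLE, mode="simple",
                             experiment_key=group.experiment_key, evidence=evidence)
    direction = "long-lived" if signs == {1} else "short-lived"
    total = sum(abs(v) for v in vals[:-1])
    category = "synergistic" if abs(vals[-1]) > total else NOT_SYNERGISTIC
    return EpistasisCall(combination, category, direction, mode="simple",
                         experiment_key=group.experiment_key, evidence=evidence)


def monotony(
    group: ExperimentGroup,
    combination: MutantModel,
    *,
    tie_tolerance: float = 0.0,
) -> MonotonyResult:
    """Partially-known monotony of an n-mutant along assayed paths.

    Enumerates every WT -> combination intervention path whose nodes all
    have a lifespan in this experiment; a path is monotonic-positive iff
    lifespan strictly increases at every step (negative: strictly
    decreases; an exact tie is non-monotonic).  One non-monotonic known
    path means the combination contains dependency relationships.
    """
    genes = combination.gene_set
    n = len(genes)
    lifespans = group.mean_lifespans()
    org = combination.organism

    def ls(gene_subset: frozenset[str]) -> float | None:
        return lifespans.get((org, canonical_name(gene_subset)))

    if ls(frozenset()) is None or ls(genes) is None:
        return MonotonyResult(combination, 0, math.factorial(n), "no_known_path")

    known = increasing = decreasing = bad = 0
    for order in itertools.permutations(sorted(genes)):
        values = []
        complete = True
        for k in range(n + 1):
            v = ls(frozenset(order[:k]))
            if v is None:
                complete = False
                break
            values.append(v)
        if not complete:
            continue
        known += 1
        up = all(b - a > tie_tolerance for a, b in zip(values, values[1:]))
        down = all(a - b > tie_tolerance for a, b in zip(values, values[1:]))
        if up:
            increasing += 1
        elif down:
            decreasing += 1
        else:
            bad += 1

    total = math.factorial(n)
    if known == 0:
        verdict = "no_known_path"
    elif bad:
        verdict = "contains_dependency"
    elif increasing:
        verdict = "monotonic_positive"
    else:
        verdict = "monotonic_negative"
    return MonotonyResult(combination, known, total, verdict)


def aggregate_calls(calls) -> dict:
    """Union summary of epistasis calls for one (organism, combination).

    Conflicting categories across experiments are all reported, each with
    its supporting experiment count; never collapsed into one.  If only
    ``insufficient_data`` calls exist, the summary says so.
    """
    keys = {c.combination.key() for c in calls if c.combination is not None}
    if len(keys) > 1:
        raise ValueError("aggregate_calls expects calls for a single combination")
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.category] = counts.get(call.category, 0) + 1
    informative = {k: v for k, v in counts.items() if k != INSUFFICIENT}
    if not informative:
        return {"summary": "Not enough data to assess", "categories": {}}
    return {"summary": "; ".join(sorted(informative)), "categories": informative}
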