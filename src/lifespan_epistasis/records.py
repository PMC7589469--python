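"""Domain model for curated lifespan records of multi-gene mutant strains.

The unit of observation is one cohort's (mean or median) lifespan for a
strain — wild type (WT), single mutant, or higher-order n-mutant — under
stated conditions (temperature, diet) in one published study.  Observations
from the same experiment share a WT control and are the only ones that may
be compared for epistasis inference.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

ORGANISMS = ("C. elegans", "D. melanogaster", "M. musculus")

#: intervention type -> functional direction
INTERVENTION_DIRECTION = {
    "loss-of-function mutation": "inhibit",
    "knockout": "inhibit",
    "RNAi": "inhibit",
    "gain-of-function mutation": "activate",
    "overexpression": "activate",
}

#: reserved canonical name for the wild-type (0-mutant) strain
WT_NAME = "wild type"


def canonical_name(gene_symbols) -> str:
    """Deterministic display name for a gene combination.

    Distinct gene symbols are sorted alphabetically (case-insensitive,
    byte-order tiebreak) and joined with ";", so e.g. ``{daf-2, daf-16}``
    and ``{daf-16, daf-2}`` both yield ``"daf-16;daf-2"``.  The empty set
    (wild type) maps to the reserved name ``"wild type"``.
    """
    genes = {g.gene_symbol if isinstance(g, GeneIntervention) else g for g in gene_symbols}
    if not genes:
        return WT_NAME
    return ";".join(sorted(genes, key=lambda g: (g.lower(), g)))


@dataclass(frozen=True)
class GeneIntervention:
    """One modified gene: symbol, allele, and how it was perturbed."""

    gene_symbol: str
    intervention_type: str
    allele: str = ""

    def __post_init__(self):
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if self.intervention_type not in INTERVENTION_DIRECTION:
            raise ValueError(
                f"unknown intervention_type {self.intervention_type!r}; "
                f"expected one of {sorted(INTERVENTION_DIRECTION)}"
            )

    @property
    def direction(self) -> str:
        """'inhibit' or 'activate', determined by the intervention type."""
        return INTERVENTION_DIRECTION[self.intervention_type]


@dataclass(frozen=True)
class MutantModel:
    """A strain: organism plus a set of gene interventions (WT = empty set).

    Model identity is at the gene level: alleles are recorded on the
    interventions but two strains perturbing the same genes are the same
    model.
    """

    organism: str
    interventions: frozenset[GeneIntervention] = frozenset()

    def __post_init__(self):
        if self.organism not in ORGANISMS:
            raise ValueError(f"unknown organism {self.organism!r}")
        object.__setattr__(self, "interventions", frozenset(self.interventions))

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(iv.gene_symbol for iv in self.interventions)

    @property
    def n(self) -> int:
        """Number of distinct intervened genes (0 for wild type)."""
        return len(self.gene_set)

    @property
    def canonical_name(self) -> str:
        return canonical_name(self.gene_set)

    @property
    def is_wt(self) -> bool:
        return self.n == 0

    def key(self) -> tuple[str, str]:
        return (self.organism, self.canonical_name)


@dataclass(frozen=True)
class LifespanObservation:
    """One cohort's lifespan value with conditions and study provenance."""

    model: MutantModel
    lifespan_days: float
    lifespan_metric: str = "mean"  # when a study reports both, mean is preferred
    temperature_c: float | None = None
    diet: str | None = None
    study_id: str = ""
    experiment_key: str = ""

    def __post_init__(self):
        if not self.lifespan_days > 0:
            raise ValueError("lifespan_days must be positive")
        if self.lifespan_metric not in ("mean", "median"):
            raise ValueError("lifespan_metric must be 'mean' or 'median'")
        if not self.experiment_key:
            object.__setattr__(self, "experiment_key", default_experiment_key(self))


def default_experiment_key(obs: LifespanObservation) -> str:
    """Grouping key for same-experiment comparability: (study, temperature, diet)."""
    t = "" if obs.temperature_c is None else f"{obs.temperature_c:g}"
    return f"{obs.study_id}|{t}|{obs.diet or ''}"


@dataclass
class ExperimentGroup:
    """Co-comparable observations sharing one experiment key and WT control."""

    experiment_key: str
    observations: list[LifespanObservation] = field(default_factory=list)

    def __post_init__(self):
        for obs in self.observations:
            if obs.experiment_key != self.experiment_key:
                raise ValueError("observation experiment_key mismatch")

    @property
    def wt_lifespan_days(self) -> float | None:
        """Mean WT lifespan in this group, or None if no WT was assayed."""
        vals = [o.lifespan_days for o in self.observations if o.model.is_wt]
        return sum(vals) / len(vals) if vals else None

    def models(self) -> list[MutantModel]:
        seen, out = set(), []
        for obs in self.observations:
            k = obs.model.key()
            if k not in seen:
                seen.add(k)
                out.append(obs.model)
        return out

    def mean_lifespans(self) -> dict[tuple[str, str], float]:
        """Per-model arithmetic mean lifespan (replicate cohorts averaged)."""
        acc: dict[tuple[str, str], list[float]] = defaultdict(list)
        for obs in self.observations:
            acc[obs.model.key()].append(obs.lifespan_days)
        return {k: sum(v) / len(v) for k, v in acc.items()}

    def lifespan_of(self, model: MutantModel) -> float | None:
        return self.mean_lifespans().get(model.key())


def group_observations(observations) -> list[ExperimentGroup]:
    """Bin observations into ExperimentGroups by experiment_key (input order kept)."""
    groups: dict[str, list[LifespanObservation]] = {}
    for obs in observations:
        groups.setdefault(obs.experiment_key, []).append(obs)
    return [ExperimentGroup(k, v) for k, v in groups.items()]


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


def inclusion_filter(group: ExperimentGroup, assume_prior_lag: bool = False) -> FilterResult:
    """Apply the curation inclusion rules to one experiment group.

    A group passes iff (a) some n-mutant with n >= 2 has at least one
    (n-1)-mutant in the group whose gene set is a subset of its own — an
    n-mutant was compared against a strain it was incrementally
    constructed from — and (b) at least one mutant exceeds the group's WT
    lifespan by strictly more than 10%.  ``assume_prior_lag`` relaxes (b)
    for groups without a WT control, asserting (on the caller's
    authority, it is not computed here) that one of the interventions is
    an established lifespan modulator.

    Both conditions are existential, so the filter is monotone in
    evidence: adding observations can only add witnesses, never turn a
    pass into a fail.
    """
    mutants = [o for o in group.observations if not o.model.is_wt]
    if not mutants:
        return FilterResult(False, "no mutants")

    gene_sets = {m.gene_set for m in group.models() if not m.is_wt}
    anchored = any(
        len(gs) >= 2
        and any(len(other) == len(gs) - 1 and other < gs for other in gene_sets)
        for gs in gene_sets
    )
    if not anchored:
        return FilterResult(False, "no (n-1)-mutant comparison")

    wt_values = [o.lifespan_days for o in group.observations if o.model.is_wt]
    if not wt_values:
        if assume_prior_lag:
            return FilterResult(True)
        return FilterResult(False, "no wild-type control")
    # cohort-level comparison: some mutant cohort beats some WT cohort by >10%
    if not any(o.lifespan_days > 1.10 * min(wt_values) for o in mutants):
        return FilterResult(False, "no >10% increase")
    return FilterResult(True)


def qc_lifespan_distributions(groups) -> pd.DataFrame:
    """Per-(organism, strain, temperature) lifespan summary, for outlier review.

    Columns: organism, canonical_name, temperature_c, count, min, max, mean,
    sd (days).  SD is sample SD (ddof=1) and NaN for singleton cells.
    """
    rows = [
        {
            "organism": o.model.organism,
            "canonical_name": o.model.canonical_name,
            "temperature_c": o.temperature_c,
            "lifespan_days": o.lifespan_days,
        }
        for g in groups
        for o in g.observations
    ]
    cols = ["organism", "canonical_name", "temperature_c", "count", "min", "max", "mean", "sd"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["organism", "canonical_name", "temperature_c"], dropna=False)["lifespan_days"]
        .agg(count="count", min="min", max="max", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    out["sd"] = out["sd"].where(out["count"] >= 2, math.nan)
    return out[cols]
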