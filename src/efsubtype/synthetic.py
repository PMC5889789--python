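"""Synthetic cohorts, planted-partition networks and connectome sets.

The study's raw questionnaire and imaging data are not deposited, so every
downstream stage is exercised against generated data with known ground
truth.  Three generators are provided:

* :func:`generate_cohort` draws six-scale score profiles from latent groups
  whose medians and spreads default to the published per-cluster values
  (residual-score units), together with age, sex, validity-flag and
  diagnosis labels with the published enrichment pattern.
* :func:`generate_planted_network` builds signed similarity networks with a
  planted community structure for benchmarking the clustering stage.
* :func:`generate_connectomes` builds per-participant FA-like weight
  matrices whose expected node degree is shifted on designated effect nodes
  for benchmarking the PLS stage.

All generators are deterministic given their integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SCALES

#: Normal-consistency constant: for a normal sample, sd = 1.4826 * MAD.
MAD_TO_SD: float = 1.4826

#: Diagnosis labels, canonical order.
DIAGNOSES: tuple[str, ...] = ("adhd", "asd", "learning_deficit", "other", "none")

#: Latent group names keyed to the published cluster profiles.
DEFAULT_GROUPS: tuple[str, ...] = ("cognitive_control", "learning", "conduct")

#: Per-group scale medians in residual-score units (rows follow
#: DEFAULT_GROUPS, columns follow preprocess.SCALES).  The cognitive-control
#: group is elevated on inattention, hyperactivity/impulsivity and executive
#: function; the learning group on learning problems; the conduct group on
#: aggression and peer-relationship problems.
DEFAULT_GROUP_PROFILES: np.ndarray = np.array(
    [
        [0.71, 0.63, -0.15, 0.60, -0.53, -0.56],
        [0.11, -0.76, 0.90, -0.10, -0.59, -0.45],
        [0.01, 0.38, -0.58, -0.13, 0.26, 0.67],
    ]
)

#: Matching per-group scale MADs.
DEFAULT_GROUP_SPREADS: np.ndarray = np.array(
    [
        [0.404, 0.636, 0.642, 0.599, 0.452, 0.571],
        [0.810, 0.682, 0.524, 0.760, 0.497, 0.665],
        [0.959, 0.886, 0.876, 0.953, 1.048, 0.938],
    ]
)

#: Per-group diagnosis probabilities (rows: DEFAULT_GROUPS, columns:
#: DIAGNOSES), reproducing the published diagnosis-by-cluster enrichment:
#: ADHD concentrated in the cognitive-control cluster, learning deficits in
#: the learning cluster.
DEFAULT_DIAGNOSIS_RATES: np.ndarray = np.array(
    [
        [33 / 150, 13 / 150, 3 / 150, 7 / 150, 94 / 150],
        [4 / 145, 5 / 145, 22 / 145, 8 / 145, 106 / 145],
        [24 / 147, 6 / 147, 7 / 147, 8 / 147, 102 / 147],
    ]
)

#: Fraction of boys in the referred sample (295 of 442).
DEFAULT_MALE_FRACTION: float = 295 / 442

#: Fraction of responses with a high negative-impression validity score
#: (80 of 442).
DEFAULT_NEGATIVE_RATE: float = 80 / 442

#: Whole-sample T-score mean and SD per scale, used to map synthetic
#: residual-scale scores onto a T-like reporting scale.
_T_NORMS: np.ndarray = np.array(
    [
        [79.74, 11.95],
        [72.87, 16.33],
        [75.95, 11.91],
        [73.81, 12.90],
        [62.95, 17.26],
        [71.94, 17.97],
    ]
)


class SpecError(ValueError):
    """Raised when a generator specification violates an invariant."""


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic questionnaire cohort.

    Attributes
    ----------
    n_per_group:
        Children per latent group (>= 2).
    group_profiles:
        (k, 6) per-group scale medians, residual-score units.
    group_spreads:
        (k, 6) per-group scale MADs, all > 0.
    age_range_months:
        Uniform age range (low, high), months.
    diagnosis_rates:
        (k, 5) probability table over :data:`DIAGNOSES`; rows sum to 1.
    male_fraction:
        Bernoulli probability that a child is male.
    negative_rate:
        Probability of a high negative-impression validity flag.
    seed:
        Integer seed; all draws flow from it.
    """

    n_per_group: int = 150
    group_profiles: np.ndarray = field(
        default_factory=lambda: DEFAULT_GROUP_PROFILES.copy()
    )
    group_spreads: np.ndarray = field(
        default_factory=lambda: DEFAULT_GROUP_SPREADS.copy()
    )
    age_range_months: tuple[float, float] = (62.0, 215.0)
    diagnosis_rates: np.ndarray = field(
        default_factory=lambda: DEFAULT_DIAGNOSIS_RATES.copy()
    )
    male_fraction: float = DEFAULT_MALE_FRACTION
    negative_rate: float = DEFAULT_NEGATIVE_RATE
    group_names: tuple[str, ...] = DEFAULT_GROUPS
    seed: int = 0

    def __post_init__(self):
        profiles = np.asarray(self.group_profiles, dtype=float)
        spreads = np.asarray(self.group_spreads, dtype=float)
        rates = np.asarray(self.diagnosis_rates, dtype=float)
        object.__setattr__(self, "group_profiles", profiles)
        object.__setattr__(self, "group_spreads", spreads)
        object.__setattr__(self, "diagnosis_rates", rates)
        if self.n_per_group < 2:
            raise SpecError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if profiles.ndim != 2 or profiles.shape[1] != len(SCALES):
            raise SpecError("group_profiles must be (k, 6)")
        if spreads.shape != profiles.shape:
            raise SpecError("group_spreads must match group_profiles shape")
        if np.any(spreads < 0):
            raise SpecError("group_spreads must be non-negative")
        if rates.shape != (profiles.shape[0], len(DIAGNOSES)):
            raise SpecError("diagnosis_rates must be (k, 5)")
        if np.any(rates < 0) or not np.allclose(rates.sum(axis=1), 1.0):
            raise SpecError("diagnosis_rates rows must be probabilities summing to 1")
        if not (0 <= self.male_fraction <= 1):
            raise SpecError("male_fraction must lie in [0, 1]")
        if not (0 <= self.negative_rate <= 1):
            raise SpecError("negative_rate must lie in [0, 1]")
        lo, hi = self.age_range_months
        if not lo <= hi:
            raise SpecError("age_range_months must satisfy low <= high")
        if len(self.group_names) != profiles.shape[0]:
            raise SpecError("group_names length must match number of groups")

    @property
    def n_groups(self) -> int:
        return self.group_profiles.shape[0]


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Specification of a signed network with planted communities."""

    n_nodes: int = 120
    n_communities: int = 3
    p_within: float = 0.9
    p_between: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise SpecError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if not 1 <= self.n_communities <= self.n_nodes:
            raise SpecError("n_communities must lie in [1, n_nodes]")
        if not (0 <= self.p_between <= self.p_within <= 1):
            raise SpecError("need 0 <= p_between <= p_within <= 1")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ConnectomeSpec:
    """Specification of a synthetic FA-weighted connectome set.

    ``effect_nodes`` maps each group index to the node indices whose
    expected binary degree is shifted by ``effect_size`` edges for members
    of that group; the shift is implanted through edge-presence probability
    so that it survives binarization.
    """

    n_nodes: int = 34
    n_per_group: int = 30
    effect_nodes: tuple[tuple[int, ...], ...] = ((0, 1, 2, 3), (17, 18, 19, 20))
    effect_size: float = 8.0
    base_density: float = 0.3
    weight_range: tuple[float, float] = (0.2, 0.8)
    group_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise SpecError("n_nodes must be >= 2")
        if self.n_per_group < 2:
            raise SpecError("n_per_group must be >= 2")
        if not (0 < self.base_density <= 1):
            raise SpecError("base_density must lie in (0, 1]")
        lo, hi = self.weight_range
        if not (0 < lo <= hi < 1):
            raise SpecError("weight_range must lie within (0, 1)")
        for nodes in self.effect_nodes:
            for i in nodes:
                if not 0 <= i < self.n_nodes:
                    raise SpecError(f"effect node {i} outside [0, {self.n_nodes})")
        expected = self.base_density * (self.n_nodes - 1) + self.effect_size
        if not 0 <= expected <= self.n_nodes - 1:
            raise SpecError(
                "effect_size pushes expected degree outside [0, n_nodes - 1]"
            )
        names = self.group_names
        if names is not None and len(names) != len(self.effect_nodes):
            raise SpecError("group_names length must match effect_nodes")

    @property
    def n_groups(self) -> int:
        return len(self.effect_nodes)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table from the latent-group model.

    Scale scores are ``group median + N(0, (1.4826 * MAD)^2)`` — the normal
    distribution whose median and MAD match the requested ones.  Ages are
    uniform over the age range, sex is Bernoulli(male_fraction), diagnoses
    are drawn from the per-group rate table, and a T-like age-standardized
    score per scale is derived from the standardized raw score via the
    whole-sample T norms (clipped to [20, 100]).

    Returns
    -------
    pandas.DataFrame
        Cohort table (see :mod:`efsubtype.preprocess`) with ``group_truth``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_groups
    n = k * spec.n_per_group
    group_idx = np.repeat(np.arange(k), spec.n_per_group)

    sd = MAD_TO_SD * spec.group_spreads
    scores = spec.group_profiles[group_idx] + rng.normal(size=(n, len(SCALES))) * sd[
        group_idx
    ]

    ages = rng.uniform(*spec.age_range_months, size=n)
    sexes = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    negative = rng.random(n) < spec.negative_rate
    diag_codes = np.array(
        [rng.choice(len(DIAGNOSES), p=spec.diagnosis_rates[g]) for g in group_idx]
    )

    # T-like reporting scale: standardize each raw column over the cohort,
    # then map onto the published whole-sample T mean/SD.
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    t_scores = np.clip(_T_NORMS[:, 0] + _T_NORMS[:, 1] * z, 20.0, 100.0)

    table = pd.DataFrame(
        {
            "child_id": [f"child_{i:04d}" for i in range(n)],
            "age_months": ages,
            "sex": sexes,
        }
    )
    for j, scale in enumerate(SCALES):
        table[scale] = scores[:, j]
    for j, scale in enumerate(SCALES):
        table[f"t_{scale}"] = t_scores[:, j]
    table["negative_impression"] = negative
    table["diagnosis"] = [DIAGNOSES[c] for c in diag_codes]
    table["group_truth"] = [spec.group_names[g] for g in group_idx]
    return table


def _community_sizes(n_nodes: int, n_communities: int) -> np.ndarray:
    base = n_nodes // n_communities
    sizes = np.full(n_communities, base)
    sizes[: n_nodes % n_communities] += 1
    return sizes


def generate_planted_network(spec: PlantedPartitionSpec):
    """Build a signed network with a planted community structure.

    Within-community edges appear with probability ``p_within`` and
    between-community edges with ``p_between``; every present edge has
    weight 1 plus N(0, noise_sd^2) noise.  Absent edges are exactly zero.

    Returns
    -------
    (SimilarityNetwork, numpy.ndarray)
        The network and the planted community label per node.
    """
    from .network import SimilarityNetwork

    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    sizes = _community_sizes(n, spec.n_communities)
    labels = np.repeat(np.arange(spec.n_communities), sizes)

    same = labels[:, None] == labels[None, :]
    p = np.where(same, spec.p_within, spec.p_between)
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < p[iu]
    weights_u = present.astype(float)
    if spec.noise_sd > 0:
        weights_u = weights_u + present * rng.normal(
            scale=spec.noise_sd, size=len(iu[0])
        )
    w = np.zeros((n, n))
    w[iu] = weights_u
    w = w + w.T
    net = SimilarityNetwork(
        node_ids=[f"node_{i:04d}" for i in range(n)], weights=w, check_bounds=False
    )
    return net, labels


def generate_connectomes(spec: ConnectomeSpec):
    """Build a synthetic connectome set with planted degree effects.

    Baseline edges are Bernoulli(base_density) with FA-like weights uniform
    in ``weight_range``.  For a participant in group g, every edge incident
    to one of g's effect nodes has its presence probability raised by
    ``effect_size / (n_nodes - 1)``, so the expected binary degree of each
    effect node increases by approximately ``effect_size`` edges.

    Returns
    -------
    ConnectomeSet
    """
    from .pls import ConnectomeSet

    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    k = spec.n_groups
    names = spec.group_names or tuple(f"group_{g}" for g in range(k))
    delta = spec.effect_size / (n - 1)

    iu = np.triu_indices(n, k=1)
    matrices = []
    ids = []
    groups = []
    for g in range(k):
        effect = np.zeros(n, dtype=bool)
        effect[list(spec.effect_nodes[g])] = True
        bump = delta * (effect[:, None].astype(float) + effect[None, :])
        p = np.clip(spec.base_density + bump, 0.0, 1.0)
        for participant in range(spec.n_per_group):
            present = rng.random(len(iu[0])) < p[iu]
            weights_u = present * rng.uniform(*spec.weight_range, size=len(iu[0]))
            w = np.zeros((n, n))
            w[iu] = weights_u
            w = w + w.T
            matrices.append(w)
            ids.append(f"sub_{names[g]}_{participant:03d}")
            groups.append(names[g])
    return ConnectomeSet(
        participant_ids=ids,
        node_labels=[f"region_{i:03d}" for i in range(n)],
        matrices=np.array(matrices),
        groups=np.array(groups),
    )


def subsample_size(smallest_group: int, fraction: float = 0.65) -> int:
    """Bootstrap subsample size: ceil(fraction * smallest group size)."""
    return math.ceil(fraction * smallest_group)
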