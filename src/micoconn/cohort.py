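"""Synthetic developmental cohorts with programmed network effects.

The statistical stages are exercised on cohorts of subject records —
age, sex, intracranial volume (ICV) and a weighted connectome — whose
edge weights carry known linear age effects, sex offsets, age-by-sex
slope differences and noise, per canonical network. The defaults mirror
a developmental sample of 88 children aged 8-19 years (46 female).

Edge model, for an edge inside network g of a subject with age a and
male indicator m:

    w = baseline_g + slope_g * (a - age_min) + sexoff_g * m
        + agesex_g * (a - age_min) * m + subject_offset + N(0, sd_g)

truncated at zero. Between-network edges take a common baseline and
noise with no covariate effects. ICV is log-normal with a male offset
(correlation with sex ~0.3) so that head-size adjustment has something
to adjust for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .parcellation import NetworkAssignment

__all__ = [
    "CANONICAL_NETWORKS",
    "GroupEffect",
    "EffectSpec",
    "SubjectRecord",
    "canonical_assignment",
    "simulate_cohort",
    "null_cohort",
]

CANONICAL_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "fronto_parietal",
    "default_mode",
    "subcortical",
)


def canonical_assignment(
    nodes_per_network: int | dict[str, int] = 8,
    networks: tuple[str, ...] = CANONICAL_NETWORKS,
) -> NetworkAssignment:
    """ROI -> network mapping for a synthetic parcellation.

    Labels are consecutive positive integers, assigned network-by-network
    in the order given; pass a dict to vary network sizes (e.g. a
    26-node visual network).
    """
    if isinstance(nodes_per_network, int):
        sizes = {g: nodes_per_network for g in networks}
    else:
        sizes = dict(nodes_per_network)
    mapping: dict[int, str] = {}
    label = 1
    for g in networks:
        for _ in range(sizes[g]):
            mapping[label] = g
            label += 1
    return NetworkAssignment(mapping=mapping)


@dataclass(frozen=True)
class GroupEffect:
    """Programmed effects on the edges inside one network."""

    baseline: float = 0.5
    age_slope: float = 0.0  # per year, applied to (age - age_min)
    sex_offset: float = 0.0  # added for males
    age_sex_slope: float = 0.0  # male-minus-female slope difference
    edge_noise_sd: float = 0.05
    age_effect_nodes: tuple[int, ...] | None = None  # within-group node indices

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.edge_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class EffectSpec:
    """Full generative specification of a cohort's connectomes."""

    groups: dict[str, GroupEffect] = field(default_factory=dict)
    default: GroupEffect = GroupEffect()
    between_baseline: float = 0.25
    between_noise_sd: float = 0.05
    subject_offset_sd: float = 0.02

    def effect_for(self, group: str) -> GroupEffect:
        return self.groups.get(group, self.default)


@dataclass
class SubjectRecord:
    """One synthetic participant."""

    id: str
    age: float
    sex: str  # 'M' or 'F'
    icv: float
    connectome: Connectome

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.icv <= 0:
            raise ValueError("ICV must be positive")


def simulate_cohort(
    n: int = 88,
    age_range: tuple[float, float] = (8.0, 19.0),
    n_female: int = 46,
    assignment: NetworkAssignment | None = None,
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Generate a cohort of subject records with programmed effects.

    Ages are uniform on ``age_range``; exactly ``n_female`` subjects are
    female (order shuffled); connectome edges follow the edge model of
    the module docstring. Deterministic for a given seed.
    """
    if n < 2:
        raise ValueError("cohort needs at least 2 subjects")
    if not 0 <= n_female <= n:
        raise ValueError("n_female must be between 0 and n")
    assignment = assignment if assignment is not None else canonical_assignment()
    effects = effects if effects is not None else EffectSpec()
    for g in effects.groups:
        if g not in assignment.groups():
            raise ValueError(f"effect spec references unknown group {g!r}")

    rng = np.random.default_rng(seed)
    labels = np.array(sorted(assignment.mapping))
    node_group = np.array([assignment.mapping[int(r)] for r in labels])
    n_rois = labels.size
    groups_sorted = assignment.groups()
    group_nodes = {g: np.flatnonzero(node_group == g) for g in groups_sorted}

    ages = rng.uniform(age_range[0], age_range[1], size=n)
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes)
    male = (sexes == "M").astype(float)
    icv = np.exp(np.log(1.4e6) + 0.066 * male + rng.normal(0, 0.1, size=n))

    # per-edge static structure (identical across subjects)
    iu, ju = np.triu_indices(n_rois, k=1)
    same = node_group[iu] == node_group[ju]
    base = np.full(iu.size, effects.between_baseline)
    slope = np.zeros(iu.size)
    sexoff = np.zeros(iu.size)
    agesex = np.zeros(iu.size)
    noise_sd = np.full(iu.size, effects.between_noise_sd)
    for g in groups_sorted:
        eff = effects.effect_for(g)
        mask = same & (node_group[iu] == g)
        base[mask] = eff.baseline
        sexoff[mask] = eff.sex_offset
        noise_sd[mask] = eff.edge_noise_sd
        if eff.age_effect_nodes is None:
            smask = mask
        else:
            flagged = set(group_nodes[g][list(eff.age_effect_nodes)])
            touches = np.isin(iu, list(flagged)) | np.isin(ju, list(flagged))
            smask = mask & touches
        slope[smask] = eff.age_slope
        agesex[smask] = eff.age_sex_slope

    records: list[SubjectRecord] = []
    for s in range(n):
        da = ages[s] - age_range[0]
        mean = base + slope * da + sexoff * male[s] + agesex * da * male[s]
        offset = rng.normal(0, effects.subject_offset_sd) if effects.subject_offset_sd else 0.0
        w = mean + offset + rng.normal(0, 1.0, size=iu.size) * noise_sd
        np.clip(w, 0.0, None, out=w)
        m = np.zeros((n_rois, n_rois))
        m[iu, ju] = w
        m[ju, iu] = w
        conn = Connectome(
            matrix=m,
            labels=labels,
            weighting="IASF",
            groups=dict(assignment.mapping),
        )
        records.append(
            SubjectRecord(
                id=f"sub-{s:03d}",
                age=float(ages[s]),
                sex=str(sexes[s]),
                icv=float(icv[s]),
                connectome=conn,
            )
        )
    return records


def null_cohort(
    n: int = 88,
    seed: int = 0,
    assignment: NetworkAssignment | None = None,
    noise_sd: float = 0.05,
    subject_offset_sd: float = 0.0,
) -> list[SubjectRecord]:
    """Cohort with no age or sex effects anywhere, noise kept positive.

    The type-I-error harness: any detected age or sex association in a
    null cohort is a false positive. The subject-level offset defaults
    to zero here — it would correlate the per-network tests within a
    subject (networks own disjoint edge sets, so edge noise alone keeps
    them independent), without changing any marginal null property.
    """
    if noise_sd <= 0:
        raise ValueError("null cohort noise must be positive")
    spec = EffectSpec(
        default=GroupEffect(edge_noise_sd=noise_sd),
        subject_offset_sd=subject_offset_sd,
    )
    return simulate_cohort(
        n=n, n_female=n // 2, assignment=assignment, effects=spec, seed=seed
    )
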