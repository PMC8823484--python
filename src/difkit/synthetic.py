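"""Synthetic item-response cohorts with controllable DIF.

Generates grouped dichotomous response data under the 2PL model so the whole
analysis chain is testable without any external dataset.  A
:class:`SyntheticSpec` fixes the group sizes, per-group trait distributions
(normal, or a two-component normal mixture for skewed traits), base item
parameters and per-item, per-group parameter shifts:

* a difficulty shift (``db``) makes the item uniformly harder or easier for a
  group at every trait level -- uniform DIF (a group main effect);
* a discrimination shift (``da``) changes the item's slope for a group --
  non-uniform DIF (a group-by-trait interaction).

The default recipe mirrors a two-group 15-item depression-screen cohort with
unbalanced group sizes of 684 and 789, discriminations in [0.8, 2] and
difficulties in [-1.5, 1.5].  Everything is reproducible from the spec's seed;
Monte-Carlo studies spawn independent child seeds from a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .regression import DIFConfig, GroupFactor, dif_scan
from .scale import ResponseMatrix

__all__ = [
    "TraitDistribution",
    "SyntheticSpec",
    "TruthRecord",
    "generate",
    "make_gds_like",
    "Scenario",
    "calibration_study",
]


@dataclass(frozen=True)
class TraitDistribution:
    """Normal trait, or a two-component normal mixture for asymmetric traits."""

    mean: float = 0.0
    sd: float = 1.0
    mix_weight: float = 0.0  # weight of the second component
    mix_mean: float = 0.0
    mix_sd: float = 1.0

    def __post_init__(self):
        if self.sd <= 0 or self.mix_sd <= 0:
            raise ValueError("trait SDs must be positive")
        if not 0.0 <= self.mix_weight < 1.0:
            raise ValueError("mixture weight must lie in [0, 1)")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        theta = rng.normal(self.mean, self.sd, size=n)
        if self.mix_weight > 0:
            second = rng.random(n) < self.mix_weight
            theta[second] = rng.normal(self.mix_mean, self.mix_sd, size=int(second.sum()))
        return theta

    def pdf(self, x: np.ndarray) -> np.ndarray:
        main = stats.norm.pdf(x, self.mean, self.sd)
        if self.mix_weight == 0:
            return main
        return (1 - self.mix_weight) * main + self.mix_weight * stats.norm.pdf(
            x, self.mix_mean, self.mix_sd
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative recipe for a grouped 2PL cohort.

    ``dif`` maps a 1-based item index to ``{level: (da, db)}`` parameter
    shifts applied on top of the base ``(a, b)`` for persons of that group
    level.  ``covariates`` maps extra categorical column names to level lists
    (sampled uniformly, independent of the trait).
    """

    group_levels: tuple
    group_sizes: tuple
    traits: tuple  # one TraitDistribution per level
    a: tuple
    b: tuple
    dif: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if len(self.group_levels) != len(self.group_sizes) or len(self.group_levels) < 1:
            raise ValueError("group levels and sizes must align")
        if any(int(s) <= 0 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if len(self.a) != len(self.b):
            raise ValueError("a and b must have the same length")
        if any(ai <= 0 for ai in self.a):
            raise ValueError("base discriminations must be positive")
        if len(self.traits) != len(self.group_levels):
            raise ValueError("one trait distribution per group level")
        k = len(self.a)
        for item, shifts in self.dif.items():
            if not 1 <= int(item) <= k:
                raise ValueError(f"DIF injection on unknown item {item}")
            for level, (da, db) in shifts.items():
                if level not in self.group_levels:
                    raise ValueError(f"DIF injection for unknown level {level!r}")
                if self.a[int(item) - 1] + da <= 0:
                    raise ValueError(
                        f"discrimination shift on item {item} makes a <= 0 for {level!r}"
                    )

    @property
    def n_items(self) -> int:
        return len(self.a)

    @property
    def n_persons(self) -> int:
        return int(sum(self.group_sizes))

    def params_for(self, level):
        """(a, b) arrays in force for one group level, shifts applied."""
        a = np.array(self.a, dtype=float)
        b = np.array(self.b, dtype=float)
        for item, shifts in self.dif.items():
            if level in shifts:
                da, db = shifts[level]
                a[int(item) - 1] += da
                b[int(item) - 1] += db
        return a, b

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "group_levels": list(self.group_levels),
            "group_sizes": [int(s) for s in self.group_sizes],
            "traits": [
                {
                    "mean": t.mean,
                    "sd": t.sd,
                    "mix_weight": t.mix_weight,
                    "mix_mean": t.mix_mean,
                    "mix_sd": t.mix_sd,
                }
                for t in self.traits
            ],
            "a": [float(x) for x in self.a],
            "b": [float(x) for x in self.b],
            "dif": {
                str(item): {str(lev): [float(da), float(db)] for lev, (da, db) in shifts.items()}
                for item, shifts in self.dif.items()
            },
            "covariates": {k: list(v) for k, v in self.covariates.items()},
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        levels = tuple(d["group_levels"])
        return cls(
            group_levels=levels,
            group_sizes=tuple(int(s) for s in d["group_sizes"]),
            traits=tuple(TraitDistribution(**t) for t in d["traits"]),
            a=tuple(d["a"]),
            b=tuple(d["b"]),
            dif={
                int(item): {
                    _match_level(lev, levels): tuple(shift) for lev, shift in shifts.items()
                }
                for item, shifts in d.get("dif", {}).items()
            },
            covariates={k: tuple(v) for k, v in d.get("covariates", {}).items()},
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _match_level(lev, levels):
    """YAML/JSON keys arrive as strings; map back onto the declared levels."""
    if lev in levels:
        return lev
    for cand in levels:
        if str(cand) == str(lev):
            return cand
    raise ValueError(f"DIF injection for unknown level {lev!r}")


@dataclass
class TruthRecord:
    """Everything the generator knew: traits, per-group parameters, injections."""

    theta: np.ndarray
    group: np.ndarray
    a_by_level: dict
    b_by_level: dict
    dif_items: tuple
    spec: SyntheticSpec

    def to_json(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "group": [str(g) for g in self.group],
            "a_by_level": {str(k): v.tolist() for k, v in self.a_by_level.items()},
            "b_by_level": {str(k): v.tolist() for k, v in self.b_by_level.items()},
            "dif_items": list(self.dif_items),
            "spec": self.spec.to_dict(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "TruthRecord":
        spec = SyntheticSpec.from_dict(d["spec"])
        levels = spec.group_levels
        return cls(
            theta=np.asarray(d["theta"], dtype=float),
            group=np.array([_match_level(g, levels) for g in d["group"]], dtype=object),
            a_by_level={_match_level(k, levels): np.asarray(v) for k, v in d["a_by_level"].items()},
            b_by_level={_match_level(k, levels): np.asarray(v) for k, v in d["b_by_level"].items()},
            dif_items=tuple(d["dif_items"]),
            spec=spec,
        )


def generate(spec: SyntheticSpec):
    """Draw a cohort: (scored ResponseMatrix, covariate DataFrame, TruthRecord).

    Traits are sampled per group from the spec's distributions; responses are
    Bernoulli under each person's group-specific 2PL parameters.  The
    covariate table holds the group column plus any extra independent factors.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_items
    thetas, groups = [], []
    for level, size, trait in zip(spec.group_levels, spec.group_sizes, spec.traits):
        thetas.append(trait.sample(int(size), rng))
        groups.extend([level] * int(size))
    theta = np.concatenate(thetas)
    group = np.array(groups, dtype=object)
    n = len(theta)

    values = np.empty((n, k))
    a_by_level, b_by_level = {}, {}
    start = 0
    for level, size in zip(spec.group_levels, spec.group_sizes):
        size = int(size)
        a, b = spec.params_for(level)
        a_by_level[level] = a
        b_by_level[level] = b
        th = theta[start : start + size]
        p = 1.0 / (1.0 + np.exp(-a[None, :] * (th[:, None] - b[None, :])))
        values[start : start + size] = (rng.random((size, k)) < p).astype(float)
        start += size

    person_ids = np.array([f"p{i:05d}" for i in range(1, n + 1)], dtype=object)
    item_ids = np.array([f"item_{j}" for j in range(1, k + 1)], dtype=object)
    rm = ResponseMatrix(values, person_ids, item_ids, scored=True)

    cov = pd.DataFrame({"group": group}, index=pd.Index(person_ids, name="person_id"))
    for name, levels in spec.covariates.items():
        cov[name] = rng.choice(np.asarray(levels, dtype=object), size=n)
    truth = TruthRecord(
        theta=theta,
        group=group,
        a_by_level=a_by_level,
        b_by_level=b_by_level,
        dif_items=tuple(sorted(spec.dif)),
        spec=spec,
    )
    return rm, cov, truth


def make_gds_like(
    seed: int,
    group_sizes=(684, 789),
    group_levels=("reference", "focal"),
    trait_means=(0.0, 0.0),
    trait_sds=(1.0, 1.0),
    dif=None,
    n_items: int = 15,
) -> SyntheticSpec:
    """Spec shaped like a two-group 15-item depression-screen cohort.

    Base discriminations are drawn uniformly from [0.8, 2] and difficulties
    from [-1.5, 1.5] (seeded); groups default to the unbalanced 684/789 split
    with standard-normal traits and no DIF unless ``dif`` is given.
    """
    rng = np.random.default_rng(seed)
    a = tuple(rng.uniform(0.8, 2.0, size=n_items))
    b = tuple(rng.uniform(-1.5, 1.5, size=n_items))
    traits = tuple(
        TraitDistribution(mean=float(m), sd=float(s)) for m, s in zip(trait_means, trait_sds)
    )
    return SyntheticSpec(
        group_levels=tuple(group_levels),
        group_sizes=tuple(int(s) for s in group_sizes),
        traits=traits,
        a=a,
        b=b,
        dif=dict(dif or {}),
        seed=int(seed),
    )


def model_implied_proportions(spec: SyntheticSpec, level, n_nodes: int = 201) -> np.ndarray:
    """Marginal endorsement probability per item for one group, by quadrature."""
    idx = spec.group_levels.index(level)
    trait = spec.traits[idx]
    grid = np.linspace(-8, 8, n_nodes)
    w = trait.pdf(grid)
    w = w / w.sum()
    a, b = spec.params_for(level)
    p = 1.0 / (1.0 + np.exp(-a[:, None] * (grid[None, :] - b[:, None])))
    return p @ w


@dataclass(frozen=True)
class Scenario:
    """One cell of a calibration study grid."""

    name: str
    n_per_group: int = 500
    delta_b: float = 0.0
    delta_a: float = 0.0
    dif_item: int = 4
    trait: TraitDistribution = TraitDistribution()
    focal_trait: TraitDistribution | None = None
    alpha: float = 0.01
    n_items: int = 15


def calibration_study(
    scenarios,
    replicates: int,
    seed: int,
    ability: str = "true",
) -> pd.DataFrame:
    """Monte-Carlo flag rates (type-I error / power) over a scenario grid.

    For each scenario and replicate a fresh cohort is generated, the DIF scan
    is run (matching on the true simulated trait by default, ``ability='true'``;
    ``'eap'`` refits a pooled 2PL first) and the uniform / non-uniform flag
    rates are tallied separately for null items and for the injected item.
    99% exact (Clopper-Pearson) intervals accompany every rate.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if ability not in ("true", "eap"):
        raise ValueError("ability must be 'true' or 'eap'")
    master = np.random.SeedSequence(seed)
    rows = []
    for scenario in scenarios:
        children = master.spawn(replicates)
        null_flags_u = null_flags_n = null_tests = 0
        dif_flags_u = dif_flags_n = dif_tests = 0
        config = DIFConfig(alpha=scenario.alpha)
        has_dif = scenario.delta_b != 0.0 or scenario.delta_a != 0.0
        for child in children:
            child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            rng_params = np.random.default_rng(child_seed)
            a = tuple(rng_params.uniform(0.8, 2.0, size=scenario.n_items))
            b = tuple(rng_params.uniform(-1.5, 1.5, size=scenario.n_items))
            dif = (
                {scenario.dif_item: {"focal": (scenario.delta_a, scenario.delta_b)}}
                if has_dif
                else {}
            )
            spec = SyntheticSpec(
                group_levels=("reference", "focal"),
                group_sizes=(scenario.n_per_group, scenario.n_per_group),
                traits=(scenario.trait, scenario.focal_trait or scenario.trait),
                a=a,
                b=b,
                dif=dif,
                seed=child_seed,
            )
            rm, cov, truth = generate(spec)
            g = GroupFactor.from_labels(cov["group"].to_numpy(), levels=spec.group_levels)
            if ability == "true":
                theta = truth.theta
            else:
                from .irt import eap_scores, fit_2pl

                theta = eap_scores(rm, fit_2pl(rm)).theta
            results = dif_scan(rm, theta, g, config)
            for r in results:
                if has_dif and r.item == scenario.dif_item:
                    dif_tests += 1
                    dif_flags_u += int(r.flag_uniform)
                    dif_flags_n += int(r.flag_nonuniform)
                else:
                    null_tests += 1
                    null_flags_u += int(r.flag_uniform)
                    null_flags_n += int(r.flag_nonuniform)

        def ci(successes, trials):
            if trials == 0:
                return (float("nan"), float("nan"))
            res = stats.binomtest(successes, trials).proportion_ci(
                confidence_level=0.99, method="exact"
            )
            return float(res.low), float(res.high)

        row = {
            "scenario": scenario.name,
            "n_per_group": scenario.n_per_group,
            "delta_b": scenario.delta_b,
            "delta_a": scenario.delta_a,
            "alpha": scenario.alpha,
            "replicates": replicates,
            "null_tests": null_tests,
            "null_rate_uniform": null_flags_u / null_tests if null_tests else float("nan"),
            "null_rate_nonuniform": null_flags_n / null_tests if null_tests else float("nan"),
        }
        row["null_rate_uniform_lo"], row["null_rate_uniform_hi"] = ci(null_flags_u, null_tests)
        if has_dif:
            row["power_uniform"] = dif_flags_u / dif_tests
            row["power_nonuniform"] = dif_flags_n / dif_tests
            row["power_uniform_lo"], row["power_uniform_hi"] = ci(dif_flags_u, dif_tests)
        rows.append(row)
    return pd.DataFrame(rows)
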