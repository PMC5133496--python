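"""Synthetic multi-family expression data with planted coexpression modules.

The generator emulates the study design the pipeline targets: a handful of
large pedigrees, probe expression with additive polygenic, shared-family
and residual variance, latent-factor coexpression modules (shared across
families or private to one), covariate effects (age, sex), and two
quantitative traits — a causal trait driven by a subset of probes (a
systolic-blood-pressure analog) and a null trait with the same variance
structure but independent of every probe (a Q1 analog).

Per-probe model::

    X = lambda * F_module + g + v + beta_age * age + beta_sex * sex + e

with ``F`` a per-module, per-family standard-normal latent factor, ``g`` a
polygenic effect generated by gene dropping through the pedigree
(founders ~ N(0, sigma_g^2); offspring = midparent + Mendelian-sampling
noise N(0, sigma_g^2 / 2)), ``v`` a family-constant draw and ``e`` iid
noise.  The covariance of ``g`` across the pedigree is 2 K sigma_g^2 by
construction, matching the mixed-model engine's genetic kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedkin import Pedigree, PedRecord

__all__ = [
    "SimulationError",
    "ModuleSpec",
    "SimConfig",
    "simulate_pedigree",
    "simulate_expression",
    "simulate_traits",
    "simulate_dataset",
    "load_config",
    "default_config",
]


class SimulationError(ValueError):
    pass


@dataclass
class ModuleSpec:
    """One planted coexpression module.

    ``loading`` is the latent-factor coefficient lambda in [0, 1];
    ``shared`` plants the factor in every family, otherwise only in
    ``home_family`` (by index) and the module's probes are plain
    background elsewhere.
    """

    size: int
    loading: float = 0.8
    shared: bool = True
    home_family: int = 0

    def validate(self) -> None:
        if self.size < 2:
            raise SimulationError("module size must be >= 2")
        if not 0.0 <= self.loading <= 1.0:
            raise SimulationError("module loading must be in [0, 1]")


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the target design: five families of sizes
    65/55/45/62/49 (276 individuals), probes with polygenic, shared-family
    and residual variance, six planted modules, and a causal trait driven
    by 15 probes spread over distinct modules plus background.
    """

    family_sizes: tuple[int, ...] = (65, 55, 45, 62, 49)
    n_probes: int = 2000
    modules: list[ModuleSpec] = field(default_factory=lambda: [
        ModuleSpec(size=100, loading=0.8, shared=True),
        ModuleSpec(size=90, loading=0.8, shared=True),
        ModuleSpec(size=80, loading=0.7, shared=True),
        ModuleSpec(size=70, loading=0.7, shared=True),
        ModuleSpec(size=60, loading=0.8, shared=False, home_family=0),
        ModuleSpec(size=50, loading=0.8, shared=False, home_family=3),
    ])
    # per-probe variance components
    sigma_g2: float = 0.4
    sigma_v2: float = 0.2
    sigma_e2: float = 1.0
    # trait construction
    n_causal: int = 15
    causal_effect: float = 0.3
    trait_polygenic_var: float = 1.0
    trait_noise_var: float = 1.0
    # covariates
    age_range: tuple[float, float] = (20.0, 80.0)
    expr_age_effect: float = 0.005
    expr_sex_effect: float = 0.1
    trait_age_effect: float = 0.2
    trait_sex_effect: float = 2.0
    seed: int = 1

    def validate(self) -> None:
        if any(s < 3 for s in self.family_sizes):
            raise SimulationError("family sizes must be >= 3")
        total = sum(m.size for m in self.modules)
        if total > self.n_probes:
            raise SimulationError("module sizes exceed n_probes")
        for m in self.modules:
            m.validate()
            if not m.shared and not 0 <= m.home_family < len(self.family_sizes):
                raise SimulationError("home_family index out of range")
        for name in ("sigma_g2", "sigma_v2", "sigma_e2",
                     "trait_polygenic_var", "trait_noise_var"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "family_sizes" in d:
            d["family_sizes"] = tuple(d["family_sizes"])
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "modules" in d:
            d["modules"] = [ModuleSpec(**m) for m in d["modules"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(json.load(fh))


def default_config() -> SimConfig:
    """The packaged default scenario (gaw19-like.json)."""
    text = resources.files("famnet").joinpath("configs/gaw19-like.json").read_text()
    return SimConfig.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def _grow_family(fam: str, size: int, rng: np.random.Generator,
                 max_generations: int = 8) -> list[PedRecord]:
    """Grow one pedigree to exactly ``size`` members.

    A founder couple seeds generation 1; each subsequent generation mates
    existing members with introduced founder spouses and draws 2-4
    children per couple, stopping the moment the target size is reached.
    """
    if size < 3:
        raise SimulationError("family size must be >= 3")
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{fam}-{counter}"

    records: list[PedRecord] = []

    def add(father=None, mother=None, sex=None) -> PedRecord:
        if sex is None:
            sex = int(rng.integers(1, 3))
        rec = PedRecord(fam, new_id(), father, mother, sex)
        records.append(rec)
        return rec

    pa = add(sex=1)
    ma = add(sex=2)
    current = [(pa, ma)]
    generation = 1
    while len(records) < size:
        generation += 1
        if generation > max_generations:
            raise SimulationError(
                f"family {fam}: cannot reach size {size} within "
                f"{max_generations} generations"
            )
        next_couples: list[tuple[PedRecord, PedRecord]] = []
        for father, mother in current:
            n_children = int(rng.integers(2, 5))
            for _ in range(n_children):
                if len(records) >= size:
                    return records
                child = add(father=father.individual_id,
                            mother=mother.individual_id)
                # most children marry in a spouse and found the next couple
                if len(records) < size and rng.random() < 0.75:
                    spouse = add(sex=1 if child.sex == 2 else 2)
                    pair = (child, spouse) if child.sex == 1 else (spouse, child)
                    next_couples.append(pair)
                    if len(records) >= size:
                        return records
        if not next_couples:
            # force one lineage to continue
            child = add(father=current[0][0].individual_id,
                        mother=current[0][1].individual_id)
            if len(records) >= size:
                return records
            spouse = add(sex=1 if child.sex == 2 else 2)
            pair = (child, spouse) if child.sex == 1 else (spouse, child)
            next_couples.append(pair)
            if len(records) >= size:
                return records
        current = next_couples
    return records


def simulate_pedigree(config: SimConfig,
                      rng: np.random.Generator | None = None) -> Pedigree:
    """Multi-family pedigree with exactly the configured family sizes."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    records: list[PedRecord] = []
    for i, size in enumerate(config.family_sizes):
        records.extend(_grow_family(f"F{i + 1}", size, rng))
    return Pedigree(records)


# ---------------------------------------------------------------------------
# Expression and traits
# ---------------------------------------------------------------------------

def _gene_drop(ped: Pedigree, sigma_g2: float, n_traits: int,
               rng: np.random.Generator) -> np.ndarray:
    """Polygenic effects by gene dropping; returns samples x n_traits.

    Founders draw N(0, sigma_g2); each offspring is the parent midpoint
    plus Mendelian-sampling noise N(0, sigma_g2 / 2) (non-inbred form).
    The resulting covariance across the pedigree is 2 K sigma_g2.
    """
    ids = ped.individual_ids
    index = {iid: i for i, iid in enumerate(ids)}
    G = np.zeros((len(ids), n_traits))
    if sigma_g2 == 0:
        return G
    sd_f = np.sqrt(sigma_g2)
    sd_m = np.sqrt(sigma_g2 / 2.0)
    for iid in ped.topological_order():
        rec = ped[iid]
        i = index[iid]
        if rec.is_founder:
            G[i] = rng.normal(0.0, sd_f, size=n_traits)
        else:
            mid = 0.5 * (G[index[rec.father_id]] + G[index[rec.mother_id]])
            G[i] = mid + rng.normal(0.0, sd_m, size=n_traits)
    return G


def _covariates(ped: Pedigree, config: SimConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    ids = ped.individual_ids
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=len(ids))
    sex = np.array([ped[i].sex for i in ids], dtype=float)
    sex[sex == 0] = rng.integers(1, 3, size=int((sex == 0).sum()))
    return pd.DataFrame({"age": age, "sex": sex}, index=pd.Index(ids, name="sample_id"))


def module_assignments(config: SimConfig) -> pd.Series:
    """Probe id -> planted module label ('background' for the rest)."""
    labels = []
    probe_ids = [f"probe{i + 1:05d}" for i in range(config.n_probes)]
    pos = 0
    for m_idx, m in enumerate(config.modules, start=1):
        labels.extend([f"sim_module{m_idx}"] * m.size)
        pos += m.size
    labels.extend(["background"] * (config.n_probes - pos))
    return pd.Series(labels, index=pd.Index(probe_ids, name="probe_id"))


def simulate_expression(
    ped: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Probes-by-samples expression matrix with planted structure."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 22]))
    ids = ped.individual_ids
    n = len(ids)
    P = config.n_probes
    if covariates is None:
        covariates = _covariates(ped, config, rng)
    fam_of = np.array([ped.family_of(i) for i in ids])
    families = ped.family_ids

    X = np.zeros((P, n))
    # polygenic component, vectorized across probes
    X += _gene_drop(ped, config.sigma_g2, P, rng).T
    # shared-family environment
    if config.sigma_v2 > 0:
        for fam in families:
            sel = fam_of == fam
            X[:, sel] += rng.normal(
                0.0, np.sqrt(config.sigma_v2), size=(P, 1)
            )
    # latent-factor modules
    assign = module_assignments(config)
    for m_idx, m in enumerate(config.modules, start=1):
        rows = (assign == f"sim_module{m_idx}").to_numpy()
        lam = np.full(len(families), m.loading if m.shared else 0.0)
        if not m.shared:
            lam[m.home_family] = m.loading
        for f_i, fam in enumerate(families):
            if lam[f_i] == 0:
                continue
            sel = fam_of == fam
            F = rng.normal(size=int(sel.sum()))
            X[np.ix_(rows, sel)] += lam[f_i] * F[None, :]
    # residual noise and covariates
    X += rng.normal(0.0, np.sqrt(config.sigma_e2), size=(P, n))
    X += config.expr_age_effect * covariates["age"].to_numpy()[None, :]
    X += config.expr_sex_effect * (covariates["sex"].to_numpy() - 1.5)[None, :]
    return pd.DataFrame(X, index=assign.index, columns=pd.Index(ids, name="sample_id"))


def causal_probe_ids(config: SimConfig) -> list[str]:
    """Default causal set: one probe per planted module, rest background.

    Mirrors a trait whose generating genes sit in distinct pathways: the
    first probe of each planted module plus background probes until
    ``n_causal`` ids are collected.
    """
    assign = module_assignments(config)
    chosen: list[str] = []
    for m_idx in range(1, len(config.modules) + 1):
        members = assign.index[assign == f"sim_module{m_idx}"]
        if len(members) and len(chosen) < config.n_causal:
            chosen.append(members[0])
    background = assign.index[assign == "background"]
    for pid in background:
        if len(chosen) >= config.n_causal:
            break
        chosen.append(pid)
    if len(chosen) < config.n_causal:
        raise SimulationError("not enough probes for the requested causal set")
    return chosen


def simulate_traits(
    expr: pd.DataFrame,
    ped: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    covariates: pd.DataFrame | None = None,
    causal_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Phenotype table: causal trait (SBP analog), null trait (Q1 analog).

    The causal trait sums ``causal_effect`` times each causal probe's
    expression plus an independent polygenic effect, covariate effects and
    noise; the null trait has the same architecture minus the probe term
    and is independent of all probes given pedigree and covariates.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 33]))
    ids = list(expr.columns)
    if covariates is None:
        covariates = _covariates(ped, config, rng)
    covariates = covariates.loc[ids]
    if causal_ids is None:
        causal_ids = causal_probe_ids(config)
    missing = [c for c in causal_ids if c not in expr.index]
    if missing:
        raise SimulationError(f"causal probe ids absent from expression: {missing[:5]}")

    G = _gene_drop(ped, config.trait_polygenic_var, 2, rng)
    order = {iid: k for k, iid in enumerate(ped.individual_ids)}
    rows = [order[i] for i in ids]
    G = G[rows]
    noise = rng.normal(0.0, np.sqrt(config.trait_noise_var), size=(len(ids), 2))
    cov_part = (config.trait_age_effect * covariates["age"].to_numpy()
                + config.trait_sex_effect * (covariates["sex"].to_numpy() - 1.5))
    causal_part = config.causal_effect * expr.loc[list(causal_ids), ids].sum(axis=0)

    sbp = causal_part.to_numpy() + G[:, 0] + noise[:, 0] + cov_part
    q1 = G[:, 1] + noise[:, 1] + cov_part
    out = pd.DataFrame(
        {"SBP": sbp, "Q1": q1,
         "age": covariates["age"].to_numpy(),
         "sex": covariates["sex"].to_numpy()},
        index=pd.Index(ids, name="sample_id"),
    )
    return out


def simulate_dataset(config: SimConfig | None = None, seed: int | None = None):
    """Full scenario: pedigree, expression, phenotypes, ground truth.

    Returns ``(ped, expr, pheno, truth)`` where ``truth`` records the
    planted module memberships, causal probes and variance components for
    use as test oracles.
    """
    if config is None:
        config = default_config()
    if seed is not None:
        config.seed = seed
    config.validate()
    root = np.random.SeedSequence([config.seed, 7])
    ss_ped, ss_cov, ss_expr, ss_trait = root.spawn(4)
    ped = simulate_pedigree(config, np.random.default_rng(ss_ped))
    covariates = _covariates(ped, config, np.random.default_rng(ss_cov))
    expr = simulate_expression(ped, config, np.random.default_rng(ss_expr),
                               covariates=covariates)
    causal = causal_probe_ids(config)
    pheno = simulate_traits(expr, ped, config, np.random.default_rng(ss_trait),
                            covariates=covariates, causal_ids=causal)
    assign = module_assignments(config)
    truth = {
        "modules": {
            label: list(assign.index[assign == label])
            for label in assign.unique() if label != "background"
        },
        "module_specs": [
            {"size": m.size, "loading": m.loading, "shared": m.shared,
             "home_family": m.home_family}
            for m in config.modules
        ],
        "causal_probes": causal,
        "variance_components": {
            "sigma_g2": config.sigma_g2,
            "sigma_v2": config.sigma_v2,
            "sigma_e2": config.sigma_e2,
        },
        "seed": config.seed,
    }
    return ped, expr, pheno, truth
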