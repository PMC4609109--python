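"""Synthetic expression data with the statistical structure of the study system.

The generator emulates a serial thermal-adaptation experiment: an ancestor
strain and a lineage of evolved strains, each assayed in triplicate at the
regular temperature (``r``), in triplicate at its evolution temperature
(``e``), and in duplicate after a transient heat shock (``hs``).  The default
design is 4 strains x (3 + 3 + 2) = 32 arrays.

The planted structure, all on the log2 scale:

* a *baseline* expression level per gene, shared by every array;
* a large shared *heat-shock response* -- a sparse up-regulon with strong
  induction, a broader repressed component (growth/translation genes go down
  under stress), and a small background perturbation;
* *cumulative genotype effects*: each evolved strain adds an independent
  per-gene increment on top of its predecessor, mirroring the serial lineage;
* *evolution-temperature effects* constructed to be negatively correlated
  with the strain's genotype effect (expression moved by mutations is moved
  back by the growth temperature -- transcriptome homeostasis);
* *negative epistasis*: in evolved strains the combined genotype + heat-shock
  deviation under hs is damped by a factor (1 - e), so the population
  regression slope of the simultaneous change on the additive change is
  exactly 1 - e by construction;
* a *growth rate* per array that decreases with the magnitude of the array's
  expected displacement from its own strain's regular-temperature steady
  state (heat shock and high growth temperatures carry a fitness cost;
  adaptive mutations do not), planting the growth axis that the leading
  principal component tracks.

Replicate noise is i.i.d. Normal(0, noise_sd) per gene and array.  Identical
seed and configuration give bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import validate_meta

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_design",
    "generate_truth",
    "generate_expression",
    "generate_genesets",
    "simulate",
]

DEFAULT_STRAINS = ("Anc", "41B", "43B", "45L")
DEFAULT_EVOLUTION_TEMPS = {"41B": 41.2, "43B": 43.2, "45L": 44.8}


@dataclass
class SimulationConfig:
    """Effect-size and design settings for the synthetic generator.

    The defaults are the study conditions: 4 strains, 3/3/2 replicates,
    ~4,000 genes, a dominant shared heat-shock response, modest cumulative
    genotype effects, an inverse genotype/temperature correlation of -0.6
    and a 25% multiplicative epistatic cancellation.
    """

    n_genes: int = 4000
    strains: tuple[str, ...] = DEFAULT_STRAINS
    ancestor: str = "Anc"
    n_steady_reps: int = 3
    n_hs_reps: int = 2
    include_ancestor_e: bool = True
    regular_temp: float = 36.9
    hs_temp: float = 44.8
    evolution_temps: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVOLUTION_TEMPS)
    )
    # log2 effect sizes
    baseline_sd: float = 1.5
    sigma_g: float = 0.6            # per-increment genotype effect sd
    hs_up_frac: float = 0.06        # heat-shock regulon (strong induction)
    hs_up_mean: float = 5.0
    hs_up_sd: float = 1.5
    hs_down_frac: float = 0.12      # repressed growth/translation component
    hs_down_mean: float = -2.5
    hs_down_sd: float = 1.0
    hs_background_sd: float = 0.5
    sigma_t: float = 0.45           # evolution-temperature effect sd
    gt_anticorr: float = -0.6       # target corr(genotype_effect, temp_effect)
    hs_alignment: dict[str, float] | None = None  # optional per-strain beta
    epistasis_coef: float = 0.25    # fraction of combined effect cancelled
    noise_sd: float = 0.2           # replicate noise sd per array
    # planted growth-rate model: g = growth_max - growth_cost * RMS(deviation)
    growth_max: float = 0.7
    growth_cost: float = 0.35
    growth_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not (0.0 <= self.epistasis_coef < 1.0):
            raise ValueError("epistasis_coef must be in [0, 1)")
        if not abs(self.gt_anticorr) < 1.0:
            raise ValueError("|gt_anticorr| must be < 1")
        for name in ("baseline_sd", "sigma_g", "sigma_t", "noise_sd",
                     "hs_up_sd", "hs_down_sd", "hs_background_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not (0.0 <= self.hs_up_frac <= 1.0 and 0.0 <= self.hs_down_frac <= 1.0
                and self.hs_up_frac + self.hs_down_frac <= 1.0):
            raise ValueError("heat-shock fractions must be in [0,1] and sum to <= 1")
        if self.ancestor not in self.strains:
            raise ValueError(f"ancestor {self.ancestor!r} not among strains {self.strains}")

    def evolved(self) -> list[str]:
        return [s for s in self.strains if s != self.ancestor]

    def evolution_temp(self, strain: str) -> float:
        """Evolution-stimulating temperature for a strain's e-condition.

        The ancestor has no evolution temperature of its own; its e-arrays
        (when enabled) are assayed at the heat-shock/reference-high
        temperature.
        """
        return self.evolution_temps.get(strain, self.hs_temp)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strains"] = list(self.strains)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "strains" in d:
            d["strains"] = tuple(d["strains"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind one synthetic dataset."""

    baseline: pd.Series                 # per-gene log2 baseline
    hs_effect: pd.Series                # per-gene heat-shock response
    genotype_effect: pd.DataFrame       # genes x strains, cumulative
    temp_effect: pd.DataFrame           # genes x strains
    epistasis_coef: float
    gt_anticorr: float
    noise_sd: float
    seed: int
    hs_regulon: list[str] = field(default_factory=list)  # planted up-regulon
    ancestor: str = "Anc"

    @property
    def gene_ids(self) -> pd.Index:
        return self.baseline.index

    def to_json(self, path) -> None:
        payload = {
            "epistasis_coef": self.epistasis_coef,
            "gt_anticorr": self.gt_anticorr,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "ancestor": self.ancestor,
            "hs_regulon": list(self.hs_regulon),
            "gene_ids": list(self.gene_ids),
            "baseline": self.baseline.tolist(),
            "hs_effect": self.hs_effect.tolist(),
            "genotype_effect": {s: self.genotype_effect[s].tolist()
                                for s in self.genotype_effect.columns},
            "temp_effect": {s: self.temp_effect[s].tolist()
                            for s in self.temp_effect.columns},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        genes = pd.Index(payload["gene_ids"], name="gene_id")
        return cls(
            baseline=pd.Series(payload["baseline"], index=genes),
            hs_effect=pd.Series(payload["hs_effect"], index=genes),
            genotype_effect=pd.DataFrame(payload["genotype_effect"], index=genes),
            temp_effect=pd.DataFrame(payload["temp_effect"], index=genes),
            epistasis_coef=payload["epistasis_coef"],
            gt_anticorr=payload["gt_anticorr"],
            noise_sd=payload["noise_sd"],
            seed=payload["seed"],
            hs_regulon=payload["hs_regulon"],
            ancestor=payload["ancestor"],
        )


@dataclass
class SyntheticDataset:
    matrix: pd.DataFrame
    meta: pd.DataFrame
    genesets: dict[str, list[str]]
    truth: SyntheticTruth
    config: SimulationConfig


def generate_design(
    n_steady_reps: int = 3,
    n_hs_reps: int = 2,
    strains: tuple[str, ...] = DEFAULT_STRAINS,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Lay out the array design: one row of sample metadata per array.

    Each strain receives ``n_steady_reps`` arrays at the regular temperature
    (r), ``n_steady_reps`` at its evolution temperature (e) and ``n_hs_reps``
    heat-shock arrays (hs).  With the defaults this is the 32-array design.
    When the config disables the ancestor's e-condition, those arrays are
    omitted.
    """
    if n_steady_reps < 1 or n_hs_reps < 1:
        raise ValueError("replicate counts must be >= 1")
    if not strains:
        raise ValueError("strain list must be non-empty")
    if config is None:
        unknown = [s for s in strains if s not in DEFAULT_STRAINS]
        if unknown:
            raise ValueError(
                f"unknown strain label(s): {unknown}; custom strains require "
                "an explicit SimulationConfig naming them"
            )
        config = SimulationConfig(strains=tuple(strains))
    else:
        unknown = [s for s in strains if s not in set(config.strains)]
        if unknown:
            raise ValueError(f"unknown strain label(s): {unknown}")
    rows = []
    for strain in strains:
        plan = [("r", n_steady_reps, config.regular_temp)]
        if strain != config.ancestor or config.include_ancestor_e:
            plan.append(("e", n_steady_reps, config.evolution_temp(strain)))
        plan.append(("hs", n_hs_reps, config.hs_temp))
        for condition, n_reps, temp in plan:
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{strain}_{condition}_{rep}",
                        "strain": strain,
                        "condition": condition,
                        "replicate": rep,
                        "temperature_C": temp,
                        "growth_rate": np.nan,
                    }
                )
    return validate_meta(pd.DataFrame(rows))


def generate_truth(
    n_genes: int | None = None,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw the ground-truth per-gene effects for one synthetic dataset.

    Genotype effects accumulate along the evolved-strain lineage: each strain
    after the ancestor adds an independent Normal(0, sigma_g) increment to its
    predecessor's effect.  The evolution-temperature effect of each evolved
    strain is a correlated Gaussian mixture with its genotype effect so that
    the realized Pearson correlation approaches ``gt_anticorr``; optionally a
    per-strain multiple of the heat-shock response is added (``hs_alignment``)
    to plant an increasing alignment between temperature- and heat-shock-
    mediated changes.
    """
    config = config or SimulationConfig()
    if n_genes is not None and n_genes != config.n_genes:
        config = dataclasses.replace(config, n_genes=n_genes)
    n = config.n_genes
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7EA]))
    width = max(4, len(str(n)))
    genes = pd.Index([f"g{i:0{width}d}" for i in range(1, n + 1)], name="gene_id")

    baseline = pd.Series(rng.normal(0.0, config.baseline_sd, n), index=genes)

    # Heat-shock response: sparse strong up-regulon, broader repressed block,
    # small background wobble everywhere else.
    n_up = int(round(config.hs_up_frac * n))
    n_down = int(round(config.hs_down_frac * n))
    perm = rng.permutation(n)
    up_idx, down_idx = perm[:n_up], perm[n_up:n_up + n_down]
    hs = rng.normal(0.0, config.hs_background_sd, n)
    hs[up_idx] = rng.normal(config.hs_up_mean, config.hs_up_sd, n_up)
    hs[down_idx] = rng.normal(config.hs_down_mean, config.hs_down_sd, n_down)
    hs_effect = pd.Series(hs, index=genes)
    regulon = list(genes[np.sort(up_idx)])

    genotype = pd.DataFrame(0.0, index=genes, columns=list(config.strains))
    cumulative = np.zeros(n)
    for strain in config.evolved():
        cumulative = cumulative + rng.normal(0.0, config.sigma_g, n)
        genotype[strain] = cumulative

    rho = config.gt_anticorr
    temp = pd.DataFrame(0.0, index=genes, columns=list(config.strains))
    for strain in config.strains:
        z = rng.normal(0.0, 1.0, n)
        g = genotype[strain].to_numpy()
        g_sd = g.std()
        if strain == config.ancestor or g_sd == 0.0:
            t = config.sigma_t * z
        else:
            t = config.sigma_t * (rho * (g - g.mean()) / g_sd + np.sqrt(1 - rho**2) * z)
        if config.hs_alignment:
            beta = config.hs_alignment.get(strain, 0.0)
            if beta:
                t = t + beta * (hs - hs.mean())
        temp[strain] = t

    return SyntheticTruth(
        baseline=baseline,
        hs_effect=hs_effect,
        genotype_effect=genotype,
        temp_effect=temp,
        epistasis_coef=config.epistasis_coef,
        gt_anticorr=config.gt_anticorr,
        noise_sd=config.noise_sd,
        seed=int(seed),
        hs_regulon=regulon,
        ancestor=config.ancestor,
    )


def expected_profile(truth: SyntheticTruth, strain: str, condition: str) -> pd.Series:
    """Noise-free expected log2 expression for one (strain, condition)."""
    if strain not in truth.genotype_effect.columns:
        raise ValueError(f"truth does not cover strain {strain!r}")
    g = truth.genotype_effect[strain]
    if condition == "r":
        shift = g
    elif condition == "e":
        shift = g + truth.temp_effect[strain]
    elif condition == "hs":
        if strain == truth.ancestor:
            shift = truth.hs_effect
        else:
            shift = (1.0 - truth.epistasis_coef) * (g + truth.hs_effect)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return truth.baseline + shift


def generate_expression(
    truth: SyntheticTruth,
    design: pd.DataFrame,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Realize noisy arrays from a truth object and a design.

    Log2 expression of gene g on array (strain s, condition c) is the
    expected profile of (s, c) plus Normal(0, noise_sd) noise.  Evolved
    strains' hs arrays carry the damped combined effect
    (1 - e) * (genotype + heat-shock), which makes the population regression
    slope of the simultaneous change on the additive change exactly 1 - e.

    Each array is also assigned a planted growth rate,
    ``growth_max - growth_cost * RMS(expected displacement from the strain's
    own r-state)`` plus a small jitter: stress- or temperature-displaced
    states (heat shock, growth at high temperature) grow slowly, while
    genotype-mediated steady-state differences carry no cost -- the
    mutations are adaptive.  For an e-array the displacement is exactly the
    strain's temp_effect, so its magnitude scales the planted fitness
    variable.
    """
    if design.empty:
        raise ValueError("design must be non-empty")
    config = config or SimulationConfig()
    missing = sorted(set(design["strain"]) - set(truth.genotype_effect.columns))
    if missing:
        raise ValueError(f"truth does not cover strains {missing}")
    if len(truth.gene_ids) != len(truth.baseline):
        raise ValueError("truth gene dimensions disagree")
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else int(seed), 0xE49])
    )
    n = len(truth.gene_ids)
    columns: dict[str, np.ndarray] = {}
    growth: list[float] = []
    for _, row in design.iterrows():
        mean = expected_profile(truth, row["strain"], row["condition"])
        steady = expected_profile(truth, row["strain"], "r")
        displacement = mean - steady
        rms = float(np.sqrt(np.mean(np.square(displacement))))
        g_rate = config.growth_max - config.growth_cost * rms
        g_rate += float(rng.normal(0.0, config.growth_noise_sd))
        growth.append(max(g_rate, 0.01))
        noise = rng.normal(0.0, truth.noise_sd, n)
        columns[row["sample_id"]] = mean.to_numpy() + noise
    matrix = pd.DataFrame(columns, index=truth.gene_ids)
    meta = design.copy().reset_index(drop=True)
    meta["growth_rate"] = growth
    return SyntheticDataset(matrix=matrix, meta=meta, genesets={}, truth=truth,
                            config=config)


def generate_genesets(
    genes,
    n_sets: int = 20,
    size_range: tuple[int, int] = (16, 50),
    planted: dict | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Sample named gene sets, optionally with one planted enriched set.

    Random sets draw members uniformly without replacement; sizes are uniform
    in ``size_range``.  A ``planted`` spec -- ``{"name", "top_genes", "odds",
    "size"}`` -- adds a set whose members are drawn with ``odds``-fold
    preference from ``top_genes`` (e.g. the true heat-shock regulon), giving
    a known over-representation signal for enrichment tests.
    """
    genes = list(genes)
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(genes)):
        raise ValueError(f"size_range {size_range} infeasible for {len(genes)} genes")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E5]))
    width = max(3, len(str(n_sets)))
    sets: dict[str, list[str]] = {}
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"set_{i:0{width}d}"] = [genes[j] for j in np.sort(members)]
    if planted:
        name = planted.get("name", "planted")
        top = [g for g in planted["top_genes"] if g in set(genes)]
        odds = float(planted.get("odds", 10.0))
        size = int(planted.get("size", max(lo, min(hi, 30))))
        if size > len(genes):
            raise ValueError("planted set larger than gene universe")
        weights = np.ones(len(genes))
        top_set = set(top)
        for j, g in enumerate(genes):
            if g in top_set:
                weights[j] = odds
        weights = weights / weights.sum()
        members = rng.choice(len(genes), size=size, replace=False, p=weights)
        sets[name] = [genes[j] for j in np.sort(members)]
    return sets


def simulate(config: SimulationConfig | None = None, seed: int = 0,
             n_sets: int = 20, planted_odds: float = 10.0) -> SyntheticDataset:
    """End-to-end dataset: design + truth + expression + gene sets.

    The planted gene set (``"planted_hs"``) is drawn with ``planted_odds``
    preference from the 100 genes with the strongest true heat-shock
    response, giving a known over-representation signal.
    """
    config = config or SimulationConfig()
    design = generate_design(config.n_steady_reps, config.n_hs_reps,
                             config.strains, config=config)
    truth = generate_truth(config=config, seed=seed)
    dataset = generate_expression(truth, design, config=config)
    strongest = list(truth.hs_effect.abs().sort_values(ascending=False).index[:100])
    planted = {"name": "planted_hs", "top_genes": strongest,
               "odds": planted_odds, "size": 50}
    dataset.genesets = generate_genesets(
        truth.gene_ids, n_sets=n_sets, planted=planted,
        seed=seed + 1_000_003,
    )
    return dataset
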