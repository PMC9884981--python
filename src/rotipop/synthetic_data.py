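"""Synthetic inputs for every pipeline stage.

The generators emulate a rotifer culture study: replicate cohorts of ten
neonates censused every 8 h for survival and reproduction, logistic
population-density trajectories observed daily, and 16S OTU count tables
for three culture media (sterile, sterile + lake bacterioplankton, natural
lake water) sampled at four growth stages.

Cohort survival is a Bernoulli chain over an age-indexed hazard schedule;
offspring are Poisson per surviving mother with an age-indexed mean (a
zero-variance deterministic switch exists for exact tests).  OTU counts
come from a latent Gaussian copula over log-normal abundances — which
preserves planted rank correlations through the multinomial observation
layer — closed to a composition and observed as a multinomial draw at a
sampled sequencing depth.  A fraction of OTUs carries a chloroplast
lineage so the cleaning stage has something to remove.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .demography import CohortTable, DensityTable
from .errors import InvalidConfigError
from .otu_pipeline import OtuTable

__all__ = [
    "CohortSimConfig",
    "OtuSimConfig",
    "CompositionEffect",
    "simulate_cohort",
    "simulate_density",
    "simulate_otu_table",
    "simulate_tree",
    "default_cohort_config",
    "default_otu_config",
]

# Study-like age schedules on an 8-h census grid (18 intervals, 144 h max
# lifespan): no mortality for the first 64 h then a rising hazard, first
# reproduction after 24 h, peak fecundity mid-life, senescent decline.
DEFAULT_HAZARD = np.array(
    [0.0] * 8 + [0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
)
DEFAULT_FECUNDITY = np.array(
    [0.0, 0.0, 0.0, 1.0, 1.8, 2.2, 2.4, 2.4, 2.2, 1.8, 1.2, 0.8, 0.5, 0.3, 0.2, 0.1, 0.0, 0.0]
)

_ORDER_POOL = [
    "Burkholderiales", "Pseudomonadales", "Micrococcales", "Caulobacterales",
    "Bifidobacteriales", "Flavobacteriales", "Rhizobiales", "Sphingomonadales",
    "Exiguobacterales", "Frankiales", "Bacteroidales", "Oscillospirales",
    "Solirubrobacterales", "Microtrichales", "Rickettsiales", "Synechococcales",
]
_PHYLUM_OF = {
    "Burkholderiales": ("Proteobacteria", "Gammaproteobacteria"),
    "Pseudomonadales": ("Proteobacteria", "Gammaproteobacteria"),
    "Micrococcales": ("Actinobacteriota", "Actinobacteria"),
    "Caulobacterales": ("Proteobacteria", "Alphaproteobacteria"),
    "Bifidobacteriales": ("Actinobacteriota", "Actinobacteria"),
    "Flavobacteriales": ("Bacteroidota", "Bacteroidia"),
    "Rhizobiales": ("Proteobacteria", "Alphaproteobacteria"),
    "Sphingomonadales": ("Proteobacteria", "Alphaproteobacteria"),
    "Exiguobacterales": ("Firmicutes", "Bacilli"),
    "Frankiales": ("Actinobacteriota", "Actinobacteria"),
    "Bacteroidales": ("Bacteroidota", "Bacteroidia"),
    "Oscillospirales": ("Firmicutes", "Clostridia"),
    "Solirubrobacterales": ("Actinobacteriota", "Thermoleophilia"),
    "Microtrichales": ("Actinobacteriota", "Acidimicrobiia"),
    "Rickettsiales": ("Proteobacteria", "Alphaproteobacteria"),
    "Synechococcales": ("Cyanobacteria", "Cyanophyceae"),
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Design of a simulated cohort life-table experiment.

    ``hazard_schedule[i]`` is the death probability of a mother during the
    i-th census interval; ``fecundity_schedule[i]`` the mean female
    offspring per surviving mother in that interval.  ``mixis_prob`` is the
    probability any single offspring is mictic (sexual).
    """

    n_individuals: int = 10
    n_replicates: int = 3
    census_interval: float = 8.0
    hazard_schedule: np.ndarray = field(default_factory=lambda: DEFAULT_HAZARD.copy())
    fecundity_schedule: np.ndarray = field(
        default_factory=lambda: DEFAULT_FECUNDITY.copy()
    )
    mixis_prob: float = 0.03
    deterministic_fecundity: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        hz = np.asarray(self.hazard_schedule, dtype=float)
        fc = np.asarray(self.fecundity_schedule, dtype=float)
        object.__setattr__(self, "hazard_schedule", hz)
        object.__setattr__(self, "fecundity_schedule", fc)
        if hz.size == 0 or fc.size == 0:
            raise InvalidConfigError("empty hazard or fecundity schedule")
        if hz.size != fc.size:
            raise InvalidConfigError("hazard and fecundity schedules differ in length")
        if np.any((hz < 0) | (hz > 1)):
            raise InvalidConfigError("hazard probabilities must lie in [0, 1]")
        if np.any(fc < 0):
            raise InvalidConfigError("fecundity means must be non-negative")
        if not 0 <= self.mixis_prob <= 1:
            raise InvalidConfigError("mixis_prob must lie in [0, 1]")
        if self.n_individuals < 1 or self.n_replicates < 1:
            raise InvalidConfigError("need at least one individual and one replicate")

    def expected_life_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ages, l_x, m_x) implied by the schedules — the generating truth."""
        hz = self.hazard_schedule
        n = hz.size
        ages = self.census_interval * np.arange(n + 1)
        l_x = np.concatenate([[1.0], np.cumprod(1.0 - hz)])
        m_x = np.concatenate([self.fecundity_schedule, [0.0]])
        return ages, l_x, m_x


def default_cohort_config(seed: int = 0, **overrides) -> CohortSimConfig:
    return CohortSimConfig(seed=seed, **overrides)


def simulate_cohort(config: CohortSimConfig) -> CohortTable:
    """Simulate replicate cohorts censused on a uniform age grid.

    Survival is an independent Bernoulli draw per mother per interval with
    the scheduled hazard; offspring are Poisson with mean ``n_alive * m``
    (or exactly ``round(n_alive * m)`` in deterministic mode); each
    offspring is mictic independently with ``mixis_prob``.
    """
    rng = np.random.default_rng(config.seed)
    n_int = config.hazard_schedule.size
    times = config.census_interval * np.arange(n_int + 1)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        alive = config.n_individuals
        for i, t in enumerate(times):
            if i < n_int:
                mean_births = alive * config.fecundity_schedule[i]
                if config.deterministic_fecundity:
                    births = int(round(mean_births))
                else:
                    births = int(rng.poisson(mean_births)) if mean_births > 0 else 0
                mictic = int(rng.binomial(births, config.mixis_prob)) if births else 0
            else:
                births = mictic = 0
            rows.append(
                {
                    "replicate": rep,
                    "time_h": float(t),
                    "survivors": int(alive),
                    "births_total": births,
                    "births_mictic": mictic,
                }
            )
            if i < n_int and alive > 0:
                deaths = rng.binomial(alive, config.hazard_schedule[i])
                alive -= int(deaths)
    return CohortTable(pd.DataFrame(rows), interval=config.census_interval)


def simulate_density(
    r_true: float,
    K: float,
    n0: float,
    days: int,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
) -> DensityTable:
    """Logistic density trajectory with multiplicative lognormal noise.

    The mean path is ``N(t) = K / (1 + (K/n0 - 1) exp(-r t))``; each
    observation is multiplied by a lognormal factor with unit mean and
    coefficient of variation ``noise_cv`` (densities stay positive and the
    error scales with abundance).
    """
    if n0 <= 0 or K <= 0:
        raise InvalidConfigError("n0 and K must be positive")
    if K <= n0:
        raise InvalidConfigError("carrying capacity K must exceed n0")
    if r_true <= 0:
        raise InvalidConfigError("r_true must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(days + 1, dtype=float)
    mean_path = K / (1.0 + (K / n0 - 1.0) * np.exp(-r_true * t))
    sigma2 = np.log1p(noise_cv**2)
    rows = []
    for rep in range(1, n_replicates + 1):
        if noise_cv > 0:
            factors = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=t.size)
        else:
            factors = np.ones_like(t)
        dens = mean_path * factors
        for d, v in zip(t, dens):
            rows.append({"replicate": rep, "day": float(d), "density": float(v)})
    return DensityTable(pd.DataFrame(rows), n0=n0)


@dataclass(frozen=True)
class CompositionEffect:
    """Multiplicative log-abundance shift for an OTU block in one design cell.

    ``group``/``stage`` of ``None`` match every level; ``log_shift`` is added
    to the latent log-abundance of the listed OTU indices.
    """

    group: str | None
    stage: str | None
    otu_indices: tuple
    log_shift: float


@dataclass(frozen=True)
class OtuSimConfig:
    """Design of a simulated samples x OTUs sequencing experiment."""

    n_samples_per_cell: int = 4
    groups: tuple = ("SE", "SEB", "NW")
    stages: tuple = ("T1", "T2", "T3", "T4")
    n_otus: int = 120
    base_composition: np.ndarray | None = None
    effects: tuple = ()
    corr_block: tuple = ()  # OTU indices sharing the latent correlation
    latent_corr: np.ndarray | None = None
    gradient_loadings: np.ndarray | None = None  # per-OTU response to a
    # per-sample community gradient (drives inter-taxon correlations)
    log_sd: float = 1.0  # latent log-abundance SD
    depth_range: tuple = (5000, 10000)
    chloroplast_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 2:
            raise InvalidConfigError("need at least two OTUs")
        if self.base_composition is not None:
            bc = np.asarray(self.base_composition, dtype=float)
            object.__setattr__(self, "base_composition", bc)
            if bc.size != self.n_otus:
                raise InvalidConfigError("base_composition length != n_otus")
            if np.any(bc <= 0) or not np.isclose(bc.sum(), 1.0):
                raise InvalidConfigError("base_composition must be positive and sum to 1")
        if self.latent_corr is not None:
            C = np.asarray(self.latent_corr, dtype=float)
            object.__setattr__(self, "latent_corr", C)
            if C.shape != (len(self.corr_block), len(self.corr_block)):
                raise InvalidConfigError("latent_corr shape != corr_block size")
            if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise InvalidConfigError("latent_corr must be symmetric with unit diagonal")
            if np.linalg.matrix_rank(C) < C.shape[0]:
                raise InvalidConfigError("latent_corr is singular")
        if self.gradient_loadings is not None:
            gl = np.asarray(self.gradient_loadings, dtype=float)
            object.__setattr__(self, "gradient_loadings", gl)
            if gl.size != self.n_otus:
                raise InvalidConfigError("gradient_loadings length != n_otus")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise InvalidConfigError("depth_range must satisfy 1 <= min <= max")
        if not 0 <= self.chloroplast_frac < 1:
            raise InvalidConfigError("chloroplast_frac must lie in [0, 1)")


def default_otu_config(seed: int = 0, **overrides) -> OtuSimConfig:
    """Study-shaped default: 3 groups x 4 stages x 4 replicates, a planted
    rho=0.8 block of eight taxa, group/stage composition shifts, rare
    group-exclusive OTU blocks (most numerous in the natural-water group)
    and a 10% chloroplast fraction."""
    rng = np.random.default_rng(seed)
    n_otus = overrides.pop("n_otus", 150)
    if n_otus < 60:
        raise InvalidConfigError("default design needs n_otus >= 60")
    base = rng.lognormal(0.0, 1.5, size=n_otus)
    # the last 30 OTUs are rare, group-exclusive taxa; blocks below scale
    # with the core (shared) OTU count
    core = n_otus - 30
    se_only = tuple(range(core, core + 5))
    seb_only = tuple(range(core + 5, core + 15))
    nw_only = tuple(range(core + 15, n_otus))
    base[core:] *= 0.2
    base /= base.sum()
    block = tuple(range(10, 18))
    corr = np.full((len(block), len(block)), 0.8)
    np.fill_diagonal(corr, 1.0)
    absent = -15.0  # log shift that silences a block outside its home group
    effects = (
        # the sterile medium is dominated by a few resident families while
        # bacterioplankton-exposed media carry extra diversity in one block
        CompositionEffect("SE", None, tuple(range(0, 10)), 1.2),
        CompositionEffect("SEB", None, tuple(range(20, min(35, core))), 1.0),
        CompositionEffect("NW", None, tuple(range(20, min(50, core))), 1.2),
        # late growth stages shift a genus block up
        CompositionEffect(None, "T3", tuple(range(core - 5, core)), 1.5),
        CompositionEffect(None, "T4", tuple(range(core - 5, core)), 0.8),
        # group-exclusive rare taxa
        CompositionEffect("SEB", None, se_only, absent),
        CompositionEffect("NW", None, se_only, absent),
        CompositionEffect("SE", None, seb_only, absent),
        CompositionEffect("NW", None, seb_only, absent),
        CompositionEffect("SE", None, nw_only, absent),
        CompositionEffect("SEB", None, nw_only, absent),
    )
    # a community-state gradient with order-coherent loadings: taxonomy is
    # assigned round-robin over the order pool, so loading by (i mod pool)
    # makes whole orders co-vary and the co-occurrence network non-trivial
    n_pool = len(_ORDER_POOL)
    per_order = np.zeros(n_pool)
    per_order[:6] = 1.2
    per_order[6:10] = -1.0
    loadings = per_order[np.arange(n_otus) % n_pool]
    return OtuSimConfig(
        n_otus=n_otus,
        base_composition=base,
        effects=effects,
        corr_block=block,
        latent_corr=corr,
        gradient_loadings=loadings,
        seed=seed,
        **overrides,
    )


def _make_taxonomy(n_otus: int, n_chloro: int, rng: np.random.Generator) -> list[str]:
    """7-rank semicolon lineages; the first n_chloro OTUs are chloroplast."""
    lineages = []
    for i in range(n_otus):
        if i < n_chloro:
            lineages.append(
                "d__Bacteria;p__Cyanobacteria;c__Cyanophyceae;o__Chloroplast;"
                "f__Chloroplast;g__Chloroplast;s__unclassified"
            )
            continue
        order = _ORDER_POOL[i % len(_ORDER_POOL)]
        phylum, klass = _PHYLUM_OF[order]
        # some lineages stop at order/family to exercise unclassified handling
        depth_draw = rng.random()
        fam = f"f__{order[:-4]}aceae" if depth_draw > 0.15 else "f__"
        gen = f"g__{order[:-4]}a{i}" if depth_draw > 0.35 else "g__"
        lineages.append(
            f"d__Bacteria;p__{phylum};c__{klass};o__{order};{fam};{gen};s__"
        )
    return lineages


def simulate_otu_table(config: OtuSimConfig) -> tuple[OtuTable, dict]:
    """Draw an OTU count table plus the ground truth that generated it.

    Latent log-abundances are ``log(base) + design effects + log_sd * z``
    with ``z`` standard normal, correlated inside ``corr_block`` via the
    Cholesky factor of ``latent_corr`` (a Gaussian copula on log-normal
    abundances).  Softmax closure gives the composition; counts are a
    multinomial draw at a depth uniform on ``depth_range``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_otus
    base = config.base_composition
    if base is None:
        base = np.full(n, 1.0 / n)
    log_base = np.log(base)
    n_chloro = int(round(config.chloroplast_frac * n))
    taxonomy = _make_taxonomy(n, n_chloro, rng)

    chol = None
    block = np.asarray(config.corr_block, dtype=int)
    if config.latent_corr is not None and block.size:
        chol = np.linalg.cholesky(config.latent_corr)

    sample_rows = []
    meta_rows = []
    truth_depths = {}
    for group in config.groups:
        for stage in config.stages:
            for rep in range(1, config.n_samples_per_cell + 1):
                sid = f"{group}_{stage}_r{rep}"
                z = rng.standard_normal(n)
                if chol is not None:
                    z[block] = chol @ rng.standard_normal(block.size)
                log_ab = log_base + config.log_sd * z
                if config.gradient_loadings is not None:
                    log_ab = log_ab + config.gradient_loadings * rng.standard_normal()
                for eff in config.effects:
                    if (eff.group is None or eff.group == group) and (
                        eff.stage is None or eff.stage == stage
                    ):
                        log_ab[np.asarray(eff.otu_indices, dtype=int)] += eff.log_shift
                comp = np.exp(log_ab - log_ab.max())
                comp /= comp.sum()
                depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
                counts = rng.multinomial(depth, comp)
                sample_rows.append(counts)
                meta_rows.append(
                    {"sample_id": sid, "group": group, "stage": stage, "replicate": rep}
                )
                truth_depths[sid] = depth

    otu_ids = [f"OTU{i + 1}" for i in range(n)]
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    counts = pd.DataFrame(
        np.vstack(sample_rows), index=metadata.index, columns=otu_ids, dtype=int
    )
    table = OtuTable(
        counts=counts,
        taxonomy=pd.Series(taxonomy, index=otu_ids, name="taxonomy"),
        metadata=metadata,
    )
    truth = {
        "base_composition": base.tolist(),
        "chloroplast_otus": otu_ids[:n_chloro],
        "corr_block": [otu_ids[i] for i in block],
        "latent_corr": None
        if config.latent_corr is None
        else np.asarray(config.latent_corr).tolist(),
        "effects": [
            {
                "group": e.group,
                "stage": e.stage,
                "otus": [otu_ids[i] for i in e.otu_indices],
                "log_shift": e.log_shift,
            }
            for e in config.effects
        ],
        "depths": truth_depths,
        "seed": config.seed,
    }
    return table, truth


def simulate_tree(otu_ids, seed: int = 0) -> TreeNode:
    """Random bifurcating rooted tree over the given tip labels.

    Built by repeated random pairwise joins (a coalescent-style topology)
    with exponential branch lengths; every branch length is positive.
    """
    otu_ids = list(otu_ids)
    if len(otu_ids) < 2:
        raise InvalidConfigError("need at least two tip identifiers")
    if len(set(otu_ids)) != len(otu_ids):
        raise InvalidConfigError("duplicate tip identifiers")
    rng = np.random.default_rng(seed)
    nodes = [f"{name}:{rng.exponential(0.5) + 1e-3:.6f}" for name in otu_ids]
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(i), int(j)
        blen = rng.exponential(0.5) + 1e-3
        merged = f"({nodes[i]},{nodes[j]}):{blen:.6f}"
        keep = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes = keep + [merged]
    # the root carries no edge of its own
    newick = f"({nodes[0]},{nodes[1]});" if len(nodes) == 2 else nodes[0] + ";"
    return TreeNode.read(io.StringIO(newick))
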