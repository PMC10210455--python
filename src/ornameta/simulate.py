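"""Synthetic effect-size datasets with the exact structure the model assumes.

The generator draws a Yule species tree, species effects that are correlated
according to the Brownian matrix of that tree, independent species-, study-
and observation-level effects, categorical moderators with optional level
effects, per-effect host sample sizes, Fisher-z sampling error (variance
``1/(n-3)``) that is compound-symmetrically correlated within an experiment
(same host individuals), and an optional significance-censoring step that
turns nonsignificant effects into "directionless" records — emulating how
such results reach the literature without a sign.

True values are generated on the Fisher-z scale; the observed correlation is
``r = tanh(z)``.  Ground truth is retained for parameter-recovery tests.

Default magnitudes echo a large cross-species ornament-parasite synthesis:
83 species, ~1.9 studies per species, ~2.9 effects per study (k ~= 460),
variance components {phylogeny 0.005, species 0.010, study 0.012,
observation 0.017} (z² units) and a grand mean of -0.084 (z units).
Censoring is off by default — the default configuration is the well-specified
model the estimator assumes; :func:`study_like_params` switches censoring on.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .data import Dataset, impute_directionless, r_sampling_variance
from .phylo import brownian_correlation, grafen_transform, set_unit_branch_lengths


@dataclass
class ModeratorSim:
    """Sampling scheme and true level effects (z units) for one moderator."""

    levels: tuple[str, ...]
    weights: tuple[float, ...]
    effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.levels) != len(self.weights):
            raise ValueError("levels and weights must align")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("moderator sampling weights must sum to 1")


def default_moderators() -> dict[str, ModeratorSim]:
    """Realistic label sets for the twelve moderators; all effects zero."""
    return {
        "host_taxon": ModeratorSim(
            ("arachnid", "insect", "fish", "amphibian", "reptile", "bird", "mammal"),
            (0.03, 0.12, 0.25, 0.05, 0.05, 0.40, 0.10),
        ),
        "host_sex": ModeratorSim(("male", "female"), (0.8, 0.2)),
        "paternal_care": ModeratorSim(("yes", "no"), (0.4, 0.6)),
        "parasite_taxon": ModeratorSim(
            ("virus", "bacterium", "protist", "nematode", "platyhelminth", "arthropod"),
            (0.05, 0.05, 0.25, 0.25, 0.15, 0.25),
        ),
        "parasite_type": ModeratorSim(("endoparasite", "ectoparasite"), (0.6, 0.4)),
        "transmission_risk": ModeratorSim(("low", "medium", "high"), (0.4, 0.3, 0.3)),
        "mate_choice_evidence": ModeratorSim(("yes", "no"), (0.5, 0.5)),
        "dynamism_score": ModeratorSim(("0", "1", "2"), (0.10, 0.35, 0.55)),
        # levels/weights unused: derived from dynamism_score (2 <-> dynamic)
        "dynamism_binary": ModeratorSim(("static", "dynamic"), (0.45, 0.55)),
        "parasite_measurement": ModeratorSim(
            ("intensity", "presence_absence", "experimental_group"), (0.6, 0.25, 0.15)
        ),
        "uninfected_present": ModeratorSim(("yes", "no"), (0.6, 0.4)),
        "study_type": ModeratorSim(
            ("observational", "manipulation", "resistance"), (0.7, 0.15, 0.15)
        ),
    }


@dataclass
class SimParams:
    """Generating parameters of a synthetic effect-size dataset."""

    n_species: int = 83
    birth_rate: float = 1.0
    studies_per_species: float = 1.7  # Poisson mean, min 1
    effects_per_study: float = 2.9  # Poisson mean, min 1
    sigma2: dict[str, float] = field(
        default_factory=lambda: {
            "phylogeny": 0.005,
            "species": 0.010,
            "study": 0.012,
            "obs": 0.017,
        }
    )
    beta0: float = -0.084  # grand mean, z units
    moderators: dict[str, ModeratorSim] = field(default_factory=default_moderators)
    n_meanlog: float = 3.3  # per-effect host sample size ~ lognormal
    n_sdlog: float = 0.6
    n_min: int = 10
    n_max: int = 1000
    rho_within: float = 0.5  # sampling correlation within an experiment
    censor_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 0 for s in self.sigma2.values()):
            raise ValueError("variance components must be non-negative")
        if not (0.0 <= self.censor_prob <= 1.0):
            raise ValueError("censor_prob must be in [0, 1]")
        if not (0.0 <= self.rho_within < 1.0):
            raise ValueError("rho_within must be in [0, 1)")


def study_like_params(seed: int = 0) -> SimParams:
    """Defaults plus reporting censorship (~14% directionless) and modest
    dynamism / transmission-risk level effects of the fitted magnitudes."""
    mods = default_moderators()
    mods["dynamism_binary"].effects = {"static": 0.05, "dynamic": -0.05}
    mods["transmission_risk"].effects = {"low": 0.06, "medium": -0.02, "high": -0.06}
    return SimParams(moderators=mods, censor_prob=0.25, seed=seed)


@dataclass
class SimTruth:
    """Ground truth retained from one generator run."""

    params: SimParams
    tree_newick: str
    z_true: np.ndarray  # per effect, fixed + random parts
    z_fixed: np.ndarray  # beta0 + moderator effects
    random_parts: dict[str, np.ndarray]  # per-effect realized random effects

    def to_json(self, path) -> None:
        payload = {
            "params": _params_dict(self.params),
            "tree_newick": self.tree_newick,
            "z_true": self.z_true.tolist(),
            "z_fixed": self.z_fixed.tolist(),
            "random_parts": {k: v.tolist() for k, v in self.random_parts.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _params_dict(params: SimParams) -> dict:
    d = asdict(params)
    d["moderators"] = {
        name: {"levels": list(m.levels), "weights": list(m.weights), "effects": m.effects}
        for name, m in params.moderators.items()
    }
    return d


def simulate_tree(n_species: int, seed: int = 0, birth_rate: float = 1.0) -> dendropy.Tree:
    """Yule (pure-birth) species tree, Grafen-ultrametrized to depth 1.

    Tips are relabeled ``sp001`` ... in traversal order; deterministic given
    the seed.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
        repeat_until_success=True,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:03d}"
    return grafen_transform(set_unit_branch_lengths(tree))


def simulate_dataset(params: SimParams) -> tuple[Dataset, SimTruth]:
    """Draw one synthetic dataset and its ground truth.

    Directionless (censored) records carry ``r = NaN`` and the flag set;
    :func:`ornameta.data.impute_directionless` turns them into ``r = 0``
    records exactly as the analysis pipeline would.
    """
    rng = np.random.default_rng(params.seed)
    tree = simulate_tree(params.n_species, seed=params.seed, birth_rate=params.birth_rate)
    A = brownian_correlation(tree)
    m = len(A.labels)

    L = np.linalg.cholesky(A.matrix + 1e-10 * np.eye(m))
    phylo_eff = np.sqrt(params.sigma2["phylogeny"]) * (L @ rng.standard_normal(m))
    species_eff = np.sqrt(params.sigma2["species"]) * rng.standard_normal(m)
    s_study = np.sqrt(params.sigma2["study"])
    s_obs = np.sqrt(params.sigma2["obs"])

    mod_names = list(params.moderators)
    rows: list[dict] = []
    z_true_l, z_fixed_l = [], []
    parts: dict[str, list] = {"phylogeny": [], "species": [], "study": [], "obs": []}
    eff_counter = 0

    for si, sp in enumerate(A.labels):
        n_studies = max(1, int(rng.poisson(params.studies_per_species)))
        for st in range(n_studies):
            study_id = f"{sp}_study{st + 1}"
            study_eff = s_study * rng.standard_normal()
            n_eff = max(1, int(rng.poisson(params.effects_per_study)))
            n_exp = 1 + (int(rng.binomial(n_eff - 1, 0.5)) if n_eff > 1 else 0)
            exp_of = rng.integers(0, n_exp, size=n_eff)

            block: list[dict] = []
            for e in range(n_eff):
                eff_counter += 1
                mods = {}
                for name in mod_names:
                    if name == "dynamism_binary":
                        continue
                    spec = params.moderators[name]
                    mods[name] = str(
                        rng.choice(spec.levels, p=np.asarray(spec.weights))
                    )
                mods["dynamism_binary"] = (
                    "dynamic" if mods["dynamism_score"] == "2" else "static"
                )
                z_fix = params.beta0 + sum(
                    params.moderators[name].effects.get(mods[name], 0.0)
                    for name in mod_names
                )
                obs_eff = s_obs * rng.standard_normal()
                z_t = z_fix + phylo_eff[si] + species_eff[si] + study_eff + obs_eff
                n_i = int(
                    np.clip(
                        np.round(rng.lognormal(params.n_meanlog, params.n_sdlog)),
                        params.n_min,
                        params.n_max,
                    )
                )
                block.append(
                    dict(
                        effect_id=f"e{eff_counter:05d}",
                        study_id=study_id,
                        experiment_id=f"{study_id}_exp{exp_of[e] + 1}",
                        species=sp,
                        n=n_i,
                        z_fixed=z_fix,
                        z_true=z_t,
                        obs_eff=obs_eff,
                        mods=mods,
                    )
                )

            # Compound-symmetric Fisher-z sampling error within each experiment.
            common = {x: rng.standard_normal() for x in range(n_exp)}
            for e, rec in enumerate(block):
                s_i = np.sqrt(1.0 / (rec["n"] - 3.0))
                rho = params.rho_within
                eps = s_i * (
                    np.sqrt(rho) * common[int(exp_of[e])]
                    + np.sqrt(1.0 - rho) * rng.standard_normal()
                )
                z_obs = rec["z_true"] + eps
                r_i = float(np.tanh(z_obs))
                censored = (
                    params.censor_prob > 0
                    and abs(r_i) * np.sqrt(rec["n"] - 1.0) < 1.959964
                    and rng.random() < params.censor_prob
                )
                row = dict(
                    effect_id=rec["effect_id"],
                    study_id=rec["study_id"],
                    experiment_id=rec["experiment_id"],
                    species=rec["species"],
                    r=np.nan if censored else r_i,
                    n=rec["n"],
                    v=np.nan if censored else r_sampling_variance(r_i, rec["n"]),
                    directionless=censored,
                    year=int(rng.integers(1985, 2023)),
                    male_morph_synchronous=bool(rng.random() < 0.6),
                    **rec["mods"],
                )
                rows.append(row)
                z_true_l.append(rec["z_true"])
                z_fixed_l.append(rec["z_fixed"])
                parts["phylogeny"].append(phylo_eff[si])
                parts["species"].append(species_eff[si])
                parts["study"].append(study_eff)
                parts["obs"].append(rec["obs_eff"])

    table = pd.DataFrame(rows)
    dataset = Dataset(
        table, [f"simulated (seed={params.seed}, n_species={params.n_species})"]
    )
    truth = SimTruth(
        params=params,
        tree_newick=tree.as_string(schema="newick").strip(),
        z_true=np.asarray(z_true_l),
        z_fixed=np.asarray(z_fixed_l),
        random_parts={k: np.asarray(x) for k, x in parts.items()},
    )
    return dataset, truth


@dataclass
class CensorSummary:
    n_censored: int
    n_total: int
    naive_mean: float  # censored records dropped
    imputed_mean: float  # censored records entered as r = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _z_weighted_mean(r: np.ndarray, n: np.ndarray) -> float:
    """Fisher-z inverse-variance weighted mean, reported back on the r scale.

    Weights ``n - 3`` are bounded, unlike r-scale weights ``1/v`` which blow
    up as |r| -> 1 and make single extreme records dominate.
    """
    z = np.arctanh(r)
    w = n - 3.0
    return float(np.tanh(np.sum(w * z) / np.sum(w)))


def censor_report(dataset: Dataset, truth: SimTruth) -> CensorSummary:
    """Contrast dropping censored records with imputing them as r = 0.

    Both summaries are Fisher-z weighted means back-transformed to r;
    dropping nonsignificant results pulls the mean away from zero, which is
    the bias the directionless-imputation rule exists to avoid.
    """
    table = dataset.table
    if len(table) != len(truth.z_true):
        raise ValueError("dataset does not match the supplied truth")
    mask = table["directionless"].astype(bool)
    n_cens = int(mask.sum())

    kept = table[~mask]
    naive = _z_weighted_mean(
        kept["r"].to_numpy(dtype=float), kept["n"].to_numpy(dtype=float)
    )
    imputed = impute_directionless(dataset).table
    imp = _z_weighted_mean(
        imputed["r"].to_numpy(dtype=float), imputed["n"].to_numpy(dtype=float)
    )
    return CensorSummary(n_cens, len(table), naive, imp)
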