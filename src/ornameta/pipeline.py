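"""Full-analysis orchestration: overall models, moderator meta-regressions,
the dynamism x transmission interaction, subsample sensitivity analysis, and
publication-bias regressions, plus report rendering.

Every entry point takes an imputed-or-raw :class:`~ornameta.data.Dataset`
and a host tree, builds the standard four-component random structure
(phylogeny with the Brownian matrix; species, study and observation as
identity components), and returns plain result objects that serialize to
JSON/CSV.  All randomness is driven by an explicit seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset, impute_directionless, subset_dataset
from .heterogeneity import HeterogeneityResult, i2_partition, marginal_r2
from .model import (
    FitOptions,
    FitResult,
    ModelError,
    ModelSpec,
    RandomComponent,
    fit_mlma,
)

logger = logging.getLogger(__name__)


def standard_random_components() -> list[RandomComponent]:
    """Phylogeny (Brownian), species, study, and observation ID."""
    return [
        RandomComponent("phylogeny", "species", "brownian"),
        RandomComponent("species", "species"),
        RandomComponent("study", "study_id"),
        RandomComponent("observation", "effect_id"),
    ]


def _prepare(dataset: Dataset) -> Dataset:
    if dataset.table["r"].isna().any():
        dataset = impute_directionless(dataset)
    return dataset


@dataclass
class OverallResult:
    fits: dict[str, FitResult]
    heterogeneity: HeterogeneityResult

    def to_dict(self) -> dict:
        return {
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
            "heterogeneity": self.heterogeneity.to_dict(),
        }


def run_overall(
    dataset: Dataset,
    tree,
    scale: str = "r",
    options: FitOptions | None = None,
) -> OverallResult:
    """The four overall models: full data, directional-only, the male
    morphological same-time subset, and the full data with a 0.5
    within-experiment sampling correlation.  I² is attached for the full
    model."""
    dataset = _prepare(dataset)
    fits: dict[str, FitResult] = {}
    base = ModelSpec(random=standard_random_components(), scale=scale)
    fits["full"] = fit_mlma(dataset, base, tree=tree, options=options)
    fits["directional_only"] = fit_mlma(
        subset_dataset(dataset, "directional_only"), base, tree=tree, options=options
    )
    fits["male_morph_synchronous"] = fit_mlma(
        subset_dataset(dataset, "male_morph_synchronous"),
        base,
        tree=tree,
        options=options,
    )
    cov_spec = ModelSpec(
        random=standard_random_components(), rho_within=0.5, scale=scale
    )
    fits["full_experiment_cov"] = fit_mlma(dataset, cov_spec, tree=tree, options=options)
    return OverallResult(fits, i2_partition(fits["full"], dataset))


@dataclass
class ModeratorResult:
    moderator: str
    fit_qm: FitResult  # with intercept; carries the omnibus QM
    fit_levels: FitResult  # intercept dropped; per-level means
    r2_marginal: float
    k: int
    level_k: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "moderator": self.moderator,
            "qm": {
                "statistic": self.fit_qm.qm[0],
                "df": self.fit_qm.qm[1],
                "p": self.fit_qm.qm[2],
            },
            "r2_marginal": self.r2_marginal,
            "k": self.k,
            "level_k": self.level_k,
            "levels": self.fit_levels.to_dict()["coefficients"],
        }

    def levels_frame(self) -> pd.DataFrame:
        rows = []
        for nm, b, (lo, hi) in zip(
            self.fit_levels.beta_names, self.fit_levels.beta, self.fit_levels.ci
        ):
            level = nm.split("[", 1)[1].rstrip("]")
            rows.append(
                {
                    "moderator": self.moderator,
                    "level": level,
                    "mean": b,
                    "ci_low": lo,
                    "ci_high": hi,
                    "k": self.level_k.get(level, 0),
                }
            )
        return pd.DataFrame(rows)


def run_moderator(
    dataset: Dataset,
    tree,
    moderator: str,
    drop_threshold: int = 10,
    scale: str = "r",
    options: FitOptions | None = None,
) -> ModeratorResult:
    """One categorical meta-regression: records missing the moderator are
    dropped listwise, levels with ``drop_threshold`` or fewer records are
    excluded, the with-intercept fit carries the QM omnibus test, and an
    intercept-dropped refit yields per-level mean correlations."""
    dataset = _prepare(dataset)
    sub = subset_dataset(
        dataset, "drop_small_categories", moderator=moderator, threshold=drop_threshold
    )
    n_levels = sub.table[moderator].nunique()
    if n_levels < 2:
        raise ModelError(
            f"moderator {moderator!r} has {n_levels} usable level(s) after drops"
        )
    spec_qm = ModelSpec(
        random=standard_random_components(), moderator=moderator, scale=scale
    )
    fit_qm = fit_mlma(sub, spec_qm, tree=tree, options=options)
    spec_lv = ModelSpec(
        random=standard_random_components(),
        moderator=moderator,
        intercept=False,
        scale=scale,
    )
    fit_lv = fit_mlma(sub, spec_lv, tree=tree, options=options)
    return ModeratorResult(
        moderator=moderator,
        fit_qm=fit_qm,
        fit_levels=fit_lv,
        r2_marginal=marginal_r2(fit_qm),
        k=fit_qm.k,
        level_k={str(k): int(v) for k, v in fit_qm.level_k.items()},
    )


def run_interaction(
    dataset: Dataset,
    tree,
    m1: str = "dynamism_binary",
    m2: str = "transmission_risk",
    drop_threshold: int = 10,
    scale: str = "r",
    options: FitOptions | None = None,
) -> FitResult:
    """Two-moderator model with interaction; QM tests the interaction terms.

    Cells of the m1 x m2 cross with ``drop_threshold`` or fewer records are
    removed; a missing cell among the surviving levels is a design error."""
    dataset = _prepare(dataset)
    table = dataset.table[dataset.table[[m1, m2]].notna().all(axis=1)]
    counts = table.groupby([m1, m2], observed=True).size()
    big = counts[counts > drop_threshold]
    keep_cells = set(big.index)
    mask = [
        (a, b) in keep_cells for a, b in zip(table[m1], table[m2])
    ]
    table = table[np.asarray(mask)]
    lev1 = sorted(table[m1].unique())
    lev2 = sorted(table[m2].unique())
    for a in lev1:
        for b in lev2:
            if (a, b) not in keep_cells:
                raise ModelError(
                    f"empty design cell after drops: {m1}={a!r}, {m2}={b!r}"
                )
    sub = dataset.with_table(
        table, f"interaction cells > {drop_threshold}: {sorted(keep_cells)}"
    )
    spec = ModelSpec(
        random=standard_random_components(), interaction=(m1, m2), scale=scale
    )
    return fit_mlma(sub, spec, tree=tree, options=options)


@dataclass
class SensitivityResult:
    B: int
    m_removed: int
    seed: int
    frac_p_above_05: float
    mean_of_means: float
    percentile_ci: tuple[float, float]
    n_failed: int
    replicates: pd.DataFrame  # columns: estimate, p

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "m_removed": self.m_removed,
            "seed": self.seed,
            "frac_p_above_05": self.frac_p_above_05,
            "mean_of_means": self.mean_of_means,
            "percentile_ci": list(self.percentile_ci),
            "n_failed": self.n_failed,
        }


def run_sensitivity_subsample(
    dataset: Dataset,
    tree,
    m_remove: int = 165,
    B: int = 1000,
    seed: int = 0,
    scale: str = "r",
    options: FitOptions | None = None,
) -> SensitivityResult:
    """Random-removal robustness check of the overall mean.

    Each replicate removes ``m_remove`` effects uniformly without replacement,
    refits the four-component intercept-only model, and records the intercept
    and its Wald p-value.  Fully reproducible given the seed; replicates that
    fail to converge are excluded and counted (more than 5% failing is an
    error)."""
    dataset = _prepare(dataset)
    k = dataset.k
    if m_remove >= k:
        raise ModelError("m_remove must be smaller than the dataset")
    rng = np.random.default_rng(seed)
    spec = ModelSpec(random=standard_random_components(), scale=scale)
    est, pvals, failed = [], [], 0
    for b in range(B):
        idx = rng.choice(k, size=k - m_remove, replace=False)
        idx.sort()
        sub = dataset.with_table(
            dataset.table.iloc[idx], f"sensitivity replicate {b}"
        )
        try:
            fit = fit_mlma(sub, spec, tree=tree, options=options)
        except (ModelError, np.linalg.LinAlgError) as exc:
            logger.warning("replicate %d failed: %s", b, exc)
            failed += 1
            continue
        est.append(float(fit.beta[0]))
        pvals.append(float(fit.p_values[0]))
    if failed > 0.05 * B:
        raise ModelError(f"{failed}/{B} sensitivity replicates failed")
    est_a, p_a = np.asarray(est), np.asarray(pvals)
    return SensitivityResult(
        B=B,
        m_removed=m_remove,
        seed=seed,
        frac_p_above_05=float(np.mean(p_a > 0.05)),
        mean_of_means=float(est_a.mean()),
        percentile_ci=(
            float(np.percentile(est_a, 2.5)),
            float(np.percentile(est_a, 97.5)),
        ),
        n_failed=failed,
        replicates=pd.DataFrame({"estimate": est_a, "p": p_a}),
    )


@dataclass
class BiasResult:
    slope_year: tuple[float, float, float] | None  # (beta, ci_low, ci_high)
    slope_size: tuple[float, float, float]
    predictor_definitions: str
    funnel: pd.DataFrame  # effect r vs precision 1/SE

    def to_dict(self) -> dict:
        def trip(t):
            return None if t is None else {"beta": t[0], "ci_low": t[1], "ci_high": t[2]}

        return {
            "slope_year": trip(self.slope_year),
            "slope_size": trip(self.slope_size),
            "predictor_definitions": self.predictor_definitions,
        }


def run_bias_tests(
    dataset: Dataset,
    tree,
    size_predictor: str = "se",
    scale: str = "r",
    options: FitOptions | None = None,
) -> BiasResult:
    """Two Egger-type publication-bias meta-regressions under the full
    random-effects structure: mean-centered publication year, and a precision
    predictor — the standard error ``sqrt(v)`` by default, ``sqrt(n)`` as the
    alternative."""
    dataset = _prepare(dataset)
    table = dataset.table.copy()

    slope_year = None
    if "year" in table.columns and table["year"].notna().all():
        spec = ModelSpec(
            random=standard_random_components(), covariate="year", scale=scale
        )
        fit = fit_mlma(dataset, spec, tree=tree, options=options)
        slope_year = (float(fit.beta[1]), float(fit.ci[1, 0]), float(fit.ci[1, 1]))
    else:
        logger.warning("no usable publication-year column; year test skipped")

    if size_predictor == "se":
        table["size_pred"] = np.sqrt(table["v"].to_numpy(dtype=float))
        definition = "size predictor = standard error sqrt(v) (Egger); year mean-centered"
    elif size_predictor == "sqrt_n":
        table["size_pred"] = np.sqrt(table["n"].to_numpy(dtype=float))
        definition = "size predictor = sqrt(n); year mean-centered"
    else:
        raise ModelError(f"unknown size predictor {size_predictor!r}")
    ds2 = dataset.with_table(table, f"bias predictor: {size_predictor}")
    spec = ModelSpec(
        random=standard_random_components(), covariate="size_pred", scale=scale
    )
    fit2 = fit_mlma(ds2, spec, tree=tree, options=options)
    slope_size = (float(fit2.beta[1]), float(fit2.ci[1, 0]), float(fit2.ci[1, 1]))

    funnel = pd.DataFrame(
        {
            "effect_id": table["effect_id"],
            "r": table["r"],
            "inv_se": 1.0 / np.sqrt(table["v"].to_numpy(dtype=float)),
        }
    )
    return BiasResult(slope_year, slope_size, definition, funnel)


def plot_funnel(bias: BiasResult, path) -> None:
    """Simple funnel render (effect vs 1/SE); requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(bias.funnel["r"], bias.funnel["inv_se"], s=8, alpha=0.5)
    ax.set_xlabel("correlation r")
    ax.set_ylabel("precision (1 / SE)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(bundle: dict, out_dir) -> list[Path]:
    """Write a results bundle to ``out_dir``: a JSON report, CSV tables for
    moderator levels and the funnel, and a plain-text summary.  Output is
    byte-identical across re-runs with the same inputs (no timestamps)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    payload: dict = {}
    lines: list[str] = []

    if "config" in bundle:
        payload["config"] = bundle["config"]
    if "overall" in bundle:
        ov: OverallResult = bundle["overall"]
        payload["overall"] = ov.to_dict()
        for name, fit in ov.fits.items():
            b, (lo, hi) = fit.beta[0], fit.ci[0]
            lines.append(
                f"overall[{name}]: k = {fit.k}, mean = {b:.3f}, "
                f"95% CI = {lo:.3f} to {hi:.3f}"
            )
        het = ov.heterogeneity
        lines.append(
            "I2 total = {:.1f}% ({})".format(
                het.i2_total,
                ", ".join(
                    f"{k} {v:.1f}%" for k, v in het.i2_by_component.items()
                ),
            )
        )
    if "moderators" in bundle:
        frames = []
        payload["moderators"] = {}
        for res in bundle["moderators"]:
            payload["moderators"][res.moderator] = res.to_dict()
            frames.append(res.levels_frame())
            stat, df, p = res.fit_qm.qm
            lines.append(
                f"moderator {res.moderator}: QM({df}) = {stat:.2f}, p = {p:.3g}, "
                f"marginal R2 = {res.r2_marginal:.3f}, k = {res.k}"
            )
        levels_csv = out / "moderator_levels.csv"
        pd.concat(frames, ignore_index=True).to_csv(levels_csv, index=False)
        written.append(levels_csv)
    if "interaction" in bundle:
        fit: FitResult = bundle["interaction"]
        payload["interaction"] = fit.to_dict()
        stat, df, p = fit.qm
        lines.append(f"interaction: QM({df}) = {stat:.2f}, p = {p:.3g}, k = {fit.k}")
    if "sensitivity" in bundle:
        sens: SensitivityResult = bundle["sensitivity"]
        payload["sensitivity"] = sens.to_dict()
        reps_csv = out / "sensitivity_replicates.csv"
        sens.replicates.to_csv(reps_csv, index=False)
        written.append(reps_csv)
        lines.append(
            f"sensitivity: {sens.B} reps removing {sens.m_removed}; "
            f"p > .05 in {100 * sens.frac_p_above_05:.1f}% of reps; "
            f"mean of means = {sens.mean_of_means:.3f} "
            f"(95% CI {sens.percentile_ci[0]:.3f} to {sens.percentile_ci[1]:.3f})"
        )
    if "bias" in bundle:
        bias: BiasResult = bundle["bias"]
        payload["bias"] = bias.to_dict()
        funnel_csv = out / "funnel.csv"
        bias.funnel.to_csv(funnel_csv, index=False)
        written.append(funnel_csv)
        if bias.slope_year:
            lines.append(
                f"bias (year): slope = {bias.slope_year[0]:.4f} "
                f"(95% CI {bias.slope_year[1]:.4f} to {bias.slope_year[2]:.4f})"
            )
        lines.append(
            f"bias (size): slope = {bias.slope_size[0]:.4f} "
            f"(95% CI {bias.slope_size[1]:.4f} to {bias.slope_size[2]:.4f}); "
            f"{bias.predictor_definitions}"
        )

    report_json = out / "results.json"
    with open(report_json, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    written.append(report_json)
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
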