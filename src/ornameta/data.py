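"""Effect-size dataset: schema, validation, construction and subsetting.

The unit of analysis is one Pearson correlation ``r`` between parasite load
and sexual-ornament quality, measured on ``n`` host individuals, carried with
its large-sample sampling variance ``v = (1 - r^2)^2 / (n - 1)``.  Studies
that report a nonsignificant correlation without its sign are kept as
"directionless" records and enter the analysis as ``r = 0`` rather than being
discarded, which would bias the pooled mean away from zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The twelve categorical moderators recorded for every correlation.
MODERATORS: tuple[str, ...] = (
    "host_taxon",
    "host_sex",
    "paternal_care",
    "parasite_taxon",
    "parasite_type",
    "transmission_risk",
    "mate_choice_evidence",
    "dynamism_score",
    "dynamism_binary",
    "parasite_measurement",
    "uninfected_present",
    "study_type",
)

REQUIRED_COLUMNS: tuple[str, ...] = (
    "effect_id",
    "study_id",
    "experiment_id",
    "species",
    "r",
    "n",
    "directionless",
)

OPTIONAL_COLUMNS: tuple[str, ...] = ("v", "year", "male_morph_synchronous") + MODERATORS


class DatasetError(ValueError):
    """Schema- or invariant-level problem in an effect-size table."""

    def __init__(self, message: str, row_errors: list[tuple[int, str]] | None = None):
        self.row_errors = row_errors or []
        if self.row_errors:
            detail = "; ".join(f"row {i}: {msg}" for i, msg in self.row_errors[:20])
            message = f"{message} ({detail})"
        super().__init__(message)


@dataclass
class Dataset:
    """An ordered collection of effect-size records plus provenance.

    ``table`` holds one row per correlation with the canonical columns
    (:data:`REQUIRED_COLUMNS`, sampling variance ``v``, the moderators, and
    optional ``year`` / ``male_morph_synchronous``).
    """

    table: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.table)

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def with_table(self, table: pd.DataFrame, note: str) -> "Dataset":
        return Dataset(table.reset_index(drop=True), self.provenance + [note])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def r_sampling_variance(r, n):
    """Large-sample sampling variance of a Pearson correlation.

    ``v = (1 - r^2)^2 / (n - 1)``; strictly decreasing in both ``n`` and
    ``|r|``.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| = 1 gives a degenerate (zero) sampling variance")
    if np.any(n < 4):
        raise ValueError("sampling variance of r requires n >= 4")
    v = (1.0 - r**2) ** 2 / (n - 1.0)
    return float(v) if v.ndim == 0 else v


def fisher_transform(value, direction: str = "forward", n=None):
    """Fisher's variance-stabilizing transform of a correlation.

    Forward maps ``r`` to ``z = arctanh(r)`` (variance ``1/(n-3)`` attached
    when ``n`` is given); inverse maps ``z`` back via ``tanh``.
    """
    value = np.asarray(value, dtype=float)
    if direction == "forward":
        if np.any(np.abs(value) >= 1):
            raise ValueError("Fisher transform requires |r| < 1")
        z = np.arctanh(value)
        z = float(z) if z.ndim == 0 else z
        if n is not None:
            n = np.asarray(n, dtype=float)
            if np.any(n <= 3):
                raise ValueError("Fisher-z variance 1/(n-3) requires n > 3")
            var = 1.0 / (n - 3.0)
            return z, (float(var) if np.ndim(var) == 0 else var)
        return z
    if direction == "inverse":
        r = np.tanh(value)
        return float(r) if r.ndim == 0 else r
    raise ValueError(f"unknown direction {direction!r}")


def convert_statistic(kind: str, value: float, df_or_n: float) -> float:
    """Convert a reported test statistic to a Pearson correlation.

    Supported: ``t`` (df), ``F1`` (F with 1 numerator df; denominator df
    given), ``chi2_1`` (1-df chi-square; total n given), ``d`` (Cohen's d,
    equal-group conversion).  Anything else is out of scope here.
    """
    if kind == "t":
        if df_or_n <= 0:
            raise ValueError("t conversion requires df > 0")
        return float(np.sign(value) * np.sqrt(value**2 / (value**2 + df_or_n)))
    if kind == "F1":
        if value < 0 or df_or_n <= 0:
            raise ValueError("F conversion requires F >= 0 and df > 0")
        return float(np.sqrt(value / (value + df_or_n)))
    if kind == "chi2_1":
        if value < 0 or df_or_n <= 0:
            raise ValueError("chi-square conversion requires chi2 >= 0 and n > 0")
        return float(np.sqrt(value / df_or_n))
    if kind == "d":
        return float(value / np.sqrt(value**2 + 4.0))
    raise NotImplementedError(f"statistic kind {kind!r} is not supported")


def _normalize_categories(table: pd.DataFrame) -> pd.DataFrame:
    for col in MODERATORS:
        if col in table.columns:
            table[col] = (
                table[col].astype("string").str.strip().str.lower()
            ).astype(object)
    return table


def validate_table(table: pd.DataFrame) -> list[tuple[int, str]]:
    """Row-level invariant checks; returns ``(row_index, message)`` pairs."""
    errors: list[tuple[int, str]] = []
    dup = table["effect_id"].duplicated()
    for i in table.index[dup]:
        errors.append((int(i), f"duplicate effect_id {table.at[i, 'effect_id']!r}"))
    for i, row in table.iterrows():
        i = int(i)
        n = row["n"]
        if pd.isna(n) or float(n) != int(n) or n < 4:
            errors.append((i, f"n must be an integer >= 4, got {n!r}"))
            continue
        r = row["r"]
        directionless = bool(row["directionless"])
        if pd.isna(r):
            if not directionless:
                errors.append((i, "missing r on a non-directionless record"))
        else:
            if abs(r) > 1:
                errors.append((i, f"|r| <= 1 violated (r = {r})"))
            if directionless and r != 0:
                errors.append((i, f"directionless record must have r = 0, got {r}"))
        v = row.get("v")
        if v is not None and not pd.isna(v) and v <= 0:
            errors.append((i, f"sampling variance must be positive, got {v}"))
        score = row.get("dynamism_score")
        binary = row.get("dynamism_binary")
        if (
            score is not None
            and binary is not None
            and not pd.isna(score)
            and not pd.isna(binary)
        ):
            if (str(score).strip() == "2") != (str(binary).strip() == "dynamic"):
                errors.append(
                    (i, "dynamism_binary must be 'dynamic' iff dynamism_score = 2")
                )
    return errors


def load_dataset(path, schema: dict[str, str] | None = None) -> Dataset:
    """Read a CSV effect-size table into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file with a header row (comma separated, UTF-8, decimal point).
    schema
        Optional map from canonical column names to the file's column names,
        absorbing whatever headers the source table uses.
    """
    raw = pd.read_csv(path, encoding="utf-8")
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in raw.columns}
        missing = [canon for canon, src in schema.items() if src not in raw.columns]
        if missing:
            raise DatasetError(f"schema maps absent columns: {missing}")
        raw = raw.rename(columns=rename)
    absent = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if absent:
        raise DatasetError(f"missing required columns: {absent}")

    table = raw.copy()
    for col in ("effect_id", "study_id", "experiment_id", "species"):
        table[col] = table[col].astype(str).str.strip()
    for col in ("r", "n", "v", "year"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    bad_r = table.index[table["r"].isna() & raw["r"].notna()]
    if len(bad_r):
        raise DatasetError(
            "non-numeric r values", [(int(i), f"r = {raw.at[i, 'r']!r}") for i in bad_r]
        )
    for col in ("directionless", "male_morph_synchronous"):
        if col in table.columns:
            table[col] = (
                table[col]
                .astype("string")
                .str.strip()
                .str.lower()
                .map({"true": True, "false": False, "1": True, "0": False})
                .fillna(False)
                .astype(bool)
            )
    table = _normalize_categories(table)
    if "v" not in table.columns:
        table["v"] = np.nan
    needs_v = table["v"].isna() & table["r"].notna() & (table["r"].abs() < 1)
    if needs_v.any():
        table.loc[needs_v, "v"] = r_sampling_variance(
            table.loc[needs_v, "r"].to_numpy(), table.loc[needs_v, "n"].to_numpy()
        )

    errors = validate_table(table)
    if errors:
        raise DatasetError("dataset failed validation", errors)
    return Dataset(table.reset_index(drop=True), [f"loaded from {path}"])


def impute_directionless(dataset: Dataset) -> Dataset:
    """Assign ``r = 0`` and ``v = 1/(n-1)`` to every directionless record.

    Non-directionless records are untouched.  The choice ``v = 1/(n-1)`` is
    the r-scale sampling-variance formula evaluated at ``r = 0``.
    """
    table = dataset.table.copy()
    mask = table["directionless"].astype(bool)
    missing_n = mask & table["n"].isna()
    if missing_n.any():
        raise DatasetError(
            "cannot impute directionless records lacking n",
            [(int(i), "missing n") for i in table.index[missing_n]],
        )
    table.loc[mask, "r"] = 0.0
    table.loc[mask, "v"] = 1.0 / (table.loc[mask, "n"].to_numpy(dtype=float) - 1.0)
    count = int(mask.sum())
    logger.info("imputed %d directionless records as r = 0", count)
    return dataset.with_table(table, f"imputed {count} directionless records")


def subset_dataset(
    dataset: Dataset,
    filter_name: str,
    moderator: str | None = None,
    threshold: int = 10,
) -> Dataset:
    """Apply one of the named analysis subsets.

    ``all`` is the identity; ``directional_only`` keeps records with a signed
    correlation; ``male_morph_synchronous`` keeps the male-morphological,
    same-time subset; ``drop_small_categories`` removes records whose level of
    ``moderator`` has ``threshold`` or fewer records (and records missing that
    moderator).
    """
    table = dataset.table
    if filter_name == "all":
        return dataset.with_table(table.copy(), "subset: all (identity)")
    if filter_name == "directional_only":
        out = table[~table["directionless"].astype(bool)]
        note = f"subset: directional_only (k = {len(out)})"
    elif filter_name == "male_morph_synchronous":
        if "male_morph_synchronous" not in table.columns:
            raise DatasetError("dataset lacks the male_morph_synchronous flag")
        out = table[table["male_morph_synchronous"].astype(bool)]
        note = f"subset: male_morph_synchronous (k = {len(out)})"
    elif filter_name == "drop_small_categories":
        if moderator is None or moderator not in table.columns:
            raise DatasetError(f"unknown moderator column {moderator!r}")
        present = table[table[moderator].notna()]
        counts = present[moderator].value_counts()
        keep = counts.index[counts > threshold]
        out = present[present[moderator].isin(keep)]
        note = (
            f"subset: drop_small_categories({moderator}, >{threshold}) "
            f"kept {sorted(keep)} (k = {len(out)})"
        )
    else:
        raise DatasetError(f"unknown filter {filter_name!r}")
    if len(out) == 0:
        raise DatasetError(f"filter {filter_name!r} produced an empty dataset")
    return dataset.with_table(out, note)
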