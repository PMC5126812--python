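"""File I/O: cohort CSV round-trips, packaged fixtures, spec/config files.

Cohort CSV layout: ``id,disease,age,sex,mo,sc,ua,pd,ad,vas,utility``.
The ``utility`` column is optional on read — when absent it is
recomputed from a value set.  Row-level validation problems are
collected and reported together with their CSV line numbers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    DISEASES,
    AgeParams,
    Cohort,
    CohortSpec,
    Couplings,
    MixtureParams,
    VasParams,
)
from .eq5d import DIMENSIONS, ValueSet, apply_value_set

__all__ = [
    "load_england_value_set",
    "load_table2_counts",
    "load_reference_values",
    "read_cohort",
    "write_cohort",
    "spec_from_yaml",
    "spec_from_dict",
]


def _data_path(name: str):
    return resources.files("boneqol.data").joinpath(name)


def load_england_value_set() -> ValueSet:
    """The packaged EQ-5D-5L value set for England (Devlin et al. 2018
    decrements; floor −0.285)."""
    with resources.as_file(_data_path("england_value_set.csv")) as p:
        return ValueSet.from_csv(p, name="england")


def load_table2_counts() -> pd.DataFrame:
    """Published per-dimension response-level counts by disease
    (columns ``dimension, disease, level, count``)."""
    with resources.as_file(_data_path("table2_counts.csv")) as p:
        return pd.read_csv(p, comment="#")


def load_reference_values() -> dict:
    """Published summary values the synthetic pipeline is calibrated to."""
    import json

    with resources.as_file(_data_path("reference_values.json")) as p:
        return json.loads(Path(p).read_text())


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV (full precision utilities)."""
    cohort.df.to_csv(path, index=False)


def read_cohort(path: str | Path, value_set: ValueSet | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    When the ``utility`` column is missing, utilities are recomputed
    from ``value_set`` (required in that case).  All row-level problems
    are reported at once, each with its CSV line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = ["id", "disease", "age", "sex", "mo", "sc", "ua", "pd", "ad", "vas"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")

    errors: list[str] = []

    def line(i: int) -> int:
        return i + 2  # header occupies line 1

    dupes = df.loc[df["id"].duplicated(), "id"]
    for i, pid in dupes.items():
        errors.append(f"line {line(i)}: duplicate id {pid!r}")
    for i, disease in df["disease"].items():
        if disease not in DISEASES:
            errors.append(f"line {line(i)}: unknown disease label {disease!r}")
    for col in ("mo", "sc", "ua", "pd", "ad"):
        for i, v in df[col].items():
            if pd.isna(v) or not float(v).is_integer() or not 1 <= int(v) <= 5:
                errors.append(
                    f"line {line(i)}: {col} level must be an integer in 1..5, got {v!r}"
                )
    for i, v in df["vas"].items():
        if not pd.isna(v) and not 0 <= float(v) <= 100:
            errors.append(f"line {line(i)}: vas must lie in [0, 100], got {v!r}")
    if errors:
        raise ValueError(
            f"{path.name}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
        )

    for col in ("mo", "sc", "ua", "pd", "ad"):
        df[col] = df[col].astype(int)

    if "utility" not in df.columns or df["utility"].isna().all():
        if value_set is None:
            raise ValueError(
                f"{path.name}: no utility column and no value set supplied to "
                "recompute it"
            )
        dec = {dim: np.array([value_set.decrement(dim, l) for l in range(1, 6)])
               for dim in DIMENSIONS}
        df["utility"] = 1.0 - sum(
            dec[dim][df[dim.lower()].to_numpy() - 1] for dim in DIMENSIONS
        )
    return Cohort(df)


# ---------------------------------------------------------------------------
# Cohort specs as YAML/JSON


def spec_from_dict(raw: dict) -> CohortSpec:
    """Build a :class:`CohortSpec` from a plain mapping (YAML/JSON).

    Absent keys keep the packaged study-calibrated defaults.
    """
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "utility_mode" in raw:
        kwargs["utility_mode"] = raw["utility_mode"]
    if "n_by_disease" in raw:
        kwargs["n_by_disease"] = {k: int(v) for k, v in raw["n_by_disease"].items()}
    if "age_params" in raw:
        kwargs["age_params"] = {
            k: AgeParams(**v) for k, v in raw["age_params"].items()
        }
    if "sex_female_prob" in raw:
        kwargs["sex_female_prob"] = dict(raw["sex_female_prob"])
    if "vas_params" in raw:
        kwargs["vas_params"] = {
            k: VasParams(**v) for k, v in raw["vas_params"].items()
        }
    if "utility_mixture" in raw:
        m = raw["utility_mixture"]
        kwargs["utility_mixture"] = MixtureParams(
            weights=tuple(m.get("weights", (0.45, 0.55))),
            means=tuple(m.get("means", (0.45, 0.85))),
            sds=tuple(m.get("sds", (0.29, 0.12))),
            bounds=tuple(m.get("bounds", (-0.285, 1.0))),
        )
    if "couplings" in raw:
        kwargs["couplings"] = {
            k: Couplings(**v) for k, v in raw["couplings"].items()
        }
    if "level_probs" in raw:
        kwargs["level_probs"] = {
            disease: {dim: np.asarray(p, dtype=float) for dim, p in dims.items()}
            for disease, dims in raw["level_probs"].items()
        }
    return CohortSpec(**kwargs)


def spec_from_yaml(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return spec_from_dict(raw)
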