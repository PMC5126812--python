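"""Seeded synthetic-cohort generator.

The study population this package analyses — 109 UK adults with a rare
bone disease (43 osteogenesis imperfecta, 42 fibrous dysplasia, 24
X-linked hypophosphatemia) — was never deposited.  This module generates
cohorts with the same statistical structure so every downstream stage
(descriptive statistics, exact tests, the cost-utility simulation) is
testable end to end:

* group sizes, age distributions (truncated normal at the published
  mean/SD/range) and sex ratios match the published demographics table;
* per-dimension EQ-5D-5L response levels are multinomial draws at the
  published level frequencies;
* health utilities follow a bimodal two-component truncated-normal
  mixture calibrated so that the overall mean is ~0.65 and the expected
  mean of the lowest 15 utilities out of 43 is ~0.339 — the two moments
  that drive the economic simulation;
* within the OI group, age is coupled to the usual-activities level
  (Pearson r ≈ +0.39), to the VAS (r ≈ −0.42) and to utility (slope
  ≈ −0.005 per year) through a Gaussian copula.

All randomness flows from one master seed; each (disease, stream) pair
gets an independent child generator via ``numpy.random.SeedSequence``
spawn keys, so adding a stream never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eq5d import DIMENSIONS, HealthState, ValueSet

__all__ = [
    "DISEASES",
    "MixtureParams",
    "AgeParams",
    "Couplings",
    "CohortSpec",
    "Patient",
    "Cohort",
    "gen_utilities",
    "gen_responses",
    "gen_cohort",
    "default_spec",
]

#: Disease groups, in reporting order.
DISEASES: tuple[str, ...] = ("OI", "FD", "XLH")

# Column layout of the cohort table.
COHORT_COLUMNS = (
    "id", "disease", "age", "sex", "mo", "sc", "ua", "pd", "ad", "vas", "utility",
)

# Fixed stream indices for per-(disease, stream) child seeds.  Append
# only — reordering would change every seeded cohort.
_STREAMS = {"latent": 0, "levels": 1, "sex": 2, "utility": 3}


def _child_rng(master_seed: int, disease: str, stream: str) -> np.random.Generator:
    key = (DISEASES.index(disease), _STREAMS[stream])
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Marginal distributions


@dataclass(frozen=True)
class MixtureParams:
    """Two-component truncated-normal mixture for health utility.

    Components are truncated to ``bounds`` (value-set floor to 1) and
    mixed with ``weights``.  The defaults are a calibration: with a low
    component N(0.45, 0.29) at weight 0.45 and a high component
    N(0.85, 0.12) at weight 0.55, truncated to [−0.285, 1], the overall
    mean is ≈ 0.650 (SD ≈ 0.273) and the expected mean of the lowest 15
    of a 43-draw sample is ≈ 0.339.  See ``scripts/calibrate_mixture.py``
    for the derivation.
    """

    weights: tuple[float, float] = (0.45, 0.55)
    means: tuple[float, float] = (0.45, 0.85)
    sds: tuple[float, float] = (0.29, 0.12)
    bounds: tuple[float, float] = (-0.285, 1.0)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {self.weights}")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be non-negative")
        if any(s <= 0 for s in self.sds):
            raise ValueError(f"mixture SDs must be positive, got {self.sds}")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("mixture bounds must satisfy lo < hi")

    def _frozen(self):
        lo, hi = self.bounds
        return [
            stats.truncnorm((lo - m) / s, (hi - m) / s, loc=m, scale=s)
            for m, s in zip(self.means, self.sds)
        ]

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comps = self._frozen()
        which = rng.random(n) < self.weights[0]
        lo_draws = comps[0].rvs(size=n, random_state=rng)
        hi_draws = comps[1].rvs(size=n, random_state=rng)
        return np.where(which, lo_draws, hi_draws)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        c0, c1 = self._frozen()
        return self.weights[0] * c0.cdf(x) + self.weights[1] * c1.cdf(x)

    def ppf(self, q: np.ndarray) -> np.ndarray:
        """Quantile function by vectorised bisection (mixture CDFs have
        no closed-form inverse)."""
        q = np.asarray(q, dtype=float)
        lo = np.full(q.shape, self.bounds[0])
        hi = np.full(q.shape, self.bounds[1])
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            below = self.cdf(mid) < q
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class AgeParams:
    """Truncated-normal age distribution (years)."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("age SD must be positive")
        if self.low >= self.high:
            raise ValueError("age range must satisfy low < high")

    def _frozen(self):
        return stats.truncnorm(
            (self.low - self.mean) / self.sd,
            (self.high - self.mean) / self.sd,
            loc=self.mean,
            scale=self.sd,
        )

    def ppf(self, q: np.ndarray) -> np.ndarray:
        return self._frozen().ppf(q)


@dataclass(frozen=True)
class VasParams:
    """Truncated-normal VAS distribution on [0, 100]."""

    mean: float
    sd: float

    def ppf(self, q: np.ndarray) -> np.ndarray:
        d = stats.truncnorm((0 - self.mean) / self.sd, (100 - self.mean) / self.sd,
                            loc=self.mean, scale=self.sd)
        return d.ppf(q)


@dataclass(frozen=True)
class Couplings:
    """Target dependencies between age and other OI variables.

    ``age_usual_activity`` and ``age_vas`` are Pearson correlations;
    ``utility_age_slope`` is the least-squares slope of utility on age
    (utility units per year, typically negative).
    """

    age_usual_activity: float = 0.0
    age_vas: float = 0.0
    utility_age_slope: float = 0.0


# ---------------------------------------------------------------------------
# Cohort spec


def _default_level_probs() -> dict[str, dict[str, np.ndarray]]:
    """Published per-disease, per-dimension level frequencies, normalised."""
    from .io import load_table2_counts

    counts = load_table2_counts()
    probs: dict[str, dict[str, np.ndarray]] = {}
    for disease in DISEASES:
        probs[disease] = {}
        for dim in DIMENSIONS:
            sub = counts[(counts.disease == disease) & (counts.dimension == dim)]
            c = sub.sort_values("level")["count"].to_numpy(dtype=float)
            probs[disease][dim] = c / c.sum()
    return probs


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic cohort.

    Defaults reproduce the published study conditions: 43/42/24
    participants, published age and sex distributions, published
    response-level frequencies, the calibrated utility mixture, and the
    published OI age couplings.
    """

    n_by_disease: dict[str, int] = field(
        default_factory=lambda: {"OI": 43, "FD": 42, "XLH": 24}
    )
    age_params: dict[str, AgeParams] = field(
        default_factory=lambda: {
            "OI": AgeParams(40.4, 14.4, 18, 70),
            "FD": AgeParams(44.3, 14.5, 18, 75),
            "XLH": AgeParams(46.3, 16.3, 22, 78),
        }
    )
    sex_female_prob: dict[str, float] = field(
        default_factory=lambda: {"OI": 0.77, "FD": 0.69, "XLH": 0.79}
    )
    vas_params: dict[str, VasParams] = field(
        default_factory=lambda: {
            "OI": VasParams(69.4, 21.4),
            "FD": VasParams(64.1, 23.0),
            "XLH": VasParams(60.8, 26.9),
        }
    )
    level_probs: dict[str, dict[str, np.ndarray]] = field(
        default_factory=_default_level_probs
    )
    utility_mixture: MixtureParams = field(default_factory=MixtureParams)
    couplings: dict[str, Couplings] = field(
        default_factory=lambda: {
            "OI": Couplings(age_usual_activity=0.39, age_vas=-0.42,
                            utility_age_slope=-0.005),
            "FD": Couplings(),
            "XLH": Couplings(),
        }
    )
    utility_mode: str = "mixture"  # "mixture" or "valueset"
    seed: int = 0

    def __post_init__(self) -> None:
        for disease, n in self.n_by_disease.items():
            if disease not in DISEASES:
                raise ValueError(f"unknown disease {disease!r}")
            if n < 3:
                raise ValueError(
                    f"need at least 3 participants per disease for tertiles, "
                    f"got {n} for {disease}"
                )
        for disease in self.n_by_disease:
            for dim, p in self.level_probs[disease].items():
                p = np.asarray(p, dtype=float)
                if p.shape != (5,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                    raise ValueError(
                        f"level probabilities for {disease}/{dim} must be 5 "
                        f"non-negative values summing to 1"
                    )
        if self.utility_mode not in ("mixture", "valueset"):
            raise ValueError(f"utility_mode must be 'mixture' or 'valueset', "
                             f"got {self.utility_mode!r}")


def default_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The study-calibrated cohort spec with a chosen master seed."""
    spec = CohortSpec(seed=seed)
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# Patients and cohorts


@dataclass(frozen=True)
class Patient:
    """One participant record."""

    id: str
    disease: str
    age: float
    sex: str
    state: HealthState
    utility: float


class Cohort:
    """Ordered participant collection backed by a pandas DataFrame.

    Columns: ``id, disease, age, sex, mo, sc, ua, pd, ad, vas, utility``.
    Ids must be unique.
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(COHORT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"cohort table is missing columns {sorted(missing)}")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate patient ids: {dupes}")
        self.df = df.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, disease: str) -> "Cohort":
        return Cohort(self.df[self.df.disease == disease])

    def patients(self) -> Iterator[Patient]:
        for row in self.df.itertuples():
            yield Patient(
                id=row.id,
                disease=row.disease,
                age=float(row.age),
                sex=row.sex,
                state=HealthState(
                    int(row.mo), int(row.sc), int(row.ua), int(row.pd), int(row.ad),
                    vas=None if pd.isna(row.vas) else int(row.vas),
                ),
                utility=float(row.utility),
            )

    def utilities(self) -> np.ndarray:
        return self.df["utility"].to_numpy(dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        sizes = self.df["disease"].value_counts().to_dict()
        return f"Cohort(n={len(self)}, {sizes})"


# ---------------------------------------------------------------------------
# Generators


def gen_utilities(
    n: int,
    mixture: MixtureParams | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` health utilities from the bimodal mixture.

    Deterministic given the seed; all values lie within the mixture's
    truncation bounds.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    mixture = mixture or MixtureParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return mixture.rvs(n, rng)


def _draw_levels(
    n: int, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(np.asarray(probs, dtype=float))
    if abs(cum[-1] - 1.0) > 1e-9:
        raise ValueError(f"level probabilities must sum to 1, got {cum[-1]}")
    return 1 + np.searchsorted(cum, rng.random(n), side="right").clip(0, 4)


def gen_responses(
    n: int,
    level_probs: Mapping[str, np.ndarray],
    seed: int | np.random.Generator = 0,
) -> list[HealthState]:
    """Draw ``n`` EQ-5D-5L states, each dimension an independent
    multinomial at the supplied level probabilities."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    levels = {dim: _draw_levels(n, level_probs[dim], rng) for dim in DIMENSIONS}
    return [
        HealthState(*(int(levels[dim][i]) for dim in DIMENSIONS))
        for i in range(n)
    ]


# --- Gaussian-copula calibration -------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(96)
_GH_Z = np.sqrt(2.0) * _GH_NODES
_GH_W = _GH_WEIGHTS / np.sqrt(np.pi)


def _margin_moments(ppf) -> tuple[float, float, float]:
    """Mean, SD and first Hermite coefficient E[X·Z] of X = ppf(Φ(Z))."""
    q = stats.norm.cdf(_GH_Z)
    x = ppf(q)
    mean = float(np.sum(_GH_W * x))
    var = float(np.sum(_GH_W * (x - mean) ** 2))
    a1 = float(np.sum(_GH_W * x * _GH_Z))
    return mean, np.sqrt(var), a1


def _latent_rho(r_target: float, sd_x: float, a1_x: float,
                sd_y: float, a1_y: float) -> float:
    """Latent normal correlation inducing Pearson r_target between the
    transformed margins (first-order Hermite inversion)."""
    rho = r_target * sd_x * sd_y / (a1_x * a1_y)
    if abs(rho) >= 0.999:
        raise ValueError(
            f"infeasible coupling: target correlation {r_target} requires "
            f"latent correlation {rho:.3f}"
        )
    return rho


def _categorical_ppf(probs: np.ndarray):
    cum = np.cumsum(probs)

    def ppf(q: np.ndarray) -> np.ndarray:
        return 1.0 + np.searchsorted(cum, q, side="right").clip(0, 4)

    return ppf


def gen_cohort(spec: CohortSpec, value_set: ValueSet | None = None) -> Cohort:
    """Generate a full synthetic cohort from a spec.

    Within each disease group, ages, sexes and the four uncoupled
    dimensions are independent draws; age, the usual-activities level,
    the VAS and (in mixture mode) the utility share a one-factor
    Gaussian copula whose latent correlations are calibrated so the
    generated sample hits the spec's target couplings in expectation.

    In ``valueset`` mode utilities are recomputed from the generated
    responses under ``value_set`` instead of drawn from the mixture; the
    utility–age coupling is then whatever the response couplings induce.
    """
    if spec.utility_mode == "valueset" and value_set is None:
        raise ValueError("utility_mode='valueset' requires a value set")

    frames = []
    for disease in DISEASES:
        if disease not in spec.n_by_disease:
            continue
        n = spec.n_by_disease[disease]
        age_p = spec.age_params[disease]
        vas_p = spec.vas_params[disease]
        probs = spec.level_probs[disease]
        coup = spec.couplings.get(disease, Couplings())
        mix = spec.utility_mixture

        # margin moments for latent-correlation calibration
        _, sd_age, a1_age = _margin_moments(age_p.ppf)
        ua_ppf = _categorical_ppf(probs["UA"])
        _, sd_ua, a1_ua = _margin_moments(ua_ppf)
        _, sd_vas, a1_vas = _margin_moments(vas_p.ppf)
        _, sd_ut, a1_ut = _margin_moments(mix.ppf)

        r_util = coup.utility_age_slope * sd_age / sd_ut
        rho_ua = _latent_rho(coup.age_usual_activity, sd_age, a1_age, sd_ua, a1_ua)
        rho_vas = _latent_rho(coup.age_vas, sd_age, a1_age, sd_vas, a1_vas)
        rho_ut = _latent_rho(r_util, sd_age, a1_age, sd_ut, a1_ut)

        # one-factor latent construction: z_age is the factor
        rng = _child_rng(spec.seed, disease, "latent")
        z_age = rng.standard_normal(n)
        eps = rng.standard_normal((3, n))
        z_ua = rho_ua * z_age + np.sqrt(1 - rho_ua**2) * eps[0]
        z_vas = rho_vas * z_age + np.sqrt(1 - rho_vas**2) * eps[1]
        z_ut = rho_ut * z_age + np.sqrt(1 - rho_ut**2) * eps[2]

        age = age_p.ppf(stats.norm.cdf(z_age))
        ua = ua_ppf(stats.norm.cdf(z_ua)).astype(int)
        vas = np.rint(vas_p.ppf(stats.norm.cdf(z_vas))).astype(int)

        lrng = _child_rng(spec.seed, disease, "levels")
        mo = _draw_levels(n, probs["MO"], lrng)
        sc = _draw_levels(n, probs["SC"], lrng)
        pdl = _draw_levels(n, probs["PD"], lrng)
        ad = _draw_levels(n, probs["AD"], lrng)

        srng = _child_rng(spec.seed, disease, "sex")
        sex = np.where(srng.random(n) < spec.sex_female_prob[disease], "F", "M")

        if spec.utility_mode == "mixture":
            utility = mix.ppf(stats.norm.cdf(z_ut))
        else:
            dec = {dim: np.array([value_set.decrement(dim, l) for l in range(1, 6)])
                   for dim in DIMENSIONS}
            utility = 1.0 - (
                dec["MO"][mo - 1] + dec["SC"][sc - 1] + dec["UA"][ua - 1]
                + dec["PD"][pdl - 1] + dec["AD"][ad - 1]
            )

        frames.append(pd.DataFrame({
            "id": [f"{disease}-{i + 1:03d}" for i in range(n)],
            "disease": disease,
            "age": age,
            "sex": sex,
            "mo": mo.astype(int),
            "sc": sc.astype(int),
            "ua": ua,
            "pd": pdl.astype(int),
            "ad": ad.astype(int),
            "vas": vas,
            "utility": utility,
        }))

    return Cohort(pd.concat(frames, ignore_index=True))
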