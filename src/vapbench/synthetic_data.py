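"""Synthetic arm-level evidence bases with the structure the analysis assumes.

Each stratum (benchmark groups; control/intervention arms of the SDD and
non-antimicrobial prevention series) is generated from a logit-normal
random-effects model over binomial groups: a group's true log-odds is drawn
from ``Normal(logit(mu), tau^2)``, its denominator from a log-normal
distribution quantile-matched to the stratum's median/IQR of patients per
group, and its event count from a binomial at the back-transformed true
incidence.  Group-level covariates are drawn independently of the counts.

Two mechanisms perturb the null model: an additive *contextual shift* on the
log-odds of SDD control arms (emulating spill-over of the intervention onto
concurrent controls), and a *censoring rule* that drops low-incidence
control arms with some probability after observation (emulating publication
bias on reported results).

Each stratum draws from its own child seed stream, so adding or resizing a
stratum does not perturb the draws of the others.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import yaml
from scipy import stats

from .group_data import GroupRecord
from .logit_core import invlogit, logit, logit_proportion
from .meta_regression import ModelSpec, run_model
from .random_effects import pool_random_effects

__all__ = [
    "StratumConfig",
    "SimulationConfig",
    "default_config",
    "benchmark_only_config",
    "null_profile_config",
    "simulate_groups",
    "recovery_experiment",
    "RecoveryReport",
    "config_to_yaml",
    "config_from_yaml",
]

_Z75 = stats.norm.ppf(0.75)  # quantile used to match an IQR to a log-normal sigma


@dataclass(frozen=True)
class StratumConfig:
    """Generating parameters of one stratum of groups.

    ``mu_pct`` is the true pooled incidence per 100 patients and ``tau2``
    the between-group variance of true log-odds.  ``denom_median`` /
    ``denom_q1`` / ``denom_q3`` parameterize the log-normal denominator
    model by quantile matching; denominators are rounded and floored at 10
    patients.  Covariate generators are independent Bernoulli/Beta draws.
    """

    name: str
    series: str
    arm_role: str
    k: int
    mu_pct: float
    tau2: float
    denom_median: float
    denom_q1: float
    denom_q3: float
    bronchoscopic_p: float = 0.5
    trauma_mean: float = 0.2
    trauma_concentration: float = 2.0
    mv_lt90_p: float = 0.1
    quality_p: float | None = None
    duplex_p: float = 0.0
    european_p: float = 0.6
    year_range: tuple[int, int] = (1990, 2000)
    source_review: str = "synthetic"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"stratum {self.name!r}: k must be >= 2, got {self.k}")
        if self.tau2 < 0:
            raise ValueError(f"stratum {self.name!r}: tau2 must be >= 0")
        if not 0 < self.mu_pct < 100:
            raise ValueError(f"stratum {self.name!r}: mu_pct must be in (0, 100)")
        for p_name in ("bronchoscopic_p", "mv_lt90_p", "duplex_p", "european_p"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"stratum {self.name!r}: {p_name} must be in [0, 1]")
        if self.quality_p is not None and not 0.0 <= self.quality_p <= 1.0:
            raise ValueError(f"stratum {self.name!r}: quality_p must be in [0, 1]")
        if not self.denom_q1 <= self.denom_median <= self.denom_q3:
            raise ValueError(f"stratum {self.name!r}: denominator quantiles unordered")

    @property
    def mu_logit(self) -> float:
        return logit(self.mu_pct / 100.0)


@dataclass(frozen=True)
class SimulationConfig:
    """A full synthetic evidence base: strata plus optional perturbations.

    ``contextual_shift`` (log-odds) is added to the true effects of SDD
    control arms only.  ``censor_threshold_pct`` / ``censor_drop_p`` drop
    control arms whose *observed* incidence falls below the threshold with
    the given probability.
    """

    seed: int
    strata: tuple[StratumConfig, ...]
    contextual_shift: float = 0.0
    censor_threshold_pct: float | None = None
    censor_drop_p: float = 0.0

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum is required")
        if not 0.0 <= self.censor_drop_p <= 1.0:
            raise ValueError("censor_drop_p must be in [0, 1]")

    def true_mu_logit(self, stratum: StratumConfig) -> float:
        shift = (
            self.contextual_shift
            if stratum.series == "sdd" and stratum.arm_role == "control"
            else 0.0
        )
        return stratum.mu_logit + shift


def default_config(seed: int = 0) -> SimulationConfig:
    """The five-stratum evidence-base geometry used throughout.

    Stratum sizes, true pooled incidences, heterogeneity and denominator
    medians/IQRs follow the observed evidence base: 45 benchmark groups
    (22.1%, tau^2 0.34, denominators 264 (83-567)); 35 control / 35
    intervention non-antimicrobial arms (20.4% / 17.1%; denominators 54
    (29-92)); 33 control / 34 intervention SDD arms (35.7% / 16.0%;
    denominators 57 (33-130)).  Covariate frequencies mirror the study
    characteristics (bronchoscopic diagnosis, trauma mix, <90%-ventilated
    and majority-quality counts, duplex SDD controls).
    """
    strata = (
        StratumConfig(
            name="benchmark", series="benchmark", arm_role="benchmark",
            k=45, mu_pct=22.1, tau2=0.34,
            denom_median=264, denom_q1=83, denom_q3=567,
            bronchoscopic_p=23 / 45, trauma_mean=0.12, mv_lt90_p=5 / 45,
            quality_p=None, european_p=28 / 45, year_range=(1990, 2000),
        ),
        StratumConfig(
            name="nonanti-control", series="non_antimicrobial", arm_role="control",
            k=35, mu_pct=20.4, tau2=0.41,
            denom_median=54, denom_q1=29, denom_q3=92,
            bronchoscopic_p=5 / 35, trauma_mean=0.15, mv_lt90_p=2 / 35,
            quality_p=16 / 35, european_p=19 / 35, year_range=(1994, 2000),
        ),
        StratumConfig(
            name="nonanti-intervention", series="non_antimicrobial",
            arm_role="intervention",
            k=35, mu_pct=17.1, tau2=0.35,
            denom_median=54, denom_q1=29, denom_q3=92,
            bronchoscopic_p=5 / 35, trauma_mean=0.15, mv_lt90_p=2 / 35,
            quality_p=16 / 35, european_p=19 / 35, year_range=(1994, 2000),
        ),
        StratumConfig(
            name="sdd-control", series="sdd", arm_role="control",
            k=33, mu_pct=35.7, tau2=0.63,
            denom_median=57, denom_q1=33, denom_q3=130,
            bronchoscopic_p=8 / 33, trauma_mean=0.34, mv_lt90_p=4 / 33,
            quality_p=4 / 33, duplex_p=4 / 33, european_p=30 / 33,
            year_range=(1991, 1997),
        ),
        StratumConfig(
            name="sdd-intervention", series="sdd", arm_role="intervention",
            k=34, mu_pct=16.0, tau2=0.59,
            denom_median=57, denom_q1=33, denom_q3=130,
            bronchoscopic_p=8 / 33, trauma_mean=0.34, mv_lt90_p=4 / 33,
            quality_p=4 / 33, european_p=30 / 33, year_range=(1991, 1997),
        ),
    )
    return SimulationConfig(seed=seed, strata=strata)


def benchmark_only_config(
    seed: int = 0, k: int = 45, mu_pct: float = 22.1, tau2: float = 0.34
) -> SimulationConfig:
    """A single benchmark stratum with the observed geometry; handy for
    coverage and parameter-recovery experiments."""
    base = default_config(seed).strata[0]
    stratum = dataclasses.replace(base, k=k, mu_pct=mu_pct, tau2=tau2)
    return SimulationConfig(seed=seed, strata=(stratum,))


def null_profile_config(seed: int = 0, k_controls: int = 33) -> SimulationConfig:
    """Benchmark stratum plus a control stratum exchangeable with it.

    The null hypothesis of the profiling analysis: control arms drawn from
    the same logit-normal incidence distribution (and denominator model) as
    the benchmark, with no contextual shift and no censoring.  Under this
    configuration about 2.5% of control arms should fall above the
    benchmark 95% prediction band.
    """
    bench = default_config(seed).strata[0]
    null_control = dataclasses.replace(
        bench, name="null-control", series="sdd", arm_role="control",
        k=k_controls,
    )
    return SimulationConfig(seed=seed, strata=(bench, null_control))


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Quantile-matched log-normal: mu = log(median), sigma from the IQR."""
    mu = math.log(median)
    sigma = 0.0 if q3 <= q1 else math.log(q3 / q1) / (2.0 * _Z75)
    return mu, sigma


def _stratum_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def simulate_groups(config: SimulationConfig) -> list[GroupRecord]:
    """Draw one synthetic evidence base; fully reproducible from the seed."""
    records: list[GroupRecord] = []
    for stratum in config.strata:
        rng = _stratum_rng(config.seed, stratum.name)
        mu = config.true_mu_logit(stratum)
        ln_mu, ln_sigma = _lognormal_params(
            stratum.denom_median, stratum.denom_q1, stratum.denom_q3
        )
        for i in range(stratum.k):
            theta = rng.normal(mu, math.sqrt(stratum.tau2))
            denom = max(10, int(round(rng.lognormal(ln_mu, ln_sigma))))
            events = int(rng.binomial(denom, invlogit(theta)))
            trauma = float(
                rng.beta(
                    stratum.trauma_concentration * stratum.trauma_mean,
                    stratum.trauma_concentration * (1.0 - stratum.trauma_mean),
                )
            )
            quality = (
                None
                if stratum.quality_p is None
                else bool(rng.random() < stratum.quality_p)
            )
            record = GroupRecord(
                study_id=f"{stratum.name}-{i + 1:02d}",
                group_label=f"{stratum.name}-{i + 1:02d}",
                arm_role=stratum.arm_role,
                series=stratum.series,
                events=events,
                denominator=denom,
                bronchoscopic_diagnosis=bool(rng.random() < stratum.bronchoscopic_p),
                trauma_proportion=trauma,
                mv_lt90=bool(rng.random() < stratum.mv_lt90_p),
                quality_majority=quality,
                duplex=bool(rng.random() < stratum.duplex_p),
                concurrent=True,
                european=bool(rng.random() < stratum.european_p),
                publication_year=int(
                    rng.integers(stratum.year_range[0], stratum.year_range[1] + 1)
                ),
                source_review=stratum.source_review,
            )
            # censoring acts on the observed incidence of control arms only
            if (
                config.censor_threshold_pct is not None
                and stratum.arm_role == "control"
                and record.vap_pct < config.censor_threshold_pct
                and rng.random() < config.censor_drop_p
            ):
                continue
            records.append(record)
    return records


@dataclass(frozen=True)
class StratumRecovery:
    """Monte-Carlo summary of estimator behaviour in one stratum."""

    stratum: str
    reps: int
    true_mu_logit: float
    true_tau2: float
    mean_mu_logit: float
    bias_mu_logit: float
    rmse_mu_logit: float
    mcse_mu_logit: float
    mean_tau2: float
    bias_tau2: float
    mcse_tau2: float
    ci_coverage: float
    pi_coverage: float
    coverage_mcse: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class RecoveryReport:
    strata: tuple[StratumRecovery, ...]
    sdd_coefficient_mean: float | None = None
    sdd_coefficient_mcse: float | None = None

    def to_dict(self) -> dict:
        return {
            "strata": [s.to_dict() for s in self.strata],
            "sdd_coefficient_mean": self.sdd_coefficient_mean,
            "sdd_coefficient_mcse": self.sdd_coefficient_mcse,
        }


def recovery_experiment(
    config: SimulationConfig,
    reps: int = 500,
    level: float = 0.95,
    tau2_method: str = "dl",
    fit_series_model: bool = False,
) -> RecoveryReport:
    """Simulate -> pool ``reps`` times; report bias, RMSE and coverage.

    Per stratum: bias and RMSE of the pooled log-odds, mean tau^2, coverage
    of the confidence interval for the true mean, and coverage of the
    prediction interval for the true log-odds of a fresh group drawn from
    the same random-effects distribution, each with Monte-Carlo standard
    errors.  With ``fit_series_model`` a series-indicator meta-regression
    (benchmark + control arms) is fitted per replicate and the mean SDD
    coefficient reported.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    names = [s.name for s in config.strata]
    mu_hat: dict[str, list[float]] = {n: [] for n in names}
    tau2_hat: dict[str, list[float]] = {n: [] for n in names}
    ci_cover: dict[str, list[bool]] = {n: [] for n in names}
    pi_cover: dict[str, list[bool]] = {n: [] for n in names}
    sdd_coefs: list[float] = []
    fresh_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), zlib.crc32(b"fresh-groups")])
    )
    for rep in range(reps):
        rep_seed = (int(config.seed) * 1_000_003 + rep) % (2**31 - 1)
        rep_config = dataclasses.replace(config, seed=rep_seed)
        groups = simulate_groups(rep_config)
        for stratum in config.strata:
            members = [g for g in groups if g.study_id.startswith(stratum.name + "-")]
            if len(members) < 2:
                continue
            estimates = [logit_proportion(g.events, g.denominator) for g in members]
            summary = pool_random_effects(
                estimates, level=level, tau2_method=tau2_method
            )
            true_mu = config.true_mu_logit(stratum)
            mu_hat[stratum.name].append(summary.mu_logit)
            tau2_hat[stratum.name].append(summary.tau2)
            ci_cover[stratum.name].append(
                summary.ci_logit[0] <= true_mu <= summary.ci_logit[1]
            )
            theta_new = fresh_rng.normal(true_mu, math.sqrt(stratum.tau2))
            pi_cover[stratum.name].append(
                summary.pi_logit[0] <= theta_new <= summary.pi_logit[1]
            )
        if fit_series_model:
            spec = ModelSpec(model_id="series", arm_scope="control",
                             tau2_method="reml")
            fit = run_model(groups, spec)
            sdd_coefs.append(fit.coefficient("series_sdd"))
    recoveries = []
    for stratum in config.strata:
        mus = np.array(mu_hat[stratum.name])
        taus = np.array(tau2_hat[stratum.name])
        cis = np.array(ci_cover[stratum.name], dtype=float)
        pis = np.array(pi_cover[stratum.name], dtype=float)
        n = len(mus)
        true_mu = config.true_mu_logit(stratum)
        recoveries.append(
            StratumRecovery(
                stratum=stratum.name,
                reps=n,
                true_mu_logit=true_mu,
                true_tau2=stratum.tau2,
                mean_mu_logit=float(mus.mean()),
                bias_mu_logit=float(mus.mean() - true_mu),
                rmse_mu_logit=float(np.sqrt(np.mean((mus - true_mu) ** 2))),
                mcse_mu_logit=float(mus.std(ddof=1) / math.sqrt(n)),
                mean_tau2=float(taus.mean()),
                bias_tau2=float(taus.mean() - stratum.tau2),
                mcse_tau2=float(taus.std(ddof=1) / math.sqrt(n)),
                ci_coverage=float(cis.mean()),
                pi_coverage=float(pis.mean()),
                coverage_mcse=float(
                    math.sqrt(max(pis.mean() * (1 - pis.mean()), 1e-12) / n)
                ),
            )
        )
    report = RecoveryReport(
        strata=tuple(recoveries),
        sdd_coefficient_mean=float(np.mean(sdd_coefs)) if sdd_coefs else None,
        sdd_coefficient_mcse=(
            float(np.std(sdd_coefs, ddof=1) / math.sqrt(len(sdd_coefs)))
            if len(sdd_coefs) > 1
            else None
        ),
    )
    return report


def config_to_yaml(config: SimulationConfig, destination: str | IO[str]) -> None:
    payload = {
        "seed": config.seed,
        "contextual_shift": config.contextual_shift,
        "censor_threshold_pct": config.censor_threshold_pct,
        "censor_drop_p": config.censor_drop_p,
        "strata": [
            {**dataclasses.asdict(s), "year_range": list(s.year_range)}
            for s in config.strata
        ],
    }
    if hasattr(destination, "write"):
        yaml.safe_dump(payload, destination, sort_keys=False)
    else:
        with open(destination, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(source: str | IO[str]) -> SimulationConfig:
    if hasattr(source, "read"):
        payload = yaml.safe_load(source)
    else:
        with open(source) as fh:
            payload = yaml.safe_load(fh)
    strata = tuple(
        StratumConfig(**{**s, "year_range": tuple(s["year_range"])})
        for s in payload["strata"]
    )
    return SimulationConfig(
        seed=int(payload["seed"]),
        strata=strata,
        contextual_shift=float(payload.get("contextual_shift", 0.0) or 0.0),
        censor_threshold_pct=payload.get("censor_threshold_pct"),
        censor_drop_p=float(payload.get("censor_drop_p", 0.0) or 0.0),
    )
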