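"""Seeded generator of a synthetic home-cage polysubstance cohort.

Emulates the five inputs the pipeline consumes: an animal roster (single-sex
cages of four), a six-station map (two water stations plus 5% / 10% ethanol
and 5 / 20 ug/ml fentanyl), the RFID read stream, the volumetric
drinking-monitor stream, and the 12-parameter open-field / elevated-zero-maze
behaviour table.  The generative model plants the structure the analyses
look for:

* a two-rate (light/dark) Poisson visit process per animal,
* station choice by softmax over per-(phenotype, sex, substance) weights,
  with the female fentanyl weight doubled (the planted sex x substance
  interaction) and an additive per-day drift on the log fentanyl weight
  (escalating preference),
* lognormal visit bout durations emitting RFID reads at a nominal rate and,
  with fixed probability, 1 Hz drink rows whose summed volume is gamma,
* three latent behavioural phenotypes drawn from a 3 x 12 multivariate
  normal mixture, serialized as ground truth.

Everything is driven by one integer seed; identical configs give
byte-identical fixture files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotype_clustering import BEHAVIOR_PARAMS

__all__ = [
    "SimConfig",
    "CohortFixture",
    "SUBSTANCE_CATEGORIES",
    "DEFAULT_STATIONS",
    "default_substance_weights",
    "default_phenotype_means",
    "default_phenotype_cov",
    "generate_cohort",
    "generate_behavior_table",
    "generate_drinking_streams",
    "simulate_cohort",
    "write_fixture_set",
]

#: substance/dose categories, keyed as "<substance>:<dose_label>"
SUBSTANCE_CATEGORIES = (
    "water:none",
    "ethanol:5%",
    "ethanol:10%",
    "fentanyl:5ug",
    "fentanyl:20ug",
)

#: default six-station layout: two water stations (one per long wall) plus
#: one station per drug/dose
DEFAULT_STATIONS = pd.DataFrame(
    {
        "station": ["S1", "S2", "S3", "S4", "S5", "S6"],
        "substance": ["water", "ethanol", "ethanol", "water", "fentanyl", "fentanyl"],
        "dose_label": ["none", "5%", "10%", "none", "5ug", "20ug"],
    }
)


def default_substance_weights(
    female_fentanyl_mult: float = 2.0, phenotype_tilt: bool = True
) -> dict:
    """Choice weights per (phenotype, sex, category).

    Baseline weights favour water and the low fentanyl dose; females carry
    ``female_fentanyl_mult`` on both fentanyl doses (the planted sex effect);
    the three phenotypes tilt toward, respectively, low-dose fentanyl,
    high-dose fentanyl, and water, echoing the qualitative cluster-specific
    consumption profiles the analysis is meant to resolve.

    ``phenotype_tilt=False`` makes weights identical across phenotypes,
    giving a subject-homogeneous cohort in which the mixed ANOVA's
    compound-symmetry assumption holds — the right regime for checking the
    test's null calibration.
    """
    base = {
        "water:none": 1.0,
        "ethanol:5%": 0.5,
        "ethanol:10%": 0.3,
        "fentanyl:5ug": 0.8,
        "fentanyl:20ug": 0.4,
    }
    pheno_mult = {
        0: {"fentanyl:5ug": 1.5},
        1: {"fentanyl:20ug": 2.5, "fentanyl:5ug": 1.5},
        2: {"water:none": 1.2},
    }
    if not phenotype_tilt:
        pheno_mult = {0: {}, 1: {}, 2: {}}
    weights = {}
    for ph in range(3):
        for sex in ("M", "F"):
            for cat in SUBSTANCE_CATEGORIES:
                w = base[cat] * pheno_mult[ph].get(cat, 1.0)
                if sex == "F" and cat.startswith("fentanyl"):
                    w *= female_fentanyl_mult
                weights[(ph, sex, cat)] = w
    return weights


def default_phenotype_means() -> np.ndarray:
    """3 x 12 matrix of behaviour-parameter means (rows = phenotypes).

    Row 0: anxiety-like (low centre/open-arm exploration, long latencies);
    row 1: exploratory/risk-taking; row 2: intermediate.  Column order is
    :data:`~sipflow.phenotype_clustering.BEHAVIOR_PARAMS`.  Units: distances
    m, speeds m/s, times and latencies s, entries counts.
    """
    return np.array(
        [
            # OFBdist OFBspd OFBCT OFBCE OFBCL OFBCD EZMdist EZMspd OAT  OAE  OAL  OAD
            [12.0, 0.040, 10.0, 4.0, 90.0, 1.5, 10.0, 0.035, 25.0, 3.0, 100.0, 1.0],
            [26.0, 0.090, 60.0, 22.0, 10.0, 8.0, 22.0, 0.075, 90.0, 15.0, 12.0, 6.0],
            [20.0, 0.065, 30.0, 12.0, 40.0, 4.0, 16.0, 0.055, 55.0, 8.0, 45.0, 3.0],
        ]
    )


def default_phenotype_cov() -> np.ndarray:
    """Diagonal 12 x 12 covariance; SDs chosen so the default phenotype
    means sit >= ~3 within-cluster SDs apart on most parameters."""
    sds = np.array(
        [2.0, 0.008, 8.0, 3.0, 12.0, 1.0, 2.0, 0.007, 12.0, 2.0, 15.0, 0.8]
    )
    return np.diag(sds**2)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 32 males + 24 females in
    single-sex cages of four, seven days of continuous access, lights on at
    06:00, nocturnal activity (dark-phase visit rate x3), doubled female
    fentanyl choice weight, and three latent behavioural phenotypes mixed
    roughly 20/10/70.
    """

    n_males: int = 32
    n_females: int = 24
    cage_size: int = 4
    n_days: int = 7
    lights_on_hour: float = 6.0
    base_visit_rate: float = 0.5  # visits/hour, light phase
    dark_rate_multiplier: float = 3.0
    substance_weights: dict | None = None  # (phenotype, sex, category) -> weight
    escalation_slope: float = 0.1  # per-day additive drift on log fentanyl weight
    drink_prob: float = 0.6
    bout_median_s: float = 10.0
    bout_sigma: float = 0.5  # lognormal sigma of bout duration
    rfid_hz: float = 100.0
    volume_shape: float = 2.0
    volume_scale: float = 100.0  # gamma scale, ul; mean bout volume 200 ul
    body_weight_mean: float = 25.0
    body_weight_sd: float = 2.0
    phenotype_means: np.ndarray = field(default_factory=default_phenotype_means)
    phenotype_cov: np.ndarray = field(default_factory=default_phenotype_cov)
    phenotype_mix: tuple = (0.2, 0.1, 0.7)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_males, self.n_females, self.cage_size, self.n_days) < 0:
            raise ValueError("counts must be nonnegative")
        if self.base_visit_rate < 0 or self.dark_rate_multiplier < 0:
            raise ValueError("rates must be nonnegative")
        mix = np.asarray(self.phenotype_mix, dtype=float)
        if abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
            raise ValueError("phenotype_mix must be nonnegative and sum to 1")
        means = np.asarray(self.phenotype_means, dtype=float)
        if means.shape != (len(mix), 12):
            raise ValueError(f"phenotype_means must be {len(mix)} x 12")
        cov = np.asarray(self.phenotype_cov, dtype=float)
        if cov.shape != (12, 12) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("phenotype_cov must be symmetric 12 x 12")
        if np.linalg.eigvalsh(cov).min() < -1e-8:
            raise ValueError("phenotype_cov must be positive semi-definite")

    def weights(self) -> dict:
        return (
            self.substance_weights
            if self.substance_weights is not None
            else default_substance_weights()
        )


@dataclass
class CohortFixture:
    """A complete simulated experiment plus its ground truth."""

    animals: pd.DataFrame
    stations: pd.DataFrame
    rfid: pd.DataFrame
    vdm: pd.DataFrame
    behavior: pd.DataFrame
    truth: dict  # {"phenotype": {tag: int}, "config": {...}}


def generate_cohort(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Roster of single-sex cages plus the default station map.

    Body weights are normal(mean, sd) truncated at zero by resampling.
    Raises if either sex count is not divisible by the cage size.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    for sex, n in (("male", cfg.n_males), ("female", cfg.n_females)):
        if n % cfg.cage_size:
            raise ValueError(
                f"{sex} count {n} not divisible by cage_size {cfg.cage_size}"
            )
    rows = []
    cage_idx = 0
    for sex_code, n in (("M", cfg.n_males), ("F", cfg.n_females)):
        for i in range(n):
            if i % cfg.cage_size == 0:
                cage_idx += 1
            w = rng.normal(cfg.body_weight_mean, cfg.body_weight_sd)
            while w <= 0:
                w = rng.normal(cfg.body_weight_mean, cfg.body_weight_sd)
            rows.append(
                {
                    "tag": f"{sex_code}{i + 1:03d}",
                    "sex": sex_code,
                    "body_weight_g": round(float(w), 2),
                    "cage": f"C{cage_idx:02d}",
                }
            )
    animals = pd.DataFrame(rows, columns=["tag", "sex", "body_weight_g", "cage"])
    return animals, DEFAULT_STATIONS.copy()


def generate_behavior_table(
    cfg: SimConfig, animals: pd.DataFrame, rng: np.random.Generator | None = None
):
    """Draw the 12-parameter behaviour table from the phenotype mixture.

    Each animal gets a latent phenotype (categorical on ``phenotype_mix``)
    and a 12-vector from N(mean_row, cov), clipped at zero since all twelve
    parameters (times, counts, distances, speeds, latencies) are nonnegative.
    Returns (behavior table, Series of true labels indexed by tag).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = len(animals)
    mix = np.asarray(cfg.phenotype_mix, dtype=float)
    labels = rng.choice(len(mix), size=n, p=mix)
    means = np.asarray(cfg.phenotype_means, dtype=float)
    vals = np.empty((n, 12))
    for i, lab in enumerate(labels):
        vals[i] = rng.multivariate_normal(
            means[lab], cfg.phenotype_cov, method="svd"
        )
    vals = np.clip(vals, 0.0, None)
    behavior = pd.DataFrame(vals, columns=list(BEHAVIOR_PARAMS))
    behavior.insert(0, "tag", animals["tag"].to_numpy())
    truth = pd.Series(labels, index=animals["tag"], name="phenotype")
    return behavior, truth


def _phase_is_dark(hour_of_day: np.ndarray) -> np.ndarray:
    return hour_of_day >= 12.0


def generate_drinking_streams(
    cfg: SimConfig,
    animals: pd.DataFrame,
    stations: pd.DataFrame,
    truth: pd.Series,
    rng: np.random.Generator | None = None,
):
    """Simulate the RFID and VDM streams for a cohort.

    Visit times follow a two-rate Poisson process (``base_visit_rate`` in the
    light phase, times ``dark_rate_multiplier`` in the dark).  Each visit
    picks a station by softmax over the animal's substance weights, with the
    log fentanyl weight drifted by ``escalation_slope * (day - 1)``; bout
    duration is lognormal (median ``bout_median_s``); reads are emitted at
    ``rfid_hz`` for the bout, and with probability ``drink_prob`` the visit
    also emits 1 Hz drink rows whose summed volume is
    gamma(``volume_shape``, ``volume_scale``).  All timestamps are clipped to
    [0, n_days * 24 h).  Returns (rfid, vdm) DataFrames sorted by time.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    horizon = cfg.n_days * 86400.0
    weights = cfg.weights()
    station_ids = stations["station"].to_numpy()
    station_cat = (
        stations["substance"].astype(str) + ":" + stations["dose_label"].astype(str)
    ).to_numpy()
    is_fent = np.array([c.startswith("fentanyl") for c in station_cat])
    mu = np.log(cfg.bout_median_s)
    read_dt = 1.0 / cfg.rfid_hz

    rfid_t, rfid_ant, rfid_tag = [], [], []
    vdm_t, vdm_st, vdm_vol = [], [], []

    for _, row in animals.iterrows():
        tag, sex = row["tag"], row["sex"]
        ph = int(truth[tag])
        base_w = np.array([weights[(ph, sex, c)] for c in station_cat])
        for day in range(cfg.n_days):
            w = base_w.copy()
            w[is_fent] *= np.exp(cfg.escalation_slope * day)
            probs = w / w.sum()
            for phase, rate in ((0, cfg.base_visit_rate),
                                (1, cfg.base_visit_rate * cfg.dark_rate_multiplier)):
                n_visits = rng.poisson(rate * 12.0)
                if n_visits == 0:
                    continue
                t0 = day * 86400.0 + phase * 43200.0
                starts = np.sort(t0 + rng.uniform(0.0, 43200.0, size=n_visits))
                for t_start in starts:
                    st_idx = rng.choice(len(station_ids), p=probs)
                    dur = rng.lognormal(mu, cfg.bout_sigma)
                    t_end = min(t_start + dur, horizon - read_dt)
                    if t_end <= t_start:
                        continue
                    times = np.arange(t_start, t_end + read_dt / 2, read_dt)
                    rfid_t.append(times)
                    rfid_ant.append(np.repeat(station_ids[st_idx], times.size))
                    rfid_tag.append(np.repeat(tag, times.size))
                    if rng.random() < cfg.drink_prob:
                        drink_dur = (t_end - t_start) * 0.7
                        n_rows = max(1, int(drink_dur))
                        dt = (
                            t_start
                            + 0.1
                            + np.arange(n_rows, dtype=float)
                        )
                        dt = dt[dt <= t_end]
                        if dt.size == 0:
                            dt = np.array([t_start + (t_end - t_start) / 2])
                        total = rng.gamma(cfg.volume_shape, cfg.volume_scale)
                        vdm_t.append(dt)
                        vdm_st.append(np.repeat(station_ids[st_idx], dt.size))
                        vdm_vol.append(np.full(dt.size, total / dt.size))

    def _stack(ts, cols):
        if not ts:
            return pd.DataFrame({name: pd.Series(dtype=dt)
                                 for name, dt, _ in cols})
        t = np.concatenate(ts)
        order = np.argsort(t, kind="stable")
        return pd.DataFrame(
            {name: np.concatenate(vals)[order] for name, _, vals in cols}
        )

    rfid = _stack(
        rfid_t,
        [("t_sec", float, rfid_t), ("antenna", str, rfid_ant), ("tag", str, rfid_tag)],
    )
    vdm = _stack(
        vdm_t,
        [("t_sec", float, vdm_t), ("station", str, vdm_st), ("volume_ul", float, vdm_vol)],
    )
    return rfid, vdm


def simulate_cohort(cfg: SimConfig) -> CohortFixture:
    """Run the full generator: roster, behaviour, streams, ground truth."""
    cfg.validate()
    animals, stations = generate_cohort(cfg)
    behavior, truth = generate_behavior_table(cfg, animals)
    rfid, vdm = generate_drinking_streams(cfg, animals, stations, truth)
    truth_doc = {
        "phenotype": {t: int(v) for t, v in truth.items()},
        "config": {
            "n_males": cfg.n_males,
            "n_females": cfg.n_females,
            "n_days": cfg.n_days,
            "seed": cfg.seed,
        },
    }
    return CohortFixture(
        animals=animals,
        stations=stations,
        rfid=rfid,
        vdm=vdm,
        behavior=behavior,
        truth=truth_doc,
    )


def write_fixture_set(fixture: CohortFixture, out_dir) -> dict:
    """Write the five CSVs plus truth.json; returns the path map.

    Files round-trip losslessly through the ``stream_io`` readers and are
    byte-identical across runs with the same config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "animals": out / "animals.csv",
        "stations": out / "stations.csv",
        "rfid": out / "rfid.csv",
        "vdm": out / "vdm.csv",
        "behavior": out / "behavior.csv",
        "truth": out / "truth.json",
    }
    fixture.animals.to_csv(paths["animals"], index=False)
    fixture.stations.to_csv(paths["stations"], index=False)
    # default float repr is shortest-round-trip, so readers recover the
    # exact in-memory values
    fixture.rfid.to_csv(paths["rfid"], index=False)
    fixture.vdm.to_csv(paths["vdm"], index=False)
    fixture.behavior.to_csv(paths["behavior"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(fixture.truth, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
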